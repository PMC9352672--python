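"""2D behaviour map: t-SNE training, KDE + watershed regions, post-embedding.

Training embeds the N x 746 feature matrix into 2D with t-SNE. A density
surface is built by placing a Gaussian kernel on every embedded point, its
peaks (separated by a minimum distance) seed a watershed of the inverted
density, and each watershed region — a recurring syllable type — is given a
letter label.

New syllables are classified without re-running t-SNE by *post-embedding*:
the query's conditional neighbour distribution p over its `perplexity`
nearest training points (Gaussian kernel on a Kullback-Leibler divergence
between the unit-sum feature vectors, with the kernel width found by binary
search so that 2^H(p) equals the perplexity) is matched against the
Student-t conditional q in 2D by minimising KL(p || q) with Nelder-Mead,
started from the centroid of the neighbours' embeddings. Queries unlike any
training point have no finite minimum — the optimizer shoots off to
infinity — and are reported as diverged / unclassified.
"""

from __future__ import annotations

import json
import string
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize
from scipy.special import logsumexp
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EmbeddingModel",
    "BehaviourMap",
    "Classification",
    "UNCLASSIFIED",
    "train_embedding",
    "build_behaviour_map",
    "post_embed",
    "classify",
    "classify_batch",
    "feature_kl_divergence",
    "conditional_p",
    "conditional_q",
    "kl_objective",
    "save_model",
    "load_model",
]

UNCLASSIFIED = "UNCLASSIFIED"

_EPS = 1e-300  # floor for zero bins inside logs; 0*log0 := 0 is handled separately


@dataclass
class EmbeddingModel:
    """Trained t-SNE embedding plus a ball-tree index over the features."""

    training_features: np.ndarray  # (N, d), rows are unit-sum profile pairs
    training_embedding: np.ndarray  # (N, 2)
    perplexity: float
    seed: int
    _nn: NearestNeighbors | None = field(default=None, repr=False, compare=False)

    @property
    def n(self) -> int:
        return self.training_features.shape[0]

    @property
    def neighbor_index(self) -> NearestNeighbors:
        if self._nn is None:
            self._nn = NearestNeighbors(algorithm="ball_tree").fit(
                self.training_features)
        return self._nn

    @property
    def bbox_diagonal(self) -> float:
        span = self.training_embedding.max(0) - self.training_embedding.min(0)
        return float(np.hypot(*span))


@dataclass
class BehaviourMap:
    """Density surface, watershed regions and labelled peaks over an embedding."""

    density: np.ndarray          # (grid, grid); axis 0 = x, axis 1 = y
    regions: np.ndarray          # int labels, same shape, 1..K everywhere
    peaks: dict[str, np.ndarray]  # letter -> (2,) embedding coordinates
    label_names: dict[int, str]  # watershed region id -> letter
    origin: np.ndarray           # (2,) embedding coords of cell (0, 0) corner
    cell_size: np.ndarray        # (2,) embedding units per cell
    kernel_bandwidth: float
    min_peak_distance: float

    @property
    def n_regions(self) -> int:
        return len(self.peaks)

    def _cell(self, point: np.ndarray) -> tuple[int, int] | None:
        ij = np.floor((np.asarray(point) - self.origin) / self.cell_size).astype(int)
        if np.any(ij < 0) or np.any(ij >= self.regions.shape):
            return None
        return int(ij[0]), int(ij[1])

    def region_at(self, point: np.ndarray) -> str | None:
        """Letter label of the region containing ``point``, None if off-grid."""
        cell = self._cell(point)
        if cell is None:
            return None
        return self.label_names.get(int(self.regions[cell]))


@dataclass(frozen=True)
class Classification:
    point: np.ndarray | None
    label: str
    certainty: float  # distance from region peak; smaller = more certain
    latency: float = 0.0


def train_embedding(features: np.ndarray, perplexity: float = 30,
                    seed: int = 0) -> EmbeddingModel:
    """Embed the feature matrix into 2D with t-SNE (deterministic given seed)."""
    features = np.asarray(features, dtype=np.float64)
    n = features.shape[0]
    if n < 3 * perplexity:
        raise ValueError(f"need at least 3*perplexity={3 * perplexity:g} points, got {n}")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed)
    emb = tsne.fit_transform(features).astype(np.float64)
    return EmbeddingModel(features, emb, float(perplexity), int(seed))


def _letters() -> list[str]:
    single = list(string.ascii_uppercase)
    return single + [a + b for a in single for b in single]


def build_behaviour_map(model: EmbeddingModel,
                        kernel_bandwidth: float | str = 15.0,
                        min_peak_distance: float | str = 15.0,
                        grid_size: int = 1000) -> BehaviourMap:
    """Gaussian-KDE density, peak detection and watershed segmentation.

    The density is a 2D histogram of the embedded points smoothed by a
    Gaussian of ``kernel_bandwidth`` (embedding units) over a grid covering
    the bounding box padded by twice the bandwidth. Peaks closer than
    ``min_peak_distance`` are merged; the watershed of the inverted density,
    seeded at the peaks, assigns every grid cell to a region. Regions are
    lettered A, B, ... in order of decreasing peak density.

    The numeric defaults (15 embedding units each) correspond to a
    production-scale training set of tens of thousands of points. Because
    t-SNE layouts grow with the number of points, both parameters accept
    ``"auto"``: bandwidth = 4% of the embedding bounding-box diagonal and
    peak distance = twice the bandwidth, which reproduces ~15 at production
    scale and scales down consistently for smaller maps.
    """
    emb = model.training_embedding
    if kernel_bandwidth == "auto":
        kernel_bandwidth = 0.04 * model.bbox_diagonal
    if min_peak_distance == "auto":
        min_peak_distance = 2.0 * kernel_bandwidth
    lo = emb.min(0) - 2 * kernel_bandwidth
    hi = emb.max(0) + 2 * kernel_bandwidth
    cell = (hi - lo) / grid_size
    hist, _, _ = np.histogram2d(emb[:, 0], emb[:, 1], bins=grid_size,
                                range=[[lo[0], hi[0]], [lo[1], hi[1]]])
    density = gaussian_filter(hist, sigma=kernel_bandwidth / cell, mode="constant")
    density /= density.sum()

    min_dist_cells = max(1, int(np.ceil(min_peak_distance / cell.mean())))
    peaks_ij = peak_local_max(density, min_distance=min_dist_cells,
                              threshold_rel=1e-4, exclude_border=False)
    if peaks_ij.shape[0] < 1:
        raise ValueError("no density peaks found; cannot build a behaviour map")

    order = np.argsort(-density[peaks_ij[:, 0], peaks_ij[:, 1]])
    peaks_ij = peaks_ij[order]
    markers = np.zeros_like(density, dtype=np.int32)
    for k, (i, j) in enumerate(peaks_ij, start=1):
        markers[i, j] = k
    regions = watershed(-density, markers)

    letters = _letters()
    label_names = {k: letters[k - 1] for k in range(1, peaks_ij.shape[0] + 1)}
    peak_coords = {
        letters[k]: lo + (peaks_ij[k] + 0.5) * cell
        for k in range(peaks_ij.shape[0])
    }
    return BehaviourMap(density, regions, peak_coords, label_names,
                        origin=lo, cell_size=cell,
                        kernel_bandwidth=kernel_bandwidth,
                        min_peak_distance=min_peak_distance)


def feature_kl_divergence(z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """KL(z || x_j) per neighbour row, on unit-sum renormalized vectors.

    Zero query bins contribute nothing (0*log 0 := 0); zero neighbour bins
    under query mass are floored to keep the divergence finite but very large.
    """
    z = np.asarray(z, dtype=np.float64)
    if np.any(~np.isfinite(z)):
        raise ValueError("query features contain NaN/inf")
    z = z / z.sum()
    Xn = X / X.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = z[None, :] * (np.log(np.maximum(z[None, :], _EPS))
                              - np.log(np.maximum(Xn, _EPS)))
    terms[:, z == 0] = 0.0
    return terms.sum(axis=1)


def conditional_p(distances: np.ndarray, perplexity: float,
                  literal_affinity: bool = False,
                  tol: float = 1e-6) -> tuple[np.ndarray, float]:
    """Conditional distribution over neighbours with perplexity calibration.

    ``p_j ∝ exp(-D_j² / 2σ²)`` with σ found by binary search so that the
    Shannon perplexity 2^H(p) matches ``perplexity`` (within ``tol`` of its
    log2). ``literal_affinity=True`` instead uses the unnormalized affinity
    ``p_j ∝ D_j²`` verbatim; note σ then cancels and no calibration exists.
    Returns (p, sigma).
    """
    D2 = np.asarray(distances, dtype=np.float64) ** 2
    if literal_affinity:
        p = D2 / D2.sum()
        return p, np.nan

    target = np.log2(perplexity)
    scale = max(float(D2.max()), 1e-30)  # work in units of the largest D²

    def entropy_bits(beta: float) -> tuple[np.ndarray, float]:
        logp = -(D2 / scale) * beta
        logp = logp - logsumexp(logp)
        p = np.exp(logp)
        h = -np.sum(p * logp) / np.log(2)
        return p, h

    # entropy decreases monotonically in beta; grow beta_hi until it crosses
    # the target. If all distances are (near-)tied the entropy has a floor
    # above the target and no calibration exists — the capped near-uniform
    # p is returned as-is (its perplexity is then simply the neighbour count).
    beta_lo, beta_hi = 0.0, 1.0
    p, h = entropy_bits(beta_hi)
    for _ in range(100):
        if h < target or beta_hi > 1e15:
            break
        beta_lo = beta_hi
        beta_hi *= 2.0
        p, h = entropy_bits(beta_hi)
    beta = beta_hi
    if h < target:
        for _ in range(200):
            beta = 0.5 * (beta_lo + beta_hi)
            p, h = entropy_bits(beta)
            if abs(h - target) < tol:
                break
            if h > target:
                beta_lo = beta
            else:
                beta_hi = beta
    sigma = np.sqrt(scale / (2.0 * beta)) if beta > 0 else np.inf
    return p, float(sigma)


def conditional_q(y: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Student-t (1 dof) conditional distribution of neighbours given 2D point y."""
    d2 = np.sum((Y - y) ** 2, axis=1)
    w = 1.0 / (1.0 + d2)
    return w / w.sum()


def kl_objective(y: np.ndarray, Y: np.ndarray, p: np.ndarray) -> float:
    """KL(p || q(y)) — the post-embedding objective."""
    q = conditional_q(y, Y)
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(np.maximum(q[mask], _EPS)))))


def _median_nn_spacing(Y: np.ndarray) -> float:
    """Median nearest-neighbour distance within a 2D point set."""
    d2 = ((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    return float(np.median(np.sqrt(d2.min(axis=1))))


def post_embed(z: np.ndarray, model: EmbeddingModel,
               divergence_radius: float | None = None,
               literal_affinity: bool = False,
               neighbor_multiple: float = 3.0) -> np.ndarray | None:
    """Place a new feature vector into the trained 2D embedding.

    Returns the optimal 2D location, or None (diverged) when the Nelder-Mead
    solution lands further than ``divergence_radius`` (default 5x the
    embedding bounding-box diagonal) from the embedding centroid — the
    signature of a query unlike any training point.

    ``neighbor_multiple`` sets the neighbour count as a multiple of the
    perplexity. With exactly ``perplexity`` neighbours the calibration is
    degenerate: the maximum entropy of k outcomes is log2 k, so matching
    perplexity k forces p to be uniform, and KL(uniform || q) is globally
    minimized by sending the embedding to infinity (where q is exactly
    uniform). Three times the perplexity — the conventional t-SNE ratio —
    keeps p informative and the minimum finite for in-distribution queries.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    k = min(int(round(model.perplexity * neighbor_multiple)), model.n)
    idx = model.neighbor_index.kneighbors(z[None, :], n_neighbors=k,
                                          return_distance=False)[0]
    D = feature_kl_divergence(z, model.training_features[idx])
    p, _ = conditional_p(D, model.perplexity, literal_affinity=literal_affinity)
    Y = model.training_embedding[idx]
    # The objective can be multimodal when p spreads over neighbours from
    # distinct 2D basins; a handful of informed starts (plain centroid per
    # the original scheme, p-weighted centroid, heaviest neighbour) with one
    # fresh-simplex restart each reliably reaches the global minimum.
    starts = [Y.mean(axis=0), p @ Y, Y[int(np.argmax(p))]]
    res = None
    for y0 in starts:
        r = minimize(kl_objective, y0, args=(Y, p), method="Nelder-Mead",
                     options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 500})
        r = minimize(kl_objective, r.x, args=(Y, p), method="Nelder-Mead",
                     options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 500})
        if res is None or r.fun < res.fun:
            res = r
    y = res.x
    radius = divergence_radius if divergence_radius is not None \
        else 5.0 * model.bbox_diagonal
    center = model.training_embedding.mean(axis=0)
    if not np.all(np.isfinite(y)) or np.linalg.norm(y - center) > radius:
        return None
    # As ||y|| grows, q tends to the uniform distribution and the objective
    # to log(k) - H(p): the objective's value "at infinity". A solution that
    # does not beat that limit has no finite preference — unless it sits
    # right among its neighbours' embeddings, which happens when the
    # neighbours form one tight clump (any point in the clump ties with
    # infinity). The spatial check separates the two: a stall far from
    # every neighbour is the flat plateau that leads to infinity.
    mask = p > 0
    f_inf = np.log(len(p)) + float(np.sum(p[mask] * np.log(p[mask])))
    if res.fun >= f_inf - 1e-6 * max(1.0, abs(f_inf)):
        d_near = float(np.min(np.linalg.norm(Y - y, axis=1)))
        spacing = _median_nn_spacing(Y)
        # measured regimes sit decades apart: stalls inside the neighbour
        # clump land within a few spacings; run-offs and between-cluster
        # stalls land tens to many orders of magnitude further out
        if d_near > 20.0 * spacing:
            return None
    return y


def classify(z: np.ndarray, model: EmbeddingModel, bmap: BehaviourMap,
             **post_kwargs) -> Classification:
    """Post-embed a feature vector and label it by its watershed region.

    Certainty is the Euclidean distance (embedding units) from the region's
    density peak: points far from the peak are more likely mis-classified.
    """
    import time
    t0 = time.perf_counter()
    y = post_embed(z, model, **post_kwargs)
    if y is None:
        return Classification(None, UNCLASSIFIED, np.inf,
                              time.perf_counter() - t0)
    label = bmap.region_at(y)
    if label is None:
        return Classification(y, UNCLASSIFIED, np.inf, time.perf_counter() - t0)
    certainty = float(np.linalg.norm(y - bmap.peaks[label]))
    return Classification(y, label, certainty, time.perf_counter() - t0)


def classify_batch(features: np.ndarray, model: EmbeddingModel,
                   bmap: BehaviourMap, workers: int = 1,
                   **post_kwargs) -> list[Classification]:
    """Classify many feature vectors; results are order-independent of workers."""
    rows = list(np.asarray(features))
    if workers <= 1:
        return [classify(z, model, bmap, **post_kwargs) for z in rows]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(lambda z: classify(z, model, bmap, **post_kwargs), rows))


def save_model(path, model: EmbeddingModel, bmap: BehaviourMap | None = None) -> None:
    """Persist model (and optional map) as an .npz archive + JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {
        "training_features": model.training_features,
        "training_embedding": model.training_embedding,
    }
    manifest: dict = {"perplexity": model.perplexity, "seed": model.seed}
    if bmap is not None:
        arrays.update(density=bmap.density, regions=bmap.regions,
                      origin=bmap.origin, cell_size=bmap.cell_size)
        manifest["map"] = {
            "kernel_bandwidth": bmap.kernel_bandwidth,
            "min_peak_distance": bmap.min_peak_distance,
            "label_names": {str(k): v for k, v in bmap.label_names.items()},
            "peaks": {k: list(map(float, v)) for k, v in bmap.peaks.items()},
        }
    np.savez_compressed(path / "model.npz", **arrays)
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(path) -> tuple[EmbeddingModel, BehaviourMap | None]:
    path = Path(path)
    arrays = np.load(path / "model.npz")
    manifest = json.loads((path / "manifest.json").read_text())
    model = EmbeddingModel(arrays["training_features"],
                           arrays["training_embedding"],
                           manifest["perplexity"], manifest["seed"])
    bmap = None
    if "map" in manifest:
        m = manifest["map"]
        bmap = BehaviourMap(
            arrays["density"], arrays["regions"],
            {k: np.asarray(v) for k, v in m["peaks"].items()},
            {int(k): v for k, v in m["label_names"].items()},
            arrays["origin"], arrays["cell_size"],
            m["kernel_bandwidth"], m["min_peak_distance"])
    return model, bmap
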