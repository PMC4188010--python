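"""Texton dictionary construction and histogram features.

A texton is a prototype 8-vector of filter-bank responses.  The dictionary
is built in two stages: per-image variational-Bayes Gaussian mixtures find
the recurring response motifs of each training image (the number of
components is selected by the data), and DP-means clustering of the pooled
per-image centres removes the inter-image redundancy while keeping rare but
genuine textures as their own entries.  Precipitation-texture images and
crystal-containing images contribute separate sub-dictionaries that are
concatenated.

New images are described by the frequency histogram of nearest-texton
labels (Euclidean distance) over their in-mask pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist
from sklearn.mixture import BayesianGaussianMixture

__all__ = [
    "TextonDictionary",
    "TextonMap",
    "TextonHistogram",
    "cluster_image_textons",
    "dp_means",
    "dp_means_objective",
    "build_dictionary",
    "label_pixels",
    "texton_histogram",
    "chi2_distance",
    "ward_cluster",
]

DEFAULT_DICT_SIZE = 300
DEFAULT_LAMBDA = 0.5
VBGMM_MAX_COMPONENTS = 25
VBGMM_WEIGHT_THRESHOLD = 1e-3


@dataclass
class TextonDictionary:
    """Ordered texton prototypes.

    ``entries`` is K x 8; ``source`` tags each entry as coming from the
    precipitate or the crystal sub-dictionary.  Entry 0 is the texton of
    lowest magnitude and the rest are sorted by increasing Euclidean
    distance to entry 0.
    """

    entries: np.ndarray
    source: np.ndarray  # array of 'precipitate' / 'crystal'

    def __len__(self) -> int:
        return self.entries.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.entries, columns=[f"c{j}" for j in range(self.entries.shape[1])]
        )
        df["source"] = self.source
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TextonDictionary":
        df = pd.read_csv(path)
        src = df.pop("source").to_numpy()
        return cls(df.to_numpy(dtype=float), src)


@dataclass
class TextonMap:
    """Per-pixel dictionary indices; -1 marks masked/excluded pixels."""

    labels: np.ndarray  # H x W int


@dataclass
class TextonHistogram:
    counts: np.ndarray  # length K
    n_pixels: int


def cluster_image_textons(
    responses: np.ndarray,
    max_components: int = VBGMM_MAX_COMPONENTS,
    weight_threshold: float = VBGMM_WEIGHT_THRESHOLD,
    seed: int = 0,
    return_labels: bool = False,
):
    """Cluster one image's pixel response vectors with a VB Gaussian mixture.

    A Dirichlet-process mixture with a generous component cap lets the data
    choose the effective number of components; components whose posterior
    weight falls below ``weight_threshold`` are pruned.  Returns the retained
    component means (and, optionally, per-point component labels re-indexed
    to the retained means, -1 for points of pruned components).
    """
    X = np.asarray(responses, dtype=float)
    if X.ndim != 2:
        raise ValueError("responses must be an N x D matrix")
    if np.unique(X, axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct response vectors")
    n_components = min(max_components, X.shape[0])
    gmm = BayesianGaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        weight_concentration_prior_type="dirichlet_process",
        max_iter=500,
        tol=1e-2,
        random_state=seed,
        reg_covar=1e-6,
    )
    raw_labels = gmm.fit_predict(X)
    # a pruned component may still be argmax for a few points; keep only
    # components that both exceed the weight threshold and own >=1 point
    owned = np.bincount(raw_labels, minlength=n_components) > 0
    keep = np.flatnonzero((gmm.weights_ >= weight_threshold) & owned)
    if keep.size == 0:
        keep = np.array([int(np.argmax(gmm.weights_))])
    centres = gmm.means_[keep]
    if not return_labels:
        return centres
    remap = -np.ones(n_components, dtype=int)
    remap[keep] = np.arange(keep.size)
    return centres, remap[raw_labels]


def dp_means_objective(
    X: np.ndarray, centres: np.ndarray, assignments: np.ndarray, lam: float
) -> float:
    """Sum of squared point-to-centre distances plus lambda^2 per cluster."""
    d2 = ((X - centres[assignments]) ** 2).sum()
    return float(d2 + lam ** 2 * centres.shape[0])


def _sweep(X, lam, z, order, max_iter):
    """Assignment sweeps with the lambda rule until assignments stabilize."""
    keep = np.unique(z)  # compact labels so every cluster id is populated
    remap = -np.ones(z.max() + 1, dtype=int)
    remap[keep] = np.arange(keep.size)
    z = remap[z]
    for _ in range(max_iter):
        changed = False
        n_clusters = z.max() + 1
        centres = np.vstack([X[z == k].mean(axis=0) for k in range(n_clusters)])
        for i in order:
            d2 = ((centres - X[i]) ** 2).sum(axis=1)
            j = int(np.argmin(d2))
            if d2[j] > lam ** 2:
                centres = np.vstack([centres, X[i]])
                j = centres.shape[0] - 1
            if z[i] != j:
                z[i] = j
                changed = True
        # drop clusters that lost all their points
        keep = np.unique(z)
        remap = -np.ones(z.max() + 1, dtype=int)
        remap[keep] = np.arange(keep.size)
        z = remap[z]
        if not changed:
            break
    return z


def _refine(X, lam, z):
    """Objective-driven merge and single-point-split moves.

    The greedy lambda rule never merges clusters whose separation lies in
    (lam, lam*sqrt(2)) even though merging lowers the objective there, and
    it can strand a far point inside a cluster; applying the cheapest
    improving merge/split until none remains fixes both local traps.
    Returns the refined assignments (may be unchanged).
    """
    z = z.copy()
    lam2 = lam ** 2
    # relocation scans are quadratic-ish; keep them for modest inputs where
    # exactness matters and bound the total number of moves
    allow_moves = z.size <= 512
    for _ in range(8 * z.size):
        k = z.max() + 1
        centres = np.vstack([X[z == c].mean(axis=0) for c in range(k)])
        sizes = np.bincount(z, minlength=k).astype(float)
        best_delta, best_move = -1e-12, None
        if k > 1:
            d2 = cdist(centres, centres, metric="sqeuclidean")
            w = sizes[:, None] * sizes[None, :] / (sizes[:, None] + sizes[None, :])
            gain = lam2 - w * d2  # objective drop when merging a with b
            np.fill_diagonal(gain, -np.inf)
            a, b = np.unravel_index(np.argmax(gain), gain.shape)
            if gain[a, b] > best_delta:
                best_delta, best_move = gain[a, b], ("merge", a, b)
        big = sizes[z] >= 2
        if big.any():
            r2 = ((X - centres[z]) ** 2).sum(axis=1)
            denom = np.where(big, sizes[z] - 1, 1.0)
            gain = sizes[z] / denom * r2 - lam2  # drop when splitting i
            gain[~big] = -np.inf
            i = int(np.argmax(gain))
            if gain[i] > best_delta:
                best_delta, best_move = gain[i], ("split", i, None)
        if k > 1 and allow_moves:
            # size-corrected relocation of one point to another cluster
            # (the plain nearest-centre sweep ignores the mean shift a
            # move induces, which matters for small clusters)
            d2all = cdist(X, centres, metric="sqeuclidean")
            r2 = d2all[np.arange(len(z)), z]
            denom = np.where(sizes[z] >= 2, sizes[z] - 1, np.inf)
            leave = sizes[z] / denom * r2  # cost removed from the old cluster
            enter = sizes[None, :] / (sizes[None, :] + 1.0) * d2all
            enter[np.arange(len(z)), z] = np.inf
            gain = leave[:, None] - enter
            i, c = np.unravel_index(np.argmax(gain), gain.shape)
            if gain[i, c] > best_delta:
                best_delta, best_move = gain[i, c], ("move", i, c)
        if best_move is None:
            return z
        kind, a, b = best_move
        if kind == "merge":
            z[z == b] = a
        elif kind == "move":
            z[a] = b
        else:
            z[a] = z.max() + 1
        keep = np.unique(z)
        remap = -np.ones(z.max() + 1, dtype=int)
        remap[keep] = np.arange(keep.size)
        z = remap[z]
    return z


def _farthest_first_init(X: np.ndarray, k: int, start: int) -> np.ndarray:
    """Assignments to k farthest-first seed points."""
    seeds = [start]
    d2 = ((X - X[start]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        seeds.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return np.argmin(cdist(X, X[seeds], metric="sqeuclidean"), axis=1)


def _dp_means_once(X: np.ndarray, lam: float, z0: np.ndarray, order: np.ndarray,
                   max_iter: int):
    def solution(z):
        centres = np.vstack([X[z == k].mean(axis=0) for k in range(z.max() + 1)])
        return dp_means_objective(X, centres, z, lam), centres, z

    z = _sweep(X, lam, z0, order, max_iter)
    best = solution(z)
    # alternate refinement and re-sweeping; keep the best state visited in
    # case the lambda rule and the merge moves disagree and oscillate
    for _ in range(max_iter):
        z_ref = _refine(X, lam, z)
        cand = solution(z_ref)
        if cand[0] < best[0] - 1e-12:
            best = cand
        z_new = _sweep(X, lam, z_ref, order, max_iter)
        cand = solution(z_new)
        if cand[0] < best[0] - 1e-12:
            best = cand
        if np.array_equal(z_new, z):
            break
        z = z_new
    return best


def dp_means(
    X: np.ndarray,
    lam: float,
    max_iter: int = 100,
    n_restarts: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """DP-means clustering: a point farther than ``lam`` from every centre
    spawns a new cluster, at a penalty of lam^2 per cluster in the objective.

    The assignment sweep is order and initialization dependent, so the
    algorithm is restarted from the canonical single-cluster state plus
    farthest-first partitions at several cluster counts (small inputs only)
    and from seeded sweep orders; the solution with the lowest objective is
    returned as (centres, assignments).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n == 0:
        raise ValueError("dp_means requires at least one point")
    if not lam > 0:
        raise ValueError("lambda must be positive")
    if n_restarts is None:
        n_restarts = 8 if n <= 64 else 1
    rng = np.random.default_rng(seed)

    inits: list[tuple[np.ndarray, np.ndarray]] = [
        (np.zeros(n, dtype=int), np.arange(n))
    ]
    if n <= 64:
        for k in range(2, min(n, 8) + 1):
            inits.append((_farthest_first_init(X, k, 0), np.arange(n)))
            inits.append(
                (_farthest_first_init(X, k, int(rng.integers(n))), rng.permutation(n))
            )
        for _ in range(n_restarts):
            k = int(rng.integers(1, min(n, 8) + 1))
            inits.append((rng.integers(0, k, n), rng.permutation(n)))
    for _ in range(max(0, n_restarts - 1)):
        inits.append((np.zeros(n, dtype=int), rng.permutation(n)))

    best = None
    for z0, order in inits:
        cand = _dp_means_once(X, lam, z0, order, max_iter)
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand
    return best[1], best[2]


def _order_dictionary(entries: np.ndarray, source: np.ndarray):
    norms = np.linalg.norm(entries, axis=1)
    anchor = int(np.argmin(norms))
    d = np.linalg.norm(entries - entries[anchor], axis=1)
    order = np.argsort(d, kind="stable")
    return entries[order], source[order]


def _merge_closest(entries: np.ndarray, source: np.ndarray, target: int):
    # reduce to exactly `target` entries by repeatedly averaging the
    # closest pair (single-step Ward-like merges)
    entries = entries.copy()
    source = list(source)
    while entries.shape[0] > target:
        d = cdist(entries, entries)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        i, j = min(i, j), max(i, j)
        entries[i] = (entries[i] + entries[j]) / 2.0
        entries = np.delete(entries, j, axis=0)
        # crystal provenance wins on a mixed merge so crystal textons are
        # never silently relabelled
        if source[j] == "crystal":
            source[i] = "crystal"
        del source[j]
    return entries, np.asarray(source)


def build_dictionary(
    precipitate_responses: list[np.ndarray],
    crystal_responses: list[np.ndarray],
    crystal_in_mask: list[np.ndarray],
    lam: float = DEFAULT_LAMBDA,
    target_size: int | None = None,
    seed: int = 0,
) -> TextonDictionary:
    """Two-stage texton dictionary construction.

    Each element of ``precipitate_responses``/``crystal_responses`` is the
    N x 8 matrix of filter responses of one training image's droplet pixels;
    ``crystal_in_mask`` gives, per crystal image, a boolean vector marking
    which of its pixels lie inside the ground-truth crystal regions.  A
    per-image VB-GMM yields candidate centres; a centre of a crystal image
    is treated as crystal related when at least half of its supporting
    pixels fall inside the crystal mask.  Pooled precipitate centres and
    pooled crystal centres are each reduced by DP-means and concatenated.

    With ``target_size`` set, lambda is calibrated by bisection so the final
    dictionary has exactly that many entries (closest-pair merging resolves
    the rare case where no lambda yields the exact count).
    """
    if len(precipitate_responses) == 0 or len(crystal_responses) == 0:
        raise ValueError("need at least one image in each training set")
    ss = np.random.SeedSequence(seed)
    precip_seeds = ss.spawn(len(precipitate_responses))
    crystal_seeds = ss.spawn(len(crystal_responses))

    precip_centres = []
    for resp, s in zip(precipitate_responses, precip_seeds):
        precip_centres.append(
            cluster_image_textons(resp, seed=int(s.generate_state(1)[0] % 2**31))
        )
    precip_centres = np.vstack(precip_centres)

    crystal_centres = []
    for resp, in_mask, s in zip(crystal_responses, crystal_in_mask, crystal_seeds):
        centres, labels = cluster_image_textons(
            resp, seed=int(s.generate_state(1)[0] % 2**31), return_labels=True
        )
        in_mask = np.asarray(in_mask, dtype=bool)
        for k in range(centres.shape[0]):
            pts = labels == k
            if pts.sum() and in_mask[pts].mean() >= 0.5:
                crystal_centres.append(centres[k])
    if crystal_centres:
        crystal_centres = np.vstack(crystal_centres)
    else:
        import warnings

        warnings.warn(
            "no crystal-related cluster centres found; "
            "building a precipitate-only dictionary",
            stacklevel=2,
        )
        crystal_centres = np.empty((0, precip_centres.shape[1]))

    def reduce_at(l: float):
        cp, _ = dp_means(precip_centres, l, seed=seed)
        if crystal_centres.shape[0]:
            cc, _ = dp_means(crystal_centres, l, seed=seed)
        else:
            cc = crystal_centres
        return cp, cc

    if target_size is None:
        cp, cc = reduce_at(lam)
    else:
        max_available = (
            np.unique(precip_centres, axis=0).shape[0]
            + (np.unique(crystal_centres, axis=0).shape[0]
               if crystal_centres.shape[0] else 0)
        )
        if max_available < target_size:
            raise ValueError(
                f"cannot reach {target_size} entries from "
                f"{max_available} distinct candidate centres"
            )
        lo, hi = 1e-4, 8.0  # K(lo) ~ all centres, K(hi) ~ few
        best = None  # smallest K >= target
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            cp, cc = reduce_at(mid)
            k = cp.shape[0] + cc.shape[0]
            if k == target_size:
                best = (k, cp, cc)
                break
            if k > target_size:
                if best is None or k < best[0]:
                    best = (k, cp, cc)
                lo = mid
            else:
                hi = mid
        k, cp, cc = best
        if k > target_size:
            # no lambda gives the exact count; merge surplus entries,
            # trimming the larger sub-dictionary first
            surplus = k - target_size
            trim_p = min(surplus, max(0, cp.shape[0] - 1))
            if trim_p:
                cp, _ = _merge_closest(
                    cp, np.array(["precipitate"] * cp.shape[0]), cp.shape[0] - trim_p
                )
            surplus -= trim_p
            if surplus:
                cc, _ = _merge_closest(
                    cc, np.array(["crystal"] * cc.shape[0]), cc.shape[0] - surplus
                )

    entries = np.vstack([cp, cc]) if cc.shape[0] else cp
    source = np.array(["precipitate"] * cp.shape[0] + ["crystal"] * cc.shape[0])
    entries, source = _order_dictionary(entries, source)
    return TextonDictionary(entries, source)


def label_pixels(
    responses, dictionary: TextonDictionary, mask: np.ndarray | None = None
) -> TextonMap:
    """Label every in-mask valid pixel with its nearest texton.

    ``responses`` is a :class:`~droptex.filterbank.ResponseImage`; distance
    is Euclidean, ties broken towards the lowest dictionary index (argmin
    behaviour).  Pixels outside the mask or inside the filter border are
    labelled -1.
    """
    if len(dictionary) == 0:
        raise ValueError("empty dictionary")
    resp = responses.responses
    use = responses.valid.copy()
    if mask is not None:
        use &= np.asarray(mask, dtype=bool)
    labels = -np.ones(resp.shape[:2], dtype=int)
    pts = resp[use]
    if pts.shape[0]:
        d = cdist(pts, dictionary.entries, metric="sqeuclidean")
        labels[use] = np.argmin(d, axis=1)
    return TextonMap(labels)


def texton_histogram(tmap: TextonMap, dict_size: int) -> TextonHistogram:
    lab = tmap.labels[tmap.labels >= 0]
    if lab.size and lab.max() >= dict_size:
        raise ValueError("label exceeds dictionary size")
    counts = np.bincount(lab, minlength=dict_size)
    return TextonHistogram(counts, int(lab.size))


def _as_prob(h) -> np.ndarray:
    v = np.asarray(h.counts if isinstance(h, TextonHistogram) else h, dtype=float)
    s = v.sum()
    return v / s if s > 0 else v


def chi2_distance(x, y) -> float:
    """Symmetric chi-squared distance between unit-normalized histograms:
    d = 1/2 * sum (x_i - y_i)^2 / (x_i + y_i), empty bins contributing 0."""
    p, q = _as_prob(x), _as_prob(y)
    if p.shape != q.shape:
        raise ValueError("histograms must have equal length")
    denom = p + q
    num = (p - q) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return float(0.5 * terms.sum())


def ward_cluster(histograms: list, n_clusters: int) -> np.ndarray:
    """Agglomerative (Ward) clustering of droplet histograms under the
    chi-squared distance; returns 0-based cluster labels."""
    n = len(histograms)
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters must be in [1, n]")
    P = np.vstack([_as_prob(h) for h in histograms])
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(chi2_distance(P[i], P[j]))
    Z = hierarchy.linkage(np.asarray(condensed), method="ward")
    return hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust") - 1
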