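"""Subtype separation: k-means on PARAFAC sample signatures, cluster means.

Each detected IED contributes one row of the sample-signature matrix; events
generated by the same cortical source load the same atoms and cluster
together.  The cluster count is chosen by the mean silhouette score over a
candidate range, and the per-cluster mean epoch (the subtype's
representative time course, "mean value X") feeds the source localization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ..errors import AssignmentError_, ConfigError
from ..ieddetect.epochs import IEDTensor
from .parafac import ParafacResults

__all__ = ["ClusterAssignment", "MeanIED", "cluster_samples", "cluster_means", "merge_small_clusters"]


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    silhouette: float
    centroids: np.ndarray
    features: np.ndarray | None = None  # the (possibly normalized) rows used

    def __post_init__(self) -> None:
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.k:
            raise AssignmentError_("labels must lie in [0, k)")
        if self.k > 0 and len(np.unique(self.labels)) != self.k:
            raise AssignmentError_("every cluster must be non-empty")

    def counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class MeanIED:
    """Cluster-mean IED: electrodes x time average epoch of one subtype."""

    time_course: np.ndarray  # electrodes x time
    kind: str                # majority kind of member events
    n_events: int
    sampling_rate: float
    window_ms: float

    def topography_at(self, latency_ms: float) -> np.ndarray:
        """Scalp map (electrode vector) at a latency within the window."""
        idx = int(round(latency_ms / 1000.0 * self.sampling_rate))
        idx = np.clip(idx, 0, self.time_course.shape[1] - 1)
        return self.time_course[:, idx]

    def gfp(self) -> np.ndarray:
        """Global field power: across-channel sd per time point."""
        return self.time_course.std(axis=0)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.time_course.shape[1]) / self.sampling_rate * 1000.0
        ax.plot(t, self.time_course.T, color="0.7", lw=0.5)
        ax.plot(t, self.gfp(), color="C3", lw=1.5, label="GFP")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("potential (uV)")
        ax.set_title(f"{self.kind} subtype mean (n={self.n_events})")
        ax.legend()
        return ax


def _within_dispersion(x: np.ndarray, labels: np.ndarray, k: int) -> float:
    w = 0.0
    for c in range(k):
        m = x[labels == c]
        if m.size:
            w += float(((m - m.mean(axis=0)) ** 2).sum())
    return max(w, 1e-300)


def cluster_samples(
    model: ParafacResults,
    k_range: tuple[int, ...] | range = (1, 2, 3, 4, 5),
    seed: int = 0,
    n_init: int = 10,
    method: str = "gap",
    n_references: int = 20,
    normalize: bool = False,
) -> ClusterAssignment:
    """k-means on sample signatures with data-driven cluster count.

    With ``normalize=True`` signatures are scaled to unit length before
    clustering (direction-only comparison); useful when the decomposition
    rank exceeds one and event amplitudes vary widely.

    ``method="gap"`` (default) picks k by the gap statistic — the
    log-dispersion of the clustering compared against uniform reference
    draws over the data's bounding box — choosing the smallest k whose gap
    is within one reference standard error of the next; unlike the raw
    silhouette it genuinely supports k = 1 (a single unimodal subtype must
    not be split).  ``method="silhouette"`` picks the k with maximal mean
    silhouette over the range.  Identical signatures short-circuit to one
    cluster, and a singleton ``k_range`` fixes k.
    """
    x = np.asarray(model.sample, dtype=float)
    if normalize:
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        x = x / np.where(norms > 0, norms, 1.0)
    n = x.shape[0]
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) == 1 and (ks[0] < 1 or ks[0] > n):
        raise ConfigError(f"k={ks[0]} outside [1, {n}]")
    ks = [k for k in ks if 1 <= k <= n]
    if not ks:
        raise ConfigError(f"k_range {sorted(set(k_range))} outside [1, {n}]")

    def single() -> ClusterAssignment:
        return ClusterAssignment(
            labels=np.zeros(n, dtype=int), k=1, silhouette=0.0,
            centroids=x.mean(axis=0, keepdims=True), features=x,
        )

    spread = np.linalg.norm(x - x.mean(axis=0), axis=1).max()
    scale = max(np.linalg.norm(x, axis=1).max(), 1e-30)
    if spread <= 1e-10 * scale:
        return single()

    fits: dict[int, KMeans] = {}

    def fit_k(k: int, data: np.ndarray, cache: bool = True) -> np.ndarray:
        if k == 1:
            return np.zeros(data.shape[0], dtype=int)
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(data)
        if cache:
            fits[k] = km
        return km.labels_

    def finish(k: int) -> ClusterAssignment:
        if k == 1:
            return single()
        km = fits[k]
        sil = float(silhouette_score(x, km.labels_))
        return ClusterAssignment(km.labels_, k, sil, km.cluster_centers_, features=x)

    if len(ks) == 1:
        fit_k(ks[0], x)
        return finish(ks[0])

    if method == "silhouette":
        best = None
        for k in ks:
            if k == 1 or k >= n:
                continue
            labels = fit_k(k, x)
            if len(np.unique(labels)) < k:
                continue
            sil = float(silhouette_score(x, labels))
            if best is None or sil > best[0]:
                best = (sil, k)
        return finish(best[1]) if best else single()
    if method != "gap":
        raise ConfigError("method must be 'gap' or 'silhouette'")

    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    log_w = {}
    gap = {}
    s_k = {}
    refs = [rng.uniform(lo, hi, size=x.shape) for _ in range(n_references)]
    for k in ks:
        if k > 1 and k >= n:
            continue
        labels = fit_k(k, x)
        log_w[k] = np.log(_within_dispersion(x, labels, k))
        ref_logs = []
        for ref in refs:
            rl = fit_k(k, ref, cache=False)
            ref_logs.append(np.log(_within_dispersion(ref, rl, k)))
        gap[k] = float(np.mean(ref_logs) - log_w[k])
        s_k[k] = float(np.std(ref_logs) * np.sqrt(1.0 + 1.0 / n_references))

    valid = sorted(gap)
    chosen = valid[-1]
    for i, k in enumerate(valid[:-1]):
        nxt = valid[i + 1]
        if gap[k] >= gap[nxt] - s_k[nxt]:
            chosen = k
            break
    return finish(chosen)


def merge_small_clusters(
    assignment: ClusterAssignment,
    features: np.ndarray,
    min_fraction: float = 0.1,
    min_size: int = 2,
) -> ClusterAssignment:
    """Absorb clusters below a minimum size into their nearest neighbor.

    Isolated detections (false alarms, misfit events) occasionally form
    tiny clusters; a genuine IED subtype fires many times per recording,
    so clusters smaller than ``max(min_size, min_fraction * n)`` are
    dissolved and their members reassigned to the nearest surviving
    centroid.
    """
    n = assignment.labels.size
    threshold = max(min_size, int(np.ceil(min_fraction * n)))
    counts = assignment.counts()
    keep = np.flatnonzero(counts >= threshold)
    if keep.size in (0, assignment.k):
        return assignment
    centroids = assignment.centroids[keep]
    relabel = {int(c): i for i, c in enumerate(keep)}
    labels = np.empty(n, dtype=int)
    for i, lbl in enumerate(assignment.labels):
        if int(lbl) in relabel:
            labels[i] = relabel[int(lbl)]
        else:
            d = np.linalg.norm(centroids - features[i], axis=1)
            labels[i] = int(np.argmin(d))
    k = keep.size
    if k > 1:
        sil = float(silhouette_score(features, labels))
    else:
        sil = 0.0
    new_centroids = np.vstack([
        features[labels == c].mean(axis=0) for c in range(k)
    ])
    return ClusterAssignment(labels, k, sil, new_centroids, features=features)


def merge_similar_clusters(
    tensor: IEDTensor,
    assignment: ClusterAssignment,
    threshold: float = 0.9,
) -> ClusterAssignment:
    """Merge clusters whose mean IEDs are near-identical.

    Amplitude variability can split one physiological subtype into several
    clusters whose mean spatio-temporal patterns coincide up to scale.
    Two clusters are unified when the product of their peak-window
    topography correlation and their GFP-profile correlation reaches
    ``threshold`` — distinct generators differ in topography, distinct
    waveform kinds in their power time course.
    """
    k = assignment.k
    if k <= 1:
        return assignment
    center = tensor.n_times // 2
    half = max(int(round(0.01 * tensor.sampling_rate)), 1)  # +/-10 ms
    topos, gfps = [], []
    for c in range(k):
        mem = np.flatnonzero(assignment.labels == c)
        m = tensor.values[:, :, mem].mean(axis=2)
        topo = m[:, center - half : center + half + 1].mean(axis=1)
        gfp = m.std(axis=0)
        topos.append(topo / max(np.linalg.norm(topo), 1e-30))
        gfps.append(gfp / max(np.linalg.norm(gfp), 1e-30))
    parent = list(range(k))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(k):
        for j in range(i + 1, k):
            # same generator: same scalp pattern AND same power time course
            score = abs(float(np.dot(topos[i], topos[j]))) * float(
                np.dot(gfps[i], gfps[j])
            )
            if score >= threshold:
                parent[find(i)] = find(j)
    roots = sorted({find(c) for c in range(k)})
    if len(roots) == k:
        return assignment
    relabel = {r: i for i, r in enumerate(roots)}
    labels = np.array([relabel[find(int(l))] for l in assignment.labels])
    k_new = len(roots)
    feats = assignment.features
    if feats is None:
        feats = assignment.centroids[assignment.labels]
    centroids = np.vstack([feats[labels == c].mean(axis=0) for c in range(k_new)])
    sil = float(silhouette_score(feats, labels)) if k_new > 1 else 0.0
    return ClusterAssignment(labels, k_new, sil, centroids, features=assignment.features)


def cluster_means(tensor: IEDTensor, assignment: ClusterAssignment) -> list[MeanIED]:
    """Average epochs within each cluster into one MeanIED per subtype."""
    if assignment.labels.size != tensor.n_samples:
        raise AssignmentError_("labels must cover all tensor samples")
    kinds = np.array(tensor.events.kinds)
    out = []
    for c in range(assignment.k):
        members = np.flatnonzero(assignment.labels == c)
        if members.size == 0:
            raise AssignmentError_(f"cluster {c} is empty")
        mean_epoch = tensor.values[:, :, members].mean(axis=2)
        majority = Counter(kinds[members]).most_common(1)[0][0]
        out.append(
            MeanIED(
                time_course=mean_epoch,
                kind=str(majority),
                n_events=int(members.size),
                sampling_rate=tensor.sampling_rate,
                window_ms=tensor.window_ms,
            )
        )
    return out
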