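"""Cluster-driven solvent/matrix peak filtering.

DESI solvent and MALDI matrix ions are not tissue chemistry: their spatial
intensity distribution concentrates off tissue and is therefore negatively
correlated with tissue-related m/z channels.  This module separates the two
populations by (1) accumulating the feature-by-feature Pearson correlation
matrix over all pixels of all samples — streaming one sample at a time via
sufficient statistics (pixel count, per-feature sums, squared sums and the
cross-product matrix), so memory holds one sample plus one p x p matrix — and
(2) partitioning the rows of the correlation matrix into two clusters with
k-means (default) or a two-component Gaussian mixture.  Tissue features are
mutually correlated, background features anti-correlate with them, so the
correlation rows are nearly linearly separable; delocalized tissue features
(present at reduced intensity across the whole image) still correlate more
with tissue than with background and land in the tissue cluster.

Which of the two clusters is tissue is decided by a heuristic (replacing the
visual inspection usable at small scale): if tissue masks exist, the cluster
with the higher mean on/off-mask intensity ratio; otherwise the cluster with
the higher mean within-cluster correlation.  A manual override always wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .store import SampleDataset, StepMetadata, Workspace

__all__ = [
    "MomentAccumulator",
    "FeatureClusters",
    "accumulate",
    "finalize_correlation",
    "cluster_features",
    "assign_tissue_label",
    "apply_filter",
    "filter_workspace",
]


@dataclass
class MomentAccumulator:
    """Streaming sufficient statistics for the pooled correlation matrix."""

    n_features: int
    n: int = 0
    sum_x: np.ndarray = None
    sum_xx: np.ndarray = None
    sum_xy: np.ndarray = None

    def __post_init__(self):
        if self.sum_x is None:
            self.sum_x = np.zeros(self.n_features)
            self.sum_xx = np.zeros(self.n_features)
            self.sum_xy = np.zeros((self.n_features, self.n_features))

    def merge(self, other: "MomentAccumulator") -> "MomentAccumulator":
        if other.n_features != self.n_features:
            raise ValueError("accumulators have different feature axes")
        return MomentAccumulator(
            n_features=self.n_features,
            n=self.n + other.n,
            sum_x=self.sum_x + other.sum_x,
            sum_xx=self.sum_xx + other.sum_xx,
            sum_xy=self.sum_xy + other.sum_xy,
        )


@dataclass
class FeatureClusters:
    """Two-way partition of the common feature axis."""

    labels: np.ndarray  # 'A' or 'B' per feature
    method: str
    seed: int
    tissue_label: str | None = None
    separation: float = float("nan")
    degenerate: np.ndarray | None = None  # zero-variance flags
    decision: str = ""

    def tissue_indices(self) -> np.ndarray:
        if self.tissue_label is None:
            raise ValueError("tissue label not assigned yet")
        return np.flatnonzero(self.labels == self.tissue_label)

    def background_indices(self) -> np.ndarray:
        if self.tissue_label is None:
            raise ValueError("tissue label not assigned yet")
        return np.flatnonzero(self.labels != self.tissue_label)


def accumulate(s: SampleDataset, acc: MomentAccumulator) -> MomentAccumulator:
    """Fold one sample's pixels into the accumulator (in place)."""
    x = s.intensities
    if x.shape[1] != acc.n_features:
        raise ValueError(
            f"sample {s.sample_id!r} has {x.shape[1]} features, accumulator expects {acc.n_features}"
        )
    acc.n += x.shape[0]
    acc.sum_x += x.sum(axis=0)
    acc.sum_xx += (x * x).sum(axis=0)
    acc.sum_xy += x.T @ x
    return acc


def finalize_correlation(acc: MomentAccumulator) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation matrix from accumulated moments.

    Returns ``(corr, degenerate)`` where degenerate flags zero-variance
    features; their rows/columns are set to 0 (diagonal included), all other
    diagonal entries are exactly 1.
    """
    if acc.n < 2:
        raise ValueError("need at least 2 accumulated pixels for a correlation")
    n = acc.n
    mean = acc.sum_x / n
    cov = acc.sum_xy / n - np.outer(mean, mean)
    var = np.diag(cov).copy()
    scale = np.maximum(np.abs(acc.sum_xx / n), 1.0)
    degenerate = var <= 1e-12 * scale
    sd = np.sqrt(np.where(degenerate, 1.0, var))
    corr = cov / np.outer(sd, sd)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, np.where(degenerate, 0.0, 1.0))
    return corr, degenerate


def cluster_features(
    corr: np.ndarray,
    method: str = "kmeans",
    seed: int = 17,
    degenerate: np.ndarray | None = None,
    pca_threshold: int = 500,
) -> FeatureClusters:
    """Partition features into two clusters from their correlation rows.

    Each feature is represented by its row of the correlation matrix.
    Zero-variance features are excluded from clustering and assigned to the
    background cluster afterwards by convention (a constant channel carries
    no spatial tissue signal).  For the Gaussian mixture with many features
    the rows are first reduced to their top principal directions.
    Deterministic for a given seed.
    """
    p = corr.shape[0]
    if degenerate is None:
        degenerate = np.zeros(p, dtype=bool)
    active = np.flatnonzero(~degenerate)
    if active.size < 3:
        raise ValueError("need at least 3 non-degenerate features to cluster")
    rows = corr[np.ix_(active, active)]
    if method == "kmeans":
        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        raw = km.fit_predict(rows)
    elif method == "gmm":
        feats = rows
        if rows.shape[1] > pca_threshold:
            feats = PCA(n_components=10, random_state=seed).fit_transform(rows)
        gm = GaussianMixture(n_components=2, covariance_type="full", random_state=seed, n_init=3)
        raw = gm.fit_predict(feats)
    else:
        raise ValueError("method must be 'kmeans' or 'gmm'")
    if len(np.unique(raw)) < 2:
        raise ValueError("clustering collapsed to a single cluster")
    # canonical labelling: the cluster containing the first active feature is 'A'
    first = raw[0]
    labels = np.full(p, "B", dtype="<U1")
    labels[active[raw == first]] = "A"
    # degenerate features provisionally join 'B'; assign_tissue_label moves
    # them to whichever cluster ends up as background
    labels[degenerate] = "B"
    sep = _separation_score(rows, raw)
    return FeatureClusters(labels=labels, method=method, seed=seed, separation=sep, degenerate=degenerate)


def _separation_score(rows: np.ndarray, raw: np.ndarray) -> float:
    """Silhouette-like score: between-centroid distance over mean within-cluster spread."""
    c0 = rows[raw == 0].mean(axis=0)
    c1 = rows[raw == 1].mean(axis=0)
    between = np.linalg.norm(c0 - c1)
    within = 0.5 * (
        np.linalg.norm(rows[raw == 0] - c0, axis=1).mean()
        + np.linalg.norm(rows[raw == 1] - c1, axis=1).mean()
    )
    return float(between / within) if within > 0 else float("inf")


def assign_tissue_label(
    clusters: FeatureClusters,
    ws: Workspace | None = None,
    override: str | None = None,
    corr: np.ndarray | None = None,
) -> FeatureClusters:
    """Decide which cluster is tissue.

    Priority: explicit ``override``; else, when any sample carries a tissue
    mask, the cluster with the higher mean on-mask/off-mask intensity ratio;
    else the cluster with the higher mean within-cluster correlation
    (requires ``corr``).  Degenerate features always stay in the background
    cluster.  The decision path is recorded on the result.
    """
    if override is not None:
        if override not in ("A", "B"):
            raise ValueError("override must be 'A' or 'B'")
        clusters.tissue_label = override
        clusters.decision = "manual override"
    else:
        masked = False
        if ws is not None:
            ratios = {"A": [], "B": []}
            for s in ws.iter_samples():
                usable = s.tissue_mask is not None and s.tissue_mask.any() and not s.tissue_mask.all()
                if usable:
                    masked = True
                    on = s.intensities[s.tissue_mask].mean(axis=0)
                    off = s.intensities[~s.tissue_mask].mean(axis=0)
                    r = (on + 1e-12) / (off + 1e-12)
                    for lab in ("A", "B"):
                        sel = clusters.labels == lab
                        if sel.any():
                            ratios[lab].append(float(np.mean(r[sel])))
                del s
            if masked:
                mean_ratio = {lab: float(np.mean(v)) for lab, v in ratios.items() if v}
                clusters.tissue_label = max(mean_ratio, key=mean_ratio.get)
                clusters.decision = f"tissue-mask on/off intensity ratio {mean_ratio}"
        if not masked:
            if corr is None:
                raise ValueError("without masks or an override, the correlation matrix is required")
            mean_corr = {}
            for lab in ("A", "B"):
                sel = (clusters.labels == lab) & ~(clusters.degenerate
                                                   if clusters.degenerate is not None
                                                   else np.zeros(len(clusters.labels), bool))
                idx = np.flatnonzero(sel)
                if idx.size >= 2:
                    block = corr[np.ix_(idx, idx)]
                    mean_corr[lab] = float((block.sum() - idx.size) / (idx.size * (idx.size - 1)))
                elif idx.size:
                    mean_corr[lab] = -np.inf
            clusters.tissue_label = max(mean_corr, key=mean_corr.get)
            clusters.decision = f"mean within-cluster correlation {mean_corr}"
    # degenerate features can never be tissue
    if clusters.degenerate is not None and clusters.degenerate.any():
        bg = "A" if clusters.tissue_label == "B" else "B"
        clusters.labels = clusters.labels.copy()
        clusters.labels[clusters.degenerate] = bg
    return clusters


def apply_filter(s: SampleDataset, clusters: FeatureClusters) -> SampleDataset:
    """Remove background-labelled columns from a sample."""
    keep = clusters.tissue_indices()
    if keep.size == 0:
        raise ValueError("refusing to filter: the tissue cluster is empty")
    out = SampleDataset(
        sample_id=s.sample_id,
        mz=s.mz[keep].copy(),
        intensities=s.intensities[:, keep].copy(),
        coords=s.coords.copy(),
        tissue_mask=None if s.tissue_mask is None else s.tissue_mask.copy(),
    )
    return out


def filter_workspace(
    ws: Workspace,
    method: str = "kmeans",
    seed: int = 17,
    override: str | None = None,
) -> FeatureClusters:
    """Full streaming filter stage: accumulate, correlate, cluster, apply.

    Both clusters' m/z lists are recorded in the metadata ledger; background
    columns are removed from every sample and from the common axis.
    """
    common = ws.common_mz
    if common is None:
        first = ws.get_sample(ws.sample_ids[0])
        common = first.mz
    input_hash = ws.digest()
    acc = MomentAccumulator(n_features=common.size)
    for s in ws.iter_samples():
        accumulate(s, acc)
        del s  # one sample resident at a time
    corr, degenerate = finalize_correlation(acc)
    clusters = cluster_features(corr, method=method, seed=seed, degenerate=degenerate)
    clusters = assign_tissue_label(clusters, ws=ws, override=override, corr=corr)
    keep = clusters.tissue_indices()
    removed = clusters.background_indices()
    for s in ws.iter_samples():
        ws.write_sample(apply_filter(s, clusters), signed_ok=True)
        del s
    ws.set_common_mz(common[keep])
    ws.record_step(
        StepMetadata(
            "filter",
            parameters={
                "method": method,
                "seed": seed,
                "override": override,
                "tissue_label": clusters.tissue_label,
                "decision": clusters.decision,
                "separation": clusters.separation,
                "tissue_mz": [float(v) for v in common[keep]],
                "background_mz": [float(v) for v in common[removed]],
            },
            input_state_hash=input_hash,
            output_state_hash=ws.digest(),
        )
    )
    return clusters
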