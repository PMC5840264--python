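"""Kernel-density m/z alignment across samples, plus lock-mass correction.

Mass spectrometers drift: the same ionic species is observed at slightly
different m/z in different samples (ppm-scale relative error).  To compare
samples feature-by-feature the per-sample m/z axes must be consolidated onto
one *common m/z feature vector*.  Two strategies are provided:

Kernel clustering (reference-free)
    All sample features are pooled into a histogram whose bins are uniform in
    log(m/z) — so a "5 ppm" bin is 5 ppm wide at every mass.  A loess smoother
    (local-linear, tricube weights) evaluates the occurrence frequency on a
    refined grid (1 ppm spacing by default), and cluster centroids are placed
    where the first difference of the smoothed curve changes sign from
    positive to negative.  Each sample feature is then matched to its nearest
    centroid within a maximum drift window (100 ppm by default).

Internal lock mass (reference-based)
    Given reference ions of known m/z, the sample-level drift is the median of
    the observed-minus-theoretical shifts over all references matched within
    the drift window, and is subtracted from the whole axis.

A reference-free method can only make samples mutually consistent — a shift
common to every sample is invisible to it — so :func:`align_workspace` runs
two passes: a wide-window pass that collapses each drift-spread feature into
one provisional centroid near the centre of its pooled spread, a per-sample
recalibration by the median matched drift, and a standard-width second pass
on the recalibrated axes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .store import SampleDataset, StepMetadata, Workspace, array_digest

__all__ = [
    "MzHistogram",
    "CommonMzVector",
    "FeatureMatch",
    "LockMassReference",
    "build_histogram",
    "detect_centroids",
    "cluster_mz_values",
    "match_sample",
    "apply_alignment",
    "lockmass_correct",
    "align_workspace",
]

PPM = 1e-6


@dataclass
class MzHistogram:
    """Occurrence histogram of pooled sample features, uniform in log(m/z).

    ``log_edges`` are bin edges in log(m/z); ``counts[i]`` is the number of
    pooled features falling in bin i (each feature increments exactly one
    bin).  ``smoothed``/``refined_log`` are filled by :func:`detect_centroids`.
    """

    log_edges: np.ndarray
    counts: np.ndarray
    bin_ppm: float
    refined_log: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    @property
    def grid(self) -> np.ndarray:
        """Bin centres in Da."""
        return np.exp(0.5 * (self.log_edges[:-1] + self.log_edges[1:]))


@dataclass
class CommonMzVector:
    """Consolidated cross-sample m/z feature axis."""

    centroids: np.ndarray
    bin_ppm: float
    max_drift_ppm: float = 100.0

    def __post_init__(self):
        self.centroids = np.asarray(self.centroids, dtype=np.float64)

    def __len__(self) -> int:
        return self.centroids.size


@dataclass
class FeatureMatch:
    """Nearest-centroid assignment of one sample's features.

    ``assignment[j]`` is the common-centroid index for sample feature j, or
    -1 if no centroid lies within the drift window; ``drift_ppm[j]`` is the
    signed relative deviation (NaN when unmatched).
    """

    sample_id: str
    assignment: np.ndarray
    drift_ppm: np.ndarray

    @property
    def n_unmatched(self) -> int:
        return int(np.sum(self.assignment < 0))


@dataclass
class LockMassReference:
    """Known reference ion m/z values for internal lock-mass correction."""

    reference_mz: np.ndarray
    max_drift: float = 100.0
    units: str = "ppm"  # window and correction units: "ppm" or "da"

    def __post_init__(self):
        self.reference_mz = np.asarray(self.reference_mz, dtype=np.float64)
        if self.reference_mz.size == 0 or np.any(self.reference_mz <= 0):
            raise ValueError("reference_mz must be positive and non-empty")
        if np.any(np.diff(self.reference_mz) <= 0):
            raise ValueError("reference_mz must be strictly increasing")
        if self.units not in ("ppm", "da"):
            raise ValueError("units must be 'ppm' or 'da'")


# -- histogram -----------------------------------------------------------


def build_histogram(source, bin_ppm: float = 5.0) -> MzHistogram:
    """Pool all sample feature m/z values into a log-uniform histogram.

    ``source`` is a :class:`Workspace` or an iterable of 1-D m/z arrays.  Each
    feature occurrence increments exactly one bin; intensities are ignored.
    The grid covers [min, max] of the pooled values with a one-bin margin on
    each side.
    """
    if bin_ppm <= 0:
        raise ValueError("bin_ppm must be positive")
    if isinstance(source, Workspace):
        mz_lists = []
        for s in source.iter_samples():
            mz_lists.append(s.mz)
            del s  # keep at most one sample resident while streaming
    else:
        mz_lists = [np.asarray(a, dtype=np.float64) for a in source]
    mz_lists = [a for a in mz_lists if a.size]
    if not mz_lists:
        raise ValueError("no m/z values to histogram")
    logs = np.concatenate([np.log(a) for a in mz_lists])
    step = np.log1p(bin_ppm * PPM)
    lo = logs.min() - 1.5 * step
    n_bins = int(np.ceil((logs.max() + 1.5 * step - lo) / step)) + 1
    edges = lo + step * np.arange(n_bins + 1)
    counts, _ = np.histogram(logs, bins=edges)
    return MzHistogram(log_edges=edges, counts=counts.astype(np.int64), bin_ppm=bin_ppm)


# -- loess smoothing and centroid detection -------------------------------


def _loess_eval(x: np.ndarray, y: np.ndarray, x0: np.ndarray, half_width: float) -> np.ndarray:
    """Local-linear tricube-weighted fit of (x, y) evaluated at points x0.

    Closed-form weighted regression per evaluation point; falls back to the
    weighted mean where the local design is degenerate.
    """
    d = x0[:, None] - x[None, :]
    u = np.abs(d) / half_width
    w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
    sw = w.sum(axis=1)
    swx = (w * d).sum(axis=1)
    swy = (w * y).sum(axis=1)
    swxx = (w * d * d).sum(axis=1)
    swxy = (w * d * y).sum(axis=1)
    denom = sw * swxx - swx**2
    out = np.zeros_like(sw)
    ok = (sw > 0) & (denom > 1e-300 * np.maximum(sw * swxx, 1.0))
    out[ok] = (swxx[ok] * swy[ok] - swx[ok] * swxy[ok]) / denom[ok]
    mean_only = (sw > 0) & ~ok
    out[mean_only] = swy[mean_only] / sw[mean_only]
    return out


def _plateau_maxima(values: np.ndarray) -> np.ndarray:
    """Indices where the first difference changes + -> -, plateaus broken to
    the lowest index of the plateau; endpoints never qualify."""
    d = np.diff(values)
    idx = []
    last_sign = 0
    rise_end = -1
    for i, di in enumerate(d):
        s = 0 if di == 0 else (1 if di > 0 else -1)
        if s == 0:
            continue
        if s < 0 and last_sign > 0:
            idx.append(rise_end + 1)  # first point of the (possibly flat) top
        if s > 0:
            rise_end = i
        last_sign = s
    return np.asarray(idx, dtype=np.int64)


def detect_centroids(
    h: MzHistogram,
    refine_ppm: float = 1.0,
    span_bins: float = 7.0,
    min_height: float = 1e-9,
) -> CommonMzVector:
    """Place a centroid at each positive-to-negative sign change of the
    smoothed histogram's first difference on the refined grid.

    ``span_bins`` sets the loess window width in units of coarse histogram
    bins (full width; half-window = span_bins * bin_ppm / 2 in ppm).
    ``min_height`` discards sign changes whose smoothed value is not positive,
    guarding against numerical ripple far from any data.
    Smoothing is only evaluated near occupied bins; elsewhere the histogram is
    identically zero and can hold no centroid.
    """
    step = np.log1p(h.bin_ppm * PPM)
    rstep = np.log1p(refine_ppm * PPM)
    if rstep > step:
        raise ValueError("refined grid must be at least as fine as the coarse bins")
    centers = 0.5 * (h.log_edges[:-1] + h.log_edges[1:])
    counts = h.counts.astype(np.float64)
    occupied = np.flatnonzero(counts > 0)
    if occupied.size == 0:
        warnings.warn("all-zero m/z histogram; no centroids detected")
        return CommonMzVector(np.array([]), h.bin_ppm)

    half = 0.5 * span_bins * step
    # merge occupied bins into regions closer than one window
    pad_bins = int(np.ceil(half / step)) + 1
    regions: list[tuple[int, int]] = []
    start = prev = occupied[0]
    for i in occupied[1:]:
        if i - prev <= 2 * pad_bins:
            prev = i
        else:
            regions.append((start, prev))
            start = prev = i
    regions.append((start, prev))

    lattice0 = centers[0]
    refined_all: list[np.ndarray] = []
    smoothed_all: list[np.ndarray] = []
    centroid_logs: list[float] = []
    for b0, b1 in regions:
        clo = max(0, b0 - pad_bins)
        chi = min(counts.size - 1, b1 + pad_bins)
        x = centers[clo : chi + 1]
        y = counts[clo : chi + 1]
        # refined lattice points shared across calls (anchored at lattice0)
        k0 = int(np.floor((x[0] - lattice0) / rstep))
        k1 = int(np.ceil((x[-1] - lattice0) / rstep))
        rx = lattice0 + rstep * np.arange(k0, k1 + 1)
        sm = _loess_eval(x, y, rx, half)
        refined_all.append(rx)
        smoothed_all.append(sm)
        for i in _plateau_maxima(sm):
            if sm[i] > min_height:
                centroid_logs.append(rx[i])

    h.refined_log = np.concatenate(refined_all)
    h.smoothed = np.concatenate(smoothed_all)
    cents = np.exp(np.sort(np.asarray(centroid_logs)))
    # enforce separation of more than one refined-grid step
    if cents.size > 1:
        keep = [0]
        for i in range(1, cents.size):
            if np.log(cents[i]) - np.log(cents[keep[-1]]) > rstep:
                keep.append(i)
        cents = cents[keep]
    return CommonMzVector(cents, h.bin_ppm)


def cluster_mz_values(
    mz_arrays, bin_ppm: float = 5.0, refine_ppm: float = 1.0, span_bins: float = 7.0
) -> np.ndarray:
    """Consolidate a collection of m/z arrays into cluster centroids.

    Convenience wrapper (histogram + loess + peak detection) used both for
    cross-sample alignment and for within-sample consolidation of
    processed-mode imzML spectra.
    """
    h = build_histogram(mz_arrays, bin_ppm=bin_ppm)
    return detect_centroids(h, refine_ppm=refine_ppm, span_bins=span_bins).centroids


# -- matching and application ---------------------------------------------


def match_sample(
    s: SampleDataset, common: CommonMzVector, max_drift_ppm: float = 100.0
) -> FeatureMatch:
    """Assign each sample feature to its nearest common centroid within the
    drift window; features farther than ``max_drift_ppm`` stay unmatched."""
    if len(common) == 0:
        raise ValueError("common m/z vector is empty")
    c = common.centroids
    pos = np.searchsorted(c, s.mz)
    pos = np.clip(pos, 1, c.size - 1) if c.size > 1 else np.zeros(s.mz.size, dtype=int)
    left = np.clip(pos - 1, 0, c.size - 1)
    right = np.clip(pos, 0, c.size - 1)
    pick = np.where(np.abs(s.mz - c[left]) <= np.abs(s.mz - c[right]), left, right)
    drift = (s.mz - c[pick]) / c[pick] / PPM
    assignment = pick.astype(np.int64)
    unmatched = np.abs(drift) > max_drift_ppm
    assignment[unmatched] = -1
    drift = np.where(unmatched, np.nan, drift)
    if np.all(unmatched) and s.mz.size:
        warnings.warn(f"sample {s.sample_id!r}: no feature matched within {max_drift_ppm} ppm")
    return FeatureMatch(sample_id=s.sample_id, assignment=assignment, drift_ppm=drift)


def apply_alignment(
    s: SampleDataset, match: FeatureMatch, common: CommonMzVector
) -> tuple[SampleDataset, dict]:
    """Re-grid a sample onto the common axis.

    Features mapping to the same centroid are summed per pixel; centroids with
    no matched feature become zero columns; unmatched features are dropped.
    Returns the aligned sample and an accounting dict (counts and total
    intensity dropped) for the metadata ledger.
    """
    if match.assignment.size != s.mz.size:
        raise ValueError("match does not correspond to this sample's feature axis")
    n_c = len(common)
    out = np.zeros((s.n_pixels, n_c), dtype=np.float64)
    matched = match.assignment >= 0
    np.add.at(out.T, match.assignment[matched], s.intensities[:, matched].T)
    dropped_total = float(s.intensities[:, ~matched].sum())
    aligned = SampleDataset(
        sample_id=s.sample_id,
        mz=common.centroids.copy(),
        intensities=out,
        coords=s.coords.copy(),
        tissue_mask=None if s.tissue_mask is None else s.tissue_mask.copy(),
    )
    info = {
        "n_unmatched": int(np.sum(~matched)),
        "dropped_intensity": dropped_total,
        "median_drift_ppm": float(np.nanmedian(match.drift_ppm)) if matched.any() else float("nan"),
    }
    return aligned, info


def lockmass_correct(
    s: SampleDataset, ref: LockMassReference
) -> tuple[SampleDataset, float]:
    """Correct a sample's m/z axis with internal lock-mass references.

    For each reference ion, the nearest sample feature within the drift
    window defines a shift (observed minus theoretical); the sample-level
    drift is the median of those shifts and is removed from the whole axis —
    additively when ``ref.units == 'da'``, multiplicatively for ppm.
    """
    shifts = []
    for r in ref.reference_mz:
        j = int(np.argmin(np.abs(s.mz - r)))
        if ref.units == "ppm":
            shift = (s.mz[j] - r) / r / PPM
        else:
            shift = s.mz[j] - r
        if abs(shift) <= ref.max_drift:
            shifts.append(shift)
    if not shifts:
        raise ValueError(
            "no lock-mass reference matched within the drift window; increase the "
            "window or use the reference-free kernel alignment"
        )
    drift = float(np.median(shifts))
    if ref.units == "ppm":
        new_mz = s.mz * (1.0 - drift * PPM)
    else:
        new_mz = s.mz - drift
    corrected = SampleDataset(
        sample_id=s.sample_id,
        mz=new_mz,
        intensities=s.intensities.copy(),
        coords=s.coords.copy(),
        tissue_mask=None if s.tissue_mask is None else s.tissue_mask.copy(),
    )
    return corrected, drift


# -- workspace-level driver ------------------------------------------------


def align_workspace(
    ws: Workspace,
    bin_ppm: float = 5.0,
    max_drift_ppm: float = 100.0,
    refine_ppm: float = 1.0,
    span_bins: float = 7.0,
    passes: int = 2,
    lockmass: LockMassReference | None = None,
) -> CommonMzVector:
    """Build the common m/z vector and re-grid every sample onto it.

    With ``lockmass`` given, each sample is first drift-corrected against the
    reference ions.  Otherwise, when ``passes == 2``, a wide-window kernel
    pass (window covering twice the drift window) yields provisional
    centroids; each sample is recalibrated by the median of its matched
    drifts; the second pass then runs at the standard window.  Samples are
    streamed one at a time throughout.
    """
    if len(ws) == 0:
        raise ValueError("workspace is empty")
    input_hash = ws.digest()

    drifts_removed: dict[str, float] = {}
    if lockmass is not None:
        for s in ws.iter_samples():
            corrected, drift = lockmass_correct(s, lockmass)
            drifts_removed[s.sample_id] = drift
            ws.write_sample(corrected)
            del s, corrected
    elif passes >= 2:
        wide_span = max(span_bins, 2.0 * max_drift_ppm / bin_ppm)
        h = build_histogram(ws, bin_ppm=bin_ppm)
        provisional = detect_centroids(h, refine_ppm=refine_ppm, span_bins=wide_span)
        provisional.max_drift_ppm = max_drift_ppm
        estimates: dict[str, float] = {}
        for s in ws.iter_samples():
            m = match_sample(s, provisional, max_drift_ppm=max_drift_ppm)
            if np.isfinite(m.drift_ppm).any():
                estimates[s.sample_id] = float(np.nanmedian(m.drift_ppm))
            del s, m
        # only *relative* drift between samples is identifiable; when every
        # sample shows the same apparent drift (e.g. an already-aligned
        # workspace measured against provisional centroids) there is nothing
        # to recalibrate and doing so would only chase centroid-grid noise
        spread = (max(estimates.values()) - min(estimates.values())) if estimates else 0.0
        if spread > 0.5 * refine_ppm:
            for s in ws.iter_samples():
                if s.sample_id in estimates:
                    d = estimates[s.sample_id]
                    drifts_removed[s.sample_id] = d
                    s.mz = s.mz / (1.0 + d * PPM)
                    ws.write_sample(s)
                del s

    h = build_histogram(ws, bin_ppm=bin_ppm)
    common = detect_centroids(h, refine_ppm=refine_ppm, span_bins=span_bins)
    common.max_drift_ppm = max_drift_ppm

    # refine each centroid to the mean of the sample features assigned to it:
    # group means stay inside their nearest-neighbour cells (order preserved)
    # and exactly coincident features reproduce their position bit-exactly,
    # making alignment idempotent; centroids with no matched feature keep
    # their grid position
    sums = np.zeros(len(common))
    hits = np.zeros(len(common), dtype=np.int64)
    for s in ws.iter_samples():
        m = match_sample(s, common, max_drift_ppm=max_drift_ppm)
        matched = m.assignment >= 0
        np.add.at(sums, m.assignment[matched], s.mz[matched])
        np.add.at(hits, m.assignment[matched], 1)
        del s, m
    common.centroids = np.where(hits > 0, sums / np.maximum(hits, 1), common.centroids)

    unmatched: dict[str, int] = {}
    for s in ws.iter_samples():
        m = match_sample(s, common, max_drift_ppm=max_drift_ppm)
        aligned, info = apply_alignment(s, m, common)
        unmatched[s.sample_id] = info["n_unmatched"]
        ws.write_sample(aligned)
        del s, m, aligned

    ws.set_common_mz(common.centroids, bin_ppm=bin_ppm, max_drift_ppm=max_drift_ppm)
    ws.record_step(
        StepMetadata(
            "mzalign",
            parameters={
                "bin_ppm": bin_ppm,
                "max_drift_ppm": max_drift_ppm,
                "refine_ppm": refine_ppm,
                "span_bins": span_bins,
                "passes": passes,
                "lockmass": None if lockmass is None else list(map(float, lockmass.reference_mz)),
                "lockmass_units": None if lockmass is None else lockmass.units,
                "n_centroids": int(len(common)),
                "drift_removed": drifts_removed,
                "unmatched": unmatched,
            },
            input_state_hash=input_hash,
            output_state_hash=ws.digest(),
        )
    )
    return common
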