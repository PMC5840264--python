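"""Variance stabilizing transformation (started log) and its diagnostic.

MS peak intensities carry multiplicative as well as additive technical noise:
the standard deviation of a repeatedly measured peak grows with its mean, so
strong signals dominate any variance-sensitive downstream analysis (PCA and
friends).  Under the two-component model

    x = (mu + eps_add) * exp(eps_mult),   eps_add ~ N(0, sa^2), eps_mult ~ N(0, sm^2)

the started-logarithm ln(x + c) with a small positive offset c stabilizes the
variance: for mu >> sa/sm the transformed standard deviation converges to sm,
independent of mu, while the offset keeps zeros and small counts finite.

The offset is a fixed count value (50 by default) or is estimated as the
lower 5% quantile of all strictly positive intensities pooled over the
workspace.  The quantile is computed out-of-core in two streaming passes: a
log-spaced global histogram locates the bin containing the requested order
statistic, and a second pass extracts the exact value within that bin.

The flatness diagnostic ranks features by mean intensity and follows the
running median of the per-feature standard deviation; absent heteroscedastic
structure that curve is horizontal, summarized here by the slope of a least
squares line through (rank, running median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import SampleDataset, StepMetadata, Workspace

__all__ = [
    "VstParams",
    "estimate_offset",
    "apply_started_log",
    "vst_workspace",
    "variance_rank_diagnostic",
]


@dataclass
class VstParams:
    """Started-log parameters.

    ``offset`` in intensity counts (used directly in ``fixed`` mode);
    ``quantile_level`` is the positive-intensity quantile used in
    ``quantile`` mode.  The logarithm is natural.
    """

    offset: float = 50.0
    mode: str = "fixed"  # "fixed" | "quantile"
    quantile_level: float = 0.05
    n_bins: int = 1024

    def __post_init__(self):
        if self.offset <= 0:
            raise ValueError("offset must be positive")
        if self.mode not in ("fixed", "quantile"):
            raise ValueError("mode must be 'fixed' or 'quantile'")
        if not 0 < self.quantile_level < 0.5:
            raise ValueError("quantile_level must lie in (0, 0.5)")


def estimate_offset(ws: Workspace, params: VstParams | None = None) -> float:
    """Return the started-log offset for a workspace.

    Fixed mode returns ``params.offset``.  Quantile mode streams the samples
    twice: pass 1 accumulates a histogram of positive intensities on
    ``params.n_bins`` log-spaced bins; pass 2 collects the values inside the
    bin containing the requested order statistic and picks it exactly.
    """
    params = params or VstParams()
    if params.mode == "fixed":
        return float(params.offset)

    lo = np.inf
    hi = -np.inf
    n_pos = 0
    for s in ws.iter_samples():
        pos = s.intensities[s.intensities > 0]
        if pos.size:
            lo = min(lo, float(pos.min()))
            hi = max(hi, float(pos.max()))
            n_pos += pos.size
        del s, pos  # one sample resident at a time
    if n_pos == 0:
        raise ValueError("no positive intensities in the workspace")
    if lo == hi:
        return float(lo)

    edges = np.geomspace(lo, hi, params.n_bins + 1)
    edges[0] *= 1 - 1e-12  # keep the global minimum inside the first bin
    edges[-1] *= 1 + 1e-12
    counts = np.zeros(params.n_bins, dtype=np.int64)
    for s in ws.iter_samples():
        pos = s.intensities[s.intensities > 0]
        if pos.size:
            counts += np.histogram(pos, bins=edges)[0]
        del s, pos

    k = int(np.ceil(params.quantile_level * n_pos))  # k-th smallest positive value
    cum = np.cumsum(counts)
    b = int(np.searchsorted(cum, k))
    within_rank = k - (cum[b - 1] if b > 0 else 0)

    values = []
    for s in ws.iter_samples():
        pos = s.intensities[s.intensities > 0]
        values.append(pos[(pos >= edges[b]) & (pos < edges[b + 1])])
        del s, pos
    values = np.sort(np.concatenate(values))
    return float(values[within_rank - 1])


def apply_started_log(
    s: SampleDataset, offset: float, recenter: bool = True
) -> SampleDataset:
    """Replace every intensity x by ln(x + offset).

    With ``recenter`` (default), ln(offset) is subtracted so zero maps to
    zero and sparse matrices stay sparse-friendly.
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    if s.intensities.size and s.intensities.min() < 0:
        raise ValueError("intensities must be non-negative before the started log")
    out = s.copy()
    out.intensities = np.log(s.intensities + offset)
    if recenter:
        out.intensities -= np.log(offset)
    return out


def vst_workspace(
    ws: Workspace, params: VstParams | None = None, recenter: bool = True
) -> float:
    """Apply the started log to every sample, streaming; returns the offset.

    Refuses to run twice on the same workspace — the metadata ledger guards
    against double transformation.
    """
    params = params or VstParams()
    if ws.has_step("vst"):
        raise RuntimeError("workspace has already been variance-stabilized (see metadata ledger)")
    input_hash = ws.digest()
    offset = estimate_offset(ws, params)
    for s in ws.iter_samples():
        ws.write_sample(apply_started_log(s, offset, recenter=recenter), signed_ok=True)
        del s
    ws.record_step(
        StepMetadata(
            "vst",
            parameters={
                "offset": offset,
                "mode": params.mode,
                "quantile_level": params.quantile_level,
                "recenter": recenter,
                "log_base": "e",
            },
            input_state_hash=input_hash,
            output_state_hash=ws.digest(),
        )
    )
    return offset


def variance_rank_diagnostic(
    s: SampleDataset, window: int = 51, use_mask: bool = True
) -> tuple[pd.DataFrame, float]:
    """Standard deviation as a function of ranked mean intensity.

    Restricted to tissue pixels when a mask is present (the diagnostic assumes
    a putatively homogeneous region, so residual variation is technical).
    Returns a table with one row per feature, ordered by mean rank, holding
    the per-feature std and the running median of std in a sliding window
    over rank, plus the slope of a least-squares line through
    (rank, running median) as a scalar flatness score.
    """
    x = s.intensities
    if use_mask and s.tissue_mask is not None and s.tissue_mask.any():
        x = x[s.tissue_mask]
    n_feat = x.shape[1]
    if window < 1 or window > n_feat:
        raise ValueError(f"window must lie in [1, {n_feat}]")
    means = x.mean(axis=0)
    stds = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(n_feat)
    order = np.argsort(means, kind="stable")
    ranked_std = stds[order]
    running = (
        pd.Series(ranked_std)
        .rolling(window, center=True, min_periods=max(1, window // 2))
        .median()
        .to_numpy()
    )
    rank = np.arange(1, n_feat + 1)
    slope = float(np.polyfit(rank, running, 1)[0]) if n_feat > 1 else 0.0
    table = pd.DataFrame(
        {
            "rank": rank,
            "feature_index": order,
            "mz": s.mz[order],
            "mean": means[order],
            "std": ranked_std,
            "running_median_std": running,
        }
    )
    return table, slope
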