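"""Intra- and inter-sample intensity normalization.

Overall spectral intensity varies for reasons unrelated to biology: matrix
deposition inhomogeneity, tissue thickness, detector gain, source conditions.
Intra-sample normalization removes pixel-to-pixel variation inside one sample;
inter-sample normalization removes sample-to-sample variation by one uniform
scaling factor per sample, derived from its homogenized ("average") tissue
profile.

Three factor estimators are provided for either scope:

``mean``
    Factor = mean of all peak intensities of the unit (total ion current up to
    a constant).  Uses every feature, zeros included.
``median``
    Factor = median of the positive peak intensities of the unit.  Zeros are
    excluded because centroided MSI matrices are sparse and a zero median is
    degenerate.
``mfc`` (median fold change)
    Factor = median of the per-feature ratios unit/reference over features
    positive in both.  The reference defaults to the element-wise median
    spectrum (intra) or the median of the sample profiles (inter).  Because
    the median of ratios ignores the magnitude of any minority of genuinely
    changing features, the estimator tolerates large asymmetric biological
    fold changes affecting up to half of the features.

Degenerate units (all-zero, or too few shared positive features for mfc)
receive factor 1 and a flag rather than raising — one bad pixel must not
abort a multi-hundred-sample run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .store import SampleDataset, StepMetadata, Workspace

__all__ = [
    "NormalizationFactors",
    "intra_factors",
    "apply_intra",
    "sample_profile",
    "inter_factors",
    "apply_inter",
    "fold_change_diagnostics",
    "normalize_workspace",
]

METHODS = ("mean", "median", "mfc")


@dataclass
class NormalizationFactors:
    """Scaling factors for one scope ('intra' per spectrum, 'inter' per sample)."""

    scope: str
    method: str
    factors: np.ndarray  # per spectrum (intra) or per sample (inter)
    unit_ids: list = field(default_factory=list)  # sample ids for inter scope
    reference_profile: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # boolean flags, parallel to factors

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=np.float64)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.factors.shape, dtype=bool)
        if np.any(self.factors <= 0):
            raise ValueError("normalization factors must be positive")


def _check_method(method: str) -> None:
    if method not in METHODS:
        raise ValueError(f"unknown normalization method {method!r}; choose from {METHODS}")


def _mfc_factor(x: np.ndarray, ref: np.ndarray, min_shared: int) -> tuple[float, bool]:
    shared = (x > 0) & (ref > 0)
    if shared.sum() < min_shared:
        return 1.0, True
    return float(np.median(x[shared] / ref[shared])), False


def intra_factors(
    s: SampleDataset,
    method: str = "mfc",
    reference: np.ndarray | None = None,
    min_shared: int = 10,
) -> NormalizationFactors:
    """Per-spectrum scaling factors for one sample.

    For ``mfc`` the reference defaults to the element-wise median spectrum
    across all pixels of the sample.
    """
    _check_method(method)
    x = s.intensities
    if x.size and x.min() < 0:
        raise ValueError("intensities must be non-negative (normalize before the VST)")
    n = s.n_pixels
    factors = np.ones(n)
    degenerate = np.zeros(n, dtype=bool)
    ref = None
    if method == "mean":
        f = x.mean(axis=1)
        degenerate = f <= 0
        factors = np.where(degenerate, 1.0, f)
    elif method == "median":
        for i in range(n):
            pos = x[i][x[i] > 0]
            if pos.size == 0:
                degenerate[i] = True
            else:
                factors[i] = np.median(pos)
    else:  # mfc
        ref = np.median(x, axis=0) if reference is None else np.asarray(reference, dtype=np.float64)
        if ref.shape != (s.n_features,):
            raise ValueError("reference profile length must equal the feature axis")
        for i in range(n):
            factors[i], degenerate[i] = _mfc_factor(x[i], ref, min_shared)
    return NormalizationFactors(
        scope="intra",
        method=method,
        factors=factors,
        unit_ids=[s.sample_id],
        reference_profile=ref,
        degenerate=degenerate,
    )


def apply_intra(s: SampleDataset, f: NormalizationFactors) -> SampleDataset:
    """Divide each spectrum (row) by its factor; zeros stay zero."""
    if f.factors.shape != (s.n_pixels,):
        raise ValueError("factor count does not match the sample's pixel count")
    out = s.copy()
    out.intensities = s.intensities / f.factors[:, None]
    return out


def sample_profile(s: SampleDataset, use_mask: bool = True) -> np.ndarray:
    """Homogenized sample profile: element-wise mean over (tissue) spectra."""
    x = s.intensities
    if use_mask and s.tissue_mask is not None:
        if not s.tissue_mask.any():
            raise ValueError(f"tissue mask of sample {s.sample_id!r} selects zero pixels")
        x = x[s.tissue_mask]
    return x.mean(axis=0)


def inter_factors(
    profiles: dict[str, np.ndarray],
    method: str = "mfc",
    min_shared: int = 10,
) -> NormalizationFactors:
    """Per-sample scaling factors from homogenized sample profiles.

    ``mean``/``median`` derive each sample's factor from its own profile; the
    ``mfc`` reference is the element-wise median across sample profiles.
    """
    _check_method(method)
    if not profiles:
        raise ValueError("no sample profiles given")
    ids = list(profiles)
    mat = np.asarray([profiles[k] for k in ids], dtype=np.float64)
    for k, row in zip(ids, mat):
        if not np.any(row > 0):
            raise ValueError(f"sample {k!r} has an entirely zero profile")
    factors = np.ones(len(ids))
    degenerate = np.zeros(len(ids), dtype=bool)
    ref = None
    if method == "mean":
        factors = mat.mean(axis=1)
    elif method == "median":
        for i, row in enumerate(mat):
            factors[i] = np.median(row[row > 0])
    else:
        if len(ids) < 2:
            raise ValueError("mfc inter-sample normalization needs at least 2 samples")
        ref = np.median(mat, axis=0)
        for i, row in enumerate(mat):
            factors[i], degenerate[i] = _mfc_factor(row, ref, min_shared)
    return NormalizationFactors(
        scope="inter",
        method=method,
        factors=factors,
        unit_ids=ids,
        reference_profile=ref,
        degenerate=degenerate,
    )


def apply_inter(s: SampleDataset, factor: float) -> SampleDataset:
    """Divide every intensity of the sample by one uniform factor."""
    if not factor > 0:
        raise ValueError("inter-sample factor must be positive")
    out = s.copy()
    out.intensities = s.intensities / factor
    return out


def fold_change_diagnostics(
    ws: Workspace, scope: str = "intra", reference: np.ndarray | None = None
) -> pd.DataFrame:
    """Box-plot summaries of log-fold changes against a reference profile.

    For scope ``intra``, one row per spectrum (log ratios of the spectrum to
    its sample's median spectrum); for ``inter``, one row per sample profile
    against the cross-sample median profile.  After successful normalization
    the medians should centre on zero.
    """
    rows = []
    if scope == "intra":
        for s in ws.iter_samples():
            ref = np.median(s.intensities, axis=0) if reference is None else reference
            for i in range(s.n_pixels):
                rows.append((s.sample_id, i, *_logfc_summary(s.intensities[i], ref)))
            del s  # one sample resident at a time
        cols = ["sample_id", "spectrum"]
    elif scope == "inter":
        profiles = {}
        for s in ws.iter_samples():
            profiles[s.sample_id] = sample_profile(s)
            del s
        mat = np.asarray(list(profiles.values()))
        ref = np.median(mat, axis=0) if reference is None else reference
        for k, row in profiles.items():
            rows.append((k, 0, *_logfc_summary(row, ref)))
        cols = ["sample_id", "spectrum"]
    else:
        raise ValueError("scope must be 'intra' or 'inter'")
    return pd.DataFrame(rows, columns=cols + ["median", "q1", "q3", "lo_whisker", "hi_whisker", "n_shared"])


def _logfc_summary(x: np.ndarray, ref: np.ndarray):
    shared = (x > 0) & (ref > 0)
    if not shared.any():
        return (np.nan,) * 5 + (0,)
    lfc = np.log(x[shared] / ref[shared])
    q1, med, q3 = np.percentile(lfc, [25, 50, 75])
    iqr = q3 - q1
    lo = lfc[lfc >= q1 - 1.5 * iqr].min()
    hi = lfc[lfc <= q3 + 1.5 * iqr].max()
    return med, q1, q3, lo, hi, int(shared.sum())


def normalize_workspace(
    ws: Workspace,
    scope: str = "intra",
    method: str = "mfc",
    min_shared: int = 10,
    use_mask: bool = True,
) -> NormalizationFactors | None:
    """Run one normalization stage over the whole workspace, streaming.

    Intra scope processes each sample independently (factors are not
    retained per pixel in the ledger, only summary statistics).  Inter scope
    makes two streaming passes: profile collection, then uniform scaling.
    """
    _check_method(method)
    input_hash = ws.digest()
    if scope == "intra":
        n_degenerate = 0
        for s in ws.iter_samples():
            f = intra_factors(s, method=method, min_shared=min_shared)
            n_degenerate += int(f.degenerate.sum())
            ws.write_sample(apply_intra(s, f))
            del s, f
        ws.record_step(
            StepMetadata(
                "normalize-intra",
                parameters={"method": method, "min_shared": min_shared, "n_degenerate": n_degenerate},
                input_state_hash=input_hash,
                output_state_hash=ws.digest(),
            )
        )
        return None
    elif scope == "inter":
        profiles = {}
        for s in ws.iter_samples():
            profiles[s.sample_id] = sample_profile(s, use_mask=use_mask)
            del s
        f = inter_factors(profiles, method=method, min_shared=min_shared)
        lookup = dict(zip(f.unit_ids, f.factors))
        for s in ws.iter_samples():
            ws.write_sample(apply_inter(s, lookup[s.sample_id]))
            del s
        ws.record_step(
            StepMetadata(
                "normalize-inter",
                parameters={
                    "method": method,
                    "min_shared": min_shared,
                    "use_mask": use_mask,
                    "factors": {k: float(v) for k, v in lookup.items()},
                },
                input_state_hash=input_hash,
                output_state_hash=ws.digest(),
            )
        )
        return f
    raise ValueError("scope must be 'intra' or 'inter'")
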