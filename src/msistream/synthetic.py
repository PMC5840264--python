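"""Synthetic multi-sample MSI workspaces with planted ground truth.

Every pipeline stage in this package has a recovery test: the generator
plants the very distortions the pipeline is meant to remove — per-sample
ppm-scale m/z drift, per-pixel and per-sample multiplicative intensity
scaling, additive + multiplicative heteroscedastic noise, an elliptical
tissue mask, and background (solvent/matrix-like) feature channels whose
intensity concentrates off tissue and therefore anti-correlates with tissue
channels — and hands back a :class:`SyntheticTruth` holding every planted
quantity, so tests never re-derive truth from the generated data.

The model for one pixel intensity of feature f in sample s is::

    x = pixel_scale_p * sample_scale_s * base_f * field(f, p) * exp(N(0, sm^2)) + N(0, sa^2)

clipped at zero, where ``field`` is the spatial template: tissue features are
high on the mask and nearly absent off it; background features the reverse;
optional "delocalized" tissue features keep a sizeable off-mask floor.  Base
intensities are log-normal across features, spanning about three decades, to
exercise heteroscedasticity.  Observed m/z values are the true positions
shifted by the sample's drift plus a small per-feature jitter.

No attempt is made to simulate isotope patterns, adduct chemistry or
instrument line shapes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .store import SampleDataset, Workspace, create_workspace

__all__ = [
    "SyntheticParams",
    "SyntheticTruth",
    "generate",
    "perturb_asymmetric",
    "mfc_recovery_study",
]

PPM = 1e-6


@dataclass
class SyntheticParams:
    """Generation settings; defaults are the package's standard study conditions."""

    n_samples: int = 6
    shape: tuple[int, int] = (40, 40)  # (ny, nx) pixel grid
    n_features: int = 200
    n_background: int = 40
    n_delocalized: int = 0
    mz_range: tuple[float, float] = (100.0, 1000.0)
    drift_ppm_range: tuple[float, float] = (-50.0, 50.0)
    jitter_ppm: float = 0.5
    sample_scale_range: tuple[float, float] = (0.5, 2.0)
    pixel_scale_sigma: float = 0.3
    sigma_mult: float = 0.2
    sigma_add: float = 10.0
    base_median: float = 1000.0
    base_log10_sigma: float = 1.0  # ~3 decades of base intensity
    off_tissue_level: float = 0.02
    background_on_level: float = 0.05
    delocalized_off_level: float = 0.4
    seed: int = 17

    def __post_init__(self):
        if self.n_background + self.n_delocalized > self.n_features:
            raise ValueError("background + delocalized features exceed n_features")
        if self.sample_scale_range[0] <= 0:
            raise ValueError("sample scales must be positive")
        lo, hi = self.drift_ppm_range
        if lo > hi:
            raise ValueError("invalid drift range")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated workspace."""

    params: SyntheticParams
    true_mz: np.ndarray
    sample_drift_ppm: dict[str, float]
    sample_scale: dict[str, float]
    pixel_scale: dict[str, np.ndarray]
    background_feature_ids: np.ndarray
    delocalized_feature_ids: np.ndarray
    tissue_masks: dict[str, np.ndarray]
    noise: tuple[float, float]  # (sigma_add, sigma_mult)
    seed: int
    perturbed: dict = field(default_factory=dict)

    @property
    def tissue_feature_ids(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.true_mz.size), self.background_feature_ids)


def _ellipse_mask(ny: int, nx: int, rng: np.random.Generator) -> np.ndarray:
    cy = ny / 2 + rng.uniform(-0.05, 0.05) * ny
    cx = nx / 2 + rng.uniform(-0.05, 0.05) * nx
    ry = 0.35 * ny * rng.uniform(0.9, 1.1)
    rx = 0.35 * nx * rng.uniform(0.9, 1.1)
    yy, xx = np.mgrid[0:ny, 0:nx]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate(params: SyntheticParams | None = None, path: str | None = None) -> tuple[Workspace, SyntheticTruth]:
    """Build a synthetic workspace; regeneration from the same params and seed
    is bit-identical.

    ``path`` defaults to an in-memory-unfriendly temp-less location only when
    given; callers normally pass an explicit file path (tests use tmp dirs).
    """
    params = params or SyntheticParams()
    if path is None:
        raise ValueError("an explicit workspace path is required")
    rng = np.random.default_rng(params.seed)
    ny, nx = params.shape
    n_pix = ny * nx
    p = params.n_features

    # true m/z: near-uniform in log(m/z) with jitter bounded well below spacing
    lo, hi = np.log(params.mz_range[0]), np.log(params.mz_range[1])
    spacing = (hi - lo) / p
    logs = lo + spacing * (0.5 + np.arange(p)) + rng.uniform(-0.3, 0.3, size=p) * spacing
    true_mz = np.exp(logs)

    base = params.base_median * 10.0 ** rng.normal(0.0, params.base_log10_sigma, size=p)
    special = rng.choice(p, size=params.n_background + params.n_delocalized, replace=False)
    background_ids = np.sort(special[: params.n_background])
    delocalized_ids = np.sort(special[params.n_background :])

    yy, xx = np.mgrid[0:ny, 0:nx]
    coords = np.column_stack([xx.ravel(), yy.ravel()])  # row-major by (y, x)

    ws = create_workspace(path, overwrite=True)
    drifts: dict[str, float] = {}
    scales: dict[str, float] = {}
    pixel_scales: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for k in range(params.n_samples):
        sid = f"sample{k:03d}"
        drift = rng.uniform(*params.drift_ppm_range)
        scale = rng.uniform(*params.sample_scale_range)
        mask = _ellipse_mask(ny, nx, rng).ravel()
        pixel_scale = np.exp(rng.normal(0.0, params.pixel_scale_sigma, size=n_pix))

        # spatial template per feature class
        field_mat = np.empty((n_pix, p))
        on = mask[:, None].astype(float)
        field_mat[:] = on + (1.0 - on) * params.off_tissue_level
        field_mat[:, background_ids] = (1.0 - on) + on * params.background_on_level
        if delocalized_ids.size:
            field_mat[:, delocalized_ids] = on + (1.0 - on) * params.delocalized_off_level

        mult = np.exp(rng.normal(0.0, params.sigma_mult, size=(n_pix, p)))
        add = rng.normal(0.0, params.sigma_add, size=(n_pix, p))
        intens = pixel_scale[:, None] * scale * base[None, :] * field_mat * mult + add
        np.clip(intens, 0.0, None, out=intens)

        jitter = rng.normal(0.0, params.jitter_ppm, size=p)
        mz = true_mz * (1.0 + drift * PPM) * (1.0 + jitter * PPM)

        ws.add_sample(
            SampleDataset(sample_id=sid, mz=mz, intensities=intens, coords=coords, tissue_mask=mask)
        )
        drifts[sid] = float(drift)
        scales[sid] = float(scale)
        pixel_scales[sid] = pixel_scale
        masks[sid] = mask

    truth = SyntheticTruth(
        params=params,
        true_mz=true_mz,
        sample_drift_ppm=drifts,
        sample_scale=scales,
        pixel_scale=pixel_scales,
        background_feature_ids=background_ids,
        delocalized_feature_ids=delocalized_ids,
        tissue_masks=masks,
        noise=(params.sigma_add, params.sigma_mult),
        seed=params.seed,
    )
    return ws, truth


def perturb_asymmetric(
    ws: Workspace,
    truth: SyntheticTruth,
    fraction: float,
    fold: float,
    direction: str = "increase",
    sample_ids: list[str] | None = None,
    seed_offset: int = 1,
) -> Workspace:
    """Multiply a seeded random subset of ceil(fraction * p) features by
    ``fold`` in a designated subset of samples, emulating genuine asymmetric
    biological change.  The subset is recorded in ``truth.perturbed``.

    ``direction``: 'increase' multiplies by fold; 'decrease' divides;
    'mixed' flips a fair coin per feature.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fold < 1.0:
        raise ValueError("fold must be >= 1")
    p = truth.true_mz.size
    k = math.ceil(fraction * p)
    rng = np.random.default_rng(truth.seed + seed_offset)
    chosen = np.sort(rng.choice(p, size=k, replace=False)) if k else np.array([], dtype=int)
    if direction == "increase":
        mult = np.full(k, fold)
    elif direction == "decrease":
        mult = np.full(k, 1.0 / fold)
    elif direction == "mixed":
        mult = np.where(rng.random(k) < 0.5, fold, 1.0 / fold)
    else:
        raise ValueError("direction must be 'increase', 'decrease' or 'mixed'")
    targets = sample_ids if sample_ids is not None else ws.sample_ids
    for s in ws.iter_samples():
        if s.sample_id in targets and k:
            s.intensities[:, chosen] *= mult[None, :]
            ws.write_sample(s)
        del s
    truth.perturbed = {
        "feature_ids": chosen,
        "multipliers": mult,
        "fold": fold,
        "fraction": fraction,
        "direction": direction,
        "sample_ids": list(targets),
    }
    return ws


def mfc_recovery_study(
    n_spectra: int = 100,
    n_features: int = 2000,
    fractions=None,
    n_seeds: int = 20,
    fold: float = 3.0,
    direction: str = "increase",
    scale_range: tuple[float, float] = (0.5, 2.0),
    base_log10_sigma: float = 1.0,
    methods: tuple[str, ...] = ("mfc", "mean"),
    seed: int = 0,
):
    """Robustness sweep of normalization-factor recovery under asymmetric
    perturbation.

    Spectra are a shared log-normal base profile times a known per-spectrum
    scale factor drawn uniformly from ``scale_range``; at each perturbed
    fraction f a per-spectrum random subset of round(f * n_features) features
    is multiplied by ``fold`` (increases only by default).  Each spectrum's
    factor is re-estimated against the unperturbed base profile — as the
    median of ratios over shared positive features (mfc) or as the ratio of
    means (mean / total ion current) — and compared with the planted factor.

    Returns a DataFrame with one row per (method, fraction): the median and
    the 90th percentile of the relative recovery error pooled over spectra
    and seeds.
    """
    import pandas as pd

    if fractions is None:
        fractions = np.round(np.arange(0.0, 0.7001, 0.05), 2)
    records = []
    for frac in fractions:
        k = int(round(frac * n_features))
        errors = {m: [] for m in methods}
        for rep in range(n_seeds):
            rng = np.random.default_rng([seed, rep])
            base = 10.0 ** rng.normal(0.0, base_log10_sigma, size=n_features)
            scales = rng.uniform(*scale_range, size=n_spectra)
            mult = np.ones((n_spectra, n_features))
            if k:
                for i in range(n_spectra):
                    idx = rng.choice(n_features, size=k, replace=False)
                    mult[i, idx] = fold
            spectra = scales[:, None] * base[None, :] * mult
            for m in methods:
                if m == "mfc":
                    est = np.median(spectra / base[None, :], axis=1)
                elif m == "mean":
                    est = spectra.mean(axis=1) / base.mean()
                else:
                    raise ValueError(f"unknown method {m!r}")
                errors[m].append(np.abs(est - scales) / scales)
        for m in methods:
            pooled = np.concatenate(errors[m])
            records.append(
                {
                    "method": m,
                    "fraction": float(frac),
                    "median_rel_error": float(np.median(pooled)),
                    "p90_rel_error": float(np.percentile(pooled, 90)),
                }
            )
    return pd.DataFrame(records)
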