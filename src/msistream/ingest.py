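"""Readers for external MSI data: imzML and delimited centroided peak lists.

imzML (the open MSI standard, XML index + .ibd binary) comes in two dialects:
*continuous*, where every pixel shares one m/z axis, and *processed*, where
each pixel carries its own centroid list.  Continuous files map directly onto
a pixel-by-feature matrix.  Processed files are consolidated first: all
observed per-pixel m/z values are clustered with the same kernel-density
machinery used for cross-sample alignment (5 ppm bins by default), each
pixel's peaks are then assigned to the nearest consolidated feature, with
intensities of peaks collapsing onto one feature summed.

Instrument-software text exports are covered by :func:`read_peaklist` with a
configurable :class:`PeakListDialect`; the default is an open, documented
format — comma-delimited with a ``x,y,mz,intensity`` header — since vendor
export schemas vary.  Records are grouped by pixel, duplicate (pixel, m/z)
entries are summed, and the m/z axis is the sorted union of observed values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mzalign
from .store import SampleDataset

__all__ = ["PeakListDialect", "read_imzml", "read_peaklist"]


@dataclass
class PeakListDialect:
    """Column mapping for delimited peak-list files."""

    delimiter: str = ","
    x_col: str = "x"
    y_col: str = "y"
    mz_col: str = "mz"
    intensity_col: str = "intensity"
    header: bool = True

    def __post_init__(self):
        roles = [self.x_col, self.y_col, self.mz_col, self.intensity_col]
        if len(set(roles)) != 4:
            raise ValueError("x, y, mz and intensity must map to four distinct columns")


def read_imzml(
    path: str,
    sample_id: str | None = None,
    bin_ppm: float = 5.0,
    max_drift_ppm: float = 100.0,
) -> SampleDataset:
    """Read an imzML + ibd pair into a dense :class:`SampleDataset`.

    ``bin_ppm``/``max_drift_ppm`` control the within-sample axis
    consolidation used for processed-mode files; continuous files take the
    shared axis verbatim.  Pixel coordinates are converted to 0-based.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    ibd = os.path.splitext(path)[0] + ".ibd"
    if not os.path.exists(ibd):
        raise FileNotFoundError(f"missing ibd binary companion: {ibd}")
    parser = ImzMLParser(path)
    flags = parser.metadata.file_description.param_by_name
    if flags.get("continuous"):
        mode = "continuous"
    elif flags.get("processed"):
        mode = "processed"
    else:
        raise ValueError(f"{path}: imzML file declares neither continuous nor processed mode")

    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    n_pix = len(parser.coordinates)
    coords = np.asarray([(c[0] - 1, c[1] - 1) for c in parser.coordinates], dtype=np.int64)

    spectra = []
    for i in range(n_pix):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        ints = np.asarray(ints, dtype=np.float64)
        if mzs.size > 1 and np.any(np.diff(mzs) <= 0):
            raise ValueError(f"{path}: non-monotone m/z axis in spectrum {i}")
        spectra.append((mzs, ints))

    if mode == "continuous":
        mz = spectra[0][0]
        intensities = np.vstack([s[1] for s in spectra])
        return SampleDataset(sample_id=sid, mz=mz, intensities=intensities, coords=coords)

    # processed: consolidate per-pixel axes into one sample-level axis
    centroids = mzalign.cluster_mz_values([s[0] for s in spectra], bin_ppm=bin_ppm)
    common = mzalign.CommonMzVector(centroids, bin_ppm=bin_ppm, max_drift_ppm=max_drift_ppm)
    intensities = np.zeros((n_pix, len(common)))
    for i, (mzs, ints) in enumerate(spectra):
        pseudo = SampleDataset(sample_id=f"{sid}:{i}", mz=mzs, intensities=ints[None, :], coords=np.array([[0, 0]]))
        m = mzalign.match_sample(pseudo, common, max_drift_ppm=max_drift_ppm)
        matched = m.assignment >= 0
        np.add.at(intensities[i], m.assignment[matched], ints[matched])
    return SampleDataset(sample_id=sid, mz=common.centroids, intensities=intensities, coords=coords)


def read_peaklist(
    path: str,
    dialect: PeakListDialect | None = None,
    sample_id: str | None = None,
) -> SampleDataset:
    """Read a delimited centroided peak list into a dense sample matrix.

    The m/z axis is the sorted union of observed m/z values (exact match);
    missing (pixel, m/z) records are zero-filled and duplicates summed.
    """
    dialect = dialect or PeakListDialect()
    try:
        df = pd.read_csv(
            path,
            sep=dialect.delimiter,
            header=0 if dialect.header else None,
            names=None if dialect.header else [dialect.x_col, dialect.y_col, dialect.mz_col, dialect.intensity_col],
        )
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: unparsable peak list: {e}") from e
    for col in (dialect.x_col, dialect.y_col, dialect.mz_col, dialect.intensity_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sub = df[[dialect.x_col, dialect.y_col, dialect.mz_col, dialect.intensity_col]].copy()
    sub.columns = ["x", "y", "mz", "intensity"]
    bad = sub[sub.isna().any(axis=1)]
    if len(bad):
        # +2 accounts for the header line and 1-based file line numbers
        line = int(bad.index[0]) + (2 if dialect.header else 1)
        raise ValueError(f"{path}: unparsable record at line {line}")
    if (sub["intensity"] < 0).any():
        line = int(sub.index[(sub["intensity"] < 0).to_numpy()][0]) + (2 if dialect.header else 1)
        raise ValueError(f"{path}: negative intensity at line {line}")

    grouped = sub.groupby(["x", "y", "mz"], sort=True)["intensity"].sum().reset_index()
    mz_axis = np.sort(grouped["mz"].unique())
    pixels = grouped[["x", "y"]].drop_duplicates().sort_values(["y", "x"]).to_numpy(dtype=np.int64)
    pix_index = {tuple(p): i for i, p in enumerate(map(tuple, pixels))}
    mz_index = {v: j for j, v in enumerate(mz_axis)}
    intensities = np.zeros((len(pixels), mz_axis.size))
    for x, y, mz, inten in grouped.itertuples(index=False):
        intensities[pix_index[(x, y)], mz_index[mz]] += inten
    sid = sample_id or os.path.splitext(os.path.basename(path))[0]
    return SampleDataset(sample_id=sid, mz=mz_axis, intensities=intensities, coords=pixels)
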