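"""HDF5-backed workspace for multi-sample MSI peak data.

A mass spectrometry imaging (MSI) experiment produces, per tissue section
("sample"), a centroided peak intensity matrix: one row per pixel, one column
per m/z feature.  Large studies hold hundreds of such samples, far more than
fits in memory, so every pipeline stage in this package streams samples one at
a time from a single HDF5 container and writes results back.  The container
also carries an append-only ledger of processing metadata (step name,
parameters, timestamps, content digests) so any run can be audited and
replayed.

Layout of the workspace file::

    /samples/<sample_id>/{mz, intensities, coords, tissue_mask}
    /common_mz                  consolidated cross-sample m/z axis
    /metadata/<k>               k-th processing step, JSON, ordered by k

Floating point arrays are stored at 64-bit precision so that digests of
reprocessed data are bit-exact.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import os
import weakref
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SampleDataset",
    "StepMetadata",
    "Workspace",
    "ValidationError",
    "array_digest",
    "create_workspace",
    "open_workspace",
]


class ValidationError(ValueError):
    """A dataset violates one of its structural invariants."""


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def array_digest(*arrays: np.ndarray) -> str:
    """SHA-256 content digest over raw array bytes plus shapes.

    Shape is hashed alongside the bytes so that reshaped data cannot collide
    with the original.
    """
    h = hashlib.sha256()
    for a in arrays:
        a = np.ascontiguousarray(a)
        h.update(str(a.dtype).encode())
        h.update(np.asarray(a.shape, dtype=np.int64).tobytes())
        h.update(a.tobytes())
    return h.hexdigest()


@dataclass(eq=False)  # identity semantics; instances are weakref-tracked
class SampleDataset:
    """One sample's pixel-by-feature peak intensity matrix.

    Parameters
    ----------
    sample_id:
        Unique identifier within a workspace.
    mz:
        Feature m/z values in Da, strictly increasing, all positive.
    intensities:
        ``(n_pixels, n_features)`` matrix of peak intensities in detector
        counts.  Non-negative at every stage before the variance stabilizing
        transform; may be signed afterwards.
    coords:
        ``(n_pixels, 2)`` integer pixel positions ``(x, y)``, 0-based.
    tissue_mask:
        Optional boolean vector per pixel; True marks on-tissue pixels.
    """

    sample_id: str
    mz: np.ndarray
    intensities: np.ndarray
    coords: np.ndarray
    tissue_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.coords = np.asarray(self.coords, dtype=np.int64)
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def validate(self, signed_ok: bool = False) -> None:
        """Raise :class:`ValidationError` naming the first violated invariant."""
        if self.mz.ndim != 1 or self.intensities.ndim != 2 or self.coords.ndim != 2:
            raise ValidationError(f"{self.sample_id}: mz must be 1-D, intensities and coords 2-D")
        if self.mz.size and not np.all(self.mz > 0):
            raise ValidationError(f"{self.sample_id}: mz values must be positive")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValidationError(f"{self.sample_id}: mz must be strictly increasing")
        if self.intensities.shape[1] != self.mz.size:
            raise ValidationError(
                f"{self.sample_id}: intensities has {self.intensities.shape[1]} columns "
                f"but mz has {self.mz.size} entries"
            )
        if self.coords.shape != (self.intensities.shape[0], 2):
            raise ValidationError(
                f"{self.sample_id}: coords shape {self.coords.shape} does not match "
                f"{self.intensities.shape[0]} pixels"
            )
        if not signed_ok and self.intensities.size and self.intensities.min() < 0:
            raise ValidationError(f"{self.sample_id}: intensities must be non-negative")
        if self.coords.shape[0]:
            uniq = np.unique(self.coords, axis=0)
            if uniq.shape[0] != self.coords.shape[0]:
                raise ValidationError(f"{self.sample_id}: duplicate (x, y) pixel coordinates")
        if self.tissue_mask is not None and self.tissue_mask.shape != (self.intensities.shape[0],):
            raise ValidationError(f"{self.sample_id}: tissue_mask length does not match pixel count")

    def digest(self) -> str:
        arrays = [self.mz, self.intensities, self.coords]
        if self.tissue_mask is not None:
            arrays.append(self.tissue_mask)
        return array_digest(*arrays)

    def copy(self) -> "SampleDataset":
        return SampleDataset(
            sample_id=self.sample_id,
            mz=self.mz.copy(),
            intensities=self.intensities.copy(),
            coords=self.coords.copy(),
            tissue_mask=None if self.tissue_mask is None else self.tissue_mask.copy(),
        )


@dataclass
class StepMetadata:
    """Provenance record for one mutating workspace operation.

    ``parameters`` must be complete enough that re-running the step from the
    same input state reproduces ``output_state_hash``.
    """

    step_name: str
    parameters: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=_utcnow)
    input_state_hash: str = ""
    output_state_hash: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "step_name": self.step_name,
                "parameters": self.parameters,
                "timestamp": self.timestamp,
                "input_state_hash": self.input_state_hash,
                "output_state_hash": self.output_state_hash,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StepMetadata":
        d = json.loads(text)
        return cls(**d)


class Workspace:
    """Single-file HDF5 container of all samples plus the processing ledger.

    Open workspaces hold the file handle; use as a context manager or call
    :meth:`close`.  ``peak_resident`` counts the maximum number of sample
    intensity matrices simultaneously alive in memory, which streaming stages
    keep at 1 — this is the out-of-core contract and is asserted in tests.
    """

    def __init__(self, path: str, _file: h5py.File):
        self.path = str(path)
        self._file = _file
        self._resident: "weakref.WeakSet[SampleDataset]" = weakref.WeakSet()
        self.peak_resident = 0

    # -- lifecycle -----------------------------------------------------------

    @classmethod
    def create(cls, path: str, overwrite: bool = False) -> "Workspace":
        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"workspace exists at {path}; pass overwrite=True to replace it")
        f = h5py.File(path, "w")
        f.create_group("samples").attrs["order"] = json.dumps([])
        f.create_group("metadata")
        ws = cls(path, f)
        ws.record_step(StepMetadata("init", parameters={"overwrite": overwrite}))
        return ws

    @classmethod
    def open(cls, path: str, mode: str = "r+") -> "Workspace":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return cls(path, h5py.File(path, mode))

    def close(self) -> None:
        if self._file:
            self._file.close()

    def __enter__(self) -> "Workspace":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- samples -------------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return json.loads(self._file["samples"].attrs["order"])

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._file["samples"]

    def add_sample(self, s: SampleDataset) -> None:
        if s.sample_id in self:
            raise ValueError(f"duplicate sample_id {s.sample_id!r}")
        self._write(s, new=True)
        self.record_step(
            StepMetadata(
                "add_sample",
                parameters={"sample_id": s.sample_id, "n_pixels": s.n_pixels, "n_features": s.n_features},
                output_state_hash=s.digest(),
            )
        )

    def write_sample(self, s: SampleDataset, signed_ok: bool = False) -> None:
        """Replace an existing sample's arrays (used by pipeline stages)."""
        if s.sample_id not in self:
            raise KeyError(s.sample_id)
        self._write(s, new=False, signed_ok=signed_ok)

    def _write(self, s: SampleDataset, new: bool, signed_ok: bool | None = None) -> None:
        if signed_ok is None:
            signed_ok = False
        s.validate(signed_ok=signed_ok or self.has_step("vst"))
        grp = self._file["samples"]
        if not new:
            del grp[s.sample_id]
        g = grp.create_group(s.sample_id)
        g.create_dataset("mz", data=s.mz.astype(np.float64))
        g.create_dataset("intensities", data=s.intensities.astype(np.float64))
        g.create_dataset("coords", data=s.coords.astype(np.int64))
        if s.tissue_mask is not None:
            g.create_dataset("tissue_mask", data=s.tissue_mask.astype(bool))
        if new:
            order = self.sample_ids
            order.append(s.sample_id)
            grp.attrs["order"] = json.dumps(order)
        self._file.flush()

    def get_sample(self, sample_id: str) -> SampleDataset:
        if sample_id not in self:
            raise KeyError(sample_id)
        g = self._file["samples"][sample_id]
        s = SampleDataset(
            sample_id=sample_id,
            mz=g["mz"][()],
            intensities=g["intensities"][()],
            coords=g["coords"][()],
            tissue_mask=g["tissue_mask"][()] if "tissue_mask" in g else None,
        )
        self._resident.add(s)
        self.peak_resident = max(self.peak_resident, len(self._resident))
        return s

    def iter_samples(self):
        """Yield each sample exactly once, in insertion order, one at a time."""
        for sid in self.sample_ids:
            yield self.get_sample(sid)

    def reset_resident_peak(self) -> None:
        self.peak_resident = len(self._resident)

    # -- common m/z axis -----------------------------------------------------

    @property
    def common_mz(self) -> np.ndarray | None:
        if "common_mz" not in self._file:
            return None
        return self._file["common_mz"][()]

    def set_common_mz(self, centroids: np.ndarray, **attrs) -> None:
        if "common_mz" in self._file:
            del self._file["common_mz"]
        d = self._file.create_dataset("common_mz", data=np.asarray(centroids, dtype=np.float64))
        for k, v in attrs.items():
            d.attrs[k] = v
        self._file.flush()

    # -- provenance ledger ---------------------------------------------------

    def record_step(self, meta: StepMetadata) -> None:
        grp = self._file["metadata"]
        k = len(grp)
        grp.create_dataset(str(k), data=meta.to_json())
        self._file.flush()

    @property
    def metadata(self) -> list[StepMetadata]:
        grp = self._file["metadata"]
        out = []
        for k in sorted(grp, key=int):
            raw = grp[k][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            out.append(StepMetadata.from_json(raw))
        return out

    def has_step(self, step_name: str) -> bool:
        return any(m.step_name == step_name for m in self.metadata)

    def digest(self) -> str:
        """Content digest of the full data state (all samples + common axis)."""
        h = hashlib.sha256()
        for sid in self.sample_ids:
            s = self.get_sample(sid)
            h.update(sid.encode())
            h.update(s.digest().encode())
            del s  # one sample resident at a time
        cm = self.common_mz
        if cm is not None:
            h.update(array_digest(cm).encode())
        return h.hexdigest()


def create_workspace(path: str, overwrite: bool = False) -> Workspace:
    return Workspace.create(path, overwrite=overwrite)


def open_workspace(path: str, mode: str = "r+") -> Workspace:
    return Workspace.open(path, mode=mode)
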