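"""Per-subject voxel-pair functional connectivity.

For a seed region of interest, the pair universe is every unordered
(ROI voxel, brain voxel) pair: each ROI voxel against every non-ROI brain
voxel, plus each within-ROI pair counted once. Per subject, FC is the
Pearson correlation of the two voxels' time series, Fisher z-transformed
(arctanh). Values sit in a subjects x pairs store (HDF5, float32) so that
millions of pairs stay addressable out of core.

Degenerate voxels: a voxel with zero temporal variance has no defined
correlation; its pairs are stored as NaN and the voxel is recorded in a
registry so downstream tests can exclude (and count) them. Numerically
perfect correlations (duplicate series) are clipped to +/-(1 - 1e-12)
before arctanh, yielding a large finite z instead of +/-inf.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .io_atlas import Atlas, SubjectScan

__all__ = [
    "PairIndex",
    "PairFCStore",
    "enumerate_pairs",
    "pearson_fc",
    "fisher_z",
    "subject_pair_fc",
    "compute_store",
]

R_CLIP = 1.0 - 1e-12


@dataclasses.dataclass
class PairIndex:
    """Deterministic enumeration of the seed-anchored voxel-pair universe.

    ``pairs[k] = (i, j)`` holds atlas enumeration positions. Order: first the
    within-ROI upper triangle (i < j, i-major), then ROI x non-ROI pairs
    (ROI voxel major, brain voxel ascending).
    """

    pairs: np.ndarray
    roi_id: int
    n_roi: int
    n_brain: int

    @property
    def n_pairs(self) -> int:
        return int(self.pairs.shape[0])


def enumerate_pairs(atlas: Atlas, roi_id: int) -> PairIndex:
    """Enumerate all unordered (ROI voxel, brain voxel) pairs exactly once.

    Count is ``|ROI| * (|brain| - |ROI|) + |ROI| * (|ROI| - 1) / 2``.
    """
    roi = atlas.voxel_indices(roi_id)
    if roi.size < 2:
        raise ValueError(f"seed region {roi_id} has fewer than 2 voxels")
    n = atlas.n_voxels
    in_roi = np.zeros(n, dtype=bool)
    in_roi[roi] = True
    non_roi = np.flatnonzero(~in_roi)

    a, b = np.triu_indices(roi.size, k=1)
    within = np.stack([roi[a], roi[b]], axis=1)
    cross_i = np.repeat(roi, non_roi.size)
    cross_j = np.tile(non_roi, roi.size)
    cross = np.stack([cross_i, cross_j], axis=1)
    pairs = np.concatenate([within, cross], axis=0).astype(np.int32)
    return PairIndex(pairs=pairs, roi_id=int(roi_id), n_roi=int(roi.size), n_brain=n)


def pearson_fc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two time series; NaN for constant input."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z-transform arctanh(r); |r| >= 1 is clipped to keep z finite."""
    r = np.clip(np.asarray(r, dtype=np.float64), -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def _standardize(scan: SubjectScan) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; return matrix + zero-variance voxels."""
    x = scan.data
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    zero_var = np.flatnonzero(norm == 0.0)
    safe = np.where(norm == 0.0, 1.0, norm)
    return xc / safe[:, None], zero_var


def subject_pair_fc(
    scan: SubjectScan,
    pair_index: PairIndex,
    chunk_size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z FC for every pair of one subject.

    ``chunk_size`` bounds how many pairs are materialized at once (a pure
    memory contract: results are bit-identical for any chunking). Returns
    ``(z, zero_variance_voxels)``; pairs touching a zero-variance voxel are
    NaN.
    """
    if scan.data.shape[0] < pair_index.n_brain:
        raise ValueError("scan does not cover all voxels referenced by pairs")
    xn, zero_var = _standardize(scan)
    pairs = pair_index.pairs
    n_pairs = pairs.shape[0]
    if chunk_size is None or chunk_size >= n_pairs:
        chunk_size = n_pairs
    z = np.empty(n_pairs, dtype=np.float64)
    for start in range(0, n_pairs, chunk_size):
        sl = slice(start, min(start + chunk_size, n_pairs))
        r = np.einsum("ij,ij->i", xn[pairs[sl, 0]], xn[pairs[sl, 1]])
        z[sl] = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    if zero_var.size:
        bad = np.isin(pairs[:, 0], zero_var) | np.isin(pairs[:, 1], zero_var)
        z[bad] = np.nan
    return z, zero_var


@dataclasses.dataclass
class PairFCStore:
    """Subjects x pairs matrix of Fisher-z values plus bookkeeping.

    ``zero_variance`` is an (m, 2) array of (subject row, voxel enumeration
    index) records for voxels that had no temporal variance in that scan.
    """

    z: np.ndarray  # float32, subjects x pairs
    pair_index: PairIndex
    subject_ids: list[str]
    zero_variance: np.ndarray

    @property
    def n_subjects(self) -> int:
        return int(self.z.shape[0])

    def subject_rows(self, subject_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.subject_ids)}
        try:
            return np.array([lookup[s] for s in subject_ids], dtype=np.int64)
        except KeyError as err:
            raise KeyError(f"subject not in store: {err.args[0]}") from None

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("z", data=self.z, dtype="f4")
            f.create_dataset("pairs", data=self.pair_index.pairs, dtype="i4")
            f.create_dataset(
                "subjects",
                data=np.array([s.encode() for s in self.subject_ids]),
            )
            f.create_dataset(
                "zero_variance",
                data=self.zero_variance.reshape(-1, 2),
                dtype="i8",
            )
            f.attrs["roi_id"] = self.pair_index.roi_id
            f.attrs["n_roi"] = self.pair_index.n_roi
            f.attrs["n_brain"] = self.pair_index.n_brain

    @classmethod
    def load(cls, path: str | Path) -> "PairFCStore":
        with h5py.File(path, "r") as f:
            pair_index = PairIndex(
                pairs=f["pairs"][()],
                roi_id=int(f.attrs["roi_id"]),
                n_roi=int(f.attrs["n_roi"]),
                n_brain=int(f.attrs["n_brain"]),
            )
            return cls(
                z=f["z"][()],
                pair_index=pair_index,
                subject_ids=[s.decode() for s in f["subjects"][()]],
                zero_variance=f["zero_variance"][()].reshape(-1, 2),
            )


def compute_store(
    scans: list[SubjectScan],
    pair_index: PairIndex,
    chunk_size: int | None = None,
) -> PairFCStore:
    """Run :func:`subject_pair_fc` over a cohort into a float32 store."""
    n_pairs = pair_index.n_pairs
    z = np.empty((len(scans), n_pairs), dtype=np.float32)
    registry: list[tuple[int, int]] = []
    for row, scan in enumerate(scans):
        zi, zero_var = subject_pair_fc(scan, pair_index, chunk_size=chunk_size)
        z[row] = zi.astype(np.float32)
        registry.extend((row, int(v)) for v in zero_var)
    zero = np.array(registry, dtype=np.int64).reshape(-1, 2)
    return PairFCStore(
        z=z,
        pair_index=pair_index,
        subject_ids=[s.subject_id for s in scans],
        zero_variance=zero,
    )
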