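"""Motion QC and amplitude-of-low-frequency-fluctuation (ALFF) computation.

The ALFF of a voxel is the mean of the single-sided amplitude spectrum
(``2|X_k|/N``) over the discrete-Fourier frequencies falling inside a
low-frequency band, computed on the linearly detrended time series with no
taper and no zero padding.  Voxel maps are standardized by the whole-brain
mean and averaged within atlas parcels to yield region-wise features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BoldImage",
    "ParcellationAtlas",
    "MotionParameters",
    "AlffMap",
    "FeatureMatrix",
    "linear_detrend",
    "framewise_displacement",
    "summary_fd",
    "exclude_high_motion",
    "compute_voxel_alff",
    "standardize_alff",
    "region_average",
    "build_feature_matrix",
]

MIN_TIMEPOINTS = 16
DEFAULT_BAND = (0.01, 0.08)
DEFAULT_HEAD_RADIUS_MM = 50.0


class DegenerateInputError(ValueError):
    """Input too short / too small for the requested computation."""


@dataclass
class BoldImage:
    """4D BOLD-like voxel grid (x, y, z, t) with sampling interval ``tr``."""

    data: np.ndarray
    tr: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got ndim={self.data.ndim}")
        if self.data.shape[3] < MIN_TIMEPOINTS:
            raise ValueError(
                f"need >= {MIN_TIMEPOINTS} volumes, got {self.data.shape[3]}"
            )
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial dims")
        if not self.mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class ParcellationAtlas:
    """3D integer label volume; 0 is background, regions are 1..R."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if (self.labels < 0).any():
            raise ValueError("atlas labels must be non-negative")

    @property
    def region_labels(self) -> np.ndarray:
        labs = np.unique(self.labels)
        return labs[labs > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_labels.size)


@dataclass
class MotionParameters:
    """Per-volume rigid-body parameters: 3 translations (mm), 3 rotations (rad)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters need 6 columns, got {self.params.shape[1]}"
            )

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass
class AlffMap:
    """Voxel-wise ALFF values with the band they were computed over."""

    values: np.ndarray
    band: tuple[float, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("ALFF map must be 3D")
        if (self.values < 0).any():
            raise ValueError("ALFF values must be non-negative")


@dataclass
class FeatureMatrix:
    """Scans x regions table of region-wise ALFF with pairing metadata.

    ``values`` rows are scans; columns are integer region labels.  ``labels``
    codes condition as +1 (post) / -1 (pre).  ``subject_ids`` pair the two
    scans of each subject.
    """

    values: pd.DataFrame
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        n = len(self.values)
        if self.labels.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError("labels/subject_ids must align with rows")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be coded +1/-1")
        if (self.labels == 1).sum() != (self.labels == -1).sum():
            raise ValueError("unbalanced conditions: unpaired subject present")
        for sid in np.unique(self.subject_ids):
            rows = self.labels[self.subject_ids == sid]
            if sorted(rows.tolist()) != [-1, 1]:
                raise ValueError(f"subject {sid!r} lacks exactly one scan per condition")

    @property
    def region_labels(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)

    @property
    def n_subjects(self) -> int:
        return int(np.unique(self.subject_ids).size)

    def subset_regions(self, regions: Iterable[int]) -> "FeatureMatrix":
        regions = [r for r in self.values.columns if r in set(regions)]
        return FeatureMatrix(self.values[regions].copy(), self.labels.copy(),
                             self.subject_ids.copy())

    def paired_arrays(self, regions: Sequence[int] | None = None):
        """Return (subject order, pre matrix, post matrix) aligned by subject."""
        cols = list(regions) if regions is not None else list(self.values.columns)
        sids = np.unique(self.subject_ids)
        pre = np.empty((sids.size, len(cols)))
        post = np.empty((sids.size, len(cols)))
        vals = self.values[cols].to_numpy()
        for i, sid in enumerate(sids):
            pre[i] = vals[(self.subject_ids == sid) & (self.labels == -1)][0]
            post[i] = vals[(self.subject_ids == sid) & (self.labels == 1)][0]
        return sids, pre, post

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "subject_id", self.subject_ids)
        out.insert(1, "condition", np.where(self.labels == 1, "post", "pre"))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        sids = df.pop("subject_id").to_numpy()
        cond = df.pop("condition").to_numpy()
        labels = np.where(cond == "post", 1, -1)
        df.columns = [int(c) for c in df.columns]
        return cls(df, labels, sids)


def linear_detrend(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares line (slope and mean) along ``axis``."""
    ts = np.asarray(ts, dtype=float)
    if ts.shape[axis] < 3:
        raise DegenerateInputError("need at least 3 samples to detrend")
    return signal.detrend(ts, axis=axis, type="linear")


def framewise_displacement(
    mp: MotionParameters, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Power FD: sum of absolute backward differences, rotations scaled to mm.

    FD[0] = 0; FD[i] = sum|d trans| + head_radius * sum|d rot| for i >= 1.
    """
    if mp.n_volumes < 2:
        raise ValueError("need at least 2 volumes for framewise displacement")
    d = np.abs(np.diff(mp.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def summary_fd(
    mp: MotionParameters,
    statistic: str = "mean",
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
) -> float:
    fd = framewise_displacement(mp, head_radius=head_radius)
    if statistic == "mean":
        return float(fd.mean())
    if statistic == "max":
        return float(fd.max())
    raise ValueError(f"unknown FD summary statistic {statistic!r}")


def exclude_high_motion(
    motion: Mapping[tuple, MotionParameters],
    threshold: float,
    statistic: str = "mean",
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
):
    """Drop subjects whose summary FD in either condition exceeds ``threshold``.

    ``motion`` maps (subject_id, condition) -> MotionParameters.  Returns
    (retained subject ids, exclusion log); the log records each excluded
    subject with the offending scans and their summary FD.
    """
    per_subject: dict = {}
    for (sid, cond), mp in motion.items():
        per_subject.setdefault(sid, {})[cond] = summary_fd(
            mp, statistic=statistic, head_radius=head_radius
        )
    retained, log = [], []
    for sid in sorted(per_subject):
        over = {c: v for c, v in per_subject[sid].items() if v > threshold}
        if over:
            log.append({
                "subject_id": sid,
                "reason": f"{statistic} FD > {threshold} mm",
                "fd": {c: round(v, 6) for c, v in per_subject[sid].items()},
                "offending_conditions": sorted(over),
            })
        else:
            retained.append(sid)
    return retained, log


def _band_bins(n: int, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Indices of rfft bins with frequency in the closed interval ``band``.

    The zero-frequency bin is never in-band.
    """
    lo, hi = band
    nyq = 1.0 / (2.0 * tr)
    if not (0.0 < lo <= hi):
        raise ValueError(f"invalid band {band}")
    if hi > nyq + 1e-12:
        raise ValueError(f"band {band} exceeds Nyquist frequency {nyq}")
    freqs = np.fft.rfftfreq(n, d=tr)
    idx = np.nonzero((freqs >= lo - 1e-12) & (freqs <= hi + 1e-12) & (freqs > 0))[0]
    if idx.size == 0:
        raise DegenerateInputError(
            f"no DFT bin falls inside band {band} for N={n}, tr={tr}"
        )
    return idx


def amplitude_spectrum(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Single-sided amplitude spectrum 2|X_k|/N (no taper, no padding)."""
    ts = np.asarray(ts, dtype=float)
    n = ts.shape[axis]
    return 2.0 * np.abs(np.fft.rfft(ts, axis=axis)) / n


def compute_voxel_alff(
    img: BoldImage,
    band: tuple[float, float] = DEFAULT_BAND,
    detrend: bool = True,
) -> AlffMap:
    """Mean in-band amplitude-spectrum value per in-mask voxel.

    Out-of-mask voxels are set to 0.  The series is linearly detrended first
    unless ``detrend=False`` (then the caller guarantees it already was).
    """
    idx = _band_bins(img.n_volumes, img.tr, band)
    ts = img.data[img.mask]  # (n_vox, t)
    if detrend:
        ts = linear_detrend(ts, axis=-1)
    amp = amplitude_spectrum(ts, axis=-1)
    alff = amp[:, idx].mean(axis=1)
    out = np.zeros(img.data.shape[:3])
    out[img.mask] = alff
    return AlffMap(out, band=tuple(band), standardized=False)


def standardize_alff(m: AlffMap, mask: np.ndarray) -> AlffMap:
    """Divide each in-mask voxel by the in-mask mean ALFF."""
    mask = np.asarray(mask, dtype=bool)
    mean = m.values[mask].mean()
    if mean <= 0:
        raise ZeroDivisionError(
            "in-mask mean ALFF is zero; cannot standardize (all-flat input?)"
        )
    vals = np.zeros_like(m.values)
    vals[mask] = m.values[mask] / mean
    return AlffMap(vals, band=m.band, standardized=True)


def region_average(m: AlffMap, atlas: ParcellationAtlas) -> pd.Series:
    """Mean standardized ALFF per atlas region, indexed by region label.

    Regions with no in-mask voxels (identified as voxels where the map is
    defined, i.e. inside the atlas labels) yield NaN with a warning.
    """
    if m.values.shape != atlas.labels.shape:
        raise ValueError(
            f"shape mismatch: map {m.values.shape} vs atlas {atlas.labels.shape}"
        )
    if not m.standardized:
        raise ValueError("region_average expects a standardized ALFF map")
    labels = atlas.labels.ravel()
    vals = m.values.ravel()
    nmax = int(labels.max())
    sums = np.bincount(labels, weights=vals, minlength=nmax + 1)
    counts = np.bincount(labels, minlength=nmax + 1)
    region_labels = atlas.region_labels
    with np.errstate(invalid="ignore"):
        means = sums[region_labels] / counts[region_labels]
    empty = counts[region_labels] == 0
    if empty.any():
        warnings.warn(
            f"{empty.sum()} region(s) have no voxels and yield NaN", stacklevel=2
        )
    return pd.Series(means, index=region_labels, name="alff")


def build_feature_matrix(
    region_vectors: Mapping[tuple, pd.Series]
) -> FeatureMatrix:
    """Assemble per-scan region vectors into a FeatureMatrix.

    ``region_vectors`` maps (subject_id, condition) -> region Series with
    condition in {"pre", "post"}.  Columns that are NaN in any scan (regions
    missing from the mask) are dropped with a warning.
    """
    rows, sids, labels = [], [], []
    for (sid, cond), vec in sorted(region_vectors.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        if cond not in ("pre", "post"):
            raise ValueError(f"unknown condition {cond!r}")
        rows.append(vec)
        sids.append(sid)
        labels.append(1 if cond == "post" else -1)
    df = pd.DataFrame(rows).reset_index(drop=True)
    bad = df.columns[df.isna().any()]
    if len(bad):
        warnings.warn(
            f"dropping {len(bad)} region(s) with missing values: {list(bad)[:10]}...",
            stacklevel=2,
        )
        df = df.drop(columns=bad)
    return FeatureMatrix(df, np.asarray(labels), np.asarray(sids))
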