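"""Synthetic paired-cohort generator with known planted effects.

Produces everything the downstream pipeline consumes: a parcellation atlas,
paired pre/post BOLD-like 4D images, per-scan rigid-body motion traces,
behavioral scores, and a truth record naming the planted regions.

Signal model per in-mask voxel::

    y(t) = baseline + drift * t
         + gain * base_amp[region] * factor * osc(t)
         + AR(1) noise

where ``osc`` is a sum of unit sinusoids at the DFT frequencies inside the
oscillation band (random phases per voxel), ``gain`` is a subject-level
factor shared across conditions (inducing the paired correlation), and
``factor = 1 + scan_jitter * eta + delta`` with ``eta ~ N(0,1)`` drawn per
scan and region.  For planted regions in the post condition,
``delta = effect_size * scan_jitter * sqrt(2)``, so the paired post-pre
difference of standardized region ALFF has standardized mean difference
(Cohen's d) approximately ``effect_size``: the subject gain cancels under
whole-brain standardization and the denominator is sd of the jitter
difference, ``scan_jitter * sqrt(2)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .alff import BoldImage, MotionParameters, ParcellationAtlas

__all__ = ["SyntheticConfig", "Cohort", "generate_atlas",
           "generate_subject_image", "generate_cohort"]

_COND_CODE = {"pre": 1, "post": 2}

# sub-stream tags for SeedSequence spawning
_ATLAS, _AMPS, _SCAN, _GAIN, _BEHAV, _MOTION = range(6)

# E[FD] = (3 + 3) * sqrt(2/pi) * step  ~= 4.79 * step  (rotations scaled back
# to the same step size by the 50 mm head radius)
_FD_PER_STEP = 6.0 * np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic paired cohort."""

    n_subjects: int = 30
    n_regions: int = 246
    volume_dims: tuple[int, int, int] = (18, 18, 12)
    n_volumes: int = 175
    tr: float = 2.0
    planted_regions: tuple[int, ...] = ()
    effect_size: float = 0.0
    osc_band: tuple[float, float] = (0.01, 0.08)
    noise_ar1: float = 0.4
    noise_sd: float = 0.5
    scan_jitter: float = 0.12
    subject_gain_sd: float = 0.2
    cfmt_mean_sd: tuple[float, float] = (56.9, 4.29)
    high_motion_subjects: tuple[int, ...] = ()
    cfmt_coupled_regions: tuple[int, ...] = ()
    cfmt_coupling: float = 0.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "volume_dims", tuple(int(d) for d in self.volume_dims))
        object.__setattr__(self, "osc_band", tuple(float(f) for f in self.osc_band))
        object.__setattr__(self, "cfmt_mean_sd", tuple(float(v) for v in self.cfmt_mean_sd))
        object.__setattr__(self, "planted_regions",
                           tuple(sorted(int(r) for r in self.planted_regions)))
        object.__setattr__(self, "high_motion_subjects",
                           tuple(sorted(int(s) for s in self.high_motion_subjects)))
        object.__setattr__(self, "cfmt_coupled_regions",
                           tuple(sorted(int(r) for r in self.cfmt_coupled_regions)))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_volumes < 16:
            raise ValueError("n_volumes must be >= 16")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        bad = [r for r in self.planted_regions if not 1 <= r <= self.n_regions]
        if bad:
            raise ValueError(f"planted regions outside 1..{self.n_regions}: {bad}")
        bad = [s for s in self.high_motion_subjects if not 1 <= s <= self.n_subjects]
        if bad:
            raise ValueError(f"high-motion subjects outside 1..{self.n_subjects}: {bad}")

    @property
    def subject_ids(self) -> list[int]:
        return list(range(1, self.n_subjects + 1))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        raw = json.loads(Path(path).read_text())
        return cls(**raw)


@dataclass
class Cohort:
    """A fully generated synthetic cohort plus its ground truth."""

    config: SyntheticConfig
    atlas: ParcellationAtlas
    images: dict          # (subject_id, condition) -> BoldImage
    motion: dict          # (subject_id, condition) -> MotionParameters
    behavior: pd.DataFrame
    truth: dict

    def write(self, outdir) -> None:
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.eye(4)
        nib.save(nib.Nifti1Image(self.atlas.labels.astype(np.int16), affine),
                 outdir / "atlas.nii.gz")
        for (sid, cond), img in self.images.items():
            ni = nib.Nifti1Image(img.data.astype(np.float32), affine)
            ni.header.set_zooms((1.0, 1.0, 1.0, img.tr))
            nib.save(ni, outdir / f"sub-{sid:03d}_{cond}_bold.nii.gz")
        for (sid, cond), mp in self.motion.items():
            np.savetxt(outdir / f"sub-{sid:03d}_{cond}_motion.txt", mp.params,
                       fmt="%.8f")
        self.behavior.to_csv(outdir / "behavior.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _rng(config: SyntheticConfig, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed,) + key))


def _ellipsoid_mask(dims: tuple[int, int, int]) -> np.ndarray:
    axes = [(np.arange(d) + 0.5 - d / 2.0) / (d / 2.0) for d in dims]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return xx**2 + yy**2 + zz**2 <= 1.0 + 1e-12


def generate_atlas(config: SyntheticConfig) -> ParcellationAtlas:
    """Partition an ellipsoidal mask into ``n_regions`` labeled parcels."""
    mask = _ellipsoid_mask(config.volume_dims)
    n_vox = int(mask.sum())
    if n_vox < config.n_regions:
        raise ValueError(
            f"volume_dims {config.volume_dims} give only {n_vox} in-mask voxels "
            f"for {config.n_regions} regions"
        )
    flat = np.flatnonzero(mask.ravel())
    order = _rng(config, _ATLAS).permutation(flat)
    labels = np.zeros(int(np.prod(config.volume_dims)), dtype=np.int32)
    for lab, chunk in enumerate(np.array_split(order, config.n_regions), start=1):
        labels[chunk] = lab
    return ParcellationAtlas(labels.reshape(config.volume_dims))


def _base_amplitudes(config: SyntheticConfig) -> np.ndarray:
    # heterogeneous but subject-invariant region base amplitudes
    return _rng(config, _AMPS).uniform(0.8, 1.2, size=config.n_regions)


def _subject_gain(config: SyntheticConfig, subject_id: int) -> float:
    g = 1.0 + _rng(config, _GAIN, subject_id).normal(0.0, config.subject_gain_sd)
    return float(max(g, 0.3))


def _behavior_row(config: SyntheticConfig, subject_id: int) -> dict:
    rng = _rng(config, _BEHAV, subject_id)
    c_mean, c_sd = config.cfmt_mean_sd
    cfmt_pre = float(np.clip(rng.normal(c_mean, c_sd), 0.0, 72.0))
    cfmt_post = float(np.clip(cfmt_pre + rng.normal(0.4, 1.5), 0.0, 72.0))
    ret_pre = float(np.clip(rng.normal(0.61, 0.05), 0.0, 1.0))
    ret_post = float(np.clip(ret_pre + rng.normal(0.23, 0.04), 0.0, 1.0))
    rt_pre = float(max(rng.normal(3.08, 0.30), 0.2))
    rt_post = float(max(rt_pre + rng.normal(-0.55, 0.25), 0.2))
    return {
        "subject_id": subject_id,
        "cfmt_pre": cfmt_pre, "cfmt_post": cfmt_post,
        "ret_pre": ret_pre, "ret_post": ret_post,
        "ret_rt_pre": rt_pre, "ret_rt_post": rt_post,
    }


def _region_factors(config: SyntheticConfig, subject_id: int,
                    condition: str, rng: np.random.Generator) -> np.ndarray:
    """Per-region amplitude multipliers for one scan."""
    eta = rng.normal(0.0, 1.0, size=config.n_regions)
    factor = 1.0 + config.scan_jitter * eta
    if condition == "post" and config.planted_regions:
        delta = config.effect_size * config.scan_jitter * np.sqrt(2.0)
        # whole-brain standardization divides by the global mean, which the
        # planted boost itself inflates by ~ delta * n_planted / n_regions;
        # pre-compensate so the standardized effect lands on effect_size
        delta /= 1.0 - len(config.planted_regions) / config.n_regions
        factor[np.array(config.planted_regions) - 1] += delta
    if config.cfmt_coupling and config.cfmt_coupled_regions:
        beh = _behavior_row(config, subject_id)
        cfmt = beh["cfmt_post"] if condition == "post" else beh["cfmt_pre"]
        z = (cfmt - config.cfmt_mean_sd[0]) / config.cfmt_mean_sd[1]
        idx = np.array(config.cfmt_coupled_regions) - 1
        factor[idx] += config.cfmt_coupling * config.scan_jitter * z
    return np.maximum(factor, 0.05)


def generate_subject_image(
    config: SyntheticConfig,
    atlas: ParcellationAtlas,
    subject_id: int,
    condition: str,
) -> BoldImage:
    """One scan: drift + AR(1) noise + band-limited oscillation per voxel."""
    if condition not in _COND_CODE:
        raise ValueError(f"condition must be 'pre' or 'post', got {condition!r}")
    rng = _rng(config, _SCAN, subject_id, _COND_CODE[condition])

    mask = atlas.labels > 0
    region_of_vox = atlas.labels[mask] - 1          # (V,)
    n_vox = region_of_vox.size
    n, tr = config.n_volumes, config.tr
    t_sec = np.arange(n) * tr

    freqs = np.fft.rfftfreq(n, d=tr)
    lo, hi = config.osc_band
    fsel = freqs[(freqs >= lo - 1e-12) & (freqs <= hi + 1e-12) & (freqs > 0)]
    omega_t = 2.0 * np.pi * np.outer(fsel, t_sec)   # (K, T)

    amp_region = _base_amplitudes(config) * _subject_gain(config, subject_id) \
        * _region_factors(config, subject_id, condition, rng)
    amp_vox = amp_region[region_of_vox]             # (V,)

    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_vox, fsel.size))
    osc = np.cos(phases) @ np.sin(omega_t) + np.sin(phases) @ np.cos(omega_t)
    ts = amp_vox[:, None] * osc

    innov = rng.normal(0.0, config.noise_sd * np.sqrt(1.0 - config.noise_ar1**2),
                       size=(n_vox, n))
    ts += signal.lfilter([1.0], [1.0, -config.noise_ar1], innov, axis=1)

    drift = rng.normal(0.0, 0.01, size=n_vox)
    ts += 100.0 + drift[:, None] * t_sec[None, :]

    data = np.zeros(config.volume_dims + (n,), dtype=np.float32)
    data[mask] = ts
    return BoldImage(data, tr=tr, mask=mask)


def _generate_motion(config: SyntheticConfig, subject_id: int,
                     condition: str) -> MotionParameters:
    rng = _rng(config, _MOTION, subject_id, _COND_CODE[condition])
    # per-frame displacement step chosen so mean Power FD ~= 4.79 * step
    step = 0.08 if subject_id in config.high_motion_subjects else 0.015
    d_trans = rng.normal(0.0, step, size=(config.n_volumes - 1, 3))
    d_rot = rng.normal(0.0, step / 50.0, size=(config.n_volumes - 1, 3))
    steps = np.hstack([d_trans, d_rot])
    params = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionParameters(params)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Full paired cohort: images, motion traces, behavior, truth record."""
    atlas = generate_atlas(config)
    images, motion, rows = {}, {}, []
    for sid in config.subject_ids:
        for cond in ("pre", "post"):
            images[(sid, cond)] = generate_subject_image(config, atlas, sid, cond)
            motion[(sid, cond)] = _generate_motion(config, sid, cond)
        rows.append(_behavior_row(config, sid))
    behavior = pd.DataFrame(rows)
    truth = {
        "planted_regions": list(config.planted_regions),
        "effect_size": config.effect_size,
        "high_motion_subjects": list(config.high_motion_subjects),
        "cfmt_coupled_regions": list(config.cfmt_coupled_regions),
        "cfmt_coupling": config.cfmt_coupling,
        "seed": config.seed,
    }
    return Cohort(config, atlas, images, motion, behavior, truth)
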