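"""Synthetic dynamic-PET acquisition: frame schedules, phantoms, noise.

Two protocols are simulated.  The *standard* protocol is a 6-min cardiac
single-bed list-mode acquisition (sub-framed), a short dead time while the
scanner switches to whole-body mode, then 16 continuous-bed-motion passes
(5 of 2 min followed by 11 of 5 min), so the last three frames cover
60–75 min post injection.  The *two-short* protocol keeps only the 0–6 min
and 60–75 min frames — the subset a patient would actually be scanned for.

Noise is zero-mean Gaussian in image space with per-voxel standard
deviation ``sigma0 * sqrt(activity / frame_duration)``, the usual
frame-duration scaling of reconstructed-image noise.  Noise streams are
keyed by (seed, frame start time), so frames shared between the two
protocols receive bit-identical noise — mirroring the study design in
which both datasets come from one physical scan session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .idif import TimeActivityCurve
from .kinetics import InputFunction, KineticParams, TissueCurve, tissue_curve

__all__ = [
    "FrameSchedule",
    "Region",
    "PhantomSpec",
    "DynamicImage",
    "NoiseModel",
    "build_schedule",
    "frame_average",
    "render_phantom",
    "save_dynamic",
    "load_dynamic",
]

#: default sub-framing of the 6-min cardiac list-mode acquisition (seconds)
CARDIAC_SUBFRAMES_S = [5.0] * 12 + [15.0] * 8 + [30.0] * 6
#: dead time (min) between the cardiac bed and the first whole-body pass;
#: reconciles the 6 + 5*2 + 11*5 = 71 min of listed acquisitions with the
#: 75-min total scan time and the 60-75 min window of the last three passes
DEAD_TIME_MIN = 4.0


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered half-open frame intervals [start, end) in minutes."""

    frames: tuple
    protocol_id: str

    def __post_init__(self):
        arr = np.asarray(self.frames, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("frames must be (start, end) pairs")
        if np.any(arr[:, 1] <= arr[:, 0]) or np.any(arr[1:, 0] < arr[:-1, 1] - 1e-9):
            raise ValueError("frames must be non-overlapping and increasing")
        object.__setattr__(self, "frames", tuple(map(tuple, arr)))

    @property
    def starts(self) -> np.ndarray:
        return np.array([s for s, _ in self.frames])

    @property
    def ends(self) -> np.ndarray:
        return np.array([e for _, e in self.frames])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2

    @property
    def durations(self) -> np.ndarray:
        return self.ends - self.starts

    def __len__(self) -> int:
        return len(self.frames)

    def restrict(self, windows) -> "FrameSchedule":
        """Frames fully contained in any of the (t0, t1) windows."""
        keep = []
        for s, e in self.frames:
            if any(s >= w0 - 1e-9 and e <= w1 + 1e-9 for w0, w1 in windows):
                keep.append((s, e))
        return FrameSchedule(tuple(keep), "two_short")


def build_schedule(protocol_id: str,
                   cardiac_subframes_s=None,
                   dead_time_min: float = DEAD_TIME_MIN) -> FrameSchedule:
    """The clinical frame schedule for either protocol.

    standard: cardiac sub-frames tiling [0, 6), a dead time, 5 passes of
    2 min, 11 passes of 5 min (last three exactly [60,65), [65,70), [70,75)).
    two_short: the subset of standard covering [0, 6) and [60, 75).
    """
    if cardiac_subframes_s is None:
        cardiac_subframes_s = CARDIAC_SUBFRAMES_S
    frames = []
    t = 0.0
    for dur_s in cardiac_subframes_s:
        frames.append((t, t + dur_s / 60.0))
        t += dur_s / 60.0
    if abs(t - 6.0) > 1e-9:
        raise ValueError("cardiac sub-frames must tile [0, 6) minutes")
    t += dead_time_min
    for _ in range(5):
        frames.append((t, t + 2.0))
        t += 2.0
    for _ in range(11):
        frames.append((t, t + 5.0))
        t += 5.0
    full = FrameSchedule(tuple(frames), "standard")
    if protocol_id == "standard":
        return full
    if protocol_id == "two_short":
        return full.restrict([(0.0, 6.0), (60.0, 75.0)])
    raise ValueError(f"unknown protocol {protocol_id!r}")


def frame_average(curve, schedule: FrameSchedule,
                  source: str = "tissue") -> TimeActivityCurve:
    """Exact per-frame mean of a continuous curve: (1/Δt)·∫ over the frame.

    ``curve`` is an :class:`InputFunction` or :class:`TissueCurve`; both
    expose exact cumulative integrals for analytic inputs.
    """
    starts, ends = schedule.starts, schedule.ends
    upper = np.asarray(curve.integral(ends), float)
    lower = np.asarray(curve.integral(starts), float)
    vals = (upper - lower) / (ends - starts)
    tag = "aorta_idif" if isinstance(curve, InputFunction) and source == "tissue" else source
    return TimeActivityCurve(starts, ends, vals, tag)


@dataclass(frozen=True)
class Region:
    """A geometric phantom region carrying one kinetic parameter set.

    ``geometry`` is ``sphere`` (center voxel indices + diameter mm) or
    ``box`` (inclusive voxel index bounds).  ``params`` is a
    :class:`KineticParams`, or None for the blood-pool (aorta) region whose
    voxels carry Cp itself.
    """

    name: str
    geometry: str
    center: tuple = ()
    diameter_mm: float = 0.0
    bounds: tuple = ()        # ((i0,i1),(j0,j1),(k0,k1)) inclusive, box only
    params: KineticParams | None = None

    def mask(self, shape, voxel_size_mm: float) -> np.ndarray:
        if self.geometry == "sphere":
            idx = np.indices(shape, dtype=float)
            c = np.asarray(self.center, float).reshape(3, 1, 1, 1)
            d2 = (((idx - c) * voxel_size_mm) ** 2).sum(axis=0)
            return d2 <= (self.diameter_mm / 2) ** 2
        if self.geometry == "box":
            m = np.zeros(shape, bool)
            (i0, i1), (j0, j1), (k0, k1) = self.bounds
            m[i0:i1 + 1, j0:j1 + 1, k0:k1 + 1] = True
            return m
        raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom: grid, voxel size, labelled regions, blood glucose."""

    grid_shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 4.0
    regions: tuple = ()
    aorta_label: str = "aorta"
    blood_glucose: float = 5.5   # mmol/L

    def __post_init__(self):
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region labels must be unique")
        if self.aorta_label not in names:
            raise ValueError("exactly one aorta region is required")

    def masks(self) -> dict:
        out = {}
        for r in self.regions:
            m = r.mask(self.grid_shape, self.voxel_size_mm)
            if not m.any():
                raise ValueError(f"region {r.name!r} lies outside the grid")
            out[r.name] = m
        # overlap check
        stack = np.zeros(self.grid_shape, int)
        for m in out.values():
            stack += m
        if stack.max() > 1:
            raise ValueError("phantom regions overlap")
        return out

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian image-space noise, sd = sigma0 * sqrt(activity / Δt_frame)."""

    sigma0: float = 0.5     # kBq/ml at 1 kBq/ml mean activity and 1-min frame
    seed: int = 0

    def __post_init__(self):
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")

    def frame_rng(self, frame_start_min: float) -> np.random.Generator:
        key = int(round(frame_start_min * 1000))
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


@dataclass(frozen=True)
class DynamicImage:
    """4D dynamic volume (x, y, z, frame) in kBq/ml with its schedule."""

    data: np.ndarray
    schedule: FrameSchedule
    voxel_size_mm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.data.shape[3] != len(self.schedule):
            raise ValueError("frame count must match schedule")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image values must be finite")

    def restrict(self, windows) -> "DynamicImage":
        """Sub-image over frames inside the given time windows."""
        sub = self.schedule.restrict(windows)
        keep = [i for i, fr in enumerate(self.schedule.frames) if fr in sub.frames]
        return DynamicImage(self.data[..., keep], sub, self.voxel_size_mm,
                            dict(self.meta))


def render_phantom(spec: PhantomSpec, f: InputFunction, s: FrameSchedule,
                   noise: NoiseModel | None = None) -> DynamicImage:
    """Simulate a dynamic acquisition of the phantom.

    Each voxel's frame series is the exact frame average of its region's
    tissue curve (aorta voxels carry the plasma curve Cp), plus Gaussian
    noise per the :class:`NoiseModel`.  Background voxels are zero.
    """
    masks = spec.masks()
    data = np.zeros(spec.grid_shape + (len(s),), dtype=np.float64)
    for r in spec.regions:
        if r.name == spec.aorta_label:
            tac = frame_average(f, s, source="aorta_idif")
        else:
            tac = frame_average(tissue_curve(r.params, f), s)
        data[masks[r.name]] = tac.activity
    meta = {"protocol_id": s.protocol_id, "glucose_mmol_l": spec.blood_glucose}
    if noise is not None and noise.sigma0 > 0:
        durs = s.durations
        for k in range(len(s)):
            rng = noise.frame_rng(s.starts[k])
            sd = noise.sigma0 * np.sqrt(np.maximum(data[..., k], 0.0) / durs[k])
            data[..., k] += rng.standard_normal(spec.grid_shape) * sd
        meta["noise_sigma0"] = noise.sigma0
        meta["seed"] = noise.seed
    return DynamicImage(data, s, spec.voxel_size_mm, meta)


# ------------------------------------------------------------------ NIfTI I/O
def save_dynamic(img: DynamicImage, path) -> None:
    """Write a 4D NIfTI plus a JSON sidecar with frame timing (seconds)."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([img.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(img.data.astype(np.float32), affine), path)
    sidecar = {
        "FrameStartSeconds": [s * 60.0 for s in img.schedule.starts],
        "FrameEndSeconds": [e * 60.0 for e in img.schedule.ends],
        "ProtocolID": img.schedule.protocol_id,
        "Units": "kBq/ml",
        **{k: v for k, v in img.meta.items()},
    }
    path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1) + "\n")


def load_dynamic(path) -> DynamicImage:
    import nibabel as nib

    path = Path(path)
    ni = nib.load(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    frames = tuple(
        (s / 60.0, e / 60.0)
        for s, e in zip(sidecar["FrameStartSeconds"], sidecar["FrameEndSeconds"]))
    sched = FrameSchedule(frames, sidecar.get("ProtocolID", "standard"))
    meta = {k: v for k, v in sidecar.items()
            if k not in ("FrameStartSeconds", "FrameEndSeconds", "ProtocolID", "Units")}
    vox = float(ni.header.get_zooms()[0])
    return DynamicImage(np.asarray(ni.dataobj, np.float64), sched, vox, meta)
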