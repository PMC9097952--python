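"""Patlak graphical analysis and parametric-map generation.

For an irreversible tracer the transformed coordinates

    x(t) = ∫_0^t Cp dτ / Cp(t),        y(t) = C_t(t) / Cp(t)

become linear once tracer has equilibrated between plasma and the
reversible tissue compartment; the slope is the net influx rate Ki and the
intercept the apparent distribution volume V.  Following the clinical
workflow modelled here, the line is fitted by ordinary least squares to the
last three frames (60–75 min post injection), and

    MR_FDG = Ki × blood glucose   (µmol/min/ml, glucose in mmol/L)
    DV     = 100 × V              (percent)

are emitted as parametric maps, together with an SUV map averaged over the
same three frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acquisition import DynamicImage
from .idif import GapModel, TimeActivityCurve, cumulative_plasma_integral

__all__ = ["PatlakFit", "ParametricMaps", "patlak_points", "fit_line", "make_maps"]


@dataclass(frozen=True)
class PatlakFit:
    """Slope/intercept of the Patlak line plus derived clinical quantities."""

    ki: float                 # 1/min
    v: float                  # unitless
    points: tuple             # ((x, y), ...) as fitted
    glucose: float | None = None

    @property
    def mr_fdg(self) -> float | None:
        return None if self.glucose is None else self.ki * self.glucose

    @property
    def dv_percent(self) -> float:
        return 100.0 * self.v

    @property
    def valid(self) -> bool:
        return np.isfinite(self.ki) and np.isfinite(self.v)


def patlak_points(tissue: TimeActivityCurve,
                  input_tac: TimeActivityCurve,
                  gap: GapModel | None = None,
                  n_frames: int = 3) -> list[tuple[float, float]]:
    """Patlak coordinates for the last ``n_frames`` frames.

    The tissue and input TACs must share those frames; the Patlak time
    variable is the frame midpoint.  Frames where Cp <= 0 yield NaN points
    (flagged invalid downstream).
    """
    ts, te = tissue.frame_start[-n_frames:], tissue.frame_end[-n_frames:]
    if not (np.allclose(ts, input_tac.frame_start[-n_frames:]) and
            np.allclose(te, input_tac.frame_end[-n_frames:])):
        raise ValueError("tissue and input TACs must share the fit frames")
    tmid = (ts + te) / 2
    cp = input_tac.activity[-n_frames:]
    ct = tissue.activity[-n_frames:]
    pts = []
    for k in range(n_frames):
        if cp[k] <= 0:
            pts.append((np.nan, np.nan))
            continue
        xint = cumulative_plasma_integral(input_tac, gap, tmid[k])
        pts.append((xint / cp[k], ct[k] / cp[k]))
    return pts


def fit_line(points) -> PatlakFit:
    """Ordinary least-squares line through the Patlak points."""
    pts = [(x, y) for x, y in points if np.isfinite(x) and np.isfinite(y)]
    if len(pts) < 2:
        return PatlakFit(np.nan, np.nan, tuple(points))
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        return PatlakFit(np.nan, np.nan, tuple(points))
    ki = ((x - xm) * (y - ym)).sum() / sxx
    return PatlakFit(float(ki), float(ym - ki * xm), tuple(points))


@dataclass(frozen=True)
class ParametricMaps:
    """Voxel-wise MR_FDG, DV and SUV maps on the phantom grid."""

    mr_map: np.ndarray        # µmol/min/ml
    dv_map: np.ndarray        # percent
    suv_map: np.ndarray | None
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    @property
    def ki_map(self) -> np.ndarray:
        g = self.provenance.get("glucose_mmol_l")
        return self.mr_map / g


def make_maps(img: DynamicImage, input_tac: TimeActivityCurve,
              glucose: float, gap: GapModel | None = None,
              dose_mbq: float | None = None, weight_kg: float | None = None,
              n_frames: int = 3) -> ParametricMaps:
    """Voxel-wise Patlak fit over the last ``n_frames`` frames.

    The input-function coordinates x_k are common to all voxels, so the OLS
    slope/intercept are computed in closed form over the whole volume at
    once.  Voxels with non-positive plasma activity are NaN.  The SUV map is
    the mean of the last three frames scaled by weight/dose (kBq/ml ×
    kg/MBq, unit tissue density); it is omitted with a warning when dose or
    weight is missing.
    """
    sched = img.schedule
    ts, te = sched.starts[-n_frames:], sched.ends[-n_frames:]
    if not (np.allclose(ts, input_tac.frame_start[-n_frames:]) and
            np.allclose(te, input_tac.frame_end[-n_frames:])):
        raise ValueError("image and input TAC must share the fit frames")
    tmid = (ts + te) / 2
    cp = input_tac.activity[-n_frames:]
    good = cp > 0
    if good.sum() < 2:
        shape = img.data.shape[:3]
        nanmap = np.full(shape, np.nan)
        warnings.warn("plasma activity non-positive on the fit frames; maps are NaN")
        return ParametricMaps(nanmap, nanmap.copy(), None, img.voxel_size_mm,
                              {"protocol_id": sched.protocol_id,
                               "glucose_mmol_l": glucose})
    ts, te, tmid, cp = ts[good], te[good], tmid[good], cp[good]
    x = np.array([cumulative_plasma_integral(input_tac, gap, t) for t in tmid]) / cp

    late = img.data[..., -n_frames:][..., good]
    y = late / cp  # broadcast over the frame axis

    xm = x.mean()
    sxx = ((x - xm) ** 2).sum()
    ym = y.mean(axis=-1)
    ki = ((y * (x - xm)).sum(axis=-1)) / sxx
    v = ym - ki * xm

    mr = ki * glucose
    dv = 100.0 * v

    suv = None
    if dose_mbq is not None and weight_kg is not None:
        suv = np.maximum(late.mean(axis=-1) * weight_kg / dose_mbq, 0.0)
    else:
        warnings.warn("dose/weight not provided; SUV map omitted")

    prov = {"protocol_id": sched.protocol_id, "glucose_mmol_l": glucose,
            "gap_family": None if gap is None else gap.family,
            "n_fit_frames": n_frames, **img.meta}
    return ParametricMaps(mr, dv, suv, img.voxel_size_mm, prov)
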