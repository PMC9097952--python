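"""Image-derived input function (IDIF) handling.

Covers the workflow of extracting an aortic TAC from a dynamic image,
merging the early (0–6 min) and late (60–75 min) acquisitions of the
two-short-dynamic protocol into a single CSV-backed TAC, bridging the
unmeasured 6–60 min interval with a fitted plasma-clearance model, and
computing the cumulative plasma integral ∫Cp dτ that forms the Patlak
x-axis.

Frame values are treated as exact frame averages, so the integral over a
contiguous sampled stretch is the exact sum of value×duration; only
unsampled gaps need the fitted model (or, for short gaps such as the
dead time between the cardiac bed and the whole-body passes, a trapezoid
bridge).
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TimeActivityCurve",
    "GapModel",
    "extract_idif",
    "merge_tacs",
    "split_tac",
    "fit_gap_model",
    "cumulative_plasma_integral",
    "write_tac_csv",
    "read_tac_csv",
]

TAC_CSV_HEADER = "frame_start_s,frame_end_s,activity_kBq_ml"

#: gaps no longer than this (minutes) may be bridged by a trapezoid when no
#: gap model is supplied — covers the dead time between the cardiac bed and
#: the first whole-body pass
SHORT_GAP_MIN = 5.0


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged activity: per-frame (start, end) minutes and kBq/ml."""

    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray
    source: str = "tissue"   # aorta_idif | tissue | merged

    def __post_init__(self):
        fs = np.asarray(self.frame_start, float)
        fe = np.asarray(self.frame_end, float)
        a = np.asarray(self.activity, float)
        object.__setattr__(self, "frame_start", fs)
        object.__setattr__(self, "frame_end", fe)
        object.__setattr__(self, "activity", a)
        if not (fs.shape == fe.shape == a.shape):
            raise ValueError("frame_start, frame_end, activity must align")
        if np.any(fe <= fs):
            raise ValueError("frames must have positive duration")
        if np.any(fs[1:] < fe[:-1] - 1e-9):
            raise ValueError("frames must be sorted and non-overlapping")
        if not np.all(np.isfinite(a)):
            raise ValueError("activities must be finite")

    @property
    def midpoints(self) -> np.ndarray:
        return (self.frame_start + self.frame_end) / 2

    @property
    def durations(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    def __len__(self) -> int:
        return self.frame_start.size

    def restrict(self, t0: float, t1: float) -> "TimeActivityCurve":
        """Frames fully inside [t0, t1]."""
        keep = (self.frame_start >= t0 - 1e-9) & (self.frame_end <= t1 + 1e-9)
        return TimeActivityCurve(self.frame_start[keep], self.frame_end[keep],
                                 self.activity[keep], self.source)


def extract_idif(img, aorta_voi: np.ndarray) -> TimeActivityCurve:
    """Mean TAC over the aorta VOI of a dynamic image.

    ``img`` is a :class:`wbpatlak.acquisition.DynamicImage`; ``aorta_voi`` a
    boolean mask over its 3D grid.
    """
    mask = np.asarray(aorta_voi, bool)
    if mask.shape != img.data.shape[:3]:
        raise ValueError("VOI shape does not match image grid")
    if not mask.any():
        raise ValueError("empty VOI")
    series = img.data[mask].mean(axis=0)
    starts = np.array([s for s, _ in img.schedule.frames])
    ends = np.array([e for _, e in img.schedule.frames])
    return TimeActivityCurve(starts, ends, series, source="aorta_idif")


def merge_tacs(early: TimeActivityCurve, late: TimeActivityCurve) -> TimeActivityCurve:
    """Concatenate the 0–6 min and 60–75 min TACs into one merged curve."""
    if early.frame_end[-1] > late.frame_start[0] + 1e-9:
        raise ValueError("early and late TACs overlap or are unordered")
    return TimeActivityCurve(
        np.concatenate([early.frame_start, late.frame_start]),
        np.concatenate([early.frame_end, late.frame_end]),
        np.concatenate([early.activity, late.activity]),
        source="merged",
    )


def split_tac(tac: TimeActivityCurve, at: float = 6.0):
    """Inverse of :func:`merge_tacs`: frames before/after the cut time."""
    first = tac.frame_end <= at + 1e-9
    a = TimeActivityCurve(tac.frame_start[first], tac.frame_end[first],
                          tac.activity[first], tac.source)
    b = TimeActivityCurve(tac.frame_start[~first], tac.frame_end[~first],
                          tac.activity[~first], tac.source)
    return a, b


# ---------------------------------------------------------------- CSV dialect
def write_tac_csv(tac: TimeActivityCurve, path_or_buf) -> None:
    """Write the merged-TAC CSV dialect (times in seconds, LF, '.' decimal).

    Floats are written with ``repr`` so a write→read round trip is bit-exact.
    """
    lines = [TAC_CSV_HEADER]
    for s, e, a in zip(tac.frame_start, tac.frame_end, tac.activity):
        lines.append(f"{float(s) * 60.0!r},{float(e) * 60.0!r},{float(a)!r}")
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)


def read_tac_csv(path_or_buf, source: str = "merged") -> TimeActivityCurve:
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf, encoding="utf-8") as fh:
            text = fh.read()
    lines = [ln for ln in text.split("\n") if ln.strip()]
    if lines[0].strip() != TAC_CSV_HEADER:
        raise ValueError(f"unexpected TAC CSV header: {lines[0]!r}")
    rows = [tuple(float(x) for x in ln.split(",")) for ln in lines[1:]]
    arr = np.array(rows, float)
    return TimeActivityCurve(arr[:, 0] / 60.0, arr[:, 1] / 60.0, arr[:, 2], source)


# ----------------------------------------------------------------- gap model
@dataclass(frozen=True)
class GapModel:
    """Plasma-clearance model bridging the unsampled 6–60 min interval.

    families: ``tri_exponential`` (sum of positive decaying exponentials
    fitted to all post-peak samples — the default; FDG plasma clearance is
    classically multi-exponential), ``input_model_refit`` (refit of the
    Feng-type input model to all samples, appropriate when the measured
    curve carries a Feng-shaped peak), ``loglinear_bridge`` (single
    exponential through the gap endpoints).
    """

    family: str
    amplitudes: np.ndarray
    rates: np.ndarray          # positive decay rates (1/min)
    residual_norm: float = 0.0
    t_ref: float = 0.0         # model time origin (min)
    feng_coefficients: dict | None = None   # input_model_refit only

    def _refit_input(self):
        from .kinetics import InputFunction
        return InputFunction("feng4", self.feng_coefficients, self.t_ref)

    def curve(self, t):
        if self.family == "input_model_refit":
            out = np.maximum(self._refit_input().evaluate(t), 0.0)
            return out if np.ndim(out) else float(out)
        u = np.asarray(t, float) - self.t_ref
        out = np.zeros_like(u)
        for a, r in zip(self.amplitudes, self.rates):
            out = out + a * np.exp(-r * u)
        out = np.maximum(out, 0.0)
        return out if out.ndim else float(out)

    def integral(self, t0: float, t1: float) -> float:
        """Exact ``∫_{t0}^{t1}`` of the fitted curve."""
        if self.family == "input_model_refit":
            f = self._refit_input()
            return float(f.integral(t1) - f.integral(t0))
        u0, u1 = t0 - self.t_ref, t1 - self.t_ref
        total = 0.0
        for a, r in zip(self.amplitudes, self.rates):
            if r > 1e-12:
                total += a / r * (np.exp(-r * u0) - np.exp(-r * u1))
            else:
                total += a * (u1 - u0)
        return float(total)

    def to_json(self) -> str:
        return json.dumps({
            "family": self.family,
            "amplitudes": list(map(float, self.amplitudes)),
            "rates": list(map(float, self.rates)),
            "residual_norm": float(self.residual_norm),
            "t_ref": float(self.t_ref),
            "feng_coefficients": self.feng_coefficients,
        })

    @classmethod
    def from_json(cls, text: str) -> "GapModel":
        d = json.loads(text)
        return cls(d["family"], np.array(d["amplitudes"]), np.array(d["rates"]),
                   d["residual_norm"], d["t_ref"], d.get("feng_coefficients"))


class GapFitError(RuntimeError):
    """Gap-model fit did not converge; carries diagnostics."""


def _fit_exponentials(t: np.ndarray, y: np.ndarray, n_exp: int,
                      weights: np.ndarray | None = None):
    """Fit sum_i a_i exp(-r_i t) with a_i >= 0, r_i > 0 by variable projection.

    For fixed rates the amplitudes are a non-negative linear least-squares
    problem (solved by NNLS); only the log-rates are optimized, from a grid
    of log-spaced starting tuples.  This is far more robust on the
    two-window (early + late) sampling design than a joint fit.
    """
    from itertools import product

    from scipy.optimize import nnls

    w = np.ones_like(y) if weights is None else weights

    def amplitudes_for(logr):
        design = np.exp(-np.outer(t, np.exp(logr)))
        a, _ = nnls(design * w[:, None], y * w)
        return a, design

    def resid(logr):
        a, design = amplitudes_for(logr)
        return (design @ a - y) * w

    tiers = ([1.0, 2.0, 4.0], [0.08, 0.15], [0.008, 0.015])
    starts = [np.log(r0) for r0 in product(*tiers[:n_exp])]
    best = None
    for r0 in starts:
        try:
            sol = least_squares(resid, np.asarray(r0), method="trf",
                                x_scale="jac", max_nfev=3000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise GapFitError("exponential fit failed for all starts")
    a, _ = amplitudes_for(best.x)
    r = np.exp(best.x)
    keep = a > 0
    a, r = a[keep], r[keep]
    if a.size == 0:
        raise GapFitError("exponential fit degenerated to zero amplitudes")
    order = np.argsort(-r)
    return a[order], r[order], float(np.sqrt(2 * best.cost))


def _fit_feng(t: np.ndarray, y: np.ndarray):
    """Refit the Feng-type input model (including its delay) to a full TAC."""
    ymax = float(np.max(y))
    ipk = int(np.argmax(y))
    t0_init = max(float(t[ipk]) - 0.3, 0.0)

    def model(theta, tt):
        a1, a2, a3 = np.exp(theta[:3])
        l1, l2, l3 = -np.exp(theta[3:6])
        t0 = theta[6]
        u = np.maximum(tt - t0, 0.0)
        vals = ((a1 * u - a2 - a3) * np.exp(l1 * u)
                + a2 * np.exp(l2 * u) + a3 * np.exp(l3 * u))
        return np.where(tt >= t0, vals, 0.0)

    def resid(theta):
        return model(theta, t) - y

    scale = ymax / 100.0
    best = None
    for fast in (2.0, 4.0, 6.0):
        theta0 = np.concatenate([
            np.log(np.array([500.0, 30.0, 15.0]) * max(scale, 1e-6)),
            np.log([fast, 0.1, 0.01]), [t0_init]])
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise GapFitError("input-model refit failed")
    a1, a2, a3 = np.exp(best.x[:3])
    l1, l2, l3 = -np.exp(best.x[3:6])
    coeffs = {"A1": float(a1), "A2": float(a2), "A3": float(a3),
              "l1": float(l1), "l2": float(l2), "l3": float(l3)}
    return coeffs, float(best.x[6]), float(np.sqrt(2 * best.cost))


def fit_gap_model(tac: TimeActivityCurve, family: str = "tri_exponential",
                  settle_min: float = 1.0) -> GapModel:
    """Fit a clearance model to the post-peak samples of a (merged) TAC.

    The fit uses frame midpoints; samples at or before the activity peak are
    left untouched (they are measured data, not clearance).  For the
    tri-exponential family, samples within ``settle_min`` minutes after the
    peak are additionally excluded: immediately post peak the bolus is still
    dispersing and the curve is not yet in its multi-exponential clearance
    regime, which would otherwise distort the extrapolated tail.  Samples
    are weighted by sqrt(duration/activity), the inverse-variance weight of
    the frame-duration noise model.
    """
    t = tac.midpoints
    y = tac.activity
    ipk = int(np.argmax(y))
    tpost, ypost = t[ipk:], np.maximum(y[ipk:], 0.0)
    if tpost.size < 3:
        raise GapFitError("need at least 3 post-peak samples")

    if family == "tri_exponential":
        sel = tpost >= tpost[0] + settle_min
        if sel.sum() < 6:        # short curves: fall back to all post-peak
            sel = np.ones_like(sel, bool)
        tsel, ysel = tpost[sel], ypost[sel]
        t_ref = float(tsel[0])
        # drop to fewer exponentials for nearly-flat data
        spread = ysel.max() - ysel.min()
        n_exp = 3 if spread > 1e-9 * max(ysel.max(), 1.0) else 1
        n_exp = min(n_exp, max(1, tsel.size - 1))
        durs = tac.durations[ipk:][sel]
        w = np.sqrt(durs / np.maximum(ysel, 0.01 * ysel.max()))
        a, r, rn = _fit_exponentials(tsel - t_ref, ysel, n_exp, w)
        model = GapModel(family, a, r, rn, t_ref)
    elif family == "input_model_refit":
        coeffs, t0, rn = _fit_feng(t, np.maximum(y, 0.0))
        model = GapModel(family, np.array([]), np.array([]), rn, t0, coeffs)
    elif family == "loglinear_bridge":
        # single exponential through the last early and first late sample
        pre = ypost[tpost <= 6.0 + 1e-9]
        t_pre = tpost[tpost <= 6.0 + 1e-9]
        post = ypost[tpost >= 6.0]
        t_post = tpost[tpost >= 6.0]
        if pre.size == 0 or post.size == 0:
            raise GapFitError("loglinear bridge needs samples on both sides")
        y0, y1 = max(pre[-1], 1e-12), max(post[0], 1e-12)
        r = np.log(y0 / y1) / (t_post[0] - t_pre[-1])
        a = y0 * np.exp(r * (t_pre[-1] - t_ref))
        model = GapModel(family, np.array([a]), np.array([r]), 0.0, t_ref)
    else:
        raise ValueError(f"unknown gap family {family!r}")

    if np.any(model.curve(np.linspace(0, 75, 76)) < -1e-9):
        warnings.warn("gap model produced negative values; clamped at 0")
    return model


# --------------------------------------------------- cumulative plasma integral
def cumulative_plasma_integral(tac: TimeActivityCurve, gap: GapModel | None,
                               t: float) -> float:
    """``∫_0^t Cp dτ`` from a frame-sampled TAC, bridging unsampled gaps.

    Sampled stretches contribute exactly (frame average × duration); a gap
    between frames is integrated with the fitted model when given, with a
    trapezoid of the flanking frame values when the gap is short, and raises
    otherwise.  A partial first frame rises linearly from 0 at t=0.
    """
    if t < -1e-12:
        raise ValueError("t must be non-negative")
    fs, fe, act = tac.frame_start, tac.frame_end, np.maximum(tac.activity, 0.0)
    total = 0.0
    prev_end = 0.0
    prev_val = 0.0
    for i in range(len(tac)):
        # unsampled stretch before frame i (dead time / the 6-60 min gap)
        if fs[i] > prev_end + 1e-9 and t > prev_end + 1e-12:
            g0, g1 = prev_end, min(fs[i], t)
            if gap is not None:
                total += gap.integral(g0, g1)
            elif fs[i] - prev_end <= SHORT_GAP_MIN + 1e-9:
                # trapezoid between the flanking frame values
                v0, v1 = prev_val, act[i]
                frac = (g1 - g0) / (fs[i] - prev_end)
                vm = v0 + (v1 - v0) * frac
                total += (g1 - g0) * (v0 + vm) / 2
            else:
                raise ValueError("t spans an unsampled gap and no gap model given")
        if t <= fs[i] + 1e-12:
            return float(total)
        # frame i contributes its exact average over the covered part
        total += act[i] * (min(t, fe[i]) - fs[i])
        prev_end, prev_val = fe[i], act[i]
        if t <= fe[i] + 1e-12:
            return float(total)
    if t > prev_end + 1e-9:
        if gap is not None:
            total += gap.integral(prev_end, t)
        else:
            raise ValueError("t beyond sampled range and no gap model given")
    return float(total)
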