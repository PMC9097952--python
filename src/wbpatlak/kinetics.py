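"""Continuous-time forward model for irreversible FDG kinetics.

The arterial plasma input Cp(t) is modelled by an exponential-family curve
(a Feng-type four-parameter-pair model by default) and tissue activity by the
irreversible two-tissue-compartment (2TC) model

    dC1/dt = K1*Cp - (k2+k3)*C1,     dC2/dt = k3*C1,
    C_t(t) = C1 + C2 + vb*Cp(t),

whose Patlak macro-parameters are the net influx rate Ki = K1*k3/(k2+k3)
(slope) and the apparent distribution volume V = vb + K1*k2/(k2+k3)**2
(intercept).  For exponential-family inputs everything — tissue curves,
cumulative plasma integrals, frame averages — is evaluated in closed form
through :mod:`wbpatlak.expsum`.

Units: time in minutes, activity in kBq/ml, rate constants in 1/min
(K1 in ml/min/ml).  All activities are decay-corrected to injection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .expsum import ExpSum

__all__ = [
    "InputFunction",
    "KineticParams",
    "TissueCurve",
    "feng4_default",
    "evaluate_input",
    "integrate_input",
    "tissue_curve",
    "patlak_asymptote",
]

#: Feng-type defaults: Cp(u) = (A1*u - A2 - A3)*e^{l1*u} + A2*e^{l2*u} + A3*e^{l3*u}
#: with u = t - t_peak_offset.  Amplitudes in kBq/ml (A1 in kBq/ml/min), rates 1/min.
#: Magnitudes give an aortic peak near 75 kBq/ml and a 60-min tail near 10 kBq/ml,
#: typical of a ~300 MBq FDG injection.
FENG4_DEFAULT_COEFFS = {
    "A1": 851.1,
    "A2": 21.88,
    "A3": 20.81,
    "l1": -4.1339,
    "l2": -0.1191,
    "l3": -0.0104,
}


class ConfigurationError(ValueError):
    """Unknown model identifier or malformed coefficient set."""


@dataclass(frozen=True)
class InputFunction:
    """Arterial plasma input curve Cp(t).

    model_id is one of ``feng4`` (Feng-type, Cp(0)=0, sharp early peak),
    ``tri_exponential`` (sum of decaying exponentials), or ``tabulated``
    (sampled curve, linearly interpolated).  ``t_peak_offset`` delays the
    whole analytic curve: Cp(t) = 0 for t < t_peak_offset.
    """

    model_id: str = "feng4"
    coefficients: dict = field(default_factory=lambda: dict(FENG4_DEFAULT_COEFFS))
    t_peak_offset: float = 0.5
    times: np.ndarray | None = None     # tabulated only
    values: np.ndarray | None = None    # tabulated only

    def __post_init__(self):
        if self.model_id not in ("feng4", "tri_exponential", "tabulated"):
            raise ConfigurationError(f"unknown input model {self.model_id!r}")
        if self.model_id == "tabulated":
            if self.times is None or self.values is None:
                raise ConfigurationError("tabulated input requires times and values")
            t = np.asarray(self.times, float)
            if np.any(np.diff(t) <= 0):
                raise ConfigurationError("tabulated times must be strictly increasing")

    # --------------------------------------------------------------- analytics
    def expsum(self) -> ExpSum:
        """Closed-form representation in shifted time u = t - t_peak_offset."""
        c = self.coefficients
        if self.model_id == "feng4":
            return ExpSum({
                (1, c["l1"]): c["A1"],
                (0, c["l1"]): -(c["A2"] + c["A3"]),
                (0, c["l2"]): c["A2"],
                (0, c["l3"]): c["A3"],
            })
        if self.model_id == "tri_exponential":
            amps = c["amplitudes"]
            rates = c["rates"]
            if len(amps) != len(rates):
                raise ConfigurationError("amplitudes and rates must have equal length")
            terms = {}
            for a, r in zip(amps, rates):
                terms[(0, float(r))] = terms.get((0, float(r)), 0.0) + float(a)
            return ExpSum(terms)
        raise ConfigurationError("tabulated input has no closed form")

    @property
    def is_analytic(self) -> bool:
        return self.model_id != "tabulated"

    # --------------------------------------------------------------- interface
    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        if self.model_id == "tabulated":
            tt = np.asarray(self.times, float)
            vv = np.asarray(self.values, float)
            out = np.interp(t, tt, vv, left=0.0, right=float(vv[-1]))
            return out if out.ndim else float(out)
        u = t - self.t_peak_offset
        out = np.where(u >= 0, self.expsum()(np.maximum(u, 0.0)), 0.0)
        return out if out.ndim else float(out)

    def integral(self, t):
        """Exact cumulative integral ``∫_0^t Cp dτ`` (kBq·min/ml)."""
        t = np.asarray(t, dtype=float)
        if self.model_id == "tabulated":
            tt = np.asarray(self.times, float)
            vv = np.asarray(self.values, float)
            if np.any(t > tt[-1] + 1e-9):
                raise ValueError("tabulated input does not cover requested time")
            cum = np.concatenate([[0.0], np.cumsum(np.diff(tt) * (vv[:-1] + vv[1:]) / 2)])
            out = np.interp(t, tt, cum)
            return out if out.ndim else float(out)
        anti = self.expsum().antiderivative()
        u = np.maximum(t - self.t_peak_offset, 0.0)
        out = anti(u)
        return out if np.ndim(out) else float(out)


def feng4_default(t_peak_offset: float = 0.5, scale: float = 1.0) -> InputFunction:
    """The default Feng-type arterial input, optionally amplitude-scaled."""
    coeffs = dict(FENG4_DEFAULT_COEFFS)
    for key in ("A1", "A2", "A3"):
        coeffs[key] *= scale
    return InputFunction("feng4", coeffs, t_peak_offset)


@dataclass(frozen=True)
class KineticParams:
    """Micro-parameters of the irreversible 2TC model.

    K1 (ml/min/ml), k2 and k3 (1/min), vb (blood volume fraction in [0,1)).
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.05

    def __post_init__(self):
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0 <= self.vb < 1):
            raise ValueError("vb must lie in [0, 1)")
        if self.k2 + self.k3 <= 0:
            raise ValueError("k2 + k3 must be positive")

    @property
    def ki_true(self) -> float:
        return self.K1 * self.k3 / (self.k2 + self.k3)

    @property
    def v_true(self) -> float:
        return self.vb + self.K1 * self.k2 / (self.k2 + self.k3) ** 2

    @classmethod
    def from_macro(cls, ki: float, v: float, vb: float = 0.05,
                   beta: float = 0.2) -> "KineticParams":
        """Invert (Ki, V) to micro-parameters for a chosen efflux scale.

        ``beta = k2 + k3`` sets the equilibration rate.  Requires
        ``v >= vb`` and ``ki >= 0``; the construction gives
        K1 = ki + (v - vb)*beta, k3 = ki*beta/K1, k2 = beta - k3.
        """
        if v < vb:
            raise ValueError("target V must be at least vb")
        K1 = ki + (v - vb) * beta
        if K1 <= 0:
            raise ValueError("degenerate macro targets (K1 would be <= 0)")
        k3 = ki * beta / K1
        return cls(K1=K1, k2=beta - k3, k3=k3, vb=vb)


@dataclass(frozen=True)
class TissueCurve:
    """Tissue activity C_t(t) induced by (KineticParams, InputFunction)."""

    params: KineticParams
    input_function: InputFunction
    _expsum: ExpSum | None = None   # closed form in shifted time, if analytic

    def evaluate(self, t):
        t = np.asarray(t, dtype=float)
        if self._expsum is not None:
            u = t - self.input_function.t_peak_offset
            out = np.where(u >= 0, self._expsum(np.maximum(u, 0.0)), 0.0)
            return out if out.ndim else float(out)
        return self._numeric(t)

    def integral(self, t):
        """Exact ``∫_0^t C_t dτ`` for analytic inputs."""
        if self._expsum is None:
            raise NotImplementedError("integral requires an analytic input")
        anti = self._expsum.antiderivative()
        u = np.maximum(np.asarray(t, float) - self.input_function.t_peak_offset, 0.0)
        out = anti(u)
        return out if np.ndim(out) else float(out)

    def _numeric(self, t):
        # fine-grid convolution fallback for tabulated inputs
        p, f = self.params, self.input_function
        beta = p.k2 + p.k3
        grid = np.arange(0.0, float(np.max(t)) + 0.005, 0.005)
        cp = f.evaluate(grid)
        icp = np.concatenate([[0.0], np.cumsum(np.diff(grid) * (cp[:-1] + cp[1:]) / 2)])
        kern = np.exp(-beta * grid)
        conv = np.convolve(cp, kern)[: grid.size] * 0.005
        ct = p.ki_true * icp + p.K1 * p.k2 / beta * conv + p.vb * cp
        out = np.interp(np.asarray(t, float), grid, ct)
        return out if out.ndim else float(out)


def evaluate_input(f: InputFunction, t) -> np.ndarray:
    """Evaluate Cp on a non-negative, sorted time grid (kBq/ml)."""
    t = np.asarray(t, dtype=float)
    if t.size and (np.any(t < 0) or np.any(np.diff(t) < 0)):
        raise ValueError("time grid must be non-negative and sorted")
    return np.asarray(f.evaluate(t))


def integrate_input(f: InputFunction, t):
    """Exact cumulative plasma integral ``∫_0^t Cp dτ`` (kBq·min/ml)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be non-negative")
    return f.integral(t)


def tissue_curve(p: KineticParams, f: InputFunction) -> TissueCurve:
    """Closed-form irreversible 2TC solution driven by the input f.

    C_t = Ki*∫Cp + (K1*k2/β)*(Cp ⊛ e^{-βt}) + vb*Cp  with β = k2+k3;
    the blood signal rides on top of the per-voxel tissue solution, so the
    asymptotic Patlak slope of C_t/Cp is exactly Ki = K1*k3/β and the
    asymptotic intercept approaches V = vb + K1*k2/β² (for a slowly varying
    input).
    """
    beta = p.k2 + p.k3
    if not f.is_analytic:
        return TissueCurve(p, f, None)
    cp = f.expsum()
    icp = cp.antiderivative()
    conv = cp.convolve_exp(beta)
    es = p.ki_true * icp + (p.K1 * p.k2 / beta) * conv + p.vb * cp
    return TissueCurve(p, f, es)


def patlak_asymptote(p: KineticParams) -> tuple[float, float]:
    """Ground-truth Patlak slope Ki and intercept V for the 2TC parameters."""
    return p.ki_true, p.v_true
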