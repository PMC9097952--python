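"""Closed-form algebra for sums of ``c * t**n * exp(lam*t)`` terms.

Arterial input models of the exponential family (Feng-type, multi-exponential)
and the irreversible two-tissue-compartment solution they induce all live in
this function class, which is closed under addition, scalar multiplication,
multiplication by ``exp(mu*t)``, antidifferentiation, and convolution with a
decaying exponential.  That closure is what makes exact tissue curves, exact
cumulative plasma integrals and exact frame averages possible without any
numerical quadrature.
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

import numpy as np

# rates closer to zero than this are treated as exactly zero (polynomial term)
_LAM_TOL = 1e-12

Term = Tuple[int, float]  # (power n, rate lam)


class ExpSum:
    """A finite sum ``f(t) = sum_k c_k * t**n_k * exp(lam_k * t)``.

    Terms are stored as a dict ``{(n, lam): c}``.  ``lam == 0.0`` encodes a
    pure polynomial term.
    """

    __slots__ = ("terms",)

    def __init__(self, terms: Dict[Term, float] | None = None):
        self.terms: Dict[Term, float] = {}
        if terms:
            for (n, lam), c in terms.items():
                if c != 0.0:
                    self._accumulate(int(n), float(lam), float(c))

    def _accumulate(self, n: int, lam: float, c: float) -> None:
        if abs(lam) < _LAM_TOL:
            lam = 0.0
        key = (n, lam)
        new = self.terms.get(key, 0.0) + c
        if new == 0.0:
            self.terms.pop(key, None)
        else:
            self.terms[key] = new

    # ------------------------------------------------------------------ algebra
    def __add__(self, other: "ExpSum") -> "ExpSum":
        out = ExpSum()
        for (n, lam), c in self.terms.items():
            out._accumulate(n, lam, c)
        for (n, lam), c in other.terms.items():
            out._accumulate(n, lam, c)
        return out

    def __mul__(self, scalar: float) -> "ExpSum":
        out = ExpSum()
        for (n, lam), c in self.terms.items():
            out._accumulate(n, lam, c * scalar)
        return out

    __rmul__ = __mul__

    def __sub__(self, other: "ExpSum") -> "ExpSum":
        return self + (other * -1.0)

    def shift_exp(self, mu: float) -> "ExpSum":
        """Return ``f(t) * exp(mu*t)``."""
        out = ExpSum()
        for (n, lam), c in self.terms.items():
            out._accumulate(n, lam + mu, c)
        return out

    # --------------------------------------------------------------- evaluation
    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for (n, lam), c in self.terms.items():
            term = np.full_like(t, c)
            if n:
                term = term * t**n
            if lam != 0.0:
                term = term * np.exp(lam * t)
            out = out + term
        return out if out.ndim else float(out)

    def value_at_zero(self) -> float:
        return sum(c for (n, lam), c in self.terms.items() if n == 0)

    # ----------------------------------------------------------------- calculus
    def antiderivative(self) -> "ExpSum":
        """The antiderivative F with F(0) = 0 (i.e. ``F(t) = ∫_0^t f``)."""
        out = ExpSum()
        for (n, lam), c in self.terms.items():
            if lam == 0.0:
                out._accumulate(n + 1, 0.0, c / (n + 1))
            else:
                # ∫ t^n e^{lam t} dt by the reduction
                #   I_n = t^n e^{lam t}/lam - (n/lam) I_{n-1}
                coef = c
                k = n
                while k > 0:
                    out._accumulate(k, lam, coef / lam)
                    coef = -coef * k / lam
                    k -= 1
                out._accumulate(0, lam, coef / lam)
        # anchor at zero
        f0 = out.value_at_zero()
        if f0 != 0.0:
            out._accumulate(0, 0.0, -f0)
        return out

    def definite_integral(self, t):
        return self.antiderivative()(t)

    def convolve_exp(self, beta: float) -> "ExpSum":
        """Return ``(f ⊛ e^{-beta t})(t) = ∫_0^t e^{-beta (t-s)} f(s) ds``."""
        return self.shift_exp(beta).antiderivative().shift_exp(-beta)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        parts = [f"{c:g}*t^{n}*e^({lam:g}t)" for (n, lam), c in sorted(self.terms.items())]
        return "ExpSum(" + " + ".join(parts or ["0"]) + ")"


def expsum_constant(c: float) -> ExpSum:
    return ExpSum({(0, 0.0): c})


def expsum_exponential(amplitude: float, rate: float) -> ExpSum:
    """``amplitude * exp(rate * t)`` (pass a negative rate for decay)."""
    return ExpSum({(0, rate): amplitude})


def expsum_t_exponential(amplitude: float, rate: float) -> ExpSum:
    """``amplitude * t * exp(rate * t)``."""
    return ExpSum({(1, rate): amplitude})
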