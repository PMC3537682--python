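"""Parametric spatial signal families evaluated on a periodic domain.

The signal S(theta) is the upstream input of every motif. Four parametric
families cover the shapes used throughout: a cosine gradient a + b*cos(theta),
a sine gradient a + b*sin(theta), a localized Gaussian bump
a + A*exp(-(d(theta,theta0)/alpha)^2) with the periodic distance d, and a
square pulse equal to a + A on [theta1, theta2) and a outside. A tabulated
custom profile is interpolated periodically onto the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .domain import SpatialDomain, periodic_interp
from .errors import SignalValidityError

FORMS = ("cosine_gradient", "sine_gradient", "localized_bump", "square_pulse", "custom")


@dataclass(frozen=True)
class SignalProfile:
    """Specification of a spatial signal S(theta).

    Parameters
    ----------
    form : str
        One of cosine_gradient | sine_gradient | localized_bump |
        square_pulse | custom.
    a : float
        Baseline level (>= 0).
    b : float
        Gradient amplitude (cosine/sine forms); requires |b| <= a.
    A : float
        Bump/pulse amplitude above baseline.
    theta0, alpha : float
        Bump center and width scale (alpha > 0).
    theta1, theta2 : float
        Square-pulse interval, left-closed / right-open.
    table : (theta, value) arrays
        Tabulated custom profile.
    """

    form: str
    a: float = 0.0
    b: float = 0.0
    A: float = 0.0
    theta0: float = 0.0
    alpha: float = 1.0
    theta1: float = 0.0
    theta2: float = 0.0
    table: Optional[Sequence] = None

    def __post_init__(self):
        if self.form not in FORMS:
            raise SignalValidityError(
                f"unknown signal form {self.form!r}; expected one of {FORMS}"
            )
        if self.a < 0:
            raise SignalValidityError(f"baseline a must be >= 0, got {self.a}")
        if self.form in ("cosine_gradient", "sine_gradient") and abs(self.b) > self.a:
            raise SignalValidityError(
                f"gradient requires |b| <= a to keep the signal non-negative "
                f"(a={self.a}, b={self.b})"
            )
        if self.form == "localized_bump" and not self.alpha > 0:
            raise SignalValidityError(f"bump width alpha must be > 0, got {self.alpha}")
        if self.form == "custom" and self.table is None:
            raise SignalValidityError("custom signal requires a (theta, value) table")


def _periodic_distance(theta, theta0, length):
    d = np.abs((theta - theta0) % length)
    return np.minimum(d, length - d)


def make_signal(spec: SignalProfile, domain: SpatialDomain) -> np.ndarray:
    """Evaluate a signal specification on the nodes of a domain.

    Raises
    ------
    SignalValidityError
        If any node value would be negative.
    """
    th = domain.theta
    if spec.form == "cosine_gradient":
        values = spec.a + spec.b * np.cos(th)
    elif spec.form == "sine_gradient":
        values = spec.a + spec.b * np.sin(th)
    elif spec.form == "localized_bump":
        d = _periodic_distance(th, spec.theta0, domain.length)
        values = spec.a + spec.A * np.exp(-((d / spec.alpha) ** 2))
    elif spec.form == "square_pulse":
        t1 = spec.theta1 % domain.length
        t2 = spec.theta2 % domain.length
        if t1 <= t2:
            inside = (th >= t1) & (th < t2)
        else:  # pulse wraps around the origin
            inside = (th >= t1) | (th < t2)
        values = np.where(inside, spec.a + spec.A, spec.a)
    elif spec.form == "custom":
        t_tab, v_tab = np.asarray(spec.table[0]), np.asarray(spec.table[1])
        values = periodic_interp(th, t_tab, v_tab, domain.length)
    else:  # pragma: no cover - guarded in __post_init__
        raise SignalValidityError(f"unknown form {spec.form!r}")
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise SignalValidityError(
            f"signal {spec.form!r} takes negative values (min {values.min():.3g})"
        )
    return values
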