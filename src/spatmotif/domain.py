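"""Uniform periodic 1-D grid, discrete Laplacian and spatial averaging.

The spatial coordinate theta lives on the half-open interval [0, length) with
the two ends identified (the domain is a circle, default circumference 2*pi).
All fields are sampled at the n_points uniformly spaced nodes
theta_i = i * length / n_points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError, SizingError

TWO_PI = 2.0 * np.pi

#: Minimum node count for which the 3-point periodic Laplacian stencil is
#: meaningfully resolved.
MIN_POINTS = 8


@dataclass(frozen=True)
class SpatialDomain:
    """A uniform periodic grid on [0, length).

    Attributes
    ----------
    n_points : int
        Number of grid nodes (>= 8).
    length : float
        Domain circumference; dimensionless, default 2*pi.
    """

    n_points: int
    length: float = TWO_PI
    theta: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if int(self.n_points) != self.n_points or self.n_points < MIN_POINTS:
            raise SizingError(
                f"n_points must be an integer >= {MIN_POINTS}, got {self.n_points!r}"
            )
        if not self.length > 0:
            raise SizingError(f"length must be positive, got {self.length!r}")
        object.__setattr__(self, "n_points", int(self.n_points))
        object.__setattr__(self, "length", float(self.length))
        theta = np.arange(self.n_points) * (self.length / self.n_points)
        theta.setflags(write=False)
        object.__setattr__(self, "theta", theta)

    @property
    def spacing(self) -> float:
        """Node spacing h = length / n_points."""
        return self.length / self.n_points

    def check_field(self, field_values) -> np.ndarray:
        """Validate a per-node field against this grid and return it as an array."""
        arr = np.asarray(field_values, dtype=float)
        if arr.ndim != 1 or arr.shape[0] != self.n_points:
            raise ShapeError(
                f"field of shape {arr.shape} does not match domain with "
                f"{self.n_points} nodes"
            )
        return arr

    def doubled(self) -> "SpatialDomain":
        """The same circle discretized at twice the resolution."""
        return SpatialDomain(2 * self.n_points, self.length)


def build_domain(n_points: int, length: float = TWO_PI) -> SpatialDomain:
    """Build a uniform periodic grid with theta_i = i*length/n_points."""
    return SpatialDomain(n_points, length)


def periodic_laplacian(field_values, domain: SpatialDomain) -> np.ndarray:
    """Second-order central-difference Laplacian with periodic wrap-around.

    (f_{i-1} - 2 f_i + f_{i+1}) / h**2, exact annihilation of constants.
    """
    f = domain.check_field(field_values)
    h2 = domain.spacing ** 2
    return (np.roll(f, 1) - 2.0 * f + np.roll(f, -1)) / h2


def spatial_average(field_values, domain: SpatialDomain) -> float:
    """Spatial mean <f> = (1/L) * integral of f over the circle.

    On a uniform periodic grid the trapezoid rule reduces to the plain node
    mean, which is exact for trigonometric modes below the Nyquist frequency.
    """
    f = domain.check_field(field_values)
    if f.size == 0:
        raise ShapeError("cannot average an empty field")
    return float(np.mean(f))


def periodic_interp(theta_new, theta_old, values, length: float = TWO_PI) -> np.ndarray:
    """Periodic linear interpolation of (theta_old, values) onto theta_new."""
    theta_old = np.asarray(theta_old, dtype=float) % length
    values = np.asarray(values, dtype=float)
    order = np.argsort(theta_old)
    to, vo = theta_old[order], values[order]
    # pad one period on each side so np.interp sees the wrap-around
    tp = np.concatenate([to[-1:] - length, to, to[:1] + length])
    vp = np.concatenate([vo[-1:], vo, vo[:1]])
    return np.interp(np.asarray(theta_new, dtype=float) % length, tp, vp)
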