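"""Single-node dynamics: vector field, bifurcation structure and potential.

Each node obeys the complex normal form

    dz/dt = f(z) = (lambda - 1 + i*omega) z + 2 z |z|^2 - z |z|^4,

a subcritical Hopf normal form with a quintic saturation term.  For
0 < lambda < 1 the origin (rest state) coexists with a stable limit cycle
(oscillatory state); the two basins are separated by an unstable limit
cycle.  In modulus the drift is the gradient of a scalar potential, which
is what makes the escape problem analytically tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "NodeParameters",
    "BifurcationSummary",
    "drift",
    "radial_drift",
    "limit_cycle_radii",
    "potential",
]


@dataclass(frozen=True)
class NodeParameters:
    """Parameters of a single bistable node.

    Attributes
    ----------
    lambda_ :
        Excitability (dimensionless).  The rest state at the origin is
        linearly stable for ``lambda_ < 1``; bistability requires
        ``0 < lambda_ < 1``.
    omega :
        Angular frequency of the limit cycle, rad per model-second.  A
        value of 20 rad/s gives the ~3 Hz oscillation characteristic of
        spike-and-wave discharges.
    alpha :
        Noise amplitude (per sqrt model-second), the scale of the
        independent complex Wiener increments driving each node.
    """

    lambda_: float
    omega: float = 20.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not math.isfinite(self.lambda_):
            raise ValueError(f"lambda_ must be finite, got {self.lambda_}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class BifurcationSummary:
    """Attractor structure of the single node at a given excitability.

    ``regime`` is one of ``monostable_rest`` (lambda <= 0),
    ``bistable`` (0 < lambda < 1) and ``monostable_oscillation``
    (lambda >= 1).  ``r_stable_sq``/``r_unstable_sq`` are the squared
    moduli of the stable and unstable limit cycles where these exist
    (``None`` otherwise).
    """

    regime: str
    r_stable_sq: float | None
    r_unstable_sq: float | None


def drift(z: complex | np.ndarray, p: NodeParameters) -> complex | np.ndarray:
    """Deterministic vector field f(z) of a single node.

    Returns ``(lambda - 1 + i*omega) z + 2 z |z|^2 - z |z|^4``.  Accepts
    scalars or arrays of complex states.
    """
    z = np.asarray(z, dtype=complex) if not np.isscalar(z) else z
    r2 = np.abs(z) ** 2
    return (p.lambda_ - 1 + 1j * p.omega) * z + 2 * z * r2 - z * r2**2


def radial_drift(r: float | np.ndarray, lambda_: float) -> float | np.ndarray:
    """Radial component of the drift, ``(lambda-1) r + 2 r^3 - r^5``.

    The modulus of a noise-free trajectory obeys ``dr/dt = radial_drift``;
    the rotational part of the field moves only the phase.
    """
    r = np.asarray(r, dtype=float) if not np.isscalar(r) else r
    return (lambda_ - 1) * r + 2 * r**3 - r**5


def limit_cycle_radii(lambda_: float) -> BifurcationSummary:
    """Squared limit-cycle radii and regime at a given excitability.

    The nonzero roots of the radial drift satisfy the quartic
    ``r^4 - 2 r^2 + (1 - lambda) = 0``, giving squared radii
    ``1 +/- sqrt(lambda)``.  (Note: the radii follow from the drift; the
    commonly quoted shorthand ``1 +/- lambda`` is not a root of the
    quartic and is inconsistent with the potential barrier formula --
    see README.)  The unstable cycle shrinks onto the origin at the
    subcritical Hopf point ``lambda = 1`` and the two cycles annihilate
    in a limit point at ``lambda = 0``, ``|z| = 1``.
    """
    if lambda_ < 0:
        return BifurcationSummary("monostable_rest", None, None)
    s = math.sqrt(lambda_)
    r_stable_sq = 1 + s
    r_unstable_sq = 1 - s
    if lambda_ == 0:
        # Limit point: the two cycles coincide at |z| = 1 (half-stable).
        return BifurcationSummary("monostable_rest", 1.0, 1.0)
    if lambda_ < 1:
        return BifurcationSummary("bistable", r_stable_sq, r_unstable_sq)
    if lambda_ == 1:
        # Hopf point: unstable cycle dies on the origin.
        return BifurcationSummary("monostable_oscillation", r_stable_sq, 0.0)
    return BifurcationSummary("monostable_oscillation", r_stable_sq, None)


def potential(r: float | np.ndarray, lambda_: float) -> float | np.ndarray:
    """Radial potential ``psi(r)`` with ``-d psi/d r = radial_drift``.

    ``psi(r) = (1-lambda) r^2 / 2 - r^4 / 2 + r^6 / 6`` with the gauge
    ``psi(0) = 0``.  Barrier heights are differences of ``psi`` so the
    gauge is immaterial; it is fixed for reproducibility.  The rotational
    part of the field is divergence-free along level sets and does not
    enter the potential.
    """
    r = np.asarray(r, dtype=float) if not np.isscalar(r) else r
    r2 = r**2
    return (1 - lambda_) * r2 / 2 - r2**2 / 2 + r2**3 / 6
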