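"""Lifetime <-> Po2 calibration and hemoglobin saturation.

The phosphorescent probe's decay rate is linear in oxygen partial pressure
(Stern-Volmer behaviour): ``1/tau = 1/tau0 + kq * Po2``, where ``tau0`` is
the unquenched lifetime and ``kq`` the quenching constant.  Hemoglobin
saturation follows the Hill equation
``So2 = 100 * Po2**n / (Po2**n + P50**n)`` with the mouse-hemoglobin
constants n = 2.59 and P50 = 40.2 mm Hg.

The calibration constants ``tau0`` and ``kq`` are configuration values
plausible for a PtP-C343-class probe, not a measured curve for any
particular instrument: every quantitative check in this package is a
round trip (the same curve converts Po2 to lifetime in the simulator and
back in the analysis), so results do not depend on the specific default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvariantError

__all__ = [
    "CalibrationCurve",
    "HillParams",
    "lifetime_from_po2",
    "po2_from_lifetime",
    "so2_from_po2",
    "so2_if_estimated_from_po2_mean",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Stern-Volmer-like quenching curve: 1/tau = 1/tau0 + kq * Po2.

    tau0 : unquenched lifetime, µs.
    kq : quenching constant, (µs * mm Hg)^-1.

    The relation is strictly linear in the quencher; a different functional
    form (e.g. a two-site quadratic) can be substituted by subclassing and
    overriding :meth:`rate_from_po2` / :meth:`po2_from_rate` without
    touching any caller.
    """

    tau0_us: float = 50.0
    kq: float = 4e-4

    def __post_init__(self) -> None:
        if self.tau0_us <= 0:
            raise InvariantError("tau0 must be > 0")
        if self.kq <= 0:
            raise InvariantError("kq must be > 0")

    def rate_from_po2(self, po2):
        return 1.0 / self.tau0_us + self.kq * np.asarray(po2, dtype=float)

    def po2_from_rate(self, rate):
        return (np.asarray(rate, dtype=float) - 1.0 / self.tau0_us) / self.kq


@dataclass(frozen=True)
class HillParams:
    """Hill-equation parameters for mouse hemoglobin."""

    n: float = 2.59
    p50_mmhg: float = 40.2

    def __post_init__(self) -> None:
        if self.n <= 0 or self.p50_mmhg <= 0:
            raise InvariantError("Hill n and P50 must be > 0")


def lifetime_from_po2(po2_mmhg, curve: CalibrationCurve = CalibrationCurve()):
    """Phosphorescence lifetime (µs) at a given Po2 (mm Hg).

    Strictly decreasing in Po2; equals ``tau0`` at Po2 = 0.
    Accepts scalars or arrays.
    """
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 < 0):
        raise InvariantError("Po2 must be >= 0")
    tau = 1.0 / curve.rate_from_po2(po2)
    return float(tau) if np.isscalar(po2_mmhg) else tau


def po2_from_lifetime(tau_us, curve: CalibrationCurve = CalibrationCurve(),
                      *, tol: float = 1e-6, clamp: bool = False):
    """Invert the calibration: Po2 (mm Hg) from a lifetime (µs).

    Lifetimes in (tau0, tau0*(1+tol)] are treated as the unquenched limit
    and mapped to 0 mm Hg.  Longer lifetimes are physically impossible
    under the curve and raise, unless ``clamp=True`` in which case they are
    also mapped to 0 (callers that clamp should flag the event).
    """
    tau = np.asarray(tau_us, dtype=float)
    if np.any(tau <= 0):
        raise InvariantError("lifetime must be > 0")
    limit = curve.tau0_us * (1.0 + tol)
    if np.any(tau > limit) and not clamp:
        raise InvariantError(
            f"lifetime above unquenched limit tau0 = {curve.tau0_us} µs")
    po2 = np.maximum(curve.po2_from_rate(1.0 / tau), 0.0)
    return float(po2) if np.isscalar(tau_us) else po2


def so2_from_po2(po2_mmhg, hill: HillParams = HillParams()):
    """Hemoglobin saturation (%) from Po2 (mm Hg) via the Hill equation.

    Strictly increasing and bounded in [0, 100); exactly 50% at Po2 = P50.
    """
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(po2 < 0):
        raise InvariantError("Po2 must be >= 0")
    ratio = np.power(po2 / hill.p50_mmhg, hill.n)
    so2 = 100.0 * ratio / (ratio + 1.0)
    return float(so2) if np.isscalar(po2_mmhg) else so2


def so2_if_estimated_from_po2_mean(po2_mean_mmhg, hill: HillParams = HillParams()):
    """Saturation that *would* be inferred if Po2Mean were (incorrectly)
    taken to represent the oxygen seen by hemoglobin.

    So2 must be estimated from the erythrocyte-border Po2: the capillary
    average mixes in the lower plasma/interstitial values and yields a
    systematically lower, misleading saturation.  This helper exists only
    to illustrate that error; the pipeline itself always uses Po2RBC.
    """
    return so2_from_po2(po2_mean_mmhg, hill)
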