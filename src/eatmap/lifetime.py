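"""Decay pooling and single-exponential lifetime fitting.

Individual cycles carry too few phosphorescence photons for a stable fit,
so decays are pooled (element-wise summed) over a selected set of cycles
and a single exponential ``A exp(-t/tau) + C`` is fitted to the pooled
histogram by Levenberg-Marquardt nonlinear least squares.  The first
``discard_bins`` bins after the end of the on-phase are excluded (detector
settling).  Weights approximate Poisson counting variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Union

import numpy as np
from scipy.optimize import curve_fit

from .core import AcquisitionConfig, Recording
from .exceptions import EmptySelectionError, FitError, InvariantError

__all__ = ["DecayHistogram", "LifetimeFit", "aggregate_decays", "fit_lifetime"]

# A cycle selector is either a boolean mask over cycles or a predicate
# applied to each cycle's midpoint time in ms.
CycleSelector = Union[np.ndarray, Callable[[np.ndarray], np.ndarray]]


@dataclass
class DecayHistogram:
    """Pooled off-phase photon histogram.

    bin_times_us are bin centers measured from the end of the on-phase;
    counts are summed over ``n_cycles_pooled`` cycles.
    """

    bin_times_us: np.ndarray
    counts: np.ndarray
    n_cycles_pooled: int

    def __post_init__(self) -> None:
        self.bin_times_us = np.asarray(self.bin_times_us, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.bin_times_us.shape != self.counts.shape:
            raise InvariantError("bin_times and counts must align")
        if np.any(self.counts < 0):
            raise InvariantError("histogram counts must be >= 0")
        if self.n_cycles_pooled < 1:
            raise InvariantError("n_cycles_pooled must be >= 1")


@dataclass
class LifetimeFit:
    """Result of a single-exponential decay fit.

    tau_us and tau_se_us come from the Levenberg-Marquardt fit and the
    diagonal of its parameter covariance; ``converged`` is False when the
    optimizer did not reach its tolerance (never silently ignored: callers
    that need tau must check it).
    """

    tau_us: float
    tau_se_us: float
    amplitude: float
    offset: float
    n_decays: int
    converged: bool
    residual_norm: float

    def __post_init__(self) -> None:
        if self.converged and not self.tau_us > 0:
            raise InvariantError("converged fit must have tau > 0")
        if self.converged and self.tau_se_us < 0:
            raise InvariantError("tau_se must be >= 0")


def aggregate_decays(recording: Recording, selector: CycleSelector) -> DecayHistogram:
    """Sum decay histograms over the cycles picked by ``selector``.

    ``selector`` may be a boolean mask over cycles or a callable mapping
    the vector of cycle midpoint times (ms) to such a mask.
    """
    if callable(selector):
        mask = np.asarray(selector(recording.cycle_midtimes_ms()), dtype=bool)
    else:
        mask = np.asarray(selector, dtype=bool)
    if mask.shape != (recording.n_cycles,):
        raise InvariantError("selector mask must have one entry per cycle")
    n_sel = int(mask.sum())
    if n_sel == 0:
        raise EmptySelectionError("no decays in window")
    counts = recording.decay_counts[mask].sum(axis=0, dtype=np.int64)
    return DecayHistogram(recording.acquisition.bin_times_us(), counts, n_sel)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Log-linear regression on background-subtracted counts.
    tail = max(1, len(y) // 10)
    c0 = float(np.median(y[-tail:]))
    z = y - c0
    pos = z > 0
    if pos.sum() >= 3:
        w = np.sqrt(z[pos])  # emphasize high-count (low log-noise) bins
        slope, intercept = np.polyfit(t[pos], np.log(z[pos]), 1, w=w)
        if slope < 0:
            return float(np.exp(intercept)), float(-1.0 / slope), c0
    # degenerate fallback: quarter of the observed span
    span = t[-1] - t[0]
    a0 = max(float(y.max() - c0), 1e-6)
    return a0, max(span / 4.0, 1e-3), c0


def fit_lifetime(
    hist: DecayHistogram,
    acq: AcquisitionConfig,
    *,
    weighted: bool = True,
    xtol: float = 1e-8,
    max_iter: int = 200,
) -> LifetimeFit:
    """Fit ``counts(t) = A exp(-t/tau) + C`` to a pooled decay histogram.

    The first ``acq.discard_bins`` bins are excluded.  With
    ``weighted=True`` (default) residuals are weighted by 1/max(count, 1),
    the Poisson-variance approximation; ``weighted=False`` gives ordinary
    least squares.  The standard error of tau comes from the fit
    covariance.  Non-convergence is reported through ``converged=False``
    with the last diagnostics, never raised.
    """
    t = hist.bin_times_us[acq.discard_bins:]
    y = np.asarray(hist.counts[acq.discard_bins:], dtype=float)
    if len(t) < 10:
        raise FitError("fewer than 10 usable bins after discarding")
    if not np.any(y > 0):
        raise FitError("all-zero decay histogram")

    a0, tau0, c0 = _initial_guess(t, y)
    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None

    def model(tt, a, tau, c):
        return a * np.exp(-tt / np.abs(tau)) + c

    try:
        popt, pcov = curve_fit(
            model, t, y, p0=[a0, tau0, c0], sigma=sigma,
            absolute_sigma=weighted, method="lm",
            xtol=xtol, maxfev=max_iter * (len(t) + 4),
        )
        converged = True
    except RuntimeError:
        return LifetimeFit(tau_us=float("nan"), tau_se_us=float("nan"),
                           amplitude=float("nan"), offset=float("nan"),
                           n_decays=hist.n_cycles_pooled, converged=False,
                           residual_norm=float("nan"))
    a, tau, c = popt
    tau = abs(float(tau))
    resid = y - model(t, *popt)
    if sigma is not None:
        resid = resid / sigma
    tau_se = float(np.sqrt(max(pcov[1, 1], 0.0)))
    if not weighted:
        # curve_fit already rescales pcov by reduced chi^2 when sigma=None
        pass
    if not np.isfinite(tau_se):
        tau_se = float("nan")
    if tau <= 0 or not np.isfinite(tau):
        converged = False
    return LifetimeFit(tau_us=tau, tau_se_us=tau_se, amplitude=float(a),
                       offset=float(c), n_decays=hist.n_cycles_pooled,
                       converged=converged,
                       residual_norm=float(np.linalg.norm(resid)))
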