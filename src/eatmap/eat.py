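"""Erythrocyte-associated transient (EAT) extraction.

Capillary Po2 is not constant: it peaks when an erythrocyte occupies the
excitation point and relaxes toward the interstitial value in the plasma
gap between cells.  This module bins the phosphorescence decays of a
measurement by their time to the nearest detected RBC border and produces
the three Po2 readouts:

* ``po2_rbc`` — decays adjacent to an RBC border (the erythrocyte value);
* ``po2_inter_rbc`` — decays at mid-distance between consecutive RBCs,
  clear of a guard zone around the borders (the interstitial proxy);
* ``po2_mean`` — one fit over every decay, ignoring RBC positions (the
  value a naive capillary measurement would report).

Hemoglobin saturation is always estimated from ``po2_rbc``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .calibration import (CalibrationCurve, HillParams, po2_from_lifetime,
                          so2_from_po2)
from .core import EATResult, Recording
from .detection import RBCTransit, flow_metrics, occupancy_mask
from .exceptions import (EatmapError, FitError, InvariantError,
                         WindowUnsatisfiedError)
from .lifetime import LifetimeFit, aggregate_decays, fit_lifetime

__all__ = [
    "EATWindows",
    "EATProfile",
    "time_to_nearest_border",
    "extract_eat",
    "eat_profile",
]


@dataclass(frozen=True)
class EATWindows:
    """Decay-binning windows around RBC borders.

    rbc_half_width_ms : half-width of the border window (total border span
        per the method's convention lies in the 1-4 ms range).
    inter_min_window_ms : minimum cumulative mid-distance span that must be
        available across the measurement's inter-RBC gaps.
    inter_guard_ms : exclusion zone next to each border when defining the
        mid-distance pool; defaults to twice the half-width.
    border_mode : which decays count as "at the border".
        ``"inside"`` (default) pools decays whose cycle lies inside the
        cell within ``rbc_half_width_ms`` of a border — the Po2 profile
        plateaus at the erythrocyte value there, so the read-out is
        undiluted by the relaxing plasma just outside.  ``"symmetric"``
        straddles the border (|distance| <= half-width), mixing in plasma
        decays and biasing the border Po2 low when the EAT relaxes on a
        ms scale; it is kept for comparison with that convention.
    """

    rbc_half_width_ms: float = 1.5
    inter_min_window_ms: float = 5.0
    inter_guard_ms: Optional[float] = None
    border_mode: str = "inside"

    def __post_init__(self) -> None:
        if self.rbc_half_width_ms <= 0 or self.inter_min_window_ms <= 0:
            raise InvariantError("window widths must be > 0")
        if self.guard_ms < self.rbc_half_width_ms:
            raise InvariantError("inter_guard must be >= rbc_half_width")
        if self.border_mode not in ("inside", "symmetric"):
            raise InvariantError("border_mode must be 'inside' or 'symmetric'")

    @property
    def guard_ms(self) -> float:
        return (2.0 * self.rbc_half_width_ms
                if self.inter_guard_ms is None else self.inter_guard_ms)


@dataclass
class EATProfile:
    """Po2 as a function of signed time to the nearest RBC border.

    Negative bin centers lie inside the cell.  Bins pooling fewer than the
    decay floor are masked (po2 = NaN) rather than reported from an
    unstable fit.
    """

    bin_centers_ms: np.ndarray
    po2_mmhg: np.ndarray          # NaN where masked
    n_decays: np.ndarray
    fits: list                    # LifetimeFit or None per bin


def _genuine_borders(transits: Sequence[RBCTransit]) -> np.ndarray:
    """All real FWHM border times (ms); clamped edges of truncated
    transits are excluded because they are trace artifacts, not borders."""
    borders = []
    for tr in transits:
        if not tr.truncated_left:
            borders.append(tr.entry_ms)
        if not tr.truncated_right:
            borders.append(tr.exit_ms)
    return np.sort(np.asarray(borders, dtype=float))


def time_to_nearest_border(
    times_ms: np.ndarray, transits: Sequence[RBCTransit]
) -> tuple[np.ndarray, np.ndarray]:
    """Signed time (ms) from each cycle midpoint to the nearest RBC border.

    Returns ``(distance, inside)`` where distance is negative for cycles
    inside a transit.  With no transits (or no genuine borders) distances
    are NaN and inside is all-False: callers must treat those cycles as
    unassignable.  Agrees exactly with an exhaustive all-pairs search.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    ordered = sorted(transits, key=lambda t: t.entry_ms)
    for a, b in zip(ordered, ordered[1:]):
        if b.entry_ms < a.exit_ms:
            raise InvariantError("transits must be non-overlapping")
    borders = _genuine_borders(ordered)
    inside = occupancy_mask(ordered, times_ms)
    if len(borders) == 0:
        return np.full(len(times_ms), np.nan), inside
    idx = np.clip(np.searchsorted(borders, times_ms), 1, len(borders) - 1) \
        if len(borders) > 1 else np.zeros(len(times_ms), dtype=int)
    if len(borders) > 1:
        left = np.abs(times_ms - borders[idx - 1])
        right = np.abs(times_ms - borders[idx])
        dist = np.minimum(left, right)
    else:
        dist = np.abs(times_ms - borders[0])
    return np.where(inside, -dist, dist), inside


def _interior_gap_mask(
    times_ms: np.ndarray, transits: Sequence[RBCTransit], guard_ms: float
) -> tuple[np.ndarray, float]:
    """Mask of cycles in the central (guarded) span of inter-RBC gaps, and
    the cumulative eligible span (ms) across all interior gaps."""
    ordered = sorted(transits, key=lambda t: t.entry_ms)
    mask = np.zeros(len(times_ms), dtype=bool)
    eligible = 0.0
    for a, b in zip(ordered, ordered[1:]):
        lo, hi = a.exit_ms + guard_ms, b.entry_ms - guard_ms
        if hi > lo:
            eligible += hi - lo
            mask |= (times_ms >= lo) & (times_ms <= hi)
    return mask, eligible


def _po2_with_se(fit: LifetimeFit, calib: CalibrationCurve, what: str):
    """Convert a lifetime fit to Po2 with a delta-method standard error."""
    if not fit.converged:
        raise FitError(f"lifetime fit failed to converge for {what}")
    po2 = po2_from_lifetime(fit.tau_us, calib, clamp=True)
    clamped = fit.tau_us > calib.tau0_us
    # d(po2)/d(tau) = -1/(kq tau^2)
    se = fit.tau_se_us / (calib.kq * fit.tau_us ** 2)
    return po2, se, clamped


def extract_eat(
    recording: Recording,
    transits: Sequence[RBCTransit],
    windows: EATWindows = EATWindows(),
    calib: CalibrationCurve = CalibrationCurve(),
    hill: HillParams = HillParams(),
) -> EATResult:
    """Per-measurement Po2RBC / Po2InterRBC / Po2Mean, So2 and flow metrics.

    Decays are partitioned by time to the nearest RBC border: the border
    pool and the mid-distance pool are disjoint by construction (the guard
    zone is at least the border half-width) and every decay enters the
    Po2Mean pool.  The mid-distance pool is accumulated across all
    inter-RBC gaps after excluding the guard zone; it must total at least
    ``inter_min_window_ms``, otherwise the capillary's flow is too fast
    for an interstitial read-out and the measurement is rejected.
    """
    complete = [t for t in transits if not t.truncated]
    if len(complete) == 0:
        raise EatmapError("no complete RBC transit in measurement")
    times = recording.cycle_midtimes_ms()
    dist, inside = time_to_nearest_border(times, transits)

    w = windows.rbc_half_width_ms
    if windows.border_mode == "inside":
        rbc_mask = inside & (np.abs(dist) <= w)
    else:
        rbc_mask = np.abs(dist) <= w

    gap_mask, eligible = _interior_gap_mask(times, transits, windows.guard_ms)
    inter_mask = gap_mask & ~inside & (dist >= windows.guard_ms)
    if eligible < windows.inter_min_window_ms:
        raise WindowUnsatisfiedError(
            f"interRBC window unsatisfied (fast flow): eligible span "
            f"{eligible:.2f} ms < {windows.inter_min_window_ms} ms")

    # window accounting: the two pools never share a decay
    assert not np.any(rbc_mask & inter_mask), "border/mid-distance overlap"

    acq = recording.acquisition
    results = {}
    for name, mask in (("rbc", rbc_mask), ("inter_rbc", inter_mask),
                       ("mean", np.ones(recording.n_cycles, dtype=bool))):
        fit = fit_lifetime(aggregate_decays(recording, mask), acq)
        po2, se, clamped = _po2_with_se(fit, calib, f"po2_{name}")
        results[name] = dict(po2=po2, po2_se=se, tau_us=fit.tau_us,
                             tau_se_us=fit.tau_se_us, n_decays=fit.n_decays,
                             clamped=clamped, residual_norm=fit.residual_norm)

    fm = flow_metrics(transits, recording)
    return EATResult(
        po2_rbc=results["rbc"]["po2"],
        po2_inter_rbc=results["inter_rbc"]["po2"],
        po2_mean=results["mean"]["po2"],
        so2=so2_from_po2(results["rbc"]["po2"], hill),
        rbc_flow=fm.rbc_flow,
        hematocrit=fm.hematocrit,
        diagnostics={**results, "flow": fm, "eligible_inter_span_ms": eligible},
    )


def eat_profile(
    recording: Recording,
    transits: Sequence[RBCTransit],
    bin_width_ms: float = 0.5,
    calib: CalibrationCurve = CalibrationCurve(),
    min_decays: int = 500,
    span_ms: Optional[tuple[float, float]] = None,
) -> EATProfile:
    """Po2 profile versus signed time to the nearest RBC border.

    Decays are grouped into ``bin_width_ms`` bins of signed border
    distance and each bin fitted independently; bins pooling fewer than
    ``min_decays`` cycles are masked.  ``span_ms`` restricts the profile
    extent (default: the observed distance range).
    """
    if bin_width_ms <= 0:
        raise InvariantError("bin width must be > 0")
    times = recording.cycle_midtimes_ms()
    dist, _ = time_to_nearest_border(times, transits)
    valid = np.isfinite(dist)
    if not np.any(valid):
        raise EatmapError("no transits: profile undefined")
    lo, hi = (dist[valid].min(), dist[valid].max()) if span_ms is None else span_ms
    edges = np.arange(np.floor(lo / bin_width_ms),
                      np.ceil(hi / bin_width_ms) + 1) * bin_width_ms
    centers = 0.5 * (edges[:-1] + edges[1:])
    po2 = np.full(len(centers), np.nan)
    n = np.zeros(len(centers), dtype=int)
    fits: list = [None] * len(centers)
    which = np.digitize(dist, edges) - 1
    acq = recording.acquisition
    for k in range(len(centers)):
        mask = valid & (which == k)
        n[k] = int(mask.sum())
        if n[k] < min_decays:
            continue
        fit = fit_lifetime(aggregate_decays(recording, mask), acq)
        fits[k] = fit
        if fit.converged:
            po2[k] = po2_from_lifetime(fit.tau_us, calib, clamp=True)
    return EATProfile(centers, po2, n, fits)
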