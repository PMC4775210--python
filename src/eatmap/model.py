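"""Model/Results interface for one point measurement.

:class:`EATModel` bundles a recording with the analysis configuration;
:meth:`EATModel.fit` runs baseline estimation, transit detection and EAT
extraction and returns an :class:`EATResults` carrying the Po2 estimates,
their standard errors (delta method through the calibration curve),
flow metrics, fit diagnostics, a ``summary()`` table and plotting helpers.

    >>> model = EATModel.from_file("cap000_m0.h5")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, HillParams
from .core import EATResult, Recording
from .detection import (DetectionParams, RBCTransit, detect_transits,
                        estimate_baseline, flow_metrics)
from .eat import EATProfile, EATWindows, eat_profile, extract_eat
from .io import read_recording, result_row

__all__ = ["EATModel", "EATResults"]

_PARAM_NAMES = ["po2_rbc", "po2_inter_rbc", "po2_mean", "so2",
                "rbc_flow", "hematocrit"]
_UNITS = {"po2_rbc": "mm Hg", "po2_inter_rbc": "mm Hg", "po2_mean": "mm Hg",
          "so2": "%", "rbc_flow": "cells/s", "hematocrit": "%"}


class EATModel:
    """Erythrocyte-associated-transient oximetry model for one recording."""

    def __init__(
        self,
        recording: Recording,
        detection: DetectionParams = DetectionParams(),
        windows: EATWindows = EATWindows(),
        calibration: CalibrationCurve = CalibrationCurve(),
        hill: HillParams = HillParams(),
    ) -> None:
        self.recording = recording
        self.detection = detection
        self.windows = windows
        self.calibration = calibration
        self.hill = hill

    @classmethod
    def from_file(cls, path: Union[str, Path], **kwargs) -> "EATModel":
        return cls(read_recording(path), **kwargs)

    def fit(self) -> "EATResults":
        """Run the full per-measurement pipeline deterministically."""
        rec = self.recording
        baseline = estimate_baseline(
            rec.fluorescence,
            window=self.detection.baseline_window_cycles,
            quantile=self.detection.baseline_quantile)
        transits = detect_transits(rec.fluorescence, baseline, self.detection,
                                   cycle_period_us=rec.acquisition.cycle_period_us)
        result = extract_eat(rec, transits, self.windows,
                             self.calibration, self.hill)
        return EATResults(self, result, transits, baseline)


class EATResults:
    """Fitted per-measurement results.

    Attributes
    ----------
    params : pandas.Series
        Point estimates of the six measurement quantities.
    bse : pandas.Series
        Standard errors for the Po2 quantities (propagated from the
        lifetime-fit covariance through the calibration curve); NaN for
        the counting quantities (flow, hematocrit, So2).
    transits : list of RBCTransit
    result : EATResult
        The raw result object including fit diagnostics.
    """

    def __init__(self, model: EATModel, result: EATResult,
                 transits: list, baseline: np.ndarray) -> None:
        self.model = model
        self.result = result
        self.transits = transits
        self.baseline = baseline
        self.params = pd.Series(
            {name: getattr(result, name) for name in _PARAM_NAMES})
        d = result.diagnostics
        self.bse = pd.Series({
            "po2_rbc": d["rbc"]["po2_se"],
            "po2_inter_rbc": d["inter_rbc"]["po2_se"],
            "po2_mean": d["mean"]["po2_se"],
            "so2": np.nan, "rbc_flow": np.nan, "hematocrit": np.nan,
        })

    def to_row(self) -> dict:
        """Flat results-table row (see :data:`eatmap.io.RESULTS_COLUMNS`)."""
        return result_row(self.model.recording.metadata, self.result)

    def profile(self, bin_width_ms: float = 0.5, min_decays: int = 500,
                span_ms: Optional[tuple] = None) -> EATProfile:
        """Po2 versus signed time to the nearest RBC border."""
        return eat_profile(self.model.recording, self.transits,
                           bin_width_ms, self.model.calibration,
                           min_decays=min_decays, span_ms=span_ms)

    def summary(self) -> str:
        meta = self.model.recording.metadata
        d = self.result.diagnostics
        fm = d["flow"]
        lines = [
            "EAT oximetry results".center(58),
            "=" * 58,
            f"measurement: {meta.measurement_id}   capillary: {meta.capillary_id}",
            f"region: {meta.region}   depth: {meta.depth_um:.0f} um",
            f"cycles: {self.model.recording.n_cycles}   "
            f"duration: {self.model.recording.duration_s:.2f} s   "
            f"transits: {fm.n_transits}",
            "-" * 58,
            f"{'quantity':<16}{'estimate':>12}{'std err':>10}  unit",
        ]
        for name in _PARAM_NAMES:
            se = self.bse[name]
            se_s = f"{se:>10.2f}" if np.isfinite(se) else f"{'--':>10}"
            lines.append(f"{name:<16}{self.params[name]:>12.2f}{se_s}"
                         f"  {_UNITS[name]}")
        lines.append("-" * 58)
        for key, label in (("rbc", "border"), ("inter_rbc", "mid-distance"),
                           ("mean", "all decays")):
            g = d[key]
            lines.append(
                f"tau {label:<13}{g['tau_us']:>8.2f} +/- {g['tau_se_us']:.3f} us"
                f"   n decays: {g['n_decays']}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_profile(self, ax=None, bin_width_ms: float = 0.5,
                     min_decays: int = 500):
        """Plot the EAT Po2 profile around the RBC border."""
        import matplotlib.pyplot as plt

        prof = self.profile(bin_width_ms, min_decays)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(prof.bin_centers_ms, prof.po2_mmhg, "o-", label="profile")
        for val, name in ((self.result.po2_rbc, "Po2 RBC"),
                          (self.result.po2_inter_rbc, "Po2 inter-RBC"),
                          (self.result.po2_mean, "Po2 mean")):
            ax.axhline(val, ls="--", lw=0.8, alpha=0.6)
            ax.annotate(name, (prof.bin_centers_ms[-1], val), fontsize=8)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_xlabel("time to nearest RBC border (ms)")
        ax.set_ylabel("Po2 (mm Hg)")
        return ax

    def plot_trace(self, ax=None, t_max_ms: float = 500.0):
        """Plot the fluorescence trace, baseline and detected transits."""
        import matplotlib.pyplot as plt

        rec = self.model.recording
        t = rec.cycle_midtimes_ms()
        sel = t <= t_max_ms
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(t[sel], rec.fluorescence[sel], lw=0.5, label="fluorescence")
        ax.plot(t[sel], self.baseline[sel], lw=1.0, label="baseline")
        for tr in self.transits:
            if tr.entry_ms > t_max_ms:
                break
            ax.axvspan(tr.entry_ms, min(tr.exit_ms, t_max_ms),
                       alpha=0.2, color="red")
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("photons / cycle")
        ax.legend(loc="upper right", fontsize=8)
        return ax
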