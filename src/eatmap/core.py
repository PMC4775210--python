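"""Shared data model for phosphorescence-lifetime point measurements.

A *measurement* is a train of excitation/collection cycles at one point
inside a capillary.  Each 250 µs cycle has an on-phase (two-photon
excitation; green fluorescence photons counted) and an off-phase during
which the phosphorescence decay of the oxygen probe is recorded as a
photon-count histogram at 1.25 MHz.  The on-phase fluorescence carries the
red-blood-cell transit signal (the probe is excluded from erythrocytes, so
an RBC at the focus produces a dip); the off-phase decays carry the oxygen
signal through the quenched lifetime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .exceptions import InvariantError

__all__ = [
    "AcquisitionConfig",
    "CycleRecord",
    "RecordingMetadata",
    "Recording",
    "EATResult",
]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Cycle timing of the gated two-photon acquisition.

    Parameters
    ----------
    excitation_period_us : float
        Duration of the laser-on (excitation) phase, µs.
    recording_period_us : float
        Duration of the laser-off (phosphorescence recording) phase, µs.
    cycle_period_us : float
        Full cycle period, µs.  The default timing (24 + 225 µs within a
        250 µs cycle, i.e. a 4 kHz repetition rate) leaves 1 µs of implicit
        dead time; timestamps always use ``cycle_period_us``.
    sampling_rate_mhz : float
        Off-phase digitizer rate, MHz; sets the decay histogram bin width.
    discard_bins : int
        Number of initial off-phase bins dropped before lifetime fitting
        (detector settling after the on-phase).
    """

    excitation_period_us: float = 24.0
    recording_period_us: float = 225.0
    cycle_period_us: float = 250.0
    sampling_rate_mhz: float = 1.25
    discard_bins: int = 6

    def __post_init__(self) -> None:
        if min(self.excitation_period_us, self.recording_period_us,
               self.cycle_period_us) <= 0:
            raise InvariantError("all acquisition durations must be > 0")
        if self.sampling_rate_mhz <= 0:
            raise InvariantError("sampling rate must be > 0")
        if self.excitation_period_us + self.recording_period_us > self.cycle_period_us + 1e-9:
            raise InvariantError(
                "excitation + recording period exceeds the cycle period")
        if self.n_bins < 10:
            raise InvariantError("off-phase must span at least 10 bins")
        if not 0 <= self.discard_bins < self.n_bins:
            raise InvariantError(
                f"discard_bins must lie in [0, {self.n_bins})")

    @property
    def n_bins(self) -> int:
        """Number of off-phase histogram bins per cycle."""
        return int(math.floor(self.sampling_rate_mhz * self.recording_period_us))

    @property
    def bin_width_us(self) -> float:
        return 1.0 / self.sampling_rate_mhz

    @property
    def repetition_rate_hz(self) -> float:
        """Cycle repetition rate in Hz (4 kHz for the default 250 µs cycle)."""
        return 1e6 / self.cycle_period_us

    def bin_times_us(self) -> np.ndarray:
        """Bin-center times (µs) measured from the end of the on-phase.

        Off-phase bin i covers [excitation + i/f, excitation + (i+1)/f)
        within the cycle; times here are relative to the excitation end so
        the decay model is ``A exp(-t/tau) + C`` with t >= 0.
        """
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_us

    def cycle_midtimes_ms(self, n_cycles: int) -> np.ndarray:
        """Midpoint time (ms) of cycles 0..n_cycles-1 from recording start."""
        return (np.arange(n_cycles) + 0.5) * self.cycle_period_us * 1e-3


@dataclass(frozen=True)
class CycleRecord:
    """One excitation/collection cycle: an on-phase fluorescence photon
    count and the off-phase decay histogram."""

    cycle_index: int
    fluorescence_count: int
    decay_counts: np.ndarray

    def validate(self, acq: AcquisitionConfig) -> None:
        if self.cycle_index < 0:
            raise InvariantError("cycle_index must be >= 0")
        if self.fluorescence_count < 0:
            raise InvariantError("fluorescence count must be >= 0")
        dc = np.asarray(self.decay_counts)
        if dc.ndim != 1 or len(dc) != acq.n_bins:
            raise InvariantError(
                f"decay_counts must have length {acq.n_bins}, got {dc.shape}")
        if np.any(dc < 0):
            raise InvariantError("decay counts must be >= 0")


@dataclass
class RecordingMetadata:
    capillary_id: str = "unknown"
    region: str = "cortex"  # "glomerular_layer" | "cortex"
    depth_um: float = 0.0
    session_id: str = "session0"
    measurement_id: str = "m0"
    seed: Optional[int] = None


class Recording:
    """A full point measurement: ordered cycles plus capillary metadata.

    Cycles are stored columnar (fluorescence vector + dense decay-count
    matrix) because a typical measurement is 10,000-40,000 cycles of ~281
    bins each; :meth:`cycle` materializes a single :class:`CycleRecord`.
    """

    def __init__(
        self,
        acquisition: AcquisitionConfig,
        fluorescence: np.ndarray,
        decay_counts: np.ndarray,
        metadata: Optional[RecordingMetadata] = None,
        cycle_index: Optional[np.ndarray] = None,
    ) -> None:
        fluorescence = np.asarray(fluorescence)
        decay_counts = np.asarray(decay_counts)
        if fluorescence.ndim != 1:
            raise InvariantError("fluorescence must be a 1-D count vector")
        n = len(fluorescence)
        if n == 0:
            raise InvariantError("empty recording")
        if decay_counts.shape != (n, acquisition.n_bins):
            raise InvariantError(
                f"decay_counts must have shape ({n}, {acquisition.n_bins}), "
                f"got {decay_counts.shape}")
        if cycle_index is None:
            cycle_index = np.arange(n, dtype=np.int64)
        else:
            cycle_index = np.asarray(cycle_index, dtype=np.int64)
            if cycle_index.shape != (n,):
                raise InvariantError("cycle_index must match the cycle count")
            if np.any(np.diff(cycle_index) <= 0):
                raise InvariantError("cycle_index must be strictly increasing")
            if cycle_index[0] < 0:
                raise InvariantError("cycle_index must be >= 0")
        if not np.issubdtype(fluorescence.dtype, np.integer) or \
                not np.issubdtype(decay_counts.dtype, np.integer):
            raise InvariantError("photon counts must be integers")
        if fluorescence.min() < 0 or decay_counts.min() < 0:
            raise InvariantError("photon counts must be >= 0")
        self.acquisition = acquisition
        self.fluorescence = fluorescence
        self.decay_counts = decay_counts
        self.cycle_index = cycle_index
        self.metadata = metadata if metadata is not None else RecordingMetadata()

    @property
    def n_cycles(self) -> int:
        return len(self.fluorescence)

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.acquisition.cycle_period_us * 1e-6

    def cycle_midtimes_ms(self) -> np.ndarray:
        return self.acquisition.cycle_midtimes_ms(self.n_cycles)

    def cycle(self, i: int) -> CycleRecord:
        return CycleRecord(int(self.cycle_index[i]),
                           int(self.fluorescence[i]),
                           self.decay_counts[i])

    def __iter__(self) -> Iterator[CycleRecord]:
        return (self.cycle(i) for i in range(self.n_cycles))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (self.acquisition == other.acquisition
                and np.array_equal(self.fluorescence, other.fluorescence)
                and np.array_equal(self.decay_counts, other.decay_counts)
                and np.array_equal(self.cycle_index, other.cycle_index)
                and self.metadata == other.metadata)

    def __repr__(self) -> str:
        return (f"<Recording {self.metadata.measurement_id}: "
                f"{self.n_cycles} cycles x {self.acquisition.n_bins} bins, "
                f"{self.duration_s:.2f} s>")


@dataclass
class EATResult:
    """Per-measurement oximetry output.

    ``po2_rbc`` is oxygen partial pressure read at the erythrocyte border,
    ``po2_inter_rbc`` at mid-distance between consecutive erythrocytes
    (a proxy for interstitial Po2), ``po2_mean`` from all decays pooled
    regardless of RBC position.  ``so2`` is hemoglobin saturation estimated
    from ``po2_rbc`` via the Hill equation.  ``diagnostics`` carries one
    lifetime-fit record per Po2 quantity (tau, tau SE, n decays pooled).
    """

    po2_rbc: float
    po2_inter_rbc: float
    po2_mean: float
    so2: float
    rbc_flow: float
    hematocrit: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("po2_rbc", "po2_inter_rbc", "po2_mean"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        if not 0 <= self.so2 <= 100:
            raise InvariantError("so2 must lie in [0, 100]")
        if not 0 <= self.hematocrit <= 100:
            raise InvariantError("hematocrit must lie in [0, 100]")
        if self.rbc_flow < 0:
            raise InvariantError("rbc_flow must be >= 0")
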