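"""Synthetic photon-stream generator with known ground truth.

No raw microscope recordings accompany this package, so every pipeline
stage is validated by parameter recovery on simulated measurements.  The
generator emulates the three physical layers of a real point measurement:

1. *RBC traffic* — a renewal process of erythrocyte transits through the
   excitation point.  The plasma gap between consecutive cells is gamma
   distributed (shape ``arrival_shape``) with mean chosen so the
   entry-to-entry interval averages exactly ``1/rbc_flow_true``; each
   transit lasts ``hematocrit_true / (100 * rbc_flow_true)``, making the
   long-run occupancy exactly the hematocrit.  Cells never overlap, as in
   a single-file capillary.
2. *EAT Po2 profile* — inside a cell Po2 equals the erythrocyte value;
   in the gap it relaxes exponentially from the border value toward the
   interstitial value with time constant ``eat_relax_time_ms``.
3. *Photon statistics* — per cycle, the on-phase fluorescence count is
   Poisson with mean reduced by ``dip_contrast`` while a cell occupies the
   focus (dye exclusion), and each off-phase bin is Poisson around a
   single-exponential decay whose lifetime follows from the cycle's Po2
   through the Stern-Volmer calibration, plus a uniform background.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve, lifetime_from_po2
from .core import AcquisitionConfig, Recording, RecordingMetadata
from .detection import RBCTransit
from .eat import time_to_nearest_border
from .exceptions import InvariantError
from .io import write_recording

__all__ = [
    "GroundTruth",
    "po2_at",
    "simulate_transits",
    "simulate_recording",
    "CapillaryGroup",
    "StudySpec",
    "default_study_spec",
    "generate_study",
]

#: Reference decay-bin width (µs): ``decay_amplitude`` is the expected
#: photon count in the first off-phase bin *at this width*; simulations at
#: other sampling rates scale the per-bin mean proportionally.
REFERENCE_BIN_WIDTH_US = 0.8

#: Maximum admissible RBC occupancy.  Above this the plasma gaps become
#: shorter than a detectable dip separation and transits are no longer
#: individually resolvable.
MAX_OCCUPANCY = 0.95


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one simulated measurement.

    Po2 values in mm Hg; flow in cells/s; hematocrit in %; rates are
    expected photon counts (per on-phase for ``fluor_rate``, per
    reference-width off-phase bin for ``decay_amplitude`` and
    ``background_rate``).
    """

    po2_rbc_true: float = 60.0
    po2_inter_true: float = 23.0
    eat_relax_time_ms: float = 1.5
    rbc_flow_true: float = 30.0
    hematocrit_true: float = 35.0
    dip_contrast: float = 0.8
    fluor_rate: float = 50.0
    decay_amplitude: float = 2.0
    background_rate: float = 0.02
    arrival_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.po2_rbc_true >= self.po2_inter_true >= 0:
            raise InvariantError("need po2_rbc_true >= po2_inter_true >= 0")
        if not 0 < self.hematocrit_true < 100:
            raise InvariantError("hematocrit must lie in (0, 100)")
        if self.rbc_flow_true <= 0:
            raise InvariantError("rbc_flow must be > 0")
        if not 0 < self.dip_contrast <= 1:
            raise InvariantError("dip_contrast must lie in (0, 1]")
        if self.eat_relax_time_ms <= 0 or self.arrival_shape <= 0:
            raise InvariantError("relax time and arrival shape must be > 0")
        if min(self.fluor_rate, self.decay_amplitude) <= 0 or self.background_rate < 0:
            raise InvariantError("photon rates must be positive")
        if self.occupancy > MAX_OCCUPANCY:
            raise InvariantError(
                f"occupancy {self.occupancy:.2f} > {MAX_OCCUPANCY}: transits "
                "would not be individually resolvable")

    @property
    def transit_duration_ms(self) -> float:
        """Single-cell dwell time: hematocrit / (100 * flow)."""
        return 1000.0 * self.hematocrit_true / (100.0 * self.rbc_flow_true)

    @property
    def occupancy(self) -> float:
        return self.hematocrit_true / 100.0


def po2_at(t_rel_ms, truth: GroundTruth):
    """Po2 (mm Hg) at a signed time from the nearest RBC border.

    ``t_rel_ms <= 0`` (inside the cell) returns the erythrocyte value;
    outside, Po2 relaxes exponentially toward the interstitial value:
    ``inter + (rbc - inter) * exp(-t / eat_relax_time)``.  Continuous at
    the border.  Accepts scalars or arrays; NaN (no border defined) maps
    to the interstitial value.
    """
    t = np.asarray(t_rel_ms, dtype=float)
    amp = truth.po2_rbc_true - truth.po2_inter_true
    with np.errstate(invalid="ignore"):
        outside = truth.po2_inter_true + amp * np.exp(
            -np.clip(t, 0.0, None) / truth.eat_relax_time_ms)
        po2 = np.where(t <= 0, truth.po2_rbc_true, outside)
    po2 = np.where(np.isnan(t), truth.po2_inter_true, po2)
    return float(po2) if np.isscalar(t_rel_ms) else po2


def simulate_transits(
    truth: GroundTruth, duration_s: float, rng: np.random.Generator
) -> list[RBCTransit]:
    """Renewal-process RBC transits over ``[0, duration_s]``.

    Gaps between consecutive cells are gamma(shape=arrival_shape) with
    mean ``1/flow - T_rbc`` so the entry-to-entry interval has mean exactly
    ``1/flow``; the empirical flow converges to ``rbc_flow_true`` and the
    occupancy to ``hematocrit_true / 100``.  A burn-in before t=0 makes
    the process stationary at the recording start; transits straddling the
    recording edges are clipped and flagged truncated.
    """
    if duration_s <= 0:
        raise InvariantError("duration must be > 0")
    T_ms = truth.transit_duration_ms
    gap_mean_ms = 1000.0 / truth.rbc_flow_true - T_ms
    dur_ms = duration_s * 1000.0
    burnin_ms = max(1000.0, 20 * 1000.0 / truth.rbc_flow_true)
    n_expect = int((dur_ms + burnin_ms) * truth.rbc_flow_true / 1000.0)
    shape = truth.arrival_shape
    scale = gap_mean_ms / shape

    transits: list[RBCTransit] = []
    t = -burnin_ms + rng.gamma(shape, scale)
    # draw gaps in blocks to stay vectorized
    while t < dur_ms:
        gaps = rng.gamma(shape, scale, size=max(n_expect, 64))
        for g in gaps:
            entry, exit_ = t, t + T_ms
            if exit_ > 0 and entry < dur_ms:
                transits.append(RBCTransit(
                    max(entry, 0.0), min(exit_, dur_ms), 1.0,
                    truncated_left=entry < 0, truncated_right=exit_ > dur_ms))
            t = exit_ + g
            if t >= dur_ms:
                break
    return transits


def simulate_recording(
    truth: GroundTruth,
    acq: AcquisitionConfig = AcquisitionConfig(),
    n_cycles: int = 40_000,
    calib: CalibrationCurve = CalibrationCurve(),
    metadata: Optional[RecordingMetadata] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Recording, list[RBCTransit]]:
    """Simulate one measurement; returns the Recording and true transits.

    Po2 is evaluated once per cycle at the cycle midpoint (EATs evolve on
    ms scales, three orders of magnitude slower than one cycle).  Photon
    counts are Poisson as described in the module docstring; with the same
    seed the output is identical across runs.
    """
    if n_cycles < 1:
        raise InvariantError("n_cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    duration_s = n_cycles * acq.cycle_period_us * 1e-6
    transits = simulate_transits(truth, duration_s, rng)

    times = acq.cycle_midtimes_ms(n_cycles)
    dist, inside = time_to_nearest_border(times, transits)
    po2 = po2_at(dist, truth)
    tau = lifetime_from_po2(po2, calib)

    fluor_mean = truth.fluor_rate * (1.0 - truth.dip_contrast * inside)
    fluor = rng.poisson(fluor_mean).astype(np.int64)

    bin_scale = acq.bin_width_us / REFERENCE_BIN_WIDTH_US
    lam = (truth.decay_amplitude * bin_scale
           * np.exp(-acq.bin_times_us()[None, :] / tau[:, None])
           + truth.background_rate * bin_scale)
    decays = rng.poisson(lam).astype(np.uint16)

    meta = metadata if metadata is not None else RecordingMetadata(seed=truth.seed)
    rec = Recording(acq, fluor, decays, meta)
    return rec, transits


# ---------------------------------------------------------------------------
# Study-scale generation

#: Depth sampling ranges (µm) used when a group requests capillaries in a
#: named cortical layer; chosen inside the unambiguous classification bands.
LAYER_DEPTH_RANGES = {"I": (10.0, 55.0), "II/III": (95.0, 255.0),
                      "IV": (345.0, 410.0)}


@dataclass(frozen=True)
class CapillaryGroup:
    """A homogeneous group of capillaries in a study specification.

    Capillary-level truths are drawn uniformly from the stated ranges;
    measurement-level truths add Gaussian within-capillary jitter with the
    stated SDs (defaults match the magnitude of within-capillary
    measurement scatter seen in vivo: ~2.6 mm Hg for the interstitial
    value and ~5.4 mm Hg at the erythrocyte).
    """

    n_capillaries: int = 5
    region: str = "cortex"
    depth_range_um: tuple[float, float] = (30.0, 410.0)
    layers: Optional[Sequence[str]] = None   # overrides depth_range_um
    po2_inter_range: tuple[float, float] = (15.0, 35.0)
    eat_amplitude_range: tuple[float, float] = (25.0, 45.0)
    flow_range: tuple[float, float] = (20.0, 50.0)
    hematocrit_range: tuple[float, float] = (25.0, 45.0)
    po2_inter_jitter_sd: float = 2.6
    po2_rbc_jitter_sd: float = 5.4
    flow_jitter_rel_sd: float = 0.1
    hematocrit_jitter_sd: float = 3.0


@dataclass(frozen=True)
class StudySpec:
    groups: tuple[CapillaryGroup, ...] = (CapillaryGroup(),)
    measurements_per_capillary: tuple[int, int] = (4, 8)
    n_cycles: int = 40_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudySpec":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        groups = tuple(
            CapillaryGroup(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in g.items()})
            for g in raw.pop("groups", [{}]))
        for key in ("measurements_per_capillary",):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(groups=groups, **raw)


def default_study_spec(seed: int = 0) -> StudySpec:
    """The default study: 5 capillaries, 4-8 measurements each, 40,000
    cycles (10 s) per measurement."""
    return StudySpec(seed=seed)


def _draw_truth(group: CapillaryGroup, rng: np.random.Generator) -> dict:
    inter = rng.uniform(*group.po2_inter_range)
    amp = rng.uniform(*group.eat_amplitude_range)
    return dict(
        po2_inter_true=inter,
        po2_rbc_true=inter + amp,
        rbc_flow_true=rng.uniform(*group.flow_range),
        hematocrit_true=rng.uniform(*group.hematocrit_range),
    )


def _jitter_truth(base: dict, group: CapillaryGroup,
                  rng: np.random.Generator) -> dict:
    inter = max(1.0, base["po2_inter_true"]
                + rng.normal(0.0, group.po2_inter_jitter_sd))
    rbc = max(inter + 5.0, base["po2_rbc_true"]
              + rng.normal(0.0, group.po2_rbc_jitter_sd))
    flow = max(2.0, base["rbc_flow_true"]
               * (1.0 + rng.normal(0.0, group.flow_jitter_rel_sd)))
    hct = float(np.clip(base["hematocrit_true"]
                        + rng.normal(0.0, group.hematocrit_jitter_sd), 5.0, 90.0))
    return dict(po2_inter_true=inter, po2_rbc_true=rbc,
                rbc_flow_true=flow, hematocrit_true=hct)


def generate_study(
    spec: StudySpec,
    out_dir: Union[str, Path],
    acq: AcquisitionConfig = AcquisitionConfig(),
    calib: CalibrationCurve = CalibrationCurve(),
    base_truth: GroundTruth = GroundTruth(),
) -> pd.DataFrame:
    """Generate a whole study on disk: one recording per measurement plus
    a ground-truth manifest (``manifest.csv``, one row per measurement).

    Per-measurement seeds are spawned deterministically from ``spec.seed``
    and recorded in both the manifest and each recording's metadata.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    rows = []
    cap_counter = 0
    for gi, group in enumerate(spec.groups):
        for _ in range(group.n_capillaries):
            cap_id = f"cap{cap_counter:03d}"
            cap_counter += 1
            if group.layers:
                layer = group.layers[master.integers(len(group.layers))]
                depth = master.uniform(*LAYER_DEPTH_RANGES[layer])
            else:
                depth = master.uniform(*group.depth_range_um)
            cap_truth = _draw_truth(group, master)
            lo, hi = spec.measurements_per_capillary
            n_meas = int(master.integers(lo, hi + 1))
            for mi in range(n_meas):
                meas_truth = _jitter_truth(cap_truth, group, master)
                seed = int(master.integers(2**31 - 1))
                truth = replace(base_truth, seed=seed, **meas_truth)
                meas_id = f"{cap_id}_m{mi}"
                meta = RecordingMetadata(
                    capillary_id=cap_id, region=group.region,
                    depth_um=float(depth), session_id=f"group{gi}",
                    measurement_id=meas_id, seed=seed)
                rec, _ = simulate_recording(truth, acq, spec.n_cycles,
                                            calib, metadata=meta)
                fname = f"{meas_id}.h5"
                write_recording(rec, out_dir / fname)
                rows.append({
                    "measurement_id": meas_id, "capillary_id": cap_id,
                    "region": group.region, "depth_um": float(depth),
                    "session_id": f"group{gi}", "file": fname, "seed": seed,
                    **{k: getattr(truth, k) for k in (
                        "po2_rbc_true", "po2_inter_true", "eat_relax_time_ms",
                        "rbc_flow_true", "hematocrit_true", "dip_contrast",
                        "fluor_rate", "decay_amplitude", "background_rate",
                        "arrival_shape")},
                })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
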