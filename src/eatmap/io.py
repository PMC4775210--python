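"""Reading and writing recordings, results tables and configuration.

A recording is one HDF5 file (schema attribute ``eatmap_schema = 1``) with
groups::

    /acquisition   cycle timing as attributes
    /cycles        fluorescence vector, decay-count matrix, cycle index
    /metadata      capillary id, region, depth, session, measurement, seed

Results tables and ground-truth manifests are plain CSV (UTF-8, comma
separated, "." decimal).  Configuration round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence, Union

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import AcquisitionConfig, Recording, RecordingMetadata
from .exceptions import CorruptFileError, InvariantError, SchemaError

__all__ = [
    "SCHEMA_VERSION",
    "RESULTS_COLUMNS",
    "write_recording",
    "read_recording",
    "write_results_table",
    "read_results_table",
    "load_config",
    "dump_config",
]

SCHEMA_VERSION = 1

_ACQ_FIELDS = ("excitation_period_us", "recording_period_us",
               "cycle_period_us", "sampling_rate_mhz", "discard_bins")
_META_FIELDS = ("capillary_id", "region", "depth_um", "session_id",
                "measurement_id")

#: Fixed column order of the per-measurement results table.
RESULTS_COLUMNS = [
    "measurement_id", "capillary_id", "region", "depth_um", "session_id",
    "po2_rbc", "po2_inter_rbc", "po2_mean", "so2", "rbc_flow", "hematocrit",
    "tau_rbc_us", "tau_rbc_se_us", "n_decays_rbc",
    "tau_inter_us", "tau_inter_se_us", "n_decays_inter",
    "tau_mean_us", "tau_mean_se_us", "n_decays_mean",
]


def write_recording(rec: Recording, path: Union[str, Path]) -> None:
    """Write a validated recording to an HDF5 container.

    Refuses to write anything that does not satisfy the Recording
    invariants (validation happens at construction, so any live Recording
    is writable).  ``read_recording`` restores it bit-exactly.
    """
    if not isinstance(rec, Recording):
        raise InvariantError("write_recording expects a Recording")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["eatmap_schema"] = SCHEMA_VERSION
        g = f.create_group("acquisition")
        for name in _ACQ_FIELDS:
            g.attrs[name] = getattr(rec.acquisition, name)
        c = f.create_group("cycles")
        c.create_dataset("fluorescence", data=rec.fluorescence.astype(np.int64),
                         compression="gzip", compression_opts=4)
        c.create_dataset("decay_counts", data=rec.decay_counts.astype(np.uint16),
                         compression="gzip", compression_opts=4)
        c.create_dataset("cycle_index", data=rec.cycle_index,
                         compression="gzip", compression_opts=4)
        m = f.create_group("metadata")
        for name in _META_FIELDS:
            m.attrs[name] = getattr(rec.metadata, name)
        if rec.metadata.seed is not None:
            m.attrs["seed"] = int(rec.metadata.seed)


def read_recording(path: Union[str, Path]) -> Recording:
    """Read and validate a recording container.

    Raises :class:`CorruptFileError` when the file is not readable HDF5,
    :class:`SchemaError` when it is HDF5 but missing fields, carries an
    unknown schema version, or has a decay matrix whose bin count does not
    match its acquisition timing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise CorruptFileError(f"{path} is not a readable HDF5 file: {e}") from e
    with f:
        version = f.attrs.get("eatmap_schema")
        if version is None:
            raise SchemaError(f"{path}: missing eatmap_schema attribute")
        if int(version) != SCHEMA_VERSION:
            raise SchemaError(f"{path}: unsupported schema version {version}")
        try:
            acq_attrs = {k: f["acquisition"].attrs[k] for k in _ACQ_FIELDS}
            fluor = f["cycles/fluorescence"][()]
            decays = f["cycles/decay_counts"][()]
            idx = f["cycles/cycle_index"][()]
            meta_attrs = {k: f["metadata"].attrs[k] for k in _META_FIELDS}
            seed = f["metadata"].attrs.get("seed")
        except KeyError as e:
            raise SchemaError(f"{path}: missing field {e}") from e
    acq_attrs["discard_bins"] = int(acq_attrs["discard_bins"])
    acq = AcquisitionConfig(**{k: float(v) if k != "discard_bins" else v
                               for k, v in acq_attrs.items()})
    if decays.ndim != 2 or decays.shape[1] != acq.n_bins:
        raise SchemaError(
            f"{path}: decay matrix has {decays.shape} bins, acquisition "
            f"timing implies {acq.n_bins}")
    meta = RecordingMetadata(
        capillary_id=str(meta_attrs["capillary_id"]),
        region=str(meta_attrs["region"]),
        depth_um=float(meta_attrs["depth_um"]),
        session_id=str(meta_attrs["session_id"]),
        measurement_id=str(meta_attrs["measurement_id"]),
        seed=None if seed is None else int(seed),
    )
    return Recording(acq, fluor, decays, meta, cycle_index=idx)


def result_row(metadata: RecordingMetadata, result) -> dict:
    """Flatten one measurement's EATResult (+ metadata) into a table row."""
    d = result.diagnostics
    row = {
        "measurement_id": metadata.measurement_id,
        "capillary_id": metadata.capillary_id,
        "region": metadata.region,
        "depth_um": metadata.depth_um,
        "session_id": metadata.session_id,
        "po2_rbc": result.po2_rbc,
        "po2_inter_rbc": result.po2_inter_rbc,
        "po2_mean": result.po2_mean,
        "so2": result.so2,
        "rbc_flow": result.rbc_flow,
        "hematocrit": result.hematocrit,
    }
    for key, short in (("rbc", "rbc"), ("inter_rbc", "inter"), ("mean", "mean")):
        diag = d.get(key, {})
        row[f"tau_{short}_us"] = diag.get("tau_us", np.nan)
        row[f"tau_{short}_se_us"] = diag.get("tau_se_us", np.nan)
        row[f"n_decays_{short}"] = diag.get("n_decays", 0)
    return row


def write_results_table(rows: Union[pd.DataFrame, Sequence[dict]],
                        path: Union[str, Path]) -> None:
    """Write the per-measurement results table (one row per measurement).

    Values are written at full float precision, comfortably beyond the
    0.1 mm Hg / 0.1% / 0.1 cells/s reporting precision of the quantities.
    An empty input produces a header-only file.
    """
    df = pd.DataFrame(list(rows)) if not isinstance(rows, pd.DataFrame) else rows
    if df.empty:
        df = pd.DataFrame(columns=RESULTS_COLUMNS)
    df = df.reindex(columns=RESULTS_COLUMNS)
    df.to_csv(path, index=False)


def read_results_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"results table missing columns {sorted(missing)}")
    return df


def dump_config(obj, path: Union[str, Path]) -> None:
    """Serialize a (possibly nested) dataclass config to YAML."""
    def to_plain(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: to_plain(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, dict):
            return {k: to_plain(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [to_plain(v) for v in x]
        if isinstance(x, (np.integer,)):
            return int(x)
        if isinstance(x, (np.floating,)):
            return float(x)
        return x

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(to_plain(obj), fh, sort_keys=False)


def load_config(path: Union[str, Path]) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return {} if data is None else data
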