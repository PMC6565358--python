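"""File formats: TSV tables, YAML configs, HDF5 epoch containers.

Every table written by the pipeline carries a comment header with the
package version and a hash of the generating configuration, so outputs can
be traced back to their exact settings.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .erp import EpochSet
from .task import Session

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "session_tables",
    "write_session",
    "write_epochs",
    "read_epochs",
    "load_config",
]


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config) -> str:
    """Stable short hash of any (nested dataclass / dict) configuration."""
    payload = json.dumps(_to_plain(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seqerp {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def session_tables(session: Session) -> dict[str, pd.DataFrame]:
    """trials / sequences / events frames (BIDS-events-like columns)."""
    dur = session.config.trial_duration
    trials = pd.DataFrame(
        dict(index=[t.index for t in session.trials],
             onset_ms=[t.onset for t in session.trials],
             digit=[t.digit for t in session.trials],
             colour=[t.colour for t in session.trials],
             role=[t.role for t in session.trials],
             block=[t.block for t in session.trials])
    )
    sequences = pd.DataFrame(
        dict(sequence=range(len(session.sequences)),
             cue_type=[s.cue_type for s in session.sequences],
             compliance=[s.compliance for s in session.sequences],
             start_index=[s.start_index for s in session.sequences],
             realized_length=[s.realized_length for s in session.sequences],
             block=[s.block for s in session.sequences],
             cued_colour=[s.cued_colour for s in session.sequences])
    )
    events = pd.DataFrame(
        dict(onset_ms=[e.trial_index * dur for e in session.events],
             duration_ms=[dur] * len(session.events),
             trial_index=[e.trial_index for e in session.events],
             klass=[e.klass for e in session.events],
             sequence=[e.sequence for e in session.events],
             uncertainty=[e.uncertainty for e in session.events])
    )
    return dict(trials=trials, sequences=sequences, events=events)


def write_session(session: Session, outdir) -> None:
    outdir = Path(outdir)
    for name, df in session_tables(session).items():
        write_table(df, outdir / f"{name}.tsv", session.config)
    with open(outdir / "task_config.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(session.config), fh)


def write_epochs(epochs: EpochSet, path, config=None) -> None:
    """HDF5 layout: /epochs (n x C x T, uV), /times, /channels, /labels."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        grp = f.create_group("channels")
        grp.create_dataset("names", data=np.array(epochs.channels, dtype="S"))
        grp.create_dataset("coords", data=epochs.coords)
        f.create_dataset("labels",
                         data=np.array(epochs.labels, dtype="S"))
        f.attrs["participant"] = epochs.participant
        f.attrs["seqerp_version"] = __version__
        if config is not None:
            f.attrs["config_hash"] = config_hash(config)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            f["epochs"][()],
            f["times"][()],
            [n.decode() for n in f["channels/names"][()]],
            f["channels/coords"][()],
            [l.decode() for l in f["labels"][()]],
            int(f.attrs.get("participant", 0)),
        )


def load_config(path) -> dict:
    """YAML or JSON pipeline configuration as a plain dict."""
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".json",):
            return json.load(fh)
        return yaml.safe_load(fh)
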