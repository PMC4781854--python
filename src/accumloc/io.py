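"""Reading and writing the epoch container, trial tables, and reports.

The package's signal container is an HDF5 file with layout::

    /signals         channels x samples float32
    /fs              scalar sampling rate (Hz)
    /channel_labels  UTF-8 strings
    /channel_area    UTF-8 Brodmann labels
    /subject_id      attribute on the root group
    /features/{name} optional 50 Hz feature tracks (channels x samples)

Trial/event tables are tab-separated text.  EDF input is supported through
mne when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Session, TrialRecord

__all__ = [
    "write_session",
    "read_session",
    "write_trial_table",
    "read_trial_table",
    "write_features",
    "read_edf_recording",
    "write_tsv",
    "write_json",
]

TRIAL_COLUMNS = [
    "trial_index",
    "stimulus_class",
    "list_length",
    "is_target",
    "summed_similarity",
    "correct",
    "trial_onset_s",
    "probe_onset_s",
    "rt_s",
]


def write_session(path: str | Path, session: Session) -> None:
    """Write signals + channel metadata to the epoch container (HDF5)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=session.signal.astype(np.float32))
        f.create_dataset("fs", data=float(session.fs))
        str_dt = h5py.string_dtype("utf-8")
        f.create_dataset("channel_labels", data=session.channel_labels, dtype=str_dt)
        f.create_dataset("channel_area", data=session.channel_areas, dtype=str_dt)
        f.attrs["subject_id"] = session.subject_id


def read_session(path: str | Path, trials: list[TrialRecord] | None = None) -> Session:
    with h5py.File(path, "r") as f:
        return Session(
            subject_id=str(f.attrs["subject_id"]),
            fs=float(f["fs"][()]),
            signal=f["signals"][()],
            channel_labels=[s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][()]],
            channel_areas=[s.decode() if isinstance(s, bytes) else s for s in f["channel_area"][()]],
            trials=trials or [],
        )


def write_features(path: str | Path, features: dict[str, np.ndarray]) -> None:
    """Append 50 Hz feature tracks under /features/{name}."""
    with h5py.File(path, "a") as f:
        grp = f.require_group("features")
        for name, arr in features.items():
            if name in grp:
                del grp[name]
            grp.create_dataset(name, data=np.asarray(arr, np.float32))


def write_trial_table(path: str | Path, trials: list[TrialRecord]) -> None:
    df = pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in trials],
            "stimulus_class": [t.stimulus_class for t in trials],
            "list_length": [t.list_length for t in trials],
            "is_target": [int(t.is_target) for t in trials],
            "summed_similarity": [t.summed_similarity for t in trials],
            "correct": [int(t.correct) for t in trials],
            "trial_onset_s": [t.trial_onset for t in trials],
            "probe_onset_s": [t.probe_onset for t in trials],
            "rt_s": [t.rt for t in trials],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_trial_table(path: str | Path) -> list[TrialRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table is missing columns: {sorted(missing)}")
    return [
        TrialRecord(
            trial_index=int(r.trial_index),
            stimulus_class=str(r.stimulus_class),
            list_length=int(r.list_length),
            is_target=bool(r.is_target),
            summed_similarity=float(r.summed_similarity),
            correct=bool(r.correct),
            rt=float(r.rt_s),
            trial_onset=float(r.trial_onset_s),
            probe_onset=float(r.probe_onset_s),
            response_time_abs=float(r.probe_onset_s) + float(r.rt_s),
        )
        for r in df.itertuples()
    ]


def read_edf_recording(
    path: str | Path,
    trials: list[TrialRecord],
    subject_id: str,
    channel_areas: list[str],
) -> Session:
    """Load a continuous EDF recording as a Session (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Session(
        subject_id=subject_id,
        fs=float(raw.info["sfreq"]),
        signal=raw.get_data().astype(np.float32),
        channel_labels=list(raw.ch_names),
        channel_areas=channel_areas,
        trials=trials,
    )


def write_feature_bundle(path: str | Path, bundle) -> None:
    """Persist a FeatureBundle: /features/{name} tracks plus window table."""
    from .bands import FEATURES

    str_dt = h5py.string_dtype("utf-8")
    with h5py.File(path, "w") as f:
        grp = f.create_group("features")
        for i, name in enumerate(FEATURES):
            grp.create_dataset(name, data=bundle.data[i].astype(np.float32))
        f.create_dataset("channel_labels", data=bundle.channel_labels, dtype=str_dt)
        f.create_dataset("channel_area", data=bundle.channel_areas, dtype=str_dt)
        f.create_dataset("cell_excluded", data=bundle.cell_excluded)
        f.attrs["subject_id"] = bundle.subject_id
        f.attrs["fs"] = bundle.table.fs
        f.attrs["buffer"] = bundle.table.buffer
        win = f.create_group("windows")
        win.create_dataset("trial_ids", data=bundle.table.trial_ids)
        win.create_dataset("rts", data=bundle.table.rts)
        win.create_dataset("start_idx", data=bundle.table.start_idx)
        win.create_dataset("n_samples", data=bundle.table.n_samples)


def read_feature_bundle(path: str | Path):
    from .bands import FEATURES
    from .spectral import FeatureBundle, WindowTable

    with h5py.File(path, "r") as f:
        table = WindowTable(
            trial_ids=f["windows/trial_ids"][()],
            rts=f["windows/rts"][()],
            start_idx=f["windows/start_idx"][()],
            n_samples=f["windows/n_samples"][()],
            fs=float(f.attrs["fs"]),
            buffer=float(f.attrs["buffer"]),
        )
        data = np.stack([f["features"][name][()] for name in FEATURES])
        return FeatureBundle(
            subject_id=str(f.attrs["subject_id"]),
            channel_labels=[
                s.decode() if isinstance(s, bytes) else s for s in f["channel_labels"][()]
            ],
            channel_areas=[
                s.decode() if isinstance(s, bytes) else s for s in f["channel_area"][()]
            ],
            data=data.astype(float),
            table=table,
            cell_excluded=f["cell_excluded"][()].astype(bool),
        )


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_regressor_tsv(path: str | Path, regressor) -> None:
    """Regressor samples with trial boundaries, for plotting/parity checks."""
    table = regressor.table
    trial_of_sample = np.repeat(table.trial_ids, table.n_samples)
    pd.DataFrame(
        {
            "sample": np.arange(len(regressor.values)),
            "trial_id": trial_of_sample,
            "kind": regressor.kind,
            "value": regressor.values,
        }
    ).to_csv(path, sep="\t", index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
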