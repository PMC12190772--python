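"""On-disk formats: delimited voltage matrices with JSON sidecars, EDF
reading, montage neighbor maps, and ground-truth serialization.

The native recording format is a plain CSV matrix (samples x channels,
header row of channel labels, µV) plus a JSON sidecar holding the sampling
rate, labels, and optional electrode positions — trivially diffable and
re-readable. EDF files are read through :mod:`mne` when it is installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import EEGRecording
from .synth import GroundTruth

__all__ = [
    "read_recording",
    "write_recording",
    "read_montage",
    "write_montage",
    "ground_truth_to_json",
    "ground_truth_from_json",
]


def write_recording(rec: EEGRecording, path: str | Path, sidecar: str | Path | None = None) -> None:
    """CSV matrix + JSON sidecar (fs, channel labels, positions)."""
    path = Path(path)
    pd.DataFrame(rec.data, columns=rec.channel_labels).to_csv(path, index=False)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = {"fs": rec.fs, "channel_labels": rec.channel_labels}
    if rec.positions is not None:
        meta["positions"] = rec.positions.tolist()
    sidecar.write_text(json.dumps(meta, indent=1))


def read_recording(
    path: str | Path,
    sidecar: str | Path | None = None,
    channel_selection: list[str] | None = None,
) -> EEGRecording:
    """Load an EDF file or a delimited matrix + JSON sidecar.

    ``channel_selection`` restricts and orders the channels; naming an
    absent channel is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        rec = _read_edf(path)
    else:
        rec = _read_delimited(path, sidecar)
    if channel_selection is not None:
        missing = [c for c in channel_selection if c not in rec.channel_labels]
        if missing:
            raise ValueError(f"selection names absent channels: {missing}")
        cols = [rec.channel_labels.index(c) for c in channel_selection]
        rec = EEGRecording(
            data=rec.data[:, cols],
            fs=rec.fs,
            channel_labels=list(channel_selection),
            positions=rec.positions[cols] if rec.positions is not None else None,
        )
    return rec


def _read_delimited(path: Path, sidecar: str | Path | None) -> EEGRecording:
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} required for delimited recordings")
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks required field 'fs'")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    labels = meta.get("channel_labels", list(df.columns))
    if list(df.columns) != list(labels):
        raise ValueError(
            f"channel labels in {path.name} disagree with sidecar {sidecar.name}"
        )
    positions = np.asarray(meta["positions"], dtype=float) if "positions" in meta else None
    return EEGRecording(
        data=df.to_numpy(dtype=float), fs=float(meta["fs"]),
        channel_labels=list(labels), positions=positions,
    )


def _read_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("reading EDF requires the 'mne' package (msalpha[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts -> µV
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]), channel_labels=list(raw.ch_names))


def write_montage(neighbor_map: dict[str, list[str]], path: str | Path,
                  positions: dict[str, list[float]] | None = None) -> None:
    payload: dict = {"neighbors": neighbor_map}
    if positions:
        payload["positions"] = positions
    Path(path).write_text(json.dumps(payload, indent=1))


def read_montage(path: str | Path) -> tuple[dict[str, list[str]], dict[str, list[float]] | None]:
    payload = json.loads(Path(path).read_text())
    if "neighbors" not in payload:
        raise ValueError(f"montage {path} lacks 'neighbors'")
    return payload["neighbors"], payload.get("positions")


def ground_truth_to_json(gt: GroundTruth) -> str:
    d = {
        "templates": gt.templates.tolist(),
        "tp_matrix": gt.tp_matrix.tolist(),
        "mean_durations": gt.mean_durations.tolist(),
        "alpha_cf": gt.alpha_cf,
        "alpha_peak_power": gt.alpha_peak_power,
        "aperiodic_offset": gt.aperiodic_offset,
        "aperiodic_exponent": gt.aperiodic_exponent,
        "seed": gt.seed,
    }
    if gt.label_sequence is not None:
        # run-length encode: compact and loss-free
        labels = np.asarray(gt.label_sequence)
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change, [len(labels)]])
        d["label_rle"] = [
            [int(labels[starts[i]]), int(starts[i + 1] - starts[i])]
            for i in range(len(starts) - 1)
        ]
    return json.dumps(d)


def ground_truth_from_json(text: str) -> GroundTruth:
    d = json.loads(text)
    labels = None
    if "label_rle" in d:
        labels = np.concatenate(
            [np.full(n, state, dtype=np.int64) for state, n in d["label_rle"]]
        )
    return GroundTruth(
        templates=np.asarray(d["templates"]),
        tp_matrix=np.asarray(d["tp_matrix"]),
        mean_durations=np.asarray(d["mean_durations"]),
        alpha_cf=d["alpha_cf"],
        alpha_peak_power=d["alpha_peak_power"],
        aperiodic_offset=d["aperiodic_offset"],
        aperiodic_exponent=d["aperiodic_exponent"],
        seed=d["seed"],
        label_sequence=labels,
    )
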