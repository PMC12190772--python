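"""Raw-recording cleanup: filters, epoching, channel repair, re-referencing.

Stage order in :func:`preprocess_pipeline` is fixed: notch -> band-pass ->
non-overlapping epochs -> artifact-epoch rejection -> per-epoch bad-channel
detection and neighbor interpolation -> average reference. All filters are
zero-phase (forward-backward IIR), so microstate timing downstream is not
phase-shifted.

The artifact rejector is a documented amplitude + gradient threshold
stand-in for unspecified visual/algorithmic screening of real recordings.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal

from .core import EEGRecording, EpochSet

__all__ = [
    "bandpass_filter",
    "notch_filter",
    "segment_epochs",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference_average",
    "reject_artifact_epochs",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)


def bandpass_filter(rec: EEGRecording, low: float = 1.0, high: float = 45.0,
                    order: int = 6) -> EEGRecording:
    """Zero-phase Butterworth band-pass between ``low`` and ``high`` Hz."""
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got {low}, {high}")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=0))


def notch_filter(rec: EEGRecording, freq: float = 50.0, quality: float = 30.0) -> EEGRecording:
    """Zero-phase IIR notch at the mains frequency (default 50 Hz)."""
    nyq = rec.fs / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} Hz outside (0, {nyq})")
    b, a = signal.iirnotch(freq, quality, fs=rec.fs)
    return rec.copy_with(signal.filtfilt(b, a, rec.data, axis=0))


def segment_epochs(rec: EEGRecording, epoch_length_s: float = 4.0) -> EpochSet:
    """Cut into non-overlapping fixed-length epochs; remainder is discarded."""
    n_per = int(round(epoch_length_s * rec.fs))
    n_epochs = rec.n_samples // n_per
    if n_epochs == 0:
        warnings.warn(
            f"recording ({rec.duration_s:.2f} s) shorter than one "
            f"{epoch_length_s} s epoch; returning empty set"
        )
    epochs = [
        rec.copy_with(rec.data[i * n_per : (i + 1) * n_per]) for i in range(n_epochs)
    ]
    return EpochSet(epochs=epochs, epoch_length_s=epoch_length_s)


def detect_bad_channels(epoch: EEGRecording, threshold_uv: float = 200.0) -> list[str]:
    """Channels whose absolute voltage strictly exceeds ``threshold_uv`` anywhere.

    A sample at exactly the threshold passes (strict inequality convention).
    """
    exceed = np.any(np.abs(epoch.data) > threshold_uv, axis=0)
    return [epoch.channel_labels[i] for i in np.flatnonzero(exceed)]


def interpolate_channels(
    epoch: EEGRecording, bad: list[str], neighbor_map: dict[str, list[str]]
) -> EEGRecording:
    """Replace bad channels with the (distance-weighted) mean of good neighbors.

    Weights are inverse Euclidean distance when channel positions are
    available; otherwise the unweighted mean of the listed neighbors.
    """
    if not bad:
        return epoch.copy_with(epoch.data.copy())
    idx = {label: i for i, label in enumerate(epoch.channel_labels)}
    bad_set = set(bad)
    data = epoch.data.copy()
    for label in bad:
        if label not in idx:
            raise KeyError(f"bad channel {label!r} not in recording")
        neighbors = [n for n in neighbor_map.get(label, []) if n in idx and n not in bad_set]
        if not neighbors:
            raise ValueError(f"channel {label!r} has no good neighbors to interpolate from")
        cols = [idx[n] for n in neighbors]
        if epoch.positions is not None:
            dist = np.linalg.norm(
                epoch.positions[cols] - epoch.positions[idx[label]], axis=1
            )
            w = 1.0 / np.maximum(dist, 1e-9)
        else:
            w = np.ones(len(cols))
        w = w / w.sum()
        data[:, idx[label]] = epoch.data[:, cols] @ w
    return epoch.copy_with(data)


def rereference_average(epoch: EEGRecording) -> EEGRecording:
    """Subtract the per-sample mean across channels (average reference)."""
    if epoch.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return epoch.copy_with(epoch.data - epoch.data.mean(axis=1, keepdims=True))


def reject_artifact_epochs(
    epochs: EpochSet,
    amplitude_uv: float = 400.0,
    gradient_uv_per_ms: float = 100.0,
) -> EpochSet:
    """Drop epochs with extreme amplitude or sample-to-sample gradient.

    An epoch is rejected when any |v| exceeds ``amplitude_uv`` or any
    per-sample step exceeds ``gradient_uv_per_ms`` scaled to the sampling
    interval. This is a threshold stand-in for manual/automatic artifact
    screening of real data (blinks, EMG, movement); the synthetic generator
    produces none of those, so default thresholds are generous.
    """
    if amplitude_uv <= 0 or gradient_uv_per_ms <= 0:
        raise ValueError("thresholds must be positive")
    kept = []
    for e in epochs:
        step_limit = gradient_uv_per_ms * 1000.0 / e.fs
        max_amp = float(np.max(np.abs(e.data))) if e.n_samples else 0.0
        max_step = float(np.max(np.abs(np.diff(e.data, axis=0)))) if e.n_samples > 1 else 0.0
        if max_amp > amplitude_uv or max_step > step_limit:
            continue
        kept.append(e)
    n_rejected = len(epochs) - len(kept)
    if n_rejected:
        logger.info("rejected %d/%d epochs as artifacts", n_rejected, len(epochs))
    if not kept:
        warnings.warn("all epochs rejected by artifact thresholds")
    return EpochSet(
        epochs=kept,
        epoch_length_s=epochs.epoch_length_s,
        rejected_count=epochs.rejected_count + n_rejected,
        interpolation_log=epochs.interpolation_log,
    )


def preprocess_pipeline(
    rec: EEGRecording,
    neighbor_map: dict[str, list[str]] | None = None,
    notch_hz: float | None = 50.0,
    band: tuple[float, float] = (1.0, 45.0),
    epoch_length_s: float = 4.0,
    bad_channel_uv: float = 200.0,
    artifact_amplitude_uv: float = 400.0,
    artifact_gradient_uv_per_ms: float = 100.0,
) -> EpochSet:
    """Full cleanup of one recording in the fixed stage order.

    Bad channels are detected per epoch and interpolated when a neighbor map
    is provided (an epoch whose bad channels cannot be repaired is dropped);
    every surviving epoch ends average-referenced.
    """
    if notch_hz is not None:
        rec = notch_filter(rec, notch_hz)
    rec = bandpass_filter(rec, band[0], band[1])
    epoch_set = segment_epochs(rec, epoch_length_s)
    epoch_set = reject_artifact_epochs(
        epoch_set, artifact_amplitude_uv, artifact_gradient_uv_per_ms
    )
    cleaned, log, dropped = [], [], 0
    for e in epoch_set:
        bad = detect_bad_channels(e, bad_channel_uv)
        if bad:
            if neighbor_map is None:
                dropped += 1
                continue
            try:
                e = interpolate_channels(e, bad, neighbor_map)
            except ValueError:
                dropped += 1
                continue
        cleaned.append(rereference_average(e))
        log.append(bad)
    if dropped:
        logger.info("dropped %d epochs with unrepairable channels", dropped)
    return EpochSet(
        epochs=cleaned,
        epoch_length_s=epoch_length_s,
        rejected_count=epoch_set.rejected_count + dropped,
        interpolation_log=log,
    )
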