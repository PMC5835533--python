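"""Epoch preprocessing: band-pass filter, artifact rejection, condition
collapsing, baseline correction and condition averaging.

Pipeline order is filter -> reject -> collapse -> (baseline) -> average.
Collapsing and averaging are idempotent; rejection only ever adds flags.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EpochSet, EvokedTable

__all__ = [
    "bandpass",
    "baseline_correct",
    "reject_epochs",
    "collapse_conditions",
    "average_evoked",
    "RejectionError",
]

#: ms at each epoch edge considered untrusted after zero-phase filtering
EDGE_EXCLUSION_MS = 50.0


class RejectionError(RuntimeError):
    """Artifact rejection would leave fewer than 2 trials in a condition."""


def bandpass(epochs: EpochSet, low_hz: float = 1.0, high_hz: float = 120.0) -> EpochSet:
    """Zero-phase Butterworth band-pass (4th order, forward-backward).

    Removes DC and slow drifts below ``low_hz`` and high-frequency content
    above ``high_hz``. The corner must stay below Nyquist; at 512 Hz a
    1-120 Hz band passes.
    """
    nyq = epochs.fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist ({nyq} Hz)")
    sos = signal.butter(4, [low_hz, high_hz], btype="band", fs=epochs.fs, output="sos")
    out = epochs.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1)
    return out


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/electrode's mean pre-stimulus (t < 0) amplitude."""
    pre = epochs.times < 0.0
    if not pre.any():
        raise ValueError("no pre-stimulus samples to baseline on")
    out = epochs.copy()
    out.data = out.data - out.data[:, :, pre].mean(axis=-1, keepdims=True)
    return out


def reject_epochs(epochs: EpochSet, z_threshold: float = 6.0) -> EpochSet:
    """Flag trials containing high-amplitude transients.

    A stand-in for visual inspection: per electrode and condition, each
    trial's deviation from the across-trial median waveform is z-scored
    robustly (median/MAD of the pooled residuals); a trial is flagged when
    any sample at any electrode exceeds ``z_threshold``. The first and last
    ``EDGE_EXCLUSION_MS`` of the epoch are not scanned: zero-phase filtering
    leaves transients there, and those samples are flagged untrusted in
    reports anyway. Existing flags are never removed.

    Raises
    ------
    RejectionError
        if flagging would leave fewer than 2 usable trials in any condition.
    """
    out = epochs.copy()
    if not np.isfinite(z_threshold):
        return out
    trusted = (out.times >= out.times[0] + EDGE_EXCLUSION_MS) & (
        out.times <= out.times[-1] - EDGE_EXCLUSION_MS
    )
    newly_flagged = np.zeros(out.n_trials, dtype=bool)
    for cond in out.conditions:
        mask = out.kept(cond)
        if mask.sum() < 3:
            raise ValueError(f"need >= 3 trials in condition {cond!r} before rejection")
        block = out.data[mask][:, :, trusted]  # (trials, electrodes, samples)
        resid = block - np.median(block, axis=0, keepdims=True)
        mad = np.median(np.abs(resid), axis=(0, 2), keepdims=True)  # per electrode
        scale = np.where(mad > 0, mad / 0.6744897501960817, np.inf)
        z = np.abs(resid) / scale
        bad = (z > z_threshold).any(axis=(1, 2))
        idx = np.flatnonzero(mask)[bad]
        newly_flagged[idx] = True
    out.rejected = out.rejected | newly_flagged
    for cond in out.conditions:
        if out.kept(cond).sum() < 2:
            raise RejectionError(
                f"rejection at z={z_threshold} leaves <2 trials in condition {cond!r}"
            )
    return out


def collapse_conditions(epochs: EpochSet, mapping: dict[str, str]) -> EpochSet:
    """Relabel conditions (e.g. past -> then, future -> then, now -> now).

    Pure relabeling: trial count and data are untouched. Every label present
    in the data must appear in ``mapping``.
    """
    present = set(epochs.conditions)
    missing = present - set(mapping)
    if missing:
        raise ValueError(f"mapping missing labels present in data: {sorted(missing)}")
    out = epochs.copy()
    out.condition = np.array([mapping[str(c)] for c in epochs.condition], dtype=object)
    return out


def average_evoked(epochs: EpochSet) -> EvokedTable:
    """Mean iEP per (electrode, condition) over non-rejected trials."""
    conditions = epochs.conditions
    n_elec = epochs.n_electrodes
    data = np.empty((n_elec, len(conditions), epochs.n_samples))
    n_trials = np.zeros((n_elec, len(conditions)), dtype=int)
    for c, cond in enumerate(conditions):
        mask = epochs.kept(cond)
        if mask.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 usable trials")
        data[:, c, :] = epochs.data[mask].mean(axis=0)
        n_trials[:, c] = mask.sum()
    return EvokedTable(
        data=data,
        times=epochs.times.copy(),
        fs=epochs.fs,
        electrode_ids=list(epochs.electrode_ids),
        conditions=conditions,
        n_trials=n_trials,
        task=epochs.task,
    )
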