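"""Task-modulation features of evoked responses.

For each electrode the between-condition modulation in a time window is the
absolute signed area between the two mean iEPs, normalized by the absolute
area under the baseline condition's iEP in the same window:

    modulation = |∫_w S_b(t) − S_a(t) dt| / |∫_w S_a(t) dt|

with the early window spanning 100-400 ms post-stimulus and the late window
400-800 ms. The feature is dimensionless, non-negative, invariant to a
common rescaling of both waveforms and — crucially for depth electrodes,
whose recording polarity depends on their position relative to the local
generator — invariant to a global sign flip.

The normalization uses the absolute *signed* integral of the baseline
waveform; an ``abs_auc`` flag switches to the rectified area ∫|S_a| for the
alternative reading of "area under the curve".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CONDITION_PAIRS, ElectrodeMeta, EvokedTable

__all__ = [
    "window_integral",
    "raw_modulation",
    "task_modulation",
    "features_for_dataset",
    "DegenerateDenominatorError",
    "EARLY_WINDOW",
    "LATE_WINDOW",
]

EARLY_WINDOW = (100.0, 400.0)
LATE_WINDOW = (400.0, 800.0)


class DegenerateDenominatorError(ZeroDivisionError):
    """Baseline-condition window integral is numerically zero."""


def window_integral(
    waveform: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> float:
    """Signed trapezoidal area (µV·ms) of ``waveform`` over ``window``.

    The waveform is treated as piecewise linear between samples; the window
    boundaries are hit exactly by linear interpolation, so the value is
    independent of whether a sample happens to fall on a boundary. Windows
    are half-open ``[w0, w1)`` by convention; for the continuous integral
    the excluded endpoint has measure zero.
    """
    waveform = np.asarray(waveform, dtype=float)
    times = np.asarray(times, dtype=float)
    w0, w1 = float(window[0]), float(window[1])
    if not (w0 < w1):
        raise ValueError(f"empty or inverted window {window}")
    if w0 < times[0] or w1 > times[-1]:
        raise ValueError(f"window {window} outside time axis [{times[0]}, {times[-1]}] ms")
    inner = (times > w0) & (times < w1)
    grid = np.concatenate(([w0], times[inner], [w1]))
    vals = np.concatenate(
        ([np.interp(w0, times, waveform)], waveform[inner], [np.interp(w1, times, waveform)])
    )
    return float(np.trapezoid(vals, grid))


def raw_modulation(
    s_a: np.ndarray, s_b: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> float:
    """|signed area between the two condition waveforms| in µV·ms."""
    return abs(window_integral(np.asarray(s_b) - np.asarray(s_a), times, window))


def _denominator(
    s_a: np.ndarray, times: np.ndarray, window: tuple[float, float], abs_auc: bool
) -> float:
    if abs_auc:
        return window_integral(np.abs(s_a), times, window)
    return abs(window_integral(s_a, times, window))


def task_modulation(
    s_a: np.ndarray,
    s_b: np.ndarray,
    times: np.ndarray,
    window: tuple[float, float],
    abs_auc: bool = False,
) -> float:
    """Normalized task modulation (dimensionless, >= 0).

    Raises
    ------
    DegenerateDenominatorError
        when the baseline integral is numerically zero, i.e. below
        ``1e-9 * window_length * max|s_a|``. Such electrodes must be
        excluded rather than silently assigned 0.
    """
    s_a = np.asarray(s_a, dtype=float)
    denom = _denominator(s_a, times, window, abs_auc)
    eps = 1e-9 * (window[1] - window[0]) * max(np.max(np.abs(s_a)), np.finfo(float).tiny)
    if denom <= eps:
        raise DegenerateDenominatorError(
            f"baseline integral {denom:.3g} µV·ms below tolerance {eps:.3g} in window {window}"
        )
    return raw_modulation(s_a, s_b, times, window) / denom


@dataclass(frozen=True)
class ModulationFeatures:
    """Early/late task-modulation pair of one electrode."""

    electrode_id: str
    early: float
    late: float
    task: str
    early_window: tuple[float, float]
    late_window: tuple[float, float]


def features_for_dataset(
    evoked: EvokedTable,
    meta: list[ElectrodeMeta],
    early_window: tuple[float, float] = EARLY_WINDOW,
    late_window: tuple[float, float] = LATE_WINDOW,
    abs_auc: bool = False,
) -> pd.DataFrame:
    """Early/late modulation features for every electrode of a dataset.

    Returns a DataFrame with columns ``electrode_id, region, hemisphere,
    patient, task, early, late``. Electrodes whose baseline integral is
    degenerate in either window are excluded with a warning (their ids go
    to the DataFrame's ``attrs['excluded']``).
    """
    cond_a, cond_b = CONDITION_PAIRS[evoked.task]
    for cond in (cond_a, cond_b):
        if cond not in evoked.conditions:
            raise ValueError(f"evoked table lacks condition {cond!r} for task {evoked.task!r}")
    meta_by_id = {m.electrode_id: m for m in meta}
    rows, excluded = [], []
    for eid in evoked.electrode_ids:
        s_a = evoked.waveform(eid, cond_a)
        s_b = evoked.waveform(eid, cond_b)
        try:
            early = task_modulation(s_a, s_b, evoked.times, early_window, abs_auc)
            late = task_modulation(s_a, s_b, evoked.times, late_window, abs_auc)
        except DegenerateDenominatorError as exc:
            warnings.warn(
                f"electrode {eid}: degenerate baseline denominator, excluded ({exc})",
                stacklevel=2,
            )
            excluded.append(eid)
            continue
        m = meta_by_id.get(eid)
        rows.append(
            {
                "electrode_id": eid,
                "region": m.region.value if m else "OTHER",
                "hemisphere": m.hemisphere.value if m else "",
                "patient": m.patient if m else "",
                "task": evoked.task,
                "early": early,
                "late": late,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["electrode_id", "region", "hemisphere", "patient", "task", "early", "late"]
    )
    frame.attrs["excluded"] = excluded
    frame.attrs["early_window"] = tuple(early_window)
    frame.attrs["late_window"] = tuple(late_window)
    return frame
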