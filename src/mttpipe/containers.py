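"""Core in-memory containers for epoched intracranial EEG data.

The analysis operates on fixed-length stimulus-locked epochs recorded from
depth electrodes. Three containers move through the pipeline:

``EpochSet``
    trials x electrodes x samples voltage array with per-trial condition
    labels and rejection flags.
``ElectrodeMeta``
    per-electrode identity: region (lateral temporal cortex, hippocampal
    formation, or other), hemisphere and patient.
``EvokedTable``
    per-(electrode, condition) mean waveforms -- the intracranial evoked
    potentials (iEPs) that the task-modulation features are computed from.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "Region",
    "Hemisphere",
    "ElectrodeMeta",
    "EpochSet",
    "EvokedTable",
    "CONDITION_PAIRS",
]

#: baseline-first condition pair for each supported task
CONDITION_PAIRS = {"time": ("now", "then"), "space": ("here", "there")}


class Region(str, Enum):
    LTC = "LTC"
    HIPP = "HIPP"
    OTHER = "OTHER"


class Hemisphere(str, Enum):
    LEFT = "L"
    RIGHT = "R"


@dataclass(frozen=True)
class ElectrodeMeta:
    """Identity and anatomical labelling of one depth-electrode contact."""

    electrode_id: str
    region: Region
    hemisphere: Hemisphere
    patient: str = "sim"

    def __post_init__(self) -> None:
        object.__setattr__(self, "region", Region(self.region))
        object.__setattr__(self, "hemisphere", Hemisphere(self.hemisphere))


@dataclass
class EpochSet:
    """Trial-level epoched voltages for one task block.

    Attributes
    ----------
    data
        ``(n_trials, n_electrodes, n_samples)`` float array, microvolts.
    times
        Millisecond axis of length ``n_samples``; ``times[0]`` is the epoch
        start (negative = pre-stimulus).
    fs
        Sampling rate in Hz.
    condition
        Per-trial condition label (e.g. ``now`` / ``then``).
    phase
        Per-trial secondary factor of the 2x2 design (``before`` /
        ``after``); carried as metadata only.
    rejected
        Per-trial artifact flag; rejected trials are excluded from averages
        and statistics.
    electrode_ids
        Column labels for the electrode axis.
    task
        ``"time"`` or ``"space"``.
    """

    data: np.ndarray
    times: np.ndarray
    fs: float
    condition: np.ndarray
    rejected: np.ndarray
    electrode_ids: list[str]
    task: str = "time"
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.condition = np.asarray(self.condition, dtype=object)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, electrodes, samples)")
        n_trials, n_elec, n_samples = self.data.shape
        if len(self.times) != n_samples:
            raise ValueError("times length does not match sample axis")
        if len(self.condition) != n_trials or len(self.rejected) != n_trials:
            raise ValueError("per-trial arrays do not match trial axis")
        if len(self.electrode_ids) != n_elec:
            raise ValueError("electrode_ids do not match electrode axis")
        if len(set(self.electrode_ids)) != n_elec:
            raise ValueError("electrode_ids must be unique")
        dt = 1000.0 / self.fs
        if n_samples > 1 and not np.allclose(np.diff(self.times), dt, rtol=1e-9):
            raise ValueError("times spacing must equal 1000/fs ms")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if len(self.phase) != n_trials:
                raise ValueError("phase does not match trial axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(str(c), None)
        return list(seen)

    def electrode_index(self, electrode_id: str) -> int:
        try:
            return self.electrode_ids.index(electrode_id)
        except ValueError:
            raise KeyError(f"unknown electrode_id {electrode_id!r}") from None

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Boolean trial mask: not rejected, optionally within one condition."""
        mask = ~self.rejected
        if condition is not None:
            mask = mask & (self.condition == condition)
        return mask

    def copy(self) -> "EpochSet":
        return replace(
            self,
            data=self.data.copy(),
            times=self.times.copy(),
            condition=self.condition.copy(),
            rejected=self.rejected.copy(),
            electrode_ids=list(self.electrode_ids),
            phase=None if self.phase is None else self.phase.copy(),
        )


@dataclass
class EvokedTable:
    """Per-(electrode, condition) mean iEP waveforms.

    ``data[e, c]`` is the arithmetic mean over non-rejected trials of
    condition ``conditions[c]`` at electrode ``electrode_ids[e]``;
    ``n_trials[e, c]`` records how many trials entered each cell.
    """

    data: np.ndarray  # (n_electrodes, n_conditions, n_samples)
    times: np.ndarray
    fs: float
    electrode_ids: list[str]
    conditions: list[str]
    n_trials: np.ndarray
    task: str = "time"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        if self.data.shape[:2] != self.n_trials.shape:
            raise ValueError("n_trials shape mismatch")
        if self.data.shape[2] != len(self.times):
            raise ValueError("waveform length does not match times")
        if np.any(self.n_trials < 2):
            raise ValueError("every (electrode, condition) cell needs >= 2 trials")

    def waveform(self, electrode_id: str, condition: str) -> np.ndarray:
        e = self.electrode_ids.index(electrode_id)
        c = self.conditions.index(condition)
        return self.data[e, c]
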