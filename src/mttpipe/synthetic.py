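"""Trial-level intracranial evoked-potential simulator.

Real stereo-EEG epochs from self-projection experiments are not publicly
depositable, so every downstream stage is exercised on synthetic data with
the same statistical structure: a small set of depth electrodes in the
lateral temporal cortex (LTC) and hippocampal formation (HIPP) of each
hemisphere, ~120 trials per task block split over a 2x2 condition design,
stimulus-locked epochs from -100 to +800 ms, and region-specific condition
effects — an early (~100-300 ms) amplitude modulation at LTC electrodes and
a late (~400-600 ms) modulation at hippocampal electrodes.

The evoked kernel is a sum of Gaussian deflections; condition effects are
injected multiplicatively inside their time windows with a raised-cosine
taper so that the band-pass filter downstream sees no step edges. Each
electrode may have its recording polarity flipped (depth contacts on
opposite sides of a local generator record sign-inverted potentials), and a
small fraction of trials carries an unflagged high-amplitude transient that
the automated rejection stage must find.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import CONDITION_PAIRS, ElectrodeMeta, EpochSet

__all__ = ["GeneratorConfig", "generate_evoked_template", "generate_dataset"]

#: default evoked kernel: an early positivity and a later slow wave of
#: opposite polarity, as in typical biphasic depth-electrode iEPs. The two
#: areas nearly cancel over the epoch, so the 1 Hz high-pass (applied to the
#: epoch rather than a continuous recording) barely perturbs the window
#: integrals, while each analysis window keeps a large baseline area for the
#: modulation features to normalize by.
DEFAULT_COMPONENTS = ((150.0, 40.0, 10.0), (500.0, 58.0, -6.9))


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the simulator.

    Counts default to the implanted-electrode composition the pipeline is
    designed around (6 LTC + 6 HIPP left, 3 LTC + 5 HIPP right). Effects are
    dimensionless multiplicative condition modulations: inside
    ``effect_window_early`` the non-baseline condition template at LTC
    electrodes equals the baseline template times ``1 + early_effect``
    (likewise late/HIPP).
    """

    n_ltc_left: int = 6
    n_hipp_left: int = 6
    n_ltc_right: int = 3
    n_hipp_right: int = 5
    trials_per_condition: int = 60
    sampling_rate: float = 512.0
    epoch_window: tuple[float, float] = (-100.0, 800.0)
    component_spec: tuple[tuple[float, float, float], ...] = DEFAULT_COMPONENTS
    early_effect: float = 0.5
    late_effect: float = 0.5
    effect_window_early: tuple[float, float] = (100.0, 300.0)
    effect_window_late: tuple[float, float] = (400.0, 600.0)
    taper_ms: float = 20.0
    noise_sd: float = 1.5
    polarity_flip_prob: float = 0.3
    artifact_rate: float = 0.02
    task: str = "time"
    seed: int = 0

    def __post_init__(self) -> None:
        start, end = self.epoch_window
        if not (start < 0.0 < end):
            raise ValueError("epoch_window must straddle stimulus onset (start < 0 < end)")
        for w in (self.effect_window_early, self.effect_window_late):
            if not (0.0 <= w[0] < w[1] <= end):
                raise ValueError(f"effect window {w} must lie within [0, epoch end]")
        counts = (
            self.n_ltc_left + self.n_hipp_left + self.n_ltc_right + self.n_hipp_right,
            self.trials_per_condition,
        )
        if min(counts) <= 0:
            raise ValueError("electrode and trial counts must be positive")
        for name in ("polarity_flip_prob", "artifact_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.task not in CONDITION_PAIRS:
            raise ValueError(f"task must be one of {sorted(CONDITION_PAIRS)}")

    def times(self) -> np.ndarray:
        """Millisecond sample axis of one epoch.

        The grid starts at the epoch start and extends to the first sample at
        or beyond the epoch end, so integration windows touching the epoch
        end stay inside the axis.
        """
        dt = 1000.0 / self.sampling_rate
        n = int(math.ceil((self.epoch_window[1] - self.epoch_window[0]) / dt - 1e-9)) + 2
        return self.epoch_window[0] + dt * np.arange(n)


def generate_evoked_template(
    component_spec: tuple[tuple[float, float, float], ...] | list, times: np.ndarray
) -> np.ndarray:
    """Sum-of-Gaussians evoked kernel.

    Each component ``(latency_ms, width_ms, amplitude_uv)`` contributes
    ``A * exp(-(t - mu)^2 / (2 sigma^2))``; an empty component list yields
    the zero waveform.
    """
    times = np.asarray(times, dtype=float)
    wave = np.zeros_like(times)
    for comp in component_spec:
        mu, sigma, amp = (float(v) for v in comp)
        if not all(np.isfinite([mu, sigma, amp])) or sigma <= 0:
            raise ValueError(f"non-finite or degenerate component {comp}")
        wave += amp * np.exp(-((times - mu) ** 2) / (2.0 * sigma**2))
    return wave


def raised_cosine_window(
    times: np.ndarray, window: tuple[float, float], taper_ms: float
) -> np.ndarray:
    """Indicator of ``window`` with raised-cosine flanks of ``taper_ms``.

    Equals 1 on ``[w0 + taper, w1 - taper]``, 0 outside ``[w0, w1]``, and
    follows half-cosine ramps inside the taper bands, so multiplicative
    effects switch on and off smoothly.
    """
    w0, w1 = window
    taper = min(taper_ms, (w1 - w0) / 2.0)
    t = np.asarray(times, dtype=float)
    env = np.zeros_like(t)
    inside = (t >= w0) & (t <= w1)
    env[inside] = 1.0
    if taper > 0:
        rise = inside & (t < w0 + taper)
        env[rise] = 0.5 * (1.0 - np.cos(np.pi * (t[rise] - w0) / taper))
        fall = inside & (t > w1 - taper)
        env[fall] = 0.5 * (1.0 - np.cos(np.pi * (w1 - t[fall]) / taper))
    return env


def _electrode_rng(seed: int, index: int) -> np.random.Generator:
    # substream per electrode: adding electrodes never perturbs existing ones
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _dataset_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0xA11CE,)))


def condition_templates(config: GeneratorConfig, region: str) -> dict[str, np.ndarray]:
    """Noise-free per-condition templates for an electrode of ``region``."""
    times = config.times()
    base = generate_evoked_template(config.component_spec, times)
    cond_a, cond_b = CONDITION_PAIRS[config.task]
    if region == "LTC":
        env = raised_cosine_window(times, config.effect_window_early, config.taper_ms)
        modulated = base * (1.0 + config.early_effect * env)
    elif region == "HIPP":
        env = raised_cosine_window(times, config.effect_window_late, config.taper_ms)
        modulated = base * (1.0 + config.late_effect * env)
    else:
        modulated = base.copy()
    return {cond_a: base, cond_b: modulated}


def _electrode_plan(config: GeneratorConfig) -> list[ElectrodeMeta]:
    plan = []
    groups = [
        ("LTC", "L", config.n_ltc_left),
        ("HIPP", "L", config.n_hipp_left),
        ("LTC", "R", config.n_ltc_right),
        ("HIPP", "R", config.n_hipp_right),
    ]
    k = 0
    for region, hemi, n in groups:
        for j in range(n):
            plan.append(
                ElectrodeMeta(
                    electrode_id=f"{hemi.lower()}_{region.lower()}{j + 1:02d}",
                    region=region,
                    hemisphere=hemi,
                    patient="sim",
                )
            )
            k += 1
    return plan


def generate_dataset(config: GeneratorConfig) -> tuple[EpochSet, list[ElectrodeMeta]]:
    """Simulate one task block.

    Returns an :class:`EpochSet` (no trials pre-flagged: artifact trials are
    left for the rejection stage to find) and the electrode metadata list.
    The same ``config.seed`` always yields bit-identical output.
    """
    meta = _electrode_plan(config)
    times = config.times()
    n_samples = len(times)
    cond_a, cond_b = CONDITION_PAIRS[config.task]
    n_per = config.trials_per_condition
    n_trials = 2 * n_per

    condition = np.array([cond_a] * n_per + [cond_b] * n_per, dtype=object)
    # before/after factor of the 2x2 design: metadata only, no injected effect
    phase = np.array(
        [("before" if i % 2 == 0 else "after") for i in range(n_trials)], dtype=object
    )

    data = np.empty((n_trials, len(meta), n_samples))
    for e, m in enumerate(meta):
        rng = _electrode_rng(config.seed, e)
        templates = condition_templates(config, m.region.value)
        trial_wave = np.empty((n_trials, n_samples))
        trial_wave[:n_per] = templates[cond_a]
        trial_wave[n_per:] = templates[cond_b]
        trial_wave = trial_wave + rng.normal(0.0, config.noise_sd, (n_trials, n_samples))
        if rng.random() < config.polarity_flip_prob:
            trial_wave = -trial_wave
        data[:, e, :] = trial_wave

    # widespread high-amplitude transients on a random subset of trials,
    # drawn from a dataset-level substream; deliberately NOT flagged
    rng_ds = _dataset_rng(config.seed)
    artifact = rng_ds.random(n_trials) < config.artifact_rate
    for i in np.flatnonzero(artifact):
        latency = rng_ds.uniform(times[0] + 50.0, times[-1] - 50.0)
        width = 15.0
        sign = rng_ds.choice([-1.0, 1.0])
        burst = (
            sign
            * 10.0
            * config.noise_sd
            * np.exp(-((times - latency) ** 2) / (2.0 * width**2))
        )
        data[i] += burst[None, :]

    epochs = EpochSet(
        data=data,
        times=times,
        fs=config.sampling_rate,
        condition=condition,
        rejected=np.zeros(n_trials, dtype=bool),
        electrode_ids=[m.electrode_id for m in meta],
        task=config.task,
        phase=phase,
    )
    return epochs, meta
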