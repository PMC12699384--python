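"""Headless trial loop: scheduling, adaptive staircases and trial logging.

The engine runs a target-in-noise detection or categorization experiment
against any *responder* (a callable mapping a :class:`Trial` to a response
index).  All randomness is derived per-trial from the session master seed by
a counter scheme — noise ``k`` uses ``SeedSequence((master_seed, 0, k))``,
trial-level draws (rove, interval order, responder noise) use
``SeedSequence((master_seed, tag, trial_index))`` — so any single waveform or
trial is regenerable in isolation and an interrupted session can be resumed
bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .signals import (
    NoiseSpec, Waveform, apply_ramps, generate_noise, mix_at_snr, pure_tone,
    rove_level, set_level,
)

__all__ = [
    "ExperimentConfig",
    "StaircaseState",
    "SessionData",
    "Trial",
    "Task",
    "tone_in_noise_task",
    "make_task",
    "schedule_trials",
    "staircase_update",
    "run_experiment",
    "weighted_updown_equilibrium",
    "weighted_up_step_for_target",
    "noise_seed",
    "rebuild_noise",
    "rebuild_stimulus",
]

# spawn-key tags for the per-trial counter scheme
_TAG_NOISE = 0
_TAG_SCHEDULE = 1
_TAG_TRIAL = 2


# --------------------------------------------------------------------------
# Task: how a trial's stimulus is assembled from noise + target + expvar
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Task:
    """Stimulus assembly recipe for one experiment.

    ``targets`` holds one waveform per target alternative (a zero-amplitude
    waveform encodes a target-absent alternative in yes/no detection).  The
    experimental variable is interpreted as the SNR (dB) at which the target
    is mixed into the masker, in ``snr_mode`` convention.
    """

    name: str
    targets: tuple[Waveform, ...]
    snr_mode: str = "broadband_rms"
    level_db: float = 65.0
    ramp_s: float = 0.01
    params: dict = field(default_factory=dict)

    def assemble(self, noise: Waveform, target_idx: int, expvar: float) -> Waveform:
        """Mix target ``target_idx`` (1-based) into ``noise`` at SNR ``expvar``."""
        noise = set_level(noise, self.level_db)
        target = self.targets[target_idx - 1]
        stim = mix_at_snr(target, noise, expvar, mode=self.snr_mode)
        if self.ramp_s > 0:
            stim = apply_ramps(stim, self.ramp_s)
        return stim


def tone_in_noise_task(freq_hz: float = 500.0, tone_s: float = 0.1,
                       rate: float = 10000.0, level_db: float = 65.0,
                       snr_mode: str = "es_over_n0", ramp_s: float = 0.0,
                       dbfs_ref: float = 100.0) -> Task:
    """Yes/no tone-in-noise detection: target 1 = absent, target 2 = tone."""
    n = int(round(tone_s * rate))
    silence = Waveform(np.full(n, 1e-300), rate, dbfs_ref)  # target absent
    tone = pure_tone(freq_hz, tone_s, rate, dbfs_ref)
    return Task("tone_in_noise", (silence, tone), snr_mode=snr_mode,
                level_db=level_db, ramp_s=ramp_s,
                params={"freq_hz": freq_hz, "tone_s": tone_s, "rate": rate,
                        "level_db": level_db, "snr_mode": snr_mode,
                        "ramp_s": ramp_s, "dbfs_ref": dbfs_ref})


_TASK_REGISTRY: dict[str, Callable[..., Task]] = {
    "tone_in_noise": tone_in_noise_task,
}


def make_task(name: str, **params) -> Task:
    if name not in _TASK_REGISTRY:
        raise ValueError(f"unknown task {name!r}; known: {sorted(_TASK_REGISTRY)}")
    return _TASK_REGISTRY[name](**params)


# --------------------------------------------------------------------------
# Configuration and state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentConfig:
    """The full protocol of one session of trials.

    ``adapt`` selects the per-trial rule for the experimental variable
    (expvar, e.g. the SNR in dB): ``constant`` (method of constant stimuli),
    ``transformed_updown`` (n-up/m-down), or ``weighted_updown``
    (1-up/1-down with asymmetric steps; the default up/down ratio 2.4130
    targets 70.7 % correct).  ``probe_periodicity`` inserts an easy trial at
    ``startvar + probe_boost`` every so many trials; probes never enter the
    staircase statistics.
    """

    n_targets: int = 2
    n_presentation: int = 2000
    session_len: int = 400
    intervals: int = 1
    adapt: str = "weighted_updown"
    startvar: float = 0.0
    maxvar: float = 10.0
    step_resolution: str = "linear"
    start_stepsize: float = 2.0
    min_stepsize: float = 0.4144
    adapt_stepsize_factor: float = 0.5
    updown_rule: tuple[int, int] = (1, 1)
    weighted_ratio: float = 2.4130
    probe_periodicity: int = 0
    probe_boost: float = 31.0
    rove_range: float = 0.0
    noise_kind: str = "white"
    noise_duration_s: float = 0.5
    rate: float = 10000.0
    noise_params: dict = field(default_factory=dict)
    dbfs: float = 100.0
    master_seed: int = 0
    task_name: str = "tone_in_noise"
    task_params: dict = field(default_factory=dict)
    response_names: tuple[str, ...] = ("target 1", "target 2")
    synth_audio: bool = True

    def __post_init__(self):
        if self.adapt not in ("constant", "transformed_updown", "weighted_updown"):
            raise ValueError(f"unknown adapt mode {self.adapt!r}")
        if self.step_resolution not in ("linear", "multiplicative"):
            raise ValueError(f"unknown step_resolution {self.step_resolution!r}")
        if self.intervals not in (1, 2):
            raise ValueError("intervals must be 1 or 2")
        if self.startvar > self.maxvar:
            raise ValueError("startvar must not exceed maxvar")
        if self.start_stepsize <= 0 or self.min_stepsize <= 0:
            raise ValueError("step sizes must be positive")

    @property
    def n_trials(self) -> int:
        return self.n_targets * self.n_presentation

    def make_task(self) -> Task:
        return make_task(self.task_name, **self.task_params)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["updown_rule"] = list(self.updown_rule)
        d["response_names"] = list(self.response_names)
        return d

    @classmethod
    def from_dict(cls, d) -> "ExperimentConfig":
        d = dict(d)
        if "updown_rule" in d:
            d["updown_rule"] = tuple(d["updown_rule"])
        if "response_names" in d:
            d["response_names"] = tuple(d["response_names"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class StaircaseState:
    """Adaptive-track state for one session block."""

    expvar: float
    stepsize: float
    direction: str = "none"  # direction of the last expvar movement
    n_reversals: int = 0
    consec_correct: int = 0
    consec_incorrect: int = 0
    history: list = field(default_factory=list)  # (expvar, is_correct, reversal)


def staircase_update(state: StaircaseState, is_correct: bool,
                     config: ExperimentConfig) -> StaircaseState:
    """Advance the adaptive track by one (non-probe) trial.

    Weighted 1-up/1-down: a correct response lowers expvar by ``stepsize``, an
    incorrect one raises it by ``stepsize * weighted_ratio``.  Transformed
    n-up/m-down moves only after the required run of consecutive responses.
    The step size shrinks by ``adapt_stepsize_factor`` every two reversals,
    floored at ``min_stepsize``; expvar is clipped at ``maxvar``.
    """
    if config.adapt == "constant":
        return state

    # the history buffer is shared with the input state (cheap for long runs)
    s = replace(state)
    n_up, n_down = config.updown_rule

    move = None  # "down" (harder) | "up" (easier)
    if config.adapt == "weighted_updown":
        move = "down" if is_correct else "up"
    else:  # transformed n-up / m-down
        if is_correct:
            s.consec_correct += 1
            s.consec_incorrect = 0
            if s.consec_correct >= n_down:
                move = "down"
                s.consec_correct = 0
        else:
            s.consec_incorrect += 1
            s.consec_correct = 0
            if s.consec_incorrect >= n_up:
                move = "up"
                s.consec_incorrect = 0

    reversal = False
    if move is not None:
        if config.adapt == "weighted_updown":
            step = s.stepsize if move == "down" else s.stepsize * config.weighted_ratio
        else:
            step = s.stepsize
        if config.step_resolution == "linear":
            s.expvar = s.expvar - step if move == "down" else s.expvar + step
        else:  # multiplicative: steps act as factors
            factor = step if step > 0 else 1.0
            s.expvar = s.expvar / factor if move == "down" else s.expvar * factor
        s.expvar = min(s.expvar, config.maxvar)

        if s.direction != "none" and move != s.direction:
            reversal = True
            s.n_reversals += 1
            if s.n_reversals % 2 == 0:
                s.stepsize = max(s.stepsize * config.adapt_stepsize_factor,
                                 config.min_stepsize)
        s.direction = move

    s.history.append((s.expvar, bool(is_correct), reversal))
    return s


def weighted_updown_equilibrium(step_up: float, step_down: float) -> float:
    """Percent correct tracked by a weighted 1-up/1-down staircase.

    At equilibrium the expected movement is zero, ``p * step_down =
    (1 - p) * step_up``, hence ``p = step_up / (step_up + step_down)``.
    """
    return 100.0 * step_up / (step_up + step_down)


def weighted_up_step_for_target(p_correct: float, step_down: float = 1.0) -> float:
    """Up step giving a weighted 1-up/1-down equilibrium at ``p_correct``."""
    if not 0 < p_correct < 1:
        raise ValueError("p_correct must be in (0, 1)")
    return step_down * p_correct / (1.0 - p_correct)


# --------------------------------------------------------------------------
# Scheduling
# --------------------------------------------------------------------------

def schedule_trials(config: ExperimentConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the presentation order, target assignment and probe positions.

    Returns ``(stim_order, target_assignment, probe_flags)``: ``stim_order``
    is a permutation of noise ids ``0..n_trials-1`` in presentation order,
    ``target_assignment[k]`` the 1-based target of noise id ``k`` (each
    target appears exactly ``n_presentation`` times), and ``probe_flags[i]``
    marks presentation positions that are probe trials (every
    ``probe_periodicity``-th trial, 1-based).
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence((config.master_seed, _TAG_SCHEDULE)))
    n = config.n_trials
    if n % config.n_targets != 0:
        raise ValueError("n_trials must be divisible by n_targets")
    target_assignment = np.repeat(np.arange(1, config.n_targets + 1),
                                  config.n_presentation)
    stim_order = rng.permutation(n)
    probe_flags = np.zeros(n, dtype=bool)
    if config.probe_periodicity > 0:
        probe_flags[config.probe_periodicity - 1::config.probe_periodicity] = True
    return stim_order, target_assignment, probe_flags


# --------------------------------------------------------------------------
# Per-trial regeneration
# --------------------------------------------------------------------------

def noise_seed(master_seed: int, noise_id: int) -> int:
    """Deterministic per-noise seed: SeedSequence((master_seed, 0, noise_id))."""
    ss = np.random.SeedSequence((int(master_seed), _TAG_NOISE, int(noise_id)))
    return int(ss.generate_state(1)[0])


def _noise_spec(config: ExperimentConfig, noise_id: int) -> NoiseSpec:
    return NoiseSpec(kind=config.noise_kind, duration_s=config.noise_duration_s,
                     rate=config.rate,
                     seed=noise_seed(config.master_seed, noise_id),
                     kind_params=dict(config.noise_params),
                     dbfs_ref=config.dbfs)


def _trial_rng(config: ExperimentConfig, i: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.master_seed, _TAG_TRIAL, int(i))))


@dataclass
class Trial:
    """One presentation handed to the responder."""

    index: int                      # presentation position, 0-based
    noise_id: int
    target: int                     # 1-based target (or target interval)
    expvar: float
    is_probe: bool
    stimuli: list | None            # list[Waveform] (one per interval) or None
    noise: "Waveform | None"
    rng: np.random.Generator        # per-trial stream for responder noise
    config: ExperimentConfig


# --------------------------------------------------------------------------
# The trial loop
# --------------------------------------------------------------------------

@dataclass
class SessionData:
    """Presentation-order trial log of one session."""

    config: ExperimentConfig
    stim_order: np.ndarray
    target_assignment: np.ndarray    # per noise id, 1-based
    noise_id: np.ndarray
    n_target: np.ndarray             # 1-based, presentation order
    n_response: np.ndarray
    expvar: np.ndarray
    is_correct: np.ndarray
    is_probe: np.ndarray
    rove_offset: np.ndarray
    reversal_count: np.ndarray       # staircase reversals completed within block

    @property
    def n_trials(self) -> int:
        return len(self.n_target)

    @property
    def responses01(self) -> np.ndarray:
        """Responses coded 0/1 with 1 = 'response 2' (unified sign convention)."""
        return (self.n_response == 2).astype(int)

    def block_of(self, i: int) -> int:
        return i // self.config.session_len

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "noise_id": self.noise_id,
            "n_target": self.n_target,
            "n_response": self.n_response,
            "expvar": self.expvar,
            "is_correct": self.is_correct.astype(int),
            "is_probe": self.is_probe.astype(int),
            "rove_offset": self.rove_offset,
            "reversal_count": self.reversal_count,
        })

    def percent_correct(self, exclude_probes: bool = True) -> float:
        keep = ~self.is_probe if exclude_probes else slice(None)
        return 100.0 * float(np.mean(self.is_correct[keep]))


def rebuild_noise(session: SessionData, i: int) -> Waveform:
    """Regenerate the masker presented on trial ``i`` (presentation order)."""
    return generate_noise(_noise_spec(session.config, int(session.noise_id[i])))


def rebuild_stimulus(session: SessionData, i: int) -> Waveform:
    """Reassemble the full stimulus of trial ``i`` (target interval for 2-I)."""
    cfg = session.config
    task = cfg.make_task()
    noise = rebuild_noise(session, i)
    stim = task.assemble(noise, int(session.n_target[i]) if cfg.intervals == 1
                         else 2, float(session.expvar[i]))
    if session.rove_offset[i] != 0.0:
        stim = replace(stim, samples=stim.samples * 10 ** (session.rove_offset[i] / 20.0))
    return stim


def run_experiment(config: ExperimentConfig,
                   responder: Callable[[Trial], int],
                   start_trial: int = 0,
                   prior: SessionData | None = None) -> SessionData:
    """Run (or resume) a full simulated session.

    ``responder`` receives a :class:`Trial` and must return a valid 1-based
    response index.  Probe trials are presented at ``startvar + probe_boost``
    (capped at ``maxvar``) and bypass the staircase.  The expvar track and
    the step size reset at every block boundary.  Given the same config (and
    a deterministic responder), the result is bit-identical across runs and
    across save/resume splits.
    """
    n = config.n_trials
    stim_order, target_assignment, probe_flags = schedule_trials(config)
    task = config.make_task() if config.synth_audio else None

    noise_id = stim_order.copy()
    n_target = np.zeros(n, dtype=int)
    n_response = np.zeros(n, dtype=int)
    expvar_arr = np.zeros(n)
    is_correct = np.zeros(n, dtype=bool)
    rove_offset = np.zeros(n)
    reversal_count = np.zeros(n, dtype=int)

    if prior is not None:
        sl = slice(0, start_trial)
        n_target[sl] = prior.n_target[sl]
        n_response[sl] = prior.n_response[sl]
        expvar_arr[sl] = prior.expvar[sl]
        is_correct[sl] = prior.is_correct[sl]
        rove_offset[sl] = prior.rove_offset[sl]
        reversal_count[sl] = prior.reversal_count[sl]

    state = StaircaseState(config.startvar, config.start_stepsize)
    # replay recorded responses to rebuild the staircase at the resume point
    block_start = (start_trial // config.session_len) * config.session_len
    for j in range(block_start, start_trial):
        if not probe_flags[j]:
            state = staircase_update(state, bool(is_correct[j]), config)

    for i in range(start_trial, n):
        if i % config.session_len == 0:
            state = StaircaseState(config.startvar, config.start_stepsize)
        k = int(stim_order[i])
        probe = bool(probe_flags[i])
        # probes are deliberately easy and may exceed the staircase cap
        expvar = config.startvar + config.probe_boost if probe else state.expvar
        trial_rng = _trial_rng(config, i)

        if config.intervals == 1:
            target = int(target_assignment[k])
        else:
            target = int(trial_rng.integers(1, 3))  # interval holding target 2

        stimuli = None
        noise = None
        offset = 0.0
        if config.synth_audio:
            noise = generate_noise(_noise_spec(config, k))
            if config.intervals == 1:
                stim = task.assemble(noise, target, expvar)
                if config.rove_range > 0:
                    stim, offset = rove_level(stim, config.rove_range, trial_rng)
                stimuli = [stim]
            else:
                s2 = task.assemble(noise, 2, expvar)
                s1 = task.assemble(noise, 1, expvar)
                if config.rove_range > 0:
                    s2, offset = rove_level(s2, config.rove_range, trial_rng)
                    s1, _ = rove_level(s1, config.rove_range, trial_rng)
                stimuli = [s2, s1] if target == 1 else [s1, s2]

        trial = Trial(i, k, target, expvar, probe, stimuli, noise,
                      trial_rng, config)
        resp = int(responder(trial))
        n_resp_options = config.n_targets if config.intervals == 1 else 2
        if not 1 <= resp <= n_resp_options:
            raise ValueError(
                f"responder returned invalid response {resp} on trial {i} "
                f"(noise {k}, target {target})")

        n_target[i] = target
        n_response[i] = resp
        expvar_arr[i] = expvar
        is_correct[i] = resp == target
        rove_offset[i] = offset
        if not probe and config.adapt != "constant":
            state = staircase_update(state, bool(is_correct[i]), config)
        # reversals completed in this block up to and including this trial
        reversal_count[i] = state.n_reversals

    return SessionData(config, stim_order, target_assignment, noise_id,
                       n_target, n_response, expvar_arr, is_correct,
                       probe_flags, rove_offset, reversal_count)
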