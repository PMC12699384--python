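"""Canonical ready-made configurations for simulation studies.

The tone-in-noise preset mirrors the classic yes/no detection layout: a
100-ms, 500-Hz tone gated into the temporal middle of a 300-ms white-noise
masker, answered by a template-matching observer with a gammatone-envelope
front-end.  Channel spacing (1 ERB over 200-2000 Hz) and masker length are
chosen so a full 4,000-trial session simulates in seconds while keeping the
tone inside a well-resolved region of the image.
"""

from __future__ import annotations

import numpy as np

from .experiment import ExperimentConfig, SessionData, run_experiment
from .observer import ObserverSpec, TemplateObserver
from .representation import ReprSpec, StimulusTensor, dataload, zscore_pixels

__all__ = [
    "tone_frontend",
    "tone_in_noise_config",
    "tone_observer",
    "simulate_tone_session",
    "CUE_REGION",
    "NULL_REGION",
]

RATE = 5000.0
TONE_HZ = 500.0
TONE_S = 0.1
NOISE_S = 0.3

# cue region: tone frequency +/- ~1.5 ERB during the gated tone;
# null region: same band in the trailing masker-only segment
CUE_REGION = (380.0, 650.0, 0.10, 0.20)
NULL_REGION = (380.0, 650.0, 0.22, 0.30)


def tone_frontend(bwmul: float = 1.0) -> ReprSpec:
    return ReprSpec(tf_type="gammatone", bwmul=bwmul,
                    f_limits=(200.0, 2000.0), binwidth=0.01)


def tone_in_noise_config(n_presentation: int = 2000, master_seed: int = 0,
                         adapt: str = "weighted_updown", startvar: float = 12.0,
                         **overrides) -> ExperimentConfig:
    """Yes/no tone-in-noise protocol (target 1 absent, target 2 present).

    expvar is 10 log10(Es/N0) in dB.  With the default weighted 1-up/1-down
    staircase the track self-homes to 70.7% correct, holding the tone near
    threshold so errors are driven by the masker fluctuations — the regime
    reverse correlation needs.
    """
    kw = dict(n_targets=2, n_presentation=n_presentation, session_len=400,
              intervals=1, adapt=adapt, startvar=startvar, maxvar=40.0,
              noise_kind="white", noise_duration_s=NOISE_S, rate=RATE,
              task_name="tone_in_noise",
              task_params={"freq_hz": TONE_HZ, "tone_s": TONE_S, "rate": RATE,
                           "snr_mode": "es_over_n0"},
              master_seed=master_seed,
              response_names=("tone absent", "tone present"))
    kw.update(overrides)
    return ExperimentConfig(**kw)


def tone_observer(bwmul: float = 1.0, in_var: float = 4e-7,
                  det_lev: float = 30.0) -> TemplateObserver:
    """Template observer calibrated for the tone-in-noise preset.

    ``in_var`` puts the internal-noise standard deviation on the same order
    as the masker-driven fluctuation of the decision variable, mimicking a
    listener whose errors reflect both external and internal noise.
    """
    return TemplateObserver(ObserverSpec(frontend=tone_frontend(bwmul),
                                         det_lev=det_lev, in_var=in_var))


def simulate_tone_session(n_presentation: int = 2000, master_seed: int = 0,
                          bwmul: float = 1.0, zscore: bool = True,
                          **cfg_overrides):
    """Run a full simulated session and prepare it for estimation.

    Returns ``(session, tensor, responses, template)``: the trial log, the
    z-scored noise-alone tensor in presentation order, the 0/1 responses
    (1 = "tone present") and the observer's internal template.
    """
    cfg = tone_in_noise_config(n_presentation, master_seed, **cfg_overrides)
    obs = tone_observer(bwmul)
    session = run_experiment(cfg, obs)
    tensor = dataload(session, tone_frontend(bwmul))
    if zscore:
        tensor = zscore_pixels(tensor)
    return session, tensor, session.responses01, obs.template
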