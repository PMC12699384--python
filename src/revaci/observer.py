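"""Artificial listener: auditory front-end plus template-matching detector.

The observer forms an internal template as the average difference between
the front-end representations of the two targets, presented in noise at an
easy ("supra-threshold") level ``det_lev``.  At test time it projects the
incoming representation onto the template, adds Gaussian internal noise of
variance ``in_var``, and answers by signal-detection: yes/no tasks respond
"target 2" when the decision value exceeds ``thres_for_bias``; two-interval
tasks pick the interval with the larger decision value (ties to interval 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiment import ExperimentConfig, Trial
from .representation import ReprSpec, represent
from .signals import generate_noise

__all__ = [
    "ObserverSpec",
    "Template",
    "build_template",
    "decide",
    "TemplateObserver",
    "make_responder",
    "psychometric_responder",
]


@dataclass(frozen=True)
class ObserverSpec:
    """Parameters of the artificial listener.

    ``det_lev`` is the expvar value used when forming the template (a level
    at which the task is very easy); ``templ_num`` the number of noisy
    presentations averaged into the template; ``in_var`` the variance of the
    additive internal noise on the decision variable.
    """

    frontend: ReprSpec = field(default_factory=ReprSpec)
    det_lev: float = -6.0
    templ_num: int = 10
    in_var: float = 1.0
    thres_for_bias: float = 0.0
    decision: str = "optimal_detector"

    def __post_init__(self):
        if self.templ_num < 1:
            raise ValueError("templ_num must be >= 1")
        if self.in_var < 0:
            raise ValueError("in_var must be >= 0")
        if self.decision != "optimal_detector":
            raise ValueError("only the 'optimal_detector' back-end is available")

    def to_dict(self) -> dict:
        return {"frontend": self.frontend.to_dict(), "det_lev": self.det_lev,
                "templ_num": self.templ_num, "in_var": self.in_var,
                "thres_for_bias": self.thres_for_bias, "decision": self.decision}

    @classmethod
    def from_dict(cls, d) -> "ObserverSpec":
        return cls(frontend=ReprSpec.from_dict(d.get("frontend", {})),
                   det_lev=float(d.get("det_lev", -6.0)),
                   templ_num=int(d.get("templ_num", 10)),
                   in_var=float(d.get("in_var", 1.0)),
                   thres_for_bias=float(d.get("thres_for_bias", 0.0)),
                   decision=d.get("decision", "optimal_detector"))


@dataclass
class Template:
    """Normalized internal template (frequency x time)."""

    weights: np.ndarray
    frontend: ReprSpec
    degenerate: bool = False  # all-zero template (identical targets, no noise)


def build_template(config: ExperimentConfig, spec: ObserverSpec,
                   rng: np.random.Generator) -> Template:
    """Average ``templ_num`` supra-threshold target differences into a template.

    Each presentation draws a fresh masker, assembles both targets at
    ``det_lev``, and accumulates frontend(target-2 stimulus) minus
    frontend(target-1 stimulus); the mean difference is normalized to unit
    Euclidean norm (zero templates are flagged, not normalized).
    """
    from .signals import NoiseSpec

    task = config.make_task()
    acc = None
    for _ in range(spec.templ_num):
        # draw an independent masker for each presentation
        nspec = NoiseSpec(kind=config.noise_kind,
                          duration_s=config.noise_duration_s,
                          rate=config.rate, seed=int(rng.integers(0, 2**31)),
                          kind_params=dict(config.noise_params),
                          dbfs_ref=config.dbfs)
        noise = generate_noise(nspec)
        s2 = task.assemble(noise, 2, spec.det_lev)
        s1 = task.assemble(noise, 1, spec.det_lev)
        m2, _, _ = represent(s2, spec.frontend)
        m1, _, _ = represent(s1, spec.frontend)
        diff = m2 - m1
        acc = diff if acc is None else acc + diff
    mean = acc / spec.templ_num
    norm = float(np.linalg.norm(mean))
    if norm == 0:
        return Template(mean, spec.frontend, degenerate=True)
    return Template(mean / norm, spec.frontend)


def decide(representations, template: Template, spec: ObserverSpec,
           rng: np.random.Generator) -> tuple[int, float]:
    """Answer one trial from one or two front-end matrices.

    Returns ``(response index, decision value)``.  For a single
    representation the rule is yes/no: respond 2 iff the noisy projection
    exceeds ``thres_for_bias``.  For two, respond with the interval whose
    projection is larger (ties broken to interval 1).
    """
    if isinstance(representations, np.ndarray):
        representations = [representations]
    dvs = []
    for rep in representations:
        rep = np.asarray(rep)
        if rep.shape != template.weights.shape:
            raise ValueError(
                f"representation shape {rep.shape} does not match template "
                f"{template.weights.shape}")
        dv = float(np.sum(rep * template.weights))
        if spec.in_var > 0:
            dv += float(rng.normal(0.0, np.sqrt(spec.in_var)))
        dvs.append(dv)
    if len(dvs) == 1:
        return (2 if dvs[0] > spec.thres_for_bias else 1), dvs[0]
    # two-interval: pick the larger; exact tie goes to interval 1
    return (1 if dvs[0] >= dvs[1] else 2), dvs[0] - dvs[1]


class TemplateObserver:
    """Responder closing the loop between experiment engine and detector.

    Builds its template lazily on the first trial (using a stream derived
    from the session master seed) and thereafter answers each trial from the
    trial's own per-trial random stream, so whole sessions are reproducible.

    For single-interval (yes/no) tasks the raw template projection sits on a
    large noise-floor pedestal, so the observer keeps an internal criterion:
    initialized as the mean projection of both targets mixed at the session
    start level, then tracked as an exponential moving average of recent
    decision values (rate ``criterion_ema``).  ``thres_for_bias`` offsets
    this criterion.  Two-interval decisions compare intervals directly and
    need no criterion.
    """

    def __init__(self, spec: ObserverSpec, criterion_ema: float = 0.02):
        self.spec = spec
        self.template: Template | None = None
        self.criterion: float = 0.0
        self.criterion_ema = criterion_ema

    def prepare(self, config: ExperimentConfig) -> None:
        from .signals import NoiseSpec

        rng = np.random.default_rng(
            np.random.SeedSequence((config.master_seed, 99)))
        self.template = build_template(config, self.spec, rng)
        # initial criterion: mean projection of the two targets at startvar
        task = config.make_task()
        dvs = []
        for _ in range(self.spec.templ_num):
            nspec = NoiseSpec(kind=config.noise_kind,
                              duration_s=config.noise_duration_s,
                              rate=config.rate, seed=int(rng.integers(0, 2**31)),
                              kind_params=dict(config.noise_params),
                              dbfs_ref=config.dbfs)
            noise = generate_noise(nspec)
            for tgt in (1, 2):
                rep, _, _ = represent(task.assemble(noise, tgt, config.startvar),
                                      self.spec.frontend)
                dvs.append(float(np.sum(rep * self.template.weights)))
        self.criterion = float(np.mean(dvs))

    def __call__(self, trial: Trial) -> int:
        if self.template is None:
            self.prepare(trial.config)
        if trial.stimuli is None:
            raise ValueError("TemplateObserver requires synthesized audio "
                             "(config.synth_audio=True)")
        reps = [represent(s, self.spec.frontend)[0] for s in trial.stimuli]
        if len(reps) > 1:
            resp, _ = decide(reps, self.template, self.spec, trial.rng)
            return resp
        spec_eff = ObserverSpec(frontend=self.spec.frontend,
                                det_lev=self.spec.det_lev,
                                templ_num=self.spec.templ_num,
                                in_var=self.spec.in_var,
                                thres_for_bias=self.spec.thres_for_bias
                                + self.criterion)
        resp, dv = decide(reps[0], self.template, spec_eff, trial.rng)
        a = self.criterion_ema
        self.criterion = (1 - a) * self.criterion + a * dv
        return resp


def psychometric_responder(midpoint: float = 0.0, slope: float = 1.0):
    """Audio-free responder with a cumulative-Gaussian psychometric function.

    The probability of a *correct* response is ``Phi((expvar - midpoint) /
    slope)`` — monotone increasing in expvar.  Useful for staircase
    calibration checks without synthesizing stimuli.
    """
    from scipy.stats import norm

    def responder(trial: Trial) -> int:
        p_correct = float(norm.cdf((trial.expvar - midpoint) / slope))
        correct = trial.rng.random() < p_correct
        n_alt = trial.config.n_targets if trial.config.intervals == 1 else 2
        if correct:
            return trial.target
        others = [r for r in range(1, n_alt + 1) if r != trial.target]
        return int(others[trial.rng.integers(len(others))])

    return responder


_RESPONDERS = {
    "psychometric": lambda **kw: psychometric_responder(**kw),
    "template_observer": lambda **kw: TemplateObserver(ObserverSpec.from_dict(kw)),
}


def make_responder(name: str, **params):
    """Look up a responder factory by name (for configs and the CLI)."""
    if name not in _RESPONDERS:
        raise ValueError(f"unknown responder {name!r}; known: {sorted(_RESPONDERS)}")
    return _RESPONDERS[name](**params)
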