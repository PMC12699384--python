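"""Trial selection ahead of classification-image estimation.

Four combinable filters, applied in a fixed, documented order:

1. ``trialtype`` — keep all trials, correct/incorrect only, or trials of one
   target ("t1"/"t2");
2. ``expvar_after_reversal`` — within each session block, drop the staircase
   convergence phase before the Nth reversal;
3. ``expvar_limits`` — keep trials whose expvar lies in [lo, hi];
4. ``no_bias`` — remove majority-response trials, most extreme
   |expvar - mean| first, until both response classes are equally frequent
   (the mean is taken over the trials surviving the earlier filters).

Probe trials are always excluded.  An empty result raises with a per-filter
attrition report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment import SessionData

__all__ = ["SelectionCriteria", "select_trials"]

TRIALTYPES = ("total", "correct", "incorrect", "t1", "t2")


@dataclass(frozen=True)
class SelectionCriteria:
    trialtype: str = "total"
    expvar_limits: tuple[float, float] | None = None
    expvar_after_reversal: int = 0
    no_bias: bool = False

    def __post_init__(self):
        if self.trialtype not in TRIALTYPES:
            raise ValueError(f"trialtype must be one of {TRIALTYPES}")
        if self.expvar_after_reversal < 0:
            raise ValueError("expvar_after_reversal must be >= 0")
        if self.expvar_limits is not None and \
                self.expvar_limits[0] > self.expvar_limits[1]:
            raise ValueError("expvar_limits must satisfy lo <= hi")

    def to_dict(self) -> dict:
        return {"trialtype_analysis": self.trialtype,
                "expvar_limits": list(self.expvar_limits) if self.expvar_limits else None,
                "expvar_after_reversal": self.expvar_after_reversal,
                "no_bias": int(self.no_bias)}

    @classmethod
    def from_dict(cls, d) -> "SelectionCriteria":
        lim = d.get("expvar_limits")
        return cls(trialtype=d.get("trialtype_analysis", d.get("trialtype", "total")),
                   expvar_limits=tuple(lim) if lim else None,
                   expvar_after_reversal=int(d.get("expvar_after_reversal", 0)),
                   no_bias=bool(d.get("no_bias", False)))


def select_trials(session: SessionData,
                  criteria: SelectionCriteria | None = None) -> np.ndarray:
    """Return the sorted presentation-order indices surviving ``criteria``."""
    if criteria is None:
        criteria = SelectionCriteria()
    n = session.n_trials
    keep = ~session.is_probe
    attrition = [("probes", int(keep.sum()))]

    tt = criteria.trialtype
    if tt == "correct":
        keep &= session.is_correct
    elif tt == "incorrect":
        keep &= ~session.is_correct
    elif tt == "t1":
        keep &= session.n_target == 1
    elif tt == "t2":
        keep &= session.n_target == 2
    attrition.append(("trialtype", int(keep.sum())))

    if criteria.expvar_after_reversal > 0:
        keep &= session.reversal_count >= criteria.expvar_after_reversal
    attrition.append(("expvar_after_reversal", int(keep.sum())))

    if criteria.expvar_limits is not None:
        lo, hi = criteria.expvar_limits
        keep &= (session.expvar >= lo) & (session.expvar <= hi)
    attrition.append(("expvar_limits", int(keep.sum())))

    idx = np.flatnonzero(keep)
    if criteria.no_bias and idx.size:
        idx = _balance_responses(session, idx)
    attrition.append(("no_bias", int(idx.size)))

    if idx.size == 0:
        report = ", ".join(f"after {name}: {left}" for name, left in attrition)
        raise ValueError(f"trial selection left no trials ({report})")
    return np.sort(idx)


def _balance_responses(session: SessionData, idx: np.ndarray) -> np.ndarray:
    """Equalize response-class counts by dropping extreme-expvar majority trials."""
    r = session.responses01[idx]
    n1, n0 = int(r.sum()), int(idx.size - r.sum())
    if n1 == n0:
        return idx
    majority = 1 if n1 > n0 else 0
    excess = abs(n1 - n0)
    mean_ev = float(session.expvar[idx].mean())
    dist = np.abs(session.expvar[idx] - mean_ev)
    maj_pos = np.flatnonzero(r == majority)
    drop_local = maj_pos[np.argsort(-dist[maj_pos], kind="stable")[:excess]]
    mask = np.ones(idx.size, dtype=bool)
    mask[drop_local] = False
    return idx[mask]
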