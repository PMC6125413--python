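"""Action selection: turning an action-value table into p(a_t | m_t).

Three schemes: deterministic argmax over sequences (the emitted action
is the first element of the maximizing sequence), the softmax policy
with precision γ (normalized over *full* sequences, then marginalized to
the first action — not per-step softmax), and Thompson sampling (sample
one world hypothesis from the posterior factor, act greedily under it).

Ties in argmax are broken lexicographically in the declared label order
of the action space, smallest first, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exact_inference import CompletePosterior, posterior_factor
from .genmodel import GenerativeModel, enumerate_action_sequences
from .motivations import ActionValueTable, MotivationConfig, motivation_value
from .paloop import History
from .probtables import Categorical, FiniteSpace

__all__ = [
    "SelectionConfig",
    "argmax_select",
    "softmax_policy",
    "softmax_sequence_dist",
    "thompson_select",
    "thompson_policy",
]


@dataclass
class SelectionConfig:
    scheme: str = "argmax"          # argmax | softmax | thompson
    gamma: float = 1.0              # softmax precision
    seed: int | None = None

    def __post_init__(self):
        if self.scheme not in ("argmax", "softmax", "thompson"):
            raise ValueError(f"unknown selection scheme {self.scheme!r}")
        if self.scheme == "softmax" and not (
            np.isfinite(self.gamma) and self.gamma > 0
        ):
            raise ValueError("softmax precision gamma must be finite and > 0")


def _seq_sort_key(space: FiniteSpace):
    return lambda seq: tuple(space.index(a) for a in seq)


def argmax_select(Q: ActionValueTable, action_space: FiniteSpace):
    """The maximizing sequence (ties: lexicographically first)."""
    if len(Q) == 0:
        raise ValueError("empty action-value table")
    key = _seq_sort_key(action_space)
    best = max(sorted(Q.sequences(), key=key), key=lambda s: (Q[s],))
    # max() keeps the first of equal values; sorting first makes that the
    # lexicographically smallest sequence
    return best


def softmax_sequence_dist(Q: ActionValueTable, gamma: float):
    """exp(γQ̂)/Z over full sequences, computed with a max shift."""
    if gamma <= 0 or not np.isfinite(gamma):
        raise ValueError("gamma must be finite and > 0")
    seqs = sorted(Q.sequences())
    vals = np.array([Q[s] for s in seqs])
    logits = gamma * vals
    logits -= logits.max()
    w = np.exp(logits)
    return seqs, w / w.sum()


def softmax_policy(Q: ActionValueTable, gamma: float,
                   action_space: FiniteSpace) -> Categorical:
    """First-action marginal of the softmax over sequences."""
    seqs, probs = softmax_sequence_dist(Q, gamma)
    p = np.zeros(len(action_space))
    for seq, w in zip(seqs, probs):
        p[action_space.index(seq[0])] += w
    return Categorical(action_space, p)


def thompson_select(gm: GenerativeModel, h: History, cfg: MotivationConfig,
                    rng: np.random.Generator, candidates=None):
    """Two-step selection: sample (ê_{t-1}, θ) from the posterior factor,
    evaluate the motivation on the predictive factor alone, take argmax.

    Motivations that evaluate the parameter posterior are incompatible:
    a sampled θ carries no residual uncertainty to reduce.
    """
    if cfg.requires_parameter_posterior:
        raise ValueError(
            f"motivation {cfg.name!r} evaluates the parameter posterior and "
            "cannot be combined with Thompson sampling"
        )
    cp = CompletePosterior(gm, posterior_factor(gm, h))
    e_prev, theta = cp.sample_parameter(rng)
    e_label = None if e_prev is None else gm.Ehat.labels[e_prev]
    point = CompletePosterior.from_point(gm, h.t, e_label, theta)
    if candidates is None:
        length = point.horizon_length - cfg.horizon_reduction
        candidates = enumerate_action_sequences(gm, length)
    Q = ActionValueTable(
        {tuple(a): motivation_value(cfg, point, a) for a in candidates},
        t=h.t,
    )
    return argmax_select(Q, gm.Ahat)


def thompson_policy(gm: GenerativeModel, h: History, cfg: MotivationConfig,
                    candidates=None) -> Categorical:
    """The exact action distribution Thompson sampling induces.

    Mixes the per-component greedy first actions by posterior weight —
    the deterministic p(a_t | m_t) of the scheme, used when an agent
    contract must return a distribution rather than a sample.  Exact for
    the ensemble backend; on the dirichlet backend components are
    represented by their posterior-mean parameter point.
    """
    if cfg.requires_parameter_posterior:
        raise ValueError(
            f"motivation {cfg.name!r} is incompatible with Thompson sampling"
        )
    cp = CompletePosterior(gm, posterior_factor(gm, h))
    p = np.zeros(len(gm.Ahat))
    for comp in cp.factor.components:
        if comp.theta is not None:
            theta = comp.theta
        else:
            theta = comp.counts.mean_point(gm.Ehat, gm.Shat, gm.Ahat)
        e_label = None if comp.e_prev is None else gm.Ehat.labels[comp.e_prev]
        point = CompletePosterior.from_point(gm, h.t, e_label, theta)
        if candidates is None:
            length = point.horizon_length - cfg.horizon_reduction
            cands = enumerate_action_sequences(gm, length)
        else:
            cands = candidates
        Q = ActionValueTable(
            {tuple(a): motivation_value(cfg, point, a) for a in cands},
            t=h.t,
        )
        best = argmax_select(Q, gm.Ahat)
        p[gm.Ahat.index(best[0])] += comp.weight
    return Categorical(gm.Ahat, p / p.sum())
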