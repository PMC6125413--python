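"""Intrinsic-motivation functionals and the induced action-value tables.

Every motivation is a pure function 𝔐(d, â) of a complete posterior d
(exact, variational, or the predictive-only object used by Thompson
sampling) and a candidate future action sequence â:

* ``fep`` — expected free energy: the negative conditional entropy of
  future sensor values given future environment states, optionally plus
  the information gain about parameters, optionally minus a KL to a goal
  prior over sensor values.  Per-timestep mode (the common convention in
  the active-inference literature) sums the per-τ terms; joint mode uses
  the block quantities over whole paths.
* ``empowerment`` — the channel capacity from the tail action sequence
  to the final sensor value, i.e. how much the agent could influence
  what it will sense.
* ``predictive_info`` — the mutual information between the first and
  second halves of the future sensor path.
* ``ksa`` — knowledge seeking: the information gain (mutual information
  between future sensor paths and parameters) over the full horizon.

Information gain is computed exactly on ensemble-backed posteriors
(finite discrete joint over sensor paths × parameter points) and by
seeded Monte Carlo over θ on the Dirichlet backend, where the parameter
posterior is a mixture of Dirichlets without a closed-form KL.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exact_inference import (
    CompletePosterior,
    complete_posterior,
    log_dirichlet_blocks_pdf,
)
from .genmodel import (
    GenerativeModel,
    ParameterPoint,
    enumerate_action_sequences,
    sensor_axis,
    env_axis,
)
from .paloop import History
from .probtables import (
    Categorical,
    JointTable,
    channel_capacity,
    conditional_entropy,
    entropy,
    kl_divergence,
    marginalize,
    xlogx,
)

__all__ = [
    "MotivationConfig",
    "GoalPrior",
    "ActionValueTable",
    "MatrixFEPModel",
    "fep_value",
    "info_gain",
    "empowerment_value",
    "predictive_info_value",
    "ksa_value",
    "motivation_value",
    "bayesian_Q",
    "variational_Q",
    "fep_matrix_value",
]

_ALL_BLOCKS = ("theta1", "theta2", "theta3")


@dataclass
class GoalPrior:
    """Desired per-time sensor distributions p_d(ŝ_τ).

    ``rows`` is either a single probability vector over Ŝ (stationary
    goal) or one vector per future offset.
    """

    rows: np.ndarray | list

    def vector(self, offset: int, n_s: int) -> np.ndarray:
        rows = self.rows
        if isinstance(rows, np.ndarray) and rows.ndim == 1:
            v = rows
        else:
            v = np.asarray(rows[offset], dtype=float)
        if v.shape != (n_s,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("goal prior row is not a distribution over sensors")
        return v / v.sum()


@dataclass
class MotivationConfig:
    name: str
    per_timestep: bool = True          # fep: Eq.-style per-τ sum vs joint blocks
    include_info_gain: bool = False    # fep: add the information-gain term
    goal_prior: GoalPrior | None = None
    blocks: tuple[str, ...] = _ALL_BLOCKS   # which θ blocks count for info gain
    m: int = 1                         # empowerment lookahead (tail length)
    k: int | None = None               # predictive-info half horizon
    mc_samples: int | None = None      # Monte Carlo J for dirichlet info gain
    mc_seed: int | None = None

    def __post_init__(self):
        if self.name not in ("fep", "empowerment", "predictive_info", "ksa"):
            raise ValueError(f"unknown motivation {self.name!r}")
        if self.m < 1:
            raise ValueError("empowerment lookahead m must be >= 1")
        if self.k is not None and self.k < 1:
            raise ValueError("predictive-info half horizon k must be >= 1")
        self.blocks = tuple(self.blocks)
        for b in self.blocks:
            if b not in _ALL_BLOCKS:
                raise ValueError(f"unknown parameter block {b!r}")

    @property
    def requires_parameter_posterior(self) -> bool:
        """True when the motivation evaluates the belief over θ itself,
        which rules out Thompson sampling."""
        return self.name == "ksa" or (self.name == "fep" and self.include_info_gain)

    @property
    def horizon_reduction(self) -> int:
        """How far the evaluated-action horizon T̂ᵃ sits below T̂."""
        return self.m if self.name == "empowerment" else 0


@dataclass
class ActionValueTable:
    """Q̂: a complete mapping from candidate action sequences to values."""

    entries: dict[tuple[str, ...], float]
    t: int = 0

    def __post_init__(self):
        for seq, v in self.entries.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for sequence {seq}")

    def __getitem__(self, seq) -> float:
        return self.entries[tuple(seq)]

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self):
        return list(self.entries)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sequence,value\n")
            for seq, v in sorted(self.entries.items()):
                fh.write(f"{'|'.join(seq)},{v!r}\n")


# ---------------------------------------------------------------------------
# expected free energy


def fep_value(d: CompletePosterior, a_seq, cfg: MotivationConfig) -> float:
    """Expected-free-energy motivation (sign: larger is better)."""
    actions = tuple(a_seq)
    jt = d.joint_future(actions)
    h = len(actions)
    n_s = len(d.gm.Shat)
    value = 0.0
    if cfg.per_timestep:
        for r in range(h):
            tau = d.t + r
            pair = marginalize(jt, [sensor_axis(tau), env_axis(tau)])
            value -= conditional_entropy(pair, sensor_axis(tau), env_axis(tau))
            if cfg.goal_prior is not None:
                ps = marginalize(pair, sensor_axis(tau)).probs
                value -= kl_divergence(ps, cfg.goal_prior.vector(r, n_s))
        if cfg.include_info_gain:
            value += sum(info_gain(d, actions, cfg, per_time=True))
    else:
        value -= conditional_entropy(jt, d.sensor_axes(h), d.env_axes(h))
        if cfg.goal_prior is not None:
            ps = marginalize(jt, d.sensor_axes(h)).probs
            goal = cfg.goal_prior.vector(0, n_s)
            for r in range(1, h):
                goal = np.multiply.outer(goal, cfg.goal_prior.vector(r, n_s))
            value -= kl_divergence(ps, goal)
        if cfg.include_info_gain:
            value += info_gain(d, actions, cfg)
    return float(value)


# ---------------------------------------------------------------------------
# information gain


def _block_key(theta: ParameterPoint, blocks) -> bytes:
    parts = []
    if "theta1" in blocks:
        parts.append(np.round(theta.t1, 12).tobytes())
    if "theta2" in blocks:
        parts.append(np.round(theta.t2, 12).tobytes())
    if "theta3" in blocks:
        parts.append(np.round(theta.t3, 12).tobytes())
    return b"".join(parts)


def _exact_info_gain(d: CompletePosterior, actions, blocks, per_time):
    weights, preds = d.sensor_predictive_by_parameter(actions)
    if blocks != _ALL_BLOCKS:
        # merge parameter points identical on the counted blocks
        merged: dict[bytes, list[int]] = {}
        theta_by_pid = {}
        groups: dict[int, list[int]] = {}
        for i, c in enumerate(d.factor.components):
            theta_by_pid[c.param_id] = c.theta
        pids = sorted({c.param_id for c in d.factor.components})
        for gi, pid in enumerate(pids):
            key = _block_key(theta_by_pid[pid], blocks)
            merged.setdefault(key, []).append(gi)
        new_w, new_p = [], []
        for idxs in merged.values():
            w = sum(weights[i] for i in idxs)
            p = sum(weights[i] * preds[i] for i in idxs) / w
            new_w.append(w)
            new_p.append(p)
        weights, preds = np.array(new_w), new_p
    mean = sum(w * p for w, p in zip(weights, preds))
    if per_time:
        h = preds[0].ndim
        out = []
        for r in range(h):
            other = tuple(i for i in range(h) if i != r)
            m_r = mean.sum(axis=other)
            ig = sum(
                w * float(np.sum(xlogx(p.sum(axis=other))
                                 - p.sum(axis=other)
                                 * np.log(np.where(m_r > 0, m_r, 1.0))))
                for w, p in zip(weights, preds)
            )
            out.append(max(ig, 0.0))
        return out
    ig = sum(w * kl_divergence(p, mean) for w, p in zip(weights, preds))
    return max(float(ig), 0.0)


def _mc_info_gain(d: CompletePosterior, actions, cfg, per_time):
    """Seeded Monte Carlo estimate of I(Ŝ : Θ | â) on the Dirichlet backend.

    θ is drawn from the mixture-of-Dirichlets posterior (component by
    weight, then Dirichlet rows).  The sensor predictive given θ mixes
    the per-component predictives with the component responsibilities
    p(component | θ), obtained from the Dirichlet density ratios, so the
    estimator targets the mutual information with Θ alone rather than
    with (Θ, ê_{t-1}).
    """
    if cfg.mc_samples is None or cfg.mc_seed is None:
        raise ValueError(
            "information gain on the dirichlet backend needs Monte Carlo "
            "configuration (mc_samples and mc_seed)"
        )
    J = int(cfg.mc_samples)
    if J < 1:
        raise ValueError("mc_samples must be >= 1")
    if cfg.blocks != _ALL_BLOCKS:
        raise ValueError("block-restricted info gain is exact-ensemble only")
    rng = np.random.default_rng(cfg.mc_seed)
    if d.factor.backend == "ensemble":
        # θ samples are the ensemble points themselves; used to validate
        # the estimator against the exact discrete computation
        weights, preds = d.sensor_predictive_by_parameter(actions)
        mean = sum(w * p for w, p in zip(weights, preds))
        h = preds[0].ndim
        total = np.zeros(h) if per_time else 0.0
        draws = rng.choice(len(weights), size=J, p=weights / weights.sum())
        for gi in draws:
            if per_time:
                for r in range(h):
                    other = tuple(i for i in range(h) if i != r)
                    total[r] += kl_divergence(preds[gi].sum(axis=other),
                                              mean.sum(axis=other))
            else:
                total += kl_divergence(preds[gi], mean)
        if per_time:
            return [float(x / J) for x in total]
        return float(total / J)
    gm = d.gm
    comps = d.factor.components
    weights = d.factor.weights()
    mean = d.sensor_path_predictive(actions)
    a_idx = [gm.Ahat.index(a) for a in actions]
    n_s, n_e = len(gm.Shat), len(gm.Ehat)
    h = len(actions)
    env_ax = tuple(range(h, 2 * h))
    from .exact_inference import _point_future_array  # shared primitive

    # distinct counts objects (shared blocks appear once)
    distinct: list = []
    comp_block: list[int] = []
    for c in comps:
        for bi, b in enumerate(distinct):
            if b is c.counts:
                comp_block.append(bi)
                break
        else:
            distinct.append(c.counts)
            comp_block.append(len(distinct) - 1)

    total = 0.0 if not per_time else np.zeros(h)
    for _ in range(J):
        ci = int(rng.choice(len(comps), p=weights))
        b = comps[ci].counts
        t1 = np.stack([rng.dirichlet(row) for row in b.xi1])
        t2 = np.stack([
            np.stack([rng.dirichlet(b.xi2[a, i]) for i in range(n_e)])
            for a in range(b.xi2.shape[0])
        ])
        t3 = rng.dirichlet(b.xi3)
        theta = _RawTheta(t1, t2, t3)
        logpdf = np.array([log_dirichlet_blocks_pdf(blk, theta)
                           for blk in distinct])
        logresp = np.log(np.where(weights > 0, weights, 1e-300)) \
            + logpdf[comp_block]
        logresp -= logresp.max()
        resp = np.exp(logresp)
        resp /= resp.sum()
        pred = sum(
            rc * _point_future_array(theta, c.e_prev, a_idx, n_s, n_e
                                     ).sum(axis=env_ax)
            for rc, c in zip(resp, comps) if rc > 0
        )
        if per_time:
            for r in range(h):
                other = tuple(i for i in range(h) if i != r)
                total[r] += kl_divergence(pred.sum(axis=other),
                                          mean.sum(axis=other))
        else:
            total += kl_divergence(pred, mean)
    if per_time:
        return [float(x / J) for x in total]
    return float(total / J)


class _RawTheta:
    """Array-only stand-in for a ParameterPoint (internal MC plumbing)."""

    __slots__ = ("t1", "t2", "t3")

    def __init__(self, t1, t2, t3):
        self.t1, self.t2, self.t3 = t1, t2, t3


def info_gain(d: CompletePosterior, a_seq, cfg: MotivationConfig,
              per_time: bool = False, force_mc: bool = False):
    """I_d(Ŝ : Θ | â) in nats (or the per-τ list when ``per_time``).

    Exact on the ensemble backend; seeded Monte Carlo on the dirichlet
    backend.  ``force_mc`` runs the Monte Carlo estimator even where the
    exact path exists (used to validate its convergence).
    """
    actions = tuple(a_seq)
    if d.factor.backend == "ensemble" and not force_mc:
        return _exact_info_gain(d, actions, cfg.blocks, per_time)
    return _mc_info_gain(d, actions, cfg, per_time)


# ---------------------------------------------------------------------------
# empowerment, predictive information, knowledge seeking


def empowerment_value(d: CompletePosterior, a_prefix, cfg: MotivationConfig,
                      tol: float = 1e-10, max_iter: int = 10_000) -> float:
    """Capacity (nats) of the tail-action → final-sensor channel.

    The prefix â_{t:T̂ᵃ} is the evaluated sequence; the m tail actions
    are the channel input, treated open-loop as one composite alphabet.
    """
    prefix = tuple(a_prefix)
    m = cfg.m
    labels = d.gm.Ahat.labels
    rows = []
    for tail in itertools.product(labels, repeat=m):
        pred = d.sensor_path_predictive(prefix + tail)
        # marginal of the final sensor value
        rows.append(pred.sum(axis=tuple(range(pred.ndim - 1))))
    return channel_capacity(np.asarray(rows), tol=tol, max_iter=max_iter)


def predictive_info_value(d: CompletePosterior, a_seq,
                          k: int | None = None) -> float:
    """Mutual information between the first and second k future sensors."""
    actions = tuple(a_seq)
    h = len(actions)
    if k is None:
        k = h // 2
    if k < 1:
        raise ValueError("predictive information needs a half horizon k >= 1")
    if h < 2 * k:
        raise ValueError(
            f"horizon of length {h} too short: predictive information with "
            f"k={k} needs at least {2 * k} future steps"
        )
    pred = d.sensor_path_predictive(actions)
    if pred.ndim > 2 * k:
        pred = pred.sum(axis=tuple(range(2 * k, pred.ndim)))
    n = int(np.prod(pred.shape[:k]))
    P = pred.reshape(n, -1)
    px, py = P.sum(axis=1), P.sum(axis=0)
    mi = -xlogx(px).sum() - xlogx(py).sum() + xlogx(P).sum()
    return max(float(mi), 0.0)


def ksa_value(d: CompletePosterior, a_seq, cfg: MotivationConfig) -> float:
    """Knowledge-seeking value: full-horizon information gain."""
    return info_gain(d, a_seq, cfg)


def motivation_value(cfg: MotivationConfig, d: CompletePosterior, a_seq) -> float:
    if cfg.name == "fep":
        return fep_value(d, a_seq, cfg)
    if cfg.name == "empowerment":
        return empowerment_value(d, a_seq, cfg)
    if cfg.name == "predictive_info":
        return predictive_info_value(d, a_seq, cfg.k)
    return ksa_value(d, a_seq, cfg)


# ---------------------------------------------------------------------------
# action-value tables


def _candidate_length(d: CompletePosterior, cfg: MotivationConfig) -> int:
    length = d.horizon_length - cfg.horizon_reduction
    if length < 1:
        raise ValueError(
            "model horizon too short for this motivation's lookahead"
        )
    return length


def bayesian_Q(gm: GenerativeModel, h: History, cfg: MotivationConfig,
               candidates=None) -> ActionValueTable:
    """Q̂(â) = 𝔐(exact complete posterior, â) over all candidates."""
    d = complete_posterior(gm, h)
    return value_table(d, cfg, candidates)


def variational_Q(gm: GenerativeModel, r, cfg: MotivationConfig,
                  candidates=None) -> ActionValueTable:
    """Q̂(â) under the approximate complete posterior defined by r."""
    from .variational import approximate_complete_posterior

    d = approximate_complete_posterior(gm, r)
    return value_table(d, cfg, candidates)


def value_table(d: CompletePosterior, cfg: MotivationConfig,
                candidates=None) -> ActionValueTable:
    if candidates is None:
        candidates = enumerate_action_sequences(d.gm, _candidate_length(d, cfg))
    entries = {tuple(a): motivation_value(cfg, d, a) for a in candidates}
    return ActionValueTable(entries, t=d.t)


# ---------------------------------------------------------------------------
# matrix-form specialization of the expected free energy


@dataclass
class MatrixFEPModel:
    """The familiar matrix parameterization: A (sensor given state,
    columns indexed by state), per-action transition matrices B with
    B[a][j, i] = p(next = j | prev = i), per-time goal vectors C over
    sensors, and a belief vector over the current state."""

    A: np.ndarray
    B: dict[str, np.ndarray]
    C: list[np.ndarray]
    s_init: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.s_init = np.asarray(self.s_init, dtype=float)
        if not np.allclose(self.A.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns of A must be distributions over sensors")
        for a, Ba in self.B.items():
            Ba = np.asarray(Ba, dtype=float)
            if not np.allclose(Ba.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"columns of B[{a!r}] must be distributions")
            self.B[a] = Ba
        self.C = [np.asarray(c, dtype=float) for c in self.C]
        for c in self.C:
            if abs(c.sum() - 1.0) > 1e-9 or np.any(c < 0):
                raise ValueError("goal vectors must be distributions")
        if abs(self.s_init.sum() - 1.0) > 1e-9:
            raise ValueError("s_init must be a distribution over states")


def fep_matrix_value(mm: MatrixFEPModel, a_seq) -> float:
    """Expected free energy in matrix form.

    Propagates the state belief with the B matrices, maps to predicted
    outcomes with A, and accumulates per time step the negative expected
    sensor entropy 1·(A ∘ log A)·s plus the negative KL of the predicted
    outcome to the goal vector.  Identical (to 1e-10) to
    :func:`fep_value` in per-timestep mode without information gain on
    the point-mass specialization.
    """
    actions = tuple(a_seq)
    if len(actions) != len(mm.C):
        raise ValueError("need one goal vector per evaluated time step")
    AlogA = xlogx(mm.A)             # elementwise, 0 log 0 = 0
    s = mm.s_init
    value = 0.0
    for r, a in enumerate(actions):
        if a not in mm.B:
            raise ValueError(f"no transition matrix for action {a!r}")
        s = mm.B[a] @ s
        o = mm.A @ s
        value += float(AlogA.sum(axis=0) @ s)
        value -= kl_divergence(o, mm.C[r])
    return value
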