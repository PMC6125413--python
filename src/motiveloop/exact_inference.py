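"""Exact Bayesian complete posteriors over latent states and parameters.

At time t the agent's knowledge state splits into (i) a *posterior
factor* — the belief over the latent state just before now, ê_{t-1}, and
the parameters θ, given all past sensor values and actions — and (ii) the
model's fixed *predictive factor*, the forward law over future sensors
and states given (ê_{t-1}, θ) and a candidate future action sequence.
The :class:`CompletePosterior` pairs the two and answers every joint /
marginal query the intrinsic-motivation functionals need.

Backends
--------
dirichlet
    The posterior factor is an exact weighted mixture over latent
    trajectories ê_{<t}; each component carries the conjugate Dirichlet
    counts accumulated along its trajectory.  Component weights are the
    sequential (Pólya) predictive products of the observed data along the
    trajectory, normalized.  Future predictives run the same sequential
    predictive forward with running counts — exact by exchangeability of
    the Dirichlet-multinomial.  Cost grows as |Ê|^t (capped).
ensemble
    The parameter belief is a finite weighted set of points; latent
    trajectories are collapsed by the forward algorithm, leaving one
    component per (parameter point, ê_{t-1}) pair.  Cost is linear in t.

Weights are held in log space and combined with log-sum-exp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .genmodel import (
    DirichletBlocks,
    GenerativeModel,
    ParameterBelief,
    ParameterPoint,
    env_axis,
    sensor_axis,
    validate_action_sequence,
)
from .paloop import History
from .probtables import Categorical, CondTable, FiniteSpace, JointTable, marginalize

__all__ = [
    "ImpossibleHistoryError",
    "UnsupportedBackendError",
    "PosteriorComponent",
    "PosteriorFactor",
    "CompletePosterior",
    "posterior_factor",
    "complete_posterior",
    "posterior_predictive_env",
    "posterior_predictive_sensors",
    "parameter_posterior",
    "parameter_posterior_given_sensors",
    "log_dirichlet_blocks_pdf",
    "DirichletContextPredictor",
    "FixedNextSensorPredictor",
    "URLPosterior",
    "url_specialize",
    "history_space_model",
]


class ImpossibleHistoryError(ValueError):
    """The observed history has probability zero under the model."""


class UnsupportedBackendError(TypeError):
    """The requested operation is not exact on this parameter backend."""


@dataclass
class PosteriorComponent:
    weight: float
    log_weight: float
    e_prev: int | None            # index of ê_{t-1}; None only at t = 0
    param_id: int                 # ensemble point index, or component index
    theta: ParameterPoint | None = None       # ensemble backend
    counts: DirichletBlocks | None = None     # dirichlet backend


@dataclass
class PosteriorFactor:
    """Mixture representation of q(ê_{t-1}, θ | sa_{<t}, ξ)."""

    backend: str
    t: int
    components: list[PosteriorComponent]
    log_evidence: float           # log q(s_{<t} | a_{<t}, ξ)
    conditioning: tuple = ()      # (t, hash of sa_{<t}) audit record

    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def to_dict(self) -> dict:
        out = {"backend": self.backend, "t": self.t,
               "log_evidence": self.log_evidence, "components": []}
        for c in self.components:
            rec = {"weight": c.weight, "e_prev": c.e_prev, "param_id": c.param_id}
            if c.counts is not None:
                rec["counts"] = {"xi1": c.counts.xi1.tolist(),
                                 "xi2": c.counts.xi2.tolist(),
                                 "xi3": c.counts.xi3.tolist()}
            out["components"].append(rec)
        return out


def _indices(space: FiniteSpace, labels) -> list[int]:
    return [space.index(x) for x in labels]


def posterior_factor(gm: GenerativeModel, h: History) -> PosteriorFactor:
    """Exact posterior factor from a non-empty history (t >= 1)."""
    t = h.t
    if t < 1:
        raise ValueError("posterior_factor requires a non-empty history")
    s_idx = _indices(gm.Shat, h.sensors)
    a_idx = _indices(gm.Ahat, h.actions)
    key = (t, hash((h.sensors, h.actions)))
    if gm.prior.backend == "dirichlet":
        return _dirichlet_posterior_factor(gm, s_idx, a_idx, key)
    if gm.prior.backend == "ensemble":
        return _ensemble_posterior_factor(gm, s_idx, a_idx, key)
    raise UnsupportedBackendError(f"backend {gm.prior.backend!r}")


def _dirichlet_posterior_factor(gm, s_idx, a_idx, key) -> PosteriorFactor:
    t = len(s_idx)
    n_e = len(gm.Ehat)
    gm.check_cap(n_e ** t, "latent-trajectory enumeration |Ehat|^t")
    prior = gm.prior.dirichlet
    comps: list[PosteriorComponent] = []
    logws: list[float] = []
    for path in itertools.product(range(n_e), repeat=t):
        c = prior.copy()
        logw = 0.0
        dead = False
        for tau, e in enumerate(path):
            if tau == 0:
                row = c.xi3
                logw += np.log(row[e] / row.sum())
                row[e] += 1.0
            else:
                row = c.xi2[a_idx[tau - 1], path[tau - 1]]
                logw += np.log(row[e] / row.sum())
                row[e] += 1.0
            srow = c.xi1[e]
            p = srow[s_idx[tau]] / srow.sum()
            if p <= 0.0:
                dead = True
                break
            logw += np.log(p)
            srow[s_idx[tau]] += 1.0
        if dead:
            continue
        comps.append(PosteriorComponent(0.0, logw, path[-1], len(comps), counts=c))
        logws.append(logw)
    if not comps:
        raise ImpossibleHistoryError("history has zero probability under the prior")
    log_ev = float(logsumexp(logws))
    for c in comps:
        c.weight = float(np.exp(c.log_weight - log_ev))
        c.log_weight -= log_ev
    return PosteriorFactor("dirichlet", t, comps, log_ev, key)


def _ensemble_posterior_factor(gm, s_idx, a_idx, key) -> PosteriorFactor:
    t = len(s_idx)
    comps: list[PosteriorComponent] = []
    logws: list[float] = []
    for k, (w0, theta) in enumerate(zip(gm.prior.weights, gm.prior.points)):
        if w0 <= 0.0:
            continue
        # scaled forward algorithm over latent states
        alpha = theta.t3 * theta.t1[:, s_idx[0]]
        logscale = 0.0
        ok = True
        for tau in range(1, t):
            alpha = (alpha @ theta.t2[a_idx[tau - 1]]) * theta.t1[:, s_idx[tau]]
            z = alpha.sum()
            if z <= 0.0:
                ok = False
                break
            logscale += np.log(z)
            alpha = alpha / z
        z = alpha.sum()
        if not ok or z <= 0.0:
            continue
        logscale += np.log(z)
        alpha = alpha / z
        for j in range(len(gm.Ehat)):
            if alpha[j] > 0.0:
                lw = np.log(w0) + logscale + np.log(alpha[j])
                comps.append(PosteriorComponent(0.0, lw, j, k, theta=theta))
                logws.append(lw)
    if not comps:
        raise ImpossibleHistoryError("history has zero probability under every "
                                     "ensemble point")
    log_ev = float(logsumexp(logws))
    for c in comps:
        c.weight = float(np.exp(c.log_weight - log_ev))
        c.log_weight -= log_ev
    return PosteriorFactor("ensemble", t, comps, log_ev, key)


# ---------------------------------------------------------------------------
# future predictives per component


def _point_future_array(theta: ParameterPoint, e_prev, a_idx, n_s, n_e):
    """Array over (ŝ-path, ê-path) for fixed θ; shape ([n_s]*h, [n_e]*h)."""
    h = len(a_idx)
    probs = np.zeros(tuple([n_s] * h + [n_e] * h))
    for e_path in itertools.product(range(n_e), repeat=h):
        pe = 1.0
        prev = e_prev
        for r, e in enumerate(e_path):
            pe *= theta.t3[e] if prev is None and r == 0 else theta.t2[a_idx[r], prev, e]
            prev = e
        if pe == 0.0:
            continue
        sensor_rows = [theta.t1[e] for e in e_path]
        ps = sensor_rows[0]
        for row in sensor_rows[1:]:
            ps = np.multiply.outer(ps, row)
        probs[(Ellipsis,) + e_path] = pe * ps
    return probs


def _polya_future_array(counts: DirichletBlocks, e_prev, a_idx, n_s, n_e):
    """Joint Dirichlet-multinomial predictive over (ŝ-path, ê-path).

    Sequential predictive with running counts along every enumerated
    future path; exact by exchangeability.
    """
    h = len(a_idx)
    probs = np.zeros(tuple([n_s] * h + [n_e] * h))
    for e_path in itertools.product(range(n_e), repeat=h):
        c2 = counts.xi2.copy()
        pe = 1.0
        prev = e_prev
        for r, e in enumerate(e_path):
            if prev is None and r == 0:
                row = counts.xi3
                pe *= row[e] / row.sum()
            else:
                row = c2[a_idx[r], prev]
                pe *= row[e] / row.sum()
                row[e] += 1.0
            prev = e
        if pe == 0.0:
            continue
        for s_path in itertools.product(range(n_s), repeat=h):
            c1 = counts.xi1.copy()
            ps = 1.0
            for e, s in zip(e_path, s_path):
                row = c1[e]
                ps *= row[s] / row.sum()
                row[s] += 1.0
            probs[s_path + e_path] = pe * ps
    return probs


class CompletePosterior:
    """Queryable pairing of a posterior factor with the predictive factor.

    For every future action sequence â the induced joint over
    (ŝ-path, ê-path) is the weighted mixture of per-component forward
    predictives; it normalizes to 1 by construction.  Joints are memoized
    per action sequence.
    """

    def __init__(self, gm: GenerativeModel, factor: PosteriorFactor):
        self.gm = gm
        self.factor = factor
        self.t = factor.t
        self._cache: dict = {}

    @property
    def horizon_end(self) -> int:
        return self.gm.horizon_end(self.t)

    @property
    def horizon_length(self) -> int:
        return self.horizon_end - self.t + 1

    @classmethod
    def from_point(cls, gm: GenerativeModel, t: int, e_prev,
                   theta: ParameterPoint) -> "CompletePosterior":
        """Degenerate posterior at one (ê_{t-1}, θ): the predictive-only
        object used by Thompson sampling."""
        j = None if e_prev is None else gm.Ehat.index(e_prev)
        comp = PosteriorComponent(1.0, 0.0, j, 0, theta=theta)
        return cls(gm, PosteriorFactor("ensemble", t, [comp], 0.0))

    # -- core joint ------------------------------------------------------
    def _future_arrays(self, actions: tuple[str, ...]):
        key = actions
        if key in self._cache:
            return self._cache[key]
        a_idx = [self.gm.Ahat.index(a) for a in actions]
        n_s, n_e = len(self.gm.Shat), len(self.gm.Ehat)
        h = len(a_idx)
        self.gm.check_cap((n_s * n_e) ** h, "future-path enumeration")
        arrays = []
        for c in self.factor.components:
            if c.theta is not None:
                arr = _point_future_array(c.theta, c.e_prev, a_idx, n_s, n_e)
            else:
                arr = _polya_future_array(c.counts, c.e_prev, a_idx, n_s, n_e)
            arrays.append(arr)
        self._cache[key] = arrays
        return arrays

    def joint_future(self, a_seq) -> JointTable:
        """Joint over (ŝ_{t..}, ê_{t..}) given the future action sequence.

        Axes are named ``Shat[r]`` / ``Ehat[r]`` for r = t, t+1, ...
        """
        actions = validate_action_sequence(self.gm, a_seq)
        if len(actions) < 1:
            raise ValueError("need at least one future action")
        arrays = self._future_arrays(actions)
        probs = sum(c.weight * arr
                    for c, arr in zip(self.factor.components, arrays))
        h = len(actions)
        spaces = tuple(
            [self.gm.Shat.rename(sensor_axis(self.t + r)) for r in range(h)]
            + [self.gm.Ehat.rename(env_axis(self.t + r)) for r in range(h)]
        )
        return JointTable(spaces, probs)

    def sensor_axes(self, h: int | None = None) -> list[str]:
        h = self.horizon_length if h is None else h
        return [sensor_axis(self.t + r) for r in range(h)]

    def env_axes(self, h: int | None = None) -> list[str]:
        h = self.horizon_length if h is None else h
        return [env_axis(self.t + r) for r in range(h)]

    def sensor_path_predictive(self, a_seq) -> np.ndarray:
        """Marginal predictive over ŝ-paths, shape [|Ŝ|]*h."""
        actions = validate_action_sequence(self.gm, a_seq)
        arrays = self._future_arrays(actions)
        h = len(actions)
        env_ax = tuple(range(h, 2 * h))
        return sum(c.weight * arr.sum(axis=env_ax)
                   for c, arr in zip(self.factor.components, arrays))

    def sensor_predictive_by_parameter(self, a_seq):
        """(weights over parameter points, per-point ŝ-path predictives).

        Groups mixture components sharing a parameter point (ensemble
        backend) or a component identity (dirichlet backend, where each
        component has distinct counts).
        """
        actions = validate_action_sequence(self.gm, a_seq)
        arrays = self._future_arrays(actions)
        h = len(actions)
        env_ax = tuple(range(h, 2 * h))
        groups: dict[int, list[int]] = {}
        for i, c in enumerate(self.factor.components):
            groups.setdefault(c.param_id, []).append(i)
        weights, preds = [], []
        for pid in sorted(groups):
            idxs = groups[pid]
            w = sum(self.factor.components[i].weight for i in idxs)
            if w <= 0.0:
                continue
            arr = sum(self.factor.components[i].weight * arrays[i].sum(axis=env_ax)
                      for i in idxs) / w
            weights.append(w)
            preds.append(arr)
        return np.array(weights), preds

    # -- marginals & parameter views ------------------------------------
    def posterior_predictive_env(self, a_seq) -> JointTable:
        jt = self.joint_future(a_seq)
        return marginalize(jt, self.env_axes(len(tuple(a_seq))))

    def posterior_predictive_sensors(self, a_seq) -> JointTable:
        jt = self.joint_future(a_seq)
        return marginalize(jt, self.sensor_axes(len(tuple(a_seq))))

    def parameter_posterior(self) -> ParameterBelief:
        """Marginal belief over θ; independent of any future actions."""
        f = self.factor
        if f.backend == "ensemble":
            by_param: dict[int, float] = {}
            theta_of: dict[int, ParameterPoint] = {}
            for c in f.components:
                by_param[c.param_id] = by_param.get(c.param_id, 0.0) + c.weight
                theta_of[c.param_id] = c.theta
            pids = sorted(by_param)
            return ParameterBelief.from_points(
                [theta_of[k] for k in pids],
                np.array([by_param[k] for k in pids]),
            )
        return ParameterBelief(
            "dirichlet_mixture",
            mixture=[(c.weight, c.counts) for c in f.components],
        )

    def parameter_posterior_given_sensors(self, a_seq, s_future) -> ParameterBelief:
        """Belief over θ after additionally observing the future sensors.

        Exact only on the ensemble backend; the dirichlet-backend object
        is a mixture of Dirichlets handled by seeded Monte Carlo inside
        the motivation functionals.
        """
        if self.factor.backend != "ensemble":
            raise UnsupportedBackendError(
                "conditional parameter posterior is exact only on the ensemble "
                "backend; use the Monte Carlo information-gain path instead"
            )
        actions = validate_action_sequence(self.gm, a_seq)
        s_idx = tuple(self.gm.Shat.index(s) for s in s_future)
        if len(s_idx) != len(actions):
            raise ValueError("future sensors must cover the action horizon")
        arrays = self._future_arrays(actions)
        h = len(actions)
        env_ax = tuple(range(h, 2 * h))
        by_param: dict[int, float] = {}
        theta_of: dict[int, ParameterPoint] = {}
        for c, arr in zip(self.factor.components, arrays):
            lik = float(arr.sum(axis=env_ax)[s_idx])
            by_param[c.param_id] = by_param.get(c.param_id, 0.0) + c.weight * lik
            theta_of[c.param_id] = c.theta
        total = sum(by_param.values())
        if total <= 0.0:
            raise ImpossibleHistoryError("future sensor path has zero probability")
        pids = sorted(by_param)
        return ParameterBelief.from_points(
            [theta_of[k] for k in pids],
            np.array([by_param[k] / total for k in pids]),
        )

    # -- sampling --------------------------------------------------------
    def sample_component(self, rng: np.random.Generator) -> PosteriorComponent:
        w = self.factor.weights()
        i = int(rng.choice(len(w), p=w / w.sum()))
        return self.factor.components[i]

    def sample_parameter(self, rng: np.random.Generator):
        """Draw (ê_{t-1} index, θ) from the posterior factor."""
        c = self.sample_component(rng)
        if c.theta is not None:
            return c.e_prev, c.theta
        b = c.counts
        t1 = np.stack([rng.dirichlet(row) for row in b.xi1])
        t2 = np.stack([
            np.stack([rng.dirichlet(b.xi2[a, i]) for i in range(b.xi2.shape[1])])
            for a in range(b.xi2.shape[0])
        ])
        t3 = rng.dirichlet(b.xi3)
        theta = ParameterPoint(
            CondTable(self.gm.Shat, (self.gm.Ehat,), t1),
            CondTable(self.gm.Ehat, (self.gm.Ahat, self.gm.Ehat), t2),
            Categorical(self.gm.Ehat, t3),
        )
        return c.e_prev, theta


def complete_posterior(gm: GenerativeModel, h: History) -> CompletePosterior:
    return CompletePosterior(gm, posterior_factor(gm, h))


# module-level conveniences mirroring the CompletePosterior query surface
def posterior_predictive_env(cp: CompletePosterior, a_seq) -> JointTable:
    return cp.posterior_predictive_env(a_seq)


def posterior_predictive_sensors(cp: CompletePosterior, a_seq) -> JointTable:
    return cp.posterior_predictive_sensors(a_seq)


def parameter_posterior(cp: CompletePosterior) -> ParameterBelief:
    return cp.parameter_posterior()


def parameter_posterior_given_sensors(cp, a_seq, s_future) -> ParameterBelief:
    return cp.parameter_posterior_given_sensors(a_seq, s_future)


def log_dirichlet_blocks_pdf(blocks: DirichletBlocks, theta: ParameterPoint) -> float:
    """log density of θ under independent Dirichlet rows (all three blocks)."""
    total = 0.0
    for conc, rows in ((blocks.xi1, theta.t1),
                       (blocks.xi2.reshape(-1, blocks.xi2.shape[-1]),
                        theta.t2.reshape(-1, theta.t2.shape[-1])),
                       (blocks.xi3[None, :], theta.t3[None, :])):
        conc = conc.reshape(-1, conc.shape[-1])
        for a, x in zip(conc, rows):
            if np.any((x <= 0) & (a != 1.0)):
                return -np.inf
            xs = np.where(x > 0, x, 1.0)
            total += float(gammaln(a.sum()) - gammaln(a).sum()
                           + ((a - 1.0) * np.log(xs)).sum())
    return total


# ---------------------------------------------------------------------------
# Universal-RL specialization: mixtures of next-sensor predictors.
#
# Setting the modelled state space Ê to the space of histories makes
# ê_{t-1} = sa_{<t} an *observed* quantity, so the posterior collapses to
# Bayes-rule weight updates over a class of next-sensor predictors —
# the finite Bayesian universal-RL agent.


class FixedNextSensorPredictor:
    """A fixed (non-learning) model q(ŝ | context, â) given by a callable.

    ``fn(sensors, actions, a)`` returns a probability vector over S;
    ``a`` is None for the initial (t = 0) sensor value.
    """

    def __init__(self, S: FiniteSpace, fn):
        self.S = S
        self.fn = fn

    def predictive(self, sensors, actions, a) -> np.ndarray:
        p = np.asarray(self.fn(tuple(sensors), tuple(actions), a), dtype=float)
        if p.shape != (len(self.S),) or np.any(p < 0):
            raise ValueError("predictor returned an invalid distribution")
        return p / p.sum()

    def observe(self, sensors, actions, a, s) -> None:  # no internal state
        pass

    def reset(self) -> None:
        pass


class DirichletContextPredictor:
    """Per-context conjugate predictor: counts over S for every (context, â).

    ``context_fn(sensors, actions)`` maps a history prefix to the context
    the counts are keyed on; the default is the full prefix (the
    history-space state), under which every context is fresh.  Coarser
    context functions (e.g. a constant, or the last sensor value) make
    contexts recur; with flat concentration 1 the one-step predictive for
    a context seen n times is then the Laplace rule (n_s + 1) / (n + |S|).
    """

    def __init__(self, S: FiniteSpace, concentration: float = 1.0,
                 context_fn=None):
        if concentration <= 0:
            raise ValueError("concentration must be > 0")
        self.S = S
        self.c = float(concentration)
        self.context_fn = context_fn or (lambda sensors, actions:
                                         (tuple(sensors), tuple(actions)))
        self.counts: dict = {}

    def _key(self, sensors, actions, a):
        return (self.context_fn(tuple(sensors), tuple(actions)), a)

    def predictive(self, sensors, actions, a) -> np.ndarray:
        n = self.counts.get(self._key(sensors, actions, a),
                            np.zeros(len(self.S)))
        conc = n + self.c
        return conc / conc.sum()

    def observe(self, sensors, actions, a, s) -> None:
        key = self._key(sensors, actions, a)
        n = self.counts.setdefault(key, np.zeros(len(self.S)))
        n[self.S.index(s)] += 1.0

    def reset(self) -> None:
        self.counts = {}


@dataclass
class URLPosterior:
    S: FiniteSpace
    A: FiniteSpace
    predictors: list
    weights: np.ndarray
    history: History
    log_evidence: float

    def predictive(self, a) -> Categorical:
        """One-step mixture predictive q(s_t | a_t, sa_{<t}, ξ)."""
        sensors, actions = self.history.sensors, self.history.actions
        p = sum(w * m.predictive(sensors, actions, a)
                for w, m in zip(self.weights, self.predictors))
        return Categorical(self.S, p)


def url_specialize(S: FiniteSpace, A: FiniteSpace, predictors,
                   prior_weights, h: History) -> URLPosterior:
    """Bayes-rule weight updates over a class of next-sensor predictors.

    Replays the history through every predictor: the weight of model θ
    after observing (a_t, s_t) is w(θ) · q(s_t | a_t, sa_{<t}, θ) /
    normalizer, applied sequentially; learning predictors (per-context
    Dirichlet) update their own counts along the way.
    """
    predictors = list(predictors)
    for m in predictors:
        m.reset()
    logw = np.log(np.asarray(prior_weights, dtype=float))
    for tau in range(h.t):
        s = h.sensors[tau]
        a = None if tau == 0 else h.actions[tau - 1]
        ctx_s, ctx_a = h.sensors[:tau], h.actions[:max(tau - 1, 0)]
        liks = np.array([
            m.predictive(ctx_s, ctx_a, a)[S.index(s)] for m in predictors
        ])
        with np.errstate(divide="ignore"):
            logw = logw + np.log(liks)
        if np.all(np.isneginf(logw)):
            raise ImpossibleHistoryError(
                f"sensor {s!r} at step {tau} impossible under every model"
            )
        for m in predictors:
            m.observe(ctx_s, ctx_a, a, s)
    w = np.exp(logw - logsumexp(logw))
    return URLPosterior(S, A, predictors, w, h, float(logsumexp(logw)))


def history_space_model(S: FiniteSpace, A: FiniteSpace, predictors,
                        prior_weights, T: int,
                        horizon: tuple[str, int] = ("rolling", 0),
                        ) -> GenerativeModel:
    """The generative model with Ê set to the space of histories.

    Each fixed next-sensor predictor becomes one ensemble point: the
    dynamics block concatenates (â, ŝ) onto the history state with the
    predictor's sensor probability, the sensor block deterministically
    emits the last recorded sensor value, and the initial-state block is
    the predictor's t = 0 predictive.  Histories of maximal length are
    absorbing.  Intended for small instances: |Ê| grows exponentially
    with T.
    """
    hist_states: list[tuple[tuple, tuple]] = []
    for length in range(1, T + 1):
        for sensors in itertools.product(S.labels, repeat=length):
            for actions in itertools.product(A.labels, repeat=length - 1):
                hist_states.append((sensors, actions))

    def label(state):
        sensors, actions = state
        return "|".join([",".join(sensors), ",".join(actions)])

    Ehat = FiniteSpace("Ehat", tuple(label(st) for st in hist_states))
    Shat = FiniteSpace("Shat", S.labels)
    Ahat = FiniteSpace("Ahat", A.labels)
    index = {st: i for i, st in enumerate(hist_states)}
    n_e, n_s, n_a = len(Ehat), len(S), len(A)
    points = []
    for m in predictors:
        t1 = np.zeros((n_e, n_s))
        for (sensors, _), i in index.items():
            t1[i, S.index(sensors[-1])] = 1.0
        t2 = np.zeros((n_a, n_e, n_e))
        for (sensors, actions), i in index.items():
            if len(sensors) == T:          # absorbing frontier
                t2[:, i, i] = 1.0
                continue
            for ai, a in enumerate(A.labels):
                pred = m.predictive(sensors, actions, a)
                for si, s in enumerate(S.labels):
                    succ = (sensors + (s,), actions + (a,))
                    t2[ai, i, index[succ]] = pred[si]
        t3 = np.zeros(n_e)
        init = m.predictive((), (), None)
        for si, s in enumerate(S.labels):
            t3[index[((s,), ())]] = init[si]
        points.append(ParameterPoint(
            CondTable(Shat, (Ehat,), t1),
            CondTable(Ehat, (Ahat, Ehat), t2),
            Categorical(Ehat, t3),
        ))
    prior = ParameterBelief.from_points(points, np.asarray(prior_weights, float))
    return GenerativeModel(Ehat, Shat, Ahat, prior, horizon)
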