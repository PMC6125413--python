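"""The agent-internal hierarchical generative model.

The model mirrors the true loop with hatted spaces (Ŝ = S and Â = A are
enforced at the points of contact with data; Ê is free and need not equal
E) and three parameter blocks with conjugate Dirichlet priors:

* θ¹ — sensor model q(ŝ | ê), one Dirichlet row per ê (prior ξ¹),
* θ² — dynamics model q(ê' | â, ê), one row per (â, ê) (prior ξ²),
* θ³ — initial state model q(ê₀), a single row (prior ξ³).

Two parameter-belief backends are supported and every downstream
operation declares which it accepts:

* ``dirichlet`` — continuous Dirichlet blocks; sequential (Pólya)
  predictives make posterior computations exact in closed form;
* ``ensemble`` — a weighted finite set of parameter points, mirroring a
  countable model class; all sums are finite and exact.

Hyperparameters ξ are fixed; they are never inferred here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .probtables import Categorical, CondTable, FiniteSpace, JointTable

__all__ = [
    "DirichletBlocks",
    "ParameterPoint",
    "ParameterBelief",
    "GenerativeModel",
    "EnumerationCapError",
    "sensor_axis",
    "env_axis",
    "validate_action_sequence",
    "enumerate_action_sequences",
    "model_joint",
    "predictive_factor",
    "sample_model",
    "sample_theta",
]


class EnumerationCapError(RuntimeError):
    """An exact enumeration would exceed the configured state cap."""


def sensor_axis(r: int) -> str:
    """Axis name for the modelled sensor value at absolute time r."""
    return f"Shat[{r}]"


def env_axis(r: int) -> str:
    """Axis name for the modelled environment state at absolute time r."""
    return f"Ehat[{r}]"


@dataclass
class DirichletBlocks:
    """Concentration arrays for the three parameter blocks.

    Shapes: ``xi1`` (|Ê|, |Ŝ|), ``xi2`` (|Â|, |Ê|, |Ê|) with the last axis
    the successor state, ``xi3`` (|Ê|,).
    """

    xi1: np.ndarray
    xi2: np.ndarray
    xi3: np.ndarray

    def __post_init__(self):
        self.xi1 = np.asarray(self.xi1, dtype=float)
        self.xi2 = np.asarray(self.xi2, dtype=float)
        self.xi3 = np.asarray(self.xi3, dtype=float)
        for name, arr, ndim in (("xi1", self.xi1, 2), ("xi2", self.xi2, 3),
                                ("xi3", self.xi3, 1)):
            if arr.ndim != ndim:
                raise ValueError(f"{name} must have {ndim} axes, got {arr.ndim}")
            if np.any(arr <= 0):
                raise ValueError(f"{name}: concentrations must be > 0")

    @classmethod
    def flat(cls, n_e: int, n_s: int, n_a: int, concentration: float = 1.0):
        c = float(concentration)
        return cls(np.full((n_e, n_s), c), np.full((n_a, n_e, n_e), c),
                   np.full(n_e, c))

    def copy(self) -> "DirichletBlocks":
        return DirichletBlocks(self.xi1.copy(), self.xi2.copy(), self.xi3.copy())

    def mean_point(self, Ehat, Shat, Ahat) -> "ParameterPoint":
        """Posterior/prior mean as a concrete parameter point."""
        t1 = self.xi1 / self.xi1.sum(axis=-1, keepdims=True)
        t2 = self.xi2 / self.xi2.sum(axis=-1, keepdims=True)
        t3 = self.xi3 / self.xi3.sum()
        return ParameterPoint(
            CondTable(Shat, (Ehat,), t1),
            CondTable(Ehat, (Ahat, Ehat), t2),
            Categorical(Ehat, t3),
        )


@dataclass
class ParameterPoint:
    """A concrete θ = (θ¹, θ², θ³)."""

    theta1: CondTable       # q(ŝ | ê)
    theta2: CondTable       # q(ê' | â, ê)
    theta3: Categorical     # q(ê₀)

    @property
    def t1(self) -> np.ndarray:
        return self.theta1.table

    @property
    def t2(self) -> np.ndarray:
        return self.theta2.table

    @property
    def t3(self) -> np.ndarray:
        return self.theta3.probs


@dataclass
class ParameterBelief:
    """Belief over θ: ``dirichlet``, ``ensemble`` or ``dirichlet_mixture``.

    The mixture backend (weighted set of Dirichlet blocks) arises as the
    marginal parameter posterior under the dirichlet backend; it is not a
    valid *prior* backend for a GenerativeModel.
    """

    backend: str
    dirichlet: DirichletBlocks | None = None
    points: list[ParameterPoint] | None = None
    weights: np.ndarray | None = None
    mixture: list[tuple[float, DirichletBlocks]] | None = None

    def __post_init__(self):
        if self.backend == "dirichlet":
            if self.dirichlet is None:
                raise ValueError("dirichlet backend needs concentration blocks")
        elif self.backend == "ensemble":
            if not self.points:
                raise ValueError("ensemble backend needs at least one point")
            if self.weights is None:
                self.weights = np.full(len(self.points), 1.0 / len(self.points))
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("ensemble weights must be a distribution")
            self.weights = w / w.sum()
        elif self.backend == "dirichlet_mixture":
            if not self.mixture:
                raise ValueError("mixture backend needs at least one component")
            total = sum(w for w, _ in self.mixture)
            self.mixture = [(w / total, b) for w, b in self.mixture]
        else:
            raise ValueError(f"unknown parameter-belief backend {self.backend!r}")

    @classmethod
    def from_dirichlet(cls, blocks: DirichletBlocks) -> "ParameterBelief":
        return cls("dirichlet", dirichlet=blocks)

    @classmethod
    def from_points(cls, points, weights=None) -> "ParameterBelief":
        return cls("ensemble", points=list(points),
                   weights=None if weights is None else np.asarray(weights, float))

    def mean_point(self, Ehat, Shat, Ahat) -> ParameterPoint:
        if self.backend == "dirichlet":
            return self.dirichlet.mean_point(Ehat, Shat, Ahat)
        if self.backend == "ensemble":
            t1 = sum(w * p.t1 for w, p in zip(self.weights, self.points))
            t2 = sum(w * p.t2 for w, p in zip(self.weights, self.points))
            t3 = sum(w * p.t3 for w, p in zip(self.weights, self.points))
            return ParameterPoint(CondTable(Shat, (Ehat,), t1),
                                  CondTable(Ehat, (Ahat, Ehat), t2),
                                  Categorical(Ehat, t3))
        t1 = sum(w * b.xi1 / b.xi1.sum(-1, keepdims=True) for w, b in self.mixture)
        t2 = sum(w * b.xi2 / b.xi2.sum(-1, keepdims=True) for w, b in self.mixture)
        t3 = sum(w * b.xi3 / b.xi3.sum() for w, b in self.mixture)
        return ParameterPoint(CondTable(Shat, (Ehat,), t1),
                              CondTable(Ehat, (Ahat, Ehat), t2),
                              Categorical(Ehat, t3))


@dataclass
class GenerativeModel:
    """Spaces, prior parameter belief and horizon convention of the model.

    ``horizon`` is either ``("rolling", n)`` — the modelled end time is
    T̂ = t + n, a rolling window n steps ahead of the current time — or
    ``("fixed", T̂)``.  ``cap`` bounds exact enumerations: any operation
    about to enumerate more than ``cap`` joint states raises
    :class:`EnumerationCapError` instead.
    """

    Ehat: FiniteSpace
    Shat: FiniteSpace
    Ahat: FiniteSpace
    prior: ParameterBelief
    horizon: tuple[str, int] = ("rolling", 2)
    cap: int = 1_000_000

    def __post_init__(self):
        mode, val = self.horizon
        if mode not in ("rolling", "fixed") or int(val) < 0:
            raise ValueError(f"invalid horizon {self.horizon!r}")
        if self.prior.backend == "dirichlet":
            b = self.prior.dirichlet
            shapes = (b.xi1.shape, b.xi2.shape, b.xi3.shape)
            want = ((len(self.Ehat), len(self.Shat)),
                    (len(self.Ahat), len(self.Ehat), len(self.Ehat)),
                    (len(self.Ehat),))
            if shapes != want:
                raise ValueError(f"prior block shapes {shapes} != {want}")
        elif self.prior.backend == "dirichlet_mixture":
            raise ValueError("a dirichlet_mixture belief cannot serve as the prior")

    def horizon_end(self, t: int) -> int:
        mode, val = self.horizon
        return t + val if mode == "rolling" else val

    def check_spaces(self, S: FiniteSpace, A: FiniteSpace) -> None:
        """Enforce Ŝ = S and Â = A label-for-label."""
        if self.Shat.labels != S.labels:
            raise ValueError("model sensor labels differ from the true sensor space")
        if self.Ahat.labels != A.labels:
            raise ValueError("model action labels differ from the true action space")

    def check_cap(self, n_states: int, what: str) -> None:
        if n_states > self.cap:
            raise EnumerationCapError(
                f"{what} would enumerate {n_states} states (cap {self.cap})"
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "spaces": {"Ehat": list(self.Ehat.labels),
                       "Shat": list(self.Shat.labels),
                       "Ahat": list(self.Ahat.labels)},
            "horizon": list(self.horizon),
            "backend": self.prior.backend,
        }
        if self.prior.backend == "dirichlet":
            b = self.prior.dirichlet
            d["xi"] = {"xi1": b.xi1.tolist(), "xi2": b.xi2.tolist(),
                       "xi3": b.xi3.tolist()}
        else:
            d["ensemble"] = {
                "weights": self.prior.weights.tolist(),
                "points": [
                    {"theta1": p.t1.tolist(), "theta2": p.t2.tolist(),
                     "theta3": p.t3.tolist()}
                    for p in self.prior.points
                ],
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeModel":
        Ehat = FiniteSpace("Ehat", tuple(d["spaces"]["Ehat"]))
        Shat = FiniteSpace("Shat", tuple(d["spaces"]["Shat"]))
        Ahat = FiniteSpace("Ahat", tuple(d["spaces"]["Ahat"]))
        if d["backend"] == "dirichlet":
            prior = ParameterBelief.from_dirichlet(DirichletBlocks(
                d["xi"]["xi1"], d["xi"]["xi2"], d["xi"]["xi3"]))
        else:
            pts = [
                ParameterPoint(
                    CondTable(Shat, (Ehat,), np.asarray(p["theta1"], float)),
                    CondTable(Ehat, (Ahat, Ehat), np.asarray(p["theta2"], float)),
                    Categorical(Ehat, np.asarray(p["theta3"], float)),
                )
                for p in d["ensemble"]["points"]
            ]
            prior = ParameterBelief.from_points(pts, d["ensemble"]["weights"])
        mode, val = d.get("horizon", ["rolling", 2])
        return cls(Ehat, Shat, Ahat, prior, (mode, int(val)))


def validate_action_sequence(gm: GenerativeModel, actions) -> tuple[str, ...]:
    actions = tuple(str(a) for a in actions)
    for a in actions:
        gm.Ahat.index(a)
    return actions


def enumerate_action_sequences(gm: GenerativeModel, length: int):
    """All action sequences of the given length, in label (lexicographic) order."""
    gm.check_cap(len(gm.Ahat) ** max(length, 0), "action-sequence enumeration")
    return [tuple(seq) for seq in itertools.product(gm.Ahat.labels, repeat=length)]


def model_joint(gm: GenerativeModel, theta: ParameterPoint,
                e_seq, s_seq, a_seq) -> float:
    """Probability of one full assignment under the model for fixed θ.

    Sequences share the time range 0..n with ``a_seq`` covering 1..n, so
    ``len(a_seq) == len(e_seq) - 1``.  The parameter prior factor is
    excluded: this is Π of the sensor/dynamics/initial-state factors only.
    """
    e_seq = [gm.Ehat.index(e) for e in e_seq]
    s_seq = [gm.Shat.index(s) for s in s_seq]
    a_seq = [gm.Ahat.index(a) for a in a_seq]
    if len(e_seq) != len(s_seq) or len(a_seq) != len(e_seq) - 1:
        raise ValueError(
            f"inconsistent sequence lengths: {len(e_seq)} states, "
            f"{len(s_seq)} sensors, {len(a_seq)} actions"
        )
    p = theta.t3[e_seq[0]] * theta.t1[e_seq[0], s_seq[0]]
    for r in range(1, len(e_seq)):
        p *= theta.t2[a_seq[r - 1], e_seq[r - 1], e_seq[r]]
        p *= theta.t1[e_seq[r], s_seq[r]]
    return float(p)


def predictive_factor(gm: GenerativeModel, theta: ParameterPoint,
                      a_future, e_prev, t_start: int = 0) -> JointTable:
    """Exact forward law over (ŝ_{t:T̂}, ê_{t:T̂}) for fixed θ and ê_{t-1}.

    ``a_future`` supplies â_t..â_T̂ (one action per future step);
    ``e_prev`` is the label of ê_{t-1}, or ``None`` at t = 0, in which
    case the first step uses the initial-state model θ³.  Axes are named
    ``Shat[r]`` / ``Ehat[r]`` for absolute times r = t_start..T̂.
    """
    actions = validate_action_sequence(gm, a_future)
    h = len(actions)
    if h < 1:
        raise ValueError("horizon length must be >= 1")
    n_e, n_s = len(gm.Ehat), len(gm.Shat)
    gm.check_cap((n_e * n_s) ** h, "predictive-factor enumeration")
    shape = tuple([n_s] * h + [n_e] * h)
    probs = np.zeros(shape)
    prev0 = None if e_prev is None else gm.Ehat.index(e_prev)
    a_idx = [gm.Ahat.index(a) for a in actions]
    for e_path in itertools.product(range(n_e), repeat=h):
        pe = 1.0
        prev = prev0
        for r, e in enumerate(e_path):
            if prev is None and r == 0:
                pe *= theta.t3[e]
            else:
                pe *= theta.t2[a_idx[r], prev, e]
            prev = e
        if pe == 0.0:
            continue
        for s_path in itertools.product(range(n_s), repeat=h):
            ps = 1.0
            for e, s in zip(e_path, s_path):
                ps *= theta.t1[e, s]
            probs[s_path + e_path] = pe * ps
    spaces = tuple(
        [gm.Shat.rename(sensor_axis(t_start + r)) for r in range(h)]
        + [gm.Ehat.rename(env_axis(t_start + r)) for r in range(h)]
    )
    return JointTable(spaces, probs)


def sample_theta(gm: GenerativeModel, rng: np.random.Generator) -> ParameterPoint:
    """Draw θ from the prior (Dirichlet rows or ensemble point)."""
    b = gm.prior
    if b.backend == "ensemble":
        k = int(rng.choice(len(b.points), p=b.weights))
        return b.points[k]
    blocks = b.dirichlet
    t1 = np.stack([rng.dirichlet(row) for row in blocks.xi1])
    t2 = np.stack([
        np.stack([rng.dirichlet(blocks.xi2[a, i]) for i in range(blocks.xi2.shape[1])])
        for a in range(blocks.xi2.shape[0])
    ])
    t3 = rng.dirichlet(blocks.xi3)
    return ParameterPoint(
        CondTable(gm.Shat, (gm.Ehat,), t1),
        CondTable(gm.Ehat, (gm.Ahat, gm.Ehat), t2),
        Categorical(gm.Ehat, t3),
    )


def sample_model(gm: GenerativeModel, a_seq, rng: np.random.Generator):
    """Ancestral sample (θ, ê_{0:n}, ŝ_{0:n}) for a given action sequence.

    ``a_seq`` covers times 1..n; the trajectory has n+1 entries starting
    from the initial-state model.
    """
    theta = sample_theta(gm, rng)
    actions = validate_action_sequence(gm, a_seq)
    e = Categorical(gm.Ehat, theta.t3).sample(rng)
    e_seq, s_seq = [e], [Categorical(gm.Shat, theta.t1[gm.Ehat.index(e)]).sample(rng)]
    for a in actions:
        e = theta.theta2.row(a, e).sample(rng)
        e_seq.append(e)
        s_seq.append(Categorical(gm.Shat, theta.t1[gm.Ehat.index(e)]).sample(rng))
    return theta, e_seq, s_seq
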