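"""Exact probability algebra on finite labeled spaces.

Every distribution in the package — environment dynamics, generative-model
factors, posteriors, channels — is built from the four containers defined
here: :class:`FiniteSpace`, :class:`Categorical`, :class:`CondTable` and
:class:`JointTable`.  All information-theoretic functionals (entropy,
KL divergence, mutual information, channel capacity) operate on these
containers and use natural logarithms; results are in nats, with an
optional bits conversion on output only.

Conventions
-----------
* ``0 * log 0 := 0`` throughout.
* KL divergence returns ``+inf`` on an absolute-continuity violation
  instead of raising, because intrinsic-motivation functionals may
  legitimately evaluate it.
* Distributions are renormalized silently when their mass deviates from 1
  by at most ``RENORM_TOL`` (1e-9) and rejected beyond that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiniteSpace",
    "Categorical",
    "CondTable",
    "JointTable",
    "ZeroSupportError",
    "marginalize",
    "condition",
    "kl_divergence",
    "entropy",
    "conditional_entropy",
    "mutual_information",
    "channel_capacity",
    "nats_to_bits",
    "xlogx",
]

#: distributions off by more than this are rejected outright
RENORM_TOL = 1e-9
#: mass error accepted without renormalization
STRICT_TOL = 1e-12


class ZeroSupportError(ValueError):
    """Conditioning on (or dividing by) an event of probability zero."""


def _as_prob_vector(probs, what: str) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{what}: negative probability entry")
    total = p.sum()
    if abs(total - 1.0) > RENORM_TOL:
        raise ValueError(f"{what}: mass {total!r} is not 1 within {RENORM_TOL}")
    if abs(total - 1.0) > STRICT_TOL:
        p = p / total
    return p


@dataclass(frozen=True)
class FiniteSpace:
    """An ordered, finite set of distinct symbolic labels.

    The label order is part of the identity of the space: it fixes array
    axis layouts, lexicographic tie-breaking in action selection, and the
    iteration order of every enumeration.
    """

    name: str
    labels: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        if len(labels) < 1:
            raise ValueError(f"space {self.name!r}: needs at least one label")
        if len(set(labels)) != len(labels):
            raise ValueError(f"space {self.name!r}: labels not unique")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "_index", {x: i for i, x in enumerate(labels)})

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label) -> int:
        try:
            return self._index[str(label)]
        except KeyError:
            raise KeyError(f"label {label!r} not in space {self.name!r}") from None

    def rename(self, name: str) -> "FiniteSpace":
        """Same labels under a different axis name (for time-indexed copies)."""
        return FiniteSpace(name, self.labels)


@dataclass
class Categorical:
    """A probability distribution over one :class:`FiniteSpace`."""

    space: FiniteSpace
    probs: np.ndarray

    def __post_init__(self):
        p = _as_prob_vector(self.probs, f"Categorical over {self.space.name!r}")
        if p.shape != (len(self.space),):
            raise ValueError(
                f"Categorical over {self.space.name!r}: shape {p.shape} "
                f"does not match space size {len(self.space)}"
            )
        self.probs = p

    @classmethod
    def uniform(cls, space: FiniteSpace) -> "Categorical":
        n = len(space)
        return cls(space, np.full(n, 1.0 / n))

    @classmethod
    def point_mass(cls, space: FiniteSpace, label) -> "Categorical":
        p = np.zeros(len(space))
        p[space.index(label)] = 1.0
        return cls(space, p)

    def prob(self, label) -> float:
        return float(self.probs[self.space.index(label)])

    def sample(self, rng: np.random.Generator) -> str:
        return self.space.labels[int(rng.choice(len(self.space), p=self.probs))]


@dataclass
class CondTable:
    """A complete conditional probability table p(target | conditioners).

    Stored densely as an array with one axis per conditioner followed by
    the target axis, so a row exists for every conditioning tuple by
    construction.
    """

    target: FiniteSpace
    conditioners: tuple[FiniteSpace, ...]
    table: np.ndarray  # shape (*conditioner sizes, |target|)

    def __post_init__(self):
        self.conditioners = tuple(self.conditioners)
        expected = tuple(len(s) for s in self.conditioners) + (len(self.target),)
        arr = np.asarray(self.table, dtype=float)
        if arr.shape != expected:
            raise ValueError(
                f"CondTable for {self.target.name!r}: shape {arr.shape} != {expected}"
            )
        flat = arr.reshape(-1, len(self.target))
        rows = [
            _as_prob_vector(row, f"CondTable row {k} for {self.target.name!r}")
            for k, row in enumerate(flat)
        ]
        self.table = np.asarray(rows).reshape(expected)

    @classmethod
    def from_rows(cls, target, conditioners, rows: dict) -> "CondTable":
        """Build from a mapping of conditioning label tuples to row vectors."""
        conditioners = tuple(conditioners)
        shape = tuple(len(s) for s in conditioners) + (len(target),)
        arr = np.empty(shape)
        for combo in itertools.product(*(s.labels for s in conditioners)):
            key = combo if len(combo) > 1 else combo[0]
            if key not in rows and combo in rows:
                key = combo
            try:
                row = rows[key]
            except KeyError:
                raise ValueError(f"missing row for conditioning tuple {combo}") from None
            idx = tuple(s.index(x) for s, x in zip(conditioners, combo))
            arr[idx] = np.asarray(row, dtype=float)
        return cls(target, conditioners, arr)

    def row(self, *labels) -> Categorical:
        idx = tuple(s.index(x) for s, x in zip(self.conditioners, labels))
        return Categorical(self.target, self.table[idx])


@dataclass
class JointTable:
    """A joint distribution over an ordered collection of finite spaces.

    Space *names* must be unique within one table; marginalization and
    conditioning address axes by name.
    """

    spaces: tuple[FiniteSpace, ...]
    probs: np.ndarray

    def __post_init__(self):
        self.spaces = tuple(self.spaces)
        names = [s.name for s in self.spaces]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate space names in joint: {names}")
        arr = np.asarray(self.probs, dtype=float)
        expected = tuple(len(s) for s in self.spaces)
        if arr.shape != expected:
            raise ValueError(f"joint shape {arr.shape} != {expected}")
        if np.any(arr < 0):
            raise ValueError("negative entry in joint table")
        total = arr.sum()
        if abs(total - 1.0) > RENORM_TOL:
            raise ValueError(f"joint mass {total!r} is not 1 within {RENORM_TOL}")
        if abs(total - 1.0) > STRICT_TOL:
            arr = arr / total
        self.probs = arr

    def axis(self, name: str) -> int:
        for i, s in enumerate(self.spaces):
            if s.name == name:
                return i
        raise KeyError(f"no space named {name!r} in joint over "
                       f"{[s.name for s in self.spaces]}")

    def space(self, name: str) -> FiniteSpace:
        return self.spaces[self.axis(name)]

    @classmethod
    def from_categoricals(cls, *cats: Categorical) -> "JointTable":
        """Product (independent) joint of categorical marginals."""
        probs = cats[0].probs
        for c in cats[1:]:
            probs = np.multiply.outer(probs, c.probs)
        return cls(tuple(c.space for c in cats), probs)


def _resolve_names(names) -> tuple[str, ...]:
    if isinstance(names, (str, FiniteSpace)):
        names = [names]
    return tuple(n.name if isinstance(n, FiniteSpace) else str(n) for n in names)


def marginalize(j: JointTable, keep) -> JointTable:
    """Marginal of ``j`` over the named spaces, in the order given."""
    keep = _resolve_names(keep)
    if not keep:
        raise ValueError("keep must be a non-empty subset of the joint's spaces")
    keep_axes = [j.axis(name) for name in keep]  # raises on unknown name
    drop = tuple(i for i in range(len(j.spaces)) if i not in keep_axes)
    summed = j.probs.sum(axis=drop) if drop else j.probs
    # remaining axes are in original order; permute to requested order
    remaining = [i for i in range(len(j.spaces)) if i not in drop]
    perm = [remaining.index(a) for a in keep_axes]
    return JointTable(tuple(j.spaces[a] for a in keep_axes), summed.transpose(perm))


def condition(j: JointTable, on, value) -> JointTable:
    """Condition the joint on ``space == value``; renormalized slice.

    Raises :class:`ZeroSupportError` when the conditioning value has zero
    marginal probability.
    """
    (name,) = _resolve_names([on])
    ax = j.axis(name)
    space = j.spaces[ax]
    sl = np.take(j.probs, space.index(value), axis=ax)
    mass = sl.sum()
    if mass <= 0.0:
        raise ZeroSupportError(
            f"conditioning on zero-probability value {value!r} of {name!r}"
        )
    rest = tuple(s for i, s in enumerate(j.spaces) if i != ax)
    if not rest:
        raise ValueError("cannot condition a one-dimensional joint on its only space")
    return JointTable(rest, sl / mass)


def xlogx(p: np.ndarray) -> np.ndarray:
    """Elementwise ``p * log(p)`` with the 0 log 0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    mask = p > 0
    out[mask] = p[mask] * np.log(p[mask])
    return out


def _probs_of(p) -> np.ndarray:
    if isinstance(p, Categorical):
        return p.probs
    if isinstance(p, JointTable):
        return p.probs
    return np.asarray(p, dtype=float)


def kl_divergence(p, q) -> float:
    """KL(p ‖ q) in nats; ``+inf`` where q lacks support that p has."""
    pa, qa = _probs_of(p), _probs_of(q)
    if pa.shape != qa.shape:
        raise ValueError(f"shape mismatch in KL: {pa.shape} vs {qa.shape}")
    mask = pa > 0
    if np.any(qa[mask] <= 0):
        return float("inf")
    return float(np.sum(pa[mask] * (np.log(pa[mask]) - np.log(qa[mask]))))


def entropy(p, bits: bool = False) -> float:
    """Shannon entropy of a Categorical or JointTable (joint entropy)."""
    h = float(-xlogx(_probs_of(p)).sum())
    return nats_to_bits(h) if bits else h


def conditional_entropy(j: JointTable, target, given) -> float:
    """H(target | given) = H(target, given) − H(given); groups allowed."""
    target = _resolve_names(target)
    given = _resolve_names(given)
    both = marginalize(j, target + given)
    return entropy(both) - entropy(marginalize(j, given))


def mutual_information(j: JointTable, x, y, given=None) -> float:
    """I(X : Y [| Z]) from an enumerated joint; groups of axes allowed.

    Computed as H(X|Z) − H(X|Y,Z), which keeps the chain-rule identity
    exact at machine precision.
    """
    x = _resolve_names(x)
    y = _resolve_names(y)
    if given is None:
        hx = entropy(marginalize(j, x))
        hxy = conditional_entropy(j, x, y)
        return hx - hxy
    z = _resolve_names(given)
    return conditional_entropy(j, x, z) - conditional_entropy(j, x, y + z)


def channel_capacity(
    channel: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> float:
    """Capacity (nats) of a discrete memoryless channel, rows = inputs.

    Blahut–Arimoto alternating optimization starting from the uniform
    input distribution.  Iterates until the gap between the upper bound
    ``max_x D(p(·|x) ‖ q)`` and the lower bound ``Σ_x p(x) D(p(·|x) ‖ q)``
    is below ``tol``; each iteration's lower bound is non-decreasing.

    Raises ``RuntimeError`` with the remaining gap if ``max_iter`` is hit.
    """
    P = np.asarray(channel, dtype=float)
    if P.ndim != 2:
        raise ValueError("channel must be a 2-D array (inputs x outputs)")
    rows = P / P.sum(axis=1, keepdims=True)
    n_in = rows.shape[0]
    px = np.full(n_in, 1.0 / n_in)
    logrows = np.where(rows > 0, np.log(np.where(rows > 0, rows, 1.0)), 0.0)
    for _ in range(max_iter):
        qy = px @ rows
        with np.errstate(divide="ignore"):
            logqy = np.where(qy > 0, np.log(np.where(qy > 0, qy, 1.0)), -np.inf)
        # D_x = KL(row_x || qy); rows with support outside qy cannot occur
        # since qy has support wherever any selected row does
        D = np.array([
            float(np.sum(rows[i][rows[i] > 0]
                         * (logrows[i][rows[i] > 0] - logqy[rows[i] > 0])))
            for i in range(n_in)
        ])
        lower = float(px @ D)
        upper = float(D.max())
        if upper - lower < tol:
            return lower
        w = px * np.exp(D - D.max())
        px = w / w.sum()
    raise RuntimeError(
        f"capacity iteration did not converge: gap estimate {upper - lower:.3e}"
    )


def nats_to_bits(x: float) -> float:
    return x / np.log(2.0)
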