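"""Active inference proper: joint belief-and-policy optimization.

The self-referential objective couples the variational free energy of
perception with a KL that pulls the policy toward a softmax *prior over
action sequences* derived from the variational action-value table:

    J[φ, π] = F[φ, sa_{<t}, ξ] + KL( r(â | π) ‖ q(â | φ) ),
    q(â | φ) ∝ exp( γ · Q̂(â, φ) ).

Because q(â | φ) depends on φ through the value table, the minimization
does not split into independent perception and action problems — unlike
its non-self-referential precursor, where the action target is the
softmax of the *Bayesian* value table and the two coordinate problems
separate exactly.

Two optimizers are provided.  ``two_step`` is the constructive solution:
run coordinate-ascent variational inference for φ* (pure F), then set
π* to the softmax prior at φ*, which attains KL = 0.  ``joint_descent``
honors the self-referential coupling: a seeded derivative-free adaptive
random search over (state-factor logits, θ parameters, π logits) whose
accepted-step objective trace is non-increasing by construction.

The full formulation treats the precision γ itself as a random variable
on a finite grid with a prior; the posterior over γ is optimized jointly
with π by exact coordinate updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmodel import DirichletBlocks, GenerativeModel
from .motivations import ActionValueTable, MotivationConfig, variational_Q
from .paloop import History
from .selection import softmax_sequence_dist
from .variational import MeanFieldPosterior, cavi_optimize, free_energy

__all__ = [
    "ActionSeqDistribution",
    "AIConfig",
    "AIResult",
    "action_prior",
    "ai_objective",
    "ai_optimize",
    "ai_optimize_gamma",
    "ai_action",
]


@dataclass
class ActionSeqDistribution:
    """A categorical over an enumerated set of future action sequences."""

    sequences: list[tuple[str, ...]]
    probs: np.ndarray

    def __post_init__(self):
        self.sequences = [tuple(s) for s in self.sequences]
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("sequence distribution is not normalized")
        self.probs = p / p.sum()

    @classmethod
    def point_mass(cls, sequences, seq) -> "ActionSeqDistribution":
        p = np.zeros(len(sequences))
        p[list(sequences).index(tuple(seq))] = 1.0
        return cls(list(sequences), p)

    def kl_to(self, other: "ActionSeqDistribution") -> float:
        if self.sequences != other.sequences:
            raise ValueError("sequence sets differ")
        mask = self.probs > 0
        if np.any(other.probs[mask] <= 0):
            return float("inf")
        return float(np.sum(self.probs[mask]
                            * (np.log(self.probs[mask])
                               - np.log(other.probs[mask]))))

    def first_action_marginal(self, action_space) -> np.ndarray:
        p = np.zeros(len(action_space))
        for seq, w in zip(self.sequences, self.probs):
            p[action_space.index(seq[0])] += w
        return p


@dataclass
class AIConfig:
    gamma: float = 1.0
    gamma_grid: list[float] | None = None      # enables the full-Γ variant
    gamma_prior: np.ndarray | None = None      # weights on the grid (flat default)
    optimizer: str = "two_step"                # two_step | joint_descent
    tol: float = 1e-6
    max_evals: int = 2000
    seed: int = 0
    cavi_tol: float = 1e-8
    cavi_max_sweeps: int = 500

    def __post_init__(self):
        if self.optimizer not in ("two_step", "joint_descent"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.gamma_grid is not None:
            grid = [float(g) for g in self.gamma_grid]
            if not grid or any(g <= 0 for g in grid):
                raise ValueError("gamma grid must be non-empty and positive")
            self.gamma_grid = grid
            if self.gamma_prior is None:
                self.gamma_prior = np.full(len(grid), 1.0 / len(grid))
            w = np.asarray(self.gamma_prior, dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("gamma prior must be a distribution")
            self.gamma_prior = w / w.sum()
        elif not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValueError("gamma must be finite and > 0")


@dataclass
class AIResult:
    phi_star: MeanFieldPosterior
    pi_star: ActionSeqDistribution
    objective: float
    f_term: float
    kl_term: float
    gamma_posterior: np.ndarray | None = None
    trace: list[float] = field(default_factory=list)
    converged: bool = True


def action_prior(Q_phi: ActionValueTable, gamma: float) -> ActionSeqDistribution:
    """Softmax prior over full action sequences, q(â | φ) ∝ exp(γ Q̂)."""
    seqs, probs = softmax_sequence_dist(Q_phi, gamma)
    return ActionSeqDistribution(seqs, probs)


def ai_objective(gm: GenerativeModel, h: History, phi: MeanFieldPosterior,
                 pi: ActionSeqDistribution, cfg: MotivationConfig,
                 gamma: float) -> float:
    """F[φ] + KL(r(â|π) ‖ softmax of the variational value table at φ)."""
    f = free_energy(gm, h, phi)
    prior = action_prior(variational_Q(gm, phi, cfg), gamma)
    if pi.sequences != prior.sequences:
        raise ValueError("π is defined over a different candidate set")
    return f + pi.kl_to(prior)


def _two_step(gm, h, motivation, cfg) -> AIResult:
    rng = np.random.default_rng(cfg.seed)
    phi, trace = cavi_optimize(gm, h, tol=cfg.cavi_tol,
                               max_sweeps=cfg.cavi_max_sweeps, rng=rng)
    f = trace.values[-1]
    prior = action_prior(variational_Q(gm, phi, motivation), cfg.gamma)
    return AIResult(phi, prior, objective=f, f_term=f, kl_term=0.0,
                    trace=list(trace.values), converged=trace.converged)


# -- parameter-vector packing for the joint descent -------------------------


def _pack(phi: MeanFieldPosterior, pi: ActionSeqDistribution,
          extra: np.ndarray | None = None) -> np.ndarray:
    parts = [np.log(np.maximum(f, 1e-12)) for f in phi.env_factors]
    if phi.backend == "dirichlet":
        parts += [np.log(phi.phi.xi1).ravel(), np.log(phi.phi.xi2).ravel(),
                  np.log(phi.phi.xi3).ravel()]
    else:
        parts.append(np.log(np.maximum(phi.rho, 1e-12)))
    parts.append(np.log(np.maximum(pi.probs, 1e-12)))
    if extra is not None:
        parts.append(np.log(np.maximum(extra, 1e-12)))
    return np.concatenate(parts)


def _unpack(x: np.ndarray, template_phi: MeanFieldPosterior,
            sequences, n_extra: int = 0):
    def softmax(v):
        v = v - v.max()
        e = np.exp(v)
        return e / e.sum()

    pos = 0
    env = []
    for f in template_phi.env_factors:
        n = len(f)
        env.append(softmax(x[pos:pos + n]))
        pos += n
    if template_phi.backend == "dirichlet":
        shapes = [template_phi.phi.xi1.shape, template_phi.phi.xi2.shape,
                  template_phi.phi.xi3.shape]
        blocks = []
        for shp in shapes:
            n = int(np.prod(shp))
            blocks.append(np.exp(np.clip(x[pos:pos + n], -230, 230)).reshape(shp))
            pos += n
        phi = MeanFieldPosterior(env, "dirichlet", phi=DirichletBlocks(*blocks))
    else:
        n = len(template_phi.rho)
        phi = MeanFieldPosterior(env, "ensemble", rho=softmax(x[pos:pos + n]))
        pos += n
    n_seq = len(sequences)
    pi = ActionSeqDistribution(sequences, softmax(x[pos:pos + n_seq]))
    pos += n_seq
    extra = softmax(x[pos:pos + n_extra]) if n_extra else None
    return phi, pi, extra


def _adaptive_search(fun, x0, rng, tol, max_evals):
    """Accept-if-lower random search; returns (x, trace, converged)."""
    x = x0.copy()
    f = fun(x)
    trace = [f]
    sigma = 0.3
    rejects = 0
    evals = 1
    while evals < max_evals and sigma > 1e-9:
        step = rng.normal(scale=sigma, size=x.shape)
        cand = x + step
        fc = fun(cand)
        evals += 1
        if np.isfinite(fc) and fc < f:
            improvement = f - fc
            x, f = cand, fc
            trace.append(f)
            rejects = 0
            sigma *= 1.1
            if improvement < tol and len(trace) > 5:
                return x, trace, True
        else:
            rejects += 1
            if rejects >= 20:
                sigma *= 0.5
                rejects = 0
    return x, trace, sigma <= 1e-9


def _joint_descent(gm, h, motivation, cfg) -> AIResult:
    start = _two_step(gm, h, motivation, cfg)
    rng = np.random.default_rng(cfg.seed)
    sequences = start.pi_star.sequences
    x0 = _pack(start.phi_star, start.pi_star)

    def objective(x):
        try:
            phi, pi, _ = _unpack(x, start.phi_star, sequences)
            return ai_objective(gm, h, phi, pi, motivation, cfg.gamma)
        except (ValueError, FloatingPointError):
            return float("inf")

    x, trace, converged = _adaptive_search(objective, x0, rng,
                                           cfg.tol, cfg.max_evals)
    phi, pi, _ = _unpack(x, start.phi_star, sequences)
    prior = action_prior(variational_Q(gm, phi, motivation), cfg.gamma)
    f = free_energy(gm, h, phi)
    return AIResult(phi, pi, objective=trace[-1], f_term=f,
                    kl_term=pi.kl_to(prior), trace=trace, converged=converged)


def ai_optimize(gm: GenerativeModel, h: History, motivation: MotivationConfig,
                cfg: AIConfig) -> AIResult:
    """Minimize the active-inference objective with a fixed precision γ."""
    if cfg.optimizer == "two_step":
        return _two_step(gm, h, motivation, cfg)
    return _joint_descent(gm, h, motivation, cfg)


def ai_optimize_gamma(gm: GenerativeModel, h: History,
                      motivation: MotivationConfig, cfg: AIConfig) -> AIResult:
    """Full variant: optimize additionally over a categorical belief on a
    finite γ grid against its prior.

    A singleton grid reduces exactly (bitwise) to :func:`ai_optimize`.
    """
    if cfg.gamma_grid is None:
        raise ValueError("ai_optimize_gamma needs a gamma grid")
    if len(cfg.gamma_grid) == 1:
        sub = AIConfig(gamma=cfg.gamma_grid[0], optimizer=cfg.optimizer,
                       tol=cfg.tol, max_evals=cfg.max_evals, seed=cfg.seed,
                       cavi_tol=cfg.cavi_tol, cavi_max_sweeps=cfg.cavi_max_sweeps)
        res = ai_optimize(gm, h, motivation, sub)
        res.gamma_posterior = np.array([1.0])
        return res
    if cfg.optimizer == "two_step":
        return _two_step_gamma(gm, h, motivation, cfg)
    return _joint_descent_gamma(gm, h, motivation, cfg)


def _gamma_kl_term(pi: ActionSeqDistribution, rho: np.ndarray,
                   priors: list[ActionSeqDistribution],
                   gamma_prior: np.ndarray) -> float:
    """KL of r(â, γ) = r(â|π) r(γ) from q(â|γ, φ) q(γ | ξ^Γ)."""
    kl = 0.0
    for rg, wg, prior in zip(rho, gamma_prior, priors):
        if rg <= 0:
            continue
        if wg <= 0:
            return float("inf")
        kl += rg * (np.log(rg) - np.log(wg) + pi.kl_to(prior))
    return kl


def _two_step_gamma(gm, h, motivation, cfg) -> AIResult:
    rng = np.random.default_rng(cfg.seed)
    phi, trace = cavi_optimize(gm, h, tol=cfg.cavi_tol,
                               max_sweeps=cfg.cavi_max_sweeps, rng=rng)
    f = trace.values[-1]
    Q = variational_Q(gm, phi, motivation)
    priors = [action_prior(Q, g) for g in cfg.gamma_grid]
    sequences = priors[0].sequences
    logq = [np.log(np.maximum(p.probs, 1e-300)) for p in priors]
    rho = cfg.gamma_prior.copy()
    pi = ActionSeqDistribution(sequences, sum(r * p.probs
                                              for r, p in zip(rho, priors)))
    prev = float("inf")
    for _ in range(500):
        # π update: geometric mean of the per-γ softmax targets
        logpi = sum(r * lq for r, lq in zip(rho, logq))
        logpi = logpi - logpi.max()
        p = np.exp(logpi)
        pi = ActionSeqDistribution(sequences, p / p.sum())
        # γ update: prior reweighted by exp(−KL(π ‖ q_γ))
        kls = np.array([pi.kl_to(pr) for pr in priors])
        logrho = np.log(cfg.gamma_prior) - kls
        logrho -= logrho.max()
        rho = np.exp(logrho)
        rho /= rho.sum()
        val = _gamma_kl_term(pi, rho, priors, cfg.gamma_prior)
        if abs(prev - val) < 1e-12:
            break
        prev = val
    kl = _gamma_kl_term(pi, rho, priors, cfg.gamma_prior)
    return AIResult(phi, pi, objective=f + kl, f_term=f, kl_term=kl,
                    gamma_posterior=rho, trace=list(trace.values),
                    converged=trace.converged)


def _joint_descent_gamma(gm, h, motivation, cfg) -> AIResult:
    start = _two_step_gamma(gm, h, motivation, cfg)
    rng = np.random.default_rng(cfg.seed)
    sequences = start.pi_star.sequences
    n_gamma = len(cfg.gamma_grid)
    x0 = _pack(start.phi_star, start.pi_star, extra=start.gamma_posterior)

    def objective(x):
        try:
            phi, pi, rho = _unpack(x, start.phi_star, sequences, n_extra=n_gamma)
            f = free_energy(gm, h, phi)
            Q = variational_Q(gm, phi, motivation)
            priors = [action_prior(Q, g) for g in cfg.gamma_grid]
            return f + _gamma_kl_term(pi, rho, priors, cfg.gamma_prior)
        except (ValueError, FloatingPointError):
            return float("inf")

    x, trace, converged = _adaptive_search(objective, x0, rng,
                                           cfg.tol, cfg.max_evals)
    phi, pi, rho = _unpack(x, start.phi_star, sequences, n_extra=n_gamma)
    f = free_energy(gm, h, phi)
    return AIResult(phi, pi, objective=trace[-1], f_term=f,
                    kl_term=trace[-1] - f, gamma_posterior=rho,
                    trace=trace, converged=converged)


def ai_action(res: AIResult, rng: np.random.Generator, action_space) -> str:
    """Sample the next action from the first-action marginal of π*."""
    p = res.pi_star.first_action_marginal(action_space)
    return action_space.labels[int(rng.choice(len(action_space), p=p))]
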