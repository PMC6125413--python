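"""Agent assembly and the experiment loop.

An experiment configuration wires one environment, one generative
model, one inference backend (exact Bayesian or mean-field
variational), one intrinsic motivation and one action-selection scheme
(or the active-inference optimizer) into an agent contract
p(a_t | m_t), then runs the true perception-action loop and logs one
JSON-Lines record per step.

Incompatible combinations (Thompson sampling with a motivation that
evaluates the parameter posterior) are rejected at assembly time, not
mid-run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .activeinf import AIConfig, ai_optimize, ai_optimize_gamma
from .exact_inference import complete_posterior
from .fixtures import (
    FixtureSpec,
    ensemble_model_for,
    generative_model_for,
    make_fixture,
)
from .genmodel import GenerativeModel
from .motivations import (
    GoalPrior,
    MotivationConfig,
    value_table,
)
from .paloop import EnvironmentSpec, History, run_loop
from .probtables import Categorical
from .selection import (
    SelectionConfig,
    argmax_select,
    softmax_policy,
    thompson_policy,
)
from .variational import approximate_complete_posterior, cavi_optimize

__all__ = [
    "ExperimentConfig",
    "AssembledAgent",
    "assemble_agent",
    "run_experiment",
    "load_config",
]


@dataclass
class ExperimentConfig:
    environment: dict | EnvironmentSpec
    steps: int = 5
    seed: int = 0
    horizon: int = 2
    inference: str = "exact"                  # exact | variational
    model: dict = field(default_factory=dict)  # backend, concentration, ...
    motivation: dict = field(default_factory=lambda: {"name": "fep"})
    selection: dict | None = None             # scheme, gamma
    active_inference: dict | None = None      # optimizer, gamma / gamma_grid
    log_values: bool = False                  # record per-candidate Q values

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.inference not in ("exact", "variational"):
            raise ValueError(f"unknown inference backend {self.inference!r}")
        if (self.selection is None) == (self.active_inference is None):
            raise ValueError(
                "exactly one of 'selection' and 'active_inference' is required"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {"environment", "steps", "seed", "horizon", "inference",
                 "model", "motivation", "selection", "active_inference",
                 "log_values"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "environment" not in d:
            raise ValueError("config needs an 'environment' section")
        return cls(**d)


def load_config(path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ExperimentConfig.from_dict(data)


def _build_environment(cfg: ExperimentConfig) -> EnvironmentSpec:
    env = cfg.environment
    if isinstance(env, EnvironmentSpec):
        return env
    if "file" in env:
        return EnvironmentSpec.from_json(env["file"])
    if "kind" in env:
        kw = {k: v for k, v in env.items() if k != "sizes"}
        if "sizes" in env:
            kw["sizes"] = tuple(env["sizes"])
        return make_fixture(FixtureSpec(**kw))
    return EnvironmentSpec.from_dict(env)


def _build_model(cfg: ExperimentConfig, env: EnvironmentSpec) -> GenerativeModel:
    m = dict(cfg.model)
    backend = m.pop("backend", "dirichlet")
    if backend == "dirichlet":
        gm = generative_model_for(
            env, n=cfg.horizon,
            concentration=float(m.pop("concentration", 1.0)),
            Ehat_size=m.pop("Ehat_size", None),
            xi1=np.asarray(m["xi1"], float) if "xi1" in m else None,
        )
        m.pop("xi1", None)
    elif backend == "ensemble":
        specs = m.pop("environments", None)
        if specs is None:
            envs = [env]
        else:
            envs = [make_fixture(FixtureSpec(**s)) if "kind" in s
                    else EnvironmentSpec.from_dict(s) for s in specs]
        gm = ensemble_model_for(envs, n=cfg.horizon, weights=m.pop("weights", None))
    else:
        raise ValueError(f"unknown model backend {backend!r}")
    if m:
        raise ValueError(f"unknown model keys: {sorted(m)}")
    gm.check_spaces(env.S, env.A)
    return gm


def _build_motivation(cfg: ExperimentConfig) -> MotivationConfig:
    m = dict(cfg.motivation)
    if "goal_prior" in m:
        m["goal_prior"] = GoalPrior(np.asarray(m["goal_prior"], float))
    if "blocks" in m:
        m["blocks"] = tuple(m["blocks"])
    mot = MotivationConfig(**m)
    if mot.requires_parameter_posterior and mot.mc_seed is None:
        # derive a deterministic MC stream for dirichlet-backend info gain
        mot.mc_seed = (cfg.seed * 9973 + 17) % (2**31)
        if mot.mc_samples is None:
            mot.mc_samples = 200
    return mot


class AssembledAgent:
    """The action-generation contract p(a_t | m_t) plus diagnostics.

    Calling the agent on a history returns a Categorical over actions;
    ``last_info`` holds the value table / free energy / objective of the
    most recent call for logging.
    """

    def __init__(self, cfg: ExperimentConfig, env: EnvironmentSpec):
        self.cfg = cfg
        self.env = env
        self.gm = _build_model(cfg, env)
        self.motivation = _build_motivation(cfg)
        self.selection = None if cfg.selection is None else SelectionConfig(
            **{k: v for k, v in cfg.selection.items()})
        self.ai_config = None
        if cfg.active_inference is not None:
            ai = dict(cfg.active_inference)
            ai.setdefault("seed", cfg.seed)
            if "gamma_prior" in ai:
                ai["gamma_prior"] = np.asarray(ai["gamma_prior"], float)
            self.ai_config = AIConfig(**ai)
        if (self.selection is not None
                and self.selection.scheme == "thompson"
                and self.motivation.requires_parameter_posterior):
            raise ValueError(
                f"motivation {self.motivation.name!r} evaluates the parameter "
                "posterior and cannot be paired with Thompson sampling"
            )
        if cfg.inference == "variational" and self.ai_config is None \
                and self.selection.scheme == "thompson":
            raise ValueError("Thompson sampling uses the exact posterior factor")
        self.last_info: dict = {}

    def __call__(self, h: History) -> Categorical:
        if self.ai_config is not None:
            return self._active_inference(h)
        if self.cfg.inference == "exact":
            if self.selection.scheme == "thompson":
                dist = thompson_policy(self.gm, h, self.motivation)
                self.last_info = {"scheme": "thompson"}
                return dist
            d = complete_posterior(self.gm, h)
        else:
            r, trace = cavi_optimize(self.gm, h)
            self.last_info = {"F": trace.values[-1], "sweeps": trace.sweeps}
            d = approximate_complete_posterior(self.gm, r)
        Q = value_table(d, self.motivation)
        self.last_info["Q"] = {"|".join(k): v for k, v in Q.entries.items()}
        if self.selection.scheme == "argmax":
            best = argmax_select(Q, self.gm.Ahat)
            return Categorical.point_mass(self.gm.Ahat, best[0])
        return softmax_policy(Q, self.selection.gamma, self.gm.Ahat)

    def _active_inference(self, h: History) -> Categorical:
        if self.ai_config.gamma_grid is not None:
            res = ai_optimize_gamma(self.gm, h, self.motivation, self.ai_config)
        else:
            res = ai_optimize(self.gm, h, self.motivation, self.ai_config)
        self.last_info = {"objective": res.objective, "F": res.f_term,
                          "KL": res.kl_term}
        p = res.pi_star.first_action_marginal(self.gm.Ahat)
        return Categorical(self.gm.Ahat, p)


def assemble_agent(cfg: ExperimentConfig,
                   env: EnvironmentSpec | None = None) -> AssembledAgent:
    if env is None:
        env = _build_environment(cfg)
    return AssembledAgent(cfg, env)


def run_experiment(cfg: ExperimentConfig, out_path) -> str:
    """Run the loop and write one JSON-Lines record per step.

    The final line is a summary record.  Records are deterministic for a
    fixed (config, seed) apart from the wall-clock fields.
    """
    env = _build_environment(cfg)
    agent = assemble_agent(cfg, env)
    rng = np.random.default_rng(cfg.seed)
    t0 = time.perf_counter()
    records = run_loop(env, agent, cfg.steps, rng)
    out_path = str(out_path)
    with open(out_path, "w") as fh:
        for rec in records:
            row = {"t": rec.t, "s": rec.s, "a": rec.a}
            if cfg.log_values and rec.t > 0 and "Q" in agent.last_info:
                row["diag"] = {k: v for k, v in agent.last_info.items()
                               if k != "Q"}
            fh.write(json.dumps(row) + "\n")
        summary = {
            "summary": True,
            "steps": cfg.steps,
            "seed": cfg.seed,
            "sensors": [r.s for r in records],
            "actions": [r.a for r in records[1:]],
            "wall_clock_s": time.perf_counter() - t0,
        }
        fh.write(json.dumps(summary) + "\n")
    return out_path
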