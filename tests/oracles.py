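"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's sequential-predictive machinery:
the ensemble oracle enumerates complete latent trajectories with plain
CPT products, and the Dirichlet oracle scores complete trajectories with
the closed-form Dirichlet-multinomial marginal (ratios of multivariate
Beta functions of count arrays) — a different route to the same law.
"""

import itertools

import numpy as np
from scipy.special import gammaln

from motiveloop import GenerativeModel, History


def _log_beta(c: np.ndarray) -> float:
    return float(gammaln(c).sum() - gammaln(c.sum()))


def brute_joint_future(gm: GenerativeModel, h: History, a_future):
    """Normalized joint over (ŝ-future, ê-future) given history and actions.

    Shape: [|Ŝ|]*h + [|Ê|]*h, matching CompletePosterior.joint_future.
    """
    t = h.t
    hlen = len(a_future)
    acts = list(h.actions) + list(a_future)
    n_e, n_s = len(gm.Ehat), len(gm.Shat)
    s_hist = [gm.Shat.index(s) for s in h.sensors]
    a_idx = [gm.Ahat.index(a) for a in acts]
    out = np.zeros(tuple([n_s] * hlen + [n_e] * hlen))
    T = t + hlen - 1
    for e_path in itertools.product(range(n_e), repeat=T + 1):
        for s_fut in itertools.product(range(n_s), repeat=hlen):
            s_all = s_hist + list(s_fut)
            if gm.prior.backend == "ensemble":
                p = 0.0
                for w, th in zip(gm.prior.weights, gm.prior.points):
                    q = th.t3[e_path[0]] * th.t1[e_path[0], s_all[0]]
                    for r in range(1, T + 1):
                        q *= th.t2[a_idx[r - 1], e_path[r - 1], e_path[r]]
                        q *= th.t1[e_path[r], s_all[r]]
                    p += w * q
            else:
                xi = gm.prior.dirichlet
                c1, c2, c3 = xi.xi1.copy(), xi.xi2.copy(), xi.xi3.copy()
                c3[e_path[0]] += 1
                c1[e_path[0], s_all[0]] += 1
                for r in range(1, T + 1):
                    c2[a_idx[r - 1], e_path[r - 1], e_path[r]] += 1
                    c1[e_path[r], s_all[r]] += 1
                lw = _log_beta(c3) - _log_beta(xi.xi3)
                for j in range(n_e):
                    lw += _log_beta(c1[j]) - _log_beta(xi.xi1[j])
                for ai in range(c2.shape[0]):
                    for i in range(n_e):
                        lw += _log_beta(c2[ai, i]) - _log_beta(xi.xi2[ai, i])
                p = np.exp(lw)
            out[tuple(s_fut) + tuple(e_path[t:])] += p
    return out / out.sum()


def brute_posterior_over_paths(gm: GenerativeModel, h: History):
    """Exact p(ê_{0:t-1}, k | data) for ensemble models (path, point index)."""
    assert gm.prior.backend == "ensemble"
    t = h.t
    n_e = len(gm.Ehat)
    s_idx = [gm.Shat.index(s) for s in h.sensors]
    a_idx = [gm.Ahat.index(a) for a in h.actions]
    probs = {}
    for k, (w, th) in enumerate(zip(gm.prior.weights, gm.prior.points)):
        for path in itertools.product(range(n_e), repeat=t):
            p = w * th.t3[path[0]] * th.t1[path[0], s_idx[0]]
            for r in range(1, t):
                p *= th.t2[a_idx[r - 1], path[r - 1], path[r]]
                p *= th.t1[path[r], s_idx[r]]
            probs[(path, k)] = p
    total = sum(probs.values())
    return {key: v / total for key, v in probs.items()}, total


def brute_evidence(gm: GenerativeModel, h: History) -> float:
    """q(s_{<t} | a_{<t}, ξ) by complete enumeration (either backend)."""
    t = h.t
    n_e = len(gm.Ehat)
    s_idx = [gm.Shat.index(s) for s in h.sensors]
    a_idx = [gm.Ahat.index(a) for a in h.actions]
    total = 0.0
    for path in itertools.product(range(n_e), repeat=t):
        if gm.prior.backend == "ensemble":
            for w, th in zip(gm.prior.weights, gm.prior.points):
                p = w * th.t3[path[0]] * th.t1[path[0], s_idx[0]]
                for r in range(1, t):
                    p *= th.t2[a_idx[r - 1], path[r - 1], path[r]]
                    p *= th.t1[path[r], s_idx[r]]
                total += p
        else:
            xi = gm.prior.dirichlet
            c1, c2, c3 = xi.xi1.copy(), xi.xi2.copy(), xi.xi3.copy()
            c3[path[0]] += 1
            c1[path[0], s_idx[0]] += 1
            for r in range(1, t):
                c2[a_idx[r - 1], path[r - 1], path[r]] += 1
                c1[path[r], s_idx[r]] += 1
            lw = _log_beta(c3) - _log_beta(xi.xi3)
            for j in range(n_e):
                lw += _log_beta(c1[j]) - _log_beta(xi.xi1[j])
            for ai in range(c2.shape[0]):
                for i in range(n_e):
                    lw += _log_beta(c2[ai, i]) - _log_beta(xi.xi2[ai, i])
            total += np.exp(lw)
    return total


def loop_entropy(p: np.ndarray) -> float:
    """Elementwise-loop entropy in nats (independent of the vector code)."""
    total = 0.0
    for x in np.asarray(p).ravel():
        if x > 0:
            total -= x * np.log(x)
    return total
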