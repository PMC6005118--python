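"""Variational belief updating and expected-free-energy policy evaluation.

State inference runs message-passing sweeps over each hidden-state factor:
per-time log-likelihood messages (marginalized over the other factors'
current beliefs) are combined with forward and backward transition messages
and renormalized, iterated to a fixed point.  For single-factor models one
sweep reaches the exact smoothed posterior; with several factors the sweeps
implement a mean-field fixed point across factors.

Policies are scored by their expected free energy

    G(pi) = expected cost - salience - novelty

summed over the policy horizon.  Expected cost is the cross-entropy between
predicted outcomes and log-preferences; salience is the expected state
information gain; novelty is the expected Dirichlet information gain about
the likelihood mapping, computed in closed form (digamma / log) for a
one-observation update.  The policy posterior is softmax(ln E - gamma * G).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, log_softmax, softmax

from .mdp_core import GenerativeModel, Modality

__all__ = [
    "BeliefState",
    "EFEDecomposition",
    "update_state_beliefs",
    "free_energy",
    "expected_free_energy",
    "expected_cost",
    "salience_term",
    "novelty_term",
    "policy_posterior",
    "action_marginal",
    "bma_states",
    "select_action",
]

_EPS = 1e-16
_SALIENCE_ENUM_CAP = 200_000


def _ln(x: np.ndarray) -> np.ndarray:
    return np.log(x + _EPS)


# ---------------------------------------------------------------------------
# State inference
# ---------------------------------------------------------------------------

@dataclass
class BeliefState:
    """Posterior beliefs at one epoch of a trial.

    ``states`` holds one (T, dim_f) array per hidden-state factor;
    ``policy`` is the posterior over policies and ``bma`` the
    policy-averaged predictive state posterior over the joint state space.
    """

    states: list[np.ndarray]
    policy: np.ndarray | None = None
    bma: np.ndarray | None = None


def _expected_lnA(model: GenerativeModel, m: Modality, outcome: int,
                  qs: list[np.ndarray], t: int, factor: int) -> np.ndarray:
    """Expected log-likelihood message from modality ``m`` to one factor.

    ln A[outcome] is reshaped over the modality's dependent factors and
    averaged under the current beliefs of every dependent factor except
    ``factor``.
    """
    dims = tuple(model.factor_dims[f] for f in m.factors)
    lnA = _ln(m.A[outcome]).reshape(dims)
    # Average over every dependent factor except `factor`, collapsing axes
    # from the back so axis bookkeeping stays simple.
    for i in reversed(range(len(m.factors))):
        f = m.factors[i]
        if f == factor:
            continue
        lnA = np.tensordot(lnA, qs[f][t], axes=([i], [0]))
    return lnA


def update_state_beliefs(model: GenerativeModel,
                         observations: list[dict[str, int]],
                         actions: list[int],
                         max_iters: int = 16,
                         tol: float = 1e-8,
                         return_history: bool = False):
    """Posterior state expectations given outcomes up to time T.

    ``observations[t]`` maps modality name -> outcome index (a modality may
    be omitted at a time point); ``actions[t]`` generated the transition
    from t to t+1, so ``len(actions) == T - 1``.  Returns one (T, dim_f)
    array per factor (optionally with the free-energy history across
    sweeps).  Raises if the fixed point is not reached within ``max_iters``
    sweeps.
    """
    T = len(observations)
    if len(actions) != T - 1:
        raise ValueError("need exactly T-1 actions for T observation epochs")
    qs = [np.full((T, d), 1.0 / d) for d in model.factor_dims]

    history = []
    for _ in range(max_iters):
        delta = 0.0
        for f, dim in enumerate(model.factor_dims):
            # emission potentials for this factor, all time points
            lnphi = np.zeros((T, dim))
            for t in range(T):
                for m in model.modalities:
                    if f not in m.factors or m.name not in observations[t]:
                        continue
                    lnphi[t] += _expected_lnA(model, m, observations[t][m.name], qs, t, f)
            phi = np.exp(lnphi - lnphi.max(axis=1, keepdims=True))
            # forward pass
            alpha = np.empty((T, dim))
            a = model.D[f] * phi[0]
            alpha[0] = a / a.sum()
            for t in range(1, T):
                B = model.transitions.B(f, actions[t - 1])
                a = phi[t] * (B @ alpha[t - 1])
                alpha[t] = a / a.sum()
            # backward pass
            beta = np.ones((T, dim))
            for t in range(T - 2, -1, -1):
                B = model.transitions.B(f, actions[t])
                b = B.T @ (beta[t + 1] * phi[t + 1])
                beta[t] = b / b.sum()
            new = alpha * beta
            new /= new.sum(axis=1, keepdims=True)
            delta = max(delta, float(np.abs(new - qs[f]).max()))
            qs[f] = new
        if return_history:
            history.append(free_energy(model, qs, observations, actions))
        if delta < tol:
            break
    else:
        raise RuntimeError("state-belief updates did not converge")
    if return_history:
        return qs, history
    return qs


def free_energy(model: GenerativeModel,
                beliefs: list[np.ndarray],
                observations: list[dict[str, int]],
                actions: list[int]) -> float:
    """Variational free energy of factorized beliefs (diagnostic).

    Computed under the mean-field factorization over time points and
    factors; an upper bound on surprise, -ln P(o), for any normalized
    beliefs, tight when the exact posterior factorizes.
    """
    T = len(observations)
    F = 0.0
    for f, q in enumerate(beliefs):
        F += float((q * _ln(q)).sum())  # -entropy
        F -= float(q[0] @ _ln(model.D[f]))
        for t in range(1, T):
            B = model.transitions.B(f, actions[t - 1])
            F -= float(q[t] @ (_ln(B) @ q[t - 1]))
    for t in range(T):
        for m in model.modalities:
            if m.name not in observations[t]:
                continue
            msg = _ln(m.A[observations[t][m.name]]).reshape(
                tuple(model.factor_dims[f] for f in m.factors))
            for i in reversed(range(len(m.factors))):
                msg = np.tensordot(msg, beliefs[m.factors[i]][t], axes=([i], [0]))
            F -= float(msg)
    return F


# ---------------------------------------------------------------------------
# Expected free energy
# ---------------------------------------------------------------------------

@dataclass
class EFEDecomposition:
    """Per-policy expected cost, salience, novelty and total G.

    G = cost - salience - novelty, each summed over the policy horizon.
    """

    cost: np.ndarray
    salience: np.ndarray
    novelty: np.ndarray

    @property
    def G(self) -> np.ndarray:
        return self.cost - self.salience - self.novelty


def _joint_predictive(model: GenerativeModel, m: Modality,
                      xs: list[np.ndarray]) -> np.ndarray:
    """Predictive distribution over the columns of modality ``m``."""
    w = np.ones(1)
    for f in m.factors:
        w = np.einsum("i,j->ij", w, xs[f]).reshape(-1)
    return w


def _unit_update_kl_table(counts: np.ndarray) -> np.ndarray:
    """KL[Dir(a + e_i) || Dir(a)] for every outcome i and column j.

    Closed form for a single-observation Dirichlet update:
    ln a0 - ln a_ij + digamma(a_ij + 1) - digamma(a0 + 1).
    """
    a0 = counts.sum(axis=0, keepdims=True)
    return np.log(a0) - np.log(counts) + digamma(counts + 1.0) - digamma(a0 + 1.0)


def _salience_value(model: GenerativeModel, xs: list[np.ndarray]) -> float:
    """Expected state information gain for predictive beliefs ``xs``.

    Exact: enumerates joint outcomes across modalities over the joint state
    space.  Skipped (zero) when the predictive state is already certain.
    """
    x = np.ones(1)
    for q in xs:
        x = np.einsum("i,j->ij", x, q).reshape(-1)
    if x.max() > 1.0 - 1e-12:
        return 0.0
    # per-modality likelihood over joint states
    likes = []
    for m in model.modalities:
        A = m.A
        dims = tuple(model.factor_dims[f] for f in m.factors)
        full = A.reshape((m.n_outcomes,) + dims)
        # broadcast over all factors
        shape = [m.n_outcomes] + [1] * model.n_factors
        for i, f in enumerate(m.factors):
            shape[1 + f] = dims[i]
        full = full.reshape(shape)
        full = np.broadcast_to(full, [m.n_outcomes] + list(model.factor_dims))
        likes.append(full.reshape(m.n_outcomes, -1))
    n_combo = int(np.prod([m.n_outcomes for m in model.modalities]))
    if n_combo * x.size > _SALIENCE_ENUM_CAP:
        raise ValueError("salience enumeration too large for exact evaluation")
    lnx = _ln(x)
    total = 0.0
    for combo in itertools.product(*[range(m.n_outcomes) for m in model.modalities]):
        po_s = np.ones_like(x)
        for k, i in enumerate(combo):
            po_s = po_s * likes[k][i]
        po = float(po_s @ x)
        if po <= 0:
            continue
        post = po_s * x / po
        kl = float(post @ (_ln(post) - lnx))
        total += po * kl
    return total


def expected_free_energy(model: GenerativeModel,
                         current: list[np.ndarray] | None = None,
                         novelty_weight: float = 1.0) -> EFEDecomposition:
    """Evaluate cost, salience and novelty for every policy.

    ``current`` holds the per-factor posterior over the present state
    (defaults to the initial priors D).  Counts are held fixed along the
    rollout; each policy's terms are summed over its horizon.
    """
    if current is None:
        current = [d.copy() for d in model.D]
    space = model.policy_space
    P = space.n_policies

    ln_pref = {m.name: log_softmax(m.C) for m in model.modalities}
    kl_tables = {m.name: _unit_update_kl_table(m.counts)
                 for m in model.modalities if m.learnable}

    cost = np.zeros(P)
    sal = np.zeros(P)
    nov = np.zeros(P)
    for p, policy in enumerate(space.policies):
        xs = [q.copy() for q in current]
        for u in policy:
            xs = [model.transitions.B(f, u) @ xs[f] for f in range(model.n_factors)]
            for m in model.modalities:
                w = _joint_predictive(model, m, xs)
                o_pred = m.A @ w
                cost[p] += -float(o_pred @ ln_pref[m.name])
                if m.learnable:
                    tbl = kl_tables[m.name]
                    nov[p] += novelty_weight * float(w @ (m.A * tbl).sum(axis=0))
            sal[p] += _salience_value(model, xs)
    return EFEDecomposition(cost=cost, salience=sal, novelty=nov)


def expected_cost(model: GenerativeModel, policy: int,
                  current: list[np.ndarray] | None = None) -> float:
    """Expected cost of one policy (cross-entropy with log-preferences)."""
    return float(expected_free_energy(model, current).cost[policy])


def salience_term(model: GenerativeModel, policy: int,
                  current: list[np.ndarray] | None = None) -> float:
    """Expected state information gain of one policy."""
    return float(expected_free_energy(model, current).salience[policy])


def novelty_term(model: GenerativeModel, policy: int,
                 current: list[np.ndarray] | None = None) -> float:
    """Expected likelihood (Dirichlet) information gain of one policy."""
    return float(expected_free_energy(model, current).novelty[policy])


# ---------------------------------------------------------------------------
# Policy posterior and action selection
# ---------------------------------------------------------------------------

def policy_posterior(E: np.ndarray, G: np.ndarray, gamma: float) -> np.ndarray:
    """softmax(ln E - gamma * G)."""
    E = np.asarray(E, dtype=float)
    G = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(G)):
        raise ValueError("expected free energy must be finite")
    return softmax(np.log(E) - gamma * G)


def action_marginal(model: GenerativeModel, q_pi: np.ndarray) -> np.ndarray:
    """Posterior over the next action, marginalizing the policy posterior."""
    q_u = np.zeros(model.n_actions)
    for p, policy in enumerate(model.policy_space.policies):
        q_u[policy[0]] += q_pi[p]
    return q_u


def bma_states(per_policy: np.ndarray, q_pi: np.ndarray) -> np.ndarray:
    """Bayesian model average of per-policy state posteriors."""
    per_policy = np.asarray(per_policy, dtype=float)
    return per_policy.T @ q_pi


def select_action(posterior: np.ndarray, mode: str = "sample",
                  rng: np.random.Generator | None = None,
                  seed: int | None = None) -> int:
    """Draw (or maximize) an action from its posterior.

    'sample' draws with the given rng/seed; 'argmax' takes the most probable
    action, ties broken by lowest index.
    """
    posterior = np.asarray(posterior, dtype=float)
    if mode == "argmax":
        return int(np.argmax(posterior))
    if mode == "sample":
        if rng is None:
            rng = np.random.default_rng(seed)
        return int(rng.choice(len(posterior), p=posterior / posterior.sum()))
    raise ValueError(f"unknown action-selection mode: {mode!r}")
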