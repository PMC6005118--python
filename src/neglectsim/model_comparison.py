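"""Lesion-deficit decoding by Bayesian model comparison of scanpaths.

Each candidate model is replayed in open loop over an observed fixation
sequence: it receives the recorded outcome stream, accumulates its own
Dirichlet counts, and at every epoch assigns a posterior probability to the
saccade that was actually made.  The summed log probability of the recorded
saccades is the model's log evidence for that trial (there are no free
parameters, so the evidence reduces to the expected log likelihood).  A
softmax over models (uniform model prior) turns seed-averaged evidences
into posterior model probabilities, and simulating data from every model in
the bank yields a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from . import inference, learning
from .environment import Display, TrialRecord, generate_display, run_trial
from .lesions import LesionSpec, apply_lesion
from .mdp_core import GenerativeModel, build_flat_model, build_multiscale_model

__all__ = [
    "ModelBank",
    "EvidenceTable",
    "default_bank",
    "replay_log_evidence",
    "model_posteriors",
    "confusion_experiment",
]


@dataclass
class ModelBank:
    """Labeled candidate lesions sharing one task and state space."""

    specs: dict[str, LesionSpec]

    def __post_init__(self) -> None:
        if len(set(self.specs)) != len(self.specs):
            raise ValueError("model labels must be unique")

    @property
    def labels(self) -> list[str]:
        return list(self.specs)

    def build(self, display: Display, config,
              kind: str = "multiscale") -> dict[str, GenerativeModel]:
        builder = build_flat_model if kind == "flat" else build_multiscale_model
        healthy = builder(display.targets, config)
        out = {}
        for label, spec in self.specs.items():
            m = apply_lesion(healthy, spec)
            m.label = label
            out[label] = m
        return out


def default_bank(scale: str | None = "coarse") -> ModelBank:
    """Healthy plus the three neglect lesions at default magnitudes."""
    return ModelBank({
        "healthy": LesionSpec("none"),
        "A1": LesionSpec("A1", scale=scale),
        "E": LesionSpec("E", scale=scale),
        "C2": LesionSpec("C2", scale=scale),
    })


@dataclass
class EvidenceTable:
    """Per (dataset, model) summed log evidence and per-dataset posteriors."""

    log_evidence: pd.DataFrame  # rows: generating dataset, cols: candidate
    posterior: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.posterior.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-8):
            raise ValueError("posterior rows must sum to 1")


# ---------------------------------------------------------------------------
# Replay scoring
# ---------------------------------------------------------------------------

def replay_log_evidence(record: TrialRecord, model: GenerativeModel,
                        eta: float = 1.0, novelty_weight: float = 1.0,
                        per_epoch: bool = False):
    """Log evidence of a candidate model for one recorded trial.

    The candidate is run open loop: its beliefs and Dirichlet counts evolve
    from the recorded outcome stream while its actions are clamped to the
    recorded saccades.  Returns sum_t ln q_model(action_t) (or the
    per-epoch terms).
    """
    if record.model_kind != model.kind:
        raise ValueError("record and model use different state spaces")
    model = model.copy()
    current = [d.copy() for d in model.D]
    terms = []
    from .environment import _delta_beliefs  # local import to avoid cycle

    for e in record.epochs:
        efe = inference.expected_free_energy(model, current,
                                             novelty_weight=novelty_weight)
        q_pi = inference.policy_posterior(model.policy_space.E, efe.G, model.gamma)
        q_u = inference.action_marginal(model, q_pi)
        terms.append(float(np.log(q_u[e.action] + 1e-300)))
        current = _delta_beliefs(model, e.fixation)
        learning.update_model_counts(model, e.onset, current, eta)
        learning.update_model_counts(model, e.offset, current, eta)
    if per_epoch:
        return terms
    return float(sum(terms))


def model_posteriors(log_evidence: np.ndarray) -> np.ndarray:
    """Softmax posterior over models under a uniform model prior."""
    le = np.asarray(log_evidence, dtype=float)
    if not np.all(np.isfinite(le)):
        raise ValueError("log evidences must be finite")
    return softmax(le)


# ---------------------------------------------------------------------------
# Confusion experiment
# ---------------------------------------------------------------------------

def confusion_experiment(bank: ModelBank, config, n_saccades: int = 40,
                         n_seeds: int = 10, kind: str = "multiscale",
                         n_targets: int = 16, layout: str = "balanced",
                         action_mode: str = "sample",
                         base_seed: int = 0) -> EvidenceTable:
    """Simulate data from every model and score it under every model.

    For each generating model and seed a fresh display is drawn, a trial is
    simulated, and every candidate (built for the same display) scores the
    recorded saccades; log evidences are averaged over seeds and soft-maxed
    per row.  Generation samples saccades from the policy posterior:
    stochastic behavior is what makes the evidence informative (for sampled
    data the generating model maximizes expected log evidence; deterministic
    scanpaths from different lesions can coincide exactly).
    """
    mode = action_mode
    labels = bank.labels
    total = pd.DataFrame(0.0, index=labels, columns=labels)
    for s in range(n_seeds):
        seed = base_seed + s
        display = generate_display(n_targets, layout, seed=seed)
        models = bank.build(display, config, kind=kind)
        for gen in labels:
            rec = run_trial(models[gen], display, n_saccades, seed=seed,
                            action_mode=mode, eta=config.eta)
            for cand in labels:
                total.loc[gen, cand] += replay_log_evidence(
                    rec, models[cand], eta=config.eta)
    log_ev = total / n_seeds
    post = log_ev.apply(lambda row: pd.Series(model_posteriors(row.to_numpy()),
                                              index=labels), axis=1)
    return EvidenceTable(log_evidence=log_ev, posterior=post)
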