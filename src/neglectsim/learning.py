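"""Dirichlet count accumulation: short-term synaptic memory for cancellation.

Observing outcome ``i`` while believing the hidden state occupies column
``j`` with probability ``s_j`` adds ``eta * s_j`` to the count ``a[i, j]``.
Within a trial this is how the agent remembers which targets it has already
canceled: once a location has emitted a red outcome, its predicted visual
outcome shifts toward red, raising the expected cost and lowering the
novelty of refixating it.  Counts are reset between trials (within-trial
working memory); only visual-stream modalities learn — the proprioceptive
mapping is a fixed identity.
"""

from __future__ import annotations

import numpy as np

from .inference import _joint_predictive
from .mdp_core import GenerativeModel

__all__ = ["accumulate_counts", "update_model_counts"]


def accumulate_counts(a: np.ndarray, outcome: int | np.ndarray,
                      posterior: np.ndarray, eta: float = 1.0) -> np.ndarray:
    """Return counts updated by one observation.

    ``a' = a + eta * onehot(outcome) x posterior``; total count mass grows
    by exactly ``eta`` per observation (posterior normalized).
    """
    a = np.asarray(a, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    if np.isscalar(outcome) or np.ndim(outcome) == 0:
        o = np.zeros(a.shape[0])
        o[int(outcome)] = 1.0
    else:
        o = np.asarray(outcome, dtype=float)
    if o.shape[0] != a.shape[0] or posterior.shape[0] != a.shape[1]:
        raise ValueError("outcome/posterior shapes do not match the count array")
    return a + eta * np.outer(o, posterior)


def update_model_counts(model: GenerativeModel, observations: dict[str, int],
                        state_posterior: list[np.ndarray],
                        eta: float = 1.0) -> None:
    """Accumulate counts of every learnable modality, in place on ``model``.

    ``state_posterior`` holds one belief vector per hidden-state factor; the
    posterior over a modality's columns is the product over its dependent
    factors.
    """
    for m in model.modalities:
        if not m.learnable or m.name not in observations:
            continue
        w = _joint_predictive(model, m, state_posterior)
        m.counts = accumulate_counts(m.counts, observations[m.name], w, eta)
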