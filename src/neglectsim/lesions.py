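"""In-silico lesions producing visual neglect.

Three functional lesions are applied to a healthy generative model (the
environment itself is never lesioned):

* ``A1`` — the Dirichlet counts of visual-stream likelihood columns on the
  *neglected* side are inflated by a factor kappa.  The likelihood
  probabilities are unchanged (count scaling is normalization-invariant),
  but the neglected side becomes familiar: observations there no longer
  promise belief updates, so the intact side is comparatively novel.
  Anatomically a disconnection of the second branch of the superior
  longitudinal fasciculus.
* ``E`` — a fixed bias of the policy prior: ln E is incremented for every
  saccade landing on the intact side (putamen / habitual policy bias).
* ``C2`` — prior preferences for proprioceptive outcomes on the intact
  side (pulvinar input to dorsal parietal cortex): the agent expects to be
  looking rightward, and acts so as to fulfil that expectation.

In the multiscale model each lesion can be applied at the quadrant
('coarse'), subquadrant ('mid') or cell ('fine') scale: the left/right
predicate is evaluated on that factor alone, which yields egocentric
neglect of the array at the coarse scale and allocentric (within-object)
neglect at the fine scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp_core import (
    GenerativeModel,
    GridLocation,
    factor_side_is_left,
    loc_to_factors,
)

__all__ = [
    "DEFAULT_MAGNITUDES",
    "LesionSpec",
    "lesion_A1",
    "lesion_E",
    "lesion_C2",
    "apply_lesion",
]

DEFAULT_MAGNITUDES = {"A1": 100.0, "E": 4.0, "C2": 4.0}

_SCALE_FACTOR = {"coarse": 0, "mid": 1, "fine": 2}


@dataclass(frozen=True)
class LesionSpec:
    """Which lesion to apply, to which side, how strongly, at which scale.

    ``side`` names the neglected hemifield (default left).  ``scale`` is
    only meaningful for multiscale models (giving one for a flat model is
    an error; None means coarse for multiscale); ``magnitude=None`` selects
    the per-kind default (kappa=100 for A1, +4 log-units for E and C2).
    """

    kind: str = "none"
    side: str = "left"
    magnitude: float | None = None
    scale: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "A1", "E", "C2"):
            raise ValueError(f"unknown lesion kind: {self.kind!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side: {self.side!r}")
        if self.scale is not None and self.scale not in _SCALE_FACTOR:
            raise ValueError(f"unknown scale: {self.scale!r}")
        if self.magnitude is not None and self.magnitude <= 0:
            raise ValueError("lesion magnitude must be positive")

    def scale_factor(self) -> int:
        return _SCALE_FACTOR[self.scale or "coarse"]

    def strength(self) -> float:
        if self.magnitude is not None:
            return float(self.magnitude)
        return DEFAULT_MAGNITUDES[self.kind]


# ---------------------------------------------------------------------------
# Side predicates
# ---------------------------------------------------------------------------

def _flat_side_mask(left: bool) -> np.ndarray:
    """Boolean mask over the 64 grid locations for one hemifield."""
    mask = np.array([GridLocation.from_index(i).left_hemifield for i in range(64)])
    return mask if left else ~mask

def _factor_level_mask(left: bool) -> np.ndarray:
    mask = np.array([factor_side_is_left(v) for v in range(4)])
    return mask if left else ~mask


def _modality_column_mask(model: GenerativeModel, m, factor: int,
                          left: bool) -> np.ndarray | None:
    """Mask over modality columns whose `factor` coordinate is on `side`.

    None when the modality does not depend on the lesioned factor.
    """
    if factor not in m.factors:
        return None
    dims = tuple(model.factor_dims[f] for f in m.factors)
    axis = m.factors.index(factor)
    level_mask = _factor_level_mask(left)
    grid = np.zeros(dims, dtype=bool)
    idx = [slice(None)] * len(dims)
    idx[axis] = level_mask
    grid[tuple(idx)] = True
    return grid.reshape(-1)


def _destination_side_mask(model: GenerativeModel, spec: LesionSpec,
                           left: bool) -> np.ndarray:
    """Mask over actions whose destination is on the given side at the
    lesion's scale."""
    if model.kind == "flat":
        return _flat_side_mask(left)
    vals = model.destinations[:, spec.scale_factor()]
    return _factor_level_mask(left)[vals]


def _check(model: GenerativeModel, spec: LesionSpec) -> None:
    if model.kind not in ("flat", "multiscale"):
        raise ValueError("lesions apply to cancellation-task models only")
    if model.kind == "flat" and spec.scale is not None:
        raise ValueError("a lesion scale only applies to multiscale models")


# ---------------------------------------------------------------------------
# Lesion constructors
# ---------------------------------------------------------------------------

def lesion_A1(model: GenerativeModel, spec: LesionSpec) -> GenerativeModel:
    """Inflate neglected-side visual Dirichlet counts by kappa.

    Likelihood probabilities are untouched; only the implied confidence
    (and hence novelty) changes.  In the multiscale model every learnable
    modality that depends on the lesioned factor is scaled on the columns
    whose coordinate at that factor lies on the neglected side.
    """
    _check(model, spec)
    out = model.copy()
    kappa = spec.strength()
    left = spec.side == "left"
    if model.kind == "flat":
        mask = _flat_side_mask(left)
        vis = out.modality("visual")
        vis.counts = vis.counts.copy()
        vis.counts[:, mask] *= kappa
        out.label = "A1"
        return out
    factor = spec.scale_factor()
    for m in out.modalities:
        if not m.learnable:
            continue
        mask = _modality_column_mask(out, m, factor, left)
        if mask is None:
            continue
        m.counts = m.counts.copy()
        m.counts[:, mask] *= kappa
    out.label = "A1"
    return out


def lesion_E(model: GenerativeModel, spec: LesionSpec) -> GenerativeModel:
    """Bias the policy prior toward intact-side saccades.

    ln E of every policy whose (first) destination lies on the intact side
    is incremented by the lesion magnitude; E is renormalized.
    """
    _check(model, spec)
    out = model.copy()
    intact_mask = _destination_side_mask(model, spec, left=spec.side != "left")
    lnE = np.log(out.policy_space.E)
    for p, policy in enumerate(out.policy_space.policies):
        if intact_mask[policy[0]]:
            lnE[p] += spec.strength()
    E = np.exp(lnE - lnE.max())
    out.policy_space.E = E / E.sum()
    out.label = "E"
    return out


def lesion_C2(model: GenerativeModel, spec: LesionSpec) -> GenerativeModel:
    """Prefer proprioceptive outcomes on the intact side.

    The healthy model has uniform (zero) proprioceptive preferences; the
    lesion sets them to +magnitude for intact-side locations at the chosen
    scale, zero elsewhere.
    """
    _check(model, spec)
    out = model.copy()
    left_intact = spec.side != "left"
    if model.kind == "flat":
        prop = out.modality("proprioception")
        C = np.zeros(prop.n_outcomes)
        C[_flat_side_mask(left_intact)] = spec.strength()
        prop.C = C
    else:
        scale_name = {"coarse": "quadrant", "mid": "subquadrant", "fine": "cell"}
        prop = out.modality(f"proprio_{scale_name[spec.scale or 'coarse']}")
        C = np.zeros(4)
        C[_factor_level_mask(left_intact)] = spec.strength()
        prop.C = C
    out.label = "C2"
    return out


def apply_lesion(model: GenerativeModel, spec: LesionSpec) -> GenerativeModel:
    """Dispatch on the lesion kind; 'none' returns a relabeled copy."""
    if spec.kind == "none":
        out = model.copy()
        out.label = "healthy"
        return out
    return {"A1": lesion_A1, "E": lesion_E, "C2": lesion_C2}[spec.kind](model, spec)
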