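"""Generative-model construction for the saccadic cancellation task.

The agent searches an 8x8 array of targets by saccading between grid
locations.  Hidden states are fixation locations; outcomes are a visual
modality (white / black / red, i.e. empty / target / canceled target) and a
proprioceptive modality reporting eye position.  Two state-space encodings
are provided:

* a *flat* model with a single 64-level location factor, and
* a *multiscale* model in which location is encoded by three quadtree
  factors (quadrant, subquadrant, cell; 4 levels each, 4**3 = 64 locations)
  with visual outcomes read out at three spatial resolutions (quadrant
  target density, subquadrant target density, and the fine white/black/red
  appearance).  Only the finest resolution distinguishes canceled targets;
  the density channels are color-blind.

Likelihood beliefs are Dirichlet counts (``a``); normalizing each column
gives the categorical likelihood ``A``.  Saccades are deterministic
transitions: every column of ``B(u)`` is the unit vector at the saccade
destination.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GRID_SIZE",
    "N_LOCATIONS",
    "WHITE",
    "BLACK",
    "RED",
    "VISUAL_OUTCOMES",
    "GridLocation",
    "FactorizedLocation",
    "loc_to_factors",
    "factors_to_loc",
    "normalize_counts",
    "Modality",
    "TransitionSet",
    "PolicySpace",
    "GenerativeModel",
    "build_flat_model",
    "build_multiscale_model",
    "random_toy_model",
]

GRID_SIZE = 8
N_LOCATIONS = GRID_SIZE * GRID_SIZE

# Visual outcome coding shared by the flat model and the finest multiscale
# resolution.
WHITE, BLACK, RED = 0, 1, 2
VISUAL_OUTCOMES = ("white", "black", "red")

# Density-channel cardinalities: a quadrant holds up to 16 targets, a
# subquadrant up to 4.
N_DENSITY_COARSE = 17
N_DENSITY_MID = 5

_EPS = 1e-16


# ---------------------------------------------------------------------------
# Locations
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GridLocation:
    """A cell of the 8x8 display, row-major indexed.

    Columns 0-3 form the left hemifield, columns 4-7 the right.
    """

    row: int
    col: int

    def __post_init__(self) -> None:
        if not (0 <= self.row < GRID_SIZE and 0 <= self.col < GRID_SIZE):
            raise ValueError(f"location out of range: ({self.row}, {self.col})")

    @property
    def index(self) -> int:
        return self.row * GRID_SIZE + self.col

    @classmethod
    def from_index(cls, index: int) -> "GridLocation":
        if not 0 <= index < N_LOCATIONS:
            raise ValueError(f"location index out of range: {index}")
        return cls(index // GRID_SIZE, index % GRID_SIZE)

    @property
    def left_hemifield(self) -> bool:
        return self.col < GRID_SIZE // 2


@dataclass(frozen=True)
class FactorizedLocation:
    """Quadtree address of a grid cell: quadrant / subquadrant / cell.

    At every level the four quadrants are ordered [upper-left, upper-right,
    lower-left, lower-right], so values 0 and 2 are the left-hand quadrants.
    """

    quadrant: int
    subquadrant: int
    cell: int

    def __post_init__(self) -> None:
        for v in (self.quadrant, self.subquadrant, self.cell):
            if not 0 <= v < 4:
                raise ValueError(f"factor value out of range: {self}")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.quadrant, self.subquadrant, self.cell)


def loc_to_factors(loc: GridLocation) -> FactorizedLocation:
    """Quadtree address of a grid location (2x2 blocks, applied recursively)."""
    q = 2 * (loc.row >= 4) + (loc.col >= 4)
    s = 2 * ((loc.row % 4) >= 2) + ((loc.col % 4) >= 2)
    c = 2 * (loc.row % 2) + (loc.col % 2)
    return FactorizedLocation(int(q), int(s), int(c))


def factors_to_loc(fac: FactorizedLocation) -> GridLocation:
    """Inverse of :func:`loc_to_factors`."""
    row = 4 * (fac.quadrant // 2) + 2 * (fac.subquadrant // 2) + fac.cell // 2
    col = 4 * (fac.quadrant % 2) + 2 * (fac.subquadrant % 2) + fac.cell % 2
    return GridLocation(row, col)


def factor_side_is_left(value: int) -> bool:
    """Whether a quadtree factor value lies on the left at its own scale."""
    return value in (0, 2)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def normalize_counts(a: np.ndarray) -> np.ndarray:
    """Column-normalize Dirichlet counts into a likelihood matrix.

    ``A[i, j] = a[i, j] / sum_k a[k, j]``; invariant under positive rescaling
    of ``a``.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= 0):
        raise ValueError("Dirichlet counts must be strictly positive")
    return a / a.sum(axis=0, keepdims=True)


@dataclass
class Modality:
    """One outcome modality of the generative model.

    ``factors`` lists the hidden-state factors the likelihood depends on;
    its columns enumerate the joint levels of those factors in C order.
    Learnable modalities carry Dirichlet counts from which ``A`` is derived;
    fixed modalities (proprioception) carry ``A`` directly.
    """

    name: str
    n_outcomes: int
    factors: tuple[int, ...]
    counts: np.ndarray | None = None
    A_fixed: np.ndarray | None = None
    C: np.ndarray | None = None
    learnable: bool = False

    def __post_init__(self) -> None:
        if self.C is None:
            self.C = np.zeros(self.n_outcomes)
        self.C = np.asarray(self.C, dtype=float)
        if self.learnable and self.counts is None:
            raise ValueError(f"learnable modality {self.name!r} needs counts")
        if not self.learnable and self.A_fixed is None:
            raise ValueError(f"fixed modality {self.name!r} needs A_fixed")

    @property
    def A(self) -> np.ndarray:
        if self.learnable:
            return normalize_counts(self.counts)
        return self.A_fixed

    @property
    def n_columns(self) -> int:
        return self.A.shape[1]

    def likelihood_entropy(self) -> np.ndarray:
        """Per-column entropy H of the likelihood (diagnostic)."""
        A = self.A
        return -(A * np.log(A + _EPS)).sum(axis=0)


# ---------------------------------------------------------------------------
# Transitions and policies
# ---------------------------------------------------------------------------

@dataclass
class TransitionSet:
    """Per-factor, per-action column-stochastic transition matrices.

    ``matrices[f][u]`` is ``B(u)`` for hidden-state factor ``f``.  For
    saccades every column is the unit vector at the destination, so the
    transition is deterministic and independent of the current location.
    """

    matrices: list[np.ndarray]  # each (n_actions, dim_f, dim_f)

    @property
    def n_actions(self) -> int:
        return self.matrices[0].shape[0]

    def B(self, factor: int, action: int) -> np.ndarray:
        return self.matrices[factor][action]

    @staticmethod
    def saccades(factor_dims: tuple[int, ...],
                 destinations: np.ndarray) -> "TransitionSet":
        """Deterministic saccade transitions.

        ``destinations[u, f]`` gives the level of factor ``f`` after action
        ``u``, regardless of the current state.
        """
        destinations = np.asarray(destinations, dtype=int)
        mats = []
        for f, dim in enumerate(factor_dims):
            m = np.zeros((destinations.shape[0], dim, dim))
            for u in range(destinations.shape[0]):
                m[u, destinations[u, f], :] = 1.0
            mats.append(m)
        return TransitionSet(mats)


@dataclass
class PolicySpace:
    """Allowable policies (action sequences), prior E and precision gamma."""

    policies: list[tuple[int, ...]]
    E: np.ndarray
    gamma: float = 1.0

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if np.any(self.E <= 0) or not np.all(np.isfinite(np.log(self.E))):
            raise ValueError("policy prior E must be strictly positive and finite in log")
        if len(self.policies) != len(self.E):
            raise ValueError("E must have one entry per policy")

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    @property
    def depth(self) -> int:
        return len(self.policies[0])


# ---------------------------------------------------------------------------
# Generative model
# ---------------------------------------------------------------------------

@dataclass
class GenerativeModel:
    """Bundle of the MDP quantities: A/a, B, C, D, E, gamma.

    ``kind`` is 'flat', 'multiscale' or 'toy'.  ``destinations`` maps each of
    the 64 saccade actions to its per-factor landing level (None for toy
    models with genuinely stochastic transitions).
    """

    kind: str
    factor_dims: tuple[int, ...]
    modalities: list[Modality]
    transitions: TransitionSet
    D: list[np.ndarray]
    policy_space: PolicySpace
    destinations: np.ndarray | None = None
    label: str = "healthy"

    def __post_init__(self) -> None:
        for d in self.D:
            if abs(float(np.sum(d)) - 1.0) > 1e-10:
                raise ValueError("initial-state prior D must sum to 1")

    # -- conveniences -----------------------------------------------------

    @property
    def n_factors(self) -> int:
        return len(self.factor_dims)

    @property
    def n_actions(self) -> int:
        return self.transitions.n_actions

    @property
    def gamma(self) -> float:
        return self.policy_space.gamma

    def modality(self, name: str) -> Modality:
        for m in self.modalities:
            if m.name == name:
                return m
        raise KeyError(name)

    def copy(self) -> "GenerativeModel":
        return copy.deepcopy(self)

    def modality_column(self, m: Modality, joint_levels: tuple[int, ...]) -> int:
        """Column index of modality ``m`` for the given per-factor levels."""
        col = 0
        for f in m.factors:
            col = col * self.factor_dims[f] + joint_levels[f]
        return col

    def destination_column(self, m: Modality, action: int) -> int:
        levels = tuple(self.destinations[action])
        return self.modality_column(m, levels)


def _depth_policies(n_actions: int, depth: int) -> list[tuple[int, ...]]:
    if depth == 1:
        return [(u,) for u in range(n_actions)]
    return [tuple(p) for p in itertools.product(range(n_actions), repeat=depth)]


def _initial_counts(n_outcomes: int, true_outcomes: np.ndarray,
                    e0: float, e1: float) -> np.ndarray:
    """Near-uniform Dirichlet counts with a weak increment on the truth.

    Implements the "very weak, but accurate" initial beliefs about target
    locations: ``a = e0 + e1 * onehot(true outcome)`` per column.
    """
    n_cols = len(true_outcomes)
    a = np.full((n_outcomes, n_cols), float(e0))
    a[true_outcomes, np.arange(n_cols)] += float(e1)
    return a


def _visual_preferences(config) -> np.ndarray:
    return np.array([config.c_white, config.c_black, config.c_red], dtype=float)


def _validate_targets(targets) -> set[GridLocation]:
    out = set()
    for t in targets:
        if not isinstance(t, GridLocation):
            raise ValueError(f"targets must be GridLocation, got {t!r}")
        out.add(t)
    return out


def build_flat_model(targets, config) -> GenerativeModel:
    """Healthy flat (single 64-state factor) cancellation-task model.

    Visual Dirichlet counts are near-uniform plus a weak increment on the
    true display outcome of each location; the proprioceptive likelihood is
    the 64x64 identity so the fixated location is always fully observable.
    """
    targets = _validate_targets(targets)
    target_idx = {t.index for t in targets}

    true_visual = np.array(
        [BLACK if i in target_idx else WHITE for i in range(N_LOCATIONS)]
    )
    visual = Modality(
        name="visual",
        n_outcomes=3,
        factors=(0,),
        counts=_initial_counts(3, true_visual, config.e0, config.e1),
        C=_visual_preferences(config),
        learnable=True,
    )
    proprio = Modality(
        name="proprioception",
        n_outcomes=N_LOCATIONS,
        factors=(0,),
        A_fixed=np.eye(N_LOCATIONS),
        C=np.zeros(N_LOCATIONS),
        learnable=False,
    )

    destinations = np.arange(N_LOCATIONS)[:, None]
    transitions = TransitionSet.saccades((N_LOCATIONS,), destinations)

    D = np.zeros(N_LOCATIONS)
    D[GridLocation(config.start_row, config.start_col).index] = 1.0

    policies = _depth_policies(N_LOCATIONS, config.policy_depth)
    space = PolicySpace(
        policies=policies,
        E=np.full(len(policies), 1.0 / len(policies)),
        gamma=config.gamma,
    )
    return GenerativeModel(
        kind="flat",
        factor_dims=(N_LOCATIONS,),
        modalities=[visual, proprio],
        transitions=transitions,
        D=[D],
        policy_space=space,
        destinations=destinations,
    )


def build_multiscale_model(targets, config) -> GenerativeModel:
    """Healthy multiscale (quadrant x subquadrant x cell) model.

    Outcome modalities: quadrant target density (0-16), subquadrant target
    density (0-4), the fine white/black/red appearance, and one identity
    proprioceptive channel per spatial factor.  The density channels count
    targets whether or not they have been canceled (color-blind coarse
    vision); only the fine channel registers cancellation.
    """
    targets = _validate_targets(targets)
    facs = [loc_to_factors(t) for t in targets]

    coarse_truth = np.zeros(4, dtype=int)
    mid_truth = np.zeros(16, dtype=int)
    for f in facs:
        coarse_truth[f.quadrant] += 1
        mid_truth[f.quadrant * 4 + f.subquadrant] += 1

    fine_truth = np.full(64, WHITE, dtype=int)
    for f in facs:
        fine_truth[f.quadrant * 16 + f.subquadrant * 4 + f.cell] = BLACK

    density_coarse = Modality(
        name="density_coarse",
        n_outcomes=N_DENSITY_COARSE,
        factors=(0,),
        counts=_initial_counts(N_DENSITY_COARSE, coarse_truth, config.e0, config.e1),
        learnable=True,
    )
    density_mid = Modality(
        name="density_mid",
        n_outcomes=N_DENSITY_MID,
        factors=(0, 1),
        counts=_initial_counts(N_DENSITY_MID, mid_truth, config.e0, config.e1),
        learnable=True,
    )
    visual = Modality(
        name="visual",
        n_outcomes=3,
        factors=(0, 1, 2),
        counts=_initial_counts(3, fine_truth, config.e0, config.e1),
        C=_visual_preferences(config),
        learnable=True,
    )
    proprio = [
        Modality(
            name=f"proprio_{scale}",
            n_outcomes=4,
            factors=(f,),
            A_fixed=np.eye(4),
            C=np.zeros(4),
            learnable=False,
        )
        for f, scale in enumerate(("quadrant", "subquadrant", "cell"))
    ]

    destinations = np.array(
        [loc_to_factors(GridLocation.from_index(i)).as_tuple()
         for i in range(N_LOCATIONS)]
    )
    transitions = TransitionSet.saccades((4, 4, 4), destinations)

    start = loc_to_factors(GridLocation(config.start_row, config.start_col))
    D = []
    for f, v in enumerate(start.as_tuple()):
        d = np.zeros(4)
        d[v] = 1.0
        D.append(d)

    policies = _depth_policies(N_LOCATIONS, config.policy_depth)
    space = PolicySpace(
        policies=policies,
        E=np.full(len(policies), 1.0 / len(policies)),
        gamma=config.gamma,
    )
    return GenerativeModel(
        kind="multiscale",
        factor_dims=(4, 4, 4),
        modalities=[density_coarse, density_mid, visual] + proprio,
        transitions=transitions,
        D=D,
        policy_space=space,
        destinations=destinations,
    )


# ---------------------------------------------------------------------------
# Toy models (diagnostics and validation)
# ---------------------------------------------------------------------------

def random_toy_model(rng: np.random.Generator,
                     n_states: int = 4,
                     n_outcomes: int = 3,
                     n_actions: int = 2,
                     gamma: float = 1.0,
                     deterministic_b: bool = False) -> GenerativeModel:
    """Small single-factor model with random A, B, D for validation runs."""
    A = rng.dirichlet(np.ones(n_outcomes), size=n_states).T  # (O, S)
    mats = np.empty((n_actions, n_states, n_states))
    for u in range(n_actions):
        if deterministic_b:
            dest = rng.integers(n_states)
            mats[u] = 0.0
            mats[u, dest, :] = 1.0
        else:
            mats[u] = rng.dirichlet(np.ones(n_states), size=n_states).T
    D = rng.dirichlet(np.ones(n_states))
    modality = Modality(
        name="obs",
        n_outcomes=n_outcomes,
        factors=(0,),
        counts=A * 4.0,  # positive counts normalizing back to A exactly
        C=rng.normal(size=n_outcomes),
        learnable=True,
    )
    policies = [(u,) for u in range(n_actions)]
    space = PolicySpace(policies, np.full(n_actions, 1.0 / n_actions), gamma)
    return GenerativeModel(
        kind="toy",
        factor_dims=(n_states,),
        modalities=[modality],
        transitions=TransitionSet([mats]),
        D=[D],
        policy_space=space,
        destinations=None,
    )
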