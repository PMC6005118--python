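"""Ground-truth cancellation-task world and the closed-loop trial runner.

A :class:`Display` is the true state of the 8x8 array (empty / target /
canceled).  Fixating an uncanceled target produces a black onset outcome and
a red offset outcome (the target is canceled during the fixation); both
observations drive inference and Dirichlet learning.  After the offset
observation the agent re-evaluates the expected free energy of all saccadic
policies, forms the policy posterior softmax(ln E - gamma G), selects the
next saccade, and the loop repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, learning
from .mdp_core import (
    BLACK,
    GRID_SIZE,
    N_LOCATIONS,
    RED,
    VISUAL_OUTCOMES,
    WHITE,
    GenerativeModel,
    GridLocation,
    loc_to_factors,
)

__all__ = [
    "EMPTY",
    "TARGET",
    "CANCELED",
    "Display",
    "generate_display",
    "emit_outcomes",
    "step_display",
    "EpochRecord",
    "TrialRecord",
    "run_trial",
    "laterality_stats",
]

EMPTY, TARGET, CANCELED = 0, 1, 2


# ---------------------------------------------------------------------------
# Display
# ---------------------------------------------------------------------------

@dataclass
class Display:
    """True state of the target array.

    The canceled set only ever grows within a trial and is always a subset
    of the initial targets.
    """

    grid: np.ndarray  # (8, 8) int, values in {EMPTY, TARGET, CANCELED}

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        if self.grid.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError("display grid must be 8x8")
        if not np.isin(self.grid, [EMPTY, TARGET, CANCELED]).all():
            raise ValueError("display cells must be empty, target or canceled")

    def copy(self) -> "Display":
        return Display(self.grid.copy())

    @property
    def targets(self) -> set[GridLocation]:
        """All target locations, canceled or not."""
        rows, cols = np.nonzero(self.grid != EMPTY)
        return {GridLocation(int(r), int(c)) for r, c in zip(rows, cols)}

    @property
    def canceled(self) -> set[GridLocation]:
        rows, cols = np.nonzero(self.grid == CANCELED)
        return {GridLocation(int(r), int(c)) for r, c in zip(rows, cols)}

    def cell(self, loc: GridLocation) -> int:
        return int(self.grid[loc.row, loc.col])

    def quadrant_target_count(self, quadrant: int) -> int:
        r0, c0 = 4 * (quadrant // 2), 4 * (quadrant % 2)
        return int((self.grid[r0:r0 + 4, c0:c0 + 4] != EMPTY).sum())

    def subquadrant_target_count(self, quadrant: int, subquadrant: int) -> int:
        r0 = 4 * (quadrant // 2) + 2 * (subquadrant // 2)
        c0 = 4 * (quadrant % 2) + 2 * (subquadrant % 2)
        return int((self.grid[r0:r0 + 2, c0:c0 + 2] != EMPTY).sum())

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write one row per target (columns row,col), canceled or not."""
        rows = sorted((t.row, t.col) for t in self.targets)
        pd.DataFrame(rows, columns=["row", "col"]).to_csv(path, index=False)

    @classmethod
    def from_targets(cls, targets) -> "Display":
        grid = np.zeros((GRID_SIZE, GRID_SIZE), dtype=int)
        for t in targets:
            grid[t.row, t.col] = TARGET
        return cls(grid)

    @classmethod
    def from_csv(cls, path) -> "Display":
        df = pd.read_csv(path, comment="#")
        return cls.from_targets(
            GridLocation(int(r), int(c)) for r, c in zip(df["row"], df["col"])
        )


def generate_display(n_targets: int, layout: str = "uniform",
                     seed: int | None = None) -> Display:
    """Seeded reproducible target layouts.

    ``layout`` is 'uniform' (anywhere on the grid) or 'balanced' (targets
    split equally between the two hemifields; n_targets must be even).
    """
    if not 0 <= n_targets <= N_LOCATIONS:
        raise ValueError("n_targets must be between 0 and 64")
    rng = np.random.default_rng(seed)
    if layout == "uniform":
        idx = rng.choice(N_LOCATIONS, size=n_targets, replace=False)
    elif layout == "balanced":
        if n_targets % 2:
            raise ValueError("balanced layout needs an even target count")
        half = n_targets // 2
        left = [r * GRID_SIZE + c for r in range(GRID_SIZE) for c in range(4)]
        right = [r * GRID_SIZE + c for r in range(GRID_SIZE) for c in range(4, 8)]
        idx = np.concatenate([
            rng.choice(left, size=half, replace=False),
            rng.choice(right, size=half, replace=False),
        ])
    else:
        raise ValueError(f"unknown layout mode: {layout!r}")
    return Display.from_targets(GridLocation.from_index(int(i)) for i in idx)


# ---------------------------------------------------------------------------
# Outcome generation
# ---------------------------------------------------------------------------

def _appearance(cell_state: int, after_fixation: bool) -> int:
    if cell_state == EMPTY:
        return WHITE
    if cell_state == CANCELED:
        return RED
    return RED if after_fixation else BLACK


def emit_outcomes(display: Display, fixation: GridLocation,
                  kind: str = "flat") -> tuple[dict[str, int], dict[str, int]]:
    """Onset and offset outcome dictionaries for a fixation.

    Onset reports the cell's current appearance; offset reports it after
    the cancellation rule (a fixated target turns red).  Density outcomes
    count targets whether canceled or not, so they are identical at onset
    and offset.  Proprioception reports the fixated location exactly.
    """
    cell = display.cell(fixation)
    onset: dict[str, int] = {"visual": _appearance(cell, after_fixation=False)}
    offset: dict[str, int] = {"visual": _appearance(cell, after_fixation=True)}
    if kind == "flat":
        onset["proprioception"] = offset["proprioception"] = fixation.index
    elif kind == "multiscale":
        fac = loc_to_factors(fixation)
        dens_c = display.quadrant_target_count(fac.quadrant)
        dens_m = display.subquadrant_target_count(fac.quadrant, fac.subquadrant)
        for d in (onset, offset):
            d["density_coarse"] = dens_c
            d["density_mid"] = dens_m
            d["proprio_quadrant"] = fac.quadrant
            d["proprio_subquadrant"] = fac.subquadrant
            d["proprio_cell"] = fac.cell
    else:
        raise ValueError(f"unknown model kind: {kind!r}")
    return onset, offset


def step_display(display: Display, fixation: GridLocation) -> Display:
    """Cancel the fixated target (if any); idempotent on canceled cells."""
    out = display.copy()
    if out.grid[fixation.row, fixation.col] == TARGET:
        out.grid[fixation.row, fixation.col] = CANCELED
    return out


# ---------------------------------------------------------------------------
# Trial runner
# ---------------------------------------------------------------------------

@dataclass
class EpochRecord:
    """One saccade epoch: where the eye landed and what it saw."""

    epoch: int
    action: int
    fixation: GridLocation
    onset: dict[str, int]
    offset: dict[str, int]
    policy_posterior: np.ndarray
    efe: inference.EFEDecomposition
    bma: np.ndarray


@dataclass
class TrialRecord:
    """Time-indexed record of a simulated cancellation trial."""

    epochs: list[EpochRecord]
    display_initial: Display
    display_final: Display
    seed: int | None
    model_label: str
    model_kind: str
    config_hash: str = ""
    trial_id: int = 0

    @property
    def fixations(self) -> list[GridLocation]:
        return [e.fixation for e in self.epochs]

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def to_frame(self) -> pd.DataFrame:
        """Scanpath table: one row per epoch."""
        rows = [
            {
                "trial_id": self.trial_id,
                "epoch": e.epoch,
                "row": e.fixation.row,
                "col": e.fixation.col,
                "onset_outcome": VISUAL_OUTCOMES[e.onset["visual"]],
                "offset_outcome": VISUAL_OUTCOMES[e.offset["visual"]],
                "model_label": self.model_label,
                "seed": self.seed,
            }
            for e in self.epochs
        ]
        return pd.DataFrame(
            rows,
            columns=["trial_id", "epoch", "row", "col", "onset_outcome",
                     "offset_outcome", "model_label", "seed"],
        )


def _delta_beliefs(model: GenerativeModel, loc: GridLocation) -> list[np.ndarray]:
    """Per-factor delta beliefs at a known fixation location."""
    if model.kind == "flat":
        levels = (loc.index,)
    else:
        levels = loc_to_factors(loc).as_tuple()
    out = []
    for dim, v in zip(model.factor_dims, levels):
        q = np.zeros(dim)
        q[v] = 1.0
        out.append(q)
    return out


def run_trial(model: GenerativeModel, display: Display, n_saccades: int,
              seed: int | None = None, action_mode: str = "argmax",
              eta: float = 1.0, novelty_weight: float = 1.0,
              config_hash: str = "", trial_id: int = 0) -> TrialRecord:
    """Closed-loop simulation of one cancellation trial.

    Per epoch: evaluate G for every policy -> policy posterior -> select a
    saccade -> observe the onset and offset outcomes at the new fixation
    (accumulating Dirichlet counts after each) -> display updates.  The
    input model and display are not mutated.
    """
    model = model.copy()
    world = display.copy()
    rng = np.random.default_rng(seed)

    current = [d.copy() for d in model.D]  # agent starts at the D location
    epochs: list[EpochRecord] = []
    for t in range(1, n_saccades + 1):
        efe = inference.expected_free_energy(model, current,
                                             novelty_weight=novelty_weight)
        q_pi = inference.policy_posterior(model.policy_space.E, efe.G,
                                          model.gamma)
        q_u = inference.action_marginal(model, q_pi)
        u = inference.select_action(q_u, mode=action_mode, rng=rng)
        fix = GridLocation.from_index(u)

        onset, offset = emit_outcomes(world, fix, model.kind)
        current = _delta_beliefs(model, fix)
        learning.update_model_counts(model, onset, current, eta)
        world = step_display(world, fix)
        learning.update_model_counts(model, offset, current, eta)

        # predictive state posterior averaged over policies (recorded before
        # the saccade's outcome is known would equal this mixture of
        # per-policy destination beliefs)
        dest_beliefs = np.zeros((model.policy_space.n_policies, N_LOCATIONS))
        for p, pol in enumerate(model.policy_space.policies):
            dest_beliefs[p, pol[0]] = 1.0
        bma = inference.bma_states(dest_beliefs, q_pi)

        epochs.append(EpochRecord(
            epoch=t, action=u, fixation=fix, onset=onset, offset=offset,
            policy_posterior=q_pi, efe=efe, bma=bma,
        ))

    return TrialRecord(
        epochs=epochs,
        display_initial=display.copy(),
        display_final=world,
        seed=seed,
        model_label=model.label,
        model_kind=model.kind,
        config_hash=config_hash,
        trial_id=trial_id,
    )


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def laterality_stats(record: TrialRecord) -> dict:
    """Hemifield and within-scale laterality summary of a trial.

    Conditional laterality at a scale is the fraction of fixations landing
    on the right-hand side *at that scale* (right quadrants of the array,
    right subquadrants within their quadrant, right cells within their
    subquadrant).
    """
    if not record.epochs:
        raise ValueError("empty trial record")
    fixes = record.fixations
    n = len(fixes)
    right = sum(not f.left_hemifield for f in fixes)
    facs = [loc_to_factors(f) for f in fixes]

    def right_at(vals) -> float:
        return sum(v in (1, 3) for v in vals) / n

    quadrant_occupancy = np.zeros(4)
    for f in facs:
        quadrant_occupancy[f.quadrant] += 1
    quadrant_occupancy /= n

    init_targets = record.display_initial.targets
    canc = record.display_final.canceled
    targets_left = sum(t.left_hemifield for t in init_targets)
    targets_right = len(init_targets) - targets_left
    canceled_left = sum(c.left_hemifield for c in canc)
    canceled_right = len(canc) - canceled_left

    return {
        "n_fixations": n,
        "left_fraction": 1.0 - right / n,
        "right_fraction": right / n,
        "quadrant_occupancy": quadrant_occupancy,
        "right_quadrant_fraction": right_at([f.quadrant for f in facs]),
        "within_quadrant_right_fraction": right_at([f.subquadrant for f in facs]),
        "within_subquadrant_right_fraction": right_at([f.cell for f in facs]),
        "targets_left": targets_left,
        "targets_right": targets_right,
        "canceled_left": canceled_left,
        "canceled_right": canceled_right,
    }
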