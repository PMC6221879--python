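"""Multi-generation truncation-selection experiments.

Three schemes acting on final (time point T) weights:

* ``individual`` — mass selection: the heaviest fraction of individuals.
* ``group-mean`` — group selection: all members of the groups with the
  highest average weight.
* ``group-variance`` — group selection for uniformity: all members of the
  groups with the *lowest* within-group weight variance.

Selected individuals become the parents of the next generation according to
their (randomly assigned, 1:1) sex: males are used as sires, females as
dams.  Dams are shuffled and dealt round-robin to shuffled sires, and
per-dam litter sizes are balanced so each generation is restored to exactly
2 * n_groups offspring.  The per-generation trajectory records the mean
within-group variance, the realized mean b, the three mean breeding values
and the mean final weight, which together characterize how each scheme
moves competition and variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ExtinctionError, InvalidParameterError
from .model_core import Individual, SimParams, scenario_params
from .population import (
    Cohort,
    ParentPanel,
    _offspring_cohort,
    sample_base_population,
    simulate_cohort,
)
from .summary_stats import within_group_variance

__all__ = ["SCHEMES", "SelectionExperiment", "select_parents", "run_selection_experiment",
           "run_selection_replicates"]

SCHEMES = ("individual", "group-mean", "group-variance")

_TRAJECTORY_COLUMNS = (
    "generation", "within_var", "mean_b", "mean_A_D", "mean_A_I",
    "mean_A_GR", "mean_weight",
)


@dataclass
class SelectionExperiment:
    """Configuration and (after running) per-generation trajectory."""

    scheme: str = "individual"
    proportion: float = 0.11
    n_generations: int = 10
    params: SimParams = field(default_factory=lambda: scenario_params(1))
    trajectory: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise InvalidParameterError(f"scheme must be one of {SCHEMES}")
        if not 0 < self.proportion <= 1:
            raise InvalidParameterError("proportion must be in (0, 1]")
        if self.n_generations < 1:
            raise InvalidParameterError("n_generations must be >= 1")


def _select_rows(
    cohort: Cohort, scheme: str, proportion: float, time_point: int = -1
) -> np.ndarray:
    """Row indices of selected individuals; ties broken by id for determinism."""
    w = cohort.weights[:, time_point]
    if scheme == "individual":
        n_sel = max(2, round(proportion * cohort.n))
        # sort by (-weight, id): heaviest first, deterministic under ties
        order = np.lexsort((cohort.ids, -w))
        return order[:n_sel]
    pairs = cohort.pair_members
    if scheme == "group-mean":
        score = -w[pairs].mean(axis=1)            # highest mean first
    elif scheme == "group-variance":
        d = w[pairs[:, 0]] - w[pairs[:, 1]]
        score = d * d                             # lowest variance first
    else:
        raise InvalidParameterError(f"unknown scheme {scheme!r}")
    n_sel_groups = max(1, round(proportion * len(pairs)))
    group_id_tiebreak = cohort.ids[pairs].min(axis=1)
    order = np.lexsort((group_id_tiebreak, score))
    return pairs[order[:n_sel_groups]].ravel()


def select_parents(
    cohort: Cohort,
    scheme: str,
    proportion: float,
    rng: np.random.Generator | None = None,
    time_point: int = -1,
) -> list[Individual]:
    """Selected individuals as scalar objects (object-level API).

    Deterministic given the cohort (``rng`` is accepted for interface
    symmetry but truncation selection needs no randomness).
    """
    if scheme not in SCHEMES:
        raise InvalidParameterError(f"scheme must be one of {SCHEMES}")
    rows = _select_rows(cohort, scheme, proportion, time_point)
    return [cohort.individual(r) for r in sorted(rows)]


def _breed(
    cohort: Cohort,
    selected_rows: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    generation: int,
) -> Cohort:
    """Next generation from the selected parents (population size restored)."""
    sel = np.asarray(selected_rows)
    males = sel[cohort.sex[sel] == 0]
    females = sel[cohort.sex[sel] == 1]
    if len(males) < 1 or len(females) < 1:
        raise ExtinctionError(
            f"generation {generation}: selection left {len(males)} sires and "
            f"{len(females)} dams"
        )

    def panel(rows: np.ndarray) -> ParentPanel:
        eff = cohort.effects
        return ParentPanel(
            ids=cohort.ids[rows],
            effects=type(eff)(**{
                k: np.asarray(getattr(eff, k))[rows]
                for k in ("A_GR", "E_p_GR", "A_D", "E_D", "A_I", "E_I")
            }),
        )

    sire_panel, dam_panel = panel(males), panel(females)
    n_target = 2 * params.n_groups
    n_dams = len(females)
    # random mating: shuffled dams dealt round-robin to shuffled sires
    sire_order = rng.permutation(len(males))
    dam_order = rng.permutation(n_dams)
    dam_sire = np.empty(n_dams, dtype=np.intp)
    dam_sire[dam_order] = sire_order[np.arange(n_dams) % len(males)]
    # balanced litter sizes summing to the target population size
    litters = np.full(n_dams, n_target // n_dams, dtype=int)
    litters[: n_target % n_dams] += 1
    dam_rows = np.repeat(np.arange(n_dams), litters)
    sire_rows = dam_sire[dam_rows]
    return _offspring_cohort(
        generation=generation,
        sire_rows=sire_rows,
        dam_rows=dam_rows,
        sire_panel=sire_panel,
        dam_panel=dam_panel,
        params=params,
        rng=rng,
        id_start=int(cohort.ids.max()) + 1,
    )


def _record(cohort: Cohort) -> dict:
    eff = cohort.effects
    return {
        "generation": cohort.generation,
        "within_var": within_group_variance(cohort),
        "mean_b": float(np.mean(cohort.b_own)),
        "mean_A_D": float(np.mean(eff.A_D)),
        "mean_A_I": float(np.mean(eff.A_I)),
        "mean_A_GR": float(np.mean(eff.A_GR)),
        "mean_weight": float(np.mean(cohort.weights[:, -1])),
    }


def run_selection_experiment(
    exp: SelectionExperiment, rng: np.random.Generator
) -> SelectionExperiment:
    """Run one replicate: base generation plus n_generations of selection.

    Returns a copy of ``exp`` whose trajectory has n_generations + 1 rows
    (the base generation is row 0).
    """
    params = exp.params
    cohort = simulate_cohort(sample_base_population(params, rng), params, rng)
    rows = [_record(cohort)]
    for g in range(1, exp.n_generations + 1):
        selected = _select_rows(cohort, exp.scheme, exp.proportion)
        cohort = _breed(cohort, selected, params, rng, generation=g)
        simulate_cohort(cohort, params, rng)
        rows.append(_record(cohort))
    return replace(exp, trajectory=pd.DataFrame(rows, columns=_TRAJECTORY_COLUMNS))


def run_selection_replicates(
    exp: SelectionExperiment, n_replicates: int, seed: int
) -> pd.DataFrame:
    """Mean trajectory over replicates (columns as per replicate, averaged).

    Replicate r uses an independent stream spawned from (seed, r), so
    results do not depend on execution order.
    """
    frames = []
    for r in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        frames.append(run_selection_experiment(exp, rng).trajectory)
    stacked = pd.concat(frames)
    return stacked.groupby("generation", as_index=False).mean()
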