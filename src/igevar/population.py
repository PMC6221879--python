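"""Base populations, Mendelian inheritance, pair assignment, cohort simulation.

A generation is held as a :class:`Cohort`: structure-of-arrays over
individuals (ids, pedigree, sex, the six lifetime effects, the weight
trajectory) plus the pairing (member index pairs and the two interaction
coefficients per pair).  The array layout is what makes whole-breeding-
program simulations cheap; the object API of :mod:`igevar.model_core`
(:class:`~igevar.model_core.Individual`, :class:`~igevar.model_core.Group`)
is available through :meth:`Cohort.groups` for small-scale work, and both
paths implement the identical equations.

Inheritance is purely additive: each of the three breeding values of an
offspring is the parental midpoint plus an independent Mendelian-sampling
deviate ~ Normal(0, base additive variance / 2) (non-inbred, unrelated
parents), while the three environmental effects are drawn fresh at birth.
Pair assignment is a uniform random perfect matching; the "non-sib" policy
additionally forbids paternal half/full sibs as mates, so that sire-level
statistics separate an individual's own group from the groups its sibs
serve in as mates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidParameterError, MatchingError, StateError
from .model_core import EffectSet, Group, Individual, SimParams, compute_b

__all__ = [
    "ParentPanel",
    "Cohort",
    "sample_effects",
    "sample_base_population",
    "make_offspring",
    "assign_groups",
    "match_pairs",
    "simulate_cohort",
]

log = logging.getLogger(__name__)

_EFFECT_NAMES = ("A_GR", "E_p_GR", "A_D", "E_D", "A_I", "E_I")
_GENETIC = ("A_GR", "A_D", "A_I")
_ENVIRONMENTAL = ("E_p_GR", "E_D", "E_I")


def _effect_variances(params: SimParams) -> dict[str, float]:
    return {
        "A_GR": params.var_A_GR,
        "E_p_GR": params.var_Ep_GR,
        "A_D": params.var_AD,
        "E_D": params.var_ED,
        "A_I": params.var_AI,
        "E_I": params.var_EI,
    }


def sample_effects(params: SimParams, n: int, rng: np.random.Generator) -> EffectSet:
    """Draw n independent effect sets from the base-population distributions.

    All six effects are mutually independent zero-mean normals (all genetic
    correlations are zero by construction).  Draw order is fixed (A_GR,
    E_p_GR, A_D, E_D, A_I, E_I) for reproducibility.
    """
    var = _effect_variances(params)
    return EffectSet(**{
        name: rng.normal(0.0, np.sqrt(var[name]), size=n) for name in _EFFECT_NAMES
    })


@dataclass(frozen=True)
class ParentPanel:
    """Ids and effects of one parental sex (sires or dams) of a generation."""

    ids: np.ndarray
    effects: EffectSet

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class Cohort:
    """One generation: individuals (arrays), their pairing, and trajectories.

    ``pair_members[g] = (i, j)`` are the row indices of group g's two
    members; ``b_values[g] = (b_ij, b_ji)`` the coefficient acting on each.
    ``weights`` has one column per stored time point; after simulation its
    shape is (n, n_time_points + 1).
    """

    generation: int
    ids: np.ndarray
    sire_ids: np.ndarray
    dam_ids: np.ndarray
    sex: np.ndarray            # 0 = male, 1 = female
    effects: EffectSet         # array-valued
    weights: np.ndarray        # (n, >=1)
    pair_members: np.ndarray | None = None   # (n_groups, 2) int
    b_values: np.ndarray | None = None       # (n_groups, 2) float
    sires: ParentPanel | None = None
    dams: ParentPanel | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_groups(self) -> int:
        self._require_groups()
        return len(self.pair_members)

    @property
    def n_time_points(self) -> int:
        """Number of growth increments simulated so far."""
        return self.weights.shape[1] - 1

    def _require_groups(self) -> None:
        if self.pair_members is None or self.b_values is None:
            raise StateError("cohort has no group assignment; call form_groups first")

    @property
    def partner_index(self) -> np.ndarray:
        """(n,) row index of each individual's group mate."""
        self._require_groups()
        out = np.empty(self.n, dtype=np.intp)
        out[self.pair_members[:, 0]] = self.pair_members[:, 1]
        out[self.pair_members[:, 1]] = self.pair_members[:, 0]
        return out

    @property
    def group_index(self) -> np.ndarray:
        """(n,) group number of each individual."""
        self._require_groups()
        out = np.empty(self.n, dtype=np.intp)
        g = np.arange(len(self.pair_members))
        out[self.pair_members[:, 0]] = g
        out[self.pair_members[:, 1]] = g
        return out

    @property
    def b_own(self) -> np.ndarray:
        """(n,) interaction coefficient acting on each individual."""
        self._require_groups()
        out = np.empty(self.n, dtype=float)
        out[self.pair_members[:, 0]] = self.b_values[:, 0]
        out[self.pair_members[:, 1]] = self.b_values[:, 1]
        return out

    def form_groups(self, params: SimParams, rng: np.random.Generator) -> None:
        """Assign all individuals to pairs and compute both b's per pair."""
        pairs = match_pairs(self.sire_ids, rng, policy=params.grouping)
        eff = self.effects
        i, j = pairs[:, 0], pairs[:, 1]
        b_ij = params.b_bar + eff.A_D[i] + eff.E_D[i] + eff.A_I[j] + eff.E_I[j]
        b_ji = params.b_bar + eff.A_D[j] + eff.E_D[j] + eff.A_I[i] + eff.E_I[i]
        self.pair_members = pairs
        self.b_values = np.column_stack([b_ij, b_ji])

    def individual(self, row: int) -> Individual:
        """Materialize one individual as a scalar object."""
        eff = EffectSet(**{k: float(getattr(self.effects, k)[row]) for k in _EFFECT_NAMES})
        return Individual(
            id=int(self.ids[row]),
            effects=eff,
            sire_id=int(self.sire_ids[row]),
            dam_id=int(self.dam_ids[row]),
            sex=int(self.sex[row]),
            weights=[float(w) for w in self.weights[row]],
        )

    def groups(self) -> Iterator[Group]:
        """Materialize the pairing as scalar Group objects (small cohorts)."""
        self._require_groups()
        for (i, j), (b_ij, b_ji) in zip(self.pair_members, self.b_values):
            yield Group(self.individual(i), self.individual(j), float(b_ij), float(b_ji))

    # ----- tabular output -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per individual per stored time point."""
        self._require_groups()
        n, t = self.weights.shape
        base = pd.DataFrame({
            "generation": self.generation,
            "id": np.repeat(self.ids, t),
            "sire": np.repeat(self.sire_ids, t),
            "dam": np.repeat(self.dam_ids, t),
            "group": np.repeat(self.group_index, t),
            "time_point": np.tile(np.arange(t), n),
            "weight": self.weights.ravel(),
        })
        for name in _EFFECT_NAMES:
            base[name] = np.repeat(getattr(self.effects, name), t)
        base["b_value"] = np.repeat(self.b_own, t)
        return base

    def write_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def pedigree_frame(self) -> pd.DataFrame:
        """3-column pedigree (id, sire, dam); 0 marks an unknown parent."""
        return pd.DataFrame({"id": self.ids, "sire": self.sire_ids, "dam": self.dam_ids})

    def write_pedigree(self, path) -> None:
        self.pedigree_frame().to_csv(path, sep="\t", index=False)


# ----- matching -----------------------------------------------------------


def match_pairs(
    sire_ids: np.ndarray | Sequence[int],
    rng: np.random.Generator,
    policy: str = "random",
    max_tries: int = 1000,
) -> np.ndarray:
    """Uniform random perfect matching of indices 0..n-1 into (n/2, 2) pairs.

    Policy "non-sib" forbids pairs sharing a sire; infeasible pairs are
    repaired by re-shuffling the offending individuals together with an
    equal number of randomly chosen compliant pairs, which preserves
    uniformity among compliant matchings to very good approximation.
    """
    sire_ids = np.asarray(sire_ids)
    n = len(sire_ids)
    if n % 2:
        raise MatchingError(f"cannot pair an odd number of individuals ({n})")
    pairs = rng.permutation(n).reshape(-1, 2)
    if policy == "random":
        return pairs
    if policy != "non-sib":
        raise ConfigError(f"unknown grouping policy {policy!r}")
    for _ in range(max_tries):
        bad = sire_ids[pairs[:, 0]] == sire_ids[pairs[:, 1]]
        n_bad = int(bad.sum())
        if n_bad == 0:
            return pairs
        good_rows = np.flatnonzero(~bad)
        k = min(len(good_rows), n_bad)
        extra = rng.choice(good_rows, size=k, replace=False) if k else np.array([], dtype=int)
        rows = np.concatenate([np.flatnonzero(bad), extra])
        pool = pairs[rows].ravel()
        pairs[rows] = rng.permutation(pool).reshape(-1, 2)
    raise MatchingError(f"no sib-free matching found in {max_tries} repair rounds")


def assign_groups(
    individuals: Sequence[Individual],
    rng: np.random.Generator,
    policy: str = "random",
    b_bar: float = 0.0,
) -> list[Group]:
    """Pair scalar individuals under the given policy and compute their b's."""
    sires = np.asarray([ind.sire_id for ind in individuals])
    pairs = match_pairs(sires, rng, policy=policy)
    return [
        Group.form(individuals[i], individuals[j], b_bar) for i, j in pairs
    ]


# ----- reproduction -------------------------------------------------------


def _mendelian(mid: np.ndarray, base_var: float, rng: np.random.Generator) -> np.ndarray:
    """Offspring breeding values: parental midpoint + N(0, base_var / 2)."""
    return mid + rng.normal(0.0, np.sqrt(base_var / 2.0), size=np.shape(mid))


def make_offspring(
    sire: Individual, dam: Individual, params: SimParams, rng: np.random.Generator
) -> Individual:
    """One offspring of two scalar parents (no initial weight assigned)."""
    var = _effect_variances(params)
    values: dict[str, float] = {}
    for name in _GENETIC:
        mid = 0.5 * (getattr(sire.effects, name) + getattr(dam.effects, name))
        values[name] = float(_mendelian(np.asarray(mid), var[name], rng))
    for name in _ENVIRONMENTAL:
        values[name] = float(rng.normal(0.0, np.sqrt(var[name])))
    return Individual(id=0, effects=EffectSet(**values), sire_id=sire.id, dam_id=dam.id,
                      sex=int(rng.integers(2)))


def _offspring_cohort(
    generation: int,
    sire_rows: np.ndarray,
    dam_rows: np.ndarray,
    sire_panel: ParentPanel,
    dam_panel: ParentPanel,
    params: SimParams,
    rng: np.random.Generator,
    id_start: int,
) -> Cohort:
    """Vectorized offspring generation given per-offspring parent rows."""
    n = len(sire_rows)
    var = _effect_variances(params)
    values: dict[str, np.ndarray] = {}
    for name in _EFFECT_NAMES:  # fixed draw order
        if name in _GENETIC:
            mid = 0.5 * (
                getattr(sire_panel.effects, name)[sire_rows]
                + getattr(dam_panel.effects, name)[dam_rows]
            )
            values[name] = _mendelian(mid, var[name], rng)
        else:
            values[name] = rng.normal(0.0, np.sqrt(var[name]), size=n)
    sex = rng.integers(0, 2, size=n)
    start = rng.normal(params.start_weight_mean, params.start_weight_sd, size=n)
    cohort = Cohort(
        generation=generation,
        ids=np.arange(id_start, id_start + n, dtype=np.int64),
        sire_ids=sire_panel.ids[sire_rows].astype(np.int64),
        dam_ids=dam_panel.ids[dam_rows].astype(np.int64),
        sex=sex,
        effects=EffectSet(**values),
        weights=start[:, None],
        sires=sire_panel,
        dams=dam_panel,
    )
    cohort.form_groups(params, rng)
    return cohort


def sample_base_population(params: SimParams, rng: np.random.Generator) -> Cohort:
    """Unrelated parents -> one offspring generation, paired and ready to grow.

    n_sires sires and n_sires * n_dams_per_sire dams are drawn from the base
    distributions (mutually independent effects); dams are nested within
    sires (hierarchical half-sib design) and each dam produces
    n_offspring_per_dam offspring.  Offspring initial weights are
    Normal(start_weight_mean, start_weight_sd^2).
    """
    n_dams = params.n_sires * params.n_dams_per_sire
    sire_panel = ParentPanel(
        ids=np.arange(1, params.n_sires + 1, dtype=np.int64),
        effects=sample_effects(params, params.n_sires, rng),
    )
    dam_panel = ParentPanel(
        ids=np.arange(params.n_sires + 1, params.n_sires + n_dams + 1, dtype=np.int64),
        effects=sample_effects(params, n_dams, rng),
    )
    dam_rows = np.repeat(np.arange(n_dams), params.n_offspring_per_dam)
    sire_rows = dam_rows // params.n_dams_per_sire
    return _offspring_cohort(
        generation=0,
        sire_rows=sire_rows,
        dam_rows=dam_rows,
        sire_panel=sire_panel,
        dam_panel=dam_panel,
        params=params,
        rng=rng,
        id_start=params.n_sires + n_dams + 1,
    )


# ----- growth -------------------------------------------------------------


def simulate_cohort(cohort: Cohort, params: SimParams, rng: np.random.Generator) -> Cohort:
    """Grow every pair for n_time_points synchronous increments (in place).

    Vectorized form of the per-group update: at each step all individuals
    receive mu + A_GR + E_p + E_t + b_own * (partner - own weight), with the
    interaction term evaluated at the previous time point for everyone and
    one fresh vector of temporary effects per step.
    """
    cohort._require_groups()
    if cohort.weights.shape[1] != 1:
        raise StateError("cohort already simulated")
    n, T = cohort.n, params.n_time_points
    partner = cohort.partner_index
    b_own = cohort.b_own
    fixed = params.mu_GR + cohort.effects.A_GR + cohort.effects.E_p_GR
    sd_t = np.sqrt(params.var_Et_GR)
    w = np.empty((n, T + 1), dtype=float)
    w[:, 0] = cohort.weights[:, 0]
    for t in range(1, T + 1):
        prev = w[:, t - 1]
        e_t = rng.normal(0.0, sd_t, size=n)
        w[:, t] = prev + fixed + e_t + b_own * (prev[partner] - prev)
    if (w < 0).any():
        log.warning(
            "negative body weights in generation %d (%d records); "
            "no floor is imposed under absolute growth",
            cohort.generation, int((w < 0).sum()),
        )
    cohort.weights = w
    return cohort
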