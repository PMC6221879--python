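"""Core model: a heritable interaction coefficient coupling paired growth curves.

The target trait is growth rate of body weight between consecutive time
points.  For a focal individual *i* paired with group mate *j*, the growth
increment is

    P[t,i] - P[t-1,i] = mu_GR + A_GR,i + E_p,i + E_t,i
                        + b_ij * (P[t-1,j] - P[t-1,i])

where ``b_ij`` is the interaction coefficient acting on *i*: negative values
mean competition (the heavier mate suppresses the focal's growth), positive
values cooperation ("helping the one who lags behind").  ``b_ij`` is itself a
quantitative trait composed of a direct contribution of the focal individual
(resistance to competition) and an indirect contribution of its partner
(cooperativeness):

    b_ij = b_bar + A_D,i + E_D,i + A_I,j + E_I,j

``b`` is non-symmetric: b_ij != b_ji in general, because the direct effects
of *i* and the indirect effects of *j* enter b_ij while b_ji takes the
complementary set.

This module houses the two equations as exact pure functions, the scalar
per-group data types (:class:`EffectSet`, :class:`Individual`,
:class:`Group`), the deterministic-plus-noise per-time-point update for one
pair, and the parameter set :class:`SimParams` whose defaults are the
standard simulation conditions (five scenarios differing only in ``b_bar``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidParameterError, StateError

__all__ = [
    "SCENARIO_B_BARS",
    "SimParams",
    "scenario_params",
    "EffectSet",
    "Individual",
    "Group",
    "compute_b",
    "growth_increment",
    "advance_time_point",
    "simulate_group_trajectory",
]

#: Population-average interaction coefficient of the five standard scenarios:
#: 1 strong competition ... 3 neutral ... 5 strong cooperation.
SCENARIO_B_BARS: tuple[float, ...] = (-0.08, -0.05, 0.0, 0.05, 0.08)


@dataclass(frozen=True)
class SimParams:
    """All simulation parameters.

    Defaults are the standard conditions: mean growth 10 g per step, growth
    variances (1, 0.4, 0.6) g^2 summing to a phenotypic growth variance of
    2 g^2, and 0.225e-3 for each of the four variance components of ``b``.
    The five scenarios differ only in ``b_bar``.

    Structural choices (population/family design, number of time points)
    default to a hierarchical half-sib design of 100 sires x 10 dams x 10
    offspring = 10000 individuals = 5000 pairs grown for 10 increments,
    sized so the sire-level variability correlations stabilize across
    replicates (100 paternal half-sib offspring per sire).
    """

    mu_GR: float = 10.0            # mean growth rate per time step (g)
    var_A_GR: float = 1.0          # additive genetic variance of growth rate (g^2)
    var_Ep_GR: float = 0.4         # permanent environmental variance (g^2)
    var_Et_GR: float = 0.6         # temporary environmental variance (g^2)
    b_bar: float = 0.0             # population-average interaction coefficient (1/g)
    var_AD: float = 0.225e-3       # direct genetic variance of b
    var_AI: float = 0.225e-3       # indirect genetic variance of b
    var_ED: float = 0.225e-3       # direct environmental variance of b
    var_EI: float = 0.225e-3       # indirect environmental variance of b
    start_weight_mean: float = 10.0           # mean weight at time 0 (g)
    start_weight_sd: float = math.sqrt(2.0)   # sd of weight at time 0 (g)
    n_groups: int = 5000           # number of 2-member groups
    n_time_points: int = 10        # growth increments after the initial weight
    n_replicates: int = 100
    seed: int | None = None
    n_sires: int = 100
    n_dams_per_sire: int = 10
    n_offspring_per_dam: int = 10
    grouping: str = "non-sib"      # "random" | "non-sib"

    def __post_init__(self) -> None:
        for name in (
            "var_A_GR", "var_Ep_GR", "var_Et_GR",
            "var_AD", "var_AI", "var_ED", "var_EI",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("mu_GR", "b_bar", "start_weight_mean", "start_weight_sd"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.start_weight_sd < 0:
            raise InvalidParameterError("start_weight_sd must be >= 0")
        if self.n_groups < 1:
            raise InvalidParameterError("n_groups must be >= 1")
        if self.n_time_points < 1:
            raise InvalidParameterError("n_time_points must be >= 1")
        if min(self.n_sires, self.n_dams_per_sire, self.n_offspring_per_dam) < 1:
            raise InvalidParameterError("family design counts must be >= 1")
        if self.grouping not in ("random", "non-sib"):
            raise ConfigError(f"unknown grouping policy {self.grouping!r}")
        if self.n_offspring != 2 * self.n_groups:
            raise ConfigError(
                "family design produces "
                f"{self.n_offspring} offspring but 2 * n_groups = {2 * self.n_groups}"
            )

    @property
    def n_offspring(self) -> int:
        return self.n_sires * self.n_dams_per_sire * self.n_offspring_per_dam

    @property
    def var_P_GR(self) -> float:
        """Phenotypic variance of growth rate excluding b (sum of the three)."""
        return self.var_A_GR + self.var_Ep_GR + self.var_Et_GR

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def scenario_params(scenario: int, **overrides) -> SimParams:
    """Parameters of one of the five standard scenarios (1..5).

    Scenario 1 is strong competition (b_bar = -0.08), 3 neutral, 5 strong
    cooperation (+0.08).  Keyword overrides replace any field.
    """
    if not 1 <= scenario <= len(SCENARIO_B_BARS):
        raise ConfigError(f"scenario must be in 1..{len(SCENARIO_B_BARS)}, got {scenario}")
    return SimParams(b_bar=SCENARIO_B_BARS[scenario - 1], **overrides)


@dataclass(frozen=True)
class EffectSet:
    """The six lifetime effects of one individual.

    All are drawn once at birth and constant for life; the temporary growth
    effect E_t is *not* stored here because it is redrawn at every time step.
    Fields may be scalars or equal-length numpy arrays (one individual per
    element); all model functions are elementwise.
    """

    A_GR: float = 0.0   # breeding value for growth rate (g)
    E_p_GR: float = 0.0  # permanent environmental effect on growth rate (g)
    A_D: float = 0.0    # direct breeding value for b (resistance to competition)
    E_D: float = 0.0    # direct environmental effect on b
    A_I: float = 0.0    # indirect breeding value for b (cooperativeness)
    E_I: float = 0.0    # indirect environmental effect on b

    def __post_init__(self) -> None:
        for name in ("A_GR", "E_p_GR", "A_D", "E_D", "A_I", "E_I"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InvalidParameterError(f"EffectSet.{name} must be finite")


@dataclass
class Individual:
    """One individual: identity, pedigree links, lifetime effects, trajectory.

    ``weights`` holds P_0..P_T once simulated (length n_time_points + 1).
    ``sire_id``/``dam_id`` are 0 for base individuals with unknown parents.
    """

    id: int
    effects: EffectSet
    sire_id: int = 0
    dam_id: int = 0
    sex: int | None = None  # 0 = male, 1 = female
    weights: list[float] = field(default_factory=list)


@dataclass
class Group:
    """An ordered pair with its two asymmetric interaction coefficients.

    ``b_ij`` acts on member_i, ``b_ji`` on member_j; they are computed once
    when the pair is formed and held constant over the whole trajectory.
    """

    member_i: Individual
    member_j: Individual
    b_ij: float
    b_ji: float

    @classmethod
    def form(cls, member_i: Individual, member_j: Individual, b_bar: float) -> "Group":
        """Pair two individuals, computing both coefficients from their effects."""
        return cls(
            member_i=member_i,
            member_j=member_j,
            b_ij=compute_b(b_bar, member_i.effects, member_j.effects),
            b_ji=compute_b(b_bar, member_j.effects, member_i.effects),
        )


def _require_finite(**values) -> None:
    for name, v in values.items():
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError(f"{name} must be finite, got {v!r}")


def compute_b(b_bar, focal: EffectSet, partner: EffectSet):
    """Interaction coefficient acting on the focal individual.

    b = b_bar + A_D(focal) + E_D(focal) + A_I(partner) + E_I(partner).
    Pure and exact; elementwise over array-valued effect sets.
    """
    _require_finite(b_bar=b_bar)
    return b_bar + focal.A_D + focal.E_D + partner.A_I + partner.E_I


def growth_increment(mu_GR, A_GR, E_p, E_t, b_ij, partner_prev_weight, focal_prev_weight):
    """One growth increment of the focal individual.

    mu + A_GR + E_p + E_t + b_ij * (partner - focal previous weight).
    Pure and exact; elementwise over arrays.
    """
    _require_finite(
        mu_GR=mu_GR, A_GR=A_GR, E_p=E_p, E_t=E_t, b_ij=b_ij,
        partner_prev_weight=partner_prev_weight, focal_prev_weight=focal_prev_weight,
    )
    return mu_GR + A_GR + E_p + E_t + b_ij * (partner_prev_weight - focal_prev_weight)


def advance_time_point(group: Group, params: SimParams, rng: np.random.Generator) -> Group:
    """Append the next weight to both members (synchronous update, in place).

    Both interaction terms use the weights at the *previous* time point, so
    the update order of the two members cannot matter.  Each member gets a
    fresh independent temporary effect ~ Normal(0, var_Et_GR); member_i's
    draw is taken first.
    """
    i, j = group.member_i, group.member_j
    if not i.weights or not j.weights:
        raise StateError("both members need a previous weight; simulate from time 0")
    w_i, w_j = i.weights[-1], j.weights[-1]
    sd = math.sqrt(params.var_Et_GR)
    e_t_i, e_t_j = rng.normal(0.0, sd, size=2)
    i.weights.append(
        w_i + growth_increment(params.mu_GR, i.effects.A_GR, i.effects.E_p_GR,
                               e_t_i, group.b_ij, w_j, w_i)
    )
    j.weights.append(
        w_j + growth_increment(params.mu_GR, j.effects.A_GR, j.effects.E_p_GR,
                               e_t_j, group.b_ji, w_i, w_j)
    )
    return group


def simulate_group_trajectory(
    group: Group, params: SimParams, rng: np.random.Generator
) -> Group:
    """Grow one pair for n_time_points increments (weights P_0..P_T)."""
    if not group.member_i.weights or not group.member_j.weights:
        raise StateError("members need initial weights at time 0")
    for _ in range(params.n_time_points):
        advance_time_point(group, params, rng)
    return group


def trajectory_array(group: Group) -> np.ndarray:
    """(2, T+1) array of the pair's weights (member_i row first)."""
    return np.asarray([group.member_i.weights, group.member_j.weights], dtype=float)
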