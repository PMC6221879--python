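"""Closed-form law of the within-pair weight difference.

Conditional on the pair's two interaction coefficients, the difference
d_t = P_{t,i} - P_{t,j} follows the linear recursion

    d_t = c * d_{t-1} + delta_perm + delta_temp_t,      c = 1 - b_ij - b_ji,

because the two synchronous growth increments subtract to
-(b_ij + b_ji) * d_{t-1} plus the difference of the members' growth effects.
``delta_perm`` is the (constant) difference of permanent per-step effects,
A_GR + E_p, with variance 2*(1-r)*var_A_GR + 2*var_Ep_GR for mates of
genetic relatedness r; ``delta_temp_t`` is the per-step difference of
temporary effects with variance 2*var_Et_GR.  Unrolling,

    d_T = c^T d_0 + sum_{k=0}^{T-1} c^k (delta_perm + delta_temp_{T-k}),

so the conditional expectation is c^T * d_0 and the conditional variance is

    (sum_{k<T} c^k)^2 * permVar + (sum_{k<T} c^{2k}) * tempVar + c^{2T} * Var(d_0).

Competition (b_ij + b_ji < 0, c > 1) amplifies the difference; cooperation
(c < 1) shrinks it.  This module is the independent oracle against which the
Monte-Carlo simulator is tested; it deliberately shares no code with it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .model_core import SimParams

__all__ = [
    "PairDifferenceLaw",
    "expected_pair_difference",
    "variance_pair_difference",
    "law_from_params",
]


@dataclass(frozen=True)
class PairDifferenceLaw:
    """Conditional law of the pair difference after T steps given (b_ij, b_ji)."""

    c: float            # difference multiplier per step, 1 - b_ij - b_ji
    d0: float = 0.0     # initial difference (g)
    T: int = 0          # number of growth increments
    perm_var: float = 0.0   # variance of the permanent per-step difference (g^2)
    temp_var: float = 0.0   # variance of the temporary per-step difference (g^2)
    d0_var: float = 0.0     # variance of the initial difference (g^2)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.c, self.d0])):
            raise InvalidParameterError("c and d0 must be finite")
        if self.T < 0:
            raise InvalidParameterError("T must be >= 0")
        for name in ("perm_var", "temp_var", "d0_var"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InvalidParameterError(f"{name} must be finite and >= 0")


def law_from_params(
    params: SimParams,
    b_ij: float,
    b_ji: float,
    d0: float = 0.0,
    T: int | None = None,
    relatedness: float = 0.0,
    random_start: bool = False,
) -> PairDifferenceLaw:
    """Build the difference law for a pair under the given parameters.

    ``relatedness`` is the additive genetic relatedness r of the two mates
    (0 unrelated, 0.25 half sibs, 0.5 full sibs); it scales only the genetic
    part of the permanent-difference variance, by 2*(1-r).  With
    ``random_start`` the initial difference is treated as random with
    variance 2*start_weight_sd^2 (d0 then only sets its mean).
    """
    return PairDifferenceLaw(
        c=1.0 - b_ij - b_ji,
        d0=d0,
        T=params.n_time_points if T is None else T,
        perm_var=2.0 * (1.0 - relatedness) * params.var_A_GR + 2.0 * params.var_Ep_GR,
        temp_var=2.0 * params.var_Et_GR,
        d0_var=2.0 * params.start_weight_sd**2 if random_start else 0.0,
    )


def expected_pair_difference(law: PairDifferenceLaw) -> float:
    """E(d_T | b_ij, b_ji) = c^T * d0; zero whenever the initial difference is."""
    return law.c**law.T * law.d0


def _geom(c: float, T: int) -> float:
    # sum_{k=0}^{T-1} c^k, stable at c == 1
    if T == 0:
        return 0.0
    if np.isclose(c, 1.0):
        # second-order expansion around c = 1 keeps float accuracy near 1
        return float(T) if c == 1.0 else (c**T - 1.0) / (c - 1.0)
    return (c**T - 1.0) / (c - 1.0)


def variance_pair_difference(law: PairDifferenceLaw) -> float:
    """V(d_T | b_ij, b_ji); strictly increasing in -(b_ij + b_ji) for T >= 1."""
    c, T = law.c, law.T
    perm_coeff = _geom(c, T) ** 2
    temp_coeff = _geom(c * c, T)
    return (
        perm_coeff * law.perm_var
        + temp_coeff * law.temp_var
        + c ** (2 * T) * law.d0_var
    )
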