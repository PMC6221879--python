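"""Estimating the population-average interaction coefficient from pair data.

With repeated weights on paired individuals, the average level of
competition can be estimated by regressing each individual's growth
increment on the previous-time-point weight difference with its mate:

    y_{t,i} = P_{t+1,i} - P_{t,i} = mu + b * (P_{t,j} - P_{t,i}) + e_{t,i}

fitted by ordinary least squares over all (group, time, focal-role)
records.  The reported standard errors are the conventional OLS ones and
are *naive*: records of the same individual share its permanent effects, so
residuals are dependent.  They are returned flagged as such rather than
corrected.  When the interaction coefficient itself varies between pairs,
the OLS slope is a leverage-weighted average of pair-level coefficients
(pairs with low b sums diverge more and contribute larger covariates), so a
small bias toward more negative values is expected under competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidParameterError, StateError, UndefinedStatisticError
from .population import Cohort

__all__ = ["PairRecord", "build_pair_records", "records_from_table", "estimate_fixed_b",
           "FixedBEstimate"]


@dataclass(frozen=True)
class PairRecord:
    """One focal-role observation: increment y and covariate delta at time t."""

    group: int
    t: int
    focal: int
    y: float      # P_{t+1, focal} - P_{t, focal} (g)
    delta: float  # P_{t, mate} - P_{t, focal} (g)


RECORD_COLUMNS = ("group", "t", "focal", "y", "delta")


def build_pair_records(cohort: Cohort) -> pd.DataFrame:
    """Long table of 2 * n_groups * T records from a simulated cohort.

    Each (group, t) yields two records, one per focal role, whose covariates
    are exact negatives of each other.
    """
    cohort._require_groups()
    T = cohort.n_time_points
    if T < 1:
        raise StateError("cohort has no simulated increments")
    w = cohort.weights
    partner = cohort.partner_index
    n = cohort.n
    t_idx = np.arange(T)
    y = (w[:, 1:] - w[:, :-1]).ravel()                 # (n*T,) focal-major
    delta = (w[partner, :-1] - w[:, :-1]).ravel()
    return pd.DataFrame({
        "group": np.repeat(cohort.group_index, T),
        "t": np.tile(t_idx, n),
        "focal": np.repeat(cohort.ids, T),
        "y": y,
        "delta": delta,
    })


def records_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Pair records from a tidy cohort table (id/group/time_point/weight).

    Accepts the table written by :meth:`igevar.population.Cohort.write_table`
    (extra columns are ignored), so the estimator can run on files.
    """
    required = {"id", "group", "time_point", "weight"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"cohort table lacks columns: {sorted(missing)}")
    wide = table.pivot_table(index=["group", "id"], columns="time_point",
                             values="weight", sort=True)
    if wide.isna().any().any():
        raise StateError("unequal trajectory lengths across individuals")
    records = []
    for group, sub in wide.groupby(level="group", sort=True):
        if len(sub) != 2:
            raise StateError(f"group {group} does not have exactly 2 members")
        ids = sub.index.get_level_values("id").to_numpy()
        w = sub.to_numpy()
        for focal, mate in ((0, 1), (1, 0)):
            y = np.diff(w[focal])
            delta = w[mate, :-1] - w[focal, :-1]
            for t in range(len(y)):
                records.append((group, t, ids[focal], y[t], delta[t]))
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


@dataclass(frozen=True)
class FixedBEstimate:
    """OLS fit of the single fixed-b model."""

    mu_hat: float
    b_hat: float
    se_mu: float
    se_b: float
    n_records: int
    se_kind: str = "naive-ols"  # residual dependence across repeated records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": ["mu", "b"],
            "estimate": [self.mu_hat, self.b_hat],
            "se": [self.se_mu, self.se_b],
            "se_kind": self.se_kind,
            "n_records": self.n_records,
        })


def estimate_fixed_b(records: pd.DataFrame) -> FixedBEstimate:
    """Fit y = mu + b * delta + e by OLS over all pair records."""
    if len(records) < 3:
        raise UndefinedStatisticError("need >= 3 records to fit two parameters")
    delta = np.asarray(records["delta"], dtype=float)
    y = np.asarray(records["y"], dtype=float)
    if np.ptp(delta) == 0:
        raise UndefinedStatisticError("covariate is constant: design is rank deficient")
    fit = sm.OLS(y, sm.add_constant(delta)).fit()
    return FixedBEstimate(
        mu_hat=float(fit.params[0]),
        b_hat=float(fit.params[1]),
        se_mu=float(fit.bse[0]),
        se_b=float(fit.bse[1]),
        n_records=int(fit.nobs),
    )
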