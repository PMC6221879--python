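"""Population-level variability statistics of a simulated cohort.

The headline quantities are the average within-group variance of body
weight at the final time point, the phenotypic variance over the whole
population, and the group-mate correlation

    rho = (sigma2_between - sigma2_within) / (sigma2_between + sigma2_within).

Conventions.  The per-group variance uses the population (ddof = 0)
denominator, so a pair contributes (P_i - P_j)^2 / 4; the between-group
component is the variance of group means.  Under these matched (ddof = 0)
denominators total = between + within is an exact identity, rho equals the
Pearson correlation of randomly ordered group-mate pairs, and for
independent group mates the within-group variance is half the phenotypic
variance — the neutral-scenario benchmark.  ``ddof`` arguments are exposed
where another convention is wanted.

The sire-level correlations quantify inherited variability: per sire, the
variance of his offspring's final weights (VarP_off) and of the weights of
his offspring's group mates (VarP_gm), correlated against the sire's direct
(A_D) and indirect (A_I) breeding value for b.  A negative r(A_D, VarP_off)
means genetically competition-resistant families are more uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, StateError, UndefinedStatisticError
from .model_core import Group
from .population import Cohort

__all__ = [
    "within_group_variance",
    "between_group_variance",
    "phenotypic_variance",
    "groupmate_correlation",
    "SireVariabilityCorrelations",
    "sire_variability_correlations",
    "extract_extreme_groups",
    "ScenarioResult",
]


def _weights_at(cohort: Cohort, time_point: int) -> np.ndarray:
    if not -cohort.weights.shape[1] <= time_point < cohort.weights.shape[1]:
        raise StateError(
            f"time point {time_point} not simulated "
            f"(stored: 0..{cohort.weights.shape[1] - 1})"
        )
    return cohort.weights[:, time_point]


def within_group_variance(cohort: Cohort, time_point: int = -1, ddof: int = 0) -> float:
    """Mean over groups of the variance of the two members' weights.

    With ddof=0 (default) a pair contributes (P_i - P_j)^2 / 4; with ddof=1,
    (P_i - P_j)^2 / 2.
    """
    w = _weights_at(cohort, time_point)
    d = w[cohort.pair_members[:, 0]] - w[cohort.pair_members[:, 1]]
    return float(np.mean(d * d) / (2.0 * (2 - ddof)))


def between_group_variance(cohort: Cohort, time_point: int = -1, ddof: int = 0) -> float:
    """Variance of group means."""
    w = _weights_at(cohort, time_point)
    means = w[cohort.pair_members].mean(axis=1)
    if len(means) <= ddof:
        raise UndefinedStatisticError(f"need more than {ddof} group(s) for ddof={ddof}")
    return float(np.var(means, ddof=ddof))


def phenotypic_variance(cohort: Cohort, time_point: int = -1, ddof: int = 1) -> float:
    """Variance of all individuals' weights at the time point (sample, n-1)."""
    w = _weights_at(cohort, time_point)
    if len(w) < 2:
        raise UndefinedStatisticError("need at least 2 individuals")
    return float(np.var(w, ddof=ddof))


def groupmate_correlation(between_var: float, within_var: float) -> float:
    """rho = (sigma2_b - sigma2_w) / (sigma2_b + sigma2_w).

    Negative under competition (dissimilar mates), positive under
    cooperation, ~0 for independent mates.
    """
    if not np.all(np.isfinite([between_var, within_var])):
        raise InvalidParameterError("variance components must be finite")
    total = between_var + within_var
    if total == 0:
        raise UndefinedStatisticError("rho undefined: both variance components are zero")
    return (between_var - within_var) / total


@dataclass(frozen=True)
class SireVariabilityCorrelations:
    """Pearson correlations of sire breeding values with family variability."""

    r_AD_varoff: float  # sire A_D vs variance of his offspring's weights
    r_AI_vargm: float   # sire A_I vs variance of his offspring's group mates
    r_AI_varoff: float  # cross term: A_I vs own-offspring variance
    r_AD_vargm: float   # cross term: A_D vs group-mate variance

    def as_dict(self) -> dict[str, float]:
        return {
            "r_AD_varoff": self.r_AD_varoff,
            "r_AI_vargm": self.r_AI_vargm,
            "r_AI_varoff": self.r_AI_varoff,
            "r_AD_vargm": self.r_AD_vargm,
        }


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation undefined: a vector is constant")
    return float(np.corrcoef(x, y)[0, 1])


def sire_variability_correlations(
    cohort: Cohort, time_point: int = -1
) -> SireVariabilityCorrelations:
    """Correlate sire breeding values for b with family weight variability.

    Requires the cohort's sire panel and a grouping in which no individual
    is paired with a paternal sib (otherwise own-family and mate-family
    variances are confounded).  Offspring variances use ddof=1 within sire.
    """
    if cohort.sires is None:
        raise StateError("cohort has no sire panel; was it bred from a pedigree?")
    w = _weights_at(cohort, time_point)
    df = pd.DataFrame({
        "sire": cohort.sire_ids,
        "own": w,
        "gm": w[cohort.partner_index],
    })
    counts = df.groupby("sire")["own"].size()
    if (counts < 2).any():
        raise UndefinedStatisticError("every sire needs >= 2 offspring")
    if len(counts) < 3:
        raise UndefinedStatisticError("need >= 3 sires")
    per_sire = df.groupby("sire").agg(
        var_off=("own", "var"), var_gm=("gm", "var")
    )
    panel = pd.DataFrame({
        "A_D": cohort.sires.effects.A_D,
        "A_I": cohort.sires.effects.A_I,
    }, index=cohort.sires.ids)
    merged = per_sire.join(panel, how="inner")
    a_d = merged["A_D"].to_numpy()
    a_i = merged["A_I"].to_numpy()
    var_off = merged["var_off"].to_numpy()
    var_gm = merged["var_gm"].to_numpy()
    return SireVariabilityCorrelations(
        r_AD_varoff=_pearson(a_d, var_off),
        r_AI_vargm=_pearson(a_i, var_gm),
        r_AI_varoff=_pearson(a_i, var_off),
        r_AD_vargm=_pearson(a_d, var_gm),
    )


def extract_extreme_groups(
    cohort: Cohort,
    criterion: str = "lowest-sum-b",
    initial_diff_sd: float | None = 2.0,
    band: float = 0.25,
) -> list[Group]:
    """Pick showcase groups for growth-curve plots.

    Keeps groups whose absolute initial weight difference lies within
    ``band`` standard deviations of ``initial_diff_sd`` standard deviations
    (sd of individual starting weight, estimated from the cohort), then
    ranks by b_ij + b_ji.  Criteria: "lowest-sum-b" / "highest-sum-b"
    return the single most extreme group; "mixed-signs" returns all kept
    groups whose two b values have opposite signs, ordered by |b_ij - b_ji|
    descending.  ``initial_diff_sd=None`` disables the difference filter.
    Returns [] (with a warning) if the filter leaves nothing.
    """
    import logging

    cohort._require_groups()
    if criterion not in ("lowest-sum-b", "highest-sum-b", "mixed-signs"):
        raise InvalidParameterError(f"unknown criterion {criterion!r}")
    w0 = cohort.weights[:, 0]
    d0 = np.abs(w0[cohort.pair_members[:, 0]] - w0[cohort.pair_members[:, 1]])
    keep = np.ones(len(d0), dtype=bool)
    if initial_diff_sd is not None:
        sd = float(np.std(w0, ddof=1))
        keep = np.abs(d0 - initial_diff_sd * sd) <= band * sd
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        logging.getLogger(__name__).warning(
            "no group matches the initial-difference filter (~%s sd)", initial_diff_sd
        )
        return []
    b = cohort.b_values
    if criterion == "mixed-signs":
        mixed = idx[np.sign(b[idx, 0]) * np.sign(b[idx, 1]) < 0]
        order = mixed[np.argsort(-np.abs(b[mixed, 0] - b[mixed, 1]), kind="stable")]
        chosen = order
    else:
        sums = b[idx].sum(axis=1)
        pick = idx[np.argmin(sums)] if criterion == "lowest-sum-b" else idx[np.argmax(sums)]
        chosen = np.asarray([pick])
    out = []
    for g in chosen:
        i, j = cohort.pair_members[g]
        out.append(Group(cohort.individual(i), cohort.individual(j),
                         float(b[g, 0]), float(b[g, 1])))
    return out


@dataclass
class ScenarioResult:
    """Replicate-level and aggregated statistics for one scenario."""

    b_bar: float
    replicates: pd.DataFrame = field(default_factory=pd.DataFrame)

    #: columns of the per-replicate table
    COLUMNS = (
        "replicate", "within_var", "between_var", "phenotypic_var", "rho",
        "cv_percent", "r_AD_varoff", "r_AI_vargm", "r_AI_varoff", "r_AD_vargm",
    )

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean and SD over replicates of every statistic."""
        stats = self.replicates.drop(columns=["replicate"])
        return pd.DataFrame({"mean": stats.mean(), "sd": stats.std(ddof=1)})

    def write(self, path) -> None:
        """Per-replicate rows followed by an aggregate block, tab-delimited."""
        with open(path, "w") as fh:
            fh.write(f"# b_bar = {self.b_bar}\n")
            self.replicates.to_csv(fh, sep="\t", index=False)
            fh.write("# aggregate over replicates\n")
            self.aggregate.to_csv(fh, sep="\t", index_label="statistic")


def replicate_statistics(cohort: Cohort, replicate: int, time_point: int = -1) -> dict:
    """All per-replicate scalar statistics collected by the scenario runner."""
    w = _weights_at(cohort, time_point)
    within = within_group_variance(cohort, time_point)
    between = between_group_variance(cohort, time_point)
    mean_w = float(np.mean(w))
    row = {
        "replicate": replicate,
        "within_var": within,
        "between_var": between,
        "phenotypic_var": phenotypic_variance(cohort, time_point),
        "rho": groupmate_correlation(between, within),
        "cv_percent": 100.0 * float(np.std(w, ddof=1)) / mean_w if mean_w else np.nan,
    }
    row.update(sire_variability_correlations(cohort, time_point).as_dict())
    return row
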