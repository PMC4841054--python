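"""Sex comparison of anthropometric measurements by ANCOVA.

Within each age group, each measurement is compared between sexes with a
linear model ``value ~ sex + height + age``.  The sex effect is reported
as a two-sided p value (partial F test, equivalent to the squared t on
the sex coefficient), as least-squares (covariate-adjusted) means
evaluated at the included subjects' covariate means, and as a modified
Cohen's d whose denominator is the square root of the covariate-adjusted
within-groups mean square rather than the raw pooled SD:

    d = (adj_mean_male - adj_mean_female) / sqrt(MS_within_adjusted)

Positive d means males larger.  Magnitude guideline: |d| < 0.20 very
small, < 0.50 small, <= 0.80 moderate, > 0.80 large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import ADULT_GROUP, AGE_GROUPS, AgeGroup, Cohort
from .distances import MEASUREMENT_NAMES, REGIONS, region_of

__all__ = [
    "AncovaResult",
    "ancova_sex_test",
    "modified_cohens_d",
    "classify_effect_size",
    "ancova_table",
    "regional_mean_effects",
    "growth_attainment",
]


@dataclass
class AncovaResult:
    measurement: str
    age_group: str
    n_male: int
    n_female: int
    adjusted_mean_male: float
    adjusted_mean_female: float
    p_value: float
    ms_within_adjusted: float
    d: float
    magnitude: str


class AncovaEstimationError(ValueError):
    """Raised when the ANCOVA design matrix is rank-deficient."""


def modified_cohens_d(
    adjusted_mean_male: float, adjusted_mean_female: float, ms_within_adjusted: float
) -> float:
    """Covariate-adjusted standardized mean difference (males positive)."""
    diff = adjusted_mean_male - adjusted_mean_female
    if ms_within_adjusted < 0:
        raise ValueError("ms_within_adjusted must be non-negative")
    if ms_within_adjusted == 0:
        if diff == 0:
            return 0.0
        raise ValueError("effect size undefined: zero within-groups mean square "
                         "with nonzero adjusted mean difference")
    return diff / np.sqrt(ms_within_adjusted)


def classify_effect_size(d: float) -> str:
    """Magnitude label for |d|; 'large' requires |d| strictly above 0.80."""
    if not np.isfinite(d):
        raise ValueError(f"effect size must be finite, got {d}")
    magnitude = abs(d)
    if magnitude > 0.80:
        return "large"
    if magnitude >= 0.50:
        return "moderate"
    if magnitude >= 0.20:
        return "small"
    return "very_small"


def ancova_sex_test(
    values: np.ndarray,
    sex: np.ndarray,
    height: np.ndarray,
    age: np.ndarray,
) -> tuple[float, float, float, float, int, int]:
    """Fit ``value ~ sex + height + age`` and summarize the sex term.

    Parameters are aligned 1-d arrays; ``sex`` holds "M"/"F" labels.

    Returns
    -------
    (adj_mean_male, adj_mean_female, p_value, ms_within, n_male, n_female)
    with adjusted means evaluated at the covariate means of the included
    subjects and ms_within the residual mean square on n - 4 df.
    """
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    height = np.asarray(height, dtype=float)
    age = np.asarray(age, dtype=float)
    male = (sex == "M").astype(float)
    n_male = int(male.sum())
    n_female = int(len(male) - male.sum())
    if n_male < 2 or n_female < 2:
        raise AncovaEstimationError(
            f"need >= 2 subjects per sex, got {n_male} male / {n_female} female"
        )
    design = np.column_stack([np.ones_like(values), male, height, age])
    if np.linalg.matrix_rank(design) < 4:
        deficiency = []
        if np.ptp(height) == 0:
            deficiency.append("height is constant")
        if np.ptp(age) == 0:
            deficiency.append("age is constant")
        if not deficiency:
            deficiency.append("sex exactly confounded with a covariate")
        raise AncovaEstimationError(
            "rank-deficient ANCOVA design: " + "; ".join(deficiency)
        )
    fit = sm.OLS(values, design).fit()
    beta = fit.params
    h_bar, a_bar = height.mean(), age.mean()
    adj_mean_female = float(beta[0] + beta[2] * h_bar + beta[3] * a_bar)
    adj_mean_male = float(adj_mean_female + beta[1])
    p_value = float(fit.pvalues[1])
    ms_within = float(fit.mse_resid)
    return adj_mean_male, adj_mean_female, p_value, ms_within, n_male, n_female


def _result_for(
    measurement: str, group: AgeGroup, values, sex, height, age
) -> AncovaResult:
    m_male, m_female, p, ms, n_m, n_f = ancova_sex_test(values, sex, height, age)
    d = modified_cohens_d(m_male, m_female, ms)
    return AncovaResult(
        measurement=measurement,
        age_group=group.label,
        n_male=n_m,
        n_female=n_f,
        adjusted_mean_male=m_male,
        adjusted_mean_female=m_female,
        p_value=p,
        ms_within_adjusted=ms,
        d=float(d),
        magnitude=classify_effect_size(float(d)),
    )


def ancova_table(
    measurements: pd.DataFrame,
    cohort: Cohort,
    groups: list[AgeGroup] | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """All (measurement, age group) ANCOVA comparisons as one long table.

    Subjects missing a given measurement are dropped from that cell only
    (pairwise deletion).  Cells that cannot be fit (too few subjects of a
    sex) are reported with a ``skipped`` reason instead of numbers.  With
    ``fdr=True`` an extra column of Benjamini-Hochberg adjusted p values
    is appended (raw p values are always reported).
    """
    groups = list(groups) if groups is not None else list(AGE_GROUPS)
    meta = pd.DataFrame(
        {
            "sex": [s.sex for s in cohort.subjects],
            "height": [s.height for s in cohort.subjects],
            "age": [s.age for s in cohort.subjects],
            "group": [s.age_group.label for s in cohort.subjects],
        },
        index=pd.Index(cohort.subject_ids, name="subject_id"),
    )
    rows = []
    for group in groups:
        in_group = meta.index[meta["group"] == group.label]
        for name in MEASUREMENT_NAMES:
            values = measurements.loc[measurements.index.intersection(in_group), name]
            values = values.dropna()
            sub = meta.loc[values.index]
            base = {"measurement": name, "region": region_of(name),
                    "age_group": group.label}
            try:
                res = _result_for(name, group, values.to_numpy(), sub["sex"].to_numpy(),
                                  sub["height"].to_numpy(), sub["age"].to_numpy())
            except AncovaEstimationError as exc:
                rows.append({**base, "skipped": str(exc)})
                continue
            rows.append({
                **base,
                "n_male": res.n_male, "n_female": res.n_female,
                "adjusted_mean_male": res.adjusted_mean_male,
                "adjusted_mean_female": res.adjusted_mean_female,
                "p_value": res.p_value,
                "ms_within_adjusted": res.ms_within_adjusted,
                "d": res.d, "magnitude": res.magnitude,
                "skipped": "",
            })
    table = pd.DataFrame(rows)
    if fdr and "p_value" in table:
        from statsmodels.stats.multitest import multipletests

        mask = table["p_value"].notna()
        adjusted = np.full(len(table), np.nan)
        if mask.any():
            adjusted[mask.to_numpy()] = multipletests(
                table.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        table["p_value_fdr"] = adjusted
    return table


def regional_mean_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of signed d per (age group, region).

    Regions with no estimable measurement in a group are absent (NaN),
    never imputed as zero.
    """
    fitted = table.dropna(subset=["d"]) if "d" in table else table.iloc[0:0]
    if fitted.duplicated(subset=["measurement", "age_group"]).any():
        raise ValueError("duplicate (measurement, age_group) rows")
    wide = (
        fitted.groupby(["age_group", "region"])["d"].mean().unstack("region")
    )
    order = [g.label for g in AGE_GROUPS if g.label in wide.index]
    return wide.reindex(index=order, columns=[r for r in REGIONS if r in wide.columns])


def growth_attainment(measurements: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Percent of same-sex adult (22-25y) size attained, by region.

    Per measurement: 100 * (group mean / same-sex adult-group mean);
    region value = unweighted mean over the region's measurements.
    Indexed by (sex, age_group) with one column per region.
    """
    meta = pd.DataFrame(
        {
            "sex": [s.sex for s in cohort.subjects],
            "group": [s.age_group.label for s in cohort.subjects],
        },
        index=pd.Index(cohort.subject_ids, name="subject_id"),
    )
    data = measurements.join(meta, how="inner")
    adult = data[data["group"] == ADULT_GROUP.label]
    if adult.empty or adult["sex"].nunique() < 2:
        raise ValueError("adult reference group must contain both sexes")
    adult_means = adult.groupby("sex")[list(MEASUREMENT_NAMES)].mean()
    if (adult_means <= 0).any().any() or adult_means.isna().any().any():
        bad = adult_means.columns[(adult_means <= 0).any() | adult_means.isna().any()]
        raise ValueError(f"non-positive or missing adult mean for {list(bad)}")
    group_means = data.groupby(["sex", "group"])[list(MEASUREMENT_NAMES)].mean()
    pct = 100.0 * group_means / adult_means.reindex(
        group_means.index.get_level_values("sex")
    ).to_numpy()
    region_map = {name: region_of(name) for name in MEASUREMENT_NAMES}
    regional = pct.T.groupby(region_map).mean().T
    order = [
        (sex, g.label)
        for sex in ("M", "F")
        for g in AGE_GROUPS
        if (sex, g.label) in regional.index
    ]
    regional = regional.reindex(order)
    regional.index.names = ["sex", "age_group"]
    return regional[[r for r in REGIONS if r in regional.columns]]
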