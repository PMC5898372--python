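"""Classical association statistics for genotype-response tables.

Genetic-model encodings (dominant, recessive, over-dominant, additive),
2x2 contingency machinery (odds ratios with Woolf confidence intervals,
Fisher's exact test, Pearson chi-square), Bonferroni correction, and
normality-gated group comparisons of continuous covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiscreteCohort, RESPONDER, NON_RESPONDER

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "GENETIC_MODELS",
    "encode_model",
    "odds_ratio_ci",
    "fisher_exact",
    "chi_square_2x2",
    "bonferroni",
    "compare_groups",
    "association_scan",
]

GENETIC_MODELS = ("dominant", "recessive", "over-dominant", "additive")

Z_95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table: rows = exposure groups, columns = (Res, NonRes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def swapped_rows(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass
class AssociationResult:
    """One genetic-model test: OR with CI, raw and corrected p-values."""

    variable: str
    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected_p: float
    test: str
    zero_cell_adjusted: bool = False
    degenerate: bool = False


def encode_model(
    column: pd.Series, var_schema, model: str
) -> pd.Series:
    """Collapse a genotype column under a genetic contrast model.

    dominant: het + hom-alt vs hom-ref; recessive: hom-alt vs rest;
    over-dominant: het vs both homozygote classes; additive: variant-allele
    dosage 0/1/2.  Missing cells stay missing (``None``).
    """
    if model not in GENETIC_MODELS:
        raise ValueError(f"unknown genetic model {model!r}")
    hom_ref, het, hom_alt = (
        s for s in var_schema.states if s != var_schema.missing_label
    )
    if model == "dominant":
        mapping = {hom_ref: hom_ref, het: f"{het}+{hom_alt}", hom_alt: f"{het}+{hom_alt}"}
    elif model == "recessive":
        mapping = {hom_ref: f"{hom_ref}+{het}", het: f"{hom_ref}+{het}", hom_alt: hom_alt}
    elif model == "over-dominant":
        mapping = {hom_ref: f"{hom_ref}+{hom_alt}", het: het, hom_alt: f"{hom_ref}+{hom_alt}"}
    else:  # additive dosage
        mapping = {hom_ref: 0, het: 1, hom_alt: 2}
    out = column.map(mapping)
    return out  # unmapped (missing) labels become NaN/None


def odds_ratio_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[float, float, float, bool]:
    """Odds ratio ad/bc with the Woolf log-normal confidence interval.

    Zero cells trigger the Haldane-Anscombe adjustment (0.5 added to every
    cell) for both the OR and its CI; the returned flag records this.
    Returns ``(or, ci_low, ci_high, adjusted)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("odds ratio undefined: table has an all-zero margin")
    adjusted = 0 in (a, b, c, d)
    if adjusted:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = float(stats.norm.ppf(0.5 + level / 2))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = np.log(or_)
    return (
        float(or_),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        adjusted,
    )


def fisher_exact(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (hypergeometric probability ordering)."""
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_2x2(
    table: ContingencyTable2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on a 2x2 table; Yates correction optional."""
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        raise ValueError("chi-square undefined: table has an all-zero margin")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m * p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value out of range: {p}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return min(1.0, m * p)


def compare_groups(
    values, groups, normality_alpha: float = 0.05
) -> tuple[float, str]:
    """Compare a continuous covariate across groups with a normality gate.

    Shapiro-Wilk per group at ``normality_alpha`` selects the branch: if all
    groups look normal, Student's t (2 groups) or one-way ANOVA (>2); else
    Mann-Whitney U or Kruskal-Wallis H.  Returns ``(p, method)``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    samples = [values[groups == g] for g in labels]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2:
        raise ValueError("compare_groups requires at least two groups")
    for s in samples:
        if len(s) < 2:
            raise ValueError("every group must have at least two observations")
    normal = all(
        # Shapiro requires n>=3 and non-constant data; treat tiny or constant
        # groups as non-normal only when genuinely untestable
        (len(s) >= 3 and np.ptp(s) > 0 and stats.shapiro(s)[1] > normality_alpha)
        or (np.ptp(s) == 0)
        for s in samples
    )
    if len(samples) == 2:
        if normal:
            p = stats.ttest_ind(*samples, equal_var=True)[1]
            method = "t-test"
        else:
            p = stats.mannwhitneyu(*samples, alternative="two-sided")[1]
            method = "mann-whitney"
    else:
        if normal:
            p = stats.f_oneway(*samples)[1]
            method = "anova"
        else:
            p = stats.kruskal(*samples)[1]
            method = "kruskal-wallis"
    return float(p), method


# -- cohort-level scan -----------------------------------------------------


def _two_level_table(encoded: pd.Series, response: pd.Series) -> ContingencyTable2x2 | None:
    """Build the 2x2 (exposure x Res/NonRes) table from encoded labels."""
    mask = encoded.notna() & response.isin([RESPONDER, NON_RESPONDER])
    enc = encoded[mask]
    resp = response[mask]
    levels = sorted(enc.unique())
    if len(levels) != 2:
        return None
    g0, g1 = levels
    return ContingencyTable2x2(
        int(((enc == g1) & (resp == RESPONDER)).sum()),
        int(((enc == g1) & (resp == NON_RESPONDER)).sum()),
        int(((enc == g0) & (resp == RESPONDER)).sum()),
        int(((enc == g0) & (resp == NON_RESPONDER)).sum()),
    )


def association_scan(
    cohort: DiscreteCohort,
    models: tuple[str, ...] = GENETIC_MODELS,
    bonferroni_m: int | None = None,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Test every genotype column under each genetic model against response.

    Two-level models yield an OR with 95% CI and a p-value from Pearson
    chi-square (or Fisher's exact test when any expected cell count falls
    below ``min_expected``).  The additive model uses the Cochran-Armitage
    dosage trend (chi-square on the score regression).  Bonferroni ``m``
    defaults to the number of tests actually run.
    """
    resp_name = cohort.response_variable.name
    response = cohort.data[resp_name]
    results: list[dict] = []
    for var in cohort.variables_of_kind("genotype"):
        col = cohort.data[var.name]
        for model in models:
            encoded = encode_model(col, var, model)
            if model == "additive":
                rec = _additive_trend(var.name, encoded, response)
            else:
                rec = _two_level_test(var.name, model, encoded, response, min_expected)
            results.append(rec)
    df = pd.DataFrame(results)
    m = bonferroni_m if bonferroni_m is not None else int(df["p_value"].notna().sum())
    m = max(m, 1)
    df["corrected_p"] = [
        bonferroni(p, m) if np.isfinite(p) else np.nan for p in df["p_value"]
    ]
    df.attrs["bonferroni_m"] = m
    return df


def _two_level_test(
    name: str, model: str, encoded: pd.Series, response: pd.Series, min_expected: float
) -> dict:
    base = {
        "variable": name, "model": model, "odds_ratio": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
        "test": "none", "zero_cell_adjusted": False, "degenerate": False,
    }
    table = _two_level_table(encoded, response)
    if table is None:
        base["degenerate"] = True
        return base
    arr = table.as_array()
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if (expected < min_expected).any():
        p = fisher_exact(table)
        test = "fisher"
    else:
        _, p = chi_square_2x2(table)
        test = "chi2"
    try:
        or_, lo, hi, adj = odds_ratio_ci(table)
    except ValueError:
        or_, lo, hi, adj = np.nan, np.nan, np.nan, False
    base.update(
        odds_ratio=or_, ci_low=lo, ci_high=hi, p_value=p, test=test,
        zero_cell_adjusted=adj,
    )
    return base


def _additive_trend(name: str, dosage: pd.Series, response: pd.Series) -> dict:
    """Cochran-Armitage trend test on allele dosage (0/1/2)."""
    mask = dosage.notna()
    x = dosage[mask].astype(float).to_numpy()
    y = (response[mask] == RESPONDER).to_numpy(dtype=float)
    base = {
        "variable": name, "model": "additive", "odds_ratio": np.nan,
        "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
        "test": "trend", "zero_cell_adjusted": False, "degenerate": False,
    }
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        base["degenerate"] = True
        return base
    n = len(x)
    # score test: z^2 = n * corr(x, y)^2 ~ chi2(1)
    r = np.corrcoef(x, y)[0, 1]
    chi2 = n * r * r
    base["p_value"] = float(stats.chi2.sf(chi2, df=1))
    return base
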