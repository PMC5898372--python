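"""Genotype quality control: call rate, Hardy-Weinberg equilibrium, MAF.

A SNP column enters association analysis only if it passes all three tests:
call rate > 0.90, HWE chi-square p-value > 0.05, and minor allele frequency
> 0.01.  All thresholds are strict inequalities.  Missing cells count against
the call rate but are excluded from the HWE and MAF computations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DiscreteCohort

__all__ = [
    "GenotypeCounts",
    "QCThresholds",
    "QCReport",
    "call_rate",
    "hwe_test",
    "hwe_exact_test",
    "maf",
    "apply_qc",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one biallelic SNP column."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for f in (self.n_hom_ref, self.n_het, self.n_hom_alt, self.n_missing):
            if f < 0:
                raise ValueError("genotype counts must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing

    @classmethod
    def from_column(cls, cohort: DiscreteCohort, name: str) -> "GenotypeCounts":
        var = cohort.variable(name)
        if var.kind != "genotype":
            raise ValueError(f"{name!r} is not a genotype variable")
        col = cohort.data[name]
        hom_ref, het, hom_alt = (
            s for s in var.states if s != var.missing_label
        )
        return cls(
            int((col == hom_ref).sum()),
            int((col == het).sum()),
            int((col == hom_alt).sum()),
            int((col == var.missing_label).sum()) if var.missing_label else 0,
        )


@dataclass(frozen=True)
class QCThresholds:
    """Strict lower bounds for the three inclusion tests."""

    min_call_rate: float = 0.90
    min_hwe_p: float = 0.05
    min_maf: float = 0.01


def call_rate(counts: GenotypeCounts) -> float:
    """Fraction of records with a genotype call."""
    if counts.n_total < 1:
        raise ValueError("call_rate requires at least one record")
    return counts.n_typed / counts.n_total


def _allele_freq(counts: GenotypeCounts) -> float:
    """Maximum-likelihood reference-allele frequency from typed calls."""
    if counts.n_typed < 1:
        raise ValueError("no typed calls")
    return (2 * counts.n_hom_ref + counts.n_het) / (2 * counts.n_typed)


def hwe_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Hardy-Weinberg goodness-of-fit chi-square test.

    Expected genotype counts are computed from the maximum-likelihood allele
    frequency; the statistic is compared against chi-square with one degree
    of freedom (three classes minus one estimated allele frequency minus one).
    Returns ``(chi2, p)``.  If only one allele is observed the test is
    undefined and ``(0.0, 1.0)`` is returned.
    """
    n = counts.n_typed
    if n < 1:
        raise ValueError("hwe_test requires at least one typed call")
    p = _allele_freq(counts)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([counts.n_hom_ref, counts.n_het, counts.n_hom_alt], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_test(counts: GenotypeCounts) -> float:
    """Exact conditional HWE test (two-sided, by probability ordering).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of outcomes no more likely than the
    observed one.  Useful when expected homozygote counts are small; the
    chi-square version remains the default pass/fail criterion.
    """
    n = counts.n_typed
    if n < 1:
        raise ValueError("exact HWE test requires at least one typed call")
    n_ref = 2 * counts.n_hom_ref + counts.n_het  # reference allele count
    n_alt = 2 * n - n_ref
    rare = min(n_ref, n_alt)
    # heterozygote count has the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each possible het count (conditional
    # on allele counts): n! 2^het / (hom_ref! het! hom_alt!)
    from scipy.special import gammaln

    hom_rare = (rare - hets) // 2
    hom_common = (max(n_ref, n_alt) - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = counts.n_het
    p_obs = probs[hets == obs]
    if len(p_obs) == 0:
        raise ValueError("observed heterozygote count incompatible with alleles")
    return float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())


def maf(counts: GenotypeCounts) -> float:
    """Minor allele frequency, in [0, 0.5]."""
    p = _allele_freq(counts)
    return min(p, 1.0 - p)


def _evaluate(counts: GenotypeCounts, thresholds: QCThresholds) -> dict:
    cr = call_rate(counts)
    chi2, p_hwe = hwe_test(counts)
    f = maf(counts) if counts.n_typed >= 1 else float("nan")
    row = {
        "call_rate": cr,
        "hwe_chi2": chi2,
        "hwe_p": p_hwe,
        "maf": f,
        "pass_call_rate": cr > thresholds.min_call_rate,
        "pass_hwe": p_hwe > thresholds.min_hwe_p,
        "pass_maf": f > thresholds.min_maf,
    }
    row["passed"] = bool(
        row["pass_call_rate"] and row["pass_hwe"] and row["pass_maf"]
    )
    return row


@dataclass
class QCReport:
    """Per-SNP QC metrics, flags, and the surviving SNP list."""

    table: pd.DataFrame  # index = SNP name
    thresholds: QCThresholds

    @property
    def surviving(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="snp")

    def to_json(self, path) -> None:
        payload = {
            "thresholds": asdict(self.thresholds),
            "snps": self.table.reset_index()
            .rename(columns={"index": "snp"})
            .to_dict(orient="records"),
            "surviving": self.surviving,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def apply_qc(
    cohort: DiscreteCohort, thresholds: QCThresholds | None = None
) -> tuple[QCReport, DiscreteCohort]:
    """Run all three tests on every genotype column and drop the failures.

    Returns the per-SNP report and a cohort with failing SNP columns removed
    (all other variables untouched).
    """
    thresholds = thresholds or QCThresholds()
    geno = cohort.variables_of_kind("genotype")
    if not geno:
        raise ValueError("cohort has no genotype columns")
    rows = {}
    for var in geno:
        counts = GenotypeCounts.from_column(cohort, var.name)
        rows[var.name] = _evaluate(counts, thresholds)
    table = pd.DataFrame.from_dict(rows, orient="index")
    report = QCReport(table=table, thresholds=thresholds)
    failed = [name for name in table.index if not table.loc[name, "passed"]]
    return report, cohort.drop_variables(failed)
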