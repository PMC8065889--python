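"""Driver-gene burden statistics and the exact 2x2 test.

Genes carrying somatic variants are split into cancer drivers and
non-drivers by a configurable driver list (IntOGen-style, endometrial and
ovarian cancers). Per compartment the "mutation chance" of a class is the
number of variants in that class divided by the number of panel genes in
the class — a per-gene mutation rate, unnormalised for gene length. Class
enrichment within a compartment tests variant counts against panel class
sizes; the between-compartment comparison tests the two compartments'
class counts against each other. Both use Fisher's exact test with the
minimum-likelihood two-sided rule, computed here by explicit hypergeometric
enumeration in log space.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .io_formats import GenePanel, VariantRecord

__all__ = [
    "BurdenTable",
    "classify_variants",
    "burden_counts",
    "fisher_exact_2x2",
    "class_enrichment_test",
    "compartment_comparison_test",
    "recurrence_summary",
]


@dataclass(frozen=True)
class BurdenTable:
    """Per-compartment variant counts and mutation chances by gene class."""

    compartment: str
    n_driver_variants: int
    n_nondriver_variants: int
    n_driver_genes: int
    n_nondriver_genes: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_driver_variants, self.n_nondriver_variants) < 0:
            raise ValueError("variant counts must be >= 0")
        if min(self.n_driver_genes, self.n_nondriver_genes) <= 0:
            raise ValueError("gene class sizes must be > 0")

    @property
    def chance_driver(self) -> float:
        return self.n_driver_variants / self.n_driver_genes

    @property
    def chance_nondriver(self) -> float:
        return self.n_nondriver_variants / self.n_nondriver_genes


def classify_variants(
    records: Sequence[VariantRecord], driver_set: Iterable[str]
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Partition variants into (driver, non-driver) lists, per variant.

    A gene with two variants contributes two counts to its class. Genes not
    in the driver set — including genes missing from the panel — classify
    non-driver.
    """
    drivers = {g.upper() for g in driver_set}
    driver_records = [r for r in records if r.gene.upper() in drivers]
    nondriver_records = [r for r in records if r.gene.upper() not in drivers]
    return driver_records, nondriver_records


def burden_counts(
    records: Sequence[VariantRecord], panel: GenePanel, compartment: str
) -> BurdenTable:
    """Burden table for one compartment (ECT or EU).

    Only records whose compartment equals ``compartment`` are counted:
    variants present in both tissues belong to neither per-compartment
    burden (the cohort's 24/31 split likewise excludes its 4 shared
    variants).
    """
    if compartment not in {"ECT", "EU"}:
        raise ValueError("burden is computed per single compartment (ECT or EU)")
    selected = [r for r in records if r.compartment == compartment]
    driver_records, nondriver_records = classify_variants(selected, panel.driver_genes)
    return BurdenTable(
        compartment=compartment,
        n_driver_variants=len(driver_records),
        n_nondriver_variants=len(nondriver_records),
        n_driver_genes=panel.n_driver,
        n_nondriver_genes=panel.n_nondriver,
    )


def _log_hypergeom_pmf(k: np.ndarray, M: int, n: int, N: int) -> np.ndarray:
    # P(X=k) for k successes drawn in N draws from M objects with n successes
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + gammaln(M - n + 1)
        - gammaln(N - k + 1)
        - gammaln(M - n - N + k + 1)
        - (gammaln(M + 1) - gammaln(N + 1) - gammaln(M - N + 1))
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]], alternative: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table of non-negative counts.

    Two-sided p-values use the minimum-likelihood rule: with margins fixed,
    sum the hypergeometric probabilities of every table whose point
    probability does not exceed that of the observed table (up to a 1e-7
    relative tolerance for ties). Point probabilities are computed with
    log-gamma factorials, so large tables do not overflow. One-sided
    alternatives ("less"/"greater") sum the corresponding tail of the
    distribution of the top-left cell.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    M = a + b + c + d  # population
    n = a + b  # row-1 margin
    N = a + c  # column-1 margin
    if n == 0 or N == 0 or n == M or N == M:
        raise ValueError("both margins must be strictly positive")
    lo, hi = max(0, N - (M - n)), min(n, N)
    support = np.arange(lo, hi + 1)
    logpmf = _log_hypergeom_pmf(support, M, n, N)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()  # renormalise: support sums to 1 exactly
    observed = pmf[a - lo]
    if alternative == "two-sided":
        p = pmf[pmf <= observed * (1 + 1e-7)].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(p, 1.0))


def class_enrichment_test(bt: BurdenTable, alternative: str = "two-sided") -> BurdenTable:
    """Driver-class enrichment within one compartment.

    Tests the 2x2 table [[driver variants, non-driver variants],
    [driver genes, non-driver genes]].
    """
    p = fisher_exact_2x2(
        [
            [bt.n_driver_variants, bt.n_nondriver_variants],
            [bt.n_driver_genes, bt.n_nondriver_genes],
        ],
        alternative=alternative,
    )
    return replace(bt, p_value=p)


def compartment_comparison_test(
    ect: BurdenTable, eu: BurdenTable, alternative: str = "two-sided"
) -> float:
    """Compare driver vs non-driver variant counts between compartments."""
    if (ect.n_driver_genes, ect.n_nondriver_genes) != (
        eu.n_driver_genes,
        eu.n_nondriver_genes,
    ):
        raise ValueError("burden tables must share one panel")
    return fisher_exact_2x2(
        [
            [ect.n_driver_variants, ect.n_nondriver_variants],
            [eu.n_driver_variants, eu.n_nondriver_variants],
        ],
        alternative=alternative,
    )


def recurrence_summary(
    records: Sequence[VariantRecord],
) -> tuple[dict[str, set[str]], list[tuple[VariantRecord, VariantRecord]]]:
    """Genes mutated in more than one patient, and recurrent variants.

    Returns ``(multi_patient_genes, recurrent_pairs)``: a map from gene
    symbol to its patient set (only genes seen in >=2 patients), and every
    pair of records from different patients sharing an identical
    (locus, alt) — i.e. the same variant recurring across patients.
    """
    patients_by_gene: dict[str, set[str]] = defaultdict(set)
    by_site: dict[tuple, list[VariantRecord]] = defaultdict(list)
    for rec in records:
        patients_by_gene[rec.gene.upper()].add(rec.patient_id)
        by_site[(rec.locus.chrom, rec.locus.pos, rec.locus.alt)].append(rec)
    multi = {g: ps for g, ps in patients_by_gene.items() if len(ps) > 1}
    recurrent: list[tuple[VariantRecord, VariantRecord]] = []
    for recs in by_site.values():
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                if recs[i].patient_id != recs[j].patient_id:
                    recurrent.append((recs[i], recs[j]))
    return multi, recurrent
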