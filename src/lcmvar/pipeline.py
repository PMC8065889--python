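"""End-to-end orchestration: simulate -> call -> verify -> burden.

The headline entry point is :func:`cohort_summary`, which runs the full
downstream analysis on the bundled 59-variant cohort table: compartment
accounting, driver/non-driver burden with exact tests, recurrence, and ADS
verification of the four tissue-shared variants. Every number it reports
is recomputed from the bundled inputs at call time.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import burden as burden_mod
from . import calling, verification
from .io_formats import (
    CallerConfig,
    GenePanel,
    Locus,
    SampleTrio,
    SiteReadCounts,
    VariantRecord,
    load_ads_fixture,
    load_cohort_variants,
    load_panel,
)

__all__ = [
    "gene_at",
    "records_from_calls",
    "cohort_summary",
    "read_trio_manifest",
    "write_trio_manifest",
]


def gene_at(panel: GenePanel, chrom: str, pos: int) -> str | None:
    """Gene whose panel region (0-based half-open) contains a 1-based pos."""
    for e in panel.entries:
        if e.chrom == chrom and e.start < pos <= e.end:
            return e.gene
    return None


def records_from_calls(
    compartments: Mapping[Locus, str],
    counts: Sequence[SiteReadCounts],
    trio: SampleTrio,
    panel: GenePanel,
) -> list[VariantRecord]:
    """Annotate somatic calls into variant records.

    VAF is taken from the tissue replicate with the most alt reads among
    those carrying the variant; gene symbols come from the panel regions
    (calls outside any region get gene ``UNPLACED``).
    """
    best: dict[Locus, SiteReadCounts] = {}
    tissue_ids = set(trio.ectopic_replicates) | set(trio.eutopic_replicates)
    for c in counts:
        if c.sample_id in tissue_ids and c.locus in compartments:
            if c.locus not in best or c.alt_reads > best[c.locus].alt_reads:
                best[c.locus] = c
    records = []
    for locus, compartment in sorted(compartments.items()):
        gene = gene_at(panel, locus.chrom, locus.pos) or "UNPLACED"
        vaf = calling.compute_vaf(best[locus]) if locus in best and best[locus].depth else 0.0
        records.append(
            VariantRecord(
                locus=locus,
                gene=gene,
                consequence="missense",
                vaf=round(vaf, 6),
                compartment=compartment,
                patient_id=trio.patient_id,
            )
        )
    return records


def cohort_summary(config: CallerConfig = CallerConfig()) -> dict:
    """Recompute the cohort's headline numbers from bundled data.

    Returns a dict with variant accounting (total and per-compartment),
    burden tables with exact-test p-values, the between-compartment
    p-value, recurrence results, and the ADS verification outcomes of the
    four variants shared by both tissues.
    """
    records = load_cohort_variants()
    panel = load_panel()

    counts = {"total": len(records)}
    for comp in ("ECT", "EU", "BOTH"):
        counts[comp] = sum(r.compartment == comp for r in records)

    bt_ect = burden_mod.class_enrichment_test(
        burden_mod.burden_counts(records, panel, "ECT")
    )
    bt_eu = burden_mod.class_enrichment_test(
        burden_mod.burden_counts(records, panel, "EU")
    )
    p_between = burden_mod.compartment_comparison_test(bt_ect, bt_eu)

    multi_patient_genes, recurrent_pairs = burden_mod.recurrence_summary(records)

    ads = load_ads_fixture()
    shared = [r for r in records if r.compartment == "BOTH"]
    extra = [
        r
        for r in records
        if (r.patient_id, r.gene) in ads and r.compartment != "BOTH"
    ]
    results = [
        verification.verify_variant(r, ads[(r.patient_id, r.gene)], config)
        for r in shared + extra
    ]
    report = verification.verification_report(results)
    shared_statuses = {
        (r.variant.gene): r.status for r in results if r.variant.compartment == "BOTH"
    }

    return {
        "counts": counts,
        "burden_ect": bt_ect,
        "burden_eu": bt_eu,
        "p_enrichment_ect": bt_ect.p_value,
        "p_enrichment_eu": bt_eu.p_value,
        "p_between_compartments": p_between,
        "multi_patient_genes": set(multi_patient_genes),
        "n_recurrent_variants": len(recurrent_pairs),
        "verification": report,
        "shared_variant_status": shared_statuses,
    }


def read_trio_manifest(path: str | Path) -> list[SampleTrio]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise ValueError(f"{path}: trio manifest must be a list of patients")
    trios = []
    for i, item in enumerate(raw):
        try:
            trios.append(
                SampleTrio(
                    patient_id=str(item["patient_id"]),
                    blood=str(item["blood"]),
                    eutopic_replicates=tuple(item.get("eutopic_replicates", ())),
                    ectopic_replicates=tuple(item.get("ectopic_replicates", ())),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: entry {i}: {exc}") from exc
    return trios


def write_trio_manifest(trios: Sequence[SampleTrio], path: str | Path) -> None:
    raw = [
        {
            "patient_id": t.patient_id,
            "blood": t.blood,
            "eutopic_replicates": list(t.eutopic_replicates),
            "ectopic_replicates": list(t.ectopic_replicates),
        }
        for t in trios
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
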