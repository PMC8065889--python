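"""Rule-based somatic determination for matched tissue/blood read counts.

The caller applies two count-threshold rules rather than a statistical
error model, which is appropriate for WGA/LCM material where allele
fractions are distorted and conventional callers (tuned to bulk-tissue
error profiles) return nothing:

* *presence* — a variant is present in a sample when at least
  ``min_alt_reads`` reads (default 2) carry the alternate allele;
* *absence* — a variant is positively absent from a sample only when
  coverage strictly exceeds ``min_ref_depth_for_absence`` (default 20x)
  and no non-reference base at all is seen there. Anything else is
  *indeterminate*: absence that cannot be established is never treated
  as established.

A variant is **somatic** when present in the tissue and positively absent
from the matched blood; blood indeterminacy yields an ``indeterminate``
call that is surfaced, not dropped.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import replace
from typing import Iterable, Mapping, Sequence

from .io_formats import (
    CallerConfig,
    Locus,
    NONCODING_CONSEQUENCES,
    SILENT_CONSEQUENCES,
    SampleTrio,
    SiteReadCounts,
    VariantRecord,
)

__all__ = [
    "is_present",
    "is_absent",
    "call_somatic",
    "compute_vaf",
    "filter_non_silent",
    "assign_compartments",
    "annotate_population_af",
    "call_trio",
]

SOMATIC = "somatic"
NOT_SOMATIC = "not_somatic"
INDETERMINATE = "indeterminate"
ABSENT = "absent"


def is_present(counts: SiteReadCounts, config: CallerConfig = CallerConfig()) -> bool:
    """Presence rule: at least ``min_alt_reads`` alt-supporting reads."""
    return counts.alt_reads >= config.min_alt_reads


def is_absent(counts: SiteReadCounts, config: CallerConfig = CallerConfig()) -> str:
    """Absence rule; returns ``"absent"`` or ``"indeterminate"``.

    Absent requires depth strictly above ``min_ref_depth_for_absence`` and
    zero non-reference reads (alt or any other allele). The rule never
    returns "present" — presence is a separate decision.
    """
    clean = counts.alt_reads == 0 and counts.other_reads == 0
    covered = counts.depth > config.min_ref_depth_for_absence
    return ABSENT if (clean and covered) else INDETERMINATE


def call_somatic(
    tissue: SiteReadCounts,
    blood: SiteReadCounts,
    config: CallerConfig = CallerConfig(),
) -> str:
    """Somatic status of one site: somatic / not_somatic / indeterminate."""
    if tissue.locus != blood.locus:
        raise ValueError(
            f"locus mismatch: tissue {tissue.locus} vs blood {blood.locus}"
        )
    if not is_present(tissue, config):
        return NOT_SOMATIC
    return SOMATIC if is_absent(blood, config) == ABSENT else INDETERMINATE


def compute_vaf(counts: SiteReadCounts) -> float:
    """Variant allele frequency, alt_reads / depth."""
    if counts.depth == 0:
        raise ValueError(
            f"VAF undefined at zero depth ({counts.locus.chrom}:{counts.locus.pos})"
        )
    return counts.alt_reads / counts.depth


def filter_non_silent(
    records: Sequence[VariantRecord], strict: bool = False
) -> list[VariantRecord]:
    """Drop silent variants; optionally also non-coding ones.

    Synonymous records are always removed. With ``strict=True`` UTR,
    intronic and upstream records are removed as well; the default keeps
    them, matching how the bundled cohort table was curated (it retains a
    handful of UTR/intronic rows among its non-silent variants).
    """
    removed = set(SILENT_CONSEQUENCES)
    if strict:
        removed |= NONCODING_CONSEQUENCES
    for rec in records:
        if not rec.consequence:
            raise ValueError(f"record {rec.gene} has no consequence annotation")
    return [r for r in records if r.consequence not in removed]


def assign_compartments(
    somatic_calls: Mapping[str, Iterable[Locus]],
    trio: SampleTrio,
) -> dict[Locus, str]:
    """Compartment of each somatic locus from per-sample somatic calls.

    ``somatic_calls`` maps sample_id -> loci called somatic in that sample.
    A locus somatic in at least one ectopic replicate only maps to ECT,
    eutopic only to EU, both tissues to BOTH. Each (locus, alt) appears
    once in the result regardless of how many replicates support it.
    """
    tissues: dict[Locus, set[str]] = defaultdict(set)
    for sample_id, loci in somatic_calls.items():
        tissue = trio.tissue_of(sample_id)
        if tissue == "BLOOD":
            raise ValueError("blood sample cannot carry somatic calls")
        for locus in loci:
            tissues[locus].add(tissue)
    return {
        locus: ("BOTH" if len(ts) == 2 else next(iter(ts)))
        for locus, ts in tissues.items()
    }


def annotate_population_af(
    records: Sequence[VariantRecord],
    af_table: Mapping[Locus, float],
    max_population_af: float | None = None,
) -> list[VariantRecord]:
    """Attach gnomAD-style population frequencies; optionally filter.

    Loci absent from ``af_table`` get frequency 0. When
    ``max_population_af`` is given, records strictly above the ceiling are
    removed after annotation; with ``None`` the call only annotates.
    """
    annotated = [
        replace(rec, gnomad_af=float(af_table.get(rec.locus, 0.0))) for rec in records
    ]
    if max_population_af is None:
        return annotated
    return [r for r in annotated if r.gnomad_af <= max_population_af]


def call_trio(
    counts: Sequence[SiteReadCounts],
    trio: SampleTrio,
    config: CallerConfig = CallerConfig(),
) -> tuple[dict[Locus, str], list[tuple[str, Locus, str]]]:
    """Run the somatic rules over every site of one patient trio.

    Returns ``(compartment_by_locus, call_status_rows)`` where the status
    rows record (sample_id, locus, somatic/not_somatic/indeterminate) for
    every tissue sample x locus with blood coverage data, for audit output.
    """
    by_sample: dict[str, dict[Locus, SiteReadCounts]] = defaultdict(dict)
    for c in counts:
        by_sample[c.sample_id][c.locus] = c
    blood_sites = by_sample.get(trio.blood, {})
    somatic_calls: dict[str, set[Locus]] = defaultdict(set)
    status_rows: list[tuple[str, Locus, str]] = []
    for sample_id in (*trio.ectopic_replicates, *trio.eutopic_replicates):
        for locus, tissue_counts in by_sample.get(sample_id, {}).items():
            blood = blood_sites.get(locus)
            if blood is None:
                # no blood evidence at all: absence cannot be established
                status = (
                    INDETERMINATE
                    if is_present(tissue_counts, config)
                    else NOT_SOMATIC
                )
            else:
                status = call_somatic(tissue_counts, blood, config)
            status_rows.append((sample_id, locus, status))
            if status == SOMATIC:
                somatic_calls[sample_id].add(locus)
    return assign_compartments(somatic_calls, trio), status_rows
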