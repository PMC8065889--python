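"""Amplicon-deep-sequencing (ADS) confirmation of candidate variants.

Candidates from the discovery sequencing are re-sequenced at >2000x over
every available replicate (including WGA replicates that never entered the
discovery run). Detection in the deep data uses the same >=2-read rule plus
a VAF floor: at 2000x, two reads are 0.1% — the magnitude of the
sequencing-error rate — so a floor (default 0.5%) keeps noise from
counting as confirmation. A variant detected in at least one replicate is
confirmed; detected in none of >=1 tested replicates it is excluded as a
WGA/PCR artifact; with no ADS data it is unevaluable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import CallerConfig, SiteReadCounts, VariantRecord

__all__ = ["VerificationResult", "ads_detects", "verify_variant", "verification_report"]

CONFIRMED = "confirmed"
EXCLUDED = "excluded"
UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class VerificationResult:
    """Per-variant ADS outcome across replicates."""

    variant: VariantRecord
    replicate_outcomes: tuple[tuple[str, bool, int, int], ...]  # (sample, detected, depth, alt)
    status: str
    n_detected: int
    n_tested: int

    def __post_init__(self) -> None:
        if self.n_detected > self.n_tested:
            raise ValueError("n_detected cannot exceed n_tested")
        if self.status == EXCLUDED and not (self.n_detected == 0 and self.n_tested >= 1):
            raise ValueError("excluded requires 0 detections among >=1 tested")
        if self.status == CONFIRMED and self.n_detected < 1:
            raise ValueError("confirmed requires >=1 detection")


def ads_detects(counts: SiteReadCounts, config: CallerConfig = CallerConfig()) -> bool:
    """Detection in one ADS replicate: >=2 alt reads AND VAF above the floor."""
    if counts.alt_reads < config.ads_min_alt_reads:
        return False
    if counts.depth == 0:
        return False
    return counts.alt_reads / counts.depth >= config.ads_min_vaf


def verify_variant(
    variant: VariantRecord,
    ads_counts: Sequence[SiteReadCounts],
    config: CallerConfig = CallerConfig(),
) -> VerificationResult:
    """Confirm/exclude one variant from its ADS replicate counts.

    Confirmed iff detected in at least one replicate; excluded iff detected
    in none of >=1; unevaluable when no ADS data was provided.
    """
    outcomes = tuple(
        (c.sample_id, ads_detects(c, config), c.depth, c.alt_reads) for c in ads_counts
    )
    n_detected = sum(1 for _, det, _, _ in outcomes if det)
    if not outcomes:
        status = UNEVALUABLE
    elif n_detected >= 1:
        status = CONFIRMED
    else:
        status = EXCLUDED
    return VerificationResult(
        variant=variant,
        replicate_outcomes=outcomes,
        status=status,
        n_detected=n_detected,
        n_tested=len(outcomes),
    )


def verification_report(results: Sequence[VerificationResult]) -> pd.DataFrame:
    """Tabulate verification outcomes, one row per variant.

    Columns: patient, gene, hgvs_c, compartment, status, n_detected,
    n_tested. The three status counts always sum to the number of input
    variants.
    """
    rows = [
        {
            "patient_id": r.variant.patient_id,
            "gene": r.variant.gene,
            "hgvs_c": r.variant.hgvs_c,
            "compartment": r.variant.compartment,
            "status": r.status,
            "n_detected": r.n_detected,
            "n_tested": r.n_tested,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "gene",
            "hgvs_c",
            "compartment",
            "status",
            "n_detected",
            "n_tested",
        ],
    )
    df.attrs["summary"] = {
        CONFIRMED: int((df["status"] == CONFIRMED).sum()) if len(df) else 0,
        EXCLUDED: int((df["status"] == EXCLUDED).sum()) if len(df) else 0,
        UNEVALUABLE: int((df["status"] == UNEVALUABLE).sum()) if len(df) else 0,
    }
    return df
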