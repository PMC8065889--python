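"""Synthetic matched-trio sequencing data with WGA/LCM noise structure.

The generator emulates the statistical situation the caller faces with
laser-microdissected, whole-genome-amplified glandular epithelium:

* heterozygous germline variants shared by blood and both tissues
  (alt reads binomial at VAF 0.5);
* low-frequency somatic variants (true VAF drawn from a configurable
  range, default 1–10%) private to one tissue compartment or shared by
  both, absent from blood except for sequencing error;
* per-base sequencing error producing stray alt reads anywhere;
* WGA artifacts — spurious low-VAF variants private to a single
  amplification replicate, the mechanism that makes replicate
  re-sequencing informative;
* WGA allelic dropout — a true variant yielding zero alt reads in one
  replicate;
* overdispersed coverage: per-site depth is negative-binomial. The default
  mean (159x) and dispersion (0.7396) jointly put 82% of sites at >=20x,
  the regime of the targeted discovery sequencing; amplicon re-sequencing
  (ADS) is simulated at Poisson depth around 2500x.

Everything is deterministic under a fixed seed; per-patient substreams are
derived from the global seed so patients are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from .io_formats import (
    GenePanel,
    Locus,
    SampleTrio,
    SiteReadCounts,
    VariantRecord,
    load_panel,
)

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "simulate_trio",
    "simulate_cohort",
    "simulate_ads",
    "write_truth_vcf",
]

_BASES = "ACGT"

#: negative-binomial size parameter putting 82% of sites at >=20x when the
#: mean is 159x (calibrated against the NB survival function)
DEFAULT_COVERAGE_DISPERSION = 0.7396


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the trio/ADS simulator (see module docstring)."""

    n_patients: int = 13
    panel: GenePanel | None = None  # None -> bundled panel
    n_germline_per_patient: int = 30
    n_somatic_ect: int = 2
    n_somatic_eu: int = 2
    n_somatic_shared: int = 1
    n_null_per_patient: int = 20
    somatic_vaf_range: tuple[float, float] = (0.01, 0.10)
    coverage_mean: float = 159.0
    coverage_dispersion: float = DEFAULT_COVERAGE_DISPERSION
    ads_coverage_mean: float = 2500.0
    seq_error_rate: float = 0.001
    wga_artifact_rate: float = 0.5
    wga_dropout_prob: float = 0.1
    n_replicates_per_tissue: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.somatic_vaf_range
        if not 0 < lo <= hi <= 1:
            raise ValueError(f"bad somatic_vaf_range ({lo}, {hi})")
        for name in ("seq_error_rate", "wga_artifact_rate", "wga_dropout_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.coverage_mean <= 0 or self.ads_coverage_mean <= 0:
            raise ValueError("coverage means must be > 0")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be > 0")

    def resolved_panel(self) -> GenePanel:
        return self.panel if self.panel is not None else load_panel()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "somatic_vaf_range" in raw:
            raw["somatic_vaf_range"] = tuple(raw["somatic_vaf_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw.pop("panel")
        raw["somatic_vaf_range"] = list(self.somatic_vaf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class TruthSet:
    """Simulation ground truth for one patient.

    ``somatic`` rows are (locus, true_vaf, compartment); ``artifacts`` are
    (locus, sample_id) — the single replicate carrying the spurious call.
    ``null_sites`` carry no variant anywhere (sequencing error only).
    Germline, somatic, artifact and null locus sets are pairwise disjoint.
    """

    patient_id: str
    germline: tuple[Locus, ...]
    somatic: tuple[tuple[Locus, float, str], ...]
    artifacts: tuple[tuple[Locus, str], ...]
    null_sites: tuple[Locus, ...] = ()

    def __post_init__(self) -> None:
        sets = [
            set(self.germline),
            {l for l, _, _ in self.somatic},
            {l for l, _ in self.artifacts},
            set(self.null_sites),
        ]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("truth categories must be pairwise disjoint")

    @property
    def somatic_loci(self) -> frozenset[Locus]:
        return frozenset(l for l, _, _ in self.somatic)


def _patient_rng(config: SimulationConfig, patient_index: int, stream: int = 0) -> np.random.Generator:
    # fixed-offset substreams: (seed, patient, stream) fully determine draws
    return np.random.default_rng([config.rng_seed, patient_index, stream])


def _draw_loci(rng: np.random.Generator, panel: GenePanel, n: int, taken: set[Locus]) -> list[Locus]:
    entries = panel.entries
    loci: list[Locus] = []
    positions_taken = {(l.chrom, l.pos) for l in taken}
    while len(loci) < n:
        e = entries[int(rng.integers(len(entries)))]
        pos = int(rng.integers(e.start + 1, e.end + 1))
        if (e.chrom, pos) in positions_taken:
            continue
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(rng.integers(3)) + _BASES.index(ref) + 1) % 4]
        locus = Locus(e.chrom, pos, ref, alt)
        positions_taken.add((e.chrom, pos))
        loci.append(locus)
        taken.add(locus)
    return loci


def _depth(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_trio(
    config: SimulationConfig, patient_index: int
) -> tuple[SampleTrio, list[SiteReadCounts], TruthSet]:
    """Simulate one patient: blood plus replicated eutopic/ectopic samples.

    Returns the trio manifest, per-site read counts for every sample at
    every truth locus, and the ground truth. The available panel positions
    must accommodate the requested site counts.
    """
    panel = config.resolved_panel()
    n_sites = (
        config.n_germline_per_patient
        + config.n_somatic_ect
        + config.n_somatic_eu
        + config.n_somatic_shared
        + config.n_null_per_patient
    )
    n_positions = sum(e.end - e.start for e in panel.entries)
    if n_sites + config.n_replicates_per_tissue * 2 > n_positions:
        raise ValueError("requested sites exceed available panel positions")

    patient_id = f"SIM{patient_index:03d}"
    eu_reps = tuple(f"{patient_id}_EU_{r+1}" for r in range(config.n_replicates_per_tissue))
    ect_reps = tuple(f"{patient_id}_ECT_{r+1}" for r in range(config.n_replicates_per_tissue))
    trio = SampleTrio(
        patient_id=patient_id,
        blood=f"{patient_id}_BLOOD",
        eutopic_replicates=eu_reps,
        ectopic_replicates=ect_reps,
    )

    rng = _patient_rng(config, patient_index, stream=0)
    taken: set[Locus] = set()
    germline = tuple(_draw_loci(rng, panel, config.n_germline_per_patient, taken))
    lo, hi = config.somatic_vaf_range
    somatic: list[tuple[Locus, float, str]] = []
    for compartment, count in (
        ("ECT", config.n_somatic_ect),
        ("EU", config.n_somatic_eu),
        ("BOTH", config.n_somatic_shared),
    ):
        for locus in _draw_loci(rng, panel, count, taken):
            somatic.append((locus, float(rng.uniform(lo, hi)), compartment))
    artifacts: list[tuple[Locus, str]] = []
    for rep in (*ect_reps, *eu_reps):
        if rng.random() < config.wga_artifact_rate:
            (locus,) = _draw_loci(rng, panel, 1, taken)
            artifacts.append((locus, rep))
    null_sites = tuple(_draw_loci(rng, panel, config.n_null_per_patient, taken))
    truth = TruthSet(patient_id, germline, tuple(somatic), tuple(artifacts), null_sites)

    # variant VAF carried by each (locus, sample); everything else is error
    artifact_vaf = {
        (locus, rep): float(rng.uniform(lo, hi)) for locus, rep in artifacts
    }
    carriers: dict[Locus, dict[str, float]] = {}
    for locus in germline:
        carriers[locus] = {s: 0.5 for s in trio.all_samples}
    for locus, vaf, compartment in somatic:
        reps: tuple[str, ...] = ()
        if compartment in ("ECT", "BOTH"):
            reps += ect_reps
        if compartment in ("EU", "BOTH"):
            reps += eu_reps
        carrying = dict.fromkeys(reps, vaf)
        if config.wga_dropout_prob > 0 and rng.random() < config.wga_dropout_prob:
            dropped = reps[int(rng.integers(len(reps)))]
            carrying[dropped] = 0.0
        carriers[locus] = carrying
    for (locus, rep), vaf in artifact_vaf.items():
        carriers[locus] = {rep: vaf}
    for locus in null_sites:
        carriers[locus] = {}

    counts: list[SiteReadCounts] = []
    all_loci = [*germline, *(l for l, _, _ in somatic), *(l for l, _ in artifacts), *null_sites]
    for locus in all_loci:
        for sample in trio.all_samples:
            depth = _depth(rng, config.coverage_mean, config.coverage_dispersion)
            p_alt = carriers[locus].get(sample, 0.0)
            if p_alt == 0.0:
                p_alt = config.seq_error_rate
            alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
            counts.append(
                SiteReadCounts(
                    sample_id=sample,
                    locus=locus,
                    depth=depth,
                    alt_reads=alt,
                    ref_reads=depth - alt,
                    other_reads=0,
                )
            )
    return trio, counts, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SampleTrio], list[SiteReadCounts], list[TruthSet]]:
    """Simulate all ``n_patients`` trios under one config."""
    trios, counts, truths = [], [], []
    for idx in range(config.n_patients):
        trio, c, truth = simulate_trio(config, idx)
        trios.append(trio)
        counts.extend(c)
        truths.append(truth)
    return trios, counts, truths


def simulate_ads(
    truth: TruthSet,
    variants: Sequence[VariantRecord],
    config: SimulationConfig,
) -> list[SiteReadCounts]:
    """Simulate amplicon re-sequencing of selected variants.

    Every ADS replicate of a compartment carrying a true somatic variant
    yields alt reads binomial at its true VAF; WGA artifacts (and any other
    locus) yield alt reads only at the sequencing-error rate in every
    replicate, since the artifact is private to one amplification and does
    not reproduce. Depth is Poisson around ``ads_coverage_mean``.
    """
    rng = np.random.default_rng(
        [config.rng_seed, zlib.crc32(truth.patient_id.encode()) % (2**31), 7]
    )
    truth_vaf = {l: (v, comp) for l, v, comp in truth.somatic}
    reps = [
        (f"{truth.patient_id}_ADS_ECT_{r+1}", "ECT")
        for r in range(config.n_replicates_per_tissue)
    ] + [
        (f"{truth.patient_id}_ADS_EU_{r+1}", "EU")
        for r in range(config.n_replicates_per_tissue)
    ]
    counts: list[SiteReadCounts] = []
    for rec in variants:
        info = truth_vaf.get(rec.locus)
        for sample_id, tissue in reps:
            depth = int(rng.poisson(config.ads_coverage_mean))
            carries = info is not None and (info[1] == "BOTH" or info[1] == tissue)
            p_alt = info[0] if carries else config.seq_error_rate
            alt = int(rng.binomial(depth, p_alt)) if depth > 0 else 0
            counts.append(
                SiteReadCounts(
                    sample_id=sample_id,
                    locus=rec.locus,
                    depth=depth,
                    alt_reads=alt,
                    ref_reads=depth - alt,
                    other_reads=0,
                )
            )
    return counts


def write_truth_vcf(truths: Sequence[TruthSet], path: str | Path) -> None:
    """Write simulation ground truth as a VCF with a TRUTH INFO key."""
    header = pysam.VariantHeader()
    chroms = sorted({l.chrom for t in truths for l in _truth_loci(t)})
    for chrom in chroms:
        header.contigs.add(chrom, length=250_000_000)
    header.info.add("TRUTH", "1", "String", "germline|somatic|artifact|null")
    header.info.add("PATIENT", "1", "String", "Patient identifier")
    header.info.add("TRUE_VAF", "1", "Float", "Simulated variant allele frequency")
    rows = []
    for t in truths:
        for locus in t.germline:
            rows.append((locus, "germline", t.patient_id, 0.5))
        for locus, vaf, _comp in t.somatic:
            rows.append((locus, "somatic", t.patient_id, vaf))
        for locus, _rep in t.artifacts:
            rows.append((locus, "artifact", t.patient_id, None))
        for locus in t.null_sites:
            rows.append((locus, "null", t.patient_id, None))
    rows.sort(key=lambda r: (r[0].chrom, r[0].pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus, kind, patient, vaf in rows:
            row = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,
                stop=locus.pos - 1 + len(locus.ref),
                alleles=(locus.ref, locus.alt),
            )
            row.info["TRUTH"] = kind
            row.info["PATIENT"] = patient
            if vaf is not None:
                row.info["TRUE_VAF"] = vaf
            vcf.write(row)


def _truth_loci(t: TruthSet):
    yield from t.germline
    yield from (l for l, _, _ in t.somatic)
    yield from (l for l, _ in t.artifacts)
    yield from t.null_sites
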