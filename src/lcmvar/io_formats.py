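"""Domain types and readers/writers for the pipeline's external formats.

The pipeline's unit of evidence is a per-sample, per-site read-count record
(:class:`SiteReadCounts`); candidate and called variants travel as
:class:`VariantRecord` in VCF with a small set of INFO keys; panels, driver
lists and site counts are plain TSV/BED.

Bundled reference data
----------------------
The package ships a variant table from a deep-infiltrating-endometriosis
cohort (13 patients, matched blood / eutopic endometrium / ectopic nodule,
laser-microdissected glandular epithelium): 59 somatic variants with gene,
transcript, HGVS description and gnomAD allele frequency. Genomic
coordinates are not part of that table, so :func:`load_cohort_variants`
assigns each variant a deterministic placeholder locus inside its gene's
synthetic panel region and parses ref/alt from the cDNA change. The bundled
panel (1296 genes, 85 drivers) and driver list are likewise synthetic
reconstructions that reproduce the cohort's class sizes; files are named
``*_synthetic`` accordingly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

__all__ = [
    "Locus",
    "SiteReadCounts",
    "VariantRecord",
    "SampleTrio",
    "PanelEntry",
    "GenePanel",
    "CallerConfig",
    "CONSEQUENCES",
    "COMPARTMENTS",
    "consequence_from_hgvs",
    "read_site_counts",
    "write_site_counts",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_panel_bed",
    "load_driver_list",
    "load_panel",
    "load_cohort_variants",
    "load_ads_fixture",
]

_DNA = set("ACGT")

CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "inframe_indel",
        "splice_region",
        "synonymous",
        "utr",
        "intronic",
        "upstream",
    }
)

#: "Silent" consequences removed by the non-silent filter in both modes.
SILENT_CONSEQUENCES = frozenset({"synonymous"})

#: Additionally removed when the filter runs in strict mode.
NONCODING_CONSEQUENCES = frozenset({"utr", "intronic", "upstream"})

COMPARTMENTS = ("ECT", "EU", "BOTH", "NONE")


class FormatError(ValueError):
    """A file violated its expected format (named line where possible)."""


@dataclass(frozen=True, order=True)
class Locus:
    """A genomic SNV/indel locus: 1-based position plus ref and alt alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r})")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _DNA:
                raise ValueError(f"allele {allele!r} not over A/C/G/T")


@dataclass(frozen=True)
class SiteReadCounts:
    """Read support at one locus in one sample.

    ``depth`` must equal ``alt_reads + ref_reads + other_reads``;
    ``other_reads`` counts reads supporting neither ref nor the candidate
    alt (any third allele).
    """

    sample_id: str
    locus: Locus
    depth: int
    alt_reads: int
    ref_reads: int
    other_reads: int = 0

    def __post_init__(self) -> None:
        for name in ("depth", "alt_reads", "ref_reads", "other_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        total = self.alt_reads + self.ref_reads + self.other_reads
        if total != self.depth:
            raise ValueError(
                f"depth {self.depth} != alt+ref+other = {total} "
                f"at {self.locus.chrom}:{self.locus.pos} in {self.sample_id}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """An annotated candidate or called variant (one table row / VCF line)."""

    locus: Locus
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: str = "missense"
    vaf: float = 0.0
    compartment: str = "NONE"
    gnomad_af: float = 0.0
    patient_id: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if not 0.0 <= self.gnomad_af <= 1.0:
            raise ValueError(f"gnomad_af {self.gnomad_af} outside [0, 1]")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class SampleTrio:
    """One patient's blood reference plus eutopic/ectopic LCM replicates."""

    patient_id: str
    blood: str
    eutopic_replicates: tuple[str, ...] = ()
    ectopic_replicates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.blood:
            raise ValueError("blood sample id required")
        if not (self.eutopic_replicates or self.ectopic_replicates):
            raise ValueError("at least one tissue replicate required")
        ids = [self.blood, *self.eutopic_replicates, *self.ectopic_replicates]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids within a trio must be unique")

    @property
    def all_samples(self) -> tuple[str, ...]:
        return (self.blood, *self.eutopic_replicates, *self.ectopic_replicates)

    def tissue_of(self, sample_id: str) -> str:
        if sample_id in self.ectopic_replicates:
            return "ECT"
        if sample_id in self.eutopic_replicates:
            return "EU"
        if sample_id == self.blood:
            return "BLOOD"
        raise KeyError(f"{sample_id} not in trio {self.patient_id}")


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    chrom: str
    start: int  # 0-based half-open, BED convention
    end: int
    is_driver: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region {self.start}-{self.end} for {self.gene}")


@dataclass(frozen=True)
class GenePanel:
    """The capture panel: gene symbols, regions, and driver flags."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        symbols = [e.gene for e in self.entries]
        if len(symbols) != len(set(symbols)):
            raise ValueError("panel gene symbols must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries)

    @property
    def driver_genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries if e.is_driver)

    @property
    def nondriver_genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.entries if not e.is_driver)

    @property
    def n_driver(self) -> int:
        return sum(e.is_driver for e in self.entries)

    @property
    def n_nondriver(self) -> int:
        return len(self.entries) - self.n_driver

    def entry(self, gene: str) -> PanelEntry:
        gene = gene.upper()
        for e in self.entries:
            if e.gene == gene:
                return e
        raise KeyError(gene)

    def with_driver_set(self, drivers: Iterable[str]) -> "GenePanel":
        drivers = {d.upper() for d in drivers}
        return GenePanel(
            tuple(replace(e, is_driver=e.gene in drivers) for e in self.entries)
        )


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds of the rule-based somatic caller and the ADS verifier.

    ``min_alt_reads``: reads with the alternate allele required to call a
    variant present in a sample. ``min_ref_depth_for_absence``: coverage a
    site must *exceed* (strict >) with zero non-reference reads before the
    variant is declared absent from blood. ``max_population_af``: optional
    gnomAD ceiling; ``None`` means annotate only. ADS thresholds govern
    detection in the high-depth verification data, where a 2-read minimum
    alone would sit at the sequencing-error floor.
    """

    min_alt_reads: int = 2
    min_ref_depth_for_absence: int = 20
    max_population_af: float | None = None
    ads_min_alt_reads: int = 2
    ads_min_vaf: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_alt_reads < 0 or self.min_ref_depth_for_absence < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.ads_min_vaf <= 1.0:
            raise ValueError("ads_min_vaf outside [0, 1]")
        if self.max_population_af is not None and not (
            0.0 <= self.max_population_af <= 1.0
        ):
            raise ValueError("max_population_af outside [0, 1]")


# ---------------------------------------------------------------------------
# HGVS-derived consequence (pattern mapping only, not an HGVS engine)
# ---------------------------------------------------------------------------

import re

_RE_SUB = re.compile(r"([ACGT]+)\s*>\s*([ACGT]+)\s*$")
_RE_INS = re.compile(r"ins([ACGT]+)\s*$")
_RE_DEL = re.compile(r"del([ACGT]*)\s*$")
_RE_INTRON_OFFSET = re.compile(r"c\.\d+([+-]\d+)")

#: intronic positions within this many bases of the exon edge count as
#: splice-region (the VEP convention extends to +/-8)
_SPLICE_REGION_BP = 8


def consequence_from_hgvs(hgvs_c: str, hgvs_p: str = "") -> str:
    """Map an HGVS description to a coarse consequence class.

    Protein-level notation wins when present (fs -> frameshift, a gained
    stop -> nonsense, in-frame del/ins/dup -> inframe_indel, otherwise
    missense unless the residue is unchanged). Pure cDNA notation is
    classified by position: 5'/3' UTR (``c.-``/``c.*``), near-exon intronic
    offsets as splice_region, deeper offsets as intronic.
    """
    p = hgvs_p.strip()
    if p and p not in {"p.?", "p.="}:
        if p.endswith("fs") or "fs" in p.split("_")[-1]:
            return "frameshift"
        if p.endswith("*") or p.endswith("Ter"):
            return "nonsense"
        if p.endswith(("del", "dup")) or "delins" in p or p.endswith("ins"):
            return "inframe_indel"
        m = re.match(r"p\.([A-Za-z]{3})\d+([A-Za-z]{3})$", p)
        if m and m.group(1) == m.group(2):
            return "synonymous"
        return "missense"
    c = hgvs_c.strip()
    if c.startswith("c.-"):
        return "utr"
    if c.startswith("c.*"):
        return "utr"
    m = _RE_INTRON_OFFSET.search(c)
    if m:
        offset = abs(int(m.group(1)))
        return "splice_region" if offset <= _SPLICE_REGION_BP else "intronic"
    return "missense"


def _alleles_from_hgvs_c(hgvs_c: str) -> tuple[str, str]:
    """Ref/alt alleles implied by a cDNA change (anchor base 'A' for indels)."""
    c = hgvs_c.replace(" ", "")
    m = _RE_SUB.search(c)
    if m:
        return m.group(1), m.group(2)
    m = _RE_INS.search(c)
    if m:
        return "A", "A" + m.group(1)
    m = _RE_DEL.search(c)
    if m:
        deleted = m.group(1) or "N"
        if deleted == "N" or not set(deleted) <= _DNA:
            deleted = "ACGT"[: max(1, len(deleted))] or "A"
        return "A" + deleted, "A"
    return "A", "C"


def _placeholder_locus(entry: PanelEntry, gene: str, hgvs_c: str) -> Locus:
    """Deterministic placeholder coordinates inside the gene's panel region."""
    span = entry.end - entry.start
    offset = zlib.crc32(f"{gene}|{hgvs_c}".encode()) % span
    ref, alt = _alleles_from_hgvs_c(hgvs_c)
    return Locus(entry.chrom, entry.start + 1 + offset, ref, alt)


# ---------------------------------------------------------------------------
# TSV site counts
# ---------------------------------------------------------------------------

_SITE_COLS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "ref_reads",
    "other_reads",
]


def read_site_counts(path: str | Path) -> list[SiteReadCounts]:
    """Read a per-site read-count TSV (one row per sample x locus)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in _SITE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out: list[SiteReadCounts] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            locus = Locus(str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
            out.append(
                SiteReadCounts(
                    sample_id=str(row.sample_id),
                    locus=locus,
                    depth=int(row.depth),
                    alt_reads=int(row.alt_reads),
                    ref_reads=int(row.ref_reads),
                    other_reads=int(row.other_reads),
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_site_counts(counts: Iterable[SiteReadCounts], path: str | Path) -> None:
    rows = [
        (
            c.sample_id,
            c.locus.chrom,
            c.locus.pos,
            c.locus.ref,
            c.locus.alt,
            c.depth,
            c.alt_reads,
            c.ref_reads,
            c.other_reads,
        )
        for c in counts
    ]
    pd.DataFrame(rows, columns=_SITE_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_INFO = [
    ("GENE", "1", "String", "Gene symbol"),
    ("CSQ", "1", "String", "Consequence class"),
    ("HGVSC", "1", "String", "HGVS cDNA description"),
    ("HGVSP", "1", "String", "HGVS protein description"),
    ("TRANSCRIPT", "1", "String", "RefSeq transcript"),
    ("GNOMAD_AF", "1", "Float", "gnomAD all-population allele frequency"),
    ("COMPARTMENT", "1", "String", "Tissue compartment (ECT/EU/BOTH/NONE)"),
    ("VAF", "1", "Float", "Variant allele frequency"),
    ("PATIENT", "1", "String", "Patient identifier"),
]

_REQUIRED_INFO = ("GENE", "CSQ", "HGVSC", "HGVSP", "GNOMAD_AF", "COMPARTMENT", "VAF")

_CONTIGS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CONTIG_LEN = 250_000_000

# HGVS strings contain characters VCF INFO reserves (';', '=', ' '); they are
# percent-encoded on write and decoded on read.
_ENC = {";": "%3B", "=": "%3D", " ": "%20", ",": "%2C"}


def _info_encode(s: str) -> str:
    for raw, enc in _ENC.items():
        s = s.replace(raw, enc)
    return s or "."


def _info_decode(s: str) -> str:
    if s == ".":
        return ""
    for raw, enc in _ENC.items():
        s = s.replace(enc, raw)
    return s


def _vcf_header() -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in _CONTIGS:
        header.contigs.add(contig, length=_CONTIG_LEN)
    for name, number, vtype, desc in _VCF_INFO:
        header.info.add(name, number, vtype, desc)
    return header


def write_variants_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write annotated variants as VCF v4.2 with the pipeline's INFO keys."""
    header = _vcf_header()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for rec in sorted(records, key=lambda r: (_CONTIGS.index(r.locus.chrom), r.locus.pos)):
            row = vcf.new_record(
                contig=rec.locus.chrom,
                start=rec.locus.pos - 1,
                stop=rec.locus.pos - 1 + len(rec.locus.ref),
                alleles=(rec.locus.ref, rec.locus.alt),
            )
            row.info["GENE"] = rec.gene
            row.info["CSQ"] = rec.consequence
            row.info["HGVSC"] = _info_encode(rec.hgvs_c)
            row.info["HGVSP"] = _info_encode(rec.hgvs_p)
            row.info["TRANSCRIPT"] = _info_encode(rec.transcript)
            row.info["GNOMAD_AF"] = rec.gnomad_af
            row.info["COMPARTMENT"] = rec.compartment
            row.info["VAF"] = rec.vaf
            row.info["PATIENT"] = _info_encode(rec.patient_id)
            vcf.write(row)


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF written by :func:`write_variants_vcf` (round-trip stable)."""
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for row in vcf:
            info = row.info
            missing = [k for k in _REQUIRED_INFO if k not in info]
            if missing:
                raise FormatError(
                    f"{path}: record {row.contig}:{row.pos} missing INFO keys {missing}"
                )
            out.append(
                VariantRecord(
                    locus=Locus(row.contig, row.pos, row.ref, row.alts[0]),
                    gene=str(info["GENE"]),
                    transcript=_info_decode(str(info.get("TRANSCRIPT", "."))),
                    hgvs_c=_info_decode(str(info["HGVSC"])),
                    hgvs_p=_info_decode(str(info["HGVSP"])),
                    consequence=str(info["CSQ"]),
                    vaf=round(float(info["VAF"]), 6),
                    compartment=str(info["COMPARTMENT"]),
                    gnomad_af=round(float(info["GNOMAD_AF"]), 8),
                    patient_id=_info_decode(str(info.get("PATIENT", "."))),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Panel BED + driver list
# ---------------------------------------------------------------------------


def read_panel_bed(path: str | Path) -> GenePanel:
    """Read a BED3+1 panel (4th column = gene symbol); no driver flags set."""
    entries = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}, line {i}: expected 4 BED columns")
            chrom, start, end, gene = parts[:4]
            try:
                entries.append(PanelEntry(gene.upper(), chrom, int(start), int(end)))
            except ValueError as exc:
                raise FormatError(f"{path}, line {i}: {exc}") from exc
    return GenePanel(tuple(entries))


def load_driver_list(path: str | Path) -> set[str]:
    """Read a driver-gene list (one symbol per line, ``#`` comments)."""
    symbols: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(line.upper())
    if not symbols:
        raise FormatError(f"{path}: driver list is empty")
    return symbols


# ---------------------------------------------------------------------------
# Bundled data
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    path = resources.files("lcmvar").joinpath("data", name)
    with resources.as_file(path) as p:
        return Path(p)


def load_panel(driver_flags: bool = True) -> GenePanel:
    """The bundled 1296-gene panel; with the synthetic 85-gene driver set."""
    panel = read_panel_bed(_data_path("panel_synthetic.bed"))
    if driver_flags:
        panel = panel.with_driver_set(load_driver_list(_data_path("driver_genes_synthetic.tsv")))
    return panel


def bundled_driver_list_path() -> Path:
    return _data_path("driver_genes_synthetic.tsv")


def load_cohort_variants() -> list[VariantRecord]:
    """The bundled 59-variant cohort table as annotated records.

    Sample labels such as ``EEP001ECT`` carry the patient id and compartment;
    rows listed under both an ECT and an EU label become compartment BOTH.
    Placeholder loci are synthesised deterministically (see module docstring).
    """
    path = _data_path("cohort_variants.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    panel = load_panel()
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        labels = str(row.sample_label).split()
        if not labels:
            raise FormatError(f"{path}, line {i}: empty sample label")
        patients = {lbl.replace("ECT", "").replace("EU", "") for lbl in labels}
        if len(patients) != 1:
            raise FormatError(f"{path}, line {i}: mixed patients {labels}")
        tissues = {"ECT" if lbl.endswith("ECT") else "EU" for lbl in labels}
        compartment = "BOTH" if tissues == {"ECT", "EU"} else tissues.pop()
        gene = str(row.gene).upper()
        try:
            entry = panel.entry(gene)
        except KeyError as exc:
            raise FormatError(f"{path}, line {i}: gene {gene} not in panel") from exc
        records.append(
            VariantRecord(
                locus=_placeholder_locus(entry, gene, str(row.hgvs_c)),
                gene=gene,
                transcript=str(row.transcript),
                hgvs_c=str(row.hgvs_c),
                hgvs_p=str(row.hgvs_p),
                consequence=consequence_from_hgvs(str(row.hgvs_c), str(row.hgvs_p)),
                compartment=compartment,
                gnomad_af=float(row.gnomad_af),
                patient_id=patients.pop(),
            )
        )
    return records


def load_ads_fixture() -> dict[tuple[str, str], list[SiteReadCounts]]:
    """Bundled synthetic ADS read counts, keyed by (patient_id, gene).

    Loci are resolved against the bundled cohort table so ADS counts align
    with the corresponding :class:`VariantRecord`.
    """
    variants = {(v.patient_id, v.gene): v for v in load_cohort_variants()}
    df = pd.read_csv(_data_path("ads_counts_synthetic.tsv"), sep="\t", comment="#")
    out: dict[tuple[str, str], list[SiteReadCounts]] = {}
    for row in df.itertuples(index=False):
        key = (str(row.patient_id), str(row.gene).upper())
        if key not in variants:
            raise FormatError(f"ADS fixture references unknown variant {key}")
        locus = variants[key].locus
        depth, alt = int(row.depth), int(row.alt_reads)
        out.setdefault(key, []).append(
            SiteReadCounts(
                sample_id=str(row.sample_id),
                locus=locus,
                depth=depth,
                alt_reads=alt,
                ref_reads=depth - alt,
                other_reads=0,
            )
        )
    return out
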