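"""I/O for population variant catalogues, clinical annotations and reports.

Three input dialects are supported:

* **gnomAD-style VCF** — biallelic SNV records whose INFO column carries, for
  each population label ``pop``, the integer keys ``AN_<pop>`` (total called
  alleles), ``AC_<pop>`` (ALT allele count) and ``nhomalt_<pop>`` (number of
  ALT-homozygous individuals).  Read and written through :mod:`pysam`.
* **genotype-table TSV** (GME-Variome style) — columns ``chrom pos ref alt``
  followed by one column per region holding comma-joined
  ``homref,het,homalt`` counts; ``.`` marks a region with no call data for
  that row.
* **clinical-annotation TSV** (ClinVar-style export) — one row per assertion
  with the variant key, rsID, gene symbol, HGVS change and a free-text
  clinical-significance label, kept verbatim.

The report writer emits a human-readable TSV (p-values rounded to three
decimals for display) and a machine-readable JSON that keeps full precision
and the stage-count funnel.

All coordinates are 1-based on GRCh37 autosomes; only biallelic SNVs are
retained (multi-allelic sites and indels are skipped and counted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .exact_stats import TestResult

logger = logging.getLogger(__name__)

AUTOSOMES = tuple(str(c) for c in range(1, 23))
BASES = frozenset("ACGT")


class PopdiffError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(PopdiffError):
    """A line or cell could not be parsed in the expected dialect."""


class ValidationError(PopdiffError):
    """Parsed values violate a count invariant (e.g. AC > AN)."""


class SchemaError(PopdiffError):
    """A required column or INFO key is missing from an input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """Biallelic SNV identity: chromosome, 1-based position, REF and ALT.

    This quadruple is the join key everywhere; two catalogues describe the
    same variant only when all four fields match exactly.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValidationError(
                f"chromosome {self.chrom!r} is not an autosome label 1..22"
            )
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} must be >= 1 (1-based)")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValidationError(
                f"alleles must be single uppercase bases, got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValidationError(f"REF and ALT are identical at {self.chrom}:{self.pos}")

    @property
    def sort_key(self) -> tuple[int, int, str, str]:
        return (int(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # e.g. "8:118184783 C>T"
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCounts:
    """Diploid genotype counts for one variant in one population/region."""

    homref: int
    het: int
    homalt: int

    def __post_init__(self) -> None:
        for name in ("homref", "het", "homalt"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} count must be a non-negative integer, got {v!r}")

    @property
    def n_individuals(self) -> int:
        return self.homref + self.het + self.homalt

    @property
    def ref_alleles(self) -> int:
        return 2 * self.homref + self.het

    @property
    def alt_alleles(self) -> int:
        return 2 * self.homalt + self.het

    @property
    def alt_frequency(self) -> Optional[float]:
        """ALT allele frequency, or None for a zero-individual cell."""
        n = self.n_individuals
        return self.alt_alleles / (2 * n) if n > 0 else None

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            self.homref + other.homref, self.het + other.het, self.homalt + other.homalt
        )


@dataclass(frozen=True)
class AlleleInfo:
    """Allele-level summary for one population (gnomAD INFO fields).

    ``AN`` is the number of called chromosomes, ``AC`` the ALT allele count
    and ``nhomalt`` the number of ALT-homozygous individuals; the reference
    allele count is derived as AN − AC.
    """

    population: str
    AN: int
    AC: int
    nhomalt: int

    def validate(self, context: str = "") -> None:
        where = f" at {context}" if context else ""
        if self.AN < 0 or self.AC < 0 or self.nhomalt < 0:
            raise ValidationError(f"negative allele-count field{where}")
        if self.AN % 2 != 0:
            raise ValidationError(f"odd AN={self.AN}{where}: cannot form diploid genotypes")
        if self.AC > self.AN:
            raise ValidationError(f"AC={self.AC} exceeds AN={self.AN}{where}")
        if 2 * self.nhomalt > self.AC:
            raise ValidationError(
                f"nhomalt={self.nhomalt} implies more ALT alleles than AC={self.AC}{where}"
            )
        # derived het and hom-ref individual counts must be non-negative
        het = self.AC - 2 * self.nhomalt
        if het + self.nhomalt > self.AN // 2:
            raise ValidationError(
                f"AN={self.AN}, AC={self.AC}, nhomalt={self.nhomalt} imply a negative "
                f"hom-ref count{where}"
            )


def genotype_counts_from_allele_info(info: AlleleInfo) -> GenotypeCounts:
    """Reconstruct the full genotype distribution from (AN, AC, nhomalt).

    With N = AN/2 diploid individuals, the three fields determine the
    genotype counts uniquely:

        homalt = nhomalt,  het = AC − 2·nhomalt,  homref = N − het − homalt.
    """
    info.validate(context=f"population {info.population}")
    homalt = info.nhomalt
    het = info.AC - 2 * info.nhomalt
    homref = info.AN // 2 - het - homalt
    return GenotypeCounts(homref, het, homalt)


@dataclass(frozen=True)
class ClinvarAnnotation:
    """One clinical assertion for a variant, kept verbatim from the table."""

    key: VariantKey
    rsid: str
    gene: str
    change: str
    significance: str

    def __post_init__(self) -> None:
        if not self.significance:
            raise ValidationError(f"empty clinical significance for {self.key}")


# ---------------------------------------------------------------------------
# gnomAD-style VCF
# ---------------------------------------------------------------------------


class GnomadVcfReader:
    """Iterate (VariantKey, {population: AlleleInfo | None}) over a VCF.

    Multi-allelic lines and indels are skipped (counted in
    ``n_skipped_multiallelic`` / ``n_skipped_indel``); a population whose
    three INFO keys are not all present on a line is reported as ``None``
    (absent).  Lines on non-autosomal contigs are skipped as well.
    """

    def __init__(self, path: str | Path, populations: Sequence[str]):
        self.path = Path(path)
        self.populations = list(populations)
        self.n_data_lines = 0
        self.n_parsed = 0
        self.n_skipped_multiallelic = 0
        self.n_skipped_indel = 0
        self.n_skipped_contig = 0

    def __iter__(self) -> Iterator[tuple[VariantKey, dict[str, Optional[AlleleInfo]]]]:
        try:
            vcf = pysam.VariantFile(str(self.path))
        except (OSError, ValueError) as exc:
            raise ParseError(f"cannot open VCF {self.path}: {exc}") from exc
        with vcf:
            records = iter(vcf)
            while True:
                try:
                    rec = next(records)
                except StopIteration:
                    break
                except Exception as exc:  # pysam raises plain ValueError on bad lines
                    raise ParseError(
                        f"malformed VCF record at data line {self.n_data_lines + 1} "
                        f"of {self.path}: {exc}"
                    ) from exc
                self.n_data_lines += 1
                parsed = self._parse_record(rec)
                if parsed is not None:
                    self.n_parsed += 1
                    yield parsed

    def _parse_record(self, rec) -> Optional[tuple[VariantKey, dict[str, Optional[AlleleInfo]]]]:
        alts = rec.alts
        if alts is None or len(alts) != 1:
            self.n_skipped_multiallelic += 1
            return None
        ref = (rec.ref or "").upper()
        alt = alts[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
            self.n_skipped_indel += 1
            return None
        if rec.chrom not in AUTOSOMES:
            self.n_skipped_contig += 1
            return None
        key = VariantKey(rec.chrom, rec.pos, ref, alt)
        infos: dict[str, Optional[AlleleInfo]] = {}
        for pop in self.populations:
            an = rec.info.get(f"AN_{pop}")
            ac = rec.info.get(f"AC_{pop}")
            nh = rec.info.get(f"nhomalt_{pop}")
            if an is None or ac is None or nh is None:
                infos[pop] = None
                continue
            info = AlleleInfo(pop, int(_scalar(an)), int(_scalar(ac)), int(_scalar(nh)))
            info.validate(context=f"{key} population {pop}")
            infos[pop] = info
        return key, infos


def _scalar(value):
    """pysam returns Number=A INFO values as 1-tuples; unwrap them."""
    if isinstance(value, tuple):
        return value[0]
    return value


def read_gnomad_vcf(
    path: str | Path, populations: Sequence[str]
) -> GnomadVcfReader:
    """Open a gnomAD-style VCF for streaming; see :class:`GnomadVcfReader`."""
    return GnomadVcfReader(path, populations)


def detect_populations(path: str | Path) -> list[str]:
    """Population labels declared in a VCF header (keys ``AN_<pop>`` with
    matching ``AC_<pop>`` and ``nhomalt_<pop>``), in header order."""
    with pysam.VariantFile(str(path)) as vcf:
        keys = list(vcf.header.info.keys())
    pops = []
    for k in keys:
        if k.startswith("AN_"):
            pop = k[3:]
            if f"AC_{pop}" in keys and f"nhomalt_{pop}" in keys:
                pops.append(pop)
    return pops


def write_gnomad_vcf(
    path: str | Path,
    records: Sequence[tuple[VariantKey, Optional[str], Mapping[str, Optional[AlleleInfo]]]],
    populations: Sequence[str],
) -> Path:
    """Write (key, rsid, {pop: AlleleInfo|None}) records as a gnomAD-style VCF.

    Populations absent for a variant simply omit their INFO keys on that
    line, mirroring how sites with no calls appear in the real resource.
    """
    path = Path(path)
    header = pysam.VariantHeader()
    for chrom in AUTOSOMES:
        header.contigs.add(chrom, length=250_000_000)
    for pop in populations:
        header.info.add(f"AN_{pop}", 1, "Integer", f"Total number of called alleles in {pop}")
        header.info.add(f"AC_{pop}", 1, "Integer", f"Alternate allele count in {pop}")
        header.info.add(
            f"nhomalt_{pop}", 1, "Integer", f"Number of ALT-homozygous individuals in {pop}"
        )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for key, rsid, infos in records:
            rec = out.new_record(
                contig=key.chrom, start=key.pos - 1, alleles=(key.ref, key.alt)
            )
            if rsid:
                rec.id = rsid
            for pop in populations:
                info = infos.get(pop)
                if info is None:
                    continue
                rec.info[f"AN_{pop}"] = info.AN
                rec.info[f"AC_{pop}"] = info.AC
                rec.info[f"nhomalt_{pop}"] = info.nhomalt
            out.write(rec)
    return path


# ---------------------------------------------------------------------------
# Genotype-table TSV (GME dialect)
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


def read_gme_table(
    path: str | Path, regions: Sequence[str]
) -> Iterator[tuple[VariantKey, dict[str, Optional[GenotypeCounts]]]]:
    """Stream (VariantKey, {region: GenotypeCounts | None}) from a triplet TSV.

    A region cell of ``.`` marks absent data.  A triplet that is not three
    comma-joined integers raises :class:`ParseError`; a negative count raises
    :class:`ValidationError`.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot read genotype table {path}: {exc}") from exc
    missing = [c for c in list(_KEY_COLUMNS) + list(regions) if c not in frame.columns]
    if missing:
        raise SchemaError(f"genotype table {path} lacks column(s) {missing}")
    for idx, row in enumerate(frame.itertuples(index=False), start=2):  # line 1 is header
        row = row._asdict()
        try:
            pos = int(row["pos"])
        except ValueError as exc:
            raise ParseError(f"{path} line {idx}: non-integer position {row['pos']!r}") from exc
        key = VariantKey(row["chrom"], pos, row["ref"].upper(), row["alt"].upper())
        counts: dict[str, Optional[GenotypeCounts]] = {}
        for region in regions:
            cell = row[region]
            if cell == ".":
                counts[region] = None
                continue
            parts = cell.split(",")
            if len(parts) != 3:
                raise ParseError(
                    f"{path} line {idx}: region {region!r} cell {cell!r} is not a "
                    "homref,het,homalt triplet"
                )
            try:
                triplet = [int(p) for p in parts]
            except ValueError as exc:
                raise ParseError(
                    f"{path} line {idx}: non-integer genotype count in {cell!r}"
                ) from exc
            if any(v < 0 for v in triplet):
                raise ValidationError(f"{path} line {idx}: negative genotype count in {cell!r}")
            counts[region] = GenotypeCounts(*triplet)
        yield key, counts


def detect_regions(path: str | Path) -> list[str]:
    """Region labels of a genotype table: every column after chrom/pos/ref/alt."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[:4] != _KEY_COLUMNS:
        raise SchemaError(f"genotype table {path} must start with columns {_KEY_COLUMNS}")
    return header[4:]


def write_gme_table(
    path: str | Path,
    records: Sequence[tuple[VariantKey, Mapping[str, Optional[GenotypeCounts]]]],
    regions: Sequence[str],
) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(list(_KEY_COLUMNS) + list(regions)) + "\n")
        for key, counts in records:
            cells = [key.chrom, str(key.pos), key.ref, key.alt]
            for region in regions:
                gc = counts.get(region)
                cells.append("." if gc is None else f"{gc.homref},{gc.het},{gc.homalt}")
            fh.write("\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# Clinical-annotation TSV (ClinVar dialect)
# ---------------------------------------------------------------------------

_CLINVAR_COLUMNS = ["chrom", "pos", "ref", "alt", "rsid", "gene", "change", "significance"]


def read_clinvar_table(path: str | Path) -> list[ClinvarAnnotation]:
    """Parse a clinical-annotation export; duplicates are preserved."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CLINVAR_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"annotation table {path} lacks column(s) {missing}")
    annotations = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            pos = int(row["pos"])
        except ValueError as exc:
            raise ParseError(f"{path} line {idx}: non-integer position {row['pos']!r}") from exc
        key = VariantKey(row["chrom"], pos, row["ref"].upper(), row["alt"].upper())
        annotations.append(
            ClinvarAnnotation(key, row["rsid"], row["gene"], row["change"], row["significance"])
        )
    return annotations


def write_clinvar_table(path: str | Path, annotations: Sequence[ClinvarAnnotation]) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_CLINVAR_COLUMNS) + "\n")
        for ann in annotations:
            fh.write(
                "\t".join(
                    [
                        ann.key.chrom,
                        str(ann.key.pos),
                        ann.key.ref,
                        ann.key.alt,
                        ann.rsid,
                        ann.gene,
                        ann.change,
                        ann.significance,
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "rsid",
    "marks",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "clinical_significance",
    "obs_ref",
    "obs_alt",
    "exp_ref",
    "exp_alt",
    "p_allele",
    "obs_homref",
    "obs_het",
    "obs_homalt",
    "exp_homref",
    "exp_het",
    "exp_homalt",
    "p_genotype",
]


def result_marks(result: "TestResult") -> str:
    """Legend marks: ``*`` clinically significant, ``#`` allele-test BH
    significant, ``§`` genotype-test BH significant."""
    marks = ""
    if result.clinically_significant:
        marks += "*"
    if result.bh_allele:
        marks += "#"
    if result.bh_genotype:
        marks += "§"
    return marks


def _fmt_expected(value: float) -> str:
    return "" if value is None or math.isnan(value) else f"{value:.1f}"


def _jsonable(value):
    """Convert numpy scalars/arrays and NaN to JSON-safe python objects."""
    if isinstance(value, np.ndarray):
        return [_jsonable(v) for v in value.tolist()]
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        v = float(value)
        return None if math.isnan(v) else v
    return value


def write_report(
    rows: Sequence["TestResult"],
    out_dir: str | Path,
    funnel: Optional[Mapping[str, int]] = None,
) -> tuple[Path, Path]:
    """Write ``report.tsv`` (display rounding) and ``report.json`` (full
    precision plus the stage-count funnel).  Returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "report.tsv"
    json_path = out_dir / "report.json"

    with open(tsv_path, "w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for r in rows:
            t = r.tables
            cells = [
                r.rsid,
                result_marks(r),
                r.key.chrom,
                str(r.key.pos),
                r.key.ref,
                r.key.alt,
                r.gene,
                r.significance,
                str(int(t.allele_obs[0, 0])),
                str(int(t.allele_obs[0, 1])),
                _fmt_expected(t.allele_expected_focal[0]),
                _fmt_expected(t.allele_expected_focal[1]),
                f"{r.p_allele:.3f}",
                str(int(t.genotype_obs[0, 0])),
                str(int(t.genotype_obs[0, 1])),
                str(int(t.genotype_obs[0, 2])),
                _fmt_expected(t.genotype_expected_focal[0]),
                _fmt_expected(t.genotype_expected_focal[1]),
                _fmt_expected(t.genotype_expected_focal[2]),
                f"{r.p_genotype:.3f}",
            ]
            fh.write("\t".join(cells) + "\n")

    payload = {
        "funnel": dict(funnel) if funnel is not None else None,
        "results": [
            {
                "chrom": r.key.chrom,
                "pos": r.key.pos,
                "ref": r.key.ref,
                "alt": r.key.alt,
                "rsid": r.rsid,
                "gene": r.gene,
                "clinical_significance": r.significance,
                "clinically_significant": bool(r.clinically_significant),
                "marks": result_marks(r),
                "allele_observed": _jsonable(r.tables.allele_obs),
                "allele_expected_focal": _jsonable(r.tables.allele_expected_focal),
                "genotype_observed": _jsonable(r.tables.genotype_obs),
                "genotype_expected_focal": _jsonable(r.tables.genotype_expected_focal),
                "p_allele": _jsonable(r.p_allele),
                "p_genotype": _jsonable(r.p_genotype),
                "bh_allele": bool(r.bh_allele),
                "bh_genotype": bool(r.bh_genotype),
                "residuals_allele": _jsonable(r.residuals_allele),
                "residuals_genotype": _jsonable(r.residuals_genotype),
            }
            for r in rows
        ],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote report for %d variants to %s", len(rows), out_dir)
    return tsv_path, json_path
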