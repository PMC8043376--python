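"""Synthetic cohort generation with known ground truth.

Two generators are provided:

* :func:`simulate_cohort` draws a multi-population cohort under
  Hardy–Weinberg equilibrium: each variant gets a baseline ALT frequency p
  from a Beta distribution (rare-heavy by default, as in exome data), every
  label draws its genotype triplet multinomially from ((1−p)², 2p(1−p), p²),
  and the focal label may carry planted frequency deltas.  Per-(variant, label) missingness and a sparse clinical
  annotation overlay complete the picture.  The seed fully determines all
  outputs (byte-identical files).
* :func:`table2_fixture` emits a fixed 18-variant cohort whose focal-region
  genotype counts equal the published observed counts for the 18
  clinically annotated T2D SNPs analysed against the Arabian Peninsula, and
  whose pooled reference cohort is built at 250× the published expected
  proportions, so the integration pipeline reproduces the published
  expected cells (within print rounding) and funnel size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    AlleleInfo,
    ClinvarAnnotation,
    GenotypeCounts,
    ValidationError,
    VariantKey,
    write_clinvar_table,
    write_gme_table,
    write_gnomad_vcf,
)

logger = logging.getLogger(__name__)

#: Default catalogue layout: eight VCF populations and seven table regions.
GNOMAD_POPULATIONS = ("afr", "amr", "asj", "eas", "fin", "nfe", "sas", "oth")
GME_REGIONS = (
    "Northeast_Africa",
    "Northwest_Africa",
    "Arabian_Peninsula",
    "Israel",
    "Syrian_Desert",
    "Turkish_Peninsula",
    "Central_Asia",
)
DEFAULT_FOCAL = "Arabian_Peninsula"

#: Clinical-significance labels with sampling weights mirroring the
#: composition of the 18-SNP reference annotation table (7 benign, 3 likely
#: benign, 3 uncertain, 3 conflicting, 1 risk factor, 1 drug response).
DEFAULT_SIGNIFICANCE_POOL = (
    ("Benign", 7.0),
    ("Likely benign", 3.0),
    ("Uncertain significance", 3.0),
    ("Conflicting interpretations of pathogenicity", 3.0),
    ("risk factor", 1.0),
    ("drug response", 1.0),
)


@dataclass(frozen=True)
class LabelSpec:
    """One population/region: its name, catalogue and cohort size."""

    name: str
    catalogue: str  # "vcf" | "table"
    n_individuals: int

    def __post_init__(self) -> None:
        if self.catalogue not in ("vcf", "table"):
            raise ValidationError(f"catalogue must be 'vcf' or 'table', got {self.catalogue!r}")
        if self.n_individuals < 0:
            raise ValidationError("n_individuals must be non-negative")


def default_labels(
    focal_size: int = 171, others_size: int = 5000
) -> tuple[LabelSpec, ...]:
    """The standard 15-label layout: 8 VCF populations and 7 table regions,
    with the focal region at exome-study scale (171 individuals)."""
    labels = [LabelSpec(p, "vcf", others_size) for p in GNOMAD_POPULATIONS]
    for region in GME_REGIONS:
        size = focal_size if region == DEFAULT_FOCAL else others_size
        labels.append(LabelSpec(region, "table", size))
    return tuple(labels)


@dataclass
class SimConfig:
    """Full description of one simulated cohort; the seed fixes everything."""

    n_variants: int = 500
    labels: tuple[LabelSpec, ...] = field(default_factory=default_labels)
    focal: str = DEFAULT_FOCAL
    baseline_af_params: tuple[float, float] = (0.2, 2.0)
    planted: tuple[tuple[int, float], ...] = ()
    missing_rate: float = 0.02
    rare_fraction: float = 0.0
    annotation_fraction: float = 0.036
    significance_pool: tuple[tuple[str, float], ...] = DEFAULT_SIGNIFICANCE_POOL
    seed: int = 0

    def __post_init__(self) -> None:
        focal_labels = [l for l in self.labels if l.name == self.focal]
        if len(focal_labels) != 1:
            raise ValidationError(f"exactly one label must be named {self.focal!r}")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0 <= self.rare_fraction <= 1:
            raise ValidationError("rare_fraction must be in [0, 1]")
        if not 0 <= self.annotation_fraction <= 1:
            raise ValidationError("annotation_fraction must be in [0, 1]")
        for idx, _delta in self.planted:
            if not 0 <= idx < self.n_variants:
                raise ValidationError(f"planted index {idx} out of range")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated variant."""

    key: VariantKey
    rsid: str
    baseline_af: float
    focal_af: float
    planted: bool
    annotated: bool
    significance: Optional[str]


@dataclass(frozen=True)
class SimulatedCohort:
    """Paths of the four emitted files plus the in-memory truth records."""

    vcf: Path
    gme: Path
    clinvar: Path
    truth: Path
    records: tuple[TruthRecord, ...]


def _hw_probs(p: float) -> np.ndarray:
    """Hardy–Weinberg genotype proportions (homref, het, homalt)."""
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def simulate_cohort(config: SimConfig, out_dir: str | Path) -> SimulatedCohort:
    """Generate the VCF, genotype-table, annotation and truth files.

    Writes ``cohort.vcf``, ``cohort_gme.tsv``, ``cohort_clinvar.tsv`` and
    ``cohort_truth.tsv`` under ``out_dir``.  Running twice with the same
    config produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    # --- variant keys: unique (chrom, pos), coordinate-sorted ------------
    chroms = rng.integers(1, 23, size=n)
    seen: set[tuple[int, int]] = set()
    positions = np.empty(n, dtype=np.int64)
    for i in range(n):
        while True:
            pos = int(rng.integers(1, 50_000_000))
            if (int(chroms[i]), pos) not in seen:
                seen.add((int(chroms[i]), pos))
                positions[i] = pos
                break
    order = np.lexsort((positions, chroms))
    chroms, positions = chroms[order], positions[order]
    base_idx = rng.integers(0, 4, size=n)
    alt_offset = rng.integers(1, 4, size=n)
    bases = np.array(list("ACGT"))
    refs = bases[base_idx]
    alts = bases[(base_idx + alt_offset) % 4]
    keys = [
        VariantKey(str(int(c)), int(p), str(r), str(a))
        for c, p, r, a in zip(chroms, positions, refs, alts)
    ]
    rsids = [f"rs9{90000000 + i}" for i in range(n)]

    # --- allele frequencies ---------------------------------------------
    a, b = config.baseline_af_params
    baseline = rng.beta(a, b, size=n)
    n_rare = int(round(config.rare_fraction * n))
    rare_idx = rng.choice(n, size=n_rare, replace=False) if n_rare else np.array([], dtype=int)
    # rare variants sit well below the 0.01 filter threshold so that
    # finite-cohort sampling noise cannot push a label across it
    baseline[rare_idx] = rng.uniform(1e-4, 0.005, size=n_rare)
    focal_af = baseline.copy()
    planted_mask = np.zeros(n, dtype=bool)
    for idx, delta in config.planted:
        target = baseline[idx] + delta
        clipped = float(np.clip(target, 0.0, 1.0))
        if clipped != target:
            warnings.warn(
                f"planted delta at variant {idx} pushes the focal frequency to "
                f"{target:.3f}; clipped to {clipped:.3f}"
            )
        if clipped == baseline[idx]:
            raise ValidationError(f"planted delta at variant {idx} leaves the frequency unchanged")
        focal_af[idx] = clipped
        planted_mask[idx] = True

    # --- genotype draws and missingness ---------------------------------
    label_names = [l.name for l in config.labels]
    genotype: dict[str, list[Optional[GenotypeCounts]]] = {}
    missing = rng.random((n, len(config.labels))) < config.missing_rate
    for j, label in enumerate(config.labels):
        p_vec = focal_af if label.name == config.focal else baseline
        pvals = np.stack([_hw_probs(p) for p in p_vec])
        draws = rng.multinomial(label.n_individuals, pvals)
        genotype[label.name] = [
            None if missing[i, j] else GenotypeCounts(*map(int, draws[i]))
            for i in range(n)
        ]

    # --- annotation overlay ----------------------------------------------
    planted_idx = np.nonzero(planted_mask)[0]
    n_annotated = max(int(round(config.annotation_fraction * n)), len(planted_idx))
    remaining = np.setdiff1d(np.arange(n), planted_idx)
    extra = rng.choice(remaining, size=n_annotated - len(planted_idx), replace=False)
    annotated_idx = np.sort(np.concatenate([planted_idx, extra]))
    sig_labels = [s for s, _ in config.significance_pool]
    weights = np.array([w for _, w in config.significance_pool], dtype=float)
    weights /= weights.sum()
    significance = {
        int(i): str(rng.choice(sig_labels, p=weights)) for i in annotated_idx
    }

    # --- emit files -------------------------------------------------------
    vcf_labels = [l.name for l in config.labels if l.catalogue == "vcf"]
    table_labels = [l.name for l in config.labels if l.catalogue == "table"]
    vcf_records = []
    for i, key in enumerate(keys):
        infos: dict[str, Optional[AlleleInfo]] = {}
        for name in vcf_labels:
            gc = genotype[name][i]
            infos[name] = (
                None
                if gc is None
                else AlleleInfo(name, 2 * gc.n_individuals, gc.alt_alleles, gc.homalt)
            )
        vcf_records.append((key, rsids[i], infos))
    vcf_path = write_gnomad_vcf(out_dir / "cohort.vcf", vcf_records, vcf_labels)

    gme_records = [
        (key, {name: genotype[name][i] for name in table_labels})
        for i, key in enumerate(keys)
    ]
    gme_path = write_gme_table(out_dir / "cohort_gme.tsv", gme_records, table_labels)

    annotations = [
        ClinvarAnnotation(
            key=keys[i],
            rsid=rsids[i],
            gene=f"GENE{i:04d}",
            change=f"c.{i + 1}A>G",
            significance=significance[i],
        )
        for i in annotated_idx
    ]
    clinvar_path = write_clinvar_table(out_dir / "cohort_clinvar.tsv", annotations)

    records = tuple(
        TruthRecord(
            key=keys[i],
            rsid=rsids[i],
            baseline_af=float(baseline[i]),
            focal_af=float(focal_af[i]),
            planted=bool(planted_mask[i]),
            annotated=i in significance,
            significance=significance.get(i),
        )
        for i in range(n)
    )
    truth_path = out_dir / "cohort_truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\trsid\tbaseline_af\tfocal_af\tplanted\tannotated\tsignificance\n"
        )
        for rec in records:
            fh.write(
                "\t".join(
                    [
                        rec.key.chrom,
                        str(rec.key.pos),
                        rec.key.ref,
                        rec.key.alt,
                        rec.rsid,
                        f"{rec.baseline_af:.6f}",
                        f"{rec.focal_af:.6f}",
                        str(int(rec.planted)),
                        str(int(rec.annotated)),
                        rec.significance or ".",
                    ]
                )
                + "\n"
            )
    logger.info(
        "simulated cohort: %d variants, %d labels, %d annotated, %d planted (seed %d)",
        n,
        len(config.labels),
        len(annotated_idx),
        len(planted_idx),
        config.seed,
    )
    return SimulatedCohort(vcf_path, gme_path, clinvar_path, truth_path, records)


# ---------------------------------------------------------------------------
# Published 18-SNP reference table and its cohort fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceSnp:
    """Published counts and annotation for one of the 18 reference T2D SNPs.

    ``obs_*`` are the observed Arabian-Peninsula (focal) counts; ``exp_*``
    the printed expected focal counts (others'-pool proportions scaled to
    the focal total); ``p_*`` the printed exact-test p-values; ``marks``
    the printed legend (* clinically significant, # allele-test BH
    significant, § genotype-test BH significant).
    """

    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    change: str
    significance: str
    obs_allele: tuple[int, int]
    exp_allele: tuple[int, int]
    p_allele: float
    obs_genotype: tuple[int, int, int]
    exp_genotype: tuple[int, int, int]
    p_genotype: float
    marks: str


#: The published reference results, in the published row order.
REFERENCE_SNPS: tuple[ReferenceSnp, ...] = (
    ReferenceSnp("rs41265094", "2", 227661003, "C", "G", "IRS1",
                 "c.2452G>C (p.Gly818Arg)", "Likely benign",
                 (342, 0), (339, 3), 0.249, (171, 0, 0), (168, 3, 0), 0.248, ""),
    ReferenceSnp("rs1801276", "2", 227661921, "C", "G", "IRS1",
                 "c.1534G>C (p.Ala512Pro)", "Benign",
                 (342, 0), (337, 5), 0.062, (171, 0, 0), (166, 5, 0), 0.061, ""),
    ReferenceSnp("rs1044498", "6", 132172368, "A", "C", "ENPP1",
                 "c.517A>C (p.Lys173Gln)", "Benign",
                 (245, 97), (275, 67), 0.009, (92, 61, 18), (115, 45, 11), 0.037, "#"),
    ReferenceSnp("rs1799999", "7", 113518434, "C", "A", "PPP1R3A",
                 "c.2713G>T (p.Asp905Tyr)", "Uncertain significance",
                 (285, 57), (267, 75), 0.099, (117, 51, 3), (109, 49, 13), 0.039, ""),
    ReferenceSnp("rs13266634", "8", 118184783, "C", "T", "SLC30A8",
                 "c.973C>T (p.Arg325Trp)", "risk factor",
                 (298, 44), (244, 98), 0.000, (130, 38, 3), (88, 68, 15), 0.000, "*#§"),
    ReferenceSnp("rs5219", "11", 17409572, "T", "C", "KCNJ11",
                 "c.67A>G (p.Lys23Glu)", "drug response",
                 (70, 272), (123, 219), 0.000, (12, 46, 113), (23, 76, 72), 0.000, "*#§"),
    ReferenceSnp("rs566325901", "12", 121177120, "A", "G", "ACADS",
                 "c.1108A>G (p.Met370Val)", "Conflicting interpretations of pathogenicity",
                 (341, 1), (341, 1), 1.000, (170, 1, 0), (170, 1, 0), 1.000, ""),
    ReferenceSnp("rs121434581", "17", 7189048, "G", "A", "SLC2A4",
                 "c.1147G>A (p.Val383Ile)", "Uncertain significance",
                 (337, 5), (341, 1), 0.217, (167, 3, 1), (170, 1, 0), 0.371, ""),
    ReferenceSnp("rs1801483", "17", 79767715, "G", "A", "GCGR",
                 "c.118G>A (p.Gly40Ser)", "Benign",
                 (225, 15), (238, 2), 0.002, (106, 13, 1), (118, 2, 0), 0.003, "#§"),
    ReferenceSnp("rs41309435", "19", 40741862, "C", "A", "AKT2",
                 "c.1110G>T (p.Pro370 =)", "Benign",
                 (342, 0), (341, 1), 1.000, (171, 0, 0), (170, 1, 0), 1.000, ""),
    ReferenceSnp("rs776435289", "19", 40743996, "C", "G", "AKT2",
                 "c.711G>C p.Leu237 =)", "Likely benign",
                 (342, 0), (342, 0), 1.000, (171, 0, 0), (171, 0, 0), 1.000, ""),
    ReferenceSnp("rs199761368", "19", 40744854, "G", "A", "AKT2",
                 "c.666C>T (p.His222 =)", "Benign",
                 (341, 1), (341, 1), 1.000, (170, 1, 0), (170, 1, 0), 1.000, ""),
    ReferenceSnp("rs139125633", "19", 40761070, "G", "A", "AKT2",
                 "c.282C>T (p.Asp94 =)", "Likely benign",
                 (342, 0), (342, 0), 1.000, (171, 0, 0), (171, 0, 0), 1.000, ""),
    ReferenceSnp("rs35588791", "19", 40762915, "G", "A", "AKT2",
                 "c.93C>T (p.Ser31 =)", "Benign",
                 (342, 0), (341, 1), 1.000, (171, 0, 0), (170, 1, 0), 1.000, ""),
    ReferenceSnp("rs1799816", "19", 7125518, "C", "T", "INSR",
                 "c.3034G>A (p.Val1012Met)", "Conflicting interpretations of pathogenicity",
                 (335, 7), (339, 3), 0.340, (164, 7, 0), (168, 3, 0), 0.337, ""),
    ReferenceSnp("rs142204928", "20", 43043159, "G", "A", "HNF4A",
                 "c.439G>A (p.Val147Ile)", "Conflicting interpretations of pathogenicity",
                 (341, 1), (341, 1), 1.000, (170, 1, 0), (170, 1, 0), 1.000, ""),
    ReferenceSnp("rs147638455", "20", 43058267, "A", "G", "HNF4A",
                 "c.1321A>G (p.Ile441Val)", "Uncertain significance",
                 (331, 11), (342, 0), 0.001, (160, 11, 0), (171, 0, 0), 0.001, "#§"),
    ReferenceSnp("rs2076026", "20", 43942676, "T", "C", "RBPJL",
                 "c.759T>C (p.Ala253 =)", "Benign",
                 (329, 13), (311, 31), 0.007, (159, 11, 1), (143, 25, 3), 0.016, "#"),
)

#: Scale factor relating the printed expected focal proportions to the
#: fixture's pooled reference cohort.
FIXTURE_SCALE = 250

#: VCF population labels used by the fixture: the 250× reference cohort is
#: split into a hom-ref pool and an ALT-carrier pool so that every SNP
#: carries at least one label with ALT frequency > 0.01 and therefore
#: survives the common-variant filter, while the pooled expected
#: proportions stay at the printed values.
FIXTURE_POPULATIONS = ("pool_ref", "pool_alt")


def table2_fixture(out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write the 18-SNP reference cohort (VCF, genotype table, annotations).

    The focal region column holds the published observed genotype counts;
    the two VCF pools jointly hold ``FIXTURE_SCALE``× the published expected
    genotype proportions.  The two SNPs with zero ALT alleles everywhere
    receive a 2-individual hom-alt spike in the carrier pool (a < 0.02
    perturbation of the expected counts, far below print rounding) so that
    every SNP passes the common-variant filter, as in the published funnel.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_records = []
    gme_records = []
    annotations = []
    for snp in sorted(REFERENCE_SNPS, key=lambda s: (int(s.chrom), s.pos)):
        key = VariantKey(snp.chrom, snp.pos, snp.ref, snp.alt)
        e_hr, e_het, e_ha = snp.exp_genotype
        het_n = FIXTURE_SCALE * e_het
        ha_n = FIXTURE_SCALE * e_ha
        if het_n + ha_n == 0:
            ha_n = 2  # carrier-pool spike for the two all-REF SNPs
        ref_pool = AlleleInfo("pool_ref", 2 * FIXTURE_SCALE * e_hr, 0, 0)
        alt_pool = AlleleInfo("pool_alt", 2 * (het_n + ha_n), het_n + 2 * ha_n, ha_n)
        vcf_records.append((key, snp.rsid, {"pool_ref": ref_pool, "pool_alt": alt_pool}))
        gme_records.append((key, {DEFAULT_FOCAL: GenotypeCounts(*snp.obs_genotype)}))
        annotations.append(
            ClinvarAnnotation(key, snp.rsid, snp.gene, snp.change, snp.significance)
        )
    vcf_path = write_gnomad_vcf(out_dir / "fixture.vcf", vcf_records, FIXTURE_POPULATIONS)
    gme_path = write_gme_table(out_dir / "fixture_gme.tsv", gme_records, [DEFAULT_FOCAL])
    clinvar_path = write_clinvar_table(out_dir / "fixture_clinvar.tsv", annotations)
    return vcf_path, gme_path, clinvar_path
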