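"""End-to-end orchestration: read → merge → filter → annotate → test →
correct → residuals → report.

The stage order is fixed: coordinate merge, common-variant filter,
clinical-annotation intersection, focal-vs-rest aggregation with expected
counts, exact tests on the allele (2×2) and genotype (2×3) tables,
Benjamini–Hochberg correction applied to the two test families
independently, adjusted-residual analysis for the BH-significant variants
only, clinical flagging and report output.  Every stage logs its variant
count (the funnel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from .exact_stats import (
    TestResult,
    adjusted_residuals,
    benjamini_hochberg,
    fisher_exact_2x2,
    fisher_exact_2xk,
)
from .formats_io import (
    detect_populations,
    detect_regions,
    read_clinvar_table,
    read_gme_table,
    read_gnomad_vcf,
    write_report,
)
from .integration import (
    aggregate_focal_vs_others,
    filter_common,
    intersect_clinvar,
    merge_by_key,
)

logger = logging.getLogger(__name__)

DEFAULT_CLINICAL_LABELS = frozenset({"risk factor", "drug response"})


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    ``af_threshold`` is the common-variant cutoff (ALT frequency, strict
    inequality); ``af_filter_mode`` decides whether one (``any``) or every
    (``all``) non-absent label must exceed it; ``q`` is the BH false
    discovery level; ``clinical_labels`` are the significance strings that
    count as clinically significant.
    """

    vcf_path: Path
    gme_path: Path
    clinvar_path: Path
    output_dir: Optional[Path] = None
    focal: str = "Arabian_Peninsula"
    af_threshold: float = 0.01
    af_filter_mode: str = "any"
    q: float = 0.05
    clinical_labels: frozenset[str] = DEFAULT_CLINICAL_LABELS
    n_bins: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.af_threshold <= 0.5:
            raise ValueError(f"af_threshold must be in (0, 0.5], got {self.af_threshold}")
        if not 0 < self.q < 1:
            raise ValueError(f"q must be in (0, 1), got {self.q}")


@dataclass
class FunnelCounts:
    """Variant counts after each pipeline stage."""

    n_vcf: int = 0
    n_table: int = 0
    n_merged: int = 0
    n_common: int = 0
    n_annotated: int = 0
    n_tested: int = 0
    n_sig_allele: int = 0
    n_sig_genotype: int = 0
    n_clinical: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> tuple[list[TestResult], FunnelCounts]:
    """Execute the full analysis; returns results in coordinate order.

    An empty result at any stage completes with empty downstream output
    (logged) rather than raising.  When ``config.output_dir`` is set the
    report TSV/JSON and an audit TSV of the annotated variants are written
    there.
    """
    funnel = FunnelCounts()

    populations = detect_populations(config.vcf_path)
    regions = detect_regions(config.gme_path)
    vcf_reader = read_gnomad_vcf(config.vcf_path, populations)
    vcf_records = list(vcf_reader)
    funnel.n_vcf = len(vcf_records)
    logger.info(
        "VCF: %d usable records (%d multi-allelic, %d indel lines skipped)",
        vcf_reader.n_parsed,
        vcf_reader.n_skipped_multiallelic,
        vcf_reader.n_skipped_indel,
    )
    gme_records = list(read_gme_table(config.gme_path, regions))
    funnel.n_table = len(gme_records)

    merged = merge_by_key(vcf_records, gme_records)
    funnel.n_merged = len(merged)

    # A variant whose focal cell is absent cannot enter the focal-vs-rest
    # comparison at all; drop it before filtering so every annotated
    # variant downstream is testable.
    testable = [v for v in merged if v.counts.get(config.focal) is not None]
    if len(testable) < len(merged):
        logger.info("dropped %d variants with an absent focal cell", len(merged) - len(testable))

    common = filter_common(testable, threshold=config.af_threshold, mode=config.af_filter_mode)
    funnel.n_common = len(common)

    annotations = read_clinvar_table(config.clinvar_path)
    pairs = intersect_clinvar(common, annotations)
    funnel.n_annotated = len(pairs)
    if not pairs:
        logger.warning("no variants left after the clinical intersection")

    results: list[TestResult] = []
    for variant, annotation in pairs:
        tables = aggregate_focal_vs_others(variant, config.focal)
        results.append(
            TestResult(
                key=variant.key,
                rsid=annotation.rsid,
                tables=tables,
                p_allele=fisher_exact_2x2(tables.allele_obs),
                p_genotype=fisher_exact_2xk(tables.genotype_obs),
                significance=annotation.significance,
                clinically_significant=annotation.significance in config.clinical_labels,
                gene=annotation.gene,
            )
        )
    funnel.n_tested = len(results)

    # BH within each test family separately
    allele_flags = benjamini_hochberg([r.p_allele for r in results], q=config.q)
    genotype_flags = benjamini_hochberg([r.p_genotype for r in results], q=config.q)
    for r, fa, fg in zip(results, allele_flags, genotype_flags):
        r.bh_allele = fa
        r.bh_genotype = fg
        if fa or fg:  # residual analysis only for significant variants
            r.residuals_allele = adjusted_residuals(r.tables.allele_obs)
            r.residuals_genotype = adjusted_residuals(r.tables.genotype_obs)
    funnel.n_sig_allele = sum(allele_flags)
    funnel.n_sig_genotype = sum(genotype_flags)
    funnel.n_clinical = sum(r.clinically_significant for r in results)
    logger.info(
        "tested %d variants: %d allele-significant, %d genotype-significant, %d clinical",
        funnel.n_tested,
        funnel.n_sig_allele,
        funnel.n_sig_genotype,
        funnel.n_clinical,
    )

    if config.output_dir is not None:
        out_dir = Path(config.output_dir)
        write_report(results, out_dir, funnel=funnel.as_dict())
        _write_audit(pairs, out_dir, config.focal)
    return results, funnel


def _write_audit(pairs, out_dir: Path, focal: str) -> None:
    """Intermediate TSV of the merged, filtered, annotated variants."""
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "annotated_variants.tsv"
    labels: list[str] = []
    for variant, _ann in pairs:
        for label in variant.counts:
            if label not in labels:
                labels.append(label)
    with open(path, "w") as fh:
        fh.write("\t".join(["chrom", "pos", "ref", "alt", "rsid", "significance"] + labels) + "\n")
        for variant, ann in pairs:
            cells = [
                variant.key.chrom,
                str(variant.key.pos),
                variant.key.ref,
                variant.key.alt,
                ann.rsid,
                ann.significance,
            ]
            for label in labels:
                gc = variant.counts.get(label)
                cells.append("." if gc is None else f"{gc.homref},{gc.het},{gc.homalt}")
            fh.write("\t".join(cells) + "\n")
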