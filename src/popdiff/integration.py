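"""Catalogue integration: coordinate merge, common-variant filter,
clinical-annotation intersection and focal-vs-rest aggregation.

The merge is an inner join on the exact (chrom, pos, ref, alt) key — no
liftover, no strand flipping, no rsID matching.  Allele-level records from
the VCF side are converted to genotype counts at merge time so that every
label, whichever catalogue it came from, is represented the same way.

The common-variant filter keeps a variant when its ALT allele frequency
strictly exceeds the threshold (default 0.01) in at least one non-absent
label (``mode="any"``); ``mode="all"`` demands it in every non-absent
label.  Absent labels are real missingness: they contribute neither a
frequency to the filter nor counts to the pooled "others" row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .exact_stats import expected_counts
from .formats_io import (
    AlleleInfo,
    ClinvarAnnotation,
    GenotypeCounts,
    ValidationError,
    VariantKey,
    genotype_counts_from_allele_info,
)

logger = logging.getLogger(__name__)


@dataclass
class MergedVariant:
    """One variant present in both catalogues, all labels as genotype counts."""

    key: VariantKey
    counts: dict[str, Optional[GenotypeCounts]]
    source: dict[str, str]  # label -> "vcf" | "table"


@dataclass
class AggregatedTables:
    """Focal-vs-others observed tables plus expected focal rows.

    Rows are (focal, others); allele columns are (REF, ALT), genotype
    columns (REF/REF, REF/ALT, ALT/ALT).  Expected rows are NaN when every
    non-focal label is absent (no reference population to compare against).
    """

    allele_obs: np.ndarray
    genotype_obs: np.ndarray
    allele_expected_focal: np.ndarray
    genotype_expected_focal: np.ndarray


def _materialize_vcf(
    gnomad: Iterable[tuple[VariantKey, Mapping[str, Optional[AlleleInfo]]]],
) -> dict[VariantKey, dict[str, Optional[GenotypeCounts]]]:
    out: dict[VariantKey, dict[str, Optional[GenotypeCounts]]] = {}
    for key, infos in gnomad:
        if key in out:
            raise ValidationError(f"duplicate key {key} in the VCF catalogue")
        out[key] = {
            pop: (None if info is None else genotype_counts_from_allele_info(info))
            for pop, info in infos.items()
        }
    return out


def merge_by_key(
    gnomad: Iterable[tuple[VariantKey, Mapping[str, Optional[AlleleInfo]]]],
    gme: Iterable[tuple[VariantKey, Mapping[str, Optional[GenotypeCounts]]]],
) -> list[MergedVariant]:
    """Inner join of the two catalogues on the exact variant key.

    Returns variants in genomic-coordinate order.  Raises
    :class:`ValidationError` on a duplicate key within one catalogue or on a
    label used by both catalogues.
    """
    vcf_side = _materialize_vcf(gnomad)
    table_side: dict[VariantKey, dict[str, Optional[GenotypeCounts]]] = {}
    for key, counts in gme:
        if key in table_side:
            raise ValidationError(f"duplicate key {key} in the genotype-table catalogue")
        table_side[key] = dict(counts)

    merged: list[MergedVariant] = []
    for key in sorted(set(vcf_side) & set(table_side), key=lambda k: k.sort_key):
        vcf_counts = vcf_side[key]
        gme_counts = table_side[key]
        overlap = set(vcf_counts) & set(gme_counts)
        if overlap:
            raise ValidationError(
                f"label(s) {sorted(overlap)} appear in both catalogues; labels must be unique"
            )
        counts = {**vcf_counts, **gme_counts}
        source = {label: "vcf" for label in vcf_counts}
        source.update({label: "table" for label in gme_counts})
        merged.append(MergedVariant(key=key, counts=counts, source=source))
    logger.info(
        "merged catalogues: %d vcf x %d table -> %d shared variants",
        len(vcf_side),
        len(table_side),
        len(merged),
    )
    return merged


def filter_common(
    variants: Sequence[MergedVariant],
    threshold: float = 0.01,
    mode: str = "any",
) -> list[MergedVariant]:
    """Keep variants whose ALT frequency strictly exceeds ``threshold``.

    ``mode="any"`` requires one non-absent label above the threshold,
    ``mode="all"`` requires every non-absent label above it.  Labels with
    zero called individuals contribute no frequency.  Idempotent and
    order-independent.
    """
    if not 0 < threshold <= 0.5:
        raise ValidationError(f"threshold must be in (0, 0.5], got {threshold}")
    if mode not in ("any", "all"):
        raise ValidationError(f"mode must be 'any' or 'all', got {mode!r}")
    kept = []
    for variant in variants:
        freqs = [
            gc.alt_frequency
            for gc in variant.counts.values()
            if gc is not None and gc.alt_frequency is not None
        ]
        if not freqs:
            continue
        ok = any(f > threshold for f in freqs) if mode == "any" else all(
            f > threshold for f in freqs
        )
        if ok:
            kept.append(variant)
    logger.info("common-variant filter (>%g, mode=%s): %d -> %d", threshold, mode, len(variants), len(kept))
    return kept


def intersect_clinvar(
    variants: Sequence[MergedVariant],
    annotations: Sequence[ClinvarAnnotation],
) -> list[tuple[MergedVariant, ClinvarAnnotation]]:
    """Inner join with the annotation table on the variant key.

    One output row per matching annotation (duplicate annotations on a key
    yield duplicate rows), in variant-coordinate order.
    """
    by_key: dict[VariantKey, list[ClinvarAnnotation]] = {}
    for ann in annotations:
        by_key.setdefault(ann.key, []).append(ann)
    pairs = [
        (variant, ann)
        for variant in variants
        for ann in by_key.get(variant.key, [])
    ]
    logger.info(
        "clinical intersection: %d variants x %d annotations -> %d rows",
        len(variants),
        len(annotations),
        len(pairs),
    )
    return pairs


def aggregate_focal_vs_others(variant: MergedVariant, focal: str) -> AggregatedTables:
    """Build the focal-vs-rest 2×2 allele and 2×3 genotype tables.

    The others row sums genotype counts elementwise over every non-focal,
    non-absent label; allele rows are derived from the genotype rows.
    Expected focal rows use :func:`popdiff.exact_stats.expected_counts`; if
    every non-focal label is absent they are NaN and the downstream exact
    tests return p = 1 on the degenerate margin.
    """
    focal_gc = variant.counts.get(focal)
    if focal_gc is None:
        raise ValidationError(f"focal label {focal!r} is absent for variant {variant.key}")
    others = GenotypeCounts(0, 0, 0)
    for label, gc in variant.counts.items():
        if label == focal or gc is None:
            continue
        others = others + gc
    genotype_obs = np.array(
        [
            [focal_gc.homref, focal_gc.het, focal_gc.homalt],
            [others.homref, others.het, others.homalt],
        ],
        dtype=np.int64,
    )
    allele_obs = np.array(
        [
            [focal_gc.ref_alleles, focal_gc.alt_alleles],
            [others.ref_alleles, others.alt_alleles],
        ],
        dtype=np.int64,
    )
    if others.n_individuals > 0:
        allele_expected = expected_counts(allele_obs[0], allele_obs[1])
        genotype_expected = expected_counts(genotype_obs[0], genotype_obs[1])
    else:
        allele_expected = np.full(2, np.nan)
        genotype_expected = np.full(3, np.nan)
    return AggregatedTables(
        allele_obs=allele_obs,
        genotype_obs=genotype_obs,
        allele_expected_focal=allele_expected,
        genotype_expected_focal=genotype_expected,
    )
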