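"""Exact contingency statistics for focal-vs-rest frequency comparison.

For each variant the analysis forms a two-row table — focal population on
top, the pooled remaining populations below — with either two columns
(REF/ALT allele counts) or three (REF/REF, REF/ALT, ALT/ALT genotype
counts), and asks whether the focal row deviates from the pooled row.

Implemented here, from first principles:

* ``expected_counts`` — focal-row expectation under equal frequencies,
  E_j = (focal total) · others_j / (others total).
* ``fisher_exact_2x2`` / ``fisher_exact_2xk`` — exact conditional tests.
  The two-sided p-value follows the probability-mass convention: the sum of
  (multivariate) hypergeometric point probabilities of every table sharing
  the observed margins whose probability does not exceed the observed one
  (relative tie tolerance 1e-7, the convention used across scientific
  software).  Point probabilities are computed with log-gamma arithmetic so
  pooled-row totals up to ~10^6 are exact to double precision; the 2×K test
  enumerates the free cells of the smaller-total row.
* ``benjamini_hochberg`` — step-up false-discovery-rate control.
* ``adjusted_residuals`` — Haberman's adjusted standardized residuals,
  r_ij = (O−E) / sqrt(E (1 − row_i/N)(1 − col_j/N)), used post hoc to tell
  which cells drive a significant table; on a 2×2 table every squared
  residual equals the Pearson chi-square statistic.
* ``allele_frequency_spectrum`` — per-label ALT-frequency histograms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .formats_io import ValidationError, VariantKey

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .integration import AggregatedTables, MergedVariant

# Relative tolerance for "no more probable than observed" ties.
TIE_RELTOL = 1e-7
_LOG_TIE = math.log1p(TIE_RELTOL)


# ---------------------------------------------------------------------------
# Expected counts
# ---------------------------------------------------------------------------


def expected_counts(
    focal_row: Sequence[float], others_row: Sequence[float]
) -> np.ndarray:
    """Focal-row counts expected if the focal frequencies matched the rest.

    E_j = (sum of focal_row) · others_j / (sum of others_row).  The output
    sums to the focal total exactly (conservation).
    """
    f = np.asarray(focal_row, dtype=float)
    o = np.asarray(others_row, dtype=float)
    if f.shape != o.shape or f.ndim != 1:
        raise ValidationError("focal and others rows must be 1-D and the same length")
    if (f < 0).any() or (o < 0).any():
        raise ValidationError("counts must be non-negative")
    total = o.sum()
    if total <= 0:
        raise ValidationError("no reference population: others' counts are all zero")
    return f.sum() * o / total


# ---------------------------------------------------------------------------
# Exact tests
# ---------------------------------------------------------------------------


def _log_binom(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _validate_table(table, k_min: int) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < k_min:
        raise ValidationError(f"expected a 2xK table with K >= {k_min}, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValidationError("table cells must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValidationError("table cells must be non-negative")
    return t.astype(np.int64)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test on a 2×2 table (probability-mass method).

    Degenerate margins (any zero row or column total) give p = 1.
    """
    t = _validate_table(table, 2)
    if t.shape[1] != 2:
        raise ValidationError(f"fisher_exact_2x2 needs a 2x2 table, got shape {t.shape}")
    r1 = int(t[0].sum())
    r2 = int(t[1].sum())
    c1 = int(t[:, 0].sum())
    c2 = int(t[:, 1].sum())
    n = r1 + r2
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = _log_binom(c1, support) + _log_binom(c2, r1 - support) - _log_binom(n, r1)
    lp_obs = logpmf[int(t[0, 0]) - lo]
    selected = logpmf <= lp_obs + _LOG_TIE
    if selected.all():  # every table counted: total probability is exactly 1
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logpmf[selected]))))


def _enumerate_row_logpmf(cols: np.ndarray, n1: int) -> np.ndarray:
    """Log point probabilities of every first row x with sum n1, 0<=x<=cols.

    Enumerates feasible rows column by column, carrying partial sums and
    partial log binomial products as flat numpy arrays (no per-table Python
    loop), then conditions on the row margin via the C(N, n1) denominator.
    """
    k = len(cols)
    n_total = int(cols.sum())
    suffix = np.concatenate([np.cumsum(cols[::-1])[::-1], [0]])  # suffix[j] = sum cols[j:]
    sums = np.zeros(1, dtype=np.int64)
    logs = np.zeros(1, dtype=float)
    for j in range(k - 1):
        max_x = np.minimum(int(cols[j]), n1 - sums)
        min_x = np.maximum(0, n1 - sums - int(suffix[j + 1]))
        counts = max_x - min_x + 1
        keep = counts > 0
        sums, logs, min_x, counts = sums[keep], logs[keep], min_x[keep], counts[keep]
        total = int(counts.sum())
        owner = np.repeat(np.arange(len(sums)), counts)
        offsets = np.repeat(np.cumsum(counts) - counts, counts)
        xs = min_x[owner] + (np.arange(total) - offsets)
        logs = logs[owner] + _log_binom(int(cols[j]), xs)
        sums = sums[owner] + xs
    last = n1 - sums  # feasible by construction: 0 <= last <= cols[-1]
    logs = logs + _log_binom(int(cols[-1]), last) - _log_binom(n_total, n1)
    return logs


def fisher_exact_2xk(table) -> float:
    """Exact conditional test on a 2×K table (Freeman–Halton extension).

    Enumerates every table sharing the observed margins by iterating the
    K−1 free cells of the smaller-total row; sums the multivariate
    hypergeometric probabilities no greater than the observed one.  Reduces
    exactly to :func:`fisher_exact_2x2` at K = 2.
    """
    t = _validate_table(table, 2)
    r1 = int(t[0].sum())
    r2 = int(t[1].sum())
    if min(r1, r2) == 0:
        return 1.0
    cols = t.sum(axis=0)
    if (cols > 0).sum() <= 1:
        return 1.0
    # enumerate the smaller row for the smallest state space
    row = t[0] if r1 <= r2 else t[1]
    n1 = min(r1, r2)
    n_total = r1 + r2
    logs = _enumerate_row_logpmf(cols.astype(np.int64), n1)
    lp_obs = float(
        _log_binom(cols, row).sum() - _log_binom(n_total, n1)
    )
    selected = logs <= lp_obs + _LOG_TIE
    if selected.all():
        return 1.0
    return float(min(1.0, math.exp(logsumexp(logs[selected]))))


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues: Sequence[float], q: float = 0.05) -> list[bool]:
    """Benjamini–Hochberg step-up FDR control at level ``q``.

    Sort the m p-values ascending, find the largest k with
    p_(k) <= k·q/m, and reject every hypothesis with p <= p_(k).  Tied
    p-values therefore share a fate.  Flags are returned in input order.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValidationError(f"q must be in (0, 1), got {q}")
    m = p.size
    order = np.sort(p)
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= thresholds)[0]
    if passing.size == 0:
        return [False] * m
    cutoff = order[passing[-1]]
    return [bool(v) for v in (p <= cutoff)]


# ---------------------------------------------------------------------------
# Residual analysis
# ---------------------------------------------------------------------------


def independence_expected(observed) -> np.ndarray:
    """Expected cells under row/column independence: row_i · col_j / N."""
    o = np.asarray(observed, dtype=float)
    n = o.sum()
    if n <= 0:
        raise ValidationError("cannot form expected cells for an empty table")
    return np.outer(o.sum(axis=1), o.sum(axis=0)) / n


def adjusted_residuals(observed, expected_full=None) -> np.ndarray:
    """Haberman's adjusted standardized residuals for a 2×K table.

    r_ij = (O_ij − E_ij) / sqrt(E_ij (1 − row_i/N)(1 − col_j/N)), with the
    expected cells derived from the observed margins (computed here when
    ``expected_full`` is omitted).  Cells whose standard error vanishes
    (E = 0, or a margin equal to the grand total) are returned as NaN.
    """
    o = np.asarray(observed, dtype=float)
    e = independence_expected(o) if expected_full is None else np.asarray(expected_full, float)
    if o.shape != e.shape:
        raise ValidationError(f"observed {o.shape} and expected {e.shape} shapes differ")
    n = o.sum()
    rows = o.sum(axis=1) / n
    cols = o.sum(axis=0) / n
    var = e * (1.0 - rows)[:, None] * (1.0 - cols)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (o - e) / np.sqrt(var)
    r[var <= 0] = np.nan
    return r


# ---------------------------------------------------------------------------
# Per-variant test results
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """Everything the report prints for one tested variant."""

    __test__ = False  # not a pytest class, despite the name

    key: VariantKey
    rsid: str
    tables: "AggregatedTables"
    p_allele: float
    p_genotype: float
    bh_allele: bool = False
    bh_genotype: bool = False
    residuals_allele: Optional[np.ndarray] = None
    residuals_genotype: Optional[np.ndarray] = None
    significance: str = ""
    clinically_significant: bool = False
    gene: str = ""


# ---------------------------------------------------------------------------
# Allele-frequency spectra
# ---------------------------------------------------------------------------


@dataclass
class SpectrumHistogram:
    """ALT-frequency histograms, one per label (plus focal/others pools)."""

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)


def allele_frequency_spectrum(
    variants: Iterable["MergedVariant"],
    labels: Sequence[str],
    n_bins: int = 50,
    focal: Optional[str] = None,
) -> SpectrumHistogram:
    """Histogram ALT allele frequencies per label over [0, 1].

    Bins are half-open [lo, hi) with the last bin closed (numpy convention).
    A variant contributes to a label's histogram only when that label is
    non-absent with at least one called individual; when ``focal`` is given,
    two pooled histograms are added under the focal label's own name and
    ``"Others"`` (counts summed over all non-focal labels per variant).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    per_label: dict[str, list[float]] = {label: [] for label in labels}
    if focal is not None:
        per_label.setdefault(focal, [])
        per_label["Others"] = []
    for variant in variants:
        pooled = None
        for label in labels:
            gc = variant.counts.get(label)
            if gc is None:
                continue
            af = gc.alt_frequency
            if af is not None:
                per_label[label].append(af)
            if focal is not None and label != focal:
                pooled = gc if pooled is None else pooled + gc
        if focal is not None and pooled is not None and pooled.alt_frequency is not None:
            per_label["Others"].append(pooled.alt_frequency)
    counts = {
        label: np.histogram(values, bins=edges)[0] for label, values in per_label.items()
    }
    return SpectrumHistogram(bin_edges=edges, counts=counts)
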