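"""Isoform-balance classification from exon-level read counts.

Each RNA-seq library contributes unambiguous read counts for the two
alternative first exons (1A, 1B) and for a constitutive downstream exon
(exon 6) used as an internal control. Counts are normalised by exon
length to per-bp read densities (defaults 228, 245 and 426 bp). Under
the null of equal molar expression of the two isoforms, expected first-
exon counts are proportional to exon length: E_1A = N*228/473,
E_1B = N*245/473 with N = reads_1A + reads_1B, tested with a Pearson
chi-squared statistic on 1 degree of freedom and Bonferroni-corrected
across the library family (default m = 7). Libraries where one isoform
falls below a detection floor (default 2% of the exon-6 density) are
called single-isoform (B_only / A_only); the default floor (2%) is
low enough that a library with a clearly measurable minor isoform
(tens of reads) is tested rather than declared single-isoform.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ExonModel:
    len_1a: int = 228
    len_1b: int = 245
    len_6: int = 426

    def __post_init__(self) -> None:
        if min(self.len_1a, self.len_1b, self.len_6) < 1:
            raise ValueError("exon lengths must be >= 1")


class Category(str, enum.Enum):
    EQUAL = "A=B"
    B_OVER_A = "B>A"
    A_OVER_B = "A>B"
    B_ONLY = "B_only"
    A_ONLY = "A_only"
    UNDEFINED = "undefined"


@dataclass
class ExpressionCall:
    library_id: str
    category: Category
    chi2_stat: float
    p_raw: float
    p_adj: float
    fold_change_b_over_a: float
    consistency_deviation: float
    consistency_pass: bool


def normalize_counts(
    counts: tuple[int, int, int], model: ExonModel
) -> tuple[float, float, float]:
    """Per-bp read densities (reads / exon length) for exons 1A, 1B, 6."""
    a, b, six = counts
    if min(a, b, six) < 0:
        raise ValueError("read counts must be nonnegative")
    return a / model.len_1a, b / model.len_1b, six / model.len_6


def consistency_check(
    counts: tuple[int, int, int], model: ExonModel, tol: float = 0.2
) -> tuple[bool, float]:
    """Coherence of first-exon vs control-exon coverage.

    Densities are used so that, under equal per-transcript coverage
    (where the control exon's density is the mean of the two first-exon
    densities), the identity d_1A + d_1B = 2*d_6 holds; the relative
    deviation |d_1A + d_1B - 2*d_6| / (2*d_6) is compared to ``tol``.
    """
    d_a, d_b, d_6 = normalize_counts(counts, model)
    if d_6 == 0:
        return False, math.nan
    deviation = abs(d_a + d_b - 2.0 * d_6) / (2.0 * d_6)
    return deviation <= tol, deviation


def test_equal_expression(
    reads_1a: int, reads_1b: int, model: ExonModel
) -> tuple[float, float]:
    """Pearson chi-squared test of equal molar isoform expression.

    Expected counts under the null are length-proportional (not 50/50),
    consistent with the per-bp normalisation.
    """
    n = reads_1a + reads_1b
    if n < 1:
        raise ValueError("test undefined for zero total first-exon reads")
    total_len = model.len_1a + model.len_1b
    expected = [n * model.len_1a / total_len, n * model.len_1b / total_len]
    chi2, p = stats.chisquare([reads_1a, reads_1b], f_exp=expected)
    return float(chi2), float(p)


def classify_library(
    counts: tuple[int, int, int],
    model: ExonModel = ExonModel(),
    alpha: float = 0.05,
    m_tests: int = 7,
    floor: float = 0.02,
    tol: float = 0.2,
    library_id: str = "",
) -> ExpressionCall:
    """Classify one library's isoform balance.

    Bonferroni: p_adj = min(1, m_tests * p_raw). Detection floor:
    an isoform whose density is below ``floor`` times the exon-6
    density is treated as undetected.
    """
    a, b, six = counts
    ok, deviation = consistency_check(counts, model, tol)
    d_a, d_b, d_6 = normalize_counts(counts, model)
    fold = d_b / d_a if d_a > 0 else math.inf

    if a == 0 and b == 0:
        return ExpressionCall(
            library_id, Category.UNDEFINED, math.nan, math.nan, math.nan,
            math.nan, deviation, ok,
        )

    if d_6 > 0:
        a_detected = d_a >= floor * d_6
        b_detected = d_b >= floor * d_6
        if not a_detected and not b_detected:
            return ExpressionCall(
                library_id, Category.UNDEFINED, math.nan, math.nan, math.nan,
                fold, deviation, ok,
            )
        if not a_detected:
            return ExpressionCall(
                library_id, Category.B_ONLY, math.nan, math.nan, math.nan,
                fold, deviation, ok,
            )
        if not b_detected:
            return ExpressionCall(
                library_id, Category.A_ONLY, math.nan, math.nan, math.nan,
                fold, deviation, ok,
            )

    chi2, p_raw = test_equal_expression(a, b, model)
    p_adj = min(1.0, m_tests * p_raw)
    if p_adj >= alpha:
        category = Category.EQUAL
    elif d_b > d_a:
        category = Category.B_OVER_A
    else:
        category = Category.A_OVER_B
    return ExpressionCall(library_id, category, chi2, p_raw, p_adj, fold, deviation, ok)


def classify_table(
    counts: pd.DataFrame,
    model: ExonModel = ExonModel(),
    alpha: float = 0.05,
    m_tests: int | None = None,
    floor: float = 0.02,
    tol: float = 0.2,
) -> pd.DataFrame:
    """Classify every library of a counts table.

    ``counts`` needs columns library, exon_1A, exon_1B, exon_6.
    m_tests defaults to the number of libraries in the family.
    """
    if m_tests is None:
        m_tests = len(counts)
    rows = []
    for rec in counts.itertuples(index=False):
        call = classify_library(
            (int(rec.exon_1A), int(rec.exon_1B), int(rec.exon_6)),
            model=model, alpha=alpha, m_tests=m_tests, floor=floor, tol=tol,
            library_id=str(rec.library),
        )
        rows.append(
            {
                "library": call.library_id,
                "category": call.category.value,
                "chi2_stat": call.chi2_stat,
                "p_raw": call.p_raw,
                "p_adj": call.p_adj,
                "fold_change_B_over_A": call.fold_change_b_over_a,
                "consistency_deviation": call.consistency_deviation,
                "consistency_pass": call.consistency_pass,
            }
        )
    return pd.DataFrame(rows)
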