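"""Statistical stages: paired/Welch t, ANOVA+Tukey+Bonferroni, BH, ddCt.

All tests are two-tailed.  Tumour-vs-matched-normal comparisons use the
paired t on the differences; histotype-vs-histotype comparisons use the Welch
t on per-subject log2(tumour/NC) ratios, so each subject serves as its own
control.  Gene-wise screening uses one-way ANOVA with Tukey HSD between
tissue groups followed by a Bonferroni factor for the number of genes tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "log_ratio",
    "paired_t",
    "welch_t_logratio",
    "anova_tukey_bonferroni",
    "bh_adjust",
    "ddct_relative_expression",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    pvalue: float
    flag: str = ""  # degenerate-variance annotations


def log_ratio(tumour: np.ndarray, normal: np.ndarray, base: float = 2.0
              ) -> np.ndarray:
    """Per-subject log ratio of tumour to matched normal (base 2).

    Pairs with a missing (NaN) or non-positive member are dropped listwise
    with a logged count; the base cancels in any downstream t statistic.
    """
    tumour = np.asarray(tumour, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumour.shape != normal.shape:
        raise ValueError("tumour and normal vectors differ in length")
    ok = np.isfinite(tumour) & np.isfinite(normal) & (tumour > 0) & (normal > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("log_ratio: dropped %d incomplete/non-positive pairs",
                    dropped)
    return np.log(tumour[ok] / normal[ok]) / np.log(base)


def paired_t(tumour: np.ndarray, normal: np.ndarray) -> TestResult:
    """Two-sided paired Student's t on matched tumour/NC values."""
    tumour = np.asarray(tumour, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumour.shape != normal.shape:
        raise ValueError("paired_t requires equal-length vectors")
    ok = np.isfinite(tumour) & np.isfinite(normal)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("paired_t: dropped %d incomplete pairs", dropped)
    d = tumour[ok] - normal[ok]
    n = d.size
    if n < 2:
        raise ValueError("paired_t needs at least 2 complete pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            return TestResult(0.0, n - 1, 1.0, flag="zero-variance")
        return TestResult(np.inf * np.sign(d.mean()), n - 1, 0.0,
                          flag="zero-variance")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), n - 1)
    return TestResult(float(t), float(n - 1), float(min(p, 1.0)))


def welch_t_logratio(group_a: np.ndarray, group_b: np.ndarray) -> TestResult:
    """Two-sided Welch t with Satterthwaite df on two log-ratio samples."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_logratio needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, a.size + b.size - 2, 1.0,
                              flag="zero-variance")
        return TestResult(np.inf * np.sign(a.mean() - b.mean()),
                          a.size + b.size - 2, 0.0, flag="zero-variance")
    se2 = va / a.size + vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (
        (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    f_pvalue: float
    df_between: int
    df_within: int
    #: (group_i, group_j) -> (tukey p, bonferroni-adjusted p)
    comparisons: dict[tuple[str, str], tuple[float, float]]


def anova_tukey_bonferroni(
    groups: dict[str, np.ndarray],
    n_genes_tested: int = 1,
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise p values, Bonferroni-scaled.

    Tukey p values come from the studentized-range distribution at the ANOVA
    residual df (Tukey-Kramer for unequal group sizes); each is then
    multiplied by `n_genes_tested` and capped at 1 — the screening correction
    for testing many genes.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    if n_genes_tested < 1:
        raise ValueError("n_genes_tested must be >= 1")
    k = len(arrays)
    ns = {g: a.size for g, a in arrays.items()}
    N = sum(ns.values())
    means = {g: a.mean() for g, a in arrays.items()}
    sse = sum(((a - means[g]) ** 2).sum() for g, a in arrays.items())
    df_within = N - k
    mse = sse / df_within
    grand = sum(a.sum() for a in arrays.values()) / N
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in arrays)
    if mse == 0:
        f_stat, f_p = (0.0, 1.0) if ssb == 0 else (np.inf, 0.0)
    else:
        f_stat = (ssb / (k - 1)) / mse
        f_p = float(sps.f.sf(f_stat, k - 1, df_within))
    comparisons = {}
    names = list(arrays)
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = names[i], names[j]
            if mse == 0:
                p = 1.0 if means[gi] == means[gj] else 0.0
            else:
                q = abs(means[gi] - means[gj]) / np.sqrt(
                    mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj])
                )
                p = float(sps.studentized_range.sf(q, k, df_within))
            comparisons[(gi, gj)] = (p, min(p * n_genes_tested, 1.0))
    return AnovaTukeyResult(
        f_statistic=float(f_stat), f_pvalue=float(min(f_p, 1.0)),
        df_between=k - 1, df_within=df_within, comparisons=comparisons,
    )


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ddct_relative_expression(
    ct_gene: np.ndarray,
    ct_ref: np.ndarray,
    control_mean_dct: float,
) -> np.ndarray:
    """qPCR relative expression, 2^-(dCt - control dCt).

    ``dCt = Ct(gene) - Ct(reference)`` normalises against the reference gene
    (18S in the assays this mirrors); subtracting the control-group mean dCt
    and exponentiating gives fold expression relative to control.
    """
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    if not (np.all(np.isfinite(ct_gene)) and np.all(np.isfinite(ct_ref))
            and np.isfinite(control_mean_dct)):
        raise ValueError("Ct values must be finite")
    dct = ct_gene - ct_ref
    return 2.0 ** (-(dct - control_mean_dct))
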