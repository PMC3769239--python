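"""Two-group differential expression with robust FDR control.

The contrast is a plain two-group comparison (BEC vs LEC) per gene:

* Welch's two-tailed t-test (unequal variances, Satterthwaite degrees of
  freedom) on the observed values;
* log2 fold change as the difference of group means on the log2 scale, so
  "fold change >= 2" means ``|log2fc| >= 1``;
* multiple-testing correction by robust false-discovery-rate estimation:
  the null proportion is estimated as ``pi0 = min(1, 2 * mean(p))`` and
  q-values are the pi0-scaled step-up quantities
  ``q_(i) = min_{j>=i} pi0 * m * p_(j) / j`` (clipped to 1).  With
  ``pi0 = 1`` this reduces to Benjamini–Hochberg, which is exposed as an
  option for comparison.

A gene is called significant when ``|log2fc| >= log2(fc_threshold)`` and
``q <= q_threshold`` (both thresholds inclusive).  Genes with fewer than two
observed values in either group — or with two exactly constant groups at
different levels, where the statistic is undefined — are flagged untestable
and excluded from the FDR input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, SampleAnnotation, annotation_index
from .errors import ValidationError

__all__ = [
    "FdrResult",
    "welch_t",
    "log2_fold_change",
    "robust_fdr",
    "differential_table",
    "significant_genes",
]

TABLE_COLUMNS = [
    "mean_a",
    "mean_b",
    "log2fc",
    "t_stat",
    "df",
    "p",
    "q",
    "n_a",
    "n_b",
    "significant",
    "direction",
    "untestable",
]


@dataclass(frozen=True)
class FdrResult:
    """Estimated null proportion and per-test q-values (input order)."""

    pi0: float
    q_values: np.ndarray


def welch_t(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-tailed.

    Returns ``(t, df, p)``; each is ``nan`` when the statistic is undefined
    (a group with fewer than two observed values, or two constant groups at
    different levels).  Two identical constant groups give ``t=0, p=1``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        return (np.nan, np.nan, np.nan)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    diff = a.mean() - b.mean()
    if va == 0.0 and vb == 0.0:
        if diff == 0.0:
            return (0.0, float(na + nb - 2), 1.0)
        return (np.nan, np.nan, np.nan)
    se2 = va / na + vb / nb
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (float(t), float(df), float(p))


def log2_fold_change(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Difference of group means on the log2 scale (``nan`` if a group is
    empty).  A 2-fold change corresponds to an absolute value of 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        return np.nan
    return float(a.mean() - b.mean())


def robust_fdr(p_values: Iterable[float], pi0: float | None = None) -> FdrResult:
    """Robust FDR estimation: ``pi0 = min(1, 2 * mean(p))`` unless given,
    then pi0-scaled step-up q-values on the sorted p-values.

    ``pi0=1.0`` gives plain Benjamini–Hochberg.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("robust_fdr needs at least one p-value")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, 2.0 * float(p.mean()))
    elif not 0.0 <= pi0 <= 1.0:
        raise ValidationError(f"pi0 outside [0, 1]: {pi0}")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return FdrResult(pi0=float(pi0), q_values=q)


def _class_columns(
    matrix: ExpressionMatrix, annotations: Iterable[SampleAnnotation], cell_class: str
) -> list[str]:
    idx = annotation_index(annotations)
    cols = []
    for sid in matrix.sample_ids:
        ann = idx.get(sid)
        if ann is not None and ann.cell_class == cell_class:
            cols.append(sid)
    return cols


def differential_table(
    matrix: ExpressionMatrix,
    annotations: Iterable[SampleAnnotation],
    class_a: str = "BEC",
    class_b: str = "LEC",
    fc_threshold: float = 2.0,
    q_threshold: float = 0.05,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Per-gene Welch test + fold change + robust FDR for two cell classes.

    Returns a DataFrame indexed by gene id with columns ``mean_a, mean_b,
    log2fc, t_stat, df, p, q, n_a, n_b, significant, direction, untestable``.
    ``direction`` is ``A_UP``/``B_UP`` for significant genes, else ``NONE``.
    Untestable genes (fewer than two observed values in a group, or an
    undefined statistic) carry ``nan`` statistics and never enter the FDR.
    """
    annotations = list(annotations)
    cols_a = _class_columns(matrix, annotations, class_a)
    cols_b = _class_columns(matrix, annotations, class_b)
    if not cols_a:
        raise ValidationError(f"no samples of class {class_a!r} in matrix")
    if not cols_b:
        raise ValidationError(f"no samples of class {class_b!r} in matrix")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("need at least 2 samples per class")
    if fc_threshold < 1.0:
        raise ValidationError("fc_threshold must be >= 1")

    xa = matrix.values[cols_a].to_numpy(dtype=float)
    xb = matrix.values[cols_b].to_numpy(dtype=float)

    na = np.sum(~np.isnan(xa), axis=1)
    nb = np.sum(~np.isnan(xb), axis=1)
    with np.errstate(invalid="ignore"):
        mean_a = np.nansum(xa, axis=1) / np.where(na > 0, na, np.nan)
        mean_b = np.nansum(xb, axis=1) / np.where(nb > 0, nb, np.nan)
        var_a = np.full(len(na), np.nan)
        var_b = np.full(len(nb), np.nan)
        ok_a = na >= 2
        ok_b = nb >= 2
        var_a[ok_a] = np.nanvar(xa[ok_a], axis=1, ddof=1)
        var_b[ok_b] = np.nanvar(xb[ok_b], axis=1, ddof=1)

    log2fc = mean_a - mean_b
    diff = log2fc

    testable = ok_a & ok_b
    both_const = testable & (var_a == 0.0) & (var_b == 0.0)
    degenerate = both_const & (diff != 0.0)
    null_const = both_const & (diff == 0.0)
    testable = testable & ~degenerate

    t = np.full(len(na), np.nan)
    df = np.full(len(na), np.nan)
    p = np.full(len(na), np.nan)

    regular = testable & ~null_const
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_a / na + var_b / nb
        t_reg = diff / np.sqrt(se2)
        df_reg = se2**2 / (
            (var_a / na) ** 2 / np.maximum(na - 1, 1) + (var_b / nb) ** 2 / np.maximum(nb - 1, 1)
        )
    t[regular] = t_reg[regular]
    df[regular] = df_reg[regular]
    p[regular] = 2.0 * stats.t.sf(np.abs(t[regular]), df[regular])
    t[null_const] = 0.0
    df[null_const] = (na + nb - 2)[null_const]
    p[null_const] = 1.0

    q = np.full(len(na), np.nan)
    if testable.any():
        fdr = robust_fdr(p[testable], pi0=pi0)
        q[testable] = fdr.q_values

    log2_thresh = np.log2(fc_threshold)
    with np.errstate(invalid="ignore"):
        significant = testable & (np.abs(log2fc) >= log2_thresh) & (q <= q_threshold)
    direction = np.where(significant & (log2fc > 0), "A_UP", np.where(significant, "B_UP", "NONE"))

    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "t_stat": t,
            "df": df,
            "p": p,
            "q": q,
            "n_a": na,
            "n_b": nb,
            "significant": significant,
            "direction": direction,
            "untestable": ~testable,
        },
        index=matrix.values.index,
    )


def significant_genes(table: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Genes called significant, optionally restricted to one direction
    (``A_UP`` or ``B_UP``)."""
    mask = table["significant"]
    if direction is not None:
        mask = mask & (table["direction"] == direction)
    return set(table.index[mask])
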