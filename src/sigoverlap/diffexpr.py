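"""Differential-expression signature extraction from two-group matrices.

Per-gene statistics follow classic microarray practice: the fold change is the
anti-logged difference of group means on the log2 scale (2^(mean group1 -
mean group2), i.e. the young/disease value over the adult/normal value), and
the P-value is a two-sided Student's pooled-variance two-sample t-test.  A
gene enters the signature when its absolute display fold change strictly
exceeds ``fc_cut`` and its P-value is strictly below ``p_cut`` — no
multiple-testing correction is applied at extraction; corrections belong to
the overlap and enrichment layers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import GROUP1, GROUP2, ExpressionMatrix, GeneSignature

#: P-value reported for the degenerate zero-variance, unequal-means case.
P_DEGENERATE = float(np.finfo(float).tiny)


def group_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Vectorised fold change + pooled t-test P for every gene.

    Returns a frame with columns gene_id, linear_fc, p_value, degenerate.
    Degenerate genes have zero variance in both groups: P is 1 when the group
    means coincide and the smallest representable positive value otherwise.
    """
    i1 = matrix.group_columns(GROUP1)
    i2 = matrix.group_columns(GROUP2)
    n1, n2 = len(i1), len(i2)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 samples, got {n1} and {n2}")
    x1 = matrix.values[:, i1]
    x2 = matrix.values[:, i2]
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    delta = m1 - m2
    degenerate = sp2 == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, np.where(delta == 0.0, 1.0, P_DEGENERATE), p)
    return pd.DataFrame(
        {
            "gene_id": list(matrix.gene_ids),
            "linear_fc": np.exp2(delta),
            "p_value": p,
            "degenerate": degenerate,
        }
    )


def two_group_test(matrix: ExpressionMatrix, gene: str) -> tuple[float, float]:
    """(fold change, P-value) for one gene; see :func:`group_stats`."""
    if gene not in matrix.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    stats_df = group_stats(matrix)
    row = stats_df.loc[stats_df["gene_id"] == gene].iloc[0]
    return float(row["linear_fc"]), float(row["p_value"])


def extract_signature(
    matrix: ExpressionMatrix,
    fc_cut: float = 1.2,
    p_cut: float = 0.05,
    *,
    name: str = "",
) -> GeneSignature:
    """All genes with |display fold change| > fc_cut and P < p_cut.

    Both inequalities are strict, so a display fold change of exactly
    -1.2 (or +1.2) is excluded at the default cut.  The signature records the
    full measured background (every gene tested).
    """
    if fc_cut <= 1.0:
        raise ValueError(f"fc_cut must exceed 1, got {fc_cut}")
    if not 0.0 < p_cut < 1.0:
        raise ValueError(f"p_cut must be in (0, 1), got {p_cut}")
    st = group_stats(matrix)
    display = np.where(st["linear_fc"] >= 1.0, st["linear_fc"], 1.0 / st["linear_fc"])
    keep = (display > fc_cut) & (st["p_value"] < p_cut)
    sel = st[keep]
    return GeneSignature.from_stats(
        sel["gene_id"],
        sel["linear_fc"],
        sel["p_value"],
        background_n=matrix.n_genes,
        thresholds=(fc_cut, p_cut),
        background_genes=matrix.gene_ids,
        name=name,
    )
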