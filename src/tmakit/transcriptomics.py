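"""ssGSEA hypoxia scoring and hypoxia/CD8A correlation tables.

The single-sample enrichment score follows the weighted running-sum
definition: per sample, genes are ranked by expression and the score is
the sum over the ranked list of the difference between the weighted
in-set empirical CDF (weights = rank**alpha, default alpha = 0.75) and
the unweighted out-of-set ECDF.  Being rank-based, the score is
invariant to strictly monotone transforms of a sample's expression
values and to the row order of the matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, ParameterError

__all__ = ["GeneSet", "ssgsea_score", "hypoxia_cd8_table"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    """A named list of gene identifiers (e.g. an MSigDB hypoxia set)."""

    name: str
    genes: tuple

    def __post_init__(self):
        if len(self.genes) == 0:
            raise ParameterError("gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ParameterError("gene set members must be unique")


def _validate_expr(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ParameterError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.shape[1] < 1:
        raise ParameterError("expression matrix has no samples")


def ssgsea_score(
    expr: pd.DataFrame, geneset: GeneSet, alpha: float = 0.75
) -> pd.Series:
    """Per-sample single-sample GSEA score for one gene set.

    ``expr`` is genes × samples.  Gene-set members absent from the
    matrix are dropped (count logged).  Ties in expression receive
    average ranks for the weights and are walked in gene-identifier
    order, which makes the score independent of the matrix row order.
    """
    if alpha < 0:
        raise ParameterError("alpha must be nonnegative")
    _validate_expr(expr)
    present = [g for g in geneset.genes if g in expr.index]
    missing = len(geneset.genes) - len(present)
    if missing:
        log.info(
            "gene set %s: %d member(s) absent from the matrix and dropped",
            geneset.name,
            missing,
        )
    if not present:
        raise ParameterError(
            f"no member of gene set {geneset.name!r} is present in the matrix"
        )

    # canonical gene order so ties are broken identically for any row order
    expr_sorted = expr.sort_index(kind="stable")
    in_set = expr_sorted.index.isin(present)
    n_genes = len(expr_sorted)
    n_out = n_genes - in_set.sum()
    if n_out == 0:
        raise ParameterError("gene set covers the entire matrix; score undefined")

    values = expr_sorted.to_numpy(dtype=float)
    scores = np.empty(expr_sorted.shape[1])
    for s in range(values.shape[1]):
        r = stats.rankdata(values[:, s], method="average")  # 1 = lowest
        # walk genes in descending expression; ties in gene-id order
        order = np.lexsort((np.arange(n_genes), -r))
        inset_o = in_set[order]
        r_o = r[order]
        w = np.where(inset_o, r_o**alpha, 0.0)
        denom_in = w.sum()
        p_in = np.cumsum(w) / denom_in
        p_out = np.cumsum(~inset_o) / n_out
        scores[s] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=expr.columns, name=f"ssgsea_{geneset.name}")


def hypoxia_cd8_table(
    expr: pd.DataFrame,
    geneset: GeneSet,
    cd8a_gene: str = "CD8A",
    caix_gene: str = "CA9",
    alpha: float = 0.75,
    log_cd8a: bool = True,
    pseudocount: float = 1.0,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Correlation table: log CD8A vs hypoxia score and vs CAIX expression.

    Mirrors the two-row layout (hypoxia score first row, CAIX second)
    used to summarize the hypoxia/CD8 relationship per expression
    cohort.  When ``log_cd8a`` is set, CD8A expression is transformed as
    ln(value + pseudocount); leave it off for matrices already on a log
    scale.
    """
    from .association import spearman

    for g in (cd8a_gene, caix_gene):
        if g not in expr.index:
            raise ParameterError(f"gene {g!r} missing from the expression matrix")
    cd8a = expr.loc[cd8a_gene].to_numpy(dtype=float)
    if log_cd8a:
        shifted = cd8a + pseudocount
        if np.any(shifted <= 0):
            raise ParameterError(
                "log transform undefined: CD8A values + pseudocount must be positive"
            )
        cd8a = np.log(shifted)
    score = ssgsea_score(expr, geneset, alpha=alpha).to_numpy()
    caix = expr.loc[caix_gene].to_numpy(dtype=float)

    rows = []
    for label, other in (("hypoxia", score), ("CAIX", caix)):
        try:
            rho, p = spearman(cd8a, other)
        except DegenerateDataError:
            rho, p = math.nan, math.nan
        rows.append({"row": label, "cohort": cohort, "rho": rho, "p_value": p})
    return pd.DataFrame(rows).set_index("row")
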