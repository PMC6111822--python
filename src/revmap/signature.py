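"""Cross-cohort derivation of the co-regulated gene signature.

Patients in each cohort are split at the driver gene's median expression;
every other gene is scored by a Welch two-sample t statistic (high minus
low group) and ranked, most up-regulated first.  Genes that rank highly in
*every* cohort — scored by their worst (maximum) rank across cohorts, a
maximin rule — form the consistent co-regulated set; the driver plus the
top-k of these is the query signature for connectivity mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionCohort, GeneSignature
from .errors import EstimationError, InputError
from .survival import StratifiedCohort

__all__ = [
    "DifferentialRanking",
    "CorrelationResult",
    "rank_differential_genes",
    "consistent_top_genes",
    "pearson_correlation",
    "build_signature",
]


@dataclass
class DifferentialRanking:
    """Per-gene differential statistic and rank (1 = most up-regulated)."""

    table: pd.DataFrame  # index gene; columns statistic, rank, direction

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def rank_of(self, gene: str) -> int:
        return int(self.table.loc[gene, "rank"])

    def statistic_of(self, gene: str) -> float:
        return float(self.table.loc[gene, "statistic"])

    def top(self, k: int) -> List[str]:
        return list(self.table.sort_values("rank").index[:k])


def rank_differential_genes(
    cohort: ExpressionCohort,
    labels: StratifiedCohort,
    exclude: Sequence[str] = (),
    statistic: str = "welch_t",
) -> DifferentialRanking:
    """Rank genes by differential expression between high and low groups.

    The default statistic is the Welch unequal-variance t (high vs low);
    ``statistic="fold_change"`` ranks by the plain difference of group
    means instead.  Rank 1 is the largest statistic (most up-regulated in
    the high group); ties break lexicographically by gene symbol.  Genes
    in `exclude` (typically the driver itself) are omitted.
    """
    hi = labels.samples("high")
    lo = labels.samples("low")
    if len(hi) < 2 or len(lo) < 2:
        raise InputError(
            f"each group needs >= 2 samples (high={len(hi)}, low={len(lo)})"
        )
    values = cohort.values.drop(index=[g for g in exclude if g in cohort.values.index])
    a = values[hi].to_numpy()
    b = values[lo].to_numpy()
    if statistic == "welch_t":
        stat = sps.ttest_ind(a, b, axis=1, equal_var=False).statistic
        stat = np.nan_to_num(stat, nan=0.0)  # constant genes carry no signal
    elif statistic == "fold_change":
        stat = a.mean(axis=1) - b.mean(axis=1)
    else:
        raise InputError(f"unknown statistic {statistic!r}")
    # deterministic order: descending statistic, ties by gene symbol
    tab = pd.DataFrame({"gene": values.index, "statistic": stat})
    tab = tab.sort_values(["statistic", "gene"], ascending=[False, True])
    tab = tab.set_index("gene")
    tab["rank"] = np.arange(1, len(tab) + 1)
    tab["direction"] = np.where(tab["statistic"] >= 0, 1, -1)
    return DifferentialRanking(tab)


def consistent_top_genes(
    rankings: Sequence[DifferentialRanking], k: int
) -> List[str]:
    """The k genes ranked best in the worst of all cohorts.

    Consistency score of a gene = its maximum rank across the cohorts; the
    k genes with the smallest score win, ordered by score, with ties
    broken by the sum of ranks and then lexicographically.  Only genes
    present in every ranking are eligible.
    """
    if len(rankings) < 2:
        raise InputError("need at least two cohort rankings")
    if k < 1:
        raise InputError("k must be >= 1")
    shared = rankings[0].genes
    for r in rankings[1:]:
        shared = shared.intersection(r.genes)
    if len(shared) < k:
        raise InputError(
            f"only {len(shared)} genes shared between rankings, need {k}"
        )
    ranks = np.column_stack([
        r.table.loc[shared, "rank"].to_numpy() for r in rankings
    ])
    score = pd.DataFrame(
        {
            "worst": ranks.max(axis=1),
            "total": ranks.sum(axis=1),
        },
        index=shared,
    )
    score = (
        score.reset_index()
        .rename(columns={score.index.name or "index": "gene"})
        .sort_values(["worst", "total", "gene"])
    )
    return list(score["gene"].iloc[:k])


@dataclass(frozen=True)
class CorrelationResult:
    gene_a: str
    gene_b: str
    r: float
    p_two_sided: float
    n: int


def pearson_correlation(
    cohort: ExpressionCohort, gene_a: str, gene_b: str
) -> CorrelationResult:
    """Sample Pearson correlation between two genes across samples.

    The two-sided p-value comes from the t transform with n - 2 degrees
    of freedom (exact under bivariate normality).
    """
    xa = cohort.expression(gene_a).to_numpy()
    xb = cohort.expression(gene_b).to_numpy()
    n = len(xa)
    if n < 3:
        raise InputError(f"need >= 3 samples for a correlation, have {n}")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise EstimationError(
            f"zero variance in {gene_a if np.ptp(xa) == 0 else gene_b!r}"
        )
    res = sps.pearsonr(xa, xb)
    return CorrelationResult(
        gene_a=gene_a, gene_b=gene_b,
        r=float(res.statistic), p_two_sided=float(res.pvalue), n=n,
    )


def build_signature(
    driver: str,
    co_genes: Sequence[str],
    signs: Sequence[int] | None = None,
) -> GeneSignature:
    """Assemble the query signature: driver first, then the co-genes.

    All signs default to +1 (a co-up-regulated signature); explicit signs,
    one per signature gene including the driver, override this.
    """
    if driver in co_genes:
        raise InputError(f"driver {driver!r} must not appear in co_genes")
    genes = [driver, *co_genes]
    if len(set(genes)) != len(genes):
        raise InputError("duplicate genes in signature")
    if signs is None:
        signs = [1] * len(genes)
    if len(signs) != len(genes):
        raise InputError(
            f"got {len(signs)} signs for {len(genes)} genes"
        )
    return GeneSignature.from_pairs(zip(genes, signs))
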