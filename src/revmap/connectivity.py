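"""Signed-rank connectivity mapping with a perturbation-stability test.

A query signature (m signed genes) is scored against each drug's reference
profiles.  The connection strength of one profile is the signature-sign
weighted sum of the profile's signed ranks over the signature genes,

    c = sum_g sign(g) * rank(g),        c_norm = c / sum_{i=0}^{m-1} (G - i),

so c_norm = -1 marks a perfect reversal (the signature's up genes are the
profile's most down-regulated, and vice versa).  Under the null of a random
m-gene signature (genes drawn uniformly without replacement, signs +1) the
score has closed-form moments with a finite-population correction, giving a
standardized score z and, by the central limit theorem, a one-tailed normal
p-value; exact enumeration and seeded Monte-Carlo nulls are available as
verification modes.  Replicates of a drug are combined by summing scores
and null moments.

Significance is controlled at the family level by the expected-false-
positive rule: with N drugs screened, the per-drug threshold p < 1/N keeps
the expected number of falsely significant drugs at one, so with n
significant calls the overall false discovery rate is about 1/n.  The
perturbation-stability test re-scores each drug under all m leave-one-out
signatures; the fraction of them that remain significant (1.0 = all) guards
against calls driven by a single signature gene.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .datatypes import GeneSignature, ReferenceProfileSet, profile_to_array
from .errors import ConfigurationError, EstimationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectionResult",
    "ConnectivityRun",
    "connection_strength",
    "null_moments",
    "connection_pvalue",
    "score_drug",
    "perturbation_stability",
    "significance_threshold",
    "expected_false_discovery",
    "rank_drugs",
    "screen_library",
    "significance_plot",
]

EXACT_ENUMERATION_LIMIT = 100_000


@dataclass(frozen=True)
class ConnectionResult:
    """One row of the screen report (one drug)."""

    drug_id: str
    replicate_count: int
    c_total: float
    z: float
    p: float
    significance_mark: int
    perturb_stability: float | None = None


@dataclass(frozen=True)
class ConnectivityRun:
    """Settings of one connectivity screen.

    ``threshold`` is pinned to 1/N (N = drugs screened): the expected
    number of falsely significant drugs under the null is then one.
    ``tail="negative"`` screens for signature reversers (the inhibitory
    direction); ``"positive"`` for mimics.
    """

    N: int
    tail: str = "negative"
    null_method: str = "analytic"
    n_draws: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ConfigurationError("N must be >= 1")
        if self.tail not in ("negative", "positive"):
            raise ConfigurationError(f"tail must be negative/positive, got {self.tail!r}")
        if self.null_method not in ("analytic", "monte_carlo", "exact"):
            raise ConfigurationError(
                f"null_method must be analytic/monte_carlo/exact, got {self.null_method!r}"
            )
        if self.n_draws < 1:
            raise ConfigurationError("n_draws must be positive")

    @property
    def threshold(self) -> float:
        return significance_threshold(self.N)


def significance_threshold(N: int) -> float:
    """Per-drug p-value cut-off 1/N.

    Controls the expected number of falsely significant drugs at 1 when N
    drugs are screened.
    """
    if N < 1:
        raise InputError("N must be >= 1")
    return 1.0 / N


def expected_false_discovery(n_significant: int) -> float:
    """Approximate FDR of the significant set under the 1/N threshold.

    The threshold fixes the expected number of false positives at one, so
    with n significant drugs the false discovery rate is about
    1/n_significant.  Returns NaN (with a log message) when nothing was
    significant.
    """
    if n_significant < 0:
        raise InputError("n_significant must be non-negative")
    if n_significant == 0:
        logger.warning("no significant drugs; false discovery rate undefined")
        return math.nan
    return 1.0 / n_significant


def _as_rank_array(
    profile: Mapping[str, int] | np.ndarray, signature: GeneSignature,
    gene_universe: Sequence[str] | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Dense signed ranks plus the signature's gene indices."""
    if isinstance(profile, np.ndarray):
        if gene_universe is None:
            raise InputError("gene_universe required with an array profile")
        genes = list(gene_universe)
        ranks = np.asarray(profile, dtype=np.int64)
    else:
        ranks, genes = profile_to_array(profile)
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in signature.genes if g not in index]
    if missing:
        raise InputError(f"signature genes missing from profile: {missing}")
    idx = np.array([index[g] for g in signature.genes], dtype=np.int64)
    return ranks, idx


def _max_strength(G: int, m: int) -> float:
    # largest attainable |c|: the m top rank magnitudes G, G-1, ..., G-m+1
    return float(sum(G - i for i in range(m)))


def connection_strength(
    profile: Mapping[str, int] | np.ndarray,
    signature: GeneSignature,
    gene_universe: Sequence[str] | None = None,
) -> Tuple[float, float]:
    """Connection strength of one profile: (c, c normalized to [-1, 1])."""
    ranks, idx = _as_rank_array(profile, signature, gene_universe)
    c = float(np.dot(ranks[idx], signature.signs))
    return c, c / _max_strength(len(ranks), signature.m)


def null_moments(
    profile: Mapping[str, int] | np.ndarray, m: int,
    gene_universe: Sequence[str] | None = None,
) -> Tuple[float, float]:
    """Mean and variance of c under random m-gene signatures (signs +1).

    Sampling m of the G signed ranks without replacement gives
    mu = m * mean(ranks) and var = m * var(ranks) * (G - m)/(G - 1)
    (population variance with finite-population correction).
    """
    if isinstance(profile, np.ndarray):
        ranks = np.asarray(profile, dtype=float)
    else:
        ranks, _ = profile_to_array(profile)
        ranks = ranks.astype(float)
    G = len(ranks)
    if not 1 <= m <= G:
        raise InputError(f"m must lie in 1..{G}, got {m}")
    mu = m * ranks.mean()
    if m == G:
        return float(mu), 0.0
    var = m * ranks.var() * (G - m) / (G - 1)
    return float(mu), float(var)


def _null_draw_sums(
    ranks: np.ndarray, m: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Sums of m ranks drawn without replacement, n_draws times."""
    G = len(ranks)
    out = np.empty(n_draws, dtype=np.int64)
    chunk = max(1, min(n_draws, 20_000_000 // max(G, 1)))
    done = 0
    while done < n_draws:
        k = min(chunk, n_draws - done)
        keys = rng.random((k, G))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done:done + k] = ranks[idx].sum(axis=1)
        done += k
    return out


def _exact_null_sums(ranks: np.ndarray, m: int) -> np.ndarray:
    n_comb = math.comb(len(ranks), m)
    if n_comb > EXACT_ENUMERATION_LIMIT:
        raise InputError(
            f"exact enumeration needs C(G,m) <= {EXACT_ENUMERATION_LIMIT}, "
            f"got {n_comb}"
        )
    return np.array(
        [sum(c) for c in itertools.combinations(ranks.tolist(), m)], dtype=np.int64
    )


def connection_pvalue(
    c: float,
    profile: Mapping[str, int] | np.ndarray,
    m: int,
    run: ConnectivityRun,
    gene_universe: Sequence[str] | None = None,
) -> Tuple[float, float]:
    """Standardized score and one-tailed p-value for one profile.

    Analytic mode uses the normal approximation p = Phi(z) (negative
    tail) or 1 - Phi(z); ``monte_carlo`` draws seeded random signatures
    with the add-one estimator p = (1 + k)/(1 + n_draws) so p is never 0;
    ``exact`` enumerates all C(G, m) signatures when that count is at
    most 100 000.
    """
    mu, var = null_moments(profile, m, gene_universe)
    if var == 0:
        raise EstimationError("degenerate null: variance of c is zero")
    z = (c - mu) / math.sqrt(var)
    if isinstance(profile, np.ndarray):
        ranks = np.asarray(profile, dtype=np.int64)
    else:
        ranks, _ = profile_to_array(profile)
    if run.null_method == "analytic":
        p = sps.norm.cdf(z) if run.tail == "negative" else sps.norm.sf(z)
    elif run.null_method == "monte_carlo":
        rng = np.random.default_rng(run.seed)
        sums = _null_draw_sums(ranks, m, run.n_draws, rng)
        k = (sums <= c).sum() if run.tail == "negative" else (sums >= c).sum()
        p = (1.0 + k) / (1.0 + run.n_draws)
    else:  # exact
        sums = _exact_null_sums(ranks, m)
        k = (sums <= c).sum() if run.tail == "negative" else (sums >= c).sum()
        p = k / len(sums)
    return float(z), float(min(max(p, 0.0), 1.0))


def _combined_score(
    rep_ranks: np.ndarray, sig_idx: np.ndarray, signs: np.ndarray, m: int
) -> Tuple[float, float, float]:
    """(c_total, mu_total, var_total) over the replicates of one drug."""
    G = rep_ranks.shape[1]
    c_total = float((rep_ranks[:, sig_idx] * signs).sum())
    means = rep_ranks.mean(axis=1)
    variances = rep_ranks.var(axis=1)
    mu_total = float(m * means.sum())
    if m == G:
        var_total = 0.0
    else:
        var_total = float(m * (G - m) / (G - 1) * variances.sum())
    return c_total, mu_total, var_total


def score_drug(
    replicates: Sequence[Mapping[str, int]] | np.ndarray,
    signature: GeneSignature,
    run: ConnectivityRun,
    drug_id: str = "drug",
    gene_universe: Sequence[str] | None = None,
) -> ConnectionResult:
    """Score one drug: combined connection strength, z, p and mark.

    Replicate scores are summed and their null moments added (replicate
    draws independent), so n identical replicates gain a factor sqrt(n)
    in |z| over a single one.  ``significance_mark`` is 1 iff p < 1/N.
    """
    if isinstance(replicates, np.ndarray):
        if gene_universe is None:
            raise InputError("gene_universe required with array replicates")
        rep_ranks = np.atleast_2d(np.asarray(replicates, dtype=np.int64))
        genes = list(gene_universe)
    else:
        if len(replicates) < 1:
            raise InputError("drug needs at least one replicate profile")
        arrays = []
        genes = None
        for prof in replicates:
            arr, g = profile_to_array(prof, genes)
            genes = g
            arrays.append(arr)
        rep_ranks = np.vstack(arrays)
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in signature.genes if g not in index]
    if missing:
        raise InputError(f"signature genes missing from profiles: {missing}")
    sig_idx = np.array([index[g] for g in signature.genes], dtype=np.int64)

    c_total, mu, var = _combined_score(
        rep_ranks, sig_idx, signature.signs, signature.m
    )
    if var == 0:
        raise EstimationError("degenerate null: variance of combined c is zero")
    z = (c_total - mu) / math.sqrt(var)
    p = _combined_pvalue(c_total, z, rep_ranks, signature.m, run)
    return ConnectionResult(
        drug_id=drug_id,
        replicate_count=int(rep_ranks.shape[0]),
        c_total=c_total,
        z=float(z),
        p=float(p),
        significance_mark=int(p < run.threshold),
    )


def _combined_pvalue(
    c_total: float, z: float, rep_ranks: np.ndarray, m: int, run: ConnectivityRun
) -> float:
    """One-tailed p for the summed score across replicates."""
    if run.null_method == "analytic":
        return float(sps.norm.cdf(z) if run.tail == "negative" else sps.norm.sf(z))
    if run.null_method == "monte_carlo":
        rng = np.random.default_rng(run.seed)
        total = np.zeros(run.n_draws, dtype=np.int64)
        for r in range(rep_ranks.shape[0]):
            total += _null_draw_sums(rep_ranks[r], m, run.n_draws, rng)
        k = (total <= c_total).sum() if run.tail == "negative" else (total >= c_total).sum()
        return (1.0 + float(k)) / (1.0 + run.n_draws)
    # exact: only defined for a single replicate (enumeration of the sum
    # across replicates grows multiplicatively)
    if rep_ranks.shape[0] != 1:
        raise InputError("exact null is only available for single-replicate drugs")
    sums = _exact_null_sums(rep_ranks[0], m)
    k = (sums <= c_total).sum() if run.tail == "negative" else (sums >= c_total).sum()
    return float(k) / len(sums)


def perturbation_stability(
    replicates: Sequence[Mapping[str, int]] | np.ndarray,
    signature: GeneSignature,
    run: ConnectivityRun,
    gene_universe: Sequence[str] | None = None,
) -> float:
    """Fraction of leave-one-out signatures under which the drug stays
    significant.

    Each of the m genes is deleted in turn and the drug re-scored against
    the (m-1)-gene signature; the returned stability is
    (# perturbed signatures with p < 1/N) / m.  1.0 means the call does
    not hinge on any single signature gene.
    """
    if signature.m < 2:
        raise InputError("perturbation stability needs a signature with m >= 2")
    analytic_run = replace(run, null_method="analytic") \
        if run.null_method == "monte_carlo" else run
    n_pass = 0
    for g in signature.genes:
        res = score_drug(
            replicates, signature.drop(g), analytic_run,
            gene_universe=gene_universe,
        )
        n_pass += int(res.p < run.threshold)
    return n_pass / signature.m


def rank_drugs(results: Sequence[ConnectionResult]) -> List[ConnectionResult]:
    """Total ranking: ascending p, then descending stability, then
    ascending z (strongest reversal first), then drug id."""
    def key(r: ConnectionResult):
        stab = -1.0 if r.perturb_stability is None else r.perturb_stability
        return (r.p, -stab, r.z, r.drug_id)

    return sorted(results, key=key)


def screen_library(
    refset: ReferenceProfileSet,
    signature: GeneSignature,
    run: ConnectivityRun | None = None,
    with_stability: bool = True,
) -> List[ConnectionResult]:
    """Score every drug in the library and rank the results.

    When `run` is omitted, an analytic negative-tail run with N set to
    the library size (threshold 1/N) is used.  Stability is skipped with
    a warning for single-gene signatures.
    """
    if run is None:
        run = ConnectivityRun(N=refset.N)
    if run.N != refset.N:
        logger.warning(
            "run.N=%d differs from library size %d; threshold stays 1/%d",
            run.N, refset.N, run.N,
        )
    sig_idx = refset.gene_indices(signature.genes)
    signs = signature.signs
    do_stab = with_stability and signature.m >= 2
    if with_stability and not do_stab:
        logger.warning("signature has m=1; perturbation stability skipped")
    results = []
    for drug in refset.drug_ids:
        rep_ranks = refset.profiles[drug]
        c_total, mu, var = _combined_score(rep_ranks, sig_idx, signs, signature.m)
        z = (c_total - mu) / math.sqrt(var)
        p = _combined_pvalue(c_total, z, rep_ranks, signature.m, run)
        res = ConnectionResult(
            drug_id=drug,
            replicate_count=int(rep_ranks.shape[0]),
            c_total=c_total,
            z=float(z),
            p=float(p),
            significance_mark=int(p < run.threshold),
        )
        if do_stab:
            stab = _stability_fast(rep_ranks, sig_idx, signs, run) \
                if run.null_method != "exact" else perturbation_stability(
                    rep_ranks, signature, run, gene_universe=refset.gene_universe)
            res = replace(res, perturb_stability=stab)
        results.append(res)
    return rank_drugs(results)


def _stability_fast(
    rep_ranks: np.ndarray, sig_idx: np.ndarray, signs: np.ndarray,
    run: ConnectivityRun,
) -> float:
    """Analytic leave-one-out stability without re-walking the profiles.

    Deleting gene j changes the observed score by its own contribution and
    shrinks the null moments from m to m-1 genes; everything needed is a
    function of per-replicate rank means/variances already at hand.
    """
    m = len(sig_idx)
    G = rep_ranks.shape[1]
    contrib = (rep_ranks[:, sig_idx] * signs).sum(axis=0).astype(float)  # per gene j
    c_total = contrib.sum()
    means = rep_ranks.mean(axis=1)
    variances = rep_ranks.var(axis=1)
    mu_loo = (m - 1) * means.sum()
    var_loo = (m - 1) * (G - (m - 1)) / (G - 1) * variances.sum()
    if var_loo == 0:
        raise EstimationError("degenerate leave-one-out null")
    z_loo = (c_total - contrib - mu_loo) / math.sqrt(var_loo)
    p_loo = sps.norm.cdf(z_loo) if run.tail == "negative" else sps.norm.sf(z_loo)
    return float((p_loo < run.threshold).sum() / m)


def significance_plot(
    results: Sequence[ConnectionResult],
    threshold: float,
    out_path,
) -> float:
    """Scatter of drugs against -log10(p) with the significance line.

    Significant drugs with perturbation stability 1 are drawn green,
    other significant drugs red, the rest grey; the horizontal line sits
    at -log10(threshold) (3.16 for the 1/1432 threshold).  Returns the
    line's y-value.
    """
    if not results:
        raise InputError("no results to plot")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ranked = rank_drugs(results)
    y = -np.log10([r.p for r in ranked])
    x = np.arange(1, len(ranked) + 1)
    colors = [
        "green" if (r.significance_mark and (r.perturb_stability == 1.0))
        else ("red" if r.significance_mark else "0.6")
        for r in ranked
    ]
    line_y = -math.log10(threshold)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.scatter(x, y, s=12, c=colors, edgecolors="none")
    ax.axhline(line_y, color="blue", lw=1.2)
    ax.set_xlabel("drug rank")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    ax.set_title(f"connectivity screen (threshold line at {line_y:.2f})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return float(line_y)
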