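"""Synthetic expression cohorts and drug reference libraries.

The generator reproduces the statistical structure the downstream analysis
assumes, so every stage can be exercised without external downloads:

* a driver gene whose high expression shortens survival (exponential
  proportional hazards with log-hazard ``hazard_coef`` per unit of driver
  z-score);
* a block of positively co-regulated genes (the 15-gene analogue) with a
  tunable coupling to the driver;
* one negatively correlated gene (the E-cadherin analogue);
* right-censored survival by independent uniform thinning;
* a drug library of signed-rank profiles over a gene universe, with a
  chosen subset of drugs planted as signature reversers among null drugs.

Expression values are emitted on a log2-like intensity scale: standard
normal variation around a constant offset of 8.0, mimicking microarray
intensities.  All randomness flows from one integer seed per call, so the
same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort, GeneSignature, ReferenceProfileSet
from .errors import ConfigurationError, InputError

__all__ = [
    "CohortSimConfig",
    "RefSimConfig",
    "simulate_cohort",
    "simulate_reference_library",
    "INTENSITY_OFFSET",
]

#: constant added to every expression value to mimic log2 array intensities
INTENSITY_OFFSET = 8.0


@dataclass
class CohortSimConfig:
    """Parameters of one simulated expression cohort with survival."""

    n_samples: int = 200
    n_genes: int = 1000
    driver_gene: str = "SPP1"
    block_size: int = 15
    block_coupling: float = 0.7
    anti_gene_coupling: float = 0.4
    hazard_coef: float = 0.7
    baseline_hazard: float = 1.0 / 100.0  # per month
    censor_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if self.block_size < 0:
            raise ConfigurationError("block_size must be non-negative")
        if self.block_size + 2 > self.n_genes:
            raise ConfigurationError(
                "n_genes must be at least block_size + 2 (driver and anti-gene)"
            )
        for name in ("block_coupling", "anti_gene_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigurationError("censor_rate must lie in [0, 1)")

    @property
    def block_genes(self) -> List[str]:
        """Symbols of the positively co-regulated block."""
        return [f"CO{i + 1:03d}" for i in range(self.block_size)]

    @property
    def anti_gene(self) -> str:
        """Symbol of the negatively coupled gene (E-cadherin analogue)."""
        return "CDH1"

    @property
    def null_genes(self) -> List[str]:
        n_null = self.n_genes - self.block_size - 2
        return [f"G{i + 1:05d}" for i in range(n_null)]


def simulate_cohort(config: CohortSimConfig) -> ExpressionCohort:
    """Generate one expression cohort with right-censored survival.

    The driver's per-sample z-score drives both the co-regulated block
    (``block_coupling`` Pearson correlation in expectation), the anti-gene
    (negative coupling) and the exponential survival hazard
    ``baseline_hazard * exp(hazard_coef * z)``.  Each sample is
    independently censored with probability ``censor_rate`` at a uniform
    fraction of its event time.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    S = cfg.n_samples

    driver = rng.standard_normal(S)
    rows: Dict[str, np.ndarray] = {cfg.driver_gene: driver}
    c = cfg.block_coupling
    for g in cfg.block_genes:
        rows[g] = c * driver + np.sqrt(1.0 - c * c) * rng.standard_normal(S)
    a = cfg.anti_gene_coupling
    rows[cfg.anti_gene] = -a * driver + np.sqrt(1.0 - a * a) * rng.standard_normal(S)
    for g in cfg.null_genes:
        rows[g] = rng.standard_normal(S)

    sample_ids = [f"S{i + 1:04d}" for i in range(S)]
    values = pd.DataFrame(rows).T + INTENSITY_OFFSET
    values.columns = sample_ids
    values.index.name = "gene"

    hazard = cfg.baseline_hazard * np.exp(cfg.hazard_coef * driver)
    event_time = rng.exponential(1.0 / hazard)
    censored = rng.random(S) < cfg.censor_rate
    obs_time = np.where(censored, event_time * rng.random(S), event_time)
    obs_time = np.maximum(obs_time, 1e-9)  # clinical times must stay positive
    clinical = pd.DataFrame(
        {
            "time_months": obs_time,
            "event": np.where(censored, 0, 1).astype(int),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionCohort(values, clinical)


@dataclass
class RefSimConfig:
    """Parameters of one simulated drug reference library."""

    n_drugs: int = 100
    n_replicates_range: Tuple[int, int] = (1, 3)
    gene_universe: Sequence[str] = field(default_factory=list)
    planted_reversers: Sequence[str] = field(default_factory=list)
    reversal_strength: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1:
            raise ConfigurationError("n_drugs must be positive")
        lo, hi = self.n_replicates_range
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"n_replicates_range must satisfy 1 <= lo <= hi, got {(lo, hi)}"
            )
        if self.reversal_strength < 0:
            raise ConfigurationError("reversal_strength must be non-negative")
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise ConfigurationError("gene_universe contains duplicates")
        bad = set(self.planted_reversers) - set(self.drug_ids)
        if bad:
            raise ConfigurationError(
                f"planted_reversers not among generated drug ids: {sorted(bad)}"
            )

    @property
    def drug_ids(self) -> List[str]:
        return [f"drug{i + 1:04d}" for i in range(self.n_drugs)]


def _signed_ranks(stats: np.ndarray) -> np.ndarray:
    """Signed ranks of a differential-statistic vector.

    The gene with the largest |statistic| gets magnitude G; the sign is the
    statistic's sign (ties in sign at exactly zero are pushed to +1, a
    zero-probability event for continuous statistics).
    """
    G = stats.shape[-1]
    order = np.argsort(np.abs(stats), axis=-1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(1, G + 1), axis=-1)
    signs = np.where(stats >= 0, 1, -1)
    return (ranks * signs).astype(np.int64)


def simulate_reference_library(
    config: RefSimConfig, signature: GeneSignature
) -> Tuple[ReferenceProfileSet, Dict[str, bool]]:
    """Generate a drug library with planted signature reversers.

    Null drugs draw per-gene differential statistics i.i.d. standard
    normal per replicate; planted reversers additionally shift the
    signature genes' statistics by ``-reversal_strength * sign``, so a
    strong reverser pushes those genes to large negative signed ranks.
    Returns the library and a drug -> is_reverser truth mapping.
    """
    cfg = config
    universe = list(cfg.gene_universe)
    index = {g: i for i, g in enumerate(universe)}
    missing = [g for g in signature.genes if g not in index]
    if missing:
        raise InputError(f"signature genes absent from gene universe: {missing}")
    sig_idx = np.array([index[g] for g in signature.genes], dtype=np.int64)
    sig_signs = signature.signs

    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.n_replicates_range
    reversers = set(cfg.planted_reversers)
    profiles: Dict[str, np.ndarray] = {}
    truth: Dict[str, bool] = {}
    for drug in cfg.drug_ids:
        n_rep = int(rng.integers(lo, hi + 1))
        stats = rng.standard_normal((n_rep, len(universe)))
        if drug in reversers:
            stats[:, sig_idx] -= cfg.reversal_strength * sig_signs
        profiles[drug] = _signed_ranks(stats)
        truth[drug] = drug in reversers
    return ReferenceProfileSet(universe, profiles), truth


def write_truth_labels(truth: Dict[str, bool], path) -> None:
    """Write drug -> reverser truth labels as a two-column TSV."""
    pd.DataFrame(
        {"drug_id": sorted(truth), "is_reverser": [int(truth[d]) for d in sorted(truth)]}
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
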