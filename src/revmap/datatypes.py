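"""In-memory containers for the pipeline.

An :class:`ExpressionCohort` pairs a genes x samples log2-intensity matrix
with per-sample right-censored survival annotations.  A
:class:`GeneSignature` is the ordered, signed gene set used as the query in
connectivity mapping.  A :class:`ReferenceProfileSet` holds the drug
reference library: for every drug, one or more replicate profiles, each a
complete signed ranking of the gene universe (the gene with the strongest
differential response after treatment carries magnitude G, the weakest
magnitude 1; the sign encodes up/down regulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import FormatError, InputError

__all__ = ["ExpressionCohort", "GeneSignature", "ReferenceProfileSet"]


@dataclass
class ExpressionCohort:
    """Gene x sample expression matrix plus survival annotations.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (unique symbols), samples in columns (unique ids),
        finite log2-scale intensities.
    clinical : pandas.DataFrame
        Indexed by sample id, with columns ``time_months`` (> 0) and
        ``event`` (1 = death observed, 0 = censored).  Every clinical
        record must correspond to a sample column.
    """

    values: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite or non-numeric values")
        missing = self.clinical.index.difference(self.values.columns)
        if len(missing):
            raise InputError(
                f"clinical records for samples absent from the matrix: {list(missing[:5])}"
            )
        for col in ("time_months", "event"):
            if col not in self.clinical.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if (self.clinical["time_months"] <= 0).any():
            raise InputError("survival times must be positive")
        if not self.clinical["event"].isin((0, 1)).all():
            raise InputError("event indicator must be 0 or 1")

    @property
    def gene_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def expression(self, gene: str) -> pd.Series:
        """Expression of one gene across samples."""
        if gene not in self.values.index:
            raise InputError(f"gene {gene!r} not in cohort")
        return self.values.loc[gene]


@dataclass(frozen=True)
class GeneSignature:
    """Ordered set of (gene, sign) pairs; the connectivity-mapping query.

    Signs are +1 for genes up-regulated in the condition of interest and
    -1 for down-regulated genes.  The screen of interest here queries a
    16-gene all-up-regulated signature (a driver plus 15 co-regulated
    genes), so +1 is the default sign everywhere.
    """

    entries: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise InputError("signature must contain at least one gene")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            seen: set = set()
            dups = [g for g in genes if g in seen or seen.add(g)]
            raise InputError(f"duplicate genes in signature: {dups}")
        for g, s in self.entries:
            if s not in (1, -1):
                raise InputError(f"sign for {g!r} must be +1 or -1, got {s!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, int]]) -> "GeneSignature":
        return cls(tuple((str(g), int(s)) for g, s in pairs))

    @classmethod
    def from_genes(cls, genes: Iterable[str], sign: int = 1) -> "GeneSignature":
        return cls(tuple((str(g), sign) for g in genes))

    @property
    def m(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> Tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def signs(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=np.int64)

    def negated(self) -> "GeneSignature":
        """The sign-flipped signature (every +1 becomes -1 and vice versa)."""
        return GeneSignature(tuple((g, -s) for g, s in self.entries))

    def drop(self, gene: str) -> "GeneSignature":
        """Leave-one-out copy with `gene` removed."""
        kept = tuple((g, s) for g, s in self.entries if g != gene)
        if len(kept) == len(self.entries):
            raise InputError(f"gene {gene!r} not in signature")
        return GeneSignature(kept)


def _validate_profile(ranks: np.ndarray, G: int, label: str) -> None:
    mags = np.sort(np.abs(ranks))
    if not np.array_equal(mags, np.arange(1, G + 1)):
        raise FormatError(
            f"profile {label}: |rank| values are not a permutation of 1..{G}"
        )


@dataclass
class ReferenceProfileSet:
    """Drug reference library of signed-rank profiles.

    Profiles are stored densely: per drug a ``(replicates, G)`` integer
    array of signed ranks aligned to ``gene_universe`` order, with rank
    magnitudes a permutation of ``1..G`` in every replicate.
    """

    gene_universe: List[str]
    profiles: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_universe)) != len(self.gene_universe):
            raise FormatError("gene universe contains duplicate symbols")
        G = self.G
        for drug, arr in self.profiles.items():
            arr = np.asarray(arr, dtype=np.int64)
            if arr.ndim != 2 or arr.shape[1] != G:
                raise FormatError(
                    f"profiles for {drug!r} must be (replicates, {G}), got {arr.shape}"
                )
            if arr.shape[0] < 1:
                raise FormatError(f"drug {drug!r} has no replicates")
            for r in range(arr.shape[0]):
                _validate_profile(arr[r], G, f"{drug}/rep{r + 1}")
            self.profiles[drug] = arr
        self._index = {g: i for i, g in enumerate(self.gene_universe)}

    @property
    def G(self) -> int:
        return len(self.gene_universe)

    @property
    def N(self) -> int:
        """Number of drugs in the library."""
        return len(self.profiles)

    @property
    def drug_ids(self) -> List[str]:
        return sorted(self.profiles)

    def gene_indices(self, genes: Sequence[str]) -> np.ndarray:
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise InputError(f"genes absent from reference universe: {missing}")
        return np.array([self._index[g] for g in genes], dtype=np.int64)

    def replicate_count(self, drug: str) -> int:
        return int(self.profiles[drug].shape[0])

    def profile_mapping(self, drug: str, replicate: int = 0) -> Dict[str, int]:
        """One replicate profile as a gene -> signed-rank mapping."""
        arr = self.profiles[drug][replicate]
        return {g: int(r) for g, r in zip(self.gene_universe, arr)}


def profile_to_array(
    profile: Mapping[str, int], gene_universe: Sequence[str] | None = None
) -> Tuple[np.ndarray, List[str]]:
    """Convert a gene -> signed-rank mapping to a dense array.

    Returns the array plus the gene order used; validates the permutation
    invariant on the magnitudes.
    """
    genes = list(gene_universe) if gene_universe is not None else sorted(profile)
    missing = [g for g in genes if g not in profile]
    if missing:
        raise InputError(f"profile missing genes: {missing[:5]}")
    ranks = np.array([profile[g] for g in genes], dtype=np.int64)
    _validate_profile(ranks, len(genes), "<mapping>")
    return ranks, genes
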