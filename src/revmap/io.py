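"""Readers and writers for the pipeline's file shapes.

Formats (all UTF-8, tab-separated, LF line endings):

* expression matrix — first column probe/gene id, header row of sample ids;
  a simplified series-matrix dialect with no metadata block
* clinical table — columns ``sample_id``, ``time_months``, ``event``
* signature — GMT (name, description, gene tokens); a gene token may carry
  an optional ``|+1`` / ``|-1`` suffix encoding the regulation sign
* reference profiles — long table ``drug_id, replicate_index, gene,
  signed_rank``
* results table — the screen report with columns Compound, Replicate,
  P value, zscore, Significance_mark, Perturb_stability

All readers reject malformed input rather than silently repairing it, and
every writer round-trips losslessly through its paired reader.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionCohort, GeneSignature, ReferenceProfileSet
from .errors import FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_tsv",
    "write_clinical_tsv",
    "collapse_probes",
    "read_signature_gmt",
    "write_signature_gmt",
    "read_reference_profiles",
    "write_reference_profiles",
    "write_results_table",
    "read_results_table",
]


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate sample ids {dups[:5]}")
    try:
        num = df.astype(float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, val in enumerate(df[col]):
                try:
                    float(val)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric expression value {val!r} at "
                        f"row {df.index[i]!r}, column {col!r}"
                    ) from None
        raise  # pragma: no cover - unreachable
    return num


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical table (sample_id, time_months, event)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time_months", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: clinical table missing column {col!r}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in clinical table")
    return df.set_index("sample_id")


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    out = clinical.reset_index()
    out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression_tsv(path, clinical_path) -> ExpressionCohort:
    """Load an expression matrix and its clinical annotations.

    Samples are restricted to the intersection of the two files, keeping
    the order of the expression header; the number of dropped samples is
    logged.
    """
    values = _read_matrix(path)
    if values.index.duplicated().any():
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(
            f"{path}: duplicate gene/probe ids {dups[:5]}; collapse probes first"
        )
    clinical = read_clinical_tsv(clinical_path)
    shared = [s for s in values.columns if s in clinical.index]
    if not shared:
        raise InputError(
            f"no samples shared between {path} and {clinical_path}"
        )
    dropped_expr = values.shape[1] - len(shared)
    dropped_clin = clinical.shape[0] - len(shared)
    if dropped_expr or dropped_clin:
        logger.warning(
            "sample intersection: kept %d; dropped %d expression-only and "
            "%d clinical-only samples",
            len(shared), dropped_expr, dropped_clin,
        )
    logger.info("loaded cohort: %d genes x %d samples", values.shape[0], len(shared))
    return ExpressionCohort(values[shared], clinical.loc[shared])


def write_expression_tsv(values: pd.DataFrame, path) -> None:
    out = values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n", float_format="%.6f")


def collapse_probes(
    raw: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the highest mean expression across samples
    is kept (ties broken by the lexicographically smaller probe id);
    unmapped probes are dropped and counted in the log.
    """
    if not probe_to_gene:
        raise InputError("probe-to-gene mapping is empty")
    mapped = raw.index.to_series().map(dict(probe_to_gene))
    n_unmapped = int(mapped.isna().sum())
    if n_unmapped:
        logger.warning("dropping %d unmapped probes", n_unmapped)
    kept = raw.loc[mapped.notna()]
    genes = mapped.dropna()
    means = kept.mean(axis=1)
    # stable choice: highest mean, then smallest probe id
    order = pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "mean": means.to_numpy(),
            "probe": kept.index.to_numpy(),
        }
    )
    order = order.sort_values(["gene", "mean", "probe"], ascending=[True, False, True])
    chosen = order.drop_duplicates("gene", keep="first")
    out = kept.loc[chosen["probe"]]
    out.index = pd.Index(chosen["gene"].to_numpy(), name="gene")
    return out.sort_index()


_SIGN_SUFFIXES = {"+1": 1, "-1": -1, "1": 1}


def read_signature_gmt(path) -> GeneSignature:
    """Read the first gene set of a GMT file as a signed signature."""
    with open(path, encoding="utf-8") as fh:
        line = fh.readline().rstrip("\n")
    fields = line.split("\t")
    if len(fields) < 3:
        raise FormatError(f"{path}: GMT line needs name, description and >= 1 gene")
    tokens = [t for t in fields[2:] if t]
    if not tokens:
        raise FormatError(f"{path}: empty gene list")
    pairs = []
    for tok in tokens:
        if "|" in tok:
            gene, suffix = tok.rsplit("|", 1)
            if suffix not in _SIGN_SUFFIXES:
                raise FormatError(f"{path}: bad sign suffix in token {tok!r}")
            pairs.append((gene, _SIGN_SUFFIXES[suffix]))
        else:
            pairs.append((tok, 1))
    genes = [g for g, _ in pairs]
    if len(set(genes)) != len(genes):
        raise FormatError(f"{path}: duplicate genes in signature")
    return GeneSignature.from_pairs(pairs)


def write_signature_gmt(
    signature: GeneSignature, path, name: str = "signature", description: str = ""
) -> None:
    tokens = [
        g if s == 1 else f"{g}|{s:+d}" for g, s in signature.entries
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join([name, description, *tokens]) + "\n")


def read_reference_profiles(path) -> ReferenceProfileSet:
    """Read a long-format reference profile table.

    Validates that every (drug, replicate) profile covers the full gene
    universe exactly once and that rank magnitudes form a permutation.
    """
    df = pd.read_csv(
        path, sep="\t",
        dtype={"drug_id": str, "replicate_index": int, "gene": str,
               "signed_rank": int},
    )
    for col in ("drug_id", "replicate_index", "gene", "signed_rank"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if df.duplicated(["drug_id", "replicate_index", "gene"]).any():
        bad = df[df.duplicated(["drug_id", "replicate_index", "gene"])].iloc[0]
        raise FormatError(
            f"{path}: duplicate entry for drug {bad['drug_id']!r} replicate "
            f"{bad['replicate_index']} gene {bad['gene']!r}"
        )
    universe = sorted(df["gene"].unique())
    index = {g: i for i, g in enumerate(universe)}
    G = len(universe)
    profiles: Dict[str, np.ndarray] = {}
    for drug, sub in df.groupby("drug_id", sort=True):
        reps = []
        for rep, prof in sub.groupby("replicate_index", sort=True):
            if len(prof) != G:
                missing = set(universe) - set(prof["gene"])
                raise FormatError(
                    f"{path}: profile {drug}/rep{rep} missing genes "
                    f"{sorted(missing)[:5]}"
                )
            ranks = np.zeros(G, dtype=np.int64)
            ranks[[index[g] for g in prof["gene"]]] = prof["signed_rank"].to_numpy()
            if not np.array_equal(np.sort(np.abs(ranks)), np.arange(1, G + 1)):
                raise FormatError(
                    f"{path}: profile {drug}/rep{rep}: |ranks| are not a "
                    f"permutation of 1..{G}"
                )
            reps.append(ranks)
        profiles[str(drug)] = np.vstack(reps)
    return ReferenceProfileSet(universe, profiles)


def write_reference_profiles(refset: ReferenceProfileSet, path) -> None:
    rows = []
    for drug in refset.drug_ids:
        arr = refset.profiles[drug]
        for rep in range(arr.shape[0]):
            for g, r in zip(refset.gene_universe, arr[rep]):
                rows.append((drug, rep + 1, g, int(r)))
    pd.DataFrame(
        rows, columns=["drug_id", "replicate_index", "gene", "signed_rank"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


RESULT_COLUMNS = [
    "Compound", "Replicate", "P value", "zscore",
    "Significance_mark", "Perturb_stability",
]


def write_results_table(results: Sequence, path) -> None:
    """Write the connectivity screen report.

    One row per drug with columns Compound, Replicate, P value, zscore,
    Significance_mark, Perturb_stability, sorted by the screen's ranking
    rule (ascending p, then descending stability, then ascending z).
    P-values are printed in scientific notation with three significant
    digits.
    """
    from .connectivity import rank_drugs  # local import to avoid a cycle

    if not results:
        raise InputError("no results to write")
    ranked = rank_drugs(results)
    rows = [
        {
            "Compound": r.drug_id,
            "Replicate": r.replicate_count,
            "P value": f"{r.p:.2E}",
            "zscore": f"{r.z:.9f}",
            "Significance_mark": int(r.significance_mark),
            "Perturb_stability": (
                "" if r.perturb_stability is None else f"{r.perturb_stability:g}"
            ),
        }
        for r in ranked
    ]
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_results_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing result columns {missing}")
    return df
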