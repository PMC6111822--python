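"""End-to-end orchestration: stratify -> survival -> signature -> screen.

Each stage writes its outputs eagerly to the run directory so it can be
inspected or re-run on its own, and the manifest records the versions,
seeds, thresholds and row counts needed to reproduce the run byte for
byte.  Any stage failure aborts the run with the stage name and removes
partial outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from . import __version__
from .connectivity import (
    ConnectivityRun, expected_false_discovery, screen_library,
    significance_plot,
)
from .errors import InputError, RevmapError
from .io import (
    read_expression_tsv, read_reference_profiles, write_results_table,
    write_signature_gmt,
)
from .signature import (
    build_signature, consistent_top_genes, pearson_correlation,
    rank_differential_genes,
)
from .survival import median_split, survival_report

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RevmapError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Configuration of one full run.

    ``cohorts`` maps a cohort label to (expression TSV, clinical TSV)
    paths; at least two cohorts are required when k >= 1 (the consistency
    ranking needs them).  ``correlation_genes`` are partners to correlate
    with the driver (e.g. the E-cadherin and MMP9 analogues).
    """

    cohorts: Dict[str, Tuple[str, str]]
    driver: str
    refs_path: str | None = None
    k: int = 15
    tau: float | None = None
    correlation_genes: Sequence[str] = ()
    tail: str = "negative"
    null_method: str = "analytic"
    n_draws: int = 10_000
    seed: int = 0
    out_dir: str = "revmap_run"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise InputError("k must be >= 0")
        if len(self.cohorts) < 1:
            raise InputError("at least one cohort is required")
        if self.k >= 1 and len(self.cohorts) < 2:
            raise InputError("consistency ranking needs >= 2 cohorts when k >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        raw["cohorts"] = {k: tuple(v) for k, v in raw["cohorts"].items()}
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    manifest: dict = {
        "package_version": __version__,
        "driver": config.driver,
        "k": config.k,
        "seed": config.seed,
        "stages": {},
    }

    def _emit(path: Path) -> Path:
        written.append(path)
        return path

    stage = "load"
    try:
        t0 = time.perf_counter()
        cohorts = {
            label: read_expression_tsv(expr, clin)
            for label, (expr, clin) in config.cohorts.items()
        }
        manifest["stages"]["load"] = {
            "cohorts": {
                lbl: {"genes": c.n_genes, "samples": c.n_samples}
                for lbl, c in cohorts.items()
            },
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "survival"
        t0 = time.perf_counter()
        surv = {
            lbl: survival_report(c, config.driver, tau=config.tau)
            for lbl, c in cohorts.items()
        }
        path = _emit(out / "survival.json")
        path.write_text(json.dumps(surv, indent=2) + "\n", encoding="utf-8")
        manifest["stages"]["survival"] = {
            "report": str(path),
            "logrank_p": {lbl: r["logrank_p"] for lbl, r in surv.items()},
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "correlation"
        t0 = time.perf_counter()
        corr_rows = []
        for lbl, c in cohorts.items():
            for partner in config.correlation_genes:
                r = pearson_correlation(c, config.driver, partner)
                corr_rows.append(
                    {"cohort": lbl, "gene_a": r.gene_a, "gene_b": r.gene_b,
                     "r": r.r, "p": r.p_two_sided, "n": r.n}
                )
        if corr_rows:
            path = _emit(out / "correlations.tsv")
            pd.DataFrame(corr_rows).to_csv(
                path, sep="\t", index=False, lineterminator="\n"
            )
        manifest["stages"]["correlation"] = {"rows": len(corr_rows)}

        stage = "signature"
        t0 = time.perf_counter()
        if config.k >= 1:
            rankings = [
                rank_differential_genes(
                    c, median_split(c, config.driver), exclude=[config.driver]
                )
                for c in cohorts.values()
            ]
            co_genes = consistent_top_genes(rankings, config.k)
        else:
            co_genes = []
        signature = build_signature(config.driver, co_genes)
        sig_path = _emit(out / "signature.gmt")
        write_signature_gmt(signature, sig_path, name=f"{config.driver}_signature")
        manifest["stages"]["signature"] = {
            "m": signature.m,
            "genes": list(signature.genes),
            "path": str(sig_path),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        if config.refs_path is None:
            manifest["stages"]["connectivity"] = {"skipped": "no reference library"}
        else:
            stage = "connectivity"
            t0 = time.perf_counter()
            refset = read_reference_profiles(config.refs_path)
            run = ConnectivityRun(
                N=refset.N, tail=config.tail, null_method=config.null_method,
                n_draws=config.n_draws, seed=config.seed,
            )
            with_stability = signature.m >= 2
            if not with_stability:
                logger.warning("m=1 signature: perturbation stability skipped")
            results = screen_library(
                refset, signature, run, with_stability=with_stability
            )
            res_path = _emit(out / "results.tsv")
            write_results_table(results, res_path)
            plot_path = _emit(out / "significance.png")
            line_y = significance_plot(results, run.threshold, plot_path)
            n_sig = sum(r.significance_mark for r in results)
            n_stable = sum(
                1 for r in results
                if r.significance_mark and r.perturb_stability == 1.0
            )
            manifest["stages"]["connectivity"] = {
                "N": refset.N,
                "threshold": run.threshold,
                "threshold_neg_log10": line_y,
                "n_significant": n_sig,
                "n_significant_stable": n_stable,
                "expected_fdr": expected_false_discovery(n_sig) if n_sig else None,
                "results": str(res_path),
                "plot": str(plot_path),
                "seconds": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:  # noqa: BLE001 - abort cleanly with stage context
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
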