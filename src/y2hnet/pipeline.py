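"""End-to-end orchestration: catalog summary, direct and indirect reports.

A :class:`RunConfig` names the inputs; :func:`run_pipeline` loads them,
runs every stage, and writes the catalog summary, the direct-enrichment
table, the indirect-enrichment table and a YAML log of every effective
parameter (including the RNG seed and per-source Bonferroni multipliers).
Identical configurations produce byte-identical outputs; on error, partial
outputs are removed.
"""
from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import catalog as cat
from . import io as yio
from .direct import CorrectionConfig, run_direct_enrichment
from .indirect import PermutationConfig, run_indirect_enrichment

__all__ = ["PipelineError", "RunConfig", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run.

    ``gene_sets`` maps a source label to a GMT path.  ``bait_symbol`` and
    ``bait_entrez`` identify the bait; the catalog fixture identifies
    partners by Entrez ID while synthetic runs use symbols, so ``namespace``
    selects which identifier keys the enrichment inputs.
    """

    out_dir: Path
    db_catalog: Path | None = None
    ad_catalog: Path | None = None
    bait_symbol: str = "BAIT"
    bait_entrez: int = 1
    universe: Path | None = None
    network: Path | None = None
    gene_sets: dict[str, Path] = field(default_factory=dict)
    namespace: str = "entrez"  # or "symbol"
    min_obs: int = 2
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    verbosity: int = 0


def _record_key(rec: cat.InteractorRecord, namespace: str) -> str:
    return (
        str(rec.protein.entrez_id) if namespace == "entrez"
        else rec.protein.symbol
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; return the run report as a dict."""
    t0 = time.perf_counter()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {"stages": []}
    try:
        bait = cat.ProteinRef(
            symbol=cfg.bait_symbol, entrez_id=cfg.bait_entrez
        )
        seeds: frozenset[str] | None = None
        bait_key = (
            str(cfg.bait_entrez) if cfg.namespace == "entrez"
            else cfg.bait_symbol
        )
        if cfg.db_catalog or cfg.ad_catalog:
            try:
                db = cat.read_catalog_tsv(cfg.db_catalog) if cfg.db_catalog else []
                ad = cat.read_catalog_tsv(cfg.ad_catalog) if cfg.ad_catalog else []
                catalog = cat.merge_screens(db, ad, bait)
                summary = {
                    "excluding_bait": cat.summarize_counts(catalog, False),
                    "including_bait": cat.summarize_counts(catalog, True),
                    "localization_excluding_bait": cat.tally_localization(
                        catalog, False
                    ).to_dict(orient="index"),
                }
                path = out / "catalog_summary.yaml"
                with open(path, "w", encoding="utf-8") as fh:
                    yaml.safe_dump(summary, fh, sort_keys=True)
                written.append(path)
                report["catalog_summary"] = summary
                report["stages"].append("catalog")
                seeds = frozenset(
                    _record_key(r, cfg.namespace)
                    for r in catalog.partner_records(include_bait_self=False)
                )
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("catalog", str(exc)) from exc
        universe = None
        if cfg.universe:
            try:
                universe = yio.read_universe(cfg.universe)
            except Exception as exc:
                raise PipelineError("io", str(exc)) from exc
        collections = {}
        for label, path in cfg.gene_sets.items():
            try:
                collections[label] = yio.read_gmt(path, source_label=label)
            except Exception as exc:
                raise PipelineError("io", f"{path}: {exc}") from exc
        if seeds and universe and collections:
            try:
                rows = []
                for coll in collections.values():
                    rows.extend(
                        run_direct_enrichment(
                            seeds, coll, universe,
                            min_obs=cfg.min_obs, cfg=cfg.correction,
                        )
                    )
                rows.sort(key=lambda r: (r.p, r.term_id))
                path = out / "direct_enrichment.tsv"
                with open(path, "w", encoding="utf-8") as fh:
                    yio.write_enrichment_tsv(rows, fh)
                written.append(path)
                report["n_direct_rows"] = len(rows)
                report["stages"].append("direct")
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("direct", str(exc)) from exc
        per_source_m: dict[str, int] = {}
        if seeds and cfg.network and collections:
            try:
                network = yio.read_edge_list(cfg.network)
                results = run_indirect_enrichment(
                    network, seeds, bait_key,
                    list(collections.values()), cfg.permutation,
                )
                for label, coll in collections.items():
                    per_source_m[label] = sum(
                        1 for _, gs in coll if gs.members & network.nodes
                    )
                path = out / "indirect_enrichment.tsv"
                with open(path, "w", encoding="utf-8") as fh:
                    yio.write_enrichment_tsv(results, fh)
                written.append(path)
                report["n_indirect_rows"] = len(results)
                report["n_indirect_significant"] = sum(
                    r.significant for r in results
                )
                report["stages"].append("indirect")
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("indirect", str(exc)) from exc
        log = {
            "config": {
                "db_catalog": str(cfg.db_catalog) if cfg.db_catalog else None,
                "ad_catalog": str(cfg.ad_catalog) if cfg.ad_catalog else None,
                "bait_symbol": cfg.bait_symbol,
                "bait_entrez": cfg.bait_entrez,
                "universe": str(cfg.universe) if cfg.universe else None,
                "network": str(cfg.network) if cfg.network else None,
                "gene_sets": {k: str(v) for k, v in cfg.gene_sets.items()},
                "namespace": cfg.namespace,
                "min_obs": cfg.min_obs,
                "correction": {
                    "mode": cfg.correction.mode, "m": cfg.correction.m,
                },
                "permutation": {
                    "n_trials": cfg.permutation.n_trials,
                    "rng_seed": cfg.permutation.rng_seed,
                    "sampling": cfg.permutation.sampling,
                    "smoothing": cfg.permutation.smoothing,
                    "alpha": cfg.permutation.alpha,
                    "min_obs": cfg.permutation.min_obs,
                },
            },
            "per_source_m": per_source_m,
            "stages": report["stages"],
            "runtime_s": round(time.perf_counter() - t0, 3),
        }
        path = out / "run_log.yaml"
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(log, fh, sort_keys=True)
        written.append(path)
        report["log"] = log
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
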