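"""End-to-end orchestration: simulate (or load) the two compendia, run both
screens, intersect them into the shared signature, score and stratify the
tumor cohort, and run the survival comparison — emitting every stage's
output as TSV/JSON plus a machine-readable run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cell_line_screen as cls_mod
from . import clinical_stats, signature as sig_mod, tumor_screen as ts_mod
from .data_model import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    ScreenConfig,
    write_clinical,
    write_expression,
    write_signature,
)
from .synthetic import (
    ROLE_ENTITY,
    ROLE_EPI,
    ROLE_MES,
    ROLE_NULL,
    SimulationParams,
    TruthSet,
    simulate_bulk_tumors,
    simulate_cell_lines,
)

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Machine-readable ledger of one pipeline run."""

    config: dict
    stage_counts: dict = field(default_factory=dict)
    recovery: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "stage_counts": self.stage_counts,
                "recovery": self.recovery,
                "survival": self.survival,
                "manifest": self.manifest,
            },
            indent=1,
            sort_keys=True,
        )


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _recovery_metrics(sig: GeneSignature, truth: TruthSet) -> dict:
    """Sensitivity per planted role and contamination counts for both lists."""
    out: dict = {}
    epi_set, mes_set = set(sig.epithelial), set(sig.mesenchymal)
    planted_epi = set(truth.genes_with_role(ROLE_EPI))
    planted_mes = set(truth.genes_with_role(ROLE_MES))
    ent = set(truth.genes_with_role(ROLE_ENTITY))
    null = set(truth.genes_with_role(ROLE_NULL))
    out["epithelial_sensitivity"] = (
        len(epi_set & planted_epi) / len(planted_epi) if planted_epi else float("nan")
    )
    out["mesenchymal_sensitivity"] = (
        len(mes_set & planted_mes) / len(planted_mes) if planted_mes else float("nan")
    )
    out["entity_specific_in_epithelial"] = len(epi_set & ent)
    out["entity_specific_in_mesenchymal"] = len(mes_set & ent)
    out["null_in_epithelial"] = len(epi_set & null)
    out["null_in_mesenchymal"] = len(mes_set & null)
    return out


def run_pipeline(
    config: ScreenConfig = ScreenConfig(),
    params: SimulationParams | None = None,
    cell_line_matrix: ExpressionMatrix | None = None,
    tumor_matrix: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
    truth_cell_lines: TruthSet | None = None,
    truth_tumors: TruthSet | None = None,
    out_dir: str | Path | None = None,
    stratify_genes: str = "both",
) -> tuple[RunReport, GeneSignature]:
    """Run the full discovery flow and return (report, shared signature).

    Either ``params`` (simulate both compendia) or pre-loaded matrices must
    be supplied.  When ``out_dir`` is given, every stage's product is
    written before the next stage begins and checksummed into the report.
    """
    if params is not None:
        cell_line_matrix, truth_cell_lines = simulate_cell_lines(params)
        tumor_matrix, clinical, truth_tumors = simulate_bulk_tumors(params)
    if cell_line_matrix is None or tumor_matrix is None:
        raise ValueError("need either simulation params or both expression matrices")

    report = RunReport(
        config={
            "screen": config.__dict__ if not hasattr(config, "__dataclass_fields__") else {
                k: getattr(config, k) for k in config.__dataclass_fields__
            },
            "simulation": params.to_dict() if params is not None else None,
        }
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer) -> None:
        if out is None:
            return
        path = out / name
        writer(path)
        report.manifest[name] = _checksum(path)

    emit("cell_lines.expr.tsv", lambda p: write_expression(cell_line_matrix, p))
    emit("tumors.expr.tsv", lambda p: write_expression(tumor_matrix, p))
    if clinical is not None:
        emit("tumors.clinical.tsv", lambda p: write_clinical(clinical, p))
    if truth_tumors is not None:
        emit(
            "truth.json",
            lambda p: p.write_text(
                json.dumps(
                    {
                        "cell_lines": truth_cell_lines.to_json_dict()
                        if truth_cell_lines
                        else None,
                        "tumors": truth_tumors.to_json_dict(),
                    },
                    sort_keys=True,
                )
            ),
        )

    # --- cell-line screen ---
    calls, diff_results = cls_mod.run_cell_line_screen(cell_line_matrix, config)
    state_counts: dict[str, dict[str, int]] = {}
    for c in calls:
        ent = cell_line_matrix.entity_of[c.sample_id]
        state_counts.setdefault(ent, {}).setdefault(c.state, 0)
        state_counts[ent][c.state] += 1
    report.stage_counts["cell_line_states"] = state_counts
    report.stage_counts["cell_line_flags"] = {
        r.entity: {
            "epithelial": len(r.flagged("epithelial")),
            "mesenchymal": len(r.flagged("mesenchymal")),
        }
        for r in diff_results
    }
    for r in diff_results:
        emit(
            f"cell_line_screen.{r.entity}.tsv",
            lambda p, r=r: r.table.to_csv(p, sep="\t", index=False),
        )
    ccle_sig = cls_mod.intersect_cell_line_screen(diff_results, config)
    report.stage_counts["cell_line_signature"] = {
        "epithelial": len(ccle_sig.epithelial),
        "mesenchymal": len(ccle_sig.mesenchymal),
    }
    emit("cell_line_signature.tsv", lambda p: write_signature(ccle_sig, p))

    # --- tumor screen ---
    profiles = ts_mod.run_tumor_screen(tumor_matrix, config)
    report.stage_counts["tumor_classes"] = {
        p.entity: {
            "epithelial": len(p.classified(ts_mod.EPITHELIAL_STATE)),
            "mesenchymal": len(p.classified(ts_mod.MESENCHYMAL_STATE)),
        }
        for p in profiles
    }
    for p in profiles:
        emit(
            f"tumor_screen.{p.entity}.tsv",
            lambda f, p=p: p.table.to_csv(f, sep="\t", index=False),
        )
    tumor_sig = ts_mod.intersect_tumor_screen(profiles, config)
    report.stage_counts["tumor_signature"] = {
        "epithelial": len(tumor_sig.epithelial),
        "mesenchymal": len(tumor_sig.mesenchymal),
    }
    emit("tumor_signature.tsv", lambda p: write_signature(tumor_sig, p))

    # --- shared signature ---
    shared = sig_mod.intersect_screens(ccle_sig, tumor_sig)
    report.stage_counts["shared_signature"] = {
        "epithelial": len(shared.epithelial),
        "mesenchymal": len(shared.mesenchymal),
    }
    emit("shared_signature.tsv", lambda p: write_signature(shared, p))
    if truth_tumors is not None:
        report.recovery = _recovery_metrics(shared, truth_tumors)

    # --- scoring, stratification, survival ---
    if shared.all_genes and len(shared.all_genes) >= 2:
        scores = sig_mod.score_signature(tumor_matrix, shared.all_genes)
        strat = sig_mod.kmeans_stratify(tumor_matrix, shared, config, genes=stratify_genes)
        strat_df = pd.DataFrame(
            {
                "sample_id": strat.groups.index,
                "cluster": strat.groups.values,
                "score": scores.scores.reindex(strat.groups.index).values,
            }
        )
        emit("stratification.tsv", lambda p: strat_df.to_csv(p, sep="\t", index=False))
        report.stage_counts["stratification"] = {
            "epi_group": int((strat.groups == sig_mod.EPI_GROUP).sum()),
            "mes_group": int((strat.groups == sig_mod.MES_GROUP).sum()),
            "iterations": strat.iterations_run,
            "converged": strat.converged,
        }
        if clinical is not None:
            times, events, ids = clinical.endpoint("os")
            grp = strat.groups.reindex(ids)
            mask_mes = (grp == sig_mod.MES_GROUP).to_numpy()
            if mask_mes.any() and (~mask_mes).any():
                res = clinical_stats.logrank_test(
                    times[mask_mes], events[mask_mes], times[~mask_mes], events[~mask_mes]
                )
                report.survival = {
                    "endpoint": "os",
                    "logrank_statistic": res.statistic,
                    "logrank_p": res.p_value,
                    "n_mes_group": int(mask_mes.sum()),
                    "n_epi_group": int((~mask_mes).sum()),
                }
    else:
        logger.warning("shared signature too small to score/stratify")

    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report, shared


__all__ = ["RunReport", "run_pipeline"]
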