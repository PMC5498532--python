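"""Cell-line screen: anchor-ratio phenotyping, per-entity differential
testing, and all-entity intersection.

A cell line is called epithelial-like when its linear-scale CDH1/VIM
ratio exceeds the fold threshold (default 10), mesenchymal-like when the
inverse ratio does, and ambiguous otherwise; ambiguous lines are dropped
from testing.  Per entity, every gene is compared between the two states
with a two-sample Student's t-test on log2 values (pooled variance by
default, Welch behind a config switch); genes with p < alpha are flagged
by the sign of their log2 fold change.  The screen's signature is the set
of genes flagged the same way in every analyzed entity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    DataModelError,
    ExpressionMatrix,
    GeneSignature,
    ScreenConfig,
    to_linear,
    to_log2,
)

logger = logging.getLogger(__name__)

EPITHELIAL_LIKE = "epithelial_like"
MESENCHYMAL_LIKE = "mesenchymal_like"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PhenotypeCall:
    sample_id: str
    state: str
    ratio: float  # linear-scale anchor fold ratio (epithelial / mesenchymal)


@dataclass
class DiffResult:
    """Per-entity differential result over all genes.

    ``table`` columns: gene_id, mean_epi, mean_mes, log2_fc, t_stat,
    p_value, flag (epithelial / mesenchymal / none).  Means and fold
    changes are in log2 units.
    """

    entity: str
    table: pd.DataFrame
    n_epi: int
    n_mes: int

    def flagged(self, which: str) -> list[str]:
        return list(self.table.loc[self.table["flag"] == which, "gene_id"])


def classify_cell_lines(
    matrix: ExpressionMatrix, config: ScreenConfig = ScreenConfig()
) -> list[PhenotypeCall]:
    """Classify every line by the anchor fold-ratio rule (strict inequalities)."""
    lin = to_linear(matrix)
    for anchor in (config.anchor_epithelial, config.anchor_mesenchymal):
        if anchor not in lin.values.index:
            raise DataModelError(f"anchor gene {anchor!r} absent from matrix")
    epi = lin.values.loc[config.anchor_epithelial].to_numpy(float)
    mes = lin.values.loc[config.anchor_mesenchymal].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mes > 0, epi / mes, np.where(epi > 0, np.inf, np.nan))
    calls = []
    thr = config.ratio_threshold
    for sid, r in zip(lin.values.columns, ratio):
        if np.isnan(r):
            state = AMBIGUOUS
        elif r > thr:
            state = EPITHELIAL_LIKE
        elif r < 1.0 / thr:
            state = MESENCHYMAL_LIKE
        else:
            state = AMBIGUOUS
        calls.append(PhenotypeCall(sample_id=sid, state=state, ratio=float(r)))
    counts = pd.Series([c.state for c in calls]).value_counts().to_dict()
    logger.info("anchor-ratio classification (threshold %g): %s", thr, counts)
    return calls


def differential_screen(
    matrix: ExpressionMatrix,
    calls: list[PhenotypeCall],
    entity: str,
    config: ScreenConfig = ScreenConfig(),
) -> DiffResult | None:
    """Student's t-test of every gene between the entity's two states.

    Returns ``None`` (with a warning) when either state has fewer than two
    lines in this entity.  Tests run on log2-scale values.
    """
    log2m = to_log2(matrix)
    state_of = {c.sample_id: c.state for c in calls}
    samples = log2m.samples_of_entity(entity)
    epi_ids = [s for s in samples if state_of.get(s) == EPITHELIAL_LIKE]
    mes_ids = [s for s in samples if state_of.get(s) == MESENCHYMAL_LIKE]
    if len(epi_ids) < 2 or len(mes_ids) < 2:
        logger.warning(
            "entity %s skipped: %d epithelial-like / %d mesenchymal-like lines",
            entity,
            len(epi_ids),
            len(mes_ids),
        )
        return None
    a = log2m.values.loc[:, epi_ids].to_numpy(float)
    b = log2m.values.loc[:, mes_ids].to_numpy(float)
    mean_epi = a.mean(axis=1)
    mean_mes = b.mean(axis=1)
    log2_fc = mean_epi - mean_mes
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=not config.welch)
    # both groups constant: equal means -> t=0, p=1; unequal -> infinite t, p=0
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    eq = degenerate & (mean_epi == mean_mes)
    ne = degenerate & (mean_epi != mean_mes)
    t = np.where(eq, 0.0, t)
    p = np.where(eq, 1.0, p)
    t = np.where(ne, np.where(log2_fc > 0, np.inf, -np.inf), t)
    p = np.where(ne, 0.0, p)

    flag = np.where(
        (p < config.alpha) & (log2_fc > 0),
        "epithelial",
        np.where((p < config.alpha) & (log2_fc < 0), "mesenchymal", "none"),
    )
    table = pd.DataFrame(
        {
            "gene_id": log2m.values.index,
            "mean_epi": mean_epi,
            "mean_mes": mean_mes,
            "log2_fc": log2_fc,
            "t_stat": t,
            "p_value": p,
            "flag": flag,
        }
    ).reset_index(drop=True)
    logger.info(
        "entity %s: %d epithelial-flagged, %d mesenchymal-flagged genes "
        "(alpha=%g, %s t-test)",
        entity,
        int((flag == "epithelial").sum()),
        int((flag == "mesenchymal").sum()),
        config.alpha,
        "Welch" if config.welch else "pooled-variance",
    )
    return DiffResult(entity=entity, table=table, n_epi=len(epi_ids), n_mes=len(mes_ids))


def run_cell_line_screen(
    matrix: ExpressionMatrix, config: ScreenConfig = ScreenConfig()
) -> tuple[list[PhenotypeCall], list[DiffResult]]:
    """Classify lines and run the differential screen in every entity."""
    calls = classify_cell_lines(matrix, config)
    results = []
    for entity in matrix.entities:
        res = differential_screen(matrix, calls, entity, config)
        if res is not None:
            results.append(res)
    return calls, results


def intersect_cell_line_screen(
    per_entity_results: list[DiffResult], config: ScreenConfig = ScreenConfig()
) -> GeneSignature:
    """Genes flagged the same way in *every* entity, with per-entity provenance."""
    if not per_entity_results:
        raise DataModelError("no entity results to intersect")
    epi_sets = [set(r.flagged("epithelial")) for r in per_entity_results]
    mes_sets = [set(r.flagged("mesenchymal")) for r in per_entity_results]
    epi = set.intersection(*epi_sets)
    mes = set.intersection(*mes_sets)
    order = list(per_entity_results[0].table["gene_id"])
    provenance: dict[str, dict] = {}
    for g in epi | mes:
        ev: dict[str, dict] = {}
        for r in per_entity_results:
            row = r.table.loc[r.table["gene_id"] == g].iloc[0]
            ev[r.entity] = {
                "screen": "cell_line",
                "log2_fc": float(row["log2_fc"]),
                "p_value": float(row["p_value"]),
            }
        provenance[g] = ev
    return GeneSignature(
        epithelial=[g for g in order if g in epi],
        mesenchymal=[g for g in order if g in mes],
        provenance=provenance,
    )


__all__ = [
    "PhenotypeCall",
    "DiffResult",
    "classify_cell_lines",
    "differential_screen",
    "run_cell_line_screen",
    "intersect_cell_line_screen",
    "EPITHELIAL_LIKE",
    "MESENCHYMAL_LIKE",
    "AMBIGUOUS",
]
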