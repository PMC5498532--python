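"""Bulk-tumor screen: per-entity Spearman correlation of every gene with
the CDH1/VIM anchors, threshold classification, and all-entity
intersection.

Per entity, a gene is epithelial-state when r(gene, CDH1) > r_pos AND
r(gene, VIM) < r_neg, mesenchymal-state under the mirrored condition,
and unclassified otherwise (strict inequalities; defaults +0.1 / -0.1).
Spearman correlation is rank-based, so the matrix's declared scale is
immaterial here.  Genes constant within an entity have undefined
correlation and are unclassified there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataModelError, ExpressionMatrix, GeneSignature, ScreenConfig

logger = logging.getLogger(__name__)

EPITHELIAL_STATE = "epithelial"
MESENCHYMAL_STATE = "mesenchymal"
UNCLASSIFIED = "unclassified"


@dataclass
class CorrelationProfile:
    """Per-entity correlation of every gene with the two anchors.

    ``table`` columns: gene_id, r_cdh1, r_vim, class.  Undefined
    correlations (constant vectors) are NaN and the gene is unclassified.
    """

    entity: str
    table: pd.DataFrame
    n_samples: int

    def classified(self, which: str) -> list[str]:
        return list(self.table.loc[self.table["class"] == which, "gene_id"])


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if undefined."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataModelError("spearman expects two equal-length 1-d vectors")
    if len(x) < 3:
        raise DataModelError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def _spearman_vs_anchor(values: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Vectorized Spearman of every row of ``values`` against ``anchor``."""
    n = values.shape[1]
    ra = stats.rankdata(anchor)
    ra = ra - ra.mean()
    sa = np.sqrt((ra**2).sum())
    rg = stats.rankdata(values, axis=1)
    rg = rg - rg.mean(axis=1, keepdims=True)
    sg = np.sqrt((rg**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rg @ ra) / (sg * sa)
    r[sg == 0] = np.nan
    if sa == 0:
        r[:] = np.nan
    return r


def correlation_screen(
    matrix: ExpressionMatrix, entity: str, config: ScreenConfig = ScreenConfig()
) -> CorrelationProfile:
    """Correlate every gene with both anchors over the entity's samples."""
    for anchor in (config.anchor_epithelial, config.anchor_mesenchymal):
        if anchor not in matrix.values.index:
            raise DataModelError(f"anchor gene {anchor!r} absent from matrix")
    samples = matrix.samples_of_entity(entity)
    if len(samples) < config.min_samples_per_entity:
        raise DataModelError(
            f"entity {entity!r} has {len(samples)} samples, below the floor of "
            f"{config.min_samples_per_entity}"
        )
    vals = matrix.values.loc[:, samples].to_numpy(float)
    cdh1 = matrix.values.loc[config.anchor_epithelial, samples].to_numpy(float)
    vim = matrix.values.loc[config.anchor_mesenchymal, samples].to_numpy(float)
    r_cdh1 = _spearman_vs_anchor(vals, cdh1)
    r_vim = _spearman_vs_anchor(vals, vim)

    cls = np.full(len(r_cdh1), UNCLASSIFIED, dtype=object)
    ok = ~(np.isnan(r_cdh1) | np.isnan(r_vim))
    epi = ok & (r_cdh1 > config.r_pos) & (r_vim < config.r_neg)
    mes = ok & (r_cdh1 < config.r_neg) & (r_vim > config.r_pos)
    cls[epi] = EPITHELIAL_STATE
    cls[mes] = MESENCHYMAL_STATE
    table = pd.DataFrame(
        {
            "gene_id": matrix.values.index,
            "r_cdh1": r_cdh1,
            "r_vim": r_vim,
            "class": cls,
        }
    ).reset_index(drop=True)
    logger.info(
        "entity %s (n=%d): %d epithelial-state, %d mesenchymal-state genes "
        "(r_pos=%g, r_neg=%g)",
        entity,
        len(samples),
        int(epi.sum()),
        int(mes.sum()),
        config.r_pos,
        config.r_neg,
    )
    return CorrelationProfile(entity=entity, table=table, n_samples=len(samples))


def run_tumor_screen(
    matrix: ExpressionMatrix, config: ScreenConfig = ScreenConfig()
) -> list[CorrelationProfile]:
    return [correlation_screen(matrix, entity, config) for entity in matrix.entities]


def intersect_tumor_screen(
    per_entity_profiles: list[CorrelationProfile],
    config: ScreenConfig = ScreenConfig(),
) -> GeneSignature:
    """Genes classified the same way in *every* entity, with (r_cdh1, r_vim)
    provenance per entity."""
    if not per_entity_profiles:
        raise DataModelError("no entity profiles to intersect")
    epi = set.intersection(*(set(p.classified(EPITHELIAL_STATE)) for p in per_entity_profiles))
    mes = set.intersection(*(set(p.classified(MESENCHYMAL_STATE)) for p in per_entity_profiles))
    order = list(per_entity_profiles[0].table["gene_id"])
    provenance: dict[str, dict] = {}
    for g in epi | mes:
        ev: dict[str, dict] = {}
        for p in per_entity_profiles:
            row = p.table.loc[p.table["gene_id"] == g].iloc[0]
            ev[p.entity] = {
                "screen": "tumor",
                "r_cdh1": float(row["r_cdh1"]),
                "r_vim": float(row["r_vim"]),
            }
        provenance[g] = ev
    return GeneSignature(
        epithelial=[g for g in order if g in epi],
        mesenchymal=[g for g in order if g in mes],
        provenance=provenance,
    )


__all__ = [
    "CorrelationProfile",
    "spearman",
    "correlation_screen",
    "run_tumor_screen",
    "intersect_tumor_screen",
    "EPITHELIAL_STATE",
    "MESENCHYMAL_STATE",
    "UNCLASSIFIED",
]
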