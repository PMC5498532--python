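"""Shared-signature assembly, z-score signature scoring, and k-means
patient stratification with Pearson-correlation distance.

Scoring follows the average-of-z-scores convention: each signature gene
is standardized across the cohort (mean 0, sd 1) on log2 scale and a
sample's score is the mean of its per-gene z-scores.  Stratification
clusters samples represented by their z-scored signature-gene profiles
under the distance d(x, c) = 1 - PearsonCorrelation(x, c), Lloyd
iterations with plain-mean centroid updates, a fixed iteration budget
(default 50) and the best of several restarts; the cluster with the
higher mean epithelial score (falling back to the lower mesenchymal
score) is labelled the epithelial group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    DataModelError,
    ExpressionMatrix,
    GeneSignature,
    ScreenConfig,
    to_log2,
)

logger = logging.getLogger(__name__)

EPI_GROUP = "epi_group"
MES_GROUP = "mes_group"


@dataclass
class SignatureScore:
    """Per-sample average z-scores with the per-sample gene count used."""

    scores: pd.Series  # indexed by sample id
    n_genes_used: int
    dropped_genes: list[str] = field(default_factory=list)


@dataclass
class ClusterAssignment:
    """Two-group sample partition from correlation-distance k-means."""

    groups: pd.Series  # sample id -> EPI_GROUP / MES_GROUP
    iterations_run: int
    converged: bool
    objective: float  # total within-cluster (1 - r) of the winning restart
    objective_trace: list[float] = field(default_factory=list)

    def members(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def intersect_screens(cell_line_sig: GeneSignature, tumor_sig: GeneSignature) -> GeneSignature:
    """Class-wise intersection of the two screens with merged provenance."""
    epi = [g for g in cell_line_sig.epithelial if g in set(tumor_sig.epithelial)]
    mes = [g for g in cell_line_sig.mesenchymal if g in set(tumor_sig.mesenchymal)]
    provenance: dict[str, dict] = {}
    for g in epi + mes:
        merged: dict[str, dict] = {}
        for src in (cell_line_sig, tumor_sig):
            for entity, ev in src.provenance.get(g, {}).items():
                merged[f"{ev.get('screen', 'unknown')}:{entity}"] = ev
        provenance[g] = merged
    if not epi and not mes:
        logger.warning("screens share no genes: empty shared signature")
    return GeneSignature(epithelial=epi, mesenchymal=mes, provenance=provenance)


def score_signature(matrix: ExpressionMatrix, gene_list: list[str]) -> SignatureScore:
    """Average z-score of the signature genes, computed on log2 scale.

    Genes absent from the matrix are ignored; genes with zero cohort
    standard deviation are dropped and counted.  Fatal when no signature
    gene is usable.
    """
    log2m = to_log2(matrix)
    present = [g for g in gene_list if g in log2m.values.index]
    if not present:
        raise DataModelError("no signature gene present in the matrix")
    vals = log2m.values.loc[present].to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    keep = sd[:, 0] > 0
    dropped = [g for g, k in zip(present, keep) if not k]
    if dropped:
        logger.warning("dropped %d constant signature genes: %s", len(dropped), dropped[:5])
    if not keep.any():
        raise DataModelError("all signature genes are constant across the cohort")
    z = (vals[keep] - mu[keep]) / sd[keep]
    scores = pd.Series(z.mean(axis=0), index=log2m.values.columns, name="score")
    return SignatureScore(scores=scores, n_genes_used=int(keep.sum()), dropped_genes=dropped)


# ---------------------------------------------------------------------------
# k-means with Pearson-correlation distance
# ---------------------------------------------------------------------------


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and unit-normalize rows so 1 - r is half the squared distance."""
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(norm > 0, xc / norm, 0.0)
    return out


def _corr_dist(profiles_unit: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Distance matrix 1 - r between unit-normalized profiles and raw centroids."""
    c = _standardize_rows(centroids)
    return 1.0 - profiles_unit @ c.T


def _lloyd(
    profiles: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, int, bool, list[float]]:
    n = profiles.shape[0]
    unit = _standardize_rows(profiles)
    init = rng.choice(n, size=k, replace=False)
    centroids = profiles[init].copy()
    assign = np.full(n, -1)
    converged = False
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        d = _corr_dist(unit, centroids)
        new_assign = np.argmin(d, axis=1)  # ties -> lower-indexed centroid
        # re-seed empty clusters at the sample farthest from its centroid
        for c_idx in range(k):
            if not (new_assign == c_idx).any():
                far = int(np.argmax(d[np.arange(n), new_assign]))
                new_assign[far] = c_idx
        obj = float(d[np.arange(n), new_assign].sum())
        trace.append(obj)
        if (new_assign == assign).all():
            converged = True
            break
        assign = new_assign
        for c_idx in range(k):
            centroids[c_idx] = profiles[assign == c_idx].mean(axis=0)
    d = _corr_dist(unit, centroids)
    obj = float(d[np.arange(n), assign].sum())
    return assign, obj, it, converged, trace


def kmeans_stratify(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    config: ScreenConfig = ScreenConfig(),
    genes: str = "both",
) -> ClusterAssignment:
    """Partition samples into epithelial/mesenchymal groups by k-means.

    Samples are represented by their z-scored signature-gene profiles
    (``genes`` selects the epithelial list, the mesenchymal list, or both,
    the default).  Requires at least 2k samples and two usable genes.
    """
    if genes == "both":
        gene_list = signature.all_genes
    elif genes == "epithelial":
        gene_list = list(signature.epithelial)
    elif genes == "mesenchymal":
        gene_list = list(signature.mesenchymal)
    else:
        raise DataModelError(f"genes must be epithelial|mesenchymal|both, got {genes!r}")
    log2m = to_log2(matrix)
    present = [g for g in gene_list if g in log2m.values.index]
    if len(present) < 2:
        raise DataModelError("need at least 2 signature genes present for stratification")
    n = log2m.values.shape[1]
    if n < 2 * config.k:
        raise DataModelError(f"need at least {2 * config.k} samples, got {n}")
    vals = log2m.values.loc[present].to_numpy(float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise DataModelError("fewer than 2 non-constant signature genes")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    profiles = z.T  # samples x genes
    if np.allclose(profiles.std(axis=0), 0):
        raise DataModelError("all sample profiles identical; correlation distance degenerate")

    rng = np.random.default_rng(config.seed)
    best: tuple | None = None
    for _ in range(config.n_restarts):
        assign, obj, iters, conv, trace = _lloyd(profiles, config.k, config.max_iter, rng)
        if best is None or obj < best[1] - 1e-12:
            best = (assign, obj, iters, conv, trace)
    assign, obj, iters, conv, trace = best

    # orient the labels by signature scores
    sample_ids = list(log2m.values.columns)
    epi_genes = [g for g in signature.epithelial if g in log2m.values.index]
    mes_genes = [g for g in signature.mesenchymal if g in log2m.values.index]
    orient: np.ndarray | None = None
    if epi_genes:
        try:
            s = score_signature(log2m, epi_genes).scores.to_numpy()
            means = [s[assign == c].mean() for c in range(config.k)]
            orient = np.argsort(means)[::-1]  # highest epithelial score first
        except DataModelError:
            orient = None
    if orient is None and mes_genes:
        s = score_signature(log2m, mes_genes).scores.to_numpy()
        means = [s[assign == c].mean() for c in range(config.k)]
        orient = np.argsort(means)  # lowest mesenchymal score first
    if orient is None:
        orient = np.arange(config.k)
    label_of = {int(orient[0]): EPI_GROUP}
    for c in orient[1:]:
        label_of[int(c)] = MES_GROUP
    groups = pd.Series([label_of[int(c)] for c in assign], index=sample_ids, name="group")
    logger.info(
        "k-means stratification: %d %s / %d %s samples, %d iterations, converged=%s",
        int((groups == EPI_GROUP).sum()),
        EPI_GROUP,
        int((groups == MES_GROUP).sum()),
        MES_GROUP,
        iters,
        conv,
    )
    return ClusterAssignment(
        groups=groups,
        iterations_run=iters,
        converged=conv,
        objective=obj,
        objective_trace=trace,
    )


__all__ = [
    "SignatureScore",
    "ClusterAssignment",
    "intersect_screens",
    "score_signature",
    "kmeans_stratify",
    "EPI_GROUP",
    "MES_GROUP",
]
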