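"""Synthetic cell-line compendia and bulk-tumor cohorts with planted EMT truth.

Two generators share one gene universe:

* :func:`simulate_cell_lines` emulates a multi-entity cancer cell-line
  compendium (log2, array-like) in which each line is either epithelial-
  or mesenchymal-state.  Planted marker genes shift by ``effect_size``
  log2 units between the states; the CDH1/VIM anchors are separated far
  enough that the 10-fold ratio rule classifies every line correctly.

* :func:`simulate_bulk_tumors` emulates bulk RNA-seq cohorts (linear) as
  purity-weighted mixtures of a cancer-cell profile driven by a latent
  EMT score e ~ U(0,1) and a stromal profile.  Stromal cells express
  mesenchymal-class genes 1-2 orders of magnitude above baseline, which
  is what makes bulk mesenchymal screens fragile; epithelial-class genes
  are essentially absent from stroma, null genes are compartment-
  indifferent.  Survival, metastasis and nodal status are linked to e.

Every draw descends from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams, so stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    ClinicalTable,
    DataModelError,
    ExpressionMatrix,
)

DEFAULT_ENTITIES = ("colorectal", "breast", "lung", "bladder", "pancreas")

# Role labels used throughout recovery tests.
ROLE_ANCHOR_EPI = "anchor_epi"
ROLE_ANCHOR_MES = "anchor_mes"
ROLE_EPI = "epi_marker"
ROLE_MES = "mes_marker"
ROLE_ENTITY = "entity_specific"
ROLE_NULL = "null"


@dataclass(frozen=True)
class SimulationParams:
    """Free parameters of the generators.

    Defaults are the package's reference study conditions: 5 cell-line
    entities with 20+20 lines each, 3 tumor entities with 300 tumors
    each, 50+50 planted markers, 20 entity-specific genes, 900 nulls, a
    2.0-log2 state effect and 0.5-log2 noise.
    """

    n_entities: int = 5
    n_tumor_entities: int = 3
    lines_per_state_per_entity: int = 20
    n_tumors_per_entity: int = 300
    n_epi_markers: int = 50
    n_mes_markers: int = 50
    n_entity_specific: int = 20
    n_null: int = 900
    effect_size: float = 2.0
    noise_sd: float = 0.5
    baseline_log2_range: tuple[float, float] = (4.0, 10.0)
    stroma_factor_range: tuple[float, float] = (10.0, 100.0)
    stroma_composition_spread: float = 6.0
    purity_range: tuple[float, float] = (0.5, 0.95)
    hazard_ratio_mes: float = 2.0
    censor_rate: float = 0.25
    baseline_hazard: float = 0.05
    p_M1_base: float = -2.0
    p_M1_slope: float = 3.0
    p_Nplus_base: float = -1.0
    p_Nplus_slope: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_entities,
            self.n_tumor_entities,
            self.lines_per_state_per_entity,
            self.n_tumors_per_entity,
            self.n_epi_markers,
            self.n_mes_markers,
            self.n_entity_specific,
            self.n_null,
        )
        if any(c < 0 for c in counts):
            raise DataModelError("all counts must be >= 0")
        if self.n_tumor_entities > self.n_entities:
            raise DataModelError("n_tumor_entities cannot exceed n_entities")
        if not self.noise_sd > 0:
            raise DataModelError("noise_sd must be > 0")
        lo, hi = self.stroma_factor_range
        if not (lo >= 1 and lo <= hi):
            raise DataModelError("stroma_factor_range must be ordered with lower bound >= 1")
        plo, phi = self.purity_range
        if not (0 < plo <= phi <= 1):
            raise DataModelError("purity_range must lie in (0, 1]")
        if not self.hazard_ratio_mes > 0:
            raise DataModelError("hazard_ratio_mes must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise DataModelError("censor_rate must be in [0, 1)")
        if not self.baseline_hazard > 0:
            raise DataModelError("baseline_hazard must be > 0")
        if not self.stroma_composition_spread >= 1:
            raise DataModelError("stroma_composition_spread must be >= 1")

    def entities(self) -> list[str]:
        base = list(DEFAULT_ENTITIES)
        if self.n_entities <= len(base):
            return base[: self.n_entities]
        return base + [f"entity{i}" for i in range(len(base), self.n_entities)]

    def tumor_entities(self) -> list[str]:
        return self.entities()[: self.n_tumor_entities]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside each simulated dataset."""

    gene_role: dict[str, str]
    gene_entity: dict[str, str]  # designated entity of entity_specific genes
    sample_state: dict[str, str] = field(default_factory=dict)  # cell lines
    emt_score: dict[str, float] = field(default_factory=dict)  # tumors
    purity: dict[str, float] = field(default_factory=dict)  # tumors

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.gene_role.items() if r == role]

    def to_json_dict(self) -> dict:
        return {
            "gene_role": self.gene_role,
            "gene_entity": self.gene_entity,
            "sample_state": self.sample_state,
            "emt_score": self.emt_score,
            "purity": self.purity,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "TruthSet":
        return cls(
            gene_role=dict(d["gene_role"]),
            gene_entity=dict(d.get("gene_entity", {})),
            sample_state=dict(d.get("sample_state", {})),
            emt_score={k: float(v) for k, v in d.get("emt_score", {}).items()},
            purity={k: float(v) for k, v in d.get("purity", {}).items()},
        )


# ---------------------------------------------------------------------------
# Gene universe (shared between the two generators)
# ---------------------------------------------------------------------------


@dataclass
class _GeneUniverse:
    gene_ids: list[str]
    roles: dict[str, str]
    designated_entity: dict[str, str]
    baseline_log2: np.ndarray  # aligned with gene_ids
    stroma_factor: np.ndarray  # aligned with gene_ids; 1.0 for non-mesenchymal genes


def _rng(params: SimulationParams, stage: str) -> np.random.Generator:
    """Deterministic per-stage sub-stream of the master seed."""
    import zlib

    ss = np.random.SeedSequence(params.seed, spawn_key=(zlib.crc32(stage.encode()),))
    return np.random.default_rng(ss)


def _build_universe(params: SimulationParams) -> _GeneUniverse:
    entities = params.entities()
    gene_ids = ["CDH1", "VIM"]
    roles = {"CDH1": ROLE_ANCHOR_EPI, "VIM": ROLE_ANCHOR_MES}
    designated: dict[str, str] = {}
    for i in range(params.n_epi_markers):
        g = f"EPI{i + 1:04d}"
        gene_ids.append(g)
        roles[g] = ROLE_EPI
    for i in range(params.n_mes_markers):
        g = f"MES{i + 1:04d}"
        gene_ids.append(g)
        roles[g] = ROLE_MES
    for i in range(params.n_entity_specific):
        g = f"ENT{i + 1:04d}"
        gene_ids.append(g)
        roles[g] = ROLE_ENTITY
        designated[g] = entities[i % len(entities)] if entities else "unassigned"
    for i in range(params.n_null):
        g = f"NUL{i + 1:04d}"
        gene_ids.append(g)
        roles[g] = ROLE_NULL

    rng = _rng(params, "universe")
    lo, hi = params.baseline_log2_range
    baseline = rng.uniform(lo, hi, size=len(gene_ids))
    # Anchors share one baseline so the planted anchor separation, not the
    # baseline lottery, decides every line's ratio classification.
    baseline[1] = baseline[0]
    slo, shi = params.stroma_factor_range
    stroma = np.ones(len(gene_ids))
    for i, g in enumerate(gene_ids):
        if roles[g] in (ROLE_MES, ROLE_ANCHOR_MES):
            stroma[i] = rng.uniform(slo, shi)
    return _GeneUniverse(gene_ids, roles, designated, baseline, stroma)


def _anchor_shift(params: SimulationParams, ratio_threshold: float = 10.0) -> float:
    """Log2 separation of the anchors between states.

    Must exceed log2(ratio_threshold) by a comfortable noise margin so the
    fold-ratio rule classifies every simulated line correctly; 8 noise sds
    puts the misclassification probability per line below 1e-8.
    """
    return max(params.effect_size, np.log2(ratio_threshold) + 8.0 * params.noise_sd)


# ---------------------------------------------------------------------------
# Cell lines
# ---------------------------------------------------------------------------


def simulate_cell_lines(params: SimulationParams) -> tuple[ExpressionMatrix, TruthSet]:
    """Simulate a log2 cell-line compendium with two EMT states per entity."""
    uni = _build_universe(params)
    rng = _rng(params, "cell_lines")
    entities = params.entities()
    n_per = params.lines_per_state_per_entity

    sample_ids: list[str] = []
    entity_of: dict[str, str] = {}
    sample_state: dict[str, str] = {}
    cols: list[np.ndarray] = []

    shift = params.effect_size
    a_shift = _anchor_shift(params)
    role_arr = np.array([uni.roles[g] for g in uni.gene_ids])
    designated_arr = np.array([uni.designated_entity.get(g, "") for g in uni.gene_ids])

    for entity in entities:
        for state in ("epithelial", "mesenchymal"):
            for j in range(n_per):
                sid = f"{entity}_{state[:3]}_{j + 1:03d}"
                sample_ids.append(sid)
                entity_of[sid] = entity
                sample_state[sid] = state
                mu = uni.baseline_log2.copy()
                if state == "epithelial":
                    mu[role_arr == ROLE_EPI] += shift
                    mu[role_arr == ROLE_ANCHOR_EPI] += a_shift
                    mu[(role_arr == ROLE_ENTITY) & (designated_arr == entity)] += shift
                else:
                    mu[role_arr == ROLE_MES] += shift
                    mu[role_arr == ROLE_ANCHOR_MES] += a_shift
                cols.append(mu)

    values = np.array(cols).T + rng.normal(
        0.0, params.noise_sd, size=(len(uni.gene_ids), len(sample_ids))
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=uni.gene_ids, columns=sample_ids),
        scale="log2",
        entity_of=entity_of,
    )
    truth = TruthSet(
        gene_role=dict(uni.roles),
        gene_entity=dict(uni.designated_entity),
        sample_state=sample_state,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Bulk tumors
# ---------------------------------------------------------------------------


def simulate_bulk_tumors(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ClinicalTable, TruthSet]:
    """Simulate linear-scale bulk-tumor cohorts with stromal contamination.

    Each tumor draws a latent EMT score e ~ U(0,1) and a purity rho.
    Bulk = rho * cancer + (1 - rho) * stroma, then log-normal noise.
    Cancer-cell profile: epithelial-class genes respond by
    2**(effect_size*(1-e)), mesenchymal-class by 2**(effect_size*e),
    nulls are flat.  Stromal profile: mesenchymal markers at
    baseline * s_g * c_{g,t} with s_g ~ U(stroma_factor_range) and a
    per-tumor stromal-composition multiplier c (log-uniform over
    [1/spread, spread]); the VIM anchor is pan-stromal (c = 1); null and
    entity-specific genes at baseline; epithelial-class genes essentially
    absent from stroma.

    Outcomes: exponential survival with hazard
    baseline_hazard * hazard_ratio_mes**e and independent exponential
    censoring tuned to censor_rate; M1/N+ status via a logistic link in e.
    """
    uni = _build_universe(params)
    rng = _rng(params, "tumors")
    entities = params.tumor_entities()
    n_per = params.n_tumors_per_entity
    G = len(uni.gene_ids)

    role_arr = np.array([uni.roles[g] for g in uni.gene_ids])
    designated_arr = np.array([uni.designated_entity.get(g, "") for g in uni.gene_ids])
    base_lin = np.power(2.0, uni.baseline_log2)[:, None]

    is_epi_class = np.isin(role_arr, [ROLE_EPI, ROLE_ANCHOR_EPI])
    is_mes_class = np.isin(role_arr, [ROLE_MES, ROLE_ANCHOR_MES])
    is_anchor_mes = role_arr == ROLE_ANCHOR_MES

    sample_ids: list[str] = []
    entity_of: dict[str, str] = {}
    emt: dict[str, float] = {}
    purity: dict[str, float] = {}
    blocks: list[np.ndarray] = []
    e_all: list[np.ndarray] = []

    spread = params.stroma_composition_spread
    for entity in entities:
        e = rng.uniform(0.0, 1.0, n_per)
        rho = rng.uniform(*params.purity_range, n_per)
        ids = [f"{entity}_T{j + 1:04d}" for j in range(n_per)]
        sample_ids.extend(ids)
        for sid, ev, pv in zip(ids, e, rho):
            entity_of[sid] = entity
            emt[sid] = float(ev)
            purity[sid] = float(pv)
        e_all.append(e)

        response = np.ones((G, n_per))
        response[is_epi_class] = 2.0 ** (params.effect_size * (1.0 - e))[None, :]
        response[is_mes_class] = 2.0 ** (params.effect_size * e)[None, :]
        ent_rows = (role_arr == ROLE_ENTITY) & (designated_arr == entity)
        response[ent_rows] = 2.0 ** (params.effect_size * (1.0 - e))[None, :]
        cancer = base_lin * response

        stroma = np.ones((G, n_per)) * base_lin
        stroma[is_epi_class] = base_lin[is_epi_class] * 1e-2
        if spread > 1:
            comp = np.exp(
                rng.uniform(-np.log(spread), np.log(spread), size=(int(is_mes_class.sum()), n_per))
            )
        else:
            comp = np.ones((int(is_mes_class.sum()), n_per))
        # the VIM anchor tracks total stromal content, not composition
        comp[is_anchor_mes[is_mes_class]] = 1.0
        stroma[is_mes_class] = (
            base_lin[is_mes_class] * uni.stroma_factor[is_mes_class][:, None] * comp
        )

        bulk = rho[None, :] * cancer + (1.0 - rho)[None, :] * stroma
        noise = 2.0 ** rng.normal(0.0, params.noise_sd, size=(G, n_per))
        blocks.append(bulk * noise)

    values = np.concatenate(blocks, axis=1) if blocks else np.empty((G, 0))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=uni.gene_ids, columns=sample_ids),
        scale="linear",
        entity_of=entity_of,
    )

    e_vec = np.concatenate(e_all) if e_all else np.empty(0)
    clinical = _simulate_clinical(params, rng, sample_ids, entity_of, e_vec)
    truth = TruthSet(
        gene_role=dict(uni.roles),
        gene_entity=dict(uni.designated_entity),
        emt_score=emt,
        purity=purity,
    )
    return matrix, clinical, truth


def _censoring_rate_for(params: SimulationParams, hazards: np.ndarray) -> float:
    """Censoring hazard c such that the expected censored fraction matches
    censor_rate: with event hazard h and censoring hazard c, the probability
    the censoring time comes first is c / (h + c); solve the cohort average."""
    if params.censor_rate == 0:
        return 0.0
    from scipy.optimize import brentq

    target = params.censor_rate

    def f(c: float) -> float:
        return float(np.mean(c / (hazards + c)) - target)

    hi = float(hazards.max()) * target / (1 - target) * 10 + 1e-9
    while f(hi) < 0:
        hi *= 10
    return float(brentq(f, 1e-12, hi))


def _simulate_clinical(
    params: SimulationParams,
    rng: np.random.Generator,
    sample_ids: Sequence[str],
    entity_of: dict[str, str],
    e: np.ndarray,
) -> ClinicalTable:
    n = len(sample_ids)
    hazards = params.baseline_hazard * params.hazard_ratio_mes**e
    c_rate = _censoring_rate_for(params, hazards)

    def draw_endpoint() -> tuple[np.ndarray, np.ndarray]:
        t_event = rng.exponential(1.0 / hazards)
        if c_rate > 0:
            t_cens = rng.exponential(1.0 / c_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    os_time, os_event = draw_endpoint()
    rfs_time, rfs_event = draw_endpoint()

    def logistic(x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-x))

    p_m1 = logistic(params.p_M1_base + params.p_M1_slope * e)
    m_status = np.where(rng.uniform(size=n) < p_m1, "M1", "M0")
    p_np = logistic(params.p_Nplus_base + params.p_Nplus_slope * e)
    n_status = np.where(rng.uniform(size=n) < p_np, "Nplus", "N0")

    # pseudo-subtypes: quartile bins of the latent EMT score with 10% label
    # noise (stand-ins for consumed molecular-subtype labels, S1..S4)
    qs = np.quantile(e, [0.25, 0.5, 0.75]) if n else np.array([0.25, 0.5, 0.75])
    subtype_idx = np.searchsorted(qs, e)
    flip = rng.uniform(size=n) < 0.10
    subtype_idx[flip] = rng.integers(0, 4, size=int(flip.sum()))
    subtype = np.array([f"S{i + 1}" for i in subtype_idx])

    # ordinal 0-3 IHC-like score of an epithelial protein: decreasing in e
    ihc = np.clip(np.floor(4.0 * (1.0 - e) + rng.normal(0, 0.5, n)), 0, 3).astype(int)

    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "entity": [entity_of[s] for s in sample_ids],
            "m_status": m_status,
            "n_status": n_status,
            "subtype": subtype,
            "os_time": os_time,
            "os_event": os_event,
            "rfs_time": rfs_time,
            "rfs_event": rfs_event,
            "ihc_score": ihc,
        }
    )
    return ClinicalTable(df)


__all__ = [
    "SimulationParams",
    "TruthSet",
    "simulate_cell_lines",
    "simulate_bulk_tumors",
    "DEFAULT_ENTITIES",
    "ROLE_EPI",
    "ROLE_MES",
    "ROLE_ENTITY",
    "ROLE_NULL",
    "ROLE_ANCHOR_EPI",
    "ROLE_ANCHOR_MES",
]
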