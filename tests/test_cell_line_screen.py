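"""Anchor-ratio classification and the per-entity differential screen."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from emtscreen import ExpressionMatrix, ScreenConfig, simulate_cell_lines
from emtscreen.cell_line_screen import (
    AMBIGUOUS,
    EPITHELIAL_LIKE,
    MESENCHYMAL_LIKE,
    classify_cell_lines,
    differential_screen,
    intersect_cell_line_screen,
    run_cell_line_screen,
)
from emtscreen.data_model import DataModelError, GeneSignature
from emtscreen.synthetic import ROLE_ENTITY, ROLE_EPI, ROLE_NULL

from .oracles import pooled_t_oracle


def _matrix(cdh1, vim, scale="linear", entity="colon"):
    cols = [f"s{i}" for i in range(len(cdh1))]
    df = pd.DataFrame([cdh1, vim], index=["CDH1", "VIM"], columns=cols)
    return ExpressionMatrix(values=df, scale=scale, entity_of={c: entity for c in cols})


class TestClassify:
    def test_fold_rule(self):
        calls = classify_cell_lines(_matrix([2000.0], [50.0]))
        assert calls[0].state == EPITHELIAL_LIKE
        assert calls[0].ratio == pytest.approx(40.0)

    def test_exact_threshold_is_ambiguous(self):
        """'More than 10-fold' is strict: ratio exactly 10 stays unclassified."""
        calls = classify_cell_lines(_matrix([100.0], [10.0]))
        assert calls[0].state == AMBIGUOUS

    def test_log2_input_converted(self):
        calls = classify_cell_lines(_matrix([10.0], [6.0], scale="log2"))
        assert calls[0].ratio == pytest.approx(16.0)
        assert calls[0].state == EPITHELIAL_LIKE

    def test_inverse_rule_mesenchymal(self):
        calls = classify_cell_lines(_matrix([5.0], [200.0]))
        assert calls[0].state == MESENCHYMAL_LIKE

    def test_zero_vim_positive_cdh1_is_epithelial(self):
        calls = classify_cell_lines(_matrix([5.0], [0.0]))
        assert calls[0].state == EPITHELIAL_LIKE
        assert np.isinf(calls[0].ratio)

    def test_missing_anchor_fatal(self):
        df = pd.DataFrame([[1.0]], index=["CDH1"], columns=["s0"])
        m = ExpressionMatrix(values=df, scale="linear")
        with pytest.raises(DataModelError, match="VIM"):
            classify_cell_lines(m)


def _diff_matrix(epi_vals, mes_vals, gene="G1"):
    n_e, n_m = len(epi_vals), len(mes_vals)
    cols = [f"e{i}" for i in range(n_e)] + [f"m{i}" for i in range(n_m)]
    cdh1 = [10.0] * n_e + [1.0] * n_m
    vim = [1.0] * n_e + [10.0] * n_m
    df = pd.DataFrame(
        [cdh1, vim, list(epi_vals) + list(mes_vals)],
        index=["CDH1", "VIM", gene],
        columns=cols,
    )
    return ExpressionMatrix(values=df, scale="log2", entity_of={c: "colon" for c in cols})


class TestDifferentialScreen:
    def test_identical_groups_give_null_result(self):
        m = _diff_matrix([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        calls = classify_cell_lines(m)
        res = differential_screen(m, calls, "colon")
        row = res.table.set_index("gene_id").loc["G1"]
        assert row["t_stat"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert row["flag"] == "none"

    def test_textbook_pooled_t(self):
        """{8,9,10} vs {2,3,4}: matches the closed-form pooled t with df=4."""
        m = _diff_matrix([8.0, 9.0, 10.0], [2.0, 3.0, 4.0])
        calls = classify_cell_lines(m)
        res = differential_screen(m, calls, "colon")
        row = res.table.set_index("gene_id").loc["G1"]
        t_exp, p_exp = pooled_t_oracle([8, 9, 10], [2, 3, 4])
        assert row["t_stat"] == pytest.approx(t_exp, abs=1e-10)
        assert row["p_value"] == pytest.approx(p_exp, abs=1e-10)
        assert row["log2_fc"] == pytest.approx(6.0)
        assert row["flag"] == "epithelial"

    def test_oracle_equivalence_on_random_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = rng.normal(5, 1, rng.integers(3, 12))
            b = rng.normal(4, 2, rng.integers(3, 12))
            m = _diff_matrix(a, b)
            res = differential_screen(m, classify_cell_lines(m), "colon")
            row = res.table.set_index("gene_id").loc["G1"]
            t_exp, p_exp = pooled_t_oracle(a, b)
            assert row["t_stat"] == pytest.approx(t_exp, abs=1e-10)
            assert row["p_value"] == pytest.approx(p_exp, abs=1e-10)

    def test_label_swap_antisymmetry(self):
        a, b = [8.0, 9.5, 10.0], [2.0, 3.5, 4.0]
        m1 = _diff_matrix(a, b)
        m2 = _diff_matrix(b, a)
        r1 = differential_screen(m1, classify_cell_lines(m1), "colon").table.set_index("gene_id").loc["G1"]
        r2 = differential_screen(m2, classify_cell_lines(m2), "colon").table.set_index("gene_id").loc["G1"]
        assert r1["t_stat"] == pytest.approx(-r2["t_stat"])
        assert r1["log2_fc"] == pytest.approx(-r2["log2_fc"])
        assert r1["p_value"] == pytest.approx(r2["p_value"])

    def test_small_state_skipped(self):
        m = _diff_matrix([5.0], [1.0, 2.0, 3.0])
        res = differential_screen(m, classify_cell_lines(m), "colon")
        assert res is None

    def test_constant_unequal_groups_degenerate(self):
        m = _diff_matrix([7.0, 7.0], [3.0, 3.0])
        res = differential_screen(m, classify_cell_lines(m), "colon")
        row = res.table.set_index("gene_id").loc["G1"]
        assert row["p_value"] == 0.0
        assert np.isinf(row["t_stat"])


class TestIntersection:
    def _result(self, entity, flags):
        table = pd.DataFrame(
            {
                "gene_id": list(flags),
                "mean_epi": 1.0,
                "mean_mes": 0.0,
                "log2_fc": 1.0,
                "t_stat": 5.0,
                "p_value": 0.001,
                "flag": list(flags.values()),
            }
        )
        from emtscreen.cell_line_screen import DiffResult

        return DiffResult(entity=entity, table=table, n_epi=5, n_mes=5)

    def test_set_intersection(self):
        a = self._result("A", {"g1": "epithelial", "g2": "epithelial", "g3": "none"})
        b = self._result("B", {"g1": "none", "g2": "epithelial", "g3": "epithelial"})
        sig = intersect_cell_line_screen([a, b])
        assert sig.epithelial == ["g2"]
        assert set(sig.provenance["g2"]) == {"A", "B"}

    def test_gene_missing_one_entity_excluded(self):
        results = [
            self._result(e, {"g1": "epithelial"}) for e in ["A", "B", "C", "D"]
        ] + [self._result("E", {"g1": "none"})]
        assert intersect_cell_line_screen(results).epithelial == []

    def test_empty_input_fatal(self):
        with pytest.raises(DataModelError):
            intersect_cell_line_screen([])


class TestRecovery:
    def test_planted_epi_markers_flagged_everywhere(self, small_params):
        """Every planted epithelial marker is flagged in its entity at the
        default effect size, and the intersection excludes entity-specific
        and (almost surely) null genes."""
        m, truth = simulate_cell_lines(small_params)
        _, diffs = run_cell_line_screen(m, ScreenConfig())
        planted = set(truth.genes_with_role(ROLE_EPI))
        for res in diffs:
            assert planted <= set(res.flagged("epithelial"))
        sig = intersect_cell_line_screen(diffs)
        assert planted <= set(sig.epithelial)
        assert not set(sig.epithelial) & set(truth.genes_with_role(ROLE_ENTITY))
        assert len(set(sig.all_genes) & set(truth.genes_with_role(ROLE_NULL))) <= 1
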