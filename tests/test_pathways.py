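"""Pathway logic parsing/scoring and geTMM normalization."""

import numpy as np
import pandas as pd
import pytest

from redoxomics.pathways import (Complex, GeneCatalog, Group, Leaf,
                                 PathwayParseError, Step, getmm_normalize,
                                 ko_expression, parse_pathway_logic,
                                 pathway_timeseries, score_pathway, serialize,
                                 tmm_factors)


class TestParser:
    def test_single_ko(self):
        ast = parse_pathway_logic("K00001")
        assert len(ast.steps) == 1
        assert ast.steps[0].alternatives == (Leaf("K00001"),)

    def test_alternatives_and_complex(self):
        ast = parse_pathway_logic("K00001,K00002 K00003+K00004")
        assert len(ast.steps) == 2
        assert ast.steps[0].alternatives == (Leaf("K00001"), Leaf("K00002"))
        assert ast.steps[1].alternatives == (
            Complex((Leaf("K00003"), Leaf("K00004"))),)

    def test_parenthesis_neutrality(self):
        a = parse_pathway_logic("((K1,K2) K3)")
        b = parse_pathway_logic("K1,K2 K3")
        vals = {"K1": 1.0, "K2": 2.0, "K3": 5.0}
        assert score_pathway(a, vals) == score_pathway(b, vals)

    def test_nested_group_as_alternative(self):
        ast = parse_pathway_logic("(K1 K2),K3")
        step = ast.steps[0]
        assert isinstance(step.alternatives[0], Group)
        assert step.alternatives[1] == Leaf("K3")

    def test_nonessential_markers_stripped_with_warning(self):
        with pytest.warns(UserWarning):
            ast = parse_pathway_logic("K00001 -- K00002-K00003")
        assert ast.kos == {"K00001", "K00002"}

    @pytest.mark.parametrize("bad", ["", "  ", "(K1", "K1)", "K1,,K2",
                                     "K1++K2", "K1,"])
    def test_malformed_expressions_report_position(self, bad):
        with pytest.raises(PathwayParseError):
            parse_pathway_logic(bad)

    def test_round_trip(self, pathway_defs):
        for d in pathway_defs:
            ast = parse_pathway_logic(d.expression)
            assert parse_pathway_logic(serialize(ast)) == ast


class TestScoring:
    def test_hand_example_complex_average_alternative_sum(self):
        ast = parse_pathway_logic("K1,K2 K3+K4")
        assert score_pathway(ast, {"K1": 2, "K2": 3, "K3": 4, "K4": 6}) == 5.0

    def test_absent_kos_score_zero(self):
        ast = parse_pathway_logic("K1,K2 K3+K4")
        assert score_pathway(ast, {}) == 0.0
        assert score_pathway(parse_pathway_logic("K9"), {"K9": 7.0}) == 7.0

    def test_linearity_in_expression(self):
        ast = parse_pathway_logic("K1+K2 K3,K4 (K5 K6)")
        vals = {f"K{i}": float(i) for i in range(1, 7)}
        s1 = score_pathway(ast, vals)
        s3 = score_pathway(ast, {k: 3 * v for k, v in vals.items()})
        assert s3 == pytest.approx(3 * s1)

    def test_random_ast_oracle(self):
        """Structures built directly (bypassing the parser) score the same
        through serialize -> parse -> score as by direct recursion."""

        def oracle(node, vals):
            if isinstance(node, Leaf):
                return vals.get(node.ko, 0.0)
            if isinstance(node, Complex):
                xs = [oracle(m, vals) for m in node.members]
                return sum(xs) / len(xs)
            if isinstance(node, Step):
                return sum(oracle(a, vals) for a in node.alternatives)
            if isinstance(node, Group):
                xs = [oracle(s, vals) for s in node.steps]
                return sum(xs) / len(xs)
            raise TypeError

        rng = np.random.default_rng(11)

        def random_atom(depth):
            if depth > 0 and rng.random() < 0.25:
                return Group(tuple(random_step(depth - 1)
                                   for _ in range(rng.integers(1, 3))))
            return Leaf(f"K{rng.integers(1, 13):05d}")

        def random_alt(depth):
            if rng.random() < 0.3:
                return Complex(tuple(random_atom(depth)
                                     for _ in range(rng.integers(2, 4))))
            return random_atom(depth)

        def random_step(depth):
            return Step(tuple(random_alt(depth)
                              for _ in range(rng.integers(1, 4))))

        for _ in range(300):
            from redoxomics.pathways import PathwayAST

            ast = PathwayAST(tuple(random_step(2)
                                   for _ in range(rng.integers(1, 4))))
            vals = {f"K{i:05d}": float(rng.uniform(0, 10))
                    for i in range(1, 13) if rng.random() < 0.7}
            expect = sum(oracle(s, vals) for s in ast.steps) / len(ast.steps)
            parsed = parse_pathway_logic(serialize(ast))
            assert score_pathway(parsed, vals) == pytest.approx(expect, rel=1e-12)


def _uniform_catalog(genes, length=1000):
    return GeneCatalog(pd.DataFrame({
        "gene_id": genes, "mag_id": "M1", "ko": "", "length_bp": length,
    }))


class TestGeTMM:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.gamma(2, 20, 100)
        mat = np.column_stack([col, col])
        assert np.allclose(tmm_factors(mat), 1.0)

    def test_pure_depth_difference_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.gamma(2, 20, 100) + 1
        mat = np.column_stack([col, 3 * col])
        assert np.allclose(tmm_factors(mat), 1.0)

    def test_composition_invariance(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(200)]
        counts = pd.DataFrame(rng.gamma(2, 20, (200, 4)) + 1, index=genes,
                              columns=list("abcd"))
        catalog = _uniform_catalog(genes)
        n1 = getmm_normalize(counts, catalog)
        scaled = counts.copy()
        scaled["b"] *= 3.0
        n2 = getmm_normalize(scaled, catalog)
        assert np.abs(n1.values - n2.values).max() < 1e-9

    def test_gene_length_correction(self):
        counts = pd.DataFrame({"a": [100, 100]}, index=["g1", "g2"])
        catalog = GeneCatalog(pd.DataFrame({
            "gene_id": ["g1", "g2"], "mag_id": "M", "ko": "",
            "length_bp": [1000, 2000],
        }))
        out = getmm_normalize(counts, catalog)
        # same counts, double length -> half the normalized expression
        assert out.loc["g1", "a"] == pytest.approx(2 * out.loc["g2", "a"])

    def test_doubled_gene_matches_brute_force_trimmed_mean(self):
        """One high-count gene doubled in sample b: the factor equals an
        independently coded doubly-trimmed weighted mean of M-values."""
        rng = np.random.default_rng(3)
        n = 20
        a = rng.gamma(5, 50, n) + 10
        b = a.copy()
        b[np.argmax(a)] *= 2.0
        mat = np.column_stack([a, b])

        lib = mat.sum(axis=0)
        f75 = np.quantile(mat, 0.75, axis=0) / lib
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
        other = 1 - ref
        p_o, p_r = mat[:, other] / lib[other], mat[:, ref] / lib[ref]
        m = np.log2(p_o / p_r)
        av = 0.5 * np.log2(p_o * p_r)
        w = (1 - p_o) / p_o + (1 - p_r) / p_r
        # rank-based double trim: drop 30% of M and 5% of A from each side
        from scipy.stats import rankdata
        rm, ra = rankdata(m), rankdata(av)
        lo_m = np.floor(n * 0.3) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * 0.05) + 1
        hi_a = n + 1 - lo_a
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        log_f = ((m[keep] / w[keep]).sum()) / (1.0 / w[keep]).sum()
        f_other = 2.0 ** log_f
        expect = np.ones(2)
        expect[other] = f_other
        expect = expect / np.exp(np.mean(np.log(expect)))

        assert np.allclose(tmm_factors(mat), expect, rtol=1e-12)

    def test_all_zero_sample_rejected(self):
        mat = np.column_stack([np.arange(10.0) + 1, np.zeros(10)])
        with pytest.raises(ValueError):
            tmm_factors(mat)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        counts = pd.DataFrame(rng.gamma(2, 30, (50, 3)) + 1, index=genes,
                              columns=list("abc"))
        catalog = _uniform_catalog(genes)
        perm = rng.permutation(genes)
        n1 = getmm_normalize(counts, catalog)
        n2 = getmm_normalize(counts.loc[perm], catalog)
        assert np.allclose(n1.loc[perm].values, n2.values)


class TestKoAggregation:
    def test_sum_within_ko(self, tiny_catalog):
        norm = pd.DataFrame({"s1": [1.5, 2.0, 2.5, 9.0]},
                            index=["g1", "g2", "g3", "g4"])
        out = ko_expression(norm, tiny_catalog)
        assert out.loc["K00001", "s1"] == pytest.approx(4.0)  # g1 + g3
        assert out.loc["K00003", "s1"] == pytest.approx(2.0)
        assert "" not in out.index  # un-annotated gene ignored

    def test_mag_scope_restriction(self, tiny_catalog):
        norm = pd.DataFrame({"s1": [1.5, 2.0, 2.5, 9.0]},
                            index=["g1", "g2", "g3", "g4"])
        scoped = ko_expression(norm, tiny_catalog, mag_scope={"M1"})
        assert scoped.loc["K00001", "s1"] == pytest.approx(1.5)
        empty = ko_expression(norm, tiny_catalog, mag_scope=set())
        assert empty.empty


class TestTimeseries:
    def test_zscore_and_sem(self):
        scores = pd.DataFrame(
            [[1.0, 1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 3.0, 3.0]],
            index=["pw"],
            columns=[f"s{i}" for i in range(9)],
        )
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(9)],
            "day": [0, 0, 0, 7, 7, 7, 14, 14, 14],
        })
        mean, sem, z = pathway_timeseries(scores, design)
        assert list(mean.loc["pw"]) == [1.0, 2.0, 3.0]
        assert np.allclose(sem.loc["pw"], 0.0)
        assert np.allclose(z.loc["pw"], [-1.0, 0.0, 1.0])

    def test_constant_series_zscores_to_zero(self):
        scores = pd.DataFrame([[5.0] * 6], index=["pw"],
                              columns=[f"s{i}" for i in range(6)])
        design = pd.DataFrame({"sample_id": [f"s{i}" for i in range(6)],
                               "day": [0, 0, 7, 7, 14, 14]})
        _, _, z = pathway_timeseries(scores, design)
        assert np.allclose(z.loc["pw"], 0.0)

    def test_replicate_sem_formula(self):
        scores = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], index=["pw"],
                              columns=[f"s{i}" for i in range(6)])
        design = pd.DataFrame({"sample_id": [f"s{i}" for i in range(6)],
                               "day": [0, 0, 0, 7, 7, 7]})
        _, sem, _ = pathway_timeseries(scores, design)
        assert sem.loc["pw", 0] == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))

    def test_single_timepoint_rejected(self):
        scores = pd.DataFrame([[1.0, 2.0]], index=["pw"], columns=["s0", "s1"])
        design = pd.DataFrame({"sample_id": ["s0", "s1"], "day": [0, 0]})
        with pytest.raises(ValueError):
            pathway_timeseries(scores, design)
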