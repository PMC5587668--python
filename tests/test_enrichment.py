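import itertools
import json

import hypothesis.strategies as st
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings

from comboscreen import enrichment, simulate
from comboscreen.enrichment import (
    CONTROL,
    TREATED,
    ExpressionMatrix,
    GeneRank,
    GeneSet,
)
from comboscreen.errors import (
    MissingConditionError,
    NoOverlapError,
    ValidationError,
)


def brute_force_es(n, hit_positions):
    """Independent oracle: explicit KS running-sum walk over all n ranks."""
    hits = set(hit_positions)
    k = len(hits)
    rs, best = 0.0, 0.0
    for pos in range(n):
        rs += 1.0 / k if pos in hits else -1.0 / (n - k)
        if abs(rs) > abs(best):
            best = rs
    return best


def rank_of(n):
    probes = [f"P{i:03d}" for i in range(n)]
    scores = tuple(float(n - i) for i in range(n))
    return GeneRank(probe_ids=tuple(probes), scores=scores)


def set_at(rank, positions, name="s"):
    return GeneSet(name=name, members=frozenset(rank.probe_ids[p] for p in positions))


def make_matrix(values, annotations):
    """values: dict sample_id -> list of per-probe log2; annotations:
    list of (sample_id, line, treatment, rep)."""
    n = len(next(iter(values.values())))
    probes = [f"P{i:03d}" for i in range(n)]
    ann = pd.DataFrame(
        annotations,
        columns=["sample_id", "cell_line_id", "treatment", "replicate_index"],
    ).set_index("sample_id")
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probes, name="probe_id")),
        annotations=ann,
    )


class TestDeltaLog2:
    def test_duplicate_means(self):
        m = make_matrix(
            {"t1": [8.0], "t2": [8.4], "c1": [7.0], "c2": [7.4]},
            [("t1", "L", TREATED, 1), ("t2", "L", TREATED, 2),
             ("c1", "L", CONTROL, 1), ("c2", "L", CONTROL, 2)],
        )
        assert enrichment.delta_log2(m, "L").iloc[0] == pytest.approx(1.0)

    def test_identity_zero(self):
        m = make_matrix(
            {"t1": [5.0], "c1": [5.0]},
            [("t1", "L", TREATED, 1), ("c1", "L", CONTROL, 1)],
        )
        assert enrichment.delta_log2(m, "L").iloc[0] == 0.0

    def test_single_samples_plain_difference(self):
        m = make_matrix(
            {"t1": [9.5], "c1": [7.25]},
            [("t1", "L", TREATED, 1), ("c1", "L", CONTROL, 1)],
        )
        assert enrichment.delta_log2(m, "L").iloc[0] == pytest.approx(2.25)

    def test_missing_group_error(self):
        m = make_matrix({"t1": [5.0]}, [("t1", "L", TREATED, 1)])
        with pytest.raises(MissingConditionError, match="control"):
            enrichment.delta_log2(m, "L")


class TestCrossLineRank:
    def test_mean_across_lines(self):
        m = make_matrix(
            {"a_t": [1.0, 0.0], "a_c": [0.0, 0.0],
             "b_t": [3.0, 0.0], "b_c": [0.0, 0.0]},
            [("a_t", "A", TREATED, 1), ("a_c", "A", CONTROL, 1),
             ("b_t", "B", TREATED, 1), ("b_c", "B", CONTROL, 1)],
        )
        rank = enrichment.cross_line_rank(m)
        assert rank.n_lines_used == 2
        assert rank.probe_ids[0] == "P000"
        assert rank.scores[0] == pytest.approx(2.0)  # mean of {1, 3}

    def test_all_zero_ties_lexicographic(self):
        m = make_matrix(
            {"t": [5.0, 5.0, 5.0], "c": [5.0, 5.0, 5.0]},
            [("t", "L", TREATED, 1), ("c", "L", CONTROL, 1)],
        )
        rank = enrichment.cross_line_rank(m)
        assert list(rank.probe_ids) == ["P000", "P001", "P002"]

    def test_column_order_invariance(self, rng):
        mat, _ = simulate.simulate_expression(
            n_probes=50, planted_set_size=5, delta=1.0, noise_sd=0.3, seed=5
        )
        shuffled_cols = list(rng.permutation(mat.values.columns))
        shuffled = ExpressionMatrix(
            values=mat.values[shuffled_cols],
            annotations=mat.annotations.loc[shuffled_cols],
        )
        assert enrichment.cross_line_rank(mat) == enrichment.cross_line_rank(shuffled)

    def test_brute_force_oracle_small(self, rng):
        # two-loop mean-of-differences oracle on random small matrices
        for _ in range(20):
            n_probes = int(rng.integers(2, 8))
            n_lines = int(rng.integers(1, 4))
            values, ann = {}, []
            for li in range(n_lines):
                for treatment in (TREATED, CONTROL):
                    for rep in range(int(rng.integers(1, 3))):
                        sid = f"L{li}_{treatment}_{rep}"
                        values[sid] = rng.normal(8, 1, n_probes).tolist()
                        ann.append((sid, f"L{li}", treatment, rep + 1))
            m = make_matrix(values, ann)
            expected = {}
            for p_i, probe in enumerate(m.probe_ids):
                deltas = []
                for li in range(n_lines):
                    t = [values[s][p_i] for s, l, tr, _ in ann
                         if l == f"L{li}" and tr == TREATED]
                    c = [values[s][p_i] for s, l, tr, _ in ann
                         if l == f"L{li}" and tr == CONTROL]
                    deltas.append(sum(t) / len(t) - sum(c) / len(c))
                expected[probe] = sum(deltas) / len(deltas)
            rank = enrichment.cross_line_rank(m)
            for probe, score in zip(rank.probe_ids, rank.scores):
                assert score == pytest.approx(expected[probe], abs=1e-12)

    def test_planted_probes_rank_high(self):
        hits = 0
        for seed in range(20):
            mat, truth = simulate.simulate_expression(
                n_probes=500, planted_set_size=10, delta=2.0, noise_sd=0.25,
                seed=seed,
            )
            rank = enrichment.cross_line_rank(mat)
            top_decile = set(rank.probe_ids[: len(rank) // 10])
            hits += set(truth.planted_set) <= top_decile
        assert hits >= 19  # 99% criterion at reduced repeat count

    def test_missing_values_dropped_and_counted(self):
        values = pd.DataFrame(
            {"t": [1.0, np.nan], "c": [0.0, 2.0]},
            index=pd.Index(["P000", "P001"], name="probe_id"),
        )
        ann = pd.DataFrame(
            [("t", "L", TREATED, 1), ("c", "L", CONTROL, 1)],
            columns=["sample_id", "cell_line_id", "treatment", "replicate_index"],
        ).set_index("sample_id")
        m = ExpressionMatrix(values=values, annotations=ann)
        assert m.n_probes_dropped == 1
        assert list(m.probe_ids) == ["P000"]

    def test_tsv_round_trip(self, tmp_path):
        mat, _ = simulate.simulate_expression(
            n_probes=30, planted_set_size=3, delta=1.0, noise_sd=0.2, seed=1
        )
        rank = enrichment.cross_line_rank(mat)
        rank.to_tsv(tmp_path / "rank.tsv")
        back = GeneRank.from_tsv(tmp_path / "rank.tsv")
        assert back.probe_ids == rank.probe_ids
        assert np.allclose(back.scores, rank.scores)


class TestEnrichmentScore:
    @pytest.mark.parametrize("n,k", [(10, 1), (10, 3), (10, 9)])
    def test_top_k_is_one(self, n, k):
        rank = rank_of(n)
        assert enrichment.enrichment_score(rank, set_at(rank, range(k))) == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k", [(10, 2), (10, 5)])
    def test_bottom_k_is_minus_one(self, n, k):
        rank = rank_of(n)
        es = enrichment.enrichment_score(rank, set_at(rank, range(n - k, n)))
        assert es == pytest.approx(-1.0)

    def test_hand_walk_n4(self):
        rank = rank_of(4)
        es = enrichment.enrichment_score(rank, set_at(rank, [0, 2]))
        assert es == pytest.approx(0.5)  # walk: 0.5, 0.0, 0.5, 0.0

    def test_exhaustive_small_vs_oracle(self):
        for n in range(2, 7):
            rank = rank_of(n)
            for k in range(1, n):
                for pos in itertools.combinations(range(n), k):
                    expected = brute_force_es(n, pos)
                    assert enrichment.enrichment_score(
                        rank, set_at(rank, pos)
                    ) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry(self, rng):
        n = 40
        rank = rank_of(n)
        rev = GeneRank(
            probe_ids=tuple(reversed(rank.probe_ids)),
            scores=tuple(-s for s in reversed(rank.scores)),
        )
        for _ in range(10):
            pos = rng.choice(n, size=7, replace=False)
            gs = set_at(rank, pos)
            assert enrichment.enrichment_score(rev, gs) == pytest.approx(
                -enrichment.enrichment_score(rank, gs), abs=1e-12
            )

    def test_interleaved_set_es_shrinks(self):
        n = 10_000
        rank = rank_of(n)
        es = enrichment.enrichment_score(rank, set_at(rank, range(0, n, 10)))
        assert abs(es) < 0.05

    def test_no_overlap(self):
        rank = rank_of(5)
        with pytest.raises(NoOverlapError):
            enrichment.enrichment_score(rank, GeneSet("x", frozenset(["Q1"])))

    def test_full_rank_rejected(self):
        rank = rank_of(5)
        with pytest.raises(ValidationError):
            enrichment.enrichment_score(rank, set_at(rank, range(5)))

    @given(st.data())
    @settings(max_examples=100)
    def test_bounds_property(self, data):
        n = data.draw(st.integers(3, 30))
        k = data.draw(st.integers(1, n - 1))
        pos = data.draw(
            st.lists(st.integers(0, n - 1), min_size=k, max_size=k, unique=True)
        )
        rank = rank_of(n)
        es = enrichment.enrichment_score(rank, set_at(rank, pos))
        assert -1.0 <= es <= 1.0
        assert es == pytest.approx(brute_force_es(n, pos), abs=1e-12)


class TestPermutationPvalue:
    def test_reproducible(self):
        rank = rank_of(200)
        gs = set_at(rank, range(10))
        r1 = enrichment.permutation_pvalue(rank, gs, 200, seed=5)
        r2 = enrichment.permutation_pvalue(rank, gs, 200, seed=5)
        assert r1 == r2

    def test_planted_set_minimum_p(self):
        mat, truth = simulate.simulate_expression(
            n_probes=5000, planted_set_size=50, delta=2.0, noise_sd=0.25, seed=7
        )
        rank = enrichment.cross_line_rank(mat)
        res = enrichment.permutation_pvalue(
            rank, simulate.planted_gene_set(truth), 1000, seed=3
        )
        assert res.p_value == pytest.approx(1 / 1001)
        assert res.n_members_in_rank == 50

    def test_minimum_attainable_p(self):
        rank = rank_of(500)
        res = enrichment.permutation_pvalue(rank, set_at(rank, range(20)), 300, seed=1)
        assert res.p_value >= 1 / 301

    def test_saturated_set_not_significant(self):
        # rank minus one mid-list probe: for the unweighted KS with
        # k = N-1 the running sum always swings to |ES| >= 0.5 (it climbs
        # 1/k per hit and drops 1 at the single miss), so the degeneracy
        # shows up in the p-value, not in a near-zero ES
        rank = rank_of(200)
        positions = [p for p in range(200) if p != 100]
        res = enrichment.permutation_pvalue(rank, set_at(rank, positions), 100, seed=0)
        assert res.p_value > 0.5

    def test_leading_edge_positive(self):
        rank = rank_of(20)
        res = enrichment.permutation_pvalue(rank, set_at(rank, [0, 1, 2, 15]), 100, seed=0)
        assert res.es > 0
        assert set(res.leading_edge) == {"P000", "P001", "P002"}

    def test_leading_edge_negative(self):
        rank = rank_of(20)
        res = enrichment.permutation_pvalue(rank, set_at(rank, [17, 18, 19]), 100, seed=0)
        assert res.es < 0
        assert set(res.leading_edge) == {"P017", "P018", "P019"}

    def test_nperm_floor(self):
        rank = rank_of(20)
        with pytest.raises(ValidationError):
            enrichment.permutation_pvalue(rank, set_at(rank, [0]), 50, seed=0)

    def test_enrich_all_order_independent_seeds(self, tmp_path):
        rank = rank_of(100)
        sets = [set_at(rank, range(5), "top"), set_at(rank, range(95, 100), "bottom")]
        results = enrichment.enrich_all(rank, sets, 100, seed=9)
        enrichment.write_enrichment_json(results, tmp_path / "enrich.json")
        payload = json.loads((tmp_path / "enrich.json").read_text())
        assert [r["set_name"] for r in payload] == ["top", "bottom"]
        assert payload[0]["es"] == pytest.approx(1.0)
        assert payload[1]["es"] == pytest.approx(-1.0)


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [GeneSet("s1", frozenset(["A", "B"])), GeneSet("s2", frozenset(["C"]))]
        enrichment.write_gmt(sets, tmp_path / "sets.gmt")
        back = enrichment.read_gmt(tmp_path / "sets.gmt")
        assert back == sets

    def test_malformed_line(self, tmp_path):
        (tmp_path / "bad.gmt").write_text("onlyname\tdesc\n")
        with pytest.raises(ValidationError):
            enrichment.read_gmt(tmp_path / "bad.gmt")


class TestDdct:
    def test_self_calibration_identity(self):
        assert enrichment.ddct_fold_change([25, 25], [20, 20], [25, 25], [20, 20]) == 1.0

    def test_dct_2_vs_4(self):
        # dCT_sample 2, dCT_calibrator 4 -> fold = 2^-(2-4) = 4
        fold = enrichment.ddct_fold_change([22], [20], [24], [20])
        assert fold == pytest.approx(4.0)

    def test_hand_triplets(self):
        fold = enrichment.ddct_fold_change(
            [25, 25, 25], [20, 20, 20], [22, 22, 22], [20, 20, 20]
        )
        assert fold == pytest.approx(0.125)

    @given(shift=st.floats(-10, 10))
    def test_global_ct_shift_invariance(self, shift):
        base = enrichment.ddct_fold_change([25.2], [20.1], [23.7], [19.9])
        shifted = enrichment.ddct_fold_change(
            [25.2 + shift], [20.1 + shift], [23.7 + shift], [19.9 + shift]
        )
        assert shifted == pytest.approx(base, rel=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            enrichment.ddct_fold_change([np.nan], [20], [22], [20])

    def test_table_round_trip(self):
        ct, truth = simulate.simulate_ct({"IFIT1": 8.0, "IFIT2": 0.25}, seed=3)
        folds = enrichment.ddct_table(ct, ref_gene="GAPDH", calibrator="DMSO")
        treated = folds[folds["sample_id"] == "treated"].set_index("gene")
        for gene, fold in truth.true_folds.items():
            assert treated.loc[gene, "fold_change"] == pytest.approx(fold)

    def test_table_missing_reference(self):
        ct, _ = simulate.simulate_ct({"G": 2.0}, seed=0)
        with pytest.raises(ValidationError):
            enrichment.ddct_table(ct, ref_gene="ACTB", calibrator="DMSO")


class TestFromFiles:
    def test_label_mapping(self, tmp_path):
        mat, _ = simulate.simulate_expression(
            n_probes=20, planted_set_size=2, delta=1.0, noise_sd=0.1, seed=0
        )
        # re-label canonical treatments as drug/vehicle literals
        ann = mat.annotations.rename(columns={"replicate_index": "replicate"})
        ann = ann.assign(
            treatment=ann["treatment"].map({TREATED: "ganetespib", CONTROL: "DMSO"})
        )
        mat.values.to_csv(tmp_path / "expr.tsv", sep="\t", index_label="probe_id")
        ann.to_csv(tmp_path / "annot.csv", index_label="sample_id")
        back = ExpressionMatrix.from_files(
            tmp_path / "expr.tsv", tmp_path / "annot.csv",
            treated_label="ganetespib", control_label="DMSO",
        )
        r1 = enrichment.cross_line_rank(back)
        r2 = enrichment.cross_line_rank(mat)
        assert r1.probe_ids == r2.probe_ids
        assert np.allclose(r1.scores, r2.scores)  # CSV round trip loses bits

    def test_unknown_label_rejected(self, tmp_path):
        mat, _ = simulate.simulate_expression(
            n_probes=5, planted_set_size=1, delta=1.0, noise_sd=0.1, seed=0
        )
        ann = mat.annotations.rename(columns={"replicate_index": "replicate"})
        ann = ann.assign(treatment="mystery_arm")
        mat.values.to_csv(tmp_path / "expr.tsv", sep="\t", index_label="probe_id")
        ann.to_csv(tmp_path / "annot.csv", index_label="sample_id")
        with pytest.raises(ValidationError):
            ExpressionMatrix.from_files(
                tmp_path / "expr.tsv", tmp_path / "annot.csv",
                treated_label="drugX", control_label="vehicle",
            )
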