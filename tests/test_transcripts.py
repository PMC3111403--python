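"""Replicate-consistency filtering, gene resolution, matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_filter, random_feature_tables
from synray import (
    ArrayGenParams,
    ReplicateSet,
    assemble_matrix,
    call_feature,
    count_responders,
    gene_responses,
    resolve_genes,
    signed_fold_change,
    simulate_feature_tables,
    three_replicate_filter,
)


def make_reps(rows, treatment="T"):
    """rows: list of (feature_id, gene_id, [(ratio, p)] * 3)."""
    reps = []
    for i in range(3):
        reps.append(
            pd.DataFrame(
                {
                    "feature_id": [r[0] for r in rows],
                    "gene_id": [r[1] for r in rows],
                    "ratio": [r[2][i][0] for r in rows],
                    "p_value": [r[2][i][1] for r in rows],
                }
            )
        )
    return ReplicateSet(treatment, tuple(reps))


class TestCallFeature:
    @pytest.mark.parametrize(
        "ratio, p, responder, direction",
        [
            (2.0, 0.01, True, "up"),  # both thresholds inclusive
            (0.5, 0.01, True, "down"),
            (0.49, 0.005, True, "down"),
            (1.999, 0.001, False, None),
            (2.0, 0.0101, False, None),
            (3.0, 0.02, False, None),
            (0.501, 0.001, False, None),
        ],
    )
    def test_threshold_boundaries(self, ratio, p, responder, direction):
        assert call_feature(ratio, p) == (responder, direction)

    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan")])
    def test_nonpositive_ratio_rejected(self, bad):
        with pytest.raises(ValueError):
            call_feature(bad, 0.01)

    def test_signed_fold_change_convention(self):
        assert signed_fold_change(2.4) == pytest.approx(2.4)
        assert signed_fold_change(0.135) == pytest.approx(-1 / 0.135)  # -7.4-fold
        assert abs(signed_fold_change(0.9)) >= 1


class TestThreeReplicateFilter:
    def test_same_direction_survives_mixed_removed(self):
        reps = make_reps(
            [
                ("f1", "g1", [(2.5, 0.005)] * 3),  # up/up/up
                ("f2", "g2", [(2.5, 0.005), (2.5, 0.005), (0.4, 0.005)]),  # up/up/down
                ("f3", "g3", [(0.4, 0.005)] * 3),  # down/down/down
                ("f4", "g4", [(2.5, 0.02), (2.5, 0.005), (2.5, 0.005)]),  # one bad P
            ]
        )
        surv = three_replicate_filter(reps)
        assert list(surv["feature_id"]) == ["f1", "f3"]
        assert list(surv["direction"]) == ["up", "down"]
        assert surv.loc[0, "mean_p"] == pytest.approx(0.005)

    def test_mismatched_universe_rejected(self):
        reps = make_reps([("f1", "g1", [(2.5, 0.005)] * 3)])
        other = reps.replicates[1].assign(feature_id=["fX"])
        with pytest.raises(ValueError, match="universe"):
            ReplicateSet("T", (reps.replicates[0], other, reps.replicates[2]))

    def test_replicate_and_row_order_invariance(self):
        for seed in range(5):
            tables = random_feature_tables(seed, n_features_max=40)
            base = three_replicate_filter(ReplicateSet("T", tuple(tables)))
            shuffled = [
                t.sample(frac=1, random_state=seed + 1).reset_index(drop=True)
                for t in tables
            ]
            permuted = three_replicate_filter(
                ReplicateSet("T", (shuffled[2], shuffled[0], shuffled[1]))
            )
            pd.testing.assert_frame_equal(base, permuted)


class TestResolveGenes:
    def test_smallest_mean_p_wins(self):
        reps = make_reps(
            [
                ("fa", "g1", [(2.2, 0.004)] * 3),
                ("fb", "g1", [(3.1, 0.002)] * 3),
            ]
        )
        resolved = resolve_genes(three_replicate_filter(reps))
        assert len(resolved) == 1
        row = resolved.iloc[0]
        assert row["feature_id"] == "fb"
        assert row["signed_fold_change"] == pytest.approx(3.1)
        assert row["status"] == "significant"

    def test_tie_broken_lexicographically(self):
        reps = make_reps(
            [
                ("fb", "g1", [(3.0, 0.004)] * 3),
                ("fa", "g1", [(2.2, 0.004)] * 3),
            ]
        )
        resolved = resolve_genes(three_replicate_filter(reps))
        assert resolved.iloc[0]["feature_id"] == "fa"

    def test_contradictory_gene_excluded(self):
        reps = make_reps(
            [
                ("fa", "g1", [(2.5, 0.004)] * 3),
                ("fb", "g1", [(0.4, 0.002)] * 3),
                ("fc", "g2", [(2.5, 0.004)] * 3),
            ]
        )
        resolved = resolve_genes(three_replicate_filter(reps))
        by_gene = resolved.set_index("gene_id")
        assert by_gene.loc["g1", "status"] == "excluded_contradictory"
        assert by_gene.loc["g2", "status"] == "significant"

    def test_subthreshold_feature_does_not_veto(self):
        # the opposing feature never survives the filter, so no contradiction
        reps = make_reps(
            [
                ("fa", "g1", [(2.5, 0.004)] * 3),
                ("fb", "g1", [(0.7, 0.004)] * 3),
            ]
        )
        resolved = resolve_genes(three_replicate_filter(reps))
        assert list(resolved["status"]) == ["significant"]

    def test_significant_responses_meet_thresholds(self):
        for seed in range(10):
            reps = ReplicateSet("T", tuple(random_feature_tables(seed)))
            resolved = gene_responses(reps)
            sig = resolved[resolved["status"] == "significant"]
            assert (sig["signed_fold_change"].abs() >= 2.0).all()
            assert (sig["mean_p"] <= 0.01).all()


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_nested_loop_oracle(self, seed):
        tables = random_feature_tables(seed)
        reps = ReplicateSet("T", tuple(tables))
        surv = three_replicate_filter(reps)
        resolved = resolve_genes(surv)
        o_surv, o_genes = brute_force_filter(tables)
        assert set(surv["feature_id"]) == set(o_surv)
        got = resolved.set_index("gene_id")
        assert set(got.index) == set(o_genes)
        for gid, expect in o_genes.items():
            assert got.loc[gid, "status"] == expect["status"]
            if expect["status"] == "significant":
                assert got.loc[gid, "feature_id"] == expect["feature_id"]
                assert got.loc[gid, "mean_p"] == pytest.approx(expect["mean_p"])
                assert got.loc[gid, "signed_fold_change"] == pytest.approx(
                    expect["signed_fold_change"]
                )


class TestAssembleMatrix:
    def fixture_sets(self):
        # gene g1 significant in Z only; g2 significant in both; g3 in C only
        z = make_reps(
            [
                ("f1", "g1", [(4.0, 0.001)] * 3),
                ("f2", "g2", [(2.5, 0.004)] * 3),
                ("f3", "g3", [(1.3, 0.5)] * 3),
            ],
            "Z",
        )
        c = make_reps(
            [
                ("f1", "g1", [(1.3, 0.4)] * 3),
                ("f2", "g2", [(3.0, 0.003)] * 3),
                ("f3", "g3", [(0.4, 0.005)] * 3),
            ],
            "C",
        )
        return {"Z": z, "C": c}

    def test_fill_in_from_whole_array(self):
        sets = self.fixture_sets()
        responders = {t: gene_responses(rs) for t, rs in sets.items()}
        whole = {t: list(rs.replicates) for t, rs in sets.items()}
        m = assemble_matrix(responders, whole)
        assert sorted(m.values.index) == ["g1", "g2", "g3"]
        # g1 not significant in C: filled in with log2(mean whole-array ratio)
        assert m.values.loc["g1", "C"] == pytest.approx(np.log2(1.3))
        assert not m.significant.loc["g1", "C"]
        assert m.significant.loc["g1", "Z"]
        assert m.values.loc["g1", "Z"] == pytest.approx(np.log2(4.0))
        # g2 significant everywhere: no filled-in cells on its row
        assert m.significant.loc["g2"].all()
        # down-regulated g3 keeps its log2 sign
        assert m.values.loc["g3", "C"] == pytest.approx(np.log2(0.4))

    def test_empty_responders_warn_and_yield_empty_matrix(self):
        null = make_reps([("f1", "g1", [(1.1, 0.9)] * 3)], "Z")
        responders = {"Z": gene_responses(null)}
        with pytest.warns(UserWarning, match="empty"):
            m = assemble_matrix(responders, {"Z": list(null.replicates)})
        assert m.values.empty

    def test_missing_gene_in_whole_array_is_structural_error(self):
        sets = self.fixture_sets()
        responders = {t: gene_responses(rs) for t, rs in sets.items()}
        whole = {t: list(rs.replicates) for t, rs in sets.items()}
        whole["C"] = [t[t["gene_id"] != "g1"] for t in whole["C"]]
        with pytest.raises(KeyError, match="g1"):
            assemble_matrix(responders, whole)


class TestCountResponders:
    def test_planted_counts_recovered(self):
        planted = {
            "CCM": [(f"g{i + 1:04d}", "up", 3.0) for i in range(12)],
            "DHA": [(f"g{i + 1:04d}", "down", 2.5) for i in range(3)],
            "Zadd": [(f"g{i + 1:04d}", "up", 4.0) for i in range(7)],
        }
        sim = simulate_feature_tables(
            ArrayGenParams(n_genes=50, planted=planted, seed=5)
        )
        counts = count_responders(sim.replicate_sets).set_index("treatment")
        assert counts.loc["CCM", "n_genes"] == 12
        assert counts.loc["DHA", "n_genes"] == 3
        assert counts.loc["Zadd", "n_genes"] == 7

    def test_all_null_tables_count_zero(self):
        sim = simulate_feature_tables(
            ArrayGenParams(n_genes=30, planted={"A": [], "B": [], "C": []}, seed=1)
        )
        counts = count_responders(sim.replicate_sets)
        assert (counts["n_genes"] == 0).all()
        assert (counts["n_features"] == 0).all()
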