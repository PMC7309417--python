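"""Two-step ranking, normalisation, pooling, and the Venn census."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirtarrank.ranking import (
    DatabaseCoverage,
    common_targets,
    normalise_ranking,
    pool_databases,
    step1_weighted,
    step2_gene_sum,
)


def preds(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene_id", "score"])


class TestStepOneTwo:
    def test_score_times_strength(self):
        out = step1_weighted(preds([("miR-1", "CG1", 5.0)]), {"miR-1": 44.2375})
        assert out["weighted"].iloc[0] == pytest.approx(221.1875)

    def test_zero_score_weights_to_zero(self):
        out = step1_weighted(preds([("miR-1", "CG1", 0.0)]), {"miR-1": 44.2375})
        assert out["weighted"].iloc[0] == 0.0

    def test_negative_family_strength_propagates(self):
        out = step1_weighted(
            preds([("279+286+996", "CG1", 3.0)]), {"279+286+996": -4.104}
        )
        assert out["weighted"].iloc[0] == pytest.approx(-12.312)

    def test_unscreened_mirna_skipped(self, caplog):
        with caplog.at_level("WARNING"):
            out = step1_weighted(
                preds([("miR-1", "CG1", 5.0), ("miR-ghost", "CG1", 9.0)]),
                {"miR-1": 1.0},
            )
        assert len(out) == 1
        assert "miR-ghost" in caplog.text

    def test_gene_sum_example(self):
        df = preds([("a", "CG1", 10.0), ("b", "CG1", 20.0), ("c", "CG1", 30.0)])
        sigma = step2_gene_sum(step1_weighted(df, {"a": 1, "b": 1, "c": 1}))
        assert sigma["CG1"] == 60.0

    def test_gene_sum_matches_brute_force(self, rng):
        mirnas = [f"m{i}" for i in range(6)]
        genes = [f"CG{i}" for i in range(8)]
        rows = [
            (m, g, float(rng.uniform(0, 5)))
            for m in mirnas for g in genes if rng.random() < 0.6
        ]
        strengths = {m: float(rng.uniform(-5, 50)) for m in mirnas}
        sigma = step2_gene_sum(step1_weighted(preds(rows), strengths))
        for g in genes:
            brute = sum(s * strengths[m] for m, gg, s in rows if gg == g)
            if any(gg == g for _, gg, _ in rows):
                assert sigma[g] == pytest.approx(brute)


class TestNormalise:
    def test_top_gene_attains_coverage_scaled_100(self):
        sigma = pd.Series({"CG1": 200.0, "CG2": 50.0})
        cov = DatabaseCoverage("microcosm", 31, 44)
        norm = normalise_ranking(sigma, cov)
        assert norm["CG1"] == pytest.approx(100 * 31 / 44)
        assert round(norm["CG1"], 4) == 70.4545

    def test_half_of_max_full_coverage(self):
        norm = normalise_ranking(
            pd.Series({"a": 10.0, "b": 5.0}), DatabaseCoverage("mirnaorg", 44, 44)
        )
        assert norm["b"] == pytest.approx(50.0)

    def test_all_equal_all_get_fraction(self):
        norm = normalise_ranking(
            pd.Series({"a": 3.0, "b": 3.0}), DatabaseCoverage("pictar", 28, 44)
        )
        assert set(norm.round(10)) == {round(100 * 28 / 44, 10)}

    def test_degenerate_ranking_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalise_ranking(
                pd.Series({"a": -1.0, "b": 0.0}), DatabaseCoverage("pictar", 28, 44)
            )

    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=15).filter(
            lambda xs: max(xs) > 0
        )
    )
    def test_order_preserved_and_bounded(self, values):
        sigma = pd.Series(values, index=[f"g{i}" for i in range(len(values))])
        cov = DatabaseCoverage("targetscan", 40, 44)
        norm = normalise_ranking(sigma, cov)
        assert list(norm.sort_values().index) == list(sigma.sort_values().index)
        assert norm.max() == pytest.approx(100 * 40 / 44)
        # the symmetric bound holds whenever the positive maximum dominates
        # in magnitude (always true for screen-scale negative family values)
        if max(values) >= max(abs(v) for v in values):
            assert (norm.abs() <= 100 * 40 / 44 + 1e-9).all()


class TestPooling:
    def test_sum_over_databases(self):
        normalised = {
            "microcosm": pd.Series({"garz": 4.7120}),
            "pictar": pd.Series({"garz": 0.5962}),
            "mirnaorg": pd.Series({"garz": 6.4735}),
            "targetscan": pd.Series({"garz": 19.5843}),
        }
        pooled = pool_databases(normalised)
        assert pooled.loc["garz", "pooled"] == pytest.approx(31.3660)

    def test_single_database_gene(self):
        pooled = pool_databases(
            {"microcosm": pd.Series({"a": 7.0}), "pictar": pd.Series({"b": 2.0})}
        )
        assert pooled.loc["a", "pooled"] == 7.0
        assert pooled.loc["b", "pooled"] == 2.0

    def test_invariant_to_database_order(self, rng):
        series = {
            db: pd.Series(rng.uniform(0, 50, 5), index=[f"g{i}" for i in range(5)])
            for db in ("microcosm", "pictar", "mirnaorg", "targetscan")
        }
        fwd = pool_databases(series)
        rev = pool_databases(dict(reversed(list(series.items()))))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_matches_brute_force_grid(self, rng):
        dbs = ["microcosm", "pictar", "mirnaorg"]
        genes = [f"g{i}" for i in range(10)]
        series = {
            db: pd.Series(
                {g: float(rng.uniform(0, 100)) for g in genes if rng.random() < 0.7}
            )
            for db in dbs
        }
        pooled = pool_databases(series)
        for g in pooled.index:
            brute = sum(series[db].get(g, 0.0) for db in dbs)
            assert pooled.loc[g, "pooled"] == pytest.approx(brute)

    def test_rank_dense_descending_ties_lexicographic(self):
        pooled = pool_databases(
            {"microcosm": pd.Series({"b": 5.0, "a": 5.0, "c": 9.0})}
        )
        assert list(pooled.index) == ["c", "a", "b"]
        assert list(pooled["rank"]) == [1, 2, 2]


class TestCommonTargets:
    def test_identical_sets(self):
        sets = {db: {"a", "b", "c"} for db in "wxyz"}
        inter, regions = common_targets(sets)
        assert inter == {"a", "b", "c"}
        assert regions["w&x&y&z"] == 3
        assert sum(v for k, v in regions.items() if k != "w&x&y&z") == 0

    def test_disjoint_sets(self):
        inter, regions = common_targets({"w": {"a"}, "x": {"b"}, "y": {"c"}, "z": {"d"}})
        assert inter == set()
        assert regions["w"] == regions["x"] == regions["y"] == regions["z"] == 1

    def test_census_matches_brute_force(self, rng):
        names = ["microcosm", "pictar", "mirnaorg", "targetscan"]
        genes = [f"g{i}" for i in range(60)]
        sets = {
            db: {g for g in genes if rng.random() < 0.5} or {genes[0]} for db in names
        }
        inter, regions = common_targets(sets)
        assert len(regions) == 2**4 - 1
        for r in range(1, 5):
            for combo in itertools.combinations(sorted(names), r):
                expected = sum(
                    all((g in sets[db]) == (db in combo) for db in names)
                    for g in genes
                )
                assert regions["&".join(combo)] == expected
        assert inter == set.intersection(*sets.values())
        # exclusive regions partition the union
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            common_targets({"only": {"a"}})
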