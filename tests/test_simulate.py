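"""Synthetic screen generator: determinism, structure, planted recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirtarrank import ranking, simulate, strength, validation
from mirtarrank.simulate import ScreenSimConfig


@pytest.fixture(scope="module")
def small_config():
    return ScreenSimConfig(n_genes=2000, n_essential_genes=20, seed=20260920)


def run_ranking(config):
    """Full synthetic pipeline: screen -> strengths -> databases -> pooled."""
    streams = config.streams()
    screen_df, ratios, mirna_lines = simulate.simulate_mirna_screen(
        config, streams["survival"]
    )
    strengths = simulate.screen_strengths(screen_df, mirna_lines)
    db_rng = streams["databases"]
    planted = simulate.plant_essential_genes(config, db_rng)
    sim = simulate.simulate_prediction_databases(config, planted, db_rng)
    dbs = simulate.collapsed_databases(sim)
    base = {m: s.av_chi2 for m, s in strengths.items()}
    with_fams = dict(base)
    with_fams.update(
        {f: s.av_chi2 for f, s in
         strength.apply_families(strengths, sim["families"]).items()}
    )
    sigmas, covs = {}, {}
    for db, df in dbs.items():
        smap = with_fams if db == "targetscan" else base
        sigmas[db] = ranking.step2_gene_sum(ranking.step1_weighted(df, smap))
        covs[db] = ranking.DatabaseCoverage(
            db, len(sim["db_mirnas"][db]), config.n_mirnas
        )
    normalised = {db: ranking.normalise_ranking(s, covs[db]) for db, s in sigmas.items()}
    pooled = ranking.pool_databases(normalised)
    return {"pooled": pooled, "planted": planted, "sigmas": sigmas,
            "ratios": ratios, "sim": sim, "strengths": strengths}


class TestSurvivalSimulation:
    def test_same_seed_identical_output(self, small_config):
        rng1 = small_config.streams()["survival"]
        rng2 = small_config.streams()["survival"]
        a = simulate.simulate_survival(small_config, {"x": 1.0, "y": 2.0}, rng1)
        b = simulate.simulate_survival(small_config, {"x": 1.0, "y": 2.0}, rng2)
        pd.testing.assert_frame_equal(a, b)

    def test_extreme_hazard_kills_early(self, small_config):
        rng = small_config.streams()["survival"]
        df = simulate.simulate_survival(small_config, {"doomed": 1e4}, rng)
        assert df["event"].all()
        assert df["time"].median() < 1.0

    def test_censoring_at_study_end(self):
        config = ScreenSimConfig(study_days=10, baseline_hazard=0.01, seed=3)
        rng = config.streams()["survival"]
        df = simulate.simulate_survival(config, {"hardy": 0.5}, rng)
        censored = df[~df["event"]]
        assert len(censored) > 0
        assert (censored["time"] == 10).all()

    def test_null_rejection_rate_near_alpha(self):
        """Equal-hazard pairs are rejected at ~alpha by the log-rank test."""
        from mirtarrank.survival import SurvivalRecord, logrank_chi2

        config = ScreenSimConfig(seed=5)
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 200
        for _ in range(n_reps):
            df = simulate.simulate_survival(config, {"a": 1.0, "b": 1.0}, rng)
            groups = {
                g: [SurvivalRecord(r.subject_id, g, r.time, r.event)
                    for r in sub.itertuples(index=False)]
                for g, sub in df.groupby("genotype")
            }
            _, p = logrank_chi2(groups["a"], groups["b"])
            rejections += p < 0.05
        assert 0.015 <= rejections / n_reps <= 0.10


class TestDatabaseSimulation:
    def test_coverage_counts_match_study(self, small_config):
        rng = small_config.streams()["databases"]
        planted = simulate.plant_essential_genes(small_config, rng)
        sim = simulate.simulate_prediction_databases(small_config, planted, rng)
        counts = {db: len(ms) for db, ms in sim["db_mirnas"].items()}
        assert counts == {"microcosm": 31, "pictar": 28, "mirnaorg": 43,
                          "targetscan": 40}

    def test_full_coverage_full_overlap(self):
        config = ScreenSimConfig(
            n_genes=50, n_mirnas=8, n_essential_genes=2, overlap_target=1.0,
            db_coverage={db: 1.0 for db in simulate.DEFAULT_DB_COVERAGE}, seed=9,
        )
        rng = config.streams()["databases"]
        planted = simulate.plant_essential_genes(config, rng)
        sim = simulate.simulate_prediction_databases(config, planted, rng)
        dbs = simulate.collapsed_databases(sim)
        gene_sets = {db: set(df["gene_id"]) for db, df in dbs.items()}
        inter, _ = ranking.common_targets(gene_sets)
        assert inter == set.union(*gene_sets.values())

    def test_mirnaorg_raw_scores_negative_targetscan_site_lists(self, small_config):
        rng = small_config.streams()["databases"]
        planted = simulate.plant_essential_genes(small_config, rng)
        sim = simulate.simulate_prediction_databases(small_config, planted, rng)
        assert (sim["tables"]["mirnaorg"]["raw_score"] < 0).all()
        assert {"site_type", "conservation", "count"} <= set(
            sim["tables"]["targetscan"].columns
        )


class TestEndToEnd:
    def test_planted_genes_recovered_and_effect_mass_correlates(self, small_config):
        res = run_ranking(small_config)
        pooled, planted = res["pooled"], res["planted"]
        top5 = set(pooled.index[: int(0.05 * len(pooled))])
        recovered = sum(g in top5 for g in planted) / len(planted)
        assert recovered >= 0.8

        # planted effect mass (sum of targeting miRNAs' true strengths)
        # orders the planted genes consistently with the pooled score
        truth = {m: s.av_chi2 for m, s in res["strengths"].items()}
        mass = pd.Series(
            {g: sum(truth[m] for m in ms) for g, ms in planted.items()}
        )
        rho = stats.spearmanr(mass, pooled["pooled"].reindex(mass.index)).statistic
        assert rho > 0.8 or len(planted) < 5

    def test_rnai_on_planted_genes_confirms(self, small_config):
        rng = small_config.streams()["rnai"]
        genes = [f"gene{i}" for i in range(20)]
        hrs = {g: (3.0, 4.5) for g in genes}
        df = simulate.simulate_rnai_lines(small_config, hrs, rng)
        results = simulate.rnai_line_results(
            df, {g: [f"{g}/IR1", f"{g}/IR2"] for g in genes}
        )
        cats = [validation.categorize(lines) for lines in results.values()]
        assert cats.count("confirmed_2x") / len(cats) >= 0.9


def test_write_screen_emits_complete_bundle(tmp_path):
    config = ScreenSimConfig(
        n_genes=120, n_mirnas=10, n_essential_genes=3, n_flies_per_group=25,
        db_coverage={"microcosm": 0.7, "pictar": 0.6, "mirnaorg": 1.0,
                     "targetscan": 0.9},
        seed=42,
    )
    truth = simulate.write_screen(config, tmp_path)
    for fname in (
        "mirna_screen_survival.tsv", "manifest.json", "families.tsv",
        "rnai_survival.tsv", "ground_truth.json",
        "predictions_microcosm.tsv", "predictions_targetscan.tsv",
    ):
        assert (tmp_path / fname).exists(), fname
    assert len(truth["planted_genes"]) == 3
    # byte-identical regeneration under the same seed
    truth2 = simulate.write_screen(config, tmp_path / "again")
    assert truth == truth2
    a = (tmp_path / "predictions_microcosm.tsv").read_bytes()
    b = (tmp_path / "again" / "predictions_microcosm.tsv").read_bytes()
    assert a == b
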