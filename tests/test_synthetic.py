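import numpy as np
import pandas as pd
import pytest

from dollomap import (
    NoiseConfig,
    SimConfig,
    inject_noise,
    pure_birth_tree,
    run_dollo_scm,
    simulate_matrix,
    study_scale_config,
)
from dollomap.synthetic import minimal_history_families


@pytest.fixture(scope="module")
def small_tree():
    return pure_birth_tree(12, 500.0, seed=99, stem_age=600.0)


class TestSimulateMatrix:
    def test_deterministic_under_seed(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.02, loss_rate=1e-3, seed=4)
        m1, t1 = simulate_matrix(cfg)
        m2, t2 = simulate_matrix(cfg)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        pd.testing.assert_frame_equal(t1.losses, t2.losses)

    def test_zero_loss_rate_full_clades(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.02, loss_rate=0.0, seed=1)
        m, truth = simulate_matrix(cfg)
        assert len(truth.losses) == 0
        tipdesc = small_tree.tip_descendants()
        labels = np.array(small_tree.tip_labels)
        for fam, br in truth.gains.set_index("family")["branch"].items():
            below = set(labels[tipdesc[br]])
            present = set(m.data.columns[m.data.loc[fam] == 1])
            assert present == below

    def test_zero_intensity_warns_and_is_empty(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.0, loss_rate=0.0, seed=1)
        with pytest.warns(UserWarning, match="no families"):
            m, truth = simulate_matrix(cfg)
        assert m.shape[0] == 0

    def test_poisson_family_count(self, small_tree):
        """Mean simulated family count over seeds matches intensity x total
        branch time within 3 standard errors."""
        lam = 0.01 * small_tree.total_branch_time()
        counts = []
        for s in range(100):
            cfg = SimConfig(tree=small_tree, gain_intensity=0.01, loss_rate=0.0, seed=s)
            _, truth = simulate_matrix(cfg)
            counts.append(truth.tip_states.shape[0])
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 3 * se

    def test_event_times_within_branches(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.05, loss_rate=2e-3, seed=6)
        _, truth = simulate_matrix(cfg)
        for df in (truth.gains, truth.losses):
            for _, row in df.iterrows():
                b = small_tree.branch(int(row["branch"]))
                assert b.end - 1e-9 <= row["time"] <= b.start + 1e-9

    def test_burst_branch_enriched(self, small_tree):
        burst = int(small_tree.tip_ids[0])
        base = SimConfig(tree=small_tree, gain_intensity=0.02, loss_rate=0.0, seed=2)
        boosted = SimConfig(tree=small_tree, gain_intensity=0.02, loss_rate=0.0, seed=2,
                            burst_branches={burst: 25.0})
        _, t0 = simulate_matrix(base)
        _, t1 = simulate_matrix(boosted)
        n0 = (t0.gains["branch"] == burst).sum()
        n1 = (t1.gains["branch"] == burst).sum()
        assert n1 > n0 + 5

    def test_step_intensity_respects_window(self, small_tree):
        # all gain mass inside 400-300 Ma
        cfg = SimConfig(tree=small_tree, gain_intensity=[(400.0, 300.0, 0.1)],
                        loss_rate=0.0, seed=3)
        _, truth = simulate_matrix(cfg)
        assert len(truth.gains) > 0
        assert truth.gains["time"].between(300.0, 400.0).all()

    def test_validation(self, small_tree):
        with pytest.raises(ValueError):
            SimConfig(tree=small_tree, gain_intensity=-1.0, loss_rate=0.0)
        with pytest.raises(ValueError):
            SimConfig(tree=small_tree, gain_intensity=1.0, loss_rate=-0.1)
        with pytest.raises(ValueError):
            SimConfig(tree=small_tree, gain_intensity=1.0, loss_rate=0.0,
                      burst_branches={3: 0.0})


class TestDolloBound:
    def test_inferred_never_exceeds_truth_and_matches_when_minimal(self, fixture_tree):
        """Parsimony undercounts hidden losses but recovers every family
        whose true history is already minimal."""
        cfg = study_scale_config(fixture_tree, loss_rate=1e-3, seed=21)
        m, truth = simulate_matrix(cfg)
        maps = run_dollo_scm(m, fixture_tree, n_reps=1, seed=0)
        inferred = maps.loss_counts()
        true_counts = truth.loss_counts(observable_only=True)
        aligned = true_counts.reindex(inferred.index)
        assert (inferred <= aligned).all()
        minimal = minimal_history_families(truth, fixture_tree)
        assert len(minimal) > 0
        for fam in minimal:
            assert inferred[fam] == aligned[fam]


class TestInjectNoise:
    def test_identity_when_rates_zero(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.05, loss_rate=0.0, seed=5)
        m, _ = simulate_matrix(cfg)
        noisy, manifest = inject_noise(m, NoiseConfig(fn_rate=0.0, fp_singletons=0, seed=1))
        pd.testing.assert_frame_equal(noisy.data, m.data)
        assert manifest["masked_cells"] == [] and manifest["added_singletons"] == []

    def test_full_masking_of_one_tip(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.05, loss_rate=0.0, seed=5)
        m, _ = simulate_matrix(cfg)
        victim = m.taxa[0]
        noisy, manifest = inject_noise(
            m, NoiseConfig(fn_rate={victim: 1.0}, seed=1)
        )
        assert (noisy.data[victim] == 0).all()
        n_present = int(m.data[victim].sum())
        assert len(manifest["masked_cells"]) == n_present

    def test_manifest_explains_matrix_difference(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.05, loss_rate=1e-3, seed=8)
        m, _ = simulate_matrix(cfg)
        noisy, manifest = inject_noise(
            m, NoiseConfig(fn_rate=0.2, fp_singletons=2, seed=3)
        )
        rebuilt = m.data.copy()
        for fam, taxon in manifest["masked_cells"]:
            rebuilt.loc[fam, taxon] = 0
        for fam in manifest["added_singletons"]:
            taxon = fam.split("_")[1]
            row = pd.Series(0, index=rebuilt.columns, name=fam)
            row[taxon] = 1
            rebuilt = pd.concat([rebuilt, row.to_frame().T])
        rebuilt = rebuilt.drop(index=manifest["dropped_all_absent"])
        pd.testing.assert_frame_equal(
            noisy.data.sort_index(), rebuilt.sort_index().astype(np.int8)
        )

    def test_masking_inflates_apparent_losses(self, fixture_tree):
        """False negatives on a loss-free simulation create apparent losses."""
        cfg = study_scale_config(fixture_tree, loss_rate=0.0, seed=13)
        m, truth = simulate_matrix(cfg)
        assert len(truth.losses) == 0
        noisy, manifest = inject_noise(m, NoiseConfig(fn_rate=0.1, seed=2))
        maps = run_dollo_scm(noisy, fixture_tree, n_reps=1, seed=0)
        assert maps.loss_counts().sum() > 0

    def test_noise_monotone_in_fn_rate(self, fixture_tree):
        """Expected inferred losses are non-decreasing in the false-negative
        rate (checked on seed-averaged counts)."""
        cfg = study_scale_config(fixture_tree, loss_rate=0.0, seed=17)
        m, _ = simulate_matrix(cfg)
        means = []
        for rate in (0.02, 0.1, 0.3):
            tot = []
            for s in range(3):
                noisy, _ = inject_noise(m, NoiseConfig(fn_rate=rate, seed=s))
                maps = run_dollo_scm(noisy, fixture_tree, n_reps=1, seed=0)
                tot.append(maps.loss_counts().sum())
            means.append(np.mean(tot))
        assert means[0] < means[1] < means[2]

    def test_bad_rates_rejected(self, small_tree):
        cfg = SimConfig(tree=small_tree, gain_intensity=0.05, loss_rate=0.0, seed=5)
        m, _ = simulate_matrix(cfg)
        with pytest.raises(ValueError):
            inject_noise(m, NoiseConfig(fn_rate=1.5))
        with pytest.raises(ValueError):
            inject_noise(m, NoiseConfig(fp_singletons=-1))


class TestRecoveryExperiment:
    def test_report_structure_and_recovery(self, fixture_tree):
        from dollomap import recovery_experiment

        report = recovery_experiment(
            study_scale_config(fixture_tree, seed=3),
            noise_config=NoiseConfig(fn_rate=0.1, fp_singletons=3, seed=1),
            markov_truth=(0.002, 0.02, 400),
            n_reps=20,
            seed=2,
        )
        assert report["total_inferred_losses"] <= report["total_true_losses"]
        assert report["markov"]["converged"]
        assert report["markov"]["g_hat"] > 0
        assert report["noise"]["noisy_recent_losses"] >= report["noise"]["clean_recent_losses"]

    def test_programmed_burst_branch_is_flagged(self, fixture_tree):
        from dollomap import flag_rate_outliers, per_branch_rates

        # pick a deep internal branch and boost its gain intensity 30x
        internal = [b.child for b in fixture_tree.branches(include_stem=False)
                    if fixture_tree.children[b.child] and b.duration > 50]
        burst = internal[0]
        cfg = study_scale_config(fixture_tree, seed=19)
        cfg.burst_branches = {burst: 30.0}
        m, _ = simulate_matrix(cfg)
        maps = run_dollo_scm(m, fixture_tree, n_reps=1, seed=0)
        flags = flag_rate_outliers(per_branch_rates(maps, fixture_tree))
        assert flags.loc[burst, "flag_high"]


class TestPureBirthTree:
    def test_shape_and_ages(self):
        t = pure_birth_tree(20, 300.0, seed=0, stem_age=350.0)
        assert t.n_tips == 20
        assert t.root_age == pytest.approx(300.0)
        assert t.stem_age == pytest.approx(350.0)
        for b in t.branches():
            assert b.duration >= 0

    def test_committed_fixture_matches_generator(self, fixture_tree):
        assert fixture_tree.n_tips == 35
        assert fixture_tree.root_age == pytest.approx(693.0)
        assert fixture_tree.stem_age == pytest.approx(720.0)
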