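"""Generator contracts: determinism, degenerate configs, moment recovery,
and the structural phenotypes the downstream stages rely on."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from fdgmismatch.errors import ConfigError
from fdgmismatch.mismatch import cohort_assign
from fdgmismatch.polarmap import LAD_TERRITORY, territory_summary
from fdgmismatch.signatures import MITO_GENES
from fdgmismatch.synthetic import (
    BulkConfig,
    CohortConfig,
    NucleiConfig,
    simulate_bulk_expression,
    simulate_cohort,
    simulate_nuclei,
    solve_truncnorm_loc,
    truncated_normal,
)

from conftest import zero_sd_config


class TestTruncatedNormal:
    def test_mean_matching_under_severe_truncation(self, rng):
        # configured month-1 Mismatch uptake: heavy mass beyond the 100% bound
        x = truncated_normal(rng, 56.0, 23.1, 0.0, 100.0, 200_000)
        assert x.min() >= 0 and x.max() <= 100
        assert x.mean() == pytest.approx(56.0, abs=3 * x.std() / np.sqrt(x.size))

    def test_solver_agrees_with_scipy_moment(self):
        loc = solve_truncnorm_loc(56.0, 23.1, 0.0, 100.0)
        a, b = (0 - loc) / 23.1, (100 - loc) / 23.1
        assert st.truncnorm.mean(a, b, loc=loc, scale=23.1) == pytest.approx(56.0)

    def test_impossible_bounds_rejected(self, rng):
        with pytest.raises(ConfigError):
            truncated_normal(rng, 50, 5, 60, 40, 10)
        with pytest.raises(ConfigError):
            truncated_normal(rng, 150, 5, 0, 100, 10)


class TestSimulateCohort:
    def test_bit_identical_reruns(self):
        c1 = simulate_cohort(CohortConfig(), seed=11)
        c2 = simulate_cohort(CohortConfig(), seed=11)
        pd.testing.assert_frame_equal(c1.animals, c2.animals)
        pd.testing.assert_frame_equal(c1.biomarkers, c2.biomarkers)
        pd.testing.assert_frame_equal(c1.ct, c2.ct)
        for p, q in zip(c1.profiles, c2.profiles):
            np.testing.assert_array_equal(p.uptake_raw, q.uptake_raw)
            np.testing.assert_array_equal(p.transmurality, q.transmurality)
            np.testing.assert_array_equal(p.contractility, q.contractility)

    def test_zero_sd_config_classifies_perfectly(self):
        cohort = simulate_cohort(zero_sd_config(), seed=3)
        table, _ = cohort_assign(cohort.profiles)
        merged = cohort.animals.merge(table, on="animal_id")
        assert (merged["group_intended"] == merged["group"]).all()

    def test_moment_recovery_against_config(self):
        # law-of-large-numbers check of the generator against its own config
        cfg = CohortConfig(n_match=4000, n_mismatch=4000)
        cohort = simulate_cohort(cfg, seed=5)
        a = cohort.animals
        for col, spec in [("ef_day3", cfg.ef_day3), ("ef_month1", cfg.ef_month1),
                          ("infarct_day3", cfg.infarct_day3)]:
            for grp, (mean, sd) in spec.items():
                vals = a.loc[a.group_intended == grp, col]
                se = vals.std() / np.sqrt(len(vals))
                assert vals.mean() == pytest.approx(mean, abs=3 * se)
                # bounds are far from these means: SDs also recovered
                assert vals.std() == pytest.approx(sd, rel=0.1)
        gl = a.glucose
        assert gl.mean() == pytest.approx(cfg.glucose[0], abs=3 * gl.std() / np.sqrt(len(gl)))

    def test_label_recovery_rate(self):
        cfg = CohortConfig(n_match=150, n_mismatch=50)
        cohort = simulate_cohort(cfg, seed=7)
        table, _ = cohort_assign(cohort.profiles)
        merged = cohort.animals.merge(table, on="animal_id")
        assert (merged["group_intended"] == merged["group"]).mean() >= 0.95

    def test_month1_uptake_ordering(self):
        # Mismatch develops a month-1 uptake defect below the Match level
        cfg = CohortConfig(n_match=300, n_mismatch=300)
        cohort = simulate_cohort(cfg, seed=9)
        terr = {g: [] for g in ("Match", "Mismatch")}
        groups = dict(zip(cohort.animals.animal_id, cohort.animals.group_intended))
        for p in cohort.profiles_at("month1"):
            terr[groups[p.animal_id]].append(
                territory_summary(p, LAD_TERRITORY)["mean_uptake"]
            )
        assert np.mean(terr["Mismatch"]) < np.mean(terr["Match"])

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            CohortConfig(n_match=1, n_mismatch=0)
        with pytest.raises(ConfigError):
            CohortConfig(glucose=(105.0, -1.0))


class TestSimulateBulk:
    def test_null_effects_leave_scores_indistinguishable(self):
        from fdgmismatch.immune import signature_score

        cfg = BulkConfig(effects={})
        n_sig = 0
        for rep in range(10):
            bulk = simulate_bulk_expression(
                cfg, arms=(("Match", "AMI"), ("Mismatch", "AMI")),
                n_per_arm=8, seed=100 + rep,
            )
            # coherence filter off: null signatures are incoherent by design
            scores = signature_score(bulk.counts, cfg.signatures,
                                     coherence_cutoff=-1.0)["scores"]
            grp = bulk.sample_meta["group"]
            mono = scores.loc["Monocytes"]
            p = st.ranksums(mono[grp == "Match"], mono[grp == "Mismatch"]).pvalue
            n_sig += p < 0.05
        assert n_sig <= 2  # null p-values behave like a null

    def test_monocyte_effect_raises_score_in_mismatch_ami(self):
        from fdgmismatch.immune import signature_score

        cfg = BulkConfig()
        wins = 0
        for rep in range(10):
            bulk = simulate_bulk_expression(
                cfg, arms=(("Match", "AMI"), ("Mismatch", "AMI")),
                n_per_arm=10, seed=200 + rep,
            )
            scores = signature_score(bulk.counts, cfg.signatures)["scores"]
            grp = bulk.sample_meta["group"]
            mono = scores.loc["Monocytes"]
            wins += mono[grp == "Mismatch"].mean() > mono[grp == "Match"].mean()
        assert wins >= 10 * 0.95

    def test_fixed_seed_reproducible(self):
        b1 = simulate_bulk_expression(BulkConfig(), n_per_arm=2, seed=4)
        b2 = simulate_bulk_expression(BulkConfig(), n_per_arm=2, seed=4)
        pd.testing.assert_frame_equal(b1.counts, b2.counts)

    def test_signature_background_disjointness_enforced(self):
        from fdgmismatch.signatures import SignatureSet

        with pytest.raises(ConfigError):
            BulkConfig(signatures=SignatureSet({"X": ["G0001", "G0002", "G0003"]}))


class TestSimulateNuclei:
    def test_pure_cardiomyocyte_config(self, nuclei_config):
        import dataclasses

        cfg = dataclasses.replace(
            nuclei_config,
            proportions={("Border", "Match"): {"Cardiomyocytes": 1.0}},
        )
        adata = simulate_nuclei(cfg, "Border", "Match", 100, seed=1)
        assert (adata.obs["true_type"] == "Cardiomyocytes").all()

    def test_ami_region_has_heavier_mito_tail(self, nuclei_config):
        ami = simulate_nuclei(nuclei_config, "AMI", "Mismatch", 1500, seed=2)
        remote = simulate_nuclei(nuclei_config, "Remote", "Mismatch", 1500, seed=3)
        a, b = nuclei_config.mito_beta["AMI"]
        target = a / (a + b)
        se = ami.obs.mito_fraction.std() / np.sqrt(len(ami))
        assert ami.obs.mito_fraction.mean() == pytest.approx(target, abs=4 * se)
        assert ami.obs.mito_fraction.mean() > remote.obs.mito_fraction.mean()
        assert (ami.obs.mito_fraction > 0.2).mean() > (remote.obs.mito_fraction > 0.2).mean()

    def test_fixed_seed_identical_latent_labels(self, nuclei_config):
        a1 = simulate_nuclei(nuclei_config, "Border", "Match", 200, seed=5)
        a2 = simulate_nuclei(nuclei_config, "Border", "Match", 200, seed=5)
        assert (a1.obs["true_type"] == a2.obs["true_type"]).all()
        assert (a1.X != a2.X).nnz == 0

    def test_detected_genes_span_qc_boundary(self, nuclei_config):
        adata = simulate_nuclei(nuclei_config, "Border", "Match", 800, seed=6)
        assert (adata.obs.detected_genes < 200).any()
        assert (adata.obs.detected_genes >= 200).any()

    def test_mito_genes_present(self, nuclei_config):
        adata = simulate_nuclei(nuclei_config, "Border", "Match", 50, seed=7)
        assert set(MITO_GENES) <= set(adata.var_names)
        assert len(MITO_GENES) == 13

    def test_bad_proportions_rejected(self, nuclei_config):
        import dataclasses

        with pytest.raises(ConfigError, match="sum"):
            dataclasses.replace(
                nuclei_config,
                proportions={("Border", "Match"): {"Cardiomyocytes": 0.5}},
            )
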