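import numpy as np
import pandas as pd
import pytest

from senemeth import io_formats as iof
from senemeth import synthetic_data as sd
from senemeth.preprocess import compute_beta


class TestParams:
    @pytest.mark.parametrize("kwargs", [
        {"n_cpgs": 0},
        {"phi": 0.0},
        {"shared_fraction": 1.5},
        {"effect_range": (0.0, 0.4)},
        {"mixture_weights": (0.5, 0.5, 0.5)},
        {"n_cpgs": 10, "n_dm_culture": (10, 10), "n_dm_aging": (0, 0)},
    ])
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sd.SimulationParams(**kwargs)


class TestAnnotation:
    def test_deterministic(self, small_params):
        a1, s1 = sd.generate_annotation(small_params)
        a2, s2 = sd.generate_annotation(small_params)
        pd.testing.assert_frame_equal(a1, a2)
        assert s1.names() == s2.names()
        for n in s1.names():
            assert s1[n].members == s2[n].members

    def test_set_members_within_gene_universe(self, small_annotation):
        annotation, sets = small_annotation
        universe = set(annotation["gene_symbol"].dropna())
        for name in sets.names():
            assert sets[name].members <= universe

    def test_cpgs_per_gene_bounded(self, small_annotation):
        annotation, _ = small_annotation
        counts = annotation.groupby("gene_symbol").size()
        assert counts.between(1, 3).all()

    def test_tf_target_set_present(self, small_annotation):
        _, sets = small_annotation
        assert sd.TF_TARGET_SET in sets

    def test_bands_roundtrip_through_reader(self, tmp_path,
                                            small_annotation):
        annotation, _ = small_annotation
        path = tmp_path / "ann.tsv"
        iof.write_annotation_tsv(annotation, path)
        back = iof.read_annotation_tsv(path)  # validates band grammar
        assert list(back["band"]) == list(annotation["band"])


class TestMethylationStudy:
    def test_seeded_determinism(self, small_params):
        b1, d1, t1 = sd.generate_methylation_study(small_params)
        b2, d2, t2 = sd.generate_methylation_study(small_params)
        assert np.array_equal(b1.values.to_numpy(), b2.values.to_numpy())
        pd.testing.assert_frame_equal(d1.table, d2.table)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_betas_in_unit_interval(self, small_study):
        beta, _, _ = small_study
        arr = beta.values.to_numpy()
        assert np.all((arr >= 0) & (arr <= 1))

    def test_design_mirrors_default_16_sample_layout(self):
        _, design, _ = sd.generate_methylation_study(
            sd.SimulationParams(n_cpgs=50, n_dm_culture=(2, 2),
                                n_dm_aging=(2, 2), seed=0))
        tbl = design.table
        assert len(tbl) == 16
        assert tbl["donor_id"].nunique() == 8
        assert (tbl.groupby("age_group")["donor_id"].nunique() ==
                pd.Series({"elderly": 4, "young": 4},
                          name="donor_id")).all()
        assert set(tbl["passage_group"]) == {"early", "late"}

    def test_no_effects_all_null(self):
        params = sd.SimulationParams(n_cpgs=300, n_dm_culture=(0, 0),
                                     n_dm_aging=(0, 0), seed=1)
        _, _, truth = sd.generate_methylation_study(params)
        assert (truth.table["label_culture"] == "null").all()
        assert (truth.table["label_aging"] == "null").all()
        assert (truth.table["delta_culture"] == 0).all()

    def test_large_n_mean_delta_recovery(self):
        # law-of-large-numbers check: 100 hyper CpGs at +0.30, phi=200
        params = sd.SimulationParams(
            n_cpgs=3000, n_dm_culture=(100, 0), n_dm_aging=(0, 0),
            effect_range=(0.30, 0.30), phi=200.0, seed=7)
        beta, design, truth = sd.generate_methylation_study(params)
        dm = truth.true_positives("culture", "hyper")
        early = design.samples_where(passage_group="early")
        late = design.samples_where(passage_group="late")
        observed = (beta.values.loc[dm, late].mean(axis=1)
                    - beta.values.loc[dm, early].mean(axis=1))
        assert abs(observed.mean() - 0.30) < 0.02

    def test_truth_labels_match_delta_signs(self, small_study):
        _, _, truth = small_study
        t = truth.table
        assert ((t["label_culture"] == "null") ==
                (t["delta_culture"] == 0)).all()
        assert (t.loc[t["label_culture"] == "hyper", "delta_culture"]
                > 0).all()
        assert (t.loc[t["label_aging"] == "hypo", "delta_aging"] < 0).all()

    def test_shared_effects_exist(self):
        params = sd.SimulationParams(n_cpgs=500, n_dm_culture=(20, 20),
                                     n_dm_aging=(20, 20),
                                     shared_fraction=0.5, seed=3)
        _, _, truth = sd.generate_methylation_study(params)
        both = (truth.table["label_culture"] != "null") & \
               (truth.table["label_aging"] != "null")
        assert both.sum() == 20  # 0.5 * min(40, 40)

    def test_passage_drift_increases_late_effects(self):
        base = dict(n_cpgs=400, n_dm_culture=(20, 0), n_dm_aging=(0, 0),
                    effect_range=(0.2, 0.2), phi=500.0, seed=9)
        no_drift = sd.SimulationParams(**base)
        drift = sd.SimulationParams(**base, passage_drift=0.02)
        b0, d0, t0 = sd.generate_methylation_study(no_drift)
        b1, d1, t1 = sd.generate_methylation_study(drift)
        dm = t0.true_positives("culture")
        assert t1.table.loc[dm, "delta_culture"].mean() > \
            t0.table.loc[dm, "delta_culture"].mean()


class TestIntensities:
    def test_exact_roundtrip_no_noise_no_offset(self, small_study):
        beta, _, _ = small_study
        pair = sd.generate_intensities(beta, noise_sd=0.0, offset=0.0)
        back = compute_beta(pair, offset=0.0)
        np.testing.assert_allclose(back.values.to_numpy(),
                                   beta.values.to_numpy(), atol=1e-12)

    def test_exact_roundtrip_with_offset(self, small_study):
        beta, _, _ = small_study
        pair = sd.generate_intensities(beta, offset=100.0, noise_sd=0.0)
        back = compute_beta(pair, offset=100.0)
        np.testing.assert_allclose(back.values.to_numpy(),
                                   beta.values.to_numpy(), atol=1e-9)

    def test_zero_beta_gives_zero_m_channel(self):
        beta = iof.BetaMatrix(pd.DataFrame([[0.0]], index=["cg1"],
                                           columns=["s1"]))
        pair = sd.generate_intensities(beta, noise_sd=0.0)
        assert pair.methylated.iloc[0, 0] == 0.0

    def test_roundtrip_error_small_at_default_noise(self):
        rng = np.random.default_rng(5)
        n = 1000
        beta = iof.BetaMatrix(pd.DataFrame(
            rng.uniform(0.02, 0.98, size=(n, 2)),
            index=[f"cg{i}" for i in range(n)], columns=["s1", "s2"]))
        pair = sd.generate_intensities(beta, seed=5)
        back = compute_beta(pair, offset=0.0)
        err = np.abs(back.values.to_numpy() - beta.values.to_numpy())
        assert err.mean() < 0.02

    def test_channels_nonnegative(self, small_study):
        beta, _, _ = small_study
        pair = sd.generate_intensities(beta, offset=100.0, seed=1)
        assert (pair.methylated.to_numpy() >= 0).all()
        assert (pair.unmethylated.to_numpy() >= 0).all()


class TestExpression:
    def test_zero_slope_zero_noise_constant(self, small_study,
                                            small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        expr = sd.generate_expression(beta, annotation, slope=0.0,
                                      noise_sd=0.0, intercept=8.0)
        assert np.allclose(expr.intensities.to_numpy(), 8.0)

    def test_negative_slope_gives_negative_correlation(self, small_study,
                                                       small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        expr = sd.generate_expression(beta, annotation, slope=-4.0, seed=2)
        gmb = sd.gene_mean_beta(beta, annotation)
        assert len(gmb) >= 100
        r = np.corrcoef(gmb.mean(axis=1),
                        expr.intensities.mean(axis=1))[0, 1]
        assert r < -0.5

    def test_seeded_determinism(self, small_study, small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        e1 = sd.generate_expression(beta, annotation, seed=4)
        e2 = sd.generate_expression(beta, annotation, seed=4)
        pd.testing.assert_frame_equal(e1.intensities, e2.intensities)
        pd.testing.assert_frame_equal(e1.calls, e2.calls)


class TestPyroProfiles:
    def test_constant_offset_no_jitter(self, small_study, small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        profiles = sd.generate_pyro_profiles(
            beta, annotation, platform_offset=-0.1, jitter_sd=0.0, seed=0)
        for prof in profiles:
            expected = 100.0 * np.clip(
                beta.values.loc[prof.target_cpg_id].to_numpy() - 0.1,
                0.0, 1.0)
            for pos in prof.percent.index:
                np.testing.assert_allclose(
                    prof.percent.loc[pos].to_numpy(), expected, atol=1e-9)

    def test_values_clipped(self, small_study, small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        profiles = sd.generate_pyro_profiles(
            beta, annotation, platform_offset=0.29, jitter_sd=0.1, seed=1)
        for prof in profiles:
            arr = prof.percent.to_numpy()
            assert arr.min() >= 0.0 and arr.max() <= 100.0

    def test_neighbor_target_correlation_high(self, small_study,
                                              small_annotation):
        beta, _, truth = small_study
        annotation, _ = small_annotation
        targets = list(truth.true_positives("culture"))[:6]
        profiles = sd.generate_pyro_profiles(beta, annotation,
                                             target_cpgs=targets, seed=2)
        corrs = []
        for prof in profiles:
            target = prof.percent.loc[prof.target_position].to_numpy()
            for pos in prof.percent.index:
                if pos != prof.target_position:
                    corrs.append(np.corrcoef(
                        target, prof.percent.loc[pos].to_numpy())[0, 1])
        assert np.mean(corrs) >= 0.8

    def test_invalid_offset_rejected(self, small_study, small_annotation):
        beta, _, _ = small_study
        annotation, _ = small_annotation
        with pytest.raises(ValueError, match="platform_offset"):
            sd.generate_pyro_profiles(beta, annotation, platform_offset=0.5)
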