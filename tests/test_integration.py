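import numpy as np
import pandas as pd
import pytest

from senemeth import integration as intg
from senemeth import synthetic_data as sd
from senemeth.io_formats import BetaMatrix, ExpressionMatrix, PyroProfile


def _expression(calls_per_probe, intensities=None, symbols=None):
    probes = list(calls_per_probe)
    n = len(calls_per_probe[probes[0]])
    samples = [f"s{j}" for j in range(n)]
    calls = pd.DataFrame({s: [calls_per_probe[p][j] for p in probes]
                          for j, s in enumerate(samples)}, index=probes)
    if intensities is None:
        intensities = pd.DataFrame(8.0, index=probes, columns=samples)
    else:
        intensities = pd.DataFrame(intensities, index=probes,
                                   columns=samples)
    symbols = symbols or {p: p.split("_")[0] for p in probes}
    return ExpressionMatrix(intensities, calls,
                            pd.Series(symbols, index=probes))


class TestPresentFilter:
    def test_half_present_excluded(self):
        expr = _expression({"p1": list("PPPAAA")})
        assert intg.present_filter(expr) == []

    def test_majority_present_retained(self):
        expr = _expression({"p1": list("PPPPAA")})
        assert intg.present_filter(expr) == ["p1"]

    def test_all_absent_excluded(self):
        expr = _expression({"p1": list("AAAAAA")})
        assert intg.present_filter(expr) == []


class TestMatchBySymbol:
    def _annotation(self):
        return pd.DataFrame({
            "gene_symbol": ["DLX5", "RUNX3", None],
            "chromosome": "10", "band": "10q22", "island_id": "i",
            "neighbor_offsets": [[]] * 3,
        }, index=["cg1", "cg2", "cg3"])

    def test_multiple_probes_one_link(self):
        expr = _expression({"DLX5_a": list("PP"), "DLX5_b": list("PP")},
                           symbols={"DLX5_a": "DLX5", "DLX5_b": "DLX5"})
        mapping = intg.match_by_symbol(self._annotation(), expr)
        assert mapping.loc["cg1", "probe_ids"] == ("DLX5_a", "DLX5_b")

    def test_unmatched_cpgs_excluded(self):
        expr = _expression({"DLX5_a": list("PP")},
                           symbols={"DLX5_a": "DLX5"})
        mapping = intg.match_by_symbol(self._annotation(), expr)
        assert list(mapping.index) == ["cg1"]

    def test_row_order_invariance(self):
        expr = _expression({"DLX5_a": list("PP"), "RUNX3_a": list("PP")},
                           symbols={"DLX5_a": "DLX5", "RUNX3_a": "RUNX3"})
        ann = self._annotation()
        m1 = intg.match_by_symbol(ann, expr)
        m2 = intg.match_by_symbol(ann.iloc[::-1], expr)
        assert set(m1.index) == set(m2.index)

    def test_commutes_with_present_filter(self):
        expr = _expression({"DLX5_a": list("PPPPPP"),
                            "RUNX3_a": list("PAAAAA")},
                           symbols={"DLX5_a": "DLX5", "RUNX3_a": "RUNX3"})
        ann = self._annotation()
        retained = intg.present_filter(expr)
        filtered_then_matched = intg.match_by_symbol(ann, expr, retained)
        matched = intg.match_by_symbol(ann, expr)
        matched_then_filtered = matched[matched["probe_ids"].map(
            lambda ps: all(p in retained for p in ps))]
        assert list(filtered_then_matched.index) == \
            list(matched_then_filtered.index)


@pytest.fixture(scope="module")
def linked_study():
    params = sd.SimulationParams(n_cpgs=400, n_dm_culture=(10, 10),
                                 n_dm_aging=(0, 0),
                                 effect_range=(0.25, 0.35), seed=17)
    beta, design, truth = sd.generate_methylation_study(params)
    annotation, _ = sd.generate_annotation(params)
    expr = sd.generate_expression(beta, annotation, slope=-4.0,
                                  noise_sd=0.1, seed=17)
    mapping = intg.match_by_symbol(annotation, expr)
    early = design.samples_where(passage_group="early")
    late = design.samples_where(passage_group="late")
    linked = intg.link_genes(beta, expr, mapping, (early, late),
                             (early, late))
    return beta, design, truth, annotation, expr, linked


class TestMethylationExpressionSummary:
    def test_negative_coupling_bins_strictly_decreasing(self, linked_study):
        *_, linked = linked_study
        summary = intg.methylation_expression_summary(linked)
        means = summary.loc[~summary["empty"], "mean_intensity"].to_numpy()
        assert len(means) >= 2
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_flat_coupling_equal_bins(self):
        params = sd.SimulationParams(n_cpgs=200, n_dm_culture=(0, 0),
                                     n_dm_aging=(0, 0), seed=18)
        beta, design, _ = sd.generate_methylation_study(params)
        annotation, _ = sd.generate_annotation(params)
        expr = sd.generate_expression(beta, annotation, slope=0.0,
                                      noise_sd=0.0, intercept=7.0)
        mapping = intg.match_by_symbol(annotation, expr)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        linked = intg.link_genes(beta, expr, mapping, groups, groups)
        summary = intg.methylation_expression_summary(linked)
        filled = summary.loc[~summary["empty"], "mean_intensity"]
        np.testing.assert_allclose(filled, 7.0, atol=1e-12)

    def test_empty_bin_flagged(self, linked_study):
        *_, linked = linked_study
        low = linked[linked["mean_beta"] < 0.3]
        summary = intg.methylation_expression_summary(
            low, bin_edges=(0.0, 0.3, 0.6, 1.0))
        assert summary["empty"].iloc[1:].all()

    def test_bad_edges_rejected(self, linked_study):
        *_, linked = linked_study
        with pytest.raises(ValueError, match="increasing"):
            intg.methylation_expression_summary(linked, (0.5, 0.5))


class TestDeltaVsExpression:
    def test_exact_negative_coupling(self):
        linked = pd.DataFrame({
            "delta_beta": [0.3, -0.2, 0.1, -0.4],
            "log2_ratio": [-0.6, 0.4, -0.2, 0.8],
            "direction_agreement": [1.0, 1.0, 1.0, 1.0],
        }, index=["A", "B", "C", "D"])
        out = intg.delta_vs_expression(linked, ["A", "B", "C", "D"])
        assert out["correlation"] == pytest.approx(-1.0)
        assert out["agreement_fraction"] == 1.0

    def test_zero_delta_candidate_excluded(self):
        linked = pd.DataFrame({
            "delta_beta": [0.0, 0.3],
            "log2_ratio": [0.5, -0.6],
            "direction_agreement": [np.nan, 1.0],
        }, index=["A", "B"])
        out = intg.delta_vs_expression(linked, ["A", "B"])
        assert out["n_candidates"] == 1
        assert out["agreement_fraction"] == 1.0

    def test_independent_ratios_small_correlation(self):
        rng = np.random.default_rng(12)
        n = 400
        linked = pd.DataFrame({
            "delta_beta": rng.normal(0, 0.1, n),
            "log2_ratio": rng.normal(0, 0.5, n),
            "direction_agreement": np.nan,
        }, index=[f"G{i}" for i in range(n)])
        out = intg.delta_vs_expression(linked)
        # null r is ~N(0, 1/sqrt(n)); 4 sigma bound
        assert abs(out["correlation"]) < 4 / np.sqrt(n)

    def test_empty_mapping_error(self):
        with pytest.raises(ValueError):
            intg.delta_vs_expression(pd.DataFrame())

    def test_true_dm_gene_agreement_high(self, linked_study):
        beta, design, truth, annotation, expr, linked = linked_study
        dm_genes = sorted(set(annotation.loc[
            truth.true_positives("culture"), "gene_symbol"].dropna()))
        out = intg.delta_vs_expression(linked, dm_genes)
        assert out["n_candidates"] >= 6
        assert out["agreement_fraction"] >= 0.9


class TestComparePlatforms:
    def _profiles_from(self, beta, cpgs, offset=0.0):
        profiles = []
        for cpg in cpgs:
            vals = beta.values.loc[cpg]
            percent = pd.DataFrame(
                {s: [100 * np.clip(vals[s] + offset, 0, 1)] * 2
                 for s in beta.sample_ids},
                index=pd.Index([0, 25], name="position_bp"))
            profiles.append(PyroProfile(f"isl_{cpg}", cpg, 0, percent))
        return profiles

    def test_identical_platforms(self, linked_study):
        beta, design, truth, *_ = linked_study
        cpgs = list(truth.true_positives("culture"))[:4]
        profiles = self._profiles_from(beta, cpgs)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        out = intg.compare_platforms(beta, profiles, groups)
        assert out["mean_offset"] == pytest.approx(0.0, abs=1e-12)
        assert out["delta_correlation"] == pytest.approx(1.0)

    def test_constant_offset_recovered_deltas_unchanged(self, linked_study):
        beta, design, truth, *_ = linked_study
        # avoid CpGs whose shifted values would clip at the [0, 1] bounds
        in_range = beta.values.min(axis=1) > 0.12
        cpgs = [c for c in truth.true_positives("culture")
                if in_range[c]][:4]
        assert len(cpgs) == 4
        profiles = self._profiles_from(beta, cpgs, offset=-0.1)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        out = intg.compare_platforms(beta, profiles, groups)
        assert out["mean_offset"] == pytest.approx(-0.1, abs=1e-9)
        per = out["per_cpg"]
        np.testing.assert_allclose(per["pyro_delta"], per["array_delta"],
                                   atol=1e-9)
        assert out["delta_correlation"] == pytest.approx(1.0)

    def test_simulated_profiles_delta_correlation(self, linked_study):
        beta, design, truth, annotation, *_ = linked_study
        targets = list(truth.true_positives("culture"))[:6]
        profiles = sd.generate_pyro_profiles(beta, annotation,
                                             target_cpgs=targets, seed=3)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        out = intg.compare_platforms(beta, profiles, groups)
        assert len(out["per_cpg"]) == 6
        assert out["delta_correlation"] >= 0.8

    def test_missing_target_rejected(self, linked_study):
        beta, design, *_ = linked_study
        percent = pd.DataFrame({s: [50.0] for s in beta.sample_ids},
                               index=pd.Index([0], name="position_bp"))
        prof = PyroProfile("isl_x", "cg_not_there", 0, percent)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        with pytest.raises(KeyError):
            intg.compare_platforms(beta, [prof], groups)

    def test_missing_group_samples_rejected(self, linked_study):
        beta, design, truth, *_ = linked_study
        cpg = list(truth.true_positives("culture"))[0]
        percent = pd.DataFrame({"only_one": [50.0]},
                               index=pd.Index([0], name="position_bp"))
        prof = PyroProfile("isl_y", cpg, 0, percent)
        groups = (design.samples_where(passage_group="early"),
                  design.samples_where(passage_group="late"))
        with pytest.raises(ValueError, match="missing group samples"):
            intg.compare_platforms(beta, [prof], groups)
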