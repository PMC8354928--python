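"""Signature comparison, KM/KNM pairing and cross-material statistics."""

import numpy as np
import pytest

from striamark.compare import (
    ToolmarkStudy,
    compare_materials,
    compare_signatures,
    km_knm_matrix,
    summarize_material,
)
from striamark.exceptions import DesignError, StatisticsError, UnitError
from striamark.profile import AlignmentResult, Signature
from striamark.synth import StudyConfig, generate_knife, generate_mark, generate_study, material_presets


def _sig(values, label="", dx=3.0):
    values = np.asarray(values, dtype=float)
    return Signature(values, np.full(values.size, 10), dx=dx, label=label)


def _noise_study(rng, n_knives=10, p=150):
    """Fake study: per-knife shared noise signature, two copies each."""
    marks = {}
    for i in range(n_knives):
        base = rng.standard_normal(p)
        marks[f"k{i}"] = [
            _sig(base + 0.05 * rng.standard_normal(p), f"k{i}-A"),
            _sig(base + 0.05 * rng.standard_normal(p), f"k{i}-B"),
        ]
    return marks


class TestCompareSignatures:
    def test_self_comparison_is_unity_at_zero_lag(self, rng):
        sig = _sig(rng.standard_normal(200), "a")
        r = compare_signatures(sig, sig, max_lag=20)
        assert r.x_c == pytest.approx(1.0, abs=1e-12)
        assert r.lag == 0

    def test_incompatible_spacing_rejected(self, rng):
        a = _sig(rng.standard_normal(100), dx=3.0)
        b = _sig(rng.standard_normal(100), dx=5.0)
        with pytest.raises(UnitError):
            compare_signatures(a, b, max_lag=10)

    def test_symmetric_score_with_negated_lag(self, rng):
        for _ in range(10):
            a = _sig(rng.standard_normal(120))
            b = _sig(rng.standard_normal(120))
            rab = compare_signatures(a, b, max_lag=15)
            rba = compare_signatures(b, a, max_lag=15)
            assert rab.x_c == pytest.approx(rba.x_c, abs=1e-12)
            assert rab.lag == -rba.lag

    def test_null_score_matches_permutation_oracle(self):
        """Independent white-noise signatures score like permuted ones.

        The max-over-lags statistic has the same null distribution whether
        the second signature is an independent draw or a permutation of
        one, so the two mean scores must agree within sampling error.
        """
        rng = np.random.default_rng(7)
        p, n_pairs, max_lag = 400, 100, 20
        observed, permuted = [], []
        for _ in range(n_pairs):
            a = _sig(rng.standard_normal(p))
            b = _sig(rng.standard_normal(p))
            observed.append(compare_signatures(a, b, max_lag=max_lag).x_c)
            shuffled = _sig(rng.permutation(b.values))
            permuted.append(compare_signatures(a, shuffled, max_lag=max_lag).x_c)
        se = np.std(observed, ddof=1) / np.sqrt(n_pairs)
        assert abs(np.mean(observed)) < 0.5  # null scores are small
        assert np.mean(observed) == pytest.approx(np.mean(permuted), abs=3 * np.sqrt(2) * se)

    def test_km_pair_at_zero_noise_scores_unity(self):
        from striamark.profile import MarkSignatureModel

        knife = generate_knife(300, seed=3)
        quiet = material_presets()["high-fidelity"]
        quiet = type(quiet)(name="quiet", lag_sd=0.0, noise_sd=0.0, form_amplitude=0.0)
        m1 = generate_mark(knife, quiet, S=20, seed=1)
        m2 = generate_mark(knife, quiet, S=20, seed=2)
        s1 = MarkSignatureModel(m1, window=21, max_lag=10).fit().signature
        s2 = MarkSignatureModel(m2, window=21, max_lag=10).fit().signature
        assert compare_signatures(s1, s2, max_lag=10).x_c == pytest.approx(1.0, abs=1e-9)


class TestKmKnmMatrix:
    def test_standard_design_yields_ten_km_and_ten_knm(self, rng):
        results = km_knm_matrix(_noise_study(rng, 10), max_lag=15)
        assert sum(r.label == "KM" for r in results) == 10
        assert sum(r.label == "KNM" for r in results) == 10

    def test_two_knives(self, rng):
        results = km_knm_matrix(_noise_study(rng, 2), max_lag=15)
        assert sum(r.label == "KM" for r in results) == 2
        assert sum(r.label == "KNM" for r in results) == 2

    def test_all_knm_scheme_counts(self, rng):
        results = km_knm_matrix(_noise_study(rng, 10), pairing="all-knm", max_lag=15)
        assert sum(r.label == "KM" for r in results) == 10
        assert sum(r.label == "KNM" for r in results) == 180  # 2*2*C(10,2)

    def test_single_mark_knife_rejected(self, rng):
        marks = _noise_study(rng, 3)
        marks["k1"] = marks["k1"][:1]
        with pytest.raises(DesignError, match="k1"):
            km_knm_matrix(marks, max_lag=15)


class TestSummaries:
    def _results(self, km_vals, knm_vals):
        from striamark.compare import ComparisonResult

        return [ComparisonResult(v, 0, "KM") for v in km_vals] + [
            ComparisonResult(v, 0, "KNM") for v in knm_vals
        ]

    def test_fully_separated_groups(self):
        s = summarize_material(self._results([1.0] * 10, [0.0] * 10), material="m")
        assert s.xc_km_stats[0] == 1.0
        assert s.xc_knm_stats[0] == 0.0
        assert s.separation_p == pytest.approx(1.082508822446903e-05, rel=1e-6)
        assert s.separation_p < 0.01

    def test_identical_groups_do_not_separate(self):
        vals = [0.1, 0.5, 0.9, 0.3]
        s = summarize_material(self._results(vals, vals))
        assert s.separation_p == pytest.approx(1.0, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(StatisticsError):
            summarize_material(self._results([1.0], []))

    def test_synthetic_study_separates_km_from_knm(self):
        cfg = StudyConfig(n_knives=6, S=30, P=220, seed=1,
                          material=material_presets()["high-fidelity"])
        res = ToolmarkStudy(generate_study(cfg), material="hf", max_lag=30).fit()
        s = res.material_summary
        assert s.xc_km_stats[0] > s.xc_knm_stats[0]
        assert s.separation_p < 0.05
        assert len(res.to_frame()) == 12


class TestCompareMaterials:
    def _summary(self, name, values):
        from striamark.compare import MaterialSummary

        triple = (float(np.mean(values)), float(np.std(values, ddof=1)), len(values))
        return MaterialSummary(name, triple, triple, triple, triple, 1.0,
                               raw={"x_max": list(values)})

    def test_identical_materials_give_p_one(self):
        vals = [0.5, 0.6, 0.7, 0.8]
        table = compare_materials([self._summary("a", vals), self._summary("b", vals)])
        assert table.loc["a", "b"] == pytest.approx(1.0, abs=0.05)

    def test_table_symmetric_with_unit_diagonal(self, rng):
        summaries = [self._summary(n, rng.uniform(0, 1, 8)) for n in "abc"]
        table = compare_materials(summaries)
        assert np.allclose(table.values, table.values.T)
        assert np.allclose(np.diag(table.values), 1.0)

    def test_fidelity_presets_separate_on_x_max(self):
        presets = material_presets()
        summaries = []
        for name in ("high-fidelity", "low-fidelity"):
            x_max_vals = []
            for seed in range(10):
                cfg = StudyConfig(n_knives=1, marks_per_knife=1, S=30, P=220,
                                  seed=seed, material=presets[name])
                hm = next(iter(generate_study(cfg).values()))[0]
                from striamark.profile import MarkSignatureModel

                x_max_vals.append(MarkSignatureModel(hm, max_lag=30).fit().x_max)
            summaries.append(self._summary(name, x_max_vals))
        table = compare_materials(summaries, metric="x_max")
        assert table.iloc[0, 1] < 0.05
        assert np.mean(summaries[0].raw["x_max"]) > np.mean(summaries[1].raw["x_max"])
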