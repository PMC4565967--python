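"""Association statistics, expression filtering, and CEG extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lncgba import (
    AnalysisConfig,
    CoexpressionModel,
    ExpressionFilterMode,
    ExpressionMatrix,
    Method,
    compute_cegs,
    filter_expressed,
    regression_assoc,
    spearman_assoc,
)
from lncgba.errors import ValidationError

from .oracles import ols_slope_oracle, spearman_oracle, spearman_tiefree_closed_form


def _matrix(values, dataset_id="d", prefix="G"):
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"S{j}" for j in range(arr.shape[1])],
    )
    return ExpressionMatrix(dataset_id, df)


class TestSpearman:
    def test_perfect_and_reversed_monotone(self):
        rho, p = spearman_assoc([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0) and p == 0.0
        rho, _ = spearman_assoc([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_tied_example_matches_rank_pearson_oracle(self):
        x, y = [1, 2, 3, 4, 5], [5, 6, 7, 8, 7]
        rho, _ = spearman_assoc(x, y)
        assert rho == pytest.approx(0.8208, abs=5e-5)
        assert rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_scipy_including_pvalue(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = np.round(rng.normal(size=n), 1)  # induces ties
            rho, p = spearman_assoc(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_tiefree_closed_form_agreement(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            rho, _ = spearman_assoc(x, y)
            assert rho == pytest.approx(spearman_tiefree_closed_form(x, y), abs=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.integers(-50, 50), min_size=4, max_size=20, unique=True),
        st.integers(0, 2**31 - 1),
    )
    def test_invariant_under_strictly_monotone_transforms(self, xs, seed):
        y = np.random.default_rng(seed).normal(size=len(xs))
        if np.ptp(y) == 0:
            return
        x = np.asarray(xs, dtype=float)
        rho_base, p_base = spearman_assoc(x, y)
        rho_t, p_t = spearman_assoc(np.exp(x / 25.0), y**3)
        assert rho_t == pytest.approx(rho_base, abs=1e-12)
        assert p_t == pytest.approx(p_base, abs=1e-12)

    def test_degenerate_inputs_error(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_assoc([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValidationError, match="length mismatch"):
            spearman_assoc([1, 2, 3], [1, 2])


class TestRegression:
    def test_noiseless_line(self):
        x = np.arange(5.0)
        slope, r, p = regression_assoc(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert r == pytest.approx(1.0) and p == 0.0

    def test_closed_form_slope(self):
        slope, _, _ = regression_assoc([1, 2, 3], [1, 3, 2])
        assert slope == pytest.approx(0.5)
        assert slope == pytest.approx(ols_slope_oracle([1, 2, 3], [1, 3, 2]), abs=1e-12)

    def test_constant_predictor_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            regression_assoc([2, 2, 2, 2], [1, 2, 3, 4])
        with pytest.raises(ValidationError, match="at least 3"):
            regression_assoc([1, 2], [1, 2])

    def test_slope_p_equals_pearson_test_p(self, rng):
        """Algebraic identity of simple OLS: slope t-test == correlation test."""
        for _ in range(50):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = 0.3 * x + rng.normal(size=n)
            slope, r, p = regression_assoc(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)
            lr = stats.linregress(x, y)
            assert slope == pytest.approx(lr.slope, abs=1e-10)
            assert p == pytest.approx(lr.pvalue, abs=1e-10)


class TestFilterExpressed:
    def test_mean_mode_threshold(self):
        mat = _matrix([[0, 0, 0, 0], [0.0005, 0.0005, 0.0005, 0.0005], [0.5] * 4])
        cfg = AnalysisConfig()
        assert cfg.expression_threshold == 0.001
        kept = filter_expressed(mat, cfg)
        assert kept.gene_ids == ["G2"]
        assert kept.sample_ids == mat.sample_ids

    def test_fraction_mode_requires_half_the_samples(self):
        mat = _matrix([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0]])
        cfg = AnalysisConfig(
            expression_filter_mode=ExpressionFilterMode.FRACTION,
            expression_threshold=0.001,
        )
        kept = filter_expressed(mat, cfg)
        assert kept.gene_ids == ["G0"]

    def test_all_genes_removed_errors(self):
        mat = _matrix([[0, 0, 0]])
        with pytest.raises(ValidationError, match="removed every gene"):
            filter_expressed(mat, AnalysisConfig())


class TestComputeCegs:
    def _pair_matrices(self, rng, n=30):
        x = rng.lognormal(size=n)
        noise = 1e-6 * rng.normal(size=n)
        lnc = _matrix([x], prefix="L")
        pcg = _matrix([x + np.abs(noise), rng.lognormal(size=n)], prefix="P")
        return lnc, pcg

    def test_planted_pair_is_called(self, rng):
        lnc, pcg = self._pair_matrices(rng)
        ceg_sets, results = compute_cegs(
            lnc, pcg, ["L0"], AnalysisConfig(p_threshold=0.01)
        )
        assert "P0" in ceg_sets["L0"].members
        assert set(results.associations["pcg_id"]) == {"P0", "P1"}

    def test_null_admission_rate_near_alpha(self, rng):
        """~1% of independent null genes pass p <= 0.01 (binomial 99% band)."""
        n, m = 50, 1000
        x = rng.lognormal(size=n)
        null = rng.lognormal(size=(m, n))
        lnc = _matrix([x], prefix="L")
        pcg = _matrix(null, prefix="P")
        ceg_sets, _ = compute_cegs(lnc, pcg, ["L0"], AnalysisConfig(p_threshold=0.01))
        admitted = len(ceg_sets["L0"].members)
        lo, hi = stats.binom.ppf([0.005, 0.995], m, 0.01)
        assert lo <= admitted <= hi

    def test_threshold_tightening_never_grows_cegs(self, small_bundle):
        matrix, catalog, _, _ = small_bundle
        lnc = matrix.subset_genes(catalog.lncrna_ids)
        pcg = matrix.subset_genes(catalog.protein_coding_ids)
        results = CoexpressionModel(lnc, pcg, config=AnalysisConfig()).fit()
        loose = results.ceg_sets(p_threshold=0.05)
        tight_p = results.ceg_sets(p_threshold=0.001)
        tight_r = results.ceg_sets(coef_threshold=0.6, p_threshold=0.05)
        for lnc_id in loose:
            assert tight_p[lnc_id].members <= loose[lnc_id].members
            assert tight_r[lnc_id].members <= loose[lnc_id].members

    def test_sample_permutation_invariance(self, rng):
        lnc, pcg = self._pair_matrices(rng)
        perm = rng.permutation(lnc.n_samples)
        cols = [lnc.sample_ids[i] for i in perm]
        lnc_p = ExpressionMatrix(lnc.dataset_id, lnc.values[cols])
        pcg_p = ExpressionMatrix(pcg.dataset_id, pcg.values[cols])
        cfg = AnalysisConfig(p_threshold=0.05)
        _, res_a = compute_cegs(lnc, pcg, ["L0"], cfg)
        _, res_b = compute_cegs(lnc_p, pcg_p, ["L0"], cfg)
        pd.testing.assert_frame_equal(res_a.associations, res_b.associations)

    def test_sample_mismatch_errors(self, rng):
        lnc, pcg = self._pair_matrices(rng)
        bad = ExpressionMatrix(
            pcg.dataset_id, pcg.values.iloc[:, ::-1]
        )
        with pytest.raises(ValidationError, match="sample ids"):
            compute_cegs(lnc, bad, ["L0"], AnalysisConfig())

    def test_filtered_lncrna_excluded_with_warning(self, rng, caplog):
        lnc, pcg = self._pair_matrices(rng)
        silent = _matrix([[0.0] * lnc.n_samples], prefix="Z")
        lnc2 = ExpressionMatrix(
            lnc.dataset_id, pd.concat([lnc.values, silent.values])
        )
        with caplog.at_level("WARNING"):
            ceg_sets, _ = compute_cegs(lnc2, pcg, ["L0", "Z0"], AnalysisConfig())
        assert "Z0" not in ceg_sets
        assert any("Z0" in rec.getMessage() for rec in caplog.records)

    def test_spearman_and_regression_methods_agree_on_strong_signal(self, rng):
        lnc, pcg = self._pair_matrices(rng)
        for method in Method:
            cfg = AnalysisConfig(method=method, p_threshold=0.01)
            ceg_sets, _ = compute_cegs(lnc, pcg, ["L0"], cfg)
            assert "P0" in ceg_sets["L0"].members

    def test_requires_at_least_one_threshold(self, rng):
        lnc, pcg = self._pair_matrices(rng)
        with pytest.raises(ValidationError, match="at least one"):
            compute_cegs(
                lnc, pcg, ["L0"], AnalysisConfig(coef_threshold=None, p_threshold=None)
            )


class TestResultsObject:
    def test_summary_reports_counts(self, small_bundle):
        matrix, catalog, _, _ = small_bundle
        lnc = matrix.subset_genes(catalog.lncrna_ids)
        pcg = matrix.subset_genes(catalog.protein_coding_ids)
        results = CoexpressionModel(lnc, pcg).fit()
        text = results.summary()
        assert "lncRNAs screened:   2" in text
        assert "method:             regression" in text

    def test_association_table_round_trip(self, small_bundle, tmp_path):
        matrix, catalog, _, _ = small_bundle
        lnc = matrix.subset_genes(catalog.lncrna_ids)
        pcg = matrix.subset_genes(catalog.protein_coding_ids)
        results = CoexpressionModel(lnc, pcg).fit()
        path = tmp_path / "assoc.tsv"
        results.to_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == [
            "lnc_id", "pcg_id", "method", "coefficient", "r", "p_value", "n_samples",
        ]
        assert len(back) == len(results.associations)
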