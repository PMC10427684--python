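"""Negative-binomial fitting, pooling correction and unobserved analysis."""

import numpy as np
import pandas as pd
import pytest

from delforge.count_model import (
    DegenerateDataError,
    LabellingError,
    correct_pooling,
    count_histogram,
    estimate_pooling_ratio,
    fit_negative_binomial,
    unobserved_analysis,
)
from delforge.synthetic_data import simulate_nb_counts


class TestNBFit:
    def test_constant_vector_poisson_limit(self):
        fit = fit_negative_binomial([30] * 50)
        assert fit.mean == 30
        assert fit.poisson_limit

    def test_parameter_recovery(self):
        rng = np.random.default_rng(42)
        mean, r = 30.0, 2.0
        x = rng.negative_binomial(r, r / (r + mean), size=100_000)
        fit = fit_negative_binomial(x)
        assert abs(fit.mean - mean) / mean < 0.02
        assert abs(fit.dispersion - r) / r < 0.10
        assert not fit.poisson_limit

    def test_poisson_draws_flagged_or_large_dispersion(self):
        rng = np.random.default_rng(7)
        x = rng.poisson(20.0, size=50_000)
        fit = fit_negative_binomial(x)
        assert abs(fit.mean - 20.0) / 20.0 < 0.02
        assert fit.poisson_limit or fit.dispersion > 100

    def test_all_zero_raises(self):
        with pytest.raises(DegenerateDataError):
            fit_negative_binomial([0] * 20)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            fit_negative_binomial([1, 2, 3])

    def test_variance_property(self):
        fit = fit_negative_binomial(
            np.random.default_rng(0).negative_binomial(2, 2 / 32, size=5000)
        )
        assert fit.variance == pytest.approx(fit.mean + fit.mean**2 / fit.dispersion)


class TestPoolingRatio:
    def test_identical_distributions_give_unity(self):
        table, labels = simulate_nb_counts(20_000, pooling_ratio=1.0, seed=0)
        ratio, fits = estimate_pooling_ratio(table, labels)
        assert ratio == pytest.approx(1.0, abs=0.03)

    def test_sublibrary_missing_raises(self):
        table = pd.DataFrame({"input": [1, 2, 3] * 10})
        with pytest.raises(LabellingError):
            estimate_pooling_ratio(table, ["Br"] * 30)

    def test_scale_invariance(self):
        # doubling sequencing depth doubles both means, leaving the ratio
        table, labels = simulate_nb_counts(20_000, mean_br=15, pooling_ratio=1.31, seed=1)
        r1, _ = estimate_pooling_ratio(table, labels)
        table2, labels2 = simulate_nb_counts(20_000, mean_br=30, pooling_ratio=1.31, seed=1)
        r2, _ = estimate_pooling_ratio(table2, labels2)
        assert r1 == pytest.approx(r2, abs=0.05)

    def test_one_side_constant_still_defined(self):
        table = pd.DataFrame({"input": [30] * 50 + [40] * 50})
        labels = np.array(["Br"] * 50 + ["I"] * 50)
        ratio, fits = estimate_pooling_ratio(table, labels)
        assert ratio == pytest.approx(40 / 30)
        assert fits["Br"].poisson_limit and fits["I"].poisson_limit


class TestPoolingCorrection:
    def test_unity_ratio_unchanged(self):
        assert correct_pooling({"Br": 0.5, "I": 0.5}, 1.0) == {"Br": 0.5, "I": 0.5}

    def test_excess_downweighted(self):
        out = correct_pooling({"Br": 0.5, "I": 0.5}, 1.31)
        assert out["I"] == pytest.approx((0.5 / 1.31) / (0.5 + 0.5 / 1.31))
        assert out["Br"] + out["I"] == pytest.approx(1.0)

    def test_nonpositive_ratio_raises(self):
        with pytest.raises(ValueError):
            correct_pooling({"Br": 0.5, "I": 0.5}, 0.0)

    def test_corrected_simulation_equalizes(self):
        # apply the measured correction as a depth rescale of the I side
        table, labels = simulate_nb_counts(30_000, pooling_ratio=1.31, seed=3)
        ratio, _ = estimate_pooling_ratio(table, labels)
        corrected, labels2 = simulate_nb_counts(
            30_000, pooling_ratio=1.31 / ratio, seed=4
        )
        ratio2, _ = estimate_pooling_ratio(corrected, labels2)
        assert ratio2 == pytest.approx(1.0, abs=0.05)


class TestHistogram:
    def test_exact_bins(self):
        table = pd.DataFrame({"input": [0, 1, 1, 3]})
        hist = count_histogram(table)
        assert hist["n_barcodes"].to_dict() == {0: 1, 1: 2, 3: 1}

    def test_total_conservation(self):
        table, labels = simulate_nb_counts(5_000, seed=5)
        hist = count_histogram(table, by_sublibrary=labels)
        assert hist.to_numpy().sum() == len(table)

    def test_matches_nb_pmf(self):
        from scipy import stats

        mean, r, n = 30.0, 2.0, 100_000
        rng = np.random.default_rng(11)
        x = rng.negative_binomial(r, r / (r + mean), size=n)
        table = pd.DataFrame({"input": x})
        hist = count_histogram(table)["n_barcodes"]
        support = np.arange(0, int(x.max()) + 1)
        pmf = stats.nbinom.pmf(support, r, r / (r + mean))
        observed = np.zeros_like(support, dtype=float)
        observed[hist.index.to_numpy()] = hist.to_numpy()
        # lump the tail so expected counts stay reasonable
        keep = pmf * n >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(pmf[keep] * n, pmf[~keep].sum() * n)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, df=len(obs) - 1)
        assert p > 0.01


class TestUnobserved:
    def _table(self, n_side=4):
        index = pd.MultiIndex.from_product(
            [[f"s{i}" for i in range(2)], [f"c{i}" for i in range(n_side)],
             [f"b{i}" for i in range(n_side)]],
            names=["cy1", "cy2", "cy3"],
        )
        table = pd.DataFrame({"input": 10}, index=index)
        labels = np.where(
            index.get_level_values("cy1") == "s0", "I", "Br"
        )
        return table, labels

    def test_no_zeros_empty_report(self):
        table, labels = self._table()
        report = unobserved_analysis(table, labels)
        assert report.fraction_unobserved == 0.0
        assert report.flagged.empty

    def test_pair_zero_flagged(self):
        table, labels = self._table(2)
        mask = (table.index.get_level_values("cy2") == "c0") & (
            table.index.get_level_values("cy3") == "b1"
        )
        table.loc[mask, "input"] = 0
        report = unobserved_analysis(table, labels)
        pair_flags = report.flagged[report.flagged["level"] == "cy2_cy3"]
        assert ("c0", "b1") in list(pair_flags["key"])

    def test_planted_failed_cy2_in_one_sublibrary(self):
        index = pd.MultiIndex.from_product(
            [[f"s{i}" for i in range(20)], [f"c{i}" for i in range(20)],
             [f"b{i}" for i in range(20)]],
            names=["cy1", "cy2", "cy3"],
        )
        rng = np.random.default_rng(0)
        table = pd.DataFrame({"input": rng.poisson(30, len(index))}, index=index)
        labels = np.where(
            index.get_level_values("cy1").str[1:].astype(int) < 10, "I", "Br"
        )
        failed = (index.get_level_values("cy2") == "c7") & (labels == "I")
        table.loc[failed, "input"] = 0
        report = unobserved_analysis(table, labels)
        hits = report.flagged[
            (report.flagged["level"] == "cy2") & (report.flagged["key"] == "c7")
        ]
        assert list(hits["sublibrary"]) == ["I"]

    def test_fraction_identity(self):
        table, labels = self._table()
        table.iloc[:5, 0] = 0
        report = unobserved_analysis(table, labels)
        assert report.fraction_unobserved == 5 / len(table)
        assert report.n_unobserved == 5
        # per-cycle group sums account for every zero
        for cyc, grp in report.by_cycle.items():
            assert grp["n_zero"].sum() == 5
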