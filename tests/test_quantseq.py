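"""QS calibration, signal ratios, detection limits, inverse prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acariscan import (
    MutationDefinition,
    PeakSignal,
    QsCalibration,
    batch_panel,
    fit_calibration,
    predict_frequency,
    signal_ratio,
)
from acariscan.quantseq import (
    DEFAULT_STANDARD_FRACTIONS,
    UnquantifiableSignalError,
    substitution_class,
)
from acariscan.synth import ChromatogramConfig, generic_mutation, simulate_calibration_standards, simulate_chromatogram

FRACTIONS = np.asarray(DEFAULT_STANDARD_FRACTIONS)
M = generic_mutation("M1")  # A (wild) vs G (mutant)


def make_signal(h_wild, h_mut, other=0.0):
    return PeakSignal("s", M, {"A": h_wild, "G": h_mut, "C": other, "T": other})


class TestSignalRatio:
    @pytest.mark.parametrize(
        "h_wild, h_mut, expected",
        [(800.0, 0.0, 0.0), (0.0, 800.0, 100.0), (640.0, 640.0, 50.0), (300.0, 100.0, 25.0)],
    )
    def test_two_allele_ratio(self, h_wild, h_mut, expected):
        assert signal_ratio(make_signal(h_wild, h_mut)) == pytest.approx(expected)

    def test_background_channels_ignored(self):
        assert signal_ratio(make_signal(500, 500, other=400)) == pytest.approx(50.0)

    @given(scale=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        base = make_signal(321.0, 123.0, other=20.0)
        scaled = PeakSignal("s", M, {k: v * scale for k, v in base.peak_heights.items()})
        assert signal_ratio(scaled) == pytest.approx(signal_ratio(base), rel=1e-9)

    def test_both_segregating_peaks_zero_unquantifiable(self):
        sig = PeakSignal("s", M, {"A": 0.0, "G": 0.0, "C": 10.0, "T": 5.0})
        with pytest.raises(UnquantifiableSignalError):
            signal_ratio(sig)

    def test_simulated_standard_mean_near_truth(self, rng):
        cfg = ChromatogramConfig(noise_sd_frac=0.03)
        ratios = [
            signal_ratio(simulate_chromatogram(0.3, M, cfg, rng)) for _ in range(300)
        ]
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(np.mean(ratios) - 30.0) < max(2 * se, 0.5)


class TestMutationDefinition:
    def test_substitution_classes(self):
        assert substitution_class("G", "A") == "transition"
        assert substitution_class("C", "T") == "transition"
        assert substitution_class("G", "T") == "transversion"
        assert substitution_class("A", "T") == "transversion"
        with pytest.raises(ValueError):
            substitution_class("A", "A")

    def test_codon_nucleotide_consistency_enforced(self):
        with pytest.raises(ValueError, match="do not match codons"):
            MutationDefinition(
                gene="g", accession="x", codon_position=1,
                wild_codon="GGC", mutant_codon="AGC",
                substituted_position_in_codon=1, wild_nt="G", mutant_nt="T",
                abbreviation="G1S",
            )
        with pytest.raises(ValueError, match="agree at the substituted"):
            MutationDefinition(
                gene="g", accession="x", codon_position=1,
                wild_codon="GGC", mutant_codon="GGC",
                substituted_position_in_codon=1, wild_nt="G", mutant_nt="G",
                abbreviation="G1G",
            )

    def test_abbreviation_encodes_amino_acids(self):
        mut = MutationDefinition(
            gene="g", accession="x", codon_position=228,
            wild_codon="GGC", mutant_codon="AGC",
            substituted_position_in_codon=1, wild_nt="G", mutant_nt="A",
            abbreviation="G228S",
        )
        mut.check_abbreviation()  # Gly -> Ser
        bad = MutationDefinition(
            gene="g", accession="x", codon_position=228,
            wild_codon="GGC", mutant_codon="AGC",
            substituted_position_in_codon=1, wild_nt="G", mutant_nt="A",
            abbreviation="G228A",
        )
        with pytest.raises(ValueError, match="does not encode"):
            bad.check_abbreviation()


class TestCalibrationFit:
    def test_identity_calibration(self):
        curve = fit_calibration((FRACTIONS, FRACTIONS.copy()))
        assert curve.slope == pytest.approx(1.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-10)
        assert curve.r2 == pytest.approx(1.0)
        assert curve.lower_dl == 0.0
        assert curve.upper_dl == 100.0

    def test_r2_high_at_moderate_noise(self):
        # Gaussian ratio noise of sd 3%: r2 > 0.98 in >= 95% of replicates
        rng = np.random.default_rng(808)
        hits = 0
        for _ in range(100):
            ratios = FRACTIONS + rng.normal(0, 3.0, size=FRACTIONS.size)
            curve = fit_calibration((FRACTIONS, ratios))
            hits += curve.r2 > 0.98
        assert hits >= 95

    def test_detection_limits_monotone_in_noise(self):
        # deterministic residual pattern scaled by sd: lower limit rises,
        # upper limit falls as the calibration gets noisier
        pattern = np.array([1.0, -1.0, 0.5, -0.5, 1.0, -1.5, 0.5])
        lows, highs = [], []
        for sd in (1.0, 2.0, 4.0, 8.0):
            curve = fit_calibration((FRACTIONS, FRACTIONS + sd * pattern))
            lows.append(curve.lower_dl)
            highs.append(curve.upper_dl)
        assert all(a < b for a, b in zip(lows, lows[1:]))
        assert all(a > b for a, b in zip(highs, highs[1:]))
        assert all(0 < lo < hi < 100 for lo, hi in zip(lows, highs))

    def test_rank_deficient_standards_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            QsCalibration([50, 50, 50, 50, 50], [48, 51, 50, 49, 52])

    def test_near_zero_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            QsCalibration(FRACTIONS, np.full(FRACTIONS.size, 40.0) + 1e-13 * FRACTIONS).fit()

    def test_directions_agree_on_clean_data(self, rng):
        xs, ys = simulate_calibration_standards(M, ChromatogramConfig(noise_sd_frac=0.01), rng)
        classical = QsCalibration(xs, ys, mutation=M).fit(direction="classical")
        inverse = QsCalibration(xs, ys, mutation=M).fit(direction="inverse")
        for ratio in (20.0, 50.0, 80.0):
            assert classical.predict(ratio).frequency == pytest.approx(
                inverse.predict(ratio).frequency, abs=1.5
            )


@pytest.fixture(scope="module")
def noisy_curve():
    rng = np.random.default_rng(99)
    xs, ys = simulate_calibration_standards(M, ChromatogramConfig(noise_sd_frac=0.03), rng)
    return QsCalibration(xs, ys, mutation=M).fit()


class TestInversePrediction:
    def test_ratio_at_intercept_maps_to_zero(self, noisy_curve):
        est = predict_frequency(noisy_curve.intercept, noisy_curve)
        assert est.frequency == pytest.approx(0.0, abs=1e-9)
        assert noisy_curve.lower_dl > 0
        assert est.status == "below_detection"

    def test_estimates_clipped_and_censored(self, noisy_curve):
        low = predict_frequency(-20.0, noisy_curve)
        high = predict_frequency(120.0, noisy_curve)
        assert low.frequency == 0.0 and low.status == "below_detection"
        assert high.frequency == 100.0 and high.status == "above_detection"
        mid = predict_frequency(noisy_curve.slope * 50 + noisy_curve.intercept, noisy_curve)
        assert mid.status == "quantified"
        assert mid.ci95[0] < mid.frequency < mid.ci95[1]

    def test_status_is_deterministic_in_point_and_limits(self, noisy_curve):
        eps = 1e-6
        for freq in (noisy_curve.lower_dl - eps, noisy_curve.lower_dl + eps,
                     noisy_curve.upper_dl - eps, noisy_curve.upper_dl + eps):
            ratio = noisy_curve.slope * freq + noisy_curve.intercept
            est = predict_frequency(ratio, noisy_curve)
            expected = (
                "below_detection" if freq < noisy_curve.lower_dl
                else "above_detection" if freq > noisy_curve.upper_dl
                else "quantified"
            )
            assert est.status == expected

    @pytest.mark.parametrize("true_pct", [10.0, 30.0, 50.0, 70.0, 90.0])
    def test_round_trip_unbiased_within_3pct(self, noisy_curve, true_pct):
        rng = np.random.default_rng(int(true_pct) + 1)
        cfg = ChromatogramConfig(noise_sd_frac=0.03)
        est = [
            noisy_curve.predict(signal_ratio(simulate_chromatogram(true_pct / 100, M, cfg, rng))).frequency
            for _ in range(50)
        ]
        assert abs(np.mean(est) - true_pct) < 3.0

    def test_susceptible_pools_read_near_zero(self, noisy_curve, rng):
        cfg = ChromatogramConfig(noise_sd_frac=0.03)
        est = [
            noisy_curve.predict(signal_ratio(simulate_chromatogram(0.0, M, cfg, rng))).frequency
            for _ in range(30)
        ]
        assert np.mean(est) < 5.0


class TestBatchPanel:
    def _signals(self, strains, mutations, rng, fraction=0.5):
        cfg = ChromatogramConfig()
        out = []
        for s in strains:
            for m in mutations:
                out.append(simulate_chromatogram(fraction, generic_mutation(m), cfg, rng, sample=s))
        return out

    def _curves(self, mutations, rng):
        out = {}
        for m in mutations:
            xs, ys = simulate_calibration_standards(generic_mutation(m), ChromatogramConfig(), rng)
            out[m] = QsCalibration(xs, ys, mutation=generic_mutation(m)).fit()
        return out

    def test_completeness_and_nd_only_where_absent(self, rng):
        strains = [f"S{i}" for i in range(12)]
        mutations = [f"M{i}" for i in range(12)]
        signals = self._signals(strains, mutations, rng)
        dropped = signals[5]
        signals = [s for s in signals if s is not dropped]
        mat = batch_panel(signals, self._curves(mutations, rng))
        assert mat.shape == (12, 12)
        assert mat.isna().sum().sum() == 1
        assert np.isnan(mat.loc[dropped.sample, dropped.mutation_name])

    def test_missing_curve_gives_nd_and_warning_not_failure(self, rng):
        strains, mutations = ["S1"], ["M1", "M2"]
        signals = self._signals(strains, mutations, rng)
        curves = self._curves(["M1"], rng)
        with pytest.warns(UserWarning, match="no calibration curve"):
            mat = batch_panel(signals, curves)
        assert np.isnan(mat.loc["S1", "M2"]) and np.isfinite(mat.loc["S1", "M1"])

    def test_pure_resistant_strain_saturates(self, rng):
        mutations = ["M1", "M2", "M3"]
        curves = self._curves(mutations, rng)
        signals = self._signals(["RED"], mutations, rng, fraction=1.0)
        mat = batch_panel(signals, curves)
        censored = 0
        for m in mutations:
            assert mat.loc["RED", m] == pytest.approx(100.0, abs=6.0)
            censored += mat.loc["RED", m] > curves[m].upper_dl
        # saturated alleles sit above the quantifiable band (up to one
        # draw's prediction noise around the limit itself)
        assert censored >= len(mutations) - 1

    def test_sample_order_permutation_invariance(self, rng):
        strains = ["A", "B", "C"]
        mutations = ["M1", "M2"]
        signals = self._signals(strains, mutations, rng)
        curves = self._curves(mutations, rng)
        mat1 = batch_panel(signals, curves)
        mat2 = batch_panel(list(reversed(signals)), curves)
        assert mat1.sort_index(axis=0).sort_index(axis=1).equals(
            mat2.sort_index(axis=0).sort_index(axis=1)
        )
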