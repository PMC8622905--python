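"""CD melting analysis: normalization, Tm extraction, reports, statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ccmelt import fixtures, synthgen
from ccmelt.cdmelt import (
    HelicityConstants,
    MeltingCurve,
    delta_tm_report,
    fraction_unfolded,
    helicity_222,
    melt_tm,
    mre_from_raw,
    normalize,
    t_test,
    vanthoff_fit,
)
from ccmelt.errors import (
    DegenerateCurveError,
    DomainError,
    GridError,
    ParameterError,
    ReportError,
    SampleSizeError,
)


class TestMreFromRaw:
    def test_direct_substitution(self):
        # theta MRW / (10 l_cm c): -100 mdeg at 0.1 mg/mL in 1 mm, MRW 110
        assert mre_from_raw(-100.0, 0.1, 1.0, 110.0) == pytest.approx(-110000.0)
        # a 10 mm cell brings the same reading down tenfold
        assert mre_from_raw(-100.0, 0.1, 10.0, 110.0) == pytest.approx(-11000.0)
        # a realistic fully-helical reading: ~-33 mdeg -> ~-36,300
        assert mre_from_raw(-33.0, 0.1, 1.0, 110.0) == pytest.approx(-36300.0)

    def test_linearity_and_scaling(self):
        assert mre_from_raw(0.0, 0.1, 1.0, 110.0) == 0.0
        one = mre_from_raw(-50.0, 0.1, 1.0, 110.0)
        assert mre_from_raw(-50.0, 0.2, 1.0, 110.0) == pytest.approx(one / 2)

    def test_nonpositive_inputs_raise(self):
        with pytest.raises(DomainError):
            mre_from_raw(-50.0, 0.0, 1.0, 110.0)
        with pytest.raises(DomainError):
            mre_from_raw(-50.0, 0.1, -1.0, 110.0)


class TestNormalize:
    def test_minmax_endpoints_and_midpoint(self):
        curve = MeltingCurve([10.0, 20.0, 30.0], [-30000.0, -20000.0, -10000.0])
        z = normalize(curve).z
        assert z == pytest.approx([0.0, 0.5, 1.0])

    def test_flat_curve_raises(self):
        with pytest.raises(DegenerateCurveError):
            normalize(MeltingCurve([1.0, 2.0, 3.0], [5.0, 5.0, 5.0]))

    @given(st.lists(st.floats(-40000, 0), min_size=5, max_size=30, unique=True))
    def test_idempotent(self, signal):
        curve = MeltingCurve(np.arange(len(signal), dtype=float), signal)
        once = normalize(curve)
        twice = normalize(
            MeltingCurve(once.temperatures, once.z, condition=curve.condition)
        )
        assert np.allclose(once.z, twice.z)


class TestFractionUnfolded:
    def test_folded_end_maps_to_zero(self, melt_factory):
        fu = fraction_unfolded(melt_factory(tm=50, dh=400))
        assert fu.z[0] == pytest.approx(0.0, abs=0.02)
        assert fu.z[-1] == pytest.approx(1.0, abs=0.02)
        assert fu.orientation == "fraction_unfolded"

    def test_sign_flip_invariance(self, melt_factory):
        curve = melt_factory(tm=50, dh=400)
        flipped = MeltingCurve(curve.temperatures, -curve.signal)
        assert np.allclose(
            fraction_unfolded(curve).z, fraction_unfolded(flipped).z
        )

    def test_half_unfolded_at_tm(self):
        # with flat baselines the min-max normalization is the
        # thermodynamic fraction unfolded, which is 1/2 at Tm; sloping
        # baselines would bias the endpoints and shift this value
        params = synthgen.TwoStateParams(
            tm_true=50.0, dh_vh=400.0, noise_sd=0.0,
            folded_baseline=(-30000.0, 0.0), unfolded_baseline=(-3000.0, 0.0),
        )
        fu = fraction_unfolded(synthgen.simulate_melt(params))
        idx = int(np.argmin(np.abs(fu.temperatures - 50.0)))
        assert fu.z[idx] == pytest.approx(0.5, abs=0.02)


class TestMeltTm:
    def test_noiseless_recovery(self, melt_factory):
        res = melt_tm(melt_factory(tm=50, dh=400))
        assert res.determined
        assert res.tm == pytest.approx(50.0, abs=0.5)

    def test_flat_baselines_exact(self, melt_factory):
        params = synthgen.TwoStateParams(
            tm_true=50.0, dh_vh=400.0, folded_baseline=(-30000.0, 0.0),
            unfolded_baseline=(-3000.0, 0.0), noise_sd=0.0,
        )
        res = melt_tm(synthgen.simulate_melt(params))
        assert res.tm == pytest.approx(50.0, abs=0.5)

    def test_truncated_start_is_nd(self, melt_factory):
        curve = melt_factory(tm=50, dh=400, grid=np.arange(60.0, 90.1, 0.5))
        res = melt_tm(curve)
        assert not res.determined
        assert res.truncated_low

    def test_affine_invariance(self, melt_factory):
        curve = melt_factory(tm=45, dh=300, noise_sd=150, seed=7)
        base = melt_tm(curve).tm
        shifted = MeltingCurve(curve.temperatures, 2.5 * curve.signal + 12345.0)
        assert melt_tm(shifted).tm == pytest.approx(base, abs=1e-9)

    def test_window_validation(self, melt_factory):
        curve = melt_factory()
        with pytest.raises(ParameterError):
            melt_tm(curve, window=6)
        with pytest.raises(ParameterError):
            melt_tm(curve, window=3)
        with pytest.raises(GridError):
            melt_tm(MeltingCurve([1.0, 2.0, 3.0], [0.0, 1.0, 2.0]))

    def test_peak_height_monotone_in_dh(self, melt_factory):
        heights = [
            melt_tm(melt_factory(tm=50, dh=dh)).derivative_peak_height
            for dh in (300, 400, 500)
        ]
        assert heights[0] < heights[1] < heights[2]


class TestVantHoffFit:
    def test_self_consistency_noiseless(self, melt_factory):
        fit = vanthoff_fit(melt_factory(tm=47.3, dh=420))
        assert fit.tm == pytest.approx(47.3, rel=1e-4)
        assert fit.dh_vh == pytest.approx(420.0, rel=1e-4)
        assert fit.folded_baseline[0] == pytest.approx(-30000.0, rel=1e-3)

    @pytest.mark.parametrize("tm,dh", [(30.0, 300.0), (50.0, 400.0), (65.0, 500.0)])
    def test_agrees_with_derivative_max(self, melt_factory, tm, dh):
        curve = melt_factory(tm=tm, dh=dh)
        assert melt_tm(curve).tm == pytest.approx(vanthoff_fit(curve).tm, abs=0.5)

    def test_noisy_recovery_over_replicates(self, melt_factory):
        grid = np.arange(0.0, 80.0 + 1e-9, 0.5)  # 161 points
        rng = np.random.default_rng(11)
        errors = []
        for _ in range(30):
            tm = rng.uniform(25, 65)
            ref = melt_factory(tm=tm, dh=400, grid=grid)
            noise = 0.02 * (ref.signal.max() - ref.signal.min())
            curve = melt_factory(
                tm=tm, dh=400, noise_sd=noise, seed=int(rng.integers(2**31)),
                grid=grid,
            )
            errors.append(abs(vanthoff_fit(curve).tm - tm))
        assert np.quantile(errors, 0.95) <= 0.5


class TestDeltaTmReport:
    def test_measured_table_differences(self):
        report = delta_tm_report(
            [r for r in fixtures.table1_results() if "Tpm3.12" in r.sample_id],
            "Tpm3.12_65-155",
        )
        by = report.set_index(["sample_id", "condition"])
        wt = by.loc[("Tpm3.12_65-155", "non_reduced")]
        assert wt["dtm_nonreduced_minus_reduced"] == pytest.approx(15.1)
        assert wt["dtm_vs_reference"] == pytest.approx(0.0)
        r91c = by.loc[("Tpm3.12_65-155_R91C", "non_reduced")]
        assert r91c["dtm_vs_reference"] == pytest.approx(9.4)

    def test_nd_propagates(self):
        report = delta_tm_report(fixtures.table1_results(), "Tpm3.12_65-155")
        row = report[
            (report.sample_id == "Tpm3.12_65-155_R91P")
            & (report.condition == "reduced")
        ].iloc[0]
        assert row["not_determined"]
        assert np.isnan(row["tm"])
        assert np.isnan(row["dtm_vs_reference"])
        assert np.isnan(row["dtm_nonreduced_minus_reduced"])

    def test_missing_reference_raises(self):
        with pytest.raises(ReportError):
            delta_tm_report(fixtures.table1_results(), "nonexistent")


class TestHelicity:
    def test_endpoints(self):
        c = HelicityConstants()
        assert helicity_222(c.coil_limit(0.0), 98, 0.0, c) == pytest.approx(0.0)
        assert helicity_222(c.helix_limit(98), 98, 0.0, c) == pytest.approx(1.0)

    def test_reported_decrease_convention_dependent(self):
        # the measured R91P +DTT shift: MRE rises from -28370 to -19057
        f_before = helicity_222(-28370.0, 98, 0.0)
        f_after = helicity_222(-19057.0, 98, 0.0)
        relative_drop = (f_before - f_after) / f_before
        assert 0.25 < relative_drop < 0.40
        # zero-baseline convention on the raw MRE values gives ~33%
        assert (28370 - 19057) / 28370 == pytest.approx(0.328, abs=0.005)

    def test_spectrum_roundtrip(self):
        wavelengths = np.arange(190.0, 260.0, 0.5)
        for f in (0.0, 0.3, 0.72, 1.0):
            spec = synthgen.simulate_spectrum(f, wavelengths, n_residues=98)
            est = helicity_222(spec.mre_at(222.0), 98, 0.0)
            assert est == pytest.approx(f, abs=0.02)

    def test_helix_spectrum_shape(self):
        wavelengths = np.arange(190.0, 260.0, 0.5)
        spec = synthgen.simulate_spectrum(1.0, wavelengths, n_residues=98)
        assert spec.mre_at(222.0) < 0 and spec.mre_at(208.0) < 0
        assert spec.mre_at(193.0) > 0

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            helicity_222(-20000.0, 1)
        with pytest.raises(DomainError):
            synthgen.simulate_spectrum(1.2, np.arange(190.0, 260.0))


class TestTTest:
    def test_welch_hand_computation(self):
        res = t_test([1, 2, 3], [4, 5, 6], mode="unpaired")
        assert res.t == pytest.approx(-3.674, abs=0.001)
        assert res.df == pytest.approx(4.0)
        assert 0 < res.p < 0.05

    def test_identical_groups_null(self):
        res = t_test([1, 2, 3], [1, 2, 3], mode="unpaired")
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_paired_constant_difference_degenerate(self):
        res = t_test([1, 2, 3], [2, 3, 4], mode="paired")
        assert res.degenerate
        assert np.isnan(res.p)

    def test_paired_matches_scipy_direction(self):
        res = t_test([46.1, 46.0, 46.3], [28.2, 28.3, 28.1], mode="paired")
        assert res.t > 0
        assert res.df == 2
        assert res.p < 0.01

    def test_sample_size_errors(self):
        with pytest.raises(SampleSizeError):
            t_test([1.0], [1.0, 2.0])
        with pytest.raises(SampleSizeError):
            t_test([1, 2, 3], [1, 2], mode="paired")
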