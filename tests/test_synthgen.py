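"""Synthetic generators: melting curves, Crick coiled coils, trajectories."""

import numpy as np
import pytest

from ccmelt import trajgeom
from ccmelt.cdmelt import two_state_fraction_unfolded
from ccmelt.errors import GridError, ValidationError
from ccmelt.synthgen import (
    CrickParams,
    PerturbationParams,
    TwoStateParams,
    build_coiled_coil,
    perturb_trajectory,
    simulate_melt,
)


class TestSimulateMelt:
    def test_midpoint_is_exactly_half(self):
        assert two_state_fraction_unfolded(50.0, 50.0, 400.0) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_low_temperature_limit_is_folded_baseline(self):
        params = TwoStateParams(tm_true=70.0, dh_vh=500.0, noise_sd=0.0)
        curve = simulate_melt(params)
        folded = params.folded_baseline[0] + params.folded_baseline[1] * 0.0
        assert curve.signal[0] == pytest.approx(folded, rel=1e-6)

    def test_symmetry_about_tm_with_flat_baselines(self):
        params = TwoStateParams(
            tm_true=45.0, dh_vh=400.0, noise_sd=0.0,
            folded_baseline=(-30000.0, 0.0), unfolded_baseline=(-3000.0, 0.0),
            temperature_grid=np.arange(25.0, 65.1, 0.5),
        )
        f = two_state_fraction_unfolded(params.temperature_grid, 45.0, 400.0)
        # symmetric about Tm up to the curvature of 1/T over the grid
        assert np.allclose(f + f[::-1], 1.0, atol=0.01)
        mid = np.searchsorted(params.temperature_grid, 45.0)
        assert f[mid] == pytest.approx(0.5, abs=1e-12)

    def test_determinism_and_seed_sensitivity(self):
        a = simulate_melt(TwoStateParams(noise_sd=200.0, seed=42))
        b = simulate_melt(TwoStateParams(noise_sd=200.0, seed=42))
        c = simulate_melt(TwoStateParams(noise_sd=200.0, seed=43))
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(a.signal, c.signal)

    def test_short_grid_raises(self):
        with pytest.raises(GridError):
            simulate_melt(
                TwoStateParams(temperature_grid=np.arange(0.0, 4.0, 0.5))
            )
        with pytest.raises(ValidationError):
            TwoStateParams(dh_vh=-10.0)


class TestBuildCoiledCoil:
    def test_consecutive_ca_distances(self, small_coiled_coil):
        for chain in ("A", "B"):
            _, ca = small_coiled_coil.ca_positions(chain)
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert np.all(np.abs(d - 3.8) <= 0.1)

    def test_end_to_end_matches_axial_rise(self):
        cp = CrickParams(n_residues=98)
        model = build_coiled_coil("A" * 98, cp)
        _, ca = model.ca_positions("A")
        expected = cp.rise_per_residue * 97
        assert np.linalg.norm(ca[-1] - ca[0]) == pytest.approx(expected, rel=0.05)

    def test_interchain_separation_near_2r0(self):
        cp = CrickParams(n_residues=56)
        model = build_coiled_coil("A" * 56, cp)
        _, ca_a = model.ca_positions("A")
        _, ca_b = model.ca_positions("B")
        sep = np.linalg.norm(ca_a - ca_b, axis=1)[7:-7]  # mid-chain
        assert sep.mean() == pytest.approx(2 * cp.superhelix_radius, rel=0.15)

    def test_all_residues_helical(self, small_coiled_coil):
        span = trajgeom.helix_span(small_coiled_coil, "A", min_run=4)
        assert (span.first_helical_residue, span.last_helical_residue) == (1, 35)

    def test_native_numbering(self):
        model = build_coiled_coil("A" * 14, CrickParams(n_residues=14),
                                  first_position=57)
        pos, _ = model.ca_positions("A")
        assert pos[0] == 57 and pos[-1] == 70

    def test_sequence_length_mismatch_raises(self):
        with pytest.raises(ValidationError):
            build_coiled_coil("A" * 10, CrickParams(n_residues=14))


class TestPerturbTrajectory:
    def test_null_perturbation_keeps_frames_identical(self, small_coiled_coil):
        pp = PerturbationParams(
            n_frames=5, bend_amplitude=0.0, fray_amplitude=0.0, seed=1
        )
        frames = perturb_trajectory(small_coiled_coil, pp)
        _, ref = small_coiled_coil.ca_positions("A")
        for frame in frames.frames:
            _, ca = frame.ca_positions("A")
            assert np.allclose(ca, ref)

    def test_frame_zero_unperturbed(self, small_coiled_coil):
        pp = PerturbationParams(n_frames=4, bend_amplitude=0.3, seed=2)
        frames = perturb_trajectory(small_coiled_coil, pp)
        _, ref = small_coiled_coil.ca_positions("A")
        _, first = frames.frames[0].ca_positions("A")
        assert np.array_equal(first, ref)

    def test_same_seed_reproduces_frames(self, small_coiled_coil):
        pp = PerturbationParams(n_frames=6, bend_amplitude=0.2, seed=9)
        f1 = perturb_trajectory(small_coiled_coil, pp)
        f2 = perturb_trajectory(small_coiled_coil, pp)
        for a, b in zip(f1.frames, f2.frames):
            _, ca_a = a.ca_positions("A")
            _, ca_b = b.ca_positions("A")
            assert np.array_equal(ca_a, ca_b)

    def test_mean_distance_decreases_with_bend(self, small_coiled_coil):
        means = []
        for bend in (0.0, 0.1, 0.2):
            pp = PerturbationParams(
                n_frames=50, bend_amplitude=bend, fray_length=3,
                fray_amplitude=1.0, seed=4,
            )
            frames = perturb_trajectory(small_coiled_coil, pp)
            means.append(trajgeom.end_to_end(frames, "A", 1, 35).mean())
        assert means[0] > means[1] > means[2]

    def test_connectivity_outside_frayed_termini(self, small_coiled_coil):
        pp = PerturbationParams(
            n_frames=20, bend_amplitude=0.3, fray_length=4, fray_amplitude=1.5,
            seed=6,
        )
        frames = perturb_trajectory(small_coiled_coil, pp)
        for frame in frames.frames:
            for chain in ("A", "B"):
                _, ca = frame.ca_positions(chain)
                interior = ca[4:-4]
                d = np.linalg.norm(np.diff(interior, axis=0), axis=1)
                assert np.all((d >= 3.0) & (d <= 4.6))
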