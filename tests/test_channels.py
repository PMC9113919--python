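"""Channel bank, interaction kernel, likelihood and posterior recursion."""

import math

import numpy as np
import pytest

from speedscale import (
    ChannelBankSpec,
    InteractionParams,
    ParticipantParams,
    WeightPolynomial,
    apply_interactions,
    build_bank,
    channel_response,
    default_speed_grid,
    interaction_kernel,
    mc_envelope,
    posterior_update,
    run_windows,
    speed_likelihood,
    stimulus_drive,
)
from speedscale.channels import normalize_density

SQ2 = math.sqrt(2.0)


def test_default_bank_geometry(bank):
    assert bank.n_channels == 722
    speeds = 2.0**bank.log2_speed
    assert speeds.min() >= 1.0 - 1e-9
    assert speeds.max() <= 512.0 + 1e-9


def test_bad_lattice_raises():
    spec = ChannelBankSpec(log2_tf_range=(0.0, 12.0))
    with pytest.raises(ValueError, match="preferred-speed range"):
        build_bank(spec)


def test_weight_polynomial_peaks_at_printed_spatial_frequency():
    assert WeightPolynomial().peak_sf() == pytest.approx(0.21, abs=0.01)


def test_weight_transforms(bank):
    assert bank.weights.max() == pytest.approx(1.0)
    assert np.all(bank.weights >= 0)
    floored = build_bank(weight_transform="linear_floor")
    # the printed polynomial is negative everywhere on the lattice
    assert np.all(floored.weights == 0.0)


def test_zero_contrast_gives_zero_response(bank, cmap):
    m = channel_response(bank, cmap["c1"], contrast=0.0)
    assert np.all(m == 0.0)


def test_dg_at_channel_center_gives_peak_density(bank, dg_catalog):
    dgs, _ = dg_catalog
    # move a grating exactly onto a channel centre
    i = 360
    from dataclasses import replace

    spec = replace(
        dgs["c1"],
        sf0=2.0 ** bank.log2_fx[i],
        tf0=2.0 ** bank.log2_ft[i],
        v0=2.0 ** (bank.log2_ft[i] - bank.log2_fx[i]),
    )
    m = channel_response(bank, spec, contrast=0.6, g=2.0)
    expected = 4.0 * bank.weights[i] * 0.6 * bank.peak_density
    assert m[i] == pytest.approx(expected, rel=1e-9)


def test_mc_drive_matches_dense_grating_sum_oracle(bank, cmap):
    """Envelope-grid channel responses agree with a 512x512 brute-force
    grating sum to <1% relative error on driven channels."""
    from speedscale.envelope import default_grid

    spec = cmap["c1"]
    coarse = stimulus_drive(bank, mc_envelope(spec))
    dense_grid = default_grid(spec.log2_sf, spec.log2_tf, n=512)
    dense = stimulus_drive(bank, mc_envelope(spec, dense_grid))
    driven = dense > dense.max() * 1e-3
    rel = np.abs(coarse[driven] - dense[driven]) / dense[driven]
    assert rel.max() < 0.01


def test_mc_drive_convergence_with_grid_resolution(bank, cmap):
    from speedscale.envelope import default_grid

    spec = cmap["c1"]
    ref = stimulus_drive(
        bank, mc_envelope(spec, default_grid(spec.log2_sf, spec.log2_tf, n=512))
    )
    errs = []
    for n in (16, 32, 64):
        d = stimulus_drive(
            bank, mc_envelope(spec, default_grid(spec.log2_sf, spec.log2_tf, n=n))
        )
        errs.append(np.max(np.abs(d - ref)) / ref.max())
    assert errs[0] > errs[1] > errs[2]
    assert errs[1] / errs[2] > 1.5  # at least first-order convergence


def test_pattern_drive_is_mean_of_component_drives(bank, cmap, pmap):
    pat = pmap["d"]
    d_pat = stimulus_drive(bank, pat, components=cmap)
    d_comps = np.mean(
        [stimulus_drive(bank, cmap[c]) for c in pat.component_ids], axis=0
    )
    np.testing.assert_allclose(d_pat, d_comps, rtol=1e-12)


class TestInteractionKernel:
    def test_zero_at_origin(self):
        k = interaction_kernel(InteractionParams.crossed_preset())
        assert k(0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_even_symmetry(self, rng):
        k = interaction_kernel(InteractionParams.crossed_preset())
        for _ in range(20):
            dx, dt = rng.normal(0, 2, 2)
            assert k(dx, dt) == pytest.approx(k(-dx, -dt), abs=1e-12)

    def test_equal_sds_cancel(self, rng):
        p = InteractionParams(
            sigma_e1=0.3, sigma_e2=0.9, sigma_i1=0.3, sigma_i2=0.9
        )
        k = interaction_kernel(p)
        d = k(rng.normal(0, 2, 50), rng.normal(0, 2, 50))
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_packaged_kernel_inhibits_along_scale_at_three_octaves(self):
        k = interaction_kernel(InteractionParams.crossed_preset())
        # scale-axis displacement: (-1, 1)/sqrt(2) in (log2 sf, log2 tf)
        assert k(-3.0 / SQ2, 3.0 / SQ2) < 0.0

    def test_packaged_kernel_excites_along_speed_axis(self):
        k = interaction_kernel(InteractionParams.crossed_preset())
        assert k(1.0 / SQ2, 1.0 / SQ2) > 0.0


class TestApplyInteractions:
    def test_null_kernel_is_identity(self, bank, rng):
        m = np.abs(rng.normal(0, 1, bank.n_channels))
        p = InteractionParams(sigma_e1=0.3, sigma_e2=0.9, sigma_i1=0.3, sigma_i2=0.9)
        n = apply_interactions(m, bank, interaction_kernel(p))
        np.testing.assert_allclose(n, m, atol=1e-12)

    def test_single_active_channel_unchanged(self, bank):
        m = np.zeros(bank.n_channels)
        m[100] = 2.5
        n = apply_interactions(m, bank, interaction_kernel(InteractionParams.crossed_preset()))
        assert n[100] == pytest.approx(2.5)

    def test_two_channel_hand_computation(self, bank):
        k = interaction_kernel(InteractionParams.crossed_preset())
        i, j = 100, 101
        m = np.zeros(bank.n_channels)
        m[i], m[j] = 2.0, 1.0
        dij = float(
            k(bank.log2_fx[i] - bank.log2_fx[j], bank.log2_ft[i] - bank.log2_ft[j])
        )
        n = apply_interactions(m, bank, k)
        # interaction field uses peak-normalized activity (peak = 2.0)
        assert n[i] == pytest.approx(max(2.0 * (1.0 + (1.0 / 2.0) * dij), 0.0))
        assert n[j] == pytest.approx(max(1.0 * (1.0 + (2.0 / 2.0) * dij), 0.0))

    def test_literal_mode(self, bank):
        k = interaction_kernel(InteractionParams.crossed_preset())
        m = np.zeros(bank.n_channels)
        m[50] = 1.0
        n = apply_interactions(m, bank, k, mode="literal")
        assert n[50] == pytest.approx(0.0)  # d_ii = 0 so n = m * 0

    def test_interactions_disabled(self, bank, rng):
        m = np.abs(rng.normal(0, 1, bank.n_channels))
        np.testing.assert_array_equal(apply_interactions(m, bank, None), m)


class TestSpeedLikelihood:
    def test_single_channel_peaks_at_preferred_speed(self, bank):
        grid = default_speed_grid()
        n = np.zeros(bank.n_channels)
        n[200] = 1.0
        logL = speed_likelihood(n, bank, grid)
        assert grid[np.argmax(logL)] == pytest.approx(bank.log2_speed[200], abs=0.05)
        # unit peak: log psi at the preferred speed is 0
        assert logL.max() == pytest.approx(0.0, abs=1e-3)

    def test_two_equal_channels_peak_at_midpoint(self, bank):
        grid = default_speed_grid()
        n = np.zeros(bank.n_channels)
        i, j = 100, 500
        n[i] = n[j] = 1.0
        logL = speed_likelihood(n, bank, grid)
        mid = 0.5 * (bank.log2_speed[i] + bank.log2_speed[j])
        assert grid[np.argmax(logL)] == pytest.approx(mid, abs=0.05)

    def test_unequal_sigmas_rejected(self):
        bank = build_bank(ChannelBankSpec(sigma_t=0.6))
        with pytest.raises(ValueError, match="sigma_x == sigma_t"):
            speed_likelihood(np.ones(bank.n_channels), bank, default_speed_grid())


class TestPosterior:
    def test_uniform_likelihood_preserves_prior(self):
        grid = default_speed_grid()
        prior = ParticipantParams().prior_density(grid)
        post = posterior_update(prior, np.zeros_like(grid), grid)
        np.testing.assert_allclose(post, prior, rtol=1e-12)

    def test_conjugate_gaussian_closed_form(self):
        grid = default_speed_grid(n=2048)
        mu0, s0 = 3.0, 0.8
        muL, sL = 5.0, 0.5
        prior = normalize_density(np.exp(-0.5 * ((grid - mu0) / s0) ** 2), grid)
        logL = -0.5 * ((grid - muL) / sL) ** 2
        post = posterior_update(prior, logL, grid)
        mean = np.trapezoid(grid * post, grid)
        var = np.trapezoid((grid - mean) ** 2 * post, grid)
        var_c = 1.0 / (1.0 / s0**2 + 1.0 / sL**2)
        mean_c = var_c * (mu0 / s0**2 + muL / sL**2)
        assert mean == pytest.approx(mean_c, abs=1e-3)
        assert var == pytest.approx(var_c, rel=1e-3)

    def test_repeated_likelihood_converges_to_its_mode(self):
        grid = default_speed_grid()
        part = ParticipantParams()
        post = part.prior_density(grid)
        logL = -0.5 * ((grid - 4.5) / 0.7) ** 2
        for _ in range(50):
            post = posterior_update(post, logL, grid)
        assert grid[np.argmax(post)] == pytest.approx(4.5, abs=0.05)

    def test_underflow_raises(self):
        grid = default_speed_grid()
        prior = np.zeros_like(grid)
        prior[0] = 1.0
        logL = np.full_like(grid, -np.inf)
        logL[-1] = 0.0
        with pytest.raises(FloatingPointError):
            posterior_update(prior, logL, grid)


class TestRunWindows:
    def test_every_posterior_normalizes(self, bank, cmap):
        seq = run_windows(cmap["c1"], ParticipantParams(g=0.5), None, bank)
        for p in seq.posteriors:
            assert np.trapezoid(p, seq.speed_grid) == pytest.approx(1.0, abs=1e-9)

    def test_zero_contrast_keeps_prior(self, bank, cmap):
        part = ParticipantParams()
        seq = run_windows(cmap["c1"], part, None, bank, contrast=0.0)
        prior = part.prior_density(seq.speed_grid)
        for p in seq.posteriors:
            np.testing.assert_allclose(p, prior, rtol=1e-9)

    def test_posterior_variance_non_increasing(self, bank, cmap):
        seq = run_windows(cmap["c1"], ParticipantParams(g=0.5), None, bank)
        variances = [seq.var_log2(w) for w in range(seq.n_windows + 1)]
        assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))

    def test_flat_weights_dg_posterior_approaches_stimulus_speed(self, dg_catalog):
        dgs, _ = dg_catalog
        flat = build_bank(weights=WeightPolynomial((1.0, 0, 0, 0, 0, 0)))
        part = ParticipantParams(g=0.2)
        seq = run_windows(dgs["c1"], part, None, flat, n_windows=5)
        modes = [seq.mode_log2(w) for w in range(6)]
        target = math.log2(24.0)
        assert modes[0] < target
        diffs = [abs(m - target) for m in modes]
        assert all(b <= a + 1e-9 for a, b in zip(diffs, diffs[1:]))
        assert diffs[-1] < diffs[0]

    def test_interactions_change_the_sequence(self, bank, cmap):
        part = ParticipantParams(g=0.5)
        s_off = run_windows(cmap["c1"], part, None, bank)
        s_on = run_windows(cmap["c1"], part, InteractionParams.crossed_preset(), bank)
        assert not np.allclose(s_off.posteriors[-1], s_on.posteriors[-1])


def test_mechanism_scale_pattern_sublinear_speed_pattern_not(bank, cmap, pmap):
    """With the packaged kernel, summed network activity is sublinear for the
    scale-axis triplet (pattern d) and not sublinear for the speed-axis
    triplet (pattern i), relative to the component averages."""
    kernel = interaction_kernel(InteractionParams.crossed_preset())

    def summed(stim):
        m = channel_response(bank, stim, components=cmap)
        return apply_interactions(m, bank, kernel).sum()

    for pid, sublinear in (("d", True), ("i", False)):
        pat = pmap[pid]
        s_pat = summed(pat)
        s_comp = np.mean([summed(cmap[c]) for c in pat.component_ids])
        if sublinear:
            assert s_pat < s_comp
        else:
            assert s_pat >= s_comp


def test_posterior_sequence_hdf5_export(bank, cmap, tmp_path):
    import h5py

    seq = run_windows(cmap["c1"], ParticipantParams(g=0.5), None, bank)
    path = tmp_path / "seq.h5"
    seq.to_hdf5(path)
    with h5py.File(path) as f:
        np.testing.assert_array_equal(f["posteriors"][:], seq.posteriors)
        assert f["speed_grid_log2"].shape == seq.speed_grid.shape
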