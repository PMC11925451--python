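"""Generator invariants: geometry, stripes, designs, BOLD determinism."""

import numpy as np
import pandas as pd
import pytest

from v2lamina import glm, laminar
from v2lamina import synthetic as syn
from v2lamina.exceptions import ConfigurationError, InputError


class TestCorticalPatch:
    def test_flat_config_depths_at_bin_midpoints(self, flat_patch):
        v1 = flat_patch.area_voxels("V1")
        assert np.allclose(np.sort(v1["depth"].unique()), [1 / 6, 3 / 6, 5 / 6])
        assert (v1["A_inner"] == v1["A_outer"]).all()

    def test_every_area_covers_all_depth_bins(self, small_patch):
        bins = laminar.depth_bin(small_patch.voxels["depth"].to_numpy())
        for area in small_patch.grids:
            present = set(bins[(small_patch.voxels["area"] == area).to_numpy()])
            assert present == set(laminar.DEPTH_BINS)

    def test_eccentricity_spans_range(self, small_patch):
        for area in small_patch.grids:
            ecc = small_patch.area_voxels(area)["eccentricity"]
            assert ecc.min() == pytest.approx(0.0)
            assert ecc.max() == pytest.approx(18.0)

    def test_border_at_v_zero(self, small_patch):
        assert small_patch.area_voxels("V1")["v"].max() < 0
        assert small_patch.area_voxels("V2")["v"].min() == 0.0

    def test_non_positive_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.make_cortical_patch(syn.PatchConfig(area_grids={"V1": (0, 5)}))

    def test_deterministic(self):
        cfg = syn.PatchConfig(area_grids={"V1": (6, 5), "V2": (6, 5)})
        a = syn.make_cortical_patch(cfg).voxels
        b = syn.make_cortical_patch(cfg).voxels
        pd.testing.assert_frame_equal(a, b)


class TestStripeMap:
    def test_quarter_duty_band_positions(self, small_patch):
        sm = syn.make_stripe_map(small_patch, cycle_mm=8.0)
        v2 = small_patch.area_voxels("V2")
        comp = sm.of_voxels(v2["voxel_id"].to_numpy())
        u = np.mod(v2["u"].to_numpy(), 8.0)
        assert set(comp[u < 2.0]) == {"thin"}
        assert set(comp[(u >= 4.0) & (u < 6.0)]) == {"thick"}

    def test_periodic_in_phase(self, small_patch):
        a = syn.make_stripe_map(small_patch, phase_mm=0.0)
        b = syn.make_stripe_map(small_patch, phase_mm=8.0)
        assert (a.compartment == b.compartment).all()

    def test_bands_constant_along_v(self, small_patch):
        sm = syn.make_stripe_map(small_patch)
        v2 = small_patch.area_voxels("V2")
        comp = pd.Series(sm.of_voxels(v2["voxel_id"].to_numpy()))
        assert (comp.groupby(v2["iu"].to_numpy()).nunique() == 1).all()

    def test_outside_v2_is_none(self, small_patch):
        sm = syn.make_stripe_map(small_patch)
        v1 = small_patch.area_voxels("V1")
        assert set(sm.of_voxels(v1["voxel_id"].to_numpy())) == {"none"}

    def test_duty_must_sum_to_one(self, small_patch):
        with pytest.raises(ConfigurationError):
            syn.make_stripe_map(small_patch, duty=(0.3, 0.3, 0.3, 0.2))


class TestBlockDesign:
    def test_ten_blocks_per_run(self):
        d = syn.make_block_design(("chr", "ach"), n_runs=1)
        assert d.n_blocks == 10
        assert len(d.block_onsets[0]) == 10

    def test_run_length_must_divide_tr(self):
        # 16 s fixation with TR 2.4 -> 272 s = 113.33 TRs: rejected;
        # 16.8 s -> 273.6 s = 114 TRs: accepted.
        with pytest.raises(ConfigurationError):
            syn.make_block_design(("a", "b"), 1, fixation_s=16.0)
        d = syn.make_block_design(("a", "b"), 1, fixation_s=16.8)
        assert d.n_timepoints == 114

    def test_single_block_onset_at_fixation(self):
        d = syn.make_block_design(("a",), n_runs=1, blocks_per_condition=1)
        assert d.block_onsets[0] == [(16.8, "a")]

    def test_counterbalanced_alternation(self):
        d = syn.make_block_design(("chr", "ach"), n_runs=2)
        run0 = [c for _, c in d.block_onsets[0]]
        run1 = [c for _, c in d.block_onsets[1]]
        assert run0[:4] == ["chr", "ach", "chr", "ach"]
        assert run1[:2] == ["ach", "chr"]

    def test_roundtrip_dict(self):
        d = syn.make_block_design(("a", "b"), 2)
        assert syn.BlockDesign.from_dict(d.to_dict()).to_dict() == d.to_dict()


@pytest.fixture(scope="module")
def tiny_setup():
    patch = syn.make_cortical_patch(
        syn.PatchConfig(area_grids={a: (16, 10) for a in syn.AREAS})
    )
    stripes = syn.make_stripe_map(patch)
    design = syn.make_block_design(("chr", "ach"), n_runs=2)
    return patch, stripes, design


class TestSimulateBold:
    def test_same_seed_bit_identical(self, tiny_setup):
        patch, stripes, design = tiny_setup
        truth = syn.default_truth()
        a = syn.simulate_bold(patch, stripes, design, truth, "color", seed=9)
        b = syn.simulate_bold(patch, stripes, design, truth, "color", seed=9)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra, rb)

    def test_different_seed_differs(self, tiny_setup):
        patch, stripes, design = tiny_setup
        truth = syn.default_truth()
        a = syn.simulate_bold(patch, stripes, design, truth, "color", seed=9)
        b = syn.simulate_bold(patch, stripes, design, truth, "color", seed=10)
        assert not np.array_equal(a.runs[0], b.runs[0])

    def test_noise_mean_zero_within_three_se(self, tiny_setup):
        patch, stripes, design = tiny_setup
        truth = syn.default_truth()
        truth.stripe_amplitudes = {
            c: {k: 0.0 for k in v} for c, v in truth.stripe_amplitudes.items()
        }
        truth.area_amplitudes = {
            a: {k: 0.0 for k in v} for a, v in truth.area_amplitudes.items()
        }
        ds = syn.simulate_bold(patch, stripes, design, truth, "color", seed=2)
        x = np.concatenate([r.ravel() for r in ds.runs])
        # smoothing correlates neighbours; bound the SE by independent columns
        n_eff = x.size / 16
        assert abs(x.mean()) < 3 * truth.noise_sd / np.sqrt(n_eff)

    def test_planted_stripe_periodicity(self, tiny_setup):
        """The noiseless color-differential map has its spatial spectrum
        peak at the stripe frequency 1/cycle along u."""
        patch, _, design = tiny_setup
        cycle = 8.0
        stripes = syn.make_stripe_map(patch, cycle_mm=cycle)
        truth = syn.default_truth()
        truth.noise_sd = 0.0
        truth.amplitude_jitter_sd = 0.0
        truth.shared_variability = []
        ds = syn.simulate_bold(patch, stripes, design, truth, "color", seed=0)
        X = glm.build_design_matrix(design, 0)
        res = glm.fit_glm(ds.runs[0], X)
        diff = pd.Series(
            res.beta("chr") - res.beta("ach"),
            index=patch.voxels["voxel_id"].to_numpy(),
        )
        grid = patch.column_grid("V2", patch.column_means("V2", diff))
        prof = np.nanmean(grid, axis=0)
        spec = np.abs(np.fft.rfft(prof - prof.mean()))
        freqs = np.fft.rfftfreq(prof.size, d=patch.config.spacing_mm)
        assert freqs[np.argmax(spec)] == pytest.approx(1.0 / cycle, abs=freqs[1] / 2)

    def test_noiseless_betas_recover_amplitudes(self, tiny_setup):
        patch, stripes, design = tiny_setup
        truth = syn.default_truth()
        truth.noise_sd = 0.0
        truth.amplitude_jitter_sd = 0.0
        truth.shared_variability = []
        ds = syn.simulate_bold(patch, stripes, design, truth, "color", seed=0)
        X = glm.build_design_matrix(design, 0)
        res = glm.fit_glm(ds.runs[0], X)
        expected = syn.condition_amplitudes(patch, stripes, truth, "color")
        expected = expected * syn._voxel_gain(patch, truth, 0)[:, None]
        got = np.column_stack([res.beta("chr"), res.beta("ach")])
        assert np.allclose(got, expected, atol=1e-8)

    def test_shared_latent_unit_variance(self, tiny_setup):
        """The block latent recovered from noiseless coupled responses has
        unit variance (checked over >= 500 blocks)."""
        patch, stripes, _ = tiny_setup
        design = syn.make_block_design(("tex", "noi"), n_runs=60)
        truth = syn.default_truth()
        truth.noise_sd = 0.0
        truth.amplitude_jitter_sd = 0.0
        truth.shared_variability = [syn.Coupling("V2", "deep", "V4", "deep", "texture", 1.0)]
        ds = syn.simulate_bold(patch, stripes, design, truth, "texture", seed=3)
        amp = syn.condition_amplitudes(patch, stripes, truth, "texture")
        amp = amp * syn._voxel_gain(patch, truth, 3)[:, None]
        vox = patch.voxels
        bins = laminar.depth_bin(vox["depth"].to_numpy())
        node = ((vox["area"] == "V2").to_numpy()) & (bins == "deep")
        i = np.where(node)[0][0]
        s = []
        for r in range(design.n_runs):
            Xb = glm.build_design_matrix(design, r, "per_block", drift_order=0)
            res = glm.fit_glm(ds.runs[r][i : i + 1], Xb)
            for b, (_, cond) in enumerate(design.block_onsets[r]):
                j = 0 if cond == "tex" else 1
                s.append(res.beta(b)[0] / amp[i, j] - 1.0)
        s = np.asarray(s)
        assert s.size >= 500
        assert s.std() == pytest.approx(1.0, rel=0.15)
        assert abs(s.mean()) < 3.0 / np.sqrt(s.size)

    def test_mismatched_stripe_map_rejected(self, tiny_setup, small_patch):
        patch, stripes, design = tiny_setup
        other = syn.make_stripe_map(small_patch)
        with pytest.raises(InputError):
            syn.simulate_bold(patch, other, design, syn.default_truth(), "color")


class TestDiskRoundTrip:
    def test_nifti_csv_json_roundtrip(self, tiny_setup, tmp_path):
        patch, stripes, design = tiny_setup
        truth = syn.default_truth()
        ds = syn.simulate_bold(patch, stripes, design, truth, "color", seed=4)
        syn.write_dataset(ds, tmp_path)
        back = syn.read_dataset(tmp_path, patch)
        assert back.contrast == "color"
        assert back.design.to_dict() == design.to_dict()
        assert back.truth.to_dict() == truth.to_dict()
        for a, b in zip(ds.runs, back.runs):
            assert np.allclose(a, b, rtol=1e-6, atol=1e-5)  # float32 on disk
        assert (back.stripe_map.compartment == stripes.compartment).all()
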