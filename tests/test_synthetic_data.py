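import numpy as np
import pytest

from osteoflow.roc_mapping import roc_curve, superimpose
from osteoflow.stress_field import VoxelFieldSample
from osteoflow.synthetic_data import (
    MineralizationLink,
    PhantomError,
    PhantomParams,
    ScanParams,
    gen_mineralization,
    gen_scaffold_phantom,
    simulate_uct_scan,
)
from osteoflow.uct_pipeline import (
    BinaryMask,
    cylinder_mask,
    filter_components,
    gaussian_filter,
    segment,
)

# small, fast phantom used throughout: 2 mm diameter, 1 mm height, 50 um voxels
SMALL = PhantomParams(scaffold_radius=1e-3, scaffold_height=1e-3,
                      pore_diameter_range=(315e-6, 400e-6), voxel_size=50e-6, seed=11)


def _uniform_sample(shape, tau=1e-3):
    return VoxelFieldSample(np.full(shape, tau), 50e-6, np.zeros(3),
                            np.ones(shape, bool))


class TestPhantom:
    def test_measured_porosity_within_band(self):
        vol, pores = gen_scaffold_phantom(SMALL)
        env = cylinder_mask(pores.data.shape, SMALL.voxel_size,
                            SMALL.scaffold_radius, SMALL.scaffold_height).data
        frac = (pores.data & env).sum() / env.sum()
        assert abs(frac - 0.55) <= 0.02

    def test_seed_reproducibility(self):
        _, p1 = gen_scaffold_phantom(SMALL)
        _, p2 = gen_scaffold_phantom(SMALL)
        assert np.array_equal(p1.data, p2.data)

    def test_scaffold_density_subthreshold(self):
        vol, pores = gen_scaffold_phantom(SMALL)
        assert vol.data.max() < 97.5
        assert not (pores.data & (vol.data > 0)).any()

    def test_unreachable_porosity_errors(self):
        bad = PhantomParams(scaffold_radius=1e-3, scaffold_height=1e-3,
                            porosity=0.9, voxel_size=50e-6, seed=0)
        with pytest.raises(PhantomError):
            gen_scaffold_phantom(bad, max_attempts=5)


class TestMineralization:
    def test_zero_rate_zero_bonus_stays_empty(self):
        _, pores = gen_scaffold_phantom(SMALL)
        ss = _uniform_sample(pores.data.shape)
        masks = gen_mineralization(ss, pores, MineralizationLink(rate=0.0, bonus=0.0),
                                   [1, 2, 3])
        assert all(m.count() == 0 for m in masks.values())

    def test_band_link_no_noise_selects_band_exactly(self):
        _, pores = gen_scaffold_phantom(SMALL)
        rng = np.random.default_rng(0)
        tau = rng.uniform(0, 30e-3, pores.data.shape)
        ss = VoxelFieldSample(tau, 50e-6, np.zeros(3), np.ones(tau.shape, bool))
        link = MineralizationLink(rate=1.0, bonus=0.0)
        mask = gen_mineralization(ss, pores, link, [1])[1]
        in_band = (tau >= link.lo) & (tau <= link.hi) & pores.data
        assert np.array_equal(mask.data, in_band)

    def test_masks_nested_over_weeks(self):
        _, pores = gen_scaffold_phantom(SMALL)
        ss = _uniform_sample(pores.data.shape)
        masks = gen_mineralization(ss, pores, MineralizationLink(kind="uniform", rate=0.3),
                                   [2, 3, 4, 5])
        weeks = sorted(masks)
        for a, b in zip(weeks, weeks[1:]):
            assert not (masks[a].data & ~masks[b].data).any()

    def test_weeks_must_increase(self):
        _, pores = gen_scaffold_phantom(SMALL)
        ss = _uniform_sample(pores.data.shape)
        with pytest.raises(ValueError):
            gen_mineralization(ss, pores, MineralizationLink(), [3, 2])

    def test_uniform_link_gives_chance_level_roc(self):
        _, pores = gen_scaffold_phantom(SMALL)
        rng = np.random.default_rng(1)
        tau = rng.uniform(0, 30e-3, pores.data.shape)
        ss = VoxelFieldSample(tau, 50e-6, np.zeros(3), np.ones(tau.shape, bool))
        mask = gen_mineralization(ss, pores, MineralizationLink(kind="uniform", rate=0.4,
                                                                bonus=0.0, seed=2), [1])[1]
        region = BinaryMask(pores.data.copy(), 50e-6)
        curve = roc_curve(superimpose(ss, mask, region))
        assert curve.auc == pytest.approx(0.5, abs=0.02)


class TestScan:
    def test_noiseless_scan_inverts_exactly(self):
        _, pores = gen_scaffold_phantom(SMALL)
        ss = _uniform_sample(pores.data.shape)
        mask = gen_mineralization(ss, pores, MineralizationLink(kind="uniform", rate=0.5,
                                                                bonus=0.0, seed=3), [1])[1]
        scan = simulate_uct_scan(mask, ScanParams(psf_sigma=0.0, noise_sd=0.0,
                                                  mineral_density=200.0))
        assert np.array_equal(segment(scan).data, mask.data)

    def test_seed_reproducibility(self):
        mask = BinaryMask(np.zeros((8, 8, 8), bool), 36e-6)
        s1 = simulate_uct_scan(mask, ScanParams(seed=5))
        s2 = simulate_uct_scan(mask, ScanParams(seed=5))
        assert np.array_equal(s1.data, s2.data)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            ScanParams(noise_sd=-1.0)

    def test_noisy_blob_recovered_with_no_false_components(self):
        # ~500-voxel ball, noise SD 30 mg/cm^3, standard chain
        shape = (40, 40, 40)
        ax = np.arange(40) - 20
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        blob = X**2 + Y**2 + Z**2 <= 4.9**2  # 485 voxels
        scan = simulate_uct_scan(BinaryMask(blob, 36e-6),
                                 ScanParams(psf_sigma=0.0, noise_sd=30.0,
                                            mineral_density=200.0, seed=7))
        rec = filter_components(segment(gaussian_filter(scan)), 50)
        assert (rec.data & blob).sum() >= 0.95 * blob.sum()
        # empty background: no spurious component of size >= 50
        empty = simulate_uct_scan(BinaryMask(np.zeros(shape, bool), 36e-6),
                                  ScanParams(psf_sigma=0.0, noise_sd=30.0, seed=8))
        rec_empty = filter_components(segment(gaussian_filter(empty)), 50)
        assert rec_empty.count() == 0
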