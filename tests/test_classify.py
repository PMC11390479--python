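"""Bootstrap k-means seeding, annealed MRA, consensus retention and
class registration."""

import math

import numpy as np
import pytest

from chapsta import phantoms as ph
from chapsta.align import ParticleSet
from chapsta.classify import (
    BootstrapSpec,
    MRAParams,
    bootstrap_kmeans_seed,
    consensus_classify,
    mra_anneal,
    ordered_class_index,
    register_c7_classes,
)
from chapsta.classify import _FourierStack
from chapsta.volumes import EulerAngles, Volume, apply_transform, symmetrize
from conftest import masked_corr


VOXEL = 7.04


def _interior_mask():
    c = 24
    zz, yy, xx = np.meshgrid(*([np.arange(48) - c] * 3), indexing="ij")
    m = (np.sqrt(xx**2 + yy**2) * VOXEL < 20) & (np.abs(zz * VOXEL) < 32)
    return Volume(m.astype(np.float32), VOXEL)


@pytest.fixture(scope="module")
def chamber_fixture():
    """Two-state chamber cohort (40% ordered) at SNR 0.3."""
    cfg = ph.SimulationConfig(
        mixture=((ph.CHAMBER_ORDERED, 0.4), (ph.CHAMBER_DISORDERED, 0.3),
                 (ph.CHAMBER_EMPTY, 0.3)),
        snr=0.3,
    )
    stack, truth = ph.simulate_particle_stack(cfg, 200, seed=21)
    pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)
    return cfg, pset, truth


@pytest.fixture(scope="module")
def chamber_engine(chamber_fixture):
    cfg, pset, truth = chamber_fixture
    params = MRAParams(crop=24, denoise_lowpass=30.0)
    return params, _FourierStack(pset, params, _interior_mask())


class TestBootstrapKmeans:
    def test_two_state_seeds_split_along_the_substrate_contrast(
            self, chamber_fixture, chamber_engine):
        """Bootstrap averages are mixtures, so the k-means seeds separate
        weakly but consistently along the ordered-substrate direction; the
        annealed MRA then sharpens them (tested below)."""
        cfg, pset, truth = chamber_fixture
        params, engine = chamber_engine
        refs, assign = bootstrap_kmeans_seed(
            pset, _interior_mask(), BootstrapSpec(300, 40, seed=1), params,
            stack=engine)
        assert 0 < assign.sum() < 300  # both clusters populated
        m = engine.mask.astype(bool)
        assert masked_corr(refs[0].data, refs[1].data, m) < 0.999
        # the seed difference is concentrated at the substrate position
        diff = np.abs(refs[0].data - refs[1].data)
        nb = diff.shape[0]
        cb = nb // 2
        zc = cb - int(round(20 / VOXEL))
        blob = diff[zc - 2: zc + 3, cb - 2: cb + 3, cb - 2: cb + 3].mean()
        assert blob > 1.2 * diff[m].mean()

    def test_identical_particles_yield_identical_centroids(self):
        cfg = ph.SimulationConfig(mixture=((ph.CHAMBER_ORDERED, 1.0),),
                                  snr=math.inf, random_orientations=False)
        stack, truth = ph.simulate_particle_stack(cfg, 30, seed=2)
        pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)
        params = MRAParams(crop=24, denoise_lowpass=None)
        refs, _ = bootstrap_kmeans_seed(pset, _interior_mask(),
                                        BootstrapSpec(50, 10, seed=3), params)
        m = refs[0].data > -np.inf
        assert masked_corr(refs[0].data, refs[1].data, m) >= 0.999

    def test_bootstrap_size_exceeding_count_rejected(self, chamber_fixture):
        cfg, pset, truth = chamber_fixture
        with pytest.raises(ValueError):
            bootstrap_kmeans_seed(pset, _interior_mask(),
                                  BootstrapSpec(10, 10_000), MRAParams())


class TestMRAAnneal:
    def test_zero_temperature_is_exact_argmax(self, chamber_fixture,
                                              chamber_engine):
        """With T=0 the assignment must equal the brute-force best class."""
        cfg, pset, truth = chamber_fixture
        params_base, engine = chamber_engine
        refs, _ = bootstrap_kmeans_seed(
            pset, _interior_mask(), BootstrapSpec(100, 30, seed=5),
            params_base, stack=engine)
        params = MRAParams(crop=24, denoise_lowpass=30.0, n_iterations=1,
                           temperature_factor=0.0)
        model = mra_anneal(pset, refs, params, seed=6, stack=engine)
        scores = engine.score_against(refs)
        expected = np.argmax(scores, axis=1) + 1
        assert np.array_equal(model.labels, expected)

    def test_population_conservation_every_iteration(self, chamber_fixture,
                                                     chamber_engine):
        cfg, pset, truth = chamber_fixture
        params_base, engine = chamber_engine
        refs, _ = bootstrap_kmeans_seed(
            pset, _interior_mask(), BootstrapSpec(100, 30, seed=7),
            params_base, stack=engine)
        params = MRAParams(crop=24, denoise_lowpass=30.0, n_iterations=10)
        model = mra_anneal(pset, refs, params, seed=8, stack=engine)
        for pops in model.population_trace:
            assert sum(pops) == len(pset)

    def test_two_state_label_accuracy(self, chamber_fixture, chamber_engine):
        cfg, pset, truth = chamber_fixture
        params, engine = chamber_engine
        refs, _ = bootstrap_kmeans_seed(
            pset, _interior_mask(), BootstrapSpec(300, 40, seed=9), params,
            stack=engine)
        model = mra_anneal(pset, refs, params, seed=10, stack=engine)
        ordered = (truth["occupancy"] == "ordered").to_numpy()
        k = ordered_class_index(model.references)
        acc = ((model.labels == k) == ordered).mean()
        assert acc >= 0.9

    def test_default_parameters(self):
        p = MRAParams()
        assert p.n_iterations == 40
        assert p.temperature_factor == 10.0
        assert p.n_classes == 2


class TestConsensus:
    def test_noise_free_two_state_fully_retained_and_correct(self):
        cfg = ph.SimulationConfig(
            mixture=((ph.CHAMBER_ORDERED, 0.5), (ph.CHAMBER_EMPTY, 0.5)),
            snr=math.inf)
        stack, truth = ph.simulate_particle_stack(cfg, 60, seed=11)
        pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)
        interior = _interior_mask()
        res = consensus_classify(
            pset, MRAParams(crop=24, denoise_lowpass=None, n_iterations=10),
            BootstrapSpec(100, 20), interior, n_repeats=2, master_seed=12,
            focus_mask=interior)
        assert res.retained.all()
        ordered = (truth["occupancy"] == "ordered").to_numpy()
        k = ordered_class_index(res.references)
        assert ((res.labels == k) == ordered).all()

    def test_retention_monotone_in_repeats(self, chamber_fixture):
        cfg, pset, truth = chamber_fixture
        interior = _interior_mask()
        res = consensus_classify(
            pset, MRAParams(crop=24, denoise_lowpass=30.0, n_iterations=15),
            BootstrapSpec(200, 30), interior, n_repeats=4, master_seed=13,
            focus_mask=interior)
        # agreement over the first k runs can only shrink as k grows
        prev = None
        for k in range(2, 5):
            agree = np.all(res.run_labels[:k] == res.run_labels[0][None, :],
                           axis=0)
            if prev is not None:
                assert agree.sum() <= prev
            prev = agree.sum()
        assert np.array_equal(
            res.retained,
            np.all(res.run_labels == res.run_labels[0][None, :], axis=0))

    def test_retained_subset_accuracy_beats_single_runs(self, chamber_fixture):
        cfg, pset, truth = chamber_fixture
        interior = _interior_mask()
        res = consensus_classify(
            pset, MRAParams(crop=24, denoise_lowpass=30.0),
            BootstrapSpec(300, 40), interior, n_repeats=5, master_seed=14,
            focus_mask=interior)
        ordered = (truth["occupancy"] == "ordered").to_numpy()
        k = ordered_class_index(res.references)
        ret = res.retained
        assert 0.5 <= ret.mean() <= 1.0
        acc_ret = ((res.labels == k) == ordered)[ret].mean()
        assert acc_ret >= 0.9


class TestFocusedClassify:
    def _apical_disk(self):
        c = 24
        zz, yy, xx = np.meshgrid(*([np.arange(48) - c] * 3), indexing="ij")
        disk = ((zz * VOXEL > -80) & (zz * VOXEL < -52)
                & (np.sqrt(xx**2 + yy**2) * VOXEL < 36))
        return Volume(disk.astype(np.float32), VOXEL)

    def test_narrow_wide_mixture_recovered(self):
        """A disk mask on the apical region of the open ring separates the
        narrow (apical substrate, tight wall) from the wide conformation
        and recovers the planted 40:60 proportion."""
        cfg = ph.SimulationConfig(
            mixture=((ph.BULLET_NARROW, 0.4), (ph.BULLET_WIDE, 0.6)),
            snr=0.3)
        stack, truth = ph.simulate_particle_stack(cfg, 150, seed=41)
        pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)
        from chapsta.classify import focused_classify

        res = focused_classify(pset, self._apical_disk(),
                               MRAParams(crop=24, denoise_lowpass=30.0),
                               BootstrapSpec(300, 40), n_repeats=3,
                               master_seed=42)
        narrow = (truth["trans_conformation"] == "narrow").to_numpy()
        # narrow class = stronger on-axis density at the apical level
        probes = []
        for r in res.references:
            cb = r.data.shape[0] // 2
            za = cb - int(round(63 / VOXEL))
            probes.append(r.data[za - 1: za + 2, cb - 1: cb + 2,
                                 cb - 1: cb + 2].mean())
        nk = 1 + int(np.argmax(probes))
        ret = res.retained
        acc = ((res.labels == nk) == narrow)[ret].mean()
        assert acc >= 0.9
        recovered = (res.labels[ret] == nk).mean() * 100
        assert abs(recovered - 40.0) <= 5.0

    def test_empty_focus_mask_rejected(self):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),), snr=0.3)
        stack, truth = ph.simulate_particle_stack(cfg, 20, seed=43)
        pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)
        from chapsta.classify import focused_classify

        empty = Volume(np.zeros((48, 48, 48), dtype=np.float32), VOXEL)
        with pytest.raises(ValueError, match="empty"):
            focused_classify(pset, empty, MRAParams(), BootstrapSpec(20, 5))


class TestRegisterC7:
    def test_recovers_planted_rotation_multiple(self, smooth_bullet):
        # add an off-axis marker: the barrel itself is sevenfold symmetric,
        # so only a symmetry-breaking feature can pin the register
        data = smooth_bullet.data.copy()
        c = 24
        zz, yy, xx = np.meshgrid(*([np.arange(48) - c] * 3), indexing="ij")
        marker = 2.0 * np.exp(-((xx - 8) ** 2 + yy**2 + zz**2) / (2 * 2.0**2))
        ref = Volume(data + marker.astype(np.float32), smooth_bullet.voxel_size)
        rotated = apply_transform(ref, EulerAngles(2 * 360.0 / 7, 0, 0))
        out = register_c7_classes([rotated], ref)
        assert out[0][1] == 5  # inverse rotation: 5 more steps close the turn

    def test_identity_map_gets_m_zero(self, smooth_bullet):
        out = register_c7_classes([smooth_bullet], smooth_bullet)
        assert out[0][1] == 0

    def test_c7_symmetric_map_ties_to_smallest_m(self, smooth_bullet):
        sym = symmetrize(smooth_bullet, "C7")
        out = register_c7_classes([sym], sym)
        assert out[0][1] == 0
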