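"""Extraction, wedge-compensated averaging, alignment, pooling,
signal subtraction and gold-standard refinement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from chapsta import phantoms as ph
from chapsta.align import (
    AlignmentParams,
    ParticleSet,
    align_particles,
    extract_subtomograms,
    gold_standard_refine,
    pool_chambers,
    signal_subtract,
    wedge_weighted_average,
)
from chapsta.matching import MatchHit
from chapsta.volumes import (
    EulerAngles,
    Volume,
    bandpass_filter,
    euler_from_matrix,
    spherical_mask,
)
from conftest import central_sphere, masked_corr


def _angular_error_c7(truth_row, test_row):
    Rt = EulerAngles(truth_row["rot"], truth_row["tilt"],
                     truth_row["psi"]).matrix()
    Re = EulerAngles(test_row["rot"], test_row["tilt"],
                     test_row["psi"]).matrix()
    best = 180.0
    for k in range(7):
        Rs = Rt @ Rotation.from_euler("z", k * 360 / 7,
                                      degrees=True).as_matrix()
        cosang = np.clip((np.trace(Re.T @ Rs) - 1) / 2, -1, 1)
        best = min(best, float(np.degrees(np.arccos(cosang))))
    return best


@pytest.fixture(scope="module")
def bullet_stack():
    cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),), snr=0.3)
    stack, truth = ph.simulate_particle_stack(cfg, 40, seed=5)
    return cfg, stack, truth


class TestExtractSubtomograms:
    def _tomo(self):
        rng = np.random.default_rng(0)
        return Volume(rng.standard_normal((64, 96, 96)).astype(np.float32),
                      7.04)

    def test_center_hit_preserves_values(self):
        tomo = self._tomo()
        hit = MatchHit("t", (48, 48, 32), EulerAngles(), 0.9, "x")
        pset = extract_subtomograms(tomo, [hit], 32)
        assert len(pset) == 1
        assert pset.subtomogram(0).data[16, 16, 16] == tomo.data[32, 48, 48]

    def test_border_hits_dropped(self):
        tomo = self._tomo()
        hits = [
            MatchHit("t", (5, 48, 32), EulerAngles(), 0.9, "x"),  # too close
            MatchHit("t", (48, 48, 32), EulerAngles(), 0.8, "x"),
        ]
        pset = extract_subtomograms(tomo, hits, 32)
        assert len(pset) == 1

    def test_all_hits_dropped_raises(self):
        tomo = self._tomo()
        hits = [MatchHit("t", (1, 1, 1), EulerAngles(), 0.9, "x")]
        with pytest.raises(ValueError, match="no hits"):
            extract_subtomograms(tomo, hits, 32)


class TestWedgeWeightedAverage:
    def test_single_identity_particle_recovers_subtomogram(self):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                  snr=math.inf, random_orientations=False)
        stack, truth = ph.simulate_particle_stack(cfg, 1, seed=0)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        avg = wedge_weighted_average(pset)
        m = central_sphere(48, 20)
        assert masked_corr(avg.data, stack[0], m) >= 0.99

    def test_orientation_diversity_fills_the_wedge(self, geom):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                  snr=math.inf)
        stack, truth = ph.simulate_particle_stack(cfg, 100, seed=1)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        avg = wedge_weighted_average(pset)
        gt = ph.build_species_map(geom, ph.BULLET_WIDE, 48, 7.04)
        assert masked_corr(avg.data, gt.data, central_sphere(48, 20)) >= 0.95

    def test_empty_set_rejected(self):
        pset = ParticleSet(pd.DataFrame({"id": []}),
                           np.zeros((1, 8, 8, 8), np.float32), 1.0)
        with pytest.raises(ValueError):
            wedge_weighted_average(pset)


class TestAlignParticles:
    def test_fixed_point_with_zero_search(self, bullet_stack):
        cfg, stack, truth = bullet_stack
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        ref = wedge_weighted_average(pset)
        params = AlignmentParams(binning=(1,), angular_range=(0.0,),
                                 angular_step=(1.0,), max_shift=0,
                                 lowpass=(35.0,), iterations=1)
        out = align_particles(pset, ref, params, update_reference=False)
        for col in ("rot", "tilt", "psi"):
            assert np.allclose(out.table[col], pset.table[col])

    def test_alignment_reduces_perturbed_orientation_error(self, bullet_stack):
        cfg, stack, truth = bullet_stack
        rng = np.random.default_rng(2)
        pert = truth.copy()
        for i in range(len(pert)):
            ax = rng.standard_normal(3)
            ax /= np.linalg.norm(ax)
            d = Rotation.from_rotvec(
                np.radians(rng.uniform(4, 10)) * ax).as_matrix()
            e = EulerAngles(truth.rot[i], truth.tilt[i], truth.psi[i])
            e2 = euler_from_matrix(e.matrix() @ d)
            pert.loc[i, ["rot", "tilt", "psi"]] = (e2.rot, e2.tilt, e2.psi)
        pset = ParticleSet(pert, stack, 7.04, cfg.wedge)
        ref = bandpass_filter(wedge_weighted_average(pset), high_res=40.0)
        params = AlignmentParams(binning=(2,), angular_range=(12.0,),
                                 angular_step=(6.0,), lowpass=(40.0,),
                                 symmetry="C7", iterations=3)
        out = align_particles(pset, ref, params)
        before = np.median([_angular_error_c7(truth.iloc[i], pert.iloc[i])
                            for i in range(len(pert))])
        after = np.median([_angular_error_c7(truth.iloc[i],
                                             out.table.iloc[i])
                           for i in range(len(pert))])
        assert before > 5.0
        assert after <= 4.0


class TestGoldStandard:
    def test_determinism_and_noise_free_limit(self):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                  snr=math.inf)
        stack, truth = ph.simulate_particle_stack(cfg, 20, seed=3)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        params = AlignmentParams(binning=(2,), angular_range=(4.0,),
                                 angular_step=(4.0,), lowpass=(30.0,),
                                 symmetry="C7", iterations=1)
        r1 = gold_standard_refine(pset, params, seed=9)
        r2 = gold_standard_refine(pset, params, seed=9)
        assert r1.resolution == r2.resolution
        # noise-free halves agree to high resolution
        assert r1.resolution.angstrom <= 4 * 7.04

    def test_too_few_particles_refused(self):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),), snr=0.3)
        stack, truth = ph.simulate_particle_stack(cfg, 5, seed=4)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        with pytest.raises(ValueError, match="10"):
            gold_standard_refine(pset, AlignmentParams(), seed=0)


class TestPoolChambers:
    def _aligned_sets(self, n_bullets=3, n_footballs=5):
        cfgb = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                   snr=math.inf)
        sb, tb = ph.simulate_particle_stack(cfgb, max(n_bullets, 1), seed=6)
        tb["score"] = 1.0
        cfgf = ph.SimulationConfig(mixture=((ph.FOOTBALL, 1.0),),
                                   snr=math.inf)
        sf, tf = ph.simulate_particle_stack(cfgf, max(n_footballs, 1), seed=7)
        tf["score"] = 1.0
        bullets = ParticleSet(tb.iloc[:n_bullets], sb[: max(n_bullets, 1)],
                              7.04, cfgb.wedge)
        footballs = ParticleSet(tf.iloc[:n_footballs],
                                sf[: max(n_footballs, 1)], 7.04, cfgf.wedge)
        return bullets, footballs

    def test_record_count_doubles_footballs(self):
        bullets, footballs = self._aligned_sets(3, 5)
        pooled = pool_chambers(bullets, footballs)
        assert len(pooled) == 2 * 5 + 3
        assert pooled.table["id"].is_unique

    def test_football_chambers_mutually_consistent(self):
        empty_b, footballs = self._aligned_sets(0, 6)
        pooled = pool_chambers(empty_b, footballs)
        upper = ParticleSet(pooled.table.iloc[0::2].reset_index(drop=True),
                            pooled.stack, 7.04, pooled.wedge)
        lower = ParticleSet(pooled.table.iloc[1::2].reset_index(drop=True),
                            pooled.stack, 7.04, pooled.wedge)
        a = bandpass_filter(wedge_weighted_average(upper), high_res=30.0)
        b = bandpass_filter(wedge_weighted_average(lower), high_res=30.0)
        assert masked_corr(a.data, b.data, central_sphere(48, 14)) >= 0.99

    def test_chamber_frame_puts_groes_up(self, geom):
        bullets, empty_f = self._aligned_sets(4, 0)
        pooled = pool_chambers(bullets, empty_f)
        avg = wedge_weighted_average(pooled)
        c = 24
        # on the symmetry axis: the GroES dome apex sits ~55-67 A above
        # the chamber centre; the mirrored region below is open cavity
        z_top = slice(c + 8, c + 10)      # +56..+67 A
        z_bot = slice(c - 9, c - 7)       # -63..-49 A
        lid_mass = avg.data[z_top, c - 2: c + 3, c - 2: c + 3].mean()
        below_mass = avg.data[z_bot, c - 2: c + 3, c - 2: c + 3].mean()
        assert lid_mass > below_mass + 0.05

    def test_unaligned_input_rejected(self):
        bullets, footballs = self._aligned_sets(2, 2)
        bullets.table.loc[0, "score"] = np.nan
        with pytest.raises(ValueError, match="aligned"):
            pool_chambers(bullets, footballs)


class TestSignalSubtract:
    def test_all_ones_mask_is_identity(self, bullet_stack, geom):
        cfg, stack, truth = bullet_stack
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        ref = ph.build_species_map(geom, ph.BULLET_WIDE, 48, 7.04)
        keep = Volume(np.ones((48, 48, 48), dtype=np.float32), 7.04)
        out = signal_subtract(pset, ref, keep)
        assert np.allclose(out.stack, stack[: len(pset)], atol=1e-4)

    def test_full_subtraction_of_matching_reference(self, geom):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                  snr=math.inf)
        stack, truth = ph.simulate_particle_stack(cfg, 4, seed=8)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        ref = ph.build_species_map(geom, ph.BULLET_WIDE, 48, 7.04)
        keep = Volume(np.zeros((48, 48, 48), dtype=np.float32), 7.04)
        out = signal_subtract(pset, ref, keep)
        for i in range(4):
            assert np.sqrt((out.stack[i] ** 2).mean()) <= 0.15 * np.sqrt(
                (stack[i] ** 2).mean())

    def test_mask_protects_chamber_density(self, geom):
        cfg = ph.SimulationConfig(mixture=((ph.BULLET_WIDE, 1.0),),
                                  snr=math.inf, random_orientations=False)
        stack, truth = ph.simulate_particle_stack(cfg, 1, seed=9)
        pset = ParticleSet(truth.copy(), stack, 7.04, cfg.wedge)
        ref = ph.build_species_map(geom, ph.BULLET_WIDE, 48, 7.04)
        c = 24
        zz, yy, xx = np.meshgrid(*([np.arange(48) - c] * 3), indexing="ij")
        keep = ((np.sqrt(xx**2 + yy**2) * 7.04 < 22)
                & (zz * 7.04 > 0) & (zz * 7.04 < 73)).astype(np.float32)
        out = signal_subtract(pset, ref, Volume(keep, 7.04))
        outside = keep < 0.5
        rms_out = np.sqrt((out.stack[0][outside] ** 2).mean())
        rms_in0 = np.sqrt((stack[0][outside] ** 2).mean())
        assert rms_out <= 0.2 * rms_in0
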