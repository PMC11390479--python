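"""End-to-end recovery workflows on synthetic cohorts with planted truth.

Each recipe regenerates its input from a seed, runs the relevant part of
the pipeline (matching, alignment, classification, census, measurement)
and returns the recovered quantity together with bookkeeping. These are
the package's reference experiments; the test suite and the acceptance
script both drive them.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phantoms as ph
from .align import AlignmentParams, ParticleSet, align_particles, \
    resolve_flips, wedge_weighted_average
from .census import aperture_diameter, assign_state
from .classify import (
    BootstrapSpec,
    MRAParams,
    consensus_classify,
    ordered_class_index,
)
from .matching import extract_peaks, make_angular_grid, match_stack, \
    match_template, merge_remove_duplicates
from .volumes import Volume, bandpass_filter, flip_z, symmetrize

log = logging.getLogger(__name__)

VOXEL = 7.04
BOX = 48


def _derived_seeds(master_seed: int, n: int, label: str) -> list[int]:
    ss = np.random.SeedSequence([master_seed, zlib.crc32(label.encode())])
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def seven_state_count() -> int:
    """Exhaustively enumerate the valid GroES-bound state combinations."""
    states = set()
    for conf in ("narrow", "wide"):
        for occ in ("ordered", "unordered"):
            states.add(assign_state("ELES1", conf, (occ,)))
    for o1 in ("ordered", "unordered"):
        for o2 in ("ordered", "unordered"):
            states.add(assign_state("ELES2", "na", (o1, o2)))
    return len(states)


def _species_templates(geom: ph.SpeciesGeometry):
    return {
        "ELES1": ph.build_species_map(geom, ph.BULLET_WIDE, BOX, VOXEL),
        "ELES2": ph.build_species_map(geom, ph.FOOTBALL, BOX, VOXEL),
    }


@dataclass
class MixtureRecovery:
    condition: str
    planted_bullet_pct: float
    recovered_bullet_pct: float
    retained_fraction: float
    n: int


def mixture_recovery(
    condition: str = "37C",
    n: int = 1000,
    snr: float = 0.3,
    master_seed: int = 1,
    grid_step: float = 24.0,
) -> MixtureRecovery:
    """Recover the bullet:football split of a growth-condition cohort.

    Simulates the condition's species mixture as a subtomogram stack,
    template-matches both species over an angular grid (the deliberate
    overpick stage; for a centred stack duplicate removal is a no-op,
    which is logged), then runs two-class consensus classification and
    maps the retained classes back to species by template correlation.
    """
    seeds = _derived_seeds(master_seed, 3, f"mixture-{condition}")
    mixture = ph.condition_mixture(condition)
    cfg = ph.SimulationConfig(box=BOX, voxel_size=VOXEL, mixture=mixture,
                              snr=snr, seed=seeds[0])
    stack, truth = ph.simulate_particle_stack(cfg, n, seed=seeds[0])
    planted = float((truth["species"] == "ELES1").mean() * 100)

    geom = cfg.geometry
    templates = _species_templates(geom)
    matched = match_stack(
        stack, templates, cfg.wedge, VOXEL, grid_step=grid_step,
        symmetries={"ELES1": "C7", "ELES2": "D7"}, bin=1,
    )
    log.info(
        "dual-template stack matching: %d initial bullet calls, %d football "
        "calls; duplicate removal is a no-op for centred stacks",
        int((matched["template"] == "ELES1").sum()),
        int((matched["template"] == "ELES2").sum()),
    )
    # standardize all particles in the asymmetric-reference frame: the
    # bullet-grid pose aligns the shared barrel for both species
    table = truth[["id"]].copy()
    table[["rot", "tilt", "psi"]] = matched[
        ["rot_ELES1", "tilt_ELES1", "psi_ELES1"]].to_numpy()
    table["score"] = matched["score_ELES1"]
    pset = ParticleSet(table, stack, VOXEL, cfg.wedge)
    pset = resolve_flips(pset, templates["ELES1"], bin=2)
    start = bandpass_filter(wedge_weighted_average(pset), high_res=40.0)
    align = AlignmentParams(binning=(2,), angular_range=(14.0,),
                            angular_step=(7.0,), lowpass=(35.0,),
                            symmetry="C7", iterations=2)
    pset = align_particles(pset, start, align)

    # classify a pole-centred view: re-pose every particle so the trans
    # pole (second GroES site) sits at the box centre, making lid
    # presence a compact central contrast
    pole = pset.copy()
    pole.table = pset.table.copy()
    pole_off = np.array([0.0, 0.0, -88.0 / VOXEL])
    for i in range(len(pole)):
        s = pole.shift(i) + pole.euler(i).matrix() @ pole_off
        pole.table.loc[pole.table.index[i], ["dx", "dy", "dz"]] = s
    c = BOX // 2
    zz, yy, xx = np.meshgrid(*([np.arange(BOX) - c] * 3), indexing="ij",
                             sparse=True)
    sph = np.sqrt(xx**2 + yy**2 + zz**2) * VOXEL < 55
    mask = Volume(np.broadcast_to(sph, (BOX,) * 3).astype(np.float32), VOXEL)
    params = MRAParams(crop=24, denoise_lowpass=30.0)
    spec = BootstrapSpec(n_bootstrap=500, bootstrap_size=50)
    res = consensus_classify(pole, params, spec, interior_mask=mask,
                             n_repeats=5, master_seed=seeds[1],
                             focus_mask=mask)

    # identify the species classes directly: in the pole-centred view the
    # second GroES lid of a football sits at the box centre, so the
    # bullet class is the one with the weaker central density
    probes = []
    for ref in res.references:
        nb = ref.data.shape[0]
        cb = nb // 2
        zzc, yyc, xxc = np.meshgrid(*([np.arange(nb) - cb] * 3),
                                    indexing="ij", sparse=True)
        probe = (np.sqrt(zzc**2 + yyc**2 + xxc**2) * ref.voxel_size) < 25.0
        probes.append(float(ref.data[np.broadcast_to(probe, ref.data.shape)]
                            .mean()))
    bullet_class = 1 + int(np.argmin(probes))

    retained = res.retained
    rec = float((res.labels[retained] == bullet_class).mean() * 100)
    return MixtureRecovery(condition, planted, rec,
                           float(retained.mean()), n)


@dataclass
class ApertureRecovery:
    conformation: str
    planted_diameter: float
    measured_diameter: float
    n: int


def aperture_recovery(
    conformation: str = "narrow",
    n: int = 200,
    snr: float = 0.3,
    master_seed: int = 3,
) -> ApertureRecovery:
    """Measure the trans-ring opening of an aligned, C7-averaged cohort.

    Simulates bullets with the requested trans conformation at random
    orientations, assigns orientations by template-bank matching,
    locally refines the alignment against a 40 A-filtered start,
    averages with C7 symmetry and applies the azimuthal half-max rule to
    the apical slab of the (flipped) trans ring.
    """
    seeds = _derived_seeds(master_seed, 2, f"aperture-{conformation}")
    geom = ph.SpeciesGeometry()
    state = ph.BULLET_NARROW if conformation == "narrow" else ph.BULLET_WIDE
    planted = (geom.aperture_diameter_narrow if conformation == "narrow"
               else geom.aperture_diameter_wide)
    cfg = ph.SimulationConfig(box=BOX, voxel_size=VOXEL,
                              mixture=((state, 1.0),), snr=snr, seed=seeds[0])
    stack, truth = ph.simulate_particle_stack(cfg, n, seed=seeds[0])

    template = ph.build_species_map(geom, state, BOX, VOXEL)
    matched = match_stack(stack, {"bullet": template}, cfg.wedge, VOXEL,
                          grid_step=24.0, symmetries={"bullet": "C7"}, bin=1)
    table = truth[["id"]].copy()
    table[["rot", "tilt", "psi"]] = matched[["rot", "tilt", "psi"]]
    table["score"] = matched["score"]
    pset = ParticleSet(table, stack, VOXEL, cfg.wedge)
    pset = resolve_flips(pset, template, bin=2)

    start = bandpass_filter(wedge_weighted_average(pset), high_res=40.0)
    params = AlignmentParams(binning=(2,), angular_range=(14.0,),
                             angular_step=(7.0,), lowpass=(35.0,),
                             symmetry="C7", iterations=3)
    aligned = align_particles(pset, start, params)
    avg = symmetrize(wedge_weighted_average(aligned), "C7")
    result = aperture_diameter(flip_z(avg))
    if not result.found:
        raise RuntimeError("no aperture found in the cohort average")
    return ApertureRecovery(conformation, planted, result.diameter, n)


@dataclass
class OccupancyRecovery:
    planted_ordered_pct: float
    recovered_ordered_pct: float
    retained_fraction: float
    n: int


def occupancy_recovery(
    n: int = 1000,
    ordered_fraction: float = 0.40,
    snr: float = 0.3,
    master_seed: int = 5,
) -> OccupancyRecovery:
    """Recover the ordered-substrate chamber fraction by consensus MRA.

    Simulates aligned single-chamber subtomograms at the given ordered
    quota (the remainder split between disordered and empty chambers),
    seeds two classes from bootstrap-average k-means, classifies with
    annealed consensus MRA on the chamber interior, and reports the
    ordered percentage among retained particles.
    """
    seeds = _derived_seeds(master_seed, 2, "occupancy")
    rest = (1.0 - ordered_fraction) / 2
    mixture = ((ph.CHAMBER_ORDERED, ordered_fraction),
               (ph.CHAMBER_DISORDERED, rest),
               (ph.CHAMBER_EMPTY, rest))
    cfg = ph.SimulationConfig(box=BOX, voxel_size=VOXEL, mixture=mixture,
                              snr=snr, seed=seeds[0])
    stack, truth = ph.simulate_particle_stack(cfg, n, seed=seeds[0])
    planted = float((truth["occupancy"] == "ordered").mean() * 100)
    # chambers enter classification pre-aligned (as after chamber pooling):
    # rotate each subtomogram back to the reference frame via its pose
    pset = ParticleSet(truth.copy(), stack, VOXEL, cfg.wedge)

    c = BOX // 2
    zz, yy, xx = np.meshgrid(*([np.arange(BOX) - c] * 3), indexing="ij",
                             sparse=True)
    interior = ((np.sqrt(xx**2 + yy**2) * VOXEL < 20)
                & (np.abs(zz * VOXEL) < 32))
    interior = Volume(np.broadcast_to(interior, (BOX,) * 3).astype(np.float32),
                      VOXEL)
    params = MRAParams(crop=24, denoise_lowpass=30.0)
    spec = BootstrapSpec(n_bootstrap=500, bootstrap_size=50)
    res = consensus_classify(pset, params, spec, interior_mask=interior,
                             n_repeats=5, master_seed=seeds[1],
                             focus_mask=interior)
    ordered_class = ordered_class_index(res.references)
    retained = res.retained
    rec = float((res.labels[retained] == ordered_class).mean() * 100)
    return OccupancyRecovery(planted, rec, float(retained.mean()), n)


@dataclass
class RibosomeRatioRecovery:
    planted_ratio: float
    recovered_median_ratio: float
    per_tomogram: list
    n_tomograms: int


def ribosome_ratio_recovery(
    n_tomograms: int = 5,
    ratio: int = 23,
    chaperonins_per_tomogram: int = 2,
    snr: float = 0.3,
    master_seed: int = 10,
) -> RibosomeRatioRecovery:
    """Recover the ribosome:chaperonin abundance ratio by dual matching.

    Each tomogram plants ``ratio`` ribosomes per chaperonin by exact
    quota; both species are template-matched with auto cutoffs, hits are
    combined with cross-template duplicate removal, and the per-tomogram
    count ratio's median is reported.
    """
    seeds = _derived_seeds(master_seed, n_tomograms, "ribosome-ratio")
    geom = ph.SpeciesGeometry()
    n_ribo = ratio * chaperonins_per_tomogram
    n_part = n_ribo + chaperonins_per_tomogram
    mixture = ((ph.RIBOSOME, n_ribo / n_part),
               (ph.BULLET_WIDE, chaperonins_per_tomogram / n_part))
    bullet_t = ph.build_species_map(geom, ph.BULLET_WIDE, BOX, VOXEL)
    ribo_t = ph.build_species_map(geom, ph.RIBOSOME, BOX, VOXEL)
    grids = {"ELES1": make_angular_grid(30.0, "C7"),
             "RIBOSOME": make_angular_grid(45.0, "C1")}
    ratios = []
    for it in range(n_tomograms):
        cfg = ph.SimulationConfig(
            shape=(160, 288, 288), box=BOX, voxel_size=VOXEL,
            mixture=mixture, particle_count=n_part, snr=snr, seed=seeds[it],
        )
        tomo, truth, cytosol = ph.simulate_tomogram(cfg)
        hits = {}
        for name, tmpl in (("ELES1", bullet_t), ("RIBOSOME", ribo_t)):
            sv = match_template(tomo, tmpl, cfg.wedge, grids[name], bin=2,
                                template_name=name)
            hits[name] = extract_peaks(
                sv, cutoff="auto",
                min_distance=geom.diameter(name if name == "RIBOSOME"
                                           else "ELES1") / VOXEL * 0.7,
                region_mask=cytosol, tomogram_name=f"tomo{it}",
            )
        dedupe = 0.5 * geom.diameter("ELES1") / VOXEL
        merged = merge_remove_duplicates(hits["ELES1"], hits["RIBOSOME"],
                                         dedupe)
        n_chap = sum(h.template == "ELES1" for h in merged)
        n_rib = sum(h.template == "RIBOSOME" for h in merged)
        ratios.append(n_rib / max(n_chap, 1))
        log.info("tomogram %d: %d ribosomes, %d chaperonins", it, n_rib,
                 n_chap)
    return RibosomeRatioRecovery(float(ratio), float(np.median(ratios)),
                                 ratios, n_tomograms)
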