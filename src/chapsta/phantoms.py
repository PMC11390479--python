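"""Parametric chaperonin and ribosome phantoms with planted ground truth.

The generator emulates the imaging situation of in-cell tomography of
GroEL/GroES: double-ring ~140 A barrels carrying zero, one or two GroES
lids, a narrow (~45 A) or wide (~65 A) aperture on the open (trans) ring,
compact (ordered) or diffuse (disordered) encapsulated substrate density,
ribosome-like globular distractors, a +-60 degree single-axis missing
wedge, and additive white noise at a configurable SNR. Species mixtures
are applied by exact largest-remainder quota so planted proportions are
fixed numbers, not random variables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .volumes import (
    EulerAngles,
    Volume,
    WedgeSpec,
    apply_transform,
    make_wedge_mask,
    random_euler,
)

SPECIES = ("EL", "ELES1", "ELES2", "RIBOSOME", "CHAMBER")
OCCUPANCIES = ("none", "disordered", "ordered")

_SOFT = 6.0  # A, soft edge width of all density boundaries


@dataclass(frozen=True)
class SpeciesGeometry:
    """Physical dimensions (Angstrom) of the phantom species.

    GroEL outer dimensions follow known chaperonin structures (the barrel
    is ~140 A wide and ~146 A tall); the narrow/wide aperture diameters
    are the measured trans-ring openings this pipeline must recover.
    """

    outer_radius: float = 70.0
    ring_height: float = 73.0
    cavity_radius: float = 22.5
    aperture_diameter_narrow: float = 45.0
    aperture_diameter_wide: float = 65.0
    lid_height: float = 30.0
    c7_bump_amplitude: float = 0.15
    ribosome_radius: float = 120.0
    apical_zone: float = 24.0  # depth of the constant-bore apical opening

    def __post_init__(self):
        if not self.aperture_diameter_wide > self.aperture_diameter_narrow > 0:
            raise ValueError("need aperture_wide > aperture_narrow > 0")
        for name in ("outer_radius", "ring_height", "cavity_radius",
                     "lid_height", "ribosome_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def diameter(self, species: str) -> float:
        """Bounding diameter of a species in Angstrom."""
        if species == "RIBOSOME":
            return 2 * self.ribosome_radius * 1.15
        if species == "CHAMBER":
            return max(2 * self.outer_radius, self.ring_height + self.lid_height)
        lids = {"EL": 0, "ELES1": 1, "ELES2": 2}[species]
        return max(2 * self.outer_radius,
                   2 * self.ring_height + lids * self.lid_height)


@dataclass(frozen=True)
class SpeciesState:
    """One biological state: species, trans-ring conformation, occupancy.

    ``chamber_occupancy`` has one entry per GroES-capped chamber (one for
    bullets, two for footballs, one for the single-chamber phantom, none
    for EL and ribosomes). Narrow trans-rings always carry apical
    substrate density; wide ones never do.
    """

    species: str
    trans_conformation: str = "na"  # narrow | wide | na
    chamber_occupancy: tuple = ()
    trans_sp_bound: bool = False

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        n_chambers = {"EL": 0, "ELES1": 1, "ELES2": 2, "RIBOSOME": 0, "CHAMBER": 1}
        if len(self.chamber_occupancy) != n_chambers[self.species]:
            raise ValueError(
                f"{self.species} takes {n_chambers[self.species]} chamber "
                f"label(s), got {len(self.chamber_occupancy)}"
            )
        for occ in self.chamber_occupancy:
            if occ not in OCCUPANCIES:
                raise ValueError(f"unknown occupancy {occ!r}")
        if self.species == "ELES1":
            if self.trans_conformation not in ("narrow", "wide"):
                raise ValueError("ELES1 needs trans_conformation narrow or wide")
            if (self.trans_conformation == "narrow") != self.trans_sp_bound:
                raise ValueError(
                    "narrow trans-rings carry bound SP and wide ones do not"
                )
        elif self.trans_conformation != "na":
            raise ValueError(f"{self.species} takes trans_conformation 'na'")

    @property
    def n_lids(self) -> int:
        return {"EL": 0, "ELES1": 1, "ELES2": 2, "RIBOSOME": 0, "CHAMBER": 1}[
            self.species
        ]


# frequently used states
BULLET_WIDE = SpeciesState("ELES1", "wide", ("none",))
BULLET_NARROW = SpeciesState("ELES1", "narrow", ("none",), trans_sp_bound=True)
FOOTBALL = SpeciesState("ELES2", "na", ("none", "none"))
EL_ALONE = SpeciesState("EL")
RIBOSOME = SpeciesState("RIBOSOME")
CHAMBER_ORDERED = SpeciesState("CHAMBER", "na", ("ordered",))
CHAMBER_DISORDERED = SpeciesState("CHAMBER", "na", ("disordered",))
CHAMBER_EMPTY = SpeciesState("CHAMBER", "na", ("none",))


# bullet:football splits per growth condition (relative chaperonin
# abundances; free GroEL is undetectable except under GroEL overexpression)
CONDITION_SPLITS = {
    "37C": {"ELES1": 0.60, "ELES2": 0.40, "EL": 0.0},
    "HS": {"ELES1": 0.70, "ELES2": 0.30, "EL": 0.0},
    "MetK": {"ELES1": 0.55, "ELES2": 0.45, "EL": 0.0},
    "ELplus": {"ELES1": 0.10, "ELES2": 0.0, "EL": 0.90},
}

# sub-state defaults: fraction of bullets in the wide trans conformation
# (the wide state dominates, more so under heat stress) and the
# per-chamber probability of ordered substrate
WIDE_FRACTION = {"37C": 0.60, "HS": 0.75, "MetK": 0.60, "ELplus": 0.60}
ORDERED_CHAMBER_FRACTION = 1.0 / 3.0


def condition_mixture(condition: str) -> tuple:
    """Full species-state mixture emulating one growth condition."""
    split = CONDITION_SPLITS[condition]
    wide = WIDE_FRACTION[condition]
    p_ord = ORDERED_CHAMBER_FRACTION
    mix = []
    p1 = split["ELES1"]
    if p1 > 0:
        for conf, p_conf in (("wide", wide), ("narrow", 1 - wide)):
            bound = conf == "narrow"
            for occ, p_occ in (("ordered", p_ord),
                               ("disordered", (1 - p_ord) / 2),
                               ("none", (1 - p_ord) / 2)):
                mix.append((
                    SpeciesState("ELES1", conf, (occ,), trans_sp_bound=bound),
                    p1 * p_conf * p_occ,
                ))
    p2 = split["ELES2"]
    if p2 > 0:
        occ_pairs = {}
        for o1, q1 in (("ordered", p_ord), ("disordered", (1 - p_ord) / 2),
                       ("none", (1 - p_ord) / 2)):
            for o2, q2 in (("ordered", p_ord), ("disordered", (1 - p_ord) / 2),
                           ("none", (1 - p_ord) / 2)):
                key = tuple(sorted((o1, o2)))
                occ_pairs[key] = occ_pairs.get(key, 0.0) + q1 * q2
        for pair, q in sorted(occ_pairs.items()):
            mix.append((SpeciesState("ELES2", "na", pair), p2 * q))
    if split.get("EL", 0) > 0:
        mix.append((EL_ALONE, split["EL"]))
    total = sum(p for _, p in mix)
    return tuple((s, p / total) for s, p in mix)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulation run."""

    shape: tuple = (96, 192, 192)  # tomogram (z, y, x) voxels
    box: int = 48                  # particle box edge, voxels
    voxel_size: float = 7.04       # A; 2x the 3.52 A acquisition pixel
    mixture: tuple = ((BULLET_WIDE, 0.6), (FOOTBALL, 0.4))
    particle_count: int = 20
    snr: float = 0.3
    wedge: WedgeSpec = field(default_factory=WedgeSpec)
    geometry: SpeciesGeometry = field(default_factory=SpeciesGeometry)
    random_orientations: bool = True
    seed: int = 0

    def __post_init__(self):
        total = sum(p for _, p in self.mixture)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")
        if not self.snr > 0:
            raise ValueError("snr must be positive (use math.inf for noise-free)")


def quota_counts(proportions, n: int) -> list[int]:
    """Largest-remainder apportionment of ``n`` among ``proportions``."""
    raw = [p * n for p in proportions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def quota_states(mixture, n: int) -> list[SpeciesState]:
    states = []
    for (state, _), c in zip(mixture, quota_counts([p for _, p in mixture], n)):
        states.extend([state] * c)
    return states


# ---------------------------------------------------------------------------
# density construction


def _soft_ge(x, threshold, soft=_SOFT):
    """Smooth indicator of x >= threshold with a cosine edge of width soft."""
    t = np.clip((x - threshold) / soft + 0.5, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * t))


def _soft_le(x, threshold, soft=_SOFT):
    return _soft_ge(-x, -threshold, soft)


def _barrel_density(geom, zz, yy, xx, ring_spans, open_ends):
    """Double-annulus wall with constant-bore apical openings.

    ``ring_spans``: list of (z_lo, z_hi) per ring; ``open_ends``: dict
    mapping the outward-facing end coordinate of an open ring to its
    aperture radius.
    """
    r = np.sqrt(xx**2 + yy**2)
    phi = np.arctan2(yy, xx)
    density = np.zeros_like(r)
    for z_lo, z_hi in ring_spans:
        inner = np.full_like(r, geom.cavity_radius)
        for z_end, ap_radius in open_ends.items():
            if abs(z_end - z_hi) < 1e-6:  # open end faces +z
                frac = _soft_ge(zz, z_hi - geom.apical_zone)
            elif abs(z_end - z_lo) < 1e-6:  # open end faces -z
                frac = _soft_le(zz, z_lo + geom.apical_zone)
            else:
                continue
            inner = inner + frac * (ap_radius - geom.cavity_radius)
        wall = (
            _soft_ge(r, inner)
            * _soft_le(r, geom.outer_radius)
            * _soft_ge(zz, z_lo)
            * _soft_le(zz, z_hi)
        )
        density = np.maximum(density, wall)
    # sin(7*phi) keeps the y axis a two-fold axis of the double ring
    # (with the sevenfold order odd, a cos phase would not)
    density *= 1.0 + geom.c7_bump_amplitude * np.sin(7 * phi)
    return density


def _lid_density(geom, zz, yy, xx, z_base, direction):
    """GroES dome: a half-ellipsoid shell sitting on a ring end."""
    r = np.sqrt(xx**2 + yy**2)
    phi = np.arctan2(yy, xx)
    a = geom.cavity_radius + 18.0       # lateral semi-axis
    b = geom.lid_height                 # vertical semi-axis
    h = direction * (zz - z_base)       # height above the ring end
    f = np.sqrt((r / a) ** 2 + (np.maximum(h, 0.0) / b) ** 2)
    shell = _soft_ge(f, 0.62, soft=0.18) * _soft_le(f, 1.0, soft=0.18)
    shell = shell * _soft_ge(h, 0.0)
    shell *= 1.0 + geom.c7_bump_amplitude * np.sin(7 * phi)
    return shell


def _sp_blob(zz, yy, xx, center_z, sigma, amplitude, jitter=(0.0, 0.0, 0.0)):
    d2 = (
        (xx - jitter[0]) ** 2
        + (yy - jitter[1]) ** 2
        + (zz - center_z - jitter[2]) ** 2
    )
    return amplitude * np.exp(-d2 / (2 * sigma**2))


_ORDERED_SP_SIGMA = 10.0   # A; compact folded substrate
_ORDERED_SP_AMPLITUDE = 1.1
_SP_DEPTH = 20.0           # A below the chamber midplane
_DISORDER_WIDTH_FACTOR = 4.0
_DISORDER_JITTER = 10.0    # A, uniform per-instance displacement


def _ribosome_density(geom, zz, yy, xx):
    """Bumpy sphere with a fixed, deterministic surface modulation."""
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zz / np.maximum(r, 1e-9), 1.0), -1, 1))
    phi = np.arctan2(yy, xx)
    bump = (
        0.06 * np.cos(3 * phi) * np.sin(theta) ** 2
        + 0.06 * np.cos(2 * theta)
        + 0.05 * np.sin(4 * phi + 2 * theta)
    )
    radius = geom.ribosome_radius * (1.0 + bump)
    body = _soft_le(r, radius, soft=10.0)
    texture = 1.0 + 0.15 * np.cos(2 * np.pi * r / 55.0)
    return 1.2 * body * texture


def build_species_map(
    geom: SpeciesGeometry,
    state: SpeciesState,
    box: int,
    voxel_size: float,
    rng: np.random.Generator | None = None,
) -> Volume:
    """Rasterize one species state into a cubic box (barrel axis = z).

    Convention: for bullets the GroES lid caps the +z ring; the open
    trans ring faces -z. For the single-chamber phantom the lid is at +z
    and the chamber midplane sits at z = 0, with ordered substrate
    density 20 A below it. Disordered substrate carries the same
    integrated mass spread 4x wider, displaced by a per-instance random
    jitter so that it blurs out under averaging.
    """
    if box * voxel_size < geom.diameter(state.species) * 1.1:
        raise ValueError(
            f"box of {box} voxels at {voxel_size} A cannot hold {state.species} "
            f"(needs {geom.diameter(state.species) * 1.1:.0f} A with margin)"
        )
    c = box // 2
    coords = (np.arange(box) - c) * voxel_size
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij", sparse=True)
    rng = rng or np.random.default_rng(0)

    if state.species == "RIBOSOME":
        return Volume(_ribosome_density(geom, zz, yy, xx).astype(np.float32),
                      voxel_size)

    h = geom.ring_height
    if state.species == "CHAMBER":
        ring_spans = [(-h / 2, h / 2)]
        open_ends = {}
        lid_bases = [(h / 2, +1)]
        chamber_centres = [0.0]
        chamber_signs = [+1]
    else:
        ring_spans = [(-h, 0.0), (0.0, h)]
        narrow_r = geom.aperture_diameter_narrow / 2
        wide_r = geom.aperture_diameter_wide / 2
        if state.species == "EL":
            open_ends = {h: wide_r, -h: narrow_r}  # intrinsic inter-ring asymmetry
            lid_bases, chamber_centres, chamber_signs = [], [], []
        elif state.species == "ELES1":
            trans_r = narrow_r if state.trans_conformation == "narrow" else wide_r
            open_ends = {-h: trans_r}
            lid_bases = [(h, +1)]
            chamber_centres = [h / 2]
            chamber_signs = [+1]
        else:  # ELES2
            open_ends = {}
            lid_bases = [(h, +1), (-h, -1)]
            chamber_centres = [h / 2, -h / 2]
            chamber_signs = [+1, -1]

    density = _barrel_density(geom, zz, yy, xx, ring_spans, open_ends)
    for z_base, direction in lid_bases:
        density = density + _lid_density(geom, zz, yy, xx, z_base, direction)

    for occ, z_c, sign in zip(state.chamber_occupancy, chamber_centres,
                              chamber_signs):
        if occ == "none":
            continue
        centre = z_c - sign * _SP_DEPTH  # "bottom" = toward the equator
        if occ == "ordered":
            density = density + _sp_blob(
                zz, yy, xx, centre, _ORDERED_SP_SIGMA, _ORDERED_SP_AMPLITUDE
            )
        else:  # disordered: same mass, 4x wider, random per-instance jitter
            w = _DISORDER_WIDTH_FACTOR
            amp = _ORDERED_SP_AMPLITUDE / w**3
            jitter = rng.uniform(-_DISORDER_JITTER, _DISORDER_JITTER, size=3)
            density = density + _sp_blob(
                zz, yy, xx, centre, _ORDERED_SP_SIGMA * w, amp, jitter
            )

    if state.trans_sp_bound:  # apical density on the open narrow ring (-z end)
        density = density + _sp_blob(
            zz, yy, xx, -(h - 10.0), 8.0, _ORDERED_SP_AMPLITUDE
        )

    return Volume(density.astype(np.float32), voxel_size)


def support_mask(vol: Volume, threshold: float = 0.1) -> np.ndarray:
    """Binary particle support: voxels above threshold x max density."""
    return vol.data > threshold * vol.data.max()


# ---------------------------------------------------------------------------
# stacks and tomograms


def _state_row(i, state: SpeciesState, euler: EulerAngles):
    return {
        "id": i,
        "species": state.species,
        "trans_conformation": state.trans_conformation,
        "occupancy": "+".join(state.chamber_occupancy) or "na",
        "trans_sp_bound": int(state.trans_sp_bound),
        "rot": euler.rot,
        "tilt": euler.tilt,
        "psi": euler.psi,
    }


def simulate_particle_stack(config: SimulationConfig, n: int, seed: int | None = None):
    """Simulate ``n`` subtomograms; returns ``(stack, truth)``.

    Each subtomogram is a randomly oriented species map, filtered with
    the (fixed, tomogram-frame) missing-wedge mask, plus white Gaussian
    noise scaled so that var(signal inside the particle support) /
    var(noise) equals the configured SNR. The mixture is applied by exact
    quota; the same seed reproduces the stack bit for bit.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    # separate streams: the signal (states, orientations, jitter) is
    # identical across noise levels for a given seed
    rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    box, vx = config.box, config.voxel_size
    wedge_grid = make_wedge_mask(box, vx, config.wedge).grid
    states = quota_states(config.mixture, n)
    stack = np.empty((n, box, box, box), dtype=np.float32)
    rows = []
    for i, state in enumerate(states):
        euler = random_euler(rng) if config.random_orientations else EulerAngles()
        vol = build_species_map(config.geometry, state, box, vx, rng=rng)
        rotated = apply_transform(vol, euler, fill=0.0)
        clean = np.fft.ifftn(np.fft.fftn(rotated.data) * wedge_grid).real
        # SNR definition: variance of the wedge-filtered signal inside its
        # own support, over the white-noise variance
        mask = np.abs(clean) > 0.1 * np.abs(clean).max()
        sig_var = float(clean[mask].var()) if mask.any() else float(clean.var())
        if math.isfinite(config.snr):
            noise = noise_rng.standard_normal(clean.shape) * math.sqrt(
                sig_var / config.snr
            )
            clean = clean + noise
        stack[i] = clean.astype(np.float32)
        rows.append(_state_row(i, state, euler))
    truth = pd.DataFrame(rows)
    return stack, truth


def simulate_tomogram(config: SimulationConfig, seed: int | None = None):
    """Simulate a full tomogram; returns ``(tomogram, truth, cytosol_mask)``.

    Particles are planted at random positions/orientations with a
    pairwise minimum distance of the mean bounding diameter of each pair;
    the whole tomogram is wedge-filtered before noise is added, so the
    wedge region is noise-filled as in real reconstructions.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    shape, vx = tuple(config.shape), config.voxel_size
    geom = config.geometry
    states = quota_states(config.mixture, config.particle_count)
    rng.shuffle(states)

    placed = []  # (z, y, x) voxel centres
    radii = []   # exclusion radii, voxels
    rows = []
    tomogram = np.zeros(shape, dtype=np.float32)
    sig_mask = np.zeros(shape, dtype=bool)
    max_tries = 200 * max(1, len(states))
    tries = 0
    for i, state in enumerate(states):
        diameter_vox = geom.diameter(state.species) / vx
        margin = int(math.ceil(config.box / 2))
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "particle placement failed: volume too dense, reduce the "
                    "particle count or enlarge the tomogram"
                )
            pos = np.array(
                [rng.uniform(margin, s - margin) for s in shape]
            )
            ok = all(
                np.linalg.norm(pos - p) >= (r + diameter_vox / 2)
                for p, r in zip(placed, radii)
            )
            if ok:
                break
        placed.append(pos)
        radii.append(diameter_vox / 2)
        euler = random_euler(rng) if config.random_orientations else EulerAngles()
        vol = build_species_map(geom, state, config.box, vx, rng=rng)
        rotated = apply_transform(vol, euler, fill=0.0)
        zi, yi, xi = (int(round(p)) for p in pos)
        b2 = config.box // 2
        sl = (
            slice(zi - b2, zi - b2 + config.box),
            slice(yi - b2, yi - b2 + config.box),
            slice(xi - b2, xi - b2 + config.box),
        )
        tomogram[sl] += rotated.data
        sig_mask[sl] |= support_mask(rotated)
        row = _state_row(i, state, euler)
        row.update({"x": float(pos[2]), "y": float(pos[1]), "z": float(pos[0])})
        rows.append(row)

    wedge_grid = make_wedge_mask(shape, vx, config.wedge).grid
    tomogram = np.fft.ifftn(np.fft.fftn(tomogram) * wedge_grid).real
    if sig_mask.any():
        sig_var = float(tomogram[sig_mask].var())
    else:
        sig_var = 1.0
    if math.isfinite(config.snr):
        tomogram = tomogram + noise_rng.standard_normal(shape) * math.sqrt(
            sig_var / config.snr
        )
    cytosol = np.ones(shape, dtype=np.float32)
    truth = pd.DataFrame(rows)
    return (
        Volume(tomogram.astype(np.float32), vx),
        truth,
        Volume(cytosol, vx),
    )
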