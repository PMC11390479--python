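"""Subtomogram extraction, wedge-compensated averaging and alignment.

A :class:`ParticleSet` couples a particle table (pose, score, labels,
provenance) to an in-memory subtomogram stack and the tilt geometry that
produced it. The pose convention follows :mod:`chapsta.volumes`: a
subtomogram is approximately ``apply_transform(reference, euler, shift)``
plus noise, with the missing wedge fixed in the subtomogram frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .matching import MatchHit, _bin_volume
from .volumes import (
    EulerAngles,
    FourierMask,
    FSCCurve,
    Resolution,
    Volume,
    WedgeSpec,
    apply_transform,
    bandpass_filter,
    constrained_cc,
    fsc,
    make_wedge_mask,
    resolution_at_threshold,
    rotate_fourier_mask,
    spherical_mask,
    symmetrize,
)

log = logging.getLogger(__name__)

POSE_COLUMNS = ["rot", "tilt", "psi", "dx", "dy", "dz"]


@dataclass
class ParticleSet:
    """Particle table + subtomogram stack + wedge geometry."""

    table: pd.DataFrame
    stack: np.ndarray  # (n, box, box, box) float32
    voxel_size: float
    wedge: WedgeSpec = field(default_factory=WedgeSpec)

    def __post_init__(self):
        t = self.table.reset_index(drop=True).copy()
        if "id" not in t.columns:
            t.insert(0, "id", np.arange(len(t)))
        if t["id"].duplicated().any():
            raise ValueError("particle ids must be unique")
        if "sub_idx" not in t.columns:
            t["sub_idx"] = np.arange(len(t))
        for col in POSE_COLUMNS:
            if col not in t.columns:
                t[col] = 0.0
        if "score" not in t.columns:
            t["score"] = np.nan
        if len(t) and int(t["sub_idx"].max()) >= self.stack.shape[0]:
            raise ValueError("sub_idx points past the end of the stack")
        self.table = t

    def __len__(self):
        return len(self.table)

    @property
    def box(self) -> int:
        return self.stack.shape[1]

    def euler(self, i: int) -> EulerAngles:
        r = self.table.iloc[i]
        return EulerAngles(r["rot"], r["tilt"], r["psi"])

    def shift(self, i: int) -> np.ndarray:
        r = self.table.iloc[i]
        return np.array([r["dx"], r["dy"], r["dz"]], dtype=float)

    def subtomogram(self, i: int) -> Volume:
        return Volume(self.stack[int(self.table.iloc[i]["sub_idx"])],
                      self.voxel_size)

    def copy(self) -> "ParticleSet":
        return ParticleSet(self.table.copy(), self.stack, self.voxel_size,
                           self.wedge)


def invert_pose(euler: EulerAngles, shift) -> tuple[EulerAngles, np.ndarray]:
    """Pose of the reference in the particle's frame (and vice versa)."""
    inv = euler.inverse()
    s = np.asarray(shift, dtype=float)
    return inv, -(euler.matrix().T @ s)


@dataclass
class AlignmentParams:
    """Progressive-binning local alignment settings."""

    binning: tuple = (2, 1)
    angular_range: tuple = (16.0, 6.0)   # cone half-angle per pass, degrees
    angular_step: tuple = (8.0, 3.0)
    max_shift: int = 3                   # voxels, at each binning
    lowpass: tuple = (40.0, 30.0)        # reference low-pass per pass, A
    symmetry: str = "C1"
    iterations: int = 2                  # per pass
    include_flip: bool = False           # also test the 180-degree flip
    # (rescues top/bottom-ambiguous template-matching assignments)

    def __post_init__(self):
        if list(self.binning) != sorted(self.binning, reverse=True) or \
                len(set(self.binning)) != len(self.binning):
            raise ValueError("binning schedule must be strictly decreasing")
        if any(s <= 0 for s in self.angular_step):
            raise ValueError("angular steps must be positive")


# ---------------------------------------------------------------------------
# extraction


def extract_subtomograms(
    tomogram: Volume, hits: list[MatchHit], box: int
) -> ParticleSet:
    """Crop one cubic subtomogram per hit, centred on the hit voxel.

    Hits closer than box/2 to a border are dropped (and logged); an empty
    surviving set is an error.
    """
    if box % 2:
        raise ValueError("box must be even")
    b2 = box // 2
    shape = tomogram.data.shape
    subs, rows = [], []
    for i, h in enumerate(hits):
        x, y, z = (int(round(p)) for p in h.position)
        if not (b2 <= z <= shape[0] - b2 and b2 <= y <= shape[1] - b2
                and b2 <= x <= shape[2] - b2):
            log.info("hit %d at %s dropped: too close to the border", i,
                     h.position)
            continue
        subs.append(
            tomogram.data[z - b2: z + b2, y - b2: y + b2, x - b2: x + b2]
        )
        rows.append({
            "id": len(rows), "tomogram": h.tomogram,
            "x": float(h.position[0]), "y": float(h.position[1]),
            "z": float(h.position[2]),
            "rot": h.euler.rot, "tilt": h.euler.tilt, "psi": h.euler.psi,
            "score": h.score, "template": h.template,
        })
    if not rows:
        raise ValueError("no hits survive border clipping; nothing to extract")
    return ParticleSet(pd.DataFrame(rows), np.stack(subs).astype(np.float32),
                       tomogram.voxel_size)


# ---------------------------------------------------------------------------
# averaging


def aligned_particle(pset: ParticleSet, i: int, order: int = 1) -> Volume:
    """Particle ``i`` rotated/shifted back into the reference frame."""
    inv_e, inv_s = invert_pose(pset.euler(i), pset.shift(i))
    return apply_transform(pset.subtomogram(i), inv_e, inv_s, order=order)


def wedge_weighted_average(
    pset: ParticleSet, wedge_floor: float = 0.01
) -> Volume:
    """Fourier-space average compensated by the summed rotated wedges.

    Each subtomogram is rotated to the reference frame; the Fourier sum
    is divided by the sum of equally rotated wedge masks, floored at
    ``wedge_floor`` of its maximum (Wiener-style) to avoid blow-up in the
    jointly missing region.
    """
    if len(pset) == 0:
        raise ValueError("cannot average an empty particle set")
    box = pset.box
    wedge_grid = make_wedge_mask(box, pset.voxel_size, pset.wedge)
    num = np.zeros((box, box, box), dtype=np.complex64)
    den = np.zeros((box, box, box), dtype=np.float32)
    for i in range(len(pset)):
        vol = aligned_particle(pset, i)
        w = rotate_fourier_mask(wedge_grid, pset.euler(i).inverse()).grid
        num += w * sfft.fftn(vol.data)
        den += w
    den = np.maximum(den, wedge_floor * den.max())
    avg = sfft.ifftn((num / den).astype(np.complex64)).real
    return Volume(avg.astype(np.float32), pset.voxel_size)


# ---------------------------------------------------------------------------
# alignment


def _local_rotations(cone: float, step: float) -> list[EulerAngles]:
    """Rotation offsets within a cone plus in-plane twists (incl. identity)."""
    offs = [EulerAngles()]
    twists = np.arange(-cone, cone + 1e-9, step)
    tilts = np.arange(step, cone + 1e-9, step)
    n_phi = 6
    for psi in twists:
        if abs(psi) > 1e-9:
            offs.append(EulerAngles(0.0, 0.0, float(psi)))
    for t in tilts:
        for k in range(n_phi):
            phi = k * 360.0 / n_phi - 180.0
            offs.append(EulerAngles(phi, float(t), -phi))
    return offs


def _binned_set(pset: ParticleSet, b: int) -> ParticleSet:
    if b == 1:
        return pset
    binned = np.stack([_bin_volume(s, b) for s in pset.stack]).astype(np.float32)
    return ParticleSet(pset.table.copy(), binned, pset.voxel_size * b,
                       pset.wedge)


def _masked_unit(data: np.ndarray, mask: np.ndarray, n_mask: float):
    centred = mask * (data - (mask * data).sum() / n_mask)
    norm = float(np.sqrt((centred**2).sum()))
    return centred / max(norm, 1e-12)


def _score_candidate(ref_rot, wedge_grid, mask, n_mask, f_sub, max_shift):
    """Wedge-filter, mask-normalize and correlate one candidate pose.

    Returns the best constrained correlation within ``max_shift`` voxels
    and the argmax (dx, dy, dz). Same quantity as :func:`constrained_cc`
    with the subtomogram's own (fixed) wedge on both sides, computed with
    single-precision FFTs for the alignment hot loop.
    """
    filtered = sfft.ifftn(sfft.fftn(ref_rot) * wedge_grid).real.astype(np.float32)
    rr = _masked_unit(filtered, mask, n_mask)
    cc = sfft.ifftn(np.conj(sfft.fftn(rr)) * f_sub).real
    if max_shift == 0:
        return float(cc[0, 0, 0]), (0, 0, 0)
    rng = np.arange(-max_shift, max_shift + 1)
    win = cc[np.ix_(rng % cc.shape[0], rng % cc.shape[1], rng % cc.shape[2])]
    k = np.unravel_index(np.argmax(win), win.shape)
    return float(win[k]), (int(rng[k[2]]), int(rng[k[1]]), int(rng[k[0]]))


def align_particles(
    pset: ParticleSet,
    reference: Volume,
    params: AlignmentParams,
    update_reference: bool = True,
) -> ParticleSet:
    """Local orientation/shift refinement with progressive binning.

    Per pass, each particle's pose is perturbed over a cone of candidate
    rotations; the wedge-constrained correlation against the (symmetrized,
    low-passed) reference picks the best pose and the reference is
    re-averaged between iterations. A pass aborts (keeping the best
    state) if the mean score drops twice in a row.
    """
    out = pset.copy()
    out.table = out.table.copy()
    ref_full = reference
    idx = out.table.index
    for ip, b in enumerate(params.binning):
        bset = _binned_set(out, b)
        box = bset.box
        wedge_grid = make_wedge_mask(box, bset.voxel_size, bset.wedge).grid
        mask = spherical_mask(box, radius=box / 2 - 2, soft_edge=2).data
        n_mask = float(mask.sum())
        offsets = _local_rotations(params.angular_range[ip],
                                   params.angular_step[ip])
        if params.include_flip:
            flip = EulerAngles(0.0, 180.0, 0.0)
            offsets = offsets + [flip.compose(o) for o in offsets]
        f_subs = [
            sfft.fftn(_masked_unit(bset.subtomogram(i).data, mask, n_mask))
            for i in range(len(bset))
        ]
        ref_b = Volume(_bin_volume(ref_full.data, b).astype(np.float32),
                       bset.voxel_size)
        prev_mean, drops = -np.inf, 0
        for it in range(params.iterations):
            ref_use = ref_b
            if params.symmetry != "C1":
                ref_use = symmetrize(ref_use, params.symmetry)
            ref_use = bandpass_filter(ref_use, high_res=params.lowpass[ip])
            scores = np.zeros(len(bset))
            for i in range(len(bset)):
                e0 = EulerAngles(out.table.at[idx[i], "rot"],
                                 out.table.at[idx[i], "tilt"],
                                 out.table.at[idx[i], "psi"])
                best = (-np.inf, e0, np.zeros(3))
                for off in offsets:
                    cand = e0.compose(off)
                    ref_rot = apply_transform(ref_use, cand, fill=0.0).data
                    sc, sh = _score_candidate(
                        ref_rot, wedge_grid, mask, n_mask, f_subs[i],
                        params.max_shift,
                    )
                    if sc > best[0]:
                        best = (sc, cand, np.array(sh, dtype=float))
                scores[i] = best[0]
                out.table.loc[idx[i], ["rot", "tilt", "psi"]] = (
                    best[1].rot, best[1].tilt, best[1].psi)
                out.table.loc[idx[i], ["dx", "dy", "dz"]] = best[2] * b
                out.table.loc[idx[i], "score"] = best[0]
            mean_score = float(scores.mean())
            if mean_score < prev_mean:
                drops += 1
                if drops >= 2:
                    log.warning("pass bin%d aborted: mean score dropped twice",
                                b)
                    break
            else:
                drops = 0
            if update_reference:
                ref_full = wedge_weighted_average(out)
                ref_b = Volume(
                    _bin_volume(ref_full.data, b).astype(np.float32),
                    bset.voxel_size,
                )
            if abs(mean_score - prev_mean) < 1e-4:
                break
            prev_mean = mean_score
    return out


def resolve_flips(
    pset: ParticleSet,
    reference: Volume,
    cap_inner: float = 55.0,
    cap_outer: float = 115.0,
    cap_radius: float = 48.0,
    lowpass: float = 30.0,
    bin: int = 1,
) -> ParticleSet:
    """Resolve the top/bottom pose ambiguity of quasi-symmetric barrels.

    Whole-particle correlation can leave a pseudo-symmetric particle
    (e.g. a one-lidded bullet) in the 180-degree-flipped pose at low
    SNR. For each particle the current pose and its flip are rescored
    under a two-cap mask covering the polar regions (``cap_inner`` to
    ``cap_outer`` Angstrom from the equator, within ``cap_radius`` of
    the axis), where the discriminating lid density lives; the better
    pose wins.
    """
    out = pset.copy()
    out.table = out.table.copy()
    work = _binned_set(pset, bin)
    box, vx = work.box, work.voxel_size
    c = box // 2
    zz, yy, xx = np.meshgrid(*([np.arange(box) - c] * 3), indexing="ij")
    cap = (
        (np.abs(zz * vx) > cap_inner)
        & (np.abs(zz * vx) < cap_outer)
        & (np.sqrt(xx**2 + yy**2) * vx < cap_radius)
    ).astype(np.float32)
    wedge_grid = make_wedge_mask(box, vx, work.wedge).grid
    ref = bandpass_filter(
        Volume(_bin_volume(reference.data, bin).astype(np.float32), vx),
        high_res=lowpass,
    )
    flip = EulerAngles(0.0, 180.0, 0.0)
    cap_vol = Volume(cap, vx)
    n_flipped = 0
    for i in range(len(pset)):
        e0 = pset.euler(i)
        sub = work.subtomogram(i).data
        # the cap region is mirror-symmetric, so one rotated mask serves
        # both pose hypotheses
        capr = apply_transform(cap_vol, e0, fill=0.0).data
        n_cap = max(float(capr.sum()), 1.0)
        b = capr * (sub - (capr * sub).sum() / n_cap)
        b_norm = max(float(np.sqrt((b**2).sum())), 1e-9)
        scores = []
        for e in (e0, e0.compose(flip)):
            rr = apply_transform(ref, e, fill=0.0).data
            rr = sfft.ifftn(sfft.fftn(rr) * wedge_grid).real.astype(np.float32)
            a = capr * (rr - (capr * rr).sum() / n_cap)
            denom = max(float(np.sqrt((a**2).sum())) * b_norm, 1e-9)
            scores.append(float((a * b).sum()) / denom)
        if scores[1] > scores[0]:
            e1 = e0.compose(flip)
            out.table.loc[out.table.index[i], ["rot", "tilt", "psi"]] = (
                e1.rot, e1.tilt, e1.psi)
            n_flipped += 1
    if n_flipped:
        log.info("resolve_flips: flipped %d of %d particles", n_flipped,
                 len(pset))
    return out


# ---------------------------------------------------------------------------
# gold-standard refinement


@dataclass
class HalfSetResult:
    half_a: Volume
    half_b: Volume
    combined: Volume
    curve: FSCCurve
    resolution: Resolution

    def write(self, out_dir, prefix: str = "halfset") -> None:
        """Write half-maps, the combined map and a two-column FSC table
        (spatial frequency in 1/Angstrom, correlation)."""
        from pathlib import Path

        from .mrc import write_mrc

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tag, vol in (("half_a", self.half_a), ("half_b", self.half_b),
                         ("combined", self.combined)):
            write_mrc(out / f"{prefix}_{tag}.mrc", vol.data, vol.voxel_size)
        lines = [
            f"{f:.6f} {c:.4f}"
            for f, c, n in zip(self.curve.shell_freq, self.curve.corr,
                               self.curve.n_voxels) if n
        ]
        bound = " (bound)" if self.resolution.is_bound else ""
        lines.append(f"# resolution at 0.143: "
                     f"{self.resolution.angstrom:.2f} A{bound}")
        (out / f"{prefix}_fsc.txt").write_text("\n".join(lines) + "\n")


def gold_standard_refine(
    pset: ParticleSet, params: AlignmentParams, seed: int
) -> HalfSetResult:
    """Refine two random disjoint halves independently and report the FSC.

    Both halves start from the common average low-passed to 40 A so the
    half-maps stay statistically independent at high resolution.
    """
    n = len(pset)
    if n < 10:
        raise ValueError("gold-standard refinement needs at least 10 particles")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = [np.sort(perm[: n // 2]), np.sort(perm[n // 2:])]
    start = bandpass_filter(wedge_weighted_average(pset), high_res=40.0)
    maps = []
    for idx in halves:
        sub = ParticleSet(
            pset.table.iloc[idx].reset_index(drop=True),
            pset.stack, pset.voxel_size, pset.wedge,
        )
        refined = align_particles(sub, start, params)
        avg = wedge_weighted_average(refined)
        if params.symmetry != "C1":
            avg = symmetrize(avg, params.symmetry)
        maps.append(avg)
    combined = Volume(
        ((maps[0].data + maps[1].data) / 2).astype(np.float32),
        pset.voxel_size,
    )
    curve = fsc(maps[0], maps[1])
    return HalfSetResult(maps[0], maps[1], combined, curve,
                         resolution_at_threshold(curve))


# ---------------------------------------------------------------------------
# chamber pooling and signal subtraction


def pool_chambers(
    bullets: ParticleSet,
    footballs: ParticleSet,
    inter_ring_offset: float | None = None,
) -> ParticleSet:
    """Symmetry-expand footballs about their in-plane two-fold and pool
    all GroES-capped chambers into one set.

    Every football contributes two records (original pose and the pose
    composed with the 180-degree flip); every bullet contributes its
    lid-bound cis ring. Each record is recentred along the particle's own
    z axis by half the inter-ring offset so the chamber of interest sits
    at the box centre with GroES toward +z.
    """
    for pset, name in ((bullets, "bullets"), (footballs, "footballs")):
        if len(pset) and pset.table["score"].isna().any():
            raise ValueError(f"{name} must be aligned (scores missing)")
    if bullets.voxel_size != footballs.voxel_size:
        raise ValueError("voxel sizes differ")
    vx = bullets.voxel_size
    offset_vox = (inter_ring_offset or 73.0) / vx / 2.0
    flip = EulerAngles(0.0, 180.0, 0.0)
    rows, stacks, sub_idx_map = [], [], {}

    def _add(pset, i, composed_flip: bool, new_id: int, offset_base: int):
        e = pset.euler(i)
        s = pset.shift(i)
        v = np.array([0.0, 0.0, offset_vox])
        if composed_flip:
            e2 = e.compose(flip)
            s2 = s - e.matrix() @ v
        else:
            e2 = e
            s2 = s + e.matrix() @ v
        row = pset.table.iloc[i].to_dict()
        row.update({
            "id": new_id,
            "rot": e2.rot, "tilt": e2.tilt, "psi": e2.psi,
            "dx": s2[0], "dy": s2[1], "dz": s2[2],
            "sub_idx": offset_base + int(pset.table.iloc[i]["sub_idx"]),
            "source": f"{'football' if offset_base else 'bullet'}:{row['id']}",
        })
        rows.append(row)

    nid = 0
    for i in range(len(bullets)):
        _add(bullets, i, False, nid, 0)
        nid += 1
    n_bullet_stack = bullets.stack.shape[0]
    for i in range(len(footballs)):
        _add(footballs, i, False, nid, n_bullet_stack)
        nid += 1
        _add(footballs, i, True, nid, n_bullet_stack)
        nid += 1
    stack = np.concatenate([bullets.stack, footballs.stack], axis=0)
    return ParticleSet(pd.DataFrame(rows), stack, vx, bullets.wedge)


def signal_subtract(
    pset: ParticleSet, reference: Volume, keep_mask: Volume
) -> ParticleSet:
    """Subtract the reference outside ``keep_mask`` from every particle.

    The reference (times ``1 - keep_mask``) is posed into each particle's
    frame, wedge-filtered, and subtracted, leaving the density inside the
    mask untouched.
    """
    if reference.data.shape != keep_mask.data.shape:
        raise ValueError("reference and keep_mask must share a box")
    if reference.data.shape[0] != pset.box:
        raise ValueError("reference box must match the particle box")
    remove = Volume(
        (reference.data * (1.0 - keep_mask.data)).astype(np.float32),
        reference.voxel_size,
    )
    wedge_grid = make_wedge_mask(pset.box, pset.voxel_size, pset.wedge).grid
    new_stack = np.empty((len(pset), pset.box, pset.box, pset.box),
                         dtype=np.float32)
    for i in range(len(pset)):
        posed = apply_transform(remove, pset.euler(i), pset.shift(i), fill=0.0)
        posed_f = np.fft.ifftn(np.fft.fftn(posed.data) * wedge_grid).real
        new_stack[i] = pset.subtomogram(i).data - posed_f
    table = pset.table.copy()
    table["sub_idx"] = np.arange(len(pset))
    return ParticleSet(table, new_stack, pset.voxel_size, pset.wedge)
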