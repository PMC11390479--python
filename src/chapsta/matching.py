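"""Exhaustive-orientation template matching against missing-wedge tomograms.

Orientation space is covered by a Fibonacci-spiral direction set crossed
with a uniform in-plane angle, reduced modulo the template's point-group
symmetry. Tomogram scoring is FFT-based locally normalized correlation of
the rotated, low-passed, wedge-filtered template under a spherical mask;
per-voxel maxima over orientations are kept with their argmax
orientation. Subtomogram stacks are scored against the same rotated
template bank with wedge-constrained normalized dot products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    EulerAngles,
    FourierMask,
    Volume,
    WedgeSpec,
    apply_transform,
    bandpass_filter,
    make_wedge_mask,
    parse_symmetry,
    spherical_mask,
)

DEFAULT_TEMPLATE_LOWPASS = 40.0  # Angstrom


# ---------------------------------------------------------------------------
# angular grids


@dataclass
class AngularGrid:
    eulers: list
    step: float
    symmetry: str = "C1"

    def __len__(self):
        return len(self.eulers)


def make_angular_grid(step: float, symmetry: str = "C1") -> AngularGrid:
    """Quasi-uniform orientation grid at a nominal angular step (degrees).

    Directions come from a Fibonacci spiral on the sphere (half-sphere
    for Dn, whose two-fold flip makes antipodal views equivalent); the
    in-plane angle spans 360/n degrees for Cn/Dn symmetry. The identity
    orientation is always included.
    """
    if not 5 <= step <= 60:
        raise ValueError(f"step must lie in [5, 60] degrees, got {step}")
    kind, n = parse_symmetry(symmetry)
    n_dir = max(1, round(4 * 180**2 / (math.pi * step**2)))
    if kind == "D":
        n_dir = max(1, n_dir // 2)
    golden = math.pi * (3 - math.sqrt(5))
    eulers = [EulerAngles(0.0, 0.0, 0.0)]
    psi_span = 360.0 / n
    psis = np.arange(0.0, psi_span - 1e-9, step)
    if len(psis) == 0:
        psis = np.array([0.0])
    for i in range(n_dir):
        z = 1 - 2 * (i + 0.5) / n_dir
        if kind == "D":
            z = 1 - (i + 0.5) / n_dir  # upper half-sphere only
        tilt = math.degrees(math.acos(z))
        rot = math.degrees((i * golden) % (2 * math.pi)) - 180.0
        for psi in psis:
            eulers.append(EulerAngles(rot, tilt, float(psi) - 0.0))
    return AngularGrid(eulers, step, symmetry)


# ---------------------------------------------------------------------------
# hits and score volumes


@dataclass(frozen=True)
class MatchHit:
    tomogram: str
    position: tuple  # (x, y, z), 0-based voxels in the unbinned tomogram
    euler: EulerAngles
    score: float
    template: str


@dataclass
class ScoreVolume:
    scores: np.ndarray       # per-voxel max score (binned grid)
    orient_idx: np.ndarray   # argmax orientation index into grid.eulers
    grid: AngularGrid
    template: str
    bin: int
    voxel_size: float        # binned voxel size


def _bin_volume(data: np.ndarray, b: int) -> np.ndarray:
    if b == 1:
        return data
    shape = [(s // b) * b for s in data.shape]
    d = data[: shape[0], : shape[1], : shape[2]]
    return d.reshape(
        shape[0] // b, b, shape[1] // b, b, shape[2] // b, b
    ).mean(axis=(1, 3, 5))


def _template_radius(data: np.ndarray) -> float:
    """Support radius (voxels) of a centred template."""
    n = data.shape[0]
    c = n // 2
    zz, yy, xx = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij", sparse=True)
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    occupied = np.abs(data) > 0.1 * np.abs(data).max()
    return float(r[occupied].max()) if occupied.any() else n / 4


def match_template(
    tomogram: Volume,
    template: Volume,
    wedge: WedgeSpec,
    grid: AngularGrid,
    template_lowpass: float = DEFAULT_TEMPLATE_LOWPASS,
    bin: int = 2,
    template_name: str = "template",
) -> ScoreVolume:
    """Locally normalized correlation of a template over all orientations."""
    if any(t > s for t, s in zip(template.data.shape, tomogram.data.shape)):
        raise ValueError("template must not exceed the tomogram dimensions")
    tmpl = bandpass_filter(template, high_res=template_lowpass)
    t_binned = _bin_volume(tmpl.data, bin).astype(np.float32)
    tomo = _bin_volume(tomogram.data, bin).astype(np.float32)
    vx = tomogram.voxel_size * bin
    box = t_binned.shape[0]
    wedge_grid = make_wedge_mask(box, vx, wedge).grid

    radius = _template_radius(t_binned)
    mask = spherical_mask(box, radius=min(radius + 2, box / 2 - 1), soft_edge=2).data
    n_mask = float(mask.sum())

    # local mean/variance of the tomogram under the mask, via FFT
    shape = tomo.shape
    f_tomo = np.fft.rfftn(tomo)
    f_tomo2 = np.fft.rfftn(tomo * tomo)
    mask_big = np.zeros(shape, dtype=np.float32)
    c = box // 2
    mask_big[:box, :box, :box] = mask
    mask_big = np.roll(mask_big, (-c, -c, -c), axis=(0, 1, 2))
    f_mask = np.fft.rfftn(mask_big)
    axes = (0, 1, 2)
    local_sum = np.fft.irfftn(f_tomo * np.conj(f_mask), s=shape, axes=axes)
    local_sum2 = np.fft.irfftn(f_tomo2 * np.conj(f_mask), s=shape, axes=axes)
    # floor the local variance at a fraction of the global variance so that
    # structureless (e.g. noise-free background) regions cannot produce
    # spuriously normalized peaks
    local_var = local_sum2 / n_mask - (local_sum / n_mask) ** 2
    local_var = np.maximum(local_var, 0.05 * float(tomo.var()) + 1e-12)
    denom = np.sqrt(n_mask * local_var)

    t_vol = Volume(t_binned, vx)
    scores = np.full(shape, -np.inf, dtype=np.float32)
    orient = np.zeros(shape, dtype=np.int16)
    big = np.zeros(shape, dtype=np.float32)
    for idx, euler in enumerate(grid.eulers):
        rot = apply_transform(t_vol, euler, fill=0.0).data
        rot = np.fft.ifftn(np.fft.fftn(rot) * wedge_grid).real
        rot = mask * (rot - (mask * rot).sum() / n_mask)
        norm = np.sqrt((rot**2).sum())
        if norm < 1e-9:
            continue
        rot /= norm
        big[:] = 0.0
        big[:box, :box, :box] = rot
        shifted = np.roll(big, (-c, -c, -c), axis=(0, 1, 2))
        cc = np.fft.irfftn(f_tomo * np.conj(np.fft.rfftn(shifted)), s=shape,
                           axes=(0, 1, 2))
        sc = (cc / denom).astype(np.float32)
        better = sc > scores
        scores[better] = sc[better]
        orient[better] = idx
    return ScoreVolume(scores, orient, grid, template_name, bin, vx)


def extract_peaks(
    score_vol: ScoreVolume,
    cutoff="auto",
    min_distance: float = 10.0,
    region_mask: Volume | None = None,
    overpick_factor: float = 1.0,
    tomogram_name: str = "tomo",
) -> list[MatchHit]:
    """Greedy non-maximum suppression of score peaks.

    ``min_distance`` is in unbinned voxels. With ``cutoff='auto'`` the
    strict threshold is mean + 5 sigma of the (region-masked) score
    volume, then relaxed to admit up to ``overpick_factor`` times the
    strict-count of hits (deliberate overpicking for later cleanup by
    classification).
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    scores = score_vol.scores
    b = score_vol.bin
    region = None
    if region_mask is not None:
        region = _bin_volume(region_mask.data, b) > 0.5
        pool = scores[region]
    else:
        pool = scores.ravel()
    mean, sigma = float(pool.mean()), float(pool.std())
    strict = mean + 5 * sigma if cutoff == "auto" else float(cutoff)
    floor = mean + 3 * sigma if cutoff == "auto" else float(cutoff)

    is_max = scores == ndimage.maximum_filter(scores, size=3, mode="nearest")
    cand = is_max & (scores >= floor)
    if region is not None:
        cand &= region
    zs, ys, xs = np.nonzero(cand)
    if len(zs) == 0:
        return []
    vals = scores[zs, ys, xs]
    order = np.argsort(-vals)
    pts = np.stack([zs, ys, xs], axis=1)[order].astype(float)
    vals = vals[order]
    r = min_distance / b
    kept: list[int] = []
    for i in range(len(vals)):
        p = pts[i]
        if all(np.linalg.norm(p - pts[j]) >= r for j in kept):
            kept.append(i)
    kept_scores = vals[kept]
    n_strict = int((kept_scores >= strict).sum())
    n_keep = (
        max(n_strict, int(round(overpick_factor * n_strict)))
        if cutoff == "auto"
        else int((kept_scores >= strict).sum())
    )
    hits = []
    for i in kept[:n_keep]:
        z, y, x = pts[i]
        e = score_vol.grid.eulers[int(score_vol.orient_idx[int(z), int(y), int(x)])]
        off = (b - 1) / 2.0
        hits.append(
            MatchHit(
                tomogram=tomogram_name,
                position=(x * b + off, y * b + off, z * b + off),
                euler=e,
                score=float(vals[i]),
                template=score_vol.template,
            )
        )
    return hits


def merge_remove_duplicates(
    hits_a: list[MatchHit], hits_b: list[MatchHit], dedupe_distance: float
) -> list[MatchHit]:
    """Union of two hit lists; close pairs collapse to the higher score."""
    combined = sorted(hits_a + hits_b, key=lambda h: -h.score)
    kept: list[MatchHit] = []
    for h in combined:
        p = np.array(h.position)
        if all(
            np.linalg.norm(p - np.array(k.position)) >= dedupe_distance
            for k in kept
        ):
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# stack matching against a rotated template bank


def build_template_bank(
    templates: dict[str, Volume],
    grids: dict[str, AngularGrid],
    wedge: WedgeSpec,
    box: int,
    voxel_size: float,
    template_lowpass: float = DEFAULT_TEMPLATE_LOWPASS,
    bin: int = 2,
):
    """Rotate each template over its grid, wedge-filter, mask, normalize.

    Returns ``(bank, meta)`` where ``bank`` is a (R, v) float32 matrix of
    flattened normalized references and ``meta`` a DataFrame with columns
    template/euler index per row.
    """
    b_box = box // bin
    wedge_grid = make_wedge_mask(b_box, voxel_size * bin, wedge).grid
    mask = spherical_mask(b_box, radius=b_box / 2 - 2, soft_edge=2).data
    n_mask = mask.sum()
    rows = []
    refs = []
    for name, tmpl in templates.items():
        low = bandpass_filter(tmpl, high_res=template_lowpass)
        t_b = Volume(_bin_volume(low.data, bin).astype(np.float32),
                     voxel_size * bin)
        for idx, euler in enumerate(grids[name].eulers):
            rot = apply_transform(t_b, euler, fill=0.0).data
            rot = np.fft.ifftn(np.fft.fftn(rot) * wedge_grid).real
            rot = mask * (rot - (mask * rot).sum() / n_mask)
            norm = np.sqrt((rot**2).sum())
            if norm < 1e-9:
                continue
            refs.append((rot / norm).ravel().astype(np.float32))
            rows.append({"template": name, "orient_idx": idx})
    meta = pd.DataFrame(rows)
    return np.stack(refs), meta


def match_stack(
    stack: np.ndarray,
    templates: dict[str, Volume],
    wedge: WedgeSpec,
    voxel_size: float,
    grid_step: float = 30.0,
    symmetries: dict[str, str] | None = None,
    template_lowpass: float = DEFAULT_TEMPLATE_LOWPASS,
    bin: int = 2,
) -> pd.DataFrame:
    """Score every subtomogram of a centred stack against every template.

    The stack analogue of tomogram template matching: particles are
    centred, so only orientation (not translation) is searched. Returns a
    DataFrame with the best template, orientation and score per particle.
    """
    n, box = stack.shape[0], stack.shape[1]
    symmetries = symmetries or {}
    grids = {
        name: make_angular_grid(grid_step, symmetries.get(name, "C1"))
        for name in templates
    }
    bank, meta = build_template_bank(
        templates, grids, wedge, box, voxel_size, template_lowpass, bin
    )
    b_box = box // bin
    mask = spherical_mask(b_box, radius=b_box / 2 - 2, soft_edge=2).data
    n_mask = mask.sum()
    feats = np.empty((n, b_box**3), dtype=np.float32)
    for i in range(n):
        d = _bin_volume(stack[i], bin)
        d = mask * (d - (mask * d).sum() / n_mask)
        norm = np.sqrt((d**2).sum())
        feats[i] = (d / max(norm, 1e-12)).ravel()
    scores = feats @ bank.T  # (n, R)
    best = np.argmax(scores, axis=1)
    out = meta.iloc[best].reset_index(drop=True)
    out["score"] = scores[np.arange(n), best]
    eulers = [
        grids[t].eulers[i] for t, i in zip(out["template"], out["orient_idx"])
    ]
    out["rot"] = [e.rot for e in eulers]
    out["tilt"] = [e.tilt for e in eulers]
    out["psi"] = [e.psi for e in eulers]
    out.insert(0, "id", np.arange(n))
    # per-template best pose/score, for frame standardization downstream
    for name in templates:
        cols = np.nonzero((meta["template"] == name).to_numpy())[0]
        sub = scores[:, cols]
        b = np.argmax(sub, axis=1)
        idxs = meta["orient_idx"].to_numpy()[cols[b]]
        es = [grids[name].eulers[i] for i in idxs]
        out[f"score_{name}"] = sub[np.arange(n), b]
        out[f"rot_{name}"] = [e.rot for e in es]
        out[f"tilt_{name}"] = [e.tilt for e in es]
        out[f"psi_{name}"] = [e.psi for e in es]
    return out
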