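"""State taxonomy, per-tomogram census, condition comparisons and
geometric measurements of chaperonin averages.

The seven GroES-bound states (plus free GroEL) follow the in-cell
classification: asymmetric (bullet) complexes split by trans-ring
conformation (wide i/ii vs narrow iii/iv, the narrow ring always
carrying apical substrate) and cis-chamber occupancy (unordered vs
ordered), symmetric (football) complexes by the unordered pair of
chamber occupancies (v: none ordered, vi: one, vii: both).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .volumes import Volume

log = logging.getLogger(__name__)

GROES_BOUND_STATES = ("i", "ii", "iii", "iv", "v", "vi", "vii")
ALL_STATES = ("EL",) + GROES_BOUND_STATES


def assign_state(species: str, trans_label: str, chamber_labels) -> str:
    """Deterministic mapping of classification labels onto the taxonomy.

    ``chamber_labels`` holds one entry per GroES-capped chamber, each
    'ordered' or 'unordered'; bullets take one, footballs two (as an
    unordered pair), free GroEL none.
    """
    chamber_labels = tuple(chamber_labels)
    if any(c not in ("ordered", "unordered") for c in chamber_labels):
        raise ValueError(f"chamber labels must be ordered/unordered, got "
                         f"{chamber_labels}")
    if species == "EL":
        if trans_label != "na" or chamber_labels:
            raise ValueError("EL takes no trans or chamber labels")
        return "EL"
    if species == "ELES1":
        if len(chamber_labels) != 1:
            raise ValueError("a bullet has exactly one chamber label")
        if trans_label not in ("narrow", "wide"):
            raise ValueError("a bullet needs a narrow/wide trans label")
        ordered = chamber_labels[0] == "ordered"
        if trans_label == "wide":
            return "ii" if ordered else "i"
        return "iv" if ordered else "iii"
    if species == "ELES2":
        if len(chamber_labels) != 2:
            raise ValueError("a football has exactly two chamber labels")
        if trans_label != "na":
            raise ValueError("a football has no trans ring")
        n_ordered = sum(c == "ordered" for c in chamber_labels)
        return ("v", "vi", "vii")[n_ordered]
    raise ValueError(f"unknown species {species!r}")


# ---------------------------------------------------------------------------
# census


@dataclass
class CensusTable:
    """Per-(condition, tomogram) state counts and ribosome counts."""

    counts: pd.DataFrame  # columns: condition, tomogram, EL, i..vii, ribosomes

    def __post_init__(self):
        for c in ("condition", "tomogram"):
            if c not in self.counts.columns:
                raise ValueError(f"census table needs a {c!r} column")

    def proportions(self) -> pd.DataFrame:
        """Per-tomogram proportions over the chaperonin states."""
        df = self.counts.copy()
        total = df[list(ALL_STATES)].sum(axis=1)
        for s in ALL_STATES:
            df[s] = np.where(total > 0, df[s] / total.replace(0, 1), 0.0)
        df["n_chaperonins"] = total
        return df

    def condition_summary(self) -> pd.DataFrame:
        """Pooled particle fractions and mean per-tomogram proportions.

        Both readings are reported (and labelled) since figure-style
        relative abundances can be computed either way.
        """
        rows = []
        props = self.proportions()
        for cond, grp in self.counts.groupby("condition"):
            pooled_total = grp[list(ALL_STATES)].sum().sum()
            p_rows = props[props["condition"] == cond]
            for s in ALL_STATES:
                pooled = grp[s].sum() / max(pooled_total, 1)
                rows.append({
                    "condition": cond, "state": s,
                    "pooled_fraction": pooled,
                    "mean_tomogram_proportion": p_rows[s].mean(),
                })
        return pd.DataFrame(rows)

    def ribosome_ratios(self) -> pd.DataFrame:
        """Per-tomogram ribosome:chaperonin ratios and condition medians."""
        df = self.counts.copy()
        chap = df[list(ALL_STATES)].sum(axis=1)
        df["ratio"] = np.where(chap > 0, df["ribosomes"] / chap.replace(0, 1),
                               np.nan)
        med = df.groupby("condition")["ratio"].median().rename("median_ratio")
        return df[["condition", "tomogram", "ribosomes", "ratio"]].join(
            med, on="condition"
        )


def census(particles: pd.DataFrame, ribosome_hits: pd.DataFrame | None = None
           ) -> CensusTable:
    """Tabulate state counts per (condition, tomogram).

    ``particles`` needs columns condition, tomogram, state;
    ``ribosome_hits`` (optional) needs condition, tomogram. Tomograms
    with zero chaperonins keep their row with zero counts.
    """
    for c in ("condition", "tomogram", "state"):
        if c not in particles.columns:
            raise ValueError(f"particle table needs a {c!r} column")
    keys = particles[["condition", "tomogram"]].drop_duplicates()
    if ribosome_hits is not None and len(ribosome_hits):
        keys = pd.concat(
            [keys, ribosome_hits[["condition", "tomogram"]].drop_duplicates()]
        ).drop_duplicates()
    rows = []
    for cond, tomo in keys.itertuples(index=False):
        sel = particles[(particles["condition"] == cond)
                        & (particles["tomogram"] == tomo)]
        row = {"condition": cond, "tomogram": tomo}
        for s in ALL_STATES:
            row[s] = int((sel["state"] == s).sum())
        if ribosome_hits is not None and len(ribosome_hits):
            row["ribosomes"] = int(
                ((ribosome_hits["condition"] == cond)
                 & (ribosome_hits["tomogram"] == tomo)).sum()
            )
        else:
            row["ribosomes"] = 0
        rows.append(row)
    return CensusTable(pd.DataFrame(rows).sort_values(
        ["condition", "tomogram"]).reset_index(drop=True))


def compare_conditions(
    table: CensusTable, state_or_group, cond_a: str, cond_b: str
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test on per-tomogram proportions.

    Exact enumeration when both groups have n <= 10 (and no ties),
    otherwise the tie-corrected normal approximation. Returns
    (statistic, p). P values are reported uncorrected for multiple
    testing, as in the source analysis; callers log the number of
    comparisons they make.
    """
    states = ([state_or_group] if isinstance(state_or_group, str)
              else list(state_or_group))
    props = table.proportions()
    vals = props[states].sum(axis=1)
    a = vals[props["condition"] == cond_a].to_numpy()
    b = vals[props["condition"] == cond_b].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 tomograms per condition")
    if np.ptp(np.concatenate([a, b])) == 0:
        log.warning("all proportions tied across %s and %s; p = 1",
                    cond_a, cond_b)
        return 0.0, 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# geometric measurements


class ApertureResult(NamedTuple):
    diameter: float  # Angstrom (nan when no aperture found)
    found: bool


def aperture_diameter(
    ring_average: Volume,
    apical_fraction: float = 0.15,
    rule_threshold: float = 0.5,
) -> ApertureResult:
    """Ring-opening diameter by the azimuthal half-max rule.

    The input must be aligned with the symmetry axis on z and the open
    apical surface toward +z. The density's z extent is measured at 20%
    of the maximum slice mean; the apical slab is the top
    ``apical_fraction`` of that extent. The azimuthally averaged radial
    profile over the slab is scanned outward from its innermost minimum;
    the diameter is twice the radius where it first rises to
    ``rule_threshold`` of the wall maximum (linear sub-sample
    interpolation).
    """
    data = ring_average.data
    vx = ring_average.voxel_size
    nz, ny, nx = data.shape
    # z extent of the density: per-slice positive mean, background
    # (median) subtracted, grown as a contiguous run around the maximum
    # so noise floors far from the particle cannot stretch the extent
    slice_score = np.maximum(data, 0.0).mean(axis=(1, 2))
    slice_score = slice_score - np.median(slice_score)
    peak_z = int(np.argmax(slice_score))
    thr = 0.2 * slice_score[peak_z]
    z_lo = peak_z
    while z_lo > 0 and slice_score[z_lo - 1] > thr:
        z_lo -= 1
    z_hi = peak_z
    while z_hi < nz - 1 and slice_score[z_hi + 1] > thr:
        z_hi += 1
    slab_n = max(2, int(round(apical_fraction * (z_hi - z_lo + 1))))
    slab = np.arange(z_hi - slab_n + 1, z_hi + 1)

    cz, cy, cx = nz // 2, ny // 2, nx // 2
    max_r = (min(ny, nx) // 2 - 1) * vx
    radii = np.arange(0.0, max_r, vx / 4)
    angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    profile = np.zeros(len(radii))
    for iz in slab:
        ys = cy + radii[:, None] / vx * np.sin(angles)[None, :]
        xs = cx + radii[:, None] / vx * np.cos(angles)[None, :]
        vals = ndimage.map_coordinates(
            data[iz], np.stack([ys.ravel(), xs.ravel()]), order=1
        ).reshape(len(radii), len(angles))
        profile += vals.mean(axis=1)
    profile /= len(slab)

    wall_max = profile.max()
    i_wall = int(np.argmax(profile))
    i_start = int(np.argmin(profile[: i_wall + 1]))
    target = rule_threshold * wall_max
    for i in range(i_start, i_wall + 1):
        if profile[i] >= target:
            if i == 0:
                return ApertureResult(0.0, True)
            frac = (target - profile[i - 1]) / max(
                profile[i] - profile[i - 1], 1e-12
            )
            r_half = radii[i - 1] + frac * (radii[i] - radii[i - 1])
            return ApertureResult(float(2 * r_half), True)
    return ApertureResult(float("nan"), False)


class CentreOfMass(NamedTuple):
    offset: tuple  # (x, y, z) Angstrom relative to the chamber centre
    found: bool


def sp_center_of_mass(
    chamber_average: Volume,
    chamber_mask: Volume,
    density_threshold: float = 0.5,
) -> CentreOfMass:
    """Intensity-weighted centroid of above-threshold substrate density.

    Voxels inside ``chamber_mask`` with density above
    ``density_threshold`` times the in-mask maximum contribute; the
    result is in Angstrom relative to the box centre, +z toward the lid.
    """
    mask = chamber_mask.data > 0.5
    if not mask.any():
        raise ValueError("chamber mask is empty")
    data = chamber_average.data
    peak = data[mask].max()
    sel = mask & (data >= density_threshold * peak) & (data > 0)
    if not sel.any() or peak <= 0:
        return CentreOfMass((np.nan, np.nan, np.nan), False)
    zz, yy, xx = np.nonzero(sel)
    w = data[zz, yy, xx]
    c = np.array([s // 2 for s in data.shape])
    vx = chamber_average.voxel_size
    z = ((zz - c[0]) * w).sum() / w.sum() * vx
    y = ((yy - c[1]) * w).sum() / w.sum() * vx
    x = ((xx - c[2]) * w).sum() / w.sum() * vx
    return CentreOfMass((float(x), float(y), float(z)), True)
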