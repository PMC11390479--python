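"""Geometry and Fourier primitives for missing-wedge subtomogram analysis.

Conventions used throughout the package:

* Arrays are indexed ``(z, y, x)``; the electron beam runs along z and the
  single tilt axis is y, so the missing wedge is the bowtie complement in
  the (kx, kz) plane.
* Orientations are intrinsic ZYZ Euler triples ``(rot, tilt, psi)`` in
  degrees describing the transform that brings the reference frame into
  the particle frame: a particle map is ``apply_transform(reference,
  euler, shift)`` plus noise.
* The rotation origin sits at array index ``floor(N/2)`` on each axis
  (the voxel that ``fftshift`` maps the DC component to), interpolation is
  trilinear, and out-of-domain samples are filled with the volume mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Volume:
    """A 3D scalar grid with a physical voxel size in Angstrom."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 8:
            raise ValueError(f"box edge must be >= 8 voxels, got {self.data.shape}")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be positive, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def box(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_cubic(self) -> bool:
        nz, ny, nx = self.data.shape
        return nz == ny == nx

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic ZYZ Euler angles in degrees (reference -> particle)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        if not -1e-9 <= self.tilt <= 180 + 1e-9:
            raise ValueError(f"tilt must lie in [0, 180], got {self.tilt}")

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix acting on (x, y, z) column vectors."""
        return Rotation.from_euler(
            "ZYZ", [self.rot, self.tilt, self.psi], degrees=True
        ).as_matrix()

    def inverse(self) -> "EulerAngles":
        return euler_from_matrix(self.matrix().T)

    def compose(self, other: "EulerAngles") -> "EulerAngles":
        """Euler triple of ``R_self @ R_other`` (apply ``other`` first)."""
        return euler_from_matrix(self.matrix() @ other.matrix())


def euler_from_matrix(matrix: np.ndarray) -> EulerAngles:
    import warnings

    with warnings.catch_warnings():
        # at tilt ~ 0/180 the rot/psi split is degenerate; any consistent
        # choice is fine for our purposes
        warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(matrix).as_euler(
            "ZYZ", degrees=True
        )
    if tilt < 0:  # scipy may return tilt in [-180, 180]; fold into [0, 180]
        rot, tilt, psi = rot + 180.0, -tilt, psi + 180.0
    wrap = lambda a: (a + 180.0) % 360.0 - 180.0
    return EulerAngles(wrap(rot), tilt, wrap(psi))


def random_euler(rng: np.random.Generator) -> EulerAngles:
    """Uniform orientation on SO(3)."""
    return euler_from_matrix(Rotation.random(random_state=rng).as_matrix())


@dataclass(frozen=True)
class WedgeSpec:
    """Single-axis tilt geometry: +-theta_max about the y tilt axis."""

    theta_max: float = 60.0
    apodization: float = 3.0

    def __post_init__(self):
        if not 0 < self.theta_max <= 90:
            raise ValueError(f"theta_max must be in (0, 90], got {self.theta_max}")
        if self.apodization < 0:
            raise ValueError("apodization must be >= 0")


@dataclass
class FourierMask:
    """A [0, 1]-valued weight on the (unshifted) Fourier lattice."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)


class FSCCurve(NamedTuple):
    shell_freq: np.ndarray  # 1/Angstrom, strictly increasing
    corr: np.ndarray
    n_voxels: np.ndarray


class Resolution(NamedTuple):
    angstrom: float
    is_bound: bool  # True when the curve never crosses the threshold


FSC_GOLD_STANDARD_THRESHOLD = 0.143


# ---------------------------------------------------------------------------
# grids and masks


def _freq_grids(shape: Sequence[int]):
    """Integer-unit frequency coordinates (kz, ky, kx), unshifted."""
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz) * nz
    ky = np.fft.fftfreq(ny) * ny
    kx = np.fft.fftfreq(nx) * nx
    return np.meshgrid(kz, ky, kx, indexing="ij", sparse=True)


def make_wedge_mask(box, voxel_size: float, spec: WedgeSpec | None = None) -> FourierMask:
    """Fourier sampling mask for a +-theta_max single-axis tilt series.

    A voxel passes when its angle from the (kx, ky) plane, measured in the
    plane perpendicular to the y tilt axis, is within theta_max; a cosine
    edge of width ``spec.apodization`` degrees softens the boundary.
    """
    spec = spec or WedgeSpec()
    if np.isscalar(box):
        if box < 8:
            raise ValueError("box_edge must be >= 8")
        shape = (int(box),) * 3
    else:
        shape = tuple(int(b) for b in box)
    kz, _, kx = _freq_grids(shape)
    angle = np.degrees(np.arctan2(np.abs(kz), np.abs(kx)))
    grid = np.zeros(np.broadcast_shapes(kz.shape, kx.shape), dtype=np.float32)
    grid = np.where(angle <= spec.theta_max, 1.0, 0.0)
    if spec.apodization > 0 and spec.theta_max < 90:
        edge = (angle > spec.theta_max) & (angle <= spec.theta_max + spec.apodization)
        ramp = 0.5 * (1 + np.cos(np.pi * (angle - spec.theta_max) / spec.apodization))
        grid = np.where(edge, ramp, grid)
    return FourierMask(np.broadcast_to(grid, shape).astype(np.float32))


def full_mask(box) -> FourierMask:
    shape = (int(box),) * 3 if np.isscalar(box) else tuple(int(b) for b in box)
    return FourierMask(np.ones(shape, dtype=np.float32))


def spherical_mask(box: int, radius: float | None = None, soft_edge: float = 2.0) -> Volume:
    """Soft-edged sphere centred at floor(N/2); radius in voxels."""
    n = int(box)
    if radius is None:
        radius = n / 2 - max(soft_edge, 1.0)
    c = n // 2
    zz, yy, xx = np.meshgrid(*([np.arange(n) - c] * 3), indexing="ij", sparse=True)
    r = np.sqrt(zz**2 + yy**2 + xx**2)
    m = np.clip((radius + soft_edge - r) / max(soft_edge, 1e-6), 0.0, 1.0)
    m = np.where(r <= radius, 1.0, m)
    return Volume(m.astype(np.float32), 1.0)


# ---------------------------------------------------------------------------
# transforms


def _matrix_zyx(matrix_xyz: np.ndarray) -> np.ndarray:
    """Re-express an (x,y,z) rotation matrix in (z,y,x) index order."""
    return matrix_xyz[::-1, ::-1]


def apply_transform(
    vol: Volume,
    euler: EulerAngles,
    shift: Sequence[float] = (0.0, 0.0, 0.0),
    order: int = 1,
    fill: float | str = "mean",
) -> Volume:
    """Rotate about the centre voxel, then shift by ``(dx, dy, dz)`` voxels.

    Output(x) = input(R^-1 (x - c - s) + c); out-of-domain samples are
    filled with the input mean (or a given constant).
    """
    if not vol.is_cubic:
        raise ValueError(f"apply_transform requires a cubic volume, got {vol.box}")
    data = vol.data
    identity = euler.rot == euler.tilt == euler.psi == 0.0
    s_zyx = np.array([shift[2], shift[1], shift[0]], dtype=float)
    if identity and not np.any(s_zyx):
        return Volume(data.copy(), vol.voxel_size)
    rinv = _matrix_zyx(euler.matrix().T)
    c = np.array([n // 2 for n in data.shape], dtype=float)
    offset = c - rinv @ (c + s_zyx)
    cval = float(data.mean()) if fill == "mean" else float(fill)
    out = ndimage.affine_transform(
        data.astype(np.float32),
        rinv,
        offset=offset,
        order=order,
        mode="constant",
        cval=cval,
        prefilter=order > 1,
    )
    return Volume(out, vol.voxel_size)


def rotate_fourier_mask(mask: FourierMask, euler: EulerAngles) -> FourierMask:
    """Rotate a Fourier mask: out(k) = mask(R^-1 k), about DC."""
    shifted = np.fft.fftshift(mask.grid)
    rinv = _matrix_zyx(euler.matrix().T)
    c = np.array([n // 2 for n in shifted.shape], dtype=float)
    out = ndimage.affine_transform(
        shifted.astype(np.float32),
        rinv,
        offset=c - rinv @ c,
        order=1,
        mode="constant",
        cval=0.0,
    )
    return FourierMask(np.clip(np.fft.ifftshift(out), 0.0, 1.0))


def flip_z(vol: Volume) -> Volume:
    """Exact grid flip about the centre voxel along z (no interpolation)."""
    out = np.roll(vol.data[::-1, :, :], 1, axis=0) if vol.data.shape[0] % 2 == 0 \
        else vol.data[::-1, :, :]
    return Volume(np.ascontiguousarray(out), vol.voxel_size)


# ---------------------------------------------------------------------------
# filters


def bandpass_filter(
    vol: Volume,
    low_res: float | None = None,
    high_res: float | None = None,
    soft_edge_shells: int = 2,
) -> Volume:
    """Cosine-edged Fourier bandpass; resolutions in Angstrom.

    ``high_res`` attenuates beyond 1/high_res (low-pass); ``low_res``
    attenuates below 1/low_res (high-pass). The DC component (and hence
    the mean) is preserved unless ``low_res`` is set.
    """
    if low_res is not None and low_res <= 0:
        raise ValueError("low_res must be positive")
    if high_res is not None and high_res <= 0:
        raise ValueError("high_res must be positive")
    if low_res is not None and high_res is not None and not low_res > high_res:
        raise ValueError("low_res must be coarser (larger) than high_res")
    if low_res is None and high_res is None:
        return vol.copy()
    shape = vol.data.shape
    axes_freq = [np.fft.fftfreq(n, d=vol.voxel_size) for n in shape]
    kz, ky, kx = np.meshgrid(*axes_freq, indexing="ij", sparse=True)
    f = np.sqrt(kz**2 + ky**2 + kx**2)
    soft = soft_edge_shells / (min(shape) * vol.voxel_size)
    gain = np.ones_like(f)
    if high_res is not None:
        fh = 1.0 / high_res
        gain = gain * _cos_step(fh - f, soft)
    if low_res is not None:
        fl = 1.0 / low_res
        gain = gain * _cos_step(f - fl, soft)
    out = np.fft.ifftn(np.fft.fftn(vol.data) * gain).real
    return Volume(out.astype(np.float32), vol.voxel_size)


def _cos_step(d, soft):
    """1 where d >= 0, cosine roll-off to 0 over width ``soft``."""
    if soft <= 0:
        return (d >= 0).astype(float)
    ramp = 0.5 * (1 + np.cos(np.pi * np.clip(-d, 0.0, soft) / soft))
    return np.where(d >= 0, 1.0, np.where(d >= -soft, ramp, 0.0))


def apply_fourier_mask(vol: Volume, mask: FourierMask) -> Volume:
    out = np.fft.ifftn(np.fft.fftn(vol.data) * mask.grid).real
    return Volume(out.astype(np.float32), vol.voxel_size)


# ---------------------------------------------------------------------------
# symmetry


def parse_symmetry(group: str) -> tuple[str, int]:
    g = group.strip().upper()
    if len(g) < 2 or g[0] not in "CD" or not g[1:].isdigit():
        raise ValueError(f"symmetry must look like 'C7' or 'D7', got {group!r}")
    n = int(g[1:])
    if n < 1:
        raise ValueError("symmetry order must be >= 1")
    return g[0], n


def symmetry_elements(group: str) -> list[EulerAngles]:
    """Euler triples of every element of Cn or Dn (axis = z)."""
    kind, n = parse_symmetry(group)
    elems = [EulerAngles(k * 360.0 / n - (360.0 if k * 360.0 / n >= 180 else 0.0), 0.0, 0.0)
             for k in range(n)]
    if kind == "D":
        flip = EulerAngles(0.0, 180.0, 0.0)  # two-fold about y
        elems += [e.compose(flip) for e in elems[:n]]
    return elems


def symmetrize(vol: Volume, group: str) -> Volume:
    """Average over the Cn (n) or Dn (2n) group rotations about z.

    Each group element samples the *input* volume once (a single trilinear
    interpolation per element), so the result is exactly the discrete
    orbit average.
    """
    kind, n = parse_symmetry(group)
    if kind == "C" and n == 1:
        return vol.copy()
    acc = np.zeros_like(vol.data, dtype=np.float64)
    elems = symmetry_elements(group)
    for e in elems:
        acc += apply_transform(vol, e).data
    return Volume((acc / len(elems)).astype(np.float32), vol.voxel_size)


# ---------------------------------------------------------------------------
# constrained cross-correlation


def _masked_normalize(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    wsum = mask.sum()
    if wsum <= 0:
        raise ValueError("real-space mask is empty")
    mean = (mask * data).sum() / wsum
    centred = mask * (data - mean)
    norm = np.sqrt((centred**2).sum())
    if not norm > 1e-12:
        raise ValueError("volume is zero under the mask; correlation undefined")
    return centred / norm


def constrained_cc(
    ref: Volume,
    sub: Volume,
    wedge_ref: FourierMask,
    wedge_sub: FourierMask,
    real_mask: Volume,
    max_shift: int = 0,
) -> tuple[float, tuple[int, int, int]]:
    """Missing-wedge constrained normalized cross-correlation.

    Both volumes are restricted to the shared Fourier support (the product
    of the two wedge masks), zero-meaned and unit-normed under
    ``real_mask``, then correlated over integer translations within
    ``max_shift`` voxels per axis. Returns the best score (in [-1, 1] by
    Cauchy-Schwarz) and the argmax shift ``(dx, dy, dz)`` such that
    translating ``ref`` by that shift best matches ``sub``.
    """
    if ref.data.shape != sub.data.shape:
        raise ValueError("ref and sub must share a box")
    shared = wedge_ref.grid * wedge_sub.grid
    a = np.fft.ifftn(np.fft.fftn(ref.data) * shared).real
    b = np.fft.ifftn(np.fft.fftn(sub.data) * shared).real
    ah = _masked_normalize(a, real_mask.data)
    bh = _masked_normalize(b, real_mask.data)
    if max_shift == 0:
        return float(np.vdot(ah, bh).real), (0, 0, 0)
    cc = np.fft.ifftn(np.conj(np.fft.fftn(ah)) * np.fft.fftn(bh)).real
    rng = np.arange(-max_shift, max_shift + 1)
    best, best_shift = -np.inf, (0, 0, 0)
    for dz in rng:
        for dy in rng:
            for dx in rng:
                v = cc[dz % cc.shape[0], dy % cc.shape[1], dx % cc.shape[2]]
                if v > best:
                    best, best_shift = v, (int(dx), int(dy), int(dz))
    return float(best), best_shift


# ---------------------------------------------------------------------------
# Fourier shell correlation


def fsc(half_a: Volume, half_b: Volume, shell_width: int = 1) -> FSCCurve:
    """Per-shell normalized correlation of two half-maps."""
    if half_a.data.shape != half_b.data.shape:
        raise ValueError("half-maps must share a box")
    if abs(half_a.voxel_size - half_b.voxel_size) > 1e-6:
        raise ValueError("half-maps must share a voxel size")
    fa = np.fft.fftn(half_a.data)
    fb = np.fft.fftn(half_b.data)
    kz, ky, kx = _freq_grids(fa.shape)
    r = np.sqrt(kz**2 + ky**2 + kx**2)
    n = min(fa.shape)
    shell = np.minimum((r / shell_width).astype(int), 10**9)
    n_shells = n // (2 * shell_width) + 1
    keep = shell < n_shells
    idx = shell[keep].ravel()
    cross = np.bincount(idx, weights=(fa[keep] * np.conj(fb[keep])).real.ravel(),
                        minlength=n_shells)
    pa = np.bincount(idx, weights=(np.abs(fa[keep]) ** 2).ravel(), minlength=n_shells)
    pb = np.bincount(idx, weights=(np.abs(fb[keep]) ** 2).ravel(), minlength=n_shells)
    counts = np.bincount(idx, minlength=n_shells)
    rsum = np.bincount(idx, weights=r[keep].ravel(), minlength=n_shells)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where((pa > 0) & (pb > 0), cross / np.sqrt(pa * pb), 0.0)
    mean_r = np.where(counts > 0, rsum / np.maximum(counts, 1), np.arange(n_shells))
    freq = mean_r / (n * half_a.voxel_size)
    # guarantee strict monotonicity even for sparse shells
    freq = np.maximum.accumulate(freq + np.arange(n_shells) * 1e-12)
    return FSCCurve(freq, np.clip(corr, -1.0, 1.0), counts.astype(int))


def resolution_at_threshold(
    curve: FSCCurve, threshold: float = FSC_GOLD_STANDARD_THRESHOLD
) -> Resolution:
    """Resolution at the first downward threshold crossing (linear interp).

    Without a crossing the Nyquist shell resolution is returned flagged as
    a bound.
    """
    freq = np.asarray(curve.shell_freq, dtype=float)
    corr = np.asarray(curve.corr, dtype=float)
    populated = np.asarray(curve.n_voxels) > 0
    freq, corr = freq[populated], corr[populated]
    if freq.size == 0:
        raise ValueError("FSC curve is empty")
    if corr[0] < threshold:
        return Resolution(float(1.0 / freq[0]), True)
    for i in range(len(corr) - 1):
        if corr[i] >= threshold > corr[i + 1]:
            frac = (corr[i] - threshold) / (corr[i] - corr[i + 1])
            f_cross = freq[i] + frac * (freq[i + 1] - freq[i])
            return Resolution(float(1.0 / f_cross), False)
    return Resolution(float(1.0 / freq[-1]), True)
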