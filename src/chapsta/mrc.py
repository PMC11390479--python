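"""Minimal MRC2014 (mode 2) volume reader/writer.

Only the subset of the format this pipeline produces and consumes is
supported: 32-bit float little-endian volumes with cubic-or-rectangular
grids and an isotropic voxel size recorded in the cell dimensions.
Arrays are stored in the conventional (z, y, x) axis order, i.e. the MRC
column axis is the fastest-varying numpy axis, so write/read round-trips
preserve the grid bit-exactly.
"""

from __future__ import annotations

import struct

import numpy as np

HEADER_BYTES = 1024
_MODE_FLOAT32 = 2

_MODE_NAMES = {
    0: "int8",
    1: "int16",
    2: "float32",
    3: "complex int16",
    4: "complex float32",
    6: "uint16",
    12: "float16",
}


class MrcFormatError(ValueError):
    """Raised when a file is not a readable MRC2014 mode-2 volume."""


def write_mrc(path, data: np.ndarray, voxel_size: float) -> None:
    """Write ``data`` (z, y, x) as an MRC2014 mode-2 file."""
    data = np.ascontiguousarray(data, dtype="<f4")
    if data.ndim != 3:
        raise MrcFormatError(f"expected a 3D array, got ndim={data.ndim}")
    nz, ny, nx = data.shape
    header = bytearray(HEADER_BYTES)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # NX NY NZ
    struct.pack_into("<i", header, 12, _MODE_FLOAT32)       # MODE
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # NXSTART..
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # MX MY MZ
    struct.pack_into(
        "<3f", header, 40, nx * voxel_size, ny * voxel_size, nz * voxel_size
    )                                                       # CELLA
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # CELLB
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # MAPC MAPR MAPS
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<2i", header, 88, 1, 0)               # ISPG, NSYMBT
    header[208:212] = b"MAP "                               # MAP magic
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))       # little-endian stamp
    struct.pack_into("<f", header, 216, float(data.std()))  # RMS
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_mrc(path):
    """Read an MRC2014 mode-2 file, returning ``(data, voxel_size)``."""
    with open(path, "rb") as fh:
        header = fh.read(HEADER_BYTES)
        if len(header) < HEADER_BYTES:
            raise MrcFormatError(f"{path}: truncated header ({len(header)} bytes)")
        stamp = header[212:216]
        byte_order = ">" if stamp[:2] == b"\x11\x11" else "<"
        nx, ny, nz = struct.unpack(byte_order + "3i", header[0:12])
        (mode,) = struct.unpack(byte_order + "i", header[12:16])
        if mode != _MODE_FLOAT32:
            name = _MODE_NAMES.get(mode, "unknown")
            raise MrcFormatError(
                f"{path}: unsupported MRC mode {mode} ({name}); only mode 2 "
                "(float32) volumes are supported"
            )
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise MrcFormatError(f"{path}: missing MAP magic; not an MRC2014 file")
        cella_x, _, _ = struct.unpack(byte_order + "3f", header[40:52])
        (nsymbt,) = struct.unpack(byte_order + "i", header[92:96])
        if nsymbt:
            fh.read(nsymbt)
        n_values = nx * ny * nz
        raw = fh.read(n_values * 4)
        if len(raw) < n_values * 4:
            raise MrcFormatError(
                f"{path}: truncated data block ({len(raw)} of {n_values * 4} bytes)"
            )
        data = np.frombuffer(raw, dtype=byte_order + "f4").reshape(nz, ny, nx)
    voxel_size = cella_x / nx if nx else 1.0
    return np.ascontiguousarray(data.astype(np.float32)), float(voxel_size)
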