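"""STAR-dialect particle tables.

A single named data block with a ``loop_`` header (one column name per
line, ``_name`` prefix) followed by whitespace-separated rows, as used by
common subtomogram-averaging packages. Coordinates are 0-based voxel
positions with the origin at array index (0, 0, 0); angles are intrinsic
ZYZ degrees. Floats are written with Python's shortest round-trip
representation so ``read(write(t)) == t`` exactly and a write-read-write
cycle is byte-identical. Unknown columns are preserved verbatim.
"""

from __future__ import annotations

import pandas as pd

REQUIRED_COLUMNS = ("id", "tomogram", "x", "y", "z", "rot", "tilt", "psi", "score")
OPTIONAL_COLUMNS = ("class", "state", "condition", "dx", "dy", "dz")

_HEADER_COMMENT = (
    "# chapsta particle table: x/y/z are 0-based voxel coordinates "
    "(origin at volume index 0,0,0); rot/tilt/psi are intrinsic ZYZ degrees."
)

_INT_COLUMNS = {"id", "class"}
_STR_COLUMNS = {"tomogram", "state", "condition"}


class StarFormatError(ValueError):
    """Raised on malformed tables or missing required columns."""


def _format_value(col: str, value) -> str:
    if col in _STR_COLUMNS:
        return str(value)
    if col in _INT_COLUMNS:
        return str(int(value))
    try:
        return repr(float(value))
    except (TypeError, ValueError):
        return str(value)


def write_particles(path, table: pd.DataFrame, block: str = "particles") -> None:
    """Write a particle table; required columns must be present."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise StarFormatError(f"missing required column(s): {', '.join(missing)}")
    cols = list(table.columns)
    lines = [_HEADER_COMMENT, "", f"data_{block}", "", "loop_"]
    lines += [f"_{c} #{i + 1}" for i, c in enumerate(cols)]
    for _, row in table.iterrows():
        lines.append(" ".join(_format_value(c, row[c]) for c in cols))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def read_particles(path) -> pd.DataFrame:
    """Read a particle table written by :func:`write_particles`."""
    cols: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                cols = []
                rows = []
                continue
            if line.startswith("_"):
                if not in_loop:
                    raise StarFormatError(f"{path}: column outside loop_: {line}")
                cols.append(line.split()[0][1:])
                continue
            if in_loop:
                fields = line.split()
                if len(fields) != len(cols):
                    raise StarFormatError(
                        f"{path}: row has {len(fields)} fields, expected {len(cols)}"
                    )
                rows.append(fields)
    if not cols:
        raise StarFormatError(f"{path}: no loop_ block found")
    missing = [c for c in REQUIRED_COLUMNS if c not in cols]
    if missing:
        raise StarFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    table = pd.DataFrame(rows, columns=cols)
    for c in cols:
        if c in _STR_COLUMNS:
            continue
        if c in _INT_COLUMNS:
            table[c] = table[c].astype(int)
        else:
            try:
                table[c] = table[c].astype(float)
            except ValueError:
                pass  # unknown non-numeric column: keep the strings
    return table
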