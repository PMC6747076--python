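"""stdev*coeff contour grids for steric/electrostatic model interpretation.

Each retained descriptor column contributes (column standard deviation x PLS
coefficient) at its lattice position; columns removed by the minimum-sigma
filter map to 0.  The favored level is the quantile of the positive values at
the favored fraction (default 0.80) and the disfavored level the quantile of
the negative values at the disfavored fraction (default 0.20) — the usual
"contribution" contour levels.  Grids are serialized as OpenDX scalar fields
for external 3D viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .field_engine import DescriptorTable, GridSpec
from .pls_model import PLSModel

__all__ = [
    "ContourSet",
    "stdev_coeff_grid",
    "contour_levels",
    "write_contours",
    "write_dx",
    "read_dx",
]


@dataclass
class ContourSet:
    field_type: str  # "steric" | "electrostatic"
    grid: GridSpec
    values: np.ndarray  # stdev*coeff per lattice point, flat C order
    favored_level: float | None
    disfavored_level: float | None


def stdev_coeff_grid(model: PLSModel, table: DescriptorTable, field_type: str) -> np.ndarray:
    """Per-lattice-point stdev*coeff values for one field, flat (n_points,).

    The product of the model-space column sd and coefficient is invariant to
    any uniform column scaling (the scale cancels), so block scaling does not
    affect the contours.
    """
    meta = table.column_meta
    if field_type not in set(meta["field"]):
        raise ValueError(f"field type {field_type!r} absent from descriptor table")
    values = np.zeros(table.grid.n_points)
    cols = meta.index[meta["field"] == field_type]
    sd = model.x_sd[cols] if model.x_sd is not None else meta.loc[cols, "raw_sd"]
    contrib = sd.to_numpy() * model.coefficients[cols].to_numpy()
    values[meta.loc[cols, "point"].to_numpy()] = contrib
    return values


def contour_levels(
    values: np.ndarray,
    favored_fraction: float = 0.80,
    disfavored_fraction: float = 0.20,
) -> tuple[float | None, float | None]:
    """Favored/disfavored display levels from a stdev*coeff grid.

    Quantiles use linear interpolation between order statistics.  If the
    grid is one-signed the missing level is ``None`` (with a warning).
    """
    values = np.asarray(values, dtype=float)
    pos = values[values > 0]
    neg = values[values < 0]
    favored = float(np.quantile(pos, favored_fraction)) if pos.size else None
    disfavored = float(np.quantile(neg, disfavored_fraction)) if neg.size else None
    if favored is None or disfavored is None:
        warnings.warn("one-signed contour grid: only a single level produced",
                      stacklevel=2)
    return favored, disfavored


# ---------------------------------------------------------------------------
# OpenDX serialization (regular-grid scalar field dialect)
# ---------------------------------------------------------------------------

def write_dx(values: np.ndarray, grid: GridSpec, path, comment: str = "") -> None:
    nx, ny, nz = grid.counts
    values = np.asarray(values, dtype=float).reshape(nx * ny * nz)
    d = grid.spacing
    lines = []
    if comment:
        for c in comment.splitlines():
            lines.append(f"# {c}")
    lines += [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {values.size} data follows",
    ]
    body = [
        " ".join(f"{v:.6e}" for v in values[i : i + 3])
        for i in range(0, values.size, 3)
    ]
    tail = [
        'attribute "dep" string "positions"',
        'object "regular positions regular connections" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines + body + tail) + "\n")


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    counts = origin = None
    deltas = []
    data: list[float] = []
    n_items = 0
    with open(path) as fh:
        in_data = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_data:
                if line.startswith(("attribute", "object", "component")):
                    in_data = False
                    continue
                data.extend(float(t) for t in line.split())
                if len(data) >= n_items:
                    in_data = False
                continue
            if line.startswith("object 1 class gridpositions"):
                counts = tuple(int(t) for t in line.split()[-3:])
            elif line.startswith("origin"):
                origin = tuple(float(t) for t in line.split()[1:4])
            elif line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split()[-3])
                in_data = True
    if counts is None or origin is None or len(deltas) != 3:
        raise ValueError(f"not a regular-grid OpenDX file: {path}")
    spacing = deltas[0][0]
    if not (np.isclose(deltas[1][1], spacing) and np.isclose(deltas[2][2], spacing)):
        raise ValueError("anisotropic OpenDX grids are not supported")
    grid = GridSpec(origin, spacing, counts)
    values = np.asarray(data, dtype=float)
    if values.size != grid.n_points:
        raise ValueError("OpenDX item count does not match grid counts")
    return values, grid


def write_contours(contour_set: ContourSet, path_prefix) -> tuple[str, str]:
    """Write the stdev*coeff grid and a level-metadata sidecar.

    Produces ``<prefix>.dx`` (values) and ``<prefix>.levels.dx`` holding a
    grid masked to the favored/disfavored regions (+1 favored, -1
    disfavored, 0 elsewhere) so viewers without isolevel support can show
    the regions directly.
    """
    prefix = str(path_prefix)
    values_path = prefix + ".dx"
    levels_path = prefix + ".levels.dx"
    comment = (
        f"fuzzcomfa {contour_set.field_type} stdev*coeff; "
        f"favored_level={contour_set.favored_level} "
        f"disfavored_level={contour_set.disfavored_level}"
    )
    write_dx(contour_set.values, contour_set.grid, values_path, comment)
    mask = np.zeros_like(contour_set.values)
    if contour_set.favored_level is not None:
        mask[contour_set.values >= contour_set.favored_level] = 1.0
    if contour_set.disfavored_level is not None:
        mask[contour_set.values <= contour_set.disfavored_level] = -1.0
    write_dx(mask, contour_set.grid, levels_path, comment)
    return values_path, levels_path
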