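"""Structured-grid VTK output and run manifests.

Snapshots are written as legacy-ASCII VTK ``STRUCTURED_POINTS`` datasets
with float64 point data, which every VTK-based viewer reads directly.  A
minimal reader for the same dialect supports round-trip checks.  Metrics go
to CSV at 12 significant digits so byte-identical reproduction of a run is
a meaningful determinism check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from pathlib import Path

import numpy as np

from .grid import StructuredGrid

__all__ = ["write_snapshot", "read_snapshot", "write_metrics_csv", "RunManifest"]

CSV_FLOAT_FORMAT = "%.12g"


def write_snapshot(grid: StructuredGrid, fields: dict, path) -> Path:
    """Write nodal fields to a legacy-ASCII VTK structured-points file.

    ``fields`` maps array names to flat nodal arrays: scalars (n_nodes,) or
    vectors (n_nodes, 3).  An empty dict writes a geometry-only file.
    """
    path = Path(path)
    nx, ny, nz = grid.n_nodes_axis
    h = grid.spacing
    lines = [
        "# vtk DataFile Version 3.0",
        "spheromag snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {h:.17g} {h:.17g} {h:.17g}",
    ]
    if fields:
        lines.append(f"POINT_DATA {grid.n_nodes}")
    for name, data in fields.items():
        data = np.asarray(data, dtype=float)
        # VTK structured points expect x-fastest ordering, which is native here
        if data.ndim == 1:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.17g}" for v in data)
        elif data.ndim == 2 and data.shape[1] == 3:
            lines.append(f"VECTORS {name} double")
            lines.extend(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in data)
        else:
            raise ValueError(f"field {name!r} must be nodal scalar or 3-vector")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_snapshot(path):
    """Read a file written by :func:`write_snapshot`.

    Returns ``(grid, fields)``; only the dialect this package writes is
    supported.
    """
    tokens = Path(path).read_text().split("\n")
    dims = None
    spacing = None
    fields = {}
    i = 0
    n_pts = None
    while i < len(tokens):
        line = tokens[i].strip()
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(v) for v in line.split()[1:])
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("POINT_DATA"):
            n_pts = int(line.split()[1])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            i += 1  # LOOKUP_TABLE
            vals = np.array([float(tokens[i + 1 + k]) for k in range(n_pts)])
            fields[name] = vals
            i += n_pts
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            vals = np.array(
                [[float(x) for x in tokens[i + 1 + k].split()] for k in range(n_pts)]
            )
            fields[name] = vals
            i += n_pts
        i += 1
    extents = tuple((d - 1) * spacing for d in dims)
    grid = StructuredGrid(extents=extents, spacing=spacing)
    return grid, fields


def write_metrics_csv(df, path) -> Path:
    """Metrics CSV with stable column order and 12-significant-digit floats."""
    path = Path(path)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


@dataclass
class RunManifest:
    """Resolved configuration, code version and output inventory of a run."""

    config: dict
    version: str
    outputs: list

    @classmethod
    def from_config(cls, config, version: str, outputs=()) -> "RunManifest":
        return cls(config=_jsonable(config), version=version, outputs=list(outputs))

    @property
    def parameter_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "version": self.version,
            "parameter_hash": self.parameter_hash,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path
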