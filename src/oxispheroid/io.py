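"""File writers: legacy-VTK image data, CSV tables, JSON reports, manifests.

Everything written here is plain text and deterministic, so reruns with the
same configuration and seed produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import PressureField, TimeSeries, VoxelDomain

__all__ = [
    "write_vtk_image",
    "write_timeseries_csv",
    "write_table_csv",
    "write_json",
    "write_manifest",
]

#: value written for exterior (masked) cells in VTK output
VTK_MASK_VALUE = -1.0


def write_vtk_image(path, domain: VoxelDomain, field: PressureField,
                    name: str = "pO2_mmHg") -> None:
    """Write one pressure snapshot as legacy-VTK STRUCTURED_POINTS (ascii).

    Cell-center values are emitted as POINT_DATA on the cell-center lattice;
    exterior cells carry ``VTK_MASK_VALUE``.  Coordinates are micrometres.
    """
    grid = domain.grid
    full = np.full(grid.dims, VTK_MASK_VALUE)
    full[domain.mask] = field.values
    origin = np.asarray(grid.origin) + 0.5 * grid.spacing
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"oxispheroid pressure field t={field.time:.6g} s; coordinates in um\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {grid.spacing:.9g} {grid.spacing:.9g} {grid.spacing:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK expects x varying fastest
        flat = np.transpose(full, (2, 1, 0)).ravel()
        for i in range(0, flat.size, 9):
            fh.write(" ".join(f"{v:.7g}" for v in flat[i:i + 9]) + "\n")


def write_timeseries_csv(path, ts: TimeSeries) -> None:
    ts.to_dataframe().to_csv(path, index=False, lineterminator="\n",
                             float_format="%.10g")


def write_table_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(outdir, config_echo: dict, seed: int | None,
                   stage_seconds: dict[str, float], version: str) -> Path:
    """Write run metadata + an inventory (with checksums) of every file in
    the output directory.  Written atomically via a temporary file."""
    outdir = Path(outdir)
    inventory = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            inventory[str(p.relative_to(outdir))] = _sha256(p)
    payload = {
        "package": "oxispheroid",
        "version": version,
        "seed": seed,
        "config": config_echo,
        "stage_wall_clock_s": {k: round(v, 3) for k, v in stage_seconds.items()},
        "outputs": inventory,
    }
    tmp = outdir / "manifest.json.tmp"
    write_json(tmp, payload)
    final = outdir / "manifest.json"
    os.replace(tmp, final)
    return final
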