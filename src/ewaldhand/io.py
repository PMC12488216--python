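"""Readers and writers: MRC2014 maps/stacks, RELION-dialect STAR metadata,
FSC tables and JSON reports.

Column mapping (RELION dialect -> internal):

    _rlnAngleRot    alpha (deg)     _rlnDefocusU/V   defocus (A, averaged)
    _rlnAngleTilt   beta (deg)      _rlnVoltage      voltage (kV)
    _rlnAnglePsi    gamma (deg)     _rlnImagePixelSize  pixel size (A)
    _rlnImageName   index@stack (1-based in the file, 0-based internally)

Maps are written as MRC2014 mode 2 (32-bit float) with the pixel size in
the cell fields.  Readers never flip axes: the voxel grid handedness of the
file is preserved exactly as stored (axis order is logged on read), since
silent axis flips are precisely the handedness-violating transformations
the method exists to catch.  Hand ('as_given'/'inverted') is bookkeeping
that MRC cannot store; callers must track it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from .geometry import Pose
from .optics import OpticsParams
from .simulate import SyntheticDataset

logger = logging.getLogger("ewaldhand")

__all__ = [
    "ParticleMetadataTable",
    "read_mrc_volume",
    "write_mrc_volume",
    "read_mrc_stack",
    "write_mrc_stack",
    "read_particle_star",
    "write_particle_star",
    "dataset_table",
    "write_dataset",
    "write_fsc_tsv",
]


# ---------------------------------------------------------------------------
# MRC

def write_mrc_volume(path, grid: np.ndarray, pixel_size: float) -> None:
    """Write a 3D array as an MRC2014 mode-2 map with cubic voxels."""
    arr = np.ascontiguousarray(np.asarray(grid), dtype=np.float32)
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(arr)
    m.grid.unit_cell = gemmi.UnitCell(
        arr.shape[0] * pixel_size,
        arr.shape[1] * pixel_size,
        arr.shape[2] * pixel_size,
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header(2)
    m.write_ccp4_map(str(path))


def read_mrc_volume(path) -> tuple[np.ndarray, float]:
    """Read an MRC map; returns (array, pixel size in A).

    The stored axis correspondence is logged and never reordered.
    """
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True)
    cell = m.grid.unit_cell
    if arr.shape[0] == 0 or arr.size == 0:
        raise ValueError(f"{path}: empty map")
    px = cell.a / arr.shape[0]
    logger.info(
        "read %s: shape=%s cell=(%.3f, %.3f, %.3f) axis order preserved as stored",
        path, arr.shape, cell.a, cell.b, cell.c,
    )
    return arr.astype(np.float64), float(px)


def write_mrc_stack(path, stack: np.ndarray, pixel_size: float) -> None:
    """Write an (n, box, box) particle stack as an MRC(S) mode-2 file."""
    write_mrc_volume(path, np.asarray(stack), pixel_size)


def read_mrc_stack(path) -> tuple[np.ndarray, float]:
    arr, _ = read_mrc_volume(path)
    m = gemmi.read_ccp4_map(str(path))
    px = m.grid.unit_cell.b / arr.shape[1]  # image axes carry the pixel size
    return arr, float(px)


# ---------------------------------------------------------------------------
# STAR

_PARTICLE_COLUMNS = {
    "_rlnImageName": "image_name",
    "_rlnAngleRot": "alpha",
    "_rlnAngleTilt": "beta",
    "_rlnAnglePsi": "gamma",
    "_rlnDefocusU": "defocus_u",
    "_rlnDefocusV": "defocus_v",
    "_rlnOpticsGroup": "optics_group",
}
_OPTICS_COLUMNS = {
    "_rlnOpticsGroup": "optics_group",
    "_rlnVoltage": "voltage",
    "_rlnImagePixelSize": "pixel_size",
    "_rlnSphericalAberration": "spherical_aberration",
    "_rlnAmplitudeContrast": "amplitude_contrast",
}


@dataclass
class ParticleMetadataTable:
    """Per-particle metadata plus per-optics-group parameters."""

    particles: pd.DataFrame
    optics: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("alpha", "beta", "gamma", "defocus", "stack_file", "slice_index"):
            if col not in self.particles.columns:
                raise ValueError(f"particle table missing column {col!r}")
        if not np.all(np.isfinite(self.particles[["alpha", "beta", "gamma"]].values)):
            raise ValueError("non-finite Euler angles")
        if np.any(self.particles["defocus"].values <= 0):
            raise ValueError("defocus values must be positive")

    def __len__(self) -> int:
        return len(self.particles)

    def poses(self) -> list[Pose]:
        return [
            Pose(r.alpha, r.beta, r.gamma) for r in self.particles.itertuples()
        ]

    def defoci(self) -> np.ndarray:
        return self.particles["defocus"].to_numpy(dtype=float)

    def optics_params(self, curvature_scale: float = 1.0) -> OpticsParams:
        row = self.optics.iloc[0]
        return OpticsParams(
            voltage=float(row["voltage"]),
            pixel_size=float(row["pixel_size"]),
            spherical_aberration=float(row.get("spherical_aberration", 2.7)),
            amplitude_contrast=float(row.get("amplitude_contrast", 0.07)),
            curvature_scale=curvature_scale,
        )


def _split_image_name(name: str) -> tuple[str, int]:
    m = re.match(r"^(\d+)@(.+)$", name)
    if not m:
        raise ValueError(f"malformed _rlnImageName {name!r} (expected index@stack)")
    return m.group(2), int(m.group(1)) - 1  # file uses 1-based slices


def _block_to_frame(block, colmap: dict[str, str], required: tuple[str, ...]):
    present = {}
    for star_col, name in colmap.items():
        loop = block.find_loop(star_col)
        vals = list(loop)
        if vals:
            present[name] = vals
    for star_col in required:
        if colmap[star_col] not in present:
            raise ValueError(f"STAR block {block.name!r} missing column {star_col}")
    return pd.DataFrame(present)


def read_particle_star(path) -> ParticleMetadataTable:
    """Read a RELION-dialect STAR file (optics-group or legacy single block)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = gemmi.cif.read_file(str(path))
    except Exception as exc:  # gemmi reports line numbers in its message
        raise ValueError(f"malformed STAR file {path}: {exc}") from exc

    particles_block = None
    optics_block = None
    for block in doc:
        if block.find_loop("_rlnAngleRot"):
            particles_block = block
        elif block.find_loop("_rlnVoltage") and block.find_loop("_rlnOpticsGroup"):
            optics_block = block
    if particles_block is None:
        raise ValueError(f"{path}: no particle block with _rlnAngleRot found")

    pf = _block_to_frame(
        particles_block,
        _PARTICLE_COLUMNS,
        required=("_rlnImageName", "_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi",
                  "_rlnDefocusU"),
    )
    for col in ("alpha", "beta", "gamma", "defocus_u"):
        pf[col] = pf[col].astype(float)
    if "defocus_v" in pf.columns:
        pf["defocus"] = (pf["defocus_u"].astype(float) + pf["defocus_v"].astype(float)) / 2.0
    else:
        pf["defocus"] = pf["defocus_u"]
    stacks, slices = zip(*(_split_image_name(n) for n in pf["image_name"]))
    pf["stack_file"] = stacks
    pf["slice_index"] = slices

    if optics_block is not None:
        of = _block_to_frame(
            optics_block, _OPTICS_COLUMNS, required=("_rlnVoltage", "_rlnImagePixelSize")
        )
        for col in of.columns:
            if col != "optics_group":
                of[col] = of[col].astype(float)
    else:
        # legacy dialect: optics columns live in the particle loop
        volt = list(particles_block.find_loop("_rlnVoltage"))
        pix = list(particles_block.find_loop("_rlnImagePixelSize")) or list(
            particles_block.find_loop("_rlnDetectorPixelSize")
        )
        if not volt or not pix:
            raise ValueError(
                f"{path}: legacy STAR without _rlnVoltage/_rlnImagePixelSize columns"
            )
        of = pd.DataFrame(
            {"optics_group": ["1"], "voltage": [float(volt[0])],
             "pixel_size": [float(pix[0])]}
        )
    return ParticleMetadataTable(particles=pf, optics=of)


def write_particle_star(path, table: ParticleMetadataTable) -> None:
    doc = gemmi.cif.Document()
    ob = doc.add_new_block("optics")
    fields = ["OpticsGroup", "Voltage", "ImagePixelSize",
              "SphericalAberration", "AmplitudeContrast"]
    loop = ob.init_loop("_rln", fields)
    for row in table.optics.itertuples():
        loop.add_row([
            str(getattr(row, "optics_group", 1)),
            f"{row.voltage:.6f}",
            f"{row.pixel_size:.6f}",
            f"{getattr(row, 'spherical_aberration', 2.7):.6f}",
            f"{getattr(row, 'amplitude_contrast', 0.07):.6f}",
        ])
    pb = doc.add_new_block("particles")
    loop = pb.init_loop(
        "_rln",
        ["ImageName", "AngleRot", "AngleTilt", "AnglePsi",
         "DefocusU", "DefocusV", "OpticsGroup"],
    )
    for row in table.particles.itertuples():
        loop.add_row([
            f"{row.slice_index + 1:06d}@{row.stack_file}",
            f"{row.alpha:.17g}",
            f"{row.beta:.17g}",
            f"{row.gamma:.17g}",
            f"{row.defocus:.17g}",
            f"{row.defocus:.17g}",
            str(getattr(row, "optics_group", 1)),
        ])
    doc.write_file(str(path))


def dataset_table(dataset: SyntheticDataset, stack_name: str) -> ParticleMetadataTable:
    """Metadata table describing a synthetic dataset's stack."""
    n = len(dataset.particle_stack)
    particles = pd.DataFrame(
        {
            "image_name": [f"{i + 1:06d}@{stack_name}" for i in range(n)],
            "alpha": [p.alpha for p in dataset.poses],
            "beta": [p.beta for p in dataset.poses],
            "gamma": [p.gamma for p in dataset.poses],
            "defocus_u": dataset.defoci,
            "defocus_v": dataset.defoci,
            "defocus": dataset.defoci,
            "stack_file": [stack_name] * n,
            "slice_index": list(range(n)),
            "optics_group": ["1"] * n,
        }
    )
    optics = pd.DataFrame(
        {
            "optics_group": ["1"],
            "voltage": [dataset.optics.voltage],
            "pixel_size": [dataset.optics.pixel_size],
            "spherical_aberration": [dataset.optics.spherical_aberration],
            "amplitude_contrast": [dataset.optics.amplitude_contrast],
        }
    )
    return ParticleMetadataTable(particles=particles, optics=optics)


def write_dataset(out_dir, dataset: SyntheticDataset, prefix: str = "particles"):
    """Write stack (MRCS), metadata (STAR) and truth map (MRC) for a dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack_name = f"{prefix}.mrcs"
    write_mrc_stack(out / stack_name, dataset.particle_stack, dataset.optics.pixel_size)
    write_particle_star(out / f"{prefix}.star", dataset_table(dataset, stack_name))
    write_mrc_volume(out / "truth.mrc", dataset.truth_volume, dataset.optics.pixel_size)
    return out / f"{prefix}.star", out / stack_name


def write_fsc_tsv(path, curve) -> None:
    """FSC curve as a plain-text table: resolution (A), |k| (A^-1), value."""
    with open(path, "w") as fh:
        fh.write("resolution_A\tshell_center_invA\tfsc\tn_voxels\n")
        res = curve.resolutions()
        for i in range(len(curve.values)):
            r = "inf" if np.isinf(res[i]) else f"{res[i]:.4f}"
            fh.write(
                f"{r}\t{curve.shell_centers[i]:.6f}\t{curve.values[i]:.6f}\t"
                f"{int(curve.n_voxels_per_shell[i])}\n"
            )
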