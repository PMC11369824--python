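"""File formats: NIfTI volumes, delimited tables, YAML config, graph files.

Images are NIfTI-1 only. Tables are comma-delimited text with a one-line
header. Graph exports follow the BrainNet-style convention: a 6-column
node file (x y z colour size label) and a square-matrix edge file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import BoldRun, RoiAtlas, AnalysisConfig, default_affine

log = logging.getLogger("cppfmri")

__all__ = [
    "read_bold", "write_bold", "read_atlas", "write_atlas",
    "read_motion", "write_motion", "read_config", "write_config",
    "write_matrix", "read_matrix", "write_node_file", "write_edge_file",
]

MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def read_bold(path, tr_s: float | None = None, run_label: str = "") -> BoldRun:
    """Load a 4D NIfTI-1 file as a :class:`BoldRun`.

    TR is taken from the NIfTI header time step; an explicit ``tr_s``
    override wins with a logged warning (rodent headers are often wrong).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected 4D BOLD image, got {img.ndim}D")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr_s is not None:
        if header_tr > 0 and not np.isclose(header_tr, tr_s):
            log.warning(
                "%s: overriding header TR %.3f s with configured TR %.3f s",
                path, header_tr, tr_s,
            )
        tr = tr_s
    else:
        tr = header_tr
    if not tr > 0:
        raise ValueError(
            f"{path}: non-positive TR {tr!r} in header and no override given"
        )
    data = np.asarray(img.get_fdata())
    return BoldRun(
        data=data,
        tr_s=tr,
        voxel_mm=np.asarray(zooms[:3], dtype=float),
        affine=img.affine,
        run_label=run_label or path.name.split(".")[0],
    )


def write_bold(run: BoldRun, path) -> Path:
    """Write a BoldRun to NIfTI-1, storing TR in the header time step."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(run.data, dtype=np.float64), run.affine)
    img.header.set_zooms((*run.voxel_mm, run.tr_s))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_volume(vol: np.ndarray, affine: np.ndarray, path) -> Path:
    """Write a single 3D volume (stat map, cluster labels) to NIfTI-1."""
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), str(path))
    return path


def read_atlas(path, names) -> RoiAtlas:
    """Load a label volume plus a name table as a :class:`RoiAtlas`.

    The name table is comma-delimited with columns ``label,name`` and
    optionally ``x_mm,y_mm,z_mm`` for representative graph coordinates.
    """
    path = Path(path)
    img = nib.load(str(path))
    labels = np.asarray(img.get_fdata())
    tab = pd.read_csv(names)
    if not {"label", "name"} <= set(tab.columns):
        raise ValueError(f"{names}: name table needs 'label' and 'name' columns")
    name_map = {int(r.label): str(r.name) for r in tab.itertuples()}
    coords = {}
    if {"x_mm", "y_mm", "z_mm"} <= set(tab.columns):
        coords = {
            str(r.name): np.array([r.x_mm, r.y_mm, r.z_mm], dtype=float)
            for r in tab.itertuples()
        }
    zooms = img.header.get_zooms()[:3]
    return RoiAtlas(
        labels=labels, name_map=name_map,
        voxel_mm=np.asarray(zooms, dtype=float),
        affine=img.affine, coords_mm=coords,
    )


def write_atlas(atlas: RoiAtlas, path, names_path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.affine)
    img.header.set_zooms(tuple(atlas.voxel_mm))
    nib.save(img, str(path))
    rows = []
    for lab in atlas.roi_labels:
        name = atlas.name_map[lab]
        x, y, z = atlas.coords_mm[name]
        rows.append({"label": lab, "name": name, "x_mm": x, "y_mm": y, "z_mm": z})
    pd.DataFrame(rows).to_csv(names_path, index=False)


def read_motion(path) -> np.ndarray:
    """Read a 6-column motion-parameter table (one row per frame)."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, got {arr.shape[1]}")
    return arr


def write_motion(motion: np.ndarray, path) -> Path:
    motion = np.asarray(motion)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be (n_frames, 6)")
    np.savetxt(path, motion, fmt="%.6g")
    return Path(path)


def write_matrix(mat: np.ndarray, path, names: list[str] | None = None) -> Path:
    """Write a square matrix as comma-delimited text with a one-line header."""
    df = pd.DataFrame(np.asarray(mat), columns=names)
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), list(df.columns)


def read_config(path) -> AnalysisConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "bandpass_hz" in raw:
        raw["bandpass_hz"] = tuple(raw["bandpass_hz"])
    if "roi_list" in raw:
        raw["roi_list"] = tuple(raw["roi_list"])
    if "block_schedule" in raw:
        raw["block_schedule"] = tuple(tuple(b) for b in raw["block_schedule"])
    return AnalysisConfig(**raw)


def write_config(cfg: AnalysisConfig, path) -> Path:
    d = {
        "window_s": cfg.window_s,
        "fdr_q": cfg.fdr_q,
        "cluster_min_voxels": cfg.cluster_min_voxels,
        "bandpass_hz": list(cfg.bandpass_hz),
        "smooth_fwhm_factor": cfg.smooth_fwhm_factor,
        "edge_threshold_z": cfg.edge_threshold_z,
        "rng_seed": cfg.rng_seed,
        "roi_list": list(cfg.roi_list),
        "block_schedule": [list(b) for b in cfg.block_schedule],
        "bandpass_glm": cfg.bandpass_glm,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return Path(path)


def write_node_file(path, coords_mm, sizes, colours, labels) -> Path:
    """BrainNet-style node file: ``x y z colour size label``, one ROI per row."""
    path = Path(path)
    with open(path, "w") as fh:
        for xyz, col, size, lab in zip(coords_mm, colours, sizes, labels):
            fh.write(
                f"{xyz[0]:.4f}\t{xyz[1]:.4f}\t{xyz[2]:.4f}\t"
                f"{col:.6g}\t{size:.6g}\t{lab}\n"
            )
    return path


def write_edge_file(path, matrix) -> Path:
    """BrainNet-style edge file: the square weight matrix as plain text."""
    np.savetxt(path, np.asarray(matrix), fmt="%.6g", delimiter="\t")
    return Path(path)
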