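"""Core domain containers shared by every pipeline stage.

The pipeline operates on three objects: :class:`BoldRun` (a 4D BOLD
acquisition plus timing/geometry metadata), :class:`RoiAtlas` (an integer
label volume naming the regions of the cortico-limbic network), and
:class:`AnalysisConfig` (the constants of the analysis: window length,
FDR level, cluster extent, band-pass edges, smoothing factor and edge
threshold).

Conventions: NIfTI-1 is the only image dialect, world coordinates are
RAS+ in mm, voxel indices are 0-based, and time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BoldRun",
    "RoiAtlas",
    "AnalysisConfig",
    "DEFAULT_ROI_NAMES",
    "DEFAULT_VOXEL_MM",
    "default_affine",
]

#: The ten regions of the cortico-limbic network under study: three
#: amygdala nuclei (anterior cortical, basomedial, central), the
#: intermediate lateral septum, lateral habenula, ventral tegmental area,
#: two hippocampal subfields (dentate gyrus, CA1) and two cortical areas
#: (cingulate, retrosplenial).
DEFAULT_ROI_NAMES: tuple[str, ...] = (
    "ACo", "LSI", "LHb", "BMA", "CeA", "VTA", "DG", "CA1", "Cg", "RSC",
)

#: Functional voxel geometry of the acquisition protocol (mm).
DEFAULT_VOXEL_MM: tuple[float, float, float] = (0.234, 0.234, 0.9)


def default_affine(voxel_mm) -> np.ndarray:
    """Diagonal RAS+ affine for a given voxel size, origin at voxel (0,0,0)."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_mm
    return aff


@dataclass
class BoldRun:
    """A single 4D BOLD acquisition.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Intensity values, unscaled beyond the format's slope/intercept.
    tr_s : float
        Repetition time in seconds (2 s in the acquisition protocol).
    voxel_mm : ndarray, shape (3,)
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-world (RAS+ mm) transform.
    frame_times_s : ndarray, shape (t,)
        Onset time of each volume; strictly increasing with spacing tr_s.
    run_label : str
        Free-text condition tag, e.g. ``"rest_pre"`` or ``"cue_morphine"``.
    """

    data: np.ndarray
    tr_s: float
    voxel_mm: np.ndarray
    affine: np.ndarray
    frame_times_s: np.ndarray = None
    run_label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldRun.data: expected 4D (x,y,z,t), got {self.data.ndim}D"
            )
        if not self.tr_s > 0:
            raise ValueError(f"BoldRun.tr_s must be positive, got {self.tr_s}")
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=float)
        if self.voxel_mm.shape != (3,) or np.any(self.voxel_mm <= 0):
            raise ValueError("BoldRun.voxel_mm must be 3 strictly positive lengths")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("BoldRun.affine must be 4x4")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.n_frames) * self.tr_s
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.shape != (self.n_frames,):
            raise ValueError(
                f"BoldRun.frame_times_s: length {self.frame_times_s.size} does "
                f"not match t-dimension {self.n_frames}"
            )
        if self.n_frames > 1:
            dt = np.diff(self.frame_times_s)
            if np.any(dt <= 0) or not np.allclose(dt, self.tr_s, rtol=1e-6):
                raise ValueError(
                    "BoldRun.frame_times_s must increase with spacing tr_s"
                )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, run_label: str | None = None) -> "BoldRun":
        """Copy of this run with new voxel data and unchanged metadata."""
        return BoldRun(
            data=data,
            tr_s=self.tr_s,
            voxel_mm=self.voxel_mm.copy(),
            affine=self.affine.copy(),
            frame_times_s=self.frame_times_s.copy(),
            run_label=self.run_label if run_label is None else run_label,
        )


@dataclass
class RoiAtlas:
    """Labelled integer volume defining ROIs on the pipeline grid.

    Label 0 is reserved for background. ``name_map`` maps every nonzero
    label present in the volume to an ROI name, and every named ROI must
    occupy at least one voxel. ``coords_mm`` holds one representative
    world coordinate per ROI (used for graph node export).
    """

    labels: np.ndarray
    name_map: dict[int, str]
    voxel_mm: np.ndarray = None
    affine: np.ndarray = None
    coords_mm: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("RoiAtlas.labels must be a 3D integer volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ValueError("RoiAtlas.labels must be integer-valued")
            self.labels = lab
        if self.voxel_mm is None:
            self.voxel_mm = np.asarray(DEFAULT_VOXEL_MM)
        self.voxel_mm = np.asarray(self.voxel_mm, dtype=float)
        if self.affine is None:
            self.affine = default_affine(self.voxel_mm)
        present = set(np.unique(self.labels)) - {0}
        unnamed = sorted(present - set(self.name_map))
        if unnamed:
            raise ValueError(f"labels present in volume but not named: {unnamed}")
        empty = sorted(set(self.name_map) - present)
        if empty:
            names = [self.name_map[k] for k in empty]
            raise ValueError(f"named ROIs absent from volume (0 voxels): {names}")
        if 0 in self.name_map:
            raise ValueError("label 0 is reserved for background")
        if not self.coords_mm:
            self.coords_mm = {
                name: self.centroid_mm(lab) for lab, name in self.name_map.items()
            }

    @property
    def roi_labels(self) -> list[int]:
        return sorted(self.name_map)

    @property
    def roi_names(self) -> list[str]:
        """ROI names in ascending label order — the canonical column order."""
        return [self.name_map[k] for k in self.roi_labels]

    @property
    def n_rois(self) -> int:
        return len(self.name_map)

    def mask(self, roi: int | str) -> np.ndarray:
        if isinstance(roi, str):
            inv = {v: k for k, v in self.name_map.items()}
            roi = inv[roi]
        return self.labels == roi

    def centroid_mm(self, label: int) -> np.ndarray:
        ijk = np.mean(np.argwhere(self.labels == label), axis=0)
        return (self.affine @ np.append(ijk, 1.0))[:3]

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class AnalysisConfig:
    """Analysis constants, with the study protocol's values as defaults.

    ``block_schedule`` lists ``(condition, onset_s, duration_s)`` triples;
    the default is two 10-min cue blocks separated by a 5-min inter-block
    interval. ``window_s`` must divide every block duration (40 windows
    for the default schedule).
    """

    window_s: float = 30.0
    fdr_q: float = 0.05
    cluster_min_voxels: int = 16
    bandpass_hz: tuple[float, float] = (0.01, 0.1)
    smooth_fwhm_factor: float = 2.0
    edge_threshold_z: float = 0.2
    rng_seed: int = 0
    roi_list: tuple[str, ...] = DEFAULT_ROI_NAMES
    block_schedule: tuple = (
        ("cue_morphine", 0.0, 600.0),
        ("cue_saline", 900.0, 600.0),
    )
    bandpass_glm: bool = False  # GLM path is not band-pass filtered by default

    def validate(self, tr_s: float) -> None:
        low, high = self.bandpass_hz
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0 < low < high < nyquist):
            raise ValueError(
                f"bandpass_hz must satisfy 0 < low < high < Nyquist "
                f"({nyquist:g} Hz at TR {tr_s} s), got {self.bandpass_hz}"
            )
        if self.cluster_min_voxels < 1:
            raise ValueError("cluster_min_voxels must be >= 1")
        for cond, onset, dur in self.block_schedule:
            if abs(dur / self.window_s - round(dur / self.window_s)) > 1e-9:
                raise ValueError(
                    f"window_s={self.window_s} does not divide block "
                    f"'{cond}' duration {dur}"
                )

    @property
    def n_windows(self) -> int:
        return int(sum(round(d / self.window_s) for _, _, d in self.block_schedule))
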