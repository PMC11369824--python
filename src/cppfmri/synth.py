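"""Synthetic BOLD, atlas and behaviour generation with known ground truth.

Every downstream stage of the pipeline is testable against planted
truth: resting runs carry a chosen ROI x ROI population correlation
structure (additive latent Gaussian factors shared by all voxels of an
ROI, which keeps the planted covariance analytically exact); cue runs
carry window-locked HRF-convolved activations with chosen betas; the
behaviour generator plants a learner fraction and CPP-delta
distributions; and per-animal covariances can be coupled to CPP-delta
with a chosen Fisher-z slope for one ROI pair.

Voxel noise is AR(1), independent across voxels (spatial correlation
is induced later by the smoothing stage, keeping FC truth exact), plus
a per-voxel random-phase low-frequency drift. Amplitudes default to a
signal change of about 1-2% of the baseline-100 intensity, a
conventional BOLD effect size.

Determinism: identical arguments and seed give bit-identical outputs;
per-subject streams are derived from one cohort seed by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd

from .core import (BoldRun, RoiAtlas, DEFAULT_ROI_NAMES, DEFAULT_VOXEL_MM,
                   default_affine)
from .glm import HrfSpec, rat_hrf, window_column_names

log = logging.getLogger("cppfmri")

__all__ = [
    "NoiseSpec", "TaskTruth", "CovSpec", "BehaviourTruth",
    "gen_atlas", "default_atlas", "gen_rest_bold", "gen_task_bold",
    "gen_behaviour", "couple_fc_to_delta",
]

BASELINE = 100.0


@dataclass(frozen=True)
class NoiseSpec:
    """Scanner/physiological noise stand-in.

    sigma: AR(1) innovation-scaled noise SD (image units, ~1% of
    baseline); ar1_rho: lag-1 temporal autocorrelation; drift_amp:
    per-voxel random-phase slow drift amplitude; motion_amp: amplitude
    of the simulated motion-parameter random walks.
    """

    sigma: float = 1.0
    ar1_rho: float = 0.3
    drift_amp: float = 0.5
    motion_amp: float = 0.05

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not abs(self.ar1_rho) < 1:
            raise ValueError("|ar1_rho| must be < 1")


@dataclass(frozen=True)
class CovSpec:
    """Target ROI x ROI population correlation matrix for one condition."""

    matrix: np.ndarray
    coupling: float = 1.0  # global scalar on off-diagonal structure

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("CovSpec.matrix must be square")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("CovSpec.matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ValueError("CovSpec.matrix must have unit diagonal")

    def effective(self) -> np.ndarray:
        m = self.matrix.copy()
        off = ~np.eye(m.shape[0], dtype=bool)
        m[off] *= self.coupling
        return m

    def check_psd(self) -> None:
        w = np.linalg.eigvalsh(self.effective())
        if w.min() < -1e-8:
            raise ValueError(
                f"covariance not positive semi-definite: smallest eigenvalue "
                f"{w.min():.3e}"
            )


@dataclass
class TaskTruth:
    """Planted cue-run activation: per-ROI per-window betas plus schedule."""

    blocks: tuple = (("cue_morphine", 0.0, 600.0), ("cue_saline", 900.0, 600.0))
    window_s: float = 30.0
    betas: dict = field(default_factory=dict)   # roi name -> (n_windows,) betas
    hrf: HrfSpec = HrfSpec()

    @property
    def window_names(self) -> list[str]:
        return window_column_names(self.blocks, self.window_s)

    @property
    def n_windows(self) -> int:
        return len(self.window_names)

    def validate(self, roi_names) -> None:
        nw = self.n_windows
        for roi, b in self.betas.items():
            if roi not in roi_names:
                raise ValueError(f"TaskTruth: unknown ROI '{roi}'")
            b = np.asarray(b, dtype=float)
            if b.shape != (nw,) or not np.all(np.isfinite(b)):
                raise ValueError(
                    f"TaskTruth: betas for '{roi}' must be {nw} finite values"
                )


@dataclass(frozen=True)
class BehaviourTruth:
    """Planted CPP behaviour distribution.

    Learners draw their post-test morphine-side permanence fraction from
    ``learner_post_frac`` and pre from ``learner_pre_frac`` (ranges
    chosen so CPP-delta > 0 and permanence > 0.5 always hold, making
    saturated-effect classification exact); non-learners the reverse.
    """

    learner_fraction: float = 7.0 / 12.0
    learner_pre_frac: tuple = (0.42, 0.52)
    learner_post_frac: tuple = (0.55, 0.85)
    non_pre_frac: tuple = (0.48, 0.58)
    non_post_frac: tuple = (0.20, 0.45)
    session_s: float = 900.0
    neutral_s_mean: float = 150.0
    neutral_s_sd: float = 30.0
    fc_slope: float = 0.0        # planted z-per-second FC-delta coupling
    fc_pair: tuple = ("LSI", "CA1")

    def __post_init__(self):
        if not 0.0 <= self.learner_fraction <= 1.0:
            raise ValueError("learner_fraction must lie in [0,1]")


def gen_atlas(grid=(32, 32, 16), n_rois: int = 10, roi_radius_vox: int = 2,
              seed: int = 0, voxel_mm=DEFAULT_VOXEL_MM,
              names=None) -> RoiAtlas:
    """Place ``n_rois`` disjoint spherical ROIs in a background grid.

    Deterministic given the seed. Placement is rejection-sampled with a
    bounded retry budget; failure suggests a larger grid.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(int(g) for g in grid)
    labels = np.zeros(grid, dtype=np.int16)
    if names is None:
        names = (list(DEFAULT_ROI_NAMES) if n_rois == len(DEFAULT_ROI_NAMES)
                 else [f"ROI{k + 1:02d}" for k in range(n_rois)])
    if len(names) != n_rois:
        raise ValueError("names length must equal n_rois")
    r = roi_radius_vox
    ii, jj, kk = np.ogrid[-r:r + 1, -r:r + 1, -r:r + 1]
    ball = (ii ** 2 + jj ** 2 + kk ** 2) <= r ** 2
    occupied = np.zeros(grid, dtype=bool)
    name_map = {}
    for idx in range(n_rois):
        placed = False
        for _ in range(2000):
            c = [int(rng.integers(r, g - r)) for g in grid]
            sl = tuple(slice(c[d] - r, c[d] + r + 1) for d in range(3))
            if occupied[sl][ball].any():
                continue
            labels[sl][ball] = idx + 1
            occupied[sl] |= ball
            name_map[idx + 1] = names[idx]
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place ROI {idx + 1}/{n_rois} without overlap "
                f"after 2000 retries; use a larger grid or smaller radius"
            )
    return RoiAtlas(labels=labels, name_map=name_map,
                    voxel_mm=np.asarray(voxel_mm, dtype=float),
                    affine=default_affine(voxel_mm))


def default_atlas(seed: int = 0) -> RoiAtlas:
    """The packaged 10-region cortico-limbic atlas at the protocol voxel
    geometry, on the desk-scale 32x32x16 grid."""
    return gen_atlas((32, 32, 16), n_rois=10, roi_radius_vox=2, seed=seed)


def _ar1_noise(rng, shape_vox, n_frames, spec: NoiseSpec) -> np.ndarray:
    """AR(1) noise, independent per voxel, stationary marginal SD = sigma."""
    n_vox = int(np.prod(shape_vox))
    if spec.sigma == 0:
        return np.zeros((*shape_vox, n_frames))
    innov_sd = spec.sigma * np.sqrt(1.0 - spec.ar1_rho ** 2)
    e = rng.standard_normal((n_vox, n_frames)) * innov_sd
    e[:, 0] = rng.standard_normal(n_vox) * spec.sigma
    out = np.empty_like(e)
    out[:, 0] = e[:, 0]
    rho = spec.ar1_rho
    for t in range(1, n_frames):
        out[:, t] = rho * out[:, t - 1] + e[:, t]
    return out.reshape(*shape_vox, n_frames)


def _drift(rng, shape_vox, frame_times, amp) -> np.ndarray:
    """Per-voxel slow cosine drift with random phase (period ~2x run)."""
    if amp == 0:
        return np.zeros((*shape_vox, frame_times.size))
    n_vox = int(np.prod(shape_vox))
    period = 2.0 * (frame_times[-1] - frame_times[0] + 1e-9)
    phase = rng.uniform(0, 2 * np.pi, n_vox)[:, None]
    d = amp * np.cos(2 * np.pi * frame_times[None, :] / period + phase)
    return d.reshape(*shape_vox, frame_times.size)


def _motion_table(rng, n_frames, amp) -> np.ndarray:
    """Six slowly wandering motion parameters (random walks, zero start)."""
    steps = rng.standard_normal((n_frames, 6)) * amp / 10.0
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _mvn_factors(rng, cov: np.ndarray, n_frames: int) -> np.ndarray:
    """(frames, k) latent factors with population correlation ``cov``."""
    w, V = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError(
            f"covariance not positive semi-definite: smallest eigenvalue "
            f"{w.min():.3e}"
        )
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return rng.standard_normal((n_frames, cov.shape[0])) @ root.T


def gen_rest_bold(atlas: RoiAtlas, cov: CovSpec, n_frames: int = 300,
                  tr_s: float = 2.0, noise: NoiseSpec = NoiseSpec(),
                  seed: int = 0, amplitude: float = 1.5,
                  run_label: str = "rest") -> tuple[BoldRun, np.ndarray]:
    """Resting run with a planted ROI x ROI population correlation.

    Each ROI's voxels all receive amplitude x that ROI's latent factor;
    the factors are multivariate normal with correlation ``cov``. The
    default 300 frames at TR 2 s match a 10-min resting acquisition.
    Returns the run and a 6-column motion table.
    """
    if cov.matrix.shape[0] != atlas.n_rois:
        raise ValueError(
            f"cov dimension {cov.matrix.shape[0]} != {atlas.n_rois} ROIs"
        )
    cov.check_psd()
    rng = np.random.default_rng(seed)
    frame_times = np.arange(n_frames) * tr_s
    grid = atlas.labels.shape
    factors = _mvn_factors(rng, cov.effective(), n_frames)
    data = BASELINE + _ar1_noise(rng, grid, n_frames, noise)
    data += _drift(rng, grid, frame_times, noise.drift_amp)
    for i, lab in enumerate(atlas.roi_labels):
        data[atlas.labels == lab] += amplitude * factors[:, i]
    motion = _motion_table(rng, n_frames, noise.motion_amp)
    run = BoldRun(data=data, tr_s=tr_s, voxel_mm=atlas.voxel_mm,
                  affine=atlas.affine, frame_times_s=frame_times,
                  run_label=run_label)
    return run, motion


def gen_task_bold(atlas: RoiAtlas, truth: TaskTruth,
                  noise: NoiseSpec = NoiseSpec(), tr_s: float = 2.0,
                  seed: int = 0,
                  run_label: str = "cue") -> tuple[BoldRun, np.ndarray]:
    """Cue run: window-locked HRF-convolved activations on planted ROIs.

    Every window onset must align to the frame grid. Each active ROI's
    voxels carry beta x (window boxcar convolved with the HRF); frames
    of the inter-block interval carry baseline + noise only.
    """
    truth.validate(atlas.roi_names)
    for cond, onset, dur in truth.blocks:
        for x in (onset, dur, truth.window_s):
            if abs(x / tr_s - round(x / tr_s)) > 1e-9:
                raise ValueError(
                    f"block '{cond}': onset/duration/window ({x} s) not "
                    f"aligned to TR {tr_s} s"
                )
    end_s = max(onset + dur for _, onset, dur in truth.blocks)
    n_frames = int(round(end_s / tr_s))
    frame_times = np.arange(n_frames) * tr_s

    # window regressors on an oversampled grid, exactly as the GLM builds them
    oversample = 16
    dt = tr_s / oversample
    t_hi = np.arange(0.0, frame_times[-1] + tr_s, dt)
    kernel = rat_hrf(truth.hrf, dt)
    regs = []
    for cond, onset, dur in truth.blocks:
        n_win = round(dur / truth.window_s)
        for k in range(n_win):
            w0 = onset + k * truth.window_s
            box = ((t_hi >= w0) & (t_hi < w0 + truth.window_s)).astype(float)
            reg_hi = np.convolve(box, kernel)[: t_hi.size] * dt
            regs.append(np.interp(frame_times, t_hi, reg_hi))
    regs = np.column_stack(regs)  # (frames, n_windows)

    rng = np.random.default_rng(seed)
    grid = atlas.labels.shape
    data = BASELINE + _ar1_noise(rng, grid, n_frames, noise)
    data += _drift(rng, grid, frame_times, noise.drift_amp)
    for roi, betas in truth.betas.items():
        signal = regs @ np.asarray(betas, dtype=float)
        data[atlas.mask(roi)] += signal
    motion = _motion_table(rng, n_frames, noise.motion_amp)
    run = BoldRun(data=data, tr_s=tr_s, voxel_mm=atlas.voxel_mm,
                  affine=atlas.affine, frame_times_s=frame_times,
                  run_label=run_label)
    return run, motion


def gen_behaviour(n_animals: int = 12,
                  truth: BehaviourTruth = BehaviourTruth(),
                  seed: int = 0) -> pd.DataFrame:
    """Per-animal pre/post CPP records with a planted learner fraction.

    Each animal's latent learner flag is Bernoulli(learner_fraction);
    compartment times at each phase sum exactly to the 900-s session
    (minus a drawn neutral-zone time). Learners always satisfy the
    learner rule downstream, non-learners the non-learner rule, so the
    planted class counts are recoverable exactly.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        aid = f"rat{a + 1:02d}"
        learner = bool(rng.random() < truth.learner_fraction)
        pre_rng = truth.learner_pre_frac if learner else truth.non_pre_frac
        post_rng = truth.learner_post_frac if learner else truth.non_post_frac
        for phase, frac_range in (("pre", pre_rng), ("post", post_rng)):
            neutral = float(np.clip(
                rng.normal(truth.neutral_s_mean, truth.neutral_s_sd),
                0.0, 0.5 * truth.session_s))
            active = truth.session_s - neutral
            f_m = float(rng.uniform(*frac_range))
            rows.append({
                "animal_id": aid, "phase": phase, "learner_true": learner,
                "time_morphine_s": f_m * active,
                "time_saline_s": (1.0 - f_m) * active,
                "time_neutral_s": neutral,
                "distance_cm": float(rng.normal(4000.0, 400.0)),
                "mean_speed_cm_s": float(rng.normal(5.0, 0.8)),
            })
    return pd.DataFrame(rows)


def couple_fc_to_delta(cov_base: CovSpec, deltas, pair: tuple[int, int],
                       slope: float,
                       intercept: float | None = None) -> list[CovSpec]:
    """Per-animal covariances whose pair-(i,j) Fisher z tracks CPP-delta.

    Planted population z for the pair is intercept + slope x delta
    (intercept defaults to the base matrix's z), converted back to r
    and clipped to the valid range (a clip is logged as a warning).
    Matrices that lose positive semi-definiteness are repaired to the
    nearest PSD correlation matrix (eigenvalue clipping, logged).
    """
    i, j = pair
    base = cov_base.effective()
    z0 = np.arctanh(np.clip(base[i, j], -0.999999, 0.999999)) \
        if intercept is None else intercept
    out = []
    for d in np.asarray(deltas, dtype=float):
        z = z0 + slope * d
        r = np.tanh(z)
        if abs(np.tanh(z)) >= 0.99:
            log.warning(
                "couple_fc_to_delta: planted r clipped to +/-0.99 for "
                "delta=%.3g (z=%.3g)", d, z)
            r = np.clip(r, -0.99, 0.99)
        m = base.copy()
        m[i, j] = m[j, i] = r
        w, V = np.linalg.eigh(m)
        if w.min() < 1e-10:
            log.warning("couple_fc_to_delta: nearest-PSD repair applied "
                        "(min eigenvalue %.3e)", w.min())
            w = np.clip(w, 1e-8, None)
            m = V @ np.diag(w) @ V.T
            dsqrt = np.sqrt(np.diag(m))
            m = m / np.outer(dsqrt, dsqrt)
            m[i, j] = m[j, i] = np.clip(m[i, j], -0.99, 0.99)
        np.fill_diagonal(m, 1.0)
        m = (m + m.T) / 2.0
        out.append(CovSpec(m))
    return out
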