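"""Windowed GLM activity mapping.

A single ordinary-least-squares GLM is fitted voxelwise to the cue runs,
with one regressor per 30-s window of each cue block (each a boxcar
convolved with a rat-adjusted haemodynamic response function), six motion
parameters plus the whole-brain mean as nuisance regressors, and an
intercept. Per-window contrasts and matched-window condition differences
are thresholded by Benjamini-Hochberg FDR and a cluster-extent minimum.

Multi-subject analysis concatenates runs in time with shared window
regressors and per-subject nuisance/intercept blocks, so that nuisance
variance never leaks across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import BoldRun

__all__ = [
    "HrfSpec", "DesignMatrix", "GlmFit", "StatMap", "ClusterSet",
    "rat_hrf", "build_design", "concat_designs", "fit_glm", "contrast_map",
    "matched_window_difference", "fdr_threshold", "extract_clusters",
    "active_voxel_counts", "window_column_names",
]


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma haemodynamic response, rodent defaults.

    The response gamma is parametrized so its mode falls exactly at
    ``peak_s`` (shape = 1 + peak_s/peak_disp, scale = peak_disp); the
    undershoot gamma likewise at ``undershoot_s``, scaled down by
    ``ratio``. Rodent haemodynamics are substantially faster than
    human: default peak 1.5 s vs the conventional human 6 s.
    """

    peak_s: float = 1.5
    undershoot_s: float = 7.5
    peak_disp: float = 0.35
    under_disp: float = 1.2
    ratio: float = 6.0
    length_s: float = 20.0

    def validate(self) -> None:
        if self.peak_s <= 0 or self.undershoot_s <= 0:
            raise ValueError("HRF peak/undershoot times must be positive")
        if self.peak_disp <= 0 or self.under_disp <= 0:
            raise ValueError("HRF dispersions must be positive")
        if self.ratio <= 0 or self.length_s <= self.peak_s:
            raise ValueError("degenerate HRF: non-positive ratio or too-short kernel")


def rat_hrf(spec: HrfSpec, dt_s: float) -> np.ndarray:
    """Sample the double-gamma HRF kernel at step ``dt_s``, peak-normalized to 1."""
    spec.validate()
    t = np.arange(0.0, spec.length_s + dt_s / 2, dt_s)
    pos = stats.gamma.pdf(t, a=1.0 + spec.peak_s / spec.peak_disp,
                          scale=spec.peak_disp)
    neg = stats.gamma.pdf(t, a=1.0 + spec.undershoot_s / spec.under_disp,
                          scale=spec.under_disp)
    h = pos - neg / spec.ratio
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate HRF: kernel has no positive peak")
    return h / peak


@dataclass
class DesignMatrix:
    """Frame-by-regressor matrix with named, classed columns.

    Column classes are ``window`` (one per 30-s window, named
    ``<condition>_w<k>``), ``nuisance`` (motion + global signal) and
    ``intercept`` (exactly one per subject block).
    """

    matrix: np.ndarray
    names: list[str]
    classes: list[str]
    frame_times: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names) or len(self.names) != len(self.classes):
            raise ValueError("design matrix, names and classes disagree in size")
        if self.classes.count("intercept") < 1:
            raise ValueError("design must contain an intercept column")
        zero = [n for n, col in zip(self.names, self.matrix.T)
                if not np.any(col != 0)]
        if zero:
            raise ValueError(f"all-zero design columns: {zero}")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def window_names(self) -> list[str]:
        return [n for n, c in zip(self.names, self.classes) if c == "window"]

    def column(self, name: str) -> int:
        return self.names.index(name)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        w = np.zeros(len(self.names))
        for name, val in weights.items():
            w[self.column(name)] = val
        return w


def window_column_names(blocks, window_s: float) -> list[str]:
    """Window regressor names, ``<condition>_w<index>`` (1-based per block)."""
    names = []
    for cond, onset, dur in blocks:
        n_win = round(dur / window_s)
        if abs(dur - n_win * window_s) > 1e-9:
            raise ValueError(
                f"block '{cond}' duration {dur} s not divisible by "
                f"window_s={window_s}"
            )
        names += [f"{cond}_w{k + 1:02d}" for k in range(n_win)]
    return names


def build_design(
    blocks,
    window_s: float,
    frame_times: np.ndarray,
    hrf: HrfSpec = HrfSpec(),
    motion: np.ndarray | None = None,
    global_sig: np.ndarray | None = None,
    oversample: int = 16,
) -> DesignMatrix:
    """Construct the windowed design for one run.

    Each window is a half-open boxcar [onset, onset + window_s) convolved
    with the HRF on an ``oversample``-times-finer grid, then sampled at
    the frame acquisition times. Nuisance columns (6 motion + 1 global
    signal, both mean-centred) and a single intercept follow the window
    columns.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    n = frame_times.size
    tr = np.median(np.diff(frame_times)) if n > 1 else 1.0
    dt = tr / oversample
    t_hi = np.arange(0.0, frame_times[-1] + tr, dt)
    kernel = rat_hrf(hrf, dt)

    cols, names, classes = [], [], []
    for cond, onset, dur in blocks:
        n_win = round(dur / window_s)
        if abs(dur - n_win * window_s) > 1e-9:
            raise ValueError(
                f"block '{cond}' duration {dur} s not divisible by "
                f"window_s={window_s}"
            )
        for k in range(n_win):
            w0 = onset + k * window_s
            box = ((t_hi >= w0) & (t_hi < w0 + window_s)).astype(float)
            reg_hi = np.convolve(box, kernel)[: t_hi.size] * dt
            reg = np.interp(frame_times, t_hi, reg_hi)
            cols.append(reg)
            names.append(f"{cond}_w{k + 1:02d}")
            classes.append("window")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(
                f"motion table shape {motion.shape} != ({n}, 6 parameters)"
            )
        centred = motion - motion.mean(axis=0)
        for j in range(6):
            cols.append(centred[:, j])
            names.append(f"motion_{j + 1}")
            classes.append("nuisance")
    if global_sig is not None:
        g = np.asarray(global_sig, dtype=float)
        if g.shape != (n,):
            raise ValueError(f"global signal length {g.size} != {n} frames")
        cols.append(g - g.mean())
        names.append("global_signal")
        classes.append("nuisance")

    cols.append(np.ones(n))
    names.append("intercept")
    classes.append("intercept")
    return DesignMatrix(np.column_stack(cols), names, classes, frame_times)


def concat_designs(designs: list[tuple[str, DesignMatrix]]) -> DesignMatrix:
    """Concatenate per-subject designs into one group design.

    Window columns (which must share names across subjects) are stacked
    and share a single group beta; nuisance and intercept columns are
    block-diagonal per subject (renamed ``<subject>_<name>``) so nuisance
    variance cannot leak between animals.
    """
    if not designs:
        raise ValueError("no designs to concatenate")
    win_names = designs[0][1].window_names
    for sid, d in designs:
        if d.window_names != win_names:
            raise ValueError(
                f"subject {sid}: window columns differ from first subject"
            )
    n_total = sum(d.n_frames for _, d in designs)
    win_idx = [designs[0][1].column(n) for n in win_names]

    win_block = np.vstack([d.matrix[:, win_idx] for _, d in designs])
    cols = [win_block]
    names = list(win_names)
    classes = ["window"] * len(win_names)

    offset = 0
    for sid, d in designs:
        other = [j for j, c in enumerate(d.classes) if c != "window"]
        block = np.zeros((n_total, len(other)))
        block[offset: offset + d.n_frames] = d.matrix[:, other]
        cols.append(block)
        names += [f"{sid}_{d.names[j]}" for j in other]
        classes += [d.classes[j] for j in other]
        offset += d.n_frames
    times = np.concatenate([
        d.frame_times + 1e4 * i for i, (_, d) in enumerate(designs)
    ])
    return DesignMatrix(np.hstack(cols), names, classes, times)


@dataclass
class GlmFit:
    """OLS fit: beta per (regressor, voxel), residual variance, error df."""

    beta: np.ndarray            # (n_regressors, n_voxels)
    resid_var: np.ndarray       # (n_voxels,)
    df: int
    design: DesignMatrix
    xtx_inv: np.ndarray
    shape3d: tuple | None = None
    affine: np.ndarray | None = None
    voxel_mm: np.ndarray | None = None


def fit_glm(run_or_matrix, design: DesignMatrix, *, shape3d=None,
            affine=None, voxel_mm=None) -> GlmFit:
    """Fit the GLM by ordinary least squares, voxelwise.

    Accepts a :class:`BoldRun` or a plain (frames, voxels) matrix (e.g.
    a multi-subject time concatenation, in which case the shared voxel
    grid can be passed explicitly). The design must have full column
    rank; rank-deficient designs fail naming the dependent columns.
    """
    if isinstance(run_or_matrix, BoldRun):
        shape3d = run_or_matrix.shape3d
        affine = run_or_matrix.affine
        voxel_mm = run_or_matrix.voxel_mm
        Y = run_or_matrix.data.reshape(-1, run_or_matrix.n_frames).T
    else:
        Y = np.asarray(run_or_matrix, dtype=float)
    X = design.matrix
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"data frames ({Y.shape[0]}) != design frames ({X.shape[0]})"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns implicated in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [design.names[j] for j in np.argsort(diag)[: X.shape[1] - rank]]
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]} columns); "
            f"collinear columns include {bad}"
        )
    df = X.shape[0] - rank
    if df <= 0:
        raise ValueError("no error degrees of freedom: frames <= rank(design)")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    resid_var = np.einsum("ij,ij->j", resid, resid) / df
    return GlmFit(beta, resid_var, df, design, xtx_inv, shape3d, affine, voxel_mm)


@dataclass
class StatMap:
    """A voxelwise statistic map with its p-values and sign convention."""

    stat: np.ndarray
    p: np.ndarray
    df: int
    description: str = ""
    sign_convention: str = "positive = first condition greater"
    shape3d: tuple | None = None
    affine: np.ndarray | None = None
    voxel_mm: np.ndarray | None = None

    def volume(self, which: str = "stat") -> np.ndarray:
        if self.shape3d is None:
            raise ValueError("StatMap has no 3D grid attached")
        arr = self.stat if which == "stat" else self.p
        return arr.reshape(self.shape3d)


def contrast_map(fit: GlmFit, weights, description: str = "") -> StatMap:
    """t-map for a linear contrast of the fitted betas.

    t = w'beta / sqrt(sigma^2 * w'(X'X)^{-1}w), two-sided p at fit.df.
    ``weights`` may be a vector over all regressors or a {name: weight}
    mapping over a subset.
    """
    if isinstance(weights, dict):
        w = fit.design.contrast_vector(weights)
    else:
        w = np.asarray(weights, dtype=float)
    if w.size != fit.beta.shape[0]:
        raise ValueError(
            f"contrast length {w.size} != {fit.beta.shape[0]} regressors"
        )
    effect = w @ fit.beta
    var_scale = float(w @ fit.xtx_inv @ w)
    denom = np.sqrt(np.maximum(fit.resid_var * var_scale, 1e-300))
    t = np.where(denom > 0, effect / denom, 0.0)
    if var_scale == 0.0:  # null contrast
        t = np.zeros_like(effect)
    p = 2.0 * stats.t.sf(np.abs(t), fit.df)
    return StatMap(t, p, fit.df, description, shape3d=fit.shape3d,
                   affine=fit.affine, voxel_mm=fit.voxel_mm)


def matched_window_difference(fit: GlmFit, window_index: int,
                              cond_a: str, cond_b: str) -> StatMap:
    """Condition difference for one matched window (A minus B).

    ``window_index`` is 1-based within each condition's block. Positive
    statistic means condition A greater.
    """
    name_a = f"{cond_a}_w{window_index:02d}"
    name_b = f"{cond_b}_w{window_index:02d}"
    for nm in (name_a, name_b):
        if nm not in fit.design.names:
            raise ValueError(f"window regressor '{nm}' not in design")
    sm = contrast_map(fit, {name_a: 1.0, name_b: -1.0},
                      description=f"{cond_a} - {cond_b}, window {window_index}")
    sm.sign_convention = f"positive = {cond_a} greater"
    return sm


def fdr_threshold(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up over all supplied p-values.

    Returns (rejection mask, adaptive p threshold). The threshold is the
    largest p rejected (0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if np.any((p < 0) | (p > 1)) or not (0 < q < 1):
        raise ValueError("p-values must lie in [0,1] and q in (0,1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    thresh = float(p[reject].max()) if reject.any() else 0.0
    return reject.reshape(np.shape(p_values)), thresh


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ClusterSet:
    """Retained suprathreshold clusters: label volume plus a summary table."""

    labels: np.ndarray
    sizes: list[int] = field(default_factory=list)
    volumes_mm3: list[float] = field(default_factory=list)
    peak_stats: list[float] = field(default_factory=list)
    peak_ijk: list[tuple] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def total_voxels(self) -> int:
        return int(sum(self.sizes))


def extract_clusters(mask: np.ndarray, min_voxels: int = 16,
                     connectivity: int = 6, voxel_mm=None,
                     stat: np.ndarray | None = None) -> ClusterSet:
    """Connected components of a boolean mask, dropping small clusters.

    Components are found under the requested neighbourhood (6 faces,
    18 faces+edges, or 26 full); those below ``min_voxels`` are
    discarded. Cluster volume is count x voxel volume when ``voxel_mm``
    is given; peak statistic/coordinate when ``stat`` is given.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    lab, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    out = np.zeros_like(lab)
    sizes, vols, peaks, peak_ijk = [], [], [], []
    voxvol = float(np.prod(voxel_mm)) if voxel_mm is not None else np.nan
    next_id = 0
    counts = np.bincount(lab.ravel(), minlength=n + 1)
    for k in range(1, n + 1):
        if counts[k] < min_voxels:
            continue
        next_id += 1
        sel = lab == k
        out[sel] = next_id
        sizes.append(int(counts[k]))
        vols.append(counts[k] * voxvol)
        if stat is not None:
            vals = np.where(sel, np.abs(stat), -np.inf)
            ijk = np.unravel_index(np.argmax(vals), mask.shape)
            peaks.append(float(np.asarray(stat)[ijk]))
            peak_ijk.append(tuple(int(i) for i in ijk))
    return ClusterSet(out, sizes, vols, peaks, peak_ijk)


def active_voxel_counts(fit: GlmFit, window_names: list[str] | None = None,
                        q: float = 0.05, min_voxels: int = 16,
                        connectivity: int = 6) -> dict[str, int]:
    """Surviving-voxel count per window contrast (whole-brain activation
    time course across the cue presentation).

    Each window's t-map is FDR-thresholded at ``q`` (per contrast), then
    cluster-extent thresholded; the count is the number of voxels in
    retained clusters.
    """
    if fit.shape3d is None:
        raise ValueError("active_voxel_counts needs a fit with a 3D grid")
    if window_names is None:
        window_names = fit.design.window_names
    counts = {}
    for name in window_names:
        sm = contrast_map(fit, {name: 1.0}, description=name)
        reject, _ = fdr_threshold(sm.p, q)
        cs = extract_clusters(reject.reshape(fit.shape3d), min_voxels,
                              connectivity, voxel_mm=fit.voxel_mm)
        counts[name] = cs.total_voxels()
    return counts
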