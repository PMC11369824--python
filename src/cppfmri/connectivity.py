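"""ROI-pairwise and seed-based functional connectivity with group statistics.

Per subject and condition, ROI mean time series yield a Pearson
correlation matrix and its Fisher z transform. Conditions are compared
pair-by-pair with paired t-tests, BH-FDR corrected across the C(k,2)
pairs of one comparison. Seed-based analysis correlates every brain
voxel with a seed's mean series (z maps), compares conditions with a
voxelwise paired t-test, and corrects at cluster level with a
smoothness-matched Monte-Carlo extent null. Graph outputs are node
strengths (signed sum of a node's z edges) and BrainNet-style
node/edge files; brain-behaviour coupling is a per-pair simple linear
regression of CPP-delta on connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import BoldRun, RoiAtlas
from .glm import StatMap, extract_clusters, _STRUCTURES
from . import io as _io

log = logging.getLogger("cppfmri")

__all__ = [
    "RoiTimeseries", "FcMatrix", "PairedTestResult", "SeedMap",
    "roi_timeseries", "fc_matrix", "paired_fc_test", "seed_corr_map",
    "group_seed_ttest", "cluster_level_correct", "mean_seed_fc",
    "node_strength", "strength_compare", "export_graph",
    "fc_behaviour_regression", "pair_names",
]

R_CLIP = 1.0 - 1e-7


@dataclass
class RoiTimeseries:
    """Mean BOLD series per ROI: (frames, n_rois) matrix with names."""

    data: np.ndarray
    roi_names: list[str]
    subject: str = ""
    condition: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.roi_names):
            raise ValueError("RoiTimeseries: data must be (frames, n_rois)")


@dataclass
class FcMatrix:
    """Per-subject ROI x ROI Pearson r and Fisher z for one condition.

    The diagonal of r is 1 by construction; the diagonal of z is NaN
    (self-connections are excluded from all downstream statistics).
    """

    r: np.ndarray
    z: np.ndarray
    roi_names: list[str]
    subject: str = ""
    condition: str = ""

    def pair_values(self, which: str = "z") -> np.ndarray:
        """Upper-triangle values in canonical pair order."""
        m = self.z if which == "z" else self.r
        iu = np.triu_indices(len(self.roi_names), k=1)
        return m[iu]


def pair_names(roi_names: list[str]) -> list[str]:
    """Canonical ROI-pair labels, upper-triangle order ('A-B')."""
    k = len(roi_names)
    return [f"{roi_names[i]}-{roi_names[j]}"
            for i in range(k) for j in range(i + 1, k)]


def roi_timeseries(run: BoldRun, atlas: RoiAtlas) -> RoiTimeseries:
    """Per-frame mean intensity over each ROI's voxels, in label order."""
    if atlas.labels.shape != run.shape3d:
        raise ValueError(
            f"atlas grid {atlas.labels.shape} != run grid {run.shape3d}"
        )
    cols = []
    for lab in atlas.roi_labels:
        m = atlas.labels == lab
        if not m.any():
            raise ValueError(f"ROI '{atlas.name_map[lab]}' has no voxels")
        cols.append(run.data[m].mean(axis=0))
    return RoiTimeseries(np.column_stack(cols), atlas.roi_names,
                         condition=run.run_label)


def fc_matrix(ts: RoiTimeseries) -> FcMatrix:
    """Pairwise Pearson correlations and their Fisher z transform.

    z = atanh(r) with |r| clipped to 1 - 1e-7 so duplicated series give
    a finite z at the clip value rather than infinity.
    """
    X = ts.data
    if X.shape[0] < 8:
        raise ValueError("fc_matrix needs at least 8 frames")
    sd = X.std(axis=0)
    flat = [ts.roi_names[j] for j in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance ROI series: {flat}")
    r = np.corrcoef(X.T)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    np.fill_diagonal(z, np.nan)
    return FcMatrix(r, z, list(ts.roi_names), ts.subject, ts.condition)


@dataclass
class PairedTestResult:
    """Pairwise paired-t comparison of two conditions across subjects."""

    table: pd.DataFrame       # pair, t, df, p_raw, p_adj, significant
    t_matrix: np.ndarray
    p_raw_matrix: np.ndarray
    p_adj_matrix: np.ndarray
    roi_names: list[str]
    conditions: tuple[str, str] = ("", "")


def _check_paired(a, b):
    subs_a = [m.subject for m in a]
    subs_b = [m.subject for m in b]
    if subs_a != subs_b:
        raise ValueError(
            f"subject mismatch between conditions: {subs_a} vs {subs_b}"
        )
    if len(a) < 3:
        raise ValueError("paired test needs at least 3 subjects")


def paired_fc_test(cond_a: list[FcMatrix], cond_b: list[FcMatrix],
                   q: float = 0.05) -> PairedTestResult:
    """Paired t-test per ROI pair on Fisher z, BH-FDR over the pairs.

    df = n_subjects - 1 for every pair. FDR is applied across the
    C(k,2) pairs of this one comparison.
    """
    _check_paired(cond_a, cond_b)
    names = cond_a[0].roi_names
    k = len(names)
    za = np.stack([m.pair_values() for m in cond_a])  # (subjects, pairs)
    zb = np.stack([m.pair_values() for m in cond_b])
    n = za.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(za, zb, axis=0)
    t = np.where(np.isnan(t), 0.0, np.asarray(t))   # zero-variance differences
    p = np.where(np.isnan(p), 1.0, np.asarray(p))
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    iu = np.triu_indices(k, 1)

    def to_mat(v, fill=np.nan):
        m = np.full((k, k), fill)
        m[iu] = v
        m[(iu[1], iu[0])] = v
        return m

    table = pd.DataFrame({
        "pair": pair_names(names),
        "t": t, "df": n - 1, "p_raw": p, "p_adj": p_adj,
        "significant": reject,
    })
    res = PairedTestResult(table, to_mat(t, 0.0), to_mat(p, 1.0),
                           to_mat(p_adj, 1.0), names,
                           (cond_a[0].condition, cond_b[0].condition))
    return res


@dataclass
class SeedMap:
    """Voxelwise Fisher-z correlation with one seed's mean series."""

    z: np.ndarray             # 3D volume; NaN outside brain mask
    seed: str
    subject: str = ""
    condition: str = ""
    affine: np.ndarray | None = None
    voxel_mm: np.ndarray | None = None


def seed_corr_map(run: BoldRun, seed_series: np.ndarray,
                  brain_mask: np.ndarray, seed: str = "",
                  subject: str = "", condition: str = "") -> SeedMap:
    """Voxelwise Pearson correlation with the seed series, Fisher-z'd."""
    s = np.asarray(seed_series, dtype=float)
    if s.size != run.n_frames:
        raise ValueError(
            f"seed series length {s.size} != {run.n_frames} frames"
        )
    if s.std() == 0:
        raise ValueError("zero-variance seed series")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    Y = run.data[brain_mask]                      # (voxels, frames)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((Yc ** 2).sum(axis=1)) * np.sqrt((sc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Yc @ sc / denom, 0.0)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    vol = np.full(run.shape3d, np.nan)
    vol[brain_mask] = z
    return SeedMap(vol, seed, subject, condition or run.run_label,
                   run.affine, run.voxel_mm)


def group_seed_ttest(maps_a: list[SeedMap], maps_b: list[SeedMap]) -> StatMap:
    """Voxelwise paired t comparing two conditions' seed maps.

    Positive t means the first condition's connectivity is greater.
    """
    _check_paired(maps_a, maps_b)
    A = np.stack([m.z for m in maps_a])
    B = np.stack([m.z for m in maps_b])
    n = A.shape[0]
    valid = np.isfinite(A).all(axis=0) & np.isfinite(B).all(axis=0)
    d = A - B
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(A, B, axis=0)
    t = np.where(valid, np.nan_to_num(t), np.nan)
    p = np.where(valid & np.isfinite(p), p, 1.0)
    cond = (maps_a[0].condition, maps_b[0].condition)
    return StatMap(t.ravel(), p.ravel(), n - 1,
                   description=f"seed {maps_a[0].seed}: {cond[0]} vs {cond[1]}",
                   sign_convention=f"positive = {cond[0]} greater",
                   shape3d=A.shape[1:], affine=maps_a[0].affine,
                   voxel_mm=maps_a[0].voxel_mm)


def _estimate_fwhm_vox(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-axis smoothness (FWHM in voxels) from normalized gradients.

    Classic residual-smoothness estimator: FWHM_k = sqrt(4 ln2 / var(dx_k))
    for a unit-variance field. Clipped to [1, 8] voxels for stability on
    small grids.
    """
    v = np.where(mask, vol, np.nan)
    v = (v - np.nanmean(v)) / (np.nanstd(v) + 1e-12)
    fwhm = []
    for ax in range(3):
        d = np.diff(v, axis=ax)
        var = np.nanvar(d)
        if not np.isfinite(var) or var <= 0:
            fwhm.append(1.0)
            continue
        fwhm.append(float(np.sqrt(4.0 * np.log(2.0) / min(var, 4 * np.log(2)))))
    return np.clip(np.asarray(fwhm), 1.0, 8.0)


def cluster_level_correct(stat_map: StatMap, voxel_p: float = 0.05,
                          cluster_p: float = 0.05, n_null: int = 1000,
                          seed: int = 0, connectivity: int = 6,
                          brain_mask: np.ndarray | None = None,
                          fwhm_vox: np.ndarray | None = None,
                          null_extents: np.ndarray | None = None):
    """One-tailed voxel threshold plus Monte-Carlo cluster-extent correction.

    Voxels exceeding the one-tailed ``voxel_p`` t threshold form
    candidate clusters; the null distribution of the maximum cluster
    extent is built from ``n_null`` smoothness-matched Gaussian random
    fields on the same grid, and clusters whose extent exceeds the
    (1 - cluster_p) null quantile are retained. This is a documented
    Monte-Carlo substitute for closed-form random-field theory: it
    controls the same family-wise cluster error and is fully testable.

    A precomputed ``null_extents`` vector may be supplied to share one
    null table across maps of equal smoothness.
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must lie in (0,1)")
    if null_extents is None and n_null < 100:
        raise ValueError(f"n_null must be >= 100, got {n_null}")
    if stat_map.shape3d is None:
        raise ValueError("stat map has no 3D grid")
    vol = stat_map.volume("stat")
    if brain_mask is None:
        brain_mask = np.isfinite(vol)
    t_crit = stats.t.ppf(1.0 - voxel_p, stat_map.df)
    supra = np.where(brain_mask, vol, -np.inf) > t_crit

    if null_extents is None:
        if fwhm_vox is None:
            fwhm_vox = _estimate_fwhm_vox(vol, brain_mask)
        null_extents = simulate_null_extents(
            brain_mask, fwhm_vox, voxel_p, n_null, seed,
            connectivity=connectivity, df=stat_map.df)
    k_crit = float(np.quantile(null_extents, 1.0 - cluster_p))

    cs = extract_clusters(supra, min_voxels=int(np.floor(k_crit)) + 1,
                          connectivity=connectivity,
                          voxel_mm=stat_map.voxel_mm, stat=vol)
    thresh_vol = np.where(cs.labels > 0, vol, 0.0)
    out = StatMap(thresh_vol.ravel(), stat_map.p, stat_map.df,
                  stat_map.description + " [cluster-corrected]",
                  stat_map.sign_convention, stat_map.shape3d,
                  stat_map.affine, stat_map.voxel_mm)
    return out, cs


def simulate_null_extents(brain_mask: np.ndarray, fwhm_vox, voxel_p: float,
                          n_null: int, seed: int, connectivity: int = 6,
                          df: int | None = None) -> np.ndarray:
    """Max suprathreshold cluster extents of smoothness-matched null fields.

    With ``df`` given, each null field is the one-sample t statistic of
    df + 1 independent smoothed Gaussian fields, thresholded at the
    one-tailed ``voxel_p`` t quantile — matching both the smoothness and
    the heavier spatial clustering of low-df t maps. Without ``df`` a
    single standardized Gaussian field is thresholded at the z quantile.
    """
    rng = np.random.default_rng(seed)
    sigma = np.asarray(fwhm_vox, dtype=float) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    extents = np.empty(n_null)
    struct = _STRUCTURES[connectivity]
    if df is None:
        crit = stats.norm.ppf(1.0 - voxel_p)
    else:
        crit = stats.t.ppf(1.0 - voxel_p, df)
    for i in range(n_null):
        if df is None:
            field = ndimage.gaussian_filter(
                rng.standard_normal(brain_mask.shape), sigma=sigma,
                mode="reflect")
            vals = field[brain_mask]
            field = (field - vals.mean()) / vals.std()
        else:
            n_sub = df + 1
            samples = ndimage.gaussian_filter(
                rng.standard_normal((n_sub, *brain_mask.shape)),
                sigma=(0.0, *sigma), mode="reflect")
            sd = samples.std(axis=0, ddof=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                field = np.where(sd > 0,
                                 samples.mean(axis=0) / (sd / np.sqrt(n_sub)),
                                 0.0)
        supra = brain_mask & (field > crit)
        lab, n = ndimage.label(supra, structure=struct)
        extents[i] = np.bincount(lab.ravel())[1:].max() if n else 0
    return extents


def mean_seed_fc(seed_map: SeedMap, brain_mask: np.ndarray,
                 seed_mask: np.ndarray | None = None) -> float:
    """Mean z over the brain mask, excluding the seed's own voxels.

    The quantity summarizing a seed's intra-network relevance: average
    connectivity of the seed with every other voxel in the brain.
    """
    m = np.asarray(brain_mask, dtype=bool).copy()
    if seed_mask is not None:
        m &= ~np.asarray(seed_mask, dtype=bool)
    m &= np.isfinite(seed_map.z)
    if not m.any():
        raise ValueError("empty mask after seed exclusion")
    return float(seed_map.z[m].mean())


def node_strength(fc: FcMatrix, use_abs: bool = False,
                  atol: float = 1e-8) -> pd.Series:
    """Node centrality: the sum of each ROI's connections.

    strength_i = sum_{j != i} z_ij, signed by default (negative edges
    subtract); ``use_abs=True`` sums |z| instead. The z matrix must be
    symmetric to ``atol``.
    """
    z = np.array(fc.z, dtype=float)
    np.fill_diagonal(z, 0.0)
    if not np.allclose(z, z.T, atol=atol, equal_nan=True):
        raise ValueError("connectivity matrix asymmetric beyond tolerance")
    if use_abs:
        z = np.abs(z)
    return pd.Series(np.nansum(z, axis=1), index=fc.roi_names, name="strength")


def strength_compare(strengths_a: pd.DataFrame,
                     strengths_b: pd.DataFrame) -> pd.DataFrame:
    """Per-ROI two-tailed paired t on node strengths (rows = subjects)."""
    if list(strengths_a.index) != list(strengths_b.index):
        raise ValueError("subject mismatch between strength tables")
    if list(strengths_a.columns) != list(strengths_b.columns):
        raise ValueError("ROI mismatch between strength tables")
    n = len(strengths_a)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(strengths_a.to_numpy(),
                               strengths_b.to_numpy(), axis=0)
    return pd.DataFrame({
        "roi": strengths_a.columns, "t": np.where(np.isnan(t), 0.0, t),
        "df": n - 1, "p": np.where(np.isnan(p), 1.0, p),
    })


def export_graph(z_matrix: np.ndarray, roi_names: list[str], coords_mm,
                 strengths, edge_threshold_z: float,
                 node_path, edge_path) -> None:
    """Write BrainNet-style node and edge files.

    Node colour and size are the node strength (colour rescaled to [0,1]
    across the present nodes, mirroring a jet colour-map code anchored
    at the least and most central node). Edges with |z| below the
    threshold are zeroed; the threshold is a visualization choice.
    """
    z = np.array(z_matrix, dtype=float)
    np.fill_diagonal(z, 0.0)
    k = len(roi_names)
    coords = [np.asarray(coords_mm[name]) for name in roi_names]
    if len(coords) != k:
        raise ValueError("coordinates missing for some ROIs")
    s = np.asarray(strengths, dtype=float)
    span = s.max() - s.min()
    colours = (s - s.min()) / span if span > 0 else np.full(k, 0.5)
    _io.write_node_file(node_path, coords, s, colours, roi_names)
    edges = np.where(np.abs(z) >= edge_threshold_z, z, 0.0)
    _io.write_edge_file(edge_path, edges)


def fc_behaviour_regression(table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Simple linear regression of connectivity on CPP-delta, per ROI pair.

    ``table`` has one row per (subject, pair, condition) with columns
    ``cpp_delta_s`` and ``z`` (from behaviour_fc_regression_input). For
    each (pair, condition): slope, intercept, Pearson r, R^2 and the
    two-sided p of the regression, plus BH-adjusted p across pairs
    within each condition. Both raw and adjusted p are reported.
    """
    rows = []
    for (pair, cond), grp in table.groupby(["pair", "condition"], sort=True):
        x = grp["cpp_delta_s"].to_numpy(dtype=float)
        y = grp["z"].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"pair {pair}/{cond}: fewer than 3 subjects")
        if np.ptp(x) == 0:
            raise ValueError(f"pair {pair}/{cond}: constant predictor")
        res = stats.linregress(x, y)
        rows.append({
            "pair": pair, "condition": cond, "n": x.size,
            "slope": res.slope, "intercept": res.intercept,
            "pearson_r": res.rvalue, "r_squared": res.rvalue ** 2,
            "p_raw": res.pvalue,
        })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for cond, grp in out.groupby("condition"):
        _, p_adj, _, _ = multipletests(grp["p_raw"], alpha=q, method="fdr_bh")
        out.loc[grp.index, "p_adj"] = p_adj
    return out
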