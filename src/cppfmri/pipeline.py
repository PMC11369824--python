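"""End-to-end orchestration: simulate a cohort, run every analysis stage,
and write the result bundle.

``simulate_cohort`` writes a complete synthetic study (atlas, per-subject
resting and cue runs, motion tables, behaviour table, ground-truth file,
manifest) and ``run_pipeline`` consumes a manifest and writes stat maps,
FC matrices, graph files, regression tables and a provenance log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour as beh
from . import connectivity as conn
from . import glm as glm_mod
from . import io as io_mod
from . import preprocess as prep
from . import synth
from .core import AnalysisConfig, RoiAtlas

log = logging.getLogger("cppfmri")

__all__ = ["simulate_cohort", "run_pipeline", "default_network_cov"]

MANIFEST_COLS = ["subject", "rest_pre", "rest_post", "cue", "motion_cue",
                 "behaviour"]


def default_network_cov(n_rois: int = 10, background_r: float = 0.1,
                        strong_pairs=((1, 7), (2, 7), (0, 4), (8, 9)),
                        strong_r: float = 0.4) -> synth.CovSpec:
    """A modular planted network: weak background correlation everywhere
    plus a few strong pairs (by default including LSI-CA1 and LHb-CA1,
    the septo- and habenulo-hippocampal edges of interest)."""
    m = np.full((n_rois, n_rois), background_r)
    np.fill_diagonal(m, 1.0)
    for i, j in strong_pairs:
        m[i, j] = m[j, i] = strong_r
    w = np.linalg.eigvalsh(m)
    if w.min() < 1e-8:  # repair should never trigger for the defaults
        wv, V = np.linalg.eigh(m)
        m = V @ np.diag(np.clip(wv, 1e-6, None)) @ V.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
    return synth.CovSpec((m + m.T) / 2.0)


def _subject_seed(base_seed: int, subject_idx: int, stream: int) -> int:
    return (base_seed * 10007 + subject_idx * 101 + stream) % (2 ** 31 - 1)


def simulate_cohort(out_dir, n_subjects: int = 12, seed: int = 0,
                    config: AnalysisConfig | None = None,
                    grid=(32, 32, 16), roi_radius_vox: int = 2,
                    n_frames_rest: int = 300, tr_s: float = 2.0,
                    noise: synth.NoiseSpec = synth.NoiseSpec(),
                    task_beta: float = 1.5,
                    active_rois=("ACo", "CeA", "Cg"),
                    fc_slope: float = 0.0014,
                    fc_pair_idx: tuple[int, int] = (1, 7),
                    learner_fraction: float = 7.0 / 12.0) -> Path:
    """Write a full synthetic study cohort and its manifest.

    Resting covariance before CPP is coupled to each animal's CPP-delta
    for one ROI pair (default LSI-CA1) with the planted Fisher-z slope;
    post-CPP rest adds a global coupling increase for that pair's seed
    region. Cue runs activate ``active_rois`` in every morphine-context
    window at amplitude ``task_beta`` (saline-context windows at half).
    Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or AnalysisConfig(rng_seed=seed)
    cfg.validate(tr_s)

    atlas = synth.gen_atlas(grid, n_rois=len(cfg.roi_list),
                            roi_radius_vox=roi_radius_vox, seed=seed,
                            names=list(cfg.roi_list))
    io_mod.write_atlas(atlas, out / "atlas.nii.gz", out / "atlas_names.csv")

    btruth = synth.BehaviourTruth(learner_fraction=learner_fraction,
                                  fc_slope=fc_slope)
    behaviour_tab = synth.gen_behaviour(n_subjects, btruth, seed=seed + 1)
    behaviour_path = out / "behaviour.csv"
    behaviour_tab.to_csv(behaviour_path, index=False)
    scores = beh.score_cohort(behaviour_tab)
    deltas = scores.sort_values("animal_id")["cpp_delta_s"].to_numpy()

    cov_pre = default_network_cov(atlas.n_rois)
    covs_pre = synth.couple_fc_to_delta(cov_pre, deltas, fc_pair_idx, fc_slope)
    # post-CPP: the coupled pair strengthens uniformly across animals
    i, j = fc_pair_idx
    post_base = cov_pre.matrix.copy()
    post_base[i, j] = post_base[j, i] = min(post_base[i, j] + 0.25, 0.9)
    cov_post = synth.CovSpec(post_base)

    n_windows_half = cfg.n_windows // 2
    betas = {}
    for roi in active_rois:
        b = np.concatenate([np.full(n_windows_half, task_beta),
                            np.full(cfg.n_windows - n_windows_half,
                                    task_beta / 2.0)])
        betas[roi] = b
    ttruth = synth.TaskTruth(blocks=cfg.block_schedule, window_s=cfg.window_s,
                             betas=betas)

    rows = []
    subjects = sorted(scores["animal_id"])
    for s_idx, sid in enumerate(subjects):
        run_pre, _ = synth.gen_rest_bold(
            atlas, covs_pre[s_idx], n_frames_rest, tr_s, noise,
            seed=_subject_seed(seed, s_idx, 1), run_label="rest_pre")
        run_post, _ = synth.gen_rest_bold(
            atlas, cov_post, n_frames_rest, tr_s, noise,
            seed=_subject_seed(seed, s_idx, 2), run_label="rest_post")
        run_cue, motion_cue = synth.gen_task_bold(
            atlas, ttruth, noise, tr_s,
            seed=_subject_seed(seed, s_idx, 3), run_label="cue")
        paths = {}
        for tag, run in (("rest_pre", run_pre), ("rest_post", run_post),
                         ("cue", run_cue)):
            p = out / f"{sid}_{tag}.nii.gz"
            io_mod.write_bold(run, p)
            paths[tag] = p.name
        mp = out / f"{sid}_motion_cue.txt"
        io_mod.write_motion(motion_cue, mp)
        rows.append({"subject": sid, **paths, "motion_cue": mp.name,
                     "behaviour": behaviour_path.name})

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLS)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    io_mod.write_config(cfg, out / "config.yaml")

    truth = {
        "seed": seed, "n_subjects": n_subjects, "tr_s": tr_s,
        "learner_fraction": learner_fraction,
        "learner_true": {r.animal_id: bool(r.learner_true)
                         for r in behaviour_tab.drop_duplicates(
                             "animal_id").itertuples()},
        "fc_slope": fc_slope,
        "fc_pair": [cfg.roi_list[i], cfg.roi_list[j]],
        "task_beta": task_beta, "active_rois": list(active_rois),
        "cov_pre_base": cov_pre.matrix.tolist(),
        "cov_post": cov_post.matrix.tolist(),
    }
    with open(out / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    return manifest_path


def _load_manifest(manifest) -> pd.DataFrame:
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if manifest.empty:
        raise ValueError("manifest is empty: nothing to analyse")
    missing_cols = [c for c in MANIFEST_COLS if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns: {missing_cols}")
    return manifest


def run_pipeline(config: AnalysisConfig, manifest, out_dir,
                 atlas: RoiAtlas | None = None, base_dir=None,
                 overwrite: bool = False, glm_stage: bool = True) -> dict:
    """Run every analysis stage over a manifest and write the bundle.

    Stages: preprocessing (smooth; band-pass for the FC path), per-subject
    FC matrices for rest_pre/rest_post, paired FC tests, node strengths
    and graph export, the concatenated multi-subject windowed GLM with
    per-window contrast maps and active-voxel counts, behaviour scoring,
    and the FC-vs-CPP-delta regression screen. Returns a dict of the
    main in-memory results.
    """
    manifest = _load_manifest(manifest)
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True to "
            f"replace its contents"
        )
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else None

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() or base is None else base / p

    # per-subject input validation with named errors
    for row in manifest.itertuples():
        for col in ("rest_pre", "rest_post", "cue", "motion_cue", "behaviour"):
            p = resolve(getattr(row, col))
            if not p.exists():
                raise FileNotFoundError(
                    f"subject {row.subject}: missing {col} file {p}"
                )

    if atlas is None:
        raise ValueError("an RoiAtlas is required (pass atlas=...)")
    cfg = config
    spec = prep.FilterSpec(*cfg.bandpass_hz)

    # ---- behaviour ----
    behaviour_tab = pd.read_csv(resolve(manifest["behaviour"].iloc[0]))
    scores = beh.score_cohort(behaviour_tab)
    scores.to_csv(out / "cpp_scores.csv", index=False)

    # ---- FC path: smooth -> band-pass -> ROI series -> FC per condition ----
    fcs = {"rest_pre": [], "rest_post": []}
    for row in manifest.itertuples():
        for cond in ("rest_pre", "rest_post"):
            run = io_mod.read_bold(resolve(getattr(row, cond)),
                                   run_label=cond)
            cfg.validate(run.tr_s)
            run = prep.gaussian_smooth(
                run, cfg.smooth_fwhm_factor * run.voxel_mm)
            run = prep.bandpass(run, spec)
            ts = conn.roi_timeseries(run, atlas)
            ts.subject = str(row.subject)
            ts.condition = cond
            fc = conn.fc_matrix(ts)
            fcs[cond].append(fc)
            io_mod.write_matrix(
                fc.z, out / f"{row.subject}_{cond}_fc_z.csv", fc.roi_names)

    paired = conn.paired_fc_test(fcs["rest_post"], fcs["rest_pre"], cfg.fdr_q)
    paired.table.to_csv(out / "fc_paired_post_vs_pre.csv", index=False)
    io_mod.write_matrix(paired.p_adj_matrix, out / "fc_p_adj_matrix.csv",
                        paired.roi_names)

    strengths = {
        cond: pd.DataFrame(
            [conn.node_strength(m) for m in fcs[cond]],
            index=[m.subject for m in fcs[cond]])
        for cond in fcs
    }
    strength_cmp = conn.strength_compare(strengths["rest_post"],
                                         strengths["rest_pre"])
    strength_cmp.to_csv(out / "node_strength_post_vs_pre.csv", index=False)

    group_z = np.mean([m.z for m in fcs["rest_post"]], axis=0)
    mean_strength = strengths["rest_post"].mean(axis=0).to_numpy()
    conn.export_graph(group_z, atlas.roi_names, atlas.coords_mm,
                      mean_strength, cfg.edge_threshold_z,
                      out / "graph_post.node", out / "graph_post.edge")

    # ---- GLM path: smooth -> concatenated multi-subject windowed GLM ----
    results = {"scores": scores, "paired": paired,
               "strength_compare": strength_cmp, "fcs": fcs}
    if glm_stage:
        designs, mats = [], []
        shape3d = affine = voxel_mm = None
        for row in manifest.itertuples():
            run = io_mod.read_bold(resolve(row.cue), run_label="cue")
            cfg.validate(run.tr_s)
            run = prep.gaussian_smooth(
                run, cfg.smooth_fwhm_factor * run.voxel_mm)
            if cfg.bandpass_glm:
                run = prep.bandpass(run, spec)
            motion = io_mod.read_motion(resolve(row.motion_cue))
            gsig = prep.global_signal(run, np.ones(run.shape3d, dtype=bool))
            d = glm_mod.build_design(cfg.block_schedule, cfg.window_s,
                                     run.frame_times_s, motion=motion,
                                     global_sig=gsig)
            designs.append((str(row.subject), d))
            mats.append(run.data.reshape(-1, run.n_frames).T)
            shape3d, affine, voxel_mm = run.shape3d, run.affine, run.voxel_mm
        gdesign = glm_mod.concat_designs(designs)
        fit = glm_mod.fit_glm(np.vstack(mats), gdesign, shape3d=shape3d,
                              affine=affine, voxel_mm=voxel_mm)
        for name in gdesign.window_names:
            sm = glm_mod.contrast_map(fit, {name: 1.0}, description=name)
            io_mod.write_volume(sm.volume("stat"), affine,
                                out / f"contrast_{name}_t.nii.gz")
        counts = glm_mod.active_voxel_counts(
            fit, q=cfg.fdr_q, min_voxels=cfg.cluster_min_voxels)
        pd.DataFrame({"window": list(counts), "n_voxels": list(counts.values())}
                     ).to_csv(out / "active_voxel_counts.csv", index=False)
        results["fit"] = fit
        results["active_voxel_counts"] = counts

    # ---- brain-behaviour regression screen (resting conditions) ----
    reg_input = beh.behaviour_fc_regression_input(
        scores, fcs["rest_pre"] + fcs["rest_post"])
    reg = conn.fc_behaviour_regression(reg_input, cfg.fdr_q)
    reg.to_csv(out / "fc_cpp_regression.csv", index=False)
    results["regression"] = reg

    # ---- provenance ----
    import cppfmri
    prov = {
        "package_version": getattr(cppfmri, "__version__", "unknown"),
        "numpy_version": np.__version__,
        "rng_seed": cfg.rng_seed,
        "n_subjects": int(len(manifest)),
        "config": yaml.safe_load(io_mod.write_config(cfg, out / "config_used.yaml").read_text()),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2)
    return results
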