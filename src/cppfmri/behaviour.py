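"""Conditioned-place-preference scoring and the odour-screening metric.

CPP-delta is the change, in seconds, of the time an animal spends in
the morphine-paired compartment from pre- to post-conditioning during
a 15-min free-exploration test. An animal is a 'learner' when its
CPP-delta is positive and it spends more than half of its
conditioning-compartment time on the morphine side at test; a
'non-learner' shows the reverse on both counts. The two rules do not
partition all cases, so the rule gap is an explicit third class rather
than a guess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviourRecord", "CppScore", "cpp_delta", "post_morphine_fraction",
    "classify_learner", "score_cpp", "score_cohort", "locomotion_summary",
    "odour_preference", "behaviour_fc_regression_input",
]

SESSION_S = 900.0  # 15-min pre/post test session


@dataclass
class BehaviourRecord:
    """One animal x session summary from the tracking system export."""

    animal_id: str
    phase: str                      # 'pre', 'post' or 'conditioning_day_k'
    time_saline_s: float
    time_morphine_s: float
    time_neutral_s: float = 0.0
    distance_cm: float = np.nan
    mean_speed_cm_s: float = np.nan

    def __post_init__(self):
        for f in ("time_saline_s", "time_morphine_s", "time_neutral_s"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.animal_id}/{self.phase}: {f} negative")

    @property
    def total_s(self) -> float:
        return self.time_saline_s + self.time_morphine_s + self.time_neutral_s


@dataclass
class CppScore:
    """Per-animal behavioural outcome of the CPP test."""

    animal_id: str
    cpp_delta_s: float
    post_morphine_fraction: float
    label: str = ""

    def __post_init__(self):
        if not 0.0 <= self.post_morphine_fraction <= 1.0:
            raise ValueError("post_morphine_fraction must lie in [0,1]")
        if not self.label:
            self.label = classify_learner(self.cpp_delta_s,
                                          self.post_morphine_fraction)


def cpp_delta(pre: BehaviourRecord, post: BehaviourRecord) -> float:
    """Morphine-compartment time at post minus at pre (seconds)."""
    if pre.animal_id != post.animal_id:
        raise ValueError(
            f"animal mismatch: pre={pre.animal_id!r} post={post.animal_id!r}"
        )
    return post.time_morphine_s - pre.time_morphine_s


def post_morphine_fraction(post: BehaviourRecord) -> float:
    """Fraction of conditioning-compartment time spent on the morphine side.

    Computed over the two conditioning compartments only; the neutral
    zone is excluded, since the classification rule concerns permanence
    in the paired compartments.
    """
    denom = post.time_morphine_s + post.time_saline_s
    if denom <= 0:
        raise ValueError(f"{post.animal_id}: no compartment time at post")
    return post.time_morphine_s / denom


def classify_learner(delta_s: float, fraction: float) -> str:
    """Learner rule: delta > 0 and >50% morphine-side permanence.

    Non-learner: delta < 0 and <50% permanence. Any other combination
    is 'ambiguous' (the rules leave a gap; we refuse to guess).
    """
    if delta_s > 0 and fraction > 0.5:
        return "learner"
    if delta_s < 0 and fraction < 0.5:
        return "non_learner"
    return "ambiguous"


def score_cpp(pre: BehaviourRecord, post: BehaviourRecord) -> CppScore:
    """CPP-delta, permanence fraction and class label for one animal."""
    delta = cpp_delta(pre, post)
    frac = post_morphine_fraction(post)
    return CppScore(pre.animal_id, delta, frac)


def score_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Score every animal of a long-format behaviour table.

    Expects one row per animal x phase with columns ``animal_id, phase,
    time_saline_s, time_morphine_s`` (``time_neutral_s`` optional);
    phases 'pre' and 'post' are used.
    """
    out = []
    for aid, grp in records.groupby("animal_id", sort=True):
        recs = {}
        for phase in ("pre", "post"):
            sel = grp[grp["phase"] == phase]
            if len(sel) != 1:
                raise ValueError(f"animal {aid}: need exactly one '{phase}' row")
            row = sel.iloc[0]
            recs[phase] = BehaviourRecord(
                str(aid), phase,
                float(row["time_saline_s"]), float(row["time_morphine_s"]),
                float(row.get("time_neutral_s", 0.0)),
            )
        s = score_cpp(recs["pre"], recs["post"])
        out.append({
            "animal_id": s.animal_id, "cpp_delta_s": s.cpp_delta_s,
            "post_morphine_fraction": s.post_morphine_fraction,
            "label": s.label,
        })
    return pd.DataFrame(out)


def locomotion_summary(traces: dict, dt_s: float,
                       rest_speed_cm_s: float = 2.0) -> pd.DataFrame:
    """Distance and rest-excluded mean speed per (session, compartment).

    ``traces`` maps (session, compartment) to a uniformly sampled speed
    trace (cm/s). Distance is the trace integral; mean speed averages
    only samples above the rest threshold ('without rest' — the
    threshold defaults to 2 cm/s and is configurable because rest is
    not otherwise defined).
    """
    rows = []
    for (session, compartment), speeds in sorted(traces.items()):
        v = np.asarray(speeds, dtype=float)
        if v.size == 0:
            raise ValueError(f"empty speed trace for {session}/{compartment}")
        moving = v[v > rest_speed_cm_s]
        rows.append({
            "session": session, "compartment": compartment,
            "distance_cm": float(np.sum(v) * dt_s),
            "mean_speed_cm_s": float(moving.mean()) if moving.size else 0.0,
            "frac_resting": float(np.mean(v <= rest_speed_cm_s)),
        })
    return pd.DataFrame(rows)


def odour_preference(trials: pd.DataFrame) -> pd.Series:
    """Normalized odourant preference for one screening day.

    pref_i = (t_i / sum_j t_j) / t_water: each odourant's share of the
    total investigation time, divided by that day's water exploration
    time. Expects columns ``odourant, investigation_time_s, water_time_s``
    (water time constant within the day).
    """
    t = trials["investigation_time_s"].to_numpy(dtype=float)
    if np.any(t < 0):
        raise ValueError("negative investigation time")
    total = t.sum()
    if total <= 0:
        raise ValueError("total investigation time is zero")
    water = float(trials["water_time_s"].iloc[0])
    if water <= 0:
        raise ValueError("water exploration time must be positive")
    pref = (t / total) / water
    return pd.Series(pref, index=trials["odourant"].to_numpy(), name="preference")


def behaviour_fc_regression_input(scores: pd.DataFrame,
                                  fcs: list) -> pd.DataFrame:
    """Align CPP scores with per-subject FC for the brain-behaviour screen.

    One output row per (subject, ROI pair, condition), with that
    subject's CPP-delta and the pair's Fisher z. Subject sets must
    match exactly; input order is irrelevant.
    """
    from .connectivity import pair_names  # local import avoids cycle

    score_ids = sorted(scores["animal_id"].astype(str))
    fc_ids = sorted({m.subject for m in fcs})
    if score_ids != sorted(fc_ids):
        only_s = set(score_ids) - set(fc_ids)
        only_f = set(fc_ids) - set(score_ids)
        raise ValueError(
            f"subject mismatch: behaviour-only {sorted(only_s)}, "
            f"fc-only {sorted(only_f)}"
        )
    delta = scores.set_index(scores["animal_id"].astype(str))["cpp_delta_s"]
    rows = []
    for m in sorted(fcs, key=lambda m: (m.condition, m.subject)):
        pnames = pair_names(m.roi_names)
        for pair, z in zip(pnames, m.pair_values("z")):
            rows.append({
                "subject": m.subject, "condition": m.condition, "pair": pair,
                "cpp_delta_s": float(delta[m.subject]), "z": float(z),
            })
    return pd.DataFrame(rows)
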