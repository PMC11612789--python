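"""Behavioural-context attribution and call rates.

Calls are aligned to interval behaviour annotations (the confrontation
ethogram: avoidance, box, caravanning, combination, socio-negative
interaction, wire mesh, no physical interaction).  When several events
contain a call, actual interactions take precedence over position-related
events; the full priority order is explicit and configurable.  Context
shares, proximity shares and per-experiment call rates (N/min) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorEvent", "DyadExperiment", "DEFAULT_PRIORITY", "align_calls",
    "proximity_shares", "behavior_shares", "call_rates",
]

ETHOGRAM = ("avoidance", "box", "caravanning", "combination",
            "socio_negative", "wire_mesh", "no_physical_interaction")

# interactions outrank position-in-arena events
DEFAULT_PRIORITY = ("socio_negative", "combination", "caravanning",
                    "avoidance", "box", "wire_mesh", "no_physical_interaction")


@dataclass(frozen=True)
class BehaviorEvent:
    experiment_id: str
    category: str
    onset: float
    offset: float
    phase: str = "open_door"

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("event offset must exceed onset")
        if self.category not in ETHOGRAM:
            raise ValueError(f"unknown ethogram category {self.category!r}")


@dataclass(frozen=True)
class DyadExperiment:
    experiment_id: str
    individual_1: str
    individual_2: str
    sex_composition: str   # MM | FF | MF
    familiarity: str       # familiar | unfamiliar
    housing_type: str      # pair | same_sex_group
    closed_door_min: float
    open_door_min: float

    def __post_init__(self) -> None:
        if self.closed_door_min <= 0 or self.open_door_min <= 0:
            raise ValueError("phase durations must be positive")


def align_calls(calls: pd.DataFrame, events: pd.DataFrame,
                priority: tuple[str, ...] = DEFAULT_PRIORITY,
                time_col: str = "onset") -> pd.DataFrame:
    """Attach the single highest-priority behaviour containing each call.

    A call belongs to an event when its onset (configurable to midpoint via
    ``time_col``) lies inside the event interval; calls in no event get
    ``no_physical_interaction``.  Matching is within ``experiment_id``.
    """
    unknown = set(events["category"]) - set(ETHOGRAM)
    if unknown:
        raise ValueError(f"unknown ethogram categories in events: {sorted(unknown)}")
    rank = {cat: i for i, cat in enumerate(priority)}
    out = calls.copy()
    labels = []
    for row in out.itertuples():
        t = getattr(row, time_col)
        ev = events[(events["experiment_id"] == row.experiment_id)
                    & (events["onset"] <= t) & (t < events["offset"])]
        if len(ev) == 0:
            labels.append("no_physical_interaction")
        else:
            labels.append(min(ev["category"], key=lambda c: rank.get(c, len(rank))))
    out["behavior"] = labels
    return out


def proximity_shares(calls: pd.DataFrame,
                     proximity_intervals: pd.DataFrame,
                     buffer_s: float = 1.0,
                     type_col: str = "call_type") -> pd.DataFrame:
    """Per call type, the percentage of calls emitted in proximity, within
    one second of a proximity interval, and outside.

    The three buckets are mutually exclusive and sum to 100 % per call type.
    Because it is ambiguous whether "in proximity" should absorb the +/-1 s
    buffer, the table also reports ``in_proximity_incl_buffer``.
    """
    rows = []
    for ctype, grp in calls.groupby(type_col):
        buckets = {"in_proximity": 0, "within_1s": 0, "outside": 0}
        for row in grp.itertuples():
            iv = proximity_intervals[
                proximity_intervals["experiment_id"] == row.experiment_id]
            t = row.onset
            inside = ((iv["onset"] <= t) & (t < iv["offset"])).any()
            if inside:
                buckets["in_proximity"] += 1
            elif ((iv["onset"] - buffer_s <= t) & (t < iv["offset"] + buffer_s)).any():
                buckets["within_1s"] += 1
            else:
                buckets["outside"] += 1
        n = len(grp)
        rows.append({
            type_col: ctype,
            "n_calls": n,
            "in_proximity": 100.0 * buckets["in_proximity"] / n,
            "within_1s": 100.0 * buckets["within_1s"] / n,
            "outside": 100.0 * buckets["outside"] / n,
            "in_proximity_incl_buffer":
                100.0 * (buckets["in_proximity"] + buckets["within_1s"]) / n,
        })
    return pd.DataFrame(rows)


def behavior_shares(annotated_calls: pd.DataFrame,
                    type_col: str = "call_type",
                    behavior_col: str = "behavior") -> pd.DataFrame:
    """Call-type percentage shares per behaviour (rows sum to 100 %);
    behaviours with zero calls are omitted."""
    counts = (annotated_calls.groupby([behavior_col, type_col]).size()
              .unstack(fill_value=0))
    shares = counts.div(counts.sum(axis=1), axis=0) * 100.0
    shares["n_calls"] = counts.sum(axis=1)
    return shares.reset_index()


def call_rates(calls: pd.DataFrame, experiments: pd.DataFrame,
               phase: str = "open_door",
               type_col: str = "call_type") -> pd.DataFrame:
    """Calls per minute per call type per experiment (count / phase
    duration), with explicit zero rows for types an experiment lacks."""
    dur_col = f"{phase.rstrip('_phase')}_min" if not phase.endswith("_min") else phase
    if dur_col not in experiments.columns:
        dur_col = {"open_door": "open_door_min",
                   "closed_door": "closed_door_min"}[phase]
    if (experiments[dur_col] <= 0).any():
        bad = experiments.loc[experiments[dur_col] <= 0, "experiment_id"].tolist()
        raise ValueError(f"non-positive phase duration for experiment(s) {bad}")
    types = sorted(calls[type_col].dropna().unique())
    rows = []
    for exp in experiments.itertuples():
        sub = calls[calls["experiment_id"] == exp.experiment_id]
        minutes = float(getattr(exp, dur_col))
        for t in types:
            n = int((sub[type_col] == t).sum())
            rows.append({
                "experiment_id": exp.experiment_id,
                type_col: t,
                "n_calls": n,
                "rate_per_min": n / minutes,
                "sex_composition": exp.sex_composition,
                "familiarity": exp.familiarity,
                "housing_type": exp.housing_type,
                "individual_1": exp.individual_1,
                "individual_2": exp.individual_2,
            })
    return pd.DataFrame(rows)
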