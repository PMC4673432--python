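"""Estimation of fate-event frequencies and empirical time distributions.

Mirrors the experimental procedure: for each micro-well a first event
(division, differentiation or death) and its hour are determined; compiling
all wells yields first-event frequencies and empirical cumulative time
distributions.  The same is done for all later ("subsequent") events,
stratified by the acting cell's GFP state, with event times measured from
the cell's entry into the subsequent regime.

Subsequent "remain unchanged" decisions are not observable as events; their
frequency is recovered by bookkeeping: every division creates two regime
entries and every differentiation one, so the number of remain decisions of
a GFP state is (entries) − (observed non-first events of that state).
Cells whose event would fall beyond the observation horizon are
observationally identical to remaining cells and are absorbed there — the
same convention applies to wells whose first event never occurred.
Wells whose *first* event is a death are excluded from the model tables
(first-regime death is a property of the culture transfer stress, not of
the stimulated fate process) but are kept in the log for mortality
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    DIE,
    DIFFERENTIATE,
    DIVIDE,
    GFP_NEG,
    GFP_POS,
    REMAIN,
    FateModelParams,
    TimeDistribution,
)

__all__ = ["EventLog", "EstimatedTables", "extract_first_events", "compile_tables", "estimate_params"]

EVENT_COLUMNS = ["well_id", "hour", "wait", "event", "gfp_state", "is_first"]


@dataclass
class EventLog:
    """Observed fate events across a set of micro-wells.

    ``events`` has one row per observed event with columns well_id, hour
    (absolute), wait (hours since the acting cell entered its regime),
    event, gfp_state (of the acting cell), is_first.  ``n_wells`` counts
    every well in the dataset, including those with no event at all.
    """

    events: pd.DataFrame
    n_wells: int

    def __post_init__(self):
        if self.n_wells < 1:
            raise ValueError("an event log needs at least one well")
        missing = set(EVENT_COLUMNS) - set(self.events.columns)
        if missing:
            raise ValueError(f"event log missing columns {missing}")
        ev = self.events
        if len(ev) and ((ev["hour"] < 0).any()):
            raise ValueError("event hours must be non-negative")
        firsts = ev[ev["is_first"]]
        if len(firsts) and firsts["well_id"].duplicated().any():
            raise ValueError("at most one first event per well")

    def to_csv(self, path) -> None:
        self.events.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_wells: int) -> "EventLog":
        df = pd.read_csv(Path(path))
        return cls(events=df[EVENT_COLUMNS], n_wells=n_wells)


@dataclass
class EstimatedTables:
    """Estimated fate-model tables plus the sample counts behind them."""

    params: FateModelParams
    counts: dict = field(default_factory=dict)


def extract_first_events(records) -> EventLog:
    """Determine each well's first event from its hourly counts.

    The first event is the earliest of: first division (living 1 -> 2),
    first differentiation (GFP 0 -> 1 while one cell is living) and death
    of the founder (living 1 -> 0).  Wells with no event contribute no row
    (they are the "remain unchanged" wells, counted through ``n_wells``).
    Ties at the same hour are broken by the precedence
    differentiate < divide < die.
    """
    rows = []
    for rec in records:
        counts = rec.counts.sort_values("hour")
        living = counts["n_living"].to_numpy()
        gfp = counts["n_gfp_living"].to_numpy()
        hours = counts["hour"].to_numpy()
        if living[0] != 1:
            raise ValueError(f"well {rec.well_id}: records must start with exactly 1 living cell")
        candidates = []  # (hour, precedence, event)
        div = np.nonzero((living[:-1] == 1) & (living[1:] >= 2))[0]
        if div.size:
            candidates.append((int(hours[div[0] + 1]), 1, DIVIDE))
        dif = np.nonzero((gfp[:-1] == 0) & (gfp[1:] >= 1) & (living[1:] == 1))[0]
        if dif.size:
            candidates.append((int(hours[dif[0] + 1]), 0, DIFFERENTIATE))
        dth = np.nonzero((living[:-1] == 1) & (living[1:] == 0))[0]
        if dth.size:
            candidates.append((int(hours[dth[0] + 1]), 2, DIE))
        if not candidates:
            continue
        hour, _, event = min(candidates)
        rows.append((rec.well_id, hour, hour, event, GFP_NEG, True))
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EventLog(events=df, n_wells=len(list(records)))


def _time_dist(waits: np.ndarray) -> TimeDistribution | None:
    if waits.size == 0:
        return None
    return TimeDistribution.from_samples(np.maximum(waits.astype(int), 1))


def compile_tables(log: EventLog, horizon: int = 100) -> EstimatedTables:
    """Compile event frequencies and time distributions from an event log.

    Returns tables in the fate-model parameter schema, ready to drive the
    simulator.  First-event frequencies are counts over wells (death-first
    wells excluded, see module docstring); subsequent frequencies are
    counts over regime entries of each GFP state.
    """
    ev = log.events
    if log.n_wells == 0:
        raise ValueError("zero wells")

    firsts = ev[ev["is_first"]]
    die_first_wells = set(firsts.loc[firsts["event"] == DIE, "well_id"])
    n_model_wells = log.n_wells - len(die_first_wells)
    if n_model_wells <= 0:
        raise ValueError("no wells survive the first event")
    model_ev = ev[~ev["well_id"].isin(die_first_wells)]
    mfirst = model_ev[model_ev["is_first"]]

    first_counts = {ev_type: int((mfirst["event"] == ev_type).sum()) for ev_type in (DIVIDE, DIFFERENTIATE)}
    first_counts[REMAIN] = n_model_wells - sum(first_counts.values())
    first_probs = {k: v / n_model_wells for k, v in first_counts.items()}
    first_dists = {}
    for ev_type in (DIVIDE, DIFFERENTIATE):
        d = _time_dist(mfirst.loc[mfirst["event"] == ev_type, "wait"].to_numpy())
        if d is not None:
            first_dists[ev_type] = d

    # regime entries: 2 per division (daughters share the mother's state),
    # 1 per differentiation (the cell re-enters as GFP+)
    n_div_neg = int(((model_ev["event"] == DIVIDE) & (model_ev["gfp_state"] == GFP_NEG)).sum())
    n_div_pos = int(((model_ev["event"] == DIVIDE) & (model_ev["gfp_state"] == GFP_POS)).sum())
    n_diff = int((model_ev["event"] == DIFFERENTIATE).sum())
    entries = {GFP_NEG: 2 * n_div_neg, GFP_POS: n_diff + 2 * n_div_pos}

    sub = model_ev[~model_ev["is_first"]]
    sub_probs: dict = {}
    sub_dists: dict = {}
    sub_counts: dict = {}
    event_sets = {GFP_NEG: (DIVIDE, DIFFERENTIATE, DIE), GFP_POS: (DIVIDE, DIE)}
    for state in (GFP_NEG, GFP_POS):
        se = sub[sub["gfp_state"] == state]
        n_entries = entries[state]
        counts = {ev_type: int((se["event"] == ev_type).sum()) for ev_type in event_sets[state]}
        observed = sum(counts.values())
        if n_entries == 0:
            # no cell ever entered this regime: inert placeholder
            sub_probs[state] = {REMAIN: 1.0}
            sub_counts[state] = {REMAIN: 0}
            sub_dists[state] = {}
            continue
        counts[REMAIN] = max(n_entries - observed, 0)
        total = sum(counts.values())
        sub_probs[state] = {k: v / total for k, v in counts.items()}
        sub_counts[state] = counts
        dists = {}
        for ev_type in event_sets[state]:
            d = _time_dist(se.loc[se["event"] == ev_type, "wait"].to_numpy())
            if d is not None:
                dists[ev_type] = d
        sub_dists[state] = dists

    params = FateModelParams(
        first_event_probs=first_probs,
        first_event_time_dists=first_dists,
        subsequent_event_probs=sub_probs,
        subsequent_event_time_dists=sub_dists,
        horizon_hours=horizon,
    )
    return EstimatedTables(
        params=params,
        counts={
            "n_wells": log.n_wells,
            "n_die_first_wells": len(die_first_wells),
            "first": first_counts,
            "subsequent": sub_counts,
            "entries": entries,
        },
    )


def estimate_params(records, horizon: int = 100) -> EstimatedTables:
    """Full estimation pipeline over generated or observed well records.

    Restricts to bead-containing wells (unstimulated cells neither divide
    nor differentiate), uses each record's native per-cell event rows when
    present and falls back to count-based first-event extraction otherwise.
    """
    records = list(records)
    bead = [r for r in records if r.n_beads > 0]
    if not bead:
        raise ValueError("no bead-containing wells to estimate from")
    if all(getattr(r, "events", None) is not None for r in bead):
        frames = [r.events for r in bead if len(r.events)]
        df = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=EVENT_COLUMNS)
        )
        log = EventLog(events=df, n_wells=len(bead))
    else:
        log = extract_first_events(bead)
    return compile_tables(log, horizon=horizon)
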