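"""Synthetic micro-well time-lapse data generator.

Emulates the structure of the single-cell experiment: thousands of
micro-wells each seeded with one naive CD4+ T cell and 0, 1, 2 or 3+
anti-CD3/CD28 activation beads; hourly counts of living cells, GFP+
(Foxp3 reporter) cells and cumulative dead cells over 100 h.  Two
mechanisms act:

* a bead-independent stress death in the first 24 h (the transfer from
  in vivo to culture), applied with the same probability whether or not a
  bead is present;
* for surviving cells in bead-containing wells, the stochastic fate model
  (first-event and subsequent-event tables).  Surviving cells without a
  bead neither divide nor differentiate.

Counts carry no observation noise by default (manual counts are treated as
exact); a miscount model can be bolted on via the records if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import EVENT_COLUMNS
from .model import (
    DIE,
    DIFFERENTIATE,
    DIVIDE,
    GFP_NEG,
    REMAIN,
    FateModelParams,
    TimeDistribution,
    run_clone,
)

__all__ = [
    "WellConfig",
    "CloneRecord",
    "generate_wells",
    "default_ground_truth",
    "classify_clones",
    "records_to_frame",
    "records_from_frame",
    "make_records_from_death_counts",
]


def default_ground_truth() -> FateModelParams:
    """Calibrated default fate-model parameters.

    The event-time tables of the original records are not published, so the
    defaults are calibrated (grid search, see ``scripts/calibrate.py``) to
    the reported population-level facts: among stimulated surviving clones
    roughly half end mixed GFP+/GFP-, ~20% purely GFP+, ~15% purely GFP-,
    ~10% of founders never divide, a minority of clones go extinct, the lag
    to the first division spans 15 to 100 h while subsequent cycles are
    shorter and less variable, and clonal dominance (Gini) rises to a
    plateau near 0.6.
    """
    first_probs = {DIVIDE: 0.89, DIFFERENTIATE: 0.05, REMAIN: 0.06}
    first_dists = {
        # long, heavy-tailed lag to the first division spanning 15-100 h
        # (median ~39 h); mass beyond 100 h folded back by renormalisation
        DIVIDE: TimeDistribution.discretized_gamma(0.7, 110.0, 15, 100),
        # division-independent differentiation around mid-experiment
        DIFFERENTIATE: TimeDistribution.discretized_normal(44.0, 8.0, 26, 70),
    }
    sub_probs = {
        "gfp_neg": {DIVIDE: 0.617, DIFFERENTIATE: 0.16, DIE: 0.22, REMAIN: 0.003},
        "gfp_pos": {DIVIDE: 0.877, DIE: 0.12, REMAIN: 0.003},
    }
    # subsequent cycles are shorter and far less variable than the lag;
    # the same cycle-length distribution applies to both phenotypes
    cycle = TimeDistribution.discretized_normal(22.0, 9.0, 6, 44)
    death_wait = TimeDistribution.discretized_gamma(1.5, 5.0, 3, 30)
    sub_dists = {
        "gfp_neg": {
            DIVIDE: cycle,
            # commitment follows quickly once the decision falls
            DIFFERENTIATE: TimeDistribution.discretized_gamma(1.5, 1.5, 1, 6),
            DIE: death_wait,
        },
        "gfp_pos": {DIVIDE: cycle, DIE: death_wait},
    }
    return FateModelParams(
        first_event_probs=first_probs,
        first_event_time_dists=first_dists,
        subsequent_event_probs=sub_probs,
        subsequent_event_time_dists=sub_dists,
        horizon_hours=100,
        n_founders=133,
    )


def _default_bead_probs() -> dict:
    # seeding aims at single-bead wells; about a third receive none
    return {0: 0.33, 1: 0.45, 2: 0.15, 3: 0.07}


@dataclass
class WellConfig:
    """Configuration of a synthetic micro-well experiment."""

    n_wells: int = 940
    bead_count_probs: dict = field(default_factory=_default_bead_probs)
    p_death_24h: float = 0.41
    death_24h_time_dist: TimeDistribution = field(
        default_factory=lambda: TimeDistribution.uniform(1, 24)
    )
    ground_truth: FateModelParams = field(default_factory=default_ground_truth)
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.p_death_24h <= 1:
            raise ValueError("p_death_24h must be a probability")
        s = sum(self.bead_count_probs.values())
        if abs(s - 1.0) > 1e-9 or any(p < 0 for p in self.bead_count_probs.values()):
            raise ValueError("bead_count_probs must be a probability vector")


@dataclass
class CloneRecord:
    """Hourly record of one micro-well plus its underlying event rows."""

    well_id: int
    n_beads: int
    counts: pd.DataFrame  # hour, n_living, n_gfp_living, n_dead_cum
    events: pd.DataFrame | None = None  # EventLog rows for this well


def _counts_frame(hours, living, gfp, dead) -> pd.DataFrame:
    return pd.DataFrame(
        {"hour": hours, "n_living": living, "n_gfp_living": gfp, "n_dead_cum": dead}
    )


def _static_record(well_id, n_beads, horizon, death_hour=None) -> CloneRecord:
    hours = np.arange(horizon + 1)
    living = np.ones(horizon + 1, dtype=int)
    dead = np.zeros(horizon + 1, dtype=int)
    rows = []
    if death_hour is not None:
        living[death_hour:] = 0
        dead[death_hour:] = 1
        rows.append((well_id, int(death_hour), int(death_hour), DIE, GFP_NEG, True))
    return CloneRecord(
        well_id=well_id,
        n_beads=n_beads,
        counts=_counts_frame(hours, living, np.zeros(horizon + 1, dtype=int), dead),
        events=pd.DataFrame(rows, columns=EVENT_COLUMNS),
    )


def generate_wells(cfg: WellConfig) -> list:
    """Generate one synthetic micro-well record per well.

    The first-24 h stress-death draw uses the same probability in every
    well regardless of bead count; a well destined to die shows only that
    death.  Surviving cells evolve under the ground-truth fate model when
    at least one bead is present and stay single and GFP- otherwise.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    horizon = cfg.ground_truth.horizon_hours
    bead_vals = np.array(sorted(cfg.bead_count_probs))
    bead_cdf = np.cumsum([cfg.bead_count_probs[int(v)] for v in bead_vals])

    records = []
    for wid in range(cfg.n_wells):
        n_beads = int(bead_vals[np.searchsorted(bead_cdf, rng.random(), side="left")])
        if rng.random() < cfg.p_death_24h:
            u = rng.random()
            death_hour = int(
                cfg.death_24h_time_dist.hours[
                    np.searchsorted(cfg.death_24h_time_dist.cdf, u, side="left")
                ]
            )
            records.append(_static_record(wid, n_beads, horizon, death_hour))
            continue
        if n_beads == 0:
            records.append(_static_record(wid, n_beads, horizon))
            continue
        res = run_clone(cfg.ground_truth, wid, rng)
        events = pd.DataFrame(
            [(wid, e.hour, e.wait, e.event, e.gfp_state, e.is_first) for e in res.events],
            columns=EVENT_COLUMNS,
        )
        records.append(
            CloneRecord(
                well_id=wid,
                n_beads=n_beads,
                counts=_counts_frame(np.arange(horizon + 1), res.living, res.gfp, res.dead_cum),
                events=events,
            )
        )
    return records


def classify_clones(living: np.ndarray, gfp: np.ndarray) -> dict:
    """Fractions of clone outcome categories from count matrices.

    Categories (mutually exclusive, summing to 1): ``extinct`` (no living
    cell at the end), ``inactive`` (founder alive but never divided,
    differentiated or not), ``mixed`` (divided, both GFP+ and GFP- cells at
    the end), ``pure_gfp_pos`` and ``pure_gfp_neg`` (divided, single
    phenotype at the end).
    """
    living = np.asarray(living)
    gfp = np.asarray(gfp)
    final = living[:, -1]
    final_gfp = gfp[:, -1]
    divided = living.max(axis=1) > 1
    extinct = final == 0
    inactive = ~divided & ~extinct
    mixed = divided & (final_gfp >= 1) & (final_gfp < final)
    pure_pos = divided & ~extinct & (final_gfp == final)
    pure_neg = divided & ~extinct & (final_gfp == 0)
    n = living.shape[0]
    return {
        "extinct": extinct.sum() / n,
        "inactive": inactive.sum() / n,
        "mixed": mixed.sum() / n,
        "pure_gfp_pos": pure_pos.sum() / n,
        "pure_gfp_neg": pure_neg.sum() / n,
    }


def records_to_frame(records) -> pd.DataFrame:
    """Tidy CSV-ready frame: well_id, n_beads, hour, counts."""
    frames = []
    for r in records:
        df = r.counts.copy()
        df.insert(0, "well_id", r.well_id)
        df.insert(1, "n_beads", r.n_beads)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def records_from_frame(df: pd.DataFrame, events: pd.DataFrame | None = None) -> list:
    records = []
    ev_by_well = dict(tuple(events.groupby("well_id"))) if events is not None else {}
    for wid, grp in df.groupby("well_id"):
        grp = grp.sort_values("hour")
        rec_events = ev_by_well.get(wid)
        if rec_events is None and events is not None:
            rec_events = pd.DataFrame(columns=EVENT_COLUMNS)
        records.append(
            CloneRecord(
                well_id=int(wid),
                n_beads=int(grp["n_beads"].iloc[0]),
                counts=grp[["hour", "n_living", "n_gfp_living", "n_dead_cum"]].reset_index(drop=True),
                events=rec_events,
            )
        )
    return records


def make_records_from_death_counts(
    n_bead_wells: int,
    n_bead_deaths: int,
    n_nobead_wells: int,
    n_nobead_deaths: int,
    horizon: int = 100,
) -> list:
    """Deterministic record set embodying printed mortality counts.

    Builds the requested number of bead and bead-free wells with exactly
    the given numbers of first-24 h deaths; death hours cycle over 1..24 so
    both groups share the same death-time profile.  Useful for checking the
    mortality report against published count tables.
    """
    records = []
    wid = 0
    for n_wells, n_deaths, beads in (
        (n_bead_wells, n_bead_deaths, 1),
        (n_nobead_wells, n_nobead_deaths, 0),
    ):
        if n_deaths > n_wells:
            raise ValueError("more deaths than wells")
        for i in range(n_wells):
            death_hour = (i % 24) + 1 if i < n_deaths else None
            records.append(_static_record(wid, beads, horizon, death_hour))
            wid += 1
    return records
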