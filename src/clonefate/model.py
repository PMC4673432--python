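"""Stochastic decision-tree model of single CD4+ T-cell fate.

Each founder cell (one per micro-well) takes a first fate decision —
divide, differentiate (acquire the Foxp3/GFP+ regulatory phenotype) or
remain unchanged until the end — with probabilities estimated from
time-lapse records, and the time to that event is drawn from the matching
empirical cumulative time distribution.  Every cell that enters the
subsequent regime (daughters of a division, or a cell that has just
differentiated) draws from a second set of tables, conditioned on its GFP
state, in which death is an additional possible event.  Time advances on a
1 h grid for a fixed horizon (default 100 h); an event drawn beyond the
horizon never fires.

The simulation is event-driven internally (a heap of scheduled events,
ties resolved in cell-creation order) but reports the same hourly counts as
the matrix-update formulation: per clone and hour, the number of living
cells, of living GFP+ cells and the cumulative death count.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from heapq import heappop, heappush
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "DIVIDE",
    "DIFFERENTIATE",
    "DIE",
    "REMAIN",
    "GFP_NEG",
    "GFP_POS",
    "VARIANTS",
    "TimeDistribution",
    "FateModelParams",
    "CellState",
    "EventRecord",
    "CloneResult",
    "PopulationTrajectory",
    "sample_event",
    "sample_event_time",
    "init_founder",
    "resolve_event",
    "run_clone",
    "run_population",
    "make_variant",
]

DIVIDE = "divide"
DIFFERENTIATE = "differentiate"
DIE = "die"
REMAIN = "remain"

GFP_NEG = "gfp_neg"
GFP_POS = "gfp_pos"

# canonical draw order; fixed so that seeded runs are reproducible
EVENT_ORDER = (DIVIDE, DIFFERENTIATE, DIE, REMAIN)

FIRST_EVENTS = (DIVIDE, DIFFERENTIATE, REMAIN)
SUBSEQUENT_EVENTS = {
    GFP_NEG: (DIVIDE, DIFFERENTIATE, DIE, REMAIN),
    GFP_POS: (DIVIDE, DIE, REMAIN),
}

VARIANTS = (
    "full",
    "no_death",
    "fixed_first",
    "fixed_subsequent",
    "all_synchronized",
    "synchronized_immortal",
)

_PROB_TOL = 1e-9


@dataclass(frozen=True)
class TimeDistribution:
    """Empirical event-time distribution on an hourly grid.

    ``hours`` are the strictly increasing integer support points (>= 1) and
    ``pmf`` the probability mass at each; the stored CDF reaches 1 at the
    last support point.  Sampling is by inverse transform: the draw is the
    smallest support hour whose CDF is >= a uniform variate.
    """

    hours: np.ndarray
    pmf: np.ndarray
    cdf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        hours = np.asarray(self.hours, dtype=int)
        pmf = np.asarray(self.pmf, dtype=float)
        if hours.ndim != 1 or hours.size == 0 or pmf.shape != hours.shape:
            raise ValueError("hours and pmf must be matching 1-d arrays")
        if np.any(np.diff(hours) <= 0):
            raise ValueError("support hours must be strictly increasing")
        if hours[0] < 1:
            raise ValueError("support hours start at 1")
        if np.any(pmf < -_PROB_TOL):
            raise ValueError("probability mass must be non-negative")
        cdf = np.cumsum(pmf)
        if abs(cdf[-1] - 1.0) > _PROB_TOL:
            raise ValueError("time distribution mass must sum to 1")
        object.__setattr__(self, "hours", hours)
        object.__setattr__(self, "pmf", pmf)
        object.__setattr__(self, "cdf", cdf)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_pmf(cls, mapping: dict) -> "TimeDistribution":
        items = sorted((int(h), float(p)) for h, p in mapping.items())
        hours = np.array([h for h, _ in items])
        pmf = np.array([p for _, p in items])
        return cls(hours, pmf)

    @classmethod
    def point_mass(cls, hour: int) -> "TimeDistribution":
        return cls(np.array([int(hour)]), np.array([1.0]))

    @classmethod
    def uniform(cls, lo: int, hi: int) -> "TimeDistribution":
        hours = np.arange(int(lo), int(hi) + 1)
        return cls(hours, np.full(hours.size, 1.0 / hours.size))

    @classmethod
    def from_samples(cls, samples: Iterable[int]) -> "TimeDistribution":
        vals, counts = np.unique(np.asarray(list(samples), dtype=int), return_counts=True)
        return cls(vals, counts / counts.sum())

    @classmethod
    def discretized_gamma(cls, shape: float, scale: float, shift: int, max_hour: int) -> "TimeDistribution":
        """Gamma(shape, scale) shifted by ``shift`` hours, discretised to the
        1 h grid ``shift..max_hour`` and renormalised (mass beyond the last
        grid hour folded back proportionally)."""
        from scipy import stats

        hours = np.arange(int(shift), int(max_hour) + 1)
        edges = np.concatenate([[0.0], hours - shift + 0.5])
        cdf = stats.gamma.cdf(edges, a=shape, scale=scale)
        pmf = np.diff(cdf)
        pmf = pmf / pmf.sum()
        return cls(hours, pmf)

    @classmethod
    def discretized_normal(cls, mean: float, sd: float, lo: int, hi: int) -> "TimeDistribution":
        """Normal(mean, sd) truncated to ``lo..hi`` and discretised to the
        1 h grid (renormalised cell probabilities)."""
        from scipy import stats

        hours = np.arange(int(lo), int(hi) + 1)
        edges = np.concatenate([[lo - 0.5], hours + 0.5])
        cdf = stats.norm.cdf(edges, loc=mean, scale=sd)
        pmf = np.diff(cdf)
        pmf = pmf / pmf.sum()
        return cls(hours, pmf)

    # -- queries -----------------------------------------------------------
    @property
    def median(self) -> int:
        """Smallest support hour with CDF >= 0.5."""
        return int(self.hours[np.searchsorted(self.cdf, 0.5, side="left")])

    @property
    def mean(self) -> float:
        return float(np.dot(self.hours, self.pmf))

    def to_dict(self) -> dict:
        return {int(h): float(p) for h, p in zip(self.hours, self.pmf) if p > 0}


def sample_event_time(dist: TimeDistribution, rng: np.random.Generator) -> int:
    """Inverse-CDF draw from an hourly time distribution."""
    u = rng.random()
    idx = int(np.searchsorted(dist.cdf, u, side="left"))
    if idx >= dist.hours.size:
        idx = dist.hours.size - 1
    return int(dist.hours[idx])


def _check_probs(probs: dict) -> None:
    vals = list(probs.values())
    if any(p < -_PROB_TOL for p in vals):
        raise ValueError(f"negative probability in {probs!r}")
    if abs(sum(vals) - 1.0) > 1e-6:
        raise ValueError(f"probabilities must sum to 1, got {sum(vals)!r}")


def sample_event(probs: dict, rng: np.random.Generator) -> str:
    """Draw one fate event from a {event: probability} map.

    Events are traversed in the canonical order divide, differentiate,
    die, remain so that seeded draws are reproducible regardless of dict
    insertion order.
    """
    _check_probs(probs)
    u = rng.random()
    acc = 0.0
    events = [e for e in EVENT_ORDER if e in probs]
    for ev in events:
        acc += probs[ev]
        if u < acc:
            return ev
    return events[-1]


@dataclass
class FateModelParams:
    """Model parameter tables: event probabilities and time distributions.

    ``first_event_probs`` covers the founder's first decision
    (divide / differentiate / remain — founders cannot die in the model;
    early bead-independent death is a property of the culture, handled by
    the synthetic-data generator).  ``subsequent_event_probs`` maps GFP
    state ('gfp_neg' / 'gfp_pos') to the tables used by every cell after a
    division or differentiation; GFP+ cells cannot differentiate again.
    Time distributions are offsets, in hours, from the cell's entry into
    its regime (t = 0 for founders; birth hour for daughters; the
    differentiation hour for a newly GFP+ cell).
    """

    first_event_probs: dict
    first_event_time_dists: dict
    subsequent_event_probs: dict
    subsequent_event_time_dists: dict
    horizon_hours: int = 100
    n_founders: int = 133

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if set(self.first_event_probs) - set(FIRST_EVENTS):
            raise ValueError("first events are divide/differentiate/remain")
        _check_probs(self.first_event_probs)
        for ev, p in self.first_event_probs.items():
            if ev != REMAIN and p > 0 and ev not in self.first_event_time_dists:
                raise ValueError(f"first event {ev!r} has probability {p} but no time distribution")
        for state in (GFP_NEG, GFP_POS):
            probs = self.subsequent_event_probs[state]
            if set(probs) - set(SUBSEQUENT_EVENTS[state]):
                raise ValueError(f"invalid subsequent events for {state}: {set(probs)}")
            _check_probs(probs)
            dists = self.subsequent_event_time_dists.get(state, {})
            for ev, p in probs.items():
                if ev != REMAIN and p > 0 and ev not in dists:
                    raise ValueError(f"subsequent event {ev!r} ({state}) lacks a time distribution")
        if self.horizon_hours < 1 or self.n_founders < 1:
            raise ValueError("horizon_hours and n_founders must be positive")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "first_event_probs": {k: float(v) for k, v in self.first_event_probs.items()},
            "first_event_time_dists": {k: d.to_dict() for k, d in self.first_event_time_dists.items()},
            "subsequent_event_probs": {
                s: {k: float(v) for k, v in p.items()} for s, p in self.subsequent_event_probs.items()
            },
            "subsequent_event_time_dists": {
                s: {k: d.to_dict() for k, d in dd.items()}
                for s, dd in self.subsequent_event_time_dists.items()
            },
            "horizon_hours": int(self.horizon_hours),
            "n_founders": int(self.n_founders),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FateModelParams":
        return cls(
            first_event_probs=dict(d["first_event_probs"]),
            first_event_time_dists={
                k: TimeDistribution.from_pmf(v) for k, v in d["first_event_time_dists"].items()
            },
            subsequent_event_probs={s: dict(p) for s, p in d["subsequent_event_probs"].items()},
            subsequent_event_time_dists={
                s: {k: TimeDistribution.from_pmf(v) for k, v in dd.items()}
                for s, dd in d["subsequent_event_time_dists"].items()
            },
            horizon_hours=int(d.get("horizon_hours", 100)),
            n_founders=int(d.get("n_founders", 133)),
        )

    def save(self, path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))

    @classmethod
    def load(cls, path) -> "FateModelParams":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


INF_HOUR = math.inf  # schedule marker for remain-unchanged (never fires)


@dataclass
class CellState:
    """One simulated cell's fate vector (7 fields)."""

    clone_id: int
    generation: int
    alive: bool
    differentiated: bool
    birth_hour: int
    scheduled_event: str
    scheduled_hour: float  # INF_HOUR when the cell remains unchanged

    @property
    def gfp_state(self) -> str:
        return GFP_POS if self.differentiated else GFP_NEG


@dataclass(frozen=True)
class EventRecord:
    """One resolved event, as a tracker would log it."""

    clone_id: int
    hour: int
    wait: int  # hours since the acting cell entered its regime
    event: str
    gfp_state: str  # of the acting cell at the moment of the event
    is_first: bool


def init_founder(params: FateModelParams, clone_id: int, rng: np.random.Generator) -> CellState:
    """Create a founder cell with its first fate decision already drawn."""
    ev = sample_event(params.first_event_probs, rng)
    if ev == REMAIN:
        t = INF_HOUR
    else:
        t = sample_event_time(params.first_event_time_dists[ev], rng)
    return CellState(
        clone_id=clone_id,
        generation=0,
        alive=True,
        differentiated=False,
        birth_hour=0,
        scheduled_event=ev,
        scheduled_hour=t,
    )


def _draw_subsequent(cell: CellState, params: FateModelParams, entry_hour: int, rng) -> int:
    """Draw the cell's next (subsequent-regime) event in place.

    Returns the waiting time in hours (0 for remain, whose schedule is the
    infinity marker)."""
    state = cell.gfp_state
    ev = sample_event(params.subsequent_event_probs[state], rng)
    cell.scheduled_event = ev
    if ev == REMAIN:
        cell.scheduled_hour = INF_HOUR
        return 0
    wait = sample_event_time(params.subsequent_event_time_dists[state][ev], rng)
    cell.scheduled_hour = entry_hour + wait
    return wait


def resolve_event(cell: CellState, params: FateModelParams, current_hour: int, rng) -> list:
    """Resolve a cell's scheduled event at ``current_hour``.

    Returns the list of cells present afterwards: two daughters for a
    division (inheriting the mother's GFP state, each with a freshly drawn
    subsequent-regime event), the same cell turned GFP+ for a
    differentiation, and nothing for a death.
    """
    if not cell.alive:
        raise ValueError("cannot resolve an event on a dead cell")
    ev = cell.scheduled_event
    if ev == DIVIDE:
        cell.alive = False  # replaced by its daughters
        daughters = []
        for _ in range(2):
            d = CellState(
                clone_id=cell.clone_id,
                generation=cell.generation + 1,
                alive=True,
                differentiated=cell.differentiated,
                birth_hour=current_hour,
                scheduled_event=REMAIN,
                scheduled_hour=INF_HOUR,
            )
            _draw_subsequent(d, params, current_hour, rng)
            daughters.append(d)
        return daughters
    if ev == DIFFERENTIATE:
        if cell.differentiated:
            raise ValueError("differentiated cells never schedule differentiation")
        cell.differentiated = True
        _draw_subsequent(cell, params, current_hour, rng)
        return [cell]
    if ev == DIE:
        cell.alive = False
        return []
    raise ValueError(f"event {ev!r} does not resolve")


@dataclass
class CloneResult:
    """Hourly counts and event log for a single simulated clone."""

    clone_id: int
    living: np.ndarray        # (horizon+1,) living cells after each hour's events
    gfp: np.ndarray           # (horizon+1,) living GFP+ cells
    dead_cum: np.ndarray      # (horizon+1,) cumulative deaths
    events: list              # EventRecord list in resolution order
    final_generations: np.ndarray  # generation of each cell alive at horizon


def run_clone(params: FateModelParams, clone_id: int, rng: np.random.Generator) -> CloneResult:
    """Simulate one clone from a single founder over the model horizon.

    Scheduled events fire on the hourly grid; events drawn beyond the
    horizon never fire.  Same-hour ties within the clone resolve in
    cell-creation order.  Hour-t counts reflect all events scheduled at
    hours <= t.
    """
    horizon = params.horizon_hours
    d_living = np.zeros(horizon + 1, dtype=np.int64)
    d_gfp = np.zeros(horizon + 1, dtype=np.int64)
    d_dead = np.zeros(horizon + 1, dtype=np.int64)

    founder = init_founder(params, clone_id, rng)
    d_living[0] += 1

    seq = 0
    heap: list = []
    alive = {seq: founder}
    entry_hour = {seq: 0}
    if founder.scheduled_hour <= horizon:
        heappush(heap, (founder.scheduled_hour, seq, founder))

    events: list = []
    first_done = False

    while heap:
        hour, s, cell = heappop(heap)
        if not cell.alive:
            continue
        hour = int(hour)
        ev = cell.scheduled_event
        state = cell.gfp_state
        wait = hour - entry_hour[s]
        events.append(EventRecord(clone_id, hour, wait, ev, state, not first_done))
        first_done = True

        children = resolve_event(cell, params, hour, rng)
        if ev == DIVIDE:
            del alive[s]
            d_living[hour] += 1  # mother replaced by two daughters
            if cell.differentiated:
                d_gfp[hour] += 1
            for d in children:
                seq += 1
                alive[seq] = d
                entry_hour[seq] = hour
                if d.scheduled_hour <= horizon:
                    heappush(heap, (d.scheduled_hour, seq, d))
        elif ev == DIFFERENTIATE:
            d_gfp[hour] += 1
            entry_hour[s] = hour  # regime entry resets at differentiation
            if cell.scheduled_hour <= horizon:
                heappush(heap, (cell.scheduled_hour, s, cell))
        elif ev == DIE:
            del alive[s]
            d_living[hour] -= 1
            d_dead[hour] += 1
            if cell.differentiated:
                d_gfp[hour] -= 1

    return CloneResult(
        clone_id=clone_id,
        living=np.cumsum(d_living),
        gfp=np.cumsum(d_gfp),
        dead_cum=np.cumsum(d_dead),
        events=events,
        final_generations=np.array(sorted(c.generation for c in alive.values()), dtype=int),
    )


@dataclass
class PopulationTrajectory:
    """Per-clone, per-hour counts for one simulation run."""

    run_id: int
    rng_seed: str
    hours: np.ndarray
    living: np.ndarray    # (n_clones, horizon+1)
    gfp: np.ndarray
    dead_cum: np.ndarray
    final_generations: list  # per clone, generations of cells alive at horizon

    @property
    def n_clones(self) -> int:
        return self.living.shape[0]

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        n, t = self.living.shape
        return pd.DataFrame(
            {
                "run_id": np.repeat(self.run_id, n * t),
                "clone_id": np.repeat(np.arange(n), t),
                "hour": np.tile(self.hours, n),
                "n_living": self.living.ravel(),
                "n_gfp_living": self.gfp.ravel(),
                "n_dead_cum": self.dead_cum.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df, run_id: int | None = None) -> "PopulationTrajectory":
        if run_id is not None:
            df = df[df["run_id"] == run_id]
        elif "run_id" in df:
            ids = df["run_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds several runs; pass run_id")
            run_id = int(ids[0])
        df = df.sort_values(["clone_id", "hour"])
        hours = np.sort(df["hour"].unique())
        clones = np.sort(df["clone_id"].unique())
        shape = (clones.size, hours.size)
        return cls(
            run_id=int(run_id) if run_id is not None else 0,
            rng_seed="",
            hours=hours,
            living=df["n_living"].to_numpy().reshape(shape),
            gfp=df["n_gfp_living"].to_numpy().reshape(shape),
            dead_cum=df["n_dead_cum"].to_numpy().reshape(shape),
            final_generations=[],
        )


def run_clones(params: FateModelParams, rng: np.random.Generator, run_id: int = 0,
               rng_seed: str = "") -> PopulationTrajectory:
    """Simulate ``params.n_founders`` independent clones with one generator."""
    results = [run_clone(params, cid, rng) for cid in range(params.n_founders)]
    return PopulationTrajectory(
        run_id=run_id,
        rng_seed=rng_seed,
        hours=np.arange(params.horizon_hours + 1),
        living=np.stack([r.living for r in results]),
        gfp=np.stack([r.gfp for r in results]),
        dead_cum=np.stack([r.dead_cum for r in results]),
        final_generations=[r.final_generations for r in results],
    )


def run_population(params: FateModelParams, n_runs: int, master_seed: int) -> list:
    """Repeat the clonal simulation ``n_runs`` times with child seeds.

    Child seeds are spawned reproducibly from ``master_seed``; identical
    master seeds give bit-identical output.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    out = []
    for i, child in enumerate(ss.spawn(n_runs)):
        rng = np.random.default_rng(child)
        out.append(run_clones(params, rng, run_id=i, rng_seed=f"{master_seed}:{i}"))
    return out


def _no_death(probs: dict) -> dict:
    p = {k: v for k, v in probs.items() if k != DIE}
    s = sum(p.values())
    return {k: v / s for k, v in p.items()}


def make_variant(params: FateModelParams, variant: str) -> FateModelParams:
    """Build one of the fixed-parameter model variants.

    ``no_death`` zeroes the death probability (remaining probabilities
    renormalised); ``fixed_first`` / ``fixed_subsequent`` replace the
    corresponding division-time distributions by a point mass at their
    median (synchronising divisions); ``all_synchronized`` combines the two
    fixes and ``synchronized_immortal`` additionally removes death;
    ``full`` is the identity.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    p = copy.deepcopy(params)
    if variant == "full":
        return p
    if variant in ("no_death", "synchronized_immortal"):
        p.subsequent_event_probs = {s: _no_death(pr) for s, pr in p.subsequent_event_probs.items()}
    if variant in ("fixed_first", "all_synchronized", "synchronized_immortal"):
        if DIVIDE in p.first_event_time_dists:
            p.first_event_time_dists[DIVIDE] = TimeDistribution.point_mass(
                p.first_event_time_dists[DIVIDE].median
            )
    if variant in ("fixed_subsequent", "all_synchronized", "synchronized_immortal"):
        for state, dd in p.subsequent_event_time_dists.items():
            if DIVIDE in dd:
                dd[DIVIDE] = TimeDistribution.point_mass(dd[DIVIDE].median)
    p.validate()
    return p
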