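"""Numerical experiments over the fate model and generated records.

* Gini-vs-time: median hourly Gini across repeated runs with a +/- 2 sd
  band, the model-side counterpart of the experimental dominance curve.
* Parameter ablation: six model variants (full, no death, fixed first
  cycle, fixed subsequent cycles, both fixed, both fixed + immortal), each
  run many times; the response is the final-hour Gini of the total clone
  sizes.  Group differences are tested with Kruskal-Wallis and Dunn's
  all-pairs post-hoc comparison (Bonferroni-adjusted by default).
* Mortality comparison: first-24 h and whole-run death fractions in bead vs
  bead-free wells with a two-sample Kolmogorov-Smirnov test on death times.
* CTV-style dye-dilution profile: each living final cell carries intensity
  F0 * 2^-d for d completed divisions, with multiplicative log-normal noise
  on the log2 scale; the histogram shows one mode per generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .gini import gini_series
from .model import DIE, VARIANTS, FateModelParams, make_variant, run_population

__all__ = [
    "run_gini_experiment",
    "run_ablation",
    "AblationResult",
    "dunn_test",
    "mortality_comparison",
    "MortalityReport",
    "ctv_profile",
    "CtvProfile",
]


def run_gini_experiment(
    params: FateModelParams, n_runs: int, seed: int, gfp_artifice: bool = True
) -> pd.DataFrame:
    """Median hourly Gini with a +/- 2 sd band over ``n_runs`` runs.

    Returns a frame with columns hour, gini_median, gini_sd, band_lo,
    band_hi, gini_gfp_median, n_cells_median.  NaN-aware: hours where a
    run's Gini is undefined are ignored for that run.
    """
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a standard deviation")
    trajs = run_population(params, n_runs, seed)
    tot = np.stack([gini_series(t, gfp_artifice).gini_total.to_numpy() for t in trajs])
    gfp = np.stack([gini_series(t, gfp_artifice).gini_gfp.to_numpy() for t in trajs])
    cells = np.stack([t.living.sum(axis=0) for t in trajs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # hours where all runs are undefined
        med = np.nanmedian(tot, axis=0)
        sd = np.nanstd(tot, axis=0, ddof=1)
        gfp_med = np.nanmedian(gfp, axis=0)
    return pd.DataFrame(
        {
            "hour": trajs[0].hours,
            "gini_median": med,
            "gini_sd": sd,
            "band_lo": med - 2 * sd,
            "band_hi": med + 2 * sd,
            "gini_gfp_median": gfp_med,
            "n_cells_median": np.median(cells, axis=0),
        }
    )


def dunn_test(groups: dict, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's all-pairs rank comparison after a Kruskal-Wallis test.

    z_ij = (mean rank_i - mean rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Two-sided normal
    p-values; ``p_adjust`` is 'bonferroni' or 'none'.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[k], dtype=float) for k in names])
    sizes = {k: len(groups[k]) for k in names}
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, i = {}, 0
    for k in names:
        mean_ranks[k] = ranks[i : i + sizes[k]].mean()
        i += sizes[k]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_corr = ((tie_counts**3 - tie_counts).sum()) / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_corr
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(base_var * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if p_adjust == "bonferroni" else p
        rows.append((a, b, z, p, p_adj))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw", "p_adj"])


@dataclass
class AblationResult:
    """Final-hour Gini distributions of the six model variants."""

    final_gini: dict                 # variant -> (n_runs,) array
    summary: pd.DataFrame            # variant, median, mean, sd
    kruskal_stat: float
    kruskal_p: float
    posthoc: pd.DataFrame            # Dunn all-pairs comparisons
    median_order: list = field(default_factory=list)  # descending medians


def run_ablation(
    params: FateModelParams, n_runs: int, seed: int, p_adjust: str = "bonferroni"
) -> AblationResult:
    """Run all six model variants and compare their final-hour Gini values."""
    ss = np.random.SeedSequence(seed)
    variant_seeds = ss.generate_state(len(VARIANTS)) >> 1  # keep below 2**31
    final: dict = {}
    for v, vseed in zip(VARIANTS, variant_seeds):
        vp = make_variant(params, v)
        trajs = run_population(vp, n_runs, int(vseed))
        final[v] = np.array(
            [gini_series(t).gini_total.iloc[-1] for t in trajs], dtype=float
        )
    summary = pd.DataFrame(
        {
            "variant": list(final),
            "median": [np.nanmedian(final[v]) for v in final],
            "mean": [np.nanmean(final[v]) for v in final],
            "sd": [np.nanstd(final[v], ddof=1) for v in final],
        }
    )
    arrays = [final[v][~np.isnan(final[v])] for v in final]
    if all(a.std() == 0 and a[0] == arrays[0][0] for a in arrays):
        kw_stat, kw_p = 0.0, 1.0  # all groups coincide (degenerate inputs)
    else:
        kw_stat, kw_p = stats.kruskal(*arrays)
    order = sorted(final, key=lambda v: -np.nanmedian(final[v]))
    return AblationResult(
        final_gini=final,
        summary=summary,
        kruskal_stat=float(kw_stat),
        kruskal_p=float(kw_p),
        posthoc=dunn_test(final, p_adjust=p_adjust),
        median_order=order,
    )


@dataclass
class MortalityReport:
    """Death fractions and distribution comparison, bead vs no-bead wells."""

    per_group: pd.DataFrame  # group, n_wells, n_dead_24h, frac_24h, n_dead_total, frac_total
    ks_stat: float
    ks_p: float


def _first_death_hours(records) -> np.ndarray:
    hours = []
    for r in records:
        counts = r.counts
        living = counts["n_living"].to_numpy()
        h = counts["hour"].to_numpy()
        dead = np.nonzero((living[:-1] == 1) & (living[1:] == 0))[0]
        died_div = counts["n_dead_cum"].to_numpy()
        if dead.size:
            hours.append(int(h[dead[0] + 1]))
        elif died_div[-1] > 0:
            hours.append(int(h[np.argmax(died_div > 0)]))
    return np.array(hours, dtype=float)


def mortality_comparison(records) -> MortalityReport:
    """Compare death rates and death-time distributions across bead groups.

    First-24 h mortality counts founders that died by hour 24; the
    whole-run fraction counts wells with at least one death.  Death times
    of the two groups are compared with a two-sample Kolmogorov-Smirnov
    test (identical samples give statistic 0, p = 1).
    """
    records = list(records)
    groups = {
        "beads": [r for r in records if r.n_beads > 0],
        "no_beads": [r for r in records if r.n_beads == 0],
    }
    if any(len(g) == 0 for g in groups.values()):
        raise ValueError("both bead and no-bead wells are required")
    rows, times = [], {}
    for name, recs in groups.items():
        t = _first_death_hours(recs)
        times[name] = t
        n24 = int((t <= 24).sum())
        rows.append(
            {
                "group": name,
                "n_wells": len(recs),
                "n_dead_24h": n24,
                "frac_24h": n24 / len(recs),
                "n_dead_total": len(t),
                "frac_total": len(t) / len(recs),
            }
        )
    if times["beads"].size and times["no_beads"].size:
        if np.array_equal(np.sort(times["beads"]), np.sort(times["no_beads"])):
            ks_stat, ks_p = 0.0, 1.0
        else:
            ks_stat, ks_p = stats.ks_2samp(times["beads"], times["no_beads"])
    else:
        ks_stat, ks_p = float("nan"), float("nan")
    return MortalityReport(per_group=pd.DataFrame(rows), ks_stat=float(ks_stat), ks_p=float(ks_p))


@dataclass
class CtvProfile:
    """Simulated dye-dilution (CellTrace Violet) proliferation profile."""

    intensities: np.ndarray
    generations: np.ndarray
    bin_edges: np.ndarray  # in log2 intensity units
    counts: np.ndarray

    def peaks(self, smooth: int = 5, prominence: float | None = None) -> np.ndarray:
        """Locations (log2 units) of histogram modes, via peak detection on
        a moving-average-smoothed histogram."""
        from scipy.signal import find_peaks

        c = self.counts.astype(float)
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            c = np.convolve(c, kernel, mode="same")
        if prominence is None:
            prominence = max(c.max() * 0.05, 1.0)
        idx, _ = find_peaks(c, prominence=prominence)
        centers = (self.bin_edges[:-1] + self.bin_edges[1:]) / 2
        return centers[idx]


def ctv_profile(
    trajectories,
    F0: float = 1e4,
    noise_sd: float = 0.15,
    rng: np.random.Generator | None = None,
    bin_width: float = 0.1,
) -> CtvProfile:
    """Dye-dilution intensity histogram of the final living cells.

    Each cell alive at the horizon gets intensity ``F0 * 2**-d`` for its
    ``d`` completed divisions, perturbed by multiplicative log-normal noise
    with standard deviation ``noise_sd`` on the log2 scale.  Modes sit
    ~1 log2 unit apart while ``noise_sd`` is small.
    """
    if F0 <= 0:
        raise ValueError("F0 must be positive")
    gens = np.concatenate(
        [np.concatenate([np.asarray(g, dtype=int) for g in t.final_generations] or [np.array([], int)])
         for t in trajectories]
    )
    if gens.size == 0:
        raise ValueError("no living final cells in the trajectories")
    rng = np.random.default_rng(0) if rng is None else rng
    log2_i = np.log2(F0) - gens.astype(float)
    if noise_sd > 0:
        log2_i = log2_i + noise_sd * rng.standard_normal(gens.size)
    intensities = 2.0**log2_i
    lo = np.floor(log2_i.min() / bin_width) * bin_width - bin_width
    hi = np.ceil(log2_i.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(log2_i, bins=edges)
    return CtvProfile(intensities=intensities, generations=gens, bin_edges=edges, counts=counts)
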