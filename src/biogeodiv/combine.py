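"""Combining ancestral ranges with branch rates: the regional summaries.

Three summaries link the biogeographic reconstruction to diversification:

* per-geological-period source x destination dispersal percentage tables,
  built from stochastic uniform draws of each dispersal event's timing along
  its branch;
* lineage-area frequency through time (share of reconstructed lineages in
  each region per 0.5 Myr bin, range changes applied at branch midpoints);
* sliding-window region-averaged speciation/extinction/net rates, where each
  branch contributes rate*time to every region it occupies and the average is
  the occupied-branch-length-weighted mean within the window.

Areas are merged to coarse regions before summarising (default nine areas ->
six regions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import UltrametricTree
from .dec import AreaScheme, DispersalEvent, NINE_AREAS, _bits
from .branch_rates import BranchRateSeries

__all__ = [
    "AreaMerge",
    "EpochTable",
    "nine_to_six",
    "nine_to_five",
    "DEFAULT_PERIODS",
    "draw_event_times",
    "epoch_dispersal_percentages",
    "EpochDispersalResult",
    "lineage_area_frequency",
    "windowed_regional_rates",
    "WindowedRegionalRates",
]

#: geological summary periods (name, older bound, younger bound), Myr ago
DEFAULT_PERIODS = (
    ("Paleocene", 66.0, 56.0),
    ("Eocene", 56.0, 34.0),
    ("Oligocene", 34.0, 23.0),
    ("Miocene-to-present", 23.0, 0.0),
)


@dataclass(frozen=True)
class AreaMerge:
    """Total surjective map from fine areas to coarse regions."""

    source: AreaScheme
    regions: tuple[str, ...]
    assignment: tuple[int, ...]   # area index -> region index

    def __post_init__(self):
        if len(self.assignment) != self.source.n:
            raise ValueError("assignment must cover every source area")
        if set(self.assignment) != set(range(len(self.regions))):
            raise ValueError("merge map must be surjective onto the regions")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def region_of_area(self, area: int) -> int:
        return self.assignment[area]

    def merge_mask(self, mask: int) -> int:
        out = 0
        for a in _bits(mask):
            out |= 1 << self.assignment[a]
        return out

    def region_indices(self, mask: int) -> list[int]:
        return sorted(set(self.assignment[a] for a in _bits(mask)))


def _merge_from_groups(scheme: AreaScheme, groups: dict[str, tuple[str, ...]]
                       ) -> AreaMerge:
    regions = tuple(groups)
    assign = []
    for a in scheme.names:
        hits = [i for i, r in enumerate(regions) if a in groups[r]]
        if len(hits) != 1:
            raise ValueError(f"area {a} must map to exactly one region")
        assign.append(hits[0])
    return AreaMerge(source=scheme, regions=regions, assignment=tuple(assign))


def nine_to_six(scheme: AreaScheme | None = None) -> AreaMerge:
    """Nearctic/Palearctic halves merged, India folded into SEAsia."""
    scheme = scheme or AreaScheme(NINE_AREAS)
    return _merge_from_groups(scheme, {
        "Nearctic": ("WNearctic", "ENearctic"),
        "Palearctic": ("WPalearctic", "EPalearctic"),
        "Neotropics": ("Neotropics",),
        "Afrotropics": ("Afrotropics",),
        "SEAsia": ("India", "SEAsia"),
        "Australasia": ("Australasia",),
    })


def nine_to_five(scheme: AreaScheme | None = None) -> AreaMerge:
    """As :func:`nine_to_six` but with SEAsia and Australasia combined."""
    scheme = scheme or AreaScheme(NINE_AREAS)
    return _merge_from_groups(scheme, {
        "Neotropics": ("Neotropics",),
        "Afrotropics": ("Afrotropics",),
        "SEAsia+Australasia": ("India", "SEAsia", "Australasia"),
        "Palearctic": ("WPalearctic", "EPalearctic"),
        "Nearctic": ("WNearctic", "ENearctic"),
    })


@dataclass(frozen=True)
class EpochTable:
    """Contiguous, non-overlapping geological periods, oldest first."""

    periods: tuple[tuple[str, float, float], ...] = DEFAULT_PERIODS

    def __post_init__(self):
        for k, (_, old, young) in enumerate(self.periods):
            if old <= young:
                raise ValueError("period bounds must run older -> younger")
            if k + 1 < len(self.periods) and self.periods[k + 1][1] != young:
                raise ValueError("periods must be contiguous")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.periods)

    def period_of(self, age: float) -> int | None:
        """Index of the period containing ``age``; None if outside the table."""
        for k, (_, old, young) in enumerate(self.periods):
            if young <= age <= old:
                return k
        return None


# ---------------------------------------------------------------------------
# Stochastic dispersal-event timing
# ---------------------------------------------------------------------------

def draw_event_times(events: list[DispersalEvent], n_draws: int,
                     seed: int) -> list[DispersalEvent]:
    """Draw i.i.d. uniform timings for each event along its branch (in place).

    Each event receives ``n_draws`` times uniform on (child age, parent age);
    a degenerate interval collapses to its single age.  Reproducible given
    ``seed``; draw k of every event belongs to timing replicate k.
    """
    rng = np.random.default_rng(seed)
    for ev in events:
        if ev.old_age - ev.young_age <= 0:
            ev.times = np.full(n_draws, ev.young_age)
        else:
            ev.times = rng.uniform(ev.young_age, ev.old_age, size=n_draws)
    return events


@dataclass
class EpochDispersalResult:
    """Source x destination dispersal percentages per geological period."""

    table: EpochTable
    merge: AreaMerge
    per_replicate: np.ndarray   # (n_draws, n_periods, R, R) percentages
    mean: np.ndarray            # (n_periods, R, R)
    events_outside: int         # event draws older than the oldest period

    def frame(self) -> pd.DataFrame:
        rows = []
        R = self.merge.n_regions
        for p, name in enumerate(self.table.names):
            for i in range(R):
                for j in range(R):
                    rows.append({"period": name,
                                 "source": self.merge.regions[i],
                                 "destination": self.merge.regions[j],
                                 "percent": self.mean[p, i, j]})
        return pd.DataFrame(rows)


def epoch_dispersal_percentages(events: list[DispersalEvent],
                                table: EpochTable | None = None,
                                merge: AreaMerge | None = None,
                                attribution: str = "fractional",
                                ) -> EpochDispersalResult:
    """Dispersal-event percentage matrices per period, averaged over draws.

    For each timing replicate, cell (src, dst) of a period counts the events
    whose drawn time falls in the period, as a percentage of all events in
    that period.  Widespread sources are attributed 1/|source areas| to each
    source area (``attribution="fractional"``) or a full count to each
    (``attribution="all"``); destination is the merged gained area.  Periods
    with zero events in a replicate yield NaN cells.
    """
    table = table or EpochTable()
    merge = merge or nine_to_six()
    if attribution not in ("fractional", "all"):
        raise ValueError("attribution must be 'fractional' or 'all'")
    if not events:
        raise ValueError("no dispersal events")
    n_draws = len(events[0].times) if events[0].times is not None else 0
    if n_draws == 0:
        raise ValueError("event times not drawn; call draw_event_times first")
    P, R = len(table.periods), merge.n_regions
    counts = np.zeros((n_draws, P, R, R))
    outside = 0
    for ev in events:
        dst = merge.region_of_area(ev.gained_area)
        src_areas = list(_bits(ev.source_mask))
        w = 1.0 / len(src_areas) if attribution == "fractional" else 1.0
        for k in range(n_draws):
            p = table.period_of(float(ev.times[k]))
            if p is None:
                outside += 1
                continue
            for a in src_areas:
                counts[k, p, merge.region_of_area(a), dst] += w
    totals = counts.sum(axis=(2, 3), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_rep = 100.0 * counts / totals
    per_rep[np.broadcast_to(totals == 0, per_rep.shape)] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN periods
        mean = np.nanmean(per_rep, axis=0)
    return EpochDispersalResult(table=table, merge=merge,
                                per_replicate=per_rep, mean=mean,
                                events_outside=outside)


# ---------------------------------------------------------------------------
# Lineage-area frequency through time
# ---------------------------------------------------------------------------

def lineage_area_frequency(tree: UltrametricTree, node_masks,
                           merge: AreaMerge | None = None,
                           bin_width: float = 0.5,
                           norm: str = "share") -> pd.DataFrame:
    """Share of reconstructed lineages occupying each region per age bin.

    A lineage alive at a bin midpoint counts once for every region it then
    occupies; range changes along a branch apply at the branch midpoint
    (older half = parent range, younger half = child range).  With
    ``norm="share"`` region counts are normalised to sum to 1 per bin; with
    ``norm="per_lineage"`` they are divided by the number of live lineages.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    merge = merge or nine_to_six()
    n_bins = int(math.ceil(tree.root_age / bin_width - 1e-12))
    mids = (np.arange(n_bins) + 0.5) * bin_width
    R = merge.n_regions
    counts = np.zeros((n_bins, R))
    lineages = np.zeros(n_bins)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        young, old = float(tree.age[v]), float(tree.age[p])
        if old - young <= 0:
            continue
        midpoint = 0.5 * (young + old)
        sel = (mids >= young) & (mids < old)
        for b in np.nonzero(sel)[0]:
            mask = int(node_masks[p]) if mids[b] > midpoint else int(node_masks[v])
            lineages[b] += 1
            for r in merge.region_indices(mask):
                counts[b, r] += 1
    if norm == "share":
        denom = counts.sum(axis=1, keepdims=True)
    elif norm == "per_lineage":
        denom = lineages[:, None]
    else:
        raise ValueError("norm must be 'share' or 'per_lineage'")
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = counts / denom
    df = pd.DataFrame(prop, columns=list(merge.regions))
    df.insert(0, "age", mids)
    df.insert(1, "n_lineages", lineages)
    return df


# ---------------------------------------------------------------------------
# Sliding-window regional rates
# ---------------------------------------------------------------------------

@dataclass
class WindowedRegionalRates:
    """Region x window mean rates with spread over timing replicates."""

    regions: tuple[str, ...]
    window_old: np.ndarray      # (n_windows,) older edge of each window
    window_young: np.ndarray
    lam: np.ndarray             # (n_rep, R, n_windows)
    mu: np.ndarray
    net: np.ndarray
    n_rep: int

    def summary(self, q=(0.025, 0.975)) -> pd.DataFrame:
        rows = []
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            for which, arr in (("lambda", self.lam), ("mu", self.mu),
                               ("net", self.net)):
                mean = np.nanmean(arr, axis=0)
                lo = np.nanquantile(arr, q[0], axis=0)
                hi = np.nanquantile(arr, q[1], axis=0)
                for r, name in enumerate(self.regions):
                    for w in range(len(self.window_old)):
                        rows.append({
                            "rate": which, "region": name,
                            "window_old": self.window_old[w],
                            "window_young": self.window_young[w],
                            "mean": mean[r, w], "q_lo": lo[r, w],
                            "q_hi": hi[r, w]})
        return pd.DataFrame(rows)


def _occupancy_intervals(ev_by_branch, node_masks, tree, merge, rep):
    """Per (branch, region): occupied age intervals for one timing replicate.

    Areas present at both branch ends are occupied throughout; a gained area
    is occupied from its drawn time downward, a lost area from the parent end
    until its drawn time.  Region occupancy is the union over member areas.
    """
    out = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        young, old = float(tree.age[v]), float(tree.age[p])
        if old - young <= 0:
            continue
        par, chi = int(node_masks[p]), int(node_masks[v])
        area_iv = {}
        for a in _bits(par & chi):
            area_iv[a] = (young, old)
        for (a, t) in ev_by_branch.get(v, {}).get("gain", []):
            area_iv[a] = (young, float(t[rep]))
        for (a, t) in ev_by_branch.get(v, {}).get("loss", []):
            area_iv[a] = (float(t[rep]), old)
        regmap: dict[int, list[tuple[float, float]]] = {}
        for a, iv in area_iv.items():
            regmap.setdefault(merge.region_of_area(a), []).append(iv)
        out[v] = {r: _union(ivs) for r, ivs in regmap.items()}
    return out


def _union(ivs):
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for lo, hi in ivs[1:]:
        if lo <= merged[-1][1] + 1e-12:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(a, b) for a, b in merged]


def windowed_regional_rates(tree: UltrametricTree,
                            series: dict[int, BranchRateSeries],
                            node_masks,
                            events: list[DispersalEvent] | None = None,
                            merge: AreaMerge | None = None,
                            window: float = 4.0, step: float = 1.0,
                            n_rep: int = 100, seed: int = 0,
                            loss_seed_offset: int = 777,
                            ) -> WindowedRegionalRates:
    """Sliding-window mean rates per region over stochastic event timings.

    For each replicate, region A and window I the mean rate is
    sum_branches int_{I ∩ branch ∩ A-occupied} rate dt divided by the matching
    occupied branch length.  Gains use the drawn times of ``events`` (drawn
    here if absent); losses are drawn uniformly on their branch the same way.
    Windows with zero occupied length are NaN.
    """
    from .dec import extract_dispersal_events

    merge = merge or nine_to_six()
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if events is None:
        events = extract_dispersal_events(tree, node_masks)
    need_draw = any(ev.times is None or len(ev.times) < n_rep for ev in events)
    if need_draw:
        draw_event_times(events, n_rep, seed)
    # losses, drawn symmetrically
    rng = np.random.default_rng(seed + loss_seed_offset)
    ev_by_branch: dict[int, dict[str, list]] = {}
    for ev in events:
        ev_by_branch.setdefault(ev.branch, {}).setdefault("gain", []).append(
            (ev.gained_area, ev.times))
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        lost = int(node_masks[p]) & ~int(node_masks[v])
        young, old = float(tree.age[v]), float(tree.age[p])
        for a in _bits(lost):
            t = (rng.uniform(young, old, size=n_rep) if old > young
                 else np.full(n_rep, young))
            ev_by_branch.setdefault(v, {}).setdefault("loss", []).append((a, t))

    n_win = max(1, int(math.floor((tree.root_age - window) / step + 1e-9)) + 1)
    w_young = np.arange(n_win) * step
    w_old = w_young + window
    R = merge.n_regions
    lam = np.full((n_rep, R, n_win), np.nan)
    mu = np.full((n_rep, R, n_win), np.nan)
    net = np.full((n_rep, R, n_win), np.nan)
    for rep in range(n_rep):
        occ = _occupancy_intervals(ev_by_branch, node_masks, tree, merge, rep)
        num_l = np.zeros((R, n_win))
        num_m = np.zeros((R, n_win))
        den = np.zeros((R, n_win))
        for v, regions in occ.items():
            s = series.get(v)
            if s is None:
                continue
            for r, ivs in regions.items():
                for lo, hi in ivs:
                    # intersect with each rate grid cell, then each window
                    for k in range(len(s.ages)):
                        a = max(lo, float(s.cell_young[k]))
                        b = min(hi, float(s.cell_old[k]))
                        if b <= a:
                            continue
                        wlo = max(0, int(math.floor((a - window) / step)))
                        whi = min(n_win - 1, int(math.ceil(b / step)))
                        for w in range(wlo, whi + 1):
                            aa = max(a, w_young[w])
                            bb = min(b, w_old[w])
                            if bb <= aa:
                                continue
                            dt = bb - aa
                            num_l[r, w] += s.lam[k] * dt
                            num_m[r, w] += s.mu[k] * dt
                            den[r, w] += dt
        pos = den > 0
        lam[rep][pos] = num_l[pos] / den[pos]
        mu[rep][pos] = num_m[pos] / den[pos]
        net[rep][pos] = lam[rep][pos] - mu[rep][pos]
    return WindowedRegionalRates(regions=merge.regions, window_old=w_old,
                                 window_young=w_young, lam=lam, mu=mu,
                                 net=net, n_rep=n_rep)
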