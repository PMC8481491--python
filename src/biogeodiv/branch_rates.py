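"""Per-branch speciation/extinction rates through time from rate-shift samples.

A rate-shift configuration (one posterior sample of a reversible-jump
birth-death sampler, BAMM-style) is a set of events: each event starts a new
rate regime on a branch, and the regime governs everything downstream until a
nested event overrides it.  Within a regime that originated at age ``t0``
(Myr before present) the speciation rate is exponential in elapsed time,

    lambda(age) = lambda_init * exp(lambda_shape * (t0 - age)),

and the extinction rate is the constant ``mu_init``.  Rates are laid out on a
global age grid (default step 0.5 Myr) shared by every branch, evaluated at
grid-cell midpoints clipped to the branch interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo import UltrametricTree

__all__ = [
    "RateRegime",
    "MappedRegime",
    "BranchRateSeries",
    "parse_shift_config",
    "rates_on_grid",
    "average_rate_series",
    "posterior_mean_rates",
    "constant_regime",
    "rate_series_table",
]

DEFAULT_GRID_STEP = 0.5  # Myr


@dataclass(frozen=True)
class RateRegime:
    """Exponential-speciation / constant-extinction regime."""

    origin_age: float     # Myr before present where the regime starts
    lam_init: float       # speciation rate at the regime origin, /Myr
    lam_shape: float      # exponential coefficient, /Myr
    mu_init: float        # extinction rate, /Myr

    def __post_init__(self):
        if self.lam_init <= 0:
            raise ValueError("lam_init must be > 0")
        if self.mu_init < 0:
            raise ValueError("mu_init must be >= 0")

    def lam(self, age):
        return self.lam_init * np.exp(self.lam_shape * (self.origin_age - age))

    def mu(self, age):
        return self.mu_init * np.ones_like(np.asarray(age, dtype=float))

    def integral_lam(self, young: float, old: float) -> float:
        """Exact integral of lambda(age) over [young, old]."""
        s = self.lam_shape
        if s == 0:
            return self.lam_init * (old - young)
        c = self.lam_init * math.exp(s * self.origin_age)
        return c * (math.exp(-s * young) - math.exp(-s * old)) / s

    def integral_mu(self, young: float, old: float) -> float:
        return self.mu_init * (old - young)


@dataclass(frozen=True)
class MappedRegime:
    """A regime anchored to the tree: starts on the branch leading to ``node``."""

    node: int
    regime: RateRegime


@dataclass
class BranchRateSeries:
    """Rates of one branch on the global age grid.

    ``ages`` are cell midpoints clipped to the branch interval, oldest first;
    ``cell_young``/``cell_old`` are the matching cell-intersection bounds.
    """

    branch: int
    ages: np.ndarray
    cell_young: np.ndarray
    cell_old: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    mean_net: float


class ShiftConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Event-file parsing (BAMM event-data CSV)
# ---------------------------------------------------------------------------

def parse_shift_config(path, tree: UltrametricTree
                       ) -> dict[int, list[MappedRegime]]:
    """Parse a BAMM-style event-data CSV into per-sample regime mappings.

    Expected columns: generation, leftchild, rightchild, abstime, lambdainit,
    lambdashift, muinit, mushift.  ``abstime`` is time since the root;
    ``leftchild``/``rightchild`` span the node whose subtending branch carries
    the event (rightchild NA for events on terminal branches).  Every sample
    must contain a root regime (abstime 0).  ``mushift`` is accepted but must
    be zero: extinction is constant within a regime.
    """
    df = pd.read_csv(path)
    required = {"generation", "leftchild", "rightchild", "abstime",
                "lambdainit", "lambdashift", "muinit"}
    missing = required - set(df.columns)
    if missing:
        raise ShiftConfigError(f"event file missing columns: {sorted(missing)}")
    root_age = tree.root_age
    tip_idx = tree.tip_index()
    samples: dict[int, list[MappedRegime]] = {}
    for rownum, row in df.iterrows():
        gen = int(row["generation"])
        left = str(row["leftchild"])
        right = row["rightchild"]
        try:
            if pd.isna(right) or str(right) in ("", "NA"):
                node = tip_idx[left]
            else:
                node = tree.mrca([left, str(right)])
        except (KeyError, ValueError) as exc:
            raise ShiftConfigError(
                f"row {rownum}: cannot resolve node from "
                f"({left!r}, {right!r}): {exc}") from exc
        if "mushift" in df.columns and not pd.isna(row.get("mushift", 0.0)):
            if abs(float(row.get("mushift", 0.0))) > 1e-12:
                raise ShiftConfigError(
                    f"row {rownum}: non-zero mushift unsupported (mu constant)")
        origin_age = root_age - float(row["abstime"])
        reg = RateRegime(origin_age=origin_age,
                         lam_init=float(row["lambdainit"]),
                         lam_shape=float(row["lambdashift"]),
                         mu_init=float(row["muinit"]))
        samples.setdefault(gen, []).append(MappedRegime(node=node, regime=reg))
    for gen, regs in samples.items():
        has_root = any(m.node == tree.root and
                       abs(m.regime.origin_age - root_age) < 1e-6 for m in regs)
        if not has_root:
            raise ShiftConfigError(f"sample {gen}: no root regime present")
    return samples


def constant_regime(tree: UltrametricTree, lam: float, mu: float,
                    shape: float = 0.0) -> list[MappedRegime]:
    """A single tree-wide regime rooted at the crown."""
    return [MappedRegime(node=tree.root,
                         regime=RateRegime(tree.root_age, lam, shape, mu))]


# ---------------------------------------------------------------------------
# Regime resolution along branches
# ---------------------------------------------------------------------------

def _branch_pieces(tree: UltrametricTree, regimes: list[MappedRegime]
                   ) -> dict[int, list[tuple[float, float, RateRegime]]]:
    """Per branch: (young, old, regime) pieces covering the branch interval."""
    by_node: dict[int, list[RateRegime]] = {}
    for m in regimes:
        by_node.setdefault(m.node, []).append(m.regime)
    for regs in by_node.values():
        regs.sort(key=lambda r: -r.origin_age)   # oldest event first

    pieces: dict[int, list[tuple[float, float, RateRegime]]] = {}
    inherited: dict[int, RateRegime] = {}

    root = tree.root
    root_regs = by_node.get(root, [])
    if not root_regs:
        raise ShiftConfigError("no root regime: regimes do not cover the tree")
    inherited[root] = root_regs[-1]   # youngest event at the root wins below it
    for v in tree.preorder():
        if v == root:
            continue
        p = int(tree.parent[v])
        young, old = float(tree.age[v]), float(tree.age[p])
        current = inherited[p]
        cuts = []
        for reg in by_node.get(v, []):
            if not (young - 1e-9 <= reg.origin_age <= old + 1e-9):
                raise ShiftConfigError(
                    f"event at age {reg.origin_age} outside branch to node {v}")
            cuts.append(reg)
        segs = []
        hi = old
        for reg in cuts:   # oldest first
            a = min(max(reg.origin_age, young), old)
            if hi > a + 1e-12:
                segs.append((a, hi, current))
            current = reg
            hi = a
        segs.append((young, hi, current))
        pieces[v] = segs
        inherited[v] = current
    return pieces


# ---------------------------------------------------------------------------
# Grid evaluation
# ---------------------------------------------------------------------------

def grid_edges(root_age: float, dt: float) -> np.ndarray:
    """Global age-grid cell edges from 0 past the root age, step ``dt``."""
    if dt <= 0:
        raise ValueError("grid step must be positive")
    n = int(math.ceil(root_age / dt - 1e-12))
    return np.arange(n + 1) * dt


def rates_on_grid(tree: UltrametricTree, regimes: list[MappedRegime],
                  dt: float = DEFAULT_GRID_STEP) -> dict[int, BranchRateSeries]:
    """Evaluate one regime sample on the global age grid, per branch.

    Rates are evaluated at cell midpoints clipped to the branch interval; the
    mean branch net rate is the exact time-average of lambda - mu over the
    branch (closed-form regime integrals, not the grid).
    """
    edges = grid_edges(tree.root_age, dt)
    pieces = _branch_pieces(tree, regimes)
    out: dict[int, BranchRateSeries] = {}
    for v, segs in pieces.items():
        young = float(tree.age[v])
        old = float(tree.age[int(tree.parent[v])])
        if old - young <= 1e-12:
            continue
        lo = int(np.searchsorted(edges, young + 1e-12, side="right")) - 1
        hi = int(np.searchsorted(edges, old - 1e-12, side="right"))
        mids, cl, co, lam, mu = [], [], [], [], []
        for c in range(max(lo, 0), hi):
            a = max(edges[c], young)
            b = min(edges[c + 1], old)
            if b <= a + 1e-12:
                continue
            m = 0.5 * (a + b)
            reg = _regime_at(segs, m)
            mids.append(m)
            cl.append(a)
            co.append(b)
            lam.append(float(reg.lam(m)))
            mu.append(reg.mu_init)
        net_int = sum(r.integral_lam(a, b) - r.integral_mu(a, b)
                      for a, b, r in segs)
        out[v] = BranchRateSeries(
            branch=v, ages=np.array(mids[::-1]),
            cell_young=np.array(cl[::-1]), cell_old=np.array(co[::-1]),
            lam=np.array(lam[::-1]), mu=np.array(mu[::-1]),
            mean_net=net_int / (old - young))
    return out


def _regime_at(segs, age: float) -> RateRegime:
    for young, old, reg in segs:
        if young - 1e-9 <= age <= old + 1e-9:
            return reg
    return segs[-1][2]


def average_rate_series(per_sample: list[dict[int, BranchRateSeries]]
                        ) -> dict[int, BranchRateSeries]:
    """Average rate series across posterior samples, per branch-grid-cell."""
    if not per_sample:
        raise ValueError("no samples to average")
    first = per_sample[0]
    out = {}
    for v, s0 in first.items():
        lam = np.mean([s[v].lam for s in per_sample], axis=0)
        mu = np.mean([s[v].mu for s in per_sample], axis=0)
        mean_net = float(np.mean([s[v].mean_net for s in per_sample]))
        out[v] = BranchRateSeries(branch=v, ages=s0.ages.copy(),
                                  cell_young=s0.cell_young.copy(),
                                  cell_old=s0.cell_old.copy(),
                                  lam=lam, mu=mu, mean_net=mean_net)
    return out


def posterior_mean_rates(tree: UltrametricTree,
                         samples: dict[int, list[MappedRegime]],
                         dt: float = DEFAULT_GRID_STEP
                         ) -> dict[int, BranchRateSeries]:
    """Grid rates averaged over all samples of a parsed event file."""
    per = [rates_on_grid(tree, regs, dt) for _, regs in sorted(samples.items())]
    return average_rate_series(per)


def rate_series_table(series: dict[int, BranchRateSeries]) -> pd.DataFrame:
    rows = []
    for v in sorted(series):
        s = series[v]
        for k in range(len(s.ages)):
            rows.append({"branch": v, "age": s.ages[k],
                         "cell_young": s.cell_young[k],
                         "cell_old": s.cell_old[k],
                         "lambda": s.lam[k], "mu": s.mu[k]})
    return pd.DataFrame(rows)
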