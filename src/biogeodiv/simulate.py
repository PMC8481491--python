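"""Synthetic fixtures with known truth: trees, range histories, shift files.

The generator mirrors the assumptions of the inference modules: reconstructed
trees come from a forward birth-death simulation with exponentially
time-varying speciation (lambda(t) = lambda0*exp(alpha*t), t = age) and
constant extinction, pruned of extinct lineages; geographic ranges evolve as
the DEC continuous-time Markov chain with epoch-dependent generators and
cladogenetic draws at nodes; incomplete sampling is i.i.d. Bernoulli tip
retention.  Every draw flows through one seeded generator per operation so
fixtures are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import UltrametricTree, GraftPlan, graft_subclade
from .dec import (AreaScheme, StratifiedModel, DECParams, DispersalEvent,
                  StateSpace, master_state_space, anagenetic_generator,
                  clado_distribution, _bits)
from .branch_rates import MappedRegime, RateRegime
from .combine import AreaMerge

__all__ = [
    "SimulationError",
    "SimConfig",
    "simulate_tree",
    "simulate_ranges",
    "subsample_tips",
    "write_shift_config",
    "label_genera",
    "make_planted_fixture",
    "yule_tree",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Bundle of generative settings for one synthetic study."""

    seed: int = 0
    lam0: float = 0.2
    alpha: float = 0.05
    mu: float = 0.1
    crown_age: float = 19.0
    n_tips: int | None = None
    rho: float = 1.0
    exact_n: bool = False   # condition on exactly n survivors, not >= n
    root_mask: int = 1
    dec_params: DECParams = field(default_factory=lambda: DECParams(0.02, 0.005))
    scheme: AreaScheme | None = None
    model: StratifiedModel | None = None
    planted: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.n_tips is not None and self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.crown_age <= 0:
            raise ValueError("crown age must be positive")
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")


# ---------------------------------------------------------------------------
# Birth-death tree simulation
# ---------------------------------------------------------------------------

def _build_tree(parent, ages, labels) -> UltrametricTree:
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for v, p in enumerate(parent):
        if p >= 0:
            children[p].append(v)
    return UltrametricTree(parent=np.asarray(parent, dtype=int),
                           children=children, labels=list(labels),
                           age=np.asarray(ages, dtype=float))


def simulate_tree(config: SimConfig, max_attempts: int = 2000
                  ) -> tuple[UltrametricTree, dict]:
    """Forward birth-death from the crown, pruned to the reconstructed tree.

    Speciation at age t is lambda0*exp(alpha*t) (thinning of a bounding
    Poisson process), extinction is constant.  When ``n_tips`` is set, the
    simulation is conditioned on at least that many survivors by rejection
    and the survivors are then uniformly subsampled to exactly ``n_tips``;
    with ``exact_n`` the rejection instead demands exactly ``n_tips``
    survivors, which avoids the implicit extra sampling of the subsample
    variant (relevant when the tree is later fitted with a stated sampling
    fraction).
    """
    rng = np.random.default_rng(config.seed)
    T0 = config.crown_age
    lam0, alpha, mu = config.lam0, config.alpha, config.mu
    lam_age = lambda t: lam0 * math.exp(alpha * t)
    target = config.n_tips

    for attempt in range(1, max_attempts + 1):
        parent = [-1, 0, 0]
        birth = [T0, T0, T0]     # age at which the lineage began
        death = [T0, None, None]  # age at which it ended (None = active/alive)
        active = [1, 2]
        s = 0.0  # forward time since the crown
        ok = True
        while active:
            age_now = T0 - s
            if age_now <= 0:
                break
            bound = max(lam_age(age_now), lam0) + mu
            total = len(active) * bound
            s_next = s + rng.exponential(1.0 / total)
            if s_next >= T0:
                break
            age = T0 - s_next
            s = s_next
            rate = lam_age(age) + mu
            if rng.uniform() * bound > rate:
                continue  # thinning rejection
            k = rng.integers(len(active))
            v = active[k]
            if rng.uniform() * rate < lam_age(age):
                death[v] = age
                for _ in range(2):
                    parent.append(v)
                    birth.append(age)
                    death.append(None)
                    active.append(len(parent) - 1)
                active.pop(k)
            else:
                death[v] = age
                active.pop(k)
            if len(active) > 50000:
                raise SimulationError("runaway birth-death simulation")
        survivors = [v for v in range(len(parent)) if death[v] is None]
        if not active:
            survivors = []
        if target is None:
            if len(survivors) >= 2:
                break
        elif config.exact_n:
            if len(survivors) == target:
                break
        elif len(survivors) >= target:
            break
    else:
        raise SimulationError(
            f"no accepted simulation in {max_attempts} attempts")

    if target is not None and len(survivors) > target:
        survivors = list(rng.choice(survivors, size=target, replace=False))
    # build the complete tree, then the induced tree on survivors
    # node age: the split/extinction age for ended lineages, 0 for survivors
    ages = [0.0 if death[v] is None else float(death[v])
            for v in range(len(parent))]
    labels = [None] * len(parent)
    for i, v in enumerate(sorted(survivors)):
        labels[v] = f"t{i + 1}"
    full = _build_tree(parent, ages, labels)
    recon = full.subtree_on_tips([full.labels[v] for v in sorted(survivors)])
    recon.validate()
    return recon, {"attempt": attempt, "n_survivors": len(survivors),
                   "n_complete": len(parent)}


def yule_tree(n: int, crown_age: float, seed: int = 0) -> UltrametricTree:
    """Exact-size pure-birth clock tree (uniform-order split construction)."""
    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0, crown_age, size=n - 2))[::-1] if n > 2 \
        else np.empty(0)
    node_ages = np.concatenate([[crown_age], times])
    parent = [-1]
    ages = [float(node_ages[0])]
    labels: list[str | None] = [None]
    # iterative splitting: each successive split age attaches to a random
    # pendant lineage
    pend = []
    for c in range(2):
        parent.append(0)
        ages.append(0.0)
        labels.append(None)
        pend.append(len(parent) - 1)
    for t in node_ages[1:]:
        k = rng.integers(len(pend))
        v = pend[k]
        ages[v] = float(t)
        for c in range(2):
            parent.append(v)
            ages.append(0.0)
            labels.append(None)
            pend.append(len(parent) - 1)
        pend.pop(k)
    for i, v in enumerate(pend):
        labels[v] = f"t{i + 1}"
    tree = _build_tree(parent, ages, labels)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# DEC range simulation
# ---------------------------------------------------------------------------

def _clado_draw(tree, v, node_masks, start_mask, space, rng):
    """Draw daughter starting ranges at an internal node (no-op at tips)."""
    if not tree.children[v]:
        return
    par = int(node_masks[v])
    if par != 0:
        outs = [(l, r, p) for l, r, p in clado_distribution(par)
                if l in space.index and r in space.index]
        ps = np.array([p for _, _, p in outs])
        pick = rng.choice(len(outs), p=ps / ps.sum())
        d1, d2, _ = outs[pick]
    else:
        d1 = d2 = 0
    for c, d in zip(tree.children[v], (d1, d2)):
        start_mask[c] = d


def simulate_ranges(tree: UltrametricTree, params: DECParams,
                    model: StratifiedModel, seed: int = 0,
                    root_mask: int | None = None
                    ) -> tuple[dict[str, int], np.ndarray,
                               list[DispersalEvent], dict]:
    """Forward DEC simulation: anagenetic CTMC per epoch + cladogenetic draws.

    Returns (tip ranges, true node masks, true-timed dispersal events, info).
    Lineages that reach the null range are range-extinct: their subtree tips
    are reported in info["range_extinct"] and excluded from the assignment.
    """
    rng = np.random.default_rng(seed)
    space = master_state_space(model.scheme, model)
    Qs = [anagenetic_generator(params, model, e, space)
          for e in range(model.n_epochs)]
    root_mask = root_mask if root_mask is not None else space.masks[0]
    if root_mask not in space.index:
        raise ValueError("root range not in permitted state space")

    node_masks = np.zeros(tree.n_nodes, dtype=np.int64)
    events: list[DispersalEvent] = []
    start_mask = np.zeros(tree.n_nodes, dtype=np.int64)  # below-node range
    start_mask[tree.root] = root_mask

    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            node_masks[v] = start_mask[v]
            _clado_draw(tree, v, node_masks, start_mask, space, rng)
            continue
        # anagenetic evolution along the branch from parent age to node age
        mask = int(start_mask[v])
        t = float(tree.age[p])
        t_end = float(tree.age[v])
        while mask != 0 and t > t_end + 1e-13:
            e = model.epoch_of(max(t - 1e-12, 0.0))
            eb_young = model.epochs[e][1]
            i = space.index[mask]
            row = Qs[e][i].copy()
            row[i] = 0.0
            total = row.sum()
            if total <= 0:
                t = max(t_end, eb_young)
                if t <= eb_young + 1e-13 and t > t_end + 1e-13:
                    t = eb_young
                    continue
                break
            dt = rng.exponential(1.0 / total)
            if t - dt <= max(t_end, eb_young):
                t = max(t_end, eb_young)
                if abs(t - eb_young) < 1e-13 and t > t_end + 1e-13:
                    continue
                break
            t -= dt
            j = rng.choice(len(row), p=row / total)
            new_mask = space.masks[j] if j < space.null_index else 0
            gained = new_mask & ~mask
            for b in _bits(gained):
                ev = DispersalEvent(branch=v, source_mask=mask, gained_area=b,
                                    old_age=float(tree.age[p]),
                                    young_age=t_end)
                ev.times = np.array([t])
                events.append(ev)
            mask = new_mask
        node_masks[v] = mask
        _clado_draw(tree, v, node_masks, start_mask, space, rng)

    range_extinct = [tree.labels[t] for t in tree.tips if node_masks[t] == 0]
    ranges = {tree.labels[t]: int(node_masks[t]) for t in tree.tips
              if node_masks[t] != 0}
    info = {"range_extinct": range_extinct, "n_events": len(events)}
    return ranges, node_masks, events, info


# ---------------------------------------------------------------------------
# Incomplete sampling
# ---------------------------------------------------------------------------

def label_genera(tree: UltrametricTree, mean_size: float = 5.0,
                 seed: int = 0) -> UltrametricTree:
    """Relabel tips into synthetic genera of consecutive tips (tree order)."""
    rng = np.random.default_rng(seed)
    out = tree.copy()
    tips_in_order = [v for v in out.preorder() if not out.children[v]]
    g, i = 1, 0
    size = max(1, rng.geometric(1.0 / mean_size))
    for k, v in enumerate(tips_in_order):
        if i >= size:
            g += 1
            i = 0
            size = max(1, rng.geometric(1.0 / mean_size))
        i += 1
        out.labels[v] = f"g{g}_s{k + 1}"
    return out


def subsample_tips(tree: UltrametricTree, rho: float, seed: int = 0,
                   genus_of=lambda label: label.split("_")[0],
                   max_attempts: int = 100
                   ) -> tuple[UltrametricTree, pd.DataFrame]:
    """Bernoulli(rho) tip retention plus a per-genus sampling-fraction table.

    The table's ``described`` column counts tips of the complete input tree,
    emulating described richness known from taxonomy.
    """
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    rng = np.random.default_rng(seed)
    labels = tree.tip_labels
    for _ in range(max_attempts):
        keep = [lab for lab in labels if rho >= 1.0 or rng.uniform() < rho]
        if len(keep) >= 2:
            break
    else:
        raise SimulationError("subsampling kept < 2 tips in every attempt")
    pruned = tree if len(keep) == len(labels) else tree.subtree_on_tips(keep)
    described: dict[str, int] = {}
    sampled: dict[str, int] = {}
    for lab in labels:
        g = genus_of(lab)
        described[g] = described.get(g, 0) + 1
    for lab in keep:
        g = genus_of(lab)
        sampled[g] = sampled.get(g, 0) + 1
    table = pd.DataFrame(
        [{"genus": g, "described": described[g], "sampled": sampled.get(g, 0),
          "f": sampled.get(g, 0) / described[g]} for g in sorted(described)])
    return pruned, table


# ---------------------------------------------------------------------------
# Shift-config fixtures
# ---------------------------------------------------------------------------

def write_shift_config(tree: UltrametricTree,
                       samples: dict[int, list[MappedRegime]], path) -> None:
    """Write regimes as a BAMM-style event-data CSV parseable downstream."""
    rows = []
    root_age = tree.root_age
    for gen in sorted(samples):
        for m in samples[gen]:
            v = m.node
            if tree.children[v]:
                left = tree.subtree_tips(tree.children[v][0])[0]
                right = tree.subtree_tips(tree.children[v][1])[0]
                lc, rc = tree.labels[left], tree.labels[right]
            else:
                lc, rc = tree.labels[v], "NA"
            rows.append({"generation": gen, "leftchild": lc, "rightchild": rc,
                         "abstime": root_age - m.regime.origin_age,
                         "lambdainit": m.regime.lam_init,
                         "lambdashift": m.regime.lam_shape,
                         "muinit": m.regime.mu_init, "mushift": 0.0})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Planted regional structure
# ---------------------------------------------------------------------------

def make_planted_fixture(spec: list[tuple[str, int]], merge: AreaMerge,
                         seed: int = 0, backbone_root_age: float = 60.0
                         ) -> tuple[UltrametricTree, np.ndarray]:
    """Tree with monoregional clades of known region and size planted in it.

    A pectinate backbone carries one placeholder per requested clade plus two
    background tips; each placeholder is replaced (via the grafting op) by an
    exact-size pure-birth subclade whose tips and internal nodes are assigned
    the requested region.  Background nodes get a two-region range so that no
    unplanned pure clade can arise.  Returns (tree, per-node region bitmasks).
    """
    rng = np.random.default_rng(seed)
    k = len(spec)
    if k == 0:
        raise ValueError("empty planted-clade spec")
    if merge.n_regions < 2:
        raise ValueError("need >= 2 regions to plant impure background")
    # pectinate backbone: placeholders ph0..ph{k-1} + background tips b1, b2
    n_bb = k + 2
    labels = [f"ph{i}" for i in range(k)] + ["b1", "b2"]
    parent = [-1]
    ages = [backbone_root_age]
    node_labels: list[str | None] = [None]
    attach = 0
    tip_ids = []
    for i in range(n_bb - 1):
        age_i = backbone_root_age * (n_bb - 1 - i) / (n_bb - 1)
        if i > 0:
            parent.append(attach)
            ages.append(age_i)
            node_labels.append(None)
            new_int = len(parent) - 1
        else:
            new_int = 0
        parent.append(new_int)
        ages.append(0.0)
        node_labels.append(labels[i])
        tip_ids.append(len(parent) - 1)
        attach = new_int
    parent.append(attach)
    ages.append(0.0)
    node_labels.append(labels[-1])
    tree = _build_tree(parent, ages, node_labels)
    tree.validate()

    for i, (region, size) in enumerate(spec):
        ph_parent_age = float(tree.age[int(tree.parent[tree.tip_index()[f"ph{i}"]])])
        attach_age = 0.5 * ph_parent_age
        sub = yule_tree(size, crown_age=1.0, seed=int(rng.integers(2 ** 31)))
        for j, t in enumerate(sub.tips):
            sub.labels[t] = f"p{i}_{j + 1}"
        tree = graft_subclade(tree, GraftPlan(placeholder=f"ph{i}",
                                              subclade=sub,
                                              attachment_age=attach_age))

    region_idx = {name: j for j, name in enumerate(merge.regions)}
    masks = np.zeros(tree.n_nodes, dtype=np.int64)
    bg = (1 << 0) | (1 << 1)   # widespread background range (impure)
    for v in range(tree.n_nodes):
        masks[v] = bg
    for i, (region, size) in enumerate(spec):
        tips = [f"p{i}_{j + 1}" for j in range(size)]
        node = tree.mrca(tips)
        stack = [node]
        while stack:
            v = stack.pop()
            masks[v] = 1 << region_idx[region]
            stack.extend(tree.children[v])
    return tree, masks
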