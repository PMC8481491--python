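"""Time-stratified Dispersal-Extinction-Cladogenesis (DEC) model.

The DEC model describes geographic range evolution on a dated phylogeny.
Along a branch, a lineage occupying a set of areas gains an adjacent area b at
rate ``d * sum_a m[a, b]`` (summed over occupied areas ``a``, with ``m`` the
epoch-specific dispersal multiplier matrix) and loses an occupied area at rate
``e`` per area; a single-area range that loses its area enters an absorbing
null range.  At a speciation node the parent range is divided between the two
daughters: a single-area parent is inherited identically; a widespread parent
splits by vicariance (one area vs the remainder) or subset sympatry (one area
vs the full range), all ordered outcomes equiprobable.

Time stratification: geological epochs carry their own adjacency matrix
(which ranges are permitted at all) and dispersal multiplier matrix, so the
instantaneous generator changes at epoch boundaries.  Branch transition
probabilities are ordered products of per-segment matrix exponentials, oldest
segment first.

Ages are Myr before present throughout.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .phylo import UltrametricTree, TreeError

__all__ = [
    "AreaScheme",
    "StratifiedModel",
    "DECParams",
    "DECFit",
    "DispersalEvent",
    "StateSpace",
    "build_state_space",
    "master_state_space",
    "anagenetic_generator",
    "clado_distribution",
    "likelihood",
    "fit_ml",
    "extract_dispersal_events",
    "read_range_table",
    "write_range_table",
    "NINE_AREAS",
    "DEFAULT_EPOCHS",
]

#: the nine-region scheme used for global-scale runs
NINE_AREAS = (
    "WNearctic", "ENearctic", "WPalearctic", "EPalearctic",
    "Neotropics", "Afrotropics", "India", "SEAsia", "Australasia",
)

#: default epoch boundaries (Myr ago), oldest first
DEFAULT_EPOCHS = ((100.0, 80.0), (80.0, 60.0), (60.0, 30.0),
                  (30.0, 10.0), (10.0, 0.0))


class DECError(ValueError):
    pass


@dataclass(frozen=True)
class AreaScheme:
    """Ordered, named biogeographic areas; ranges are bitsets over this order."""

    names: tuple[str, ...] = NINE_AREAS
    max_range_size: int | None = None

    def __post_init__(self):
        if not (2 <= len(self.names) <= 16):
            raise DECError("area count must be in [2, 16]")
        if len(set(self.names)) != len(self.names):
            raise DECError("area names must be unique")
        if self.max_range_size is not None and self.max_range_size < 1:
            raise DECError("max range size must be >= 1")

    @property
    def n(self) -> int:
        return len(self.names)

    def mask(self, areas) -> int:
        """Bitmask for an iterable of area names (or a single name)."""
        if isinstance(areas, str):
            areas = [areas]
        m = 0
        for a in areas:
            m |= 1 << self.names.index(a)
        return m

    def unmask(self, mask: int) -> tuple[str, ...]:
        return tuple(n for i, n in enumerate(self.names) if mask >> i & 1)


@dataclass
class StratifiedModel:
    """Epoch-stratified dispersal multipliers and adjacency.

    ``epochs`` is an ordered tuple of (older_bound, younger_bound) age
    intervals, oldest first, contiguous, ending at 0.  ``dispersal`` and
    ``adjacency`` have shape (n_epochs, n_areas, n_areas); adjacency is binary
    symmetric with unit diagonal.
    """

    scheme: AreaScheme
    epochs: tuple[tuple[float, float], ...] = DEFAULT_EPOCHS
    dispersal: np.ndarray | None = None
    adjacency: np.ndarray | None = None

    def __post_init__(self):
        A, E = self.scheme.n, len(self.epochs)
        if self.dispersal is None:
            self.dispersal = np.ones((E, A, A))
        if self.adjacency is None:
            self.adjacency = np.ones((E, A, A), dtype=int)
        self.dispersal = np.asarray(self.dispersal, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        if self.dispersal.shape != (E, A, A) or self.adjacency.shape != (E, A, A):
            raise DECError("matrix shapes must be (n_epochs, n_areas, n_areas)")
        for k, (old, young) in enumerate(self.epochs):
            if old <= young:
                raise DECError("epoch bounds must run older -> younger")
            if k + 1 < len(self.epochs) and self.epochs[k + 1][0] != young:
                raise DECError("epochs must be contiguous")
        if self.epochs[-1][1] != 0.0:
            raise DECError("youngest epoch must end at the present")
        for e in range(E):
            adj = self.adjacency[e]
            if not np.array_equal(adj, adj.T) or not np.all(np.diag(adj) == 1):
                raise DECError(f"epoch {e}: adjacency must be symmetric, diag 1")
        if np.any(self.dispersal < 0) or np.any(self.dispersal > 1):
            raise DECError("dispersal multipliers must lie in [0, 1]")

    @classmethod
    def uniform(cls, scheme: AreaScheme, oldest: float = 1000.0) -> "StratifiedModel":
        """Single epoch, full adjacency, all-ones multipliers."""
        return cls(scheme=scheme, epochs=((oldest, 0.0),))

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def epoch_of(self, age: float) -> int:
        """Epoch index containing the given age (boundaries go to the older epoch)."""
        for k, (old, young) in enumerate(self.epochs):
            if age >= young:
                if age <= old + 1e-9:
                    return k
                break
        raise DECError(f"age {age} outside stratified interval")

    def segments(self, young: float, old: float) -> list[tuple[int, float]]:
        """Split the age interval [young, old] at epoch boundaries.

        Returns (epoch_index, duration) pairs ordered oldest segment first.
        """
        if old < young - 1e-12:
            raise DECError("old must be >= young")
        if old > self.epochs[0][0] + 1e-9:
            raise DECError(f"age {old} exceeds the oldest epoch bound")
        out = []
        for k, (eo, ey) in enumerate(self.epochs):
            lo = max(young, ey)
            hi = min(old, eo)
            if hi > lo + 1e-13:
                out.append((k, hi - lo))
        return out


@dataclass(frozen=True)
class DECParams:
    """Anagenetic rates: d in events/Myr/area-pair, e in losses/Myr/area."""

    d: float
    e: float

    def __post_init__(self):
        if self.d < 0 or self.e < 0:
            raise DECError("rates must be non-negative")


def _popcount(m: int) -> int:
    return bin(m).count("1")


def _bits(m: int):
    i = 0
    while m:
        if m & 1:
            yield i
        m >>= 1
        i += 1


def _connected(mask: int, adj: np.ndarray) -> bool:
    areas = list(_bits(mask))
    if len(areas) <= 1:
        return True
    seen = {areas[0]}
    frontier = [areas[0]]
    rest = set(areas[1:])
    while frontier:
        a = frontier.pop()
        for b in list(rest):
            if adj[a, b]:
                rest.discard(b)
                seen.add(b)
                frontier.append(b)
    return not rest


class StateSpace:
    """Ordered range states (bitmasks) plus a terminal absorbing null state.

    Non-null states are sorted by (range size, lexicographic area order); the
    null range sits at the last index.  This ordering is the deterministic
    tie-break everywhere in the package.
    """

    def __init__(self, scheme: AreaScheme, masks):
        key = lambda m: (_popcount(m), tuple(_bits(m)))
        self.scheme = scheme
        self.masks = sorted(set(int(m) for m in masks if m), key=key)
        self.index = {m: i for i, m in enumerate(self.masks)}
        self.null_index = len(self.masks)

    @property
    def n_states(self) -> int:
        """Total states including the null range."""
        return len(self.masks) + 1

    def __contains__(self, mask: int) -> bool:
        return mask in self.index

    def labels(self) -> list[str]:
        return ["+".join(self.scheme.unmask(m)) for m in self.masks] + ["null"]


def _permitted_masks(scheme: AreaScheme, adj: np.ndarray) -> list[int]:
    cap = scheme.max_range_size or scheme.n
    out = []
    for mask in range(1, 1 << scheme.n):
        if _popcount(mask) <= cap and _connected(mask, adj):
            out.append(mask)
    return out


def build_state_space(scheme: AreaScheme, model: StratifiedModel,
                      epoch: int) -> StateSpace:
    """Permitted ranges in one epoch: connected-under-adjacency subsets + null."""
    return StateSpace(scheme, _permitted_masks(scheme, model.adjacency[epoch]))


def master_state_space(scheme: AreaScheme, model: StratifiedModel) -> StateSpace:
    """Union of all per-epoch permitted ranges (shared indexing across epochs)."""
    masks: set[int] = set()
    for e in range(model.n_epochs):
        masks.update(_permitted_masks(scheme, model.adjacency[e]))
    return StateSpace(scheme, masks)


def anagenetic_generator(params: DECParams, model: StratifiedModel,
                         epoch: int, space: StateSpace) -> np.ndarray:
    """Instantaneous rate matrix Q over ``space`` for one epoch.

    Gains r -> r+{b}: rate d * sum_{a in r} m[a, b], only if the enlarged range
    is in ``space`` and connected under this epoch's adjacency.  Losses
    r -> r-{a}: rate e per occupied area (size-1 ranges lose into the absorbing
    null).  Rows sum to zero.
    """
    adj = model.adjacency[epoch]
    m = model.dispersal[epoch]
    cap = space.scheme.max_range_size or space.scheme.n
    S = space.n_states
    Q = np.zeros((S, S))
    for i, r in enumerate(space.masks):
        occ = list(_bits(r))
        # gains
        if len(occ) < cap:
            for b in range(space.scheme.n):
                if r >> b & 1:
                    continue
                tgt = r | (1 << b)
                if tgt not in space.index or not _connected(tgt, adj):
                    continue
                rate = params.d * sum(m[a, b] for a in occ)
                if rate > 0:
                    Q[i, space.index[tgt]] += rate
        # losses
        for a in occ:
            tgt = r & ~(1 << a)
            if tgt == 0:
                Q[i, space.null_index] += params.e
            elif tgt in space.index:
                Q[i, space.index[tgt]] += params.e
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def clado_distribution(parent_mask: int) -> list[tuple[int, int, float]]:
    """Cladogenetic daughter-range distribution for a parent range.

    Returns ordered (left_mask, right_mask, probability) triples.  A
    single-area parent is copied to both daughters with probability 1; a
    widespread parent of size k yields 4k equiprobable ordered outcomes:
    2k vicariance splits (one area vs the remainder) and 2k subset-sympatry
    outcomes (one area vs the full range).
    """
    if parent_mask == 0:
        raise DECError("null parent range has no cladogenetic outcomes")
    areas = list(_bits(parent_mask))
    if len(areas) == 1:
        return [(parent_mask, parent_mask, 1.0)]
    outcomes: list[tuple[int, int]] = []
    seen = set()
    for a in areas:
        single = 1 << a
        rest = parent_mask & ~single
        # for 2-area parents the vicariance pair of each area coincides with
        # the mirror of the other's, so deduplicate ordered pairs
        for pair in ((single, rest), (rest, single),
                     (single, parent_mask), (parent_mask, single)):
            if pair not in seen:
                seen.add(pair)
                outcomes.append(pair)
    p = 1.0 / len(outcomes)
    return [(l, r, p) for l, r in outcomes]


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

class _Propagators:
    """Per-epoch matrix exponentials via eigendecomposition, expm fallback."""

    def __init__(self, Qs: list[np.ndarray]):
        self.Qs = Qs
        self._eig = []
        for Q in Qs:
            ok = False
            try:
                w, V = np.linalg.eig(Q)
                Vinv = np.linalg.inv(V)
                ok = (np.linalg.cond(V) < 1e8 and
                      np.max(np.abs((V * w) @ Vinv - Q)) < 1e-9 *
                      max(1.0, np.max(np.abs(Q))))
            except np.linalg.LinAlgError:
                pass
            self._eig.append((w, V, Vinv) if ok else None)
        self._expm_cache: dict[tuple[int, float], np.ndarray] = {}

    def matvec(self, e: int, t: float, v: np.ndarray) -> np.ndarray:
        """expm(Q_e * t) @ v"""
        dec = self._eig[e]
        if dec is not None:
            w, V, Vinv = dec
            out = V @ (np.exp(w * t) * (Vinv @ v))
            return np.maximum(out.real, 0.0)
        return np.maximum(self.expm(e, t) @ v, 0.0)

    def vecmat(self, e: int, t: float, v: np.ndarray) -> np.ndarray:
        """v @ expm(Q_e * t)"""
        dec = self._eig[e]
        if dec is not None:
            w, V, Vinv = dec
            out = ((v @ V) * np.exp(w * t)) @ Vinv
            return np.maximum(out.real, 0.0)
        return np.maximum(v @ self.expm(e, t), 0.0)

    def expm(self, e: int, t: float) -> np.ndarray:
        key = (e, round(float(t), 12))
        if key not in self._expm_cache:
            self._expm_cache[key] = scipy.linalg.expm(self.Qs[e] * t)
        return self._expm_cache[key]


def _clado_tables(space: StateSpace):
    """All cladogenetic outcomes as flat index arrays (parent, left, right, p).

    Outcomes whose daughter ranges are not in the state space are dropped
    without renormalisation.
    """
    par, left, right, prob = [], [], [], []
    for i, r in enumerate(space.masks):
        for l, rr, p in clado_distribution(r):
            if l in space.index and rr in space.index:
                par.append(i)
                left.append(space.index[l])
                right.append(space.index[rr])
                prob.append(p)
    return (np.array(par), np.array(left), np.array(right), np.array(prob))


def _tip_vectors(tree: UltrametricTree, ranges: dict[str, int],
                 space: StateSpace) -> dict[int, np.ndarray]:
    out = {}
    for v in tree.tips:
        lab = tree.labels[v]
        if lab not in ranges:
            raise DECError(f"tip {lab!r} has no range assignment")
        mask = int(ranges[lab])
        if mask == 0:
            raise DECError(f"tip {lab!r} has an empty range")
        if mask not in space.index:
            raise DECError(f"tip {lab!r} range {mask:#x} not in permitted state space")
        vec = np.zeros(space.n_states)
        vec[space.index[mask]] = 1.0
        out[v] = vec
    return out


def _root_weights(space: StateSpace, prior: str) -> np.ndarray:
    w = np.zeros(space.n_states)
    for i, m in enumerate(space.masks):
        w[i] = 1.0 if prior == "flat" else 1.0 / _popcount(m)
    return w


def _branch_propagate(props: _Propagators, model: StratifiedModel,
                      young: float, old: float, vec: np.ndarray,
                      down: bool) -> np.ndarray:
    """Propagate a conditional-likelihood vector along one branch.

    ``down=True``: vec indexed by the child-end state, returns vector indexed
    by the parent-end state (applies the per-segment matrices oldest-first,
    i.e. right-multiplies youngest first).  ``down=False`` is the transpose
    direction used by the outside pass.
    """
    segs = model.segments(young, old)
    if down:
        for e, dt in reversed(segs):   # youngest applied to vec first
            vec = props.matvec(e, dt, vec)
    else:
        for e, dt in segs:             # oldest first
            vec = props.vecmat(e, dt, vec)
    return vec


def likelihood(tree: UltrametricTree, ranges: dict[str, int],
               params: DECParams, model: StratifiedModel,
               space: StateSpace | None = None,
               root_prior: str = "flat") -> float:
    """Log-likelihood of tip ranges under time-stratified DEC (pruning).

    ``ranges`` maps tip label -> area bitmask.  The root likelihood is the
    ``root_prior``-weighted sum of clado-combined conditional likelihoods over
    non-null root ranges (flat = unweighted).
    """
    logL, _, _ = _pruning(tree, ranges, params, model, space, root_prior)
    return logL


def _pruning(tree, ranges, params, model, space, root_prior):
    if not tree.is_bifurcating():
        raise TreeError("DEC likelihood requires a strictly bifurcating tree")
    if space is None:
        space = master_state_space(model.scheme, model)
    Qs = [anagenetic_generator(params, model, e, space)
          for e in range(model.n_epochs)]
    props = _Propagators(Qs)
    clado = _clado_tables(space)
    tipvec = _tip_vectors(tree, ranges, space)
    S = space.n_states

    c_par, c_left, c_right, c_prob = clado
    cond = {}        # node -> clado-combined conditional likelihood at node
    up = {}          # node -> conditional propagated to the top of its branch
    logscale = 0.0
    for v in tree.postorder():
        if not tree.children[v]:
            L = tipvec[v]
        else:
            a, b = (up[c] for c in tree.children[v])
            L = np.bincount(c_par, weights=c_prob * a[c_left] * b[c_right],
                            minlength=S)
        mx = float(L.max())
        if mx <= 0 or not np.isfinite(mx):
            raise DECError(f"non-finite or zero conditional likelihood at node {v}")
        L = L / mx
        logscale += np.log(mx)
        cond[v] = L
        p = tree.parent[v]
        if p >= 0:
            up[v] = _branch_propagate(props, model, float(tree.age[v]),
                                      float(tree.age[p]), L, down=True)
    w = _root_weights(space, root_prior)
    rootL = float(np.dot(w, cond[tree.root]))
    if rootL <= 0 or not np.isfinite(rootL):
        raise DECError("zero root likelihood")
    return logscale + np.log(rootL), (space, props, clado, cond, up), tipvec


def _marginals(tree, model, space, props, clado, cond, up, root_prior):
    """Marginal ancestral range probabilities by an outside (preorder) pass."""
    S = space.n_states
    c_par, c_left, c_right, c_prob = clado
    probs = np.zeros((tree.n_nodes, S))
    outside = {}
    w = _root_weights(space, root_prior)
    outside[tree.root] = w
    for v in tree.preorder():
        O = outside[v]
        m = O * cond[v]
        tot = m.sum()
        probs[v] = m / tot if tot > 0 else m
        kids = tree.children[v]
        if not kids:
            continue
        a, b = (up[c] for c in kids)
        # outside vectors at the top of each child branch
        base = O[c_par] * c_prob
        Oa = np.bincount(c_left, weights=base * b[c_right], minlength=S)
        Ob = np.bincount(c_right, weights=base * a[c_left], minlength=S)
        for c, Otop in zip(kids, (Oa, Ob)):
            outside[c] = _branch_propagate(
                props, model, float(tree.age[c]), float(tree.age[v]),
                Otop, down=False)
    return probs


@dataclass
class DECFit:
    """ML fit of the DEC model with per-node marginal range probabilities."""

    params: DECParams
    logL: float
    space: StateSpace
    node_probs: np.ndarray        # (n_nodes, n_states)
    most_probable: np.ndarray     # (n_nodes,) bitmasks
    converged: bool = True
    n_starts: int = 0

    def node_table(self, tree: UltrametricTree) -> pd.DataFrame:
        rows = []
        labels = self.space.labels()
        for v in range(tree.n_nodes):
            best = self.most_probable[v]
            rows.append({
                "node": v,
                "age": float(tree.age[v]),
                "is_tip": not tree.children[v],
                "label": tree.labels[v] or "",
                "best_range": "+".join(self.space.scheme.unmask(int(best))),
                **{labels[i]: self.node_probs[v, i]
                   for i in range(self.space.n_states)},
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({"d": self.params.d, "e": self.params.e,
                           "logL": self.logL, "converged": self.converged})


def fit_ml(tree: UltrametricTree, ranges: dict[str, int],
           model: StratifiedModel, space: StateSpace | None = None,
           root_prior: str = "flat", n_starts: int = 3,
           x0: tuple[float, float] = (0.05, 0.05),
           xatol: float = 1e-6, fatol: float = 1e-9) -> DECFit:
    """Maximum-likelihood d, e with marginal ancestral ranges at the optimum.

    Optimises on (log d, log e) with multi-start Nelder-Mead; ancestral
    marginals are computed by the standard outside/conditioning pass at the
    ML point, and the most probable range per node recorded (ties broken by
    smallest range, then lexicographic area order).
    """
    if space is None:
        space = master_state_space(model.scheme, model)

    def nll(x):
        d, e = np.exp(x)
        if d > 1e3 or e > 1e3:
            return 1e10
        try:
            return -likelihood(tree, ranges, DECParams(d, e), model,
                               space, root_prior)
        except DECError:
            return 1e10

    starts = [np.log(np.asarray(x0, dtype=float))]
    rng = np.random.default_rng(0)
    for _ in range(n_starts - 1):
        starts.append(np.log(np.asarray(x0)) + rng.normal(0, 1.5, size=2))
    best = None
    for s in starts:
        res = scipy.optimize.minimize(nll, s, method="Nelder-Mead",
                                      options={"xatol": xatol, "fatol": fatol,
                                               "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    d, e = np.exp(best.x)
    params = DECParams(float(d), float(e))
    logL, internals, _ = _pruning(tree, ranges, params, model, space, root_prior)
    space_, props, clado, cond, up = internals
    probs = _marginals(tree, model, space, props, clado, cond, up, root_prior)
    # argmax over the (size, lexicographic) state ordering breaks ties as spec'd
    best_idx = np.argmax(probs[:, :space.n_states - 1], axis=1)
    most = np.array([space.masks[i] for i in best_idx])
    return DECFit(params=params, logL=float(logL), space=space,
                  node_probs=probs, most_probable=most,
                  converged=bool(best.success), n_starts=len(starts))


# ---------------------------------------------------------------------------
# Dispersal events
# ---------------------------------------------------------------------------

@dataclass
class DispersalEvent:
    """An area gain along a branch, with optional stochastic timing draws."""

    branch: int                # child node id of the branch
    source_mask: int           # parent range at the time of the gain
    gained_area: int           # area index gained
    old_age: float             # parent node age
    young_age: float           # child node age
    times: np.ndarray | None = None


def extract_dispersal_events(tree: UltrametricTree,
                             node_masks: np.ndarray | dict[int, int]
                             ) -> list[DispersalEvent]:
    """Area gains implied by most-probable ranges at branch endpoints.

    Each area in (child range minus parent range) yields one event with the
    full parent range as source; pure losses are extirpations, not events.
    """
    events = []
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        child = int(node_masks[v])
        par = int(node_masks[p])
        gains = child & ~par
        for b in _bits(gains):
            events.append(DispersalEvent(
                branch=v, source_mask=par, gained_area=b,
                old_age=float(tree.age[p]), young_age=float(tree.age[v])))
    return events


# ---------------------------------------------------------------------------
# Range-table I/O
# ---------------------------------------------------------------------------

def read_range_table(path, scheme: AreaScheme) -> dict[str, int]:
    """TSV with tip_label column then one 0/1 column per area."""
    df = pd.read_csv(path, sep="\t")
    missing = [a for a in scheme.names if a not in df.columns]
    if missing:
        raise DECError(f"range table missing area columns: {missing}")
    out = {}
    for _, row in df.iterrows():
        mask = 0
        for i, a in enumerate(scheme.names):
            if int(row[a]):
                mask |= 1 << i
        if mask == 0:
            raise DECError(f"tip {row.iloc[0]!r} assigned empty range")
        out[str(row.iloc[0])] = mask
    return out


def write_range_table(ranges: dict[str, int], scheme: AreaScheme, path) -> None:
    rows = []
    for lab, mask in ranges.items():
        rows.append({"tip_label": lab,
                     **{a: (mask >> i) & 1 for i, a in enumerate(scheme.names)}})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
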