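"""Time-stratified DEC: state space, generators, likelihood, ancestral ranges."""

import itertools

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

import biogeodiv.dec as D
from biogeodiv.dec import (AreaScheme, DECParams, StratifiedModel,
                           anagenetic_generator, build_state_space,
                           clado_distribution, extract_dispersal_events,
                           fit_ml, likelihood, master_state_space)
from biogeodiv.phylo import parse_newick
from biogeodiv.simulate import SimConfig, simulate_ranges, simulate_tree


# --------------------------------------------------------------------------
# Independent enumeration oracle (used again by the acceptance suite)
# --------------------------------------------------------------------------

def series_expm(Q, t, K=60):
    """Matrix exponential by scaled Taylor series, coded independently."""
    m = max(1, int(np.ceil(np.max(np.abs(Q)) * t)))
    A = np.asarray(Q) * t / m
    S = np.eye(len(Q))
    term = np.eye(len(Q))
    for k in range(1, K):
        term = term @ A / k
        S = S + term
    R = np.eye(len(Q))
    for _ in range(m):
        R = R @ S
    return R


def brute_force_logL(tree, ranges, params, model, space, root_prior="flat"):
    """Sum over every combination of ancestral states and clado outcomes."""
    Qs = [anagenetic_generator(params, model, e, space)
          for e in range(model.n_epochs)]

    def pbranch(young, old):
        P = np.eye(space.n_states)
        for e, dt in model.segments(young, old):
            P = P @ series_expm(Qs[e], dt)
        return P

    Pb = {v: pbranch(float(tree.age[v]), float(tree.age[tree.parent[v]]))
          for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = [v for v in range(tree.n_nodes) if tree.children[v]]
    tipstate = {v: space.index[ranges[tree.labels[v]]] for v in tree.tips}
    S = space.n_states
    clados = {i: [(space.index[l], space.index[r], p)
                  for l, r, p in clado_distribution(space.masks[i])
                  if l in space.index and r in space.index]
              for i in range(S - 1)}
    total = 0.0
    for assign in itertools.product(range(S - 1), repeat=len(internals)):
        amap = dict(zip(internals, assign))
        prob = 1.0
        for v in internals:
            def below(c, top):
                tgt = amap[c] if tree.children[c] else tipstate[c]
                return Pb[c][top, tgt]
            c1, c2 = tree.children[v]
            prob *= sum(p * below(c1, l) * below(c2, r)
                        for l, r, p in clados[amap[v]])
        total += prob   # flat root prior: unweighted sum
    return np.log(total)


# --------------------------------------------------------------------------
# State space
# --------------------------------------------------------------------------

class TestStateSpace:
    def test_two_areas_full_adjacency(self, scheme3):
        scheme = AreaScheme(("A", "B"))
        model = StratifiedModel.uniform(scheme, 10.0)
        sp = build_state_space(scheme, model, 0)
        assert sp.labels() == ["A", "B", "A+B", "null"]

    def test_nine_areas_full_adjacency_counts(self):
        scheme = AreaScheme()
        model = StratifiedModel.uniform(scheme, 200.0)
        sp = build_state_space(scheme, model, 0)
        assert len(sp.masks) == 2 ** 9 - 1  # enumeration: all non-empty subsets
        assert sp.n_states == 512

    def test_missing_adjacency_excludes_disconnected(self, scheme3):
        adj = np.ones((1, 3, 3), dtype=int)
        adj[0, 0, 2] = adj[0, 2, 0] = 0  # no A-C edge
        model = StratifiedModel(scheme=scheme3, epochs=((10.0, 0.0),),
                                adjacency=adj)
        sp = build_state_space(scheme3, model, 0)
        assert scheme3.mask(["A", "C"]) not in sp.index
        assert scheme3.mask(["A", "B", "C"]) in sp.index  # connected via B

    def test_max_range_size_cap(self):
        scheme = AreaScheme(("A", "B", "C"), max_range_size=2)
        model = StratifiedModel.uniform(scheme, 10.0)
        sp = build_state_space(scheme, model, 0)
        assert max(bin(m).count("1") for m in sp.masks) == 2


class TestGenerator:
    def test_gain_rate_definition(self, scheme3, flat_model3):
        sp = master_state_space(scheme3, flat_model3)
        disp = np.ones((1, 3, 3))
        disp[0, 0, 1] = 0.4
        model = StratifiedModel(scheme=scheme3, epochs=((1000.0, 0.0),),
                                dispersal=disp)
        Q = anagenetic_generator(DECParams(0.1, 0.0), model, 0, sp)
        iA = sp.index[scheme3.mask("A")]
        iAB = sp.index[scheme3.mask(["A", "B"])]
        assert Q[iA, iAB] == pytest.approx(0.1 * 0.4)

    def test_zero_rates_zero_matrix(self, scheme3, flat_model3):
        sp = master_state_space(scheme3, flat_model3)
        Q = anagenetic_generator(DECParams(0.0, 0.0), flat_model3, 0, sp)
        assert np.all(Q == 0.0)

    def test_rows_sum_to_zero_and_null_absorbing(self, scheme4, flat_model4):
        sp = master_state_space(scheme4, flat_model4)
        Q = anagenetic_generator(DECParams(0.07, 0.31), flat_model4, 0, sp)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-12
        assert np.all(Q[sp.null_index] == 0.0)

    def test_transition_matrices_stochastic(self, scheme4, flat_model4):
        sp = master_state_space(scheme4, flat_model4)
        Q = anagenetic_generator(DECParams(0.05, 0.02), flat_model4, 0, sp)
        for t in (0.5, 7.0, 40.0, 100.0):
            P = scipy.linalg.expm(Q * t)
            assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-9
            assert P.min() > -1e-12


class TestClado:
    def test_single_area_identity(self):
        assert clado_distribution(0b001) == [(1, 1, 1.0)]

    def test_two_area_six_outcomes(self):
        outs = clado_distribution(0b011)
        assert len(outs) == 6
        assert all(p == pytest.approx(1 / 6) for _, _, p in outs)
        assert set((l, r) for l, r, _ in outs) == {
            (0b001, 0b010), (0b010, 0b001), (0b001, 0b011),
            (0b011, 0b001), (0b010, 0b011), (0b011, 0b010)}

    @pytest.mark.parametrize("mask", [0b111, 0b1011, 0b11111])
    def test_probabilities_sum_to_one(self, mask):
        outs = clado_distribution(mask)
        k = bin(mask).count("1")
        assert len(outs) == 4 * k
        assert sum(p for _, _, p in outs) == pytest.approx(1.0, abs=1e-12)

    def test_null_parent_rejected(self):
        with pytest.raises(ValueError):
            clado_distribution(0)

    @given(mask=st.integers(min_value=1, max_value=2 ** 9 - 1))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_outcome_structure_property(self, mask):
        """Daughters always jointly cover the parent, one daughter is a
        single area or the full range, and probabilities are uniform."""
        outs = clado_distribution(mask)
        k = bin(mask).count("1")
        assert sum(p for _, _, p in outs) == pytest.approx(1.0, abs=1e-12)
        assert len(set((l, r) for l, r, _ in outs)) == len(outs)
        for l, r, p in outs:
            assert l | r == mask
            assert p == pytest.approx(1.0 / len(outs))
            if k > 1:
                assert 1 in (bin(l).count("1"), bin(r).count("1"))


# --------------------------------------------------------------------------
# Likelihood
# --------------------------------------------------------------------------

class TestLikelihood:
    def test_frozen_ranges_concentrate_on_shared_area(self, scheme3,
                                                      flat_model3):
        t = parse_newick("(A:1,B:1);")
        ranges = {"A": 1, "B": 1}
        from biogeodiv.dec import _pruning
        _, internals, _ = _pruning(t, ranges, DECParams(0.0, 0.0),
                                   flat_model3, None, "flat")
        space, _, _, cond, _ = internals
        root_cond = cond[t.root]
        assert np.argmax(root_cond) == space.index[1]
        others = np.delete(root_cond, space.index[1])
        assert np.all(others == 0.0)

    def test_matches_enumeration_on_three_tip_case(self, scheme3):
        model = StratifiedModel(scheme=scheme3,
                                epochs=((4.0, 1.0), (1.0, 0.0)))
        sp = master_state_space(scheme3, model)
        t = parse_newick("((A:1.2,B:1.2):1.3,C:2.5);")
        ranges = {"A": 0b001, "B": 0b011, "C": 0b100}
        p = DECParams(0.05, 0.02)
        ll = likelihood(t, ranges, p, model, sp)
        oracle = brute_force_logL(t, ranges, p, model, sp)
        assert abs(ll - oracle) / abs(oracle) < 1e-8

    def test_area_relabeling_symmetry(self, scheme3, flat_model3):
        t = parse_newick("((A:1,B:1):1,C:2);")
        p = DECParams(0.08, 0.03)
        ll1 = likelihood(t, {"A": 0b001, "B": 0b010, "C": 0b100}, p,
                         flat_model3)
        # permute areas (A<->C) consistently
        ll2 = likelihood(t, {"A": 0b100, "B": 0b010, "C": 0b001}, p,
                         flat_model3)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_single_epoch_equals_boundary_split(self, scheme3):
        """Stratified model with identical epochs = unstratified model."""
        flat = StratifiedModel.uniform(scheme3, 1000.0)
        split = StratifiedModel(scheme=scheme3,
                                epochs=((1000.0, 1.7), (1.7, 0.6), (0.6, 0.0)))
        t = parse_newick("((A:1,B:1):1.5,(C:2,D:2):0.5);")
        ranges = {"A": 0b001, "B": 0b011, "C": 0b100, "D": 0b110}
        p = DECParams(0.12, 0.04)
        assert likelihood(t, ranges, p, flat) == pytest.approx(
            likelihood(t, ranges, p, split), abs=1e-9)

    def test_state_space_pruning_sanity(self, scheme3):
        """An adjacency cut yields a self-consistent pruned model: the
        explicit per-epoch space equals the master space, the generator on it
        stays stochastic, and the likelihood matches the enumeration oracle
        on the pruned space."""
        t = parse_newick("((A:1,B:1):1,C:2);")
        ranges = {"A": 0b001, "B": 0b001, "C": 0b010}
        adj = np.ones((1, 3, 3), dtype=int)
        adj[0, 0, 2] = adj[0, 2, 0] = 0
        cut = StratifiedModel(scheme=scheme3, epochs=((1000.0, 0.0),),
                              adjacency=adj)
        sp_epoch = build_state_space(scheme3, cut, 0)
        sp_master = master_state_space(scheme3, cut)
        assert sp_epoch.masks == sp_master.masks
        assert scheme3.mask(["A", "C"]) not in sp_master.index
        p = DECParams(0.05, 0.01)
        Q = anagenetic_generator(p, cut, 0, sp_master)
        P = scipy.linalg.expm(Q * 7.3)
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-9
        ll = likelihood(t, ranges, p, cut)
        oracle = brute_force_logL(t, ranges, p, cut, sp_master)
        assert abs(ll - oracle) / abs(oracle) < 1e-8

    def test_unassigned_tip_and_bad_range_rejected(self, scheme3,
                                                   flat_model3):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            likelihood(t, {"A": 1}, DECParams(0.1, 0.1), flat_model3)
        with pytest.raises(ValueError):
            likelihood(t, {"A": 1, "B": 0}, DECParams(0.1, 0.1), flat_model3)


@pytest.fixture(scope="module")
def sim_study(scheme4, flat_model4):
    cfg = SimConfig(seed=3, lam0=0.18, alpha=0.0, mu=0.03,
                    crown_age=30.0, n_tips=120)
    tree, _ = simulate_tree(cfg)
    ranges, node_masks, events, info = simulate_ranges(
        tree, DECParams(0.03, 0.01), flat_model4, seed=3, root_mask=1)
    if info["range_extinct"]:
        tree = tree.prune_tips(info["range_extinct"])
    return tree, ranges


class TestFit:

    def test_mle_beats_truth_and_marginals_normalised(self, sim_study,
                                                      flat_model4):
        tree, ranges = sim_study
        fit = fit_ml(tree, ranges, flat_model4, n_starts=2, xatol=1e-4)
        ll_truth = likelihood(tree, ranges, DECParams(0.03, 0.01),
                              flat_model4)
        assert fit.logL >= ll_truth - 1e-6
        sums = fit.node_probs.sum(axis=1)
        assert np.max(np.abs(sums - 1.0)) < 1e-9

    def test_most_probable_tie_break_prefers_small_ranges(self, scheme3,
                                                          flat_model3):
        # with d=e=0 and a single tip range the root marginal is degenerate
        t = parse_newick("(A:1,B:1);")
        fit = fit_ml(t, {"A": 0b001, "B": 0b001}, flat_model3, n_starts=1)
        assert fit.most_probable[t.root] == 0b001


class TestDispersalEvents:
    def test_gain_loss_and_identity_rules(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        # node ids: preorder root=0
        masks = np.zeros(t.n_nodes, dtype=int)
        idx = t.tip_index()
        masks[t.root] = 0b001
        inner = [v for v in range(t.n_nodes)
                 if t.children[v] and v != t.root][0]
        masks[inner] = 0b011           # gained B on the inner branch
        masks[idx["A"]] = 0b011        # unchanged: no event
        masks[idx["B"]] = 0b100        # B: lost A,B gained C -> one event
        masks[idx["C"]] = 0b001        # unchanged
        events = extract_dispersal_events(t, masks)
        by_branch = {(e.branch, e.gained_area): e for e in events}
        assert len(events) == 2
        assert (inner, 1) in by_branch
        ev = by_branch[(inner, 1)]
        assert ev.source_mask == 0b001
        assert (idx["B"], 2) in by_branch
        assert by_branch[(idx["B"], 2)].source_mask == 0b011
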