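"""Configuration-driven orchestration of the analysis stages.

Stages run in dependency order on a shared output directory:

    simulate -> dec-fit -> ancestral -> events -> combine
                                     \-> clades -> fit-bd -> stats

Every stage writes plain-text artifacts (Newick/TSV/CSV/JSON) plus an entry
in ``manifest.json`` recording the config hash, seed, produced files and
timing, so identical config+seed reruns are byte-reproducible and stale
caches are detected by hash mismatch.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .phylo import UltrametricTree, read_newick, write_newick, branching_times
from .dec import (AreaScheme, StratifiedModel, DECParams, NINE_AREAS,
                  DEFAULT_EPOCHS, master_state_space, fit_ml, likelihood,
                  extract_dispersal_events, read_range_table,
                  write_range_table, DispersalEvent)
from .branch_rates import (parse_shift_config, posterior_mean_rates,
                           rates_on_grid, constant_regime, MappedRegime,
                           RateRegime, rate_series_table)
from .combine import (AreaMerge, EpochTable, nine_to_six, nine_to_five,
                      DEFAULT_PERIODS, draw_event_times,
                      epoch_dispersal_percentages, lineage_area_frequency,
                      windowed_regional_rates)
from .regional import (find_regional_clades, assign_richness, fit_tdbd,
                       clade_report)
from .stats import anova_tukey, hierarchical_partitioning
from .simulate import (SimConfig, simulate_tree, simulate_ranges,
                       subsample_tips, label_genera, write_shift_config)

__all__ = ["RunConfig", "run", "STAGES"]

STAGES = ("simulate", "dec-fit", "ancestral", "events", "combine",
          "clades", "fit-bd", "stats")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Validated settings for a pipeline run (YAML-loadable)."""

    out_dir: str = "out"
    seed: int = 0
    # inputs (paths); unset tree/ranges means the simulate stage provides them
    tree: str | None = None
    ranges: str | None = None
    shift_config: str | None = None
    richness: str | None = None
    # model
    areas: tuple[str, ...] = NINE_AREAS
    max_range_size: int | None = None
    epochs: tuple[tuple[float, float], ...] | None = None
    dispersal: list | None = None
    adjacency: list | None = None
    root_prior: str = "flat"
    # summary settings (printed-default values)
    n_draws: int = 1000
    n_rep: int = 100
    window: float = 4.0
    step: float = 1.0
    bin_width: float = 0.5
    grid_step: float = 0.5
    min_tips: int = 4
    purity: float = 0.90
    periods: tuple = DEFAULT_PERIODS
    # synthetic-data settings
    sim: dict = field(default_factory=dict)

    def __post_init__(self):
        self.areas = tuple(self.areas)
        if self.epochs is not None:
            self.epochs = tuple(tuple(e) for e in self.epochs)
        self.periods = tuple(tuple(p) for p in self.periods)
        for name, val, lo in (("n_draws", self.n_draws, 1),
                              ("n_rep", self.n_rep, 1),
                              ("min_tips", self.min_tips, 2)):
            if val < lo:
                raise PipelineError(f"{name} must be >= {lo}")
        for name, val in (("window", self.window), ("step", self.step),
                          ("bin_width", self.bin_width),
                          ("grid_step", self.grid_step)):
            if val <= 0:
                raise PipelineError(f"{name} must be positive")
        if not (0 < self.purity <= 1):
            raise PipelineError("purity must be in (0, 1]")
        for key in ("tree", "ranges", "shift_config", "richness"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"{key} file does not exist: {p}")
        self.scheme()   # validates area names
        self.model(root_age_hint=None)  # validates epochs/matrices

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def scheme(self) -> AreaScheme:
        return AreaScheme(tuple(self.areas), self.max_range_size)

    def model(self, root_age_hint: float | None) -> StratifiedModel:
        scheme = self.scheme()
        if self.epochs is not None:
            epochs = self.epochs
        elif tuple(self.areas) == NINE_AREAS:
            epochs = DEFAULT_EPOCHS
        else:
            oldest = max(1000.0, 2 * (root_age_hint or 500.0))
            epochs = ((oldest, 0.0),)
        disp = np.asarray(self.dispersal, dtype=float) \
            if self.dispersal is not None else None
        adj = np.asarray(self.adjacency, dtype=int) \
            if self.adjacency is not None else None
        return StratifiedModel(scheme=scheme, epochs=epochs,
                               dispersal=disp, adjacency=adj)

    def merge6(self) -> AreaMerge:
        scheme = self.scheme()
        if tuple(self.areas) == NINE_AREAS:
            return nine_to_six(scheme)
        return AreaMerge(source=scheme, regions=tuple(self.areas),
                         assignment=tuple(range(len(self.areas))))

    def merge5(self) -> AreaMerge:
        scheme = self.scheme()
        if tuple(self.areas) == NINE_AREAS:
            return nine_to_five(scheme)
        return self.merge6()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------

class _Run:
    """Mutable pipeline state: lazily loaded artifacts keyed by stage."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "manifest.json"
        self.manifest = (json.loads(self.manifest_path.read_text())
                         if self.manifest_path.exists() else
                         {"version": __version__, "stages": {}})

    # -- manifest ----------------------------------------------------------
    def record(self, stage: str, files: list[str], t0: float) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": self.cfg.config_hash(),
            "seed": self.cfg.seed,
            "files": sorted(files),
            "seconds": round(time.time() - t0, 3),
        }
        self.manifest["version"] = __version__
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2,
                                                 sort_keys=True) + "\n")

    def cached(self, stage: str) -> bool:
        ent = self.manifest["stages"].get(stage)
        if not ent or ent["config_hash"] != self.cfg.config_hash():
            return False
        return all((self.out / f).exists() for f in ent["files"])

    def need(self, stage: str, path: str) -> Path:
        p = self.out / path
        if not p.exists():
            raise PipelineError(
                f"missing upstream artifact {path}; run stage '{stage}' first")
        return p

    # -- inputs ------------------------------------------------------------
    def tree(self) -> UltrametricTree:
        if self.cfg.tree:
            return read_newick(self.cfg.tree)
        return read_newick(self.need("simulate", "tree.nwk"))

    def ranges(self, scheme) -> dict[str, int]:
        src = self.cfg.ranges or self.need("simulate", "ranges.tsv")
        return read_range_table(src, scheme)

    def richness_table(self) -> dict[str, int]:
        src = self.cfg.richness
        if src is None:
            p = self.out / "richness.tsv"
            src = p if p.exists() else None
        if src is None:
            return {}
        df = pd.read_csv(src, sep="\t")
        return dict(zip(df.iloc[:, 0].astype(str), df["described"].astype(int)))

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> list[str]:
        cfg = self.cfg
        s = dict(cfg.sim)
        root_area = s.pop("root_area", cfg.areas[0])
        scheme = cfg.scheme()
        d = s.pop("d", 0.02)
        e = s.pop("e", 0.005)
        sim_cfg = SimConfig(seed=cfg.seed, root_mask=scheme.mask(root_area),
                            scheme=scheme, dec_params=DECParams(d, e), **s)
        tree, info = simulate_tree(sim_cfg)
        tree = label_genera(tree, seed=cfg.seed + 1)
        model = cfg.model(root_age_hint=tree.root_age)
        ranges, node_masks, events, rinfo = simulate_ranges(
            tree, sim_cfg.dec_params, model, seed=cfg.seed + 2,
            root_mask=sim_cfg.root_mask)
        if rinfo["range_extinct"]:
            tree = tree.prune_tips(rinfo["range_extinct"])
            keep = set(tree.tip_labels)
            ranges = {k: v for k, v in ranges.items() if k in keep}
        if sim_cfg.rho < 1.0:
            tree, gtable = subsample_tips(tree, sim_cfg.rho, seed=cfg.seed + 3)
            keep = set(tree.tip_labels)
            ranges = {k: v for k, v in ranges.items() if k in keep}
        else:
            _, gtable = subsample_tips(tree, 1.0, seed=cfg.seed + 3)
        write_newick(tree, self.out / "tree.nwk")
        write_range_table(ranges, scheme, self.out / "ranges.tsv")
        gtable.to_csv(self.out / "richness.tsv", sep="\t", index=False)
        regimes = {0: constant_regime(tree, sim_cfg.lam0, sim_cfg.mu)}
        write_shift_config(tree, regimes, self.out / "event_data.csv")
        truth = {"sim": {k: v for k, v in asdict(sim_cfg).items()
                         if not isinstance(v, (dict, DECParams))},
                 "dec": {"d": sim_cfg.dec_params.d, "e": sim_cfg.dec_params.e},
                 "info": {**info, "range_extinct":
                          rinfo["range_extinct"], "n_events": rinfo["n_events"]}}
        (self.out / "truth.json").write_text(
            json.dumps(truth, indent=2, default=str) + "\n")
        return ["tree.nwk", "ranges.tsv", "richness.tsv", "event_data.csv",
                "truth.json"]

    def stage_dec_fit(self) -> list[str]:
        tree = self.tree()
        scheme = self.cfg.scheme()
        model = self.cfg.model(root_age_hint=tree.root_age)
        ranges = self.ranges(scheme)
        fit = fit_ml(tree, ranges, model, root_prior=self.cfg.root_prior)
        (self.out / "dec_fit.json").write_text(fit.to_json() + "\n")
        self._dec_fit = fit
        return ["dec_fit.json"]

    def _load_dec(self, tree, model):
        fit = getattr(self, "_dec_fit", None)
        if fit is not None:
            return fit
        params_path = self.need("dec-fit", "dec_fit.json")
        p = json.loads(params_path.read_text())
        scheme = self.cfg.scheme()
        ranges = self.ranges(scheme)
        space = master_state_space(scheme, model)
        from .dec import _pruning, _marginals, DECFit
        params = DECParams(p["d"], p["e"])
        logL, internals, _ = _pruning(tree, ranges, params, model, space,
                                      self.cfg.root_prior)
        _, props, clado, cond, up = internals
        probs = _marginals(tree, model, space, props, clado, cond, up,
                           self.cfg.root_prior)
        best_idx = np.argmax(probs[:, :space.n_states - 1], axis=1)
        most = np.array([space.masks[i] for i in best_idx])
        fit = DECFit(params=params, logL=float(logL), space=space,
                     node_probs=probs, most_probable=most)
        self._dec_fit = fit
        return fit

    def stage_ancestral(self) -> list[str]:
        tree = self.tree()
        model = self.cfg.model(root_age_hint=tree.root_age)
        fit = self._load_dec(tree, model)
        fit.node_table(tree).to_csv(self.out / "node_ranges.tsv", sep="\t",
                                    index=False)
        ann = tree.copy()
        for v in range(ann.n_nodes):
            if ann.children[v]:
                ann.labels[v] = f"N{v}"
        write_newick(ann, self.out / "tree_annotated.nwk")
        return ["node_ranges.tsv", "tree_annotated.nwk"]

    def stage_events(self) -> list[str]:
        tree = self.tree()
        model = self.cfg.model(root_age_hint=tree.root_age)
        fit = self._load_dec(tree, model)
        events = extract_dispersal_events(tree, fit.most_probable)
        draw_event_times(events, self.cfg.n_draws, self.cfg.seed + 10)
        rows = []
        scheme = self.cfg.scheme()
        for k, ev in enumerate(events):
            rows.append({"event": k, "branch": ev.branch,
                         "source": "+".join(scheme.unmask(ev.source_mask)),
                         "gained": scheme.names[ev.gained_area],
                         "old_age": ev.old_age, "young_age": ev.young_age,
                         "mean_time": float(np.mean(ev.times))})
        pd.DataFrame(rows).to_csv(self.out / "events.tsv", sep="\t",
                                  index=False)
        self._events = events
        return ["events.tsv"]

    def _load_events(self, tree, model):
        events = getattr(self, "_events", None)
        if events is None:
            fit = self._load_dec(tree, model)
            events = extract_dispersal_events(tree, fit.most_probable)
            draw_event_times(events, self.cfg.n_draws, self.cfg.seed + 10)
        return events

    def stage_combine(self) -> list[str]:
        cfg = self.cfg
        tree = self.tree()
        model = cfg.model(root_age_hint=tree.root_age)
        fit = self._load_dec(tree, model)
        events = self._load_events(tree, model)
        merge = cfg.merge6()
        table = EpochTable(cfg.periods)
        disp = epoch_dispersal_percentages(events, table, merge)
        disp.frame().to_csv(self.out / "epoch_dispersal.tsv", sep="\t",
                            index=False)
        laf = lineage_area_frequency(tree, fit.most_probable, merge,
                                     cfg.bin_width)
        laf.to_csv(self.out / "lineage_area_frequency.tsv", sep="\t",
                   index=False)
        if cfg.shift_config:
            samples = parse_shift_config(cfg.shift_config, tree)
        else:
            p = self.out / "event_data.csv"
            if p.exists():
                samples = parse_shift_config(p, tree)
            else:
                raise PipelineError("no shift_config and no simulated "
                                    "event_data.csv; run 'simulate' first")
        series = posterior_mean_rates(tree, samples, cfg.grid_step)
        rate_series_table(series).to_csv(self.out / "branch_rates.tsv",
                                         sep="\t", index=False)
        wrr = windowed_regional_rates(
            tree, series, fit.most_probable, events=events, merge=merge,
            window=cfg.window, step=cfg.step, n_rep=cfg.n_rep,
            seed=cfg.seed + 20)
        wrr.summary().to_csv(self.out / "windowed_rates.tsv", sep="\t",
                             index=False)
        return ["epoch_dispersal.tsv", "lineage_area_frequency.tsv",
                "branch_rates.tsv", "windowed_rates.tsv"]

    def stage_clades(self) -> list[str]:
        cfg = self.cfg
        tree = self.tree()
        model = cfg.model(root_age_hint=tree.root_age)
        fit = self._load_dec(tree, model)
        merge = cfg.merge5()
        region_masks = np.array([merge.merge_mask(int(m))
                                 for m in fit.most_probable])
        events = find_regional_clades(tree, region_masks, merge,
                                      cfg.min_tips, cfg.purity)
        assign_richness(events, self.richness_table())
        rows = [{"clade": ev.node, "region": ev.region, "n": ev.n_tips,
                 "richness": ev.richness, "f": ev.f,
                 "crown_age": ev.crown_age,
                 "tips": ";".join(ev.tip_labels)} for ev in events]
        pd.DataFrame(rows).to_csv(self.out / "clades.tsv", sep="\t",
                                  index=False)
        self._clades = events
        return ["clades.tsv"]

    def _load_clades(self, tree):
        clades = getattr(self, "_clades", None)
        if clades is not None:
            return clades
        path = self.need("clades", "clades.tsv")
        df = pd.read_csv(path, sep="\t")
        from .regional import CladeEvent
        out = []
        for _, r in df.iterrows():
            out.append(CladeEvent(node=int(r["clade"]), region=r["region"],
                                  n_tips=int(r["n"]),
                                  tip_labels=str(r["tips"]).split(";"),
                                  crown_age=float(r["crown_age"]),
                                  richness=int(r["richness"]),
                                  f=float(r["f"])))
        return out

    def stage_fit_bd(self) -> list[str]:
        tree = self.tree()
        clades = self._load_clades(tree)
        fits = []
        kept = []
        for ev in clades:
            sub = tree.subtree_on_tips(ev.tip_labels)
            x = branching_times(sub)
            if len(x) < 2:
                continue
            fits.append(fit_tdbd(x, f=ev.f or 1.0, seed=self.cfg.seed + 30))
            kept.append(ev)
        report = clade_report(kept, fits)
        report.to_csv(self.out / "clade_fits.tsv", sep="\t", index=False)
        return ["clade_fits.tsv"]

    def stage_stats(self) -> list[str]:
        path = self.need("fit-bd", "clade_fits.tsv")
        df = pd.read_csv(path, sep="\t")
        out = {}
        for param in ("crown_age", "netdiv0", "netdiv_crown", "alpha",
                      "richness"):
            groups = {r: g[param].to_numpy()
                      for r, g in df.groupby("region") if len(g) >= 2}
            if len(groups) < 2:
                continue
            try:
                res = anova_tukey(groups)
            except ValueError as exc:
                out[param] = {"error": str(exc)}
                continue
            out[param] = {"F": res.F, "p": res.p,
                          "tukey": (res.tukey.to_dict("records")
                                    if res.tukey is not None else None),
                          "reason": res.reason}
        hp_out = {}
        preds = ["crown_age", "netdiv0", "netdiv_crown", "alpha"]
        for region, g in df.groupby("region"):
            if len(g) < len(preds) + 2:
                hp_out[region] = {"skipped": f"only {len(g)} clades"}
                continue
            hp = hierarchical_partitioning(g["richness"], g[preds],
                                           log_response=True)
            hp_out[region] = {
                "independent": hp.independent, "joint": hp.joint,
                "r2_full": hp.r2_full,
                "percent_independent": hp.percent_independent(),
                "best_subset": list(hp.best_subset),
            }
            hp.subsets.to_csv(self.out / f"hp_subsets_{region}.tsv",
                              sep="\t", index=False)
        (self.out / "stats.json").write_text(
            json.dumps({"anova": out, "hierarchical_partitioning": hp_out},
                       indent=2, default=float) + "\n")
        files = ["stats.json"] + [f"hp_subsets_{r}.tsv" for r in hp_out
                                  if "skipped" not in hp_out[r]]
        return files


_STAGE_FN = {
    "simulate": _Run.stage_simulate,
    "dec-fit": _Run.stage_dec_fit,
    "ancestral": _Run.stage_ancestral,
    "events": _Run.stage_events,
    "combine": _Run.stage_combine,
    "clades": _Run.stage_clades,
    "fit-bd": _Run.stage_fit_bd,
    "stats": _Run.stage_stats,
}


def run(stage: str, config: RunConfig, force: bool = False) -> dict:
    """Execute one stage or ``"all"``; returns the updated manifest.

    Cached stage outputs (matching config hash, files present) are reused
    unless ``force`` is given.
    """
    runner = _Run(config)
    stages = list(STAGES) if stage == "all" else [stage]
    if stage == "all" and config.tree is not None:
        stages.remove("simulate")
    for st in stages:
        if st not in _STAGE_FN:
            raise PipelineError(f"unknown stage {st!r}; choose from "
                                f"{STAGES + ('all',)}")
        if not force and runner.cached(st):
            continue
        t0 = time.time()
        files = _STAGE_FN[st](runner)
        runner.record(st, files, t0)
    return runner.manifest
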