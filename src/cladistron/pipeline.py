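"""End-to-end orchestration: matrix -> searches -> support -> selection ->
calibration -> trait maps -> machine-readable report.

The run is fully determined by its configuration (including every seed), and
the report echoes that configuration, so a rerun with the same config file
is byte-identical.  Stages log wall-clock timings; any stage failure
propagates with the stage name attached.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from .chronostrat import CalibrationSet, calibrate, validate_timetree
from .consensus import resample_support, select_mpc, strict_consensus
from .matrix_io import read_matrix, write_trees
from .parsimony import score_from_steps
from .search import DEFAULT_K_GRID, SearchConfig, k_sweep, search
from .simulate import SimConfig, simulate_matrix, simulate_tree
from .traits import TraitTable, map_continuous, map_discrete
from .trees import Tree

DEFAULT_CONFIG = {
    "matrix": {"synthetic": {}},
    "dialect": "nexus",
    "outgroup": [],
    "k_grid": [1, 2, 3, 6, 16],
    "search": {
        "mode": "heuristic",
        "n_replicates": 8,
        "swap": "SPR",
        "collapse_rule": "min_length_zero",
    },
    "resampling": {"scheme": "symmetric", "p": 0.33, "replicates": 200, "starts": 2},
    "calibration": None,  # {"nodes": path, "tips": path, "policy": "range_top", "eps": 0.1}
    "traits": None,  # {"discrete": path, "continuous": path}
    "seed": 0,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _merged(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_full_analysis(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the whole study pipeline; returns the report dict and, when
    ``outdir`` is given, writes report.json plus tree/support artifacts."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merged(config)
    seed = int(cfg["seed"])
    report: dict = {"config": _jsonable(cfg), "stages": {}}
    timings = report["stages"]

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, et, ev, tb):
                if ev is not None:
                    raise StageError(name, ev) from ev
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    # -- matrix -------------------------------------------------------
    with stage("matrix"):
        generating_tree = None
        if isinstance(cfg["matrix"], dict) and "synthetic" in cfg["matrix"]:
            syn = dict(cfg["matrix"]["synthetic"])
            chars_per_edge = syn.pop("perfect", None)
            sim_cfg = SimConfig(**{**syn, "seed": seed})
            generating_tree = simulate_tree(sim_cfg.n_taxa, seed)
            if chars_per_edge:
                from .simulate import perfect_matrix

                matrix = perfect_matrix(generating_tree, int(chars_per_edge))
            else:
                sim = simulate_matrix(generating_tree, sim_cfg)
                matrix = sim.matrix
        else:
            matrix = read_matrix(cfg["matrix"], cfg["dialect"])
        summary = matrix.summarize()
        report["matrix_summary"] = summary.as_dict()
        if generating_tree is not None:
            report["generating_tree"] = generating_tree.to_newick()

    s_cfg = cfg["search"]

    def mk_config(criterion, k=3.0, collapse=None):
        return SearchConfig(
            criterion=criterion,
            k=float(k),
            mode=s_cfg.get("mode", "heuristic"),
            n_replicates=int(s_cfg.get("n_replicates", 8)),
            swap=s_cfg.get("swap", "SPR"),
            seed=seed,
            collapse_rule=collapse or s_cfg.get("collapse_rule", "min_length_zero"),
        )

    # -- equal weights ------------------------------------------------
    with stage("equal_weights_search"):
        eq = search(matrix, mk_config("equal"))
        cons = strict_consensus(eq.trees) if len(eq.trees) > 1 else eq.trees[0]
        report["equal_weights"] = {
            "n_mpcs": eq.n_mpcs,
            "score": eq.best_score.as_dict(),
            "strict_consensus": cons.to_newick(),
        }

    # -- implied weights sweep ---------------------------------------
    with stage("k_sweep"):
        grid = tuple(cfg.get("k_grid") or DEFAULT_K_GRID)
        sweep = k_sweep(matrix, grid, mk_config("implied"))
        report["k_sweep"] = {
            "mpc_counts": {str(k): r.n_mpcs for k, r in sweep.results.items()},
            "stability_intervals": [
                {"k_from": a, "k_to": b, "n_mpcs": len(c)}
                for a, b, c in sweep.intervals
            ],
        }

    # -- resampling support -------------------------------------------
    with stage("support"):
        r_cfg = cfg["resampling"]
        support = resample_support(
            matrix,
            SearchConfig(
                criterion="equal", mode="heuristic",
                n_replicates=int(r_cfg.get("starts", 2)),
                swap=s_cfg.get("swap", "SPR"), collapse_rule="none",
            ),
            scheme=r_cfg.get("scheme", "symmetric"),
            p=float(r_cfg.get("p", 0.33)),
            replicates=int(r_cfg.get("replicates", 200)),
            seed=seed + 1,
        )
        report["support"] = {
            "scheme": support.scheme,
            "replicates": support.replicates,
            "n_groups": len(support.freq),
        }

    # -- MPC selection -------------------------------------------------
    with stage("mpc_selection"):
        selection = select_mpc(sweep.results, support)
        chosen = selection.chosen_tree
        out_taxa = list(cfg.get("outgroup") or [])
        if not out_taxa and matrix.ingroup is not None:
            out_taxa = [t for t, flag in zip(matrix.taxa, matrix.ingroup) if not flag]
        rooted = chosen
        if out_taxa:
            try:
                rooted = chosen.root_on_outgroup(out_taxa)
            except ValueError:
                rooted = chosen.root_on_outgroup(out_taxa[:1])
        _annotate_gc(rooted, support)
        chosen_cfg = mk_config("implied", k=selection.chosen_k)
        chosen_score = search(matrix, chosen_cfg).best_score
        report["selection"] = {
            "chosen_k": selection.chosen_k,
            "summed_gc_by_k": {str(k): round(v, 3) for k, v in selection.gc_by_k.items()},
            "chosen_tree": rooted.to_newick(),
            "chosen_score": chosen_score.as_dict(),
        }

    # -- calibration ---------------------------------------------------
    timetree = None
    if cfg.get("calibration"):
        with stage("calibration"):
            c = cfg["calibration"]
            cal = CalibrationSet.from_tsv(c.get("nodes"), c["tips"])
            target = Tree.from_newick(c["tree"]) if c.get("tree") else rooted
            timetree = calibrate(
                target, cal, c.get("policy", "range_top"), float(c.get("eps", 0.1))
            )
            val = validate_timetree(timetree, cal)
            report["calibration"] = {
                "policy": timetree.policy,
                "root_age_ma": round(timetree.tree.root.age, 3),
                "n_violations": val["n_violations"],
                "binding_constraints": val["binding_constraints"],
            }

    # -- trait maps ----------------------------------------------------
    if cfg.get("traits"):
        with stage("traits"):
            t = cfg["traits"]
            target = timetree.tree if timetree is not None else rooted
            traits_report = {}
            if t.get("discrete"):
                trait = TraitTable.from_csv(t["discrete"])
                rec = map_discrete(target, trait)
                traits_report["discrete"] = {
                    "n_changes": rec.n_changes,
                    "alphabet": rec.alphabet,
                    "root_state_set": sorted(rec.tree.root.annotations["state_set"]),
                }
            if t.get("continuous"):
                trait = TraitTable.from_csv(t["continuous"], continuous=True)
                rec = map_continuous(target, trait)
                traits_report["continuous"] = {
                    "root_value": round(rec.tree.root.annotations["value"], 4),
                    "sum_squared_change": round(rec.sum_squared_change, 6),
                }
            report["traits"] = traits_report

    report["seed"] = seed

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(_jsonable(report), sort_keys=True, indent=2) + "\n"
        )
        write_trees(eq.trees, outdir / "mpcs_equal.nex", dialect="nexus")
        (outdir / "chosen_tree.nwk").write_text(rooted.to_newick() + "\n")
        (outdir / "support.tsv").write_text(support.to_tsv())
        if timetree is not None:
            (outdir / "timetree.nwk").write_text(
                timetree.tree.to_newick(lengths=True) + "\n"
            )
    return report


def _annotate_gc(rooted: Tree, support) -> None:
    labels = frozenset(l for l in rooted.leaf_labels())
    ref = min(labels)
    below = {}
    for n in rooted.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.label])
        else:
            below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n.parent is None:
                continue
            side = below[id(n)] if ref not in below[id(n)] else labels - below[id(n)]
            if 1 < len(side) < len(labels) - 1:
                gc = support.gc(side)
                n.annotations["gc"] = gc
                if gc > 0:
                    n.label = str(int(round(gc)))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and obj != obj:  # NaN
        return None
    return obj
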