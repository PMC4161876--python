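"""End-to-end orchestration: simulate -> lift -> quantify -> screen,
plus the optional phylo / qpcr / calcium stages.

A run is driven by a validated config (YAML on disk, plain dict in
memory); every stage writes its outputs under the run directory together
with a run-metadata JSON echoing all parameters, so identical config and
seed reproduce identical artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats_io as fio
from .assay_quant import CtTable, relative_expression
from .calcium_response import CalciumTrace, call_response, summarize_population
from .ectopic_screen import ScreenConfig, run_screen
from .liftover import build_tss_windows, lift_windows_dedup
from .parsimony_phylo import mp_search, remove_gap_columns
from .synthetic_data import (
    SimulationConfig,
    simulate_calcium,
    simulate_ct_table,
    simulate_protein_family,
    simulate_screen_inputs,
)

log = logging.getLogger("ectocage")

_KNOWN_SECTIONS = {"seed", "outdir", "simulate", "lift", "screen",
                   "phylo", "qpcr", "calcium"}


def validate_config(config: dict) -> dict:
    """Check the run config before any compute; returns a normalised copy."""
    if not isinstance(config, dict):
        raise ValueError("run config must be a mapping")
    unknown = set(config) - _KNOWN_SECTIONS
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("run config requires a 'seed'")
    if "outdir" not in config:
        raise ValueError("run config requires an 'outdir'")
    out = dict(config)
    out.setdefault("simulate", {})
    out.setdefault("lift", {})
    out.setdefault("screen", {})
    sim_fields = set(SimulationConfig.__dataclass_fields__)
    bad = set(out["simulate"]) - sim_fields
    if bad:
        raise ValueError(f"unknown simulate parameters: {sorted(bad)}")
    bad = set(out["lift"]) - {"min_match", "keep_split", "window_width"}
    if bad:
        raise ValueError(f"unknown lift parameters: {sorted(bad)}")
    bad = set(out["screen"]) - {"abs_cutoff", "library_subset",
                                "pseudogene_is_artifact", "percentile_method"}
    if bad:
        raise ValueError(f"unknown screen parameters: {sorted(bad)}")
    return out


def run_pipeline(config: dict) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    config = validate_config(config)
    seed = int(config["seed"])
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    sim_cfg = SimulationConfig(seed=seed, **config["simulate"])

    # --- simulate ---------------------------------------------------------
    log.info("simulating genomes, chains and CAGE libraries (seed=%d)", seed)
    source_ann, target_ann, chains, entities, libraries, truth = (
        simulate_screen_inputs(sim_cfg)
    )
    fio.write_bed(source_ann, outdir / "source_loci.bed")
    fio.write_bed(target_ann, outdir / "target_loci.bed")
    fio.write_chain(chains, outdir / "alignment.chain")
    for lib in libraries:
        fio.write_ctss(lib, outdir / f"{lib.library_id}.ctss.tsv")
    truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)

    # --- lift -------------------------------------------------------------
    width = int(config["lift"].get("window_width", sim_cfg.window_width))
    min_match = float(config["lift"].get("min_match", 0.95))
    keep_split = bool(config["lift"].get("keep_split", False))
    tss_list = [
        (l.locus_id, l.interval.chrom, l.annotated_tss, l.interval.strand)
        for l in source_ann
    ]
    windows = build_tss_windows(tss_list, width)
    results, discarded = lift_windows_dedup(windows, chains, min_match, keep_split)
    for rid in discarded:
        log.info("discarded duplicate lift: %s", rid)

    # --- screen -----------------------------------------------------------
    subset = config["screen"].get(
        "library_subset", [l.library_id for l in libraries]
    )
    screen_cfg = ScreenConfig(
        library_subset=list(subset),
        abs_cutoff=int(config["screen"].get("abs_cutoff", 100)),
        pseudogene_is_artifact=bool(
            config["screen"].get("pseudogene_is_artifact", True)
        ),
        percentile_method=config["screen"].get("percentile_method", "linear"),
    )
    table, screen_meta = run_screen(results, libraries, target_ann, screen_cfg)
    fio.write_candidates(table, outdir / "candidates.tsv")

    # --- truth comparison -------------------------------------------------
    truth_df = truth.loci
    expressed = set(truth_df.loc[truth_df.expressed, "entity_id"])
    decoys = set(truth_df.loc[truth_df.decoy, "entity_id"])
    called = set(table.loc[table.verdict == "candidate", "receptor_id"])
    flagged = set(table.loc[table.artifact, "receptor_id"])
    report = {
        "seed": seed,
        "discarded_duplicate_lifts": discarded,
        "screen": screen_meta,
        "recovery": {
            "n_expressed_planted": len(expressed),
            "n_candidates_called": len(called),
            "sensitivity": (
                len(called & expressed) / len(expressed) if expressed else None
            ),
            "n_decoys_planted": len(decoys),
            "n_artifacts_flagged": len(flagged),
            "artifact_precision": (
                len(flagged & decoys) / len(flagged) if flagged else None
            ),
        },
    }

    # --- optional stages --------------------------------------------------
    if "phylo" in config:
        p = config["phylo"]
        msa, true_tree = simulate_protein_family(
            int(p.get("n_taxa", 8)), int(p.get("n_columns", 120)), seed,
            float(p.get("substitution_prob", 0.05)),
        )
        msa = remove_gap_columns(msa)
        best, score = mp_search(msa, int(p.get("replicates", 10)), seed)
        fio.write_newick(best[0], outdir / "mp_tree.nwk")
        report["phylo"] = {
            "parsimony_score": score,
            "n_tied_topologies": len(best),
            "recovered_true_topology": best[0].same_topology(true_tree),
        }

    if "qpcr" in config:
        ct_df, refs, calibrators, folds = simulate_ct_table(sim_cfg)
        fio.write_ct_table(ct_df, outdir / "ct_table.tsv")
        rel = relative_expression(CtTable(ct_df, refs, calibrators))
        rel.to_csv(outdir / "relative_expression.tsv", sep="\t", index=False)
        test_mask = rel["sample"].str.startswith("TEST")
        recovered = rel.loc[test_mask].groupby("gene")["fold_change"].mean()
        report["qpcr"] = {
            "planted_folds": folds,
            "recovered_folds": {g: float(v) for g, v in recovered.items()},
        }

    if "calcium" in config:
        c = config["calcium"]
        traces_df, ca_truth = simulate_calcium(sim_cfg)
        fio.write_traces(traces_df, outdir / "traces.tsv")
        ca_truth.to_csv(outdir / "truth_traces.tsv", sep="\t", index=False)
        calls = []
        for tid, grp in traces_df.groupby("trace_id", sort=True):
            trace = CalciumTrace(
                tid, grp["time"].values, grp["f340"].values,
                grp["f380"].values, sim_cfg.stimulus_window,
            )
            calls.append(call_response(
                trace,
                threshold=float(c.get("threshold", 20.0)),
                max_latency=float(c.get("max_latency", 30.0)),
            ))
        report["calcium"] = summarize_population(calls)

    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump({"config": _jsonable(config), "report": _jsonable(report)},
                  fh, indent=2, sort_keys=True)
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj
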