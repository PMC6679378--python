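"""End-to-end orchestration: simulate -> genoprob -> (normalize) -> scan ->
classify -> compare -> enrich, driven by one YAML/JSON config.

Every stage is a pure function of its inputs and the config, so a run is
fully deterministic under a fixed seed: re-running with the same config
produces a byte-identical summary.  Thresholds (significance 0.05, cis
windows 5/10 Mb, conservation windows 15 cM / 10 Mb, hotspot bin 5 cM,
1000 permutations) are all named config parameters.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, compare, enrich, io, normalize, scan, simdata
from .genoprob import genotype_probabilities

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "genoprob": True,
        "normalize": False,
        "scan": True,
        "classify": True,
        "compare": False,
        "enrich": True,
    },
    "map": {"chrom_lengths_cm": [100.0] * 5, "marker_spacing_cm": 10.0, "mb_per_cm": 2.0},
    "simulate": {
        "n_individuals": 123,
        "cross_fraction": 55 / 123,
        "female_fraction": 63 / 123,
        "n_null": 60,
        "n_cis": 20,
        "n_trans": 10,
        "n_sex": 5,
        "n_cde": 5,
        "cis_effect": 1.5,
        "trans_effect": 1.5,
        "interaction_effect": 2.0,
        "residual_sd": 1.0,
        "missing_rate": 0.0,
        "hotspots": [],
        "snp_probes": {"n": 0, "attenuation": 0.5},
    },
    "genoprob": {"step_cm": 2.5, "error_rate": 0.002},
    "normalize": {
        "bg_mean": 100.0,
        "bg_sd": 10.0,
        "signal_scale": 50.0,
        "score_threshold": 0.5,
        "sample_fraction": 0.5,
    },
    "scan": {"n_perm": 1000, "fdr": 0.05, "interactive": [], "n_perm_interactive": 200},
    "classify": {"window_strict_mb": 5.0, "window_mb": 10.0, "bin_cm": 5.0, "hotspot_alpha": 0.001},
    "compare": {"window_cm": 15.0, "window_mb": 10.0, "shared_fraction": 0.7},
    "enrich": {"n_sets": 20, "set_size": 15},
}

_SCALARS = {
    "seed": int,
    "stages": dict,
    "map": dict,
    "simulate": dict,
    "genoprob": dict,
    "normalize": dict,
    "scan": dict,
    "classify": dict,
    "compare": dict,
    "enrich": dict,
}


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in (config or {}).items():
        if key not in _SCALARS:
            raise ValueError(f"unknown config key: {key!r}")
        if not isinstance(val, _SCALARS[key]):
            raise ValueError(f"config key {key!r} must be {_SCALARS[key].__name__}")
        if isinstance(val, dict):
            unknown = set(val) - set(merged[key])
            if unknown:
                raise ValueError(f"unknown keys under {key!r}: {sorted(unknown)}")
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


def _build_architecture(cfg: dict, gmap) -> simdata.SimArchitecture:
    sim = cfg["simulate"]
    hotspots = [simdata.HotspotSpec(**h) for h in sim["hotspots"]]
    return simdata.standard_architecture(
        gmap,
        n_null=sim["n_null"],
        n_cis=sim["n_cis"],
        n_trans=sim["n_trans"],
        n_sex=sim["n_sex"],
        n_cde=sim["n_cde"],
        cis_effect=sim["cis_effect"],
        trans_effect=sim["trans_effect"],
        interaction_effect=sim["interaction_effect"],
        residual_sd=sim["residual_sd"],
        hotspots=hotspots,
        n_individuals=sim["n_individuals"],
        cross_fraction=sim["cross_fraction"],
        female_fraction=sim["female_fraction"],
        missing_rate=sim["missing_rate"],
        seed=cfg["seed"],
    )


def run_pipeline(config: dict | None = None, output_dir=None) -> dict:
    """Run the enabled stages in order and return the machine-readable report.

    When ``output_dir`` is given, all stage tables are written there as
    TSV/CSV together with ``report.json``.
    """
    cfg = validate_config(config or {})
    outdir = Path(output_dir) if output_dir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    stages = cfg["stages"]
    report = {
        "schema_version": SCHEMA_VERSION,
        "config": cfg,
        "stages_run": [],
        "summary": {},
    }
    state: dict = {}

    if stages["simulate"]:
        gmap = simdata.simulate_map(
            cfg["map"]["chrom_lengths_cm"],
            cfg["map"]["marker_spacing_cm"],
            cfg["map"]["mb_per_cm"],
        )
        arch = _build_architecture(cfg, gmap)
        cross = simdata.simulate_f2_genotypes(gmap, arch)
        expr, truth = simdata.simulate_expression(cross, gmap, arch)
        annotation = simdata.annotation_from_truth(truth)

        snp_cfg = cfg["simulate"]["snp_probes"]
        snp_list = []
        if snp_cfg["n"] > 0:
            null_genes = truth.index[~truth["has_eqtl"]].tolist()
            snp_list = null_genes[: snp_cfg["n"]]
            expr = simdata.inject_probe_artifacts(
                expr, snp_list, snp_cfg["attenuation"], cross, gmap, annotation
            )
        state.update(
            gmap=gmap, arch=arch, cross=cross, expr=expr, truth=truth,
            annotation=annotation, snp_list=snp_list,
        )
        if outdir is not None:
            io.write_map(gmap, outdir / "map.tsv")
            io.write_genotypes(cross, outdir / "genotypes.csv")
            io.write_expression(expr, outdir / "expression.tsv")
            io.write_table(truth.reset_index(), outdir / "truth.tsv")
            io.write_table(annotation, outdir / "annotation.tsv")
        report["stages_run"].append("simulate")
        report["summary"]["simulate"] = {
            "n_individuals": int(cross.n_individuals),
            "n_genes": int(len(expr)),
            "n_markers": int(len(gmap)),
        }

    if stages["normalize"]:
        ncfg = cfg["normalize"]
        linear = 30.0 * np.maximum(state["expr"] - state["expr"].to_numpy().min(), 0.0)
        raw, detection = simdata.simulate_raw_intensities(
            linear, ncfg["bg_mean"], ncfg["bg_sd"], ncfg["signal_scale"], seed=cfg["seed"] + 17
        )
        processed = normalize.preprocess(
            raw,
            detection,
            exclusion_list=state.get("snp_list", []),
            score_threshold=ncfg["score_threshold"],
            sample_fraction=ncfg["sample_fraction"],
        )
        state["expr"] = processed
        if outdir is not None:
            io.write_expression(raw, outdir / "raw_intensities.tsv")
            io.write_expression(processed, outdir / "expression_normalized.tsv")
        report["stages_run"].append("normalize")
        report["summary"]["normalize"] = {"n_probes_after": int(len(processed))}

    if stages["genoprob"]:
        gp = genotype_probabilities(
            state["cross"], state["gmap"],
            step_cm=cfg["genoprob"]["step_cm"], error_rate=cfg["genoprob"]["error_rate"],
        )
        state["genoprobs"] = gp
        if outdir is not None:
            io.write_genoprobs(gp, outdir / "genoprobs.tsv")
        report["stages_run"].append("genoprob")
        report["summary"]["genoprob"] = {"n_loci": int(gp.n_loci)}

    if stages["scan"]:
        scfg = cfg["scan"]
        cross = state["cross"]
        records, secondary = scan.scan_transcripts(
            state["expr"],
            state["genoprobs"],
            covariates=cross.covariates(),
            strata=cross.strata(),
            n_perm=scfg["n_perm"],
            seed=cfg["seed"],
            fdr=scfg["fdr"],
        )
        state["records"], state["secondary"] = records, secondary
        if outdir is not None:
            io.write_table(records, outdir / "scan_records.tsv")
            io.write_table(secondary, outdir / "scan_secondary.tsv")
        report["stages_run"].append("scan")
        report["summary"]["scan"] = {
            "n_transcripts": int(len(records)),
            "n_declared": int(records["significant"].sum()),
        }
        for mode in scfg["interactive"]:
            irec = scan.interaction_scan(
                state["expr"],
                state["genoprobs"],
                covariates=cross.covariates(),
                interacting=mode,
                strata=cross.strata(),
                n_perm=scfg["n_perm_interactive"],
                seed=cfg["seed"],
            )
            state[f"interaction_{mode}"] = irec
            if outdir is not None:
                io.write_table(irec, outdir / f"scan_interaction_{mode}.tsv")
            report["summary"][f"interaction_{mode}"] = {
                "n_significant": int((irec["pvalue"] < 0.05).sum())
            }

    if stages["classify"]:
        ccfg = cfg["classify"]
        declared = state["records"][state["records"]["significant"]]
        classified = classify.classify_records(
            declared, state["annotation"],
            window_strict_mb=ccfg["window_strict_mb"], window_mb=ccfg["window_mb"],
        )
        lengths = {c: state["gmap"].chrom_length_cm(c) for c in state["gmap"].chromosomes}
        hotspots = classify.detect_hotspots(
            classified, lengths, bin_cm=ccfg["bin_cm"], alpha=ccfg["hotspot_alpha"]
        )
        poly = classify.polygenic_genes(state["records"], state["secondary"])
        direction = classify.direction_summary(classified)
        state["classified"] = classified
        if outdir is not None:
            io.write_table(classified, outdir / "eqtl_classified.tsv")
            io.write_table(hotspots, outdir / "hotspots.tsv")
        report["stages_run"].append("classify")
        counts = classified["eqtl_class"].value_counts().to_dict()
        report["summary"]["classify"] = {
            "class_counts": {k: int(counts.get(k, 0)) for k in classify.CLASS_LABELS},
            "hotspots": hotspots.drop(columns=["members"]).to_dict("records"),
            "polygenic_genes": poly,
            "fraction_gk_down": direction["fraction_gk_down"],
        }

    if stages["compare"]:
        pcfg = cfg["compare"]
        # second tissue: same cross and truth, independent noise; effects are
        # kept for a shared fraction of eQTL genes and silenced otherwise
        rng = np.random.default_rng(np.random.SeedSequence([cfg["seed"], 21]))
        genes_b = []
        for ge in state["arch"].genes:
            keep = rng.random() < pcfg["shared_fraction"]
            genes_b.append(ge if keep else replace(ge, additive=0.0, dominance=0.0,
                                                   sex_interaction=0.0, cde_interaction=0.0))
        arch_b = replace(state["arch"], genes=genes_b, seed=state["arch"].seed + 1)
        expr_b, _ = simdata.simulate_expression(state["cross"], state["gmap"], arch_b)
        records_b, _ = scan.scan_transcripts(
            expr_b,
            state["genoprobs"],
            covariates=state["cross"].covariates(),
            strata=state["cross"].strata(),
            n_perm=cfg["scan"]["n_perm"],
            seed=cfg["seed"] + 1,
            fdr=cfg["scan"]["fdr"],
        )
        conserved = compare.conserved_crosstissue(
            state["records"], records_b, window_cm=pcfg["window_cm"]
        )
        n_a = int(state["records"]["significant"].sum())
        n_b = int(records_b["significant"].sum())
        background = len(state["records"])
        p_overlap = (
            compare.overlap_enrichment(len(conserved), n_a, n_b, background)
            if min(n_a, n_b) > 0
            else 1.0
        )
        if outdir is not None:
            io.write_table(records_b, outdir / "scan_records_tissueB.tsv")
            io.write_table(conserved, outdir / "conserved_pairs.tsv")
        report["stages_run"].append("compare")
        report["summary"]["compare"] = {
            "n_declared_a": n_a,
            "n_declared_b": n_b,
            "n_conserved": int(len(conserved)),
            "overlap_p": p_overlap,
        }

    if stages["enrich"]:
        ecfg = cfg["enrich"]
        background = list(state["expr"].index)
        declared_genes = (
            state["records"].loc[state["records"]["significant"], "transcript"].tolist()
        )
        sets = simdata.simulate_gene_sets(
            background,
            n_sets=ecfg["n_sets"],
            set_size=ecfg["set_size"],
            enriched_genes=declared_genes,
            seed=cfg["seed"],
        )
        result = enrich.hypergeom_enrich(declared_genes, sets, background)
        if outdir is not None:
            io.write_table(result, outdir / "enrichment.tsv")
        report["stages_run"].append("enrich")
        report["summary"]["enrich"] = {
            "n_sets_tested": int(len(result)),
            "top_set": result.iloc[0]["set"] if len(result) else None,
            "top_p": float(result.iloc[0]["p"]) if len(result) else None,
        }

    if outdir is not None:
        write_report(report, outdir / "report.json")
    return report


def write_report(report: dict, path) -> None:
    """Stable, versioned JSON report (sorted keys, fixed float formatting)."""
    with open(path, "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if obj is None or obj != obj:  # NaN
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
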