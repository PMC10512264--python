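"""End-to-end pipeline orchestration from a single configuration.

Runs simulate -> ancestry -> {karyotype, kmer, loh} -> summarise on a
synthetic cohort, joins the stage outputs into a per-sample summary table
and per-cross aggregates, and writes deterministic TSV/JSON artifacts.
Every threshold of the analysis is a configuration key with the study
defaults (85% assignment, 30% depth deviation, 2x mask fold, k=17,
min_count=5, 20% per-parent LOH inclusion, 10-marker runs).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, karyotype, kmer_net, loh as loh_mod
from .simulate import Cohort, CrossSpec, derive_cross_distance_map, generate_cohort

DEFAULT_PARAMS = {
    "k": 17,
    "min_count": 5,
    "min_hits": 2,
    "min_margin": 2,
    "min_assigned": 0.85,
    "parent_floor": 0.05,
    "window_size": 10_000,
    "aneuploidy_threshold": 0.30,
    "mask_fold": 2.0,
    "min_depth": 3,
    "purity": 0.9,
    "min_run": 10,
    "min_parent_frac": 0.20,
    "bin_size": 10_000,
}

_CROSS_KEYS = set(CrossSpec.__dataclass_fields__)
_TOP_KEYS = {"seed", "out_dir", "stages", "crosses", "params"}
_STAGES = {"ancestry", "karyotype", "kmer", "loh"}

__all__ = ["PipelineResult", "validate_config", "run_pipeline", "summarize_cross", "load_config"]


@dataclass
class PipelineResult:
    summary: pd.DataFrame  # one row per simulated sample
    crosses: pd.DataFrame  # per-cross aggregates
    cohort: Cohort
    profiles: dict
    reports: dict
    kmer: dict | None
    loh_segments: dict | None
    config_hash: str
    log: list[str]


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> dict:
    """Check the configuration against the documented schema; unknown keys
    raise with the offending key named."""
    for key in config:
        if key not in _TOP_KEYS:
            raise ValueError(f"unknown config key: {key!r}")
    if "seed" not in config:
        raise ValueError("config requires a 'seed'")
    if not config.get("crosses"):
        raise ValueError("config requires a non-empty 'crosses' list")
    stages = config.get("stages", sorted(_STAGES))
    for st in stages:
        if st not in _STAGES:
            raise ValueError(f"unknown stage: {st!r}")
    params = dict(DEFAULT_PARAMS)
    for key, val in (config.get("params") or {}).items():
        if key not in DEFAULT_PARAMS:
            raise ValueError(f"unknown params key: {key!r}")
        params[key] = val
    crosses = []
    for c in config["crosses"]:
        for key in c:
            if key not in _CROSS_KEYS:
                raise ValueError(f"unknown cross key: {key!r}")
        if "contribution" in c and isinstance(c["contribution"], list):
            c = {**c, "contribution": tuple(c["contribution"])}
        crosses.append(CrossSpec(**c))
    return {
        "seed": int(config["seed"]),
        "out_dir": config.get("out_dir"),
        "stages": list(stages),
        "crosses": crosses,
        "params": params,
    }


def _config_hash(config: dict) -> str:
    # output location does not change the analysis
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(config: dict) -> PipelineResult:
    """Run the configured stages in dependency order on a synthetic cohort.

    Deterministic given the config (including seed): rerunning writes
    byte-identical summaries.
    """
    cfg = validate_config(config)
    params = cfg["params"]
    log: list[str] = []
    cohort = generate_cohort(cfg["crosses"], cfg["seed"])
    log.append(f"simulate: {len(cohort.samples)} samples, {len(cohort.parents)} crosses")

    profiles: dict[str, ancestry.ContributionProfile] = {}
    decisions: dict[str, ancestry.InclusionDecision] = {}
    reports: dict[str, karyotype.AneuploidyReport] = {}
    assignments: dict[str, pd.DataFrame] = {}
    indexes = {}
    run_anc = "ancestry" in cfg["stages"] or "karyotype" in cfg["stages"] or "loh" in cfg["stages"]
    if run_anc:
        for cross, (p1, p2) in cohort.parents.items():
            nuc = ancestry.build_diagnostic_index([p1, p2], params["k"])
            mito = ancestry.build_mito_index([p1, p2], params["k"])
            indexes[cross] = (nuc, mito)
    for cross, truth, reads in cohort.samples:
        sid = truth.sample_id
        if not run_anc:
            continue
        nuc, mito = indexes[cross]
        prep = ancestry.prepare_read_kmers(reads, params["k"])
        prof, table = ancestry.compute_profile(
            sid, prep, nuc, mito, params["min_hits"], params["min_margin"],
            return_table=True)
        profiles[sid] = prof
        dec = ancestry.inclusion_filter(prof, params["min_assigned"], params["parent_floor"])
        decisions[sid] = dec
        log.append(f"inclusion[{sid}]: include={dec.include} reason={dec.reason} "
                   f"(>=85% high-quality mapping + two-parent rule)")
        assignments[sid] = table
        if "karyotype" in cfg["stages"] and dec.include:
            placements = karyotype.placements_from_assignments(table, reads.read_length)
            p1, p2 = cohort.parents[cross]
            lengths = {p.species_id: p.chrom_lengths for p in (p1, p2)}
            reports[sid] = karyotype.analyze_sample(
                placements, lengths, sid, params["window_size"],
                params["mask_fold"], params["aneuploidy_threshold"])

    kmer_result = None
    if "kmer" in cfg["stages"]:
        profs = [kmer_net.kmer_profile(reads, params["k"], params["min_count"], truth.sample_id)
                 for _cross, truth, reads in cohort.samples]
        matrix = kmer_net.distance_matrix(profs)
        cross_of = {truth.sample_id: cross for cross, truth, _ in cohort.samples}
        pdist = derive_cross_distance_map(cohort)
        kmer_result = {"matrix": matrix,
                       "stats": kmer_net.cross_statistics(matrix, cross_of, pdist)}

    loh_segments = None
    if "loh" in cfg["stages"]:
        loh_segments = {}
        for cross, truth, reads in cohort.samples:
            sid = truth.sample_id
            p1, p2 = cohort.parents[cross]
            markers = loh_mod.derive_markers(p1, p2)
            counts = loh_mod.count_alleles(markers, reads, assignments[sid])
            geno = loh_mod.genotype_markers(counts, params["min_depth"], params["purity"])
            loh_segments[sid] = loh_mod.call_loh_segments(geno, params["min_run"])

    rows = []
    for cross, truth, reads in cohort.samples:
        sid = truth.sample_id
        prof = profiles.get(sid)
        dec = decisions.get(sid)
        rep = reports.get(sid)
        p1, p2 = cohort.parents[cross]
        row = {
            "sample": sid,
            "cross": cross,
            "include": bool(dec.include) if dec else None,
            "reason": dec.reason if dec else "",
        }
        if prof is not None:
            for sp in (p1.species_id, p2.species_id):
                row[f"frac_{sp}"] = round(prof.nuclear_fraction.get(sp, 0.0), 6)
            row["unassigned"] = round(prof.unassigned, 6)
            row["majority_nuclear"] = prof.majority_nuclear or ""
            row["majority_mito"] = prof.majority_mito or ""
            row["concordant"] = "" if prof.concordant is None else str(prof.concordant)
        if rep is not None:
            row["n_gain"] = rep.n_gain
            row["n_loss"] = rep.n_loss
            row["variance"] = None if rep.variance is None else round(rep.variance, 6)
            row["slope"] = None if rep.slope is None else round(rep.slope, 10)
        if loh_segments is not None and sid in loh_segments:
            genome_len = sum(p1.chrom_lengths.values())
            row["pct_loh"] = round(
                loh_mod.loh_fraction(loh_segments[sid], genome_len), 4)
        rows.append(row)
    summary = pd.DataFrame(rows)
    crosses_df = summarize_cross(summary, kmer_result)
    result = PipelineResult(
        summary=summary, crosses=crosses_df, cohort=cohort, profiles=profiles,
        reports=reports, kmer=kmer_result, loh_segments=loh_segments,
        config_hash=_config_hash(config), log=log,
    )
    if cfg["out_dir"]:
        _write_outputs(result, Path(cfg["out_dir"]))
    return result


def summarize_cross(summary: pd.DataFrame, kmer_result: dict | None = None) -> pd.DataFrame:
    """Per-cross aggregates: % of genomes with >=1 gain / >=1 loss / both,
    mean variance +/- SE, and mean/SD shared k-mers when available."""
    rows = []
    for cross, g in summary.groupby("cross"):
        row = {"cross": cross, "n_samples": len(g)}
        if "n_gain" in g.columns:
            gg = g.dropna(subset=["n_gain"])
            n = len(gg)
            row["n_analyzed"] = n
            if n:
                row["pct_gain"] = round(100.0 * (gg["n_gain"] > 0).mean(), 4)
                row["pct_loss"] = round(100.0 * (gg["n_loss"] > 0).mean(), 4)
                row["pct_both"] = round(
                    100.0 * ((gg["n_gain"] > 0) & (gg["n_loss"] > 0)).mean(), 4)
                var = gg["variance"].dropna()
                row["mean_variance"] = round(float(var.mean()), 6) if len(var) else None
                row["se_variance"] = (round(float(var.std(ddof=1) / np.sqrt(len(var))), 6)
                                      if len(var) > 1 else None)
        rows.append(row)
    out = pd.DataFrame(rows)
    if kmer_result is not None and len(kmer_result["stats"]["per_cross"]):
        out = out.merge(kmer_result["stats"]["per_cross"][["cross", "mean_shared", "sd_shared"]],
                        on="cross", how="left")
    return out


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = f"# config_hash={result.config_hash}\n"
    for name, df in (("summary.tsv", result.summary), ("crosses.tsv", result.crosses)):
        with open(out / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    (out / "pipeline.log").write_text(header + "\n".join(result.log) + "\n")
    if result.kmer is not None:
        kmer_net.export_distances(result.kmer["matrix"], out / "distances.phylip", "phylip")
        kmer_net.export_distances(result.kmer["matrix"], out / "distances.nex", "nexus")
    if result.loh_segments is not None:
        with open(out / "loh_segments.bed", "w") as fh:
            for sid in sorted(result.loh_segments):
                for seg in result.loh_segments[sid]:
                    fh.write(f"{seg.chromosome}\t{seg.start}\t{seg.end}\t"
                             f"{sid}:{seg.retained_parent}\t{seg.n_markers}\n")
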