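"""End-to-end orchestration: simulate -> windows -> classify -> anchor ->
divergence -> trees, with a single JSON/Markdown report.

Every stage failure is re-raised as a :class:`StageError` tagged with the
stage (module) name, and the report carries a provenance block (effective
configuration, its hash, seed, package version) so a run can be reproduced
exactly.  Identical configuration and seed give a byte-identical report
body (timestamps are deliberately excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, anchor, dnds, regions, sim, trees, winstats

__all__ = ["RunConfig", "StageError", "run_all", "run_classification"]

log = logging.getLogger("stratascan")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the analysis' standard values
    (10-kb windows, 25-window smoothing, 0.1 pseudocount, 1000x25 bootstrap,
    10,000 permutations, SNP depth 5 / MAF 0.30, dedup 25%/80%, 10-kb path
    gaps, 70% orientation, 10% discard, 10% W coverage floor, dS cap 0.2,
    120-nt CDS minimum, 40%/40% tree filters, 75% support, 80% query
    coverage)."""

    seed: int = 0
    simulate: bool = True
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)

    # window scan
    window: int = 10_000
    smooth: int = 25
    pseudocount: float = 0.1
    n_boot: int = 1000
    block: int = 25
    n_perm: int = 10_000
    min_depth: int = 5
    min_maf: float = 0.30
    alpha: float = 0.05
    w_floor: float = 0.10

    # dedup / anchoring
    dedup_min_overlap: float = 0.25
    dedup_min_identity: float = 0.80
    anchor_max_gap: int = 10_000
    orient_ratio: float = 0.70
    anchor_min_fraction: float = 0.10

    # divergence
    dnds_method: str = "yn00"
    max_ds: float = 0.2
    cds_min_length: int = 120
    n_genes_genome: int = 60
    n_genes_par: int = 20
    n_genes_stratum1: int = 30
    n_genes_stratum2: int = 20
    cds_codons: int = 300

    # trees
    max_col_gap: float = 0.40
    max_taxon_missing: float = 0.40
    min_tree_support: float = 0.75
    tree_bootstrap: int = 100
    tree_codons: int = 500
    n_tree_genes_stratum1: int = 25
    n_tree_genes_stratum2: int = 25

    # gene loss
    min_qcov: float = 0.80

    # file-mode inputs
    female_profile: str | None = None
    male_profile: str | None = None
    scaffold_lengths: str | None = None
    scaffold_classes: str | None = None

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = sim.SimulationConfig(**self.sim)
        for name, lo, hi in (("min_maf", 0, 0.5), ("alpha", 0, 1), ("w_floor", 0, 1),
                             ("dedup_min_overlap", 0, 1), ("dedup_min_identity", 0, 1),
                             ("orient_ratio", 0.5, 1), ("anchor_min_fraction", 0, 1),
                             ("max_col_gap", 0, 1), ("max_taxon_missing", 0, 1),
                             ("min_tree_support", 0, 1), ("min_qcov", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.dnds_method not in ("yn00", "ng86"):
            raise ValueError("dnds_method must be 'yn00' or 'ng86'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _effective_sim(config: RunConfig) -> sim.SimulationConfig:
    return replace(config.sim, seed=config.seed)


def run_classification(config: RunConfig):
    """Stages sim -> windows -> classification/delimitation.

    Returns (genome, window table, calls, segments, envelopes dict).  This
    is the coverage/SNP half of the pipeline, shared by the full run and by
    calibration studies that do not need the sequence-level stages.
    """
    if config.simulate:
        try:
            genome = sim.simulate_genome(_effective_sim(config))
            profiles = sim.simulate_profiles(genome)
        except Exception as exc:
            raise StageError("sim", str(exc)) from exc
        try:
            windows = profiles.window_table(config.window, config.min_depth, config.min_maf)
        except Exception as exc:
            raise StageError("winstats", str(exc)) from exc
        labels = genome.labels()
        autosomes = [s for s, lab in labels.items() if lab == sim.AUTOSOME]
        ref_map = genome.default_reference_map()
        sex_order = sorted((name for name, (c, _, _) in ref_map.items() if c == "chrS"),
                           key=lambda n: ref_map[n][1])
        lengths = genome.scaffold_lengths
    else:
        for name, path in (("female profile", config.female_profile),
                           ("male profile", config.male_profile),
                           ("scaffold lengths", config.scaffold_lengths),
                           ("scaffold classes", config.scaffold_classes)):
            if path is None or not Path(path).exists():
                raise StageError("winstats", f"missing input: {name} ({path})")
        genome = None
        lengths = dict(pd.read_csv(config.scaffold_lengths, sep="\t", header=None,
                                   names=["scaffold", "length"]).itertuples(index=False))
        try:
            cf = winstats.load_profile_counts(config.female_profile, lengths)
            cm = winstats.load_profile_counts(config.male_profile, lengths)
            windows = winstats.window_table(cf, cm, lengths, config.window,
                                            config.min_depth, config.min_maf)
        except Exception as exc:
            raise StageError("winstats", str(exc)) from exc
        classes = pd.read_csv(config.scaffold_classes, sep="\t", header=None,
                              names=["scaffold", "class"])
        autosomes = list(classes.loc[classes["class"] == "autosome", "scaffold"])
        sex_order = list(classes.loc[classes["class"].isin(("PAR", "sex")), "scaffold"])

    try:
        calls = regions.classify_scaffolds(
            windows, autosomes, config.n_boot, config.block, config.n_perm,
            seed=config.seed, alpha=config.alpha, w_floor=config.w_floor,
            smooth=config.smooth)
        auto_cov = windows.loc[windows["scaffold"].isin(autosomes), "log2_cov"]
        auto_cov = auto_cov.to_numpy(dtype=float)
        auto_cov = auto_cov[np.isfinite(auto_cov)]
        window_q = (float(np.quantile(auto_cov, 0.001)), float(np.quantile(auto_cov, 0.999)))
        segments = regions.delimit_sdr(sex_order, calls, windows, lengths,
                                       window_null_quantiles=window_q, window=config.window)
    except Exception as exc:
        raise StageError("sexregions", str(exc)) from exc
    log.info("classified %d scaffolds; %d strata segments", len(calls), len(segments))
    return genome, windows, calls, segments, {"sex_order": sex_order, "autosomes": autosomes}


def _divergence_stage(config: RunConfig) -> dict:
    cfg = _effective_sim(config)
    het = cfg.heterozygosity
    pair_sets = {
        "GENOME": sim.simulate_cds_pairs(config.n_genes_genome, het,
                                         config.cds_codons, config.seed, "GENOME"),
        "PAR": sim.simulate_cds_pairs(config.n_genes_par, het,
                                      config.cds_codons, config.seed + 1, "PAR"),
        "STRATUM1": sim.simulate_cds_pairs(config.n_genes_stratum1,
                                           cfg.stratum1_zw_divergence,
                                           config.cds_codons, config.seed + 2, "STRATUM1"),
        "STRATUM2": sim.simulate_cds_pairs(config.n_genes_stratum2,
                                           het + cfg.stratum2_zw_divergence,
                                           config.cds_codons, config.seed + 3, "STRATUM2"),
    }
    estimate = dnds.yn00_estimate if config.dnds_method == "yn00" else dnds.ng86_estimate
    by_region: dict[str, list[dnds.DnDsEstimate]] = {}
    n_qc_failed = 0
    for region, pairs in pair_sets.items():
        ests = []
        for gene, h1, h2 in pairs:
            if not dnds.qc_cds(h1, config.cds_min_length) or not dnds.qc_cds(h2, config.cds_min_length):
                n_qc_failed += 1
                continue
            ests.append(estimate(dnds.prepare_pair(h1, h2)))
        by_region[region] = dnds.filter_ds(ests, config.max_ds)
    by_region["SDR"] = by_region["STRATUM1"] + by_region["STRATUM2"]
    out = {"n_qc_failed": n_qc_failed, "method": config.dnds_method}
    for metric in ("dS", "dN"):
        out[metric] = dnds.compare_regions(by_region, metric)
    return out


def _tree_stage(config: RunConfig) -> dict:
    groups = sim.simulate_gametologs(
        None,
        {"STRATUM1": config.n_tree_genes_stratum1, "STRATUM2": config.n_tree_genes_stratum2},
        seed=config.seed, n_codons=config.tree_codons)
    calls = []
    for i, grp in enumerate(groups):
        labels, seqs = grp.alignment()
        aln = trees.filter_alignment(labels, seqs, config.max_col_gap, config.max_taxon_missing)
        dm = trees.distance_matrix(aln)
        tree = trees.neighbor_joining(dm, aln.taxa)
        support = trees.bootstrap_support(aln, config.tree_bootstrap,
                                          seed=config.seed * 100_003 + i)
        call = trees.classify_topology(tree, grp.gene_id, support=support,
                                       min_support=config.min_tree_support)
        calls.append((grp, call))
    summary: dict[str, dict[str, float]] = {}
    correct_w = 0
    n_w = 0
    for grp, call in calls:
        s = summary.setdefault(grp.true_stratum, {})
        s[call.call] = s.get(call.call, 0) + 1
        if call.call == trees.W_DIVERGENT and grp.w_label is not None:
            n_w += 1
            correct_w += int(call.w_label == grp.w_label)
    per_stratum = {
        stratum: {k: v / sum(cnt.values()) for k, v in cnt.items()}
        for stratum, cnt in summary.items()
    }
    return {
        "per_stratum_fractions": per_stratum,
        "w_label_accuracy": correct_w / n_w if n_w else float("nan"),
        "n_genes": len(calls),
        "calls": [
            {"gene": grp.gene_id, "true_stratum": grp.true_stratum,
             "call": call.call, "support": call.support, "w_label": call.w_label}
            for grp, call in calls
        ],
    }


def _anchor_stage(config: RunConfig, genome: sim.TrueGenome) -> dict:
    autosomes = [s.name for s in genome.scaffolds if s.label == sim.AUTOSOME]
    shuffled = tuple(autosomes[-1:])
    alns = sim.simulate_alignments(genome, seed=config.seed, shuffled_scaffolds=shuffled)
    redundant = anchor.find_allelic_scaffolds(
        alns.self_records, alns.masked_lengths,
        config.dedup_min_overlap, config.dedup_min_identity)
    assignments = anchor.anchor_all(
        alns.reference_records, max_gap=config.anchor_max_gap,
        orient_ratio=config.orient_ratio, min_fraction=config.anchor_min_fraction)
    ref_map = genome.default_reference_map()
    n_correct = 0
    n_clean = 0
    for name, assignment in assignments.items():
        if name in alns.shuffled:
            continue
        n_clean += 1
        chrom, _, strand = ref_map[name]
        want = anchor.FORWARD if strand == "+" else anchor.REVERSE
        if assignment.chromosome == chrom and assignment.orientation == want and assignment.localized:
            n_correct += 1
    return {
        "n_redundant_removed": len(redundant),
        "planted_duplicates_removed": sorted(redundant) == sorted(alns.duplicate_truth),
        "n_anchored": len(assignments),
        "clean_assignments_correct": n_correct,
        "n_clean": n_clean,
        "shuffled_flagged_unlocalized": all(
            not assignments[s].localized for s in alns.shuffled if s in assignments),
    }


def _repeat_stage(config: RunConfig, genome: sim.TrueGenome) -> dict:
    fractions: dict[str, list[float]] = {"W": [], "Z_SDR": [], "GENOME": []}
    for s in genome.scaffolds:
        vals = regions.repeat_fraction_per_window(
            genome.repeat_intervals[s.name], s.length, config.window)
        if s.label == sim.W_SPECIFIC:
            fractions["W"].extend(vals)
        elif s.label == sim.STRATUM1_Z:
            fractions["Z_SDR"].extend(vals)
        elif s.label == sim.AUTOSOME:
            fractions["GENOME"].extend(vals)
    return regions.repeat_enrichment_test(fractions["W"], fractions["Z_SDR"],
                                          fractions["GENOME"])


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute the whole pipeline and return (and optionally write) the report."""
    genome, windows, calls, segments, ctx = run_classification(config)

    report: dict[str, Any] = {
        "provenance": {
            "package": "stratascan",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
        },
        "region_calls": {name: dataclasses.asdict(c) for name, c in sorted(calls.items())},
        "sdr_segments": [dataclasses.asdict(s) for s in segments],
        "sdr_span_bp": int(sum(s.span for s in segments)),
    }
    if config.simulate and genome is not None:
        report["truth"] = dict(genome.labels())
        try:
            report["anchoring"] = _anchor_stage(config, genome)
        except Exception as exc:
            raise StageError("anchordedupe", str(exc)) from exc
        try:
            report["repeat_enrichment"] = _repeat_stage(config, genome)
        except Exception as exc:
            raise StageError("sexregions", str(exc)) from exc
    try:
        report["divergence"] = _divergence_stage(config)
    except Exception as exc:
        raise StageError("gametolog", str(exc)) from exc
    try:
        report["topology"] = _tree_stage(config)
    except Exception as exc:
        raise StageError("strataphylo", str(exc)) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True, allow_nan=True)
        winstats.write_window_table(windows, outdir / "windows.tsv")
        with open(outdir / "report.md", "w") as fh:
            fh.write(_markdown_report(report))
    return report


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _markdown_report(report: dict) -> str:
    lines = ["# stratascan report", ""]
    prov = report["provenance"]
    lines += [f"- version: {prov['version']}",
              f"- seed: {prov['seed']}",
              f"- config hash: {prov['config_hash']}", ""]
    lines += ["## Region calls", "", "| scaffold | call | mean log2 cov | mean log2 snp |",
              "|---|---|---|---|"]
    for name, call in sorted(report["region_calls"].items()):
        lines.append(f"| {name} | {call['call']} | {call['mean_log2_cov']:.3f} | "
                     f"{call['mean_log2_snp']:.3f} |")
    lines += ["", "## SDR segments", ""]
    for seg in report["sdr_segments"]:
        lines.append(f"- stratum {seg['stratum']}: {seg['start']:,}-{seg['end']:,} bp "
                     f"({', '.join(seg['scaffolds'])})")
    lines.append(f"\nTotal SDR span: {report['sdr_span_bp']:,} bp\n")
    if "divergence" in report:
        lines += ["## Divergence (dS by region)", ""]
        for region, entry in report["divergence"]["dS"].items():
            lines.append(f"- {region}: mean dS = {entry['mean']:.6f} "
                         f"(n = {entry['n']:.0f}, p = {entry['p']:.3g})")
        lines.append("")
    if "topology" in report:
        lines += ["## Gene-tree topology", ""]
        for stratum, fracs in report["topology"]["per_stratum_fractions"].items():
            desc = ", ".join(f"{k}: {v:.0%}" for k, v in sorted(fracs.items()))
            lines.append(f"- {stratum}: {desc}")
        lines.append("")
    return "\n".join(lines)
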