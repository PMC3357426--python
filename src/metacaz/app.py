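"""Configuration, logging and the end-to-end synthetic-run driver.

One YAML config drives simulate -> search -> profile -> bin -> compare; every
stage seed is derived deterministically from the single global seed, so an
identical (seed, config) pair reproduces a byte-identical run directory.
The driver also writes a truth-evaluation report (planted-nucleotide
recovery, spurious-family fraction, binning accuracy, group separation)
because the synthetic inputs carry full ground truth.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml
from skbio import TreeNode

from . import binning, compare, io_formats, synthetic_data, tiling_profile
from .io_formats import Contig, ValidationError
from .search import ScoringParams, search_contigs
from .synthetic_data import PlantedGene, SimulatedMetagenome
from .tiling_profile import FamilyProfile, FamilyRun, TilingParams
from .util import derive_seed

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "tiling": {"tile_len": 300, "step": 150, "min_tail": 150},
    "scoring": {
        "matrix": "BLOSUM62", "gap_open": -11, "gap_extend": -1,
        "lambda_": 0.267, "k": 0.041, "evalue_cutoff": 1e-10,
    },
    "binning": {"min_len": 2000, "metric": "l1", "threshold": "auto",
                "train_fraction": 0.5},
    "profile": {"min_bin_contig_len": 1000, "run_length": "span"},
    "compare": {"filter": "gh_only", "linkage": "average"},
    "simulate": {
        "n_populations": 6,
        "genome_len": 120_000,
        "gc_values": None,
        "n_members": 3,
        "within_group_cv": 0.2,
        "per_family": 2,
        "aa_len_range": [60, 160],
        "contig_len_mu": float(np.log(3000.0)),
        "contig_len_sigma": 0.45,
        "contig_min_len": 500,
        "depth_shape": 2.0,
        "depth_scale": 3.0,
    },
    "paths": {"outdir": "runs/demo", "depth_table": None},
}


@dataclass
class RunConfig:
    seed: int
    tiling: TilingParams
    scoring: ScoringParams
    binning: dict[str, Any]
    profile: dict[str, Any]
    compare: dict[str, Any]
    simulate: dict[str, Any]
    paths: dict[str, Any]
    resolved: dict[str, Any] = field(repr=False, default_factory=dict)


def _merge(defaults: Mapping[str, Any], user: Mapping[str, Any], prefix="") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, val in user.items():
        if key not in defaults:
            raise ValidationError(f"unknown config key {prefix + key!r}")
        if isinstance(defaults[key], dict) and isinstance(val, Mapping):
            out[key] = _merge(defaults[key], val, prefix=f"{prefix}{key}.")
        else:
            out[key] = val
    return out


def validate_config(source) -> RunConfig:
    """Validate a YAML config (path, text or mapping); inject defaults.

    Unknown keys are rejected with the offending key named.
    """
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, Mapping):
            raise ValidationError("config must be a YAML mapping")
    resolved = _merge(DEFAULT_CONFIG, raw)
    tiling = TilingParams(**resolved["tiling"])
    scoring = ScoringParams(**{**resolved["scoring"],
                               "evalue_cutoff": float(resolved["scoring"]["evalue_cutoff"])})
    b = resolved["binning"]
    if b["threshold"] != "auto" and not float(b["threshold"]) > 0:
        raise ValidationError("binning.threshold must be 'auto' or > 0")
    if resolved["profile"]["run_length"] not in ("span", "tile"):
        raise ValidationError("profile.run_length must be span|tile")
    if resolved["compare"]["filter"] not in ("all", "gh_only", "biomass"):
        raise ValidationError("compare.filter must be all|gh_only|biomass")
    if resolved["compare"]["linkage"] not in ("average", "complete", "single"):
        raise ValidationError("compare.linkage must be average|complete|single")
    dt = resolved["paths"].get("depth_table")
    if dt is not None and not Path(dt).exists():
        raise ValidationError(f"paths.depth_table: no such file {dt!r}")
    return RunConfig(
        seed=int(resolved["seed"]),
        tiling=tiling,
        scoring=scoring,
        binning=resolved["binning"],
        profile=resolved["profile"],
        compare=resolved["compare"],
        simulate=resolved["simulate"],
        paths=resolved["paths"],
        resolved=resolved,
    )


# ---------------------------------------------------------------------------
# truth-based evaluation


def _intersect_len(spans_a: list[tuple[int, int]], spans_b: list[tuple[int, int]]) -> int:
    total = 0
    for a0, a1 in spans_a:
        for b0, b1 in spans_b:
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


def planted_recovery(
    runs: Sequence[FamilyRun],
    planted: Sequence[PlantedGene],
    contig_lengths: Mapping[str, int],
    min_contig_len: int = 300,
) -> float:
    """Fraction of planted coding nucleotides (on contigs >= min_contig_len)
    covered by a run of the correct family."""
    run_spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for r in runs:
        run_spans.setdefault((r.contig_id, r.family), []).append((r.start, r.end))
    denom = 0
    num = 0
    for g in planted:
        if contig_lengths.get(g.contig_id, 0) < min_contig_len:
            continue
        denom += g.length
        num += _intersect_len([(g.start, g.end)],
                              run_spans.get((g.contig_id, g.family), []))
    return num / denom if denom else float("nan")


def spurious_family_fraction(
    totals: Mapping[str, float],
    truth_families: set[str],
) -> float:
    """Largest share of total weighted nt held by any family absent from the
    truth."""
    grand = sum(totals.values())
    if grand <= 0:
        return 0.0
    worst = 0.0
    for fam, w in totals.items():
        if fam not in truth_families:
            worst = max(worst, w / grand)
    return worst


def binning_metrics(
    assignment: Mapping[str, str],
    truth: Mapping[str, str],
) -> dict[str, float]:
    """Accuracy over assigned contigs plus the assigned (non-"no match")
    fraction, on contigs present in both maps."""
    n = n_assigned = n_correct = 0
    for cid, true_bin in truth.items():
        if cid not in assignment:
            continue
        n += 1
        if assignment[cid] != binning.NO_MATCH:
            n_assigned += 1
            if assignment[cid] == true_bin:
                n_correct += 1
    return {
        "n": n,
        "assigned_fraction": n_assigned / n if n else float("nan"),
        "accuracy": n_correct / n_assigned if n_assigned else float("nan"),
    }


def root_split_separates(newick: str, groups: Mapping[str, str]) -> bool:
    """True when the two children of the dendrogram root partition the
    leaves exactly by group label."""
    tree = TreeNode.read(StringIO(newick))
    if len(tree.children) != 2:
        return False
    sides = [frozenset(t.name for t in child.tips()) if child.children
             else frozenset([child.name]) for child in tree.children]
    group_sets: dict[str, set[str]] = {}
    for label, grp in groups.items():
        group_sets.setdefault(grp, set()).add(label)
    if len(group_sets) != 2:
        return False
    a, b = (frozenset(s) for s in group_sets.values())
    return {a, b} == set(sides)


def mds_group_separation(
    coords: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
) -> dict[str, float]:
    """Mean between-group vs within-group embedded distances."""
    labels = list(coords)
    within, between = [], []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            d = float(np.linalg.norm(coords[la] - coords[lb]))
            (within if groups[la] == groups[lb] else between).append(d)
    return {
        "mean_within": float(np.mean(within)) if within else float("nan"),
        "mean_between": float(np.mean(between)) if between else float("nan"),
    }


# ---------------------------------------------------------------------------
# pipeline pieces shared by the driver, the analysis scripts and the tests


def profile_metagenome(
    contigs: Sequence[Contig],
    hits,
    depths: Mapping[str, float] | None = None,
    label: str = "metagenome",
    run_length: str = "span",
) -> tuple[FamilyProfile, list[FamilyRun]]:
    """Hits -> best hit per tile -> runs -> depth-weighted per-million."""
    lengths = {c.id: len(c) for c in contigs}
    assignments = tiling_profile.best_hit_per_tile(hits, run_length=run_length)
    runs = tiling_profile.collect_runs(assignments, lengths, depths)
    totals = tiling_profile.family_totals(runs, depths)
    profile = tiling_profile.normalize_per_million(totals, contigs, depths, label)
    return profile, runs


def run_end_to_end(config: RunConfig) -> dict[str, Any]:
    """Execute the full synthetic pipeline; returns the evaluation report.

    All outputs (inputs, hit tables, profiles, assignments, distances, tree,
    MDS, report) land in ``paths.outdir``; nothing timestamped, so reruns
    with the same seed and config are byte-identical.
    """
    outdir = Path(config.paths["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(config.resolved, sort_keys=True))

    sim = config.simulate
    t0 = time.time()
    db, _ = synthetic_data.build_family_db(
        synthetic_data.DEFAULT_FAMILIES,
        per_family=int(sim["per_family"]),
        aa_len_range=tuple(sim["aa_len_range"]),
        seed=derive_seed(config.seed, "family_db"),
    )
    io_formats.write_fasta(synthetic_data.db_to_fasta_records(db),
                           outdir / "family_db.fasta")
    pops = synthetic_data.default_populations(
        n=int(sim["n_populations"]),
        genome_len=int(sim["genome_len"]),
        gc_values=sim["gc_values"],
        seed=derive_seed(config.seed, "populations"),
    )
    panel = synthetic_data.default_panel(
        n_members=int(sim["n_members"]),
        within_group_cv=float(sim["within_group_cv"]),
        seed=derive_seed(config.seed, "panel"),
    )
    len_dist = synthetic_data.LengthDist(
        mu=float(sim["contig_len_mu"]), sigma=float(sim["contig_len_sigma"]),
        min_len=int(sim["contig_min_len"]))
    depth_dist = synthetic_data.DepthDist(
        shape=float(sim["depth_shape"]), scale=float(sim["depth_scale"]))
    metagenomes = synthetic_data.simulate_panel(panel, db, pops, len_dist, depth_dist)
    log.info("stage=simulate records_in=%d records_out=%d seconds=%.1f",
             len(pops), len(metagenomes), time.time() - t0)

    external_depths = (io_formats.read_depth_table(config.paths["depth_table"])
                       if config.paths.get("depth_table") else None)

    report: dict[str, Any] = {"seed": config.seed, "metagenomes": {}}
    profiles: list[FamilyProfile] = []
    groups: dict[str, str] = {}
    truth_families = {f for g in panel.groups for f, v in g.template.items() if v > 0}
    for mg in metagenomes:
        groups[mg.label] = mg.group
        mg_dir = outdir / mg.label
        mg_dir.mkdir(exist_ok=True)
        io_formats.write_fasta([(c.id, "", c.seq) for c in mg.contigs],
                               mg_dir / "contigs.fasta")
        io_formats.write_depth_table(mg.depths, mg_dir / "depths.tsv")
        _write_truth(mg, mg_dir)
        depths = external_depths if external_depths is not None else mg.depths

        t0 = time.time()
        hits = search_contigs(mg.contigs, db, config.tiling, config.scoring)
        io_formats.write_hit_table(hits, mg_dir / "hits.tsv")
        log.info("stage=search[%s] records_in=%d records_out=%d seconds=%.1f",
                 mg.label, len(mg.contigs), len(hits), time.time() - t0)

        profile, runs = profile_metagenome(
            mg.contigs, hits, depths, mg.label,
            run_length=config.profile["run_length"])
        profiles.append(profile)

        model = _train_on_truth(mg, config)
        assignment = binning.classify(mg.contigs, model,
                                      min_len=int(config.binning["min_len"]))
        with open(mg_dir / "bin_assignments.tsv", "w") as fh:
            for cid in sorted(assignment):
                fh.write(f"{cid}\t{assignment[cid]}\n")
        bprofiles = tiling_profile.bin_profiles(
            runs, mg.contigs, assignment, depths,
            min_contig_len=int(config.profile["min_bin_contig_len"]))
        io_formats.write_profile_matrix(bprofiles.values(),
                                        mg_dir / "bin_profiles.tsv")

        lengths = {c.id: len(c) for c in mg.contigs}
        report["metagenomes"][mg.label] = {
            "group": mg.group,
            "n_contigs": len(mg.contigs),
            "n_hits": len(hits),
            "depth_assumed_1": external_depths is not None,
            "planted_recovery": planted_recovery(runs, mg.planted, lengths),
            "spurious_family_fraction": spurious_family_fraction(
                tiling_profile.family_totals(runs, depths), truth_families),
            "binning": binning_metrics(assignment, mg.contig_population),
        }

    io_formats.write_profile_matrix(profiles, outdir / "profiles.tsv")
    matrix = compare.assemble_matrix(profiles, config.compare["filter"])
    dist = compare.spearman_distance(matrix)
    with open(outdir / "distances.tsv", "w") as fh:
        fh.write("label\t" + "\t".join(dist.labels) + "\n")
        for i, lab in enumerate(dist.labels):
            fh.write(lab + "\t" + "\t".join(f"{v:.6f}" for v in dist.values[i]) + "\n")
    newick = compare.cluster(dist, config.compare["linkage"])
    (outdir / "tree.nwk").write_text(newick + "\n")
    coords = compare.mds(dist, k=2)
    with open(outdir / "mds.tsv", "w") as fh:
        fh.write("label\tmds1\tmds2\n")
        for lab in dist.labels:
            fh.write(f"{lab}\t{coords[lab][0]:.9f}\t{coords[lab][1]:.9f}\n")
    gmat = compare.assemble_matrix(profiles, "all")
    first = {g: next(l for l in groups if groups[l] == g)
             for g in dict.fromkeys(groups.values())}
    glabels = list(first.values())
    if len(glabels) == 2:
        scatter = compare.pairwise_scatter(gmat, glabels[0], glabels[1], "biomass")
        with open(outdir / f"scatter_{glabels[0]}_vs_{glabels[1]}.tsv", "w") as fh:
            fh.write("family\tvalue_a\tvalue_b\tclass\n")
            for fam, va, vb, cls in scatter:
                fh.write(f"{fam}\t{va:.2f}\t{vb:.2f}\t{cls}\n")

    sep = mds_group_separation(coords, groups)
    separated = (root_split_separates(newick, groups)
                 and sep["mean_between"] > sep["mean_within"])
    report["comparison"] = {
        "root_split_separates_groups": root_split_separates(newick, groups),
        "mds": sep,
        "group_separation_verdict": "separated" if separated else "mixed",
        "newick": newick,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _write_truth(mg: SimulatedMetagenome, mg_dir: Path) -> None:
    with open(mg_dir / "truth_genes.tsv", "w") as fh:
        fh.write("contig_id\tstart\tend\tfamily\tstrand\tsource_protein\n")
        for g in sorted(mg.planted, key=lambda g: (g.contig_id, g.start)):
            fh.write(f"{g.contig_id}\t{g.start}\t{g.end}\t{g.family}\t"
                     f"{g.strand}\t{g.source_protein}\n")
    with open(mg_dir / "truth_bins.tsv", "w") as fh:
        for cid in sorted(mg.contig_population):
            fh.write(f"{cid}\t{mg.contig_population[cid]}\n")


def _train_on_truth(mg: SimulatedMetagenome, config: RunConfig) -> binning.BinModel:
    """Train the binner on a deterministic half of each population's contigs."""
    frac = float(config.binning.get("train_fraction", 0.5))
    by_pop: dict[str, list[Contig]] = {}
    for c in mg.contigs:
        by_pop.setdefault(mg.contig_population[c.id], []).append(c)
    labeled = []
    for pop in sorted(by_pop):
        members = [c for c in by_pop[pop] if len(c) >= 1000]
        k = max(1, int(len(members) * frac))
        labeled.extend((c, pop) for c in members[:k])
    model = binning.train(labeled)
    if config.binning["threshold"] != "auto":
        model = binning.BinModel(model.centroids,
                                 float(config.binning["threshold"]),
                                 model.metric)
    return model
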