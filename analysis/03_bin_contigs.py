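#!/usr/bin/env python
"""Composition-based binning of each panel metagenome.

Trains a trinucleotide-centroid classifier per metagenome on a labelled
half of each population's contigs (>= 1 kb), classifies all contigs
>= 2 kb, and scores the assignments against the contig-to-population
truth.  Also writes Table-3-style per-bin family profiles (contigs
>= 1 kb, per-bin depth-weighted denominators) using the hit tables from
02_search_and_profile.py.
"""

from pathlib import Path

from metacaz import binning, io_formats
from metacaz.app import binning_metrics, profile_metagenome
from metacaz.tiling_profile import bin_profiles

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = ROOT / "panel"


def read_two_col(path):
    return dict(line.split("\t")[:2] for line in path.read_text().splitlines())


def main():
    (ROOT / "bins").mkdir(parents=True, exist_ok=True)
    for contig_fasta in sorted(PANEL.glob("*.contigs.fasta")):
        label = contig_fasta.name.replace(".contigs.fasta", "")
        depths = io_formats.read_depth_table(PANEL / f"{label}.depths.tsv")
        contigs = io_formats.read_contigs(contig_fasta, depths)
        truth = read_two_col(PANEL / f"{label}.truth_bins.tsv")

        by_pop = {}
        for c in contigs:
            if len(c) >= 1000:
                by_pop.setdefault(truth[c.id], []).append(c)
        labeled = []
        for pop in sorted(by_pop):
            half = max(1, len(by_pop[pop]) // 2)
            labeled.extend((c, pop) for c in by_pop[pop][:half])
        model = binning.train(labeled)
        assignment = binning.classify(contigs, model, min_len=2000)
        with open(ROOT / "bins" / f"{label}.assignments.tsv", "w") as fh:
            for cid in sorted(assignment):
                fh.write(f"{cid}\t{assignment[cid]}\n")
        m = binning_metrics(assignment, truth)
        print(f"{label:16s} accuracy {100 * m['accuracy']:5.1f}% over "
              f"{100 * m['assigned_fraction']:4.1f}% assigned (n={m['n']})")

        fam_map = {r.protein_id: r.family
                   for r in io_formats.read_family_db(PANEL / "family_db.fasta")}
        hits = io_formats.read_hit_table(ROOT / "hits" / f"{label}.hits.tsv",
                                         fam_map)
        _, runs = profile_metagenome(contigs, hits, depths, label)
        profs = bin_profiles(runs, contigs, assignment, depths,
                             min_contig_len=1000)
        io_formats.write_profile_matrix(
            profs.values(), ROOT / "bins" / f"{label}.bin_profiles.tsv")
    print(f"assignments and per-bin profiles -> {ROOT / 'bins'}")


if __name__ == "__main__":
    main()
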