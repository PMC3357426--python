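#!/usr/bin/env python
"""Simulate the synthetic study panel.

Generates the family-labelled protein database and a panel of six
metagenomes in two groups — three "gut-like" (no lignin-oxidase families
planted) and three "free-living" (cellulase- and lignin-oxidase-rich) —
each drawn from six source populations with staggered G+C, shredded into
depth-annotated contigs.  Writes FASTA/TSV inputs plus the ground-truth
tables under results/panel/.
"""

import sys
from pathlib import Path

import yaml

from metacaz import io_formats, synthetic_data as sd
from metacaz.util import derive_seed

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "panel"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    db, _ = sd.build_family_db(sd.DEFAULT_FAMILIES, per_family=2,
                               aa_len_range=(60, 160),
                               seed=derive_seed(SEED, "family_db"))
    io_formats.write_fasta(sd.db_to_fasta_records(db), OUT / "family_db.fasta")
    pops = sd.default_populations(n=6, genome_len=120_000,
                                  seed=derive_seed(SEED, "populations"))
    panel = sd.default_panel(n_members=3, seed=derive_seed(SEED, "panel"))
    manifest = []
    for mg in sd.simulate_panel(panel, db, pops):
        io_formats.write_fasta([(c.id, "", c.seq) for c in mg.contigs],
                               OUT / f"{mg.label}.contigs.fasta")
        io_formats.write_depth_table(mg.depths, OUT / f"{mg.label}.depths.tsv")
        with open(OUT / f"{mg.label}.truth_genes.tsv", "w") as fh:
            fh.write("contig_id\tstart\tend\tfamily\tstrand\n")
            for g in sorted(mg.planted, key=lambda g: (g.contig_id, g.start)):
                fh.write(f"{g.contig_id}\t{g.start}\t{g.end}\t{g.family}\t{g.strand}\n")
        with open(OUT / f"{mg.label}.truth_bins.tsv", "w") as fh:
            for cid in sorted(mg.contig_population):
                fh.write(f"{cid}\t{mg.contig_population[cid]}\n")
        total = sum(len(c) for c in mg.contigs)
        planted = sum(g.length for g in mg.planted)
        manifest.append({"label": mg.label, "group": mg.group,
                         "contigs": len(mg.contigs), "total_nt": total,
                         "planted_genes": len(mg.planted),
                         "planted_nt": planted})
        print(f"{mg.label:16s} {len(mg.contigs):4d} contigs, {total:8d} nt, "
              f"{len(mg.planted):3d} planted genes "
              f"({100 * planted / total:.2f}% coding)")
    (OUT / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    print(f"panel written to {OUT}")


if __name__ == "__main__":
    main()
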