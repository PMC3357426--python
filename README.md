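# metacaz

Comparative functional profiling of assembled metagenomes by tiled
translated homology search against carbohydrate-active enzyme (CAZy-style)
and lignin-oxidase (FOLy-style) gene families — with depth-weighted
per-million normalization, composition-based contig binning, and
cross-metagenome comparison by Spearman correlation distance.

## Who this is for

Microbiome researchers who want to compare the *biomass-degrading
potential* of metagenomes — e.g. a lignocellulose-decay community against
gut, rumen, compost or rhizosphere communities — on the level of enzyme
family abundance rather than taxonomy, across datasets that differ wildly
in size, read length and assembly quality.

## The computation

For a metagenome assembly with per-contig mean depths, and a protein
database whose records carry family labels (GH/GT/CE/PL/CBM for
carbohydrate-active families, LO/LDA for lignin oxidases):

1. contigs are cut into 300 nt tiles overlapping by 150 nt, so long
   contigs get no gene-discovery advantage;
2. each tile is searched against the database in all six reading frames
   (Smith–Waterman; hits kept at e < 1e-10), and the best family per tile
   is chosen;
3. winning aligned spans are unioned per (contig, family) into maximal
   runs, so overlap is never double-counted;
4. run lengths are multiplied by mean contig depth, totalled per family
   `f`, and normalized:

   ```
   per_million[f] = 1e6 · Σ_runs(f) covered_nt · depth(contig)
                    ───────────────────────────────────────────
                         Σ_contigs length(contig) · depth(contig)
   ```

   — nucleotides per million depth-weighted nucleotides, invariant under
   contig duplication and under splitting a depth-d contig into d
   depth-1 copies;
5. profiles (whole-metagenome, or per composition bin for contigs ≥ 1 kb)
   are compared across metagenomes by `d = 1 − ρ` (Spearman) on the
   glycoside-hydrolase family matrix, clustered (UPGMA → Newick) and
   embedded by classical MDS.

Contig binning is nearest-centroid on strand-symmetric trinucleotide
frequency vectors (L1 distance, percentile-calibrated "no match"
threshold), trained on labelled contigs.

A first-class synthetic-data module generates everything needed to run the
pipeline end to end with ground truth: family databases, order-2 Markov
population genomes with controlled G+C and planted reverse-translated
genes, depth-annotated contigs, and grouped metagenome panels (a
"gut-like" group with no lignin-oxidase families vs a "free-living" group
with them).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
panel (seed 1): six metagenomes (three gut-like, three free-living), each
~720 kb over six source populations.

```text
$ python analysis/01_simulate_panel.py
gut_like_1        214 contigs,   720000 nt,  68 planted genes (2.58% coding)
gut_like_2        218 contigs,   720000 nt,  73 planted genes (2.72% coding)
gut_like_3        227 contigs,   720000 nt,  78 planted genes (2.90% coding)
free_living_1     208 contigs,   720000 nt,  93 planted genes (3.54% coding)
free_living_2     222 contigs,   720000 nt,  85 planted genes (3.23% coding)
free_living_3     216 contigs,   720000 nt,  98 planted genes (3.50% coding)

$ python analysis/02_search_and_profile.py
free_living_1      486 hits, recovery  99.9%, spurious 0.00%, total    35169 nt/Mnt
free_living_2      447 hits, recovery  99.8%, spurious 0.00%, total    31125 nt/Mnt
free_living_3      486 hits, recovery  99.3%, spurious 0.00%, total    30853 nt/Mnt
gut_like_1         355 hits, recovery  99.6%, spurious 0.00%, total    23117 nt/Mnt
gut_like_2         376 hits, recovery  99.6%, spurious 0.00%, total    25004 nt/Mnt
gut_like_3         394 hits, recovery  99.9%, spurious 0.00%, total    29068 nt/Mnt
profile matrix -> results/profiles.tsv
```

`recovery` is the fraction of planted coding nucleotides covered by a
correct-family run; `total` is the summed per-million profile (tens of
thousands, because the panel is deliberately enriched).

```text
$ python analysis/03_bin_contigs.py
free_living_1    accuracy 100.0% over 79.3% assigned (n=208)
free_living_2    accuracy 100.0% over 81.1% assigned (n=222)
free_living_3    accuracy 100.0% over 82.4% assigned (n=216)
gut_like_1       accuracy 100.0% over 79.4% assigned (n=214)
gut_like_2       accuracy 100.0% over 80.3% assigned (n=218)
gut_like_3       accuracy 100.0% over 77.5% assigned (n=227)
```

Composition binning assigns ~78–82% of contigs at 100% accuracy; the
remainder lands in the explicit "no match" class, as on real data.

```text
$ python analysis/04_compare_metagenomes.py
tree: (('gut_like_2':0.042,('gut_like_1':0.021,'gut_like_3':0.021):0.021):0.671,
       ('free_living_2':0.101,('free_living_1':0.068,'free_living_3':0.068):0.034):0.612);
root split separates groups: True
MDS mean distance between/within groups: 1.437/0.232
gut-like lignin-oxidase rows all zero: True
```

The UPGMA root split cleanly separates gut-like from free-living members
on glycoside-hydrolase profiles alone, and the scatter table shows the
gut-like group's complete lack of lignin-oxidase families as exact zeros.

```text
$ python analysis/05_rank_dominant_families.py
top 5 families per panel metagenome (share of total):
  free_living_1    GT4 (12.2%), GT2 (11.2%), GH5 (10.8%), GH9 (8.5%), GH13 (6.9%)
  ...
  gut_like_1       GH2 (13.8%), GH92 (12.8%), GT2 (11.4%), GH13 (11.3%), GT4 (10.9%)

published counts: top 22 of 230 families hold 19510 of 28793 candidate genes = 67.8%
```

Glycosyl transferases dominate both groups (they are ubiquitous but not
biomass-degrading); the groups differ in the hydrolases — cellulases
(GH5/GH9) in the free-living members, oligosaccharide/hemicellulose
hydrolases (GH2/GH92/GH43) in the gut-like members — which is exactly the
signal the Spearman comparison clusters on.

## Command line

A thin CLI wraps the library for shell use:

```bash
metacaz simulate --seed 1 --outdir runs/sim
metacaz search  --contigs c.fasta --db family_db.fasta --out hits.tsv
metacaz profile --contigs c.fasta --depths d.tsv --hits hits.tsv --out prof.tsv
metacaz bin     --contigs c.fasta --train labels.tsv --out bins.tsv
metacaz compare --matrix prof.tsv --out-prefix results/cmp
metacaz run     --config run.yaml        # simulate → … → compare + report
```

See `docs/methods.md` for the model, parameter defaults and their
rationale, numerical conventions, and known limitations.
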