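# Methods

## The profiling computation

`metacaz` estimates the abundance of carbohydrate-active enzyme (CAZy-style:
GH, GT, CE, PL, CBM) and lignin-oxidase (FOLy-style: LO1-LO3, LDA) gene
families in an assembled metagenome, in units that are comparable across
datasets of very different size and assembly quality:

1. **Tiling.** Every contig/scaffold is cut into overlapping tiles of
   `tile_len` = 300 nt stepped by 150 nt. Tiling restarts at 0 on each
   contig; a final partial tile is searched only if it is at least
   `min_tail` = 150 nt long (a contig shorter than that yields one tile
   covering it entirely). Tiling, rather than gene calling, makes the
   profile insensitive to the gene-discovery advantage of long contigs: a
   family segment contributes the same amount of sequence whether it sits
   on an 80 kb scaffold or a 600 nt contig.
2. **Translated search.** Each tile is compared against the family-labelled
   protein database in all six reading frames (BlastX-style). Hits with
   e-value >= 1e-10 are discarded; per (tile, database record) only the
   best local alignment is kept.
3. **Best family per tile.** Among a tile's surviving hits, the minimum
   e-value wins; ties fall back to maximum bit score, then the
   lexicographically smallest family label, then the smallest subject id —
   a total order, so the assignment is deterministic.
4. **Run collection.** The winning hits' aligned spans are lifted from
   tile-local to contig coordinates and, per (contig, family), unioned into
   maximal disjoint intervals ("runs"). Because the union counts each
   nucleotide at most once per family, the 150 nt tile overlap is never
   double-counted. Runs of different families may overlap (no cross-family
   arbitration beyond the per-tile best hit). A `run_length="tile"` mode
   attributes whole tiles instead of aligned spans, for the alternative
   reading of run length; the default is the aligned span, because
   "nucleotides attributed to a family" is what the per-million unit means.
5. **Depth weighting and normalization.** Each run's length is multiplied
   by its contig's mean assembly depth (depth 1 is assumed wherever no
   depth table is available), totalled per family, and divided by the
   metagenome's total depth-weighted base count (sum of contig length x
   depth), x 1e6. The result — nucleotides per million depth-weighted
   nucleotides — is invariant under duplicating contigs and under replacing
   one contig of depth d by d identical copies of depth 1; both invariances
   are verified end-to-end through the search engine in the test suite.
6. **Per-bin profiles.** The same totals restricted to contigs >= 1 kb and
   grouped by a contig-to-bin assignment, each bin normalized by its own
   depth-weighted base total (a flag switches to the metagenome-wide
   denominator). Contigs without an assignment form an explicit "no match"
   bin.

## The built-in translated search

The search engine exists so the pipeline is testable end-to-end without an
external aligner binary; its output is the common 12-column tabular format,
so external BlastX results can be dropped in instead at any time.

- Frames +1/+2/+3 of the tile and of its reverse complement are translated
  with the standard code; codons containing N become X; stop codons are
  kept as `*` and alignments may not cross them (each stop-free peptide
  segment is aligned separately). No frameshift handling: tiles are short.
- Scoring is Smith-Waterman with BLOSUM62 and affine gaps
  (`gap_open` = -11 for the first gap residue, `gap_extend` = -1 for each
  further one, PairwiseAligner convention). Bit score
  `= (lambda*S - ln k)/ln 2` and e-value `= m*n*2^(-bits)` use fixed
  gapped-BLOSUM62 constants `lambda` = 0.267, `k` = 0.041 without
  composition correction, with m the tile length in nt and n the total
  database residue count. These constants are configurable; they need only
  be monotone in the raw score for the pipeline's best-hit logic, and the
  1e-10 cutoff is deliberately far from the noise floor (the measured
  false-hit rate on background tiles is < 1%, in practice ~0).
- Exactness is preserved under two admissible prunes: (a) a segment whose
  per-residue best-substitution-score sum cannot reach the raw score
  implied by the cutoff is skipped; (b) a record is abandoned mid-DP once
  neither the score so far nor any continuation bound can reach that raw
  score. Both bounds only ever discard alignments that the e-value filter
  would discard; with the cutoff set to infinity they disable themselves,
  and the test suite checks bit-exact agreement with a naive full-table DP
  oracle both ways. Coordinates and alignment statistics for surviving
  hits come from Bio.Align.PairwiseAligner under identical scoring; the
  two scores are asserted equal on every hit.

## Composition-based binning

Contigs are represented by 64-component trinucleotide frequency vectors
counted over the sequence and its reverse complement (3-mers containing N
excluded), which makes classification strand-invariant by construction.
Training computes one centroid per population as the length-weighted mean
of member vectors; classification assigns each contig >= 2 kb to the
nearest centroid under L1 distance. The assignment threshold defaults to
the 95th percentile of training-member distances to their own centroid,
maximized over bins; contigs farther than that from every centroid are
labelled "no match". Two consequences worth noting:

- By construction the percentile rule sends the upper tail of the
  widest-spread training bin to "no match", so accuracy is reported *among
  assigned contigs*, with the assigned fraction alongside — mirroring how
  a large unassigned class is reported on real data.
- Short fragments have noisier composition vectors than the contigs that
  calibrated the threshold, so the assigned fraction falls with fragment
  length while accuracy among assigned stays near 1 in the separable
  regime.

The distance metric, threshold and length cutoffs are all configurable;
L1-on-frequencies with a percentile threshold is the simplest rule that
reproduces the qualitative behaviour of trinucleotide classifiers on
well-separated populations (near-perfect self-classification plus a
substantial "no match" class).

## Cross-metagenome comparison

Profiles are assembled into a family x metagenome matrix, zero-filled over
the family union. The default variable set for distance computation is the
glycoside hydrolase families only (`gh_only`); composite labels such as
GH94/GT84 are classified by the majority of their component prefixes (ties
to the first component). Distance is `1 - rho` with Spearman's rho
(average ranks on ties); a zero-variance profile has no rank order, so its
distances are defined as 1 with a warning rather than NaN. Clustering is
agglomerative with average linkage (UPGMA) by default, serialized as
Newick with ultrametric branch lengths (a join at cophenetic distance d
sits at height d/2); complete and single linkage are flags. The embedding
is classical (Torgerson) MDS — double-centered squared distances,
eigendecomposition, axes ordered by eigenvalue, negative eigenvalues
clipped to zero — with each axis oriented so its first nonzero coordinate
is positive, which makes coordinates reproducible to the byte across runs.
Scatter tables for the biomass-enzyme comparison keep zero-valued rows on
purpose: the absence of lignin-oxidase families in gut-like profiles is
the observation.

The "biomass" family filter ships as a configured default list: the GH
families acting on the principal hardwood polysaccharide linkages
(cellulose, xylan, glucomannan backbone and side chains: GH1, 2, 3, 5, 6,
7, 8, 9, 10, 11, 12, 26, 30, 39, 43, 44, 45, 48, 51, 52, 54, 61, 67, 74,
113, 115, 116, 120, 124) plus every LO/LDA-class family.

## The synthetic data generator

The generator produces the study conditions the pipeline is tested under;
every output carries ground truth (planted gene spans per contig,
contig-to-population labels, per-member template draws).

- **Family database.** Per family, a random consensus peptide (default
  length 60-160 aa) and `per_family` = 2 members mutated at 10-20% of
  positions — members are 80-90% identical to each other's source
  consensus while inter-family identity sits at the ~5% random background.
  Headers carry the family in a `|FAM=<label>` token.
- **Population genomes.** Order-2 Markov backgrounds. Each transition row
  splits probability G+C between C and G (and 1-G+C between A and T) by
  context-specific random ratios, so the stationary G+C equals the target
  exactly while different populations acquire genuinely distinct
  trinucleotide structure even at equal G+C — the signal the binner needs
  is richer than a single G+C axis, as it is for real genomes. Default
  panels use six populations at G+C 0.30-0.70 in steps of 0.08, the regime
  in which nearest-centroid binning is guaranteed solvable; real
  communities can sit closer than that, in which case the "no match" class
  grows.
- **Planted genes.** Reverse translations (uniform codon choice) of
  randomly chosen family members, inserted at non-overlapping positions on
  a random strand. Total planted coding is capped at half the genome.
- **Contigs.** Consecutive lognormal-length windows (default median 3 kb,
  sigma 0.45, minimum 500 nt; a too-short terminal remainder is absorbed
  into the final contig) with gamma-distributed mean depths floored at
  1.0. Genes split by a contig boundary are clipped, and both clipped
  parts stay in the truth table — recovery metrics must tolerate them, as
  they must on real assemblies.
- **Panels.** Two group templates in nt-per-million units: "free-living"
  (cellulase families GH6/GH9/GH12/GH48 present, LO1-LO3 and LDA7 present)
  and "gut-like" (no LO/LDA at all, no cellulases, Bacteroides-style
  oligosaccharide/hemicellulose hydrolases dominant). Member templates are
  the group template times lognormal noise with the configured
  within-group coefficient of variation (default 0.2); zero template
  entries stay exactly zero. Per-family planted gene counts use stochastic
  rounding of the expected count, so the expected realized per-million is
  exactly proportional to the member's drawn template while count variance
  stays below one gene — with plain Poisson counts, template ranks at
  desk scale were dominated by count noise. Template magnitudes total a
  few percent of sequence, deliberately dense: a few hundred kb of
  metagenome then realizes enough genes per family for stable rank
  structure, which is what the group-separation analysis consumes.

What the generator does **not** emulate: sequencing error and read-level
artifacts (contigs are exact genome windows), chimeric contigs, strain
variation, codon bias (uniform codon choice), repeat structure, and
families with genuine cross-homology (databases are random peptides, so
inter-family confusion is absent by construction). Passing tests therefore
demonstrate the correctness and calibration of the computation, not
search sensitivity on diverged real proteins.

## Problem sizes and numerical choices

The test suite and the acceptance script run, per invocation: the
profiling oracle on 200 random instances (<= 50 contigs, <= 20 families);
the alignment DP oracle on instances up to 400 nt x 200 aa; normalization
invariances end-to-end on 0.4-1 Mb; planted-gene recovery on a ~5 Mb
six-population metagenome (15 families, 3 genes each per population);
binning recovery on six 80 kb populations with 2-10 kb held-out fragments;
and a 3+3 panel of metagenomes of a few hundred kb each. These sizes are
the package's chosen desk-scale study conditions; all of them are plain
function arguments.

Other fixed choices: all coordinates are 0-based half-open on the forward
strand internally, converted to/from the 1-based inclusive tabular dialect
only at file boundaries; profile matrices are written to 2 decimals;
distances to 6 decimals; MDS coordinates to 9; every stage seed is derived
from the single run seed as `(seed * 1000003 + crc32(stage)) mod 2^31-1`,
so a seed plus the echoed config reproduces any run byte-identically.

## Known limitations

- The e-value calibration is nominal (fixed Karlin-Altschul constants, no
  length or composition correction); e-values are comparable within a run,
  not calibrated probabilities.
- Best-hit-per-tile cannot split a tile between two families; a family
  junction inside one tile attributes the whole winning span to one family.
- The binner is composition-only (no coverage feature) and requires
  labelled training contigs; threshold calibration assumes training
  contigs resemble the contigs to classify in length.
- Group separation on real data depends on the family universe and
  sequencing depth; the panel demonstrates the computation under
  conditions where the group signal is present by construction.
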