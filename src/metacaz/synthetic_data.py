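"""Synthetic metagenomes with planted gene families and full ground truth.

The generator produces every input the profiling pipeline needs without any
downloads: a family-labelled protein database emulating CAZy/FOLy, population
genomes drawn from order-2 nucleotide Markov models with controlled G+C,
contigs with mean-depth draws emulating assembly output, and multi-metagenome
panels whose family-abundance profiles carry group structure (a "gut-like"
group lacking lignin-oxidase families versus a "free-living" group containing
them).

Everything is deterministic under ``(seed, spec)``; truth tables (planted
gene spans, contig-to-population labels) accompany every output so recovery
can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from Bio.Data import CodonTable

from .io_formats import Contig, FamilyRecord, ValidationError
from .util import derive_seed, revcomp

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

# aa -> codons of the standard genetic code (stops excluded)
_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_TABLE.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class PopulationSpec:
    """One source population: an order-2 background model plus target G+C."""

    label: str
    markov: np.ndarray          # (64, 4) row-stochastic, rows indexed by 16a+4b
    gc: float
    genome_len: int

    def __post_init__(self):
        if self.markov.shape != (64, 4):
            raise ValidationError("markov table must be 64x4")
        if not np.allclose(self.markov.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("markov rows must sum to 1")
        if not (0.25 <= self.gc <= 0.75):
            raise ValidationError("gc must lie in [0.25, 0.75]")
        if self.genome_len <= 0:
            raise ValidationError("genome_len must be positive")


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one planted protein-coding segment."""

    contig_id: str
    start: int
    end: int
    family: str
    strand: str
    source_protein: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError("bad planted span")
        if self.strand not in "+-":
            raise ValidationError("strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LengthDist:
    """Lognormal contig-length model; sigma=0 gives fixed length exp(mu)."""

    mu: float = np.log(3000.0)
    sigma: float = 0.45
    min_len: int = 500

    def __post_init__(self):
        if self.min_len < 500:
            raise ValidationError("min_len must be >= 500")


@dataclass(frozen=True)
class DepthDist:
    """Gamma mean-depth model, floored at 1.0 (the no-information default)."""

    shape: float = 2.0
    scale: float = 3.0
    floor: float = 1.0


@dataclass(frozen=True)
class GroupSpec:
    label: str
    template: Mapping[str, float]   # family -> mean per-million value
    n_members: int = 3

    def __post_init__(self):
        if self.n_members < 2:
            raise ValidationError("n_members must be >= 2")
        if any(v < 0 for v in self.template.values()):
            raise ValidationError("template values must be nonnegative")


@dataclass(frozen=True)
class PanelSpec:
    groups: Sequence[GroupSpec]
    within_group_cv: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.within_group_cv < 0:
            raise ValidationError("within_group_cv must be nonnegative")


@dataclass
class SimulatedMetagenome:
    """One panel member with its full ground truth."""

    label: str
    group: str
    contigs: list[Contig]
    depths: dict[str, float]
    planted: list[PlantedGene]
    contig_population: dict[str, str]
    template_draw: dict[str, float]

    @property
    def planted_nt_by_family(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for g in self.planted:
            out[g.family] = out.get(g.family, 0.0) + g.length
        return out


# ---------------------------------------------------------------------------
# family database


def build_family_db(
    families: Sequence[str],
    per_family: int = 3,
    aa_len_range: tuple[int, int] = (120, 240),
    seed: int = 0,
) -> tuple[list[FamilyRecord], dict[str, str]]:
    """Draw a random consensus peptide per family plus mutated members.

    Members are mutated at 10-20% of positions, so intra-family identity is
    80-90% while members of different families share only the ~5% background
    identity of random sequences.  Returns the records (headers carry the
    ``|FAM=`` token implicitly via the family field) and the per-family
    consensus peptides.
    """
    if not families:
        raise ValidationError("families must be nonempty")
    if per_family < 1:
        raise ValidationError("per_family must be >= 1")
    lo, hi = aa_len_range
    if lo < 30:
        raise ValidationError("aa_len_range min must be >= 30 (too short to align)")
    rng = np.random.default_rng(seed)
    aas = np.frombuffer(AA20.encode(), dtype=np.uint8)
    records: list[FamilyRecord] = []
    consensus: dict[str, str] = {}
    for fam in families:
        length = int(rng.integers(lo, hi + 1))
        cons = rng.choice(aas, size=length)
        consensus[fam] = cons.tobytes().decode()
        fam_token = fam.replace("/", "_")
        for m in range(per_family):
            member = cons.copy()
            rate = rng.uniform(0.10, 0.20)
            n_mut = max(1, int(round(rate * length)))
            pos = rng.choice(length, size=n_mut, replace=False)
            for p in pos:
                choices = aas[aas != member[p]]
                member[p] = rng.choice(choices)
            records.append(FamilyRecord(
                protein_id=f"{fam_token}_m{m + 1}",
                family=fam,
                aaseq=member.tobytes().decode(),
            ))
    return records, consensus


def db_to_fasta_records(db: Sequence[FamilyRecord]) -> list[tuple[str, str, str]]:
    """FASTA tuples with the ``|FAM=`` family token appended to the id."""
    return [(f"{r.protein_id}|FAM={r.family}", "", r.aaseq) for r in db]


# ---------------------------------------------------------------------------
# background genomes


@njit(cache=False)
def _markov_chain(cum_rows, first, second, u):  # pragma: no cover - jitted
    n = u.shape[0]
    out = np.empty(n + 2, np.int8)
    out[0] = first
    out[1] = second
    for i in range(n):
        state = 16 * out[i] + 4 * out[i + 1]
        x = u[i]
        b = 0
        while b < 3 and x >= cum_rows[state, b]:
            b += 1
        out[i + 2] = b
    return out


def make_markov_table(gc: float, seed: int, wobble: float = 0.6) -> np.ndarray:
    """Build a 64x4 order-2 transition table with stationary G+C == gc.

    Each row splits probability gc between C and G and (1-gc) between A and T
    by context-specific random ratios, so different populations acquire
    genuinely distinct trinucleotide structure at identical G+C.
    """
    rng = np.random.default_rng(seed)
    rows = np.empty((64, 4))
    at_split = rng.beta(4, 4, size=64) * wobble + (1 - wobble) / 2
    gc_split = rng.beta(4, 4, size=64) * wobble + (1 - wobble) / 2
    rows[:, 0] = (1 - gc) * at_split          # A
    rows[:, 3] = (1 - gc) * (1 - at_split)    # T
    rows[:, 1] = gc * gc_split                # C
    rows[:, 2] = gc * (1 - gc_split)          # G
    return rows


def make_population_spec(label: str, gc: float, genome_len: int, seed: int) -> PopulationSpec:
    return PopulationSpec(label, make_markov_table(gc, derive_seed(seed, label)),
                          gc, genome_len)


def default_populations(
    n: int = 6,
    genome_len: int = 300_000,
    gc_values: Sequence[float] | None = None,
    seed: int = 0,
) -> list[PopulationSpec]:
    """Populations with pairwise G+C gaps of >= 0.08 (the solvable regime)."""
    if gc_values is None:
        gc_values = [0.30 + 0.08 * i for i in range(n)]
    if len(gc_values) != n:
        raise ValidationError("need one gc value per population")
    return [
        make_population_spec(f"pop{chr(ord('A') + i)}", gc_values[i], genome_len, seed)
        for i in range(n)
    ]


def _sample_background(spec: PopulationSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    first, second = rng.choice(4, size=2, p=p)
    cum = np.cumsum(np.ascontiguousarray(spec.markov), axis=1)
    u = rng.random(max(n - 2, 0))
    return _markov_chain(cum, np.int8(first), np.int8(second), u)[:n]


def reverse_translate(aaseq: str, rng: np.random.Generator) -> str:
    """Uniform codon choice per residue."""
    return "".join(rng.choice(CODONS_BY_AA[aa]) for aa in aaseq)


def simulate_population_genome(
    spec: PopulationSpec,
    genes: Sequence[tuple[str, int]],
    db: Sequence[FamilyRecord],
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[str, list[PlantedGene]]:
    """Order-2 background with non-overlapping reverse-translated genes.

    Each planted gene is a reverse translation of a randomly chosen family
    member, inserted on a random strand; the returned truth list is in genome
    coordinates (contig_id = population label).
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[FamilyRecord]] = {}
    for rec in db:
        by_family.setdefault(rec.family, []).append(rec)
    plan: list[tuple[str, FamilyRecord, str]] = []
    total_coding = 0
    for fam, count in genes:
        if fam not in by_family:
            raise ValidationError(f"family {fam!r} not in database")
        for _ in range(count):
            member = by_family[fam][rng.integers(len(by_family[fam]))]
            nt = reverse_translate(member.aaseq, rng)
            total_coding += len(nt)
            plan.append((fam, member, nt))
    if total_coding > 0.5 * spec.genome_len:
        raise ValidationError(
            f"planted coding length {total_coding} exceeds half of "
            f"genome_len {spec.genome_len}"
        )
    codes = _sample_background(spec, spec.genome_len, rng)
    placed: list[tuple[int, int]] = []
    truth: list[PlantedGene] = []
    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    for fam, member, nt in plan:
        glen = len(nt)
        for attempt in range(max_tries):
            start = int(rng.integers(0, spec.genome_len - glen + 1))
            end = start + glen
            if all(end <= s or start >= e for s, e in placed):
                break
        else:
            raise ValidationError(
                "could not place all planted genes without overlap; "
                "use a longer genome or fewer genes"
            )
        placed.append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = nt if strand == "+" else revcomp(nt)
        idx = np.frombuffer(ins.encode(), dtype=np.uint8)
        lut = np.zeros(256, np.int8)
        for b, ch in enumerate(BASES):
            lut[ord(ch)] = b
        codes[start:end] = lut[idx]
        truth.append(PlantedGene(spec.label, start, end, fam, strand,
                                 member.protein_id))
    genome = base_codes[codes.astype(np.intp)].tobytes().decode()
    truth.sort(key=lambda g: g.start)
    return genome, truth


# ---------------------------------------------------------------------------
# shredding


def shred_to_contigs(
    genome: str,
    planted: Sequence[PlantedGene] = (),
    len_dist: LengthDist = LengthDist(),
    depth_dist: DepthDist = DepthDist(),
    seed: int = 0,
    id_prefix: str = "c",
) -> tuple[list[Contig], list[PlantedGene], dict[str, tuple[int, int]]]:
    """Cut a genome into consecutive non-overlapping contigs with depths.

    Planted-gene coordinates are lifted onto the contigs; genes split by a
    contig boundary are clipped and both parts retained in the truth with
    their clipped spans.  Also returns each contig's genome window so spans
    can be mapped back.
    """
    rng = np.random.default_rng(seed)
    L = len(genome)
    contigs: list[Contig] = []
    windows: dict[str, tuple[int, int]] = {}
    lifted: list[PlantedGene] = []
    pos = 0
    i = 0
    while pos < L:
        clen = int(round(rng.lognormal(len_dist.mu, len_dist.sigma)))
        clen = max(clen, len_dist.min_len)
        clen = min(clen, L - pos)
        if L - pos - clen < len_dist.min_len:
            clen = L - pos      # absorb a too-short tail
        i += 1
        cid = f"{id_prefix}{i}"
        depth = max(depth_dist.floor,
                    float(rng.gamma(depth_dist.shape, depth_dist.scale)))
        contigs.append(Contig(cid, genome[pos:pos + clen], depth))
        windows[cid] = (pos, pos + clen)
        for g in planted:
            s, e = max(g.start, pos), min(g.end, pos + clen)
            if s < e:
                lifted.append(PlantedGene(cid, s - pos, e - pos, g.family,
                                          g.strand, g.source_protein))
        pos += clen
    return contigs, lifted, windows


# ---------------------------------------------------------------------------
# panels

# Default group templates (nt per million depth-weighted nt).  The gut-like
# template carries no lignin-oxidase (LO/LDA) families at all, lacks the
# cellulase families (GH6, GH9, GH12, GH48) and leans on the
# oligosaccharide/hemicellulose hydrolases typical of Bacteroides-rich gut
# communities; the free-living template is cellulase- and lignin-oxidase-
# rich.  Values are deliberately dense (a few percent of sequence) so that
# desk-scale metagenomes of a few hundred kb realize stable family ranks.
FREE_LIVING_TEMPLATE: dict[str, float] = {
    "GH2": 1000.0, "GH3": 2000.0, "GH5": 3000.0, "GH6": 1500.0, "GH8": 1200.0,
    "GH9": 2200.0, "GH10": 2000.0, "GH12": 900.0, "GH13": 2500.0,
    "GH28": 600.0, "GH43": 1800.0, "GH48": 1600.0, "GH51": 1200.0,
    "GH92": 400.0, "GH95": 300.0, "GH94/GT84": 800.0,
    "GT2": 4000.0, "GT4": 3500.0,
    "LO1": 900.0, "LO2": 1100.0, "LO3": 1300.0, "LDA7": 300.0,
}
GUT_LIKE_TEMPLATE: dict[str, float] = {
    "GH2": 3500.0, "GH3": 2800.0, "GH5": 500.0, "GH6": 0.0, "GH8": 300.0,
    "GH9": 0.0, "GH10": 400.0, "GH12": 0.0, "GH13": 3000.0,
    "GH28": 1800.0, "GH43": 2500.0, "GH48": 0.0, "GH51": 400.0,
    "GH92": 2800.0, "GH95": 2200.0, "GH94/GT84": 1200.0,
    "GT2": 4200.0, "GT4": 3800.0,
    "LO1": 0.0, "LO2": 0.0, "LO3": 0.0, "LDA7": 0.0,
}
DEFAULT_FAMILIES = sorted(FREE_LIVING_TEMPLATE)


def default_panel(n_members: int = 3, within_group_cv: float = 0.2,
                  seed: int = 0) -> PanelSpec:
    return PanelSpec(
        groups=[
            GroupSpec("gut_like", GUT_LIKE_TEMPLATE, n_members),
            GroupSpec("free_living", FREE_LIVING_TEMPLATE, n_members),
        ],
        within_group_cv=within_group_cv,
        seed=seed,
    )


def simulate_panel(
    panel: PanelSpec,
    db: Sequence[FamilyRecord],
    population_specs: Sequence[PopulationSpec],
    len_dist: LengthDist = LengthDist(),
    depth_dist: DepthDist = DepthDist(),
) -> list[SimulatedMetagenome]:
    """Simulate every member metagenome of a grouped panel.

    Per member, per-family planted nucleotide totals are drawn so their
    expectation is proportional to the group template perturbed by
    ``within_group_cv`` (multiplicative lognormal noise; a zero template
    value stays exactly zero, so LO-depleted templates yield metagenomes with
    no planted LO genes at all).
    """
    db_families = {r.family for r in db}
    mean_gene_nt: dict[str, float] = {}
    for fam in db_families:
        lens = [len(r.aaseq) * 3 for r in db if r.family == fam]
        mean_gene_nt[fam] = float(np.mean(lens))
    for grp in panel.groups:
        missing = set(grp.template) - db_families
        if missing:
            raise ValidationError(f"template families not in db: {sorted(missing)}")
    total_nt = sum(s.genome_len for s in population_specs)
    out: list[SimulatedMetagenome] = []
    for grp in panel.groups:
        for m in range(grp.n_members):
            label = f"{grp.label}_{m + 1}"
            rng = np.random.default_rng(derive_seed(panel.seed, label))
            draw: dict[str, float] = {}
            counts: dict[str, int] = {}
            for fam in sorted(grp.template):
                mean_pm = grp.template[fam]
                if mean_pm == 0:
                    draw[fam] = 0.0
                    counts[fam] = 0
                    continue
                if panel.within_group_cv > 0:
                    sigma = np.sqrt(np.log1p(panel.within_group_cv ** 2))
                    noise = rng.lognormal(-sigma ** 2 / 2, sigma)
                else:
                    noise = 1.0
                pm = mean_pm * noise
                draw[fam] = pm
                # stochastic rounding: expectation stays exactly
                # proportional to the drawn template, variance < 1 gene
                expected = pm * total_nt / 1e6 / mean_gene_nt[fam]
                counts[fam] = int(np.floor(expected)
                                  + (rng.random() < expected % 1.0))
            # distribute each family's gene count over populations by size
            p = np.array([s.genome_len for s in population_specs], float)
            p /= p.sum()
            per_pop: list[list[tuple[str, int]]] = [[] for _ in population_specs]
            for fam in sorted(counts):
                if counts[fam] == 0:
                    continue
                alloc = rng.multinomial(counts[fam], p)
                for k, c in enumerate(alloc):
                    if c:
                        per_pop[k].append((fam, int(c)))
            contigs: list[Contig] = []
            depths: dict[str, float] = {}
            planted: list[PlantedGene] = []
            contig_pop: dict[str, str] = {}
            for k, spec in enumerate(population_specs):
                gseed = derive_seed(panel.seed, f"{label}/{spec.label}")
                genome, truth = simulate_population_genome(
                    spec, per_pop[k], db, seed=gseed)
                ctgs, lifted, _ = shred_to_contigs(
                    genome, truth, len_dist, depth_dist,
                    seed=derive_seed(panel.seed, f"{label}/{spec.label}/shred"),
                    id_prefix=f"{label}.{spec.label}.c")
                contigs.extend(ctgs)
                depths.update({c.id: c.depth for c in ctgs})
                planted.extend(lifted)
                contig_pop.update({c.id: spec.label for c in ctgs})
            out.append(SimulatedMetagenome(label, grp.label, contigs, depths,
                                           planted, contig_pop, draw))
    return out
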