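"""Built-in translated homology search (BlastX-style, exact local DP).

Each tile is translated in all six frames; every stop-free peptide segment is
aligned locally (Smith-Waterman, affine gaps) against every database protein,
and per (tile, database record) the single best local alignment is kept.
Alignments never cross stop codons.  Bit scores and e-values use fixed
Karlin-Altschul-style constants, so the module is interchangeable with an
external aligner's 12-column tabular output.

The only speed device is an *admissible* branch-and-bound: a local alignment
score can never exceed the sum, over the segment's residues, of each
residue's best substitution score, so segments whose bound cannot reach the
raw score implied by the e-value cutoff are skipped.  Output is provably
identical to exhaustive DP at the same cutoff (and the cutoff can be set to
``inf`` to disable pruning entirely).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io_formats import Contig, FamilyRecord, HitRecord, ValidationError, tile_query_id
from .util import revcomp

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
MATRIX_ALPHABET = str(_BLOSUM62.alphabet)        # 'ARNDCQEGHILKMFPSTWYVBZX*'
_X_INDEX = MATRIX_ALPHABET.index("X")

_CODON_TO_AA: dict[str, str] = {}
_tab = CodonTable.unambiguous_dna_by_id[1]
for _codon, _aa in _tab.forward_table.items():
    _CODON_TO_AA[_codon] = _aa
for _codon in _tab.stop_codons:
    _CODON_TO_AA[_codon] = "*"

_AA_LUT = np.full(256, _X_INDEX, dtype=np.int8)
for _i, _ch in enumerate(MATRIX_ALPHABET):
    _AA_LUT[ord(_ch)] = _i


@dataclass(frozen=True)
class ScoringParams:
    """Substitution scoring plus bit-score / e-value calibration.

    ``lambda_`` and ``k`` default to the common gapped-BLOSUM62 values; gap
    convention is that ``gap_open`` scores the first residue of a gap and
    ``gap_extend`` each further residue.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = -11
    gap_extend: int = -1
    lambda_: float = 0.267
    k: float = 0.041
    evalue_cutoff: float = 1e-10

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValidationError("gap scores must be nonpositive")
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValidationError("lambda_ and k must be positive")
        if not self.evalue_cutoff > 0:
            raise ValidationError("evalue_cutoff must be > 0")

    @property
    def matrix_array(self) -> np.ndarray:
        mat = substitution_matrices.load(self.matrix)
        if str(mat.alphabet) != MATRIX_ALPHABET:
            raise ValidationError(f"matrix {self.matrix} has unexpected alphabet")
        arr = np.asarray(mat, dtype=np.int32)
        if not np.array_equal(arr, arr.T):
            raise ValidationError("substitution matrix must be symmetric")
        return arr

    def bitscore(self, raw: float) -> float:
        return (self.lambda_ * raw - math.log(self.k)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bitscore(raw))

    def raw_threshold(self, m: int, n: int) -> float:
        """Raw score strictly above which evalue < cutoff."""
        if math.isinf(self.evalue_cutoff):
            return 0.0          # any positive local score qualifies
        return (math.log(m * n / self.evalue_cutoff) + math.log(self.k)) / self.lambda_


@dataclass(frozen=True)
class Frame:
    """One reading frame of a tile: +1..+3 forward, -1..-3 on the revcomp."""

    label: str
    strand: str
    offset: int     # nt offset of codon 1 within the (strand-oriented) sequence
    peptide: str


def translate_frame(dna: str, offset: int) -> str:
    n = (len(dna) - offset) // 3
    return "".join(
        _CODON_TO_AA.get(dna[offset + 3 * i: offset + 3 * i + 3], "X")
        for i in range(n)
    )


def six_frame_translate(dna: str) -> list[Frame]:
    """All six reading frames; codons containing N become X, stops are '*'."""
    if len(dna) < 3:
        raise ValidationError("sequence shorter than one codon")
    dna = dna.upper()
    rc = revcomp(dna)
    frames = []
    for off in range(3):
        frames.append(Frame(f"+{off + 1}", "+", off, translate_frame(dna, off)))
    for off in range(3):
        frames.append(Frame(f"-{off + 1}", "-", off, translate_frame(rc, off)))
    return frames


# ---------------------------------------------------------------------------
# DP kernel


@njit(cache=False)
def _sw_scores_vs_db(q, db, starts, ends, go, ge, sub, qsuffix, ithresh):  # pragma: no cover
    """Best local-alignment raw score of q against each db record.

    ``qsuffix[i]`` is the sum of per-residue best substitution scores over
    query rows > i, so ``rowbest + qsuffix[i]`` bounds any alignment that
    crosses row i and ``qsuffix[i]`` alone bounds any alignment confined to
    later rows.  Once neither bound nor the score so far can exceed
    ``ithresh`` the record is abandoned early; its reported score is then
    some value <= ithresh, which the caller discards anyway, so emitted
    hits are identical to exhaustive DP.
    """
    nrec = starts.shape[0]
    out = np.zeros(nrec, np.int32)
    n = q.shape[0]
    H = np.zeros(db.shape[0] + 1, np.int32)
    E = np.zeros(db.shape[0] + 1, np.int32)
    for r in range(nrec):
        s0, s1 = starts[r], ends[r]
        m = s1 - s0
        for j in range(m + 1):
            H[j] = 0
            E[j] = 0
        best = 0
        for i in range(1, n + 1):
            diag = 0
            F = -1000000
            qi = q[i - 1]
            rowbest = 0
            for j in range(1, m + 1):
                e = E[j] + ge
                t = H[j] + go
                if t > e:
                    e = t
                E[j] = e
                f = F + ge
                t = H[j - 1] + go
                if t > f:
                    f = t
                F = f
                h = diag + sub[qi, db[s0 + j - 1]]
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                diag = H[j]
                H[j] = h
                if h > rowbest:
                    rowbest = h
            if rowbest > best:
                best = rowbest
            if best <= ithresh and rowbest + qsuffix[i] <= ithresh \
                    and qsuffix[i] <= ithresh:
                break
        out[r] = best
    return out


class EncodedDB:
    """Database proteins encoded once for the DP kernel."""

    def __init__(self, db: Sequence[FamilyRecord], scoring: ScoringParams):
        if not db:
            raise ValidationError("empty family database")
        self.records = list(db)
        self.scoring = scoring
        self.sub = np.ascontiguousarray(scoring.matrix_array)
        self.rowmax = self.sub.max(axis=1).astype(np.int64)
        seqs = [np.frombuffer(r.aaseq.encode(), dtype=np.uint8) for r in db]
        enc = [_AA_LUT[s] for s in seqs]
        self.concat = np.ascontiguousarray(np.concatenate(enc))
        lens = np.array([len(s) for s in enc], dtype=np.int64)
        self.ends = np.cumsum(lens)
        self.starts = self.ends - lens
        self.total_residues = int(lens.sum())
        self._aligner = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=substitution_matrices.load(scoring.matrix),
            open_gap_score=scoring.gap_open,
            extend_gap_score=scoring.gap_extend,
        )


@dataclass
class _Candidate:
    score: int
    frame: Frame
    seg_aa_start: int   # segment offset within the frame peptide (aa)
    seg_pep: str


def _frame_segments(pep: str):
    """Stop-free segments of a frame peptide as (aa_offset, segment)."""
    pos = 0
    for seg in pep.split("*"):
        if seg:
            yield pos, seg
        pos += len(seg) + 1


def align_tile(
    tile_seq: str,
    db: Sequence[FamilyRecord] | EncodedDB,
    scoring: ScoringParams | None = None,
) -> list[HitRecord]:
    """Best local alignment per database record, e-value filtered.

    ``qstart``/``qend`` of each hit are nucleotide offsets within the tile on
    the forward strand regardless of the frame the alignment used.
    """
    if isinstance(db, EncodedDB):
        enc = db
        scoring = enc.scoring if scoring is None else scoring
    else:
        scoring = scoring or ScoringParams()
        enc = EncodedDB(db, scoring)
    if len(tile_seq) < 30:
        raise ValidationError("tile shorter than 30 nt")
    m = len(tile_seq)
    n = enc.total_residues
    thresh = scoring.raw_threshold(m, n)
    ithresh = np.int32(max(0, math.floor(thresh)))
    best: dict[int, _Candidate] = {}
    for frame in six_frame_translate(tile_seq):
        pep_codes = _AA_LUT[np.frombuffer(frame.peptide.encode(), dtype=np.uint8)]
        for aa_off, seg in _frame_segments(frame.peptide):
            q = pep_codes[aa_off: aa_off + len(seg)]
            row = enc.rowmax[q]
            if float(row.sum()) <= thresh:
                continue        # admissible bound: cannot reach the cutoff
            qsuffix = np.zeros(len(q) + 1, dtype=np.int32)
            qsuffix[:-1] = row[::-1].cumsum()[::-1]
            scores = _sw_scores_vs_db(q, enc.concat, enc.starts, enc.ends,
                                      scoring.gap_open, scoring.gap_extend,
                                      enc.sub, qsuffix, ithresh)
            for r in np.nonzero(scores > 0)[0]:
                sc = int(scores[r])
                cur = best.get(r)
                if cur is None or sc > cur.score:
                    best[int(r)] = _Candidate(sc, frame, aa_off, seg)
    hits: list[HitRecord] = []
    for r, cand in best.items():
        if cand.score <= thresh:
            continue
        ev = scoring.evalue(cand.score, m, n)
        if ev >= scoring.evalue_cutoff:
            continue
        rec = enc.records[r]
        hits.append(_traceback_hit(tile_seq, cand, rec, enc, scoring, m, n))
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return hits


def _traceback_hit(tile_seq, cand: _Candidate, rec: FamilyRecord,
                   enc: EncodedDB, scoring: ScoringParams, m: int, n: int) -> HitRecord:
    aln = enc._aligner.align(cand.seg_pep, rec.aaseq)[0]
    if int(aln.score) != cand.score:
        raise AssertionError(
            f"traceback score {aln.score} != DP score {cand.score}")
    tblocks, qblocks = aln.aligned      # target = segment, query = db record
    seg_a = int(tblocks[0][0])
    seg_b = int(tblocks[-1][1])
    counts = aln.counts()
    identities = counts.identities
    cols = identities + counts.mismatches + counts.gaps
    gapopen = 0
    for k in range(1, len(tblocks)):
        if tblocks[k][0] > tblocks[k - 1][1]:
            gapopen += 1
        if qblocks[k][0] > qblocks[k - 1][1]:
            gapopen += 1
    frame = cand.frame
    aa_a = cand.seg_aa_start + seg_a
    aa_b = cand.seg_aa_start + seg_b
    nt_a = frame.offset + 3 * aa_a
    nt_b = frame.offset + 3 * aa_b
    if frame.strand == "-":
        nt_a, nt_b = len(tile_seq) - nt_b, len(tile_seq) - nt_a
    return HitRecord(
        query_id="",            # filled by the caller for tile context
        subject_id=rec.protein_id,
        family=rec.family,
        evalue=scoring.evalue(cand.score, m, n),
        bitscore=scoring.bitscore(cand.score),
        qstart=nt_a,
        qend=nt_b,
        pident=100.0 * identities / cols if cols else 0.0,
        length=int(cols),
        mismatch=int(counts.mismatches),
        gapopen=gapopen,
        sstart=int(qblocks[0][0]) + 1,
        send=int(qblocks[-1][1]),
    )


def search_contigs(
    contigs: Sequence[Contig],
    db: Sequence[FamilyRecord],
    tiling_params=None,
    scoring: ScoringParams | None = None,
) -> list[HitRecord]:
    """Tile every contig and search each tile against the family database.

    Results are concatenated in contig order, tile order, then descending
    bitscore; query ids are ``<contig_id>:<start>-<end>``.
    """
    from .tiling_profile import TilingParams, tile_contig

    tiling_params = tiling_params or TilingParams()
    scoring = scoring or ScoringParams()
    enc = EncodedDB(db, scoring)
    out: list[HitRecord] = []
    from dataclasses import replace
    for contig in contigs:
        for _, start, end in tile_contig(contig, tiling_params):
            tile_seq = contig.seq[start:end]
            if len(tile_seq) < 30:
                continue
            qid = tile_query_id(contig.id, start, end)
            for h in align_tile(tile_seq, enc):
                out.append(replace(h, query_id=qid))
    return out
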