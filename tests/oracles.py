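"""Independent brute-force oracles used only by the tests.

These deliberately re-derive results by the most literal method available
(full dynamic programming tables, per-nucleotide marking, rank-then-Pearson)
so they share no code path with the implementations they check.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from Bio.Align import substitution_matrices

_MAT = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_MAT.alphabet)
_STOP_SCORE = -100000    # far below any achievable local score: stops block


def _pair_score(a: str, b: str) -> int:
    if a == "*" or b == "*":
        return _STOP_SCORE
    return int(_MAT[_ALPHA.index(a), _ALPHA.index(b)])


def sw_score_oracle(query: str, subject: str, go: int = -11, ge: int = -1) -> int:
    """Naive O(nm) affine-gap local alignment score (full 2-D tables).

    The first residue of a gap scores ``go``, each further one ``ge``.
    Stop codons ('*') score so low that no optimal local alignment crosses
    one.
    """
    n, m = len(query), len(subject)
    NEG = -(10 ** 9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + ge, H[i, j - 1] + go)
            F[i, j] = max(F[i - 1, j] + ge, H[i - 1, j] + go)
            s = _pair_score(qi, subject[j - 1])
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            if H[i, j] > best:
                best = int(H[i, j])
    return best


def best_tile_scores_oracle(tile_seq: str, db, go: int = -11, ge: int = -1
                            ) -> dict[str, int]:
    """Best six-frame local score of a tile against each db record."""
    from metacaz.search import six_frame_translate

    out: dict[str, int] = {}
    for rec in db:
        best = 0
        for frame in six_frame_translate(tile_seq):
            best = max(best, sw_score_oracle(frame.peptide, rec.aaseq, go, ge))
        out[rec.protein_id] = best
    return out


def per_million_oracle(hits, contigs, depths=None):
    """Per-family per-million by literal per-nucleotide marking.

    Picks each tile's winner with the stated tie-break, marks every covered
    contig nucleotide in a boolean mask per (contig, family), and sums
    masks times depth.
    """
    depths = depths or {}
    by_tile = defaultdict(list)
    for h in hits:
        by_tile[h.query_id].append(h)
    masks: dict[tuple[str, str], np.ndarray] = {}
    lengths = {c.id: len(c) for c in contigs}
    for qid, tile_hits in by_tile.items():
        win = min(tile_hits, key=lambda h: (h.evalue, -h.bitscore, h.family,
                                            h.subject_id))
        cid = win.contig_id
        ts, _ = win.tile_span
        key = (cid, win.family)
        if key not in masks:
            masks[key] = np.zeros(lengths[cid], dtype=bool)
        masks[key][ts + win.qstart: ts + win.qend] = True
    weighted = defaultdict(float)
    cdepth = {c.id: float(depths.get(c.id, c.depth)) for c in contigs}
    for (cid, fam), mask in masks.items():
        weighted[fam] += float(mask.sum()) * cdepth[cid]
    total = sum(len(c) * cdepth[c.id] for c in contigs)
    return {f: 1e6 * w / total for f, w in weighted.items()}, dict(weighted)


def spearman_oracle(x, y) -> float:
    """Rank (average ties) then Pearson."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])
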