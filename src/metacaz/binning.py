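"""Composition-based contig binning (nearest trinucleotide centroid).

Contigs are represented by strand-symmetric trinucleotide frequency vectors
(all overlapping 3-mers of the sequence and its reverse complement, 3-mers
containing N excluded).  Training computes one length-weighted centroid per
labelled population plus a distance threshold calibrated on the training
members; classification assigns each contig above a length cut to its
nearest centroid under L1 distance, or to "no match" when the distance
exceeds the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import Contig, ValidationError

NO_MATCH = "no match"

_CODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _ch in enumerate("ACGT"):
    _CODE_LUT[ord(_ch)] = _i

# index of the reverse complement of each 3-mer
_RC_PERM = np.empty(64, dtype=np.int64)
for _idx in range(64):
    _c0, _c1, _c2 = _idx // 16, (_idx // 4) % 4, _idx % 4
    _RC_PERM[_idx] = 16 * (3 - _c2) + 4 * (3 - _c1) + (3 - _c0)


@dataclass(frozen=True)
class TrinucVector:
    """64 trinucleotide frequencies, strand-symmetric by construction."""

    freqs: np.ndarray
    n_counted: int

    def __post_init__(self):
        if self.freqs.shape != (64,):
            raise ValidationError("trinucleotide vector must have 64 entries")
        if abs(float(self.freqs.sum()) - 1.0) > 1e-9:
            raise ValidationError("trinucleotide frequencies must sum to 1")


@dataclass(frozen=True)
class BinModel:
    """Per-population centroids with an assignment distance threshold."""

    centroids: Mapping[str, np.ndarray]
    threshold: float
    metric: str = "l1"

    def __post_init__(self):
        if len(self.centroids) < 2:
            raise ValidationError("need at least 2 bins")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.metric != "l1":
            raise ValidationError(f"unknown metric {self.metric!r}")


def _trinuc_counts(seq: str) -> tuple[np.ndarray, int]:
    codes = _CODE_LUT[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if codes.shape[0] < 3:
        return np.zeros(64, dtype=np.int64), 0
    c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4)
    idx = (16 * c0 + 4 * c1 + c2)[valid].astype(np.int64)
    counts = np.bincount(idx, minlength=64)
    return counts, int(valid.sum())


def trinuc_vector(seq: str, min_len: int = 1000) -> TrinucVector:
    """Strand-symmetric trinucleotide frequency vector of a sequence."""
    if len(seq) < min_len:
        raise ValidationError(
            f"sequence of length {len(seq)} too short for a stable "
            f"composition estimate (need >= {min_len})")
    counts, n = _trinuc_counts(seq)
    sym = counts + counts[_RC_PERM]
    total = sym.sum()
    if total == 0:
        raise ValidationError("no countable trinucleotides (all-N sequence?)")
    return TrinucVector(sym / total, 2 * n)


def l1_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum())


def train(
    labeled_contigs: Iterable[tuple[Contig, str]],
    threshold_percentile: float = 95.0,
    min_len: int = 1000,
) -> BinModel:
    """Train a centroid classifier from labelled contigs.

    The centroid of each bin is the length-weighted mean of its members'
    trinucleotide vectors; the default assignment threshold is the
    ``threshold_percentile`` of training-member distances to their own
    centroid, maximized over bins.
    """
    members: dict[str, list[tuple[np.ndarray, int]]] = {}
    for contig, label in labeled_contigs:
        if len(contig) < min_len:
            continue
        v = trinuc_vector(contig.seq, min_len)
        members.setdefault(label, []).append((v.freqs, len(contig)))
    if not members:
        raise ValidationError("no training contig reaches min_len")
    centroids: dict[str, np.ndarray] = {}
    for label in sorted(members):
        if not members[label]:
            raise ValidationError(f"bin {label!r} has no valid training contig")
        vecs = np.array([v for v, _ in members[label]])
        w = np.array([float(n) for _, n in members[label]])
        centroid = (vecs * w[:, None]).sum(axis=0) / w.sum()
        centroids[label] = centroid / centroid.sum()
    thresh = 0.0
    for label, mem in members.items():
        d = [l1_distance(v, centroids[label]) for v, _ in mem]
        thresh = max(thresh, float(np.percentile(d, threshold_percentile)))
    return BinModel(centroids, max(thresh, 1e-12))


def classify(
    contigs: Iterable[Contig],
    model: BinModel,
    min_len: int = 2000,
) -> dict[str, str]:
    """Assign contigs to bins; short or distant contigs get "no match".

    Ties between equidistant centroids are broken lexicographically by bin
    label, and classification is strand-invariant by construction of the
    trinucleotide vectors.
    """
    labels = sorted(model.centroids)
    cent = np.array([model.centroids[b] for b in labels])
    out: dict[str, str] = {}
    for c in contigs:
        if len(c) < min_len:
            out[c.id] = NO_MATCH
            continue
        v = trinuc_vector(c.seq, min_len=min(min_len, 1000)).freqs
        d = np.abs(cent - v[None, :]).sum(axis=1)
        best = int(np.argmin(d))    # argmin takes the first == smallest label
        out[c.id] = labels[best] if d[best] <= model.threshold else NO_MATCH
    return out
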