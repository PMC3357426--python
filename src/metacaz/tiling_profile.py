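"""Tiled family profiling: the pipeline's core computation.

Contigs are divided into overlapping tiles (default 300 nt, step 150), each
tile gets at most one best family hit, the winning hits' aligned spans are
lifted to contig coordinates and unioned per family into maximal disjoint
runs (so the 150 nt tile overlap is never double-counted), run lengths are
weighted by mean contig depth, and family totals are normalized to
nucleotides per million depth-weighted nucleotides — at whole-metagenome or
per-bin level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import Contig, HitRecord, ValidationError


@dataclass(frozen=True)
class TilingParams:
    tile_len: int = 300
    step: int = 150
    min_tail: int = 150

    def __post_init__(self):
        if self.tile_len <= 0 or self.step <= 0 or self.min_tail < 0:
            raise ValidationError("tiling parameters must be positive")
        if self.step > self.tile_len:
            raise ValidationError("step must be <= tile_len")
        if self.min_tail > self.tile_len:
            raise ValidationError("min_tail must be <= tile_len")


@dataclass(frozen=True)
class TileAssignment:
    """The winning family for one tile, with its span in contig coordinates."""

    contig_id: str
    tile_start: int
    tile_end: int
    family: str
    evalue: float
    bitscore: float
    start: int      # aligned span, contig coordinates, 0-based half-open
    end: int


@dataclass(frozen=True)
class FamilyRun:
    """A maximal contiguous stretch of contig nucleotides attributed to one
    family."""

    contig_id: str
    family: str
    start: int
    end: int
    depth: float = 1.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError("bad run span")

    @property
    def covered_nt(self) -> int:
        return self.end - self.start


@dataclass
class FamilyProfile:
    """Per-metagenome (or per-bin) depth-weighted family abundances."""

    label: str
    weighted_nt: dict[str, float]
    total_weighted_bases: float
    per_million: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_weighted_bases <= 0:
            raise ValidationError("total_weighted_bases must be positive")
        if not self.per_million:
            self.per_million = {
                f: 1e6 * w / self.total_weighted_bases
                for f, w in self.weighted_nt.items()
            }


def tile_contig(contig: Contig | tuple[str, int], params: TilingParams = TilingParams()
                ) -> list[tuple[str, int, int]]:
    """Overlapping tiles of a contig as ``(contig_id, start, end)``.

    Starts run at multiples of ``step``; a final partial tile is emitted only
    if its length is at least ``min_tail``; tiling stops once a tile reaches
    the contig end.  A contig shorter than ``min_tail`` yields a single tile
    covering the whole contig.
    """
    if isinstance(contig, Contig):
        cid, length = contig.id, len(contig)
    else:
        cid, length = contig
    if length < 1:
        raise ValidationError("empty contig")
    tiles = []
    start = 0
    while True:
        end = min(start + params.tile_len, length)
        if start == 0 or end - start >= params.min_tail:
            tiles.append((cid, start, end))
        if end == length:
            break
        start += params.step
    return tiles


def best_hit_per_tile(
    hits: Iterable[HitRecord],
    run_length: str = "span",
) -> dict[str, TileAssignment]:
    """Pick the single best family hit of each tile.

    Ties are broken by maximum bitscore, then lexicographically smallest
    family, then smallest subject id.  The winning hit's aligned span is
    mapped from tile-local to contig coordinates; with ``run_length="tile"``
    the whole tile is attributed instead of the aligned span.
    """
    if run_length not in ("span", "tile"):
        raise ValidationError(f"unknown run_length mode {run_length!r}")
    winners: dict[str, HitRecord] = {}
    for h in hits:
        cur = winners.get(h.query_id)
        if cur is None or _hit_key(h) < _hit_key(cur):
            winners[h.query_id] = h
    out: dict[str, TileAssignment] = {}
    for qid, h in winners.items():
        ts, te = h.tile_span
        if run_length == "tile":
            a, b = ts, te
        else:
            a, b = ts + h.qstart, ts + h.qend
        out[qid] = TileAssignment(h.contig_id, ts, te, h.family,
                                  h.evalue, h.bitscore, a, b)
    return out


def _hit_key(h: HitRecord):
    return (h.evalue, -h.bitscore, h.family, h.subject_id)


def collect_runs(
    assignments: Mapping[str, TileAssignment] | Iterable[TileAssignment],
    contig_lengths: Mapping[str, int],
    depths: Mapping[str, float] | None = None,
) -> list[FamilyRun]:
    """Union per-tile winning spans into maximal disjoint per-family runs.

    Spans of adjacent or overlapping tiles sharing a family are merged, so
    each contig nucleotide is counted at most once per family; runs of
    *different* families may overlap each other.
    """
    depths = depths or {}
    if hasattr(assignments, "values"):
        assignments = list(assignments.values())
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for a in assignments:
        length = contig_lengths.get(a.contig_id)
        if length is None:
            raise ValidationError(f"unknown contig {a.contig_id!r}")
        if not (0 <= a.start < a.end <= length):
            raise ValidationError(
                f"span [{a.start},{a.end}) outside contig {a.contig_id!r} "
                f"of length {length}")
        by_key.setdefault((a.contig_id, a.family), []).append((a.start, a.end))
    runs: list[FamilyRun] = []
    for (cid, fam) in sorted(by_key):
        spans = sorted(by_key[(cid, fam)])
        cur_s, cur_e = spans[0]
        merged = []
        for s, e in spans[1:]:
            if s <= cur_e:          # overlapping or touching -> contiguous
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        d = float(depths.get(cid, 1.0))
        runs.extend(FamilyRun(cid, fam, s, e, d) for s, e in merged)
    return runs


def family_totals(
    runs: Iterable[FamilyRun],
    depths: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Depth-weighted nucleotide totals per family.

    ``weighted_nt[f] = sum over runs of f of covered_nt * depth(contig)``;
    contigs without depth information count with depth 1.
    """
    totals: dict[str, float] = {}
    for r in runs:
        d = float(depths[r.contig_id]) if depths and r.contig_id in depths else r.depth
        totals[r.family] = totals.get(r.family, 0.0) + r.covered_nt * d
    return totals


def total_weighted_bases(contigs: Iterable[Contig],
                         depths: Mapping[str, float] | None = None) -> float:
    tot = 0.0
    for c in contigs:
        d = float(depths[c.id]) if depths and c.id in depths else c.depth
        tot += len(c) * d
    return tot


def normalize_per_million(
    totals: Mapping[str, float],
    contigs: Sequence[Contig],
    depths: Mapping[str, float] | None = None,
    label: str = "metagenome",
) -> FamilyProfile:
    """Normalize family totals to nt per million depth-weighted nt."""
    if not contigs:
        raise ValidationError("normalize_per_million: no contigs")
    twb = total_weighted_bases(contigs, depths)
    if twb <= 0:
        raise ValidationError("zero total weighted bases")
    return FamilyProfile(label, dict(totals), twb)


def bin_profiles(
    runs: Iterable[FamilyRun],
    contigs: Sequence[Contig],
    assignment: Mapping[str, str],
    depths: Mapping[str, float] | None = None,
    min_contig_len: int = 1000,
    no_match_label: str = "no match",
    per_bin_denominator: bool = True,
) -> dict[str, FamilyProfile]:
    """Per-bin family profiles over contigs of at least ``min_contig_len``.

    Contigs absent from ``assignment`` fall into the ``no match`` bin.  Each
    bin's profile is normalized by that bin's own depth-weighted base total
    (set ``per_bin_denominator=False`` for a metagenome-wide denominator).
    """
    kept = [c for c in contigs if len(c) >= min_contig_len]
    if not kept:
        raise ValidationError("no contigs pass min_contig_len")
    bins: dict[str, list[Contig]] = {}
    contig_bin: dict[str, str] = {}
    for c in kept:
        b = assignment.get(c.id, no_match_label)
        bins.setdefault(b, []).append(c)
        contig_bin[c.id] = b
    bin_totals: dict[str, dict[str, float]] = {b: {} for b in bins}
    for r in runs:
        b = contig_bin.get(r.contig_id)
        if b is None:
            continue            # contig below the length cut
        d = float(depths[r.contig_id]) if depths and r.contig_id in depths else r.depth
        t = bin_totals[b]
        t[r.family] = t.get(r.family, 0.0) + r.covered_nt * d
    global_twb = total_weighted_bases(kept, depths)
    out: dict[str, FamilyProfile] = {}
    for b in sorted(bins):
        twb = total_weighted_bases(bins[b], depths) if per_bin_denominator else global_twb
        out[b] = FamilyProfile(b, bin_totals[b], twb)
    return out


def rank_families(
    profile: FamilyProfile | Mapping[str, float],
    top_n: int = 22,
) -> list[tuple[str, float, float]]:
    """Top families by value with their share of the grand total.

    Accepts a profile (ranked on ``weighted_nt``) or any family->value map
    (e.g. gene counts).  Ties are broken lexicographically.  Returns
    ``(family, value, share)`` tuples in descending order.
    """
    if top_n < 1:
        raise ValidationError("top_n must be >= 1")
    values = profile.weighted_nt if isinstance(profile, FamilyProfile) else dict(profile)
    if not values:
        raise ValidationError("empty profile")
    grand = float(sum(values.values()))
    if grand <= 0:
        raise ValidationError("profile total must be positive")
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return [(f, v, v / grand) for f, v in ranked]
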