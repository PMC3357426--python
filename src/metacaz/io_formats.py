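"""Readers and writers for every on-disk artifact the pipeline touches.

All internal coordinates are 0-based half-open on the forward contig strand.
External tabular alignment files use the common aligner dialect (1-based,
inclusive); conversion happens here, at the boundary, and nowhere else.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

log = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")
# 20 canonical residues plus X (unknown) and * (stop, used in translations).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

FAMILY_TOKEN = "|FAM="


class ValidationError(ValueError):
    """Raised when an on-disk artifact violates a stated invariant."""


@dataclass(frozen=True)
class Contig:
    """A nucleotide sequence with identifier and mean assembly depth."""

    id: str
    seq: str
    depth: float = 1.0

    def __post_init__(self):
        if not self.id:
            raise ValidationError("contig id must be nonempty")
        if len(self.seq) < 1:
            raise ValidationError(f"contig {self.id}: empty sequence")
        if self.depth <= 0:
            raise ValidationError(f"contig {self.id}: depth must be > 0")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FamilyRecord:
    """A family-labelled protein reference sequence.

    Composite labels such as ``GH94/GT84`` are treated as atomic strings,
    matching how mixed-domain families are tabulated.
    """

    protein_id: str
    family: str
    aaseq: str

    def __post_init__(self):
        if not self.family:
            raise ValidationError(f"protein {self.protein_id}: empty family label")
        bad = set(self.aaseq) - PROTEIN_ALPHABET
        if bad:
            raise ValidationError(
                f"protein {self.protein_id}: illegal residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class HitRecord:
    """One translated-search hit of a tile against a family protein.

    ``qstart``/``qend`` are nucleotide offsets of the aligned span within the
    tile, 0-based half-open, on the forward contig strand regardless of the
    frame the alignment was found in.
    """

    query_id: str
    subject_id: str
    family: str
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    pident: float = 0.0
    length: int = 0
    mismatch: int = 0
    gapopen: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValidationError("evalue must be >= 0")
        if not (0 <= self.qstart < self.qend):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: bad span "
                f"[{self.qstart},{self.qend})"
            )

    @property
    def contig_id(self) -> str:
        cid, _, _ = self.query_id.rpartition(":")
        return cid

    @property
    def tile_span(self) -> tuple[int, int]:
        _, _, span = self.query_id.rpartition(":")
        a, _, b = span.partition("-")
        return int(a), int(b)


def tile_query_id(contig_id: str, start: int, end: int) -> str:
    return f"{contig_id}:{start}-{end}"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: str = "dna") -> list[tuple[str, str, str]]:
    """Read a FASTA file, validating against the given alphabet.

    Returns ``(id, description, seq)`` tuples in file order, sequences
    uppercased.  ``description`` is the header text after the first
    whitespace (empty string if none).
    """
    if alphabet not in ("dna", "protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = DNA_ALPHABET if alphabet == "dna" else PROTEIN_ALPHABET
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    out: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValidationError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - allowed
        if bad:
            raise ValidationError(
                f"{path}: illegal {alphabet} characters {sorted(bad)} in {rec.id!r}"
            )
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append((rec.id, desc, seq))
    if not out:
        raise ValidationError(f"{path}: no FASTA records")
    return out


def write_fasta(records: Iterable[tuple[str, str, str]], path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description=desc)
        for rid, desc, seq in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def read_contigs(path, depths: Mapping[str, float] | None = None) -> list[Contig]:
    """Read contigs, joining per-contig depths (missing contigs get 1.0)."""
    depths = depths or {}
    return [
        Contig(rid, seq, float(depths.get(rid, 1.0)))
        for rid, _desc, seq in read_fasta(path, "dna")
    ]


def read_family_db(path, family_map: Mapping[str, str] | None = None) -> list[FamilyRecord]:
    """Read a family-labelled protein FASTA.

    The family is resolved through ``family_map`` when given, else from a
    ``|FAM=<label>`` token in the record id or description.
    """
    out = []
    for rid, desc, seq in read_fasta(path, "protein"):
        fam = None
        if family_map is not None:
            fam = family_map.get(rid)
        if fam is None:
            fam = _family_from_header(rid) or _family_from_header(desc)
        if fam is None:
            raise ValidationError(f"{path}: no family label for {rid!r}")
        out.append(FamilyRecord(rid, fam, seq))
    return out


def _family_from_header(text: str) -> str | None:
    if FAMILY_TOKEN not in text:
        return None
    tail = text.split(FAMILY_TOKEN, 1)[1]
    fam = tail.split()[0].split("|")[0] if tail else ""
    return fam or None


# ---------------------------------------------------------------------------
# depth table


def read_depth_table(path) -> dict[str, float]:
    """Read a two-column TSV of contig_id, mean depth.

    A missing file is not an error at join time: contigs absent from the
    returned map default to depth 1.0 downstream.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected >=2 tab-separated columns")
    # tolerate an optional header row
    if df.iloc[0, 0] in ("contig_id", "contig"):
        df = df.iloc[1:]
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        cid = str(row.iloc[0])
        try:
            depth = float(row.iloc[1])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric depth for {cid!r}") from exc
        if not math.isfinite(depth) or depth <= 0:
            raise ValidationError(f"{path}: nonpositive depth {depth} for {cid!r}")
        if cid in out:
            raise ValidationError(f"{path}: duplicate contig {cid!r}")
        out[cid] = depth
    return out


def write_depth_table(depths: Mapping[str, float], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for cid in depths:
            fh.write(f"{cid}\t{depths[cid]:g}\n")


# ---------------------------------------------------------------------------
# tabular hits (12-column aligner dialect)

HIT_COLUMNS = [
    "query_id", "subject_id", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hit_table(path, family_map: Mapping[str, str] | None = None) -> list[HitRecord]:
    """Parse 12-column tabular alignment output into :class:`HitRecord`.

    External coordinates are 1-based inclusive and converted to 0-based
    half-open.  Rows whose subject has no resolvable family are dropped (a
    count is logged).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    records: list[HitRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=12 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                (query, subject, pident, length, mismatch, gapopen,
                 qstart, qend, sstart, send, evalue, bitscore) = fields[:12]
                fam = None
                if family_map is not None:
                    fam = family_map.get(subject)
                if fam is None:
                    fam = _family_from_header(subject)
                if fam is None:
                    dropped += 1
                    continue
                records.append(HitRecord(
                    query_id=query,
                    subject_id=subject,
                    family=fam,
                    evalue=float(evalue),
                    bitscore=float(bitscore),
                    qstart=int(qstart) - 1,   # 1-based inclusive -> 0-based half-open
                    qend=int(qend),
                    pident=float(pident),
                    length=int(length),
                    mismatch=int(mismatch),
                    gapopen=int(gapopen),
                    sstart=int(sstart),
                    send=int(send),
                ))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if dropped:
        log.info("read_hit_table: dropped %d rows with unresolvable family", dropped)
    read_hit_table.last_dropped = dropped  # type: ignore[attr-defined]
    return records


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    """Write hits in the 12-column dialect (1-based inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.1f}\t{h.length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart + 1}\t{h.qend}\t"
                f"{h.sstart}\t{h.send}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# profile matrices


def write_profile_matrix(profiles, path) -> None:
    """Write per-million profiles as a TSV matrix.

    Rows are families (lexicographic over the union, zero-filled), columns
    are metagenome/bin labels; values to 2 decimals.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("write_profile_matrix: empty profile set")
    families = sorted({f for p in profiles for f in p.per_million})
    labels = [p.label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValidationError("write_profile_matrix: duplicate profile labels")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("family\t" + "\t".join(labels) + "\n")
        for fam in families:
            vals = "\t".join(f"{p.per_million.get(fam, 0.0):.2f}" for p in profiles)
            fh.write(f"{fam}\t{vals}\n")


def read_profile_matrix(path) -> pd.DataFrame:
    """Read a profile matrix back as a families x labels DataFrame."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isnull().any().any() or (df.values < 0).any():
        raise ValidationError(f"{path}: negative or missing matrix entries")
    return df
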