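"""Germline locus data model for TCR V(D)J rearrangement analysis.

A :class:`Locus` is a small, self-contained reference: an ordered set of V, D
and J gene segments placed on a single toy contig, each carrying the
coordinates of its recombination signal sequence (RSS) and, for V and J
segments, the conserved CDR3 anchor codon (the 2nd cysteine of the V region,
the phenylalanine of the J-region FGxG motif).  Real germline databases can be
loaded from a FASTA plus a tab-separated annotation table; deterministic toy
loci for simulation and testing are built with :func:`build_toy_locus`.

Coordinate conventions
----------------------
All coordinates are 0-based.  Intervals on the contig are half-open
``[start, end)``, except the on-target window around an RSS, which is stored
closed at both ends (``RSS - w`` through ``RSS + w`` inclusive) to match the
"RSS +/- 40 bp" quantification rule.  Toy loci are plus-strand only.

Segment geometry: V segments carry their RSS at the 3' end of the coding
sequence (``rss_pos == len(sequence)``); J segments begin immediately after
their RSS (``rss_pos == 0``).  Anchor codon offsets lie on a codon boundary of
the segment's own reading frame (frame 0 from the segment start).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GermlineSegment",
    "Locus",
    "LocusLoadError",
    "load_locus",
    "write_locus",
    "build_toy_locus",
    "on_target_window",
    "ANNOTATION_COLUMNS",
]

_ALPHABET = set("ACGT")

SEGMENT_TYPES = ("V", "D", "J")
FUNCTIONALITY_STATES = ("functional", "pseudogene", "nonfunctional_rss")

ANNOTATION_COLUMNS = [
    "id",
    "type",
    "locus",
    "contig_start",
    "contig_end",
    "strand",
    "functionality",
    "rss_pos",
    "anchor_codon_offset",
    "cluster",
    "positional_class",
]

# codons that never introduce a stop; used when synthesising toy coding regions
_SAFE_CODONS = [
    "GCT", "GCC", "GCA", "GGT", "GGA", "GGC", "TCT", "AGC", "ACA", "ACC",
    "CTG", "CTC", "GAA", "GAG", "GAT", "GAC", "CAG", "AAC", "AGT", "GTG",
]


class LocusLoadError(ValueError):
    """Raised when a locus definition fails validation; names the segment."""


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J segment with RSS and anchor annotation.

    ``rss_pos`` is the offset of the first RSS base relative to the segment
    sequence: ``len(sequence)`` for V segments (RSS at the 3' end) and ``0``
    for J segments (coding sequence starts right after the RSS).
    ``anchor_codon_offset`` is the 0-based offset of the conserved CDR3 anchor
    codon (Cys for V, Phe for J); D segments have none.
    """

    id: str
    segment_type: str
    locus: str
    sequence: str
    functionality: str = "functional"
    rss_pos: int = 0
    anchor_codon_offset: Optional[int] = None
    cluster: Optional[str] = None
    positional_class: Optional[str] = None
    contig_start: int = 0
    contig_end: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise LocusLoadError(f"segment {self.id}: empty sequence")
        if set(self.sequence) - _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise LocusLoadError(f"segment {self.id}: invalid alphabet {bad}")
        if self.segment_type not in SEGMENT_TYPES:
            raise LocusLoadError(
                f"segment {self.id}: unknown segment type {self.segment_type!r}"
            )
        if self.functionality not in FUNCTIONALITY_STATES:
            raise LocusLoadError(
                f"segment {self.id}: unknown functionality {self.functionality!r}"
            )
        n = len(self.sequence)
        if self.segment_type == "V" and self.rss_pos != n:
            raise LocusLoadError(
                f"segment {self.id}: V segments carry the RSS at the 3' end "
                f"(rss_pos {self.rss_pos} != {n})"
            )
        if self.segment_type == "J" and self.rss_pos != 0:
            raise LocusLoadError(
                f"segment {self.id}: J segments carry the RSS at the 5' end "
                f"(rss_pos {self.rss_pos} != 0)"
            )
        if not 0 <= self.rss_pos <= n:
            raise LocusLoadError(f"segment {self.id}: rss_pos out of range")
        a = self.anchor_codon_offset
        if a is not None:
            if self.segment_type == "D":
                raise LocusLoadError(f"segment {self.id}: D segments have no anchor")
            if not 0 <= a <= n - 3:
                raise LocusLoadError(
                    f"segment {self.id}: anchor codon offset {a} out of range"
                )
            if a % 3 != 0:
                raise LocusLoadError(
                    f"segment {self.id}: anchor offset {a} not on a codon "
                    "boundary of the segment reading frame"
                )
        if self.contig_end and self.contig_end - self.contig_start != n:
            raise LocusLoadError(
                f"segment {self.id}: contig interval does not match sequence length"
            )

    @property
    def anchor_codon(self) -> Optional[str]:
        if self.anchor_codon_offset is None:
            return None
        a = self.anchor_codon_offset
        return self.sequence[a : a + 3]

    @property
    def anchor_aa(self) -> Optional[str]:
        codon = self.anchor_codon
        return None if codon is None else str(Seq(codon).translate())

    @property
    def rss_genomic(self) -> int:
        """Contig position of the RSS (first RSS base, plus strand)."""
        return self.contig_start + self.rss_pos


@dataclass
class Locus:
    """An ordered germline locus on a single toy contig."""

    name: str
    segments: list[GermlineSegment]
    contig: Optional[str] = None
    _by_id: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LocusLoadError(f"duplicate segment ids: {dup}")
        # non-overlap and list order must match contig order
        for a, b in zip(self.segments, self.segments[1:]):
            if b.contig_start < a.contig_end:
                raise LocusLoadError(
                    f"segments {a.id} and {b.id} overlap or are out of order"
                )
        if self.contig is not None:
            for s in self.segments:
                if s.contig_end > len(self.contig):
                    raise LocusLoadError(
                        f"segment {s.id} extends past the end of the contig"
                    )
                if self.contig[s.contig_start : s.contig_end] != s.sequence:
                    raise LocusLoadError(
                        f"segment {s.id}: contig sequence disagrees with segment sequence"
                    )
        self._by_id = {s.id: s for s in self.segments}

    def __getitem__(self, seg_id: str) -> GermlineSegment:
        try:
            return self._by_id[seg_id]
        except KeyError:
            raise KeyError(f"no segment {seg_id!r} in locus {self.name}") from None

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._by_id

    def of_type(self, segment_type: str) -> list[GermlineSegment]:
        return [s for s in self.segments if s.segment_type == segment_type]

    @property
    def v_segments(self) -> list[GermlineSegment]:
        return self.of_type("V")

    @property
    def d_segments(self) -> list[GermlineSegment]:
        return self.of_type("D")

    @property
    def j_segments(self) -> list[GermlineSegment]:
        return self.of_type("J")

    def upstream_flank(self, seg_id: str, length: int) -> str:
        """Contig sequence immediately 5' of a segment (germline flank)."""
        if self.contig is None:
            raise ValueError("locus has no contig sequence")
        s = self[seg_id]
        start = max(0, s.contig_start - length)
        return self.contig[start : s.contig_start]

    def downstream_flank(self, seg_id: str, length: int) -> str:
        """Contig sequence immediately 3' of a segment."""
        if self.contig is None:
            raise ValueError("locus has no contig sequence")
        s = self[seg_id]
        return self.contig[s.contig_end : s.contig_end + length]


def on_target_window(segment: GermlineSegment, w: int = 40) -> tuple[int, int]:
    """Closed genomic interval ``[RSS - w, RSS + w]`` used for on-target calls.

    Junction breakpoints falling inside this window (inclusive at both ends)
    count toward segment usage; everything else is off-target.
    """
    if w <= 0:
        raise ValueError(f"on-target window half-width must be positive, got {w}")
    rss = segment.rss_genomic
    return (rss - w, rss + w)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise LocusLoadError(msg)


def load_locus(
    segment_fasta: str | Path,
    annotation_table: str | Path,
    contig_fasta: str | Path | None = None,
    name: str | None = None,
) -> Locus:
    """Load a locus from a segment FASTA plus TSV annotation table.

    FASTA ids must match annotation rows one-to-one.  The optional contig
    FASTA supplies the toy reference contig the coordinates refer to; without
    it, germline-flank-dependent analyses (germline/DJ read classification)
    are unavailable.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(segment_fasta), "fasta")}
    table = pd.read_csv(annotation_table, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    _require(not missing_cols, f"annotation table missing columns: {missing_cols}")

    segments = []
    seen = set()
    for row in table.itertuples(index=False):
        sid = row.id
        _require(sid in seqs, f"annotation row references absent FASTA id {sid!r}")
        seen.add(sid)
        anchor = None if row.anchor_codon_offset == "" else int(row.anchor_codon_offset)
        segments.append(
            GermlineSegment(
                id=sid,
                segment_type=row.type,
                locus=row.locus,
                sequence=seqs[sid],
                functionality=row.functionality,
                rss_pos=int(row.rss_pos),
                anchor_codon_offset=anchor,
                cluster=row.cluster or None,
                positional_class=row.positional_class or None,
                contig_start=int(row.contig_start),
                contig_end=int(row.contig_end),
                strand=row.strand,
            )
        )
    orphans = sorted(set(seqs) - seen)
    _require(not orphans, f"FASTA ids without annotation rows: {orphans}")

    contig = None
    if contig_fasta is not None:
        recs = list(SeqIO.parse(str(contig_fasta), "fasta"))
        _require(len(recs) == 1, "contig FASTA must contain exactly one record")
        contig = str(recs[0].seq).upper()

    locus_name = name or (segments[0].locus if segments else "locus")
    return Locus(name=locus_name, segments=segments, contig=contig)


def write_locus(locus: Locus, out_dir: str | Path, prefix: str | None = None) -> dict[str, Path]:
    """Write a locus as segment FASTA + annotation TSV (+ contig FASTA).

    Returns the mapping of role -> path; ``load_locus`` on these files
    reproduces an identical locus.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or locus.name
    paths = {
        "segments": out_dir / f"{prefix}.segments.fasta",
        "annotation": out_dir / f"{prefix}.segments.tsv",
    }
    records = [SeqRecord(Seq(s.sequence), id=s.id, description="") for s in locus.segments]
    SeqIO.write(records, str(paths["segments"]), "fasta")

    rows = []
    for s in locus.segments:
        rows.append(
            {
                "id": s.id,
                "type": s.segment_type,
                "locus": s.locus,
                "contig_start": s.contig_start,
                "contig_end": s.contig_end,
                "strand": s.strand,
                "functionality": s.functionality,
                "rss_pos": s.rss_pos,
                "anchor_codon_offset": "" if s.anchor_codon_offset is None else s.anchor_codon_offset,
                "cluster": s.cluster or "",
                "positional_class": s.positional_class or "",
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        paths["annotation"], sep="\t", index=False
    )
    if locus.contig is not None:
        paths["contig"] = out_dir / f"{prefix}.contig.fasta"
        SeqIO.write(
            [SeqRecord(Seq(locus.contig), id=f"{prefix}_contig", description="")],
            str(paths["contig"]),
            "fasta",
        )
    return paths


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _safe_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    return "".join(_SAFE_CODONS[i] for i in idx)


def _positional_classes(n: int, labels: tuple[str, str, str]) -> list[str]:
    """Split n positions into three contiguous positional classes."""
    out = []
    for i in range(n):
        frac = i / max(n - 1, 1)
        if frac < 1 / 3:
            out.append(labels[0])
        elif frac < 2 / 3:
            out.append(labels[1])
        else:
            out.append(labels[2])
    return out


def build_toy_locus(
    n_v: int,
    n_d: int,
    n_j: int,
    seed: int,
    v_len: int = 300,
    d_len: int = 12,
    j_len: int = 48,
    j_anchor_offset: int = 12,
    v_anchor_from_end: int = 12,
    v_spacing: int = 80,
    j_spacing: int = 520,
    pad: int = 600,
    duplicate_v_pair: bool = False,
    name: str | None = None,
) -> Locus:
    """Build a deterministic toy locus for simulation and testing.

    TRB-like when ``n_d >= 1``: the J segments are split into two clusters
    ("Jb1", "Jb2") when ``n_d == 2``, with D1 placed upstream of cluster 1 and
    D2 between the clusters, so deletional joining lets D1 reach both clusters
    but D2 only cluster 2.  TRA-like when ``n_d == 0``: V segments get
    positional classes proximal/central/distal (distal = 5'-most of the V
    array) and J segments proximal/middle/distal (proximal = 5'-most of the J
    array, nearest the V array).

    Every V segment ends with a TGT (Cys) anchor codon ``v_anchor_from_end``
    nucleotides upstream of its RSS; every J segment contains a TTTGGx
    (Phe-Gly) anchor at ``j_anchor_offset``.  Geometry keeps blunt V(D)J joins
    in frame: ``v_len``, ``d_len`` and both anchor offsets are multiples of 3.

    ``duplicate_v_pair=True`` makes the last two V segments sequence-identical
    (a Trav3-3 / Trav3d-3 style indistinguishable pair).
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("toy locus needs at least one V and one J segment")
    for val, what in ((v_len, "v_len"), (d_len, "d_len"),
                      (j_anchor_offset, "j_anchor_offset"),
                      (v_anchor_from_end, "v_anchor_from_end")):
        if val % 3 != 0:
            raise ValueError(f"{what} must be a multiple of 3, got {val}")
    rng = np.random.default_rng(seed)
    locus_name = name or ("TRB" if n_d >= 1 else "TRA")

    v_classes = _positional_classes(n_v, ("distal", "central", "proximal"))
    j_classes = _positional_classes(n_j, ("proximal", "middle", "distal"))

    def make_v(i: int) -> tuple[str, GermlineSegment]:
        a_v = v_len - v_anchor_from_end
        body = _random_bases(rng, a_v)
        tail = "TGT" + _safe_codons(rng, (v_anchor_from_end - 3) // 3)
        seq = body + tail
        return seq, GermlineSegment(
            id=f"{locus_name}V{i + 1}",
            segment_type="V",
            locus=locus_name,
            sequence=seq,
            rss_pos=v_len,
            anchor_codon_offset=a_v,
            positional_class=v_classes[i],
        )

    def make_j(i: int, cluster: Optional[str]) -> tuple[str, GermlineSegment]:
        head = _random_bases(rng, j_anchor_offset)
        n_tail_codons = (j_len - j_anchor_offset - 6) // 3
        seq = head + "TTT" + "GGA" + _safe_codons(rng, n_tail_codons)
        seq = seq + _random_bases(rng, j_len - len(seq))
        if cluster is None:
            jid = f"{locus_name}J{i + 1}"
        else:
            half = n_j // 2 if n_d == 2 else n_j
            within = i + 1 if i < half else i - half + 1
            jid = f"{locus_name}J{cluster[-1]}-{within}"
        return seq, GermlineSegment(
            id=jid,
            segment_type="J",
            locus=locus_name,
            sequence=seq,
            rss_pos=0,
            anchor_codon_offset=j_anchor_offset,
            cluster=cluster,
            positional_class=j_classes[i],
        )

    def make_d(i: int) -> tuple[str, GermlineSegment]:
        seq = _random_bases(rng, d_len)
        return seq, GermlineSegment(
            id=f"{locus_name}D{i + 1}",
            segment_type="D",
            locus=locus_name,
            sequence=seq,
            rss_pos=0,  # D RSS flanks both sides; 5' used as the reference point
        )

    # draft segments, then place on the contig in order: V array, (D1), J
    # cluster 1, (D2), J cluster 2
    drafts: list[GermlineSegment] = []
    for i in range(n_v):
        _, seg = make_v(i)
        drafts.append(seg)
    if duplicate_v_pair and n_v >= 2:
        src = drafts[-2]
        drafts[-1] = dataclasses.replace(drafts[-1], sequence=src.sequence,
                                         anchor_codon_offset=src.anchor_codon_offset)

    d_drafts = [make_d(i)[1] for i in range(n_d)]
    if n_d == 2:
        half = n_j // 2
        clusters = ["Jb1"] * half + ["Jb2"] * (n_j - half)
    elif n_d >= 1:
        clusters = ["Jb1"] * n_j
    else:
        clusters = [None] * n_j
    j_drafts = [make_j(i, clusters[i])[1] for i in range(n_j)]

    ordered: list[GermlineSegment] = list(drafts)
    if n_d == 2:
        half = n_j // 2
        ordered.append(d_drafts[0])
        ordered.extend(j_drafts[:half])
        ordered.append(d_drafts[1])
        ordered.extend(j_drafts[half:])
    else:
        ordered.extend(d_drafts)
        ordered.extend(j_drafts)

    contig_parts = [_random_bases(rng, pad)]
    pos = pad
    placed = []
    for seg in ordered:
        spacing = j_spacing if seg.segment_type in ("D", "J") else v_spacing
        spacer = _random_bases(rng, spacing)
        contig_parts.append(spacer)
        pos += spacing
        start = pos
        contig_parts.append(seg.sequence)
        pos += len(seg.sequence)
        placed.append(
            dataclasses.replace(seg, contig_start=start, contig_end=pos)
        )
    contig_parts.append(_random_bases(rng, pad))
    contig = "".join(contig_parts)

    return Locus(name=locus_name, segments=placed, contig=contig)
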