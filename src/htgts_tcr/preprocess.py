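"""Bait demultiplexing, primer trimming and mate merging.

Read 1 of every pair begins with a bait-specific nested primer, so bait
assignment is a Hamming comparison of the read prefix against the nested
primer table (default tolerance 2 substitutions; ties are flagged ambiguous
and dropped).  The matched primer prefix is trimmed; mates are merged when
they overlap (fragments shorter than two read lengths), otherwise read 1
alone — the bait side, which carries the junction by design — is analysed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .simulate import BaitPrimer, ReadPair, revcomp

__all__ = [
    "ProcessedRead",
    "PrimerTableError",
    "validate_primer_table",
    "assign_bait",
    "merge_pairs",
    "process_pairs",
    "read_fastq_pairs",
]


class PrimerTableError(ValueError):
    """Primer table unusable for demultiplexing (indistinguishable primers)."""


@dataclass
class ProcessedRead:
    """A demultiplexed, primer-trimmed, (possibly) merged read."""

    read_id: str
    bait_id: Optional[str]
    sequence: str = ""
    quality: str = ""
    merged: bool = False
    bait_ambiguous: bool = False
    discarded_reason: Optional[str] = None

    @property
    def discarded(self) -> bool:
        return self.discarded_reason is not None


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def validate_primer_table(baits: Sequence[BaitPrimer], max_mismatch: int = 2) -> None:
    """Require nested primers mutually distinguishable at the mismatch budget.

    Two primers whose common prefix differs by <= 2*max_mismatch substitutions
    could both match a read within budget, so such a table is rejected.
    """
    if not baits:
        raise PrimerTableError("primer table is empty")
    for a, b in itertools.combinations(baits, 2):
        n = min(len(a.nested_seq), len(b.nested_seq))
        if _hamming(a.nested_seq[:n], b.nested_seq[:n]) <= 2 * max_mismatch:
            raise PrimerTableError(
                f"nested primers {a.primer_id} and {b.primer_id} are within "
                f"{2 * max_mismatch} mismatches and cannot be demultiplexed"
            )


def assign_bait(read1: str, baits: Sequence[BaitPrimer],
                max_mismatch: int = 2) -> tuple[Optional[str], bool]:
    """Match the 5' end of read 1 against the nested primers.

    Returns ``(bait_id, ambiguous)``: the unique best primer within
    ``max_mismatch`` substitutions, or ``(None, True)`` on a tie and
    ``(None, False)`` when nothing matches.
    """
    best: list[BaitPrimer] = []
    best_d = max_mismatch + 1
    for b in baits:
        p = b.nested_seq
        if len(read1) < len(p):
            continue
        d = _hamming(read1[: len(p)], p)
        if d < best_d:
            best, best_d = [b], d
        elif d == best_d and d <= max_mismatch:
            best.append(b)
    if best_d > max_mismatch or not best:
        return None, False
    if len(best) > 1:
        return None, True
    return best[0].primer_id, False


def merge_pairs(r1: str, q1: str, r2: str, q2: str, min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> tuple[str, str, bool]:
    """Merge overlapping mates into a consensus.

    Read 2 is reverse-complemented and the best suffix(read1)/prefix(read2)
    overlap is taken; at conflicting positions the higher-quality base wins.
    Returns ``(sequence, quality, merged)``; unmerged pairs return read 1.
    """
    r2c = revcomp(r2)
    q2c = q2[::-1]
    best_ov, best_mm = 0, 0
    max_ov = min(len(r1), len(r2c))
    for ov in range(max_ov, min_overlap - 1, -1):
        a = r1[-ov:]
        b = r2c[:ov]
        mm = _hamming(a, b)
        if mm <= max_mismatch_frac * ov:
            best_ov, best_mm = ov, mm
            break
    if best_ov == 0:
        return r1, q1, False
    ov = best_ov
    head = r1[:-ov]
    tail = r2c[ov:]
    mid = []
    midq = []
    for i in range(ov):
        b1, b2 = r1[len(r1) - ov + i], r2c[i]
        s1, s2 = q1[len(r1) - ov + i], q2c[i]
        if b1 == b2 or s1 >= s2:
            mid.append(b1)
            midq.append(max(s1, s2) if b1 == b2 else s1)
        else:
            mid.append(b2)
            midq.append(s2)
    seq = head + "".join(mid) + tail
    qual = q1[:-ov] + "".join(midq) + q2c[ov:]
    return seq, qual, True


def process_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]],
    baits: Sequence[BaitPrimer],
    max_mismatch: int = 2,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[list[ProcessedRead], dict[str, int]]:
    """Demultiplex, trim and merge a stream of (id, r1, q1, r2, q2) tuples.

    Returns processed reads plus category counts; assigned + no_bait +
    ambiguous always partitions the input exactly.
    """
    validate_primer_table(baits, max_mismatch)
    by_id = {b.primer_id: b for b in baits}
    out: list[ProcessedRead] = []
    counts = {"input": 0, "assigned": 0, "no_bait": 0, "bait_ambiguous": 0,
              "merged": 0}
    for rid, r1, q1, r2, q2 in pairs:
        counts["input"] += 1
        bait_id, ambiguous = assign_bait(r1, baits, max_mismatch)
        if bait_id is None:
            reason = "bait_ambiguous" if ambiguous else "no_bait"
            counts[reason] += 1
            out.append(ProcessedRead(read_id=rid, bait_id=None,
                                     bait_ambiguous=ambiguous,
                                     discarded_reason=reason))
            continue
        counts["assigned"] += 1
        plen = len(by_id[bait_id].nested_seq)
        r1t, q1t = r1[plen:], q1[plen:]
        seq, qual, merged = merge_pairs(r1t, q1t, r2, q2, min_overlap,
                                        max_mismatch_frac)
        if merged:
            counts["merged"] += 1
        out.append(ProcessedRead(read_id=rid, bait_id=bait_id, sequence=seq,
                                 quality=qual, merged=merged))
    return out, counts


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Yield (id, r1, q1, r2, q2) from a pair of FASTQ files."""
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    for rec1, rec2 in zip(it1, it2):
        if rec1.id != rec2.id:
            raise ValueError(f"mate id mismatch: {rec1.id} vs {rec2.id}")
        q1 = "".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"])
        yield rec1.id, str(rec1.seq), q1, str(rec2.seq), q2
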