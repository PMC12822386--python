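"""Junction calling: bait/prey identification and rearrangement classing.

Each processed read is put into coding orientation, anchored on its bait
segment, and the remaining (prey) portion is aligned against the germline
references: V segments, D segments extended with their upstream germline
flank, and the germline flank adjoining the bait segment.  The best-scoring
interpretation classifies the read as VDJ, DJ (D and J only), germline
(read runs past the bait segment's RSS into unrearranged flank) or
unclassified.  Junction breakpoints are mapped to contig coordinates and
compared against each assigned segment's RSS +/- w window (default 40 bp) to
set per-segment on-target flags — only on-target assignments enter usage
statistics downstream.

Duplicate junctions are deliberately retained: :func:`retain_duplicates` only
tags multiplicity, mirroring bait-capture quantification where identical
junctions are genuine repeated captures of the same rearrangement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .align import Alignment, ScoringScheme, DEFAULT_SCORING, SegmentIndex, local_align
from .germline import GermlineSegment, Locus, on_target_window
from .preprocess import ProcessedRead
from .simulate import BaitPrimer, revcomp

__all__ = [
    "CallerConfig",
    "JunctionCall",
    "JunctionCaller",
    "assign_d_segment",
    "retain_duplicates",
    "dedup_report",
    "calls_to_table",
    "write_junction_table",
]

EVENT_CLASSES = ("VDJ", "DJ", "germline", "unclassified")


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for junction calling."""

    w: int = 40                    # on-target window half-width (RSS +/- w)
    k: int = 11                    # seed size for V candidate selection
    min_bait_score: int = 15       # minimum bait-segment alignment score
    min_prey_score: int = 15       # minimum prey alignment score
    strong_prey_score: int = 30    # V hit accepted without trying alternatives
    germline_min_len: int = 20     # germline flank match required past the RSS
    germline_end_slop: int = 3     # contiguity tolerance at the RSS boundary
    min_d_len: int = 5             # shortest exact D match assignable
    flank_len: int = 150           # germline flank length in extended refs
    scoring: ScoringScheme = DEFAULT_SCORING


@dataclass
class JunctionCall:
    """One read's junction interpretation."""

    read_id: str
    bait_id: str
    event_class: str = "unclassified"
    v_call: list[str] = field(default_factory=list)
    d_call: list[str] = field(default_factory=list)
    j_call: list[str] = field(default_factory=list)
    # breakpoints on the coding-oriented read (half-open junction interval)
    prey_read_end: Optional[int] = None
    bait_read_start: Optional[int] = None
    junction_seq: str = ""
    # genomic breakpoints per assigned segment id
    breakpoints: dict = field(default_factory=dict)
    on_target: dict = field(default_factory=dict)
    multiplicity: int = 1
    reason: Optional[str] = None
    sequence: str = ""            # coding-oriented read sequence
    v_alignment: Optional[Alignment] = None
    j_alignment: Optional[Alignment] = None

    @property
    def all_on_target(self) -> bool:
        return bool(self.on_target) and all(self.on_target.values())

    @property
    def duplicate_key(self) -> str:
        bp = ",".join(f"{k}:{v}" for k, v in sorted(self.breakpoints.items()))
        return "|".join([
            self.bait_id, self.event_class,
            ",".join(self.v_call), ",".join(self.d_call), ",".join(self.j_call),
            bp, self.junction_seq,
        ])


def _longest_exact_match(junction: str, d_seq: str) -> int:
    """Length of the longest contiguous exact substring shared with a D."""
    best = 0
    n = len(junction)
    for i in range(n):
        for j in range(i + best + 1, n + 1):
            if junction[i:j] in d_seq:
                best = j - i
            else:
                break
    return best


def assign_d_segment(junction_seq: str, d_segments: Sequence[GermlineSegment],
                     min_d_len: int = 5) -> list[str]:
    """D segments with the longest exact junction match of >= min_d_len.

    Returns an empty list when no D reaches ``min_d_len`` (pure-N junction);
    equally long matches to several D segments form an ambiguous set.
    """
    if not junction_seq:
        return []
    scores = {d.id: _longest_exact_match(junction_seq, d.sequence)
              for d in d_segments}
    if not scores:
        return []
    best = max(scores.values())
    if best < min_d_len:
        return []
    return sorted(did for did, s in scores.items() if s == best)


def _top_group(alignments: list[Alignment]) -> list[Alignment]:
    """All alignments tied with the best (score, span) — the ambiguous set."""
    if not alignments:
        return []
    best = alignments[0]
    return [a for a in alignments
            if a.score == best.score and a.read_span == best.read_span]


class JunctionCaller:
    """Reusable junction caller: builds alignment indexes over a locus once."""

    def __init__(self, locus: Locus, baits: Sequence[BaitPrimer],
                 config: CallerConfig | None = None):
        self.locus = locus
        self.config = config or CallerConfig()
        self.baits = {b.primer_id: b for b in baits}
        sc = self.config.scoring
        self.v_index = SegmentIndex(
            {s.id: s.sequence for s in locus.v_segments},
            k=self.config.k, scoring=sc,
        )
        self.j_index = SegmentIndex(
            {s.id: s.sequence for s in locus.j_segments},
            k=self.config.k, scoring=sc,
        )
        # D segments extended with their upstream germline flank: in a D-to-J
        # join the sequence 5' of the D remains germline, which is what
        # identifies a DJ-only allele on the bait side
        self.d_ext: dict[str, tuple[str, int]] = {}
        if locus.contig is not None:
            for d in locus.d_segments:
                flank = locus.upstream_flank(d.id, self.config.flank_len)
                self.d_ext[d.id] = (flank + d.sequence, len(flank))
        # germline flank adjoining each bait target, on the junction side
        self.germline_ref: dict[str, str] = {}
        if locus.contig is not None:
            for b in baits:
                t = locus[b.target_segment]
                if b.side == "J":
                    self.germline_ref[b.primer_id] = locus.upstream_flank(
                        t.id, self.config.flank_len)
                else:
                    self.germline_ref[b.primer_id] = locus.downstream_flank(
                        t.id, self.config.flank_len)

    # -- helpers ------------------------------------------------------------

    def _align_one(self, query: str, ref: str) -> Optional[Alignment]:
        score, (qs, qe), (ts, te), ident = local_align(query, ref,
                                                       self.config.scoring)
        if score <= 0:
            return None
        return Alignment(segment_id="", read_start=qs, read_end=qe,
                         segment_start=ts, segment_end=te, score=score,
                         identity=ident)

    def _on_target(self, seg: GermlineSegment, genomic_bp: int) -> bool:
        lo, hi = on_target_window(seg, self.config.w)
        return lo <= genomic_bp <= hi

    # -- main entry ----------------------------------------------------------

    def call_junction(self, read: ProcessedRead) -> JunctionCall:
        """Classify one processed read (bait must be assigned)."""
        if read.bait_id is None:
            raise ValueError(f"read {read.read_id} has no assigned bait")
        bait = self.baits[read.bait_id]
        cfg = self.config
        target = self.locus[bait.target_segment]
        seq = revcomp(read.sequence) if bait.side == "J" else read.sequence

        call = JunctionCall(read_id=read.read_id, bait_id=read.bait_id,
                            sequence=seq)
        if not seq:
            call.reason = "empty_sequence"
            return call

        # 1. anchor the bait segment
        bait_aln = self._align_one(seq, target.sequence)
        if bait_aln is None or bait_aln.score < cfg.min_bait_score:
            call.reason = "bait_segment_not_found"
            return call

        if bait.side == "J":
            prey_region = seq[: bait_aln.read_start]
            prey_offset = 0
        else:
            prey_region = seq[bait_aln.read_end :]
            prey_offset = bait_aln.read_end

        if len(prey_region) < cfg.k:
            call.reason = "no_prey_sequence"
            return call

        # 2. best prey interpretation
        prey_kind, prey_id, prey_aln = self._best_prey(prey_region, bait)

        if prey_kind is None:
            call.reason = "no_prey_alignment"
            return call

        if prey_kind == "germline":
            call.event_class = "germline"
            if bait.side == "J":
                call.j_call = [target.id]
            else:
                call.v_call = [target.id]
            return call

        return self._finish_rearranged(call, bait, target, bait_aln,
                                       prey_kind, prey_id, prey_aln,
                                       prey_region, prey_offset)

    def _best_prey(self, prey_region: str, bait: BaitPrimer):
        """Rank V / extended-D / germline-flank interpretations of the prey."""
        cfg = self.config
        # J-side baits read back into V (or D) territory; V-side baits read
        # forward into J territory
        index = self.v_index if bait.side == "J" else self.j_index
        kind = "V" if bait.side == "J" else "J"
        candidates = index.candidates(prey_region)
        hits = index.align(prey_region, min_score=cfg.min_prey_score - 1,
                           restrict=candidates) if candidates else []
        group = _top_group(hits)
        if group and group[0].score >= cfg.strong_prey_score:
            return kind, [a.segment_id for a in group], group

        best = (kind, [a.segment_id for a in group], group,
                group[0].score) if group else (None, None, None, 0)

        if bait.side == "J":
            for did, (ref, _flank) in self.d_ext.items():
                aln = self._align_one(prey_region, ref)
                if aln and aln.score >= cfg.min_prey_score and aln.score > best[3]:
                    best = ("D", [did], [aln], aln.score)

        germ = self.germline_ref.get(bait.primer_id)
        if germ:
            aln = self._align_one(prey_region, germ)
            if aln is not None and self._is_germline(aln, prey_region, germ, bait):
                if aln.score > best[3]:
                    best = ("germline", [bait.target_segment], [aln], aln.score)

        return best[0], best[1], best[2]

    def _is_germline(self, aln: Alignment, prey_region: str, germ: str,
                     bait: BaitPrimer) -> bool:
        """Germline reads continue past the bait RSS into contiguous flank."""
        cfg = self.config
        if aln.read_span < cfg.germline_min_len:
            return False
        if bait.side == "J":
            # flank abuts the J RSS at its 3' end; the prey region's own 3'
            # end must reach both boundaries
            return (len(germ) - aln.segment_end <= cfg.germline_end_slop
                    and len(prey_region) - aln.read_end <= cfg.germline_end_slop)
        return (aln.segment_start <= cfg.germline_end_slop
                and aln.read_start <= cfg.germline_end_slop)

    def _finish_rearranged(self, call, bait, target, bait_aln, prey_kind,
                           prey_ids, prey_alns, prey_region, prey_offset):
        cfg = self.config
        aln = prey_alns[0]

        if bait.side == "J":
            call.j_call = [target.id]
            call.j_alignment = bait_aln
            j_bp = target.contig_start + bait_aln.segment_start
            call.breakpoints[target.id] = j_bp
            call.on_target[target.id] = self._on_target(target, j_bp)
            prey_read_end = prey_offset + aln.read_end
            call.prey_read_end = prey_read_end
            call.bait_read_start = bait_aln.read_start
            call.junction_seq = call.sequence[prey_read_end : bait_aln.read_start]
        else:
            call.v_call = [target.id]
            call.v_alignment = bait_aln
            v_bp = target.contig_start + bait_aln.segment_end
            call.breakpoints[target.id] = v_bp
            call.on_target[target.id] = self._on_target(target, v_bp)
            prey_read_start = prey_offset + aln.read_start
            call.prey_read_end = prey_read_start
            call.bait_read_start = bait_aln.read_end
            call.junction_seq = call.sequence[bait_aln.read_end : prey_read_start]

        if prey_kind == "V":
            call.event_class = "VDJ"
            call.v_call = sorted(prey_ids)
            call.v_alignment = aln
            for a in prey_alns:
                seg = self.locus[a.segment_id]
                bp = seg.contig_start + a.segment_end
                call.breakpoints[a.segment_id] = bp
                call.on_target[a.segment_id] = self._on_target(seg, bp)
            call.d_call = assign_d_segment(call.junction_seq,
                                           self._d_candidates(call.j_call),
                                           cfg.min_d_len)
        elif prey_kind == "D":
            call.event_class = "DJ"
            call.d_call = list(prey_ids)
            d = self.locus[prey_ids[0]]
            _, flank_len = self.d_ext[prey_ids[0]]
            bp = d.contig_start - flank_len + aln.segment_end
            call.breakpoints[d.id] = bp
            call.on_target[d.id] = self._on_target(d, bp)
        elif prey_kind == "J":
            call.event_class = "VDJ"
            call.j_call = sorted(prey_ids)
            call.j_alignment = aln
            for a in prey_alns:
                seg = self.locus[a.segment_id]
                bp = seg.contig_start + a.segment_start
                call.breakpoints[a.segment_id] = bp
                call.on_target[a.segment_id] = self._on_target(seg, bp)
            call.d_call = assign_d_segment(call.junction_seq,
                                           self._d_candidates(call.j_call),
                                           cfg.min_d_len)
        return call

    def _d_candidates(self, j_call: list[str]) -> list[GermlineSegment]:
        """Ds legal for the called J under deletional joining (D upstream of J).

        A D segment can only join a J downstream of it, so e.g. the D between
        two J clusters is never assignable to a first-cluster J.
        """
        if not j_call:
            return self.locus.d_segments
        j_start = min(self.locus[j].contig_start for j in j_call)
        return [d for d in self.locus.d_segments if d.contig_end < j_start]

    def call_all(self, reads: Sequence[ProcessedRead]) -> list[JunctionCall]:
        return [self.call_junction(r) for r in reads
                if r.bait_id is not None and not r.discarded]


def retain_duplicates(calls: Sequence[JunctionCall]) -> list[JunctionCall]:
    """Tag duplicate multiplicity without removing anything.

    Identity transform on membership: every call is returned (duplicate
    junctions are genuine repeated captures under linear amplification), with
    ``multiplicity`` set to the count of its duplicate key.
    """
    counts = Counter(c.duplicate_key for c in calls)
    for c in calls:
        c.multiplicity = counts[c.duplicate_key]
    return list(calls)


def dedup_report(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    """Diagnostic-only table of distinct junction keys and their counts."""
    counts = Counter(c.duplicate_key for c in calls)
    return pd.DataFrame(
        [{"duplicate_key": k, "count": v} for k, v in sorted(counts.items())]
    )


def calls_to_table(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "read_id": c.read_id,
            "bait_id": c.bait_id,
            "event_class": c.event_class,
            "v_call": ",".join(c.v_call),
            "d_call": ",".join(c.d_call),
            "j_call": ",".join(c.j_call),
            "breakpoints": ";".join(f"{k}:{v}" for k, v in sorted(c.breakpoints.items())),
            "on_target": ";".join(f"{k}:{int(v)}" for k, v in sorted(c.on_target.items())),
            "all_on_target": c.all_on_target,
            "junction": c.junction_seq,
            "multiplicity": c.multiplicity,
            "duplicate_key": c.duplicate_key,
            "reason": c.reason or "",
        })
    return pd.DataFrame(rows)


def write_junction_table(calls: Sequence[JunctionCall], path: str | Path) -> None:
    calls_to_table(calls).to_csv(path, sep="\t", index=False)
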