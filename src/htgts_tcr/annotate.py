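"""Productivity determination and CDR3 extraction for VDJ junction calls.

A rearrangement is *productive* when the V and J conserved anchor codons are
both found, the V-anchor-to-J-anchor distance is a multiple of 3 (in frame),
and the anchor-to-anchor reading frame contains no stop codon — the
convention of IgBLAST-style repertoire pipelines.  The CDR3 (IMGT "junction")
spans the V conserved cysteine codon through the J conserved phenylalanine
codon, both anchors included, translated in the V frame.

Records are emitted in AIRR Rearrangement TSV form (core columns
``sequence_id, v_call, d_call, j_call, junction, junction_aa, productive,
locus`` plus bait-capture extensions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .caller import JunctionCall
from .germline import Locus
from .simulate import RecombinationEvent

__all__ = [
    "AnnotatedRearrangement",
    "determine_productivity",
    "extract_cdr3",
    "annotate_call",
    "annotate_calls",
    "annotate_event",
    "write_airr",
    "read_airr",
    "AIRR_COLUMNS",
]

AIRR_COLUMNS = [
    "sequence_id", "v_call", "d_call", "j_call", "junction", "junction_aa",
    "productive", "locus",
    # bait-capture extensions
    "bait_id", "event_class", "on_target", "duplicate_key",
    "frame", "stop_codon", "cdr3_length_aa", "multiplicity",
]


@dataclass
class AnnotatedRearrangement:
    """AIRR-style record for one junction call."""

    sequence_id: str
    v_call: list[str]
    d_call: list[str]
    j_call: list[str]
    locus: str
    bait_id: str = ""
    event_class: str = "VDJ"
    on_target: bool = False
    duplicate_key: str = ""
    multiplicity: int = 1
    frame: Optional[int] = None
    stop_codon: Optional[bool] = None
    productive: bool = False
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    reason: Optional[str] = None

    @property
    def cdr3_length_aa(self) -> Optional[int]:
        return None if self.cdr3_aa is None else len(self.cdr3_aa)


def _anchor_positions(call: JunctionCall, locus: Locus) -> Optional[tuple[int, int]]:
    """Read positions of the V and J anchor codons, via the alignments.

    Anchors are projected through the (effectively gapless) alignment blocks;
    None when either anchor falls outside its aligned interval.
    """
    if not call.v_call or not call.j_call or call.v_alignment is None \
            or call.j_alignment is None:
        return None
    v = locus[call.v_call[0]]
    j = locus[call.j_call[0]]
    va, ja = call.v_alignment, call.j_alignment
    if v.anchor_codon_offset is None or j.anchor_codon_offset is None:
        return None
    # ambiguous sets whose members disagree in anchor offset cannot be
    # annotated consistently
    for vid in call.v_call[1:]:
        if locus[vid].anchor_codon_offset != v.anchor_codon_offset:
            return None
    for jid in call.j_call[1:]:
        if locus[jid].anchor_codon_offset != j.anchor_codon_offset:
            return None
    if not (va.segment_start <= v.anchor_codon_offset
            and v.anchor_codon_offset + 3 <= va.segment_end):
        return None
    if not (ja.segment_start <= j.anchor_codon_offset
            and j.anchor_codon_offset + 3 <= ja.segment_end):
        return None
    v_pos = va.read_start + (v.anchor_codon_offset - va.segment_start)
    j_pos = ja.read_start + (j.anchor_codon_offset - ja.segment_start)
    if j_pos + 3 > len(call.sequence) or v_pos < 0 or j_pos <= v_pos:
        return None
    # the conserved residues must actually be present in the read: a
    # sequencing error in an anchor codon voids the anchor (and with it
    # productivity), as in IgBLAST-style annotation
    if str(Seq(call.sequence[v_pos : v_pos + 3]).translate()) != "C":
        return None
    if str(Seq(call.sequence[j_pos : j_pos + 3]).translate()) != "F":
        return None
    return v_pos, j_pos


def determine_productivity(call: JunctionCall, locus: Locus
                           ) -> tuple[Optional[int], Optional[bool], bool]:
    """(frame, stop_codon, productive) for a VDJ junction call.

    ``frame`` is the anchor-to-anchor distance mod 3; ``stop_codon`` scans the
    anchor-to-anchor reading frame and is None when the frame is shifted
    (translation undefined).  Missing anchors give (None, None, False).
    """
    anchors = _anchor_positions(call, locus)
    if anchors is None:
        return None, None, False
    v_pos, j_pos = anchors
    frame = (j_pos - v_pos) % 3
    if frame != 0:
        return frame, None, False
    cdr3 = call.sequence[v_pos : j_pos + 3]
    aa = str(Seq(cdr3).translate())
    stop = "*" in aa
    return 0, stop, not stop


def extract_cdr3(call: JunctionCall, locus: Locus,
                 force: bool = False) -> tuple[Optional[str], Optional[str]]:
    """CDR3 nucleotide and amino-acid sequence (anchors included).

    Out-of-frame or anchorless records return ``(None, None)``; ``force=True``
    returns the nucleotide span without translation for shifted frames.
    """
    anchors = _anchor_positions(call, locus)
    if anchors is None:
        return None, None
    v_pos, j_pos = anchors
    cdr3_nt = call.sequence[v_pos : j_pos + 3]
    if len(cdr3_nt) % 3 != 0:
        return (cdr3_nt, None) if force else (None, None)
    return cdr3_nt, str(Seq(cdr3_nt).translate())


def annotate_call(call: JunctionCall, locus: Locus) -> AnnotatedRearrangement:
    rec = AnnotatedRearrangement(
        sequence_id=call.read_id,
        v_call=list(call.v_call),
        d_call=list(call.d_call),
        j_call=list(call.j_call),
        locus=locus.name,
        bait_id=call.bait_id,
        event_class=call.event_class,
        on_target=call.all_on_target,
        duplicate_key=call.duplicate_key,
        multiplicity=call.multiplicity,
    )
    if call.event_class != "VDJ":
        rec.reason = "not_vdj"
        return rec
    frame, stop, productive = determine_productivity(call, locus)
    rec.frame, rec.stop_codon, rec.productive = frame, stop, productive
    if frame is None:
        rec.reason = "anchor_not_found"
        return rec
    if productive:
        rec.cdr3_nt, rec.cdr3_aa = extract_cdr3(call, locus)
    return rec


def annotate_calls(calls: Sequence[JunctionCall], locus: Locus
                   ) -> list[AnnotatedRearrangement]:
    return [annotate_call(c, locus) for c in calls]


def annotate_event(event: RecombinationEvent, locus: Locus
                   ) -> tuple[Optional[str], Optional[str]]:
    """CDR3 of a simulated event, straight from its assembled coding join.

    Ground-truth counterpart of :func:`extract_cdr3`, useful for checking the
    read-based annotation and for profiling simulated repertoires without
    sequencing.
    """
    if event.event_class != "VDJ" or event.v_id is None:
        return None, None
    v = locus[event.v_id]
    j = locus[event.j_id]
    v_pos = v.anchor_codon_offset
    j_pos = len(event.coding_seq) - (len(j.sequence) - j.anchor_codon_offset)
    if v_pos is None or j_pos <= v_pos:
        return None, None
    cdr3_nt = event.coding_seq[v_pos : j_pos + 3]
    if len(cdr3_nt) % 3 != 0:
        return None, None
    return cdr3_nt, str(Seq(cdr3_nt).translate())


def _join(ids: list[str]) -> str:
    return ",".join(ids)


def records_to_table(records: Sequence[AnnotatedRearrangement]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "sequence_id": r.sequence_id,
            "v_call": _join(r.v_call),
            "d_call": _join(r.d_call),
            "j_call": _join(r.j_call),
            "junction": r.cdr3_nt or "",
            "junction_aa": r.cdr3_aa or "",
            "productive": r.productive,
            "locus": r.locus,
            "bait_id": r.bait_id,
            "event_class": r.event_class,
            "on_target": r.on_target,
            "duplicate_key": r.duplicate_key,
            "frame": "" if r.frame is None else r.frame,
            "stop_codon": "" if r.stop_codon is None else r.stop_codon,
            "cdr3_length_aa": "" if r.cdr3_length_aa is None else r.cdr3_length_aa,
            "multiplicity": r.multiplicity,
        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr(records: Sequence[AnnotatedRearrangement], path: str | Path) -> None:
    """Write records as an AIRR Rearrangement TSV (header always present)."""
    records_to_table(records).to_csv(path, sep="\t", index=False)


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("productive", "on_target"):
        df[col] = df[col] == "True"
    df["multiplicity"] = df["multiplicity"].astype(int)
    return df
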