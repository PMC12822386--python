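"""Ground-truth simulator for bait-capture V(D)J rearrangement libraries.

Two layers:

* **Rearrangement model** — V(D)J events on a toy locus with junctional
  diversification (geometric exonucleolytic deletions, Poisson-length random
  N insertions), a two-allele TCRβ model with feedback inhibition (a
  productive first allele suppresses V-to-DJ on the second) and β-selection
  (cells with no productive allele are discarded), and a stepwise Vα/Jα usage
  gradient over successive rearrangement rounds.

* **Library model** — sonication into fragments averaging 0.7 kb, linear
  amplification from a biotinylated bait primer annealing downstream of the
  target segment's coding end, nested-primer trimming, 300-700 bp size
  selection and paired-end 150 bp reads with substitution errors.  Every read
  pair is linked to its generating event in a truth table; PCR duplicates of
  a captured fragment share junction coordinates but carry independent
  sequencing errors.

Productivity is computed from the assembled coding join: ``frame_shift`` is
the V-anchor-to-J-anchor distance mod 3 (equivalently the net junction length
change mod 3 on toy loci built with in-frame blunt joins).  In ``"frame"``
mode an event is productive iff in frame; in ``"full"`` mode (default) it
must additionally be stop-free from the V cysteine anchor through the J
phenylalanine anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineSegment, Locus

__all__ = [
    "JunctionModelParams",
    "RecombinationEvent",
    "LibraryParams",
    "BaitPrimer",
    "ReadPair",
    "simulate_allele_rearrangement",
    "simulate_cell",
    "simulate_cells",
    "simulate_tcra_usage_gradient",
    "beta_selection_expectation",
    "make_bait_table",
    "write_bait_table",
    "load_bait_table",
    "fragment_and_capture",
    "write_fastq",
    "write_truth_table",
    "DEFAULT_TRA_SCHEDULE",
]

_BASES = np.array(list("ACGT"))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class JunctionModelParams:
    """Junctional diversification and productivity-model settings.

    Deletion means parameterise geometric distributions on {0, 1, 2, ...};
    ``n_ins_mean`` is the Poisson mean length of untemplated N insertions per
    junction.  Deletions are clipped so conserved anchors always survive
    (V keeps its Cys codon, J its Phe codon), keeping frame and CDR3 always
    defined; the clip's effect on the mod-3 frame distribution is negligible
    because the Poisson insertion term randomises frame almost uniformly.
    """

    del_v: float = 3.0
    del_d5: float = 3.0
    del_d3: float = 3.0
    del_j: float = 3.0
    n_ins_mean: float = 4.0
    error_rate: float = 0.001
    productivity: str = "full"  # "full" (in-frame + stop-free) or "frame"
    v_weights: Optional[dict[str, float]] = None
    j_weights: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        for name in ("del_v", "del_d5", "del_d3", "del_j", "n_ins_mean", "error_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.productivity not in ("full", "frame"):
            raise ValueError("productivity mode must be 'full' or 'frame'")


@dataclass
class RecombinationEvent:
    """Simulator ground truth for one rearranged (or germline) allele."""

    cell_id: int
    allele: int
    event_class: str  # VDJ | DJ | germline
    locus: str
    v_id: Optional[str] = None
    d_id: Optional[str] = None
    j_id: Optional[str] = None
    del_v: int = 0
    del_d5: int = 0
    del_d3: int = 0
    del_j: int = 0
    n1: str = ""
    n2: str = ""
    coding_seq: str = ""
    frame_shift: Optional[int] = None
    is_productive: bool = False
    round_index: Optional[int] = None

    @property
    def key(self) -> str:
        return (
            f"{self.event_class}:{self.v_id}:{self.d_id}:{self.j_id}:"
            f"{self.del_v}:{self.del_d5}:{self.del_d3}:{self.del_j}:{self.n1}:{self.n2}"
        )


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0, 1, ...} with the given mean."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _n_insert(rng: np.random.Generator, mean: float) -> str:
    if mean <= 0:
        return ""
    n = int(rng.poisson(mean))
    if n == 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _pick(rng: np.random.Generator, segments: Sequence[GermlineSegment],
          weights: Optional[dict[str, float]]) -> GermlineSegment:
    if not segments:
        raise ValueError("empty segment pool")
    if weights is None:
        return segments[int(rng.integers(0, len(segments)))]
    w = np.array([weights.get(s.id, 0.0) for s in segments], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("segment weights sum to zero over the available pool")
    return segments[int(rng.choice(len(segments), p=w / total))]


def _usable(segments: Sequence[GermlineSegment]) -> list[GermlineSegment]:
    # segments with nonfunctional RSSs cannot recombine; pseudogenes can
    return [s for s in segments if s.functionality != "nonfunctional_rss"]


def _legal_dj_pairs(locus: Locus) -> list[tuple[GermlineSegment, GermlineSegment]]:
    """Deletional joining: a D may only join J segments downstream of it."""
    pairs = []
    for d in _usable(locus.d_segments):
        for j in _usable(locus.j_segments):
            if j.contig_start > d.contig_end:
                pairs.append((d, j))
    return pairs


def _productivity(coding: str, v: GermlineSegment, j: GermlineSegment,
                  del_j: int, mode: str) -> tuple[int, bool]:
    """Frame shift (mod 3 between anchors) and productivity of a VDJ/VJ join."""
    v_anchor = v.anchor_codon_offset
    j_anchor = len(coding) - (len(j.sequence) - j.anchor_codon_offset)
    frame_shift = (j_anchor - v_anchor) % 3
    if frame_shift != 0:
        return frame_shift, False
    if mode == "frame":
        return 0, True
    cdr3 = coding[v_anchor : j_anchor + 3]
    for p in range(0, len(cdr3) - 2, 3):
        if cdr3[p : p + 3] in ("TAA", "TAG", "TGA"):
            return 0, False
    return 0, True


def simulate_allele_rearrangement(
    locus: Locus,
    params: JunctionModelParams,
    rng: np.random.Generator,
    event_class: str = "VDJ",
    cell_id: int = 0,
    allele: int = 0,
) -> RecombinationEvent:
    """Simulate one rearrangement on one allele.

    VDJ events on loci with D segments draw a legal (D, J) pair first (a D
    joins only J segments downstream of it, so on a two-cluster TRB-like
    locus D1 reaches both J clusters while D2 reaches only cluster 2), then a
    V; loci without D segments produce direct V-to-J joins.  Deletion lengths
    are geometric, clipped so anchors survive; insertions are random ACGT of
    Poisson length.
    """
    if event_class == "germline":
        return RecombinationEvent(cell_id=cell_id, allele=allele,
                                  event_class="germline", locus=locus.name)

    has_d = len(locus.d_segments) > 0
    if event_class == "DJ" and not has_d:
        raise ValueError("locus has no D segments; cannot simulate a DJ event")

    if has_d:
        pairs = _legal_dj_pairs(locus)
        if not pairs:
            raise ValueError(
                "no legal D-to-J joining on this locus "
                "(every D lies downstream of every J)"
            )
        jw = params.j_weights
        if jw is not None:
            w = np.array([jw.get(j.id, 0.0) for _, j in pairs], dtype=float)
            if w.sum() <= 0:
                raise ValueError("j_weights sum to zero over legal D-J pairs")
            d, j = pairs[int(rng.choice(len(pairs), p=w / w.sum()))]
        else:
            d, j = pairs[int(rng.integers(0, len(pairs)))]
    else:
        d = None
        j = _pick(rng, _usable(locus.j_segments), params.j_weights)

    del_j = min(_geometric0(rng, params.del_j), j.anchor_codon_offset)
    j_part = j.sequence[del_j:]

    if event_class == "DJ":
        del_d3 = min(_geometric0(rng, params.del_d3), len(d.sequence))
        n2 = _n_insert(rng, params.n_ins_mean)
        coding = d.sequence[: len(d.sequence) - del_d3] + n2 + j_part
        return RecombinationEvent(
            cell_id=cell_id, allele=allele, event_class="DJ", locus=locus.name,
            d_id=d.id, j_id=j.id, del_d3=del_d3, del_j=del_j, n2=n2,
            coding_seq=coding, frame_shift=None, is_productive=False,
        )

    v = _pick(rng, _usable(locus.v_segments), params.v_weights)
    max_del_v = len(v.sequence) - (v.anchor_codon_offset + 3)
    del_v = min(_geometric0(rng, params.del_v), max_del_v)
    v_part = v.sequence[: len(v.sequence) - del_v]
    n1 = _n_insert(rng, params.n_ins_mean)

    if d is not None:
        del_d5 = min(_geometric0(rng, params.del_d5), len(d.sequence))
        del_d3 = min(_geometric0(rng, params.del_d3), len(d.sequence) - del_d5)
        d_part = d.sequence[del_d5 : len(d.sequence) - del_d3]
        n2 = _n_insert(rng, params.n_ins_mean)
        coding = v_part + n1 + d_part + n2 + j_part
    else:
        del_d5 = del_d3 = 0
        n2 = ""
        coding = v_part + n1 + j_part

    frame_shift, productive = _productivity(coding, v, j, del_j, params.productivity)
    return RecombinationEvent(
        cell_id=cell_id, allele=allele, event_class="VDJ", locus=locus.name,
        v_id=v.id, d_id=d.id if d is not None else None, j_id=j.id,
        del_v=del_v, del_d5=del_d5, del_d3=del_d3, del_j=del_j,
        n1=n1, n2=n2, coding_seq=coding,
        frame_shift=frame_shift, is_productive=productive,
    )


def simulate_cell(
    locus: Locus,
    params: JunctionModelParams,
    rng: np.random.Generator,
    selection: str = "none",
    p_v_to_dj: float = 1.0,
    p_rearrange: float = 1.0,
    cell_id: int = 0,
    _max_attempts: int = 10_000,
) -> list[RecombinationEvent]:
    """Simulate the two alleles of one cell under the TCRβ ordering model.

    Both alleles first perform D-to-J joining (probability ``p_rearrange``;
    otherwise the allele stays in germline configuration).  Allele 0 then
    attempts V-to-DJ with probability ``p_v_to_dj``; if its VDJ join is
    productive, feedback inhibition leaves allele 1 DJ-only, otherwise allele
    1 attempts V-to-DJ in turn.  Under ``selection="beta_selection"`` cells
    with no productive allele are discarded and resampled, modelling the
    DN-to-DP β-selection checkpoint.
    """
    if selection not in ("none", "beta_selection"):
        raise ValueError("selection must be 'none' or 'beta_selection'")
    for _ in range(_max_attempts):
        events: list[RecombinationEvent] = []
        inhibited = False
        for allele in (0, 1):
            if rng.random() >= p_rearrange:
                events.append(simulate_allele_rearrangement(
                    locus, params, rng, "germline", cell_id, allele))
                continue
            ev = simulate_allele_rearrangement(locus, params, rng, "DJ",
                                               cell_id, allele)
            if not inhibited and rng.random() < p_v_to_dj:
                ev = simulate_allele_rearrangement(locus, params, rng, "VDJ",
                                                   cell_id, allele)
                if ev.is_productive:
                    inhibited = True
            events.append(ev)
        if selection == "none" or any(e.is_productive for e in events):
            return events
    raise RuntimeError("beta selection failed to produce a surviving cell")


def simulate_cells(
    locus: Locus,
    params: JunctionModelParams,
    n_cells: int,
    rng: np.random.Generator,
    selection: str = "none",
    p_v_to_dj: float = 1.0,
    p_rearrange: float = 1.0,
) -> list[RecombinationEvent]:
    """Simulate ``n_cells`` cells (surviving cells under beta selection)."""
    events: list[RecombinationEvent] = []
    for cid in range(n_cells):
        events.extend(
            simulate_cell(locus, params, rng, selection=selection,
                          p_v_to_dj=p_v_to_dj, p_rearrange=p_rearrange,
                          cell_id=cid)
        )
    return events


def beta_selection_expectation() -> dict[str, Fraction]:
    """Exact enumeration of the two-allele feedback-inhibition model.

    Each VDJ join is in frame with probability 1/3 (junction frame offsets
    uniform mod 3).  Enumerating the 3 x 3 equiprobable frame outcomes of the
    two alleles gives the survival probability of β-selection and the
    productive fraction among VDJ joins carried by surviving cells.
    """
    survive_mass = Fraction(0)
    productive_vdj = Fraction(0)
    total_vdj = Fraction(0)
    for f1 in range(3):
        for f2 in range(3):
            mass = Fraction(1, 9)
            if f1 == 0:
                vdj = [True]  # feedback inhibition: allele 2 stays DJ-only
            else:
                vdj = [False, f2 == 0]
            if any(vdj):
                survive_mass += mass
                productive_vdj += mass * sum(vdj)
                total_vdj += mass * len(vdj)
    return {
        "survival": survive_mass,                      # 5/9
        "productive_vdj_fraction": productive_vdj / total_vdj,  # 5/7
    }


# round -> (proximal, central/middle, distal) class weights; rounds past the
# table reuse the last row.  Successive rearrangement rounds shift usage
# monotonically from proximal V / 5'-proximal J toward distal segments.
DEFAULT_TRA_SCHEDULE: dict[str, list[tuple[float, float, float]]] = {
    "V": [(0.80, 0.15, 0.05), (0.55, 0.30, 0.15), (0.30, 0.40, 0.30),
          (0.15, 0.30, 0.55), (0.05, 0.15, 0.80)],
    "J": [(0.80, 0.15, 0.05), (0.55, 0.30, 0.15), (0.30, 0.40, 0.30),
          (0.15, 0.30, 0.55), (0.05, 0.15, 0.80)],
}

_V_CLASS_ORDER = ("proximal", "central", "distal")
_J_CLASS_ORDER = ("proximal", "middle", "distal")


def _class_weights(locus: Locus, kind: str, round_index: int,
                   schedule: dict) -> dict[str, float]:
    rows = schedule[kind]
    row = rows[min(round_index, len(rows)) - 1]
    order = _V_CLASS_ORDER if kind == "V" else _J_CLASS_ORDER
    class_w = dict(zip(order, row))
    segs = _usable(locus.of_type(kind))
    counts: dict[str, int] = {}
    for s in segs:
        counts[s.positional_class] = counts.get(s.positional_class, 0) + 1
    weights = {}
    for s in segs:
        cw = class_w.get(s.positional_class)
        if cw is None:
            raise ValueError(
                f"segment {s.id} has positional class {s.positional_class!r} "
                "not covered by the round schedule"
            )
        weights[s.id] = cw / counts[s.positional_class]
    return weights


def simulate_tcra_usage_gradient(
    locus: Locus,
    round_count: int,
    rng: np.random.Generator,
    params: JunctionModelParams | None = None,
    schedule: dict | None = None,
    cell_id: int = 0,
) -> RecombinationEvent:
    """One V-to-J join sampled at rearrangement round ``round_count``.

    Successive rounds shift the sampling weight from proximal Vα / 5'-proximal
    Jα toward distal segments following ``schedule`` (class-weight table,
    see :data:`DEFAULT_TRA_SCHEDULE`); segments are uniform within a class.
    The returned event records the round index.
    """
    if round_count < 1:
        raise ValueError("round_count must be >= 1")
    if locus.d_segments:
        raise ValueError("stepwise V-J gradient applies to D-less (TRA-like) loci")
    params = params or JunctionModelParams()
    schedule = schedule or DEFAULT_TRA_SCHEDULE
    import dataclasses as _dc

    staged = _dc.replace(
        params,
        v_weights=_class_weights(locus, "V", round_count, schedule),
        j_weights=_class_weights(locus, "J", round_count, schedule),
    )
    ev = simulate_allele_rearrangement(locus, staged, rng, "VDJ", cell_id=cell_id)
    ev.round_index = round_count
    return ev


# ---------------------------------------------------------------------------
# library construction: bait primers, fragmentation, capture, reads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BaitPrimer:
    """A bait: biotinylated outer primer plus nested inner primer.

    ``side`` 'J' means the primers anneal downstream (3') of the target
    segment and read 1 runs antisense back across the segment into the
    junction; side 'V' means they anneal on the sense strand inside the V
    near its 3' (RSS) end — the part retained after rearrangement — and read
    1 runs sense across the junction.  Distances are from the target
    segment's junction-proximal coding end to the primer's near edge
    (outward into the flank for J baits, inward into the V for V baits).
    """

    primer_id: str
    target_segment: str
    side: str
    bio_seq: str
    nested_seq: str
    bio_distance: int
    nested_distance: int

    def __post_init__(self) -> None:
        if self.side not in ("J", "V"):
            raise ValueError("bait side must be 'J' or 'V'")


@dataclass(frozen=True)
class LibraryParams:
    """Sonication, size selection and sequencing settings."""

    frag_mean: float = 700.0
    frag_sd: float = 150.0
    size_min: int = 300
    size_max: int = 700
    read_len: int = 150
    error_rate: float = 0.001
    mean_duplicates: float = 0.0  # Poisson mean extra PCR copies per fragment
    up_pad: int = 400
    down_pad: int = 400

    def __post_init__(self) -> None:
        if self.size_min >= self.size_max:
            raise ValueError("size-selection window must satisfy low < high")
        if self.read_len < 1:
            raise ValueError("read length must be positive")


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str
    bait_id: str
    event: Optional[RecombinationEvent] = None
    fragment_len: int = 0
    product_len: int = 0


def make_bait_table(
    locus: Locus,
    targets: Sequence[str],
    primer_len: int = 20,
    bio_distance: int = 80,
    nested_distance: int = 8,
    v_nested_distance: int = 40,
) -> list[BaitPrimer]:
    """Derive bait primer pairs from the toy contig for the given targets.

    J targets get antisense primers in the flank downstream of the J coding
    end (``bio_distance`` / ``nested_distance`` from it).  V targets get
    sense primers inside the V, ending ``bio_distance`` / ``v_nested_distance``
    upstream of the V 3' (RSS) end; the larger V nested distance leaves
    enough V sequence downstream of the trimmed primer for the junction
    caller to anchor the bait segment.
    """
    if locus.contig is None:
        raise ValueError("bait design requires a locus with a contig sequence")
    baits = []
    for tid in targets:
        seg = locus[tid]
        if seg.segment_type == "J":
            bio_site = locus.downstream_flank(tid, bio_distance + primer_len)[
                bio_distance : bio_distance + primer_len]
            nested_site = locus.downstream_flank(tid, nested_distance + primer_len)[
                nested_distance : nested_distance + primer_len]
            bio, nested = revcomp(bio_site), revcomp(nested_site)
            side, nd = "J", nested_distance
        elif seg.segment_type == "V":
            n = len(seg.sequence)
            if bio_distance + primer_len > n:
                raise ValueError(
                    f"bait target {tid}: V segment too short for a bio primer "
                    f"{bio_distance} nt from its coding end"
                )
            bio = seg.sequence[n - bio_distance - primer_len : n - bio_distance]
            nested = seg.sequence[
                n - v_nested_distance - primer_len : n - v_nested_distance]
            side, nd = "V", v_nested_distance
        else:
            raise ValueError(f"bait target {tid} must be a V or J segment")
        baits.append(BaitPrimer(
            primer_id=f"bait_{tid}", target_segment=tid, side=side,
            bio_seq=bio, nested_seq=nested,
            bio_distance=bio_distance, nested_distance=nd,
        ))
    return baits


_BAIT_COLUMNS = ["primer_id", "target_segment", "side", "bio_sequence",
                 "nested_sequence", "bio_distance", "nested_distance"]


def write_bait_table(baits: Sequence[BaitPrimer], path: str | Path) -> None:
    rows = [
        {
            "primer_id": b.primer_id, "target_segment": b.target_segment,
            "side": b.side, "bio_sequence": b.bio_seq,
            "nested_sequence": b.nested_seq, "bio_distance": b.bio_distance,
            "nested_distance": b.nested_distance,
        }
        for b in baits
    ]
    pd.DataFrame(rows, columns=_BAIT_COLUMNS).to_csv(path, sep="\t", index=False)


def load_bait_table(path: str | Path) -> list[BaitPrimer]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        BaitPrimer(
            primer_id=r.primer_id, target_segment=r.target_segment, side=r.side,
            bio_seq=r.bio_sequence, nested_seq=r.nested_sequence,
            bio_distance=int(r.bio_distance), nested_distance=int(r.nested_distance),
        )
        for r in df.itertuples(index=False)
    ]


def _molecule_for_event(event: RecombinationEvent, locus: Locus,
                        bait: BaitPrimer, lib: LibraryParams):
    """Bait-oriented molecule for (event, bait), or None if not capturable.

    Returns ``(molecule, bio_pos, nested_pos)`` with positions of the primer
    5' ends on the bait-oriented strand (read 1 direction).
    """
    target = locus[bait.target_segment]
    up, down = lib.up_pad, lib.down_pad

    if bait.side == "J":
        if event.event_class == "germline":
            j = target
            coding_mol = locus.contig[max(0, j.contig_start - up) : j.contig_end] \
                + locus.downstream_flank(j.id, down)
        else:
            if event.j_id != bait.target_segment:
                return None
            j = locus[event.j_id]
            if event.event_class == "DJ":
                d = locus[event.d_id]
                coding_mol = locus.upstream_flank(d.id, up) + event.coding_seq \
                    + locus.downstream_flank(j.id, down)
            else:
                v = locus[event.v_id]
                coding_mol = locus.upstream_flank(v.id, up) + event.coding_seq \
                    + locus.downstream_flank(j.id, down)
        # J coding end sits `down` bases from the molecule 3' end
        j_end_in_mol = len(coding_mol) - down
        mol = revcomp(coding_mol)
        plen = len(bait.nested_seq)
        nested_start_coding = j_end_in_mol + bait.nested_distance
        bio_start_coding = j_end_in_mol + bait.bio_distance
        nested_pos = len(mol) - (nested_start_coding + plen)
        bio_pos = len(mol) - (bio_start_coding + len(bait.bio_seq))
        return mol, bio_pos, nested_pos

    # V-side bait: sense orientation, primers inside the V near its 3' end
    if event.event_class == "germline":
        v = target
        del_v = 0
        coding_mol = locus.upstream_flank(v.id, up) + v.sequence \
            + locus.downstream_flank(v.id, down)
    elif event.event_class == "VDJ" and event.v_id == bait.target_segment:
        v = locus[event.v_id]
        j = locus[event.j_id]
        del_v = event.del_v
        coding_mol = locus.upstream_flank(v.id, up) + event.coding_seq \
            + locus.downstream_flank(j.id, down)
    else:
        return None
    # exonucleolytic deletion into a primer annealing site kills the capture
    if del_v > min(bait.nested_distance, bait.bio_distance):
        return None
    plen = len(bait.nested_seq)
    v_start_in_mol = len(locus.upstream_flank(bait.target_segment, up))
    v_len = len(v.sequence)
    nested_pos = v_start_in_mol + v_len - bait.nested_distance - plen
    bio_pos = v_start_in_mol + v_len - bait.bio_distance - len(bait.bio_seq)
    if nested_pos < 0 or bio_pos < 0:
        return None
    return coding_mol, bio_pos, nested_pos


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0 or not seq:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for p in pos:
        cur = arr[p].decode()
        alternatives = [b for b in "ACGT" if b != cur]
        arr[p] = alternatives[int(rng.integers(0, 3))].encode()
    return arr.tobytes().decode()


def fragment_and_capture(
    events: Sequence[RecombinationEvent],
    locus: Locus,
    baits: Sequence[BaitPrimer],
    lib: LibraryParams,
    rng: np.random.Generator,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Sonicate, bait-capture, size-select and sequence the simulated alleles.

    Each molecule compatible with a bait is sonicated (fragment length normal
    around ``frag_mean``, bio-primer position uniform within the fragment);
    the nested-PCR product from the nested primer to the junction-side break
    is retained iff its length falls in the size-selection window, yielding
    one read pair (read 1 starts at the nested primer) plus Poisson-many PCR
    duplicates sharing the same breakpoints.  Returns the read pairs and a
    truth table linking read ids to events.
    """
    if not baits:
        raise ValueError("bait primer table is empty")
    pairs: list[ReadPair] = []
    rows = []
    mol_idx = 0
    for event in events:
        for bait in baits:
            placed = _molecule_for_event(event, locus, bait, lib)
            if placed is None:
                continue
            mol, bio_pos, nested_pos = placed
            mol_idx += 1
            frag_len = max(50, int(round(rng.normal(lib.frag_mean, lib.frag_sd))))
            bio_len = len(bait.bio_seq)
            offset = int(rng.integers(0, max(frag_len - bio_len, 1)))
            frag_end = min(bio_pos - offset + frag_len, len(mol))
            product = mol[nested_pos:frag_end]
            if not (lib.size_min <= len(product) <= lib.size_max):
                continue
            n_copies = 1 + int(rng.poisson(lib.mean_duplicates))
            r1_clean = product[: lib.read_len]
            r2_clean = revcomp(product[-lib.read_len :])
            for copy in range(n_copies):
                rid = f"c{event.cell_id}a{event.allele}m{mol_idx}d{copy}"
                seq1 = _add_errors(r1_clean, lib.error_rate, rng)
                seq2 = _add_errors(r2_clean, lib.error_rate, rng)
                rp = ReadPair(
                    read_id=rid, seq1=seq1, qual1="I" * len(seq1),
                    seq2=seq2, qual2="I" * len(seq2),
                    bait_id=bait.primer_id, event=event,
                    fragment_len=frag_len, product_len=len(product),
                )
                pairs.append(rp)
                rows.append({
                    "read_id": rid, "bait_id": bait.primer_id,
                    "cell_id": event.cell_id, "allele": event.allele,
                    "event_class": event.event_class,
                    "v_id": event.v_id or "", "d_id": event.d_id or "",
                    "j_id": event.j_id or "",
                    "del_v": event.del_v, "del_d5": event.del_d5,
                    "del_d3": event.del_d3, "del_j": event.del_j,
                    "n1": event.n1, "n2": event.n2,
                    "frame_shift": "" if event.frame_shift is None else event.frame_shift,
                    "is_productive": event.is_productive,
                    "fragment_len": frag_len, "product_len": len(product),
                })
    if not pairs:
        warnings.warn("no capturable fragments: library is empty", stacklevel=2)
    truth = pd.DataFrame(rows)
    return pairs, truth


def write_fastq(pairs: Sequence[ReadPair], r1_path: str | Path,
                r2_path: str | Path) -> None:
    """Write the mates as a plain paired FASTQ (read ids identical in both)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)
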