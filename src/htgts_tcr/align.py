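"""Seeded local alignment of reads to germline segment references.

The aligner is a Gotoh (affine-gap) local alignment with the scoring scheme
declared for the whole pipeline: match +1, mismatch -1, gap open -2, gap
extend -1, where a gap of length L costs ``gap_open + L * gap_extend`` (the
opening penalty is charged on top of the first extension).  Candidate
segments are pre-selected by exact k-mer seeding (default k = 11); when no
seed is found the query is aligned exhaustively against every reference, so
short or divergent queries never silently lose their optimum.

The dynamic programming core is numba-compiled; a pure-Python reference
implementation with the same convention lives in the test suite as an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "ScoringScheme",
    "Alignment",
    "local_align",
    "SegmentIndex",
    "align_to_segments",
]


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1


DEFAULT_SCORING = ScoringScheme()

_ENC = np.full(256, 4, dtype=np.int8)
for i, base in enumerate("ACGT"):
    _ENC[ord(base)] = i
    _ENC[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0 C=1 G=2 T=3, other=4 never matches)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _gotoh_local(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap in query (skip t)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int32)  # gap in target (skip q)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            s = match if qi == t[j - 1] and qi != 4 else mismatch
            e = E[i, j - 1]
            h = H[i, j - 1]
            eo = h + gap_open + gap_extend
            ee = e + gap_extend
            E[i, j] = eo if eo > ee else ee
            f = F[i - 1, j]
            h = H[i - 1, j]
            fo = h + gap_open + gap_extend
            fe = f + gap_extend
            F[i, j] = fo if fo > fe else fe
            v = H[i - 1, j - 1] + s
            if E[i, j] > v:
                v = E[i, j]
            if F[i, j] > v:
                v = F[i, j]
            if v < 0:
                v = 0
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return best, bi, bj, H, E, F


@njit(cache=True)
def _traceback(q, t, H, E, F, bi, bj, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Walk back from (bi, bj) to the start of the optimal local alignment."""
    i, j = bi, bj
    matches = 0
    aligned = 0
    state = 0  # 0=H, 1=E (gap in query), 2=F (gap in target)
    while i > 0 and j > 0:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] != 4) else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                if s == match:
                    matches += 1
                aligned += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aligned += 1
            if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                state = 0
            j -= 1
        else:
            aligned += 1
            if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                state = 0
            i -= 1
    return i, j, matches, aligned


@dataclass(frozen=True)
class Alignment:
    """A local alignment of a read interval to a segment interval.

    Intervals are half-open on both read and segment; ``orientation`` is
    always '+' (reads are put in coding orientation before alignment).
    """

    segment_id: str
    read_start: int
    read_end: int
    segment_start: int
    segment_end: int
    score: int
    identity: float
    orientation: str = "+"

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    def sort_key(self):
        # rank: score desc, aligned length desc, id asc
        return (-self.score, -(self.read_span), self.segment_id)


def local_align(query: str, target: str, scoring: ScoringScheme = DEFAULT_SCORING):
    """Best local alignment of query vs target under the pipeline scheme.

    Returns ``(score, (q_start, q_end), (t_start, t_end), identity)``; a score
    of 0 means no positive-scoring local alignment exists and the intervals
    are empty.
    """
    q = encode(query)
    t = encode(target)
    best, bi, bj, H, E, F = _gotoh_local(
        q, t, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best == 0:
        return 0, (0, 0), (0, 0), 0.0
    i0, j0, matches, aligned = _traceback(
        q, t, H, E, F, bi, bj,
        scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
    )
    identity = matches / aligned if aligned else 0.0
    return int(best), (i0, bi), (j0, bj), identity


class SegmentIndex:
    """Exact k-mer index over a set of named reference sequences."""

    def __init__(self, references: dict[str, str], k: int = 11,
                 scoring: ScoringScheme = DEFAULT_SCORING):
        if k < 1:
            raise ValueError("seed size k must be positive")
        self.k = k
        self.scoring = scoring
        self.references = dict(references)
        self._kmers: dict[str, set[str]] = {}
        for name, seq in self.references.items():
            for p in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[p : p + k], set()).add(name)

    def candidates(self, query: str) -> list[str]:
        """Reference names sharing at least one exact k-mer with the query."""
        k = self.k
        hits: set[str] = set()
        for p in range(len(query) - k + 1):
            hits |= self._kmers.get(query[p : p + k], set())
        return sorted(hits)

    def align(self, query: str, min_score: int = 0,
              restrict: list[str] | None = None) -> list[Alignment]:
        """Align query to candidate references (all references if unseeded).

        All alignments with score above ``min_score`` are returned, ranked by
        (score desc, aligned length desc, segment id asc); identical-scoring
        hits to sequence-identical references are all retained so downstream
        callers can report them as an ambiguous set.
        """
        names = restrict if restrict is not None else self.candidates(query)
        if not names:
            names = sorted(self.references)
        out = []
        for name in names:
            score, (qs, qe), (ts, te), ident = local_align(
                query, self.references[name], self.scoring
            )
            if score > max(min_score, 0):
                out.append(
                    Alignment(
                        segment_id=name,
                        read_start=qs,
                        read_end=qe,
                        segment_start=ts,
                        segment_end=te,
                        score=score,
                        identity=ident,
                    )
                )
        out.sort(key=Alignment.sort_key)
        return out


def align_to_segments(seq: str, locus, k: int = 11, min_score: int = 0,
                      scoring: ScoringScheme = DEFAULT_SCORING) -> list[Alignment]:
    """Align a sequence against every segment of a locus.

    Thin convenience wrapper over :class:`SegmentIndex`; pipelines that align
    many reads should build the index once (see ``caller.JunctionCaller``).
    """
    index = SegmentIndex({s.id: s.sequence for s in locus.segments}, k=k,
                         scoring=scoring)
    return index.align(seq, min_score=min_score)
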