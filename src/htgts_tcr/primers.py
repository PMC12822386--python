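"""Validation of bait (biotinylated) and nested primers for bait capture.

The design rules enforced here are the library-construction constraints of
the bait-capture protocol: biotinylated outer primers sit 20-200 bp
downstream of the target segment's coding end, nested inner primers within
70 bp of the target (between target and bio primer), annealing temperatures
of 59-60 C and GC content of 40-50% (hard ceiling 60%), no hairpin or
primer-dimer structure, and bio primers mutually spaced at least 445 bp on
the locus (over 1000 bp for a final multiplexed set).

Melting temperatures use nearest-neighbour thermodynamics at pinned
conditions (50 mM Na+, 250 nM primer) so results are reproducible; the Tm
band is a preferred band (warning) by default and a hard band under
``strict_tm``.  Hairpin/dimer screening uses the longest reverse-complement
run shared between a primer and itself (or its partner), threshold 6 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import pandas as pd
from Bio.SeqUtils import MeltingTemp, gc_fraction

from .germline import Locus
from .simulate import revcomp

__all__ = [
    "PrimerCandidate",
    "PrimerCheck",
    "SetCheck",
    "validate_primer",
    "validate_primer_set",
    "report_table",
]

# pinned thermodynamic conditions for nearest-neighbour Tm
TM_CONDITIONS = {"Na": 50.0, "dnac1": 250.0, "dnac2": 0.0}

BIO_DISTANCE_RANGE = (20, 200)       # bp downstream of the target coding end
NESTED_MAX_DISTANCE = 70             # bp, exclusive ("< 70 bp from target")
TM_BAND = (59.0, 60.0)               # degrees C, preferred annealing band
GC_PREFERRED = (0.40, 0.50)
GC_CEILING = 0.60                    # hard limit
COMPLEMENT_RUN_THRESHOLD = 6         # nt of self/cross complementarity
DEFAULT_MIN_SPACING = 445            # bp between bio primers
FINAL_SET_MIN_SPACING = 1000         # bp, final multiplexed primer set


@dataclass(frozen=True)
class PrimerCandidate:
    """A candidate primer with its placement relative to its target segment."""

    sequence: str
    role: str                         # "bio" or "nested"
    target_segment: str = ""
    distance_to_target: int = 0       # nt downstream of the target coding end
    genomic_pos: Optional[int] = None  # contig position of the annealing site

    def __post_init__(self) -> None:
        if set(self.sequence.upper()) - set("ACGT"):
            raise ValueError(
                f"primer {self.sequence!r}: non-ACGT bases are not allowed"
            )
        if self.role not in ("bio", "nested"):
            raise ValueError(f"primer role must be 'bio' or 'nested', got {self.role!r}")
        if self.distance_to_target < 0:
            raise ValueError("distance_to_target must be non-negative")

    @property
    def gc(self) -> float:
        return float(gc_fraction(self.sequence))

    @property
    def tm(self) -> float:
        return float(MeltingTemp.Tm_NN(self.sequence, **TM_CONDITIONS))


@dataclass
class PrimerCheck:
    primer: PrimerCandidate
    passed: bool
    failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class SetCheck:
    passed: bool
    failures: list[str] = field(default_factory=list)
    pairwise: pd.DataFrame = None
    worst_pair: Optional[tuple[str, str]] = None


def longest_complement_run(a: str, b: str) -> int:
    """Longest contiguous run of ``a`` base-pairing with ``b``.

    Computed as the longest common substring between ``a`` and the reverse
    complement of ``b``; ``longest_complement_run(p, p)`` screens hairpin /
    self-dimer potential.
    """
    b_rc = revcomp(b.upper())
    a = a.upper()
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b_rc:
                best = j - i
            else:
                break
    return best


def validate_primer(p: PrimerCandidate, strict_tm: bool = False,
                    bio_distance: Optional[int] = None) -> PrimerCheck:
    """Check one primer against the placement, Tm, GC and structure rules.

    ``bio_distance`` (the paired bio primer's distance) lets the nested-primer
    rule also verify the nested primer sits between target and bio primer.
    """
    failures: list[str] = []
    warn: list[str] = []

    if p.role == "bio":
        lo, hi = BIO_DISTANCE_RANGE
        if not lo <= p.distance_to_target <= hi:
            failures.append(
                f"bio distance {p.distance_to_target} outside [{lo}, {hi}] bp"
            )
    else:
        if p.distance_to_target >= NESTED_MAX_DISTANCE:
            failures.append(
                f"nested distance {p.distance_to_target} not < {NESTED_MAX_DISTANCE} bp"
            )
        if bio_distance is not None and p.distance_to_target >= bio_distance:
            failures.append("nested primer not between target and bio primer")

    if p.gc > GC_CEILING:
        failures.append(f"GC {p.gc:.2f} exceeds ceiling {GC_CEILING:.2f}")
    elif not GC_PREFERRED[0] <= p.gc <= GC_PREFERRED[1]:
        warn.append(f"GC {p.gc:.2f} outside preferred band {GC_PREFERRED}")

    tm = p.tm
    if not TM_BAND[0] <= tm <= TM_BAND[1]:
        msg = f"Tm {tm:.1f} C outside band {TM_BAND}"
        (failures if strict_tm else warn).append(msg)

    run = longest_complement_run(p.sequence, p.sequence)
    if run >= COMPLEMENT_RUN_THRESHOLD:
        failures.append(f"hairpin/self-dimer: {run} nt self-complementary run")

    return PrimerCheck(primer=p, passed=not failures, failures=failures,
                       warnings=warn)


def validate_primer_set(primers: Sequence[PrimerCandidate],
                        locus: Optional[Locus] = None,
                        min_spacing: int = DEFAULT_MIN_SPACING) -> SetCheck:
    """Pairwise spacing and cross-dimer checks over a primer set.

    Bio primers must be mutually spaced at least ``min_spacing`` bp on the
    contig (use ``FINAL_SET_MIN_SPACING`` for a final multiplexed set); any
    primer pair with a cross-complementary run of >= 6 nt fails.  Genomic
    positions come from ``genomic_pos``, or from the locus via the target
    segment and distance when absent.  A single primer passes vacuously.
    """
    if not primers:
        raise ValueError("primer set is empty")
    failures: list[str] = []
    rows = []
    worst = None
    worst_gap = None

    def pos_of(p: PrimerCandidate) -> Optional[int]:
        if p.genomic_pos is not None:
            return p.genomic_pos
        if locus is not None and p.target_segment in locus:
            seg = locus[p.target_segment]
            if seg.segment_type == "J":
                return seg.contig_end + p.distance_to_target
            return seg.contig_start - p.distance_to_target
        return None

    bios = [p for p in primers if p.role == "bio"]
    for i in range(len(bios)):
        for j in range(i + 1, len(bios)):
            a, b = bios[i], bios[j]
            pa, pb = pos_of(a), pos_of(b)
            if pa is None or pb is None:
                continue
            gap = abs(pa - pb)
            ok = gap >= min_spacing
            rows.append({"check": "spacing", "a": a.sequence, "b": b.sequence,
                         "value": gap, "passed": ok})
            if not ok:
                failures.append(
                    f"bio primers {gap} bp apart (< {min_spacing} bp minimum)"
                )
                if worst_gap is None or gap < worst_gap:
                    worst_gap, worst = gap, (a.sequence, b.sequence)

    for i in range(len(primers)):
        for j in range(i, len(primers)):
            a, b = primers[i], primers[j]
            if i == j:
                continue
            run = longest_complement_run(a.sequence, b.sequence)
            ok = run < COMPLEMENT_RUN_THRESHOLD
            rows.append({"check": "cross_dimer", "a": a.sequence,
                         "b": b.sequence, "value": run, "passed": ok})
            if not ok:
                failures.append(
                    f"cross-dimer: {run} nt complementary run between primers"
                )
                if worst is None:
                    worst = (a.sequence, b.sequence)

    pairwise = pd.DataFrame(rows, columns=["check", "a", "b", "value", "passed"])
    return SetCheck(passed=not failures, failures=failures, pairwise=pairwise,
                    worst_pair=worst)


def report_table(checks: Sequence[PrimerCheck]) -> pd.DataFrame:
    """One row per individual check outcome, for the validation report TSV."""
    rows = []
    for c in checks:
        base = {"sequence": c.primer.sequence, "role": c.primer.role,
                "target": c.primer.target_segment,
                "distance": c.primer.distance_to_target,
                "gc": round(c.primer.gc, 3), "tm": round(c.primer.tm, 2)}
        if not c.failures and not c.warnings:
            rows.append({**base, "status": "pass", "detail": ""})
        for f in c.failures:
            rows.append({**base, "status": "fail", "detail": f})
        for w in c.warnings:
            rows.append({**base, "status": "warn", "detail": w})
    return pd.DataFrame(rows)
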