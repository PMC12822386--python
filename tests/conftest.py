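"""Shared fixtures: toy loci and a small pre-built library."""

from __future__ import annotations

import numpy as np
import pytest

import htgts_tcr as h
from htgts_tcr.simulate import LibraryParams, fragment_and_capture


@pytest.fixture(scope="session")
def trb_locus():
    """TRB-like locus: 20 V, 2 D, 14 J in two clusters."""
    return h.build_toy_locus(20, 2, 14, seed=11)


@pytest.fixture(scope="session")
def tra_locus():
    """TRA-like locus (no D): 18 V, 15 J with positional classes."""
    return h.build_toy_locus(18, 0, 15, seed=13)


@pytest.fixture(scope="session")
def small_library(trb_locus):
    """A small mixed library (VDJ + DJ + germline reads) with ground truth."""
    rng = np.random.default_rng(21)
    params = h.JunctionModelParams()
    events = h.simulate_cells(trb_locus, params, 400, rng, selection="none",
                              p_v_to_dj=0.6, p_rearrange=0.85)
    baits = h.make_bait_table(trb_locus,
                              [j.id for j in trb_locus.j_segments])
    pairs, truth = fragment_and_capture(events, trb_locus, baits,
                                        LibraryParams(), rng)
    return {"locus": trb_locus, "events": events, "baits": baits,
            "pairs": pairs, "truth": truth}


@pytest.fixture(scope="session")
def called_library(small_library):
    """The small library pushed through preprocess + junction calling."""
    baits = small_library["baits"]
    pairs = small_library["pairs"]
    proc, counts = h.process_pairs(
        ((p.read_id, p.seq1, p.qual1, p.seq2, p.qual2) for p in pairs), baits)
    caller = h.JunctionCaller(small_library["locus"], baits)
    calls = h.retain_duplicates(caller.call_all(proc))
    return {**small_library, "processed": proc, "counts": counts,
            "calls": calls}
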