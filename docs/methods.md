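# Methods

This note records the models, algorithms, and numerical conventions used in
`htgts_tcr`, in enough detail to re-derive every constant that the tests and
the acceptance script check.

## 1. Germline locus model

A `Locus` is an ordered set of `GermlineSegment`s laid out on a single toy
contig with fixed inter-segment spacers.  Each segment carries:

* `sequence` — coding sequence, junction-proximal end adjacent to its RSS;
* `rss_pos` / `rss_genomic` — the recombination signal sequence position at
  the junction-proximal coding end (V: 3′ end; D: both ends, modelled at the
  segment bounds; J: 5′ end), in segment and contig coordinates;
* `anchor_codon_offset` — V segments end in the conserved Cys codon `TGT`;
  J segments contain the conserved Phe within a `TTTGGA` motif.  Anchors are
  *included* in the CDR3 (IMGT "junction" convention);
* `cluster` — J segments are split into two clusters (`Jb1`, `Jb2`) with the
  two D segments placed so that D1 precedes both clusters and D2 lies between
  them.  `nonfunctional_rss` marks segments excluded from rearrangement.

TRA-like loci have no D segments and no clusters.  `build_toy_locus` seeds
segment bodies from a PCG64 stream, so a `(n_v, n_d, n_j, seed)` tuple fully
determines the locus.  Round-trip I/O is FASTA (sequences, via Biopython) plus
a TSV side table (coordinates, annotations).

**On-target window.** A breakpoint `b` for segment `s` is on target iff
`rss_genomic − 40 ≤ b ≤ rss_genomic + 40` — a closed window; ±40 is in,
±41 is out.

## 2. Rearrangement model

One allele rearrangement (`simulate_allele_rearrangement`) draws:

1. segments — V uniformly or by `v_weights`, D uniformly, J uniformly,
   subject to the deletional-joining rule: a D may only join a J that lies
   downstream of it on the contig (hence D2 never pairs with cluster-1 Js);
2. exonuclease deletions at each coding end — geometric with mean 3,
   clipped so the conserved anchors always survive (a V keeps its Cys codon,
   a J keeps its Phe codon, D5′+D3′ deletions never exceed the D length);
3. untemplated N insertions at each junction — Poisson with mean 4,
   uniform random bases.

The coding join is assembled literally: trimmed V + N + trimmed D + N +
trimmed J (or trimmed D + N + trimmed J for incomplete DJ joins).

**Frame null (the 1/3).** Productivity in `"frame"` mode requires only that
the V-anchor-to-J-anchor distance be `≡ 0 (mod 3)`.  That distance is a fixed
germline constant plus `S = n₁ + n₂ − d_V − d_D − d_J (mod 3)`.  The clipped
geometric deletions are *not* uniform mod 3, but each Poisson(λ=4) insertion
term has characteristic function `|E ω^N| = exp(−λ(1−cos 2π/3)) = e^{−6}
≈ 2.5·10⁻³` at the cube root of unity ω, and two independent insertions enter
the sum.  The total variation distance of `S mod 3` from uniform is therefore
< 10⁻⁴ regardless of the deletion distribution: the in-frame probability is
1/3 to four decimals by construction, not by tuning.  `"full"` mode
additionally requires no stop codon in the anchor-to-anchor frame, pushing
the productive probability slightly below 1/3.

**Two-allele cell model** (`simulate_cell`). Each cell carries two alleles.
Allele 1 attempts a V(D)J join with per-join productive probability p;
feedback inhibition stops recombination as soon as a productive join exists,
so allele 2 rearranges only if allele 1 was nonproductive.  With β-selection,
cells with no productive allele die.  Enumerating with `fractions.Fraction`
at p = 1/3:

* survival = p + (1−p)p = 1 − (1−p)² = `5/9`;
* among survivors' VDJ joins: the productive fraction is
  `(2−p)/(3−2p) = 5/7 ≈ 71.43%` — case "allele 1 productive" (prob p)
  contributes 1 productive VDJ (the other allele is frozen at its DJ
  intermediate), case "allele 1 nonproductive, allele 2 productive" (prob
  (1−p)p) contributes 1 productive + 1 nonproductive VDJ.
* survivor DJ:VDJ mass = `1/(3−2p)` (≈ 0.43 at p = 1/3).

Both closed forms are exported by `beta_selection_expectation()` and checked
against ≥100,000-cell simulations in `scripts/acceptance.py`.

**Developmental stages.** A DN3-like population is modelled as
`selection="none"` with `p_v_to_dj = 0.5` (half of alleles stall at the DJ
intermediate — the V-to-DJ step is incomplete); a DP-like population as
`selection="beta_selection"` with `p_v_to_dj = 1.0`.  This makes the DN3
DJ:VDJ ratio strictly exceed the DP ratio, the qualitative ordering the
biology demands; the 0.5 is a documented free parameter, not a fit.

**TRA usage schedule** (`simulate_tcra_usage_gradient`). Successive
rearrangement rounds on a TRA-like locus use progressively more distal V and
J windows (a documented per-round window table); tests assert direction only
(distal usage increases with round), since no quantitative schedule is
specified by the underlying biology.

## 3. Library model

`fragment_and_capture` turns rearranged (or germline) alleles into paired
150 bp reads:

* sonication fragment length ~ Normal(700, 150), size selection keeps
  300–700 bp inserts;
* **J-side baits**: the biotinylated primer anneals antisense in the
  downstream genomic flank, 80 bp from the J coding end; the nested primer
  8 bp from it.  Read 1 therefore runs from the nested primer across the
  junction on the bottom strand.
* **V-side baits**: a primer placed upstream of a ~300 bp V could never reach
  the junction within 150 bp, so V baits anneal *sense-strand inside the V*
  near its 3′ RSS end — the biotin primer ends 80 bp from the V coding end
  and the nested primer 40 bp from it (`v_nested_distance`).  Capture fails
  when V-end deletion exceeds the smaller of those distances (the primer site
  was chewed away), exactly as in the real assay.
* sequencing substitutions at rate 0.001 per base; PCR duplicates are drawn
  per molecule (geometric, `mean_duplicates`) and share the clean molecule,
  so error-free duplicates produce byte-identical reads.
* each read pair is linked to its generating event in a truth table.

With all-J baits, capture yield is ~42% of events (the rest fall to size
selection or fragment placement), ~70 µs of simulation per event.

## 4. Preprocessing

`process_pairs` assigns each read 1 to a bait by best prefix match to the
nested primer (≤2 mismatches; ties are `bait_ambiguous`, worse is `no_bait`),
trims the primer, and merges mates when their 3′ overlap agrees (consensus
takes the higher-quality base; non-overlapping pairs keep read 1).  Counts
are an exact partition of the input: `input = assigned + no_bait +
bait_ambiguous`.

## 5. Junction calling

`align.local_align` is a Smith–Waterman–Gotoh affine local aligner
(numba-jit): match +1, mismatch −1, gap open −2, gap extend −1, where a gap
of length L costs `open + L·extend`.  `SegmentIndex` seeds candidate segments
by shared 11-mers and falls back to exhaustive alignment when no seed fires;
seeding never loses the optimum in tests (property-tested against a
pure-Python DP oracle implemented independently in the test suite).

`JunctionCaller` aligns the read to V, D, and J references (orientation via
the bait), classifies it as `VDJ`, `DJ`, `germline`, or `unclassified`,
reports ties as ambiguous call sets sorted by id, and maps alignment ends to
genomic breakpoints checked against the closed ±40 bp on-target window.
D assignment inside the junction requires a ≥5 bp exact match, and D
candidates are restricted to Ds upstream of the called J (deletional
joining), which eliminates D2→cluster-1 artefacts.  Duplicates are *retained*
(every read kept) but tagged with a duplicate key (bait, segments,
breakpoints, junction), with per-key multiplicity and a dedup report.

## 6. Annotation and productivity

A VDJ call is **productive** iff (i) both anchor codons are locatable through
the alignments, (ii) the codons in the *read* still translate to C and F
respectively (a sequencing error inside an anchor voids it, as in
IgBLAST-style annotation), (iii) the anchor-to-anchor distance is a multiple
of 3, and (iv) the anchor-to-anchor frame contains no stop codon.  The CDR3
is the anchor-inclusive nucleotide span and its translation; records are
written as AIRR Rearrangement TSV (`sequence_id, v_call, d_call, j_call,
junction, junction_aa, productive, locus, …` plus bait-capture extension
columns).  `annotate_event` provides the truth-side CDR3 straight from the
assembled join for validation.

## 7. Repertoire statistics

* **Usage frequencies** are computed over all retained records — duplicates
  are kept by design, not collapsed; ambiguous calls of size k
  contribute 1/k to each member and are listed as caveats; off-target records
  are excluded; stratification renormalises within stratum.
* **Productive fraction** is computed over VDJ records only, with a Wilson
  score 95% CI (`statsmodels.stats.proportion.proportion_confint`).
* **DJ:VDJ ratio** with an infinite-ratio warning when VDJ count is zero.
* **CDR3 profiles**: length histogram, median, and a position frequency
  matrix over length-matched productive CDR3s (columns sum to 1; position 1
  is the conserved C, the last the conserved F); exported as TSV suitable for
  sequence-logo tools, with a matplotlib bar-panel fallback.
* **Replicate comparisons**: per-segment two-sample tests with Holm
  correction, and a two-way ANOVA (segment × condition interaction) with
  Tukey HSD follow-up via statsmodels; both require ≥2 replicates per
  condition.

## 8. Primer validation

`validate_primer` enforces: biotin primer 20–200 bp from its target (closed
band), nested primer < 70 bp and strictly inside the biotin distance; GC hard
ceiling 60% (40–50% preferred, warning outside); Tm 59–60 °C
(nearest-neighbour `Bio.SeqUtils.MeltingTemp.Tm_NN`, 50 mM Na⁺, 250 nM
primer) as a warning by default, a failure under `strict_tm`; hairpins and
self-dimers via the longest self reverse-complementary run (≥6 fails).
`validate_primer_set` adds pairwise cross-dimer checks (≥8 complementary
run fails) and genomic spacing: ≥445 bp between any two primer positions by
default, ≥1000 bp (`FINAL_SET_MIN_SPACING`) for a final set.  Positions can
be given directly or derived from a locus (`target contig_end + distance`).

## 9. Determinism and seeds

All randomness flows through `numpy.random.Generator` objects passed
explicitly.  The CLI and the acceptance script split their single user seed
through `numpy.random.SeedSequence.spawn`, so sub-tasks are independent and
every run is byte-reproducible (the CLI test asserts byte-identical outputs
across reruns).  The acceptance script reports the exact 5/7 for the
deterministic target and guards it with a 5σ comparison against its own
100,000-cell simulation.
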