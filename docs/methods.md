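# Methods

## The problem

Biopanning a phage-display peptide library against a target enriches binders,
but the sequencing output of a screen conflates three things: genuine affinity
for the target, non-specific stickiness, and clone-to-clone differences in
bacterial amplification rate ("parasitic" clones). For targeted drug delivery
and molecular imaging the requirement is stricter than specificity: a peptide
must bind the cell type of interest *and avoid* the other cell types it will
meet in vivo. selpep implements a selectivity analysis over many independent
screens: each candidate peptide is scored by how high it is across screens
against the target (positives) relative to screens against counter-targets
(negatives), after normalizing away sequencing depth and library composition.

## Part 1 — reads to counts

Each demultiplexed FASTQ file is one screen. For every read:

1. **Flank anchoring.** The insert is located by searching for the 3' flank
   signature (9 nt for the NEB Ph.D. libraries, `GGAGGTGGA`) left to right,
   starting far enough into the read to leave room for the insert and the 5'
   flank; a match counts only if the 3 nt immediately upstream of the
   candidate insert equal the 5' signature (`TCT`). The 3' flank is the
   anchor because a 3-mer alone matches by chance every ~32 nt. Occurrences
   whose 5' signature fails are skipped, not fatal. Matching is exact; flank
   mismatch tolerance is a known limitation (see below).
2. **Ambiguity.** An insert containing any non-ACGT symbol (an uncalled base)
   is rejected.
3. **Codon-constraint filter.** NEB Ph.D. libraries are synthesised from NNK
   codons (positions 1–2 any base, position 3 G or T; 32 of 64 codons). With
   filtering on (default for the NEB presets), a read whose insert contains
   any non-NNK codon is rejected: such a read cannot be an exact copy of a
   library member, so it is almost surely a sequencing error of one.
4. **Translation.** Standard genetic code, codon by codon. The amber codon
   TAG is *inside* the NNK space; the libraries are grown in a supE host that
   reads TAG through as glutamine, so `amber_as_gln` defaults to true. TAA
   and TGA terminate; under an unconstrained scheme such reads are counted as
   stop rejections (they are unreachable when NNK filtering is on).

The five outcome bins (accepted / no-flank / ambiguous / codon / stop)
partition the total read count exactly, and this identity is asserted on
every run. Quality scores are ignored by design — the ranking operates on
relative frequencies across screens and applies no quality filtering — and
reads are processed strand-forward by default, with an optional
reverse-complement retry for unusual amplicon orientations.

## Part 2 — counts to ranking

For each screen, counts are divided by the screen's **total** read count
(including rejected reads — this matches how run summaries report depth, and
the choice cancels in the ratio), then by the depth-normalized frequency of
the same peptide in the **reference library**: an amplified but unselected
aliquot of the naive library sequenced alongside the screens. The reference
division is what defuses parasitic clones: an amplification advantage
inflates a clone in every screen *and* in the reference, so the normalized
value returns to ~1.

**Imputation.** A peptide absent from a screen cannot be assigned zero (the
ratio would divide by zero) and zero is also not the best estimate — deep
screens sample the library incompletely. Absences are imputed with the
screen's *non-zero mode* of fully normalized values: the most common strictly
positive value, which in real data is the value shared by the mass of
singleton reads, i.e. "present at the detection floor". Ties in multiplicity
break to the smallest tied value (the conservative floor). Imputation
operates after reference normalization, immediately before the ratio, and the
same mode rule is extended to the reference denominator so that clones never
observed in the naive pool still receive finite (large) normalized values.

**Ranking.** Row universe = union of peptides observed in positives ∪
negatives (reference-only peptides were never selected). The selectivity
ratio is the arithmetic mean of normalized values across positive screens
divided by the mean across negative screens, imputed cells included. Rows
sort by ratio descending, ties by mean positive value descending, then
lexicographic peptide — fully deterministic, so identical inputs give
byte-identical output files. A per-row count of non-imputed positive cells is
exported alongside: the "high in at least m of n positives" candidate rule is
a visual-inspection heuristic, so it is reported, not filtered on.

The **reference column** of the exported matrix carries the reference's
depth-normalized frequencies (normalizing the reference against itself would
be identically 1 and carry no information); it never enters the ratio.

**Ubiquitous mode** ranks by the row minimum across all positive and negative
screens, descending — the mirror-image query that surfaces peptides high
everywhere (targets expressed on all cell types, or non-specific binders).
**Round enrichment** compares two biopanning rounds, each normalized against
its own reference: mean round-2 normalized frequency over positives divided
by the round-1 equivalent, with per-round mode imputation.

## The A/L/H worked example

An eight-peptide fixture assigns each peptide a count of 0 (absent), 10 (low)
or 1000 (high) in a reference, two positive and two negative screens, all
with equal totals, so every normalized value and ratio is checkable by hand.
Four patterns carry classic predictions: high-in-positives/absent-elsewhere
must rank first; high-only-in-negatives last; one-positive-plus-one-negative
mid-table; high-everywhere-but-low-in-reference low (its ratio cancels to 1).
The other four rows were designed so that each screen's non-zero mode falls
in the low tier, as it does in real data — with only eight rows the mode is
otherwise dominated by the high tier, which no real screen resembles. The
resulting exact ordering (ratios 198.02, 100, 100, 1.98, 1.0099, 1, 1, 0.01)
is frozen in the tests and re-derived there by an independent plain-arithmetic
oracle.

## Synthetic screens

The simulator generates what the analysis assumes about real data:

* **Naive pool**: `n_unique` distinct constraint-valid inserts with
  log-normal abundance weights (`skew_sigma`; 0 = even library, default 1.2
  for the recovery experiments — a heavily skewed but not degenerate
  library). Stop-codon inserts are never emitted: library members display
  complete peptides.
* **Selective spikes** multiply a clone's sampling weight only in screens
  panned against its target; **parasitic factors** multiply it in every
  screen including the reference, because amplification bias acts wherever
  the library passes through bacteria.
* **Reads** are multinomial draws over effective weights, emitted as
  `pad5 + flank5 + insert + flank3 + pad3` (primer-like padding, so
  extraction must search), constant quality, substitution errors applied
  independently per base. Indels are excluded deliberately: an indel breaks
  flank anchoring and would conflate the error model with the extraction
  contract in tests. Everything is deterministic per seed.
* **Round 2** re-pans round 1's expected output pool (weights × factors),
  so per-round enrichment e composes to ~e² over two rounds.

What the simulator does **not** model: PCR-cycle stochasticity, phage growth
kinetics, chimeric reads, quality-correlated error profiles, or barcode
cross-talk. Passing the recovery experiments therefore shows the analysis
machinery is correct under its own assumptions, not that those assumptions
exhaust real MiSeq data.

## Study-scale validation experiments

* **Counting oracle**: 50 adversarial FASTQ fixtures (200–1000 reads mixing
  valid, flank-broken, ambiguous, codon-breaking, truncated and decoy-flank
  reads); counts and the five-way partition must equal an independent
  brute-force recount exactly.
* **Spiked recovery**: 1 reference + 3 positive + 3 negative screens of
  100,000 reads each over a 20,000-clone pool (σ = 1.2), five selective
  clones spiked 50× in positives only, five parasitic clones amplified 20×
  everywhere, per-base error 0.001. Spiked clones are drawn from the upper
  half of the naive abundance distribution (clones recovered by panning are
  by construction clones present at samplable abundance). Success: all five
  selective peptides inside the top 1% of matrix rows in ≥ 95% of 10 seeds,
  and no parasitic-only clone ever there.
* **Two-round enrichment**: per-round factor 8 on five clones, one positive
  screen plus a fresh reference per round, 50,000 reads; the measured
  round-2/round-1 ratio should recover the per-round factor (median across
  the five clones; individual clones are Poisson-noisy through the two
  independent reference draws).

These sizes run in well under a minute each on one CPU and were chosen as the
smallest scales at which the sampling noise analysis above leaves comfortable
margins; they are the package's standing test conditions, exercised by
`tests/test_acceptance.py` and recomputed by `scripts/acceptance.py`.

## Numerical and design notes

* Mode computation uses exact float equality for the tally. This is sound
  because normalized values of equal counts are computed by identical float
  operations; it is not a general-purpose density mode.
* `total_reads` for depth normalization is the full FASTQ read count, stored
  in the stats sidecar. Counts-only inputs without a sidecar fall back to the
  accepted-read sum with a warning (adequate for re-sorting, but true depth
  is lost).
* Exported ratios/frequencies carry 12 significant digits; TSV read-back
  reproduces them to that precision.
* Degenerate inputs: an empty FASTQ yields a valid all-zero screen with a
  warning; a zero-read screen cannot be normalized (error); a run without
  negatives is an error unless ubiquitous mode is requested; malformed
  FASTQ/CSV rows raise format errors naming the offending record.

## Known limitations

* Exact flank matching: a substitution inside either flank discards the read
  (~2% of reads at error rate 10⁻³ with 12 flank nt). Tolerant matching
  would recover them at the cost of occasional mis-anchoring; not
  implemented.
* No error correction or clustering of near-identical peptides: a sequencing
  error inside the insert that stays NNK-valid creates a spurious low-count
  neighbour of a real clone. The reference normalization keeps such noise
  near ratio 1, but it inflates unique-peptide counts.
* Arithmetic (not geometric) means across screens make the ratio sensitive
  to a single extreme positive screen; using several independent positive
  screens is the intended mitigation.
* No significance testing on ratios; the output is a ranked shortlist for
  inspection, not a hypothesis test.
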