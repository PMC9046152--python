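# Methods

`aquascreen` implements a contamination-aware detection pipeline for
shotgun metagenomic sequencing of very low-biomass specimens (amniotic
fluid, CSF, reagent blanks), where microbial nucleic acid introduced by
extraction kits, reagents, and the laboratory ("kitome") dominates any
genuine signal. The package covers the dry-lab half of such a study:
read cleaning, reference decontamination, tiered taxonomic assignment
from alignment tables, water-control normalization, and a conservative
four-criteria caller, together with a synthetic-data generator that
reproduces the experimental design at desk scale.

## Model and procedure

### Read QC

Paired-end Phred+33 reads pass through a fixed cascade, and a pair is
dropped whenever either mate fails (every downstream criterion needs
both mates):

1. **Adapter trimming.** The earliest occurrence of any configured
   adapter (`AGATCGGAAGAGC` and its full indexed form by default) —
   complete, or a 3'-terminal partial of ≥ `adapter_min_overlap` (5)
   bases — is removed together with everything 3' of it, tolerating
   `adapter_max_error_rate` (0.10) mismatches per aligned base. Like
   any 3'-partial-match trimmer, this step is not guaranteed to be
   bit-idempotent when a trimmed read happens to end in a short adapter
   prefix; what the pipeline guarantees (and tests) is that a second QC
   pass removes no pairs.
2. **B-tail trimming.** The maximal trailing run of Q ≤ 2 bases is
   removed. Q2 is the Illumina Read Segment Quality Control Indicator
   ('#' in Phred+33); the value is fixed, not configurable, because it
   is an instrument convention rather than a quality threshold.
3. **Duplicate removal.** Exact-sequence duplicates, first occurrence
   kept. At pair level the key is the (forward, reverse) sequence tuple
   after trimming. Reverse complements and prefix matches are *not*
   duplicates — the conservative reading, since optical/PCR duplicates
   are strand- and length-exact.
4. **Low-complexity removal.** A windowed nucleotide-triplet Shannon
   entropy score on a 0–100 scale: overlapping 3-mers are tallied in
   64-base windows moved in steps of 32 (the final window is anchored
   at the 3' end so all windows are full-size), each window scores
   `100·H / log2(min(n_triplets, 64))`, and the read score is the mean.
   Reads under `entropy_threshold` (70) are dropped. A homopolymer
   scores 0; a uniform random 100-mer scores ≈ 90.
5. **Quality filter.** Reads are dropped, with the first failing reason
   recorded, for: chastity failure (Casava header flag; assumed passing
   when the instrument did not record it), more than 20 consecutive
   identical bases, any `N`, fewer than `ceil(2/3 · floor(L/2))` of the
   first `floor(L/2)` bases at Q ≥ 30, or length < 70 bp. The ceiling
   is the strict reading of "less than two-thirds → remove"; the filter
   order only affects reason attribution, never the surviving set.

### Reference decontamination

Microbial reference sequences carrying human-like segments cause
recurrent false positives. A reference is removed whole (not masked)
when any alignment of it to the human genome has length ≥ 60 bp with
≤ 15% gaps, ≤ 15% mismatches, and ≤ 30% gaps plus mismatches, all
boundaries inclusive and all percentages relative to the alignment
length. A manifest records every reference's verdict with the
triggering alignment.

### Assignment

Alignments (12-column BLAST-style tabular; column 6 is total gap
positions by default, with a dialect flag for gap-openings files that
then require an explicit total-gaps column) are filtered by the same
60 bp / 15% / 15% / 30% rule. Reads with an accepted alignment to the
host database are subtracted outright; the best *non*-accepted host
alignment per surviving mate is retained as its residual human
homology. The three microbial tiers are interrogated strictly in order
— viral, bacterial, fungal/protozoan — and a read is assigned in at
most one tier: systematic complexity differences between the databases
make the viral tier the most specific, so a lower tier is never
consulted once a higher tier matched. Within a tier the best hit has
the greatest alignment length, ties broken by smallest e-value, then
highest bit score, then lexicographically smallest accession
(deterministic and permutation-invariant).

The **match score** of a read is the identical-base count of its
organism alignment minus that of its residual human alignment:

    score = %id_org/100 · L_org − %id_hum/100 · L_hum

Each term uses its own alignment's length — the only reading under
which both terms are commensurate base counts. Reads are retained at
score ≥ 0 but contribute to a diagnostic call only at score > 0 by
default; both thresholds are configurable because retention and
diagnosis serve different purposes (sensitivity bookkeeping vs.
conservative calling).

Species concordance is by taxon id after accession→taxon resolution,
so mates hitting different accessions of one species form a concordant
pair; such pairs count for abundance and WNS but are excluded from
interval linking (no single subject interval exists) and are logged.

### Water Normalization Score

For a taxon *t* in sample *s*,

    WNS(s, t) = [ n(s,t) / N(s) ] / [ Σ_w n(w,t) / Σ_w N(w) ]

where *n* counts species-concordant pairs, *N* is the sample's total
post-QC pair count (host and unassigned reads included — "reads
passing quality filters" is the denominator, not assigned reads), and
the pool runs over **all** water controls. A taxon absent from every
water control receives an `ABSENT_IN_WATER` sentinel that *passes* the
WNS criterion: absence from the negative controls is the strongest
possible anti-contamination evidence, and a division-by-zero convention
that failed the criterion would penalize exactly the cleanest signals.
A leave-one-out variant scores each water against the pool of the rest,
quantifying the null spread of the score.

### Diagnostic calling

A taxon is positive in a sample iff all four criteria hold:

1. **Pair concordance** — at least one read pair with both mates
   assigned to the species. Mates whose partner is unassigned or
   discordant are excluded from the diagnostic evidence; they do not
   veto the call (host subtraction and the 60 bp minimum routinely
   orphan one mate of genuine pairs).
2. **Discreteness** — at least `min_diagnostic_pairs` (3) mutually
   discrete linked pairs. Mates are linked into one subject interval
   `[min(starts), max(ends)]`; two pairs conflict when their intervals
   overlap by ≥ 50 bp. Conflict is exactly intersection of the
   end-shrunk intervals `[start, end − 49]`, so the conflict graph is
   an interval graph and greedy earliest-end scheduling on the shrunk
   intervals yields the exact maximum mutually-discrete subset —
   order-independent and deterministic, verified against exhaustive
   subset enumeration. Intervals shorter than 50 bp can never conflict
   and always count.
3. **Match score** — strictly positive for every concordant pair of the
   taxon (literal "for all reads"; a single zero-score pair fails the
   criterion rather than being silently excluded).
4. **WNS** — strictly above `wns_cutoff` (1.0), or absent in water.

The verdict is monotone: adding a discrete positive-score pair or
raising the WNS can never flip positive → negative. Calls carry a
per-criterion audit trail and a free-text confirmation-status field for
downstream wet-lab follow-up (e.g. "PCR negative").

Counts roll up from species to genus and family by lineage (totals
conserved; unresolvable lineages land in an `unclassified` bucket).
Coverage breadth/depth, insert-length histograms, and a log2-WNS
matrix (sentinel mapped to the largest finite WNS, zeros floored at
2⁻¹⁰) for PCA ordination (delegated to scikit-learn) support reporting.

## Synthetic data

The generator reproduces the validation design rather than realistic
sequence content: i.i.d. random genomes at specified GC (five 8 kb
viral spike candidates, four 40 kb bacterial + one 60 kb fungal
contaminant, a 100 kb host), spike levels of 200 / 1000 / 5000 genome
copies, five water controls, inserts ~ N(300, 30) truncated at the
100 bp read length, i.i.d. substitution errors at 0.2%, and uniform
Q37 base qualities.

Two defaults encode the study conditions:

* **Library efficiency** `reads_per_genome_copy = 0.01` pairs per
  spiked genome copy. Under the Poisson shot-noise model this puts
  200 gc at λ = 2 expected pairs — P(≥ 3 pairs) ≈ 0.32, the stochastic
  marginal-detection regime where roughly one spike in three is
  callable — while 1000 gc (λ = 10) and 5000 gc (λ = 50) are detected
  essentially always.
* **Contaminant model**: panel taxa appear at identical expected
  fractions (4 × 10⁻⁴ of the library) in water controls and samples,
  emulating a reagent kitome, so true-negative WNS concentrates near 1
  and false positives are controlled by the discreteness criterion
  rather than by abundance differences.

Desk-scale problem sizes — 500 pairs per library, 80% host (samples)
or unattributable background (waters) — were chosen so a full
multi-replicate experiment runs on one CPU in minutes; the host/
background split keeps the *fractional* contaminant composition
identical between sample types, which is the WNS null the method
assumes.

Every simulated read is recorded in a ground-truth manifest; a
violation planter injects exact numbers of QC defects (chastity
failures, 21-base runs, Ns, low-quality first halves, short reads, Q2
tails, pair duplicates, low-complexity reads) for truth-table testing
of the QC report. The bundled aligner is deliberately ungapped
(seed-and-extend on exact 16-mers, both strands, gaps always 0): it is
sufficient to exercise every downstream rule, the gap clauses being
tested directly on constructed alignment records, and it guarantees
that an error-free read is reported full-length at its true locus with
BLAST-style coordinates. Its e-value/bit score are monotone surrogates
(matches − 2·mismatches), adequate for tie-breaking but not calibrated
statistics.

What the simulation does **not** emulate: real genome sequences and
shared k-mer content between taxa (cross-mapping is therefore absent),
quality-dependent or indel-rich error profiles, PCR duplication,
GC-coverage bias, and library-size variation beyond Poisson noise.
Passing end-to-end tests demonstrates the *logic* of the pipeline —
criteria algebra, normalization, accounting — not classifier accuracy
on real reads.

## Numerical choices and degenerate inputs

* All alignment coordinates are 1-based inclusive; minus-strand subject
  hits use start > end and are normalized on access.
* Threshold comparisons on the 15%/30% rules use integer arithmetic
  (`mismatches · 100 ≤ 15 · length`), exact for all integer inputs and
  verified against `fractions.Fraction`.
* `best_hit` ties break to the smallest accession, making assignment
  deterministic under input permutation.
* Empty reads (fully trimmed) flow through and are removed as
  `too_short`; empty evidence sets yield negative verdicts with
  criterion flags all false except possibly WNS.
* WNS with zero counts everywhere is 0, not the sentinel: "not
  detected" is distinct from "enriched relative to water".
* Seeds: all generators take explicit seeds; replicate seeds are
  derived via `numpy` `SeedSequence(entropy=(base_seed, replicate))`.

## Known limitations

* The e-value tie-break assumes the upstream aligner emits comparable
  e-values across hits of one query; mixing aligners within a tier
  would make the tie-break arbitrary (though still deterministic).
* The discreteness counter treats pairs linked on different accessions
  of one species as unlinked evidence; a species whose support is
  split across many near-identical accessions can therefore undercount
  discrete pairs relative to a merged-reference analysis.
* The QC entropy filter is a reimplementation in the style of common
  triplet-entropy filters, not a bit-exact clone of any specific tool;
  the threshold (70) is configurable.
* Real-data WNS distributions are heavier-tailed than the simulated
  kitome (reagent lots differ between libraries); the leave-one-out
  water WNS is the right diagnostic to run on real controls before
  trusting the 1.0 cutoff.
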