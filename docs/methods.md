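# Methods

## Model and procedure

The pipeline infers the protospacer adjacent motif (PAM) of an endogenous
Type I-B CRISPR/Cas system from the spacers of its own array. The premise:
spacers were acquired from mobile genetic elements (MGEs), and acquisition
in Type I systems requires a PAM immediately 5' of the protospacer. A
confident set of spacer→protospacer matches therefore exposes the PAM in
the aligned upstream flanks.

Stages, in order:

1. **Orientation.** Spacer sequences must be read in crRNA orientation,
   which depends on which end of the array is leader-proximal. An explicit
   external call (e.g. from a CRISPR-locus database) takes precedence;
   otherwise a deterministic sigma70 stand-in scores both genomic flanks:
   consensus hexamers TTGACA/TATAAT separated by 15–19 nt, +1 per matching
   base (max 12), all placements enumerated. The higher-scoring flank is the
   leader side; calls within a margin (default 2.0) stay `unknown` and the
   caller must decide. When the resolution is `reverse`, repeat and spacers
   are reverse-complemented and spacer order inverted immediately, so no
   downstream stage branches on orientation.
2. **Search.** Every window of every subject, both strands, is scored
   against every spacer (vectorized Hamming over a uint8 encoding). A
   window is a hit iff mismatches/length < `max_mismatch_fraction`
   (default 0.20, strict) and mismatches within the `seed_length` (7)
   PAM-proximal positions ≤ `max_seed_mismatches` (1). Mismatch positions
   are 1-based from the PAM-proximal end. Hits overlapping the source array
   locus are excluded; overlapping same-spacer/same-strand windows collapse
   to the lowest-mismatch (ties: leftmost) one. Externally computed
   12-column tabular alignments can be imported instead; their mismatch
   geometry is recomputed from the sequences and refiltered identically,
   with partial-query rows rejected.
3. **MGE filter.** Three evidence routes in fixed precedence: title
   keyword, prophage-interval overlap, feature-label keyword. Matching is
   substring and case-insensitive because the field's keywords occur inside
   compound words (prophage, phage-like); overlap means ≥1 shared base.
   Both keyword sets are configurable.
4. **PAM call.** Upstream flanks of retained hits (truncated flanks
   excluded, not padded — padding would bias columns) are tallied into a
   4×k position frequency matrix over positions −k…−1 (k default 5, the
   flank length manipulated in interference assays). Consensus modes:
   `covering` (IUPAC code of every observed base; default, because real
   Type I-B systems show degenerate PAM sets) and `majority` (single base
   if >0.5, else code of bases ≥0.25, else N). Information content per
   column is 2 + Σ p log₂ p bits, optionally with the small-sample
   correction 3/(2·ln2·n). Candidates are exact k′-mers at −3…−1
   (k′ = 3: validated PAMs in these systems are trinucleotides), ranked by
   count then lexicographically; dinucleotide tallies at −3…−2 and −2…−1
   support "double cytosine"-style observations. Fewer than `min_mge_hits`
   (2) contributing hits yields status `insufficient_mge_hits` and no
   consensus.

## Design layer

* Native repeat flanks: last/first n (5) bases of the direct repeat are
  what precedes/follows a spacer in the native array; they are the neutral
  5' control and the fixed 3' sequence of interference constructs.
* Spacer candidates: the `length` (36; 35 accepted) bases immediately 3' of
  a degenerate PAM-pattern match, both strands, GC within closed bounds
  [0.40, 0.60].
* Editing templates: LHA = `lha_len` bases 5' of the edit, RHA = `rha_len`
  bases 3'; edited locus = LHA (+ cargo) + RHA, with a reconstruction
  invariant checked in tests. Replacement (cargo in place of an interval,
  e.g. a knock-in displacing only the PAM) is expressed as an insertion
  with a replaced interval.
* Validators: `in_frame` is deletion length ≡ 0 (mod 3) evaluated only when
  the deletion lies inside a supplied CDS interval (the frame test is
  otherwise undefined); `target_destroyed` requires the edited locus to
  contain neither PAM+protospacer nor its reverse complement — interference
  needs both, so removing or splitting either suffices for escape;
  spacer-to-arm distance is reported, not constrained (published designs
  used 26/29/40 nt without a stated rule). Amplicon prediction takes raw
  lengths; the |WT − edited| difference must equal the edit size.
* R-M scanning matches a degenerate motif (default TAAGN₅TCC) on both
  strands with overlapping matches reported; counts are invariant under
  reverse complement.
* The Pfaffl ratio E_t^(−Cp_t)/E_r^(−Cp_r) requires efficiencies in (1, 2].

## Synthetic fixtures

`generate_invader_set` emulates the immunization history the method
assumes: random background subjects (default 5 × 3 kb, enough density for
20 plants without collisions while keeping the brute-force test oracle
cheap), protospacers (36 nt) planted at non-overlapping positions on random
strands behind the stated PAM, spacers collected into a host array carrying
the A. woodii direct repeat. Injected mutations avoid the seed region by
default so every plant passes the filters; deliberate violations
(`seed_mutation_counts`) are recorded in the returned truth object. MGE
labels cycle round-robin through the three evidence routes over a
configurable fraction of subjects. One seeded numpy generator drives
everything; a fixture is byte-reproducible from its seed.

What the generator does **not** emulate: real invader pools have homology
between subjects, uneven GC, partial/decayed protospacers, and PAMs that
vary per hit. A green planted-PAM test establishes the plumbing (search,
filters, tallying) is exact — not that the method resolves weak or mixed
PAM signals, which the insufficient-hits status is designed to expose
rather than hide.

## Numerical and convention choices

* Coordinates 0-based half-open throughout; 1-based only as extra report
  columns.
* Exactly-20% mismatch is rejected (strict <): the stricter of the two
  plausible readings, minimizing false positives; threshold configurable.
* `N` counts as a mismatch by default (conservative; keeps the 20% rule
  meaningful); a wildcard policy exists. Full IUPAC codes in subjects are
  rejected.
* Gaps: the internal search is ungapped; imported gapped rows are dropped
  under the default `forbid` policy or re-aligned globally
  (Biopython PairwiseAligner) under `count_as_mismatch`, each gap column
  counted as a mismatch at the nearest spacer position.
* Locus files with a stated orientation carry crRNA-oriented sequences
  (database convention); only arrays resolved from `unknown` are flipped.
* The consensus rule, overlap-dedup rule (lowest mismatch, then leftmost)
  and the promoter-margin threshold are this package's choices where the
  original workflow left them unstated; all are parameters.
* Sequence-logo images are not rendered; the numeric PFM/IC block in the
  report is the supported surface.

## Limitations

* The promoter scorer is a stand-in adequate for deciding between two
  flanks, not a promoter predictor; real predictions should be passed as
  `external_call`.
* No E-values or alignment statistics: the exhaustive search is exact under
  its mismatch model, and subject sets are expected to be curated pools
  (tens of Mb at most), not nt-scale databases.
* 3'-PAM systems are not first-class: downstream flanks are recorded, but
  defaults, consensus and candidates all target the 5'-PAM Type I-B
  convention.
* Interference tolerating PAM-only removal with an intact protospacer is a
  design assumption (supported by the knock-in architecture it mirrors),
  not something the validator can prove.
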