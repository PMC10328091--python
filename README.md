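# pamflow

Predicting protospacer adjacent motifs (PAMs) of endogenous CRISPR/Cas
systems from the match history recorded in their own arrays, and turning a
validated PAM into genome-editing designs for Type I-B systems.

## The problem

Many genetically recalcitrant bacteria (acetogens such as *Acetobacterium
woodii* and *Clostridium autoethanogenum* among them) carry native Type I-B
CRISPR/Cas machinery that can be repurposed for genome editing — no toxic
heterologous nuclease needed. The blocker is the PAM: interference only
fires when the target carries the system's protospacer adjacent motif, which
differs between systems and is rarely known.

The spacers in a host's CRISPR array are fossils of past invaders. Finding
their protospacers in phage/plasmid sequence and reading off the 5'-flanking
bases yields PAM candidates, provided false-positive matches are filtered
hard:

* **global filter** — mismatch fraction strictly below 20% between spacer
  and protospacer;
* **seed filter** — at most one mismatch in the seven PAM-proximal (seed)
  nucleotides, where interference is decided;
* **MGE filter** — only hits attributable to mobile genetic elements count:
  title keywords (*phage*, *plasmid*), predicted prophage intervals, or
  overlapping annotations (*transposase*, *phage*, *integrase*,
  *terminase*).

From the retained hits' upstream flanks the package compiles a position
frequency matrix, a degenerate IUPAC consensus, per-position information
content IC(j) = 2 + Σ_b p_b log₂ p_b (bits), and ranked short-motif
candidates — only when at least two MGE hits contribute.

The design layer turns a validated PAM into: interference-assay constructs
(candidate PAM vs native repeat flank, both + protospacer + 3' repeat
flank), spacer candidates (bases 3' of a PAM occurrence, GC within 40-60%),
synthetic CRISPR arrays (leader + repeat + spacer + repeat), homology-arm
editing templates with validators (in-frame = deletion length ≡ 0 mod 3
inside a CDS; escape from self-targeting = the edited locus contains neither
PAM+protospacer nor its reverse complement), predicted screening-amplicon
size differences, degenerate restriction–modification site scanning
(default 5'-TAAGN₅TCC-3'), and the Pfaffl expression ratio
E_t^(−Cp_t) / E_r^(−Cp_r) for qPCR characterization.

## Worked example

`examples/predict_pam.py` plants 20 protospacers behind a 5' CCA PAM in a
synthetic invader pool, then runs the full pipeline (orient → search → MGE
filter → PAM call):

```
hits retained after filtering : 20
status                        : ok
consensus (positions -5..-1)  : NNCCA
top trinucleotide candidates  : [('CCA', 20)]
information content (bits)    : [0.01, 0.14, 2.0, 2.0, 2.0]
```

All 20 planted protospacers are recovered with zero false positives; the
three PAM-proximal positions read CCA at the maximal 2.0 bits each (fully
conserved), while positions −5/−4 are background noise near 0 bits.

`examples/design_deletion.py` designs a 300 bp in-frame deletion against
that PAM:

```
edit              : deletion of 300 bp
spacer            : ACGTTGCAGGCTAATCGTCAGGCATTGACTAATGCA (+)
PAM used          : CCA
spacer GC         : 0.47
synthetic array   : 196 bp (leader 100 + 2x repeat 30 + spacer 36)
homology arms     : 471 / 491 bp
flags             : {'in_frame': True, 'target_destroyed': True, ...}
amplicons         : WT 1262 bp vs edited 962 bp -> delta 300 (consistent=True)
```

`target_destroyed=True` means the deleted region carries the
PAM+protospacer, so the edited chromosome escapes self-targeting — the
selection that makes endogenous-CRISPR editing work. The other examples
cover array orientation (`orient_array.py`), interference-assay construct
pairs (`interference_constructs.py`), and R-M scanning plus expression
ratios (`scan_rm_and_expression.py`).

## Inputs

* subjects as FASTA (headers after the id token become the title used for
  keyword classification);
* the CRISPR locus as a small key/value text file
  (`direct_repeat <seq>`, one `spacer <seq>` line per spacer in array
  order, optional `orientation`/`leader`/coordinates — see
  `pamflow.model.read_crispr_locus`);
* optional prophage intervals as BED3 and features as a TSV
  (`record_id/start/end/strand/kind/label`);
* optionally, externally computed hits in 12-column tabular alignment
  format instead of the internal search (`import_tabular_hits`), refiltered
  through the same rules.

All coordinates are 0-based half-open; reports add 1-based presentation
columns. Output is a byte-stable TSV (hit table + consensus block), with
CSV and spreadsheet export available.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computations from
scratch: it generates the planted-PAM invader pool, executes the complete
prediction pipeline, designs and validates an in-frame deletion, and writes
the results JSON.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
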