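# Methods

## The screen

The package classifies candidate L1 locus sequences against a reference L1
element. A locus is a *screen hit* when it is (i) full-length, (ii) carries
an intact ORF1 (no premature stops, frameshifts or in-frame gaps, start
codon present), and (iii) carries an ORF2 that is free of frameshifts and
gaps but contains at least one premature stop codon. For hits, the first
premature stop at reference amino-acid position *k* predicts a truncated
ORF2 protein of *k*−1 residues; the prediction is annotated with the
complete domains retained (EN, z, RT, Cys in 5′→3′ order), the domain the
stop falls inside, an endonuclease-functionality flag, and the status of
the putative NLS motif.

The biological reasoning behind criterion (ii) is that a premature stop in
ORF1 suppresses ORF2 translation from the bicistronic transcript, so only
loci with an intact ORF1 are plausible sources of truncated ORF2 protein.

## Reference models

A `ReferenceModel` pins everything the screen measures to one coordinate
system: ORF1/ORF2 nucleotide spans, ORF2 domain boundaries (human: EN 239,
z 490, RT 773, Cys to the 1275-aa end; mouse: EN 258, Cys to the 1280-aa
end), catalytic EN residues {14: N, 43: E, 205: D, 230: H} and the KKKR
motif at aa 382–385. All coordinates are 1-based inclusive. The Cys
boundary (total ORF2 length) is always read from the loaded sequence, never
hard-coded.

The packaged sequences are **synthetic**: codon-level random sequences,
deterministic given a fixed builder seed, with every screen-relevant
coordinate pinned (start codons, stop-free ORF interiors, terminal stops,
catalytic residues, NLS codons). They reproduce the published coordinate
geometry of the human L1.3 and mouse L1spa elements without redistributing
archived accessions, and they are what makes the test suite self-contained.
A user-supplied reference FASTA replaces the packaged sequence but must
pass the same load-time assertions (stop-free ORFs; catalytic and NLS
residues at their model coordinates); any mismatch raises an integrity
error rather than silently renumbering.

Consequence: results that depend only on coordinate geometry (domain
retention, stop mapping, recovery rates) transfer directly to real
references; results that depend on nucleotide composition (e.g. alignment
scores in repetitive regions) do not, and are not claimed.

## Alignment

Locus-vs-reference comparison is a global nucleotide alignment with affine
gap scores (defaults: match +2, mismatch −3, gap open −11, gap extend −1).
Nucleotide-level alignment is deliberate: protein-level alignment would
mask frameshifts, which are a screen criterion.

Two engines share one output contract:

* **`full`** — Needleman–Wunsch/Gotoh over the whole pair (Biopython
  `PairwiseAligner`). Exact but ~0.7 s per 6-kb pair.
* **`anchored`** (default) — a unit-cost global alignment (edlib, ~2 ms)
  supplies exact-match runs ≥ 24 nt as anchors (4 nt released at each
  edge); the windows between anchors are realigned with the affine aligner
  at the configured scores and the pieces stitched. For reference-like
  loci (the screen's domain of application) this reproduces the full
  engine's indel events at ~1/100 the cost; the equivalence is asserted in
  the test suite on mutated windows.

Determinism and tie-breaking: when both sequences advance between aligned
blocks, reference-consuming columns (deletions) are emitted before
insertions; afterwards every gap run is left-normalised (shifted 5′ while
the flanking base equality preserves the score), so gap placement in repeat
runs is unique and repeated runs are byte-identical.

Terminal gap runs are not indel events: a 5′-truncated locus is described
by `reference_coverage` and `five_prime_offset` (and rejected by the
full-length test, defaults coverage ≥ 0.90 and offset ≤ 50 nt) rather than
reported as one giant deletion. A locus covering < 10% of the reference is
returned as a `NOT_COVERED` sentinel, not an error.

## ORF classification

Within an ORF span (skipped with `NOT_COVERED` when < 50% of the span is
aligned): indels with length ≢ 0 (mod 3) are frameshifts; in-frame indels
(length ≥ 3, ≡ 0 mod 3) are gaps — the cleanest codon-level reading of the
"no gaps or frame shifts" criterion, stated in all outputs. The locus is
then read codon-by-codon in the *reference* frame (the locus base aligned
to each reference position; deleted or ambiguous positions yield X, never a
stop) and every `*` strictly before the reference's own terminal stop is a
premature stop. Stops are enumerated even downstream of a gap (translation
is resumed in the reference frame), but GAP outranks PREMATURE_STOP in the
verdict, matching the screen's exclusion of gapped ORF2s. A missing start
codon is checked for ORF1 only by default — ORF2 initiation is internal and
mechanistically unsettled — and is configurable. Runs of N-derived X
residues are reported separately (`n_run_spans`) as advisory; only indels
drive gap/frameshift verdicts, since whether "gaps" meant assembly gaps or
alignment deletions is ambiguous in the source criteria.

A locus failing several criteria is attributed to the first failing one in
screen order (full-length → ORF1 → ORF2), so the failure counts partition
the input.

## Truncation annotation

`truncated_length_aa = first_stop_aa − 1`. A domain is retained iff its
boundary ≤ the truncated length; a truncation landing exactly on a boundary
has no partial domain. EN status: `incomplete` if the truncation cuts the
EN domain; `impaired` if any covered catalytic residue differs from the
model (a definite defect outranks missing data); `indeterminate` if a
catalytic position is unaligned or ambiguous; else `functional`. The flag
is necessary-not-sufficient — it only asserts the absence of the four known
inactivating substitutions. The NLS check is a literal motif comparison
(exact KKKR by default; a `basic` mode accepts ≥ 3 of 4 K/R residues),
reported descriptively: nuclear localization of truncated ORF2 proteins is
known to persist after motif mutation, so no functional claim is attached.

## Synthetic cohorts

The generator emulates the locus universe the screen assumes: each locus is
the reference element plus (a) class-defining injected mutations and (b) an
i.i.d. per-site background substitution process. Classes: `screen_hit`
(1–3 nonsense codons in ORF2, none in ORF1), `intact_both_orfs`,
`orf1_broken` (ORF1 nonsense or 1–2-nt frameshift, half the time also an
ORF2 stop, exercising precedence), `orf2_frameshift`, `orf2_gap` (in-frame
indel of 3–24 nt) and `truncated_5p` (5′ deletion of ~12% of the element up
to the end of ORF1, always failing the admission test).

Defaults: class mix {hit 0.25, intact 0.15, ORF1-broken 0.20, frameshift
0.15, gap 0.10, truncated 0.15}; background rate 0.02 substitutions/site (a
round figure for moderately diverged full-length copies — no divergence
estimate exists for the real screened loci, so this is a repository choice);
stop positions uniform on aa [2, ORF2 length]. A `figure2_like` sampler
weighting early ORF2 positions is provided for visual comparison only — the
empirical first-stop histogram has no published generative form.

Constrained background (default) re-draws any substitution that would
create an ORF stop and skips start-codon sites, so ground-truth labels stay
exact at any rate; an unconstrained mode lifts this for stress testing.
Indels are never part of the background. Each locus draws from its own
counter-derived stream (`default_rng([seed, index])`), so locus *i* is
identical for any cohort size. Not modelled: transition/transversion bias,
rate heterogeneity, 5′ inversions, 3′ transductions, subfamily structure —
passing tests therefore demonstrate correctness of the screen's logic on
reference-like inputs, not robustness to deep evolutionary divergence.

## Problem sizes and numerical choices

The validation suite uses cohorts of 40–1000 loci (alignment ~10 ms/locus
with the anchored engine); the oracle-equivalence check runs 1000
substitution-only loci against a naive direct-translation scan, and
ground-truth recovery uses a 200-locus mixed cohort at zero background,
both exact by construction of the constrained generator. Histogram bins
default to 100 aa (the empirical figure's binning is not stated
numerically; the width is a config knob printed in every report).
Degenerate inputs: loci < 100 nt are rejected; empty FASTA yields an empty
report with a warning; a failing single locus yields a failure rationale,
never a batch crash.

## Known limitations

* The headline census of the original database query (92 human / >500
  mouse loci) depends on a specific L1Base release and genome assembly; the
  pipeline reports its own counts on whatever input it is given and makes
  no claim to reproduce those numbers.
* One reference model per run; no multi-subfamily consensus handling.
* No genome-wide L1 discovery: input is a pre-extracted locus FASTA
  (optionally with a BED for strand orientation).
* No protein stability, proteolysis, toxicity or localization prediction
  beyond the descriptive motif check.
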