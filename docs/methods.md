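# Methods

## Scope and model

`aquasig` treats aquaporin characterisation as a rule-matching problem
over a small set of named residue positions, and expression profiling
as a deterministic chain from raw amplification curves to calibrated
relative quantities.  This note records the models, the defaults and
why, what the synthetic generators do and do not emulate, and the
design choices made where the design was genuinely open.

## Reference annotation and coordinate system

All residue extraction is *alignment-anchored*: a query is aligned
globally to a single annotated reference per class (PIP or TIP) and
every named coordinate is transferred through the alignment columns.
Topology prediction is never used to locate signature residues —
hydropathy methods are known to misplace sites near helix boundaries
(the conserved loop-D Leu is the classic case), so topology output is
advisory only.

Coordinates are 1-based and inclusive.  The named positions are:

| block | content | PIP reference | TIP reference |
|---|---|---|---|
| `npa` | loop-B window (10 aa, NPA−5 anchored), loop-E window (11 aa, NPA−4 anchored) | 112–121, 236–246 | 82–91, 198–208 |
| `arr` | Ar/R filter H2 (TM2), H5 (TM5), LE1, LE2 | 98, 216, 237, 243 | 60, 185, 199, 205 |
| `froger` | P1–P5 | 170, 222, 230, 263, 269 | 211, 214, 216, 222, 230 |
| `sites` | gating/modification sites | loop-B Ser 112, C-term Ser 287, loop-D His 204, loop-D Leu 208, methylation Lys 3 / Glu 6 | loop-B phosphosite Thr 97, loop-D Ile 168 |
| `permeability` | TM2 / loop-E water-permeability pair | 103, 249 | — (PIP-specific) |
| `sdp` | per-substrate SDP coordinate lists (9 each) | four substrates | two substrates (boric acid and CO₂ undefined for TIPs) |

The loop windows overlap other named positions by construction (the
loop-E window contains LE1, LE2 and NPA letters; some SDPs fall inside
windows).  Mismatch counting therefore de-duplicates by reference
coordinate, so one mutated residue is one mismatch regardless of how
many views contain it.

The shipped reference sequences are synthetic: six hydrophobic
segments (24–29 aa) joined by hydrophilic linkers, carrying the
published signature residues of the exemplar groups (FaPIP1;1,
FaTIP(a)) at the annotated coordinates.  They are explicitly labelled
synthetic; a user with a real translation (e.g. a GenBank entry) can
substitute the `[reference] sequence` in the config, keeping
coordinates aligned.

## Rule tables

Two SSSS sources ("hove", "azad") and one SDP source ("hove") ship as
plain-text configs.  A rule constrains the loop-B window, loop-E
window, Ar/R filter and Froger string (`X` = unconstrained position);
an SDP rule lists nine coordinate:residue pairs, with `/`-separated
alternatives where the published listing admits more than one residue.
Rules are data, not code: the two sources intentionally disagree
(azad defines no boron signature for PIPs or TIPs and no urea
signature for PIPs, and its TIP signatures are stricter), and both
verdict columns are always reported side by side.

Verdicts per (source, substrate): **match** (every defined position
agrees), **near-miss** (exactly one mismatching position — reported,
never counted as a match), **mismatch**, **not-defined** (source has
no rule for the class/substrate), **not-comparable** (a gap at a rule
position).  The TIP/ammonia SDP entry is deliberately absent from the
shipped SDP config: the published SDP listing excludes the TIPs
considered here, and encoding it as "not defined" lets the consensus
carry the ammonia prediction for the TIP(b) group, matching the
published conclusion.  This tension between the SDP residues and the
full-correspondence summary is documented here rather than resolved.

### Consensus policy

The default policy, `abstain-on-undefined`, requires a defined,
matching SSSS from *every* SSSS source, while an SDP source that
defines no rule abstains.  The rationale: the SSSS is each source's
primary signature and a source that withholds one for a class has
judged the evidence insufficient (a veto), whereas SDP lists are
*additional* constraints applied where published.  A pure
"any undefined source abstains" reading would predict urea and boron
for several PIP groups against the published summary; the asymmetric
rule reproduces the full-correspondence conclusions exactly.
`strict-intersection` (every source must define and match) is
available via `--policy`; it is always a subset of the default.

## Topology

Kyte–Doolittle hydropathy, sliding window of 19 (the classic TM
setting), shrunken windows at the ends.  Helices are maximal runs of
score ≥ 1.6, merged across gaps of ≤ 3 residues, kept at length ≥ 15.
With exactly six helices the inter-helix loops are labelled A–E, else
numerically.  The thresholds are calibration choices of this package
(the quantity they gate — helix count — is checked against the
six-helix expectation for full-length sequences); they were chosen so
that clean six-segment scaffolds of ≥ 24-residue segments are called
exactly six across the generator's seed space.

## Alignment and classification

Pairwise global alignment uses biopython's `PairwiseAligner`
(BLOSUM62, gap open 10, extend 0.5); the first alignment of its
deterministic enumeration is taken, so outputs are bit-reproducible.
Distances for trees are p-distances with pairwise deletion (a Poisson
correction is available behind a flag); neighbor joining is the
standard Saitou–Nei agglomeration with the Q-criterion, ties broken by
the lowest current index pair and negative branch lengths clamped to
zero.  Trees are unrooted; Newick output carries fixed-precision
branch lengths and no internal labels.

Clade assignment labels a query by the smallest label-pure clade
containing it, over all bipartitions whose defining edge has positive
length — zero-length edges encode arbitrary resolutions of ambiguous
attachments and define no clade.  Purity over a whole clade (rather
than a nearest-leaf rule) is robust to single misplaced panel taxa; a
query attached outside every pure clade stays `unknown`.

## qPCR chain

* **Efficiency.**  Per well: baseline and noise band from cycles 1–5
  (mean, mean + 10 SD); exponential phase = readings between the noise
  band and half the plateau; among contiguous windows of length 4–6
  the one maximising R² of log₁₀(F − baseline) vs cycle is chosen,
  then the baseline is refined on that window by maximising the same
  R² (this recovers curves that are already exponential at cycle 1,
  where the early-cycle mean contains signal).  E = 10^slope; the
  target estimate is the arithmetic mean over wells; windows with
  R² < 0.99 are flagged.  All constants are this package's defaults —
  the window-of-linearity idea is standard but proprietary settings
  are not published.
* **Cq.**  Threshold = 10 × noise band (or user-supplied), crossing
  located by log-linear interpolation; a curve that never crosses is
  censored, and censoring propagates (never imputed).
* **noRT rule.**  A sample is dropped when Cq(noRT) − Cq(sample) < 5;
  a censored noRT (no amplification) keeps the sample.
* **geNorm.**  M_j = mean over other candidates k of the SD across
  samples of log₂(RQ_j/RQ_k); iterative exclusion of the highest M
  until two remain; requires ≥ 3 complete-case candidates; ties break
  by input order (the later candidate drops first).
* **CNRQ** (qBase convention): RQ_{s,t} = E_t^(mean Cq_t − Cq_{s,t});
  NRQ = RQ / geometric mean of the reference-target RQs of the sample;
  CNRQ = NRQ / per-target geometric mean over samples, making the
  per-target geometric mean exactly 1 (asserted to 1e-9) and the
  result invariant to any constant Cq shift per target.
* **Statistics.**  Group comparison uses log₁₀ CNRQ (the log base is a
  package choice).  The Brown–Forsythe robust equality-of-means form
  is implemented — F* = Σnᵢ(mᵢ−m)² / Σ(1−nᵢ/N)sᵢ², Satterthwaite
  denominator df — because that is the "robust test of equality of
  means" sense of the name; with equal group sizes it reduces exactly
  to the classic one-way F.  Scheffé post hoc: a pair is significant
  when its contrast F exceeds (k−1)·F_crit(α; k−1, N−k), conservative
  by construction.  At n = 3 per group the test is conservative
  (null rejection ≈ 0.03 at α = 0.05 in a 10,000-rep simulation).

## Synthetic data

`make_group_sequence` builds one sequence per expression group:
signature residues fixed at annotated coordinates, linkers taken from
a deterministic per-subtype scaffold and mutated per-site with
probability 0.08 within the segment's own alphabet (hydrophobic
I/L/V/F in helices, hydrophilic elsewhere), then any incidentally
spelled extra NPA is deterministically broken.  The PIP2 scaffold
derives from the PIP1 scaffold by mutating 30 % of sites — real
subtypes diverge genome-wide, and without that the handful of
signature residues would be swamped by linker noise in any tree.
Everything is a pure function of (parameters, seed).

The qPCR simulator uses a logistic curve whose exponential-phase
fold-change per cycle equals the design's efficiency and whose
midpoint encodes the expression level, so a 2× level difference shifts
Cq by exactly log_E 2 cycles; multiplicative lognormal noise (default
σ = 1 %) on the signal and half that on the baseline; noRT wells
amplify a configurable number of cycles late; NTC wells never
amplify.  The default design mirrors the study conditions: seven
tissue classes × 3 replicates, eight target groups with the published
efficiencies (1.786–2.081), two stable reference genes at E = 1.911
plus two unstable candidates, programmed fold-changes in {¼, ½, 1, 2,
4} echoing leaf-/fruit-specific patterns.

What the generators do **not** emulate: real inter-replicate
biological variance (levels are exact per tissue), allele dosage in
the octoploid genome, sequencing error, primer artefacts, melt
behaviour, or genuine phylogenetic signal beyond the scaffold
construction.  Passing tests therefore demonstrate correctness of the
computations under known ground truth, not performance on noisy field
data.

## Numerical choices and degenerate inputs

Problem sizes in the test suite and acceptance script (a 21-sample ×
12-target plate, 100 additive matrices of 4–5 taxa, 10,000 null
replicates) were chosen so the full suite completes in well under a
minute while every stage is exercised end to end.  Degenerate inputs
degrade explicitly: gaps at rule positions → `not-comparable`;
sequences too short for a profile → annotation continues with a
warning and no topology; a flat amplification curve → well excluded
with reason; all wells excluded, missing reference Cq, fewer than
three geNorm candidates, or a pair of sequences with no comparable
columns → errors naming the offender.

## Known limitations

* The residue classifier covers PIP and TIP only; NIP/SIP/XIP filters
  return `unknown` by design.
* SSSS window boundaries and parts of the SDP rule residues were
  transcribed from a printed layout whose mismatch highlighting does
  not survive text extraction; positions where published matchers
  disagree carry explicit alternatives, and the transcription is
  regression-locked by the fixture grid tests.
* Clade assignment requires equal-length input (an alignment); the
  package deliberately does not build multiple sequence alignments —
  pairwise-to-reference only.
* The Brown–Forsythe/Scheffé pair assumes approximate log-normality
  of CNRQ; no multiple-testing correction beyond Scheffé is applied.
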