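# aquasig

Sequence-based characterisation of plant aquaporins (MIP water
channels) and the matching RT-qPCR relative-expression workflow, built
around the strawberry (*Fragaria × ananassa*) PIP/TIP aquaporin family.

Plant aquaporins are six-transmembrane channel proteins whose substrate
range (water, H₂O₂, urea, boric acid, CO₂, ammonia) is encoded by a
handful of conserved residues: the duplicated NPA motifs in loops B and
E, the aromatic/Arginine (Ar/R) selectivity filter (H2, H5, LE1, LE2),
Froger's positions P1–P5, and additional specificity-determining
positions (SDPs). `aquasig` turns that knowledge into a reproducible
pipeline:

* **Classification** — plasma-membrane (PIP1/PIP2) vs tonoplast (TIP)
  subfamilies, called twice and cross-checked: from conserved residues
  (Ar/R filter FHTR ⇒ PIP, with the TM2/loop-E permeability pair
  splitting PIP1 from PIP2; HIAR/HIGR ⇒ TIP, with loop-B RXSXXR/TXXR
  motifs resolving α-/δ-TIP subtypes) and from neighbor-joining clade
  placement against a labelled reference panel.
* **Substrate prediction** — residues extracted at annotated reference
  coordinates are matched against substrate-specific signature
  sequences (SSSS) from two published sources ("hove", "azad") and
  against SDP lists; per-source verdicts (match / near-miss = exactly
  one mismatching position / mismatch / not-defined / not-comparable)
  are combined into a consensus.
* **Topology** — Kyte–Doolittle sliding-window hydropathy with helix
  calling, loop labelling (A–E) and NPA-placement sanity checks.
* **qPCR quantification** — amplification efficiency per target from
  the best log-linear window of the exponential phase, Cq calling,
  the noRT exclusion rule (drop a sample when Cq(noRT) − Cq(sample) <
  5), geNorm reference-gene stability (M values), calibrated
  normalized relative quantities (CNRQ: RQ normalised to the geometric
  mean of the reference-gene RQs, calibrated so the per-target
  geometric mean over samples is 1), and Brown–Forsythe robust
  equality-of-means tests with Scheffé post hoc contrasts on log₁₀
  CNRQ.
* **Synthetic data** — generators for signature-bearing six-helix
  scaffold sequences (one per expression group, plus labelled panels)
  and for logistic-curve qPCR plates with known efficiencies, tissue
  fold-changes and noRT offsets, so every stage is testable offline
  with known ground truth.

## Worked example

```bash
aquasig simulate --out sim --seed 42        # fixtures + simulated plate
aquasig annotate --input sim/groups.fasta --out ann
aquasig qpcr --curves sim/curves.csv --design sim/design.csv --out q
```

`ann/summary.tsv` (columns trimmed):

```
query        class  arr   froger  permeability    consensus
FaPIP1;1     PIP1   FHTR  ESAFW   low-PIP1-like   -
FaPIP1;3     PIP1   FHTR  QSAFW   low-PIP1-like   h2o2
FaPIP2;1(a)  PIP2   FHTR  QSAFW   high-PIP2-like  h2o2
FaPIP2;2     PIP2   FHTR  QSAFW   high-PIP2-like  -
FaTIP(a)     TIP    HIAR  TAAYW   undetermined    -
FaTIP(b)     TIP    HIGR  TSAYW   undetermined    ammonia,urea
```

Every group shows six predicted transmembrane helices and exactly two
NPA motifs.  All PIPs carry the FHTR filter; the Glu at Froger P1
keeps FaPIP1;1/FaPIP1;2 out of every signature, FaPIP2;2 misses the
boron/CO₂ signatures by a single loop-E residue (a reported
"near-miss"), and only FaTIP(b) carries the ammonia signature.  The
consensus column requires a defined match from every SSSS source while
SDP sources abstain where they define no rule.

The qPCR run prints `references: clathrin, CHP3` — geNorm keeps the
two stable candidates (both E = 1.911) and drops the unstable ones —
and `q/stats.tsv` flags exactly the targets simulated with tissue
contrasts (e.g. the leaf-specific group FaPIP1;3, Brown–Forsythe
p < 0.001) while the flat group FaPIP1;2 stays non-significant.

As a library:

```python
from aquasig import read_fasta
from aquasig.pipeline import annotate_records, summary_frame

results = annotate_records(read_fasta("sim/groups.fasta"))
print(summary_frame(results).to_string(index=False))
```

## Layout

```
src/aquasig/
  seqio.py       FASTA / alignment I/O and domain records
  refdata.py     reference annotations + SSSS/SDP rule tables (data/*.cfg)
  topology.py    hydropathy profiles, TM helix and loop calling
  extraction.py  global alignment, coordinate transfer, residue extraction
  classify.py    residue rules, p-distances, neighbor joining, clades
  substrates.py  SSSS/SDP matching, consensus, permeability, gating
  qpcr.py        efficiency, Cq, noRT, geNorm, CNRQ, robust statistics
  synth.py       synthetic sequence and qPCR plate generators
  pipeline.py    annotate / qpcr orchestration and report frames
  cli.py         click CLI (annotate | qpcr | simulate)
```

The shipped reference sequences are synthetic scaffolds (labelled as
such) carrying the published signature residues at annotated
coordinates; `docs/methods.md` explains the model, the rule-table
transcription and the generators' assumptions in detail.
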