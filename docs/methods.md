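# Methods

This note documents the models, parameters and numerical choices behind
`rdhc-miner`, and what the synthetic benchmarks do and do not demonstrate
about real data.

## Sequence model and alphabet

All components operate on the 20 standard amino acids.  Ambiguity codes
(B, Z, X, U, O, J) are rejected at parse time because motif classes,
hydropathy values and residue masses are defined only over the standard
alphabet; a permissive mode masks them to `X`, a character that no motif
element (including the wildcard) matches and that mass computation
refuses, so masked windows drop out of analyses rather than contaminating
them.  Structural junk (non-letters) is reported before ambiguity codes,
each with its 1-based position.  All coordinates throughout the package
are 1-based with inclusive ranges, following protein-literature
convention.

## Degenerate motifs

A motif is an ordered list of residue sets: plain residues, bracketed
alternatives (`[ST]` or `[S/T]`), and `X` for the full alphabet, with
repetition written `X3`, `X(3)` or `X_3_`.  Three signatures are built in:

| name | pattern | acceptor | uniform match probability / window |
|---|---|---|---|
| `FMN_CONSENSUS` | [S/T]G[A/S]TX[S/T] | element 4 (Thr) | 160 / 20⁶ = 2.5·10⁻⁶ |
| `FTP_MOTIF` | [DN]X₂[ST]G[AS]TX[ST] | element 7 (Thr) | 128,000 / 20⁹ = 2.5·10⁻⁷ |
| `CX3CP` | CX₃CP | – | 8,000 / 20⁶ = 1.25·10⁻⁴ |

Scanning reports **all** occurrences, including overlapping ones: nothing
in the family definition excludes overlap, and one protein can carry
several motifs.  The match probability is the product of element sizes
over 20^length; the test suite confirms the hexamer count for the family
consensus by exhaustive enumeration and by Monte-Carlo scanning of 10⁶
uniform windows.

Column profiles (for logo-style analysis of aligned family members)
compute per-column residue frequencies over non-gap characters and
information content IC = log₂20 − H bits.  Gaps are excluded from both
frequency and entropy by default; a flag scales IC by the non-gap
fraction instead.  No small-sample entropy correction is applied by
default — at the alignment sizes family curation produces (order 10²
sequences) the (s−1)/(2·ln2·n) term is below 0.07 bits — but the standard
correction is available by flag.  Consensus derivation emits, per column,
the smallest frequency-ordered residue set reaching a cumulative 0.9,
collapsing to `X` above 2 residues; these defaults mirror the shape of
the published family consensus, whose classes all have ≤ 2 members.

## Topology

Transmembrane detection is a deliberately transparent hydropathy model,
not a re-implementation of ensemble predictors: a centered Kyte–Doolittle
moving average (window 19), maximal runs ≥ 1.6 as helix candidates, runs
merged across dips ≤ 3 residues, length bounds 15–30 with over-long runs
split at the internal profile minimum.  The profile is defined only where
the full window fits; terminal residues inherit the nearest defined
score, which prevents phantom helices at chain ends.  Loops alternate
inside/outside from the N-terminal side; each helix crossing flips the
side.  Orientation defaults to the positive-inside rule (maximize K+R in
inside loops; ties inside) and can be forced, which is recommended when
reproducing a known architecture.

Because this is a hydropathy heuristic, agreement with ensemble
predictors on real proteins is not guaranteed; the recovery guarantees
stated below are for the synthetic architectures, whose hydrophobic
contrast is controlled.

## Surface shaving

Digestion is strictly tryptic (cleave after K/R, not before P; no
semi-tryptic products); peptides with 0 missed cleavages tile the parent
exactly, and up to `max_missed` joins of consecutive peptides are
enumerated.  A peptide is *exposed* / *cytoplasmic* / *membrane* when its
residue fraction in O / I / H loops reaches the exposure threshold
(default 1.0 — whole-peptide localization, matching how shaving
experiments report entire peptides; configurable down to 0.5), else
*mixed*.  Peptides
outside the 6–40-residue window are flagged undetectable, a typical MS
observability range.  The topology verdict follows the shaving logic: a
shaved (whole-cell) detection set **supports** the topology when it
contains at least one exposed peptide and no cytoplasmic peptide;
any shaved cytoplasmic peptide refutes it; neither present is
uninformative.  The detection simulator is Bernoulli per detectable
peptide (sensitivity for true-compartment detection, leakage for lysis
contamination), seeded and reproducible; no intensity model.

## Identity clustering and family curation

Pairwise identity uses a global alignment with match +1, mismatch 0,
affine gaps −10 open / −0.5 extend, normalized by the **shorter** sequence
length (the CD-HIT convention; an alignment-column denominator is
available).  With this denominator, a truncated copy scores identity 1.0
— documented behaviour, not a bug.  Greedy clustering processes records
by descending length (ties lexicographic by id) and joins the first
cluster whose representative matches at ≥ threshold (default 0.95),
giving a deterministic partition.  A residue-composition upper bound
(`Σ min(countsᵃ, countsᵇ) / shorter`) is used to skip alignments that
provably cannot reach the threshold; the bound is exact-safe, so results
are identical to the unpruned computation (verified against an oracle
that replays the rule from the full identity matrix).

Family membership of a single protein is the structural rule: ≥ `min_tm`
helices (default 3, reading "multiple transmembrane segments"
conservatively — the canonical member has 6), at least one FMN-consensus
hit whose acceptor threonine lies in an **outside** loop, and ≥ 2 CX₃CP
hits.  Every failed clause yields a machine-readable reason code.
Curation then clusters accepted candidates and retains clusters with at
least one member from a genome encoding a reductive dehalogenase (rdhA);
members from rdhA-less genomes inside retained clusters are flagged but
kept.  This motif+topology classifier is the candidate source for the
pipeline; it replaces any external homology-search step, which is the one
deliberate substitution in the curation flow.

## Flavinylation mass arithmetic

All masses derive from elemental compositions (pyteomics): FMN
C₁₇H₂₁N₄O₉P = 456.3445 Da average / 456.1046 Da monoisotopic; water
18.0153 / 18.0106 Da; proton 1.00728 Da.  Covalent flavinylation adds
FMN − H₂O: **+438.33 average / +438.0940 monoisotopic** per site.  Intact
proteoforms are reported on the average-mass scale (the scale of
deconvoluted intact-protein spectra); peptides and fragments are
monoisotopic, consistent with the default search tolerances of 0.050 Da
(fragment) and 10 ppm (parent).  N-terminal Met excision follows the
methionine-aminopeptidase rule — remove the initiator Met iff residue 2
is one of A/C/G/P/S/T/V — and can be forced on or off.

The modification registry (carbamidomethyl-C fixed; oxidation-M,
pyro-Glu from N-terminal Q, phospho-S/T/Y and FMN-T variable) stores
per-mode deltas computed from formulas.  Variable-modification
enumeration yields all combinations of ≤ `max_var` site assignments, one
modification per site.  Fragment annotation generates singly charged b/y
series (modification deltas carried by the containing fragment; higher
charges as (M + z·H⁺)/z behind a flag) plus diagnostic flavin ions —
FMN+H 457.1119, FMN+H − H₂O 439.1013, FMN+H − HPO₃ 377.1456 m/z, a
user-replaceable table since diagnostic-ion conventions vary.  Matching
assigns each observed peak to at most one theoretical ion (closest within
the fragment tolerance); the parent verdict compares the deconvoluted
parent mass within the ppm tolerance.

## Synthetic data: what it emulates, what it does not

The generator plants the full family architecture: N-in layout of
I-loop – TM1 – FBD(O) – TM2 – alternating loops/TMs – C-terminal loop;
one FMN-consensus instance inside the FBD (wildcard positions avoid
cysteine, and the residue three positions upstream is kept out of {D,N},
so planted CX₃CP counts stay exact and the family consensus remains
distinguishable from the longer trafficking motif); two CX₃CP copies in
the most C-terminal loops.  Helices are 23–30 residues drawn from
{I,L,V,F,A,M} weighted toward I/L/V (mean hydropathy ≈ 4.0): with window
19 and threshold 1.6 this leaves every helix an above-threshold run
comfortably longer than the 15-residue minimum, the documented contrast
under which planted-count recovery is exact.  Loops draw from a
cysteine-free polar alphabet with K/R enriched 3× inside and depleted to
0.1× outside, making the positive-inside decision effectively
deterministic; the FBD additionally receives evenly spaced planted K/R
tryptic sites (every ~35 residues, outside the motif footprint) so the
exocytoplasmic domain yields MS-observable peptides, as the real domain
does.  Decoys are i.i.d. uniform over the 20 residues with log-uniform
lengths 80–800, which makes the enumerated motif false-positive rates
exact.  Default proteome composition follows the benchmark scenario:
five genomes, one lacking rdhA, with exactly one planted family member
assigned to the rdhA-less genome.

Mutation families apply category-preserving point substitutions
(hydrophobic↔hydrophobic, polar↔polar) at non-planted positions until the
identity to the seed lies in [target − 0.01, target]; planted positions
are immutable and an unreachable target is an error.  Synthetic spectra
jitter all theoretical ions with Gaussian m/z noise and add uniform noise
peaks, with truth stored.

These benchmarks demonstrate internal correctness — that the pipeline
recovers exactly what was planted under controlled contrast — not
real-world sensitivity: real membrane proteins have weaker and more
variable hydrophobicity contrast, compositionally biased backgrounds
(decoy false-positive rates will differ from the uniform-background
numbers), signal peptides and re-entrant loops the topology model ignores,
and real shaving data carry detection biases no Bernoulli model captures.

## Problem sizes

The shipped test suite runs the complete stack in well under a minute:
exhaustive enumeration of all 64 million hexamers, a 10⁶-window
Monte-Carlo scan, 10⁴ brute-force scan comparisons, a 500-protein
end-to-end curation with 25 planted members, and 2,000-seed spot checks
were used during development to bound the generator's failure rates
(0 / 2,000 misclassified architectures; 0 / 500 shaving verdicts off).

## Known limitations

* Identity definition (global, shorter-length denominator) is one of
  several defensible conventions; published cluster counts obtained with
  unknown tools are therefore not exact targets.
* The topology model has no signal-peptide or lipoprotein-anchor logic.
* Spectrum annotation covers singly charged b/y + diagnostics only; no
  isotope envelopes, no search-engine scoring, no FDR.
* `X`-masked sequences silently lose motif windows that span a mask —
  intended, but worth remembering when using permissive parsing.
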