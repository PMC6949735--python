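# Methods

## Scope and data model

The package analyses multi-compound, multi-target herbal formulas in four
stages: (1) ADME screening of per-herb ingredient catalogues, (2) conversion
of compound–target likelihood scores into an accepted interaction set,
(3) bipartite network construction and degree topology, (4) hypergeometric
over-representation of the target set. Identities are deliberate: compounds
are identified by catalogue id, targets by UniProt accession (gene symbols
are display metadata, normalized to uppercase), and graph nodes by the
(kind, id) pair so that the same accession in two networks is only the same
logical node after an explicit join.

Two reference tables are shipped as package data, transcribed verbatim from
their printed source including typographic quirks (the "Homosapiens"
organism spelling, Greek letters in compound names, gene symbols printed as
"IL-6"/"IL-4"). Transcribing verbatim keeps every downstream check bound to
the actual printed artifact; a `canonical_name` alias column carries cleaned
compound names.

## Drug-likeness scoring

DL is the continuous Tanimoto form T(x, y) = x·y / (‖x‖² + ‖y‖² − x·y)
between a compound descriptor vector and a reference-library centroid.
Numerical choices: dimension mismatch and non-finite entries raise; a
zero/zero input raises (the form is 0/0 there) rather than returning a
sentinel, because a silent 0 would be indistinguishable from genuine
orthogonality. The form is not scale-invariant; this is documented and
tested as a property of the score, not "fixed" by normalizing inputs.

## Half-life model

HL is an affine function of eight QSPR descriptors (nArCO, H7m, D/Dr09,
N-070, C-032, JGI6, nRC=N, Mor02e; identifier-safe spellings `DDr09`,
`N070`, `C032`, `nRCeqN`). The published coefficient listing is
typographically corrupted in its ± (standard-error) terms, so only the
leading point estimates are stored; no standard errors are kept, and the
whole coefficient set is overridable via the `hl_model.json` schema
(`intercept`, `coef` with exactly the eight names, optional `metadata` with
R² = 0.65, Q² = 0.62, F = 27.272, SEE = 8.127, N_training = 126,
N_test = 43 retained for provenance only). Where the source disagrees with
itself on a descriptor name (C-033 in the formula line vs C-032 in the
descriptor list), the descriptor list is taken as authoritative.

## Screening

Defaults: OB ≥ 30 %, DL ≥ 0.18, 4 ≤ HL ≤ 8 h; all comparisons inclusive and
performed on stored values with no re-rounding. Every record is tested on
all three axes and each violated axis recorded with a reason
(below/above/missing); a missing value fails its axis rather than passing
silently. The report partitions its input (pass ⊎ fail), which is asserted
structurally.

Applied to the shipped 41-compound catalogue, the strict screen retains 18
rows. The printed source nonetheless lists all 41 as bioactive — several of
its rows violate the stated bounds outright (e.g. rutin at OB 3.20, quercetin
at HL 14.40) and it offers no reconciliation. The package's position:
faithfulness to the stated method over the stated outcome. The screen stays
strict; reproducing the curated 41 requires the explicit
`--include-curated` fixture, and every retained-but-noncompliant row is
flagged in the audit. Retention percentages are half-up rounded to 2 dp only
at presentation (41/382 → 10.73).

## Target mapping and the synthetic edge-list fixture

Pairs with likelihood ≥ 7 are accepted (inclusive, matching the printed
rule; continuous simulated scores make ties measure-zero so the boundary
convention never matters in simulation). Deduplication is by accession;
degrees satisfy the handshake identity by construction and the operation is
idempotent.

The source prints both degree sequences of its C-T network (sums 367 on each
side) but not the edges. A concrete edge list is therefore reconstructed
once by a deterministic degree-sequence realization: a Gale–Ryser
feasibility check, then a greedy construction that processes compounds in
decreasing printed degree (ties by id) and connects each to the targets with
the largest remaining demand (ties by id). The result —
`data/ct_edges_synthetic.tsv`, labelled synthetic because the true edges are
unknown — reproduces both printed degree sequences exactly, and the test
suite regenerates it from the tables byte-for-byte. Degree-level statistics
on it (maxima, hub counts, handshake) are exact consequences of the printed
sequences; edge-level claims would not be identifiable and none are made.

## Network topology

Networks are typed bipartite graphs with set-semantics edges (duplicates
collapsed and counted), isolated declared nodes retained, and same-kind
edges rejected. Degree is the only centrality. The hub rule is
parameterized: threshold plus strict (`>`) or inclusive (`≥`) comparison,
with the rule always named in the report. This matters on the reference
network: at threshold 10 the target side has 8 hubs under the strict rule,
while the compound side has 6 strict hubs and reaches 8 only under the
inclusive rule (two compounds sit at degree exactly 10) — both printed "8"s
are reproducible, but only under different rules, so neither rule is
hard-coded. Mean degrees are kept unrounded internally (the printed
per-compound average of 4.7 matches neither 367/41 nor 367/94 and is not
targeted). Exports: SIF with ct/td/tp/tm interaction labels, GraphML with
node-kind attributes (round-trips counts), plain TSV.

The compound–target–function-module overlay merges module membership edges
onto the C-T graph; module edges to unknown targets are skipped and counted.
Its printed counterpart (140 nodes / 653 edges, with an internal 94-vs-95
target discrepancy) is not decomposable from printed data, so the merge is
validated on synthetic annotations by additive counting instead.

## Enrichment

For query size n from background N and a term of size K with overlap k, the
P-value is the upper tail P[X ≥ k] of Hypergeom(N, K, n), computed via
`scipy.stats.hypergeom.sf(k−1, N, K, n)` and verified against direct
summation of the mass function on every universe with N ≤ 12. Significance
is raw P < 0.05 by default — no multiple-testing correction, mirroring
common practice in this workflow — with Benjamini–Hochberg q-values behind
`--fdr` and an EASE-style variant (overlap reduced by one, the conservative
modified-Fisher score popularized by DAVID) behind `--ease` for sensitivity
analysis. The background defaults to the subjects of the supplied annotation
universe, not a genome; enrichment is background-sensitive and the default
is the only choice that requires no data the user did not provide. Ties in P
are broken by term id for stable output. Pathway results can be grouped into
five function modules (inflammatory, immune, metabolic,
bacterial-infection-or-mycosis, other); the module map must be a function,
and unmapped pathways land in "other function".

## Synthetic-data generator

The generator emulates the statistical shape of the real inputs, not their
chemistry (no structures or fingerprints; descriptor values are drawn, never
computed):

* **Catalogues** — four herbs with 190/87/57/48 ingredients (382 total) by
  default. OB ~ lognormal(median 25 %, σ = 0.8); DL ~ Beta(2, 5) (mode 0.2);
  HL ~ Gamma(shape 2, scale 3.575 h; median 6 h). Axes are independent, so
  the default-screen pass rate has the closed form
  P(OB ≥ 30)·P(DL ≥ 0.18)·P(4 ≤ HL ≤ 8) ≈ 0.100 — a stylistic calibration
  to roughly one-in-ten retention, chosen from these standard families, not
  a claim about any real catalogue. Empirical rates are tested against the
  closed form within 3 binomial SEs.
* **Likelihood matrices** — default 41 compounds × 94 targets. True pairs
  score ~ Normal(9, 1), background ~ Normal(3, 1.5); at the cutoff of 7 a
  true pair is accepted with probability ≈ 0.977 and a background pair with
  ≈ 0.0038, so planted hubs (defaults 73/35/26 true targets, echoing the
  printed top compound degrees) are recoverable by degree rank. Hub-target
  plantings draw their compounds from non-hub compounds so hub-compound
  degrees stay exactly as configured. Continuous scores make threshold ties
  probability-zero.
* **Annotations** — background terms include each subject with probability
  0.1; a term planted at odds ρ multiplies the inclusion odds of the
  designated query subjects by ρ, so ρ = 1 is exactly the null (used for
  type-I calibration) and ρ = 20 gives near-certain top rank (used for
  power).

One global seed expands into three independent substreams
(catalogue/likelihood/annotation) via `numpy.random.SeedSequence.spawn`, so
stages regenerate independently; emitted files use fixed float formatting
and are byte-identical under a fixed seed.

What passing synthetic tests does **not** show: real likelihood scores are
correlated across targets of one compound, real annotation terms overlap
hierarchically (GO structure), and real ADME fields are mutually dependent —
none of which the generator models. Calibration and recovery results
therefore validate the machinery, not field performance.

## Pipeline and problem sizes

The pipeline writes all stage outputs plus a manifest whose counts are
recomputed from the emitted files in tests; manifests contain no timestamps,
so fixed-seed reruns are byte-identical (paths inside the output directory
are stored relative to it). Any stage failure removes partial outputs and
names the stage.

Monte-Carlo sizes used by the test suite: 1000 null replicates for type-I
calibration, 200 replicates each for planted-hub and planted-term recovery;
the acceptance script uses 400/150/150. These sizes put 3·SE bands well
inside the tested margins while keeping a full run in seconds.

## Known limitations

* OB prediction, the ligand-similarity scoring algorithm itself, descriptor
  calculation from structures, and live database retrieval (TCMSP, UniProt,
  CTD/TTD/PharmGKB, DAVID) are out of scope; their outputs are inputs here.
* Caco-2/BBB/FASA fields are parsed but never thresholded (the workflow
  defines no bounds for them).
* The shipped edge list is one realization of the printed degree sequences;
  any statistic not determined by the degree sequences is synthetic.
* No GO graph propagation or semantic collapsing in enrichment; no
  centralities beyond degree; no layout/rendering (exports target Cytoscape).
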