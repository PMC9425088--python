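# Methods

This note documents the models behind `dualreg`, the defaults and why they
were chosen, what the synthetic benchmark does and does not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and peaks

All coordinates are 0-based half-open (BED convention), since every consumed
format is BED-like. A peak's *position* is its center, `floor((start+end)/2)`;
peak standardization resizes to an exact width around that center, clipping
at zero while preserving width (determinism over symmetry at the chromosome
edge). ChIP-seq peaks are treated as unstranded and eCLIP peaks as stranded
— eCLIP protocols preserve transcript orientation — and RNA-level overlap
tests are strand-matched, with unstranded peaks passing. The 100-kb
TSS window is closed on both sides. No genome build is assumed; coordinates
are interpreted against whatever annotation is supplied. Multi-isoform TSS
models are out of scope: one TSS per gene, defaulting to the strand-
appropriate body end unless an explicit TSS column overrides it.

## Evidence ranking

Dual-binding confidence is deliberately conservative: per molecule the
*best* record wins (databases disagree; the strongest assertion is the one
worth keeping), but across molecules the *weaker* side caps the overall
class, because a DRBP claim is only as good as its weaker half. Source
databases whose labels are confidence grades rather than class names are
translated through an editable source→class map supplied as data, not code.
Protein identifiers are opaque strings; no alias resolution is attempted.

## Transcriptional layer

The regulatory potential `S = Σ exp(−(0.5 + 4Δ))`, `Δ = |center − TSS| /
100 kb` over peaks with `Δ ≤ 1`, is the standard binding-and-expression
integration decay; the constants `a = 0.5`, `b = 4` and the window are
config-exposed (`decay_a`, `decay_b`, `window_bp`).

The activator/repressor decision orders all genes by descending S (average
ranks on ties, so unbound genes share the bottom) and KS-compares the rank
distribution of up-regulated genes — `log₂FC > 1`, adjusted `p < 0.01` —
against static genes, and likewise for down-regulated genes. The two-sample
statistic `D = sup|F_dir − F_static|` is computed exactly; its p-value uses
the asymptotic Kolmogorov survival function with the Stephens small-sample
correction `en → en + 0.12 + 0.11/en`, which keeps the null firing rate at
the nominal α for group sizes in the tens (verified by seeded simulation in
the acceptance suite; an exact test is unnecessary at these pool sizes).
The level-α event is the direction's KS test; the mean-rank comparison then
decides *which* label (activator vs repressor) a significant direction
contributes. Directions below `min_group` (default 5) genes are untestable.

Rank integration pools genes that are differential in a significant
direction *and* have S > 0, ranks them by binding (descending S) and by DE
(ascending adjusted p, average ranks on ties), and calls targets at
normalized rank product `(r_b · r_de)/n² ≤ rp_thresh`. `rp_thresh = 0.1` is
a pipeline default, not a literature value; it is the knob trading recall
for precision, and under a noise-free input (where the candidate pool *is*
the target set, and a rank cutoff inside the pool is meaningless) it should
be lifted to 1.0, as the noise-free preset in the acceptance script does.

## Splicing layer

PSI may be supplied directly or as inclusion/exclusion count pairs
(`PSI = inc/(inc+exc)`, undefined at zero coverage). The differential caller
is intentionally simple: `ΔPSI = mean(kd) − mean(ctrl)` gated at
`|ΔPSI| ≥ 0.05`, plus Welch's two-sample t-test at α = 0.05 on the replicate
PSI values. This replaces a hierarchical count-based model and is the
single largest simplification in the package: with the two replicates
typical of shRNA knockdown designs the t-test is underpowered and the ΔPSI
gate dominates, so calls should be read as effect-size-driven. Peak–event
association uses a 300-bp flank (`flank`, config-exposed; the field has no
canonical value) around the event span, strand-matched, half-open.

## Co-regulation models

Model I is the plain intersection of a regulator's two target sets. Models
II/III emit one assignment per (regulator, partner, shared gene) triple;
partners must carry their own profile, and self-partnership is excluded
(self-*regulation* — a regulator in its own target sets — is retained, as
DRBP-SFs are known to regulate their own splicing). PPI support is
corroborating evidence, not a gate: `ppi_filter` is an optional post-filter
(`apply_ppi_filter`, default off; threshold presets 0.7 and 0.4), because
biologically discussed partnerships can lack a database edge. Disease
classes are free-text labels from the supplied table, not an ontology; the
fraction for an empty gene set is reported as undefined, not zero.

## Motif scanning

PWMs come from IUPAC consensus strings (uniform over each code's bases,
pseudocount-smoothed) or MEME/JASPAR files. Scores are log₂-odds in bits
against an i.i.d. background; zero-probability entries score −∞ rather than
being force-smoothed. P-values are exact under the background model:
per-column scores are integerized at 1/1000 bit and the full null
distribution is built by convolution, so `P(score ≥ t)` agrees with
exhaustive 4^w enumeration in the same integer space (property-tested to
width 8); the only approximation is the quantization, bounded by
width × granularity/2 bits. Background model is order-0 only.

Binding-mode classification mirrors the two-layer design: DNA-layer peaks
are standardized to 500 bp, restricted to within 100 kb of the TSS, and
scanned on both strands; RNA-layer peaks are standardized to 100 bp,
restricted to the gene body strand-matched, extracted strand-aware as RNA.
A self-motif hit at `p ≤ motif_p_thresh` (default 1e−4, the conventional
scan threshold) anywhere in an eligible peak is *direct* and dominates any
partner hit; otherwise the partner motif with the best hit explains the peak
(*indirect*); with no sub-threshold hit, or no eligible peak, the gene is
*unresolved*. De novo motif discovery is out of scope — the ranked self-PWM
list stands in for a discovery step, with the first `max_self_motifs`
(default 3) used. Motif similarity is the best Pearson correlation of
flattened aligned columns over all offsets with ≥ 4 overlapping positions
(DNA: both orientations) — a documented stand-in for dedicated
motif-comparison statistics; the acceptance convention maps "similar" to
r ≥ 0.8.

## Synthetic benchmark

The generator plants a four-regulator study on one 12-Mb chromosome with
300 non-overlapping genes (~40-kb slots, 5–10-kb bodies, random strand;
regulator genes forced TF+SF, other roles at 15% each). Per regulator:

- **True transcriptional targets** (20 per direction): 5 ChIP peaks at
  half-normal |N(0, 20 kb)| offsets from the TSS, log₂FC of the planted
  sign (mean 2.5, sd 0.3, floored at 1.2), adjusted p log-uniform in
  [1e−8, 1e−4].
- **Decoy DE genes** (65 per direction) emulate secondary/indirect
  expression responses: same fold-change law, adjusted p log-uniform in
  [1e−3, 9e−3], and one weak distal peak at |N(0, 60 kb)| — secondary
  responders are rarely binding-free in real data, and this makes the
  candidate pool well-defined. The disjoint adjusted-p ranges encode the
  expectation that direct targets respond more strongly than secondary ones.
- **Background peaks** fall uniformly at 0.1 per gene per assay.
- **True splicing targets** (40 sampled, plus model-planting additions):
  one differential event (|ΔPSI| = 0.3, replicate noise sd 0.02, 3
  replicates per condition) with an overlapping strand-matched eCLIP peak;
  all other events are null.
- **Model plants:** 10 Model-I genes per regulator (forced into both
  layers); regulator pairs share splicing targets through a planted
  transcriptional edge (Model II) and transcriptional targets through a
  planted splicing edge (Model III); PPI edges (confidence 0.75–0.95) back
  the planted pairs amid low-confidence noise edges.
- **Motif instances** sampled from each regulator's width-10 IUPAC consensus
  are embedded at peak centers of Model-I genes, 70% the regulator's own
  motif (direct) and 30% a partner's (indirect), reverse-complemented on
  minus-strand genes for the RNA layer.

Ground-truth Model I/II/III assignments are *derived* by applying the set
classifiers to the true target sets, so incidental overlaps between planted
sets count as truth and recovery compares like with like. Adjusted p-values
are simulated directly rather than via a count model (DE model fitting is
out of scope), and no read-level realism is attempted: peaks are intervals,
not pileups; events are planted, not discovered; replicate noise is
Gaussian. Passing recovery thresholds on this benchmark therefore
demonstrates that the *inference machinery* recovers structure it is
designed to see at realistic effect sizes — not that the pipeline's
thresholds are optimal for any particular real dataset.

The operating point (chromosome length, peak counts, decoy counts) was set
by a power analysis of the rank-product geometry: with truth T per direction
and pool n, the worst true rank product is ≈ T²/n², so the pool must exceed
T·√10 for the 0.1 cutoff to retain all true targets, while decoys must stay
out of the (T, T) rank corner — the disjoint DE p-ranges and the weak decoy
binding accomplish both. Everything above is config-exposed through
`SimConfig`; determinism is byte-exact per seed.

## Degenerate inputs and tie-breaks

Ties in any ranking get average ranks. Empty candidate pools, all-static DE
tables and zero-peak inputs yield empty target sets with a logged notice,
not errors. Events below two replicates per condition are untestable. An
event table without recognizable replicate columns, an interval beyond its
chromosome, a malformed BED line (named by line number) and mixed protein
ids in an evidence group are hard errors. PWM columns must be stochastic to
1e−9; a motif whose every word contains a zero-probability base has an empty
null distribution and can never produce a hit.

## Known limitations

- The splicing caller ignores event interdependence, coverage and isoform
  structure; it is a replicate-mean test, not a generative model.
- The KS p-value is asymptotic (corrected); for pools below ~10 genes per
  group the permutation route would be preferable and is not implemented.
- Binding-mode classification depends entirely on the supplied motif
  library; an absent partner motif reads as "unresolved", not "no partner".
- The catalog does not resolve gene aliases and cannot reproduce any
  specific database snapshot.
- Single-TSS gene models understate promoter complexity for genes with
  alternative promoters.
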