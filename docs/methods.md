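# Methods

This note documents the statistical procedures, the synthetic-data model,
default parameters, numerical conventions, and the open design choices
made while building `ttrnet`.

## Study design and data model

The pipeline targets a three-arm culture design — low glucose (LG), high
glucose (HG), high glucose + TTR (HG+TTR) — with three RNA-seq replicates
per arm and transcript-level FPKM as the expression unit. Two contrasts
carry the biology: HG vs LG (what glucose does) and HG+TTR vs HG (what
TTR does on top of glucose). All correlation-based steps (trans edges,
co-expression) and the t-tests operate on log2(FPKM + 1), where
multiplicative noise becomes approximately additive; fold changes are
ratios of group-mean FPKM with a pseudocount.

## Differential expression

* Per transcript, a two-sided Student's (pooled-variance) *t*-test on
  log2(FPKM+1); Welch's variant is available (`variant="welch"`). Zero
  variance in both groups degenerates to (t=0, p=1) when means agree and
  (±∞, 0) otherwise.
* log2FC = log2((mean_test + c)/(mean_ctrl + c)) with pseudocount
  c = 1 on FPKM. The pseudocount handles zero-expression transcripts; its
  value is a package choice (the screening rule itself does not state
  one).
* Benjamini–Hochberg adjustment (via `statsmodels`) is applied per
  contrast across all transcripts jointly — coding and lncRNA together —
  since a single FDR gate per contrast is reported; a per-biotype split
  is not offered because nothing in the procedure depends on it.
* Significance gates: status "up" iff FC ≥ 2 ∧ p ≤ 0.05 ∧ q ≤ 0.05;
  "down" iff FC ≤ 0.5 at the same p/q gates. All three thresholds are
  configurable.
* Gene-level aggregation defaults to `any_transcript` (a gene is DE if
  any of its transcripts is). The stricter literal reading
  (`at_least_two`) is provided because the aggregation rule can be read
  either way; genes with significant transcripts in both directions are
  flagged rather than resolved.

## Converse-trend (TTR-DEG) filter

Membership requires sign(log2FC₁)·sign(log2FC₂) < 0. `strict` mode
(default) additionally requires significance in both contrasts — the
reading in which the DE sets are intersected before the trend
comparison. `lenient` requires significance only in the TTR contrast.
The strict set is a subset of the lenient set by construction, and strict
membership is symmetric in the order of the two contrasts (the sign
product is). The set splits by biotype into TTR-mRNAs and TTR-lncRNAs.

## Co-expression modules

* Adjacency a_ij = |cor(x_i, x_j)|^β (unsigned, the classic default;
  signed ((1+cor)/2)^β available). The sign convention is a package
  choice.
* Soft threshold: smallest β in 1..20 whose binned log-log degree
  regression reaches signed R² ≥ 0.8; when no power qualifies — the
  normal outcome for a 9-sample network, whose correlation estimates are
  too noisy to look scale-free — the configured fallback of β = 10 is
  used and flagged.
* TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), TOM_ii = 1,
  symmetrised and clipped to [0,1] against floating-point drift.
* Modules: average-linkage hierarchical clustering of 1 − TOM with a
  static cut (default cut height 0.9, minimum module size 10 at desk
  scale). A static cut was chosen over a dynamic hybrid cut for
  determinism and simplicity; the cut parameters are exposed. Clusters
  below the size floor become "grey"; surviving clusters take
  WGCNA-style colour names in decreasing size order.
* Module eigengene: first right singular vector of the standardised
  member × sample submatrix, oriented to correlate positively with the
  module's mean profile; variance explained is reported. Constant
  transcripts are a hard error at this stage (they have no standardised
  profile).
* Traits: glucose = 1 for HG and HG+TTR, 0 for LG; ttr = 1 for HG+TTR
  only. This binary encoding over the nine samples is the package's
  reading of "module–trait (glucose and TTR) relationships" and is
  configurable.
* Hub module = argmax over modules of min(|r_glucose|, |r_ttr|) — the
  formalisation of "highest correlation with both traits"; mean |r| is
  available as an alternative rule.
* Sample clustering (`sample_dendrogram`) is a diagnostic only; no
  automatic outlier exclusion.

## lncRNA target networks

* **cis**: a lncRNA/mRNA pair is emitted iff both lie on one chromosome
  and their spans overlap or sit within the window (default 10 kb — the
  window used for the reported networks; 100 kb is a documented
  alternative). "Within" is boundary-inclusive (gap = window counts);
  the gap is measured end-to-start between feature spans, not between
  transcription start sites — neither convention is dictated by the
  procedure, so the simpler one was chosen and is tested explicitly at
  the boundary. The relation (upstream / downstream / overlapping)
  is the strand-agnostic genomic position of the mRNA relative to the
  lncRNA; antisense overlap is reported as `overlapping` plus an
  `opposite_strand` flag.
* **trans**: Pearson correlation across all nine samples on
  log2(FPKM+1) (raw-FPKM option retained); edge iff |r| ≥ 0.95.
  Constant profiles are skipped with a warning.
* **ceRNA**: canonical seed matching replaces external target-prediction
  services. The target (written 5'→3', T/U equivalent) is scanned for
  reverse complements of miRNA positions 2–7; each hit is classified by
  m8 complementarity and an A opposite position 1 (8mer > 7mer-m8 >
  7mer-A1 > 6mer, strongest class per location; overlapping hits at
  distinct starts all reported). Free-energy or conservation scoring is
  out of scope. A triad (lncRNA, miRNA, mRNA) requires ≥ `min_sites`
  sites (default 1) of the same miRNA on both the lncRNA and the mRNA.
* **Hubs**: lncRNAs ranked by trans-network degree counting unique mRNA
  partners, ties broken lexicographically. `merge_networks` restricts
  all three edge types to a focus set of lncRNAs (by default the top 3
  hubs, mirroring a validated-lncRNA-centred network) and keeps the
  miRNA bridge nodes of their triads.

## Dense sub-networks

Input is a tab-separated edge list (optionally scored); scored edges
pass only with score > 0.4 (strict inequality — "medium confidence").
Vertex weight = k × density of the highest k-core of the closed
neighbourhood. Complexes grow greedily from the heaviest unused vertex,
admitting neighbours with weight ≥ seed_weight × (1 − 0.2). Two
additions to the textbook seed-and-grow are deliberate package choices:

* **Bridge guard**: once a complex has ≥ 2 members, a candidate must
  have ≥ 2 edges into it. This is the haircut criterion applied at
  admission time; without it, two cliques joined by a single edge merge
  into one complex whenever their vertex weights tie (in two bridged
  triangles every vertex weighs exactly 2), which defeats the purpose of
  dense-region detection.
* **Haircut** (default on) then iteratively removes members left with
  fewer than two in-complex edges, making it idempotent.

Defaults (node score cutoff 0.2, haircut on, min size 3) follow the
published app defaults of the molecular-complex-detection tool; the tool
is named in the underlying study without parameters, so these are
package choices. Seeds are visited in (weight desc, id asc) order and
growth explores sorted neighbours, so results are fully deterministic;
each node belongs to at most one complex.

## Synthetic-data generator

The generator emulates the study conditions at desk scale and emits full
ground truth. Defaults: 400 coding transcripts (one gene in ten carries
two transcripts, to exercise gene-level aggregation), 50 lncRNAs (one in
five flagged as a novel assembly), 3 replicates per arm, 40 up + 40 down
planted DE transcripts per contrast of which 30 reverse trend, log2
effect 2.0, log-scale noise sd 0.25, two 50-member trait-linked modules
at target |r| = 0.85, 8 planted cis pairs in a 10 kb window, 10 miRNAs
with 7-nt seeds, 5 ceRNA triads.

* **Expression**: log2(FPKM+1) ~ Normal(group mean, 0.25),
  back-transformed (FPKM clipped to a minimum of 1e-9 so values stay
  strictly positive). Baselines are Uniform(3, 8) on the log2 scale.
  Planted group means differ by exactly ±2.0 before noise, so realised
  fold changes centre on the planted effect (verified to within 0.05
  over 100 simulations). Library-size normalisation is not modelled —
  the upstream normalisation of the real data is unstated, so the
  generator does not guess one.
* **Modules**: members share a latent per-sample factor with loading
  3 × noise_sd, giving within-module correlation ≈ 0.9. Factors are
  constructed geometrically (correlation = dot product of centred unit
  vectors): each factor correlates with its trait at exactly the target
  rho and with every previously planted factor at exactly zero, which
  keeps planted blocks statistically separable even though the glucose
  and TTR traits themselves correlate at 0.5 in this design. Requesting
  more correlated structure than the 9-sample geometry can hold is a
  configuration error, not a silent degradation. Even-numbered modules
  track glucose, odd-numbered track TTR.
* **Annotation**: 1-based inclusive single-interval transcripts (GTF
  convention). Each planted cis pair lives on a private chromosome: pair
  0 is antisense-overlapping, pair 1 sits exactly at gap = window
  (boundary rule fixture), the rest alternate upstream/downstream at
  random gaps inside the window; decoy pairs sit at window + 1 and
  beyond and appear in the truth manifest as decoys. All remaining
  transcripts are spaced three windows apart so no accidental pair
  exists.
* **Sequences**: random-composition nucleotide sequences whose length
  equals the annotated span. Background sequences are rejection-sampled
  (cap 1000 tries) to contain no reverse complement of any miRNA 6-mer
  core, so the only seed sites in a dataset are the planted ones —
  which is why triad recovery is exact rather than probabilistic. Each
  triad member carries one embedded 8mer site: reverse complement of
  miRNA positions 2–8 followed by an A on the target's sense strand.
* **Interactions**: an optional scored edge list with three planted
  cliques (sizes 6, 5, 4; scores 0.6–0.99) over coding gene symbols and
  a sparse background (scores 0.05–0.9) thinned by the 0.4 filter.
* **Determinism**: every generator operation derives its RNG as
  `default_rng([stage_index, rng_seed])`, so each op is independently
  callable yet a config reproduces every file byte-for-byte.

### What passing tests do and do not show

The generator's noise is Gaussian on the log scale, uncorrelated across
transcripts outside planted modules, with no count overdispersion,
batch structure, library-size variation, isoform structure beyond one
interval per transcript, or realistic genome sequence. Recovery results
(trend-filter sensitivity/precision, exact triad recovery, module ARI)
therefore demonstrate correctness of the inference chain under its own
assumptions, not expected performance on real RNA-seq, where three
replicates per arm would give far noisier correlation estimates.

## Desk-scale choices

Simulated problem sizes (450 transcripts × 9 samples; 20-seed replication
for recovery rates; 100-seed batches only for calibration checks) were
chosen so the whole suite and the acceptance script each run in seconds
while keeping every planted-structure count well above the granularity of
the rates being estimated. Scale-level findings of the original study
(eleven-thousand-transcript DE lists, a 133-gene module, database-derived
interaction networks) depend on the deposited dataset and external
services and are deliberately out of scope.

## Numerical conventions

* BH ties are resolved by stable ordering; q-values are unaffected.
* TOM and adjacency matrices are explicitly symmetrised; acceptance
  checks require asymmetry < 1e-12.
* Eigengene sign: positive correlation with the module mean profile;
  exact zeros fall back to making the largest-magnitude loading
  positive.
* Written tables round floats to 6 decimals except the expression
  matrix, which is written at full precision and read back with
  round-trip float parsing so dataset round-trips compare equal.
* Pipeline manifests contain no timestamps; the config hash covers every
  semantic field and excludes filesystem paths.
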