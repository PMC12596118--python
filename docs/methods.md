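# Methods

This note records the models, parameter choices and known limits of
`lysismine`. The package reimplements, at desk scale, a genome-mining
pipeline for prokaryotic-virus lytic proteins together with its
downstream evolutionary analyses, and validates every stage against a
synthetic-data generator that plants known ground truth.

## Candidate discovery

Four routes feed the classifier, mirroring how such pipelines combine
annotation-based and annotation-free evidence:

1. profile search of annotated proteins,
2. keyword screening of annotation strings,
3. keyword screening of an alternative annotation set (when supplied),
4. ORF re-prediction followed by the same profile search.

Candidates are pooled by genomic location `(genome, start, end, strand)`
with per-route provenance. Re-predicted ORFs can extend an annotated gene
upstream to an earlier in-frame start; candidates sharing a stop-codon
anchor on one strand are collapsed, preferring annotated coordinates.

**Profile models.** A full profile HMM is deliberately simplified to a
per-column log2-odds emission profile with affine gap penalties
(open 6, extend 1 in score units), scored by local (Smith–Waterman-style)
profile-to-sequence alignment. Emission scores use
`log2(((count + α·bg) / (Σcount + α)) / bg)` with pseudocount α = 1 and a
uniform background. Statistical calibration is empirical: the best local
score on each of ≥ 500 shuffled/random decoys is fitted with a Gumbel
distribution (location μ, scale 1/λ), and
`E(s) = N_targets · exp(−λ(s − μ))`. The decision behaviour of the screen
(a hard cut at E ≤ 1e-10) is what matters downstream, and the calibration
places planted-motif scores ~10 nats below the cutoff while leaving decoy
scores orders of magnitude above it. No forward-algorithm posteriors and
no multi-domain envelopes are attempted.

**Keyword screen.** Case-insensitive substring matching with a veto list
applied first ("tail lysozyme" is a structural protein, not an
endolysin). The default keyword list (endolysin, lysin, lysozyme, holin,
spanin, Rz/Rz1, the catalytic class names, and the accessory-protein
names) is config-overridable, since no canonical list exists.

**Provirus masking.** For host-side analyses, genes overlapping any
predicted provirus region are excluded from the host protein set
regardless of region size; regions shorter than 4 kb are additionally
flagged short-fragment and discarded from the viral side. The 4 kb rule
is applied in this direction because short fragments are the ones whose
lytic genes would contaminate a phylogeny.

## QC and classification

* **TMR prediction** uses Kyte–Doolittle hydropathy, window 19, threshold
  1.6, center-position convention; runs of warm centers become segments
  and segments closer than 5 residues merge. These are the canonical
  TM-segment settings; a neural topology predictor is out of scope and
  the hydropathy scan is the package's own stand-in.
* **Endolysins**: reject on any virion-associated (VAL) structural
  domain, any TMR, or no recognizable domain; otherwise ≥ 2 distinct
  catalytic categories → `m-EAD`, exactly one → that category, binding
  domain only → `s-CBD`, unrecognized catalytic category → `unclassified`.
  "Multi-domain" is read as *distinct categories*: two hits of one
  category collapse to that category, because the subclass vocabulary is
  an enzymatic-class framing. Classification is order-invariant in the
  domain list.
* **Holins**: ≥ 1 TMR required; classes `TMRs-1`…`TMRs-4`; more than four
  segments gets a dedicated `TMRs-4+` flag rather than silent truncation,
  since the published classes stop at four without a stated rule.
* **Spanins**: the inner component must carry a TMR, the outer a lipobox
  (`[LVIMFT][ASTVIG][GAS]C` with the Cys inside the first 40 residues);
  a unimolecular spanin needs both, with the lipobox N-terminal of the
  C-terminal TMR. Labels follow gene geometry: separated → SIS/SOS,
  embedded → EIS/EOS, overlapping → OIS/OOS, single gene → USP. When
  features do not identify inner vs outer (neither or both have a TMR),
  gene order decides (inner upstream), matching the natural i-/o-spanin
  arrangement. Labels are invariant under coordinate mirroring
  (reverse-complemented genomes).
* **pE / Pei / PVAP** pass when their family profile hits; they have no
  further subclass structure here.

## Synthetic study conditions

The generator is the package's definition of the conditions under which
the pipeline is validated; its defaults are fixed and not tuned per run.

* **Scale**: the standard dataset is 60 genomes (9–20 kb, i.i.d. uniform
  nucleotides) carrying ≥ 200 planted lytic genes that cycle through
  every endolysin subclass, holin TMR class, spanin architecture, the
  three accessory types, and every designed QC-reject case
  (VAL domain, endolysin TMR, no domain, holin without TMR, outer spanin
  without lipobox, inner spanin without TMR, defective USP).
* **Composition**: non-membrane protein regions are drawn from a
  13-letter polar alphabet (Kyte–Doolittle ≤ −0.4, no Cys), so no
  accidental TMR or lipobox can arise and background purity is provable
  rather than probabilistic. Transmembrane blocks are 21 residues from
  {L,I,V,F,A}; linkers are ≥ 30 strongly polar residues (KD ≤ −3.5) — a
  19-residue window needs ≥ 13 hydrophobic residues to cross the 1.6
  threshold in the worst case, so adjacent blocks can never merge and
  the detector finds exactly the planted count.
* **Domain motifs** are 24-residue polar-composition consensus strings,
  one per family (amidase ×2, muramidase, transglycosylase,
  endopeptidase, glucosaminidase, CBD, an unrecognized-category family,
  a VAL family, and Pei/pE/PVAP families). 24 residues gives the exact
  planted copy a large, seed-robust margin below the E ≤ 1e-10 cutoff
  while staying well inside realistic domain-motif lengths.
* **Overlapping/embedded spanin pairs** are laid out on one strand with
  the outer gene in the +1 frame of the inner gene (the lambda Rz/Rz1
  arrangement). Synonymous codons for the outer gene are chosen under
  two local rules that provably keep the inner frame free of unintended
  stops, and in the overlapping arrangement two outer-gene residues are
  fixed (N,K) so their codons spell the inner gene's stop. The
  constructed locus is re-translated and checked at generation time.
* **Mutations are exact-count** (round(divergence × length) positions,
  each to a different residue), not per-site Bernoulli, so identity
  thresholds in tests are noise-free.
* **CRISPR plants** insert `n+1` identical repeats interleaved with
  spacers copied from distinct viral loci (either strand) at a controlled
  mismatch count; flanking bases are re-drawn until no array boundary can
  be extended unanimously, making exact boundary recovery well-defined.
* **Transfer scenarios** chain a bacterial donor clade (12% divergence
  per step) and radiate a viral recipient clade (0.6% radiation) from a
  transferred copy at 2% divergence — the recipients are mutually closer
  than to any donor, so the planted topology is recoverable.

What passing on these conditions does *not* show: robustness to realistic
codon usage and GC skew, to degenerate CRISPR repeats, to fragmented or
misassembled genomes, or to homologs at the twilight zone of the profile
screen. The generator deliberately omits these (no phylogenetically
structured genome simulation), so results on real data will be noisier in
exactly those dimensions.

## Sequence comparison and clustering

Protein alignments use BLOSUM62 with gap open 11 / extend 1; nucleotide
alignments use match +2 / mismatch −3, gap open 5 / extend 2 — the
community defaults behind the aligners such pipelines wrap. Identity is
BLAST-like: matching columns over alignment columns between the first and
last column where both sequences align (terminal overhangs excluded);
coverage of a sequence is the fraction of its residues inside that core.
Exact dynamic programming only — no k-mer prefilters, no banding; the
aligner is checked exactly against an independent quadratic DP oracle.

Greedy clustering visits sequences by decreasing length and joins the
first representative met at ≥ 50% identity with ≥ 90% coverage on both
sequences; at thresholds 1.0/1.0 it reduces to exact dereplication.
Markov clustering is the textbook iteration (self-loops,
column-stochastic, expansion/inflation to a fixed point) with inflation
2.0, pruning 1e-6, tolerance 1e-8, max 200 iterations; clusters are the
connected components of the limit support and can never span disconnected
input components. Ties everywhere break lexicographically by identifier,
so every stage is deterministic.

## CRISPR host prediction

Array detection is a seed-and-extend approximation of repeat-recognition
tools: exact words of length 7 recurring at array-like spacing
(repeat+spacer within [40, 110] nt under the default bounds) seed chains,
and boundaries extend only while *all* repeat instances agree on the
flanking nucleotide. Repeats within an array are therefore exact copies;
degenerate repeats are out of scope. Seed words colliding with nearby
background can chain truncated variants of one array, so detection keeps
only the maximal array per genomic span. The published filters are
applied as stated: mean spacer/repeat length ratio within [0.6, 2.5]
(the mean is used because the source does not state an aggregation) and
≥ 3 spacers. Spacer matching is ungapped on both strands — "≤ 1 SNP"
implies substitution-only — with ≥ 95% identity and full-length
placement (coverage 1). Host-range subsampling draws, per replicate,
at most `quota` species per phylum (default 100, with per-phylum
overrides such as 2000 for the three largest phyla) and averages the
per-virus distinct-species count over 10 replicates.

## Trees, HGT and cophylogeny

Distance trees replace likelihood inference at desk scale: p-distances
(pairwise deletion) or Poisson-corrected distances feed canonical
neighbor joining (negative branch lengths clamped to zero with the
deficit moved to the adjacent edge). On additive matrices NJ provably
recovers the generating topology, which is what the synthetic scenarios
produce; the tree-reliability tests used with likelihood trees are
therefore unnecessary here, at an acknowledged fidelity cost on real
data. Midpoint rooting bisects the longest tip-to-tip path and is checked
against exhaustive search.

HGT candidates come from an identity graph thresholded at ≥ 95%
(viral–viral) and ≥ 90% (pairs involving bacteria), Markov-clustered at
inflation 2.0, keeping clusters with ≥ 2 members from each source.
Direction is read off the midpoint-rooted tree: exactly one source
monophyletic → that source is the recipient clade and the paraphyletic
grade is the donor ("basal = donor"); both or neither monophyletic →
`unresolved`. This operationalizes a criterion the source literature
itself flags as tentative (near-identical sequences, no outgroup), so
the honest output for ambiguous topologies is `unresolved`, never a
guess; on clean simulated transfers the planted direction is recovered
in ≥ 90% of runs with zero wrong-direction calls.

PACo and ParaFit both start from patristic distance matrices, apply the
Cailliez correction (the smallest additive constant making the
off-diagonal distances Euclidean-embeddable, computed from the standard
2n×2n eigenproblem), and embed by classical principal coordinates
keeping positive axes. PACo's statistic is the Procrustes residual sum
of squares m² of the dependent configuration superimposed on the other
(small = congruent); ParaFitGlobal is the sum of squares of the
fourth-corner matrix C′A′B (large = congruent; checked against the R
`ape` implementation on a fixture). p-values use 999 association
permutations with +1 smoothing, in the direction appropriate to each
statistic. Type-I error at α = 0.05 is calibrated within the binomial
95% interval over 200 independent-tree replicates, and perfectly
congruent pairs reach the permutation floor p = 0.001.

## Diversity statistics

Rarefaction samples members without replacement at each size (10
replicates by default) and reports mean ± SD distinct clusters; the
sampling estimator is validated against the closed-form hypergeometric
expectation `Σ_k (1 − C(N−N_k, n)/C(N, n))`. The saturation verdict fits
a least-squares slope to the final 20% of the curve and flags
"saturated" below 0.001 new clusters per additional item — the source
judgment appears to be visual, so the criterion is the package's own,
exposed as a parameter. Genome-size correlations are Pearson r with the
two-sided t-transform p-value, reporting zero-variance inputs as
undefined rather than 0. "Normalized connectivity" of a network is read
as average degree 2|E|/|V|, with optional per-category means.

## Problem sizes and determinism

The standard validation sizes — 60 genomes / ≥ 200 planted genes for
classification, 20 seeds for CRISPR recovery, 200 additive matrices for
NJ, 100 simulated transfers, 200 replicates × 999 permutations for
cophylogeny calibration, 10,000 decoys for screen calibration — were
chosen as the smallest scales at which the binomial/quantile bounds being
asserted are meaningful. Every stochastic routine takes an explicit seed
and all iteration orders are sorted, so identical inputs and seeds yield
byte-identical outputs across the whole pipeline.
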