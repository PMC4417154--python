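# Methods

## Window scoring model

The genome is tiled into 500 bp windows with 50 bp shifts (0-based,
half-open coordinates throughout; trailing segments shorter than one window
produce no window). A window is scored for a motif with a generative HMM:
scanning left to right, position *i* is emitted either as one background
base with factor `(1−p)·bg(x_i | context)` or, if at least *w* bases have
been emitted, as the last base of a motif site with factor
`p · ½(P_W(x_{i−w+1..i}) + P_W(revcomp))`. The likelihood follows the
forward recursion

```
F(i) = (1−p)·bg(x_i|·)·F(i−1) + [i≥w]·p·½(P_W⁺+P_W⁻)·F(i−w),  F(0)=1
```

implemented in odds space against the all-background model so that
`F'(n) = L(p)/L(0)` and the window score is `log F'(n)` in nats, clamped at
0 (p = 0 is always feasible). The site probability is fitted per window by
EM: the E-step needs only the posterior expected site count, which is read
off the derivative of the log-likelihood propagated alongside the forward
pass (`E[k] = (dlogL/dp + n/(1−p))·p(1−p)/(1−p+wp)`); the M-step is
`p ← n_s/(n_s + n_b)` with `n_b = n − w·n_s`. EM starts at `p = 1/(4w)`, is
capped at `p_max = 1/w` (preventing degenerate all-site fits on repetitive
sequence), and stops when the log-likelihood changes by less than 1e-9 or
after 200 iterations. The capped M-step still maximizes the expected
complete log-likelihood over the feasible interval, so the likelihood is
non-decreasing across iterations (asserted in tests). Non-ACGT bases emit
as background with probability 0.25 and can never sit inside a site.

The forward/EM inner loop is a numba kernel. The batched path processes
windows position-by-position with the window axis innermost (vectorizable,
cache-resident ring buffers of w+1 rows) and compacts converged windows out
of the active set; windows whose log-likelihood bound exceeds the
representable range are routed to a scalar kernel with explicit rescaling.
Both kernels implement the identical model and stopping rule and agree to
1e-13 in practice; the forward recursion is checked against brute-force
enumeration of all non-overlapping site placements at small n.

The background is an order-1 Markov model (configurable order k; tables for
all orders 0..k are kept and a position uses the highest order whose
context is available and unambiguous), trained genome-wide per species with
add-0.5 smoothing. Each window is scored as a standalone sequence — the
first k positions fall back to lower-order context — so identical window
sequences always receive identical scores regardless of genomic context.

Multi-species scores are weighted averages of per-window scores of
orthologous segments, one per species, each scored with its own background;
weights are supplied with the orthology map and renormalized over the
species actually present at a window (absence of an alignment is not
treated as evidence of absent binding).

## Accessibility

Raw per-base signal (bedGraph semantics, uncovered bases = 0) is summarized
per window as the mean over the ten 50 bp subsegments of the maximum base
value within each subsegment; the same aggregator serves DNase-style
accessibility and ChIP-style occupancy. Per developmental stage, exactly
`floor(0.10 · N)` windows with the highest accessibility are called
accessible; ties at the cut break by genomic order so the mask is a pure
function of the values. Masked motif tracks keep their original scores in
accessible windows and carry 0 elsewhere (a defined value, so downstream
max/mean aggregation never sees missing data).

## TF–domain associations

Three regulatory-region definitions are built per gene: p1K and p5K
(strand-aware 1 kb / 5 kb immediately upstream of the TSS, clipped at
chromosome bounds) and IG (the gene span extended up to 50 kb per side,
each extension truncated at the nearest insulator boundary between gene and
limit). A gene's motif evidence is the maximum masked multi-species window
score over windows overlapping its region (max rather than sum/mean because
the window score already integrates sites). The TF target set is the top
`k = min(1000, 20% of universe)` genes with positive score (ties by gene
id); the universe is the set of atlas genes with a non-empty region under
the tested mode. Overlap with the domain's gene set is scored by the
hypergeometric survival function, the accessibility mask follows the
domain's stage, and the lowest of the three mode p-values is kept (ties
break p1K > p5K > IG). `S = −log10 p` is capped at 300 to keep downstream
features finite under underflow.

Expression support of an association is "specific" when the TF gene is
annotated with the domain, "related" when annotated with an ontology
ancestor or descendant of the same stage, "ubiquitous" when the TF is
flagged ubiquitously expressed in that stage, else "none". Association
quality is evaluated as the AUROC of S against TF-expression ground truth;
proximal/distal architecture is summarized by counting associations
significant under p1K but clearly not under IG (and vice versa) per TF and
per domain, with an exact two-sided binomial test of the split.

## Enhancer activity models

Open regions are non-overlapping 500 bp windows accessible in at least one
stage, kept greedily by descending maximal per-stage accessibility, and
filtered for enhancer-like motif content: a region is kept when its best
unmasked multi-species motif score (measured over all windows overlapping
the region, exactly as for the references) reaches the 5th percentile of
the same statistic over the reference enhancer set. Each region is
tentatively assigned the expression domains of its two nearest genes.

For a domain D, noisy positives are regions within 5 kb of a neighbor gene
annotated with D, accessible in D's stage and free of reference-enhancer
overlap (capped at 500 by seeded subsampling); negatives are an equal
seeded sample of stage-accessible regions with no D-annotated neighbor
(classes are balanced downward when negatives are scarce); both are split
75/25 into train/test. Features follow the activity model exactly:
`x_m = Z·S·E·R` per motif (E counts specific, related and ubiquitous
support; S and features are 0 for untested TFs) plus the per-stage
accessibility vector. The model is ridge-regularized least squares on raw
{0,1} labels. The library default penalty is 1e-6; the pipeline selects the
penalty by efficient leave-one-out cross-validation over a log-spaced grid,
which matters when training sets are tens of examples against ~25 features.

Models are evaluated on the left-out quarter and, where the reference set
permits, by RFVO (reference-overlapping regions labelled with D as
positives versus regions with neither reference overlap nor a D-annotated
neighbor); RFVO is attempted when at least 10 reference-overlapping regions
carry D among their candidate domains. A model is "good" when RFVO
AUROC > 0.7 or test AUROC > 0.6. Good models score all open regions; a
region is annotated with D when a neighbor gene carries D and its score
reaches the 95th percentile (inclusive) of the model's genome-wide score
distribution. For regions overlapping reference enhancers, candidate
domains with good models are ranked by genome-wide score percentile and the
reference domain's normalized rank `(k − rank)/(k − 1)` (1 when first, 1 by
convention when k = 1) summarizes assignment quality; regions whose
reference domain has no ranked candidate are excluded from the statistic
and counted separately.

## Synthetic world

The generator plants a known regulatory map and emits every pipeline input.
Defaults: two 300 kb chromosomes (i.i.d. bases at 50% GC), 20 TFs with
sharp PWMs (width 6–10, one dominant base per column with probability drawn
from 0.92–0.99, the regime of bacterial one-hybrid-characterized motifs),
120 genes with jittered TSS spacing and random strands, 12 expression
domains cycling over four stages, and a sparse planted map (each TF
regulates a domain with probability 0.02, at least one regulator per
domain — dominant-regulator biology; with several regulators per domain the
four sites per enhancer dilute below detectability at this genome size).

Each domain drives 8 core enhancers: 500 bp elements within 5 kb of their
target gene's TSS, at least 400 bp from other enhancers, carrying 4
PWM-sampled sites of the domain's regulator(s) written into the genome.
Atlas annotations beyond the core targets arrive at rate 1.2 per gene,
stage-diverse within a gene, and 85% of them are backed by a real planted
enhancer of that domain (curated atlases are mostly correct; the unbacked
remainder plus background open regions keep the training labels noisy).
The background genome carries homotypic decoy clusters (4 sampled sites of
a random TF within 300 bp, 8 sites/kb) emulating unannotated enhancers and
chance motif clusters; 10% of them receive a DNase-like accessibility peak
in one random stage. Accessibility per stage is the sum of Gaussian bumps
(height 8, sd 200 bp) over that stage's enhancers and open decoys plus
positive half-normal noise (sd 1, floor 0.05); ChIP-like occupancy per TF
smooths that TF's planted and decoy sites (height 5, sd 200) plus noise.
Insulator marks sit at intergenic boundary points chosen so that no
gene-to-own-enhancer linkage is crossed (boundary elements delimit
regulatory units); purely random placement would sever about half of the
IG-mode gene–enhancer links at this gene density. Orthologous segments are
per-species mutated genome copies (substitutions at 0.15/bp) with each
planted or decoy site preserved intact with probability 0.8 per species;
species weights follow a fixed toy tree (ratios 2 : 1 : ½ : ¼, normalized).
A configured fraction (0.3) of planted enhancers is exported as the
labelled reference set.

What the world does not emulate: real sequence composition (repeats,
CpG/AT structure), a real phylogeny or alignment gaps, read-level noise,
cooperative/competitive binding, and distances beyond a two-chromosome
600 kb genome. Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and well-calibrated under the
planted statistical structure, not that it reaches any particular accuracy
on real embryonic data.

## Problem sizes and determinism

Recovery experiments run the full pipeline on five default worlds
(~12,000 windows, 20 motifs, 4 species; about 70 s per world on one CPU).
The independent oracles run at small n (placement enumeration at n ≤ 10,
w ≤ 4; hypergeometric draw enumeration at N ≤ 12). All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; pipelines,
masks, training splits and evaluation sets are bit-reproducible given
(inputs, seed). The EM is deterministic; its only tolerance is the 1e-9
log-likelihood stopping rule. Scores are natural-log units; only relative
comparisons matter downstream.

## Known limitations

- The left-out test AUROC of a domain model is estimated from a handful of
  noisy-labelled examples at synthetic scale; the RFVO evaluation, where
  available, is the more reliable gate input.
- The IG region definition lets neighboring genes share windows; no
  exclusivity is enforced, so a strong shared enhancer credits several
  genes' scores.
- Spearman p-values use the large-n t-transform, which is approximate for
  small n with heavy ties.
- The exact phylogenetic weighting of the original 12-genome analysis is
  not reproduced; weights are an input of the orthology map.
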