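# Methods

This note documents the models, numerical choices and limitations behind
`mirdyn`.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Functional representation

Each gene's log2 fold-change time course y(t₁)…y(tₙ) is represented as a
continuous curve f = Σ cₖBₖ over an order-4 (cubic) B-spline basis with
knots at the sampled timepoints.  With n data points this gives
n − 2 interior knots + 4 = n + 2 basis functions (19 for the 17-point
2–112 h schedule).  Coefficients minimize

    Σᵢ (yᵢ − f(tᵢ))² + λ ∫ f″(t)² dt ,   λ = 0.05 by default.

Because n_basis > n, the unpenalized problem is underdetermined; the
penalty makes it strictly convex.  Numerically we solve the augmented
least-squares form ‖y − Bc‖² + λ‖Rc‖² with P = RᵀR (symmetric eigenvalue
square root), which is better conditioned than the normal equations.  At
λ = 0 we return the minimum-norm interpolant; note its inter-knot
derivatives are not meaningful — any analysis of derivatives should use
λ > 0.

All integrals (penalty matrix ∫B″B″ᵀ, Gram matrices ∫B⁽ᵈ⁾B⁽ᵈ⁾ᵀ over
arbitrary windows) are computed by per-interval Gauss–Legendre quadrature
with `order` nodes.  B-spline products are piecewise polynomials of
degree ≤ 2(order−1) = 6 < 2·4 − 1 + 1, so this quadrature is exact up to
rounding; the unit tests verify agreement with 10⁵-point trapezoid
quadrature at relative 1e-6.  The uneven sampling (2 h spacing early,
32 h late) is therefore handled by true functional integrals, never by
treating timepoints as equally spaced vector entries.

Functional PCA is computed on the coefficient representation with the
Gram-metric correction: with G = LLᵀ, the covariance-operator
eigenproblem reduces to the symmetric eigenproblem LᵀSL (S = coefficient
covariance); eigenvectors map back through L⁻ᵀ to harmonics orthonormal
under the L2 inner product.  A discretized-PCA oracle (fine grid,
trapezoid weights) is tested against this path.

## Similarity, classification, and FDR

The similarity primitive for both classification and clustering is the
cosine-normalized windowed first-derivative inner product,

    s(f, g) = ⟨f′, g′⟩_w / √(⟨f′, f′⟩_w ⟨g′, g′⟩_w) ∈ [−1, 1],

on top of per-curve RMS scaling, making neighbour ranking depend on
curve *shape* only.  The k-NN posterior is the unweighted direct-vote
fraction among the k most similar training curves (k = 11, odd to avoid
ties; exposed as configuration — a distance-weighted variant and CV
selection of k are deliberate non-defaults).  Calls use posterior ≥ 0.75
(target) and ≤ 0.25 (non-target).  Cross-validation is stratified with a
logged seed; AUC uses the Mann–Whitney rank form with tie halving, and
both a fold-SD standard error and the Hanley–McNeil closed form are
reported.

The shuffle FDR reruns the *identical* train→classify→threshold pipeline
on null training sets drawn uniformly from the genes passing the same
non-specific fold-change filter, and reports (mean null predicted-target
count)/(real count) per fold-change cutoff, clipped to [0, 1]
(50 replicates by default).  On data with no planted signal the ratio
concentrates near 1 only as counts grow; small-count runs are noisy,
which is why the null-calibration tests use a few thousand genes.

## Training sets

direct = external prediction list ∩ responders (|log2FC| ≥ log2 1.5 at
any timepoint, inclusive); indirect = responders with known-zero 7/8-mer
seed counts in both UTR and CDS and not predicted by any supplied
predictor, subsampled to |direct|; non-target = non-responders not
predicted, subsampled likewise.  Genes whose region sequence is absent
have *unknown* (not zero) seed status and are excluded from the seed-free
pool.  Subsampling is uniform without replacement under a logged seed,
and a filter log records every set size.

Seed matches are reverse complements of miRNA positions 2–8 (7-mer) and
2–9 (8-mer) on the sense mRNA strand, U/T equivalent, N never matching;
A1-anchored site types are not counted separately.  Every 8-mer site
contains a 7-mer site one base in, which the 7-mer scan reports
independently.

## Per-timepoint statistics

- Seed enrichment: one-sided exact binomial test of the responder
  carrier count against the all-gene carrier fraction, per timepoint.
- Up/down asymmetry: the null "up-proportion within 0.5 ± δ" (δ = 0.10)
  is tested by an exact binomial tail at the boundary nearest the
  observed proportion.  This reproduces the qualitative pattern of an
  overwhelming early asymmetry versus a balanced late response, which a
  plain sign test would not (it would reject balanced-but-large counts).
- Coherence: genes are signed at two timepoints (thresholds 1.5 at 4 h,
  1.3 at 32 h); a one-sided Fisher exact test on the up×up table within
  the either-time responder universe, plus the coherent fraction among
  genes up at t₁ and responding at t₂.
- GSEA: weighted Kolmogorov–Smirnov running sum (weight exponent 1;
  exponent 0 gives the classic KS statistic) with a gene-label
  permutation null, p = (1 + #{ES* ≥ ES})/(n_perm + 1) — deliberately a
  permutation test so that null p-values are super-uniform by
  construction.  Benjamini–Hochberg adjustment is applied within each
  timepoint; raw p-values are always reported.
- Seed-region effects: KS tests of the fold-change distributions of
  UTR-only / CDS-only / both-region carriers against no-seed genes, and
  the drop in mean FC of the upward responder set when carriers in each
  region are removed, against shuffled-miRNA controls (uniform letter
  shuffles, new seed recomputed per shuffle; 50 by default.
  Dinucleotide-preserving shuffles are not implemented).

## Clustering

The upstream method cited for graph-based functional clustering is not
algorithmically specified in public detail; `mirdyn` implements a
*reconstruction*: mutual k-NN graph (k = 20) under the derivative-cosine
similarity, edges kept only when both endpoints select each other and
the similarity is positive, then seeded Louvain modularity communities
on canonically sorted nodes (making the result invariant to gene input
order).  Communities below 10 genes dissolve into background cluster 0.
Per-cluster seed enrichment is the cluster carrier fraction over the
mean carrier fraction of background subsamples matched on UTR-length
quantile bins (5 bins, 10 repetitions, nearest-bin fallback).

## Regulatory-motif simulation

TF protein kinetics follow dY/dt = β(t) − αY with α = ln2 / 10 h and a
box de-repression drive; trajectories are piecewise exponentials in
closed form (no ODE solver error), normalized so the during-impulse
asymptote is 1.  The target gene adds a Gaussian direct de-repression
bump (feed-forward/feed-back motifs only) to a secondary first-order
response gated on Y ≥ θ (θ = 0.6), signed by the TF's activator/repressor
role; the gate's threshold-crossing time is analytic,
t* = onset − ln(1 − θ)/α under full drive (≈13.22 h after onset for the
defaults), and is strictly increasing in both θ and the half-life.  The
kinetic description in terms of production β and decay α follows the
differential equation itself.  Impulse amplitude/duration and the
secondary-response amplitude are free parameters with defaults chosen to
give the qualitative two-peak shape; they are not fitted quantities.

## Synthetic-data generator

The generator plants, in log2 space, exactly the structure the analysis
assumes:

| parameter | default | meaning |
|---|---|---|
| time grid | 2…112 h, 17 pts | microarray schedule (qPCR grid 1–40 h) |
| direct peak | 4 h, FC 1.58, σ=2 h | Gaussian de-repression bump |
| secondary peak | 32 h, FC 1.28, σ=6 h | coherent upward bump on direct genes |
| indirect response | median FC 1.4, lognormal σ 0.55, sign ±, 32 h only | downstream responses |
| noise | sd 0.15 log2, i.i.d. | per gene × time |
| counts | 150 / 1000 / 2500 / 300 | direct / indirect / non-target / housekeeping |
| seed fractions | 0.58 fg / 0.35 bg | carrier probability, direct vs rest |
| UTR-length link | Spearman ρ 0.27 | Gaussian copula to 4 h FC ranks |
| M-A bias | amplitude 0.3 log2 | one sine period over A ∈ [4, 14] |

Bumps are Gaussians truncated at 4σ so planted amplitudes are exactly
recoverable in the noiseless limit.  The indirect amplitude spread is
lognormal because a realistic fraction of downstream responses must
cross the 1.5 responder filter for training-set construction to be
possible at all; a fixed small amplitude would leave the indirect pool
nearly empty and the 32 h responder counts far below what a strong
secondary response produces.  Chance seed occurrences are scrubbed from
designated non-carriers so realized carrier fractions equal the planted
Bernoulli draws.  Housekeeping genes carry no signal and no seeds.  One
RNG stream (seeded once) feeds all sub-generators in a fixed order, so
identical configurations give bitwise-identical outputs.

What the generator does **not** emulate: probe-level array artifacts,
correlated (gene-module) noise, cell-cycle confounding, amplitude
dependence of direct responses on seed-site count or type, 3′UTR
context features, or miRNA-family cross-talk.  Passing tests therefore
demonstrate that the pipeline recovers the planted structure under the
stated noise model — not that it would achieve the same accuracy on
biological data, where class separation is far weaker.

## Problem sizes and numerical choices

The default study (3 950 genes × 17 timepoints) and 50-replicate FDR
were chosen so a full pipeline run completes in well under a minute on a
single core; calibration suites use 500 Monte-Carlo replicates.  Loess
post-normalization uses degree-1 tricube local regression with
span-fraction neighbourhoods and equivalent-kernel pointwise SEs; genes
whose fit SE exceeds 0.02, or whose A lies outside the housekeeping
range, are left unadjusted.  The published description of the SE gate is
ambiguous about direction ("imprecise … S.E. < 0.02 … not adjusted"); we
adjust only where the fit is *precise* (SE ≤ threshold), since skipping
imprecise regions is the evident intent, and expose both threshold and
direction.  The default span 0.5 suits slowly varying bias; removing a
full-period sine bias to < 0.02 per decile needs span ≈ 0.15 with an
abundant housekeeping panel, which is what the quality tests use.
Degenerate inputs (zero-RMS curves, empty responder sets, degenerate
Fisher margins, zero-variance t-test windows) are excluded-with-warning
or raise, as documented per function.

## Known limitations

- The k-NN posterior is an uncalibrated vote fraction; threshold
  semantics (0.75/0.25) follow the analysis convention, not a
  probability model.
- The Louvain-based clustering is a reconstruction of an unspecified
  upstream method; cluster catalogues are not expected to replicate.
- The loess SE is based on a global residual scale estimate (RSS/(n−2)),
  adequate for gating but not a rigorous pointwise confidence band.
- GSEA permutation p-values have resolution 1/(n_perm+1); with the
  default 999 permutations the smallest attainable p is 1e-3.
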