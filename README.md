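# mirdyn

Functional-data analysis of transcriptome dynamics after antimiR-mediated
microRNA inhibition.

When a miRNA is blocked with a complementary antimiR oligonucleotide, its
direct targets are de-repressed within hours, and downstream (indirect)
responses follow later through transcription-factor intermediates.  A
dense expression time course therefore carries a temporal signature that
can separate direct from indirect targets: direct targets show an early
upward impulse (here modelled at ~4 h, linear fold change ~1.58) followed
by a coherent secondary peak (~32 h, ~1.28), while indirect targets show
only the delayed, sign-mixed secondary response.

`mirdyn` implements the full analysis chain for such experiments:

- **Post-normalization** — residual intensity-dependent bias on the M-A
  plot (M = log2 T/C, A = mean log2 intensity) is removed per timepoint by
  centring on a loess fit through a large housekeeping-gene panel,
  skipping genes where the fit is imprecise (SE gate). qPCR validation
  data are quantified by the ΔΔCt rule against the geometric mean of three
  reference genes, with a one-sample *t*-test of the 2–4 h peak.
- **Functional representation** — each gene's log2 fold-change series is
  smoothed with an order-4 B-spline basis (knots at the sampled
  timepoints; 19 basis functions for the 17-point 2–112 h schedule) under
  a second-derivative roughness penalty (λ = 0.05). Derivatives, windowed
  inner products ∫f′g′dt, RMS scaling, and functional PCA all operate on
  exact Gram-matrix integrals, so the uneven sampling grid is handled by
  true functional integration.
- **Target prediction** — a functional k-nearest-neighbour classifier on
  cosine-normalized first-derivative inner products, trained on
  externally predicted direct targets vs seed-free responders, with
  stratified 10-fold cross-validated AUC (Mann–Whitney form,
  Hanley–McNeil SEs), posterior-threshold calls (≥0.75 target, ≤0.25
  non-target), fold-change ranking, shuffle-based FDR (identical pipeline
  rerun on null training sets), and a per-miRNA specificity scan.
- **Response dynamics** — per-timepoint seed-match enrichment (binomial),
  direct/indirect discrimination AUC, rank-based gene-set enrichment
  (weighted KS running sum, gene-label permutation null), up/down
  asymmetry (boundary binomial test of deviation >10% from parity),
  two-timepoint coherence (Fisher exact), TF-target response splits, and
  UTR/CDS seed-effect analyses with shuffled-seed controls.
- **Functional clustering** — mutual k-NN graph on derivative-cosine
  similarity + seeded Louvain communities, minimum cluster size 10, a
  background "cluster 0", and length-matched per-cluster seed-enrichment
  tests.
- **Motif simulation** — closed-form trajectories for coherent
  feed-forward / feed-back / simple-indirect motifs with TF kinetics
  dY/dt = β − α·Y (α from a 10 h half-life) and a target activation
  threshold θ = 0.6, which reproduces the delayed secondary response.
- **Synthetic data** — a generator that plants all of the above structure
  (peak amplitudes, 58% vs 35% seed-site enrichment, UTR-length/FC rank
  correlation 0.27, M-A bias, housekeeping genes, qPCR Ct tables) so the
  entire pipeline is testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from mirdyn import (SynthConfig, generate_timecourse, make_basis,
                    fit_curves, rms_scale, build_training_sets)
from mirdyn.predict import cross_validate
from mirdyn.dynamics import coherence_analysis, seed_enrichment_by_time

cfg = SynthConfig(rng_seed=1)
ds = generate_timecourse(cfg)

curves = fit_curves(ds.fc, make_basis(cfg.time_grid))
sets = build_training_sets(ds.predictions, ds.annotations, ds.fc,
                           threshold=1.5, rng_seed=0)
ids = sorted(sets.direct) + sorted(sets.indirect)
labels = np.array([1] * len(sets.direct) + [0] * len(sets.indirect))
cv = cross_validate(rms_scale(curves, window=(2, 20)).subset(ids),
                    labels, k=11, window=(2, 20), rng_seed=0)
print(f"early-window CV AUC: {cv.auc:.3f} (Hanley-McNeil SE "
      f"{cv.se_hanley:.3f})")

enr = seed_enrichment_by_time(ds.fc, ds.annotations)
best = enr.loc[enr.p_value.idxmin()]
print(f"seed enrichment peaks at t={best.time:g} h: "
      f"{100 * best.fraction:.0f}% carriers, p={best.p_value:.2e}")

coh = coherence_analysis(ds.fc, t1=4, thr1=1.5, t2=32, thr2=1.3)
print(f"coherent fraction among double-responders: "
      f"{100 * coh.coherent_fraction:.0f}%")
```

Output:

```
early-window CV AUC: 0.941 (Hanley-McNeil SE 0.017)
seed enrichment peaks at t=4 h: 56% carriers, p=3.35e-06
coherent fraction among double-responders: 100%
```

The early-window (2–20 h) classifier separates planted direct from
indirect targets almost perfectly; seed-site enrichment among strong
responders is maximal at the planted 4 h de-repression peak; and nearly
all genes responding upward at 4 h that also respond at 32 h do so in the
same (upward) direction — the signature of coherent feed-forward
regulation.

A shell interface mirrors the library:

```sh
mirdyn run-all --out results/ --seed 1
mirdyn simulate-ffl --motif ffl --theta 0.6 --half-life 10 --out traj.tsv
```

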