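# mucosa

Analysis pipeline for studying how autoantibodies against the epithelial
integrin αvβ6 disrupt TGFβ activation in the colonic mucosa. The package
is aimed at mucosal immunologists and computational biologists working
with four kinds of data around this question:

1. **Serology** — ELISA tables of anti-αvβ6 IgG/IgA optical densities in
   ulcerative colitis (UC) vs healthy subjects (HS): ROC/Youden
   seropositivity thresholds, positivity rates, and quantification in
   monoclonal-equivalent binding units via four-parameter logistic
   standard curves with LLOQ handling.
2. **Function-blocking assays** — cell-adhesion and TGFβ-reporter
   plates: per-plate normalisation, the percent-inhibition statistic
   `(1 − sample/HS mean adherence) × 100`, one-sided Welch testing
   against HS wells, and the inhibitory call (≥ 30% inhibition and
   p ≤ 0.05).
3. **Epithelial lineage signatures** — bulk expression matrices from
   treated epithelial cultures: gene-wise Z-scores across samples and
   per-sample mean-Z scores over curated marker sets (absorptive,
   goblet, stem, ...), plus a rank-based single-sample scorer.
4. **Swiss-roll spatial transcriptomics** — digital unrolling of
   spiral-sectioned colon: an Archimedean spiral `r = a + bθ` is fitted
   to the segmented cell cloud, every cell is mapped to colon-length
   position `s ∈ [0, 1]` (proximal → distal) and crypt–lumen depth
   `d ∈ [0, 1]` (base → lumen), and goblet-cell composition is compared
   between genotypes as bootstrap log2 frequency ratios along the colon.

A seeded synthetic-data module (`mucosa.simulate`) emulates every input
kind with known ground truth, so the whole pipeline runs and is tested
without any external download. See `docs/methods.md` for the models,
estimators and their assumptions.

## Worked example

```python
from mucosa import adhesion as ad, serology as se, simulate as sim

# serology: threshold a synthetic 338 HS / 194 UC cohort
table, truth = sim.simulate_serology(sim.CohortSpec(seed=11))
roc = se.compute_roc(table)
thr = se.youden_threshold(roc)
print(f"AUC {roc.auc:.3f}  threshold OD {thr.value:.3f} (J={thr.j:.3f})")
print(se.seropositivity_rates(table, thr))

# adhesion: classify 29 sera, 10 with planted blocking activity
wells, hs_ids, planted = sim.simulate_adhesion(sim.AssaySpec(seed=11))
calls = ad.classify_samples(wells, hs_ids)
print(f"inhibitory: {calls.inhibitory.sum()} of {len(calls)} sera")
```

prints

```
AUC 0.895  threshold OD 0.304 (J=0.793)
         n  n_positive  percent
group
HS     338          44     13.0
UC     194         179     92.3
inhibitory: 10 of 29 sera
```

The AUC says a random UC donor's OD exceeds a random HS donor's with
probability 0.895 in this synthetic cohort; the threshold 0.304 is the
OD cutoff maximising sensitivity + specificity − 1, giving 92.3% UC and
13.0% HS seropositivity at that line. The adhesion classifier recovers
exactly the 10 planted blocking sera.

Unrolling a two-genotype swiss-roll experiment:

```python
from mucosa import simulate as sim, unroll as ur

cells, truth = sim.simulate_swiss_roll(sim.SpatialSimSpec(seed=5))
unrolled = ur.unroll_dataset(cells)                  # one spiral fit per section
ratios = ur.compare_composition(unrolled, n_bins=3, seed=5)
mid = ratios.query("bin == 1 and cluster == 'canonical_gc_mid'").iloc[0]
print(f"mid-colon log2(KO/ctrl) = {mid.log2_ratio:.2f} "
      f"[{mid.ci_low:.2f}, {mid.ci_high:.2f}]")
```

prints `mid-colon log2(KO/ctrl) = 0.99 [0.84, 1.15]` — the planted
2-fold mid-colon expansion of a canonical goblet-cell cluster is
recovered with a bootstrap CI that covers 1 and excludes 0.

The same operations are scriptable from a shell via the `mucosa`
console command (`mucosa simulate …`, `mucosa serology roc …`,
`mucosa adhesion classify …`, `mucosa signatures score …`,
`mucosa unroll run …`).

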