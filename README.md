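# neuroplex

Multiplex structure–function connectome analysis for resting-state
electrophysiology: band-limited functional connectivity (phase-locking
value, weighted phase-lag index, transfer entropy) fused with weighted
structural connectivity (tract FA) into density-matched two-layer
multiplex networks, scored with the multiplex participation
coefficient, and analysed with a two-group / median-split / FDR
statistical workflow. A synthetic-cohort generator with planted ground
truth makes the entire chain testable end to end without any data
download.

The intended users are researchers studying how the similarity of
structural and functional connectivity patterns varies across brain
regions, frequency bands and groups (e.g. young vs old cohorts), and
how that similarity relates to cognitive performance.

## The model in brief

Per subject, each frequency band is anchored at the individual alpha
frequency (IAF): delta (IAF−8, IAF−6), theta (IAF−6, IAF−2), alpha
(IAF−2, IAF+2), beta (IAF+2, IAF+14), gamma (IAF+15, IAF+80). ROI time
series are band-limited and converted to analytic signals (zero-phase
FIR + Hilbert transform); pairwise functional connectivity is estimated
as PLV, wPLI or transfer entropy. Each functional layer is paired with
the subject's structural FA matrix; both layers are binarised by
keeping the ⌊density · possible edges⌋ strongest edges (the density
convention is 22%, the older group's minimum structural density), and
each node *i* is scored with the multiplex participation coefficient
over the M = 2 layers,

    p_i = M/(M−1) · [ 1 − Σ_α ( k_i^[α] / o_i )² ],

where k_i^[α] is the node's degree in layer α and o_i = Σ_α k_i^[α] its
overlapping degree: p_i = 1 when the node engages both layers equally,
0 when a single layer holds all its edges. Group contrasts
(covariate-adjusted pooled t), median-split subgroups (the four
individuals nearest the median on each side removed), cognition
regressions (partial or Spearman) and Benjamini–Hochberg FDR per
analysis family complete the workflow. See `docs/methods.md` for the
full account, including the synthetic generator's oscillator and
planting models.

## Worked example

`examples/03_multiplex_participation.py` builds a 32-node functional
matrix, generates FA-like structural matrices at three overlap levels,
binarises both layers at 22% density and scores participation:

```
structural overlap 1.0: mean participation 1.000 (edges shared: 109 of 109)
structural overlap 0.5: mean participation 0.949 (edges shared: 53 of 109)
structural overlap 0.0: mean participation 0.922 (edges shared: 0 of 109)
```

Identical layers give p_i = 1 at every connected node; as the layers
decouple, the per-node degrees diverge between layers and participation
falls. `examples/04_group_statistics.py` plants a participation deficit
(d = −2) at two nodes of a 46+46 cohort and recovers it through the full
pipeline (the planted nodes 1 and 5 carry positive young-minus-old t):

```
nodal group contrasts (young - old), FDR q = 0.05:
    node         t     p_raw     p_fdr
1      1  3.170902  0.002085  0.013899
5      5  3.257667  0.001591  0.013899
10    10 -3.603951  0.000516  0.010321
11    11 -2.739639  0.007431  0.037154
median split at node 1: 19 low / 19 high (8 removed)
VSTM ~ participation (education-adjusted): r = 0.688, slope = 0.411 +/- 0.066, p = 0.0000 (planted slope 0.5)
```

The slope estimate brackets the planted 0.5 within 2 standard errors;
the two opposite-signed extra contrasts are the compositional side
effect of so strong a planting (see the methods note). The numbers are
seeded and reproduced exactly by running the scripts.

The other examples cover oscillator simulation and IAF-anchored bands
(`01`), the three connectivity estimators on known ground truth (`02`)
and the file-writing end-to-end pipeline (`05`). A thin CLI wraps the
same library:

```bash
neuroplex simulate --config cfg.yaml --out cohort/
neuroplex run --config cfg.yaml --out results/
```

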