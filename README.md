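# causalflow

Directed "information flow" analysis of parcellated resting-state BOLD time
series, built for studies that ask *which brain regions predominantly send
and which predominantly receive information*, and whether that pattern
separates clinical groups (e.g. early mild cognitive impairment vs healthy
controls) and predicts cognitive or biomarker scores.

## The model

For every ordered pair of regions (i, j), the directed influence is a
pairwise Granger causality computed on delay-embedded signals:

    GCA(i, j) = max( 0,  ln[ RSS_restricted / RSS_full ] )

where the restricted regression predicts region *j*'s signal from its own
*p* lags and the full regression adds region *i*'s lags.  Two regression
back-ends are provided:

* **linear** — ordinary least squares (classical linear Granger causality);
* **product-Gaussian kernel** (default) — non-parametric multiplicative
  regression: a Nadaraya–Watson estimate whose multivariate kernel is the
  *product* of univariate Gaussian kernels over the lag columns, scored by
  leave-one-out residuals so the richer model cannot win by overfitting.
  This variant also detects nonlinear (e.g. quadratic) coupling that linear
  GCA is blind to.

From the connectivity matrix G two flow measures follow:

* **preferred information-flow direction**
  `P(i, j) = GCA(i, j) / [GCA(i, j) + GCA(j, i)]` — values above 0.5 mean
  region *i* predominantly sends to region *j* (0/0 is defined as 0.5);
* **preferred information-flow index** — region *i*'s mean of `P(i, j)`
  over all other regions *j*; above 0.5 flags a net sender, below 0.5 a
  net receiver.

Downstream, edge- and node-wise two-sample t-tests with Benjamini–Hochberg
FDR control compare the two groups; FDR-significant features feed a
leave-one-out cross-validated support-vector classifier, and lasso
regression predicts continuous outcomes, scored by Pearson's r.

Because real cohorts of this kind are access-controlled, the package ships
a first-class synthetic-cohort generator (stationary VAR(1) with optional
quadratic edges, group effects on selected couplings, outcomes generated
from the true population flow features) so that every stage is testable
against known ground truth.

## Worked example

```python
import causalflow as cf

# a ground-truth network with a reciprocal pair whose forward coupling
# is tripled (0.25 -> 0.75) in the "patient" variant
net   = cf.default_network(n_regions=8)
net_b = net.with_effects([(0, 1, 3.0)])

ts  = cf.simulate_subject_timeseries(net_b, T=500, tr=3.0, seed=11)
res = cf.InformationFlow(ts).fit()
print(res.summary())
```

```
Information flow results
====================================================
regions: 8   timepoints used: 499   TR: 3 s
estimator: product_gaussian (p=1, residuals=leave_one_out)
----------------------------------------------------
  region   flow index       role
       1       0.5655     sender
       2       0.5776     sender
       3       0.3614   receiver
       ...
```

For this subject `G[0,1] = 0.3999` and `G[1,0] = 0.0967`, so
`P[0,1] = 0.8052`: region 1 sends about four times as strongly as it
receives across the planted edge, and its flow index (0.57) flags it as a
net sender.

A two-group comparison on twenty subjects per arm:

```python
import numpy as np
rng = np.random.default_rng(0)
def cohort(network, n):
    return [cf.InformationFlow(cf.simulate_subject_timeseries(
        network, 500, 3.0, seed=int(rng.integers(0, 2**31 - 1)))).fit().flow
        for _ in range(n)]

comp = cf.GroupFlowComparison(cohort(net, 20), cohort(net_b, 20),
                              group_labels=("HC", "EMCI")).fit()
print(comp.summary())
```

```
Group information-flow comparison
====================================================
HC: n=20   EMCI: n=20
test: student t, BH-FDR q < 0.05
significant edges: 4 / 28
significant nodes: 0 / 8
  region_1->region_2: t=-12.72 q=0.0000 (increased in EMCI)
  ...
```

The planted edge (region 1 → region 2) is the top discovery: its preferred
direction rises from ≈0.5 in controls to ≈0.8 in the effect group.

The same analysis runs from the shell:

```bash
causalflow run-all --mode synthetic --n-regions 12 --n-per-group 20 20 \
    --timepoints 140 --seed 1 --out results/run1
```

which writes per-subject G and P matrices (TSV), edge-/node-wise statistics
(CSV), classification and prediction reports (JSON), and a manifest with a
content hash for every artifact.

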