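# habitatrates

Phylogenetic comparative analysis of whether **structural habitat use drives
the rate of morphological evolution**. The package targets radiations (the
motivating system is a lizard family with ~90 sampled species) in which each
species uses one of four structural habitats — rock, terrestrial,
semi-arboreal, arboreal — and asks whether lineages in different habitats
have diversified in size and shape at different rates.

It is written for comparative biologists who have:

* an ensemble of ultrametric trees (e.g. a posterior sample), branch lengths
  in relative time (root depth 1.0);
* a species → habitat assignment;
* individual-level linear morphometric measurements.

## The model

Ancestral habitat use is reconstructed by **stochastic character mapping**:
habitat evolves by a continuous-time Markov (Mk) process with rate matrix
*Q*; full histories ("maps") are sampled conditional on the tip states, so
every point of every branch carries a habitat state. Sampling many maps over
many trees integrates over reconstruction uncertainty.

Species morphology is summarized by **PCA on the correlation matrix** of
species mean log-measurements. Individuals are projected through the same
eigenvectors to estimate, for each axis, the pooled within-species variance;
each species' **sampling variance** is that pooled variance divided by its
individual count *n*ₛ.

Trait evolution follows **multi-rate Brownian motion**: a candidate model
partitions the four habitats into rate classes and assigns one rate σ²ᶜ
(trait variance per unit relative time) to each class. Under a map, the
expected covariance of species values is

    V = Σₖ σ²_class(k) · Sₖ + diag(pooled var / nₛ)

where *Sₖ*(i,j) is the time the shared root-to-tip path of species *i* and
*j* spends in habitat *k* (the *noncensored* likelihood — branches contribute
by state occupancy; the tree is never split). The likelihood is multivariate
normal; the ancestral mean (root state) is profiled out as its GLS estimate
and the rates are maximized numerically.

Ten candidate partitions are compared — the 4-rate full model, three 3-rate
models merging habitats with hypothesized shared effects, four 2-rate
models isolating one habitat, a 2-rate "incline vs ground" model, and the
1-rate null — using **AICc** (k = rate classes + root state, n = species),
**ΔAICc**, **Akaike weights**, and per-habitat **model-averaged rates**
Σₘ wₘ σ²ₘ(h), all summarized over the reconstruction ensemble.

## Worked example

The package ships a synthetic-study generator that mirrors the analysis
design (90 species, trees at root depth 1.0, 500 reconstructions = 50
jittered trees × 10 maps, four habitats, strongly habitat-structured rates,
1–36 individuals per species with median 4):

```python
from habitatrates import ensemble_pipeline as ep
from habitatrates import morphometrics as mo
from habitatrates import synthetic_data as sd

ds = sd.simulate_dataset(sd.SimConfig(seed=1))      # 500 reconstructions
pca = mo.pca_correlation(mo.species_means(ds["measurements"]))
print(round(float(pca.pct_total.iloc[0]), 1))        # 95.4  (% variation on PC 1)

traits = mo.sampling_variances(ds["measurements"], pca, 4)
summary = ep.run_ensemble(ds["maps"], traits)        # 10 models × 4 axes × 500 maps
tbl = summary.fits["pc1"]
print(tbl.loc[tbl["delta_aicc"].idxmin(), "model"])  # 2-rate incline-ground
print(round(float(
    tbl.loc[tbl["model"] == "1-rate no effect", "delta_aicc"].iloc[0]), 2))  # 4.17
```

The first number is the percent of between-species variation captured by the
dominant size axis. The second line names the AICc-preferred model for size
evolution on this synthetic study — a multi-rate model, as expected given
the generating rates (rock 1, arboreal 5, terrestrial 25, semi-arboreal 125
in trait² per unit tree depth). The last number is the single-rate null's
ΔAICc: above 2, i.e. the null is disfavoured once habitat-linked rate
variation is present.

The same pipeline runs from the shell on files
(`habitatrates simulate | map | pca | fit | ensemble | report`); see
`habitatrates --help`.

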