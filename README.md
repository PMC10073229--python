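# symbiolipo

Single-cell lipid-peroxidation profiling of coral algal symbionts.

Reef corals live in symbiosis with dinoflagellate algae. When the symbiosis
breaks down — during bleaching, or in the background turnover of healthy
colonies — individual algal cells change their metabolism long before any
colony-level signal appears. Two single-cell markers capture that change:
the amount of storage lipid a cell carries, and how peroxidised that lipid
is. Both are measurable in living cells with a ratiometric dye whose
emission shifts when lipids are oxidised, so a two-channel confocal stack
yields, per lipid body, an oxidised/reduced fluorescence ratio that is
independent of dye concentration.

`symbiolipo` is a library for that analysis end to end:

1. **Segmentation** — detect lipid bodies in a two-channel z-stack as
   26-connected components of the combined lipid signal above an Otsu (or
   fixed) threshold inside a cell mask, and measure per-channel means on the
   raw data.
2. **Per-cell metrics** — the cell's LPO ratio (unweighted mean of its
   lipid-body ratios, r̄ = (1/n)Σ ox_i/red_i) and lipid-store volume
   (V = Σ area_i × Δz, summed ROI area times slice thickness), after
   excluding inclusion bodies by explicit area/ratio cut-offs and averaging
   co-hosted symbiont pairs.
3. **Normalisation & statistics** — values relative to each species'
   endosymbiont mean; Shapiro–Wilk / Levene assumption checks with log or
   √ transforms; cell-type contrasts from the REML linear mixed model
   y = Xβ + colony intercept + ε with Satterthwaite denominator degrees of
   freedom; BIC comparison of candidate fixed-effect structures.
4. **Metabolic phenotyping** — Euclidean K-means on (relative lipid volume,
   relative LPO ratio); cluster count diagnostics (WSS elbow, silhouette,
   gap statistic with 100 bootstrap reference draws); per-cluster
   endosymbiotic/ex-symbiotic composition; and condition shifts by
   assigning, e.g., heat-treated cells to control centroids.
5. **Synthetic ground truth** — a generator for confocal-like stacks with
   planted bodies of known ratio/size/count and for per-cell tables drawn
   from a three-profile mixture with species/colony structure, so every
   stage is testable without microscope data.

## Worked example

`examples/02_profiles_from_cell_table.py` draws the default synthetic study
(three coral species, four colonies each, 450 cells from three latent
metabolic profiles with endosymbiont mixes 0.90/0.34/0.00), normalises,
clusters and prints:

```
450 cells, WSS = 48.3
centroids (rel volume, rel LPO):
  cluster 1: (0.72, 1.11)
  cluster 2: (2.21, 0.57)
  cluster 3: (4.37, 0.44)

endo:ex composition per cluster (%):
cluster  endosymbiotic  ex-symbiotic
1                 92.4           7.6
2                 38.1          61.9
3                  0.0         100.0
```

Clusters are numbered by descending LPO: cluster 1 is the high-LPO,
low-lipid profile dominated by active endosymbionts, cluster 3 the
high-lipid, low-LPO profile of ex-symbiotic cells, and cluster 2 the mixed
transition profile — each composition within sampling error of the planted
mix. The other examples cover image simulation and segmentation recovery
(`01`), mixed models and BIC (`03`, where the colony-mean reading gives
t(3) ≈ −12 to −15 for the LPO contrast), and heat-stress profile shifts
(`04`).

A thin CLI mirrors the library (`symbiolipo simulate|segment|quantify|
normalise|cluster|stats|run`); see `symbiolipo --help`.

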