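# dggekit

Analysis of PCR-DGGE community fingerprints: band detection from gel lane
densitometry, reference-marker normalization, cross-lane band matching,
diversity and stability statistics, and UPGMA clustering — plus a
ground-truthed synthetic gel simulator so the whole chain can be tested
without gel images.

## Who this is for

Denaturing gradient gel electrophoresis (DGGE) separates equal-length PCR
amplicons of a taxonomic biomarker (16S rDNA V-regions, *rpoB*, ...) by their
sequence-dependent melting position along a chemical denaturant gradient.
Each gel lane is a community fingerprint: one band ≈ one dominant phylotype,
band intensity ≈ abundance.  Microbiologists monitoring engineered
ecosystems — here, autothermal thermophilic aerobic digestion (ATAD) of
sludge, where the community turns over as reactors heat from mesophilic
inlet to a ~60 °C thermophilic stage — use such fingerprints to track
community structure, stability and succession over process time.  This
package implements the complete numerical side of that workflow on 1-D lane
intensity profiles (it does not process gel images).

## What it computes

Given a lanes × migration-position intensity matrix:

1. **Band detection** — rolling-minimum background subtraction, prominence-based
   peak search, and the inclusion rule that keeps only bands whose peak height
   exceeds 1.0% of the strongest band in the same lane.
2. **Normalization** — a piecewise-linear warp fitted through the observed bands
   of a known six-species reference marker lane maps every lane onto common
   coordinates; each band then gets a denaturant percentage (denaturant is
   linear in migration distance across the gel's stated range, e.g. 35–75%).
3. **Band matching** — single-linkage 1-D clustering of normalized band
   positions (default tolerance 0.5 denaturant-%) produces the lanes ×
   band-classes presence/absence matrix.
4. **Diversity / stability statistics** —
   * richness `S` (band count) and Shannon `H′ = −Σ pᵢ ln pᵢ` over relative
     band intensities;
   * pairwise % similarity (Dice: `100 · 2·common/(Sₐ+S_b)`), % change
     `= 100 − % similarity`, the moving-window curve of % change between
     consecutive samples, and its mean `Δt` (rate of community change);
   * range-weighted richness `Rr = N² × Dg`, with `Dg` the fraction of the
     denaturing gradient between a lane's first and last band;
   * unique-band counts (classes found in exactly one lane).
5. **Clustering** — UPGMA dendrogram on `100 − % similarity`, exported as
   Newick with ultrametric branch lengths.

The simulator (`dggekit.synthetic_data`) plants a seven-stage ATAD
succession — mesophilic species declining through Reactor 1A, new
thermophilic species appearing in Reactor 2A at higher denaturant
positions, a persistent core surviving throughout — and renders it as
Gaussian bands on a noisy, smoothly-warped baseline, with flanking marker
lanes and full ground truth.

## Worked example

```sh
dggekit run --outdir demo --seed 1
dggekit summarize demo
```

prints

```
lane         S   H_prime        Rr      Dg  unique
--------------------------------------------------
inlet       10    2.2245   40.7236  0.4072       -
R1A_4h       9    2.1365   32.9861  0.4072       -
R1A_8h       9    2.0584   32.9861  0.4072       -
R1A_16h      8    1.7990   26.0631  0.4072       -
R2A_4h       8    1.9645   41.2578  0.6447       5
R2A_23h      9    2.1175   60.9091  0.7520       6
product      9    2.1768   50.4931  0.6234       -
rate of change Dt = 39.8592
```

Reading the table: richness `S` declines through Reactor 1A (8 bands at
16 h), then the thermophilic lanes span a much wider slice of the gradient
(`Dg` 0.64–0.75 versus ~0.41) because new thermophilic bands sit further
down the gel, which lifts their range-weighted richness `Rr`.  The two
Reactor-2A lanes carry 5 and 6 bands found nowhere else (11 new bands in the
thermophilic stage).  `Δt ≈ 39.9` is dominated by the moving-window peak at
the `R1A_16h → R2A_4h` transition (75% change in this run — see
`demo/report.json`), and the dendrogram in `demo/tree.nwk` places the two
thermophilic lanes in their own cluster:

```
(((inlet,((R1A_4h,R1A_16h),R1A_8h)),product),(R2A_4h,R2A_23h));   # topology
```

Every stage is also available separately (`dggekit simulate / detect /
normalize / match / indices / cluster`) and as library functions.

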