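# Methods

## Coordinate model

A lane is a densitometric trace on a migration axis normalized to [0, 1]
(0 at the well, 1 at the gel bottom).  Denaturant concentration is taken
to be **linear in migration distance** across the gel's stated range
(e.g. 35–75%), so a normalized position maps to denaturant by linear
interpolation.  Gel hardware never reports this mapping; linearity is
the standard DGGE casting assumption and is what makes the spanned
gradient fraction `Dg` computable.  All gels are handled as 1-D
profiles; image processing (lane finding, TIFF I/O) is out of scope.

## Band detection

* **Background**: rolling minimum over a `background_window` span
  (default 0.05 migration units, several band widths) followed by a
  moving-average smooth of the same span — a 1-D morphological opening.
  The residual is clipped at zero.  Under additive noise the rolling
  minimum sits ~2–2.5 noise SD below the true baseline, which biases
  subtracted heights slightly upward; this is why the prominence floor
  below is set well above the noise SD.
* **Peak search**: local maxima (`scipy.signal.find_peaks`) with an
  absolute prominence floor `min_prominence` (default 5.0 intensity
  units, i.e. 10× the simulator's default noise SD) and a minimum mutual
  separation `min_separation` (default 0.008 = 2× the default band
  sigma: peaks closer than gel resolution are one band — comigration).
* **Inclusion rule**: bands with peak height below `min_rel_height`
  (default 1.0%) of the strongest surviving band in the same lane are
  dropped.  Heights are background-subtracted — the rule could equally
  be applied to raw heights; the subtracted convention is this package's
  choice.  The relative rule is scale-invariant; the prominence floor is
  deliberately absolute (a pure noise gate) and is the one detection
  parameter that must be rescaled if intensities change units.
* Peak **height**, not area, is the intensity measure throughout.

## Marker normalization

Each gel carries a reference lane: six known bacterial strains with
distinct melting positions spanning 90% of the gradient, loaded equally.
A strictly monotone piecewise-linear map is fitted through the observed
marker bands onto the known reference positions (order-preserving 1:1
pairing; linear extension past the terminal anchors).  If the detector
found exactly one extra band in the marker lane, the weakest is dropped
with a warning; any other count mismatch aborts — with the pairing
ambiguous, silently guessing would corrupt every downstream position.
One band too few is likewise an abort rather than a guess: there is no
way to know which reference anchor is missing.

With one marker lane its map applies to all lanes.  With two flanking
markers, each sample lane receives the pointwise convex combination of
the two fitted maps, weighted by its lane index between them.  This
assumes distortion varies smoothly across the gel — the standard
rationale for flanking references.  The blend of inverses differs from
the inverse of the blended distortion only at second order in the warp
amplitude (≲0.001 migration units at warp 0.03), far below the matching
tolerance.

## Band matching

Normalized bands from all lanes are pooled and clustered in one
dimension by single linkage, cutting links wider than `tolerance`
(default 0.5 denaturant-%: below a typical band width, above the
normalization residual).  Single linkage cannot split a run of mutually
close bands, so chained classes wider than 3× the tolerance are re-split
at their largest internal gap.  A lane contributing two bands to one
class keeps the taller (warned).  Class position = mean member
denaturant.

## Statistics

* `S` — presence count of a matrix row.
* `H′ = −Σ pᵢ ln pᵢ` over relative band intensities (nats by default;
  base is a flag).  Empty lane → NaN, deliberately distinct from the
  single-band value 0.  Intensities are used **only** here; similarity,
  uniqueness and clustering are binary, as band-intensity comparison is
  much less reproducible across gels than band presence.
* % similarity — Dice/Sørensen `100 · 2·common/(Sₐ+S_b)`, the standard
  band-based coefficient; Jaccard behind a flag.  Two empty lanes are
  defined 100% similar (no change between nothing and nothing), warned.
* % change `= 100 − % similarity`; the moving-window curve lists the %
  change of each consecutive pair in the sample order; `Δt` is the
  arithmetic mean of the curve.
* `Rr = N² × Dg` with `Dg` = (last − first band denaturant) / gradient
  span, a **fraction in [0, 1]**.  The fraction (not percent) convention
  is forced by consistency of the published values with their band
  counts (e.g. N = 18 with Rr = 113.9 implies Dg ≈ 0.35, a plausible
  third of the gel; a percent reading would imply 0.35% of the gel).
  N ≤ 1 gives a degenerate span: Dg = 0, Rr = 0.
* Unique bands — a class is unique to lane L iff L is the only lane in
  the **whole** matrix containing it; focal-subset totals equal the
  per-lane sum because uniqueness is exclusive by construction.

The printed form of the rate-of-change formula in the source material is
typographically garbled; it is implemented from its prose definition
(the average of the moving-window curve points).

## UPGMA

Distance = 100 − Dice similarity.  Agglomeration merges the closest pair
(ties broken by smallest cluster-id pair, so trees are reproducible);
the merged cluster's distance to others is the size-weighted mean of its
members' distances; merge height = distance / 2, giving an ultrametric
tree.  Newick branch lengths carry 12 significant digits so a parsed
tree reproduces heights to 1e-9; children print smallest-leaf-first.
The implementation is self-contained and is cross-checked in the tests
against scipy's average-linkage as an independent oracle.

## Synthetic gel generator

The simulator emulates a seven-lane ATAD series (inlet; Reactor 1A at
4/8/16 h; Reactor 2A at 4/23 h; product) between two flanking marker
lanes, on a 35–75% gradient by default.

**Succession scenario** (chosen once as the study conditions): a pool of
12 mesophilic species with well-separated melting positions in the upper
(low-denaturant) 5–45% of the gradient, 6 of them a persistent core;
inlet richness 10, declining to 8 by 16 h in Reactor 1A.  At the
mesophilic→thermophilic transition a `turnover` fraction (default 0.75,
i.e. 6 of 8 species) is replaced by new thermophiles whose positions
centre `thermo_shift` = 15 denaturant-% above the 16-h community mean
(jitter SD 4, rejection-sampled to keep ≥ 1 denaturant-% spacing from
all existing bands — distinct species closer than the matching tolerance
would be scientifically indistinguishable on a real gel too).  Reactor
2A at 23 h keeps one 4-h thermophile and gains six fresh ones; the
product lane reverts to a mesophilic profile plus that one adapted
thermophile.  This yields 5 and 6 lane-exclusive thermophilic bands
(11 new bands at the thermophilic stage) and richness values in the
published range.  Abundances are log-normal (median 40, σ = 0.5,
floor 10) per stage.

**Rendering**: each member is a Gaussian of constant width
(`band_sigma` = 0.004 migration units) and height = abundance, at the
warped image of its melting position; plus a half-cosine baseline
(amplitude 6, strongest at the well, emulating loading smear) and
additive Gaussian noise (SD 0.5, trace clipped at 0); 2000 grid points.
With the abundance floor at 10 the weakest planted band has SNR 20.

**Warps**: two end-of-gel warps are drawn (piecewise-linear, interior
knot offsets uniform in ±`warp_amp`, default 0.01, endpoints fixed) and
each lane's warp interpolates between them by lane index.  Interior warp
knots sit on a subset of the marker band positions, so the
marker-anchored piecewise-linear normalization model can represent the
true distortion exactly — an identifiability choice: a warp the marker
cannot express would make exact recovery impossible for *any* marker
method, which is a statement about gels, not about this algorithm.

**What the simulator does not model** (so what passing tests do not
show): PCR amplification bias, 16S copy-number variation, heteroduplex
artefacts, band-width variation with position, saturation and
comigration of unrelated sequences, and thermodynamic melting prediction
of band positions (positions are phenomenological).  Recovery results on
synthetic gels therefore validate the numerics, not the biology of a
real gel.

## Problem sizes and determinism

Default analyses use 9-lane, 2000-point gels; the detection benchmark in
the tests aggregates 50 seeded replicates; clustering cross-checks run
on 1000 random ≤6-leaf matrices.  Every random draw flows from a single
integer seed through named `numpy` generator streams, so identical
configurations give bit-identical gels, reports and trees.
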