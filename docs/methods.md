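# Methods

## Scope and model

`kmdmsi` implements a Kendrick-mass-defect workflow for positive-mode
MALDI FT-ICR imaging of lipids: per-pixel centroiding, cross-pixel
alignment, projection to (m/z, KM, KMD) space, window filtering,
series grouping, adduct/isotopologue collapsing, exact-mass annotation
and ion imaging.  All ions are treated as singly charged cations
([M+H]+, [M+Na]+, [M+K]+), which covers the lipid classes the workflow
targets (glycerides, glycerophospholipids, sphingomyelins,
lysophospholipids, sterols, acylcarnitines).

### Mass arithmetic

Monoisotopic atomic masses (Da): C 12 (exact), H 1.00782503,
N 14.00307401, O 15.99491462, Na 22.98976928, P 30.97376163,
K 38.96370649, ¹³C 13.00335484; electron 0.00054858, proton
1.00727646.  Protonated ions are M + proton; metal adducts are
M + atom − electron.  The two conventions are consistent because
proton = H − e⁻ (asserted to 1e-7 Da).  With these constants the
bundled regression fixture of published annotation tables reproduces
every identified monoisotopic row's theoretical m/z to 4 decimal
places and every printed |ΔM| to 0.2 ppm.  Known exceptions carried in
the fixture's `note` column:

* two *first-isotope* rows print masses ~1.2e-4 Da above the additive
  value (monoisotopic mass + 1.00335484); the original isotope-mass
  convention is unstated, so no agreement is forced;
* one potassiated TG row sits on a rounding boundary (computed
  ...51486 vs printed ...52, still within 1e-4);
* one row's printed composition and one row's printed name/composition
  are internally inconsistent with their own printed theoretical mass
  and were corrected during curation (a sodiated PC composition typo,
  and a lysophospholipid row whose printed mass corresponds to the
  O-19:2, not O-21:2, species).

### Kendrick projection

KM = m/z × 14.00000/14.01565; KMD = round(KM) − KM with three rounding
conventions (floor, ceiling, nearest).  Ceiling is the default because
it places lipid KMDs in the interior of [0, 1] (all published table
ions fall in [0.10, 0.50]).  KM values within 1e-9 of an integer snap
to a KMD of exactly 0, so exact CH2 multiples are stable under float
rounding.  Adding k exact CH2 masses changes KM by exactly k nominal
units, so KMD is invariant to 1e-9 — the property tests assert this.

### Isotopologue model

The isotope pattern is a carbon-only binomial: isotopologue k has
offset k × 1.00335484 Da and abundance Binom(n_C, 0.0107) at k,
normalised to the monoisotopic peak.  Minor isotopes of H/N/O/P and
the fine structure FT-ICR could resolve are deliberately ignored: for
CHNOP(K/Na) lipids carbon dominates the A+1/A+2 envelope, which is all
the validation cosine uses.

## Synthetic phantom

The generator emulates the acquisition conditions the pipeline is
designed for, with complete ground truth.

* **Geometry** — a 64×64 grid at 50 µm pitch (configurable ≥16×16;
  anatomy drawn in fractional coordinates).  Seven disjoint organ
  regions on a gelatin background: cuticle ring, brain, chelicerae,
  heart, ovary (with shell/core sub-masks), silk glands, digestive
  tubules.  The anatomy is schematic geometry; only region-conditional
  statistics matter for testing.
* **Instrument** — Gaussian peaks with FWHM(m) = m/R(m), R(m) =
  300,000 × 400/m (the FT-ICR 1/m law anchored at the stated 300,000
  FWHM at m/z 400); acquisition window 200–1400 m/z; mass jitter
  ε ~ Normal(0, 1 ppm) per peak so 99.7% of centroids stay within the
  3 ppm accuracy envelope; multiplicative log-normal intensity noise
  (CV 0.15); profile sampled at 6 points per FWHM on windows of ±3.5
  FWHM per peak (the gaps between windows carry no samples, mirroring
  a reduced profile export).  The true sinc/apodized FT-ICR line shape
  is not modelled — Gaussians are sufficient to exercise centroiding.
* **Chemistry** — planted species use real published compositions:
  TG series in the cuticle (Na/K-weighted), PA species in the ovary
  with K-weighted adducts on the shell and Na-weighted in the core
  (mirroring the follicular potassium microenvironment the imaging
  revealed), PC series in brain/heart/digestive tubules, LPC/LPE in
  the ovary, two sterols in the chelicerae, hexanoylcarnitine in the
  silk glands.  Base intensities sit in the 1e8–1e10 counts range of
  the published table intensities; per-organ per-pixel calibration is
  not attempted because only single averaged intensities are
  published.  Every species also carries a small [M+H]+ component so
  adduct families are connected to their protonated anchor.  Three
  isotopologues are simulated per ion.
* **Matrix background** — six CHCA cluster ions in every pixel:
  [M+Na]+, [M+K]+, [2M+H]+, [2M+Na]+, [2M+K]+, [3M+H]+.  The
  protonated monomer (m/z 190.05) is excluded because it falls below
  the 200–1400 acquisition window.  None of the six differ by a CH2
  multiple within 2 ppm, so they never align horizontally — which is
  exactly why matrix clusters are recognisable and removable in KMD
  space.
* **Reproducibility** — one `numpy` SeedSequence per dataset, spawned
  per pixel; identical seeds give byte-identical ground truth.

What passing tests on the phantom do *not* show: robustness to
baseline drift, peak-shape asymmetry, space-charge m/z distortion
correlated across pixels, matrix suppression, or chemical noise
continua.  Real acquisitions need the recalibration stage and possibly
wider tolerances.

## Processing choices

* **Centroiding** — `scipy.signal.find_peaks` with the stated
  defaults (threshold 200,000 counts, prominence 0, distance 5
  points); 3-point parabolic interpolation refines each apex.  The
  distance parameter is defined in profile data points and is applied
  only to profile input; it has no meaning for already-centroided
  data.
* **Alignment** — single-linkage gap clustering of the pooled sorted
  centroid list: a new bin opens when the gap exceeds the tolerance
  (default 3 ppm, the acquisition's targeted accuracy; the original
  processing did not state a value).  Representative m/z is the
  intensity-weighted mean; same-pixel members are summed so TIC is
  conserved.  The procedure is deterministic and pixel-order
  invariant.
* **Recalibration** — a simplified lock-mass model: match centroids to
  reference m/z, fit ppm(m) = a + b·m by least squares, apply the
  inverse.  The cited external recalibration method is out of scope;
  its parameters (st 0.0003, tl 0.02, lm 0.002) are recorded in the
  config for provenance only.  Off by default for synthetic data,
  whose jitter is white rather than systematic.
* **CH2 chaining** — edges between points whose mass difference is
  within 2 ppm (measured against the heavier member) of k × 14.01565
  for integer k ∈ [1, k_max]; series are connected components with ≥2
  members.  **k_max defaults to 6**: the longest published series
  spans 4 CH2 units, and allowing k ≥ 10 admits a near-exact
  cross-class isobar — the potassiated TG vs protonated PA pair
  differs from exactly 10 CH2 by ~0.12 mDa (2C+K vs 2O+P, ≈0.14 ppm
  at m/z 868) — which would bridge unrelated
  families in a single jump.  k_max 6 keeps 50% margin over real
  series spans while excluding that coincidence.
* **Vertical chaining** — the same machinery with step masses H2
  (2.01565) and O (15.99491); components are restricted to a total
  span of 3 steps, since vertical groups collect close unsaturation/
  oxidation variants rather than long ladders.
* **Collapsing** — for each point a partner is sought at m/z − shift
  (Na−H, K−H, ¹³C) within 2 ppm; union-find merges chains, the
  lowest-m/z member is the canonical protonated monoisotopic species,
  intensities are summed.  Ambiguous partners resolve to the smallest
  |ppm| and are logged.  The KMD-class pre-grouping tolerance (0.0025
  KMD units ≈ 2 mDa at the CH2 scale, matching 2 ppm at m/z ~800) is
  config-exposed.
* **Clouds** — analyst-drawn rectangles/polygons in (m/z, KMD) space,
  boundary inclusive (`shapely` for polygons).  No automatic density
  clustering by default: the published clouds are analyst selections.
* **Annotation ranking** — candidates within 6 ppm are accepted;
  above 4 ppm they are flagged *hypothetical* (the published
  discussion treats ΔM > 4 ppm annotations as tentative, and the
  largest printed match is 5.5 ppm, so a 5 ppm hard cut would reject a
  published assignment).  Ordering: ascending |ΔM|; within 0.3 ppm
  near-ties a positive-mode class priority list applies, with DG/MG
  ranked above TG because sodiated DGs and potassiated TGs are
  ~0.15 mDa isobars (3C+Na vs 4H+O+K) that mass error cannot separate
  and the published assignments resolve toward the DG; name is the
  final tie-break, making the order total and deterministic.
  Oxidation caps (≤10 double bonds, ≤10 oxygens, config-exposed)
  remove implausibly oxidised candidates before ordering.  PC/PE (and
  LPC/LPE) isomer pairs share one record with a joint name — imaging
  alone cannot distinguish them without MS/MS.
* **Imaging** — images are additive over consensus bins; cloud images
  deduplicate bins so image(A∪B) = image(A) + image(B) holds exactly
  for disjoint sets.  Per-pixel-TIC normalisation guards zero-TIC
  pixels.  Percentile clipping happens only at PNG rendering, never on
  stored data.  Pixel convention: 0-based (x=column, y=row), origin
  top-left, converted to/from imzML's 1-based coordinates at the I/O
  boundary.

## Problem sizes

The default phantom is 64×64 pixels (~51,000 simulated peaks, ~186
consensus ions); simulation plus the full pipeline takes a few seconds
on one core.  Unit and property tests use 16×16–32×32 grids.  These
sizes were chosen because every grouping statistic of interest
(series recovery, collapse, enrichment) is already fully expressed at
a few thousand pixels; nothing in the code limits larger rasters.

## Known limitations

* Single charge, positive mode only; no sulfur/halogen chemistry in
  the bundled table.
* Carbon-only isotope model; no fine isotope structure.
* The reference table is a curated offline snapshot sized to the
  published species set (plus hexanoylcarnitine and cyclo(Leu-Phe)),
  not a LIPID MAPS/HMDB mirror; real studies should extend it.
* Cloud selection is manual geometry; automatic cloud discovery is
  out of scope.
* The simplified linear recalibration stands in for the dedicated
  external method and is only appropriate for smooth drifts.
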