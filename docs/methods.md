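# Methods

This note documents the models implemented by paracellkit, the
assumptions behind them, the defaults of the synthetic-data generators,
and the numerical choices that were genuinely open.

## Electrophysiology

### TER

TER = (R_raw − R_blank) · A, in Ω·cm². A record with R_raw < R_blank is
physically impossible and is rejected rather than clamped: clamping
would silently convert a broken filter into a perfectly conducting one.
The default insert area is 1.12 cm² (12-mm Transwell).

### GHK dilution potential and its inverse

For a NaCl dilution experiment (full-strength bath apical, NaCl
replaced isosmotically by sucrose basolaterally) the constant-field
potential reduces to the two ions that differ across the baths:

    V = (RT/F) · ln[(η·Na_ap + Cl_bl) / (η·Na_bl + Cl_ap)],   η = P_Na/P_Cl

K⁺, Ca²⁺ and Mg²⁺ are at identical concentrations on both sides, so
their GHK terms cancel exactly and carry no selectivity information;
including them would only add parameters the experiment cannot
constrain. Concentrations, not activities, are used (an
`activity`-style correction would multiply both baths and largely
cancel in the ratio; no coefficients are available for these recipes).
Chloride totals count every chloride-bearing salt
(Cl = NaCl + KCl + 2·CaCl₂ + 2·MgCl₂ → 149/79 mM for the built-in
140/70 mM NaCl recipes); a `nacl_only` accounting is available for
sensitivity checks. Temperature defaults to 310.15 K.

Sign convention: potentials are apical minus basolateral. With sodium
diluted basolaterally, a cation-selective monolayer gives a positive
potential; this is asserted in the tests.

The inverse is closed-form: with x = exp(VF/RT),
η = (Cl_ap·x − Cl_bl)/(Na_ap − x·Na_bl). V must lie strictly between
the Cl⁻ and Na⁺ Nernst potentials (−16.96 and +18.52 mV for the
built-in recipes at 37 °C); outside that open interval no finite η
exists and the error message names both limits. The closed form
round-trips with the forward model to 1e-9 relative and agrees with a
Brent root search of the forward model to 1e-6.

**Noise amplification near the Nernst limit.** dη/dV grows without
bound as V approaches the Na⁺ limit: at η ≈ 18 (V ≈ 16.4 mV, ~2 mV
below the limit) a 1 mV potential error moves η by ~9 units (~50%).
Highly cation-selective monolayers therefore have intrinsically noisy η
estimates, and recovery guarantees are stated for regimes away from the
limit (see "Parameter recovery" below).

### Kimizuka–Koketsu permeabilities

For a symmetric NaCl bath of concentration C, the GHK slope conductance
is G = (F²/RT)·C·(P_Na + P_Cl). Identifying G with 1/TER gives

    P_Na + P_Cl = RT / (F²·C·TER),   P_Na = total·η/(1+η),   P_Cl = total/(1+η)

The implementation satisfies this identity exactly (reconstructed
G·TER = 1 to machine precision), which the tests enforce.

The bath concentration C is a genuine convention choice under
asymmetric baths. The default is the apical NaCl concentration
(140 mM = 1.4e-4 mol/cm³); the logarithmic mean of the two baths and an
explicit override are also available. With the default, the
high-resistance (knockout-like) worked example reproduces its reference
values to better than 2%, while the low-resistance control condition
computed on group means lands ~9% below the per-filter average it is
compared against — consistent with either a different concentration
convention or with averaging order (the mean of per-filter P_Na is not
P_Na of the mean TER and mean V when the quantities are nonlinear).
Both averaging orders are implemented (`per_record`, the default, and
`pooled`); neither is asserted to be "the" correct one.

### Tracer flux

P = (dQ/dt)/(A·C₀) with Q the apically collected tracer amount at a
single timepoint and linear accumulation assumed over the 1-h window
(valid while Q stays ≪ the basolateral pool, which it does by ~5 orders
of magnitude at these permeabilities). Fluorescence maps to
concentration through an ordinary least-squares standard curve; a
sample reading below the curve intercept is clamped to P = 0 with a
warning flag instead of returning a negative permeability.

## Junction image quantification

The manual freehand tracing of the original measurement is replaced by
an operator-free default so results are reproducible: Gaussian smooth
(0.2 µm) → Otsu threshold → morphological skeletonization → split at
nodes of degree ≥ 3 (tricellular points). Pixels within 0.5 µm of a
node are excluded before splitting because three cells meet there and a
ribbon would mix classes; segments shorter than 1 µm are dropped.
User-supplied polylines (CSV of ordered vertices) bypass the automatic
tracer.

Ribbons are Euclidean dilations of the traced polyline to 0.5 µm width
(the ROI convention of the underlying measurement). Flanking-cell
genotypes are sampled by offsetting the path ± one ribbon width along
local normals; the per-side majority label decides the class. The
default pixel size is 0.1 µm and is required metadata — it is never
guessed from the image file.

Integrated density is the plain sum of pixel gray values over the mask.
Cross-class comparisons use the per-area form (sum/area) so that
ribbons of unequal length are commensurable; whether the original
manual procedure length-matched its five traced sides is unknown, so
per-area is a documented choice, not a reproduction. The boundary
statistic (D_B − D_KO)/(D_CTL − D_KO) is invariant under any affine
per-area transform d → a·d + b (a > 0): multiplicative gain and
additive background cancel, which is the point of the D_KO subtraction.

Five sides per class are sampled uniformly at random under a mandatory
seed (recorded in the output manifest); the original procedure does not
state how its five sides were chosen. No background subtraction is
applied before D_KO/D_CTL (a flag exists), matching the convention that
subtraction enters only through the boundary statistic.

## Genotyping

Alleles align to the reference ORF globally with affine gaps (match +1,
mismatch −2, open −5, extend −1); gap-placement ties resolve to the
leftmost equivalent position. Classification:

* **START_LOST** — the allele no longer carries ATG at the position
  aligned to the reference start. This is judged on the allele side
  rather than by "a gap overlaps reference bases 0–2", because leftmost
  placement of a deletion inside a repeat run adjacent to ATG can
  formally overlap the start codon even though the mutant sequence
  still begins with an intact ATG (and, conversely, a deletion through
  the start can fortuitously recreate one at the junction).
* **FRAMESHIFT** — start intact, net coding indel not a multiple of 3.
* **IN_FRAME / WILD_TYPE** — everything else; length-preserving
  substitutions that spare the ATG are IN_FRAME.

For disrupted alleles the predicted product is translation from the
next in-frame downstream ATG of the reference (codon numbering is
1-based from the initiating ATG), modelling translation re-initiation;
its mass uses average residue masses plus one water (18.02 Da), the
convention behind kDa-style estimates on immunoblots. Monoisotopic
masses and modifications are out of scope.

## Statistics

Mean ± SEM (sample SD, n−1, over √n; n = 1 reports SEM 0 with a
degenerate flag). Bartlett's test gates the variance assumption; the
pairwise comparisons are two-sided two-sample t tests of each group
against a designated reference, Bonferroni-corrected by the number of
comparisons actually performed. Pooled-variance t is used when Bartlett
does not reject; otherwise the comparisons are still emitted with
Welch's t and flagged, without asserting that this was the original
procedure's fallback. Simulated type-I error of Bartlett at the null is
checked to land in [0.04, 0.06] over 10 000 replicates, and the
familywise error of the full gate-then-compare procedure stays ≤ 0.06.

## Synthetic data

The generators define the study conditions for every test; they use the
package's own forward models so round-trip tests exercise true
inverses.

**Mosaic images** (defaults): 200 cells in a 100 µm field at
0.1 µm/px; blue-noise centres (minimum spacing 0.6·√(field²/n), a
quasi-uniform MDCK-like packing); Voronoi edges rendered as
arc-length-weighted line deposits; control/knockout/boundary target
amplitudes 1000/150/interpolated with per-edge CV 0.10; marker
amplitude 1000 on all edges; Gaussian PSF σ = 0.2 µm; additive Gaussian
read noise σ = 2. Line-integral rendering matters: a plain rasterised
(Bresenham) line deposits ~√2 less intensity per unit length on
diagonal segments than on axis-aligned ones, which injects an
orientation-dependent bias into per-area ribbon densities; depositing
amplitude × arc-length per sub-pixel step removes it. What the
generator does **not** emulate: 3-D optics (single plane only), cell
motility, shot noise (Poisson mode exists but additive Gaussian is the
default, since the ratio statistics are insensitive to the noise
model), chromatic mis-registration, or non-junctional target pools.
Passing recovery tests therefore show the ribbon pipeline is unbiased
for ribbon-shaped signal under blur and read noise — not that it is
robust to every real-microscopy artefact.

**Electrophysiology**: true conductance from the Kimizuka–Koketsu
relation at the apical bath concentration, per-filter lognormal
conductance factor (median 1, log-sd 0.05), Gaussian potential noise
(0.3 mV), optional per-day multipliers for time-course emulation.

**Tracer**: Q = P·A·C₀·t pushed through an affine ground-truth
fluorescence curve (slope 1e12 per mol/cm³, intercept 20) that also
generates the standard-curve points.

**ORFs**: random codons excluding stops and ATG, with ATG planted at
codon 1 and at one chosen downstream codon (default 24, mirroring the
claudin-2 gene structure), terminal TAA; the default allele panel
covers wild type, ±1 frameshifts, an in-frame deletion, a start-codon
deletion, and (for ORFs ≥ 150 nt) a 52-nt deletion.

## Accuracy statements and problem sizes

* GHK round trip: 1e-9 relative over η ∈ [0.05, 100]; inversion vs
  Brent root search: 1e-6 over a 30-point potential grid.
* Kimizuka–Koketsu conductance identity: machine precision.
* Boundary-fraction recovery: mean over 20 seeded 200-cell mosaics
  within ±0.05 of the generated fraction (measured spread ≈ 0.04 SD per
  image at 5 sides/class).
* Ephys parameter recovery: at 5% conductance noise, 0.3 mV potential
  noise, 5 filters, knockout-regime truth (P_Na = 0.32e-6,
  P_Cl = 0.23e-6 cm/s), η and P_Na are both within 10% of truth in
  ≥ 90% of 500 seeded runs. At the control regime (η ≈ 18.2) the same
  guarantee holds for P_Na but not for η: the measured rate is ~82%,
  a direct consequence of the Nernst-limit noise amplification derived
  above, not an implementation defect.
* Mean-TER 2·SEM coverage with n = 5 noisy filters: Student's t theory
  gives P(|T₄| ≤ 2) ≈ 0.884, so the 200-trial simulation is checked
  against the band [0.81, 0.96] rather than a nominal-normal 95%.

## Known limitations

* The Kimizuka–Koketsu bath-concentration convention under asymmetric
  baths is a choice; absolute permeabilities carry that convention.
* TER and dilution potentials mix paracellular and transcellular
  pathways; in high-resistance monolayers the transcellular
  contribution is not negligible, so derived P values there are
  effective, not purely paracellular, quantities.
* The skeleton tracer assumes ribbon-like marker signal; fragmented or
  punctate marker staining will under-segment.
* Allele classification assumes a single contiguous indel spectrum per
  allele; complex rearrangements beyond the 60%-identity gate are
  rejected rather than interpreted.
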