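# Methods

## Measurement model

SIET estimates transepithelial ion flux from the steady concentration
microgradient that transport maintains in the unstirred layer next to the
tissue. An ion-selective microelectrode is positioned 5 µm from the surface
(inner point) and stepped 50 µm outward (outer point); the voltage
difference ΔV = V_inner − V_outer across the excursion encodes the local
concentration ratio through the electrode's empirical Nernst slope S. The
analysis chain is:

1. **Per-cycle gradient.** Each move–wait–sample cycle yields one
   inner and one outer 0.5 s voltage sample; the cycle gradient is their
   difference. A site's gradient is the grand mean of all cycle gradients
   over its two independent measurements (three cycles each). The grand
   mean equals the mean of measurement means at equal cycle counts; a
   median option is available for scans disturbed by peristaltic
   contractions, but no outlier rejection is applied by default.
2. **Reference correction.** The same excursion recorded several hundred
   µm from the tissue measures only electrode noise and drift; its gradient
   is subtracted from every tissue-site gradient.
3. **Concentration gradient.** ΔC = C_B·(10^(ΔV/S) − 1) in µmol cm⁻³
   (numerically mM), with C_B the background concentration.
4. **Flux.** J = D·ΔC/Δx in pmol cm⁻² s⁻¹ (Δx = 50 µm = 0.005 cm;
   D = 1.92×10⁻⁵ cm² s⁻¹ for K⁺, 1.55×10⁻⁵ for Na⁺). At the basal
   (haemolymph-facing) surface J > 0 is absorption and J < 0 secretion; an
   `apical` flag flips the labels for scans of the opposite surface.

Activities are treated as concentrations throughout: the calibration and
experimental salines have similar ionic strength, so activity coefficients
cancel. This assumption is encoded once in the electrode model; no
activity-coefficient parameter exists elsewhere. Temperature is not
modelled — slopes are per-electrode empirical values.

### Background concentration C_B

Two modes are provided because published SIET workflows differ:

* `measured` (default): the mean of the concentrations converted from all
  voltage samples at all tissue sites. Self-consistent under electrode
  interference (the interferent term cancels between C_B and the gradient
  ratio), but inherits any absolute drift offset as a small multiplicative
  bias (about 1.5% at the default 30 µV/min drift over a ~19 min scan),
  shared by all sites and conditions.
* `nominal`: the bath concentration of the scanned ion (3.4 mM K⁺, 20 mM
  Na⁺). Immune to drift and exact for interferent-free recordings; used
  when absolute calibration anchoring is absent.

### Electrode model

Calibration is two-point (150 mM and 15 mM of the primary salt), giving
S = (V_high − V_low)/log10(C_high/C_low); a table of three or more points
reduces to the least-squares slope. The forward response used by the
synthetic generator is Nicolsky–Eisenman:
V = V_high + S·log10((C_primary + Σ_j k_j·C_j)/C_high), anchored at the
(interferent-free) high calibration point. Defaults: K⁺ cocktail
log10 k = −3.9 (Na⁺), −4.9 (Ca²⁺, Mg²⁺); Na⁺ cocktail log10 k = −2.6 (K⁺),
−3.5 (Ca²⁺), −3.7 (Mg²⁺) — the Na⁺ values are taken from measurements of a
closely related cocktail and are a documented stand-in, not a measured
property of this exact mixture.

## Synthetic experiments

The generator exists so the pipeline's accuracy is measurable by parameter
recovery. For a site with true flux J\* it builds a planar steady-state
profile: the outer excursion point sits at the unstirred-layer boundary and
therefore at the bath concentration, the inner point at bath + ΔC with
ΔC = J\*·Δx/D — exactly the profile the conversion equation inverts, so
the noise-free chain recovers J\* to machine precision (nominal C_B,
pure-primary bath). Every sample voltage is the Nicolsky–Eisenman response
at the local composition, plus a linear common-mode drift (default
30 µV/min, shared by reference and tissue electrodes, emulating slow
evaporation of the backfilling solution; a per-recording constant offset
option emulates imperfect correction) and i.i.d. Gaussian noise (default
SD 15 µV per 0.5 s sample, sized so simulated reference-gradient scatter at
N = 10 matches the observed order of magnitude). Sample timestamps follow
the instrument schedule — 4.0 s wait, 0.5 s sample, 50 µm travel at
200 µm/s: a 9.5 s cycle, 57 s per site — so drift-induced bias arises from
the same geometry as in the real instrument. The exact within-cycle spacing
of the inner and outer samples is derived from this schedule (inner sample
centred 4.75 s before the outer one), since finer timing is not specified
by the protocol description.

Default study conditions: 10 preparations per condition; 5 ileum and 10
rectum sites per preparation (within the observed 4–5 and 6–18 ranges);
reference recording of ten 3-cycle measurements (~285 s, matching the
roughly five minutes the reference site occupies). Ground-truth fluxes:
control K⁺ +26.7 pmol cm⁻² s⁻¹ in all regions and control ileal Na⁺ −53.2
(the fluxes implied by the mean corrected control gradients +49.4 µV and
−22.0 µV at nominal bath concentrations); control rectal Na⁺ is set to a
small absorption (+8) consistent with the sub-unity Na⁺ signal:noise
observed there. The hormone condition scales ileal Na⁺ by 0.25, ileal K⁺ by
0.32 and anterior-rectum K⁺ by 0.21 — the regional effects reported for
200 nM GPA2/GPB5 — and leaves other regions unchanged.

What the generator does **not** emulate: peristaltic disturbance of the
unstirred layer (beyond the noise floor), 2-D/3-D diffusion geometry,
electrode positioning error, and nonlinear drift. Passing recovery tests
therefore demonstrate correctness of the inversion and statistics under
the stated physics, not robustness to every artifact of living
preparations.

## Statistics

The preparation is the unit of replication: each preparation contributes
its mean site flux per region. The rectum is split into anterior and
posterior halves by site count along the tissue axis; an odd count puts the
extra site in the anterior half (a tie-break the data never forced).
Conditions are compared per region with a classical (equal-variance)
one-way ANOVA; pairwise control-vs-treatment t-tests are Bonferroni
adjusted — p multiplied by the number of regional comparisons, capped at
1 — and declared significant below 0.05. A Welch option covers unequal
variances. Percent change is computed on flux magnitudes,
100·(|T| − |C|)/|C|, so reductions of secretion and absorption share one
formula; direction reversals are flagged categorically rather than signed,
because near-zero fluxes make a signed ratio unstable.

## Numerical and design notes

* Degenerate inputs raise typed errors: equal or non-positive calibration
  concentrations, zero slope, non-positive D or Δx, cycles missing an
  inner or outer sample, datasets without reference recordings, ground
  truths whose gradient would imply non-physical concentrations.
* A zero reference gradient makes signal:noise undefined; it is returned
  as a missing value, never raised, and sites with ratio < 1 are retained
  but logged as low-confidence.
* Determinism: one `numpy` generator seeded once drives a whole simulated
  condition; identical seeds give byte-identical files.
* Problem sizes in the test and acceptance runs mirror the study design
  (N = 10 preparations, 5–10 sites, 20 calibrations), which keeps every
  run in the seconds range.
* The recovered percent changes are stochastic with an intrinsic SD of
  roughly 8 percentage points for the ileal Na⁺ contrast (smaller for K⁺),
  purely from sampling noise at N = 10; the acceptance script reports
  single-batch values at the given seed rather than averaging batches,
  mirroring the study's single-experiment design.
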