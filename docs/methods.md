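# Methods

## Molecular-complementarity screening

The screen rests on the empirical observation that molecules which
cocrystallize tend to have similar shapes and polarities. Similarity is
measured with five descriptors per conformer: the short axis S and the
ratios M/L and S/L of a box enclosing the molecule's van der Waals
volume (shape), plus the dipole moment and the fraction of N and O
atoms, FNO (polarity). The complementarity score of an API–coformer
conformer pair is the sum of absolute descriptor differences, each
normalised by a cutoff δ_D calibrated so that 90% of surveyed cocrystals
differ by less than δ_D in that descriptor (δ_{M/L} = 0.31,
δ_S = 3.23 Å, δ_{S/L} = 0.28, δ_dipole = 5.94 D, δ_FNO = 0.29). The
coformer score is the mean over the Cartesian product of conformer
pairs; coformers are ranked ascending. The default-settings variant is a
PASS/FAIL rule — PASS iff every |Δ_D| ≤ δ_D — with a hit rate defined
here as the percentage of conformer pairs passing.

Choices where the method's published description is silent:

* **Box orientation.** The enclosing box is aligned with the principal
  axes of the unit-mass atomic coordinate covariance; along each axis
  the extent is max(projection + r) − min(projection − r) over atoms
  with Bondi vdW radii. Principal axes are deterministic and fast; a
  minimal-volume rotation search is available via
  `RunConfig(box_orientation="minvol")` but is not the default. Tests
  verify that on symmetric toy geometries the principal-axes box agrees
  with a dense rotation-grid search within 2%, and that the axes are
  invariant to rigid motion within 1e-6 Å.
* **Box semantics.** The box encloses the van der Waals volume (atom
  spheres), not atom centres.
* **Partial charges.** The dipole uses Gasteiger–Marsili empirical
  charges (topology-only, no QM dependency), origin at the centre of
  mass, 1 e·Å = 4.8032 D. Scores are only comparable within one charge
  model, so the model is recorded in run manifests. Net-charged species
  trigger a warning because their dipole is origin-dependent;
  zwitterionizable amino acids are processed as the neutral tautomer by
  default.
* **FNO universe.** Heavy atoms by default, making FNO independent of
  hydrogen handling; switchable to all atoms.
* **Boundary rule.** |Δ_D| equal to δ_D counts as PASS; the comparison
  carries a 1e-9 relative slack so a difference constructed to sit
  exactly on the cutoff is not failed by float rounding.
* **Hit-rate denominator.** Fraction of conformer pairs (equivalent to
  averaging each API conformation's pass fraction); an "any coformer
  conformation" mode is available via `RunConfig(hit_rate_mode="any")`.
* **Ties and failures.** Equal mean scores are ordered lexicographically
  by name. A coformer whose descriptors cannot be computed is excluded
  and reported in `RankingTable.failures`, never silently dropped.

Conformers come from seeded ETKDGv3 distance-geometry embedding with
MMFF94 minimisation (UFF for molecules outside the MMFF
parameterisation). Embedding is bitwise repeatable for a fixed
(molecule, n, seed); the default policy is ten conformers for the API,
one for rigid coformers (no rotatable bonds) and three for flexible
ones. Rotatable bonds follow the strict convention: single, non-ring
bonds between two non-terminal heavy atoms, amide C–N excluded.

## F_screen ranking

F_screen = ΔH_mix + a·(max(1, n_drug) + max(1, n_coformer)) combines the
supercooled-liquid excess enthalpy of the 1:1 pair — a proxy for the
cocrystallization free energy once the mixing-entropy and fusion terms
are neglected — with a flexibility penalty. ΔH_mix is consumed as a CSV
input: computing it requires σ-profile thermodynamics engines and
fragment databases outside this package's scope, and its quality is
limited by how the API is fragmented there. The penalty weight `a` has
no published value; the default is 0 with a mandatory warning that `a`
is a fit parameter to be calibrated on experimental outcomes. Ranking is
ascending with lexicographic tie-break.

## Dissolution analytics

All concentrations are μM, times minutes, volumes mL, masses mg. The
bookkeeping operations are exact unit algebra: ng/mL ÷ g/mol = μM;
mg ÷ g/mol = mmol; a 1:1 cocrystal dose of mass m splits as
m/(MW_api + MW_cof) formula units with component masses conserving m.

* **Supersaturation** is C_api/S with S the crystalline API's
  equilibrium solubility in the same medium; the profile variant also
  reports the maximum and its time (first occurrence on ties).
* **Congruency** is the coformer:API molar ratio per timepoint; a
  cocrystal dissolving congruently gives its stoichiometry (1.0 for
  1:1). Points with zero API concentration are flagged undefined, not
  dropped.
* **Percent dissolved** is computed from the coformer (it does not
  precipitate, so its solution concentration tracks cumulative cocrystal
  dissolution); an API-based cross-check is available and agrees only
  under congruent conditions. Values above 100% are reported with a
  warning, never clamped.
* **Solubility comparison** uses Welch's unequal-variance two-sided t
  test from summary statistics (mean, SD, n). Welch rather than pooled
  Student because triplicate solubility measurements carry no evidence
  of equal variances. Identical summaries with zero variance return
  t = 0, p = 1 by convention.

## The DSP simulator

The simulator exists to give the analytics profiles with an auditable
ground truth; it is a deliberately minimal mechanism, not a fitted
kinetic model. Undissolved cocrystal mass follows a cube-root
(surface-area-limited) law dM/dt = −k_d·M^(2/3), releasing API and
coformer in the crystal's stoichiometric ratio into a stirred volume.
Once the API concentration first exceeds a critical supersaturation
concentration c_crit, a first-order sink dC/dt −= k_p·(C − s_api)⁺
switches on permanently, representing bulk nucleation and growth of the
crystalline API; the coformer never precipitates. Integration is
explicit Euler; construction rejects k_p·dt > 0.5 to keep the sink step
stable, and a per-step ledger tracks undissolved, dissolved and
precipitated amounts so that mass conservation can be audited (it holds
to ~1e-14 relative in the shipped sweeps). Optional Gaussian noise
(seeded, truncated at zero) is applied to the sampled concentrations
only — the ledger stays noise-free.

Two stock regimes mirror the phenomenology of a supersaturating
cocrystal in plain buffer versus a micellar biorelevant medium, using
the reference dose geometry of 10.8 mg of 1:1 cocrystal
(MW 492.5/171.2) in 80 mL:

* **blank**: s_api = 0.046 μM, c_crit = 0.05 μM, k_d = 0.015
  mg^⅓/min, k_p = 150 /min, dt = 0.001 min. Precipitation engages
  within seconds, pinning the bulk API near its solubility while the
  coformer accumulates — the coformer:API ratio exceeds 100 within
  5 min (early-incongruent, surface-precipitation-like regime).
* **fassif**: s_api = 25 μM, c_crit = 100 μM, k_d = 0.0076 mg^⅓/min,
  k_p = 0.05 /min, dt = 0.1 min. Dissolution is congruent (ratio 1.0)
  for roughly three hours until the API reaches four times its
  solubility, then precipitation caps and erodes the peak.

Both run to 480 min and are noise-free by default so that ratio and
argmax checks against the ledger are exact; rate constants were chosen
once to reproduce this phenomenology and are not fitted to any measured
curve. What the simulator does **not** model: micelle solubilization,
surface nucleation as a spatial process, hydrodynamics, coformer
saturation, or assay error structure. Passing tests therefore
demonstrate that the analytics recover known ground truth, not that the
kinetic model describes real dissolution curves.

The synthetic screening-set generator plants "similar" coformers within
0.2·δ_D of a reference API vector in every descriptor (score ≤ 1,
guaranteed PASS) and "dissimilar" ones displaced ≥ 2·δ_D in the S axis
or dipole (score ≥ 2, guaranteed FAIL), so label recovery by the ranking
engine is decidable by construction.

## Problem sizes and runtime

The shipped fixture library holds 33 molecules (the API, six named
screening compounds, 26 generic coformers spanning amides, carboxylic
acids and sulfonamides). The full library screen embeds 10 API
conformers plus 1–3 per coformer and completes in a few seconds; the
simulator sweeps use 100 random parameter draws at dt = 0.1 min over a
90-min horizon. These sizes make the whole validation suite run in well
under a minute of compute while exercising every code path at realistic
chemistry.

## Known limitations

* Descriptor values depend on the conformer generator and charge model;
  rankings from other descriptor implementations (e.g. proprietary
  crystallographic software) will differ in detail, which is why the
  known-coformer check is a top-quartile criterion rather than an exact
  rank.
* The fixture library is a surrogate for a real screening library; a
  full reproduction of a 52-coformer campaign would require that
  library's exact composition.
* ΔH_mix inputs are taken at face value; no uncertainty propagation.
* The neutral-tautomer default for amino acids is a modelling choice;
  descriptor values for genuinely zwitterionic solids would differ.
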