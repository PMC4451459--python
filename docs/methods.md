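# Methods

`foldperm` analyses the folding of circular permutants of an all-α
Greek key death domain (six helices, A–F, arranged as two three-helix
bundles) by treating each permutant as a point mutant of the wild type:
equilibrium stability, chevron kinetics, Φ-values and structure-derived
topology metrics are computed from the same primitives throughout.

## Two-state equilibrium model

Equilibrium urea denaturation is described by the six-parameter
Santoro–Bolen model: a two-state transition with linear folded and
unfolded baselines,

    Y(D) = [(α_N + β_N D) + (α_D + β_D D)·K(D)] / [1 + K(D)],
    K(D) = exp(m(D − [D]50)/RT),  [D]50 = ΔG_H2O / m.

The observable is the average emission wavelength ⟨λ⟩ = Σλ·F / ΣF of
the tryptophan emission spectrum (300–400 nm), which shifts red on
unfolding. Parameters: ΔG_H2O (kcal/mol, unfolding free energy in
water), the m-value (kcal mol⁻¹ M⁻¹, cooperativity), and the four
baseline coefficients. RT uses R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ at
298.15 K (RT = 0.59248 kcal/mol); all experiments the model emulates
were performed at 25 °C.

Fitting is unweighted nonlinear least squares (`scipy.optimize.curve_fit`).
Initialisation is data-driven to remove starting-point sensitivity:
baselines from straight lines through the outer 15% of the urea range,
[D]50 from the half-signal crossing, and m from the central slope of
the transition (a logistic pre-fit). A fit landing on negative m is
retried with the signal sign flipped; a still-negative m is reported as
a fit failure rather than silently returned. Standard errors come from
the fit covariance; the [D]50 error uses first-order propagation of
(ΔG, m) including their covariance. Stability changes are the direct
difference ΔΔG = ΔG_H2O(wt) − ΔG_H2O(variant) with errors in quadrature
(positive = destabilised); the ⟨m⟩·Δ[D]50 convention, less sensitive to
m-value noise, is available as an option.

## Chevron kinetics

For a two-state folder the observed relaxation rate is

    k_obs(D) = k_f^H2O e^(−m_kf D) + k_u^H2O e^(+m_ku D),

fitted in ln k space (stopped-flow errors are approximately
fractional) with the rate constants parameterised logarithmically so
positivity is structural, using `scipy.optimize.least_squares` with
`logaddexp` for numerical stability. Data covering only one limb are
rejected with a diagnostic naming the missing limb (a limb must
contribute ≥ 5% of k_obs somewhere in the data). Rate-constant errors
are delta-method transforms of the ln-space covariance.

Derived quantities:

* **Φ-value** — Φ = ΔΔG_kin/ΔΔG_eq with ΔΔG_kin = RT·ln(k_f^wt/k_f^mut)
  evaluated on the refolding limb at a reference urea concentration
  (default 2.0 M, reducing the error of extrapolation to water).
  ΔΔG_eq defaults to the water value from the equilibrium fits; an
  unfolding-limb variant (1 − Φ_u form) is provided as a cross-check.
  |ΔΔG_eq| < 0.6 kcal/mol flags the Φ as unreliable (standard practice:
  small denominators amplify error) — flagged, never dropped.
  Because the equilibrium ΔΔG is a water value while the kinetic ratio
  is taken at 2 M, published Φ values of this kind are not exactly
  recomputable from water-extrapolated rate constants alone; the
  package therefore validates Φ on engineered constructions (Φ = 0,
  0.5, 1) rather than against printed values.
* **Tanford β** — β_T = m_kf/(m_kf + m_ku) ∈ [0, 1], the relative
  compaction of the transition state.
* **m-value consistency** — two-state behaviour requires
  RT(m_kf + m_ku) ≈ m_eq; relative deviations > 20% are flagged.

## Structure metrics

* **Helix assignment** follows the DSSP construction: backbone amide
  hydrogens are placed geometrically (1.0 Å from N, opposite the
  preceding carbonyl), the Kabsch–Sander electrostatic energy
  E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol defines a
  hydrogen bond when E < −0.5 kcal/mol, a 4-turn at i is a CO(i)→NH(i+4)
  bond, and two consecutive 4-turns (i, i+1) make residues i+1…i+4
  α-helical. Proline donors are excluded; residues with incomplete
  backbones are labelled unassignable. Only the α/not-α distinction is
  implemented — the single state the analysis uses. Multi-model (NMR)
  PDB files select one model (default the first); insertion codes are
  rejected rather than renumbered.
* **Accessible surface area** is Shrake–Rupley with a deterministic
  golden-spiral point lattice (default 960 points/atom, probe 1.4 Å,
  van der Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 Å;
  unknown elements fall back to 1.70 Å with a warning). The lattice is
  not mirror-symmetric, so symmetric atom pairs agree only to the
  discretisation error (≲ 0.2% at 960 points; the isolated-sphere and
  two-sphere cap cases agree with the analytic areas to < 1%).
* **Contact maps and RCO** — residues are in contact when any
  heavy-atom pair is within 6.0 Å at sequence separation ≥ 1 (cutoff,
  separation, and atom-pair vs residue-pair weighting all configurable
  and recorded); RCO = (1/LN)·ΣΔS over counted contacts.
* **Circular permutation** is index relabelling only:
  i → ((i − new_start) mod L) + 1, with an optional linker inserted at
  the joined native termini (index-only, no coordinates, matching the
  -GSGSS- extension used experimentally). Contacts are preserved as
  residue pairs; only sequence separations change.
* **RMSD** uses the Kabsch algorithm (SVD with reflection correction).

## Synthetic data generator

The generator emulates the study conditions with known ground truth:

* Equilibrium curves: exact model signal plus additive Gaussian noise;
  default baselines 355 nm (folded) → 372 nm (unfolded), the typical
  tryptophan average-emission range; default measurement grid 0–8 M
  urea in 0.25 M steps (33 points).
* Chevrons: exact two-state k_obs with multiplicative log-normal noise
  (rates are positive and fitted in log space).
* The default variant family encodes the published parameter table:
  m-values 1.27–1.66 kcal mol⁻¹ M⁻¹, folding rates 450–2600 s⁻¹,
  unfolding rates 0.04–26.1 s⁻¹, ΔΔG 1.74–4.44 kcal/mol. The wild-type
  absolute stability is not published; it is anchored Haldane-
  consistently at RT·ln(k_f/k_u) = 5.96 kcal/mol. Kinetic m-values are
  not published either; m_kf = 1.0 and m_ku = 0.8 M⁻¹ are adopted for
  all variants (the permutant whose unfolding m-value the study found
  doubled carries m_ku = 1.6). Note RT(1.0 + 0.8) = 1.07 kcal mol⁻¹ M⁻¹
  sits below most of the family's equilibrium m-values, so the kinetic
  consistency check flags several variants on default synthetic data —
  an honest reflection of fixing the kinetic slopes family-wide.
* Toy structures: backbone-only (N, CA, C, O) chains built by natural
  extension from ideal dihedrals — α-helix φ = −57°, ψ = −47° (1.5 Å
  rise, ~100° twist), extended strand φ = −135°, ψ = 135°, or
  seed-reproducible random coil. The synthetic death-domain mimic
  concatenates six ideal helices (16, 13, 12, 16, 14, 14 residues)
  placed far apart, so helix counting has the exactly known answer 73
  (each helix of length n yields n − 2 assignable residues). It is a
  labelled synthetic stand-in, not an experimental structure.
* Contact-map fixtures: the helix-bundle map combines measured
  ideal-helix atom-pair weights with five-residue-pair interfaces for
  each helix-helix packing (sequential neighbours, both bundles, and
  the central core pairings); permutation sites are the five loop
  midpoints, mirroring the design rule that new termini open only in
  loops. The long-range-only map pairs residue i with L+1−i and has no
  local contacts (a β-sandwich caricature).

What the generator does **not** emulate: raw stopped-flow traces
(k_obs is taken as the observable), instrument drift or correlated
baselines, intermediate/three-state behaviour, side-chain packing in
toy structures, or real NMR coordinate noise. Passing tests therefore
demonstrate correctness of the estimators and metrics under the stated
models, not robustness to violations of two-state behaviour.

## Problem sizes and numerical choices

Analysis and tests use 33-point urea grids, 100-replicate Monte-Carlo
calibration at 2% noise (seeds 1–100), exhaustive permutation checks
at L = 7, brute-force RCO cross-checks for L ≤ 20, and toy chains of
≤ 110 residues. Optimiser tolerances are `xtol = ftol = gtol = 1e-14`
for chevrons and `curve_fit` defaults for equilibrium fits; noiseless
recovery is verified to 0.1% relative error. Report JSON is written
with sorted keys so fixed seeds give byte-identical output.

## Known limitations

* The α-helix assignment implements the minimal DSSP helix rule only;
  it does not reproduce full DSSP edge-case behaviour (bulges, 3₁₀/π
  overlap resolution), so counts on experimental ensembles may differ
  by a residue or two from reference implementations.
* Φ standard errors propagate fit covariances to first order; they
  ignore the correlation between the equilibrium and kinetic ΔΔG of
  the same variant.
* The LFER and Φ–Φ lines are unweighted OLS by default, as simple
  straight-line summaries; weighted variants are available but not the
  default.
* Circular permutation of contact maps relabels indices only; it does
  not model structural relaxation at the new termini.
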