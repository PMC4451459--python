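# foldperm

Analysis pipeline for the folding of circular permutants of an all-α
Greek key protein (a six-helix death domain). Circular permutants keep
the amino-acid composition and length of the wild type but reorder the
secondary-structure elements; comparing their equilibrium stability,
folding/unfolding kinetics and contact topology asks whether chain
connectivity or secondary-structure type controls the folding
mechanism. The package is written for protein-folding labs who fit
denaturation and stopped-flow data and want the downstream Φ-value /
LFER / contact-order analysis reproducible and tested end to end.

Core models:

* **Equilibrium**: Santoro–Bolen two-state model with linear baselines,
  Y(D) = [(α_N+β_N D) + (α_D+β_D D)e^{m(D−[D]₅₀)/RT}] / [1+e^{m(D−[D]₅₀)/RT}],
  fitted for ΔG_H₂O, m, [D]₅₀ and ΔΔG between variants.
* **Kinetics**: two-state chevron ln k_obs = ln(k_f^{H₂O}e^{−m_kf D} +
  k_u^{H₂O}e^{+m_ku D}); Φ = RT ln(k_f^{wt}/k_f^{mut})|_{2 M} / ΔΔG_eq;
  Tanford β_T = m_kf/(m_kf+m_ku).
* **Structure**: Kabsch–Sander hydrogen bonds → DSSP-style α-helix
  counts; Shrake–Rupley accessible surface area; heavy-atom contact
  maps → relative contact order, including reindexing under circular
  permutation; Kabsch superposition RMSD.

No experimental data were deposited for this system, so a first-class
synthetic-data module generates every input with known ground truth
(the published parameter table is the default variant family), and the
analysis runs end to end on it.

## Worked example

```python
import foldperm as fp
from foldperm.synthetic import FADD_VARIANTS, gen_chevron, gen_equilibrium_curve

truth = FADD_VARIANTS["CP_DE"]            # most destabilised permutant
curve = gen_equilibrium_curve(truth.equilibrium_params(), noise_sd=0.34, seed=5)
eq = fp.fit_equilibrium(curve)
print(f"dG = {eq.params.dG_h2o:.2f} +/- {eq.se['dG_h2o']:.2f} kcal/mol, "
      f"m = {eq.params.m_eq:.2f} +/- {eq.se['m_eq']:.2f}")

chev = fp.fit_chevron(gen_chevron(truth.chevron_params(), lognoise_sd=0.02, seed=5))
print(f"kf = {chev.params.kf_h2o:.0f} /s, ku = {chev.params.ku_h2o:.2f} /s, "
      f"beta_T = {fp.tanford_beta(chev):.2f}")
```

prints

```
dG = 1.83 +/- 0.38 kcal/mol, m = 1.33 +/- 0.12
kf = 2579 /s, ku = 4.77 /s, beta_T = 0.55
```

i.e. the fit recovers the generating stability (1.52 kcal/mol), m-value
(1.27), and water rate constants (2600 and 4.9 s⁻¹) within their quoted
errors, and a transition state ~55% as compact as the native state.

The full analysis is a sequence of drivers:

```bash
python analysis/01_simulate.py           # synthetic curves, chevrons, toy PDBs
python analysis/02_fit_equilibrium.py    # dG, m, [D]50, ddG per variant
python analysis/03_fit_chevrons.py       # kf, ku, phi at 2 M urea, beta_T
python analysis/04_structure_metrics.py  # helix counts, ASA, RCO vs permutation
python analysis/05_report.py             # combined JSON/Markdown report + LFER
```

Tables land in `results/`. On the default synthetic family the
unfolding rates track the stability loss while folding rates stay
within a small factor of wild type, and permuting the helix-bundle
contact map at any inter-helix loop moves the relative contact order by
only a few percent (a long-range-only map moves by > 50%) — the
signature that local helical contacts dominate the folding nucleus and
make it insensitive to connectivity changes.

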