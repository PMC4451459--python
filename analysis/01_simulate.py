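#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emits, for the wild type and the five circular permutants of the
six-helix death domain:

* equilibrium urea-denaturation curves (average-emission-wavelength
  signal, 0-8 M urea, 2% additive noise on the 17 nm signal range);
* chevron datasets (k_obs vs urea, 2% multiplicative rate noise);
* noiseless twins of both (suffix ``_noiseless``) for exact-recovery
  checks;
* toy PDB structures (ideal helix, extended strand, six-helix mimic).

Ground truth is the published parameter table, anchored at a wild-type
stability of RT ln(kf/ku) ~ 5.96 kcal/mol.
"""

from pathlib import Path

from foldperm.synthetic import (
    DEFAULT_UREA_GRID,
    FADD_VARIANTS,
    ToyStructureSpec,
    build_death_domain_mimic,
    build_toy_structure,
    chevrons_to_frame,
    curves_to_frame,
    gen_chevron,
    gen_equilibrium_curve,
)
from foldperm.structure import write_structure

SEED = 20150619
NOISE_EQ = 0.34   # nm, 2% of the 17 nm folded->unfolded signal range
NOISE_CHEV = 0.02  # fractional (log-normal sd on k_obs)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    curves, curves0, chevs, chevs0 = [], [], [], []
    for n, (vid, truth) in enumerate(FADD_VARIANTS.items()):
        eq_p, ch_p = truth.equilibrium_params(), truth.chevron_params()
        curves.append(gen_equilibrium_curve(
            eq_p, DEFAULT_UREA_GRID, NOISE_EQ, seed=SEED + n, variant_id=vid))
        curves0.append(gen_equilibrium_curve(
            eq_p, DEFAULT_UREA_GRID, 0.0, variant_id=vid))
        chevs.append(gen_chevron(
            ch_p, DEFAULT_UREA_GRID, NOISE_CHEV, seed=SEED + 100 + n,
            variant_id=vid))
        chevs0.append(gen_chevron(ch_p, DEFAULT_UREA_GRID, 0.0, variant_id=vid))

    curves_to_frame(curves).to_csv(OUT / "equilibrium_curves.csv", index=False)
    curves_to_frame(curves0).to_csv(OUT / "equilibrium_curves_noiseless.csv",
                                    index=False)
    chevrons_to_frame(chevs).to_csv(OUT / "chevrons.csv", index=False)
    chevrons_to_frame(chevs0).to_csv(OUT / "chevrons_noiseless.csv", index=False)

    structures = OUT / "structures"
    structures.mkdir(exist_ok=True)
    write_structure(build_toy_structure(ToyStructureSpec(12, "ideal_helix")),
                    structures / "ideal_helix12.pdb")
    write_structure(build_toy_structure(ToyStructureSpec(12, "extended")),
                    structures / "extended12.pdb")
    write_structure(build_death_domain_mimic(),
                    structures / "death_domain_mimic_synthetic.pdb")

    print(f"wrote {len(curves)} equilibrium curves and {len(chevs)} chevrons "
          f"({len(DEFAULT_UREA_GRID)} urea points each) plus noiseless twins")
    print(f"wrote 3 toy structures under {structures}")


if __name__ == "__main__":
    main()
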