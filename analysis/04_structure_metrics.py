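#!/usr/bin/env python
"""Structure-derived observables on the toy structures.

Computes helix counts (DSSP-style), tryptophan-sized residue ASA on the
six-helix mimic, relative contact order of the helix-bundle topology
under each loop permutation, and superposition RMSD examples; writes
results/structure_metrics.json.
"""

import json
from pathlib import Path

import numpy as np

from foldperm import (
    PermutationSpec,
    accessible_surface_area,
    assign_helices,
    circular_permute,
    kabsch_rmsd,
    read_structure,
    relative_contact_order,
)
from foldperm.synthetic import bundle_contact_map, long_range_contact_map

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    structures = OUT / "structures"
    metrics = {}

    for name in ("ideal_helix12", "extended12", "death_domain_mimic_synthetic"):
        s = read_structure(structures / f"{name}.pdb")
        labels, count = assign_helices(s)
        metrics[f"helical_residues_{name}"] = count

    mimic = read_structure(structures / "death_domain_mimic_synthetic.pdb")
    mid = len(mimic) // 2
    asa = accessible_surface_area(mimic, residue_selection=[mid, mid + 20],
                                  n_sphere_points=480)
    metrics["asa_two_probe_residues_A2"] = {str(k): round(v, 1)
                                            for k, v in asa.items()}

    cmap, loop_cuts = bundle_contact_map()
    base = relative_contact_order(cmap)
    metrics["rco_helix_bundle"] = round(base, 4)
    metrics["rco_helix_bundle_loop_permutants"] = {
        f"start_{p}": round(relative_contact_order(
            circular_permute(cmap, PermutationSpec(p))), 4)
        for p in loop_cuts}
    lr = long_range_contact_map()
    metrics["rco_long_range_map"] = round(relative_contact_order(lr), 4)
    metrics["rco_long_range_central_permutant"] = round(
        relative_contact_order(circular_permute(
            lr, PermutationSpec(lr.chain_length // 2))), 4)

    helix = read_structure(structures / "ideal_helix12.pdb")
    ca = helix.backbone_coords("CA")
    rng = np.random.default_rng(0)
    perturbed = ca + rng.normal(0.0, 1.0, ca.shape)
    metrics["rmsd_helix_vs_1A_perturbed"] = round(kabsch_rmsd(ca, perturbed), 3)

    with open(OUT / "structure_metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    print(json.dumps(metrics, indent=2, sort_keys=True))
    print("\nPermuting the helix-bundle map at any loop shifts RCO by a few "
          "percent at most, while the long-range-only map shifts by more "
          "than half: local helical contacts buffer contact order against "
          "changes in connectivity.")


if __name__ == "__main__":
    main()
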