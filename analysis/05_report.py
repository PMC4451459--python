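#!/usr/bin/env python
"""Assemble the full comparative report: per-variant table, LFER lines
(ln k_f and ln k_u vs dG), and the structure metrics.

Writes results/report.json and results/report.md.
"""

import json
from pathlib import Path

import pandas as pd

from foldperm import (
    VariantSummary,
    build_report,
    delta_delta_g,
    fit_chevron,
    fit_equilibrium,
    lfer_analysis,
    phi_value,
)
from foldperm.lfer import report_to_json, report_to_markdown
from foldperm.synthetic import frame_to_chevrons, frame_to_curves

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    eq_fits = {c.variant_id: fit_equilibrium(c) for c in
               frame_to_curves(pd.read_csv(OUT / "equilibrium_curves.csv"))}
    chev_fits = {c.variant_id: fit_chevron(c) for c in
                 frame_to_chevrons(pd.read_csv(OUT / "chevrons.csv"))}

    summaries = []
    for vid in eq_fits:
        ddg = phi = None
        if vid != "WT":
            ddg = delta_delta_g(eq_fits["WT"], eq_fits[vid])
            phi = phi_value(chev_fits["WT"], chev_fits[vid], ddg,
                            reference_urea=2.0)
        summaries.append(VariantSummary(vid, eq_fits[vid], chev_fits[vid],
                                        ddg, phi))

    lfer = [lfer_analysis(summaries, x="dG", y="ln_ku"),
            lfer_analysis(summaries, x="dG", y="ln_kf")]

    structure = {}
    metrics_path = OUT / "structure_metrics.json"
    if metrics_path.exists():
        structure = json.loads(metrics_path.read_text())

    report = build_report(
        summaries, lfer, structure_metrics=structure,
        provenance={"inputs": ["equilibrium_curves.csv", "chevrons.csv"],
                    "reference_urea_M": 2.0, "seed": 20150619})
    report_to_json(report, OUT / "report.json")
    (OUT / "report.md").write_text(report_to_markdown(report))

    print(report_to_markdown(report))
    r_u = next(r for r in lfer if r.y_name == "ln_ku")
    r_f = next(r for r in lfer if r.y_name == "ln_kf")
    print(f"LFER: |r| = {abs(r_u.r):.2f} for ln k_u vs stability against "
          f"|r| = {abs(r_f.r):.2f} for ln k_f — destabilisation shows up in "
          "unfolding, not folding, so the transition state keeps its "
          "wild-type character under permutation.")


if __name__ == "__main__":
    main()
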