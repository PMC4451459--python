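"""Comparative analyses across a variant family.

Linear free-energy relationships (LFER): across a family of variants of
one protein, log rate constants are regressed on equilibrium stability.
For Greek key helical proteins the published signature is that folding
rates are insensitive to permutation while unfolding rates track the
stability loss, i.e. |r| is high for ln k_u vs dG and low for ln k_f.

Also provides the phi-phi comparison (slope ~1, intercept ~0 means the
folding nucleus is unchanged) and a machine/human-readable report
assembling per-variant fits into a summary table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .chevron import ChevronFit, PhiValue, tanford_beta
from .constants import RT_DEFAULT
from .equilibrium import DeltaDeltaG, TwoStateEqFit


@dataclass
class VariantSummary:
    """All fitted quantities for one variant (one table row)."""

    variant_id: str
    eq_fit: TwoStateEqFit
    chev_fit: ChevronFit
    ddg: DeltaDeltaG | None = None
    phi: PhiValue | None = None


@dataclass
class LferResult:
    """A straight-line relationship between two per-variant quantities."""

    x_name: str
    y_name: str
    r: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    n: int
    flags: list[str] | None = None


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays with >= 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def linear_fit(x, y) -> tuple[float, float, float, float]:
    """Ordinary least squares line; returns
    (slope, intercept, slope_se, intercept_se)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length arrays with >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x; line undefined")
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.stderr), float(res.intercept_stderr))


def lfer_analysis(
    summaries: list[VariantSummary],
    x: str = "dG",
    y: str = "ln_ku",
    weak_r: float = 0.5,
    strong_r: float = 0.9,
) -> LferResult:
    """Regression of water-extrapolated log rates on stability.

    x: "dG" (fitted dG_H2O) or "ddG"; y: "ln_kf" or "ln_ku".  Flags
    record the qualitative pattern: a strong ln k_u correlation together
    with a weak ln k_f correlation is the signature of destabilisation
    expressed purely in unfolding.
    """
    usable = [s for s in summaries if s.eq_fit is not None
              and s.chev_fit is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 variants with converged fits, "
                         f"got {len(usable)}")
    if x == "dG":
        xs = [s.eq_fit.params.dG_h2o for s in usable]
    elif x == "ddG":
        xs = [s.ddg.value if s.ddg else 0.0 for s in usable]
    else:
        raise ValueError(f"unknown x axis {x!r}")
    if y == "ln_kf":
        ys = [np.log(s.chev_fit.params.kf_h2o) for s in usable]
    elif y == "ln_ku":
        ys = [np.log(s.chev_fit.params.ku_h2o) for s in usable]
    else:
        raise ValueError(f"unknown y axis {y!r}")

    r = pearson_r(xs, ys)
    slope, intercept, s_se, i_se = linear_fit(xs, ys)
    flags = []
    if y == "ln_ku" and abs(r) >= strong_r:
        flags.append("strong unfolding-limb correlation with stability")
    if y == "ln_kf" and abs(r) <= weak_r:
        flags.append("folding rate insensitive to stability")
    return LferResult(x_name=x, y_name=y, r=r, slope=slope, slope_se=s_se,
                      intercept=intercept, intercept_se=i_se,
                      n=len(usable), flags=flags)


def phi_comparison(
    pairs: list[tuple[PhiValue, PhiValue]] | list[tuple[float, float]],
    slope_band: tuple[float, float] = (0.8, 1.2),
    intercept_tol: float = 0.1,
) -> tuple[LferResult, str]:
    """OLS of test-protein phi-values against reference phi-values.

    Returns the line plus a one-line verdict: slope within
    ``slope_band`` and |intercept| < ``intercept_tol`` reads as
    "mechanism unchanged"; a negative slope as "mechanism changed";
    anything else as inconclusive.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 phi pairs")
    ref = [p[0].phi if isinstance(p[0], PhiValue) else float(p[0])
           for p in pairs]
    test = [p[1].phi if isinstance(p[1], PhiValue) else float(p[1])
            for p in pairs]
    r = pearson_r(ref, test)
    slope, intercept, s_se, i_se = linear_fit(ref, test)
    result = LferResult(x_name="phi_ref", y_name="phi_test", r=r,
                        slope=slope, slope_se=s_se, intercept=intercept,
                        intercept_se=i_se, n=len(pairs), flags=[])
    if slope < 0:
        verdict = "mechanism changed (anticorrelated phi-values)"
        result.flags.append("negative slope")
    elif slope_band[0] <= slope <= slope_band[1] and abs(intercept) < intercept_tol:
        verdict = "mechanism unchanged (phi-values preserved)"
    else:
        verdict = "inconclusive (slope or intercept outside bands)"
    return result, verdict


# ----------------------------------------------------------------- report

def build_report(
    summaries: list[VariantSummary],
    lfer_results: list[LferResult] | None = None,
    structure_metrics: dict | None = None,
    provenance: dict | None = None,
) -> dict:
    """Assemble a machine-readable report (JSON-serialisable dict).

    One row per variant with fitted parameters and standard errors,
    plus LFER and structure sections; provenance (inputs, seed, config)
    is carried verbatim.
    """
    if not summaries:
        raise ValueError("need at least one variant summary")
    rows = []
    for s in summaries:
        eq, ch = s.eq_fit, s.chev_fit
        row = {
            "variant": s.variant_id,
            "dG_h2o": eq.params.dG_h2o, "dG_h2o_se": eq.se["dG_h2o"],
            "m_eq": eq.params.m_eq, "m_eq_se": eq.se["m_eq"],
            "d50": eq.d50,
            "kf_h2o": ch.params.kf_h2o, "kf_h2o_se": ch.se["kf_h2o"],
            "ku_h2o": ch.params.ku_h2o, "ku_h2o_se": ch.se["ku_h2o"],
            "m_kf": ch.params.m_kf, "m_ku": ch.params.m_ku,
            "beta_T": tanford_beta(ch),
            "dG_kinetic": RT_DEFAULT * float(
                np.log(ch.params.kf_h2o / ch.params.ku_h2o)),
        }
        if s.ddg is not None:
            row["ddG"] = s.ddg.value
            row["ddG_se"] = s.ddg.se
        if s.phi is not None:
            row["phi"] = s.phi.phi
            row["phi_se"] = s.phi.se
            row["phi_reliable"] = s.phi.reliable
        rows.append(row)

    report = {"variants": rows}
    if lfer_results:
        report["lfer"] = [asdict(r) for r in lfer_results]
    elif lfer_results is not None or len(summaries) < 3:
        report["lfer"] = []
        report["lfer_note"] = "insufficient variants for LFER (need >= 3)"
    if structure_metrics:
        report["structure"] = structure_metrics
    report["provenance"] = provenance or {}
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def report_to_markdown(report: dict) -> str:
    """Human-readable rendering of :func:`build_report` output."""
    lines = ["# Variant summary", ""]
    header = ("| variant | dG_H2O | m | kf_H2O | ku_H2O | beta_T "
              "| ddG | phi |")
    lines += [header, "|" + "---|" * 8]
    for row in report["variants"]:
        ddg = f"{row['ddG']:.2f}" if "ddG" in row else "-"
        phi = f"{row['phi']:.2f}" if "phi" in row else "-"
        lines.append(
            f"| {row['variant']} | {row['dG_h2o']:.2f} | {row['m_eq']:.2f} "
            f"| {row['kf_h2o']:.0f} | {row['ku_h2o']:.3g} "
            f"| {row['beta_T']:.2f} | {ddg} | {phi} |")
    if report.get("lfer"):
        lines += ["", "# LFER", ""]
        for r in report["lfer"]:
            lines.append(
                f"- {r['y_name']} vs {r['x_name']}: r = {r['r']:.3f}, "
                f"slope = {r['slope']:.3f} +/- {r['slope_se']:.3f}, "
                f"intercept = {r['intercept']:.3f} (n = {r['n']})"
                + (f"  [{'; '.join(r['flags'])}]" if r.get("flags") else ""))
    elif "lfer_note" in report:
        lines += ["", f"_{report['lfer_note']}_"]
    if "structure" in report:
        lines += ["", "# Structure metrics", ""]
        for k, v in report["structure"].items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
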