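"""Per-portion dose conversion, reference-dose compliance and the run report.

Method limits expressed per gram of food (µg_TAFP/g) are converted to an
absolute protein dose per eaten portion (mg TAFP, 25 g default portion for a
chocolate bar) and compared against the reference doses recommended or issued
by the VITAL 3.0 program, national authorities (Germany, the Netherlands,
Belgium) and the FAO/WHO expert consultation. The shipped reference-dose
table follows the published summary, including its provenance footnotes.

The per-portion limit defaults to the LOD basis: the published per-portion
column is numerically consistent with the per-gram detection limits times the
25 g portion, although it is labelled as an LOQ — the output here is therefore
called "per-portion limit" and the basis is explicit. Per-portion values are
rendered to one significant figure, matching common reporting practice for
reference doses.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .panel_io import MarkerPanel

DEFAULT_PORTION_G = 25.0

SCHEMES = ["VITAL3", "Germany", "Netherlands", "Belgium", "FAO-WHO"]


@dataclass(frozen=True)
class ComplianceVerdict:
    allergen: str
    method_limit_mg: float
    scheme: str
    reference_mg: float
    compliant: bool


def load_reference_doses() -> pd.DataFrame:
    """Reference-dose table shipped with the package (mg TAFP per portion)."""
    with resources.files("allerquant.data").joinpath("reference_doses.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"dose_mg": str})
    return df


def load_method_limits() -> pd.DataFrame:
    """Published per-marker method limits (fmol/µL and µg_TAFP/g)."""
    with resources.files("allerquant.data").joinpath("method_limits.csv").open() as fh:
        return pd.read_csv(fh)


def portion_dose(limit_per_gram: float, portion_g: float = DEFAULT_PORTION_G) -> float:
    """Convert a per-gram limit (µg/g) to an absolute dose per portion (mg)."""
    if limit_per_gram < 0:
        raise ValueError("limit must be nonnegative")
    if portion_g <= 0:
        raise ValueError("portion size must be positive")
    return limit_per_gram * portion_g / 1000.0


def round_1sf(value: float) -> float:
    """Round to one significant figure (per-portion rendering convention)."""
    if value == 0:
        return 0.0
    exp = math.floor(math.log10(abs(value)))
    return round(value, -exp)


def portion_limits(
    panel: MarkerPanel | None = None,
    portion_g: float = DEFAULT_PORTION_G,
    basis: Literal["lod", "loq"] = "lod",
    method_limits: pd.DataFrame | None = None,
    apply_compliance_cf: bool = True,
) -> dict[str, float]:
    """Per-allergen per-portion limits (mg, one significant figure).

    One limit per allergenic food: for foods with two monitored fractions
    (milk, egg) the quantitative fraction used for compliance is caseinate and
    egg white respectively. When an entry defines a ``compliance_cf`` (e.g.
    ovalbumin as 54% of egg-white protein, because reference doses refer to
    egg-white proteins only) the per-gram limit is rescaled by cCF/compliance_cf
    before conversion — only here, never in sample quantification.
    """
    limits = method_limits if method_limits is not None else load_method_limits()
    col = f"{basis}_tafp"
    chosen = {
        "Milk": "Milk caseinate",
        "Egg": "Egg white",
        "Peanut": "Peanut",
        "Soybean": "Soybean",
        "Hazelnut": "Hazelnut",
        "Almond": "Almond",
    }
    out: dict[str, float] = {}
    for allergen, entry_name in chosen.items():
        row = limits[limits["allergen_name"] == entry_name]
        if row.empty:
            continue
        per_gram = float(row[col].iloc[0])
        if apply_compliance_cf and panel is not None:
            try:
                entry = panel.entry(entry_name)
            except KeyError:
                entry = None
            if entry is not None and entry.compliance_cf is not None:
                per_gram = per_gram * entry.cCF / entry.compliance_cf
        out[allergen] = round_1sf(portion_dose(per_gram, portion_g))
    return out


def compliance(
    limits_mg: Mapping[str, float],
    doses: pd.DataFrame | None = None,
) -> list[ComplianceVerdict]:
    """One verdict per (allergen, scheme) with a numeric reference dose.

    Schemes with no issued dose ("nd") yield no verdict. Compliant means the
    method's per-portion limit is at or below the reference dose, i.e. the
    method can detect contamination at the action level.
    """
    table = doses if doses is not None else load_reference_doses()
    verdicts: list[ComplianceVerdict] = []
    for allergen, limit in limits_mg.items():
        rows = table[table["allergen"] == allergen]
        for _, row in rows.iterrows():
            raw = str(row["dose_mg"]).strip()
            if raw.lower() == "nd" or raw == "":
                continue
            ref = float(raw)
            verdicts.append(
                ComplianceVerdict(
                    allergen=allergen,
                    method_limit_mg=float(limit),
                    scheme=str(row["scheme"]),
                    reference_mg=ref,
                    compliant=bool(limit <= ref),
                )
            )
    return verdicts


def build_report(
    calibration_fits: Mapping[str, object] | None = None,
    sensitivity: Mapping[str, object] | None = None,
    quant_results: Iterable[object] = (),
    precision_results: Iterable[object] = (),
    verdicts: Iterable[ComplianceVerdict] = (),
    portion_g: float = DEFAULT_PORTION_G,
) -> dict:
    """Assemble the machine-readable validation report.

    All rounding happens here; upstream objects keep full precision. Values
    with an uncertainty budget are rendered as "value ± U (k=2)".
    """
    from .uncertainty import format_result

    def _fit_block(fit) -> dict:
        return {
            "peptide": fit.peptide_code,
            "slope": fit.slope,
            "sd_slope": fit.sd_slope,
            "intercept": fit.intercept,
            "r_squared": round(fit.r_squared, 3),
            "n": fit.n,
            "range_fmol": list(fit.range),
        }

    def _quant_block(q) -> dict:
        block = {
            "allergen": q.allergen_name,
            "x0_peptide_fmol_uL": q.x0_peptide,
            "x0_tafp_ug_g": q.x0_tafp,
            "detected": q.detected,
            "quantifiable": q.quantifiable,
            "flags": list(q.flags),
        }
        if q.budget is not None:
            b = q.budget
            block["u_x0"] = b.u_x0
            block["U_x0"] = b.U_x0
            block["k"] = b.k
            block["rendered"] = format_result(b.x0, b.U_x0, b.k)
            block["relative_contributions"] = b.relative_contributions
        return block

    def _precision_block(p) -> dict:
        return {
            "level_ug_g": p.level,
            "total_cv_percent": round(p.total_cv, 1),
            "weights_percent": {
                f: (None if w is None else round(w, 1))
                for f, (_, w) in p.components.items()
            },
            "anova_poolable": p.anova_poolable,
        }

    report = {
        "portion_g": portion_g,
        "calibration": {
            code: _fit_block(f) for code, f in (calibration_fits or {}).items()
        },
        "sensitivity": {
            code: {
                "method": s.method,
                "lod_fmol_uL": s.lod,
                "loq_fmol_uL": s.loq,
                "lod_tafp_ug_g": s.lod_tafp,
                "loq_tafp_ug_g": s.loq_tafp,
            }
            for code, s in (sensitivity or {}).items()
        },
        "quantification": [_quant_block(q) for q in quant_results],
        "precision": [_precision_block(p) for p in precision_results],
        "compliance": [asdict(v) for v in verdicts],
    }
    return report


def write_report(report: dict, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    if report.get("compliance"):
        pd.DataFrame(report["compliance"]).to_csv(out / "compliance.csv", index=False)
    return path
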