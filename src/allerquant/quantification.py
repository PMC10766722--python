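"""Interpolation, unit conversion and the detection/quantification rules.

The determined peptide content x0 (fmol/µL) is the averaged L/H ratio ȳ0
interpolated on the matrix-matched curve, (ȳ0 − a)/b. It converts to the
risk-relevant reporting unit — µg of total allergenic food protein per g of
food (µg_TAFP/g) — as

    x0_TAFP = x0_peptide · (cMM/cCF) · m · d

where cMM is the centered molar mass of the parent protein (g/mol), cCF its
centered conversion factor (share of the ingredient's total protein), m = 1e-5
folds the 1:10 matrix-to-solvent extraction ratio with SI-prefix conversion,
and d = 1.33 is the digestion dilution factor.

An allergen is *detected* when at least ``min_peptides`` of its markers each
show at least ``min_transitions`` transitions at or above the marker's LOD;
it is *quantifiable* when the quantitative marker's signal is at or above its
LOQ. Comparisons are inclusive (≥).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .calibration import RegressionFit, SensitivityLimits
from .panel_io import AllergenEntry

#: matrix-to-solvent ratio (1:10) folded with SI prefix conversion
M_FACTOR = 1e-5
#: dilution applied during the digestion protocol
D_FACTOR = 1.33


@dataclass(frozen=True)
class QuantInput:
    """Averaged signal for one quantitative marker."""

    peptide_code: str
    mean_ratio: float
    p: int  # number of replicate observations averaged

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError("p must be >= 1")


@dataclass
class QuantResult:
    """Per-allergen quantification outcome."""

    allergen_name: str
    x0_peptide: float
    x0_tafp: float | None
    detected: bool
    quantifiable: bool
    limits: SensitivityLimits | None = None
    budget: object | None = None  # UncertaintyBudget, attached when quantifiable
    evidence: list[tuple[str, int]] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def interpolate(fit: RegressionFit, y0_mean: float) -> tuple[float, bool]:
    """Peptide content (ȳ0 − a)/b in fmol/µL.

    Returns ``(value, floored)``; negative interpolations — blanks scatter
    around zero — are floored at 0 and flagged.
    """
    if fit.slope <= 0:
        raise ValueError("uninformative curve: slope must be positive")
    x0 = (y0_mean - fit.intercept) / fit.slope
    if x0 < 0:
        return 0.0, True
    return x0, False


def to_tafp(
    x0_peptide: float,
    entry: AllergenEntry,
    m: float = M_FACTOR,
    d: float = D_FACTOR,
) -> float:
    """Convert peptide content (fmol/µL) to µg_TAFP/g of food."""
    if entry.cCF <= 0:
        raise ValueError("conversion factor must be positive")
    return x0_peptide * (entry.cMM / entry.cCF) * m * d


def from_tafp(
    x_tafp: float,
    entry: AllergenEntry,
    m: float = M_FACTOR,
    d: float = D_FACTOR,
) -> float:
    """Inverse conversion: expected peptide fmol/µL for a TAFP mass fraction."""
    return x_tafp / ((entry.cMM / entry.cCF) * m * d)


def detection_rule(
    transition_values: Mapping[str, Sequence[float]],
    lods: Mapping[str, float],
    min_peptides: int = 2,
    min_transitions: int = 2,
    allow_single_peptide: bool = False,
) -> tuple[bool, list[tuple[str, int]]]:
    """Multi-peptide, multi-transition detection decision.

    Parameters
    ----------
    transition_values
        Per peptide code, the interpolated concentration of each monitored
        transition (fmol/µL; flagged/undetected transitions as NaN or negative
        values count as not detected).
    lods
        Per peptide code, the LOD on the same scale.

    Returns the detected flag plus the qualifying (peptide, transition index)
    evidence list. Comparison with the LOD is inclusive.
    """
    if len(transition_values) < min_peptides and not allow_single_peptide:
        raise ValueError(
            f"detection rule needs >= {min_peptides} configured peptides; "
            "pass allow_single_peptide=True to override"
        )
    evidence: list[tuple[str, int]] = []
    qualifying_peptides = 0
    for code, values in transition_values.items():
        lod = lods[code]
        hits = [
            (code, i)
            for i, v in enumerate(values)
            if v == v and v >= lod  # v == v filters NaN
        ]
        if len(hits) >= min_transitions:
            qualifying_peptides += 1
            evidence.extend(hits)
    needed = 1 if allow_single_peptide else min_peptides
    return qualifying_peptides >= needed, evidence


def quantify(
    inp: QuantInput,
    fit: RegressionFit,
    entry: AllergenEntry,
    limits: SensitivityLimits,
    transition_values: Mapping[str, Sequence[float]] | None = None,
    lods: Mapping[str, float] | None = None,
    poolable: bool = True,
    force: bool = False,
) -> QuantResult:
    """Assemble the full per-allergen outcome.

    ``poolable`` is the precision module's ANOVA verdict gating the averaging
    of ȳ0 across replicate groups; it must be True (or explicitly overridden
    with ``force``) before a pooled mean is interpreted.
    """
    if not poolable and not force:
        raise ValueError(
            "replicate groups are not poolable by ANOVA; refuse to average "
            "(pass force=True to override)"
        )
    x0, floored = interpolate(fit, inp.mean_ratio)
    flags = ["negative_interpolation_floored"] if floored else []
    if not poolable:
        flags.append("pooled_despite_anova")

    if transition_values is not None and lods is not None:
        detected, evidence = detection_rule(
            transition_values, lods, allow_single_peptide=len(transition_values) < 2
        )
    else:
        # fall back to the QTM-only rule when confirmation data is absent
        detected, evidence = x0 >= limits.lod and not floored, []
        flags.append("qtm_only_detection")

    quantifiable = bool(detected and not floored and x0 >= limits.loq)
    x0_tafp: float | None = None
    if quantifiable:
        x0_tafp = to_tafp(x0, entry)
    elif force and x0 > 0:
        x0_tafp = to_tafp(x0, entry)
        flags.append("<LOQ")
    return QuantResult(
        allergen_name=entry.allergen_name,
        x0_peptide=x0,
        x0_tafp=x0_tafp,
        detected=bool(detected),
        quantifiable=quantifiable,
        limits=limits,
        evidence=evidence,
        flags=flags,
    )
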