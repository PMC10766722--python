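"""Synthetic MRM and discovery datasets with the study's statistical structure.

Every downstream stage of the pipeline is testable without instrument data:
this module generates calibration curves (ten points, 0–50 fmol/µL, heavy
internal standard at 25 fmol/µL, three technical replicates), incurred-sample
measurements at 2/4/10/40 µg_TAFP/g with a biological × technical × day ×
analyst variance structure, spiked-before/spiked-after recovery pairs, and
multi-isoform discovery protein-intensity tables.

Noise is placed on the L/H ratio, not on raw areas: heavy areas fluctuate
around a constant and light areas are derived from the noisy ratio, so the
internal-standard normalisation the method relies on is structurally present.
Biological / day / analyst effects are multiplicative (log-normal) while
instrumental noise is additive Gaussian with a floor — sample preparation then
dominates at high content and the instrument near the lowest detected point,
as real validation data show. The generating slopes default to the
published-scale sensitivities of the eight quantitative markers, so synthetic
signals live on a realistic ratio scale.

A single global seed fans out into independent substreams keyed by a stable
hash of each dataset label, so datasets are reproducible yet uncorrelated.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .panel_io import MarkerPanel, AllergenEntry, validate_peak_area_table
from .quantification import from_tafp

#: published-scale method sensitivities (ratio per fmol/µL) anchoring the
#: generator defaults for the eight quantitative markers
QTM_SLOPE_ANCHORS: dict[str, float] = {
    "mc-FFV": 0.02121,
    "mw-VLV": 0.0259,
    "ew-ISQ": 0.0534,
    "ey-ATA": 0.0597,
    "p-TAN": 0.0456,
    "s-VLI": 0.0340,
    "h-ALP": 0.0391,
    "a-TEE": 0.0431,
}

#: qualitative markers respond somewhat less than their paired QTM by design
QLM_SLOPE_FRACTION = 0.8

DEFAULT_LEVELS = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 10.0, 25.0, 50.0)
HEAVY_AREA_SCALE = 1.0e5


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, platform-stable RNG substream for one dataset label."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode("utf-8"))])
    )


def default_slopes(panel: MarkerPanel) -> dict[str, float]:
    """Generating slopes for every marker in the panel."""
    slopes: dict[str, float] = {}
    for entry in panel.entries:
        qtm = entry.qtm
        base = QTM_SLOPE_ANCHORS.get(qtm.code, 0.04)
        for m in entry.markers:
            slopes[m.code] = base if m.role == "QTM" else base * QLM_SLOPE_FRACTION
    return slopes


class CalibrationDesign(BaseModel):
    """Generating design of a calibration curve experiment."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    heavy_level: float = Field(default=25.0, gt=0)
    tech_reps: int = Field(default=3, ge=1)
    true_slopes: dict[str, float] | None = None
    true_intercepts: dict[str, float] | None = None
    noise_rel: float = Field(default=0.05, ge=0, description="relative SD of ratio")
    noise_abs: float = Field(
        default=0.002, ge=0, description="absolute SD floor on the ratio scale"
    )
    matrix_attenuation: float = Field(
        default=0.85,
        gt=0,
        description=(
            "slope ratio matrix/standard: matrix curves use the generating "
            "slope, standard (buffer) curves the slope divided by this factor"
        ),
    )
    heavy_area_jitter: float = Field(default=0.05, ge=0)

    @model_validator(mode="after")
    def _levels_increasing(self) -> "CalibrationDesign":
        lv = self.levels
        if any(b <= a for a, b in zip(lv, lv[1:])) or any(v < 0 for v in lv):
            raise ValueError("levels must be nonnegative and strictly increasing")
        return self


class IncurredDesign(BaseModel):
    """Generating design of incurred-sample (ICB) measurements."""

    levels: tuple[float, ...] = (2.0, 4.0, 10.0, 40.0)
    bio_reps: int = Field(default=3, ge=1)
    tech_reps: int = Field(default=3, ge=1)
    days: int = Field(default=1, ge=1)
    analysts: int = Field(default=1, ge=1)
    sigma_sp: float = Field(default=0.08, ge=0, description="sample-prep, log scale")
    sigma_da: float = Field(default=0.05, ge=0, description="day, log scale")
    sigma_a: float = Field(default=0.02, ge=0, description="analyst, log scale")
    sigma_ia: float = Field(
        default=0.002, ge=0, description="instrumental, additive on the ratio scale"
    )


class ProteinSpec(BaseModel):
    accession: str
    molar_mass: float = Field(gt=0)
    rel_abundance: float = Field(gt=0, le=1)
    carries_marker: bool = False


class DiscoveryDesign(BaseModel):
    """Generating design of a discovery protein-intensity experiment."""

    proteins: list[ProteinSpec]
    replicates: int = Field(default=6, ge=2)
    intensity_cv: float = Field(default=0.10, ge=0)
    total_intensity: float = Field(default=1.0e9, gt=0)

    @model_validator(mode="after")
    def _abundances_sum(self) -> "DiscoveryDesign":
        s = sum(p.rel_abundance for p in self.proteins)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"relative abundances must sum to 1 (got {s})")
        return self

    @property
    def marker_accessions(self) -> set[str]:
        return {p.accession for p in self.proteins if p.carries_marker}


def milk_like_discovery_design(
    marker_shares: tuple[float, float] = (0.200, 0.174),
    n_distractors: int = 20,
    replicates: int = 6,
    intensity_cv: float = 0.10,
) -> DiscoveryDesign:
    """Default discovery design: two marker isoforms summing to a realistic
    caseinate share, remainder spread over distractor proteins."""
    rest = 1.0 - sum(marker_shares)
    weights = np.linspace(2.0, 0.5, n_distractors)
    shares = rest * weights / weights.sum()
    proteins = [
        ProteinSpec(
            accession=f"MARK{i}", molar_mass=23615.0, rel_abundance=s, carries_marker=True
        )
        for i, s in enumerate(marker_shares)
    ] + [
        ProteinSpec(accession=f"DIST{i}", molar_mass=30000.0, rel_abundance=float(s))
        for i, s in enumerate(shares)
    ]
    return DiscoveryDesign(
        proteins=proteins, replicates=replicates, intensity_cv=intensity_cv
    )


# ---------------------------------------------------------------------------
# generators


def _rows_for_ratio(
    ratio: float,
    *,
    sample_id: str,
    condition: str,
    nominal_level: float,
    peptide_code: str,
    transition_index: int,
    bio: str,
    tech: str,
    day: str,
    analyst: str,
    heavy_area: float,
) -> list[dict]:
    ratio = max(ratio, 0.0)
    base = dict(
        sample_id=sample_id,
        condition=condition,
        nominal_level=nominal_level,
        peptide_code=peptide_code,
        transition_index=transition_index,
        biological_rep=bio,
        technical_rep=tech,
        day=day,
        analyst=analyst,
    )
    return [
        dict(base, channel="light", area=ratio * heavy_area),
        dict(base, channel="heavy", area=heavy_area),
    ]


def simulate_calibration(
    design: CalibrationDesign,
    panel: MarkerPanel,
    seed: int,
    curve_type: str = "matrix",
    label: str = "",
) -> pd.DataFrame:
    """Simulate a full calibration experiment as a long peak-area table.

    ``curve_type="matrix"`` yields the matrix-matched curve at the generating
    slope; ``"standard"`` yields the buffer curve with slope divided by the
    matrix attenuation. Deterministic for a fixed seed and label.
    """
    if curve_type not in {"matrix", "standard"}:
        raise ValueError("curve_type must be 'matrix' or 'standard'")
    rng = substream(seed, f"calibration:{curve_type}:{label}")
    slopes = design.true_slopes or default_slopes(panel)
    intercepts = design.true_intercepts or {}
    rows: list[dict] = []
    for entry in panel.entries:
        for marker in entry.markers:
            if marker.code not in slopes:
                continue
            b = slopes[marker.code]
            if curve_type == "standard":
                b = b / design.matrix_attenuation
            a = intercepts.get(marker.code, 0.0)
            for level in design.levels:
                mu = a + b * level
                for tr in range(len(marker.transitions)):
                    for rep in range(design.tech_reps):
                        sigma = np.sqrt(
                            (design.noise_rel * mu) ** 2 + design.noise_abs**2
                        )
                        ratio = mu + rng.normal(0.0, sigma) if sigma > 0 else mu
                        heavy = HEAVY_AREA_SCALE * (
                            np.exp(rng.normal(0.0, design.heavy_area_jitter))
                            if design.heavy_area_jitter > 0
                            else 1.0
                        )
                        rows.extend(
                            _rows_for_ratio(
                                ratio,
                                sample_id=f"{curve_type}-L{level:g}-r{rep}",
                                condition="blank" if level == 0 else "calibrant",
                                nominal_level=level,
                                peptide_code=marker.code,
                                transition_index=tr,
                                bio="b0",
                                tech=f"t{rep}",
                                day="d0",
                                analyst="a1",
                                heavy_area=heavy,
                            )
                        )
    return validate_peak_area_table(pd.DataFrame(rows))


def _incurred_ratio_rows(
    rng: np.random.Generator,
    entry: AllergenEntry,
    truth: Mapping[str, tuple[float, float]],
    level: float,
    design: IncurredDesign,
    condition: str = "incurred",
    sample_prefix: str = "ICB",
) -> list[dict]:
    rows: list[dict] = []
    eps_day = rng.normal(0.0, design.sigma_da, design.days) if design.sigma_da else np.zeros(design.days)
    eps_an = rng.normal(0.0, design.sigma_a, design.analysts) if design.sigma_a else np.zeros(design.analysts)
    x_pep = from_tafp(level, entry)
    for d in range(design.days):
        for an in range(design.analysts):
            for bio in range(design.bio_reps):
                eps_sp = rng.normal(0.0, design.sigma_sp) if design.sigma_sp else 0.0
                mult = np.exp(eps_sp + eps_day[d] + eps_an[an])
                sid = f"{sample_prefix}{level:g}-d{d}-a{an}-b{bio}"
                for marker in entry.markers:
                    b, a = truth[marker.code]
                    mu = a + b * x_pep
                    for tr in range(len(marker.transitions)):
                        for tech in range(design.tech_reps):
                            eps_ia = (
                                rng.normal(0.0, design.sigma_ia)
                                if design.sigma_ia
                                else 0.0
                            )
                            ratio = mu * mult + eps_ia
                            rows.extend(
                                _rows_for_ratio(
                                    ratio,
                                    sample_id=sid,
                                    condition=condition,
                                    nominal_level=level,
                                    peptide_code=marker.code,
                                    transition_index=tr,
                                    bio=f"b{bio}",
                                    tech=f"t{tech}",
                                    day=f"d{d}",
                                    analyst=f"a{an + 1}",
                                    heavy_area=HEAVY_AREA_SCALE,
                                )
                            )
    return rows


def simulate_incurred(
    design: IncurredDesign,
    panel: MarkerPanel,
    truth: Mapping[str, tuple[float, float]],
    seed: int,
    label: str = "",
) -> pd.DataFrame:
    """Simulate incurred chocolate samples (ICB) at the design levels.

    ``truth`` maps peptide code to the (slope, intercept) of its generating
    calibration line; the nominal TAFP level is inverted through the unit
    conversion to the expected peptide concentration, and ratios follow
    truth × exp(ε_SP + ε_DA + ε_A) + ε_IA with the design's component SDs.
    Factor labels are recorded so variance decomposition can recover them.
    """
    rng = substream(seed, f"incurred:{label}")
    rows: list[dict] = []
    for entry in panel.entries:
        if not all(m.code in truth for m in entry.markers):
            continue
        for level in design.levels:
            rows.extend(_incurred_ratio_rows(rng, entry, truth, level, design))
    if not rows:
        raise ValueError("truth covers no panel marker")
    return validate_peak_area_table(pd.DataFrame(rows))


def simulate_discovery(design: DiscoveryDesign, seed: int, label: str = "") -> pd.DataFrame:
    """Simulate a MaxQuant-style protein-intensity table.

    Per replicate, each protein's intensity is proportional to its true
    relative abundance with log-normal noise of the design CV; marker-carrying
    accessions are flagged and given nonzero unique-peptide counts.
    """
    rng = substream(seed, f"discovery:{label}")
    sigma = np.sqrt(np.log1p(design.intensity_cv**2))
    rows = []
    for rep in range(design.replicates):
        for prot in design.proteins:
            noise = np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            rows.append(
                dict(
                    replicate_id=f"rep{rep + 1}",
                    accession=prot.accession,
                    intensity=design.total_intensity * prot.rel_abundance * noise,
                    unique_peptide_count=int(rng.integers(2, 15)),
                    carries_marker=prot.carries_marker,
                )
            )
    return pd.DataFrame(rows)


def simulate_recovery_pair(
    true_recovery: float,
    level: float,
    panel: MarkerPanel,
    truth: Mapping[str, tuple[float, float]],
    seed: int,
    reps: int = 3,
    noise_rel: float = 0.03,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate spiked-before (SB) and spiked-after (SA) sample tables.

    The SB sample's expected content is ``true_recovery`` × the SA content:
    analyte spiked before extraction/purification suffers the method's losses,
    the post-extraction spike does not. Both are carried through the ratio
    model with multiplicative noise of relative SD ``noise_rel``.
    """
    if not 0 <= true_recovery <= 1.5:
        raise ValueError("true_recovery must be a fraction (0-1.5)")
    rng = substream(seed, "recovery")
    design = IncurredDesign(
        levels=(level,),
        bio_reps=reps,
        tech_reps=1,
        days=1,
        analysts=1,
        sigma_sp=noise_rel,
        sigma_da=0.0,
        sigma_a=0.0,
        sigma_ia=0.0,
    )
    tables = []
    for condition, content in (("SB", true_recovery * level), ("SA", level)):
        rows: list[dict] = []
        for entry in panel.entries:
            if not all(m.code in truth for m in entry.markers):
                continue
            rows.extend(
                _incurred_ratio_rows(
                    rng,
                    entry,
                    truth,
                    content,
                    design,
                    condition=condition,
                    sample_prefix=condition,
                )
            )
        df = pd.DataFrame(rows)
        # label with the nominal (SA) level; the SB attenuation is the signal
        df["nominal_level"] = level
        tables.append(validate_peak_area_table(df))
    return tables[0], tables[1]
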