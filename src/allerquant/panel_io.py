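"""Marker-panel configuration and tabular I/O shared by the pipeline.

The marker panel describes, per allergenic ingredient, the signature tryptic
peptides monitored by the MRM method: one quantitative marker (QTM) used for
absolute quantification and one or more qualitative markers (QLM) used for
confirmation, each with its precursor->product transitions, the accessions of
the parent protein(s), a centered molar mass (cMM, g/mol) and a centered
conversion factor (cCF, fraction of the ingredient's total protein contributed
by the parent protein), both with rectangular-distribution standard
uncertainties.

Peak-area measurements are exchanged as a long-format table with one row per
(sample, peptide, transition, isotope channel); the analytical signal is the
light/heavy (L/H) peak-area ratio formed here.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: required columns of a long-format peak-area table
PEAK_AREA_COLUMNS = [
    "sample_id",
    "condition",
    "nominal_level",
    "peptide_code",
    "transition_index",
    "channel",
    "area",
    "biological_rep",
    "technical_rep",
    "day",
    "analyst",
]

CONDITIONS = {"blank", "calibrant", "incurred", "SB", "SA"}


class PanelValidationError(ValueError):
    """Raised when a panel file or object violates its invariants."""


class PeptideMarker(BaseModel):
    """One monitored peptide: sequence, role and MRM transitions.

    ``label_shift`` is the mass increment of the isotopically labelled
    ("heavy") analogue: +8 Da for C-terminal lysine, +10 Da for arginine.
    """

    code: str
    sequence: str
    role: Literal["QTM", "QLM"]
    label_shift: float = Field(gt=0)
    transitions: list[tuple[float, float]] = Field(min_length=1)

    @field_validator("sequence")
    @classmethod
    def _aa_alphabet(cls, v: str) -> str:
        if not v or not set(v) <= AA_ALPHABET:
            raise ValueError(
                f"sequence {v!r} contains characters outside the 20-AA alphabet"
            )
        return v


class AllergenEntry(BaseModel):
    """Per-allergen configuration: markers plus unit-conversion constants."""

    allergen_name: str
    parent_protein_accessions: list[str] = Field(min_length=1)
    markers: list[PeptideMarker] = Field(min_length=1)
    cMM: float = Field(gt=0, description="centered molar mass, g/mol")
    u_MM: float = Field(ge=0)
    cCF: float = Field(gt=0, le=1.0, description="centered conversion factor")
    u_CF: float = Field(ge=0)
    compliance_cf: float | None = Field(
        default=None,
        gt=0,
        le=1.0,
        description=(
            "optional CF override used only when converting method limits for "
            "compliance (e.g. ovalbumin as 54% of egg-white protein); never "
            "used in sample quantification"
        ),
    )

    @model_validator(mode="after")
    def _one_qtm(self) -> "AllergenEntry":
        n_qtm = sum(m.role == "QTM" for m in self.markers)
        if n_qtm != 1:
            raise ValueError(
                f"{self.allergen_name}: exactly one QTM required, found {n_qtm}"
            )
        codes = [m.code for m in self.markers]
        if len(set(codes)) != len(codes):
            raise ValueError(f"{self.allergen_name}: duplicate peptide codes")
        return self

    @property
    def qtm(self) -> PeptideMarker:
        return next(m for m in self.markers if m.role == "QTM")


class MarkerPanel(BaseModel):
    """The full marker panel for a multiplexed method."""

    entries: list[AllergenEntry] = Field(min_length=1)
    stock_rel_uncertainty: float = Field(
        default=0.30,
        ge=0,
        lt=1,
        description=(
            "relative concentration precision of the synthetic-peptide stock "
            "solutions, as quoted by amino-acid analysis (conservative bound)"
        ),
    )

    @model_validator(mode="after")
    def _unique_names_and_codes(self) -> "MarkerPanel":
        names = [e.allergen_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("allergen names must be unique within a panel")
        codes = [m.code for e in self.entries for m in e.markers]
        if len(set(codes)) != len(codes):
            raise ValueError("peptide codes must be unique within a panel")
        return self

    def entry(self, allergen_name: str) -> AllergenEntry:
        for e in self.entries:
            if e.allergen_name == allergen_name:
                return e
        raise KeyError(allergen_name)

    def marker(self, peptide_code: str) -> PeptideMarker:
        for e in self.entries:
            for m in e.markers:
                if m.code == peptide_code:
                    return m
        raise KeyError(peptide_code)

    def entry_for_peptide(self, peptide_code: str) -> AllergenEntry:
        for e in self.entries:
            if any(m.code == peptide_code for m in e.markers):
                return e
        raise KeyError(peptide_code)


def load_panel(path: str | Path) -> MarkerPanel:
    """Load and validate a marker panel from its JSON representation."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        return MarkerPanel.model_validate(raw)
    except Exception as exc:  # pydantic error carries the offending field
        raise PanelValidationError(str(exc)) from exc


def save_panel(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(panel.model_dump(mode="json"), fh, indent=2)
        fh.write("\n")


def load_default_panel() -> MarkerPanel:
    """Panel shipped with the package (six allergenic foods, eight QTMs)."""
    text = resources.files("allerquant.data").joinpath("default_panel.json").read_text()
    return MarkerPanel.model_validate(json.loads(text))


# ---------------------------------------------------------------------------
# Peak-area tables


def validate_peak_area_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format peak-area table invariants; return the table."""
    missing = [c for c in PEAK_AREA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak-area table missing columns: {missing}")
    if (table["area"] < 0).any():
        raise ValueError("peak areas must be nonnegative")
    bad_channel = set(table["channel"].unique()) - {"light", "heavy"}
    if bad_channel:
        raise ValueError(f"unknown channels: {sorted(bad_channel)}")
    bad_cond = set(table["condition"].unique()) - CONDITIONS
    if bad_cond:
        raise ValueError(f"unknown conditions: {sorted(bad_cond)}")
    return table


def read_peak_areas(path: str | Path) -> pd.DataFrame:
    return validate_peak_area_table(pd.read_csv(path))


def write_peak_areas(table: pd.DataFrame, path: str | Path) -> None:
    validate_peak_area_table(table).to_csv(path, index=False)


_KEY = [
    "sample_id",
    "condition",
    "nominal_level",
    "peptide_code",
    "transition_index",
    "biological_rep",
    "technical_rep",
    "day",
    "analyst",
]


def compute_lh_ratios(
    table: pd.DataFrame,
    transition_choice: int | Literal["all"] = 0,
) -> pd.DataFrame:
    """Form light/heavy peak-area ratios, the method's analytical signal.

    Parameters
    ----------
    table
        Long-format peak-area table (light and heavy rows).
    transition_choice
        Index of the designated quantifier transition (default the first), or
        ``"all"`` to keep one ratio per monitored transition — used by the
        detection rule, which inspects every transition of every peptide.

    Returns
    -------
    DataFrame with one row per (sample, peptide[, transition], replicate)
    carrying ``ratio`` and a ``flag`` column. A zero heavy area yields a
    flagged record (``flag="missing_heavy"``, ratio NaN) rather than a number;
    flagged records propagate downstream as "not detected".
    """
    validate_peak_area_table(table)
    wide = table.pivot_table(
        index=_KEY, columns="channel", values="area", aggfunc="first"
    )
    if "heavy" not in wide.columns:
        raise ValueError("no heavy-channel rows present")
    missing = wide.index[wide["heavy"].isna()].tolist()
    if missing:
        raise ValueError(
            f"light rows without a matching heavy row: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    out = wide.reset_index()
    if transition_choice != "all":
        out = out[out["transition_index"] == transition_choice].copy()
        if out.empty:
            raise ValueError(
                f"no rows for quantifier transition index {transition_choice}"
            )
    zero_heavy = out["heavy"] == 0
    out["ratio"] = out["light"] / out["heavy"].where(~zero_heavy)
    out["flag"] = ""
    out.loc[zero_heavy, "flag"] = "missing_heavy"
    out.loc[zero_heavy, "ratio"] = float("nan")
    cols = _KEY + ["ratio", "flag"]
    return out[cols]


def ratios_for(
    ratio_table: pd.DataFrame,
    peptide_code: str,
    condition: str | None = None,
    level: float | None = None,
) -> pd.DataFrame:
    """Convenience filter over a ratio table, excluding flagged records."""
    df = ratio_table[ratio_table["peptide_code"] == peptide_code]
    if condition is not None:
        df = df[df["condition"] == condition]
    if level is not None:
        df = df[df["nominal_level"] == level]
    return df[df["flag"] == ""]
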