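"""Conversion factors and centered molar masses from discovery proteomics.

The conversion factor (CF) of a marker's parent protein is its relative
abundance in the allergenic ingredient's total protein profile: the summed
intensity of every accession carrying the marker peptide (each identified by
at least one unique peptide) divided by the summed intensity of all identified
proteins in that replicate. Replicate CFs are reduced to a *centered* estimate
— the midpoint of the min–max range — with a rectangular-distribution standard
uncertainty of half-range/√3. Molar masses over sequenced isoforms/variants
are centered the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import math

import pandas as pd

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class CenteredEstimate:
    """Midpoint of a min–max range with rectangular standard uncertainty."""

    center: float
    u: float
    basis_min: float
    basis_max: float
    n_basis: int
    mean: float  # plain arithmetic mean, reported for transparency
    single_basis: bool = False


def _centered(values: Sequence[float]) -> CenteredEstimate:
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("at least one basis value is required")
    lo, hi = min(vals), max(vals)
    single = len(vals) < 2
    if single:
        warnings.warn(
            "centered estimate from a single basis value: uncertainty set to 0",
            stacklevel=3,
        )
    return CenteredEstimate(
        center=(lo + hi) / 2.0,
        u=0.0 if single else (hi - lo) / 2.0 / SQRT3,
        basis_min=lo,
        basis_max=hi,
        n_basis=len(vals),
        mean=sum(vals) / len(vals),
        single_basis=single,
    )


def replicate_cf(
    replicate_rows: pd.DataFrame,
    marker_accessions: Iterable[str],
    min_unique_peptides: int = 1,
) -> float:
    """Relative abundance of the marker protein(s) in one discovery replicate.

    ``replicate_rows`` must carry columns ``accession``, ``intensity`` and
    ``unique_peptide_count`` for a single replicate. Marker accessions failing
    the unique-peptide gate are excluded from the numerator.
    """
    markers = set(marker_accessions)
    if replicate_rows["accession"].duplicated().any():
        raise ValueError("duplicate accessions within one replicate")
    total = replicate_rows["intensity"].sum()
    if total <= 0:
        raise ValueError("zero total intensity in replicate")
    is_marker = replicate_rows["accession"].isin(markers)
    passes = replicate_rows["unique_peptide_count"] >= min_unique_peptides
    hit = replicate_rows[is_marker & passes]
    if hit.empty:
        raise ValueError(
            f"no marker accession passes the unique-peptide filter: {sorted(markers)}"
        )
    return float(hit["intensity"].sum() / total)


def cf_per_replicate(
    table: pd.DataFrame,
    marker_accessions: Iterable[str],
    min_unique_peptides: int = 1,
) -> dict[str, float]:
    """Per-replicate CFs over a full protein-intensity table.

    Replicates where no marker accession is quantified are excluded with a
    warning rather than contributing CF = 0.
    """
    out: dict[str, float] = {}
    for rep_id, rows in table.groupby("replicate_id"):
        try:
            out[str(rep_id)] = replicate_cf(rows, marker_accessions, min_unique_peptides)
        except ValueError as exc:
            warnings.warn(f"replicate {rep_id} excluded from CF: {exc}", stacklevel=2)
    if not out:
        raise ValueError("no replicate yielded a conversion factor")
    return out


def centered_cf(per_replicate_cfs: Sequence[float]) -> CenteredEstimate:
    """Centered conversion factor: (max+min)/2 with u = half-range/√3."""
    est = _centered(per_replicate_cfs)
    if not (0 < est.center <= 1):
        raise ValueError("conversion factors must lie in (0, 1]")
    return est


def centered_molar_mass(isoform_mms: Sequence[float]) -> CenteredEstimate:
    """Centered molar mass over sequenced isoforms/variants (g/mol)."""
    if any(v <= 0 for v in isoform_mms):
        raise ValueError("molar masses must be positive")
    return _centered(isoform_mms)
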