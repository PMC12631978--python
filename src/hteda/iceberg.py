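"""Iceberg contribution accounting under concentration addition.

The measured activity of a sample or fraction (its bioanalytical
equivalent concentration, BEQ_bio) is compared with the activity
predicted from its quantified constituents: each compound contributes
``concentration x REP`` reference-equivalents, where REP is its
relative potency versus the reference agonist (literature value, or
the ratio of reference to compound EC50). The percent of BEQ_bio
explained by each compound — and the unexplained remainder, the
submerged part of the iceberg — is reported per location.

Contributions above 100% are reported as-is and flagged as
masking-suspect: co-eluting antagonists can suppress the measured
activity so a quantified agonist appears to over-explain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import pandas as pd

from ._errors import HtedaError
from .quantify import Location, Quantification

__all__ = [
    "CompoundPotency",
    "ContributionEntry",
    "ContributionTable",
    "rep_from_ec50",
    "contribution",
    "build_contribution_table",
]

MASKING_FLAG_PCT = 100.0


@dataclass(frozen=True)
class CompoundPotency:
    """Relative potency of a compound versus the reference agonist."""

    compound: str
    rep: float
    source: Literal["literature", "ec50_ratio"] = "literature"
    ec50_ref: Optional[float] = None  # ng/L
    ec50_compound: Optional[float] = None  # ng/L

    def __post_init__(self) -> None:
        if self.rep <= 0:
            raise HtedaError(f"{self.compound}: REP must be positive")


def rep_from_ec50(
    compound: str, ec50_ref: float, ec50_compound: float
) -> CompoundPotency:
    """REP as the ratio of reference EC50 to compound EC50 (same assay,
    same units): a compound 1000-fold less potent has REP 1e-3."""
    if ec50_ref <= 0 or ec50_compound <= 0:
        raise HtedaError(
            f"EC50 values must be positive, got ({ec50_ref}, {ec50_compound})"
        )
    return CompoundPotency(
        compound=compound,
        rep=ec50_ref / ec50_compound,
        source="ec50_ratio",
        ec50_ref=ec50_ref,
        ec50_compound=ec50_compound,
    )


def contribution(concentration: float, rep: float, beq_bio: float) -> float:
    """Percent of measured activity explained by one compound.

    ``100 * concentration * REP / BEQ_bio`` with concentration and
    BEQ_bio in the same units (ug/L and ug reference-equivalents/L).
    May exceed 100 (masking diagnostic); never clipped.
    """
    if beq_bio <= 0:
        raise HtedaError(f"BEQ_bio must be positive, got {beq_bio}")
    if concentration < 0:
        raise HtedaError("concentration must be non-negative")
    return 100.0 * concentration * rep / beq_bio


@dataclass(frozen=True)
class ContributionEntry:
    compound: str
    location: Location
    concentration: float  # ug/L
    rep: float
    beq_contrib: float  # ug reference-equivalents / L
    percent: float
    confidence: Literal["high", "medium"]
    masking_suspect: bool = False


@dataclass
class ContributionTable:
    """Per-compound, per-location activity contributions."""

    entries: list[ContributionEntry]
    beq_bio: Mapping[Location, float]
    not_attributable: list[Quantification] = field(default_factory=list)

    def explained(self, location: Location) -> float:
        """Summed percent of BEQ_bio explained at a location."""
        return sum(e.percent for e in self.entries if e.location == location)

    def unexplained(self, location: Location) -> float:
        """100 minus explained; negative values indicate over-explanation."""
        return 100.0 - self.explained(location)

    @property
    def locations(self) -> list[Location]:
        return sorted(self.beq_bio, key=str)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "compound": e.compound,
                    "location": e.location,
                    "concentration_ug_per_L": e.concentration,
                    "rep": e.rep,
                    "beq_contrib_ug_per_L": e.beq_contrib,
                    "percent": e.percent,
                    "confidence": e.confidence,
                    "masking_suspect": e.masking_suspect,
                }
                for e in self.entries
            ]
        )
        return df

    def summary(self) -> str:
        lines = ["Iceberg contribution summary", "============================"]
        for loc in self.locations:
            lines.append(
                f"{loc}: BEQ_bio={self.beq_bio[loc]:.4g} ug/L, "
                f"explained={self.explained(loc):.1f}%, "
                f"unexplained={self.unexplained(loc):.1f}%"
            )
        if self.not_attributable:
            names = sorted({q.compound for q in self.not_attributable})
            lines.append(f"not attributable (no REP): {', '.join(names)}")
        return "\n".join(lines)


def build_contribution_table(
    quantifications: Sequence[Quantification],
    potencies: Sequence[CompoundPotency] | Mapping[str, CompoundPotency],
    beqs: Mapping[Location, float],
) -> ContributionTable:
    """Attribute measured activity to quantified compounds.

    One entry per (compound, location) with a known potency; compounds
    lacking a REP value go to the not-attributable section. A
    quantification at a location without a BEQ_bio value is an error.
    """
    if not isinstance(potencies, Mapping):
        potencies = {p.compound: p for p in potencies}
    entries: list[ContributionEntry] = []
    not_attrib: list[Quantification] = []
    for q in quantifications:
        pot = potencies.get(q.compound)
        if pot is None:
            not_attrib.append(q)
            continue
        if q.location not in beqs:
            raise HtedaError(
                f"no BEQ_bio for location {q.location!r} "
                f"(compound {q.compound})"
            )
        beq_bio = beqs[q.location]
        pct = contribution(q.concentration, pot.rep, beq_bio)
        entries.append(
            ContributionEntry(
                compound=q.compound,
                location=q.location,
                concentration=q.concentration,
                rep=pot.rep,
                beq_contrib=q.concentration * pot.rep,
                percent=pct,
                confidence=q.confidence,
                # relative epsilon guards against flagging float-level
                # overshoot of an exactly-100% contribution
                masking_suspect=pct > MASKING_FLAG_PCT * (1.0 + 1e-9),
            )
        )
    return ContributionTable(
        entries=entries, beq_bio=dict(beqs), not_attributable=not_attrib
    )
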