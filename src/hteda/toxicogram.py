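"""Per-fraction activity profiles and robust active-fraction calling.

A toxicogram is the activity of each collected fraction (percent of the
maximal reference-agonist response) ordered by retention time. Active
fractions are called with the modified z-score

    z_i = (X_i - M) / MAD,      MAD = median(|X_i - M|)

where X_i is the fraction's replicate-mean response and M the median
response over all fractions. The MAD is used raw, without the 1.4826
normal-consistency factor. Fractions with z strictly greater than the
threshold (default 10) are called active; contiguous runs of active
fractions are grouped into retention-time activity peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import DegenerateSpreadWarning, HtedaError
from .plate import FractionScheme

__all__ = [
    "Toxicogram",
    "ActiveFractionCall",
    "ActivityPeak",
    "modified_z_scores",
    "call_active",
    "group_peaks",
]

DEFAULT_Z_THRESHOLD = 10.0


@dataclass(frozen=True)
class ActiveFractionCall:
    """Modified z-score verdict for one fraction (all intermediates kept
    for audit)."""

    fraction_index: int
    response: float  # X_i, replicate-mean percent response
    median: float  # M over all fractions
    mad: float
    z: float
    active: bool


@dataclass(frozen=True)
class ActivityPeak:
    """A maximal run of contiguous active fractions."""

    fractions: tuple[int, ...]
    rt_start_s: float
    rt_end_s: float
    label: str = ""

    @property
    def rt_window(self) -> tuple[float, float]:
        return (self.rt_start_s, self.rt_end_s)


@dataclass
class Toxicogram:
    """Replicate-averaged per-fraction activity aligned to RT.

    ``entries`` has columns fraction_index, well, rt_start_s, rt_end_s,
    mean_response_pct, sd, n_replicates; ordered by fraction index.
    """

    entries: pd.DataFrame
    source: Literal["sample", "blank"] = "sample"
    scheme: Optional[FractionScheme] = field(default=None, repr=False)

    REQUIRED = (
        "fraction_index",
        "well",
        "rt_start_s",
        "rt_end_s",
        "mean_response_pct",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise HtedaError(f"toxicogram missing columns {missing}")
        self.entries = (
            self.entries.sort_values("fraction_index").reset_index(drop=True)
        )
        if not np.all(np.isfinite(self.entries["mean_response_pct"])):
            raise HtedaError("non-finite responses in toxicogram")

    @classmethod
    def from_responses(
        cls,
        responses: Sequence[float],
        scheme: FractionScheme,
        *,
        sd: Optional[Sequence[float]] = None,
        n_replicates: int = 1,
        source: Literal["sample", "blank"] = "sample",
    ) -> "Toxicogram":
        """Build from one mean response per fraction, in fraction order."""
        responses = np.asarray(responses, dtype=float)
        if responses.size != scheme.n_fractions:
            raise HtedaError(
                f"expected {scheme.n_fractions} responses, got {responses.size}"
            )
        rows = []
        for i, x in enumerate(responses, start=1):
            s, e = scheme.fraction_window(i)
            rows.append(
                {
                    "fraction_index": i,
                    "well": str(scheme.fraction_to_well(i)),
                    "rt_start_s": s,
                    "rt_end_s": e,
                    "mean_response_pct": float(x),
                    "sd": float(sd[i - 1]) if sd is not None else np.nan,
                    "n_replicates": n_replicates,
                }
            )
        return cls(pd.DataFrame(rows), source=source, scheme=scheme)

    @property
    def responses(self) -> np.ndarray:
        return self.entries["mean_response_pct"].to_numpy()

    def to_table(self, calls: Optional[list[ActiveFractionCall]] = None) -> pd.DataFrame:
        """Export table; with calls, adds z and active columns."""
        out = self.entries.copy()
        if calls is not None:
            by_idx = {c.fraction_index: c for c in calls}
            out["z"] = [by_idx[i].z for i in out["fraction_index"]]
            out["active"] = [by_idx[i].active for i in out["fraction_index"]]
        return out


def modified_z_scores(
    responses: Sequence[float],
    threshold: float = DEFAULT_Z_THRESHOLD,
    fraction_indices: Optional[Sequence[int]] = None,
) -> list[ActiveFractionCall]:
    """Modified z-scores and active calls for per-fraction responses.

    Degenerate spread (MAD = 0, all fractions identical) yields z = 0
    everywhere and a :class:`DegenerateSpreadWarning` — a flat profile
    carries no evidence of activity, and infinities are avoided.
    """
    x = np.asarray(responses, dtype=float)
    if x.size < 3:
        raise HtedaError(f"need >= 3 fractions, got {x.size}")
    if fraction_indices is None:
        fraction_indices = range(1, x.size + 1)
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        warnings.warn(
            "MAD is zero (all fractions identical): no activity detected",
            DegenerateSpreadWarning,
            stacklevel=2,
        )
        z = np.zeros_like(x)
    else:
        z = (x - med) / mad
    return [
        ActiveFractionCall(
            fraction_index=int(i),
            response=float(xi),
            median=med,
            mad=mad,
            z=float(zi),
            active=bool(zi > threshold),
        )
        for i, xi, zi in zip(fraction_indices, x, z)
    ]


def call_active(
    toxicogram: Toxicogram, threshold: float = DEFAULT_Z_THRESHOLD
) -> list[ActiveFractionCall]:
    """Call active fractions on a toxicogram's replicate-mean responses."""
    if len(toxicogram.entries) == 0:
        raise HtedaError("empty toxicogram")
    return modified_z_scores(
        toxicogram.responses,
        threshold=threshold,
        fraction_indices=toxicogram.entries["fraction_index"].tolist(),
    )


def group_peaks(
    calls: Sequence[ActiveFractionCall],
    scheme: FractionScheme,
    *,
    gap_tolerance: int = 0,
) -> list[ActivityPeak]:
    """Group active fractions into contiguous RT activity peaks.

    ``gap_tolerance`` allows that many consecutive inactive fractions
    inside a peak (default 0: strict contiguity).
    """
    active = sorted(c.fraction_index for c in calls if c.active)
    peaks: list[ActivityPeak] = []
    run: list[int] = []
    for idx in active:
        if run and idx - run[-1] > gap_tolerance + 1:
            peaks.append(_make_peak(run, scheme, len(peaks) + 1))
            run = []
        run.append(idx)
    if run:
        peaks.append(_make_peak(run, scheme, len(peaks) + 1))
    return peaks


def _make_peak(members: list[int], scheme: FractionScheme, number: int) -> ActivityPeak:
    starts_ends = [scheme.fraction_window(i) for i in members]
    return ActivityPeak(
        fractions=tuple(members),
        rt_start_s=min(s for s, _ in starts_ends),
        rt_end_s=max(e for _, e in starts_ends),
        label=f"peak{number}",
    )
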