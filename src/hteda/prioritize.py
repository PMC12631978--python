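"""Feature prioritization from MS2-based activity predictions.

Machine-learning classifiers trained on molecular fingerprints assign
each MS2-bearing feature a hit probability per toxicological endpoint
(e.g. two androgen-receptor reporter-gene endpoints and one nuclear
translocation endpoint). A feature is prioritized when its probability
exceeds the threshold (strictly > 0.5 by default) on at least one of
the selected endpoints. Features without predictions (no MS2 spectrum
acquired) cannot be prioritized and are counted separately, so the
reported workload reduction can be referred to either denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import HtedaError
from .features import (
    DEFAULT_MZ_TOL_PPM,
    DEFAULT_RT_TOL_S,
    FeatureTable,
    _candidate_pairs,
)
from .plate import FractionScheme
from .toxicogram import ActivityPeak

__all__ = [
    "ActivityPredictions",
    "PrioritizedList",
    "call_hits",
    "filter_by_prioritized",
    "reduction_stats",
    "overlap_with_toxicogram",
    "read_predictions",
]

DEFAULT_HIT_THRESHOLD = 0.5


@dataclass
class ActivityPredictions:
    """Per-feature, per-endpoint hit probabilities (long format).

    ``df`` columns: feature_id, endpoint, probability in [0, 1].
    """

    df: pd.DataFrame
    ion_source: str = "ESI_pos"

    def __post_init__(self) -> None:
        missing = [
            c for c in ("feature_id", "endpoint", "probability") if c not in self.df.columns
        ]
        if missing:
            raise HtedaError(f"predictions missing columns {missing}")
        p = self.df["probability"]
        if ((p < 0) | (p > 1)).any():
            raise HtedaError("hit probabilities must lie in [0, 1]")
        self.df = self.df.assign(feature_id=self.df["feature_id"].astype(str))

    @property
    def endpoints(self) -> list[str]:
        return sorted(self.df["endpoint"].unique())

    def scores_for(self, endpoints: Sequence[str]) -> pd.Series:
        """Max probability over the selected endpoints, per feature id."""
        unknown = set(endpoints) - set(self.endpoints)
        if unknown:
            raise HtedaError(
                f"unknown endpoints {sorted(unknown)}; available: {self.endpoints}"
            )
        sub = self.df[self.df["endpoint"].isin(endpoints)]
        return sub.groupby("feature_id")["probability"].max()


def read_predictions(path, ion_source: str = "ESI_pos") -> ActivityPredictions:
    df = pd.read_csv(path, sep=None, engine="python")
    return ActivityPredictions(df, ion_source=ion_source)


@dataclass
class PrioritizedList:
    """Prioritized features with the funnel counts around them."""

    features: FeatureTable  # subset of the source table
    endpoints: tuple[str, ...]
    threshold: float
    n_total: int
    n_with_ms2: int
    n_predicted: int

    @property
    def ids(self) -> list[str]:
        return self.features.df["id"].astype(str).tolist()

    @property
    def n_prioritized(self) -> int:
        return len(self.features)

    def report(self) -> pd.DataFrame:
        """Funnel report: counts at each stage with both denominators."""
        rows = [
            ("total_features", self.n_total),
            ("with_ms2", self.n_with_ms2),
            ("with_predictions", self.n_predicted),
            ("prioritized", self.n_prioritized),
        ]
        df = pd.DataFrame(rows, columns=["stage", "count"])
        df["pct_of_total"] = 100.0 * df["count"] / max(self.n_total, 1)
        df["pct_of_ms2"] = 100.0 * df["count"] / max(self.n_with_ms2, 1)
        return df


def call_hits(
    predictions: ActivityPredictions,
    features: FeatureTable,
    endpoints: Sequence[str],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    *,
    allow_negative_mode: bool = False,
) -> PrioritizedList:
    """Prioritize features scoring above threshold on >= 1 endpoint.

    The comparison is strict (probability > threshold). Negative-mode
    tables are refused unless ``allow_negative_mode`` is set, because
    fingerprint-based activity prediction is unreliable there.
    """
    if not endpoints:
        raise HtedaError("at least one endpoint required")
    if not 0 < threshold < 1:
        raise HtedaError(f"threshold must be in (0, 1), got {threshold}")
    src = features.single_source() if len(features) else ""
    if src.endswith("_neg") and not allow_negative_mode:
        raise HtedaError(
            "negative-mode predictions are refused by default (poor model "
            "performance); pass allow_negative_mode=True to override"
        )
    best = predictions.scores_for(endpoints)
    ids = features.df["id"].astype(str)
    score = ids.map(best)  # NaN for features lacking predictions
    hit = (score > threshold).fillna(False).to_numpy(dtype=bool)
    return PrioritizedList(
        features=features.subset(hit),
        endpoints=tuple(endpoints),
        threshold=threshold,
        n_total=len(features),
        n_with_ms2=int(features.df["has_ms2"].sum()),
        n_predicted=int(score.notna().sum()),
    )


def filter_by_prioritized(
    table: FeatureTable,
    prioritized: PrioritizedList,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol_s: float = DEFAULT_RT_TOL_S,
) -> FeatureTable:
    """Keep features of ``table`` matching any prioritized feature within
    the m/z (ppm) and RT tolerances."""
    if prioritized.n_prioritized == 0:
        return table.subset(np.zeros(len(table), dtype=bool))
    ii, _, _ = _candidate_pairs(
        table.df["mz"].to_numpy(float),
        table.df["rt_s"].to_numpy(float),
        prioritized.features.df["mz"].to_numpy(float),
        prioritized.features.df["rt_s"].to_numpy(float),
        mz_tol_ppm,
        rt_tol_s,
    )
    keep = np.zeros(len(table), dtype=bool)
    keep[np.unique(ii)] = True
    return table.subset(keep)


def reduction_stats(n_total: int, n_prioritized: int) -> tuple[float, float]:
    """Percent of features retained after prioritization, and the
    complementary percent reduction in elucidation workload.

    Returns full-precision values; round to one decimal for reporting
    (e.g. 83/5243 -> 1.6% retained, 98.4% reduction).
    """
    if n_total <= 0:
        raise HtedaError("n_total must be positive")
    if not 0 <= n_prioritized <= n_total:
        raise HtedaError(
            f"n_prioritized must be in [0, {n_total}], got {n_prioritized}"
        )
    retained = 100.0 * n_prioritized / n_total
    return retained, 100.0 - retained


@dataclass(frozen=True)
class PeakOverlap:
    peak_label: str
    rt_window: tuple[float, float]
    feature_ids: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.feature_ids)


def overlap_with_toxicogram(
    prioritized: PrioritizedList,
    peaks: Sequence[ActivityPeak],
    scheme: Optional[FractionScheme] = None,
) -> tuple[list[PeakOverlap], PeakOverlap]:
    """Count prioritized features inside each activity peak's RT window.

    Returns (per-peak overlaps, outside-all-peaks remainder). Windows
    are half-open like fraction windows.
    """
    df = prioritized.features.df
    assigned = np.zeros(len(df), dtype=bool)
    per_peak: list[PeakOverlap] = []
    for pk in peaks:
        lo, hi = pk.rt_window
        inside = (df["rt_s"].to_numpy(float) >= lo) & (df["rt_s"].to_numpy(float) < hi)
        per_peak.append(
            PeakOverlap(
                peak_label=pk.label or f"{lo:g}-{hi:g}s",
                rt_window=(lo, hi),
                feature_ids=tuple(df.loc[inside, "id"].astype(str)),
            )
        )
        assigned |= inside
    outside = PeakOverlap(
        peak_label="outside_peaks",
        rt_window=(float("nan"), float("nan")),
        feature_ids=tuple(df.loc[~assigned, "id"].astype(str)),
    )
    return per_peak, outside
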