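"""Non-target LC-HRMS feature tables: blank subtraction, RT-window
filtering, fraction assignment and tolerance-based matching.

Features are (m/z, retention time, intensity) records exported from
peak-picking software, one table per ionization source (ESI+, APCI+,
ESI-). Two features match when their m/z difference is within a ppm
tolerance (computed relative to the first feature's m/z) *and* their
retention times are within a seconds tolerance; the defaults (5 ppm,
30 s) are the tolerances commonly used for cross-list alignment.

Blank subtraction keeps a sample feature if it has no match in the
procedural blank, or its intensity exceeds ``ratio`` times the matched
blank intensity (default 3.0, i.e. the ">300% of procedural blanks"
rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from ._errors import HtedaError
from .plate import FractionScheme

__all__ = [
    "Feature",
    "FeatureTable",
    "DEFAULT_MZ_TOL_PPM",
    "DEFAULT_RT_TOL_S",
    "match_features",
    "blank_subtract",
    "filter_rt_window",
    "assign_fractions",
    "count_shared",
    "read_feature_table",
]

DEFAULT_MZ_TOL_PPM = 5.0
DEFAULT_RT_TOL_S = 30.0

IonSource = Literal["ESI_pos", "APCI_pos", "ESI_neg"]

COLUMNS = ("id", "mz", "rt_s", "intensity", "ion_source", "has_ms2")


@dataclass(frozen=True)
class Feature:
    """One detected LC-HRMS feature."""

    id: str
    mz: float
    rt_s: float
    intensity: float
    ion_source: str = "ESI_pos"
    has_ms2: bool = False
    annotation: Optional[dict] = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rt_s < 0 or self.intensity < 0:
            raise HtedaError(
                f"invalid feature {self.id}: mz={self.mz}, rt={self.rt_s}, "
                f"intensity={self.intensity}"
            )


@dataclass
class FeatureTable:
    """A feature list from one ionization source, pandas-backed.

    ``df`` columns: id, mz, rt_s, intensity, ion_source, has_ms2
    (extra columns pass through untouched).
    """

    df: pd.DataFrame
    provenance: Literal["sample", "blank"] = "sample"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise HtedaError(f"feature table missing columns {missing}")
        if self.df["id"].duplicated().any():
            dupes = self.df.loc[self.df["id"].duplicated(), "id"].tolist()[:5]
            raise HtedaError(f"duplicate feature ids: {dupes} ...")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ion_sources(self) -> set[str]:
        return set(self.df["ion_source"].unique())

    def single_source(self) -> str:
        srcs = self.ion_sources
        if len(srcs) != 1:
            raise HtedaError(f"expected a single ion source, got {sorted(srcs)}")
        return next(iter(srcs))

    @classmethod
    def from_features(
        cls, features: Sequence[Feature], provenance: str = "sample"
    ) -> "FeatureTable":
        df = pd.DataFrame(
            [
                {
                    "id": f.id,
                    "mz": f.mz,
                    "rt_s": f.rt_s,
                    "intensity": f.intensity,
                    "ion_source": f.ion_source,
                    "has_ms2": f.has_ms2,
                }
                for f in features
            ],
            columns=list(COLUMNS),
        )
        return cls(df, provenance=provenance)

    def subset(self, mask) -> "FeatureTable":
        return replace(self, df=self.df.loc[mask].reset_index(drop=True))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def read_feature_table(
    path, provenance: str = "sample", column_map: Optional[dict] = None
) -> FeatureTable:
    """Read a delimiter-separated feature table.

    ``column_map`` renames exporter-specific headers onto the canonical
    id/mz/rt_s/intensity/ion_source/has_ms2 names. A column named
    ``rt_min`` (minutes) is converted to ``rt_s``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=column_map)
    if "rt_min" in df.columns and "rt_s" not in df.columns:
        df["rt_s"] = df.pop("rt_min") * 60.0
    if "has_ms2" in df.columns:
        df["has_ms2"] = df["has_ms2"].astype(bool)
    df["id"] = df["id"].astype(str)
    return FeatureTable(df, provenance=provenance)


def match_features(
    a: Feature,
    b: Feature,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol_s: float = DEFAULT_RT_TOL_S,
) -> bool:
    """True iff the m/z difference (ppm, relative to ``a.mz``) and the RT
    difference are both within tolerance."""
    ppm = abs(a.mz - b.mz) / a.mz * 1e6
    return ppm <= mz_tol_ppm and abs(a.rt_s - b.rt_s) <= rt_tol_s


def _candidate_pairs(
    mz_a: np.ndarray,
    rt_a: np.ndarray,
    mz_b: np.ndarray,
    rt_b: np.ndarray,
    mz_tol_ppm: float,
    rt_tol_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All (i, j, |dmz|) index pairs within tolerance; ppm relative to a."""
    order = np.argsort(mz_b, kind="stable")
    mzb_sorted = mz_b[order]
    ii, jj = [], []
    for i, (m, t) in enumerate(zip(mz_a, rt_a)):
        tol = m * mz_tol_ppm * 1e-6
        lo = np.searchsorted(mzb_sorted, m - tol, side="left")
        hi = np.searchsorted(mzb_sorted, m + tol, side="right")
        for j in order[lo:hi]:
            if abs(t - rt_b[j]) <= rt_tol_s:
                ii.append(i)
                jj.append(j)
    ii = np.asarray(ii, dtype=int)
    jj = np.asarray(jj, dtype=int)
    dmz = np.abs(mz_a[ii] - mz_b[jj]) if ii.size else np.empty(0)
    return ii, jj, dmz


def blank_subtract(
    sample: FeatureTable,
    blank: FeatureTable,
    ratio: float = 3.0,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol_s: float = DEFAULT_RT_TOL_S,
) -> FeatureTable:
    """Remove features not sufficiently above the procedural blank.

    A sample feature is kept iff it has no blank match within tolerance,
    or its intensity is strictly greater than ``ratio`` times the
    intensity of its matched blank feature. When several blank features
    match, the highest-intensity one is used (conservative).
    """
    if sample.single_source() != blank.single_source():
        raise HtedaError(
            f"ion source mismatch: sample {sample.single_source()} vs "
            f"blank {blank.single_source()}"
        )
    if len(blank) == 0:
        return sample.subset(np.ones(len(sample), dtype=bool))
    mz_s = sample.df["mz"].to_numpy(float)
    rt_s = sample.df["rt_s"].to_numpy(float)
    mz_b = blank.df["mz"].to_numpy(float)
    rt_b = blank.df["rt_s"].to_numpy(float)
    int_b = blank.df["intensity"].to_numpy(float)
    ii, jj, _ = _candidate_pairs(mz_s, rt_s, mz_b, rt_b, mz_tol_ppm, rt_tol_s)
    best_blank = np.zeros(len(sample))
    has_match = np.zeros(len(sample), dtype=bool)
    for i, j in zip(ii, jj):
        has_match[i] = True
        best_blank[i] = max(best_blank[i], int_b[j])
    keep = (~has_match) | (
        sample.df["intensity"].to_numpy(float) > ratio * best_blank
    )
    return sample.subset(keep)


def filter_rt_window(
    table: FeatureTable, window: tuple[float, float]
) -> FeatureTable:
    """Keep features with RT in the half-open window [start, end), seconds."""
    lo, hi = window
    if not hi > lo:
        raise HtedaError(f"empty RT window [{lo}, {hi})")
    rt = table.df["rt_s"].to_numpy(float)
    return table.subset((rt >= lo) & (rt < hi))


def assign_fractions(
    table: FeatureTable, scheme: FractionScheme
) -> dict[str, Optional[int]]:
    """Map each feature id to the fraction collecting at its RT (None
    outside the collection window)."""
    return {
        str(fid): scheme.rt_to_fraction(rt)
        for fid, rt in zip(table.df["id"], table.df["rt_s"])
    }


def count_shared(
    a: FeatureTable,
    b: FeatureTable,
    mz_tol_ppm: float = DEFAULT_MZ_TOL_PPM,
    rt_tol_s: float = DEFAULT_RT_TOL_S,
) -> int:
    """Number of features shared between two lists.

    Candidate pairs within tolerance are matched greedily one-to-one by
    ascending m/z difference, so one feature never counts twice.
    """
    ii, jj, dmz = _candidate_pairs(
        a.df["mz"].to_numpy(float),
        a.df["rt_s"].to_numpy(float),
        b.df["mz"].to_numpy(float),
        b.df["rt_s"].to_numpy(float),
        mz_tol_ppm,
        rt_tol_s,
    )
    used_a: set[int] = set()
    used_b: set[int] = set()
    n = 0
    for k in np.argsort(dmz, kind="stable"):
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n += 1
    return n
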