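"""End-to-end orchestration of the HT-EDA screening workflow.

``run_pipeline`` executes the stages in order — plate geometry,
bioassay normalization and reference fit, toxicogram and active-fraction
calling, feature-table blank subtraction and RT-window filtering,
MS2-prediction-based prioritization, target/semiquant quantification,
per-location BEQ derivation and iceberg contribution accounting —
reading the interchange files of a bundle directory and writing every
intermediate plus a plain-text summary to the output directory.

All thresholds live in :class:`PipelineConfig` and are logged into the
report, so a run doubles as an audit trail of the parameters applied.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._errors import FitFailureError, HtedaError, StageError
from . import doseresponse as dr
from . import features as ft
from . import iceberg as ib
from . import prioritize as pr
from . import quantify as qt
from . import toxicogram as tg
from .plate import FractionScheme
from .simulate import ENDPOINTS

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run."""

    input_dir: str
    output_dir: str
    interval_s: float = 18.0
    n_fractions: int = 80
    z_threshold: float = 10.0
    blank_ratio: float = 3.0
    hit_threshold: float = 0.5
    mz_tol_ppm: float = 5.0
    rt_tol_s: float = 30.0
    ec_level: float = 10.0
    endpoints: tuple[str, ...] = ENDPOINTS
    sources: tuple[str, ...] = ("ESI_pos", "APCI_pos")
    is_area_ref: float = 1.0e5
    # 1/x weighting keeps the low end of a multi-decade calibration
    # accurate; set to "none" for an unweighted fit
    calibration_weighting: str = "1/x"
    seed: int = 0

    def validate(self) -> None:
        for name in ("z_threshold", "blank_ratio", "mz_tol_ppm", "rt_tol_s",
                     "ec_level", "hit_threshold", "interval_s"):
            if getattr(self, name) <= 0:
                raise HtedaError(f"{name} must be positive")
        if not Path(self.input_dir).is_dir():
            raise HtedaError(f"input directory not found: {self.input_dir}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise HtedaError(f"unknown config keys: {sorted(unknown)}")
        for tup in ("endpoints", "sources"):
            if tup in data and isinstance(data[tup], list):
                data[tup] = tuple(data[tup])
        return cls(**data)


@dataclass
class RunReport:
    """Stage-by-stage results of one pipeline run."""

    config: PipelineConfig
    scheme: FractionScheme
    toxicogram: tg.Toxicogram
    calls: list
    blank_calls: list
    peaks: list
    funnel: dict  # source -> {stage: count}
    prioritized: dict  # source -> PrioritizedList
    reduction: dict  # source -> (retained_pct, reduction_pct)
    shared_prioritized: Optional[int]
    reference_fit: dr.DoseResponseResults
    ec10_ref: float  # ng/L
    beq_by_location: dict  # location -> ug reference-equivalents / L
    censored_locations: list
    quantifications: list
    contribution: ib.ContributionTable
    warnings_log: list = field(default_factory=list)

    @property
    def active_fractions(self) -> list[int]:
        return sorted(c.fraction_index for c in self.calls if c.active)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "HT-EDA pipeline report",
            "======================",
            f"thresholds: z>{cfg.z_threshold:g}, blank ratio {cfg.blank_ratio:g}, "
            f"hit prob >{cfg.hit_threshold:g}, {cfg.mz_tol_ppm:g} ppm / "
            f"{cfg.rt_tol_s:g} s, EC level {cfg.ec_level:g}%",
            f"fractions: {self.scheme.n_fractions} x {self.scheme.interval_s:g} s",
            f"active fractions ({len(self.active_fractions)}): "
            f"{self.active_fractions}",
            "peaks: "
            + "; ".join(
                f"{p.label} {p.rt_start_s / 60:.1f}-{p.rt_end_s / 60:.1f} min "
                f"(fractions {p.fractions[0]}-{p.fractions[-1]})"
                for p in self.peaks
            ),
            f"reference EC10: {self.ec10_ref:.4g} ng/L",
        ]
        for src in sorted(self.funnel):
            f = self.funnel[src]
            ret, red = self.reduction[src]
            lines.append(
                f"{src}: total {f['total']} -> blank-passed {f['blank_passed']}"
                f" -> RT-window {f['rt_window']} -> prioritized "
                f"{f['prioritized']} ({ret:.1f}% retained, {red:.1f}% reduction)"
            )
        if self.shared_prioritized is not None:
            lines.append(f"prioritized features shared: {self.shared_prioritized}")
        lines.append(self.contribution.summary())
        if self.censored_locations:
            lines.append(
                f"EC{cfg.ec_level:g} right-censored (no BEQ): "
                f"{self.censored_locations}"
            )
        if self.warnings_log:
            lines.append("warnings: " + "; ".join(self.warnings_log))
        return "\n".join(lines)


def _parse_location(s: str):
    return s if s == "unfractionated_extract" else int(s)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on a bundle directory; see module docstring."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    wlog: list[str] = []

    def _read(name: str) -> pd.DataFrame:
        p = indir / name
        if not p.exists():
            raise FileNotFoundError(p)
        try:
            return pd.read_csv(p, sep=None, engine="python")
        except Exception:
            # delimiter sniffing fails on header-only files
            return pd.read_csv(p)

    scheme = FractionScheme(
        interval_s=config.interval_s, n_fractions=config.n_fractions
    )

    # ---- bioassay: normalization anchors and reference curve ----------
    stage = "bioassay"
    try:
        ref = _read("reference_series.csv")
        solvent = _read("solvent_controls.csv")
        background = float(solvent["value"].mean())
        top_dose = ref["dose_ng_per_L"].max()
        ref_max = float(ref.loc[ref["dose_ng_per_L"] == top_dose, "value"].mean())
        ref_mean = ref.groupby("dose_ng_per_L")["value"].mean().reset_index()
        ref_resp = dr.normalize_to_reference(
            ref_mean["value"].to_numpy(), ref_max, background
        )
        reference_fit = dr.fit_sigmoid(
            ref_mean["dose_ng_per_L"].to_numpy(),
            ref_resp,
            dose_unit="ng_per_L",
        )
        ec10_ref = reference_fit.ec(config.ec_level)
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "calibration", str(exc)) from exc

    # ---- toxicogram ---------------------------------------------------
    stage = "toxicogram"
    try:
        def _toxicogram(frame: pd.DataFrame, source: str) -> tg.Toxicogram:
            g = frame.groupby("fraction_index")["value"]
            means = g.mean().sort_index()
            sds = g.std().sort_index()
            resp = dr.normalize_to_reference(
                means.to_numpy(), ref_max, background
            )
            sd_pct = sds.to_numpy() / (ref_max - background) * 100.0
            return tg.Toxicogram.from_responses(
                resp, scheme, sd=sd_pct, n_replicates=int(
                    frame.groupby("fraction_index")["replicate"].nunique().max()
                ), source=source,
            )

        tox = _toxicogram(_read("screen_sample.csv"), "sample")
        tox_blank = _toxicogram(_read("screen_blank.csv"), "blank")
        calls = tg.call_active(tox, threshold=config.z_threshold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blank_calls = tg.call_active(tox_blank, threshold=config.z_threshold)
        peaks = tg.group_peaks(calls, scheme)
        tox.to_table(calls).to_csv(outdir / "toxicogram.tsv", sep="\t", index=False)
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "toxicogram", str(exc)) from exc

    # ---- feature tables -----------------------------------------------
    stage = "features"
    funnel: dict[str, dict] = {}
    windowed: dict[str, ft.FeatureTable] = {}
    try:
        for src in config.sources:
            sample = ft.read_feature_table(
                indir / f"features_sample_{src}.tsv", provenance="sample"
            )
            blank = ft.read_feature_table(
                indir / f"features_blank_{src}.tsv", provenance="blank"
            )
            passed = ft.blank_subtract(
                sample,
                blank,
                ratio=config.blank_ratio,
                mz_tol_ppm=config.mz_tol_ppm,
                rt_tol_s=config.rt_tol_s,
            )
            if peaks:
                masks = []
                rt = passed.df["rt_s"].to_numpy(float)
                for p in peaks:
                    masks.append((rt >= p.rt_start_s) & (rt < p.rt_end_s))
                in_window = passed.subset(np.logical_or.reduce(masks))
            else:
                in_window = passed.subset(np.zeros(len(passed), dtype=bool))
            funnel[src] = {
                "total": len(sample),
                "blank_passed": len(passed),
                "rt_window": len(in_window),
            }
            windowed[src] = in_window
            in_window.write(outdir / f"features_window_{src}.tsv")
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "features", str(exc)) from exc

    # ---- prioritization -----------------------------------------------
    stage = "prioritization"
    prioritized: dict[str, pr.PrioritizedList] = {}
    reduction: dict[str, tuple[float, float]] = {}
    try:
        for src in config.sources:
            preds = pr.read_predictions(
                indir / f"predictions_{src}.csv", ion_source=src
            )
            pl = pr.call_hits(
                preds,
                windowed[src],
                endpoints=config.endpoints,
                threshold=config.hit_threshold,
            )
            prioritized[src] = pl
            reduction[src] = (
                pr.reduction_stats(pl.n_total, pl.n_prioritized)
                if pl.n_total > 0
                else (float("nan"), float("nan"))
            )
            funnel[src]["prioritized"] = pl.n_prioritized
            pl.features.write(outdir / f"prioritized_{src}.tsv")
        shared = (
            ft.count_shared(
                prioritized[config.sources[0]].features,
                prioritized[config.sources[1]].features,
                mz_tol_ppm=config.mz_tol_ppm,
                rt_tol_s=config.rt_tol_s,
            )
            if len(config.sources) >= 2
            else None
        )
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "prioritization", str(exc)) from exc

    # ---- quantification -----------------------------------------------
    stage = "quantify"
    try:
        cal = _read("calibration.csv")
        curves = {}
        for comp, grp in cal.groupby("compound"):
            pts = grp.assign(
                area=[
                    qt.is_correct(a, i, config.is_area_ref)
                    for a, i in zip(grp["area"], grp["is_area"])
                ]
            )[["nominal_ug_per_L", "area"]]
            curves[comp] = qt.CalibrationCurve(
                compound=str(comp), points=pts,
                weighting=config.calibration_weighting,
            )
        sq_model = qt.fit_semiquant_model(_read("semiquant_calibrants.csv"))
        measured = _read("measured_areas.csv")
        quants: list[qt.Quantification] = []
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            for _, r in measured.iterrows():
                loc = _parse_location(str(r["location"]))
                corrected = qt.is_correct(
                    r["area"], r["is_area"], config.is_area_ref
                )
                if r["method"] == "target":
                    if r["compound"] not in curves:
                        raise HtedaError(
                            f"no calibration curve for target {r['compound']}"
                        )
                    q = qt.quantify_target(
                        corrected, curves[r["compound"]], location=loc
                    )
                else:
                    q = qt.semiquantify(
                        corrected,
                        float(r["logIE"]),
                        sq_model,
                        compound=str(r["compound"]),
                        location=loc,
                    )
                quants.append(q)
        wlog += [str(w.message) for w in wrec]
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "quantify", str(exc)) from exc

    # ---- per-location BEQ ---------------------------------------------
    stage = "beq"
    beqs: dict = {}
    censored: list = []
    try:
        dil = _read("dilution_series.csv")
        for loc_str, grp in dil.groupby("location"):
            loc = _parse_location(str(loc_str))
            mean = grp.groupby("ref")["value"].mean().reset_index()
            resp = dr.normalize_to_reference(
                mean["value"].to_numpy(), ref_max, background
            )
            try:
                fit = dr.fit_sigmoid(mean["ref"].to_numpy(), resp)
            except FitFailureError as exc:
                censored.append(loc)
                wlog.append(f"{loc}: dose-response fit failed ({exc})")
                continue
            est = fit.ec_estimate(config.ec_level)
            if est.censored:
                censored.append(loc)
                continue
            # ng reference-equivalents / L -> ug/L
            beqs[loc] = dr.beq_from_ec(
                ec10_ref, est.value, ec_level=config.ec_level
            ).beq / 1000.0
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "beq", str(exc)) from exc

    # ---- iceberg contribution -----------------------------------------
    stage = "iceberg"
    try:
        pot_df = _read("potencies.csv")
        potencies = [
            ib.CompoundPotency(
                compound=str(r["compound"]),
                rep=float(r["rep"]),
                source=str(r.get("source", "literature")),
            )
            for _, r in pot_df.iterrows()
        ]
        attributable = [q for q in quants if q.location in beqs]
        skipped = [q for q in quants if q.location not in beqs]
        if skipped:
            wlog.append(
                f"{len(skipped)} quantifications at locations without BEQ "
                "excluded from contribution accounting"
            )
        contrib = ib.build_contribution_table(attributable, potencies, beqs)
        contrib.to_frame().to_csv(outdir / "contributions.csv", index=False)
    except (HtedaError, FileNotFoundError) as exc:
        raise StageError(stage, "iceberg", str(exc)) from exc

    report = RunReport(
        config=config,
        scheme=scheme,
        toxicogram=tox,
        calls=calls,
        blank_calls=blank_calls,
        peaks=peaks,
        funnel=funnel,
        prioritized=prioritized,
        reduction=reduction,
        shared_prioritized=shared,
        reference_fit=reference_fit,
        ec10_ref=float(ec10_ref),
        beq_by_location=beqs,
        censored_locations=censored,
        quantifications=quants,
        contribution=contrib,
        warnings_log=wlog,
    )
    (outdir / "report.txt").write_text(report.summary() + "\n")
    (outdir / "report.json").write_text(
        json.dumps(
            {
                "active_fractions": report.active_fractions,
                "funnel": funnel,
                "reduction": {k: list(v) for k, v in reduction.items()},
                "shared_prioritized": shared,
                "ec10_ref_ng_per_L": float(ec10_ref),
                "beq_ug_per_L": {str(k): v for k, v in beqs.items()},
                "explained_pct": {
                    str(loc): contrib.explained(loc) for loc in contrib.locations
                },
                "censored_locations": [str(c) for c in censored],
            },
            indent=1,
        )
    )
    pd.DataFrame(
        [
            {
                "compound": q.compound,
                "location": str(q.location),
                "concentration_ug_per_L": q.concentration,
                "confidence": q.confidence,
                "censor": q.censor,
            }
            for q in quants
        ]
    ).to_csv(outdir / "quantifications.csv", index=False)
    return report
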