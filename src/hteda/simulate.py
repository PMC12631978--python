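"""End-to-end synthetic HT-EDA scenarios with known ground truth.

The generator emulates the data streams of a microplate-format
effect-directed analysis of a wastewater extract: a few active steroids
eluting among thousands of inactive background features, procedural
blank contamination, per-fraction bioassay luminescence driven by the
summed potency of whatever elutes into each well (pushed through the
reference agonist's sigmoidal dose-response with noise), MS2-based
activity predictions with configurable sensitivity and false-positive
rate, calibration series for target compounds, and an
ionization-efficiency calibrant set for semiquantification.

Every stream is deterministic given the scenario seed, and the bundle
carries the ground truth (which features are active, per-fraction true
BEQ, true concentrations) so each pipeline stage can be scored against
what was spiked in.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._errors import HtedaError
from .features import FeatureTable
from .plate import FractionScheme
from .prioritize import ActivityPredictions

__all__ = [
    "ActiveCompound",
    "AntagonistSpec",
    "ScenarioConfig",
    "GroundTruth",
    "ScenarioBundle",
    "generate_scenario",
    "RecoveryReport",
    "true_driver_recovery",
]

ENDPOINTS = ("AR_reporter_luc", "AR_reporter_bla", "AR_nuclear_translocation")


@dataclass(frozen=True)
class ActiveCompound:
    """A spiked bioactive compound with its chromatographic, potency and
    detection parameters."""

    name: str
    mz: float
    rt_center_s: float
    rt_sd_s: float
    concentration_ug_per_L: float
    rep: float  # relative potency vs the reference agonist
    response_factor: float  # area units per ug/L
    is_target: bool = True  # reference standard available
    sources: tuple[str, ...] = ("ESI_pos", "APCI_pos")

    @property
    def dht_eq_ng_per_L(self) -> float:
        """Total reference-equivalent potency in original-water terms."""
        return self.concentration_ug_per_L * 1000.0 * self.rep


@dataclass(frozen=True)
class AntagonistSpec:
    """A co-eluting antagonist: subtracts reference-equivalent potency
    from its fraction and from the whole extract before the sigmoid."""

    fraction_index: int = 60
    potency_ng_per_L: float = 4.0


def _default_actives() -> tuple[ActiveCompound, ...]:
    # Two RT activity peaks: a broad conjugated-metabolite peak
    # (fractions 49-54) and a sharper parent-hormone peak (58-61) with
    # two co-eluting compounds, echoing the two-peak structure seen in
    # hospital-effluent screens.
    return (
        ActiveCompound(
            name="metabolite_conjugate_M1",
            mz=467.2645,
            rt_center_s=936.0,
            rt_sd_s=27.0,
            concentration_ug_per_L=5.37,
            rep=5.0e-3,
            response_factor=2.0e4,
            is_target=False,  # semiquantified via predicted logIE
        ),
        ActiveCompound(
            name="testosterone_like_T",
            mz=289.2162,
            rt_center_s=1062.0,
            rt_sd_s=18.0,
            concentration_ug_per_L=2.0,
            rep=5.0e-3,
            response_factor=5.0e5,
        ),
        ActiveCompound(
            name="androsterone_like_A",
            mz=291.2319,
            rt_center_s=1062.0,
            rt_sd_s=18.0,
            concentration_ug_per_L=20.0,
            rep=5.0e-4,
            response_factor=3.0e5,
        ),
    )


@dataclass
class ScenarioConfig:
    """All knobs of a synthetic scenario; the seed fixes every stream."""

    seed: int = 0
    # fractionation: 18 s fractions, 80 wells of a 96-well plate
    interval_s: float = 18.0
    n_fractions: int = 80
    # feature population per ionization source
    n_background: dict = field(
        default_factory=lambda: {"ESI_pos": 5000, "APCI_pos": 1500}
    )
    ms2_prob: float = 0.575  # share of background features with MS2
    mz_range: tuple[float, float] = (80.0, 1200.0)  # scan range
    actives: tuple[ActiveCompound, ...] = field(default_factory=_default_actives)
    # reference dose-response (reference agonist, ng/L)
    ec50_ref_ng_per_L: float = 43.5  # EC10 = 43.5/9**(1/2) = 14.5 ng/L
    hill: float = 2.0
    # plate reader scale
    ref_max_lum: float = 50000.0
    solvent_background_lum: float = 2000.0
    n_replicates: int = 3
    # fraction screen enrichment and dilution series
    screen_ref: float = 10.0
    reference_doses_ng_per_L: tuple[float, ...] = tuple(
        np.geomspace(1.0, 1000.0, 10)
    )
    fraction_series_refs: tuple[float, ...] = tuple(np.geomspace(0.25, 16.0, 10))
    extract_series_refs: tuple[float, ...] = tuple(np.geomspace(0.02, 16.0, 12))
    # noise levels
    luminescence_cv: float = 0.05  # multiplicative, per replicate
    baseline_noise_pct: float = 0.5  # additive sd, percent-response units
    feature_intensity_cv: float = 0.2
    area_cv: float = 0.03
    is_area_cv: float = 0.02
    logrf_residual_sd: float = 0.15
    # MS2-based activity prediction quality
    sensitivity: float = 1.0
    false_positive_rate: float = 0.02
    endpoints: tuple[str, ...] = ENDPOINTS
    # procedural blank
    blank_contamination_rate: float = 0.15
    n_blank_only: int = 200
    # semiquant calibrants and the true logIE->logRF line
    n_semiquant_calibrants: int = 8
    semiquant_slope: float = 0.8
    semiquant_intercept: float = 0.5
    # target calibration series (ug/L)
    calibration_points: tuple[float, ...] = tuple(np.geomspace(0.1, 750.0, 12))
    is_area_ref: float = 1.0e5
    # ground-truth activity floor: a fraction is truly active when its
    # noiseless screen response reaches this percent
    activity_floor_pct: float = 5.0
    antagonist: Optional[AntagonistSpec] = None

    def validate(self) -> None:
        if self.seed < 0:
            raise HtedaError("seed must be non-negative")
        if any(n < 0 for n in self.n_background.values()):
            raise HtedaError("background feature counts must be >= 0")
        for p in (self.ms2_prob, self.sensitivity, self.false_positive_rate):
            if not 0.0 <= p <= 1.0:
                raise HtedaError(f"probability {p} outside [0, 1]")
        if self.ec50_ref_ng_per_L <= 0 or self.hill <= 0:
            raise HtedaError("reference EC50 and hill must be positive")
        if self.ref_max_lum <= self.solvent_background_lum:
            raise HtedaError("ref_max_lum must exceed solvent background")
        for c in self.actives:
            if c.concentration_ug_per_L < 0 or c.rep <= 0 or c.rt_sd_s <= 0:
                raise HtedaError(f"invalid active compound spec {c.name}")

    def noiseless(self) -> "ScenarioConfig":
        """Copy with every noise source and the prediction FPR zeroed."""
        return dataclasses.replace(
            self,
            luminescence_cv=0.0,
            baseline_noise_pct=0.0,
            feature_intensity_cv=0.0,
            area_cv=0.0,
            is_area_cv=0.0,
            logrf_residual_sd=0.0,
            false_positive_rate=0.0,
        )

    @property
    def scheme(self) -> FractionScheme:
        return FractionScheme(interval_s=self.interval_s, n_fractions=self.n_fractions)

    @property
    def ec10_ref_ng_per_L(self) -> float:
        return self.ec50_ref_ng_per_L * (1.0 / 9.0) ** (1.0 / self.hill)


@dataclass
class GroundTruth:
    """What was actually spiked: the answer key for the pipeline."""

    active_feature_ids: dict  # source -> {compound name -> feature id}
    true_active_fractions: tuple[int, ...]
    beq_chem_per_fraction: dict  # fraction -> ng/L (sum conc*REP*elution mass)
    beq_bio_per_fraction: dict  # after antagonist suppression
    beq_chem_unfractionated: float
    beq_bio_unfractionated: float
    concentrations_ug_per_L: dict  # compound -> total concentration
    reps: dict  # compound -> REP
    response_factors: dict
    elution_weights: dict  # compound -> {fraction -> mass share}


@dataclass
class ScenarioBundle:
    """Every input stream the pipeline consumes, plus the ground truth."""

    config: ScenarioConfig
    scheme: FractionScheme
    sample_features: dict  # source -> FeatureTable
    blank_features: dict  # source -> FeatureTable
    predictions: dict  # source -> ActivityPredictions
    screen_sample: pd.DataFrame  # fraction_index, well, replicate, value
    screen_blank: pd.DataFrame
    reference_series: pd.DataFrame  # dose_ng_per_L, replicate, value
    solvent_controls: pd.DataFrame  # replicate, value
    dilution_series: pd.DataFrame  # location, ref, replicate, value
    calibration: pd.DataFrame  # compound, nominal_ug_per_L, area, is_area
    semiquant_calibrants: pd.DataFrame  # compound, logIE, logRF
    measured_areas: pd.DataFrame  # compound, location, area, is_area, method, logIE
    potencies: pd.DataFrame  # compound, rep, source
    truth: GroundTruth

    def write(self, outdir) -> Path:
        """Write every component in the interchange formats plus a
        manifest and ground-truth file."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        for src, tbl in self.sample_features.items():
            p = out / f"features_sample_{src}.tsv"
            tbl.write(p)
            files[f"features_sample_{src}"] = p.name
        for src, tbl in self.blank_features.items():
            p = out / f"features_blank_{src}.tsv"
            tbl.write(p)
            files[f"features_blank_{src}"] = p.name
        for src, pred in self.predictions.items():
            p = out / f"predictions_{src}.csv"
            pred.df.to_csv(p, index=False)
            files[f"predictions_{src}"] = p.name
        simple = {
            "screen_sample": self.screen_sample,
            "screen_blank": self.screen_blank,
            "reference_series": self.reference_series,
            "solvent_controls": self.solvent_controls,
            "dilution_series": self.dilution_series,
            "calibration": self.calibration,
            "semiquant_calibrants": self.semiquant_calibrants,
            "measured_areas": self.measured_areas,
            "potencies": self.potencies,
        }
        for name, df in simple.items():
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            files[name] = p.name
        truth = dataclasses.asdict(self.truth)
        truth["true_active_fractions"] = list(self.truth.true_active_fractions)
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
        manifest = {
            "seed": self.config.seed,
            "n_fractions": self.config.n_fractions,
            "interval_s": self.config.interval_s,
            "screen_ref": self.config.screen_ref,
            "is_area_ref": self.config.is_area_ref,
            "endpoints": list(self.config.endpoints),
            "files": files,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out


def _elution_weights(c: ActiveCompound, scheme: FractionScheme) -> dict[int, float]:
    """Share of the compound's mass collected into each fraction
    (Gaussian elution profile integrated over the fraction windows)."""
    edges = scheme.start_time_s + scheme.interval_s * np.arange(
        scheme.n_fractions + 1
    )
    cdf = norm.cdf(edges, loc=c.rt_center_s, scale=c.rt_sd_s)
    w = np.diff(cdf)
    return {i + 1: float(w[i]) for i in range(scheme.n_fractions)}


def _sigmoid_pct(dose, ec50: float, hill: float) -> np.ndarray:
    dose = np.asarray(dose, dtype=float)
    out = np.zeros(dose.shape)
    pos = dose > 0
    with np.errstate(over="ignore"):
        out[pos] = 100.0 / (1.0 + (ec50 / dose[pos]) ** hill)
    return out


class _Generator:
    def __init__(self, config: ScenarioConfig):
        config.validate()
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.scheme = config.scheme

    # -- potency bookkeeping --------------------------------------------

    def beq_profiles(self):
        cfg = self.cfg
        weights = {c.name: _elution_weights(c, self.scheme) for c in cfg.actives}
        chem = {
            f: sum(
                c.dht_eq_ng_per_L * weights[c.name][f] for c in cfg.actives
            )
            for f in range(1, cfg.n_fractions + 1)
        }
        bio = dict(chem)
        chem_total = sum(c.dht_eq_ng_per_L for c in cfg.actives)
        bio_total = chem_total
        if cfg.antagonist is not None:
            f = cfg.antagonist.fraction_index
            bio[f] = max(0.0, bio[f] - cfg.antagonist.potency_ng_per_L)
            bio_total = max(0.0, bio_total - cfg.antagonist.potency_ng_per_L)
        return weights, chem, bio, chem_total, bio_total

    # -- plate luminescence ---------------------------------------------

    def _raw_lum(self, response_pct: np.ndarray, n_rep: int) -> np.ndarray:
        """(n_obs, n_rep) raw luminescence with multiplicative and
        additive (percent-units) noise applied per replicate."""
        cfg = self.cfg
        span = cfg.ref_max_lum - cfg.solvent_background_lum
        r = np.asarray(response_pct, dtype=float)[:, None]
        mult = (
            self.rng.normal(0.0, cfg.luminescence_cv, size=(r.shape[0], n_rep))
            if cfg.luminescence_cv > 0
            else np.zeros((r.shape[0], n_rep))
        )
        add = (
            self.rng.normal(0.0, cfg.baseline_noise_pct, size=(r.shape[0], n_rep))
            if cfg.baseline_noise_pct > 0
            else np.zeros((r.shape[0], n_rep))
        )
        noisy_pct = r * (1.0 + mult) + add
        return cfg.solvent_background_lum + span * noisy_pct / 100.0

    def plates(self, bio_beq: dict[int, float], bio_total: float):
        cfg = self.cfg
        scheme = self.scheme
        # fraction screen at REF = screen_ref
        doses = np.array(
            [bio_beq[f] * cfg.screen_ref for f in range(1, cfg.n_fractions + 1)]
        )
        resp = _sigmoid_pct(doses, cfg.ec50_ref_ng_per_L, cfg.hill)
        raw = self._raw_lum(resp, cfg.n_replicates)
        screen_sample = self._screen_frame(raw, scheme)
        # procedural blank plate: no activity anywhere
        raw_b = self._raw_lum(np.zeros(cfg.n_fractions), cfg.n_replicates)
        screen_blank = self._screen_frame(raw_b, scheme)
        # reference agonist dilution series
        ref_doses = np.array(cfg.reference_doses_ng_per_L)
        ref_resp = _sigmoid_pct(ref_doses, cfg.ec50_ref_ng_per_L, cfg.hill)
        ref_raw = self._raw_lum(ref_resp, cfg.n_replicates)
        reference_series = pd.DataFrame(
            {
                "dose_ng_per_L": np.repeat(ref_doses, cfg.n_replicates),
                "replicate": np.tile(
                    np.arange(1, cfg.n_replicates + 1), ref_doses.size
                ),
                "value": ref_raw.ravel(),
            }
        )
        solv_raw = self._raw_lum(np.zeros(8), cfg.n_replicates)
        solvent_controls = pd.DataFrame(
            {
                "well_index": np.repeat(np.arange(1, 9), cfg.n_replicates),
                "replicate": np.tile(np.arange(1, cfg.n_replicates + 1), 8),
                "value": solv_raw.ravel(),
            }
        )
        return screen_sample, screen_blank, reference_series, solvent_controls

    def _screen_frame(self, raw: np.ndarray, scheme: FractionScheme) -> pd.DataFrame:
        n, n_rep = raw.shape
        rows = []
        for i in range(n):
            well = str(scheme.fraction_to_well(i + 1))
            for k in range(n_rep):
                rows.append(
                    {
                        "fraction_index": i + 1,
                        "well": well,
                        "replicate": k + 1,
                        "value": raw[i, k],
                    }
                )
        return pd.DataFrame(rows)

    def dilution_series(
        self, bio_beq: dict[int, float], bio_total: float, active: Sequence[int]
    ) -> pd.DataFrame:
        cfg = self.cfg
        frames = []
        for loc, beq, refs in [
            ("unfractionated_extract", bio_total, cfg.extract_series_refs),
            *[
                (f, bio_beq[f], cfg.fraction_series_refs)
                for f in active
            ],
        ]:
            refs = np.asarray(refs, dtype=float)
            resp = _sigmoid_pct(refs * beq, cfg.ec50_ref_ng_per_L, cfg.hill)
            raw = self._raw_lum(resp, cfg.n_replicates)
            frames.append(
                pd.DataFrame(
                    {
                        "location": [str(loc)] * refs.size * cfg.n_replicates,
                        "ref": np.repeat(refs, cfg.n_replicates),
                        "replicate": np.tile(
                            np.arange(1, cfg.n_replicates + 1), refs.size
                        ),
                        "value": raw.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    # -- features and predictions ---------------------------------------

    def feature_tables(self):
        cfg = self.cfg
        rng = self.rng
        lo, hi = cfg.mz_range
        window = self.scheme.collection_window
        samples, blanks, active_ids = {}, {}, {}
        for src, n_bg in sorted(cfg.n_background.items()):
            rows = []
            # spiked actives first, with stable ids
            ids_here = {}
            for c in cfg.actives:
                if src not in c.sources:
                    continue
                fid = f"{src}_active_{c.name}"
                ids_here[c.name] = fid
                jitter = rng.normal(0.0, 2.0)
                inten = c.concentration_ug_per_L * c.response_factor
                if cfg.feature_intensity_cv > 0:
                    inten *= np.exp(
                        rng.normal(0.0, cfg.feature_intensity_cv)
                    )
                rows.append(
                    {
                        "id": fid,
                        "mz": c.mz,
                        "rt_s": max(0.0, c.rt_center_s + jitter),
                        "intensity": inten,
                        "ion_source": src,
                        "has_ms2": True,
                        "is_true_active": True,
                    }
                )
            mz = rng.uniform(lo, hi, size=n_bg)
            rt = rng.uniform(window[0], window[1], size=n_bg)
            inten = np.exp(rng.normal(11.0, 1.2, size=n_bg))
            ms2 = rng.random(n_bg) < cfg.ms2_prob
            for k in range(n_bg):
                rows.append(
                    {
                        "id": f"{src}_bg_{k:05d}",
                        "mz": mz[k],
                        "rt_s": rt[k],
                        "intensity": inten[k],
                        "ion_source": src,
                        "has_ms2": bool(ms2[k]),
                        "is_true_active": False,
                    }
                )
            df = pd.DataFrame(rows)
            samples[src] = FeatureTable(df, provenance="sample")
            blanks[src] = self._blank_table(df, src)
            active_ids[src] = ids_here
        return samples, blanks, active_ids

    def _blank_table(self, sample_df: pd.DataFrame, src: str) -> FeatureTable:
        cfg = self.cfg
        rng = self.rng
        bg = sample_df[~sample_df["is_true_active"]]
        contam = bg[rng.random(len(bg)) < cfg.blank_contamination_rate]
        rows = []
        for _, r in contam.iterrows():
            # intensity ratio lognormal around 0.5: roughly half of the
            # contaminated features fail the >300% rule downstream
            ratio = np.exp(rng.normal(np.log(0.5), 0.8))
            rows.append(
                {
                    "id": f"blank_{r['id']}",
                    "mz": r["mz"] * (1.0 + rng.normal(0.0, 1.0e-6)),
                    "rt_s": max(0.0, r["rt_s"] + rng.normal(0.0, 5.0)),
                    "intensity": r["intensity"] * ratio,
                    "ion_source": src,
                    "has_ms2": False,
                }
            )
        lo, hi = cfg.mz_range
        window = self.scheme.collection_window
        for k in range(cfg.n_blank_only):
            rows.append(
                {
                    "id": f"{src}_blankonly_{k:04d}",
                    "mz": rng.uniform(lo, hi),
                    "rt_s": rng.uniform(window[0], window[1]),
                    "intensity": np.exp(rng.normal(10.0, 1.0)),
                    "ion_source": src,
                    "has_ms2": False,
                }
            )
        return FeatureTable(pd.DataFrame(rows), provenance="blank")

    def predictions(self, samples: dict) -> dict:
        cfg = self.cfg
        rng = self.rng
        preds = {}
        for src, tbl in sorted(samples.items()):
            rows = []
            for _, r in tbl.df.iterrows():
                if not r["has_ms2"]:
                    continue
                scores = rng.uniform(0.0, 0.5, size=len(cfg.endpoints))
                if r["is_true_active"]:
                    hit = rng.random() < cfg.sensitivity
                else:
                    hit = rng.random() < cfg.false_positive_rate
                if hit:
                    scores[rng.integers(len(cfg.endpoints))] = rng.uniform(
                        0.55, 1.0
                    )
                for ep, s in zip(cfg.endpoints, scores):
                    rows.append(
                        {
                            "feature_id": r["id"],
                            "endpoint": ep,
                            "probability": float(s),
                        }
                    )
            preds[src] = ActivityPredictions(pd.DataFrame(rows), ion_source=src)
        return preds

    # -- quantification inputs ------------------------------------------

    def calibration_tables(self) -> pd.DataFrame:
        cfg = self.cfg
        rng = self.rng
        rows = []
        for c in cfg.actives:
            if not c.is_target:
                continue
            for nominal in cfg.calibration_points:
                area = nominal * c.response_factor
                if cfg.area_cv > 0:
                    area *= 1.0 + rng.normal(0.0, cfg.area_cv)
                is_area = cfg.is_area_ref * (
                    1.0 + (rng.normal(0.0, cfg.is_area_cv) if cfg.is_area_cv > 0 else 0.0)
                )
                rows.append(
                    {
                        "compound": c.name,
                        "nominal_ug_per_L": nominal,
                        "area": area * is_area / cfg.is_area_ref,
                        "is_area": is_area,
                    }
                )
        return pd.DataFrame(
            rows, columns=["compound", "nominal_ug_per_L", "area", "is_area"]
        )

    def semiquant_calibrants(self) -> pd.DataFrame:
        cfg = self.cfg
        rng = self.rng
        log_ie = np.linspace(3.5, 7.0, cfg.n_semiquant_calibrants)
        log_rf = cfg.semiquant_slope * log_ie + cfg.semiquant_intercept
        if cfg.logrf_residual_sd > 0:
            log_rf = log_rf + rng.normal(
                0.0, cfg.logrf_residual_sd, size=log_ie.size
            )
        return pd.DataFrame(
            {
                "compound": [f"calibrant_{i:02d}" for i in range(log_ie.size)],
                "logIE": log_ie,
                "logRF": log_rf,
            }
        )

    def measured_areas(
        self, weights: dict, active_fractions: Sequence[int]
    ) -> pd.DataFrame:
        cfg = self.cfg
        rng = self.rng
        locations: list = ["unfractionated_extract"] + list(active_fractions)
        rows = []
        for c in cfg.actives:
            log_ie = (
                (np.log10(c.response_factor) - cfg.semiquant_intercept)
                / cfg.semiquant_slope
            )
            for loc in locations:
                conc = (
                    c.concentration_ug_per_L
                    if loc == "unfractionated_extract"
                    else c.concentration_ug_per_L * weights[c.name][loc]
                )
                area = conc * c.response_factor
                if area < 1.0:  # below detection
                    continue
                if cfg.area_cv > 0:
                    area *= 1.0 + rng.normal(0.0, cfg.area_cv)
                is_area = cfg.is_area_ref * (
                    1.0
                    + (rng.normal(0.0, cfg.is_area_cv) if cfg.is_area_cv > 0 else 0.0)
                )
                rows.append(
                    {
                        "compound": c.name,
                        "location": str(loc),
                        "area": area * is_area / cfg.is_area_ref,
                        "is_area": is_area,
                        "method": "target" if c.is_target else "semiquant",
                        "logIE": np.nan if c.is_target else log_ie,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["compound", "location", "area", "is_area", "method", "logIE"],
        )

    def potency_table(self) -> pd.DataFrame:
        rows = [
            {"compound": c.name, "rep": c.rep, "source": "literature"}
            for c in self.cfg.actives
        ]
        return pd.DataFrame(rows, columns=["compound", "rep", "source"])


def generate_scenario(config: ScenarioConfig) -> ScenarioBundle:
    """Generate a full scenario bundle; deterministic for a given seed."""
    gen = _Generator(config)
    cfg = config
    weights, chem, bio, chem_total, bio_total = gen.beq_profiles()
    # ground-truth active fractions: noiseless screen response at or
    # above the activity floor (after antagonist suppression)
    resp0 = _sigmoid_pct(
        np.array([bio[f] for f in range(1, cfg.n_fractions + 1)]) * cfg.screen_ref,
        cfg.ec50_ref_ng_per_L,
        cfg.hill,
    )
    true_active = tuple(
        int(f)
        for f in range(1, cfg.n_fractions + 1)
        if resp0[f - 1] >= cfg.activity_floor_pct
    )
    screen_sample, screen_blank, reference_series, solvent = gen.plates(
        bio, bio_total
    )
    dilution = gen.dilution_series(bio, bio_total, true_active)
    samples, blanks, active_ids = gen.feature_tables()
    preds = gen.predictions(samples)
    calibration = gen.calibration_tables()
    semiquant = gen.semiquant_calibrants()
    measured = gen.measured_areas(weights, true_active)
    potencies = gen.potency_table()
    truth = GroundTruth(
        active_feature_ids=active_ids,
        true_active_fractions=true_active,
        beq_chem_per_fraction={int(f): v for f, v in chem.items()},
        beq_bio_per_fraction={int(f): v for f, v in bio.items()},
        beq_chem_unfractionated=chem_total,
        beq_bio_unfractionated=bio_total,
        concentrations_ug_per_L={
            c.name: c.concentration_ug_per_L for c in cfg.actives
        },
        reps={c.name: c.rep for c in cfg.actives},
        response_factors={c.name: c.response_factor for c in cfg.actives},
        elution_weights={c.name: weights[c.name] for c in cfg.actives},
    )
    return ScenarioBundle(
        config=cfg,
        scheme=gen.scheme,
        sample_features=samples,
        blank_features=blanks,
        predictions=preds,
        screen_sample=screen_sample,
        screen_blank=screen_blank,
        reference_series=reference_series,
        solvent_controls=solvent,
        dilution_series=dilution,
        calibration=calibration,
        semiquant_calibrants=semiquant,
        measured_areas=measured,
        potencies=potencies,
        truth=truth,
    )


@dataclass
class RecoveryReport:
    """How well a pipeline run recovered the spiked ground truth."""

    n_true_active_fractions: int
    n_called_active: int
    called_fractions: tuple[int, ...]
    true_active_fractions: tuple[int, ...]
    fraction_calls_correct: bool
    n_true_features: int
    n_true_features_prioritized: int
    retained_fraction: Optional[float] = None
    beq_relative_errors: dict = field(default_factory=dict)
    explained_percent: dict = field(default_factory=dict)

    @property
    def fraction_recall(self) -> float:
        if self.n_true_active_fractions == 0:
            return float("nan")
        hit = set(self.called_fractions) & set(self.true_active_fractions)
        return len(hit) / self.n_true_active_fractions


def true_driver_recovery(
    bundle: ScenarioBundle,
    *,
    calls=None,
    prioritized=None,
    beq_by_location=None,
    contribution_table=None,
) -> RecoveryReport:
    """Score pipeline outputs against the bundle's ground truth.

    Any of the outputs may be omitted; the corresponding report fields
    stay empty.
    """
    truth = bundle.truth
    called = tuple(
        sorted(c.fraction_index for c in calls if c.active)
    ) if calls is not None else ()
    true_ids = {
        fid for per_src in truth.active_feature_ids.values() for fid in per_src.values()
    }
    n_prior = 0
    retained = None
    if prioritized is not None:
        pl = prioritized if isinstance(prioritized, (list, tuple)) else [prioritized]
        got = set()
        n_pred_total = 0
        n_hit_total = 0
        for p in pl:
            got |= set(p.ids) & true_ids
            n_pred_total += p.n_predicted
            n_hit_total += p.n_prioritized
        n_prior = len(got)
        if n_pred_total:
            retained = n_hit_total / n_pred_total
    beq_err = {}
    if beq_by_location is not None:
        for loc, beq in beq_by_location.items():
            if loc == "unfractionated_extract":
                true_beq = truth.beq_bio_unfractionated
            else:
                true_beq = truth.beq_bio_per_fraction[int(loc)]
            if true_beq > 0:
                beq_err[loc] = abs(beq - true_beq) / true_beq
    explained = {}
    if contribution_table is not None:
        for loc in contribution_table.locations:
            explained[loc] = contribution_table.explained(loc)
    return RecoveryReport(
        n_true_active_fractions=len(truth.true_active_fractions),
        n_called_active=len(called),
        called_fractions=called,
        true_active_fractions=tuple(truth.true_active_fractions),
        fraction_calls_correct=(
            set(called) == set(truth.true_active_fractions)
            if calls is not None
            else False
        ),
        n_true_features=len(true_ids),
        n_true_features_prioritized=n_prior,
        retained_fraction=retained,
        beq_relative_errors=beq_err,
        explained_percent=explained,
    )
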