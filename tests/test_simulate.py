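"""Synthetic scenario generator: determinism, conservation, ground truth."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hteda import (
    ActiveCompound,
    HtedaError,
    ScenarioConfig,
    call_active,
    generate_scenario,
)
from hteda.doseresponse import normalize_to_reference
from hteda.toxicogram import Toxicogram


def _small_config(**kw):
    base = ScenarioConfig(seed=123)
    base.n_background = {"ESI_pos": 150, "APCI_pos": 60}
    return dataclasses.replace(base, **kw)


def _screen_responses(bundle):
    """Replicate-mean percent responses of the fraction screen."""
    cfg = bundle.config
    means = bundle.screen_sample.groupby("fraction_index")["value"].mean()
    return normalize_to_reference(
        means.sort_index().to_numpy(),
        cfg.ref_max_lum,
        cfg.solvent_background_lum,
    )


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        b1 = generate_scenario(_small_config())
        b2 = generate_scenario(_small_config())
        pd.testing.assert_frame_equal(b1.screen_sample, b2.screen_sample)
        pd.testing.assert_frame_equal(
            b1.sample_features["ESI_pos"].df, b2.sample_features["ESI_pos"].df
        )
        pd.testing.assert_frame_equal(
            b1.predictions["ESI_pos"].df, b2.predictions["ESI_pos"].df
        )
        assert b1.truth.true_active_fractions == b2.truth.true_active_fractions

    def test_different_seed_differs(self):
        b1 = generate_scenario(_small_config())
        b2 = generate_scenario(_small_config(seed=124))
        assert not b1.screen_sample["value"].equals(b2.screen_sample["value"])

    def test_written_bundles_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_scenario(_small_config()).write(d1)
        generate_scenario(_small_config()).write(d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()


class TestMassConservation:
    def test_elution_weights_sum_to_one(self):
        b = generate_scenario(_small_config().noiseless())
        for name, w in b.truth.elution_weights.items():
            assert sum(w.values()) == pytest.approx(1.0, rel=1e-9)

    def test_per_fraction_beq_sums_to_total(self):
        b = generate_scenario(_small_config())
        total = sum(b.truth.beq_chem_per_fraction.values())
        assert total == pytest.approx(b.truth.beq_chem_unfractionated, rel=1e-9)


class TestNoiselessResponses:
    def test_single_compound_matches_sigmoid_closed_form(self):
        cfg = _small_config().noiseless()
        cfg = dataclasses.replace(cfg, actives=cfg.actives[:1])
        b = generate_scenario(cfg)
        resp = _screen_responses(b)
        for f in range(1, cfg.n_fractions + 1):
            dose = b.truth.beq_bio_per_fraction[f] * cfg.screen_ref
            try:
                expected = (
                    100.0 / (1.0 + (cfg.ec50_ref_ng_per_L / dose) ** cfg.hill)
                    if dose > 0
                    else 0.0
                )
            except OverflowError:  # far-tail fraction: dose ~ 0
                expected = 0.0
            assert resp[f - 1] == pytest.approx(expected, abs=1e-9)

    def test_active_fractions_well_separated(self):
        # truth-active fractions respond >= the activity floor; all
        # others stay far below it, so calling is not borderline
        b = generate_scenario(_small_config().noiseless())
        resp = _screen_responses(b)
        active = set(b.truth.true_active_fractions)
        for f in range(1, b.config.n_fractions + 1):
            if f in active:
                assert resp[f - 1] >= b.config.activity_floor_pct
            else:
                assert resp[f - 1] < 0.4 * b.config.activity_floor_pct


class TestPredictions:
    def test_perfect_predictions_recover_exactly_the_actives(self):
        cfg = _small_config(false_positive_rate=0.0, sensitivity=1.0)
        b = generate_scenario(cfg)
        for src, preds in b.predictions.items():
            hits = set(
                preds.df[preds.df["probability"] > 0.5]["feature_id"]
            )
            assert hits == set(b.truth.active_feature_ids[src].values())

    def test_every_active_has_a_sample_feature(self):
        b = generate_scenario(_small_config())
        for src, by_name in b.truth.active_feature_ids.items():
            ids = set(b.sample_features[src].df["id"])
            assert set(by_name.values()) <= ids


class TestScenarioEdges:
    def test_no_actives_scenario(self, scheme):
        cfg = _small_config(actives=())
        b = generate_scenario(cfg)
        assert b.truth.true_active_fractions == ()
        # the screen carries noise only: no fraction called at z > 10
        resp = _screen_responses(b)
        tox = Toxicogram.from_responses(resp, scheme)
        assert not any(c.active for c in call_active(tox))

    def test_invalid_config_rejected_before_generation(self):
        with pytest.raises(HtedaError):
            generate_scenario(_small_config(sensitivity=1.5))
        with pytest.raises(HtedaError):
            generate_scenario(_small_config(seed=-1))
        bad = ActiveCompound(
            name="x", mz=300.0, rt_center_s=900.0, rt_sd_s=-1.0,
            concentration_ug_per_L=1.0, rep=0.1, response_factor=1.0,
        )
        with pytest.raises(HtedaError):
            generate_scenario(_small_config(actives=(bad,)))


def test_baseline_noise_degrades_active_z_scores(scheme):
    """Raising plate noise inflates the baseline MAD and shrinks the
    modified z-scores of the truly active fractions."""
    med_z = []
    for noise in (0.5, 5.0):
        zs = []
        for seed in range(3):
            cfg = dataclasses.replace(
                _small_config(seed=200 + seed), baseline_noise_pct=noise
            )
            b = generate_scenario(cfg)
            calls = call_active(
                Toxicogram.from_responses(_screen_responses(b), scheme)
            )
            by_idx = {c.fraction_index: c.z for c in calls}
            zs += [by_idx[f] for f in b.truth.true_active_fractions]
        med_z.append(np.median(zs))
    assert med_z[1] < med_z[0]
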