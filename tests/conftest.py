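"""Shared fixtures: synthetic bundles and pipeline runs reused across
test modules (session-scoped — generation and the full pipeline are the
expensive parts)."""

import dataclasses
import warnings

import pytest

from hteda import (
    AntagonistSpec,
    FractionScheme,
    PipelineConfig,
    ScenarioConfig,
    generate_scenario,
    run_pipeline,
)

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def scheme() -> FractionScheme:
    """The standard collection scheme: 80 x 18 s fractions."""
    return FractionScheme(interval_s=18.0, n_fractions=80)


@pytest.fixture(scope="session")
def default_bundle():
    """Default noisy scenario: ~5000 ESI+ / ~1500 APCI+ background
    features, 10 truly active fractions, sensitivity 1.0, FPR 0.02."""
    return generate_scenario(ScenarioConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_scenario(ScenarioConfig(seed=2).noiseless())


@pytest.fixture(scope="session")
def antagonist_bundle():
    cfg = dataclasses.replace(
        ScenarioConfig(seed=3).noiseless(), antagonist=AntagonistSpec()
    )
    return generate_scenario(cfg)


def _run(bundle, tmp_root):
    bdir = tmp_root / "bundle"
    bundle.write(bdir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(
            PipelineConfig(input_dir=str(bdir), output_dir=str(tmp_root / "out"))
        )


@pytest.fixture(scope="session")
def default_report(default_bundle, tmp_path_factory):
    return _run(default_bundle, tmp_path_factory.mktemp("default"))


@pytest.fixture(scope="session")
def noiseless_report(noiseless_bundle, tmp_path_factory):
    return _run(noiseless_bundle, tmp_path_factory.mktemp("noiseless"))


@pytest.fixture(scope="session")
def antagonist_report(antagonist_bundle, tmp_path_factory):
    return _run(antagonist_bundle, tmp_path_factory.mktemp("antagonist"))
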