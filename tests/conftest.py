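import logging

import numpy as np
import pytest

from meqtlkit.config import PipelineConfig
from meqtlkit.synthetic import SimConfig, simulate_bundle, write_bundle

logging.getLogger("meqtlkit").setLevel(logging.ERROR)


def small_config(seed: int = 1, **overrides) -> SimConfig:
    """Toy-scale study conditions for fast end-to-end tests."""
    base = dict(seed=seed, n_ref_per_pop=60, n_450k=120, n_epic=110,
                n_snps=600, n_cpgs=300, n_true_meqtls=20,
                n_true_exposure_cpgs=25, n_exposure_snps=12,
                outcome_gwas_n=1500, n_control_probes=40, n_cell_ref_cpgs=80)
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_bundle():
    return simulate_bundle(small_config())


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle, out)
    return out


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """Default (study-scale) bundle, written and run once per session."""
    from meqtlkit.pipeline import run_pipeline

    bundle = simulate_bundle(SimConfig(seed=11))
    bdir = tmp_path_factory.mktemp("study_bundle")
    write_bundle(bundle, bdir)
    out = tmp_path_factory.mktemp("study_out")
    results = run_pipeline(PipelineConfig(seed=11, bundle_dir=str(bdir),
                                          out_dir=str(out)))
    return {"bundle": bundle, "results": results, "out": out}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
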