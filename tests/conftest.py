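import warnings

import numpy as np
import pytest

from tsaquant.cli import config_from_bundle
from tsaquant.pipeline import run_all
from tsaquant.synthetic import CohortConfig, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_patients=6, n_coding=20, n_lncrna=20, n_novel=10, seed=123
    )


@pytest.fixture(scope="session")
def small_bundle(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_cohort(small_config, outdir=outdir)


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    bundle_dir = str(
        __import__("pathlib").Path(small_bundle.paths["gtf"]).parent
    )
    config = config_from_bundle(bundle_dir, outdir)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_all(config)
    return {"manifest": manifest, "outdir": outdir, "config": config}
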