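import warnings

import pytest

import scadcost as sc
from scadcost.config import default_hazards


def zero_hazard_params():
    """All transition rates zero, no covariate effects."""
    return {k: {"rate": 0.0, "log_hr": {}} for k in default_hazards()}


def plain_cost_params(**kwargs):
    """Total-cost params with no covariate effects (published worked example)."""
    base = sc.default_cost_params()
    base.covariate_effects = {}
    for k, v in kwargs.items():
        setattr(base, k, v)
    return base


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-condition cohort shared across read-only tests."""
    cfg = sc.default_config(n_patients=2000, seed=42)
    tables = sc.simulate(cfg)
    windows = sc.build_analysis_windows(tables["baseline"], tables["events"])
    return {"config": cfg, **tables, "windows": windows}


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """Full pipeline run (all models + reports) on a small cohort."""
    cfg = sc.default_config(n_patients=1200, seed=7)
    out = tmp_path_factory.mktemp("pipeline")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        results = sc.run_all(cfg, out_dir=str(out), m_imputations=2,
                             horizon_cycles=300)
    results["out_dir"] = str(out)
    return results
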