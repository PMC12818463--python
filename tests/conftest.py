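import warnings

import numpy as np
import pytest

import spafnirs as sp
from spafnirs.pipeline import RunConfig, _fit_session, process_session, run_study


@pytest.fixture(scope="session")
def default_montage():
    return sp.make_montage()


@pytest.fixture(scope="session")
def default_events():
    return sp.sample_events(seed=1)


@pytest.fixture(scope="session")
def noise_free_betas(default_montage, default_events):
    """Channel betas recovered from a noise-free session, all three models."""
    truth = sp.noise_free_truth()
    rec = sp.simulate_session(default_montage, default_events, truth, 7)
    cfg = RunConfig(sci_threshold=None)
    feats = process_session(rec, default_montage, cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        betas, _ = _fit_session(feats, default_montage, cfg)
    return betas, truth, default_montage


@pytest.fixture(scope="session")
def default_study_result():
    """One full default study (15 subjects x 2 sessions x 3 models)."""
    return run_study(RunConfig(seed=0))


def _study_metrics(seed):
    res = run_study(RunConfig(seed=seed))
    rel = res.reliability[res.reliability["roi"] == "pooled"].set_index("model")["icc"]
    tb = res.simulation.true_betas
    tb = tb[(tb.condition == "speech") & (tb.chromophore == "HbO")]
    rb = res.roi_betas
    rb = rb[(rb.condition == "speech") & (rb.chromophore == "HbO")]
    mg = rb.merge(tb, on=["subject", "session", "roi", "condition", "chromophore"],
                  suffixes=("_est", "_true"))
    rmse = {}
    for model in ("none", "ss", "ss_tcca"):
        sub = mg[mg.model == model]
        rmse[model] = float(np.sqrt(((sub.beta_est - sub.beta_true) ** 2).mean()))
    return rel.to_dict(), rmse


@pytest.fixture(scope="session")
def replicate_batch():
    """ICC and beta-RMSE metrics from 20 replicate default studies."""
    iccs, rmses = [], []
    for seed in range(20):
        icc, rmse = _study_metrics(seed)
        iccs.append(icc)
        rmses.append(rmse)
    return iccs, rmses
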