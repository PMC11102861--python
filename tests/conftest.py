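import numpy as np
import pytest

import deadkin as dk


@pytest.fixture(scope="session")
def wildtype_a20_clean():
    """Noise-free wild-type pure-poly(A) assay with its ground truth."""
    sc = dk.scenario("A20", "wild_type", noise_sigma=0.0)
    tc, truth = dk.simulate_noisy_assay(sc)
    return tc, truth


@pytest.fixture(scope="session")
def wildtype_a20_fit(wildtype_a20_clean):
    """Fitted model on the noise-free wild-type control (reused; fits are slow)."""
    tc, truth = wildtype_a20_clean
    model = dk.DeadenylationKineticsModel().fit(tc)
    return model, truth


@pytest.fixture(scope="session")
def wildtype_a20g_pair():
    """Noise-free A20G + matched A20 fits, for stalling-analysis tests."""
    scm = dk.scenario("A20G", "wild_type", noise_sigma=0.0)
    scc = dk.scenario("A20", "wild_type", noise_sigma=0.0)
    tm, truth_m = dk.simulate_noisy_assay(scm)
    tc, truth_c = dk.simulate_noisy_assay(scc)
    mm = dk.DeadenylationKineticsModel().fit(tm)
    mc = dk.DeadenylationKineticsModel().fit(tc)
    return {"mixed": mm, "control": mc, "scenario": scm, "truth": truth_m}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
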