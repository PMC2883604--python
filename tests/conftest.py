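import numpy as np
import pytest

import replitime as rt


@pytest.fixture(scope="session")
def default_run():
    """One default 6-Mb synthetic chromosome, fully analyzed.

    Session-scoped: several statistical tests share it.
    """
    cfg = rt.SimConfig(seed=1)
    probes, truth = rt.simulate_chromosome(cfg)
    features, marks, expression = rt.simulate_marks_genes(cfg, truth, probes)
    res = rt.analyze(probes, rt.PipelineConfig(seed=1))
    return {
        "cfg": cfg, "probes": probes, "truth": truth,
        "features": features, "marks": marks, "expression": expression,
        "res": res,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
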