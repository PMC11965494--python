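import numpy as np
import pytest
from scipy.stats import pearsonr

from clockunits.binding import ema_infer
from clockunits.clock_model import shipped_model
from clockunits.synth import PbmTruth, gen_pbm_dataset, random_energy_matrix


@pytest.fixture(scope="session")
def u2019():
    return shipped_model("U2019.3")


@pytest.fixture(scope="session")
def u2020():
    return shipped_model("U2020.3")


@pytest.fixture(scope="session")
def ema_recovery():
    """Planted-matrix PBM, its EMA fit and the recovery metrics; shared by
    the binding unit tests and the pipeline-level checks."""
    truth_matrix = random_energy_matrix(seed=8)
    truth = PbmTruth(matrix=truth_matrix, seed=11)
    pbm, labels = gen_pbm_dataset(truth)
    result = ema_infer(pbm, seed=0)
    r = float(pearsonr(result.matrix.energies.ravel(),
                       truth_matrix.energies.ravel())[0])
    accuracy = float(((result.posterior_bound.to_numpy() >= 0.5)
                      == labels.to_numpy()).mean())
    return {"truth_matrix": truth_matrix, "truth": truth, "pbm": pbm,
            "labels": labels, "result": result, "pearson_r": r,
            "accuracy": accuracy}
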