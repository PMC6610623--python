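import numpy as np
import pytest
import scipy.sparse as sp

import dropqc as dq
from dropqc.classify import (
    assign_training_labels, classify_droplets, split_train_test, train_classifier,
)


@pytest.fixture()
def tiny_matrix() -> dq.CountMatrix:
    """3 genes x 2 droplets with hand-checkable sums (nUMI = 3, 8)."""
    counts = np.array([[1, 0], [2, 3], [0, 5]])
    return dq.CountMatrix(sp.csr_matrix(counts), ["MT-CO1", "ACTB", "GAPDH"], ["b1", "b2"])


@pytest.fixture(scope="session")
def sim_default() -> dq.SimulatedDataset:
    """The default simulated dataset (the study conditions), seed 1."""
    return dq.simulate(dq.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def qc_default(sim_default):
    """QC table for the default dataset, using the planted housekeeping set."""
    return dq.compute_qc_table(
        sim_default.matrix, n_sshegs=64, hk=sim_default.planted_sets["housekeeping"]
    )


@pytest.fixture(scope="session")
def classified_default(sim_default, qc_default):
    """Self-labeled table, trained model and full-table predictions (seed 1)."""
    labeled = assign_training_labels(qc_default)
    train, test = split_train_test(labeled, seed=1)
    model = train_classifier(train, test, seed=1)
    predictions = classify_droplets(model, labeled)
    return labeled, model, predictions
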