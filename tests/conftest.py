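"""Shared fixtures.

The segmentation network is trained once per session on its own synthetic
cohort and reused by every test that needs a trained model; the end-to-end
observer study likewise runs once.  Problem sizes are desk-scale (48-voxel
grid, 8 training subjects, 10+10 test subjects) so the whole suite stays
within a single-CPU budget.
"""

import numpy as np
import pytest

from ctless.pipeline import StudyConfig, prepare_training_set, run_experiment, train_network
from ctless.segnet import dice_coefficient, normalize_input, predict_segments

STUDY_SEED = 5


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def trained_network(study_config):
    """Segmentation network trained on the study's synthetic cohort, plus
    held-out subjects (reconstruction pairs + truth labels) for evaluation."""
    dataset, train_ids = prepare_training_set(study_config)
    net, history = train_network(study_config, dataset=dataset)
    heldout_cfg = StudyConfig(**{**study_config.__dict__,
                                 "seed": STUDY_SEED + 1000, "n_train": 4})
    heldout, _ = prepare_training_set(heldout_cfg)
    return {"net": net, "history": history, "heldout": heldout,
            "train_ids": train_ids}


@pytest.fixture(scope="session")
def heldout_dice(trained_network):
    """Per-region Dice of the trained network on held-out subjects."""
    net = trained_network["net"]
    per_region = {k: [] for k in range(6)}
    for f_sc, f_pp, labels in trained_network["heldout"]:
        seg = predict_segments(normalize_input(f_sc), normalize_input(f_pp), net)
        for k in range(6):
            per_region[k].append(dice_coefficient(seg.labels == k, labels == k))
    return {k: float(np.mean(v)) for k, v in per_region.items()}


@pytest.fixture(scope="session")
def study_report(study_config, trained_network):
    """End-to-end three-arm observer study using the session network."""
    return run_experiment(study_config, net=trained_network["net"])
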