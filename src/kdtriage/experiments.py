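"""End-to-end synthetic experiments used by the test suite and the
reproduction script: train the two-step classifier on one synthetic cohort
and evaluate it on a freshly seeded one."""

from __future__ import annotations

import numpy as np

from .forest import ForestConfig
from .model import TwoStepKD
from .simulate import default_spec, generate

__all__ = ["synthetic_two_step_experiment"]


def synthetic_two_step_experiment(
    seed: int,
    n_per_group: int = 1000,
    n_trees: int = 500,
) -> dict:
    """Train on one seed, test on a derived fresh seed; report the headline
    metrics of both phases.

    Returns a dict with calibration-set achieved PPV/NPV (and the binomial
    standard errors of the targets at the calibrated call counts) plus test
    sensitivity/specificity/PPV/NPV and abstention rates.
    """
    train_seed = int(seed) % (2**31 - 1)
    test_seed = (train_seed + 10_007) % (2**31 - 1)
    train = generate(default_spec(n_kd=n_per_group, n_fc=n_per_group,
                                  seed=train_seed))
    test = generate(default_spec(n_kd=n_per_group, n_fc=n_per_group,
                                 seed=test_seed))
    model = TwoStepKD(train, forest_config=ForestConfig(n_trees=n_trees,
                                                        seed=train_seed))
    results = model.fit(seed=train_seed)

    th = results.model.lda_thresholds
    train_calls = results.predict_frame(train)
    n_kd_called = int((train_calls.call == "KD").sum())
    n_fc_called = int((train_calls.call == "FC").sum())
    se_ppv = float(np.sqrt(th.target_ppv * (1 - th.target_ppv)
                           / max(n_kd_called, 1)))
    se_npv = float(np.sqrt(th.target_npv * (1 - th.target_npv)
                           / max(n_fc_called, 1)))

    cs = results.evaluate(test)
    return {
        "seed": train_seed,
        "n_per_group": n_per_group,
        "calibration_ppv": th.achieved_ppv,
        "calibration_npv": th.achieved_npv,
        "target_ppv": th.target_ppv,
        "target_npv": th.target_npv,
        "se_ppv": se_ppv,
        "se_npv": se_npv,
        "test_sensitivity": float(cs.sensitivity),
        "test_specificity": float(cs.specificity),
        "test_ppv": None if cs.ppv is None else float(cs.ppv),
        "test_npv": None if cs.npv is None else float(cs.npv),
        "test_indeterminate_rate_kd": float(cs.indeterminate_rate_kd),
        "test_indeterminate_rate_fc": float(cs.indeterminate_rate_fc),
        "test_confusion": cs,
    }
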