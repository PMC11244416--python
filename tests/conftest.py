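"""Shared fixtures.

Heavy, session-scoped fixtures at the bottom run the full cross-subject
evaluation protocol (10 subjects x 60 trials, 1:4 imbalance, 9:1
subject-disjoint splits, 50-epoch fits) at the package's desk-scale problem
size: 250 Hz sampling over a 0-1000 ms epoch, i.e. T=250 samples, mask-window
length 50 samples (200 ms) starting at sample 75 (300 ms).
"""

from __future__ import annotations

import numpy as np
import pytest

import erpmask
from erpmask.model import ModelConfig, ModelParams


# -- small fixtures ----------------------------------------------------------

@pytest.fixture
def tiny_spec():
    """3 subjects x 10 trials, 4 channels, 600 ms at 250 Hz."""
    return erpmask.SyntheticSpec(
        n_subjects=3, trials_per_subject=10, imbalance_ratio=4,
        n_channels=4, n_samples=150, sampling_rate=250.0,
        noise_sd=1.0, seed=11)


@pytest.fixture
def tiny_epochs(tiny_spec):
    return erpmask.generate_dataset(tiny_spec)


@pytest.fixture
def small_config():
    """Model dimensions small enough for brute-force oracles."""
    return ModelConfig(n_scales=3, kernel_len=10, segment_start=20,
                       sharpness=5.0, n_channels=4, n_samples=60,
                       dropout_rate=0.5)


@pytest.fixture
def small_params(small_config):
    rng = np.random.default_rng(42)
    params = ModelParams.initialize(small_config, rng)
    # nontrivial running statistics so eval-mode checks exercise them
    params.bn_mean = rng.normal(0, 0.1, small_config.n_scales)
    params.bn_var = rng.uniform(0.5, 2.0, small_config.n_scales)
    params.bn_beta = rng.normal(0, 0.1, small_config.n_scales)
    return params


# -- acceptance-scale protocol ----------------------------------------------

EVAL_SR = 250.0
EVAL_T = 250
EVAL_KERNEL_LEN = 50      # 200 ms at 250 Hz
EVAL_SEGMENT_START = 75   # 300 ms at 250 Hz


def eval_scale_spec(**overrides) -> erpmask.SyntheticSpec:
    """Default study conditions at the 250 Hz evaluation scale."""
    kw = dict(n_subjects=10, trials_per_subject=60, imbalance_ratio=4,
              n_channels=30, n_samples=EVAL_T, sampling_rate=EVAL_SR, seed=0)
    kw.update(overrides)
    return erpmask.SyntheticSpec(**kw)


def train_and_score(dataset: erpmask.EpochSet, variant: str, seed: int,
                    epochs: int = 50, n_scales: int = 10,
                    kernel_len: int = EVAL_KERNEL_LEN,
                    segment_start: int = EVAL_SEGMENT_START):
    """One 9:1 subject-disjoint split, one fit, one held-out evaluation."""
    train_set, test_set = erpmask.split_by_subject(
        dataset, train_fraction=0.9, n_folds=1, seed=seed)[0]
    cfg = ModelConfig(n_scales=n_scales, kernel_len=kernel_len,
                      segment_start=segment_start, sharpness=5.0,
                      n_channels=dataset.n_channels,
                      n_samples=dataset.n_samples, variant=variant)
    tc = erpmask.TrainConfig(epochs=epochs, seed=seed)
    params, history = erpmask.fit(train_set, cfg, tc)
    scores, preds = erpmask.predict(params, test_set, tc.threshold)
    report = erpmask.evaluate_predictions(test_set.labels, preds, scores)
    return report, history


@pytest.fixture(scope="session")
def protocol_runs():
    """Masked and standard fits over five seeds on the default dataset.

    Returns {variant: {seed: EvalReport}} for seeds 0..4; the first three
    masked seeds double as the median-BA sample.
    """
    dataset = erpmask.generate_dataset(eval_scale_spec())
    runs = {"masked": {}, "standard": {}}
    for seed in range(5):
        for variant in ("masked", "standard"):
            report, _ = train_and_score(dataset, variant, seed)
            runs[variant][seed] = report
    return runs
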