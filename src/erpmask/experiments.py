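"""Ablation and sweep harness: masked vs. standard variants over grids of
scale count K, sharpness lambda, and mask-segment window (length l, start P).

Every grid cell is trained and evaluated on subject-disjoint folds; matched
masked/standard cells share identical data splits and seeds so their
comparison is paired.  Window starts are specified in samples; at a 1000 Hz
sampling rate samples and ms coincide.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd

from .epochs import EpochSet, split_by_subject
from .metrics import evaluate_predictions
from .model import ModelConfig
from .training import TrainConfig, fit, predict

__all__ = ["AblationGrid", "run_ablation"]


@dataclass
class AblationGrid:
    """Cartesian experiment grid.

    Defaults mirror the study's sweeps: scale factors K in {5, 10, 20, 30},
    sharpness in {3, 4, 5, 6, 7, 8, 10}, mask-window lengths in
    {100, 200, 300, 600} samples.  ``window_starts`` must be chosen so that
    every (l, P) pair satisfies P + l <= T.
    """

    variants: Tuple[str, ...] = ("masked", "standard")
    K_values: Tuple[int, ...] = (5, 10, 20, 30)
    lambda_values: Tuple[float, ...] = (3, 4, 5, 6, 7, 8, 10)
    window_lengths: Tuple[int, ...] = (100, 200, 300, 600)
    window_starts: Tuple[int, ...] = (400,)
    seeds: Tuple[int, ...] = (0,)
    folds: int = 1

    def validate(self, n_samples: int) -> None:
        for name in ("variants", "K_values", "lambda_values",
                     "window_lengths", "window_starts", "seeds"):
            if not getattr(self, name):
                raise ValueError(f"grid field {name} must be non-empty")
        for v in self.variants:
            if v not in ("masked", "standard"):
                raise ValueError(f"unknown variant {v!r}")
        for l, p in itertools.product(self.window_lengths, self.window_starts):
            if p + l > n_samples:
                raise ValueError(
                    f"window (l={l}, P={p}) exceeds the epoch length T={n_samples}")

    def n_cells(self) -> int:
        return (len(self.variants) * len(self.K_values) * len(self.lambda_values)
                * len(self.window_lengths) * len(self.window_starts)
                * len(self.seeds) * self.folds)


_METRICS = ("BA", "F1", "TPR", "TNR", "FPR", "precision", "recall", "AUC")


def run_ablation(dataset: EpochSet, grid: AblationGrid,
                 train_config: Optional[TrainConfig] = None,
                 dropout_rate: float = 0.5,
                 base_kernels_trainable: bool = True) -> pd.DataFrame:
    """Train and evaluate every grid cell; return one row per
    (variant, K, lambda, l, P, seed, fold).

    Rows are exhaustive over the grid — a cell whose training fails is kept
    with ``status='failed'`` and the error message, and the run continues.
    Matched masked/standard settings share splits (the split depends only on
    the seed), and a ``ba_masked_minus_standard`` column carries the paired
    balanced-accuracy difference on each matched row.
    """
    if train_config is None:
        train_config = TrainConfig()
    grid.validate(dataset.n_samples)

    # one set of subject-disjoint folds per seed, shared by every cell
    folds_by_seed = {
        seed: split_by_subject(dataset, train_config.train_fraction,
                               grid.folds, seed=seed)
        for seed in grid.seeds
    }

    rows = []
    for variant, K, lam, l, P, seed in itertools.product(
            grid.variants, grid.K_values, grid.lambda_values,
            grid.window_lengths, grid.window_starts, grid.seeds):
        for fold_i, (train_set, test_set) in enumerate(folds_by_seed[seed]):
            row = {"variant": variant, "K": K, "lambda": lam, "l": l, "P": P,
                   "seed": seed, "fold": fold_i, "status": "ok", "error": ""}
            try:
                cfg = ModelConfig(
                    n_scales=K, kernel_len=l, segment_start=P, sharpness=lam,
                    n_channels=dataset.n_channels, n_samples=dataset.n_samples,
                    dropout_rate=dropout_rate, variant=variant,
                    base_kernels_trainable=base_kernels_trainable)
                tc = dataclasses.replace(train_config, seed=seed)
                params, _ = fit(train_set, cfg, tc)
                scores, preds = predict(params, test_set, tc.threshold)
                report = evaluate_predictions(test_set.labels, preds, scores)
                for m in _METRICS:
                    row[m] = getattr(report, m)
            except Exception as exc:  # noqa: BLE001 - sweep must survive cell failures
                row["status"] = "failed"
                row["error"] = f"{type(exc).__name__}: {exc}"
                for m in _METRICS:
                    row[m] = float("nan")
            rows.append(row)

    df = pd.DataFrame(rows)
    # paired masked - standard BA per matched (K, lambda, l, P, seed, fold)
    keys = ["K", "lambda", "l", "P", "seed", "fold"]
    if {"masked", "standard"} <= set(grid.variants):
        ba = df.pivot_table(index=keys, columns="variant", values="BA")
        if {"masked", "standard"} <= set(ba.columns):
            diff = (ba["masked"] - ba["standard"]).rename("ba_masked_minus_standard")
            df = df.merge(diff.reset_index(), on=keys, how="left")
        else:
            df["ba_masked_minus_standard"] = float("nan")
    else:
        df["ba_masked_minus_standard"] = float("nan")
    return df
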