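"""Cross-validation, rank-correlation metrics, length sweeps, deduplication."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .guide_design import WINDOW_LEN, window_from_context
from .model_core import (
    ActivityModel,
    FreezePlan,
    LabeledDataset,
    ModelSpec,
    TrainConfig,
    build_model,
    predict,
    train_base,
    transfer_train,
)


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (distinct from 0) for constant inputs, where the
    coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho = float(stats.spearmanr(x, y).statistic)
    if abs(abs(rho) - 1.0) < 1e-9:  # exact at the extremes despite float error
        rho = float(np.copysign(1.0, rho))
    return rho


@dataclass
class CVResult:
    fold_rhos: list[float]
    mean_rho: float
    fold_assignments: np.ndarray
    seed: int


@dataclass
class SweepResult:
    rows: pd.DataFrame  # upstream_nt, downstream_nt, input_len, mean_rho

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)


def make_folds(n: int, k: int, seed: int) -> np.ndarray:
    """Seeded uniform shuffle into k folds with sizes within 1 of each other."""
    if n < k:
        raise ValueError("need at least k examples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    start = 0
    for fold, size in enumerate(sizes):
        assignments[perm[start: start + size]] = fold
        start += size
    return assignments


def kfold_cv(
    data: LabeledDataset,
    cfg: TrainConfig,
    k: int = 5,
    base: ActivityModel | None = None,
    plan: FreezePlan | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> CVResult:
    """k-fold cross validation with held-out Spearman rank correlation.

    With a ``base`` model and freeze ``plan``, each fold fine-tunes a copy of
    the base on the ~80% training split; with ``base=None`` an identical
    architecture (``spec``) is trained from scratch per fold (the no-transfer
    baseline).  The dataset's no-duplicate invariant guards leakage: a guide
    sequence can never appear in both train and test of a fold.
    """
    guides = data.guides()
    if len(guides) != len(set(guides)):
        raise ValueError("duplicate guide sequences in dataset; train/test leakage")
    folds = make_folds(len(data), k, seed)
    rhos: list[float] = []
    for fold in range(k):
        train_set = data.subset(np.flatnonzero(folds != fold))
        test_set = data.subset(np.flatnonzero(folds == fold))
        if base is not None:
            if plan is None:
                raise ValueError("a freeze plan is required with a base model")
            model = transfer_train(base, plan, train_set, cfg)
        else:
            if spec is None:
                raise ValueError("spec is required for from-scratch (no-transfer) CV")
            model = build_model(spec, seed=seed * 1000 + fold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                train_base(model, train_set, cfg)
        rhos.append(spearman_rho(predict(model, test_set), test_set.targets))
    return CVResult(
        fold_rhos=rhos, mean_rho=float(np.mean(rhos)), fold_assignments=folds, seed=seed
    )


def length_sweep(
    contexts43: list[str],
    targets: np.ndarray,
    cfg: TrainConfig,
    spec: ModelSpec | None = None,
    base_by_len: dict[int, ActivityModel] | None = None,
    plan: FreezePlan | None = None,
    u_max: int = 10,
    d_max: int = 13,
    k: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Mean CV rank correlation versus input-window setting.

    Settings: the bare 20-nt protospacer once, upstream extensions (u, 0) for
    u in 1..u_max, and downstream extensions (0, d) for d in 3..d_max — the
    first downstream increment of 3 nt covers the PAM.  Each setting rebuilds
    the encodings and the model (per-length base models may be supplied via
    ``base_by_len``); windows too long for the stored context are skipped
    with a warning.
    """
    if any(len(c) != WINDOW_LEN for c in contexts43):
        raise ValueError("contexts must be 43 nt")
    settings = [(0, 0)] + [(u, 0) for u in range(1, u_max + 1)] + [
        (0, d) for d in range(3, d_max + 1)
    ]
    rows = []
    for u, d in settings:
        try:
            windows = [window_from_context(c, u, d) for c in contexts43]
        except ValueError as exc:
            warnings.warn(f"skipping window ({u}, {d}): {exc}", stacklevel=2)
            continue
        data = LabeledDataset(sequences=windows, targets=targets, name=f"sweep_u{u}_d{d}")
        input_len = 20 + u + d
        base = (base_by_len or {}).get(input_len)
        run_spec = None
        if base is None:
            if spec is None:
                raise ValueError("spec required when no base model is supplied")
            run_spec = ModelSpec.from_dict({**spec.to_dict(), "input_len": input_len})
        cv = kfold_cv(data, cfg, k=k, base=base, plan=plan, spec=run_spec, seed=seed)
        rows.append(
            {"upstream_nt": u, "downstream_nt": d, "input_len": input_len,
             "mean_rho": cv.mean_rho}
        )
    return SweepResult(rows=pd.DataFrame(rows))


def dedupe_against(
    reference: LabeledDataset,
    test: LabeledDataset,
    key: str = "guide",
) -> tuple[LabeledDataset, int]:
    """Remove test entries whose guide (or full window, ``key='sequence'``)
    appears in the reference dataset.  Returns (filtered, removed_count)."""
    if key not in ("guide", "sequence"):
        raise ValueError("key must be 'guide' or 'sequence'")
    ref_keys = set(reference.guides() if key == "guide" else
                   (s.upper() for s in reference.sequences))
    test_keys = test.guides() if key == "guide" else [s.upper() for s in test.sequences]
    keep = [i for i, g in enumerate(test_keys) if g not in ref_keys]
    removed = len(test) - len(keep)
    return test.subset(keep), removed


def evaluate_external(model: ActivityModel, dataset: LabeledDataset) -> float:
    """Spearman rank correlation between model predictions and the dataset's
    measured targets."""
    return spearman_rho(predict(model, dataset), dataset.targets)
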