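"""Seeded synthetic fixtures with the statistical structure the method assumes.

Everything here is a pure function of its seed: a planted additive (plus
sparse pairwise) sequence->activity function over 28-nt windows with
PAM-proximal dominance, paired induced/repressed count tables where
enrichment is monotone in activity, toxic guides depleted under both
conditions, growth curves for the phenotype classifier, and a
large/small dataset pair with a shared-but-shifted activity function for
transfer-learning tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity_scoring import INDUCED, REPRESSED, CountMatrix, GrowthRecord
from .guide_design import ONEHOT_ROWS, PROTOSPACER_LEN
from .model_core import LabeledDataset

WINDOW = 28  # protospacer (20) + PAM (3) + 5 downstream


# ---------------------------------------------------------------------------
# Planted sequence -> activity model
# ---------------------------------------------------------------------------

@dataclass
class PlantedModel:
    """Additive per-position contributions plus sparse pairwise epistasis.

    Protospacer positions are numbered 1 (PAM-proximal) to 20 (PAM-distal);
    PAM-proximal seed positions 1-10 are window indices 10..19.
    """

    position_weights: np.ndarray  # 4 x WINDOW
    pairwise_terms: list[tuple[tuple[int, int], tuple[int, int], float]] = field(
        default_factory=list
    )  # ((pos_i, base_i), (pos_j, base_j), weight) with window indices and base row ids
    noise_sd: float = 0.0
    seed: int = 0

    def activity(self, seq: str, rng: np.random.Generator | None = None) -> float:
        if len(seq) != self.position_weights.shape[1]:
            raise ValueError("sequence length does not match planted model")
        idx = [ONEHOT_ROWS.index(c) for c in seq]
        value = float(sum(self.position_weights[b, j] for j, b in enumerate(idx)))
        for (pi, bi), (pj, bj), w in self.pairwise_terms:
            if idx[pi] == bi and idx[pj] == bj:
                value += w
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            value += float(rng.normal(0.0, self.noise_sd))
        return value

    def activities(self, seqs: list[str], rng: np.random.Generator | None = None) -> np.ndarray:
        return np.array([self.activity(s, rng) for s in seqs])


SEED_REGION_WINDOW_IDX = range(PROTOSPACER_LEN - 10, PROTOSPACER_LEN)  # positions 1-10


def make_planted_model(
    seed: int,
    seed_region_boost: float = 2.0,
    n_pairwise: int = 15,
    noise_sd: float = 0.0,
    window: int = WINDOW,
    protospacer_pam_only: bool = False,
) -> PlantedModel:
    """Draw a planted model deterministically from ``seed``.

    PAM-proximal seed positions (protospacer positions 1-10) are scaled by
    ``seed_region_boost`` so mismatches there matter most.  With
    ``protospacer_pam_only`` the weights outside protospacer+PAM are zeroed
    (used by length-sweep oracles).
    """
    rng = np.random.default_rng(seed)
    weights = rng.normal(0.0, 1.0, size=(4, window))
    weights -= weights.mean(axis=0, keepdims=True)  # per-position zero mean
    for j in SEED_REGION_WINDOW_IDX:
        weights[:, j] *= seed_region_boost
    if protospacer_pam_only:
        weights[:, PROTOSPACER_LEN + 3:] = 0.0
    pairwise = []
    for _ in range(n_pairwise):
        pi, pj = rng.choice(window, size=2, replace=False)
        bi, bj = rng.integers(0, 4, size=2)
        pairwise.append(((int(pi), int(bi)), (int(pj), int(bj)), float(rng.normal(0.0, 0.5))))
    return PlantedModel(
        position_weights=weights, pairwise_terms=pairwise, noise_sd=noise_sd, seed=seed
    )


def random_windows(n: int, rng: np.random.Generator, window: int = WINDOW) -> list[str]:
    """Random target-site windows with a fixed NGG PAM at positions 21-23."""
    bases = np.array(list(ONEHOT_ROWS))
    seqs = []
    for _ in range(n):
        chars = bases[rng.integers(0, 4, size=window)]
        chars[PROTOSPACER_LEN + 1] = "G"
        chars[PROTOSPACER_LEN + 2] = "G"
        seqs.append("".join(chars))
    return seqs


def _unique_random_windows(n: int, rng: np.random.Generator, window: int = WINDOW) -> list[str]:
    seen: dict[str, None] = {}
    while len(seen) < n:
        for s in random_windows(n - len(seen), rng, window):
            seen.setdefault(s, None)
    return list(seen)


# ---------------------------------------------------------------------------
# Screen simulation
# ---------------------------------------------------------------------------

@dataclass
class SimScreen:
    guide_names: list[str]
    sequences: list[str]
    true_activity: np.ndarray
    toxicity: np.ndarray
    counts: CountMatrix

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "guide": self.guide_names,
                "sequence": self.sequences,
                "true_activity": self.true_activity,
                "toxicity": self.toxicity,
            }
        )


def simulate_screen(
    model: PlantedModel,
    n_guides: int = 1000,
    n_toxic: int = 0,
    depth: int = 1_000_000,
    reps: int = 10,
    seed: int = 0,
    gain: float = 1.0,
    bias_sd: float = 0.5,
) -> SimScreen:
    """Paired induced/repressed multinomial count tables.

    Repressed expected proportions follow a log-normal library-composition
    bias; induced proportions multiply in ``exp(gain * activity)`` so that
    enrichment is monotone in true activity among non-toxic guides.  Toxic
    guides have their expected proportions multiplied by ``(1 - toxicity)``
    in BOTH conditions.  Counts are multinomial per sample, so per-sample
    totals equal ``depth`` exactly.
    """
    if n_toxic >= n_guides:
        raise ValueError("n_toxic must be < n_guides")
    rng = np.random.default_rng(seed)
    seqs = _unique_random_windows(n_guides, rng, model.position_weights.shape[1])
    activity = model.activities(seqs, rng if model.noise_sd > 0 else None)
    activity = (activity - activity.mean()) / activity.std()

    toxicity = np.zeros(n_guides)
    if n_toxic:
        toxic_idx = rng.choice(n_guides, size=n_toxic, replace=False)
        toxicity[toxic_idx] = rng.uniform(0.7, 0.99, size=n_toxic)

    bias = np.exp(rng.normal(0.0, bias_sd, size=n_guides))
    w_rep = bias * (1.0 - toxicity)
    w_ind = bias * np.exp(gain * activity) * (1.0 - toxicity)
    p_rep = w_rep / w_rep.sum()
    p_ind = w_ind / w_ind.sum()
    if depth < 10 * n_guides:
        import warnings

        warnings.warn("depth may be too low to represent all guides", stacklevel=2)

    cols, cond, repl = [], [], []
    for condition, p in ((REPRESSED, p_rep), (INDUCED, p_ind)):
        for r in range(reps):
            cols.append(rng.multinomial(depth, p))
            cond.append(condition)
            repl.append(r + 1)
    names = [f"g{i:05d}" for i in range(n_guides)]
    cm = CountMatrix(
        guides=names,
        samples=[f"{c}_{r}" for c, r in zip(cond, repl)],
        counts=np.column_stack(cols),
        condition=cond,
        replicate=repl,
    )
    return SimScreen(
        guide_names=names,
        sequences=seqs,
        true_activity=activity,
        toxicity=toxicity,
        counts=cm,
    )


# ---------------------------------------------------------------------------
# Transfer-learning scenario
# ---------------------------------------------------------------------------

def make_transfer_scenario(
    model: PlantedModel,
    shift: float = 0.3,
    n_large: int = 40_000,
    n_small: int = 300,
    seed: int = 0,
    large_noise_sd: float = 1.0,
    small_noise_sd: float = 0.1,
) -> tuple[LabeledDataset, LabeledDataset]:
    """A large noisy dataset scored by ``model`` and a small clean dataset
    scored by a ``shift``-interpolated perturbation of it.

    The small-domain function is ``(1-shift) * model + shift * independent
    draw``; noise sds are relative to the activity sd of each dataset.  Both
    emitted target vectors are standardized to unit (sample) sd.
    """
    if not 0.0 <= shift <= 1.0:
        raise ValueError("shift must be in [0, 1]")
    rng = np.random.default_rng(seed)
    window = model.position_weights.shape[1]

    other = make_planted_model(seed=int(rng.integers(2**31)), window=window)
    shifted = PlantedModel(
        position_weights=(1.0 - shift) * model.position_weights
        + shift * other.position_weights,
        pairwise_terms=model.pairwise_terms,
        noise_sd=0.0,
        seed=model.seed,
    )

    def build(n: int, fn: PlantedModel, noise_rel: float, name: str) -> LabeledDataset:
        seqs = _unique_random_windows(n, rng, window)
        y = fn.activities(seqs)
        y = y + rng.normal(0.0, noise_rel * y.std(), size=n)
        y = y / y.std(ddof=1)
        return LabeledDataset(sequences=seqs, targets=y, name=name)

    large = build(n_large, model, large_noise_sd, "synthetic_large")
    small = build(n_small, shifted, small_noise_sd, "synthetic_small")
    return large, small


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

def simulate_growth(
    guide: str,
    activity: float,
    toxicity: float,
    timegrid: np.ndarray,
    seed: int = 0,
    noise_sd: float = 0.005,
) -> GrowthRecord:
    """Logistic OD600 curves: induced carrying capacity rises with activity,
    toxicity suppresses growth in both conditions."""
    t = np.asarray(timegrid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timegrid must be strictly increasing")
    rng = np.random.default_rng(seed)

    def logistic(k: float, rate: float, lag: float) -> np.ndarray:
        base = 0.02
        od = base + k / (1.0 + np.exp(-rate * (t - lag)))
        return np.clip(od + rng.normal(0.0, noise_sd, size=t.shape), 0.0, None)

    act = 1.0 / (1.0 + np.exp(-3.0 * (activity - 0.5)))  # squash to (0, 1)
    k_ind = 1.0 * act * (1.0 - toxicity)
    k_rep = 1.0 * (1.0 - toxicity)
    return GrowthRecord(
        guide=guide,
        time=t,
        od_induced=logistic(k_ind, 0.02, 300.0),
        od_repressed=logistic(k_rep, 0.02, 250.0),
    )


def simulate_growth_cohort(
    n_active: int,
    n_toxic: int,
    n_inactive: int,
    seed: int = 0,
    timegrid: np.ndarray | None = None,
) -> tuple[list[GrowthRecord], list[str]]:
    """Cohort with planted phenotype classes; returns (records, true_labels)."""
    if timegrid is None:
        timegrid = np.arange(0.0, 18 * 60 + 1, 10.0)
    rng = np.random.default_rng(seed)
    records, labels = [], []
    plan = [("active", 3.0, 0.0)] * n_active + [("toxic", 0.0, 1.0)] * n_toxic + [
        ("inactive", -3.0, 0.0)
    ] * n_inactive
    for i, (label, act, tox) in enumerate(plan):
        records.append(
            simulate_growth(f"g{i:03d}", act, tox, timegrid, seed=int(rng.integers(2**31)))
        )
        labels.append(label)
    return records, labels
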