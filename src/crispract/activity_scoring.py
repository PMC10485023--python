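"""Compositional activity scores from pooled-screen read counts.

Read counts from pooled guide screens are compositional: only relative
information survives sequencing.  Scores are therefore computed on centred
log-ratio (CLR) transformed Dirichlet Monte-Carlo instances of the count
table, yielding per-guide expected between-condition differences
(``diff_btw``), within-condition dispersions (``diff_win``), relative
abundances (``rab_all``), effect sizes, and Benjamini-Hochberg adjusted
q-values.  The standardized score (``diff_btw`` divided by the dataset
standard deviation) is the regression target used by
:mod:`crispract.model_core`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INDUCED = "induced"
REPRESSED = "repressed"
CONTROL_DEAD = "control_dead"
INITIAL_POOL = "initial_pool"

_VALID_CONDITIONS = {INDUCED, REPRESSED, CONTROL_DEAD, INITIAL_POOL}


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Non-negative integer guide x sample counts with sample annotations."""

    guides: list[str]
    samples: list[str]
    counts: np.ndarray
    condition: list[str]
    replicate: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.guides), len(self.samples)):
            raise ValueError("counts shape must be (n_guides, n_samples)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(self.guides) != len(set(self.guides)):
            raise ValueError("guide names must be unique")
        if len(self.condition) != len(self.samples) or len(self.replicate) != len(self.samples):
            raise ValueError("per-sample annotations must match samples")
        bad = set(self.condition) - _VALID_CONDITIONS
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    def sample_indices(self, condition: str) -> list[int]:
        return [j for j, c in enumerate(self.condition) if c == condition]

    def subset_guides(self, keep: Sequence[str]) -> "CountMatrix":
        keep_set = set(keep)
        idx = [i for i, g in enumerate(self.guides) if g in keep_set]
        return CountMatrix(
            guides=[self.guides[i] for i in idx],
            samples=list(self.samples),
            counts=self.counts[idx],
            condition=list(self.condition),
            replicate=list(self.replicate),
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=self.guides, columns=self.samples)
        df.index.name = "guide"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, condition: Sequence[str], replicate: Sequence[int]) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            guides=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            counts=df.to_numpy(dtype=np.int64),
            condition=list(condition),
            replicate=list(replicate),
        )


@dataclass
class ScoreTable:
    """Per-guide compositional statistics; all log-ratio values in log2 units."""

    guides: list[str]
    diff_btw: np.ndarray
    diff_win: np.ndarray
    rab_all: np.ndarray
    effect: np.ndarray
    q_value: np.ndarray
    std_score: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.guides)

    def subset(self, mask: np.ndarray) -> "ScoreTable":
        return ScoreTable(
            guides=[g for g, m in zip(self.guides, mask) if m],
            diff_btw=self.diff_btw[mask],
            diff_win=self.diff_win[mask],
            rab_all=self.rab_all[mask],
            effect=self.effect[mask],
            q_value=self.q_value[mask],
            std_score=None if self.std_score is None else self.std_score[mask],
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "guide": self.guides,
                "diff_btw": self.diff_btw,
                "diff_win": self.diff_win,
                "rab_all": self.rab_all,
                "effect": self.effect,
                "q_value": self.q_value,
            }
        )
        if self.std_score is not None:
            df["std_score"] = self.std_score
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class AmpliconDesign:
    """Layout of the sequencing amplicon: random prefix, replicate barcode,
    constant guide flank, then the 20-nt guide."""

    barcode_to_sample: dict[str, tuple[str, str, int]]  # barcode -> (sample, condition, replicate)
    guide_flank5: str
    random_prefix_len: int = 4
    barcode_len: int = 12
    guide_len: int = 20

    def __post_init__(self) -> None:
        if len(self.barcode_to_sample) != len(set(self.barcode_to_sample)):
            raise ValueError("duplicate barcodes")
        for bc in self.barcode_to_sample:
            if len(bc) != self.barcode_len:
                raise ValueError(f"barcode {bc!r} is not {self.barcode_len} nt")
        samples = [s for s, _, _ in self.barcode_to_sample.values()]
        if len(samples) != len(set(samples)):
            raise ValueError("duplicate sample ids across barcodes")


def demultiplex(reads: Iterable[str], design: AmpliconDesign, guides: Sequence[str]) -> tuple[CountMatrix, dict]:
    """Exact-match demultiplexing of amplicon reads into a CountMatrix.

    ``reads`` is an iterable of read sequences (use :func:`read_fastq` for
    FASTQ files).  Reads whose barcode or guide fails an exact match are
    tallied as discarded.  Returns ``(CountMatrix, report)``.
    """
    guide_index = {g: i for i, g in enumerate(guides)}
    if len(guide_index) != len(guides):
        raise ValueError("duplicate guides in pool")
    barcodes = design.barcode_to_sample
    samples = [s for s, _, _ in barcodes.values()]
    sample_index = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(guides), len(samples)), dtype=np.int64)
    discarded = {"bad_barcode": 0, "bad_guide": 0, "too_short": 0}

    bc_start = design.random_prefix_len
    bc_end = bc_start + design.barcode_len
    g_start = bc_end + len(design.guide_flank5)
    g_end = g_start + design.guide_len

    n_total = 0
    for read in reads:
        n_total += 1
        if len(read) < g_end:
            discarded["too_short"] += 1
            continue
        info = barcodes.get(read[bc_start:bc_end])
        if info is None or read[bc_end:g_start] != design.guide_flank5:
            discarded["bad_barcode"] += 1
            continue
        gi = guide_index.get(read[g_start:g_end])
        if gi is None:
            discarded["bad_guide"] += 1
            continue
        counts[gi, sample_index[info[0]]] += 1

    cm = CountMatrix(
        guides=list(guides),
        samples=samples,
        counts=counts,
        condition=[c for _, c, _ in barcodes.values()],
        replicate=[r for _, _, r in barcodes.values()],
    )
    report = {"total": n_total, "assigned": int(counts.sum()), **discarded}
    return cm, report


def read_fastq(path) -> Iterable[str]:
    """Yield read sequences from a FASTQ file (gz accepted)."""
    from Bio import SeqIO
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_low_counts(
    cm: CountMatrix, control_condition: str = CONTROL_DEAD, min_count: int = 20
) -> tuple[CountMatrix, list[str]]:
    """Drop guides with a read count strictly below ``min_count`` in ANY
    replicate of the control condition.  Returns (filtered, removed_guides)."""
    ctrl = cm.sample_indices(control_condition)
    if not ctrl:
        raise ValueError(f"no samples with condition {control_condition!r}")
    low = (cm.counts[:, ctrl] < min_count).any(axis=1)
    removed = [g for g, bad in zip(cm.guides, low) if bad]
    kept = [g for g, bad in zip(cm.guides, low) if not bad]
    return cm.subset_guides(kept), removed


def filter_high_variance(scores: ScoreTable, diff_win_max: float = 1.0) -> ScoreTable:
    """Drop guides with within-condition dispersion strictly above the cutoff."""
    return scores.subset(~(scores.diff_win > diff_win_max))


def significant_guides(
    scores: ScoreTable, fdr: float = 0.01, direction: str = "positive"
) -> set[str]:
    """Guides with q_value < fdr (and diff_btw > 0 when direction='positive')."""
    if direction not in ("positive", "any"):
        raise ValueError("direction must be 'positive' or 'any'")
    mask = scores.q_value < fdr
    if direction == "positive":
        mask &= scores.diff_btw > 0
    return {g for g, m in zip(scores.guides, mask) if m}


# ---------------------------------------------------------------------------
# CLR Monte-Carlo scoring
# ---------------------------------------------------------------------------

def _clr(proportions: np.ndarray) -> np.ndarray:
    """Centred log-ratio (log2) per column of a guides x samples matrix."""
    logp = np.log2(proportions)
    return logp - logp.mean(axis=0, keepdims=True)


def _pair_indices(a: Sequence[int], b: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = np.meshgrid(np.asarray(a), np.asarray(b), indexing="ij")
    return ia.ravel(), ib.ravel()


def _within_pairs(idx: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    n = len(idx)
    pairs = [(idx[i], idx[j]) for i in range(n) for j in range(i + 1, n)]
    if not pairs:
        return np.array([], dtype=int), np.array([], dtype=int)
    x, y = zip(*pairs)
    return np.asarray(x), np.asarray(y)


def clr_mc_scores(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int | None = None,
    test: str = "welch",
    _min_group: int = 2,
) -> ScoreTable:
    """Dirichlet Monte-Carlo CLR difference scores between two conditions.

    Per Monte-Carlo instance, each sample's guide proportions are drawn from
    Dirichlet(counts + prior) and CLR transformed; per guide the instance
    yields the median CLR difference over all between-group sample pairs
    (``diff_btw``, b minus a), the larger of the two within-group median
    absolute pairwise differences (``diff_win``), the median CLR over all
    samples (``rab_all``), their ratio (``effect``), and a BH-adjusted
    p-value (Welch's t by default, Wilcoxon rank-sum optional).  Reported
    statistics are expectations over instances.  Deterministic given seed.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible scoring")
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    if test not in ("welch", "wilcoxon"):
        raise ValueError("test must be 'welch' or 'wilcoxon'")
    ia_all = cm.sample_indices(group_a)
    ib_all = cm.sample_indices(group_b)
    if len(ia_all) < _min_group or len(ib_all) < _min_group:
        raise ValueError(
            f"need >= {_min_group} samples per group "
            f"({group_a}: {len(ia_all)}, {group_b}: {len(ib_all)})"
        )
    n_guides = len(cm.guides)
    if n_guides < 2:
        raise ValueError("need >= 2 guides")

    rng = np.random.default_rng(seed)
    used = ia_all + ib_all
    alpha = cm.counts[:, used].astype(np.float64) + prior
    # local indices within the used-sample submatrix
    la = list(range(len(ia_all)))
    lb = list(range(len(ia_all), len(used)))
    pa, pb = _pair_indices(la, lb)
    wa1, wa2 = _within_pairs(la)
    wb1, wb2 = _within_pairs(lb)

    acc = {k: np.zeros(n_guides) for k in ("diff_btw", "diff_win", "rab_all", "effect", "q")}
    for _ in range(n_instances):
        gamma = rng.standard_gamma(alpha)
        prop = gamma / gamma.sum(axis=0, keepdims=True)
        clr = _clr(prop)

        diff_btw = np.median(clr[:, pb] - clr[:, pa], axis=1)
        win_a = (
            np.median(np.abs(clr[:, wa1] - clr[:, wa2]), axis=1) if len(wa1) else np.zeros(n_guides)
        )
        win_b = (
            np.median(np.abs(clr[:, wb1] - clr[:, wb2]), axis=1) if len(wb1) else np.zeros(n_guides)
        )
        diff_win = np.maximum(win_a, win_b)
        rab = np.median(clr, axis=1)
        effect = diff_btw / np.maximum(diff_win, 1e-9)

        if test == "welch":
            import warnings as _warnings

            with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
                _warnings.simplefilter("ignore", RuntimeWarning)
                p = stats.ttest_ind(clr[:, lb], clr[:, la], axis=1, equal_var=False).pvalue
        else:
            p = np.array(
                [
                    stats.mannwhitneyu(clr[i, lb], clr[i, la], alternative="two-sided").pvalue
                    for i in range(n_guides)
                ]
            )
        p = np.nan_to_num(p, nan=1.0)
        q = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")

        acc["diff_btw"] += diff_btw
        acc["diff_win"] += diff_win
        acc["rab_all"] += rab
        acc["effect"] += effect
        acc["q"] += q

    inv = 1.0 / n_instances
    return ScoreTable(
        guides=list(cm.guides),
        diff_btw=acc["diff_btw"] * inv,
        diff_win=acc["diff_win"] * inv,
        rab_all=acc["rab_all"] * inv,
        effect=acc["effect"] * inv,
        q_value=np.clip(acc["q"] * inv, 0.0, 1.0),
        meta={
            "group_a": group_a,
            "group_b": group_b,
            "n_instances": n_instances,
            "prior": prior,
            "seed": seed,
            "test": test,
        },
    )


def clr_point_scores(cm: CountMatrix, group_a: str, group_b: str, prior: float = 0.5) -> ScoreTable:
    """Point-estimate variant of :func:`clr_mc_scores` (no Monte-Carlo):
    proportions are (counts + prior) / column sum.  Exactly invariant to
    per-sample sequencing depth; q-values are from a single Welch test."""
    ia = cm.sample_indices(group_a)
    ib = cm.sample_indices(group_b)
    if not ia or not ib:
        raise ValueError("both groups need at least one sample")
    used = ia + ib
    alpha = cm.counts[:, used].astype(np.float64) + prior
    prop = alpha / alpha.sum(axis=0, keepdims=True)
    clr = _clr(prop)
    la = list(range(len(ia)))
    lb = list(range(len(ia), len(used)))
    pa, pb = _pair_indices(la, lb)
    wa1, wa2 = _within_pairs(la)
    wb1, wb2 = _within_pairs(lb)
    n_guides = len(cm.guides)
    diff_btw = np.median(clr[:, pb] - clr[:, pa], axis=1)
    win_a = np.median(np.abs(clr[:, wa1] - clr[:, wa2]), axis=1) if len(wa1) else np.zeros(n_guides)
    win_b = np.median(np.abs(clr[:, wb1] - clr[:, wb2]), axis=1) if len(wb1) else np.zeros(n_guides)
    diff_win = np.maximum(win_a, win_b)
    if len(la) > 1 and len(lb) > 1:
        import warnings as _warnings

        with np.errstate(divide="ignore", invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(clr[:, lb], clr[:, la], axis=1, equal_var=False).pvalue
        p = np.nan_to_num(p, nan=1.0)
        q = stats.false_discovery_control(np.clip(p, 0.0, 1.0), method="bh")
    else:
        q = np.ones(n_guides)
    return ScoreTable(
        guides=list(cm.guides),
        diff_btw=diff_btw,
        diff_win=diff_win,
        rab_all=np.median(clr, axis=1),
        effect=diff_btw / np.maximum(diff_win, 1e-9),
        q_value=q,
        meta={"group_a": group_a, "group_b": group_b, "point_estimate": True, "prior": prior},
    )


def depletion_scores(
    cm_endpoint: CountMatrix,
    initial_pool: CountMatrix,
    endpoint_condition: str = INDUCED,
    n_instances: int = 128,
    prior: float = 0.5,
    seed: int | None = None,
    flip_sign: bool = False,
    test: str = "welch",
) -> ScoreTable:
    """Depletion-mode scoring: the initial sequencing pool stands in for the
    reference condition.

    The single initial-pool sample is replicated to satisfy the two-sample
    minimum (flagged in metadata).  Active guides deplete from the endpoint,
    so they receive negative ``diff_btw``; ``flip_sign=True`` returns the
    activity-increasing orientation.
    """
    if set(cm_endpoint.guides) != set(initial_pool.guides):
        only_e = sorted(set(cm_endpoint.guides) - set(initial_pool.guides))[:5]
        only_p = sorted(set(initial_pool.guides) - set(cm_endpoint.guides))[:5]
        raise ValueError(
            f"guide sets differ (endpoint-only e.g. {only_e}, pool-only e.g. {only_p})"
        )
    pool_idx = initial_pool.sample_indices(INITIAL_POOL) or list(range(len(initial_pool.samples)))
    order = {g: i for i, g in enumerate(initial_pool.guides)}
    pool_counts = initial_pool.counts[[order[g] for g in cm_endpoint.guides]][:, pool_idx]
    replicated = pool_counts if pool_counts.shape[1] >= 2 else np.repeat(pool_counts, 2, axis=1)

    end_idx = cm_endpoint.sample_indices(endpoint_condition)
    if not end_idx:
        raise ValueError(f"no endpoint samples with condition {endpoint_condition!r}")
    merged = CountMatrix(
        guides=list(cm_endpoint.guides),
        samples=[f"pool_{i}" for i in range(replicated.shape[1])]
        + [cm_endpoint.samples[j] for j in end_idx],
        counts=np.hstack([replicated, cm_endpoint.counts[:, end_idx]]),
        condition=[INITIAL_POOL] * replicated.shape[1] + [endpoint_condition] * len(end_idx),
        replicate=list(range(replicated.shape[1])) + [cm_endpoint.replicate[j] for j in end_idx],
    )
    scores = clr_mc_scores(
        merged,
        group_a=INITIAL_POOL,
        group_b=endpoint_condition,
        n_instances=n_instances,
        prior=prior,
        seed=seed,
        test=test,
    )
    scores.meta.update({"depletion_mode": True, "pool_replicated": pool_counts.shape[1] < 2,
                        "flip_sign": flip_sign})
    if flip_sign:
        scores = replace(scores, diff_btw=-scores.diff_btw, effect=-scores.effect)
    return scores


def standardize(scores: ScoreTable) -> ScoreTable:
    """Divide diff_btw by its dataset standard deviation (sample sd, ddof=1).

    Idempotent on ``std_score``: the standardized scores have unit sd.
    """
    if len(scores) < 2:
        raise ValueError("need >= 2 guides to standardize")
    sd = float(np.std(scores.diff_btw, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in diff_btw; cannot standardize")
    out = replace(scores, std_score=scores.diff_btw / sd)
    out.meta = {**scores.meta, "diff_btw_sd": sd}
    return out


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthRecord:
    """Paired induced/repressed OD600 time series for one guide."""

    guide: str
    time: np.ndarray  # minutes, shared grid, strictly increasing
    od_induced: np.ndarray
    od_repressed: np.ndarray
    auc_induced_norm: float | None = None
    auc_repressed_norm: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od_induced = np.asarray(self.od_induced, dtype=float)
        self.od_repressed = np.asarray(self.od_repressed, dtype=float)
        if len(self.time) < 2:
            raise ValueError("need >= 2 timepoints")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


def _auc(time: np.ndarray, od: np.ndarray) -> float:
    return float(np.trapezoid(od, time))


def classify_growth(
    cohort: list[GrowthRecord],
    active_thresh: float = 1.64,
    toxic_thresh: float = 0.121,
) -> list[GrowthRecord]:
    """Label each record by trapezoidal AUC normalized to the cohort mean.

    Per condition, ``auc_norm = AUC / mean(AUC over cohort)``.  A guide is
    ``active`` when its induced auc_norm exceeds ``active_thresh``.  Guides
    with induced auc_norm below ``toxic_thresh`` are ``toxic`` when the
    repressed condition also grew below the cohort mean, else ``inactive``.
    Everything else is ``intermediate``.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    auc_ind = np.array([_auc(r.time, r.od_induced) for r in cohort])
    auc_rep = np.array([_auc(r.time, r.od_repressed) for r in cohort])
    mean_ind, mean_rep = auc_ind.mean(), auc_rep.mean()
    if mean_ind <= 0 or mean_rep <= 0:
        raise ValueError("cohort mean AUC must be positive")
    out = []
    for rec, ai, ar in zip(cohort, auc_ind / mean_ind, auc_rep / mean_rep):
        if ai > active_thresh:
            label = "active"
        elif ai < toxic_thresh:
            label = "toxic" if ar < 1.0 else "inactive"
        else:
            label = "intermediate"
        out.append(
            replace(rec, auc_induced_norm=float(ai), auc_repressed_norm=float(ar), label=label)
        )
    return out
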