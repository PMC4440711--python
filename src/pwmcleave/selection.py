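"""Parameter selection and statistical evaluation.

The enzyme-specific *offset* (penalty for never-observed residues) and
*threshold* (decision cutoff) are free parameters.  They are chosen by an
exhaustive two-dimensional grid search under k-fold cross-validation at the
substrate level: for every grid cell the matrix is re-derived on each
fold's training substrates with that cell's offset and evaluated on the
held-out fold's labelled bonds with that cell's threshold; the cell with
the maximal mean F1 across folds wins.

A window score is linear in the offset — it is the sum of the log2 ratios
of its nonzero-frequency cells plus (number of zero-frequency cells) x
offset — so each fold's frequencies are derived once and the whole grid is
evaluated by vectorised arithmetic.  This is an exact reformulation of the
per-cell re-derivation, not an approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats
from sklearn import metrics as _skl_metrics

from .alphabet import WINDOW_SIZE, encode
from .errors import InputError
from .io import BackgroundSet, SubstrateRecord
from .pwm import PWM, FrequencyMatrix, build_pwm, compute_frequencies, full_window_positions

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "MetricSet",
    "GridResult",
    "ProteinSubstrate",
    "LabeledBond",
    "split_train_test",
    "kfold_partition",
    "compute_metrics",
    "grid_search_cv",
    "train_final_model",
    "evaluate_peptides",
    "roc_auc",
    "ks_separation",
    "sample_protein_negatives",
    "score_labeled_bonds",
    "evaluate_proteins",
    "refine_cleavage_positions",
]

_COLS = np.arange(WINDOW_SIZE)


def _default_offsets() -> tuple[float, ...]:
    return tuple(np.round(np.arange(-8.0, -0.9, 0.5), 6))


def _default_thresholds() -> tuple[float, ...]:
    return tuple(np.round(np.arange(-2.0, 3.05, 0.1), 6))


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation and grid-search settings.

    The default grids (thresholds -2.0..3.0 step 0.1, offsets -8.0..-1.0
    step 0.5, in log2 units) bracket the optima reported for all eleven
    MMPs.  ``split_fraction`` is the train share of the 2:1 internal-test
    split.  One integer seed drives every random choice.
    """

    k_folds: int = 10
    grid_offsets: tuple[float, ...] = field(default_factory=_default_offsets)
    grid_thresholds: tuple[float, ...] = field(default_factory=_default_thresholds)
    seed: int = 0
    split_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise InputError("k_folds must be >= 2")
        if not self.grid_offsets or not self.grid_thresholds:
            raise InputError("grids must be non-empty")
        if list(self.grid_offsets) != sorted(self.grid_offsets):
            raise InputError("grid_offsets must be sorted")
        if list(self.grid_thresholds) != sorted(self.grid_thresholds):
            raise InputError("grid_thresholds must be sorted")
        if not 0.0 < self.split_fraction < 1.0:
            raise InputError("split_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class MetricSet:
    """Confusion-derived statistics for one evaluation.

    Rates with a zero denominator are reported as 0.0 and recorded in
    ``flagged`` so downstream averaging can exclude them knowingly.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    fpr: float
    mcc: float
    f1: float
    flagged: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "fpr": self.fpr, "mcc": self.mcc, "f1": self.f1,
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricSet:
    """Standard confusion-table statistics (TPR, FPR, precision, accuracy,
    specificity, MCC, F1).

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)).
    """
    if min(tp, fp, tn, fn) < 0:
        raise InputError("confusion counts must be non-negative")
    flagged: set[str] = set()

    def _rate(num: float, den: float, name: str) -> float:
        if den == 0:
            flagged.add(name)
            return 0.0
        return num / den

    sensitivity = _rate(tp, tp + fn, "sensitivity")
    specificity = _rate(tn, tn + fp, "specificity")
    accuracy = _rate(tp + tn, tp + fp + tn + fn, "accuracy")
    precision = _rate(tp, tp + fp, "precision")
    fpr = _rate(fp, fp + tn, "fpr")
    mcc_den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flagged.add("mcc")
        mcc = 0.0
    else:
        mcc = (float(tp) * tn - float(fp) * fn) / mcc_den
    if 2 * tp + fp + fn == 0:
        flagged.add("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    return MetricSet(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        sensitivity=sensitivity, specificity=specificity, accuracy=accuracy,
        precision=precision, fpr=fpr, mcc=mcc, f1=f1, flagged=frozenset(flagged),
    )


def split_train_test(
    substrates: Sequence[SubstrateRecord], fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[list[SubstrateRecord], list[SubstrateRecord]]:
    """Random substrate-level split into train/test at the given train share."""
    if len(substrates) < 3:
        raise InputError("need at least 3 substrates to split")
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(substrates))
    n_train = int(round(fraction * len(substrates)))
    n_train = min(max(n_train, 1), len(substrates) - 1)
    train = [substrates[i] for i in sorted(order[:n_train])]
    test = [substrates[i] for i in sorted(order[n_train:])]
    return train, test


def kfold_partition(
    substrates: Sequence[SubstrateRecord], k: int = 10, seed: int = 0
) -> list[list[SubstrateRecord]]:
    """Random substrate-level partition into k folds with sizes differing by <= 1.

    Splitting whole substrates (not bonds) keeps a peptide's positive and
    negative bonds in the same fold.
    """
    n = len(substrates)
    if n < k:
        raise InputError(f"cannot make {k} folds from {n} substrates")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [[substrates[i] for i in sorted(chunk)] for chunk in np.array_split(order, k)]


# --------------------------------------------------------------------------
# Grid-search cross-validation
# --------------------------------------------------------------------------


def _bond_features(
    freq: FrequencyMatrix, substrates: Sequence[SubstrateRecord]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bond (base score, zero-cell count, label) for offset-linear scoring."""
    Pb = freq.background_matrix
    with np.errstate(divide="ignore"):
        ratio = np.log2(freq.P / Pb)
    L = np.where(freq.P > 0, ratio, 0.0)
    Z = (freq.P == 0).astype(float)
    base: list[float] = []
    zeros: list[float] = []
    labels: list[bool] = []
    for rec in substrates:
        enc = encode(rec.sequence)
        for p1 in full_window_positions(len(rec.sequence)):
            idx = enc[p1 - 3 : p1 + 2]
            if (idx < 0).any():
                continue
            base.append(float(L[idx, _COLS].sum()))
            zeros.append(float(Z[idx, _COLS].sum()))
            labels.append(p1 == rec.cleavage_index and rec.has_full_window)
    return np.asarray(base), np.asarray(zeros), np.asarray(labels, dtype=bool)


@dataclass(frozen=True)
class GridResult:
    """Outcome of the offset x threshold grid search under k-fold CV."""

    enzyme: str
    best_offset: float
    best_threshold: float
    f1_grid: pd.DataFrame  # mean F1, index=offsets, columns=thresholds
    fold_metrics: tuple[MetricSet, ...]  # per unflagged fold, at the optimum
    summary: pd.DataFrame  # mean and sample sd of each metric across folds
    flagged_folds: tuple[int, ...]
    config: CVConfig

    @property
    def best_mean_f1(self) -> float:
        return float(self.f1_grid.loc[self.best_offset, self.best_threshold])


_RATE_NAMES = ("sensitivity", "specificity", "accuracy", "precision", "mcc", "fpr", "f1")


def _summarise_folds(fold_metrics: Sequence[MetricSet]) -> pd.DataFrame:
    rows = {}
    for name in _RATE_NAMES:
        values = [m.as_dict()[name] for m in fold_metrics if name not in m.flagged]
        if not values:
            rows[name] = (float("nan"), float("nan"))
            continue
        mean = float(np.mean(values))
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        rows[name] = (mean, sd)
    return pd.DataFrame(rows, index=["mean", "sd"]).T


def grid_search_cv(
    substrates: Sequence[SubstrateRecord],
    background: BackgroundSet,
    config: CVConfig | None = None,
    enzyme: str | None = None,
) -> GridResult:
    """Select offset and threshold by maximal mean F1 under k-fold CV.

    Ties at the maximal mean F1 are broken toward the higher threshold and
    then the larger (less negative) offset — the more conservative model.
    Folds with zero positive bonds are flagged and excluded from averaging.
    """
    config = config or CVConfig()
    if enzyme is None:
        enzyme = substrates[0].enzyme if substrates else "enzyme"
    folds = kfold_partition(substrates, config.k_folds, config.seed)
    offsets = np.asarray(config.grid_offsets, dtype=float)
    thresholds = np.asarray(config.grid_thresholds, dtype=float)

    fold_f1: list[np.ndarray] = []  # each (n_off, n_thr)
    fold_feats: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    flagged_folds: list[int] = []
    for fi, fold in enumerate(folds):
        train = [s for fj, f in enumerate(folds) if fj != fi for s in f]
        freq = compute_frequencies(train, background)
        base, zeros, labels = _bond_features(freq, fold)
        fold_feats.append((base, zeros, labels))
        if not labels.any():
            flagged_folds.append(fi)
            logger.warning("fold %d has zero positive bonds; flagged", fi)
            continue
        scores = base[None, :] + zeros[None, :] * offsets[:, None]  # (n_off, nb)
        pred = scores[:, None, :] >= thresholds[None, :, None]  # (n_off, n_thr, nb)
        tp = (pred & labels).sum(axis=2)
        fp = (pred & ~labels).sum(axis=2)
        fn = labels.sum() - tp
        denom = 2 * tp + fp + fn
        with np.errstate(invalid="ignore", divide="ignore"):
            f1 = np.where(denom > 0, 2.0 * tp / denom, 0.0)
        fold_f1.append(f1)

    if not fold_f1:
        raise InputError("all folds flagged: no fold contains a positive bond")
    mean_f1 = np.mean(fold_f1, axis=0)

    best = mean_f1.max()
    oi_cand, ti_cand = np.nonzero(mean_f1 == best)
    # conservative tie-break: highest threshold first, then largest offset
    pick = max(range(len(oi_cand)), key=lambda k: (ti_cand[k], oi_cand[k]))
    best_offset = float(offsets[oi_cand[pick]])
    best_threshold = float(thresholds[ti_cand[pick]])

    fold_metrics: list[MetricSet] = []
    for fi, (base, zeros, labels) in enumerate(fold_feats):
        if fi in flagged_folds:
            continue
        scores = base + zeros * best_offset
        pred = scores >= best_threshold
        tp = int((pred & labels).sum())
        fp = int((pred & ~labels).sum())
        fn = int((~pred & labels).sum())
        tn = int((~pred & ~labels).sum())
        fold_metrics.append(compute_metrics(tp, fp, tn, fn))

    return GridResult(
        enzyme=enzyme,
        best_offset=best_offset,
        best_threshold=best_threshold,
        f1_grid=pd.DataFrame(mean_f1, index=offsets, columns=thresholds),
        fold_metrics=tuple(fold_metrics),
        summary=_summarise_folds(fold_metrics),
        flagged_folds=tuple(flagged_folds),
        config=config,
    )


def train_final_model(
    substrates: Sequence[SubstrateRecord],
    background: BackgroundSet,
    config: CVConfig | None = None,
    enzyme: str | None = None,
) -> tuple[PWM, GridResult]:
    """Grid-search CV, then rebuild the matrix on all substrates at the optimum."""
    result = grid_search_cv(substrates, background, config, enzyme)
    freq = compute_frequencies(substrates, background)
    pwm = build_pwm(freq, result.best_offset, result.best_threshold, result.enzyme)
    return pwm, result


def evaluate_peptides(pwm: PWM, substrates: Sequence[SubstrateRecord]) -> MetricSet:
    """Confusion metrics of the PWM's threshold rule over labelled peptide bonds."""
    from .pwm import classify_bonds

    scores, labels = classify_bonds(pwm, substrates)
    if len(scores) == 0 or labels.all() or not labels.any():
        raise InputError("evaluation needs both positive and negative bonds")
    pred = scores >= pwm.threshold
    return compute_metrics(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )


# --------------------------------------------------------------------------
# ROC / KS
# --------------------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep and its area.

    The area equals the Mann–Whitney pair statistic (ties counted 1/2).
    Returns ``(points, auc)`` where ``points`` is an (n, 2) array of
    (FPR, TPR) pairs.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InputError("ROC needs both classes present")
    fpr, tpr, _ = _skl_metrics.roc_curve(labels, scores)
    auc = float(_skl_metrics.roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def ks_separation(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Two-sample Kolmogorov–Smirnov D: max absolute ECDF difference."""
    scores_pos = np.asarray(scores_pos, dtype=float)
    scores_neg = np.asarray(scores_neg, dtype=float)
    if len(scores_pos) == 0 or len(scores_neg) == 0:
        raise InputError("KS needs two non-empty samples")
    return float(_scipy_stats.ks_2samp(scores_pos, scores_neg).statistic)


# --------------------------------------------------------------------------
# Protein-level evaluation with sampled negatives
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinSubstrate:
    """A protein with its experimentally annotated P1 cleavage positions."""

    sequence_id: str
    sequence: str
    cleavage_positions: tuple[int, ...]


@dataclass(frozen=True)
class LabeledBond:
    protein_index: int
    p1_position: int
    label: bool


def sample_protein_negatives(
    proteins: Sequence[ProteinSubstrate], ratio: int = 100, seed: int = 0
) -> list[LabeledBond]:
    """Positives = annotated full-window bonds; negatives sampled 1:``ratio``.

    Negatives are drawn without replacement from the pooled non-annotated
    full-window bonds of the same proteins.  If the pool is smaller than
    ``ratio`` x positives, all of it is used (with a warning).
    """
    positives: list[LabeledBond] = []
    pool: list[LabeledBond] = []
    for pi, prot in enumerate(proteins):
        annotated = set(prot.cleavage_positions)
        for p1 in full_window_positions(len(prot.sequence)):
            if p1 in annotated:
                positives.append(LabeledBond(pi, p1, True))
            else:
                pool.append(LabeledBond(pi, p1, False))
        if not annotated:
            logger.warning("protein %s has no annotated cleavage", prot.sequence_id)
    if not positives:
        raise InputError("no annotated cleavage position carries a full window")
    n_neg = ratio * len(positives)
    rng = np.random.default_rng(seed)
    if n_neg >= len(pool):
        if n_neg > len(pool):
            logger.warning(
                "negative pool (%d) smaller than requested %d; using all", len(pool), n_neg
            )
        sampled = pool
    else:
        take = rng.choice(len(pool), size=n_neg, replace=False)
        sampled = [pool[i] for i in sorted(take)]
    return positives + sampled


def score_labeled_bonds(
    pwm: PWM, proteins: Sequence[ProteinSubstrate], bonds: Sequence[LabeledBond]
) -> tuple[np.ndarray, np.ndarray]:
    """Score each labelled bond; bonds with unscorable windows are dropped."""
    scores: list[float] = []
    labels: list[bool] = []
    enc_cache = [encode(p.sequence) for p in proteins]
    for bond in bonds:
        enc = enc_cache[bond.protein_index]
        idx = enc[bond.p1_position - 3 : bond.p1_position + 2]
        if (idx < 0).any():
            continue
        scores.append(float(pwm.matrix[idx, _COLS].sum()))
        labels.append(bond.label)
    return np.asarray(scores), np.asarray(labels, dtype=bool)


def evaluate_proteins(
    pwm: PWM,
    proteins: Sequence[ProteinSubstrate],
    ratio: int = 100,
    seed: int = 0,
) -> dict:
    """Protein-level evaluation: confusion metrics at the PWM threshold,
    ROC/AUC over the sampled bonds, and the KS D between class score
    distributions."""
    bonds = sample_protein_negatives(proteins, ratio=ratio, seed=seed)
    scores, labels = score_labeled_bonds(pwm, proteins, bonds)
    if labels.all() or not labels.any():
        raise InputError("protein evaluation needs both classes after scoring")
    pred = scores >= pwm.threshold
    metrics = compute_metrics(
        tp=int((pred & labels).sum()),
        fp=int((pred & ~labels).sum()),
        tn=int((~pred & ~labels).sum()),
        fn=int((~pred & labels).sum()),
    )
    points, auc = roc_auc(scores, labels)
    d = ks_separation(scores[labels], scores[~labels])
    return {
        "metrics": metrics,
        "roc_points": points,
        "auc": auc,
        "ks_d": d,
        "scores": scores,
        "labels": labels,
    }


# --------------------------------------------------------------------------
# Cleavage-position refinement
# --------------------------------------------------------------------------


def refine_cleavage_positions(
    pwm: PWM,
    records: Sequence[SubstrateRecord],
    max_shift: int = 4,
) -> tuple[list[SubstrateRecord], int]:
    """Reassign below-threshold reported sites to nearby above-threshold bonds.

    Experimentally reported cleavage positions can be off by a few bonds.
    If a reported bond scores below the threshold and some bond within
    ``max_shift`` bonds scores at or above it, the record is reassigned to
    the highest-scoring such bond (ties to the smaller shift, then the
    N-terminal side); otherwise it is kept.  Returns the corrected records
    and the number reassigned.
    """
    from dataclasses import replace

    corrected: list[SubstrateRecord] = []
    n_moved = 0
    for rec in records:
        enc = encode(rec.sequence)
        valid = full_window_positions(len(rec.sequence))

        def _score_at(p1: int) -> float | None:
            if p1 not in valid:
                return None
            idx = enc[p1 - 3 : p1 + 2]
            if (idx < 0).any():
                return None
            return float(pwm.matrix[idx, _COLS].sum())

        own = _score_at(rec.cleavage_index)
        if own is not None and own >= pwm.threshold:
            corrected.append(rec)
            continue
        candidates: list[tuple[float, int, int]] = []  # (score, |shift|, p1)
        for shift in range(-max_shift, max_shift + 1):
            if shift == 0:
                continue
            p1 = rec.cleavage_index + shift
            s = _score_at(p1)
            if s is not None and s >= pwm.threshold:
                candidates.append((s, abs(shift), p1))
        if candidates:
            candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
            corrected.append(replace(rec, cleavage_index=candidates[0][2]))
            n_moved += 1
        else:
            corrected.append(rec)
    return corrected, n_moved
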