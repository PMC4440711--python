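"""Deriving and applying position weight matrices for protease cleavage.

The model: substrates selected by an enzyme from a phage-display library are
aligned on their scissile bonds, and per-position residue frequencies over
the P3–P2′ window are normalised by the residue composition of an unselected
background library.  Each matrix cell is the log2 of that
foreground/background ratio.  A candidate bond's score is the sum of the
five cells its window selects; where a residue was never observed at a
position in training the cell holds a fixed *offset* penalty instead of
log2(0).  A bond is predicted cleaved when its score reaches the
enzyme-specific *threshold*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, WINDOW_SIZE, encode
from .errors import (
    BackgroundCoverageError,
    DegenerateMatrixError,
    InputError,
    UnscorableWindowError,
)
from .io import BackgroundSet, SubstrateRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FrequencyMatrix",
    "PWM",
    "ScoredSite",
    "compute_frequencies",
    "build_pwm",
    "score_window",
    "scan_sequence",
    "classify_bonds",
    "full_window_positions",
    "context10",
]

_COLS = np.arange(WINDOW_SIZE)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Foreground P3–P2′ frequencies and background residue composition.

    ``P[i, j]`` is the relative frequency of residue ``AMINO_ACIDS[i]`` at
    window position ``j`` among the ``n_substrates`` substrates that carry a
    full window.  ``Pbckgr`` is either a 20-vector (pooled composition,
    broadcast to all columns) or a 20x5 table (positional mode).
    """

    P: np.ndarray
    n_substrates: int
    Pbckgr: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.P.shape != (20, WINDOW_SIZE):
            raise InputError(f"P must be 20x{WINDOW_SIZE}, got {self.P.shape}")
        if self.Pbckgr.shape not in ((20,), (20, WINDOW_SIZE)):
            raise InputError(f"Pbckgr must be (20,) or (20, {WINDOW_SIZE})")
        if not np.allclose(self.P.sum(axis=0), 1.0, atol=1e-9):
            raise InputError("foreground columns must each sum to 1")
        if (self.P < 0).any() or (self.P > 1).any():
            raise InputError("frequencies must lie in [0, 1]")
        if (self.Pbckgr <= 0).any():
            raise BackgroundCoverageError("background frequencies must be strictly positive")

    @property
    def background_matrix(self) -> np.ndarray:
        """Background frequencies broadcast to the full 20x5 shape."""
        if self.Pbckgr.ndim == 1:
            return np.repeat(self.Pbckgr[:, None], WINDOW_SIZE, axis=1)
        return self.Pbckgr


@dataclass(frozen=True)
class PWM:
    """A 20x5 log2 foreground/background matrix with its decision parameters.

    Cells where the foreground frequency was zero hold ``offset`` exactly.
    ``score_min``/``score_max`` are the minimal and maximal achievable
    window scores (sums of per-column extrema); they anchor the [0, 1]
    normalisation used by the virtual-mass-spectrum intensities.
    """

    enzyme: str
    matrix: np.ndarray
    offset: float
    threshold: float

    def __post_init__(self) -> None:
        if self.matrix.shape != (20, WINDOW_SIZE):
            raise InputError(f"matrix must be 20x{WINDOW_SIZE}, got {self.matrix.shape}")
        if not np.isfinite(self.matrix).all():
            raise InputError("matrix cells must be finite")

    @property
    def score_min(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def score_max(self) -> float:
        return float(self.matrix.max(axis=0).sum())

    def column_argmax(self) -> str:
        """Highest-scoring residue at each window position (the learned motif)."""
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=0))


@dataclass(frozen=True)
class ScoredSite:
    """One scored peptide bond; P1 sits at 1-based residue ``p1_position``."""

    sequence_id: str
    p1_position: int
    window: str
    context10: str
    score: float
    above_threshold: bool


def full_window_positions(seq_len: int) -> range:
    """1-based P1 positions whose bonds carry a full P3–P2′ window."""
    return range(3, seq_len - 1)


def context10(sequence: str, p1_position: int) -> str:
    """10 residues around the bond (5 each side), '-'-padded at termini."""
    p = p1_position
    left = sequence[max(0, p - 5) : p]
    right = sequence[p : p + 5]
    return left.rjust(5, "-") + right.ljust(5, "-")


def compute_frequencies(
    substrates: Sequence[SubstrateRecord],
    background: BackgroundSet,
    positional_window_start: int | None = None,
) -> FrequencyMatrix:
    """Count aligned P3–P2′ residue frequencies and the background composition.

    Substrates whose annotated bond lacks a full window are excluded (and
    counted in ``n_excluded``).  By default the background is the pooled,
    position-independent residue composition of the whole background set;
    passing ``positional_window_start`` (0-based index of the P3 column
    within each background peptide) switches to per-position composition
    over that fixed window, for scaffolds where all background peptides
    share a layout.
    """
    usable = [s for s in substrates if s.has_full_window]
    n_excluded = len(substrates) - len(usable)
    if n_excluded:
        logger.info("excluded %d substrates lacking a full P3-P2' window", n_excluded)
    if not usable:
        raise InputError("no substrates with a full P3-P2' window")

    counts = np.zeros((20, WINDOW_SIZE), dtype=float)
    for rec in usable:
        idx = encode(rec.window)
        counts[idx, _COLS] += 1.0
    P = counts / len(usable)

    if positional_window_start is None:
        bg_counts = np.zeros(20, dtype=float)
        for pep in background.peptides:
            idx = encode(pep)
            bg_counts += np.bincount(idx, minlength=20)
        if (bg_counts == 0).any():
            missing = [AMINO_ACIDS[i] for i in np.flatnonzero(bg_counts == 0)]
            raise BackgroundCoverageError(
                f"background coverage: residues never observed: {missing}"
            )
        Pbckgr = bg_counts / bg_counts.sum()
    else:
        j0 = positional_window_start
        bg_counts = np.zeros((20, WINDOW_SIZE), dtype=float)
        for pep in background.peptides:
            if len(pep) < j0 + WINDOW_SIZE:
                raise InputError(
                    f"background peptide {pep!r} too short for positional window at {j0}"
                )
            idx = encode(pep[j0 : j0 + WINDOW_SIZE])
            bg_counts[idx, _COLS] += 1.0
        if (bg_counts == 0).any():
            raise BackgroundCoverageError(
                "background coverage: some residue/position never observed in positional mode"
            )
        Pbckgr = bg_counts / bg_counts.sum(axis=0, keepdims=True)

    return FrequencyMatrix(P=P, n_substrates=len(usable), Pbckgr=Pbckgr, n_excluded=n_excluded)


def build_pwm(
    freq: FrequencyMatrix,
    offset: float,
    threshold: float = 0.0,
    enzyme: str = "enzyme",
) -> PWM:
    """Turn frequencies into the log2 scoring matrix.

    ``M[i, j] = log2(P[i, j] / Pbckgr[i, j])`` where the foreground
    frequency is positive, and exactly ``offset`` where it is zero.  A
    matrix whose minimal and maximal achievable scores coincide carries no
    information and is rejected.
    """
    Pb = freq.background_matrix
    with np.errstate(divide="ignore"):
        ratio = np.log2(freq.P / Pb)
    M = np.where(freq.P > 0, ratio, float(offset))
    if not np.isfinite(M).all():
        raise InputError("non-finite PWM cell (zero background frequency)")
    pwm = PWM(enzyme=enzyme, matrix=M, offset=float(offset), threshold=float(threshold))
    if pwm.score_min >= pwm.score_max:
        raise DegenerateMatrixError(
            "degenerate PWM: score_min == score_max (foreground matches background exactly)"
        )
    return pwm


def score_window(pwm: PWM, window: str) -> float:
    """Score one P3–P2′ window: the sum of the five selected matrix cells."""
    if len(window) != WINDOW_SIZE:
        raise InputError(f"window must have length {WINDOW_SIZE}, got {window!r}")
    idx = encode(window)
    if (idx < 0).any():
        bad = window[int(np.flatnonzero(idx < 0)[0])]
        raise UnscorableWindowError(f"unscorable window {window!r}: nonstandard residue {bad!r}")
    return float(pwm.matrix[idx, _COLS].sum())


def scan_sequence(pwm: PWM, sequence: str, sequence_id: str = "seq") -> list[ScoredSite]:
    """Score every bond with a full, scorable window; ordered by position.

    Windows containing nonstandard residues (X, B, Z, U, ...) are skipped
    with a logged warning.  Sequences shorter than 5 residues yield an
    empty result.
    """
    sequence = sequence.upper()
    if len(sequence) < WINDOW_SIZE:
        logger.warning("sequence %s shorter than %d residues: no scorable bond",
                       sequence_id, WINDOW_SIZE)
        return []
    enc = encode(sequence)
    sites: list[ScoredSite] = []
    n_skipped = 0
    for p1 in full_window_positions(len(sequence)):
        idx = enc[p1 - 3 : p1 + 2]
        if (idx < 0).any():
            n_skipped += 1
            continue
        score = float(pwm.matrix[idx, _COLS].sum())
        sites.append(
            ScoredSite(
                sequence_id=sequence_id,
                p1_position=p1,
                window=sequence[p1 - 3 : p1 + 2],
                context10=context10(sequence, p1),
                score=score,
                above_threshold=score >= pwm.threshold,
            )
        )
    if n_skipped:
        logger.warning("sequence %s: skipped %d windows with nonstandard residues",
                       sequence_id, n_skipped)
    return sites


def classify_bonds(
    pwm: PWM, substrates: Sequence[SubstrateRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Label every scorable bond of every substrate against its annotation.

    The annotated bond is the positive; every other full-window bond of the
    same peptide (constant flanks included) is a negative.  A substrate
    whose annotated bond lacks a full window contributes negatives only.
    Returns parallel arrays ``(scores, labels)`` with boolean labels.
    """
    scores: list[float] = []
    labels: list[bool] = []
    for rec in substrates:
        enc = encode(rec.sequence)
        if not rec.has_full_window:
            logger.info("substrate %r: annotated bond lacks a full window; negatives only",
                        rec.sequence)
        for p1 in full_window_positions(len(rec.sequence)):
            idx = enc[p1 - 3 : p1 + 2]
            if (idx < 0).any():
                continue
            scores.append(float(pwm.matrix[idx, _COLS].sum()))
            labels.append(p1 == rec.cleavage_index and rec.has_full_window)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=bool)
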