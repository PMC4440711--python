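"""Synthetic phage-display-like substrate and background sets.

Phage substrates are peptides with constant flanks around a variable
hexamer, e.g. ``ggsgPSA-LDAtasgaet``: lowercase = constant scaffold,
uppercase = variable region, dash = scissile bond.  The generator plants a
cleavage motif by drawing the five P3–P2′ residues of the designated bond
from per-position probability vectors, leaving the remaining variable
residues uniform; background peptides carry a motif-free variable region in
the same scaffold.  With the defaults the designated bond sits between
hexamer positions 3 and 4, mirroring the experimental construct, and the
set sizes (300 substrates, 766 background peptides) match the study's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .alphabet import AA_INDEX, AMINO_ACIDS, WINDOW_SIZE
from .errors import InputError
from .io import BackgroundSet, SubstrateRecord
from .selection import ProteinSubstrate

__all__ = [
    "MotifSpec",
    "deterministic_motif",
    "peaked_motif",
    "uniform_motif",
    "generate_substrates",
    "generate_background",
    "generate_proteins",
    "write_motif_config",
]


def deterministic_motif(window: str) -> np.ndarray:
    """One-hot column distributions planting the given P3–P2′ residues."""
    if len(window) != WINDOW_SIZE:
        raise InputError(f"motif window must have length {WINDOW_SIZE}")
    columns = np.zeros((WINDOW_SIZE, 20))
    for j, aa in enumerate(window.upper()):
        if aa not in AA_INDEX:
            raise InputError(f"nonstandard residue {aa!r} in motif window")
        columns[j, AA_INDEX[aa]] = 1.0
    return columns


def peaked_motif(window: str, weight: float = 0.7) -> np.ndarray:
    """Columns with probability ``weight`` on the planted residue, rest uniform."""
    if not 0.0 < weight <= 1.0:
        raise InputError("weight must lie in (0, 1]")
    columns = deterministic_motif(window) * weight
    columns += (1.0 - weight) / 19.0 * (1.0 - deterministic_motif(window))
    return columns


def uniform_motif() -> np.ndarray:
    """Motif-free columns: every residue equally likely (null model)."""
    return np.full((WINDOW_SIZE, 20), 1.0 / 20.0)


@dataclass(frozen=True)
class MotifSpec:
    """Parameters of the synthetic phage construct.

    ``columns`` is a 5x20 table of per-position residue probabilities for
    the P3–P2′ window of the designated bond.  ``bond_offset`` is the
    number of hexamer residues preceding the bond; with the default flanks
    the full window must fit inside the variable region, so
    ``3 <= bond_offset <= hexamer_len - 2``.
    """

    columns: np.ndarray
    flank_n: str = "ggsg"
    flank_c: str = "tasgaet"
    hexamer_len: int = 6
    bond_offset: int = 3
    n_substrates: int = 300
    n_background: int = 766
    seed: int = 0

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        object.__setattr__(self, "columns", cols)
        if cols.shape != (WINDOW_SIZE, 20):
            raise InputError(f"columns must be {WINDOW_SIZE}x20, got {cols.shape}")
        if (cols < 0).any():
            raise InputError("column probabilities must be non-negative")
        if not np.allclose(cols.sum(axis=1), 1.0, atol=1e-9):
            raise InputError("each motif column must sum to 1 (zero-probability column?)")
        for flank in (self.flank_n, self.flank_c):
            if any(aa not in AA_INDEX for aa in flank.upper()):
                raise InputError(f"flank {flank!r} is not in the 20-letter alphabet")
        if self.n_substrates < 0 or self.n_background < 0:
            raise InputError("counts must be >= 0")
        if not 3 <= self.bond_offset <= self.hexamer_len - 2:
            raise InputError(
                "designated bond must leave a full P3-P2' window inside the hexamer "
                f"(3 <= bond_offset <= {self.hexamer_len - 2})"
            )

    @property
    def cleavage_index(self) -> int:
        return len(self.flank_n) + self.bond_offset

    @property
    def peptide_length(self) -> int:
        return len(self.flank_n) + self.hexamer_len + len(self.flank_c)

    @property
    def window_start(self) -> int:
        """0-based index of the P3 residue within the whole peptide."""
        return self.cleavage_index - 3


def _draw_hexamer(spec: MotifSpec, rng: np.random.Generator) -> str:
    """Variable region: window residues per spec.columns, the rest uniform."""
    residues = [""] * spec.hexamer_len
    w0 = spec.bond_offset - 3  # window start within the hexamer
    for j in range(WINDOW_SIZE):
        residues[w0 + j] = AMINO_ACIDS[rng.choice(20, p=spec.columns[j])]
    for k in range(spec.hexamer_len):
        if not residues[k]:
            residues[k] = AMINO_ACIDS[rng.integers(20)]
    return "".join(residues)


def generate_substrates(spec: MotifSpec, enzyme: str = "SYN") -> list[SubstrateRecord]:
    """Generate ``spec.n_substrates`` motif-carrying substrate records."""
    rng = np.random.default_rng(spec.seed)
    flank_n = spec.flank_n.upper()
    flank_c = spec.flank_c.upper()
    records = []
    for _ in range(spec.n_substrates):
        records.append(
            SubstrateRecord(
                enzyme=enzyme,
                sequence=flank_n + _draw_hexamer(spec, rng) + flank_c,
                cleavage_index=spec.cleavage_index,
                source_tag="synthetic",
            )
        )
    return records


def generate_background(
    spec: MotifSpec, composition: Sequence[float] | None = None
) -> BackgroundSet:
    """Generate ``spec.n_background`` motif-free peptides in the same scaffold.

    Variable-region residues are uniform by default; ``composition`` (a
    20-vector of probabilities) substitutes an empirical alphabet
    composition for more realistic nulls.  The stream is independent of the
    substrate stream (derived seed), so substrates and background can share
    one :class:`MotifSpec`.
    """
    rng = np.random.default_rng((spec.seed, 1))
    if composition is None:
        p = np.full(20, 1.0 / 20.0)
    else:
        p = np.asarray(composition, dtype=float)
        if p.shape != (20,) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise InputError("composition must be a 20-vector of probabilities")
    flank_n = spec.flank_n.upper()
    flank_c = spec.flank_c.upper()
    peptides = []
    for _ in range(spec.n_background):
        hexamer = "".join(AMINO_ACIDS[i] for i in rng.choice(20, size=spec.hexamer_len, p=p))
        peptides.append(flank_n + hexamer + flank_c)
    if not peptides:
        raise InputError("n_background must be >= 1 to build a BackgroundSet")
    return BackgroundSet(peptides=tuple(peptides), name="synthetic-background")


def generate_proteins(
    spec: MotifSpec,
    n_proteins: int = 10,
    length: int = 400,
    sites_per_protein: int = 3,
    seed: int = 0,
) -> list[ProteinSubstrate]:
    """Uniform-random proteins with planted motif windows at annotated bonds.

    Each protein receives ``sites_per_protein`` non-overlapping P3–P2′
    windows drawn from ``spec.columns``; the annotated P1 position of each
    is recorded.  Used for protein-level evaluation (negative sampling,
    ROC/AUC, KS separation) without any real proteome.
    """
    if length < 20:
        raise InputError("protein length must be >= 20")
    rng = np.random.default_rng((seed, 2))
    proteins = []
    for pi in range(n_proteins):
        seq = list(AMINO_ACIDS[i] for i in rng.integers(20, size=length))
        positions: list[int] = []
        # keep planted windows (and hence annotations) non-overlapping
        while len(positions) < sites_per_protein:
            p1 = int(rng.integers(8, length - 8))
            if all(abs(p1 - q) >= WINDOW_SIZE for q in positions):
                positions.append(p1)
        for p1 in positions:
            for j in range(WINDOW_SIZE):
                seq[p1 - 3 + j] = AMINO_ACIDS[rng.choice(20, p=spec.columns[j])]
        proteins.append(
            ProteinSubstrate(
                sequence_id=f"synprot{pi + 1}",
                sequence="".join(seq),
                cleavage_positions=tuple(sorted(positions)),
            )
        )
    return proteins


def write_motif_config(spec: MotifSpec, path: str | Path) -> None:
    """Emit the MotifSpec as YAML alongside generated data, for provenance."""
    payload = {
        "columns": {
            pos: {AMINO_ACIDS[i]: float(spec.columns[j, i]) for i in range(20) if spec.columns[j, i] > 0}
            for j, pos in enumerate(("P3", "P2", "P1", "P1'", "P2'"))
        },
        "flank_n": spec.flank_n,
        "flank_c": spec.flank_c,
        "hexamer_len": spec.hexamer_len,
        "bond_offset": spec.bond_offset,
        "n_substrates": spec.n_substrates,
        "n_background": spec.n_background,
        "seed": spec.seed,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
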