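"""The 20-residue amino-acid alphabet and the P3–P2′ scoring window.

Substrate positions follow the Schechter–Berger convention: unprimed
positions (P3, P2, P1) run toward the N-terminus from the scissile bond,
primed positions (P1′, P2′) toward the C-terminus.  The bond itself lies
between P1 and P1′.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Column labels of the scoring window, N- to C-terminal.
WINDOW_POSITIONS: tuple[str, ...] = ("P3", "P2", "P1", "P1'", "P2'")
WINDOW_SIZE: int = len(WINDOW_POSITIONS)

#: Residues tolerated in FASTA input but not scorable (no PWM column values).
NONSTANDARD: frozenset[str] = frozenset("XBZUJO*")


def encode(sequence: str) -> np.ndarray:
    """Map a sequence to integer residue codes; nonstandard residues map to -1."""
    return np.array([AA_INDEX.get(aa, -1) for aa in sequence.upper()], dtype=np.int64)


def is_standard(sequence: str) -> bool:
    return all(aa in AA_INDEX for aa in sequence.upper())
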