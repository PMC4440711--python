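"""On-disk artifacts: substrate tables, background lists, FASTA, PWM files, result tables.

Cleavage-annotated peptides use dash-in-sequence notation, e.g.
``ggsgPSA-LDAtasgaet``: the dash marks the scissile bond, lowercase letters
are the constant phage flanks.  On read everything is uppercased and the
annotation is carried as an integer ``cleavage_index`` — the number of
residues preceding the bond (so the bond lies between 1-based residues
``cleavage_index`` and ``cleavage_index + 1``, and P1 sits at residue
``cleavage_index``).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX, AMINO_ACIDS, WINDOW_POSITIONS
from .errors import InputError, MatrixFormatError, SubstrateParseError

logger = logging.getLogger(__name__)

__all__ = [
    "SubstrateRecord",
    "BackgroundSet",
    "parse_substrate_line",
    "serialize_substrate",
    "read_substrate_table",
    "write_substrate_table",
    "read_background",
    "write_background",
    "read_fasta",
    "read_pwm_file",
    "write_pwm_file",
    "write_predictions",
    "file_md5",
]


@dataclass(frozen=True)
class SubstrateRecord:
    """One peptide with its annotated scissile bond.

    The annotated bond has a full P3–P2′ window iff
    ``3 <= cleavage_index <= len(sequence) - 2``.
    """

    enzyme: str
    sequence: str
    cleavage_index: int
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence or any(aa not in AA_INDEX for aa in self.sequence):
            raise InputError(
                f"sequence {self.sequence!r} contains residues outside the "
                f"20-letter alphabet"
            )
        if not 1 <= self.cleavage_index <= len(self.sequence) - 1:
            raise InputError(
                f"cleavage_index {self.cleavage_index} out of range for "
                f"length-{len(self.sequence)} sequence"
            )

    @property
    def has_full_window(self) -> bool:
        return 3 <= self.cleavage_index <= len(self.sequence) - 2

    @property
    def window(self) -> str:
        """The P3–P2′ residues of the annotated bond (requires a full window)."""
        if not self.has_full_window:
            raise InputError("annotated bond lacks a full P3-P2' window")
        c = self.cleavage_index
        return self.sequence[c - 3 : c + 2]


@dataclass(frozen=True)
class BackgroundSet:
    """Peptides representing the unselected phage-display library."""

    peptides: tuple[str, ...]
    name: str = "background"

    def __post_init__(self) -> None:
        if not self.peptides:
            raise InputError("background set is empty")
        for pep in self.peptides:
            if not pep or any(aa not in AA_INDEX for aa in pep):
                raise InputError(f"background peptide {pep!r} is not in the 20-letter alphabet")

    def __len__(self) -> int:
        return len(self.peptides)


def parse_substrate_line(line: str, enzyme: str = "", source_tag: str = "") -> SubstrateRecord:
    """Parse one dash-annotated peptide, e.g. ``ggsgPSA-LDAtasgaet``.

    Mixed case is accepted (constant flanks are conventionally lowercase);
    the stored sequence is uppercase with the dash removed, and
    ``cleavage_index`` is the number of residues before the dash.
    """
    text = line.strip()
    n_dashes = text.count("-")
    if n_dashes == 0:
        raise SubstrateParseError(f"no cleavage dash in line {text!r}")
    if n_dashes > 1:
        raise SubstrateParseError(f"multiple cleavage dashes in line {text!r}")
    idx = text.index("-")
    if idx == 0 or idx == len(text) - 1:
        raise SubstrateParseError(f"cleavage dash at sequence end in line {text!r}")
    sequence = (text[:idx] + text[idx + 1 :]).upper()
    for aa in sequence:
        if aa not in AA_INDEX:
            raise SubstrateParseError(f"non-amino-acid character {aa!r} in line {text!r}")
    return SubstrateRecord(
        enzyme=enzyme, sequence=sequence, cleavage_index=idx, source_tag=source_tag
    )


def serialize_substrate(record: SubstrateRecord) -> str:
    """Inverse of :func:`parse_substrate_line` (uppercase, dash restored)."""
    c = record.cleavage_index
    return record.sequence[:c] + "-" + record.sequence[c:]


def read_substrate_table(path: str | Path, enzyme: str = "") -> list[SubstrateRecord]:
    """Read a whitespace/tab-separated table of dash-annotated peptides.

    Rows are either ``peptide`` or ``enzyme<TAB>peptide``; ``#`` lines are
    comments.  File order is preserved.  Malformed rows raise with the row
    number; a file with no records raises.
    """
    path = Path(path)
    records: list[SubstrateRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.split()
        try:
            if len(fields) == 1:
                rec = parse_substrate_line(fields[0], enzyme=enzyme, source_tag=str(path))
            elif len(fields) == 2:
                rec = parse_substrate_line(fields[1], enzyme=fields[0], source_tag=str(path))
            else:
                raise SubstrateParseError(f"expected 1 or 2 columns, got {len(fields)}")
        except InputError as exc:
            raise SubstrateParseError(f"{path}:{lineno}: {exc}") from exc
        records.append(rec)
    if not records:
        raise InputError(f"{path}: no records")
    logger.info("read %d substrate records from %s", len(records), path)
    return records


def write_substrate_table(
    records: Sequence[SubstrateRecord], path: str | Path, header: Sequence[str] = ()
) -> None:
    path = Path(path)
    lines = [f"# {h}" for h in header]
    lines += [f"{rec.enzyme or 'NA'}\t{serialize_substrate(rec)}" for rec in records]
    path.write_text("\n".join(lines) + "\n")


def read_background(path: str | Path, name: str | None = None) -> BackgroundSet:
    """Read a background peptide list (one plain peptide per row, ``#`` comments)."""
    path = Path(path)
    peptides: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        pep = text.split()[-1].upper()
        for aa in pep:
            if aa not in AA_INDEX:
                raise SubstrateParseError(
                    f"{path}:{lineno}: non-amino-acid character {aa!r} in peptide {pep!r}"
                )
        peptides.append(pep)
    if not peptides:
        raise InputError(f"{path}: no records")
    logger.info("read %d background peptides from %s", len(peptides), path)
    return BackgroundSet(peptides=tuple(peptides), name=name or path.stem)


def write_background(background: BackgroundSet, path: str | Path, header: Sequence[str] = ()) -> None:
    path = Path(path)
    lines = [f"# {h}" for h in header] + list(background.peptides)
    path.write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, line-wrapped) FASTA file as (id, sequence) pairs."""
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return records


# --------------------------------------------------------------------------
# PWM matrix file dialect
#
#   # optional comment lines
#   enzyme     MMP-9
#   threshold  1.500000
#   offset     -4.000000
#   residue  P3  P2  P1  P1'  P2'
#   A  <5 floats>
#   ... one row per residue, all 20 exactly once ...
# --------------------------------------------------------------------------


def read_pwm_file(path: str | Path):
    """Read a PWM matrix file; returns a :class:`pwmcleave.pwm.PWM`."""
    from .pwm import PWM  # local import to avoid a module cycle

    path = Path(path)
    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    in_matrix = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        fields = text.split()
        if not in_matrix:
            key = fields[0].lower()
            if key == "residue":
                expected = ("residue",) + WINDOW_POSITIONS
                if tuple(fields) != expected:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: column header must be {' '.join(expected)}"
                    )
                in_matrix = True
                continue
            if len(fields) != 2:
                raise MatrixFormatError(f"{path}:{lineno}: expected 'key value' header line")
            meta[key] = fields[1]
            continue
        if len(fields) != 6:
            raise MatrixFormatError(f"{path}:{lineno}: expected residue + 5 values")
        residue = fields[0].upper()
        if residue not in AA_INDEX:
            raise MatrixFormatError(f"{path}:{lineno}: unknown residue {residue!r}")
        if residue in rows:
            raise MatrixFormatError(f"{path}:{lineno}: duplicate residue row {residue!r}")
        try:
            rows[residue] = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    missing_meta = {"enzyme", "threshold", "offset"} - set(meta)
    if missing_meta:
        raise MatrixFormatError(f"{path}: missing header keys: {sorted(missing_meta)}")
    if set(rows) != set(AMINO_ACIDS):
        missing = sorted(set(AMINO_ACIDS) - set(rows))
        raise MatrixFormatError(f"{path}: matrix must have 20 residue rows (missing {missing})")
    matrix = np.array([rows[aa] for aa in AMINO_ACIDS], dtype=float)
    try:
        threshold = float(meta["threshold"])
        offset = float(meta["offset"])
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric threshold/offset") from exc
    return PWM(enzyme=meta["enzyme"], matrix=matrix, offset=offset, threshold=threshold)


def write_pwm_file(pwm, path: str | Path, header: Sequence[str] = ()) -> None:
    """Write a PWM matrix file (values at 6 decimal places; read∘write is identity)."""
    path = Path(path)
    lines = [f"# {h}" for h in header]
    lines += [
        f"enzyme\t{pwm.enzyme}",
        f"threshold\t{pwm.threshold:.6f}",
        f"offset\t{pwm.offset:.6f}",
        "residue\t" + "\t".join(WINDOW_POSITIONS),
    ]
    for i, aa in enumerate(AMINO_ACIDS):
        lines.append(aa + "\t" + "\t".join(f"{v:.6f}" for v in pwm.matrix[i]))
    path.write_text("\n".join(lines) + "\n")


def write_predictions(rows: Iterable[dict], path: str | Path, header: Sequence[str] = ()) -> None:
    """Write the prediction table: one row per above-threshold site.

    Columns: sequence id, 1-based P1 position, 10-residue context around the
    bond, P3–P2′ window, score (4 dp), and the monoisotopic masses (6 dp) of
    the N- and C-side fragments of a complete digest at that bond ('NA' when
    a fragment contains a nonstandard residue).
    """
    path = Path(path)
    columns = ("sequence_id", "p1_position", "context10", "window", "score", "n_mass", "c_mass")
    lines = [f"# {h}" for h in header]
    lines.append("\t".join(columns))
    for row in rows:
        n_mass = row.get("n_mass")
        c_mass = row.get("c_mass")
        lines.append(
            "\t".join(
                [
                    str(row["sequence_id"]),
                    str(row["p1_position"]),
                    row["context10"],
                    row["window"],
                    f"{row['score']:.4f}",
                    "NA" if n_mass is None else f"{n_mass:.6f}",
                    "NA" if c_mass is None else f"{c_mass:.6f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def file_md5(path: str | Path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()
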