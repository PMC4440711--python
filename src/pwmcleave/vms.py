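"""Virtual mass spectra of predicted digests.

Given a protein and its predicted cleavage sites, every contiguous fragment
between two cut boundaries is enumerated with its neutral monoisotopic mass
and an intensity

    Intensity(fragment) = 100 * ws1 * ws2,

where ws1 and ws2 are the cleavage-efficiency weights of the fragment's N-
and C-side boundaries: the site's PWM score mapped linearly onto [0, 1]
between the matrix's minimal and maximal achievable scores.  The protein's
own termini carry weight 1.0, so the undigested full-length molecule always
appears at intensity 100.

By default the digest is *partial*: every ordered pair of boundaries yields
a fragment, which for n sites gives (n+1)(n+2)/2 fragments.  The
``complete`` mode keeps only adjacent boundary pairs (n+1 fragments).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

from .alphabet import AA_INDEX
from .errors import DegenerateMatrixError, InputError
from .pwm import PWM, ScoredSite

__all__ = [
    "MassFragment",
    "WATER_MONOISOTOPIC",
    "normalize_score",
    "fragment_mass",
    "virtual_spectrum",
    "write_spectrum",
    "plot_spectrum",
]

#: Monoisotopic mass of water (18.010565 Da at 6 dp), added once per peptide chain.
WATER_MONOISOTOPIC: float = float(_pmass.calculate_mass(formula="H2O"))


@dataclass(frozen=True)
class MassFragment:
    """A contiguous fragment spanning 1-based residues ``start``..``end``."""

    start: int
    end: int
    sequence: str
    mass: float
    ws1: float
    ws2: float
    intensity: float


def normalize_score(pwm: PWM, score: float) -> float:
    """Map a window score linearly onto [0, 1] between score_min and score_max."""
    lo, hi = pwm.score_min, pwm.score_max
    if hi <= lo:
        raise DegenerateMatrixError("cannot normalize scores of a degenerate PWM")
    return min(1.0, max(0.0, (score - lo) / (hi - lo)))


def fragment_mass(residues: str) -> float:
    """Neutral monoisotopic mass of a peptide: residue masses plus one water."""
    residues = residues.upper()
    if not residues:
        raise InputError("empty fragment")
    for aa in residues:
        if aa not in AA_INDEX:
            raise InputError(f"nonstandard residue {aa!r}: mass undefined")
    return float(_pmass.fast_mass(residues))


def virtual_spectrum(
    pwm: PWM,
    sequence: str,
    predicted_sites: Sequence[ScoredSite],
    digest: str = "partial",
) -> list[MassFragment]:
    """Enumerate digest fragments with Eq-style intensities, sorted by mass.

    ``predicted_sites`` should be the above-threshold sites from
    ``scan_sequence``; sites flagged below threshold are ignored.
    """
    sequence = sequence.upper()
    if not sequence:
        raise InputError("empty sequence")
    if digest not in ("partial", "complete"):
        raise InputError(f"digest mode must be 'partial' or 'complete', got {digest!r}")
    L = len(sequence)
    # boundary -> cleavage-efficiency weight; termini are fixed at 1.0
    weights: dict[int, float] = {0: 1.0, L: 1.0}
    for site in predicted_sites:
        if not site.above_threshold:
            continue
        if not 1 <= site.p1_position <= L - 1:
            raise InputError(f"site position {site.p1_position} outside sequence")
        weights[site.p1_position] = normalize_score(pwm, site.score)
    boundaries = sorted(weights)
    fragments: list[MassFragment] = []
    for i, b1 in enumerate(boundaries[:-1]):
        js = (i + 1,) if digest == "complete" else range(i + 1, len(boundaries))
        for j in js:
            b2 = boundaries[j]
            frag_seq = sequence[b1:b2]
            fragments.append(
                MassFragment(
                    start=b1 + 1,
                    end=b2,
                    sequence=frag_seq,
                    mass=fragment_mass(frag_seq),
                    ws1=weights[b1],
                    ws2=weights[b2],
                    intensity=100.0 * weights[b1] * weights[b2],
                )
            )
    fragments.sort(key=lambda f: (f.mass, f.start))
    return fragments


def write_spectrum(
    fragments: Iterable[MassFragment], path: str | Path, header: Sequence[str] = ()
) -> None:
    """Write the spectrum table (mass at 6 dp, intensity at 2 dp)."""
    path = Path(path)
    lines = [f"# {h}" for h in header]
    lines.append("start\tend\tsequence\tmass\tintensity")
    for f in fragments:
        lines.append(f"{f.start}\t{f.end}\t{f.sequence}\t{f.mass:.6f}\t{f.intensity:.2f}")
    path.write_text("\n".join(lines) + "\n")


def plot_spectrum(fragments: Sequence[MassFragment], path: str | Path) -> None:
    """Simple mass-vs-intensity stick plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    masses = [f.mass for f in fragments]
    intensities = [f.intensity for f in fragments]
    ax.vlines(masses, 0, intensities, linewidth=1)
    ax.set_xlabel("monoisotopic mass (Da)")
    ax.set_ylabel("intensity (a.u.)")
    ax.set_ylim(0, 105)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
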