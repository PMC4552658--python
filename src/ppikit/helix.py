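"""Amphiphilic-helix analysis: helical wheel and hydrophobic moment.

Calmodulin recognizes basic amphiphilic alpha-helices; a candidate
binding region can therefore be delineated by scanning a protein with
the mean helical hydrophobic moment,

    muH = | sum_n h_n * exp(i*n*delta) | / N,    delta = 100 deg,

where h_n are residue hydrophobicities (Eisenberg consensus scale by
default).  High-muH windows mark segments whose hydrophobic residues
cluster on one helix face.  Coordinates are 1-based inclusive
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "HelixWindowScore",
    "HYDROPHOBICITY_SCALES",
    "wheel_coordinates",
    "hydrophobic_moment",
    "mean_hydrophobicity",
    "net_charge",
    "scan_amphiphilicity",
    "best_window",
]

# Eisenberg consensus hydrophobicity scale.
_EISENBERG = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Kyte-Doolittle, provided as an alternative scale.
_KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "eisenberg": _EISENBERG,
    "kyte-doolittle": _KYTE_DOOLITTLE,
}

# Simplified charges at neutral pH: His treated as neutral.
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

_STANDARD = set(_EISENBERG)


@dataclass(frozen=True)
class HelixWindowScore:
    """Amphiphilicity metrics for one window (1-based inclusive)."""

    start: int
    end: int
    sequence: str
    hydrophobic_moment: float
    mean_hydrophobicity: float
    net_charge: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("start/end span must equal sequence length")
        if self.hydrophobic_moment < 0:
            raise ValueError("hydrophobic moment is a magnitude, must be >= 0")


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in _STANDARD})
    if bad:
        raise ValueError(
            f"non-standard residue(s) {''.join(bad)!r}; "
            "only the 20 standard amino acids are supported"
        )
    return seq


def wheel_coordinates(
    sequence: str, angle_per_residue: float = 100.0
) -> list[tuple[str, float, float]]:
    """Helical-wheel positions: residue n (0-based) at angle n*delta on
    the unit circle, as (residue, x, y)."""
    seq = _validate_sequence(sequence)
    out = []
    for n, res in enumerate(seq):
        theta = math.radians(n * angle_per_residue)
        out.append((res, math.cos(theta), math.sin(theta)))
    return out


def hydrophobic_moment(
    sequence: str, angle_per_residue: float = 100.0, scale: str = "eisenberg"
) -> float:
    """Mean helical hydrophobic moment muH of a sequence.

    muH = |sum_n h_n exp(i*n*delta)| / N.  Invariant under a global
    rotation of the wheel; zero for any homopolymer whose wheel angles
    sum over whole turns (e.g. an 18-mer at 100 deg/residue).
    """
    seq = _validate_sequence(sequence)
    try:
        h = HYDROPHOBICITY_SCALES[scale]
    except KeyError:
        raise ValueError(
            f"unknown scale {scale!r}; available: "
            + ", ".join(sorted(HYDROPHOBICITY_SCALES))
        ) from None
    delta = math.radians(angle_per_residue)
    values = np.array([h[c] for c in seq])
    phases = np.exp(1j * delta * np.arange(len(seq)))
    return float(np.abs(np.sum(values * phases)) / len(seq))


def mean_hydrophobicity(sequence: str, scale: str = "eisenberg") -> float:
    seq = _validate_sequence(sequence)
    h = HYDROPHOBICITY_SCALES[scale]
    return float(np.mean([h[c] for c in seq]))


def net_charge(sequence: str) -> int:
    """Net charge at neutral pH (K/R = +1, D/E = -1, H = 0)."""
    seq = _validate_sequence(sequence)
    return sum(_CHARGE.get(c, 0) for c in seq)


def scan_amphiphilicity(
    protein: str,
    window: int = 18,
    angle_per_residue: float = 100.0,
    scale: str = "eisenberg",
) -> list[HelixWindowScore]:
    """Score every window of the protein (stride 1, 1-based inclusive).

    Returns L - window + 1 scores for a protein of length L; raises if
    the protein is shorter than the window.
    """
    seq = _validate_sequence(protein)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(seq) < window:
        raise ValueError(
            f"protein length {len(seq)} shorter than window {window}"
        )
    scores = []
    for i in range(len(seq) - window + 1):
        sub = seq[i : i + window]
        scores.append(
            HelixWindowScore(
                start=i + 1,
                end=i + window,
                sequence=sub,
                hydrophobic_moment=hydrophobic_moment(sub, angle_per_residue, scale),
                mean_hydrophobicity=mean_hydrophobicity(sub, scale),
                net_charge=net_charge(sub),
            )
        )
    return scores


def best_window(
    scores: Iterable[HelixWindowScore],
    roi: tuple[int, int] | None = None,
) -> tuple[HelixWindowScore, bool | None]:
    """The maximal-muH window, and whether it lies inside ``roi``
    (1-based inclusive interval; None if no ROI supplied)."""
    scores = list(scores)
    if not scores:
        raise ValueError("no window scores supplied")
    top = max(scores, key=lambda s: s.hydrophobic_moment)
    if roi is None:
        return top, None
    lo, hi = roi
    return top, bool(lo <= top.start and top.end <= hi)
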