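"""Charge-hydrophobicity (CH-plot) sequence classification.

Natively unfolded proteins combine high mean net charge with low mean
hydrophobicity.  In the (H, R) plane the two classes are separated by the
empirical boundary line

    R* = 2.785 * H - 1.151

where R is the mean net charge (|#(K,R) - #(D,E)| / length, histidine
neutral, termini ignored) and H the mean Kyte-Doolittle hydrophobicity
rescaled to [0, 1] via (kd + 4.5)/9 and averaged over sliding windows of
five residues.  A sequence plots on the disordered side when R > R*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .exceptions import ConfigurationError, DomainError

__all__ = ["SequenceProfile", "mean_net_charge", "mean_hydrophobicity",
           "uversky_classify", "profile_sequence",
           "BOUNDARY_SLOPE", "BOUNDARY_INTERCEPT"]

BOUNDARY_SLOPE = 2.785
BOUNDARY_INTERCEPT = -1.151

_STANDARD = set("ACDEFGHIKLMNPQRSTVWY")
DEFAULT_WINDOW = 5


def _validate(sequence: str) -> str:
    seq = sequence.upper()
    bad = [(i, c) for i, c in enumerate(seq) if c not in _STANDARD]
    if bad:
        spots = ", ".join(f"{c!r} at position {i + 1}" for i, c in bad[:5])
        raise ConfigurationError(
            f"non-standard residue(s) in sequence: {spots}")
    return seq


def mean_net_charge(sequence: str) -> float:
    """|#(K,R) - #(D,E)| / length; His neutral, termini ignored."""
    seq = _validate(sequence)
    if not seq:
        raise ConfigurationError("empty sequence")
    pos = sum(seq.count(c) for c in "KR")
    neg = sum(seq.count(c) for c in "DE")
    return abs(pos - neg) / len(seq)


def mean_hydrophobicity(sequence: str, window: int = DEFAULT_WINDOW) -> float:
    """Mean windowed Kyte-Doolittle hydrophobicity rescaled to [0, 1].

    Per-residue values are mapped by (kd + 4.5)/9, averaged in sliding
    windows of ``window`` residues, and the window means averaged.
    """
    seq = _validate(sequence)
    if len(seq) < window:
        raise ConfigurationError(
            f"sequence of length {len(seq)} shorter than window {window}")
    scaled = np.array([(KYTE_DOOLITTLE[c] + 4.5) / 9.0 for c in seq])
    kernel = np.ones(window) / window
    window_means = np.convolve(scaled, kernel, mode="valid")
    return float(window_means.mean())


def uversky_classify(r: float, h: float):
    """Classify a (R, H) point against the CH-plot boundary.

    Returns ``(classification, signed_distance)`` where the distance is
    R - R* (positive on the disordered side); a point on the line reports
    ``"boundary"``.
    """
    if not 0.0 <= h <= 1.0:
        raise DomainError(f"mean hydrophobicity {h} outside [0, 1]")
    if r < 0:
        raise DomainError("mean net charge must be >= 0")
    r_star = BOUNDARY_SLOPE * h + BOUNDARY_INTERCEPT
    delta = r - r_star
    if delta == 0.0:
        return "boundary", 0.0
    return ("disordered-side" if delta > 0 else "ordered-side"), delta


@dataclass(frozen=True)
class SequenceProfile:
    """CH-plot coordinates and classification of one sequence."""

    sequence: str
    mean_net_charge: float
    mean_hydrophobicity: float
    boundary_value: float
    classification: str
    distance_to_boundary: float


def profile_sequence(sequence: str, window: int = DEFAULT_WINDOW) -> SequenceProfile:
    """Compute R, H and the boundary classification for one sequence."""
    seq = _validate(sequence)
    r = mean_net_charge(seq)
    h = mean_hydrophobicity(seq, window=window)
    cls, dist = uversky_classify(r, h)
    return SequenceProfile(
        sequence=seq, mean_net_charge=r, mean_hydrophobicity=h,
        boundary_value=BOUNDARY_SLOPE * h + BOUNDARY_INTERCEPT,
        classification=cls, distance_to_boundary=dist)
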