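"""Kyte-Doolittle hydropathy profiles.

The sliding-window hydropathy average is the workhorse behind both the
signal-peptide h-region score and transmembrane-helix calling: membrane-
spanning helices show sustained window means well above cytosolic
background, and the classic Kyte-Doolittle scale with a 19-residue window
remains the standard first-pass transmembrane detector.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: Kyte & Doolittle residue hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def residue_hydropathy(aa: str) -> np.ndarray:
    """Per-residue Kyte-Doolittle values; unknown residues score 0."""
    vals = np.empty(len(aa))
    unknown = set()
    for i, res in enumerate(aa):
        try:
            vals[i] = KYTE_DOOLITTLE[res]
        except KeyError:
            vals[i] = 0.0
            unknown.add(res)
    if unknown:
        logger.warning(
            "unknown residues treated as hydropathy 0: %s", ",".join(sorted(unknown))
        )
    return vals


def hydropathy_profile(aa: str, window: int = 19) -> np.ndarray:
    """Centered moving-average hydropathy, one value per residue.

    Edges use shrunken (truncated) windows so the profile has exactly
    ``len(aa)`` entries. ``window`` must be odd and no longer than the
    sequence.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(aa):
        raise ValueError(f"window {window} exceeds sequence length {len(aa)}")
    vals = residue_hydropathy(aa)
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(aa)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)
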