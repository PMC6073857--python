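"""Jones-Taylor-Thornton (JTT) amino-acid substitution model constants.

Published exchangeability counts and equilibrium frequencies of the JTT
model (Jones, Taylor & Thornton 1992), in the conventional
A R N D C Q E G H I L K M F P S T W Y V residue order. These are the
same constants every phylogenetics engine ships (e.g. PAML jones.dat).
"""

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: symmetric exchangeability counts, lower triangle row by row
_EXCH_LOWER = [
    [58],
    [54, 45],
    [81, 16, 528],
    [56, 113, 34, 10],
    [57, 310, 86, 49, 9],
    [105, 29, 58, 767, 5, 323],
    [179, 137, 81, 130, 59, 26, 119],
    [27, 328, 391, 112, 69, 597, 26, 23],
    [36, 22, 47, 11, 17, 9, 12, 6, 16],
    [30, 38, 12, 7, 23, 72, 9, 6, 56, 229],
    [35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14],
    [54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65],
    [15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43],
    [194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17],
    [378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285],
    [475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477],
    [9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12],
    [11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71],
    [298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16],
]

#: equilibrium amino-acid frequencies
FREQS = np.array([
    0.07674792325207676, 0.051690948309051694, 0.04264495735504265, 0.05154394845605155,
    0.019802980197019805, 0.04075195924804075, 0.06182993817006184, 0.07315192684807316,
    0.022943977056022944, 0.05376094623905377, 0.0919039080960919, 0.05867594132405868,
    0.02382597617402383, 0.040125959874040135, 0.05090094909905091, 0.06876493123506877,
    0.05856494143505857, 0.014260985739014262, 0.0321019678980321, 0.066004933995066,
])


def exchangeability_matrix() -> np.ndarray:
    """Full symmetric 20x20 exchangeability matrix."""
    S = np.zeros((20, 20))
    for i, row in enumerate(_EXCH_LOWER, start=1):
        for j, v in enumerate(row):
            S[i, j] = S[j, i] = v
    return S


def rate_matrix() -> np.ndarray:
    """JTT instantaneous rate matrix Q, normalised to 1 expected
    substitution per unit time at equilibrium."""
    S = exchangeability_matrix()
    Q = S * FREQS[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(FREQS * np.diag(Q)).sum()
    return Q / scale

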