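"""Bundled amino-acid composition tables.

Two 20-entry frequency tables drive both the synthetic-sequence generators
and the prion-likeness HMM:

``BACKGROUND_AA_FREQS``
    An approximation of average human proteome composition (Met near 2%).
``PRION_AA_FREQS``
    A prion-like composition enriched in Q/N/S/G (and mildly in M and P),
    mirroring the residue preferences of yeast-prion-style low-complexity
    domains.

Both are packaged constants, normalised at import time.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_BACKGROUND = {
    "A": 0.0701, "R": 0.0564, "N": 0.0359, "D": 0.0473, "C": 0.0230,
    "Q": 0.0477, "E": 0.0710, "G": 0.0657, "H": 0.0263, "I": 0.0434,
    "L": 0.0996, "K": 0.0573, "M": 0.0200, "F": 0.0365, "P": 0.0631,
    "S": 0.0833, "T": 0.0536, "W": 0.0122, "Y": 0.0267, "V": 0.0597,
}

_PRION = {
    "A": 0.055, "R": 0.015, "N": 0.130, "D": 0.015, "C": 0.005,
    "Q": 0.170, "E": 0.015, "G": 0.110, "H": 0.020, "I": 0.015,
    "L": 0.030, "K": 0.015, "M": 0.040, "F": 0.020, "P": 0.070,
    "S": 0.130, "T": 0.045, "W": 0.005, "Y": 0.045, "V": 0.050,
}


def _as_array(table: dict[str, float]) -> np.ndarray:
    v = np.array([table[a] for a in AMINO_ACIDS], dtype=float)
    return v / v.sum()


BACKGROUND_AA_FREQS: np.ndarray = _as_array(_BACKGROUND)
PRION_AA_FREQS: np.ndarray = _as_array(_PRION)

#: Name → frequency vector, in AMINO_ACIDS order.
EMISSION_TABLES: dict[str, np.ndarray] = {
    "background": BACKGROUND_AA_FREQS,
    "prion": PRION_AA_FREQS,
}


def table_with_met_weight(table_id: str, met_weight: float) -> np.ndarray:
    """Return a copy of a named table with the Met frequency pinned to
    ``met_weight`` and the remaining entries rescaled to sum to 1 - met_weight.
    """
    if table_id not in EMISSION_TABLES:
        raise KeyError(f"unknown emission table: {table_id!r}")
    if not 0.0 <= met_weight < 1.0:
        raise ValueError("met_weight must be in [0, 1)")
    base = EMISSION_TABLES[table_id].copy()
    im = AMINO_ACIDS.index("M")
    others = np.delete(base, im)
    others = others / others.sum() * (1.0 - met_weight)
    out = np.insert(others, im, met_weight)
    return out
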