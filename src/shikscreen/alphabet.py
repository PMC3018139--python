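"""Amino-acid alphabet, encoding, and background residue frequencies.

The background model is the Robinson & Robinson (1991) amino-acid
composition estimated from a large protein database — the same null used
by classical profile-HMM search tools. It is a built-in constant so that
every result in this package is reproducible without downloads.
"""

from __future__ import annotations

import numpy as np

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residue codes treated as "unknown": scored at background (log-odds 0).
AMBIGUOUS = set("XBZJUO")

GAP_CHARS = set("-.")

_ROBINSON = np.array(
    [
        0.078047,  # A
        0.019246,  # C
        0.053640,  # D
        0.062949,  # E
        0.038556,  # F
        0.073772,  # G
        0.021992,  # H
        0.051420,  # I
        0.057438,  # K
        0.090191,  # L
        0.022425,  # M
        0.044873,  # N
        0.052028,  # P
        0.042644,  # Q
        0.051295,  # R
        0.071198,  # S
        0.058413,  # T
        0.064409,  # V
        0.013298,  # W
        0.032165,  # Y
    ]
)

#: Background amino-acid frequencies (Robinson & Robinson), normalized.
BACKGROUND = _ROBINSON / _ROBINSON.sum()
BACKGROUND.setflags(write=False)


def encode_sequence(seq: str, *, name: str = "sequence") -> np.ndarray:
    """Encode a protein string as integer codes.

    Codes 0..19 index :data:`AMINO_ACIDS`; ambiguous residues (X, B, Z,
    J, U, O) become -1 and are scored at background by the DP kernels.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a character that is neither
        a standard residue nor a recognized ambiguity code.
    """
    if not seq:
        raise ValueError(f"{name} is empty")
    codes = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq.upper()):
        idx = AA_INDEX.get(ch)
        if idx is not None:
            codes[i] = idx
        elif ch in AMBIGUOUS:
            codes[i] = -1
        else:
            raise ValueError(
                f"illegal character {ch!r} at position {i} in {name}"
            )
    return codes
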