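"""The 21-state sequence alphabet: 20 amino acids plus the gap state.

Residues are encoded as integers 0..20 in alphabetical one-letter order with
the gap ``-`` as code 20. Non-standard or ambiguous residue letters
(B, J, O, U, X, Z) and the ``.`` gap variant map to the gap code, so every
alignment column stays a categorical variable over exactly 21 states — the
441 = 21 x 21 pair-state space used throughout the feature tensors.
"""

from __future__ import annotations

import numpy as np

#: Ordered 21-symbol alphabet: amino acids A..Y alphabetically, then gap.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY-"

#: Integer code of the gap state.
GAP_CODE: int = 20

#: Number of states per position.
N_STATES: int = 21

_CODE_OF = {c: i for i, c in enumerate(ALPHABET)}
# ambiguous / non-standard residues collapse onto the gap state
for _c in "BJOUXZ.":
    _CODE_OF[_c] = GAP_CODE

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _c, _i in _CODE_OF.items():
    _LOOKUP[ord(_c)] = _i
    _LOOKUP[ord(_c.lower())] = _i
_LOOKUP[ord("-")] = GAP_CODE


def encode(seq: str) -> np.ndarray:
    """Encode a residue string into integer codes in [0, 20].

    Raises ``ValueError`` on characters outside the amino-acid/gap alphabet.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _LOOKUP[arr]
    if np.any(codes < 0):
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise ValueError(f"unencodable characters in sequence: {bad}")
    return codes.astype(np.int8)


def decode(codes: np.ndarray) -> str:
    """Decode integer codes back to a residue string (gap as '-')."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < 0 or codes.max() > GAP_CODE):
        raise ValueError("codes outside [0, 20]")
    return "".join(ALPHABET[int(c)] for c in codes)


def one_hot(codes: np.ndarray, dtype=np.float64) -> np.ndarray:
    """One-hot encode an (N, L) code matrix to (N, L, 21)."""
    codes = np.asarray(codes)
    out = np.zeros(codes.shape + (N_STATES,), dtype=dtype)
    np.put_along_axis(out, codes[..., None].astype(np.int64), 1, axis=-1)
    return out
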