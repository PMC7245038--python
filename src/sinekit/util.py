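"""Small sequence utilities shared by every module.

Coordinates are 1-based inclusive everywhere inside the package; BED output
converts to 0-based half-open at the file boundary.
"""

from __future__ import annotations

import numpy as np

# Encoding: A=0 C=1 G=2 T=3, N (and anything else)=4, mask sentinel=5.
# Codes >= 4 never match anything, including themselves.
MASK_CODE = 5

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i

_DEC = np.frombuffer(b"ACGTNX", dtype=np.uint8)

_COMPL = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A0 C1 G2 T3 N4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPL)[::-1]


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    codes = encode(seq)
    return float(np.mean((codes == 1) | (codes == 2)))


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling k-mer integer codes over an encoded sequence.

    Windows containing an ambiguous base (code >= 4) are set to -1.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ weights
    bad = (windows >= 4).any(axis=1)
    vals[bad] = -1
    return vals
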