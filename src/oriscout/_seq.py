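"""Integer encodings for DNA shared by the motif, scanner and synthetic modules.

Bases are encoded A=0, C=1, G=2, T=3; anything else (N after loading) is 4.
Contexts of a Markov model of order m are base-4 codes of m-mers.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)

_COMP_STR = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """DNA string -> int8 array (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(arr: np.ndarray) -> str:
    return "".join("ACGTN"[int(i)] for i in arr)


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return COMPLEMENT[arr[::-1]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_STR)[::-1]


def kmer_code(arr: np.ndarray) -> int:
    """Base-4 code of a k-mer given as codes (no N allowed)."""
    code = 0
    for b in arr:
        code = (code << 2) | int(b)
    return code


def code_to_kmer(code: int, k: int) -> np.ndarray:
    out = np.empty(k, dtype=np.int8)
    for i in range(k - 1, -1, -1):
        out[i] = code & 3
        code >>= 2
    return out


def rolling_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Base-4 codes of every k-mer window; -1 where the window contains N.

    Returns an array of length len(arr) - k + 1 (k >= 1).
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    valid = a < N_CODE
    codes = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        codes = (codes << 2) | np.where(valid[j : j + n], a[j : j + n], 0)
        ok &= valid[j : j + n]
    codes[~ok] = -1
    return codes
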