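"""Small nucleotide helpers shared by the simulator and the mapper.

Sequences are handled in two forms: Python strings (ACGT, what the FASTA
files carry) and ``uint8`` numpy arrays with A=0, C=1, G=2, T=3 (what the
vectorised mapper works on).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)
# complement in code space: A<->T (0<->3), C<->G (1<->2)
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array (A=0,C=1,G=2,T=3)."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside ACGTacgt")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGT string."""
    return _DECODE[arr].tobytes().decode()


def revcomp_codes(arr: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; works on 1-D or 2-D (per row) input."""
    return _COMPLEMENT[arr][..., ::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def gc_content(seq: str | np.ndarray) -> float:
    """Fraction of G+C bases."""
    arr = encode(seq) if isinstance(seq, str) else seq
    if arr.size == 0:
        raise ValueError("empty sequence")
    return float(np.mean((arr == 1) | (arr == 2)))


def random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Random sequence codes with expected GC content ``gc``."""
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def mutate_codes_exact(
    rng: np.random.Generator, arr: np.ndarray, n_subs: int
) -> np.ndarray:
    """Substitute exactly ``n_subs`` distinct sites (1-D input).

    Used where the realised identity must be guaranteed, e.g. conserved
    genes forced above a fixed identity threshold.
    """
    out = arr.copy()
    if n_subs:
        pos = rng.choice(arr.size, size=n_subs, replace=False)
        out[pos] = (out[pos] + rng.integers(1, 4, size=n_subs, dtype=np.uint8)) % 4
    return out


def mutate_codes(
    rng: np.random.Generator, arr: np.ndarray, rate: float
) -> np.ndarray:
    """Apply i.i.d. per-site substitutions at ``rate``.

    Substituted sites are replaced by one of the three other bases uniformly,
    so the realised identity equals ``1 - rate`` in expectation.
    """
    out = arr.copy()
    mask = rng.random(arr.shape) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out
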