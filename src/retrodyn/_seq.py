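"""Low-level nucleotide/peptide helpers shared across modules.

Sequences are plain uppercase ``str`` at module boundaries; hot loops work on
``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3).
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

ALPHABET = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

# transition partner of each coded base (A<->G, C<->T)
TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)
# the two transversion partners of each coded base
TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 code array."""
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT symbol {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. random sequence with expected G+C fraction ``gc``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return decode(rng.choice(4, size=length, p=p).astype(np.uint8))


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.count_nonzero(a != b))


def six_frame_peptides(seq: str) -> list[tuple[int, str]]:
    """Translate all six reading frames.

    Returns (frame, peptide) pairs; frames 0..2 are forward offsets, 3..5 the
    corresponding offsets on the reverse complement. Stop codons appear as
    ``*`` in the peptide.
    """
    out = []
    rc = revcomp(seq)
    for frame in range(3):
        for base, src in ((0, seq), (3, rc)):
            sub = src[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                out.append((base + frame, str(Seq(sub).translate())))
    return out


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """All overlapping k-mers of a code array packed into uint64 (2 bits/base)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out = (out << np.uint64(2)) | codes[j : j + n].astype(np.uint64)
    return out


def derive_seed(seed: int, *salts: int) -> int:
    """Deterministically derive a sub-seed below 2**31 from a master seed."""
    h = np.uint64(seed % (1 << 31))
    for s in salts:
        h = np.uint64((int(h) * 1000003 + int(s) + 0x9E3779B9) % (1 << 31))
    return int(h)
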