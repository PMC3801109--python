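"""Nucleotide code helpers shared across the package.

Sequences are held as numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4);
FASTA/FASTQ text is produced/consumed through the lookup tables below.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

CODE_TO_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)

ASCII_TO_CODE = np.full(256, N, dtype=np.uint8)
for _i, _ch in enumerate(b"ACGTN"):
    ASCII_TO_CODE[_ch] = _i
for _i, _ch in enumerate(b"acgtn"):
    ASCII_TO_CODE[_ch] = _i

# complement in code space; N maps to N
COMP = np.array([T, G, C, A, N], dtype=np.uint8)

TELOMERE_MOTIF = "TTAGGG"


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGTN string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode()
    return ASCII_TO_CODE[np.frombuffer(seq, dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to an ACGTN string."""
    return CODE_TO_ASCII[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (last axis)."""
    return COMP[codes][..., ::-1]


def revcomp_str(seq: str) -> str:
    return decode(revcomp(encode(seq)))


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform random A/C/G/T codes."""
    return rng.integers(0, 4, size=n, dtype=np.uint8)
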