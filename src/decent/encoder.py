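"""One-hot read encoding with a methylated-CpG channel.

Each read becomes an L x 5 binary matrix with channels ordered
(A, C, G, T, mC).  A methylated CpG cytosine sets both the C and the mC
channel, giving the row (0, 1, 0, 0, 1); methylation in CH context does not
activate the mC channel; N bases encode as all-zero rows.
"""

from __future__ import annotations

import numpy as np

CHANNELS = ("A", "C", "G", "T", "mC")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def encode_batch(seqs, meths, length: int | None = None) -> np.ndarray:
    """Vectorized encoding of many reads into an N x L x 5 float32 array.

    All reads must share one length (66 after preprocessing); pass
    ``length`` to assert it.
    """
    n = len(seqs)
    if n == 0:
        L = length or 0
        return np.zeros((0, L, 5), dtype=np.float32)
    L = len(seqs[0])
    if length is not None and L != length:
        raise ValueError(f"read length {L} != expected {length}")
    seq_arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(n, L)
    meth_arr = np.frombuffer("".join(meths).encode("ascii"), dtype=np.uint8).reshape(n, L)
    out = np.zeros((n, L, 5), dtype=np.float32)
    for base, ch in _BASE_INDEX.items():
        out[:, :, ch] = seq_arr == ord(base)
    out[:, :, 4] = meth_arr == ord("Z")
    return out


def encode(read) -> np.ndarray:
    """Encode one read (a MethylRead or a (seq, meth) pair) as L x 5."""
    seq, meth = (read.seq, read.meth) if hasattr(read, "seq") else read
    if len(seq) != len(meth):
        raise ValueError("sequence and methylation string lengths differ")
    return encode_batch([seq], [meth])[0]


def encode_readset(readset, length: int = 66) -> np.ndarray:
    """Encode a ReadSet, requiring every read to have the given length."""
    bad = [i for i, s in enumerate(readset.seq) if len(s) != length]
    if bad:
        raise ValueError(
            f"{len(bad)} reads are not {length} bp; run trimming first "
            f"(first offender: index {bad[0]})"
        )
    return encode_batch(readset.seq, readset.meth, length)


def decode(encoded: np.ndarray) -> str:
    """Invert :func:`encode` into a string over {A, C, G, T, M, N}.

    Methylated CpG cytosines (C and mC channels both set) decode to 'M';
    all-zero rows decode to 'N'.  Rows with more than one base channel set
    are rejected.
    """
    encoded = np.asarray(encoded)
    if encoded.ndim != 2 or encoded.shape[1] != 5:
        raise ValueError("expected an L x 5 encoding")
    base_part = encoded[:, :4]
    n_set = (base_part != 0).sum(axis=1)
    if (n_set > 1).any():
        raise ValueError("ambiguous row: more than one base channel set")
    letters = []
    for row, k in zip(encoded, n_set):
        if k == 0:
            letters.append("N")
            continue
        base = "ACGT"[int(np.argmax(row[:4]))]
        if base == "C" and row[4]:
            base = "M"
        letters.append(base)
    return "".join(letters)


def decode_batch(encoded: np.ndarray) -> list[str]:
    return [decode(e) for e in np.asarray(encoded)]
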