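"""Model interpretability: first-layer filter motifs and per-position
attributions.

Filter motifs are summarized as position-frequency matrices (PFMs) over
the alphabet {A, C, G, T, M}, where M marks a methylated CpG cytosine:
for each convolution filter, the input windows whose activation exceeds a
quantile of that filter's positive activations are collected and their
letters counted per position.

Attributions use integrated gradients (a Riemann-midpoint path integral
of the score gradient between a reference read and the input), which obeys
the summation-to-delta property: per-position contributions sum to the
score difference between the read and the reference, up to a small
residual that is reported on every map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import CHANNELS, decode, encode_batch, encode_readset
from .nn import Tensor
from .readio import ReadSet
from .scores import ScoreSet

__all__ = [
    "PFM",
    "AttributionMap",
    "select_typical_reads",
    "extract_pfms",
    "attribute",
    "attribute_set",
    "summarize_methylation_importance",
    "write_meme",
]

PFM_ALPHABET = ("A", "C", "G", "T", "M")


@dataclass
class PFM:
    filter_id: int
    matrix: np.ndarray  # (width, 5) column frequencies over PFM_ALPHABET
    support: int

    def __post_init__(self) -> None:
        if self.support > 0:
            sums = self.matrix.sum(axis=1)
            if not np.allclose(sums[sums > 0], 1.0, atol=1e-6):
                raise ValueError("PFM columns must sum to 1")


@dataclass
class AttributionMap:
    read_id: str
    contributions: np.ndarray  # (L, 5), signed
    method: str
    reference: str
    score: float
    reference_score: float
    residual: float  # |sum(contributions) - (score - reference_score)|


def select_typical_reads(
    readset: ReadSet, scores: ScoreSet, n_high: int, n_low: int
) -> tuple[ReadSet, ReadSet]:
    """Top-``n_high`` and bottom-``n_low`` reads by score.

    Ties at the cut are broken deterministically by read id (lexicographic),
    falling back to position for unnamed reads.
    """
    if n_high > len(readset) or n_low > len(readset):
        raise ValueError("requested more reads than available")
    ids = np.array([rid if rid else f"{i:012d}" for i, rid in enumerate(readset.read_id)])
    low = np.lexsort((ids, scores.scores))[:n_low]  # ascending score, then id
    high = np.lexsort((ids, -scores.scores))[:n_high]
    return readset[high], readset[low]


def extract_pfms(clf, readset: ReadSet, activation_quantile: float = 0.75,
                 max_windows_per_filter: int = 20_000) -> list[PFM]:
    """Position-frequency matrices for every first-layer filter.

    For each filter, windows whose activation exceeds the given quantile
    of that filter's positive activations contribute; letters are counted
    with the decoded alphabet (methylated CpG -> M) and columns normalized.
    A filter with no positive activation yields an empty PFM (support 0).
    """
    net = clf.net_ if hasattr(clf, "net_") else clf
    k = net.config.kernel_size
    L = net.config.read_length
    X = encode_readset(readset, L)
    acts = net.conv_activations(X)  # (N, L-k+1, F)
    n_filters = acts.shape[2]
    # decoded letter grid, N x L
    letters = np.array([list(decode(x)) for x in X])
    pfms: list[PFM] = []
    for f in range(n_filters):
        a = acts[:, :, f]
        pos = a[a > 0]
        if pos.size == 0:
            pfms.append(PFM(f, np.zeros((k, 5)), 0))
            continue
        thr = np.quantile(pos, activation_quantile)
        ri, ci = np.nonzero(a > thr)
        if ri.size == 0:  # e.g. all positive activations equal
            ri, ci = np.nonzero(a >= thr)
        if ri.size > max_windows_per_filter:
            ri, ci = ri[:max_windows_per_filter], ci[:max_windows_per_filter]
        counts = np.zeros((k, 5))
        for j in range(k):
            col = letters[ri, ci + j]
            for a_i, letter in enumerate(PFM_ALPHABET):
                counts[j, a_i] += (col == letter).sum()
        sums = counts.sum(axis=1, keepdims=True)
        matrix = np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)
        pfms.append(PFM(f, matrix, int(ri.size)))
    return pfms


def _model_scores(net, X: np.ndarray, target: str = "probability") -> np.ndarray:
    z = net.logits(X)
    if target == "logit":
        return z
    return 1.0 / (1.0 + np.exp(-z))


def attribute(clf, read, reference="zero", steps: int = 32, seed: int = 0,
              target: str = "probability") -> AttributionMap:
    """Integrated-gradients attribution of one read's score."""
    return attribute_set(clf, _as_batch(clf, read), reference, steps, seed, target=target)[0]


def _as_batch(clf, read) -> np.ndarray:
    net = clf.net_ if hasattr(clf, "net_") else clf
    L = net.config.read_length
    if isinstance(read, np.ndarray):
        X = read[None] if read.ndim == 2 else read
    else:
        X = encode_batch([read.seq], [read.meth])
    if X.shape[1] != L:
        raise ValueError(f"read length {X.shape[1]} does not match the model ({L})")
    return X


def _make_reference(X: np.ndarray, reference, seed: int) -> tuple[np.ndarray, str]:
    if isinstance(reference, np.ndarray):
        ref = np.broadcast_to(reference, X.shape).astype(np.float32)
        return ref, "supplied"
    if reference == "zero":
        return np.zeros_like(X), "zero"
    if reference == "shuffle":
        rng = np.random.default_rng(seed)
        ref = np.stack([x[rng.permutation(x.shape[0])] for x in X])
        return ref, "shuffle"
    raise ValueError(f"unknown reference {reference!r}")


def attribute_set(clf, reads, reference="zero", steps: int = 32, seed: int = 0,
                  batch_size: int = 64, target: str = "probability") -> list[AttributionMap]:
    """Integrated gradients for a batch of reads.

    The gradient of the maternal probability (or the raw logit, with
    ``target="logit"``) is averaged over ``steps`` midpoints along the
    straight path from the reference to the input; contributions are
    (input - reference) times that average.
    """
    if target not in ("probability", "logit"):
        raise ValueError(f"unknown attribution target {target!r}")
    net = clf.net_ if hasattr(clf, "net_") else clf
    if isinstance(reads, ReadSet):
        X = encode_readset(reads, net.config.read_length)
        ids = [rid if rid else str(i) for i, rid in enumerate(reads.read_id)]
    else:
        X = _as_batch(clf, reads)
        ids = [str(i) for i in range(len(X))]
    ref, ref_name = _make_reference(X, reference, seed)
    maps: list[AttributionMap] = []
    alphas = (np.arange(steps) + 0.5) / steps
    for i in range(0, len(X), batch_size):
        xb, rb = X[i : i + batch_size], ref[i : i + batch_size]
        diff = xb - rb
        grad_sum = np.zeros_like(xb)
        for a in alphas:
            xt = Tensor(rb + a * diff, requires_grad=True)
            out = net.forward(xt)
            if target == "probability":
                out = out.sigmoid()
            out.backward(np.ones(out.shape, dtype=np.float32))
            grad_sum += xt.grad
        contrib = diff * (grad_sum / steps)
        p_x = _model_scores(net, xb, target)
        p_r = _model_scores(net, rb, target)
        for j in range(len(xb)):
            total = float(contrib[j].sum())
            delta = float(p_x[j] - p_r[j])
            maps.append(
                AttributionMap(
                    read_id=ids[i + j],
                    contributions=contrib[j],
                    method="integrated_gradients",
                    reference=ref_name,
                    score=float(p_x[j]),
                    reference_score=float(p_r[j]),
                    residual=abs(total - delta),
                )
            )
    return maps


def summarize_methylation_importance(
    maps_high: list[AttributionMap], maps_low: list[AttributionMap]
) -> dict:
    """Per-channel mean absolute attribution for the high-score (maternal)
    and low-score (embryonic) read sets, with the mC-channel contrast."""
    if not maps_high or not maps_low:
        raise ValueError("both attribution sets must be non-empty")

    def per_channel(maps):
        stack = np.stack([np.abs(m.contributions).mean(axis=0) for m in maps])
        return stack.mean(axis=0)

    hi = per_channel(maps_high)
    lo = per_channel(maps_low)
    return {
        "channels": list(CHANNELS),
        "high_score_mean_abs": hi.tolist(),
        "low_score_mean_abs": lo.tolist(),
        "m_channel_contrast": float(hi[4] - lo[4]),
        "n_high": len(maps_high),
        "n_low": len(maps_low),
    }


def write_meme(pfms: list[PFM], path, background=None) -> None:
    """Write PFMs in MEME minimal motif format.

    The 4-letter nucleotide PFM folds M into C (an M is a cytosine); the
    M-channel frequency is written alongside as comment lines so the
    methylation signal is not lost.
    """
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: +", ""]
    bg = background or [0.25, 0.25, 0.25, 0.25]
    lines += ["Background letter frequencies", " ".join(f"{l} {p:.3f}" for l, p in zip("ACGT", bg)), ""]
    for pfm in pfms:
        if pfm.support == 0:
            continue
        lines.append(f"MOTIF filter_{pfm.filter_id}")
        lines.append(f"letter-probability matrix: alength= 4 w= {pfm.matrix.shape[0]} nsites= {pfm.support}")
        for row in pfm.matrix:
            acgt = np.array([row[0], row[1] + row[4], row[2], row[3]])
            total = acgt.sum()
            acgt = acgt / total if total > 0 else np.full(4, 0.25)
            lines.append(" ".join(f"{v:.6f}" for v in acgt))
        lines.append("# M-frequency: " + " ".join(f"{row[4]:.6f}" for row in pfm.matrix))
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
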