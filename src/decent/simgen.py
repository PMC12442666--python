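"""Synthetic genomes, class-labeled methylation reads, mixtures, and
score-level benchmark populations.

The generator emulates the two read classes found in spent embryo culture
medium: embryonic cfDNA and maternal (cumulus-cell) cfDNA.  The classes
share a genome but differ in their CpG methylation propensity on a
configurable fraction of regions, mirroring the cumulus-hypermethylated
CpG islands that carry the discriminative signal in real data.  Mixtures
at prescribed maternal fractions and spiked copy-number events on the
embryonic class make contamination estimation and CNV reconstruction
testable end to end with no external data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .readio import LABEL_EMBRYONIC, LABEL_MATERNAL, ReadSet
from .scores import ScoreSet

__all__ = [
    "SimConfig",
    "SyntheticGenome",
    "ClassMethylProfile",
    "MixSpec",
    "ScorePopulationSpec",
    "generate_genome",
    "make_class_profiles",
    "generate_reads",
    "mix_reads",
    "maternal_reads_needed",
    "generate_score_population",
    "perturb_scores",
    "default_genome_config",
]


@dataclass
class SimConfig:
    """Configuration for :func:`generate_genome`.

    ``cpg_density`` is CpG sites per bp (a CpG island sits near 0.05-0.1;
    genome-wide human averages near 0.01).  ``gc_autocorr_scale`` sets the
    correlation length of the GC track in bp.
    """

    chrom_lengths: dict[str, int]
    cpg_density: float = 0.06
    gc_window: int = 10_000
    gc_autocorr_scale: int = 200_000
    region_size: int = 1_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome required")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        if self.cpg_density < 0:
            raise ValueError("cpg_density must be >= 0")
        if self.gc_window <= 0 or self.gc_autocorr_scale <= 0 or self.region_size <= 0:
            raise ValueError("window/scale parameters must be positive")


def default_genome_config(
    n_autosomes: int = 22,
    autosome_length: int = 2_000_000,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """A scaled-down human-like karyotype: n autosomes plus X and Y.

    Chromosome lengths taper mildly with index, X matches an autosome and
    Y is half-length, so whole-chromosome dosage tests behave like the
    human case at desk scale.
    """
    lengths = {
        f"chr{i + 1}": int(autosome_length * (1.0 - 0.015 * i)) for i in range(n_autosomes)
    }
    lengths["chrX"] = autosome_length
    lengths["chrY"] = autosome_length // 2
    return SimConfig(chrom_lengths=lengths, seed=seed, **kwargs)


@dataclass
class SyntheticGenome:
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    gc_track: dict[str, np.ndarray]
    seq: dict[str, np.ndarray]  # uint8 ASCII codes
    gc_window: int
    region_size: int

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return self.seq[chrom][start:end].tobytes().decode("ascii")

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_names if c.replace("chr", "") not in ("X", "Y")]

    def n_regions(self, chrom: str) -> int:
        return -(-self.chrom_lengths[chrom] // self.region_size)

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def generate_genome(config: SimConfig) -> SyntheticGenome:
    """Generate a synthetic genome with a smooth GC landscape and planted
    CpG sites at the requested density.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    cpg_positions: dict[str, np.ndarray] = {}
    gc_track: dict[str, np.ndarray] = {}
    seqs: dict[str, np.ndarray] = {}
    names = list(config.chrom_lengths)
    for chrom in names:
        length = config.chrom_lengths[chrom]
        n_win = -(-length // config.gc_window)
        # smooth GC landscape: white noise blurred at the autocorrelation scale
        sigma_win = max(config.gc_autocorr_scale / config.gc_window, 1.0)
        noise = rng.normal(size=n_win + int(6 * sigma_win))
        kernel_x = np.arange(-int(3 * sigma_win), int(3 * sigma_win) + 1)
        kernel = np.exp(-0.5 * (kernel_x / sigma_win) ** 2)
        kernel /= kernel.sum()
        smooth = np.convolve(noise, kernel, mode="same")[: n_win]
        smooth = (smooth - smooth.mean()) / (smooth.std() + 1e-12)
        gc = np.clip(0.42 + 0.06 * smooth, 0.25, 0.65)
        gc_track[chrom] = gc

        # base sequence with per-window GC content
        win_idx = np.minimum(np.arange(length) // config.gc_window, n_win - 1)
        p_gc = gc[win_idx]
        u = rng.random(length)
        v = rng.random(length)
        # split each group evenly between its two bases
        seq = np.where(
            u < p_gc,
            np.where(v < 0.5, ord("G"), ord("C")),
            np.where(v < 0.5, ord("A"), ord("T")),
        ).astype(np.uint8)

        n_cpg = rng.poisson(config.cpg_density * length)
        if n_cpg > 0 and length >= 2:
            pos = np.sort(rng.choice(length - 1, size=min(n_cpg, (length - 1) // 2), replace=False))
            # enforce spacing >= 2 so CpGs do not overlap
            keep = np.ones(pos.size, dtype=bool)
            last = -2
            for i, p in enumerate(pos):
                if p - last < 2:
                    keep[i] = False
                else:
                    last = p
            pos = pos[keep]
            seq[pos] = ord("C")
            seq[pos + 1] = ord("G")
            # remove accidental CpGs elsewhere so cpg_positions is exhaustive
            acc = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
            extra = np.setdiff1d(acc, pos, assume_unique=False)
            seq[extra] = ord("T")
            cpg_positions[chrom] = pos.astype(np.int64)
        else:
            acc = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
            seq[acc] = ord("T")
            cpg_positions[chrom] = np.array([], dtype=np.int64)
        seqs[chrom] = seq
    return SyntheticGenome(
        chrom_names=names,
        chrom_lengths=dict(config.chrom_lengths),
        cpg_positions=cpg_positions,
        gc_track=gc_track,
        seq=seqs,
        gc_window=config.gc_window,
        region_size=config.region_size,
    )


@dataclass
class ClassMethylProfile:
    """Per-region CpG methylation probabilities for one read class.

    ``ch_unmeth_rate`` is the chance that a CH-context cytosine carries an
    unmethylated-CH call; kept small so that default reads survive the
    unmethylated-CH preprocessing filter.
    """

    class_label: str
    region_meth: dict[str, np.ndarray]
    region_size: int
    ch_unmeth_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.class_label not in (LABEL_EMBRYONIC, LABEL_MATERNAL):
            raise ValueError(f"unknown class label {self.class_label!r}")
        for chrom, probs in self.region_meth.items():
            if probs.size and (probs.min() < 0 or probs.max() > 1):
                raise ValueError(f"methylation probabilities out of [0,1] on {chrom}")
        if not 0 <= self.ch_unmeth_rate <= 1:
            raise ValueError("ch_unmeth_rate must lie in [0, 1]")


def make_class_profiles(
    genome: SyntheticGenome,
    p_embryonic: float = 0.2,
    p_maternal: float = 0.8,
    discriminative_fraction: float = 0.7,
    p_shared: float = 0.5,
    ch_unmeth_rate: float = 0.01,
    seed: int = 0,
) -> tuple[ClassMethylProfile, ClassMethylProfile]:
    """Build paired embryonic/maternal methylation profiles.

    A random ``discriminative_fraction`` of regions get class-specific CpG
    methylation probabilities (``p_embryonic`` vs ``p_maternal``); the rest
    share ``p_shared`` and are uninformative — these produce the ambiguous
    middle mode of the read-score distribution.
    """
    rng = np.random.default_rng(seed)
    emb, mat = {}, {}
    for chrom in genome.chrom_names:
        n = genome.n_regions(chrom)
        disc = rng.random(n) < discriminative_fraction
        e = np.full(n, p_shared)
        m = np.full(n, p_shared)
        e[disc] = p_embryonic
        m[disc] = p_maternal
        emb[chrom] = e
        mat[chrom] = m
    return (
        ClassMethylProfile(LABEL_EMBRYONIC, emb, genome.region_size, ch_unmeth_rate),
        ClassMethylProfile(LABEL_MATERNAL, mat, genome.region_size, ch_unmeth_rate),
    )


def _normalize_events(genome: SyntheticGenome, cnv_events) -> list[tuple[str, int, int, float]]:
    out = []
    for ev in cnv_events or []:
        chrom, start, end, cn = ev
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"CNV event on unknown chromosome {chrom!r}")
        L = genome.chrom_lengths[chrom]
        if start == "whole" or (start is None and end is None):
            start, end = 0, L
        start, end = int(start), int(end)
        if not (0 <= start < end <= L):
            raise ValueError(f"CNV event ({chrom}, {start}, {end}) outside chromosome bounds")
        if cn < 0:
            raise ValueError("copy_number must be >= 0")
        out.append((chrom, start, end, float(cn)))
    return out


def generate_reads(
    genome: SyntheticGenome,
    profile: ClassMethylProfile,
    n: int,
    read_len: int = 71,
    cnv_events=None,
    seed: int = 0,
) -> ReadSet:
    """Sample ``n`` labeled reads uniformly along the genome.

    Regions under ``cnv_events`` (tuples ``(chrom, start, end, copy_number)``,
    with ``start='whole'`` for a whole chromosome) have their sampling rate
    scaled by ``copy_number / 2``.  Each CpG on a read is methylated i.i.d.
    with its region's probability from ``profile``; CH cytosines carry
    methylated/unmethylated CH calls at the profile's background rate; all
    other positions are no-calls.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    events = _normalize_events(genome, cnv_events)

    # weighted piecewise-uniform sampling: split each chromosome at event
    # boundaries, weight each piece by its dosage (cn / 2)
    pieces = []  # (chrom, start, end, weight)
    for chrom in genome.chrom_names:
        L = genome.chrom_lengths[chrom]
        cuts = {0, L}
        for c, s, e, _ in events:
            if c == chrom:
                cuts.update((s, e))
        bounds = sorted(cuts)
        for s, e in zip(bounds[:-1], bounds[1:]):
            w = 1.0
            for c, es, ee, cn in events:
                if c == chrom and es <= s and e <= ee:
                    w = cn / 2.0
            if e - s >= read_len and w > 0:
                pieces.append((chrom, s, e, w * (e - s)))
    if not pieces:
        raise ValueError("no samplable genome segments (chromosomes shorter than read_len?)")
    weights = np.array([p[3] for p in pieces])
    counts = rng.multinomial(n, weights / weights.sum())

    sub_sets = []
    for (chrom, s, e, _), k in zip(pieces, counts):
        if k == 0:
            continue
        starts = rng.integers(s, max(e - read_len, s) + 1, size=k)
        sub_sets.append(_reads_at(genome, profile, chrom, np.sort(starts), read_len, rng))
    rs = ReadSet.concat(sub_sets)
    order = rng.permutation(len(rs))
    rs = rs[order]
    rs.provenance["class_label"] = profile.class_label
    rs.provenance["cnv_events"] = events
    return rs


def _reads_at(genome, profile, chrom, starts, read_len, rng) -> ReadSet:
    """Vectorized construction of reads at given start positions."""
    k = starts.size
    seq = genome.seq[chrom]
    # window of read_len + 1 to see the base after the last position (CpG context)
    idx = starts[:, None] + np.arange(read_len + 1)
    idx = np.minimum(idx, len(seq) - 1)
    win = seq[idx]
    bases = win[:, :read_len]
    nxt = win[:, 1 : read_len + 1]
    is_c = bases == ord("C")
    is_cpg = is_c & (nxt == ord("G"))
    is_ch = is_c & ~is_cpg

    region = (starts[:, None] + np.arange(read_len)) // profile.region_size
    p_meth = profile.region_meth[chrom][np.minimum(region, genome.n_regions(chrom) - 1)]
    u = rng.random((k, read_len))

    meth = np.full((k, read_len), ord("."), dtype=np.uint8)
    meth[is_cpg & (u < p_meth)] = ord("Z")
    meth[is_cpg & (u >= p_meth)] = ord("z")
    meth[is_ch & (u < profile.ch_unmeth_rate)] = ord("h")
    meth[is_ch & (u >= profile.ch_unmeth_rate)] = ord("H")

    strands = np.where(rng.random(k) < 0.5, "+", "-")
    seq_strs = [row.tobytes().decode("ascii") for row in bases]
    meth_strs = [row.tobytes().decode("ascii") for row in meth]
    return ReadSet(
        chrom=[chrom] * k,
        start=starts.astype(np.int64),
        strand=list(strands),
        seq=seq_strs,
        meth=meth_strs,
        label=[profile.class_label] * k,
        read_id=[""] * k,
        mate_id=[None] * k,
        mate=np.zeros(k, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# Mixtures


@dataclass
class MixSpec:
    """How to mix embryonic and maternal read pools.

    Either give explicit counts, or give ``target_fraction`` (maternal
    share of the mixture) and the whole embryonic pool is used as the base.
    """

    n_embryonic: int | None = None
    n_maternal: int | None = None
    target_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_fraction is not None:
            if not 0 <= self.target_fraction < 1:
                raise ValueError("target_fraction must lie in [0, 1)")
        elif self.n_embryonic is None or self.n_maternal is None:
            raise ValueError("give either explicit counts or a target_fraction")
        if self.n_embryonic is not None and self.n_embryonic < 0:
            raise ValueError("n_embryonic must be >= 0")
        if self.n_maternal is not None and self.n_maternal < 0:
            raise ValueError("n_maternal must be >= 0")


def maternal_reads_needed(n_embryonic: int, fraction: float) -> int:
    """Maternal reads required to contaminate an embryonic pool of size
    ``n_embryonic`` to the given maternal fraction: x / (n_e + x) = f."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    return math.ceil(fraction / (1.0 - fraction) * n_embryonic)


def _sample_pool(pool: ReadSet, k: int, rng) -> ReadSet:
    if k > len(pool):
        warnings.warn(
            f"requested {k} reads from a pool of {len(pool)}; sampling with replacement"
        )
        idx = rng.integers(0, len(pool), size=k)
    else:
        idx = rng.choice(len(pool), size=k, replace=False)
    return pool[idx]


def mix_reads(embryo: ReadSet, maternal: ReadSet, spec: MixSpec) -> ReadSet:
    """Mix the two pools per ``spec``; the true maternal fraction is recorded
    in the output provenance, and the order is shuffled."""
    rng = np.random.default_rng(spec.seed)
    if spec.target_fraction is not None:
        n_e = spec.n_embryonic if spec.n_embryonic is not None else len(embryo)
        n_m = maternal_reads_needed(n_e, spec.target_fraction)
    else:
        n_e, n_m = spec.n_embryonic, spec.n_maternal
    if n_m == 0:
        out = embryo[np.arange(len(embryo))] if n_e >= len(embryo) else _sample_pool(embryo, n_e, rng)
        out.provenance["true_fraction"] = 0.0
        out.provenance["n_embryonic"] = len(out)
        out.provenance["n_maternal"] = 0
        return out
    e = _sample_pool(embryo, n_e, rng)
    m = _sample_pool(maternal, n_m, rng)
    mixed = ReadSet.concat([e, m])
    mixed = mixed[rng.permutation(len(mixed))]
    mixed.provenance["true_fraction"] = n_m / (n_e + n_m)
    mixed.provenance["n_embryonic"] = n_e
    mixed.provenance["n_maternal"] = n_m
    return mixed


# ---------------------------------------------------------------------------
# Score-level benchmark populations


@dataclass
class ScorePopulationSpec:
    """Class-conditional score mixture emulating the trimodal score
    histogram of a trained read classifier.

    Embryonic scores mix a class mode (default 0.2) with a shared
    "ambiguous" mode at 0.5; maternal scores mix their class mode (default
    0.7) with the same shared mode.  Components are normals of width
    ``spread``, clipped to [0, 1].
    """

    n_embryonic: int = 0
    n_maternal: int = 0
    embryonic_mode: float = 0.2
    maternal_mode: float = 0.7
    ambiguous_mode: float = 0.5
    ambiguous_weight: float = 0.35
    spread: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ambiguous_weight <= 1:
            raise ValueError("component weights must sum to 1 with weights in [0, 1]")
        for m in (self.embryonic_mode, self.maternal_mode, self.ambiguous_mode):
            if not 0 <= m <= 1:
                raise ValueError("mode locations must lie in [0, 1]")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.n_embryonic < 0 or self.n_maternal < 0:
            raise ValueError("counts must be >= 0")


def generate_score_population(spec: ScorePopulationSpec) -> ScoreSet:
    """Draw a labeled score population from the class-conditional mixture."""
    rng = np.random.default_rng(spec.seed)

    def draw(n, mode):
        if n == 0:
            return np.empty(0)
        ambiguous = rng.random(n) < spec.ambiguous_weight
        centers = np.where(ambiguous, spec.ambiguous_mode, mode)
        return np.clip(centers + rng.normal(0, spec.spread, size=n), 0.0, 1.0)

    s_e = draw(spec.n_embryonic, spec.embryonic_mode)
    s_m = draw(spec.n_maternal, spec.maternal_mode)
    scores = np.concatenate([s_e, s_m])
    labels = np.concatenate(
        [np.zeros(spec.n_embryonic, dtype=int), np.ones(spec.n_maternal, dtype=int)]
    )
    order = rng.permutation(scores.size)
    out = ScoreSet(scores[order], labels[order])
    out.provenance["true_fraction"] = (
        spec.n_maternal / (spec.n_embryonic + spec.n_maternal)
        if spec.n_embryonic + spec.n_maternal
        else float("nan")
    )
    return out


def perturb_scores(
    scores: ScoreSet,
    noise_mean: float = 0.0,
    variance_max: float = 0.1,
    seed: int = 0,
    variance: float | None = None,
) -> ScoreSet:
    """Add Gaussian noise whose variance is drawn once per run, uniformly
    from [0, variance_max]; results are clipped back to [0, 1].

    A benchmark run that perturbs several mixtures shares a single
    variance draw across them: pass it via ``variance`` to bypass the
    internal draw.
    """
    if variance_max < 0:
        raise ValueError("variance_max must be >= 0")
    if variance is not None and variance < 0:
        raise ValueError("variance must be >= 0")
    rng = np.random.default_rng(seed)
    var = rng.uniform(0.0, variance_max) if variance is None else float(variance)
    noisy = scores.scores + rng.normal(noise_mean, math.sqrt(var), size=scores.scores.shape)
    out = ScoreSet(np.clip(noisy, 0.0, 1.0), scores.labels, dict(scores.provenance))
    out.provenance["noise_variance"] = var
    out.provenance["noise_mean"] = noise_mean
    return out
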