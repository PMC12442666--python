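"""Canonical synthetic benchmark scenarios.

These builders pin down the study conditions used throughout the test
suite and the acceptance script: a scaled-down human-like genome, the
default (overlapping) and separable class methylation profiles, training
sets for the read-origin model, the MAP-fidelity mixture series, and the
contaminated-aneuploidy reconstruction scenario.

Scales are chosen so every scenario runs in minutes on one CPU while the
statistical structure (trimodal scores, dosage ratios, contamination
bands) matches the full-size setting; see the methods note for the
reasoning behind each default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr

from . import simgen
from .classifier import ReadOriginClassifier
from .deconv import map_estimate, naive_estimate
from .encoder import encode_readset
from .readio import ReadSet, trim_reads
from .scores import ScoreSet

__all__ = [
    "benchmark_genome",
    "benchmark_profiles",
    "training_data",
    "train_benchmark_classifier",
    "map_fidelity_series",
    "aneuploidy_scenario",
]

# event lists give embryonic pools an XY karyotype (one X, one Y) and
# maternal (cumulus) pools an XX karyotype (two X, no Y)
XY_EVENTS = [("chrX", "whole", None, 1), ("chrY", "whole", None, 1)]
XX_EVENTS = [("chrY", "whole", None, 0)]


def benchmark_genome(
    seed: int = 0, n_autosomes: int = 6, autosome_length: int = 1_000_000
) -> simgen.SyntheticGenome:
    cfg = simgen.default_genome_config(
        n_autosomes=n_autosomes, autosome_length=autosome_length, seed=seed
    )
    return simgen.generate_genome(cfg)


def benchmark_profiles(genome, separable: bool = False, seed: int = 0):
    """Class methylation profiles.

    Default (overlapping): embryonic 0.2 vs maternal 0.8 CpG methylation
    on 70% of regions, shared 0.5 elsewhere — produces the trimodal score
    histogram.  Separable: 0.02 vs 0.98 on 90% of regions, giving nearly
    disjoint methylation signatures.
    """
    if separable:
        return simgen.make_class_profiles(
            genome, p_embryonic=0.02, p_maternal=0.98, discriminative_fraction=0.9, seed=seed
        )
    return simgen.make_class_profiles(
        genome, p_embryonic=0.2, p_maternal=0.8, discriminative_fraction=0.7, seed=seed
    )


def training_data(genome, profiles, n_per_class: int, seed: int = 0):
    """Trimmed, encoded, labeled training arrays (X of shape N x 66 x 5)."""
    emb_p, mat_p = profiles
    emb = trim_reads(simgen.generate_reads(genome, emb_p, n_per_class, seed=seed + 11))
    mat = trim_reads(simgen.generate_reads(genome, mat_p, n_per_class, seed=seed + 13))
    rs = ReadSet.concat([emb, mat])
    X = encode_readset(rs)
    y = rs.labels_array()
    return X, y


def train_benchmark_classifier(
    seed: int = 0,
    n_per_class: int = 10_000,
    separable: bool = True,
    epochs: int = 8,
    genome=None,
    profiles=None,
    **clf_kwargs,
):
    """Train the scaled-down benchmark model; returns (clf, genome, profiles).

    The architecture keeps the full model's layer sequence at reduced
    width (32 filters, 4 heads, hidden 16) so training stays CPU-friendly.
    """
    if genome is None:
        genome = benchmark_genome(seed=seed)
    if profiles is None:
        profiles = benchmark_profiles(genome, separable=separable, seed=seed + 1)
    X, y = training_data(genome, profiles, n_per_class, seed=seed)
    defaults = dict(n_filters=32, n_heads=4, lstm_hidden=16, epochs=epochs, random_state=seed)
    defaults.update(clf_kwargs)
    clf = ReadOriginClassifier(**defaults).fit(X, y)
    return clf, genome, profiles


def map_fidelity_series(
    base_seed: int = 0,
    n_runs: int = 5,
    n_reads: int = 10_000,
    fractions=None,
    noise_variance_max: float = 0.1,
):
    """MAP estimates across mixtures at true maternal fractions 0..1.

    Each run draws one noise variance uniformly from [0, variance_max],
    shared across the fraction series, perturbs each mixture's scores,
    MAP-estimates each fraction, and records the Pearson correlation
    between estimates and truth.  Returns a dict with per-run estimates,
    correlations, and regression slopes for the MAP and naive methods.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.0, 1.0001, 0.1), 10)
    fractions = np.asarray(fractions, dtype=float)
    runs = []
    for k in range(n_runs):
        run_seed = (base_seed + 20_000_019 * k) % (2**31 - 1)
        rng = np.random.default_rng(run_seed)
        var = rng.uniform(0.0, noise_variance_max)
        ests, naives = [], []
        for i, f in enumerate(fractions):
            n_m = int(round(f * n_reads))
            spec = simgen.ScorePopulationSpec(
                n_embryonic=n_reads - n_m, n_maternal=n_m, seed=run_seed + 101 * i + 1
            )
            ss = simgen.generate_score_population(spec)
            ss = simgen.perturb_scores(ss, seed=run_seed + 877 * i + 2, variance=var)
            ests.append(map_estimate(ss).r_star)
            naives.append(naive_estimate(ss).r_star)
        ests, naives = np.array(ests), np.array(naives)
        runs.append(
            {
                "seed": run_seed,
                "noise_variance": var,
                "estimates": ests,
                "naive_estimates": naives,
                "pearson_r": float(pearsonr(ests, fractions)[0]),
                "map_slope": float(np.polyfit(fractions, ests, 1)[0]),
                "naive_slope": float(np.polyfit(fractions, naives, 1)[0]),
            }
        )
    return {
        "fractions": fractions,
        "runs": runs,
        "mean_pearson_r": float(np.mean([r["pearson_r"] for r in runs])),
        "mean_map_slope": float(np.mean([r["map_slope"] for r in runs])),
        "mean_naive_slope": float(np.mean([r["naive_slope"] for r in runs])),
    }


@dataclass
class AneuploidyScenario:
    genome: object
    mixed_reads: ReadSet  # trimmed, 66 bp
    reference_reads: ReadSet  # trimmed diploid XY pool
    true_fraction: float
    events: list  # spiked embryonic CNV events


def aneuploidy_scenario(
    genome,
    profiles,
    contamination: float,
    n_embryonic: int = 40_000,
    events=None,
    seed: int = 0,
) -> AneuploidyScenario:
    """Contaminated aneuploid sample plus a matched diploid reference.

    The embryonic pool is XY and carries the spiked events (default
    whole-chromosome -16 and +18); the maternal pool is XX and diploid.
    Reads come out trimmed to 66 bp, ready for scoring.
    """
    emb_p, mat_p = profiles
    if events is None:
        events = [("chr16", "whole", None, 1), ("chr18", "whole", None, 3)]
    embryo = simgen.generate_reads(
        genome, emb_p, n_embryonic, cnv_events=list(events) + XY_EVENTS, seed=seed + 21
    )
    n_mat = simgen.maternal_reads_needed(n_embryonic, contamination)
    maternal = simgen.generate_reads(
        genome, mat_p, max(n_mat, 1), cnv_events=XX_EVENTS, seed=seed + 23
    )
    mixed = simgen.mix_reads(
        embryo, maternal, simgen.MixSpec(target_fraction=contamination, seed=seed + 29)
    )
    reference = simgen.generate_reads(
        genome, emb_p, 2 * n_embryonic, cnv_events=XY_EVENTS, seed=seed + 31
    )
    return AneuploidyScenario(
        genome=genome,
        mixed_reads=trim_reads(mixed),
        reference_reads=trim_reads(reference),
        true_fraction=mixed.provenance["true_fraction"],
        events=list(events),
    )
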