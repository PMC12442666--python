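"""Read-depth copy-number reconstruction.

A self-contained re-implementation of the classic single-cell CNV calling
workflow: tile the genome into bins (500 kb default), count read starts
per bin, remove GC-content bias with lowess, normalize against a diploid
reference profile, segment the per-bin copy-number signal with recursive
binary splitting (CBS-style), round segment means to integer states, and
classify events as whole-chromosome aneuploidies or sub-chromosomal CNVs.
Sex is called from X/Y dosage.  A display-only variance-halving transform
reproduces the shrunken per-bin scatter used for plotting.

Bin tables and profiles are plain pandas DataFrames so they can be written
as TSV and inspected directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .readio import ReadSet

__all__ = [
    "Segment",
    "make_bins",
    "count_in_bins",
    "gc_correct",
    "normalize_to_reference",
    "segment",
    "call_and_classify",
    "shrink_for_plot",
]


@dataclass
class Segment:
    chrom: str
    start_bin: int  # index into the profile's rows for this chromosome
    end_bin: int  # exclusive
    start: int  # bp
    end: int  # bp
    mean_cn: float
    n_bins: int
    state: int | None = None
    event_class: str | None = None  # aneuploidy / sub-chromosomal / neutral
    label: str | None = None


def _is_sex(chrom: str) -> bool:
    return chrom.replace("chr", "") in ("X", "Y")


def make_bins(genome, width: int = 500_000, blacklist: pd.DataFrame | None = None,
              custom_bins: pd.DataFrame | None = None) -> pd.DataFrame:
    """Tile each chromosome with fixed-width bins (last bin truncated), or
    adopt caller-supplied variable-width bins verbatim.

    Returns a DataFrame with columns chrom/start/end/gc/blacklist; GC is
    averaged from the genome's GC track over each bin.
    """
    if custom_bins is not None:
        rows = custom_bins[["chrom", "start", "end"]].copy()
    else:
        if width <= 0:
            raise ValueError("bin width must be positive")
        records = []
        for chrom in genome.chrom_names:
            L = genome.chrom_lengths[chrom]
            starts = np.arange(0, L, width)
            for s in starts:
                records.append((chrom, int(s), int(min(s + width, L))))
        rows = pd.DataFrame(records, columns=["chrom", "start", "end"])
    gc = np.empty(len(rows))
    for i, (chrom, s, e) in enumerate(zip(rows["chrom"], rows["start"], rows["end"])):
        track = genome.gc_track[chrom]
        w = genome.gc_window
        gc[i] = track[s // w : max(s // w + 1, -(-e // w))].mean()
    rows["gc"] = gc
    rows["blacklist"] = False
    if blacklist is not None:
        for _, bl in blacklist.iterrows():
            hit = (
                (rows["chrom"] == bl["chrom"])
                & (rows["start"] < bl["end"])
                & (rows["end"] > bl["start"])
            )
            rows.loc[hit, "blacklist"] = True
    return rows.reset_index(drop=True)


def count_in_bins(readset: ReadSet, grid: pd.DataFrame) -> pd.DataFrame:
    """Assign each read to the bin containing its start coordinate
    (half-open bins: a start exactly on a boundary goes right)."""
    profile = grid.copy()
    counts = np.zeros(len(grid), dtype=np.int64)
    unassigned = 0
    chrom_arr = np.asarray(readset.chrom, dtype=object)
    for chrom, sub in grid.groupby("chrom", sort=False):
        sel = chrom_arr == chrom
        if not sel.any():
            continue
        starts = readset.start[sel]
        bin_starts = sub["start"].to_numpy()
        bin_ends = sub["end"].to_numpy()
        idx = np.searchsorted(bin_starts, starts, side="right") - 1
        ok = (idx >= 0) & (starts < bin_ends[np.clip(idx, 0, None)])
        np.add.at(counts, sub.index.to_numpy()[idx[ok]], 1)
        unassigned += int((~ok).sum())
    unassigned += int((~np.isin(chrom_arr, grid["chrom"].unique())).sum())
    profile["count"] = counts
    profile.attrs["n_reads"] = len(readset)
    profile.attrs["n_unassigned"] = unassigned
    return profile


def gc_correct(profile: pd.DataFrame, span: float = 0.3) -> pd.DataFrame:
    """Divide counts by the lowess fit of count versus GC, rescaling so the
    genome-wide mean count over usable bins is preserved exactly."""
    out = profile.copy()
    usable = ~out["blacklist"].to_numpy()
    if usable.sum() < 10:
        raise ValueError("fewer than 10 usable bins; cannot fit a GC trend")
    gc = out.loc[usable, "gc"].to_numpy()
    cnt = out.loc[usable, "count"].to_numpy().astype(float)
    fit = lowess(cnt, gc, frac=span, return_sorted=False)
    fit = np.maximum(fit, 1e-9)
    corrected = np.full(len(out), np.nan)
    corr_usable = cnt / fit
    # mean-preserving rescale
    corr_usable *= cnt.mean() / corr_usable.mean()
    corrected[usable] = corr_usable
    out["corrected"] = corrected
    return out


def normalize_to_reference(
    sample: pd.DataFrame,
    reference: pd.DataFrame,
    reference_sex: str = "XY",
) -> pd.DataFrame:
    """Per-bin copy number from sample/reference depth ratios.

    The reference is assumed diploid on autosomes with sex-chromosome
    ploidy given by ``reference_sex`` ("XY": one X one Y; "XX": two X, no
    usable Y).  Ratios are median-centered to 1 over autosomal bins and
    copy number is ratio x reference ploidy per chromosome.  Bins with
    zero/absent reference signal are masked, never infinite.
    """
    for col in ("chrom", "start", "end"):
        if not (sample[col] == reference[col]).all():
            raise ValueError("sample and reference are on different bin grids")
    out = sample.copy()
    s = out["corrected"].to_numpy() if "corrected" in out else out["count"].to_numpy().astype(float)
    r = (
        reference["corrected"].to_numpy()
        if "corrected" in reference
        else reference["count"].to_numpy().astype(float)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (s / np.nansum(s)) / (r / np.nansum(r))
    ratio[~np.isfinite(ratio)] = np.nan
    ratio[r <= 0] = np.nan
    auto = ~sample["chrom"].map(_is_sex).to_numpy()
    med = np.nanmedian(ratio[auto & ~sample["blacklist"].to_numpy()])
    ratio = ratio / med
    ploidy = np.where(auto, 2.0, np.nan)
    for chrom, p in (("X", {"XY": 1.0, "XX": 2.0}[reference_sex]),
                     ("Y", {"XY": 1.0, "XX": 0.0}[reference_sex])):
        sel = sample["chrom"].str.replace("chr", "", regex=False) == chrom
        ploidy[sel.to_numpy()] = p if p > 0 else np.nan
    out["ratio"] = ratio
    out["copy_number"] = ratio * ploidy
    out.loc[out["blacklist"], ["ratio", "copy_number"]] = np.nan
    return out


def _best_split(x: np.ndarray, min_bins: int):
    """Best binary split of x by two-sample t statistic; returns
    (index, p_value) or None."""
    n = x.size
    if n < 2 * min_bins:
        return None
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    best = None
    for k in range(min_bins, n - min_bins + 1):
        n1, n2 = k, n - k
        m1 = csum[k - 1] / n1
        m2 = (csum[-1] - csum[k - 1]) / n2
        v1 = max(csq[k - 1] / n1 - m1 * m1, 0.0) * n1 / max(n1 - 1, 1)
        v2 = max((csq[-1] - csq[k - 1]) / n2 - m2 * m2, 0.0) * n2 / max(n2 - 1, 1)
        se = np.sqrt(v1 / n1 + v2 / n2)
        t = abs(m1 - m2) / se if se > 0 else (np.inf if m1 != m2 else 0.0)
        if best is None or t > best[1]:
            best = (k, t)
    if best is None:
        return None
    k, t = best
    if not np.isfinite(t):
        return k, 0.0
    df = max(x.size - 2, 1)
    p = 2.0 * stats.t.sf(t, df)
    return k, p


def segment(profile: pd.DataFrame, alpha: float = 0.01, min_bins: int = 3) -> list[Segment]:
    """Piecewise-constant segmentation of the per-bin copy number.

    Recursive binary splitting: the split maximizing the two-sample t
    statistic is accepted while its p-value falls below ``alpha`` and both
    halves keep at least ``min_bins`` bins (CBS-style).  Chromosomes whose
    bins are all masked yield a single missing segment.
    """
    segments: list[Segment] = []
    for chrom, sub in profile.groupby("chrom", sort=False):
        cn = sub["copy_number"].to_numpy()
        ok = np.isfinite(cn)
        rows = sub.reset_index(drop=True)
        if not ok.any():
            segments.append(
                Segment(chrom, 0, len(rows), int(rows["start"].iloc[0]),
                        int(rows["end"].iloc[-1]), float("nan"), 0)
            )
            continue
        kept = np.flatnonzero(ok)
        vals = cn[kept]

        def recurse(lo: int, hi: int):
            res = _best_split(vals[lo:hi], min_bins)
            if res is not None and res[1] < alpha:
                k = res[0]
                recurse(lo, lo + k)
                recurse(lo + k, hi)
            else:
                i0, i1 = kept[lo], kept[hi - 1]
                segments.append(
                    Segment(
                        chrom=chrom,
                        start_bin=int(i0),
                        end_bin=int(i1) + 1,
                        start=int(rows["start"].iloc[i0]),
                        end=int(rows["end"].iloc[i1]),
                        mean_cn=float(vals[lo:hi].mean()),
                        n_bins=hi - lo,
                    )
                )

        recurse(0, len(vals))
    return segments


def _band_span(cytobands: pd.DataFrame, chrom: str, start: int, end: int) -> str | None:
    sub = cytobands[
        (cytobands["chrom"] == chrom)
        & (cytobands["start"] < end)
        & (cytobands["end"] > start)
    ]
    if sub.empty:
        return None
    bands = sub["band"].tolist()
    return bands[0] if len(bands) == 1 else f"{bands[0]}-{bands[-1]}"


def call_and_classify(
    segments: list[Segment],
    profile: pd.DataFrame,
    cytobands: pd.DataFrame | None = None,
    y_present_cn: float = 0.5,
) -> dict:
    """Round segment means to integer states, classify events, call sex.

    Whole-chromosome events are labeled like "+19"/"-16" (aneuploidy);
    partial events get a cytoband span when a cytoband table is supplied,
    otherwise coordinates.  Sex is called from mean X/Y copy number
    (Y >= ``y_present_cn`` means a Y is present).  Returns a dict with the
    annotated segments, per-event labels, the sex call, and a
    karyotype-style summary string.
    """
    events = []
    usable_per_chrom = (
        profile[np.isfinite(profile["copy_number"])].groupby("chrom", sort=False).size()
    )
    for seg in segments:
        if not np.isfinite(seg.mean_cn):
            seg.state = None
            seg.event_class = None
            continue
        seg.state = max(int(round(seg.mean_cn)), 0)
        chrom_plain = seg.chrom.replace("chr", "")
        if _is_sex(seg.chrom):
            seg.event_class = "neutral"
            continue
        if seg.state == 2:
            seg.event_class = "neutral"
            continue
        whole = seg.n_bins >= usable_per_chrom.get(seg.chrom, 0)
        sign = "+" if seg.state > 2 else "-"
        if whole:
            seg.event_class = "aneuploidy"
            seg.label = f"{sign}{chrom_plain}"
        else:
            seg.event_class = "sub-chromosomal"
            span = _band_span(cytobands, seg.chrom, seg.start, seg.end) if cytobands is not None else None
            loc = span if span else f"{seg.start}-{seg.end}"
            seg.label = f"{sign}{chrom_plain}{span}" if span else f"{sign}{chrom_plain}:{loc}"
        events.append(seg)

    def mean_cn(chrom_plain: str) -> float:
        sel = profile["chrom"].str.replace("chr", "", regex=False) == chrom_plain
        vals = profile.loc[sel, "copy_number"]
        return float(np.nanmean(vals)) if sel.any() and np.isfinite(vals).any() else 0.0

    x_cn, y_cn = mean_cn("X"), mean_cn("Y")
    sex = "XY" if y_cn >= y_present_cn else "XX"

    n_autosomes = profile.loc[~profile["chrom"].map(_is_sex), "chrom"].nunique()
    total = 2 * n_autosomes + 2
    for seg in events:
        if seg.event_class == "aneuploidy":
            total += seg.state - 2
    labels = [seg.label for seg in events]
    karyotype = ",".join([str(total), sex] + labels)
    return {
        "segments": segments,
        "events": events,
        "event_labels": labels,
        "sex": sex,
        "x_mean_cn": x_cn,
        "y_mean_cn": y_cn,
        "karyotype": karyotype,
    }


def shrink_for_plot(values: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    """Display-only transform: within each group, keep the mean and halve
    the variance exactly (x -> mean + (x - mean) / sqrt(2))."""
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(values.shape, dtype=int)
    out = values.copy()
    for g in np.unique(groups):
        sel = (groups == g) & np.isfinite(values)
        if sel.any():
            mu = values[sel].mean()
            out[sel] = mu + (values[sel] - mu) / np.sqrt(2.0)
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_bins": s.n_bins,
                "mean_cn": s.mean_cn,
                "state": s.state,
                "event_class": s.event_class,
                "label": s.label,
            }
            for s in segments
        ]
    )
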