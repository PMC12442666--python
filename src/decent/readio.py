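"""Read records, file formats, and preprocessing rules.

A :class:`MethylRead` carries an aligned bisulfite read together with its
per-base methylation-call string in the Bismark XM dialect:

====== ==============================
symbol meaning
====== ==============================
``Z``  methylated CpG cytosine
``z``  unmethylated CpG cytosine
``H``  methylated CHH cytosine
``h``  unmethylated CHH cytosine
``X``  methylated CHG cytosine
``x``  unmethylated CHG cytosine
``.``  no call (non-cytosine position)
====== ==============================

All coordinates are 0-based half-open.  Reads are stored in reference
orientation; the strand field records which genomic strand the fragment's
5' end lies on and drives the trimming arithmetic.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LABEL_EMBRYONIC = "embryonic"
LABEL_MATERNAL = "maternal"

_METH_ALPHABET = set("ZzHhXxUu.")
_UNMETH_CH = ("h", "x")

TSV_COLUMNS = ["chrom", "start", "strand", "seq", "meth", "label", "read_id", "mate_id", "mate"]


@dataclass
class MethylRead:
    """One aligned read with per-base methylation calls.

    ``mate`` is 1 for R1, 2 for R2, 0 if unknown; ``mate_id`` pairs the two
    mates of a fragment.
    """

    chrom: str
    start: int
    strand: str
    seq: str
    meth: str
    label: str | None = None
    read_id: str = ""
    mate_id: str | None = None
    mate: int = 0

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.meth):
            raise ValueError(
                f"sequence and methylation string lengths differ "
                f"({len(self.seq)} vs {len(self.meth)})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def n_unmethylated_ch(self) -> int:
        return sum(self.meth.count(c) for c in _UNMETH_CH)

    def n_methylated_cpg(self) -> int:
        return self.meth.count("Z")


class ReadSet:
    """An ordered collection of :class:`MethylRead` records.

    Stored column-wise for speed; indexing with an int materializes a
    :class:`MethylRead`, indexing with a slice/array returns a new ReadSet.
    """

    def __init__(self, reads=None, provenance: dict | None = None, **columns):
        if reads is not None:
            reads = list(reads)
            self.chrom = [r.chrom for r in reads]
            self.start = np.array([r.start for r in reads], dtype=np.int64)
            self.strand = [r.strand for r in reads]
            self.seq = [r.seq for r in reads]
            self.meth = [r.meth for r in reads]
            self.label = [r.label for r in reads]
            self.read_id = [r.read_id for r in reads]
            self.mate_id = [r.mate_id for r in reads]
            self.mate = np.array([r.mate for r in reads], dtype=np.int8)
        else:
            n = len(columns["seq"])
            self.chrom = list(columns["chrom"])
            self.start = np.asarray(columns["start"], dtype=np.int64)
            self.strand = list(columns["strand"])
            self.seq = list(columns["seq"])
            self.meth = list(columns["meth"])
            self.label = list(columns.get("label") or [None] * n)
            self.read_id = list(columns.get("read_id") or [""] * n)
            self.mate_id = list(columns.get("mate_id") or [None] * n)
            mate = columns.get("mate")
            self.mate = (
                np.asarray(mate, dtype=np.int8) if mate is not None else np.zeros(n, dtype=np.int8)
            )
        self.provenance: dict = dict(provenance or {})

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            return MethylRead(
                chrom=self.chrom[idx],
                start=int(self.start[idx]),
                strand=self.strand[idx],
                seq=self.seq[idx],
                meth=self.meth[idx],
                label=self.label[idx],
                read_id=self.read_id[idx],
                mate_id=self.mate_id[idx],
                mate=int(self.mate[idx]),
            )
        index = np.arange(len(self))[idx] if isinstance(idx, slice) else np.asarray(idx)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return ReadSet(
            chrom=[self.chrom[i] for i in index],
            start=self.start[index],
            strand=[self.strand[i] for i in index],
            seq=[self.seq[i] for i in index],
            meth=[self.meth[i] for i in index],
            label=[self.label[i] for i in index],
            read_id=[self.read_id[i] for i in index],
            mate_id=[self.mate_id[i] for i in index],
            mate=self.mate[index],
            provenance=dict(self.provenance),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def labels_array(self) -> np.ndarray:
        """Labels as ints (0 embryonic, 1 maternal, -1 unknown)."""
        mapping = {LABEL_EMBRYONIC: 0, LABEL_MATERNAL: 1}
        return np.array([mapping.get(l, -1) for l in self.label], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "strand": self.strand,
                "seq": self.seq,
                "meth": self.meth,
                "label": self.label,
                "read_id": self.read_id,
                "mate_id": self.mate_id,
                "mate": self.mate,
            }
        )

    @staticmethod
    def concat(sets: list["ReadSet"]) -> "ReadSet":
        return ReadSet(
            chrom=sum((s.chrom for s in sets), []),
            start=np.concatenate([s.start for s in sets]) if sets else np.array([], dtype=np.int64),
            strand=sum((s.strand for s in sets), []),
            seq=sum((s.seq for s in sets), []),
            meth=sum((s.meth for s in sets), []),
            label=sum((s.label for s in sets), []),
            read_id=sum((s.read_id for s in sets), []),
            mate_id=sum((s.mate_id for s in sets), []),
            mate=np.concatenate([s.mate for s in sets]) if sets else np.array([], dtype=np.int8),
        )


@dataclass
class RegionTable:
    """Genomic intervals with per-cell-type methylation levels.

    Backed by a DataFrame with at least ``chrom``, ``start``, ``end`` plus
    one column per cell type holding its regional methylation level in
    [0, 1].  Intervals are 0-based half-open.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.table.columns:
                raise ValueError(f"region table missing required column {col!r}")
        if len(self.table) and not (self.table["start"] < self.table["end"]).all():
            raise ValueError("region starts must be < ends (half-open intervals)")
        level_cols = self.level_columns()
        for col in level_cols:
            vals = self.table[col]
            if len(vals) and ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"methylation levels in column {col!r} must lie in [0, 1]")

    def level_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("chrom", "start", "end")]

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# File formats


def write_reads_tsv(readset: ReadSet, path) -> None:
    readset.to_dataframe().to_csv(path, sep="\t", index=False)


def _load_reads_tsv(path) -> ReadSet:
    cols = {c: [] for c in TSV_COLUMNS}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"chrom", "start", "strand", "seq", "meth"} - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"TSV {path} missing required columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                seq, meth = row["seq"], row["meth"]
                if len(seq) != len(meth):
                    raise ValueError("seq/meth length mismatch")
                if row["strand"] not in ("+", "-"):
                    raise ValueError(f"bad strand {row['strand']!r}")
                cols["start"].append(int(row["start"]))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed TSV row at {path}:{lineno}: {exc}") from exc
            cols["chrom"].append(row["chrom"])
            cols["strand"].append(row["strand"])
            cols["seq"].append(seq)
            cols["meth"].append(meth)
            label = row.get("label") or None
            cols["label"].append(None if label in (None, "", "None") else label)
            cols["read_id"].append(row.get("read_id") or "")
            mate_id = row.get("mate_id") or None
            cols["mate_id"].append(None if mate_id in (None, "", "None") else mate_id)
            cols["mate"].append(int(row["mate"]) if row.get("mate") else 0)
    return ReadSet(
        chrom=cols["chrom"],
        start=np.array(cols["start"], dtype=np.int64),
        strand=cols["strand"],
        seq=cols["seq"],
        meth=cols["meth"],
        label=cols["label"],
        read_id=cols["read_id"],
        mate_id=cols["mate_id"],
        mate=np.array(cols["mate"], dtype=np.int8),
    )


def write_reads_bam(readset: ReadSet, path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write reads as BAM/SAM with the methylation string in the XM tag.

    Labels and mate pairing are preserved in auxiliary tags (XL, XP).
    """
    import pysam

    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, start, seq in zip(readset.chrom, readset.start, readset.seq):
            chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), int(start) + len(seq) + 1)
    names = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in names],
    }
    mode = "w" if str(path).endswith(".sam") else "wb"
    with pysam.AlignmentFile(str(path), mode, header=header) as fh:
        for i, read in enumerate(readset):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.read_id or f"read{i}"
            a.query_sequence = read.seq
            a.reference_name = read.chrom
            a.reference_start = read.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(read.seq)}M"
            flag = 0
            if read.strand == "-":
                flag |= 0x10
            if read.mate:
                flag |= 0x1 | (0x40 if read.mate == 1 else 0x80)
            a.flag = flag
            tags = [("XM", read.meth)]
            if read.label:
                tags.append(("XL", read.label))
            if read.mate_id:
                tags.append(("XP", read.mate_id))
            a.set_tags(tags)
            fh.write(a)


def _load_reads_bam(path) -> ReadSet:
    import pysam

    cols = {c: [] for c in TSV_COLUMNS}
    skipped = 0
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.query_sequence is None:
                    skipped += 1
                    continue
                if not rec.has_tag("XM"):
                    skipped += 1
                    continue
                meth = rec.get_tag("XM")
                if len(meth) != len(rec.query_sequence):
                    skipped += 1
                    continue
                cols["chrom"].append(rec.reference_name)
                cols["start"].append(rec.reference_start)
                cols["strand"].append("-" if rec.is_reverse else "+")
                cols["seq"].append(rec.query_sequence)
                cols["meth"].append(meth)
                cols["label"].append(rec.get_tag("XL") if rec.has_tag("XL") else None)
                cols["read_id"].append(rec.query_name or "")
                cols["mate_id"].append(rec.get_tag("XP") if rec.has_tag("XP") else None)
                mate = 0
                if rec.is_paired:
                    mate = 1 if rec.is_read1 else 2
                cols["mate"].append(mate)
    finally:
        pysam.set_verbosity(save)
    if skipped:
        warnings.warn(f"skipped {skipped} records without a usable methylation tag")
    rs = ReadSet(
        chrom=cols["chrom"],
        start=np.array(cols["start"], dtype=np.int64),
        strand=cols["strand"],
        seq=cols["seq"],
        meth=cols["meth"],
        label=cols["label"],
        read_id=cols["read_id"],
        mate_id=cols["mate_id"],
        mate=np.array(cols["mate"], dtype=np.int8),
    )
    rs.provenance["skipped_records"] = skipped
    return rs


def load_reads(path, format: str | None = None) -> ReadSet:
    """Load reads from a TSV read table or a BAM/SAM file with XM tags."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "bam" if path.suffix.lower() in (".bam", ".sam") else "tsv"
    if format == "tsv":
        return _load_reads_tsv(path)
    if format == "bam":
        return _load_reads_bam(path)
    raise ValueError(f"unknown read format {format!r}")


def write_reads(readset: ReadSet, path, chrom_lengths=None) -> None:
    path = Path(path)
    if path.suffix.lower() in (".bam", ".sam"):
        write_reads_bam(readset, path, chrom_lengths)
    else:
        write_reads_tsv(readset, path)


# ---------------------------------------------------------------------------
# Preprocessing rules


def trim_read(read: MethylRead, head_trim: int = 5, target_len: int = 66) -> MethylRead | None:
    """Trim ``head_trim`` bases from the 5' end and truncate the 3' end to
    ``target_len``; returns None (drop) if the read is too short.

    The retained bases are read-coordinate positions
    ``[head_trim, head_trim + target_len)`` counted from the 5' end.  For a
    minus-strand read the 5' end is the right-hand (highest-coordinate) end
    of the stored reference-orientation sequence, so the genomic window and
    the string slice are mirrored accordingly.
    """
    n = len(read.seq)
    if n < head_trim + target_len:
        return None
    if read.strand == "+":
        lo = head_trim
    else:
        lo = n - head_trim - target_len
    hi = lo + target_len
    return replace(
        read,
        start=read.start + lo,
        seq=read.seq[lo:hi],
        meth=read.meth[lo:hi],
    )


def trim_reads(readset: ReadSet, head_trim: int = 5, target_len: int = 66) -> ReadSet:
    """Apply :func:`trim_read` to every read; dropped reads are counted in
    the output provenance under ``n_dropped_short``."""
    kept = []
    dropped = 0
    for read in readset:
        out = trim_read(read, head_trim, target_len)
        if out is None:
            dropped += 1
        else:
            kept.append(out)
    rs = ReadSet(kept, provenance=dict(readset.provenance))
    rs.provenance["n_dropped_short"] = dropped
    return rs


def filter_ch(readset: ReadSet, max_unmeth_ch: int = 3) -> ReadSet:
    """Drop R2 reads with more than ``max_unmeth_ch`` unmethylated-CH calls,
    together with their paired R1 reads.

    Unpaired reads (no mate information) have the rule applied directly.
    An R1 whose R2 passes is never removed.
    """
    n_unmeth = np.array(
        [sum(m.count(c) for c in _UNMETH_CH) for m in readset.meth], dtype=int
    )
    over = n_unmeth > max_unmeth_ch
    bad_fragments = {
        readset.mate_id[i]
        for i in np.flatnonzero(over)
        if readset.mate[i] == 2 and readset.mate_id[i] is not None
    }
    keep = np.ones(len(readset), dtype=bool)
    for i in range(len(readset)):
        mate = readset.mate[i]
        if mate == 2 or mate == 0:
            if over[i]:
                keep[i] = False
        if readset.mate_id[i] is not None and readset.mate_id[i] in bad_fragments:
            keep[i] = False
    out = readset[keep]
    out.provenance["n_removed_ch_filter"] = int((~keep).sum())
    return out


def select_dmr_regions(
    cgi_table: RegionTable,
    target_cell: str = "cumulus",
    others: list[str] | None = None,
    hi: float = 0.80,
    lo: float = 0.20,
) -> RegionTable:
    """Select target-cell-specific hypermethylated regions.

    Keeps autosomal regions whose ``target_cell`` methylation level exceeds
    ``hi`` while every other cell type's level falls below ``lo``.
    """
    df = cgi_table.table
    if target_cell not in df.columns:
        raise KeyError(f"region table has no methylation column {target_cell!r}")
    if others is None:
        others = [c for c in cgi_table.level_columns() if c != target_cell]
    for col in others:
        if col not in df.columns:
            raise KeyError(f"region table has no methylation column {col!r}")
    autosomal = ~df["chrom"].str.replace("chr", "", regex=False).isin(["X", "Y"])
    mask = autosomal & (df[target_cell] > hi)
    for col in others:
        mask &= df[col] < lo
    return RegionTable(df[mask].reset_index(drop=True))


def filter_reads_by_regions(readset: ReadSet, regions: RegionTable) -> ReadSet:
    """Retain reads overlapping any region by at least 1 bp (half-open)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in regions.table.iterrows():
        by_chrom.setdefault(str(row["chrom"]), []).append((int(row["start"]), int(row["end"])))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = (
            np.array([s for s, _ in out], dtype=np.int64),
            np.array([e for _, e in out], dtype=np.int64),
        )
    keep = np.zeros(len(readset), dtype=bool)
    lengths = np.array([len(s) for s in readset.seq], dtype=np.int64)
    for chrom, (starts, ends) in merged.items():
        sel = np.array([c == chrom for c in readset.chrom])
        if not sel.any():
            continue
        rs = readset.start[sel]
        re_ = rs + lengths[sel]
        # candidate interval: the last one whose start is < read end
        idx = np.searchsorted(starts, re_, side="left") - 1
        ok = (idx >= 0) & (ends[np.clip(idx, 0, None)] > rs)
        keep[np.flatnonzero(sel)] = ok
    return readset[keep]
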