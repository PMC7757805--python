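"""Reading, writing and size-classing of CUT&RUN fragment intervals.

All genomic coordinates are 0-based, half-open (BED convention); a
fragment's length is ``end - start``.  Fragments are unstranded spans of
the sequenced paired-end insert.  The canonical on-disk formats are BED3
for fragments (BEDPE tolerated, collapsed to the outer span), BED for
peaks (SEACR output consumed as plain intervals), two-column TSV for
chromosome sizes and bedGraph for coverage tracks.  gzip is handled
transparently by file extension.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Fragment",
    "SampleMeta",
    "FragmentSet",
    "SizeClassScheme",
    "SizeClassCounts",
    "PeakSet",
    "FragmentParseError",
    "read_chrom_sizes",
    "read_fragments",
    "write_fragments",
    "read_peaks",
    "downsample_to_match",
    "classify_sizes",
    "coverage_bedgraph",
]


class FragmentParseError(ValueError):
    """Raised when a fragment/peak file contains malformed records."""


@dataclass(frozen=True)
class Fragment:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"end <= start for {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleMeta:
    """Sample annotation: genotype, profiled mark and replicate id."""

    genotype: str = "WT"  # WT or KO
    antibody: str = "none"  # H3K4me3 / H3K27me3 / H3K9me3 / IgG / none
    replicate: int = 1


@dataclass
class FragmentSet:
    """A sample's mapped paired-end fragments.

    ``df`` has columns ``chrom`` (str), ``start``, ``end`` (int64).  The
    optional ``truth`` frame carries the simulator's per-fragment source
    log (see :mod:`chromacross.synthetic_data`) and is ``None`` for real
    data.
    """

    df: pd.DataFrame
    meta: SampleMeta = field(default_factory=SampleMeta)
    truth: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def subset(self, mask: np.ndarray) -> "FragmentSet":
        truth = self.truth.loc[mask].reset_index(drop=True) if self.truth is not None else None
        return FragmentSet(self.df.loc[mask].reset_index(drop=True), self.meta, truth)

    def total_length(self) -> int:
        return int(self.lengths.sum())


@dataclass(frozen=True)
class SizeClassScheme:
    """Fragment size classes.

    ``small_max`` is inclusive (a 120-bp fragment is sub-nucleosomal,
    equivalently "<121 bp"); ``large_min`` is inclusive (">149 bp" means
    >=150).  Lengths in between are "mid".
    """

    small_max: int = 120
    large_min: int = 150

    def __post_init__(self):
        if self.small_max >= self.large_min:
            raise ValueError("small_max must be < large_min")

    def classify(self, lengths: np.ndarray) -> np.ndarray:
        """Return an array of 'small'/'mid'/'large' labels."""
        out = np.full(len(lengths), "mid", dtype=object)
        out[lengths <= self.small_max] = "small"
        out[lengths >= self.large_min] = "large"
        return out


@dataclass(frozen=True)
class SizeClassCounts:
    small: int
    mid: int
    large: int

    @property
    def total(self) -> int:
        return self.small + self.mid + self.large


@dataclass
class PeakSet:
    """Sorted peak intervals for one histone mark."""

    df: pd.DataFrame  # chrom, start, end [, score]
    mark: str = "none"

    def __post_init__(self):
        self.df = (
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# parsing


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a UCSC-style two-column chrom.sizes TSV into a dict."""
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FragmentParseError(f"{path}:{i}: expected two columns")
            sizes[parts[0]] = int(parts[1])
    return sizes


def read_fragments(path, chrom_sizes: dict[str, int],
                   meta: SampleMeta | None = None, fmt: str = "auto") -> FragmentSet:
    """Read BED3 or BEDPE fragments, validating against ``chrom_sizes``.

    BEDPE records (mate intervals in columns 1-3 and 4-6) are collapsed
    to the outer fragment span.  Malformed lines are reported with line
    numbers; fragments on unknown chromosomes or outside chromosome
    bounds are errors.
    """
    chroms, starts, ends = [], [], []
    errors: list[str] = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            kind = fmt
            if kind == "auto":
                kind = "bedpe" if (
                    len(parts) >= 6
                    and parts[3] in chrom_sizes
                    and parts[4].lstrip("-").isdigit()
                    and parts[5].lstrip("-").isdigit()
                ) else "bed"
            try:
                if kind == "bedpe":
                    c1, s1, e1, c2, s2, e2 = parts[0], int(parts[1]), int(parts[2]), parts[3], int(parts[4]), int(parts[5])
                    if c1 != c2:
                        errors.append(f"line {i}: interchromosomal mate pair")
                        continue
                    c, s, e = c1, min(s1, s2), max(e1, e2)
                else:
                    c, s, e = parts[0], int(parts[1]), int(parts[2])
            except (ValueError, IndexError):
                errors.append(f"line {i}: malformed record {line[:60]!r}")
                continue
            if e <= s:
                errors.append(f"line {i}: end <= start ({s}, {e})")
                continue
            if c not in chrom_sizes:
                errors.append(f"line {i}: unknown chromosome {c!r}")
                continue
            if s < 0 or e > chrom_sizes[c]:
                errors.append(f"line {i}: interval outside {c} bounds")
                continue
            chroms.append(c)
            starts.append(s)
            ends.append(e)
    if errors:
        head = "; ".join(errors[:10])
        raise FragmentParseError(f"{path}: {len(errors)} bad record(s): {head}")
    df = pd.DataFrame({"chrom": chroms,
                       "start": np.asarray(starts, dtype=np.int64),
                       "end": np.asarray(ends, dtype=np.int64)})
    return FragmentSet(df, meta or SampleMeta())


def write_fragments(fs: FragmentSet, path) -> None:
    """Write a FragmentSet as BED3 (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for c, s, e in fs.df.itertuples(index=False):
            fh.write(f"{c}\t{s}\t{e}\n")


def read_peaks(path, mark: str = "none",
               chrom_sizes: dict[str, int] | None = None) -> PeakSet:
    """Read peak intervals (first three BED columns; SEACR output accepted)."""
    chroms, starts, ends = [], [], []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                c, s, e = parts[0], int(parts[1]), int(parts[2])
            except (ValueError, IndexError):
                raise FragmentParseError(f"{path}:{i}: malformed peak record")
            if e <= s:
                raise FragmentParseError(f"{path}:{i}: end <= start")
            if chrom_sizes is not None and (c not in chrom_sizes or e > chrom_sizes[c]):
                raise FragmentParseError(f"{path}:{i}: interval outside chromosome bounds")
            chroms.append(c)
            starts.append(s)
            ends.append(e)
    df = pd.DataFrame({"chrom": chroms,
                       "start": np.asarray(starts, dtype=np.int64),
                       "end": np.asarray(ends, dtype=np.int64)})
    return PeakSet(df, mark)


# ---------------------------------------------------------------------------
# depth matching and size classes


def downsample_to_match(samples: Sequence[FragmentSet], target="min",
                        seed: int = 0) -> list[FragmentSet]:
    """Down-sample every sample to the same fragment count.

    Sampling is uniform without replacement, mirroring the shuf-based
    depth matching applied before WT/KO size-distribution comparisons.
    ``target`` is an integer or ``"min"`` (the smallest sample's size).
    """
    sizes = [len(s) for s in samples]
    if target == "min":
        target = min(sizes)
    target = int(target)
    for s, n in zip(samples, sizes):
        if target > n:
            raise ValueError(
                f"target {target} exceeds sample size {n} "
                f"({s.meta.genotype} {s.meta.antibody} rep{s.meta.replicate})"
            )
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        idx = np.sort(rng.choice(len(s), size=target, replace=False))
        mask = np.zeros(len(s), dtype=bool)
        mask[idx] = True
        out.append(s.subset(mask))
    return out


def classify_sizes(fs: FragmentSet,
                   scheme: SizeClassScheme = SizeClassScheme()) -> SizeClassCounts:
    """Count fragments per size class; classes partition the sample."""
    lengths = fs.lengths
    small = int((lengths <= scheme.small_max).sum())
    large = int((lengths >= scheme.large_min).sum())
    return SizeClassCounts(small=small, mid=len(lengths) - small - large, large=large)


# ---------------------------------------------------------------------------
# coverage


def per_base_coverage(fs: FragmentSet, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Raw per-base fragment depth per chromosome (no normalization)."""
    cov = {}
    for chrom, size in chrom_sizes.items():
        sub = fs.df[fs.df["chrom"] == chrom]
        delta = np.zeros(size + 1, dtype=np.int64)
        if len(sub):
            np.add.at(delta, sub["start"].to_numpy(), 1)
            np.add.at(delta, sub["end"].to_numpy(), -1)
        cov[chrom] = np.cumsum(delta[:-1])
    return cov


def coverage_bedgraph(fs: FragmentSet, chrom_sizes: dict[str, int],
                      out_path=None) -> pd.DataFrame:
    """Genome-mean-normalized coverage as a bedGraph table.

    Depth is scaled so the genome-wide mean depth equals 1 (total mapped
    fragment bases normalized to genome-wide coverage).  Contiguous
    equal-value runs are merged; zero-depth runs are omitted, so
    sum(value * span) over the output equals the genome length.
    """
    if len(fs) == 0:
        raise ValueError("cannot build a coverage track from an empty fragment set")
    genome = sum(chrom_sizes.values())
    mean_depth = fs.total_length() / genome
    rows = []
    for chrom, depth in per_base_coverage(fs, chrom_sizes).items():
        if not depth.any():
            continue
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(depth)]))
        vals = depth[starts] / mean_depth
        keep = vals > 0
        for s, e, v in zip(starts[keep], ends[keep], vals[keep]):
            rows.append((chrom, int(s), int(e), float(v)))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    if out_path is not None:
        out.to_csv(out_path, sep="\t", header=False, index=False, float_format="%.6g")
    return out
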