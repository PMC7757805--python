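"""Peak-level fragment statistics.

Quantifies where sub-nucleosomal fragments arise: FRiP per size class,
per-peak small/large fragment ratios, the per-peak KO/WT
ratio-of-ratios, and a permutation test on cross-replicate concordance
of those log-ratios that separates genome-wide ("global") unwrapping
from locus-specific enrichment.

Fragments are assigned to peaks by >=1 bp overlap (the bedtools-coverage
convention); a fragment overlapping two peaks is counted in both.
Midpoint-containment assignment is available via ``overlap="midpoint"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragment_io import FragmentSet, PeakSet, SizeClassScheme

__all__ = [
    "ConcordanceResult",
    "frip",
    "peak_size_ratios",
    "ratio_of_ratios",
    "replicate_concordance",
]


def _class_subset(fs: FragmentSet, scheme: SizeClassScheme, size_class: str) -> FragmentSet:
    lengths = fs.lengths
    if size_class == "small":
        mask = lengths <= scheme.small_max
    elif size_class == "large":
        mask = lengths >= scheme.large_min
    elif size_class == "all":
        mask = np.ones(len(lengths), dtype=bool)
    else:
        raise ValueError(f"unknown size class {size_class!r}")
    return fs.subset(mask)


def _per_peak_counts(frag_df: pd.DataFrame, peaks: PeakSet,
                     overlap: str = "any") -> np.ndarray:
    """Fragments assigned to each peak (>=1 bp overlap or midpoint rule).

    Counting uses sorted fragment endpoints per chromosome: the number of
    fragments intersecting [ps, pe) is N - #{start >= pe} - #{end <= ps}.
    Double counting across overlapping peaks is intentional.
    """
    counts = np.zeros(len(peaks), dtype=np.int64)
    for chrom, pk in peaks.df.groupby("chrom", sort=False):
        sub = frag_df[frag_df["chrom"] == chrom]
        if not len(sub):
            continue
        if overlap == "midpoint":
            mids = np.sort(((sub["start"] + sub["end"]) // 2).to_numpy())
            lo = np.searchsorted(mids, pk["start"].to_numpy(), side="left")
            hi = np.searchsorted(mids, pk["end"].to_numpy(), side="left")
            counts[pk.index] = hi - lo
        else:
            starts = np.sort(sub["start"].to_numpy())
            ends = np.sort(sub["end"].to_numpy())
            n = len(sub)
            right_of = n - np.searchsorted(starts, pk["end"].to_numpy(), side="left")
            left_of = np.searchsorted(ends, pk["start"].to_numpy(), side="right")
            counts[pk.index] = n - right_of - left_of
    return counts


def _merged_intervals(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = {}
    for chrom, pk in peaks.df.groupby("chrom", sort=False):
        starts, ends = [], []
        for s, e in zip(pk["start"], pk["end"]):
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        merged[chrom] = (np.asarray(starts), np.asarray(ends))
    return merged


def frip(fs: FragmentSet, peaks: PeakSet,
         scheme: SizeClassScheme = SizeClassScheme(),
         size_class: str = "all", overlap: str = "any") -> float:
    """Fraction of reads (fragments) in peaks for one size class.

    A fragment is in peaks if it overlaps any peak by >=1 bp (or has its
    midpoint inside a peak under the midpoint rule).
    """
    sub = _class_subset(fs, scheme, size_class)
    if len(sub) == 0:
        raise ValueError(f"no fragments in size class {size_class!r}")
    merged = _merged_intervals(peaks)
    hits = 0
    for chrom, grp in sub.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        mstarts, mends = merged[chrom]
        if overlap == "midpoint":
            pos = ((grp["start"] + grp["end"]) // 2).to_numpy()
            idx = np.searchsorted(mends, pos, side="right")
            ok = (idx < len(mstarts)) & (mstarts[np.minimum(idx, len(mstarts) - 1)] <= pos)
        else:
            fstart = grp["start"].to_numpy()
            fend = grp["end"].to_numpy()
            idx = np.searchsorted(mends, fstart, side="right")
            ok = (idx < len(mstarts)) & (mstarts[np.minimum(idx, len(mstarts) - 1)] < fend)
        hits += int(ok.sum())
    return hits / len(sub)


def peak_size_ratios(fs: FragmentSet, peaks: PeakSet,
                     scheme: SizeClassScheme = SizeClassScheme(),
                     pseudocount: float = 1.0,
                     overlap: str = "any") -> pd.DataFrame:
    """Per-peak small/large fragment counts and pseudocounted ratio.

    Returns one row per peak with columns ``peak_id, chrom, start, end,
    small, large, ratio`` where ``ratio = (small + pc) / (large + pc)``.
    The pseudocount keeps zero-count peaks finite and positive.
    """
    small = _per_peak_counts(_class_subset(fs, scheme, "small").df, peaks, overlap)
    large = _per_peak_counts(_class_subset(fs, scheme, "large").df, peaks, overlap)
    pk = peaks.df
    return pd.DataFrame({
        "peak_id": [f"{c}:{s}-{e}" for c, s, e in zip(pk["chrom"], pk["start"], pk["end"])],
        "chrom": pk["chrom"],
        "start": pk["start"],
        "end": pk["end"],
        "small": small,
        "large": large,
        "ratio": (small + pseudocount) / (large + pseudocount),
    })


def ratio_of_ratios(ko_rows: pd.DataFrame, wt_rows: pd.DataFrame) -> pd.DataFrame:
    """Per-peak log10(KO small/large ratio / WT small/large ratio).

    Both tables must come from :func:`peak_size_ratios` over the same
    peak universe; values are finite by construction (pseudocount).
    """
    if not ko_rows["peak_id"].equals(wt_rows["peak_id"]):
        raise ValueError("KO and WT ratio tables cover different peak universes")
    log_ratio = np.log10(ko_rows["ratio"].to_numpy() / wt_rows["ratio"].to_numpy())
    return pd.DataFrame({"peak_id": ko_rows["peak_id"], "log10_ratio": log_ratio})


@dataclass
class ConcordanceResult:
    """Cross-replicate concordance of per-peak KO/WT log-ratios.

    ``r2`` is the ordinary-least-squares R^2 of replicate 2's log-ratios
    on replicate 1's; the null distribution comes from shuffling peak
    labels of replicate 2.  ``verdict`` is "locus-specific" when the
    observed R^2 exceeds the 95th null percentile and a minimum-signal
    floor, "global" when it lies within the null band, else
    "indeterminate".
    """

    r2: float
    null_quantiles: dict[str, float]
    verdict: str
    n_peaks: int
    n_permutations: int


def _ols_r2(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(), y.var()
    if vx == 0 or vy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def replicate_concordance(rep1, rep2, n_permutations: int = 1000,
                          seed: int = 0, r2_floor: float = 0.25) -> ConcordanceResult:
    """Permutation test for locus-specific vs global unwrapping.

    If per-peak KO/WT enrichments are reproducible across replicates
    (locus-specific unwrapping) the replicate log-ratio vectors
    correlate; if unwrapping is genome-wide the per-peak excess is
    sampling noise and R^2 falls within the permutation null.
    """
    x = np.asarray(rep1, dtype=float)
    y = np.asarray(rep2, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"replicate vectors differ in length ({len(x)} vs {len(y)})")
    if len(x) < 20:
        raise ValueError("need >= 20 peaks for a meaningful concordance test")
    r2 = _ols_r2(x, y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        null[i] = _ols_r2(x, rng.permutation(y))
    q = {"p50": float(np.quantile(null, 0.50)),
         "p95": float(np.quantile(null, 0.95)),
         "p99": float(np.quantile(null, 0.99))}
    if r2 > q["p95"] and r2 >= r2_floor:
        verdict = "locus-specific"
    elif r2 <= q["p95"]:
        verdict = "global"
    else:
        verdict = "indeterminate"
    return ConcordanceResult(r2=r2, null_quantiles=q, verdict=verdict,
                             n_peaks=len(x), n_permutations=n_permutations)
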