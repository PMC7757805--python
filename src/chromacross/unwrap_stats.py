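"""Sample-level fragment-size statistics.

Diagnoses nucleosome unwrapping from a sample's fragment-length
distribution: size histograms, the observed-vs-expected chi-squared
comparing sub-nucleosomal (<=120 bp) and nucleosomal (>=150 bp) counts
between knockout and wild type after depth matching, the modal
mono-nucleosome footprint, and per-chromosome-class fragment fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fragment_io import FragmentSet, SizeClassCounts

__all__ = [
    "SizeHistogram",
    "ChiSqResult",
    "size_histogram",
    "sizeclass_chisq",
    "modal_mononucleosome_size",
    "chrom_class_fractions",
]


@dataclass
class SizeHistogram:
    """Fragment-length histogram with half-open bins [lo, lo+binwidth)."""

    edges: np.ndarray  # length nbins+1
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def rebin(self, factor: int) -> "SizeHistogram":
        """Merge ``factor`` adjacent bins; conserves the total count."""
        n = len(self.counts)
        pad = (-n) % factor
        counts = np.concatenate([self.counts, np.zeros(pad, dtype=self.counts.dtype)])
        counts = counts.reshape(-1, factor).sum(axis=1)
        edges = self.edges[::factor]
        if len(edges) < len(counts) + 1:
            edges = np.append(edges, self.edges[0] + (len(counts)) * factor * (self.edges[1] - self.edges[0]))
        return SizeHistogram(edges, counts)


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    pvalue: float
    observed: np.ndarray
    expected: np.ndarray


def size_histogram(fs: FragmentSet, binwidth: int = 1) -> SizeHistogram:
    if binwidth < 1:
        raise ValueError("binwidth must be >= 1")
    lengths = fs.lengths
    hi = int(lengths.max()) + binwidth if len(lengths) else binwidth
    edges = np.arange(0, hi + binwidth, binwidth)
    counts, _ = np.histogram(lengths, bins=edges)
    return SizeHistogram(edges, counts)


def sizeclass_chisq(ko: SizeClassCounts, wt: SizeClassCounts,
                    expected_is_exact: bool = False) -> ChiSqResult:
    """Chi-squared of observed KO small/large counts vs WT expectation.

    The two samples are assumed depth-matched upstream.  The statistic is
    the Pearson form sum((O-E)^2/E) over the two reported classes only
    (small and large; mid-size fragments do not enter), with expected
    counts equal to the WT class proportions rescaled to the KO
    small+large total, df = 1.

    Because the expected proportions are themselves estimated from a
    finite WT sample, the naive chi-squared(1) tail of this statistic is
    anticonservative: Var(O - E) = (1 + n/m) * n*q*(1-q) for KO and WT
    small+large totals n and m.  The p-value therefore refers
    ``statistic / (1 + n/m)`` to chi-squared(1).  Set
    ``expected_is_exact=True`` to treat the WT proportions as known
    (naive tail), e.g. when the reference is vastly deeper.
    """
    obs = np.array([ko.small, ko.large], dtype=float)
    ref = np.array([wt.small, wt.large], dtype=float)
    if (ref <= 0).any():
        raise ValueError(
            "WT reference has a zero class count; pool samples or widen classes"
        )
    n, m = obs.sum(), ref.sum()
    exp = ref * (n / m)
    stat = float(((obs - exp) ** 2 / exp).sum())
    scale = 1.0 if expected_is_exact else 1.0 + n / m
    p = float(stats.chi2.sf(stat / scale, df=1))
    return ChiSqResult(statistic=stat, df=1, pvalue=p, observed=obs, expected=exp)


def modal_mononucleosome_size(fs: FragmentSet, min_len: int = 121,
                              smooth_window: int = 5,
                              min_fragments: int = 1000) -> int:
    """Modal length of mono-nucleosome-sized fragments (above 120 bp).

    The 1-bp histogram of lengths >= ``min_len`` is smoothed with a
    centered moving average (``smooth_window`` bp, default 5) and the
    argmax returned; ties break toward the smaller length.
    """
    lengths = fs.lengths
    lengths = lengths[lengths >= min_len]
    if len(lengths) < min_fragments:
        raise ValueError(
            f"only {len(lengths)} fragments >= {min_len} bp "
            f"(need >= {min_fragments}) for a stable mode"
        )
    lo, hi = min_len, int(lengths.max())
    counts = np.bincount(lengths - lo, minlength=hi - lo + 1).astype(float)
    if smooth_window > 1:
        # boundary-corrected moving average: divide by the number of
        # bins actually inside the window so edge modes are not deflated
        kernel = np.ones(smooth_window)
        num = np.convolve(counts, kernel, mode="same")
        den = np.convolve(np.ones_like(counts), kernel, mode="same")
        counts = num / den
    return lo + int(np.argmax(counts))


def chrom_class_fractions(fs: FragmentSet,
                          chrom_classes: dict[str, str]) -> dict[str, float]:
    """Fraction of fragments on autosomes, chrX and chrY.

    ``chrom_classes`` maps chromosome name to one of
    {"autosome", "X", "Y"}; every chromosome in the sample must be
    classified.  Fractions sum to 1.
    """
    chroms = fs.df["chrom"]
    unknown = set(chroms.unique()) - set(chrom_classes)
    if unknown:
        raise ValueError(f"unclassified chromosomes: {sorted(unknown)}")
    out = {"autosome": 0.0, "X": 0.0, "Y": 0.0}
    n = len(fs)
    if n == 0:
        return out
    counts = chroms.map(chrom_classes).value_counts()
    for cls, c in counts.items():
        out[cls] = float(c) / n
    return out
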