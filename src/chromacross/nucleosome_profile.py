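"""Nucleosome calling, fuzziness scoring and center-anchored profiles.

Nucleosome dyads are called from the kernel-smoothed density of
mono-nucleosomal fragment midpoints; a call's "fuzziness" is the
standard deviation (bp) of the midpoints in its window, so
well-positioned nucleosomes score low.  Short-fragment profiles over the
lowest-fuzziness dyads visualize partial unwrapping: sub-nucleosomal
fragments anchor at the 5' or 3' nucleosome edge and extend toward the
dyad, and the mean inward extent of that mass past the edges
("edge penetration") quantifies how deeply MNase has cut into the
nucleosome-protected DNA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .fragment_io import FragmentSet, SizeClassScheme

__all__ = [
    "NucleosomeCall",
    "ProfileMatrix",
    "call_nucleosomes",
    "select_low_fuzziness",
    "centered_profile",
    "edge_penetration",
    "tss_metaprofile",
]


@dataclass(frozen=True)
class NucleosomeCall:
    chrom: str
    dyad: int
    occupancy: int  # fragment midpoints within +/- window/2
    fuzziness: float  # SD of those midpoints, bp


def call_nucleosomes(fs: FragmentSet, chrom_sizes: dict[str, int],
                     window: int = 147, min_support: int = 10,
                     kernel_sd: float = 15.0,
                     mono_only: bool = True) -> list[NucleosomeCall]:
    """Call nucleosome dyads from fragment-midpoint density.

    The per-base midpoint count is smoothed with a Gaussian kernel
    (``kernel_sd`` bp); local maxima separated by at least ``window`` bp
    are dyads.  Each call's occupancy is the midpoint count within
    +/- window/2 of the dyad and its fuzziness the standard deviation of
    those midpoints.  With ``mono_only`` (default) only fragments longer
    than 120 bp contribute, excluding sub-nucleosomal fragments from
    positioning.
    """
    if len(fs) == 0:
        raise ValueError("cannot call nucleosomes from an empty fragment set")
    sub = fs.subset(fs.lengths > 120) if mono_only else fs
    if len(sub) == 0:
        raise ValueError("no mono-nucleosomal fragments (length > 120) in input")
    half = window // 2
    calls: list[NucleosomeCall] = []
    for chrom, grp in sub.df.groupby("chrom", sort=False):
        size = chrom_sizes[chrom]
        mids = ((grp["start"] + grp["end"]) // 2).to_numpy()
        mids = mids[(mids >= 0) & (mids < size)]
        if not len(mids):
            continue
        density = np.bincount(mids, minlength=size).astype(float)
        density = gaussian_filter1d(density, sigma=kernel_sd, mode="constant")
        dyads, _ = find_peaks(density, distance=window)
        mids_sorted = np.sort(mids)
        lo = np.searchsorted(mids_sorted, dyads - half, side="left")
        hi = np.searchsorted(mids_sorted, dyads + half, side="right")
        for d, i, j in zip(dyads, lo, hi):
            occ = int(j - i)
            if occ < min_support:
                continue
            w = mids_sorted[i:j]
            fuzz = float(np.std(w, ddof=1)) if occ > 1 else 0.0
            calls.append(NucleosomeCall(chrom, int(d), occ, fuzz))
    return calls


def select_low_fuzziness(calls: list[NucleosomeCall], n: int = 2000) -> list[NucleosomeCall]:
    """The ``n`` best-positioned (lowest-fuzziness) nucleosome calls.

    Selection is per sample.  Ties break toward higher occupancy, then
    by genomic coordinate; if fewer than ``n`` calls exist all are
    returned with a warning.
    """
    ranked = sorted(calls, key=lambda c: (c.fuzziness, -c.occupancy, c.chrom, c.dyad))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} nucleosome calls available (requested {n})",
            stacklevel=2,
        )
        return ranked
    return ranked[:n]


@dataclass
class ProfileMatrix:
    """Normalized fragment coverage around a set of centers.

    Rows are centers (ordered by descending occupancy when built from
    nucleosome calls), columns are offsets ``-flank..+flank`` bp.
    Values are per-base fragment coverage divided by the sample's
    genome-wide mean coverage for the profiled size class, so a value of
    1 means genome-average depth.
    """

    matrix: np.ndarray
    offsets: np.ndarray
    centers: list[tuple[str, int]]

    def metaprofile(self) -> np.ndarray:
        """Column means across centers."""
        return self.matrix.mean(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=self.offsets)
        df.insert(0, "center", [f"{c}:{p}" for c, p in self.centers])
        df.to_csv(path, sep="\t", index=False, float_format="%.5g")

    def plot(self, path):  # pragma: no cover - optional rendering
        """Write a heatmap + metaprofile PNG (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax0, ax1) = plt.subplots(
            2, 1, figsize=(6, 8), height_ratios=[1, 3], sharex=True)
        ax0.plot(self.offsets, self.metaprofile())
        ax0.set_ylabel("mean normalized coverage")
        ax1.imshow(self.matrix, aspect="auto", cmap="Blues",
                   extent=[self.offsets[0], self.offsets[-1], len(self.centers), 0])
        ax1.set_xlabel("offset from center (bp)")
        ax1.set_ylabel("centers")
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _normalize_centers(centers) -> tuple[list[tuple[str, int]], list[int]]:
    """Accept NucleosomeCall lists or (chrom, pos[, strand]) tuples."""
    out, order_keys = [], []
    for c in centers:
        if isinstance(c, NucleosomeCall):
            out.append((c.chrom, c.dyad))
            order_keys.append(c.occupancy)
        else:
            out.append((c[0], int(c[1])))
            order_keys.append(0)
    return out, order_keys


def centered_profile(fs: FragmentSet, centers, chrom_sizes: dict[str, int],
                     flank: int = 500, size_class: str = "small",
                     scheme: SizeClassScheme = SizeClassScheme()) -> ProfileMatrix:
    """Coverage of class-filtered fragments around each center.

    Centers whose window extends past a chromosome end are dropped.
    Coverage is normalized by the class-filtered sample's genome-wide
    mean depth (see :func:`chromacross.fragment_io.coverage_bedgraph`).
    """
    from .peak_metrics import _class_subset

    sub = _class_subset(fs, scheme, size_class)
    genome = sum(chrom_sizes.values())
    mean_depth = sub.total_length() / genome if len(sub) else 1.0
    if mean_depth == 0:
        mean_depth = 1.0

    pts, occ = _normalize_centers(centers)
    # occupancy-descending row order (stable for plain positions)
    order = np.argsort(-np.asarray(occ), kind="stable")
    pts = [pts[i] for i in order]

    cov: dict[str, np.ndarray] = {}
    for chrom in {c for c, _ in pts}:
        size = chrom_sizes[chrom]
        grp = sub.df[sub.df["chrom"] == chrom]
        delta = np.zeros(size + 1, dtype=np.int64)
        if len(grp):
            np.add.at(delta, grp["start"].to_numpy(), 1)
            np.add.at(delta, grp["end"].to_numpy(), -1)
        cov[chrom] = np.cumsum(delta[:-1])

    offsets = np.arange(-flank, flank + 1)
    rows, kept = [], []
    for chrom, pos in pts:
        if pos - flank < 0 or pos + flank + 1 > chrom_sizes[chrom]:
            continue
        rows.append(cov[chrom][pos - flank: pos + flank + 1] / mean_depth)
        kept.append((chrom, pos))
    matrix = np.vstack(rows) if rows else np.zeros((0, len(offsets)))
    return ProfileMatrix(matrix=matrix, offsets=offsets, centers=kept)


def edge_penetration(profile: ProfileMatrix, footprint: int = 147) -> float:
    """Mean inward extent (bp) of short-fragment mass past nucleosome edges.

    Over columns within +/- footprint//2 of the dyad, computes the
    coverage-weighted center of mass of |offset| and subtracts it from
    footprint//2.  Zero means all mass sits exactly at the edges; larger
    values mean fragments reach deeper toward the dyad.
    """
    half = footprint // 2
    meta = profile.metaprofile()
    mask = np.abs(profile.offsets) <= half
    w = meta[mask]
    if w.sum() == 0:
        raise ValueError("no coverage within the nucleosome footprint")
    com = float((w * np.abs(profile.offsets[mask])).sum() / w.sum())
    return half - com


def tss_metaprofile(fs: FragmentSet, tss, chrom_sizes: dict[str, int],
                    flank: int = 1000, size_class: str = "all",
                    scheme: SizeClassScheme = SizeClassScheme(),
                    plus_strand_only: bool = False) -> ProfileMatrix:
    """Fragment profile over transcription start sites.

    ``tss`` is an iterable of (chrom, position, strand).  Minus-strand
    rows are reversed before averaging so offsets read 5'->3'; with
    ``plus_strand_only`` only + TSSs are used and no row is flipped
    (the convention of plotting + strand genes only).
    """
    tss = list(tss)
    if plus_strand_only:
        tss = [t for t in tss if t[2] == "+"]
    centers = [(c, p) for c, p, _ in tss]
    prof = centered_profile(fs, centers, chrom_sizes, flank=flank,
                            size_class=size_class, scheme=scheme)
    if not plus_strand_only:
        strand = {(c, int(p)): s for c, p, s in tss}
        for i, key in enumerate(prof.centers):
            if strand.get(key) == "-":
                prof.matrix[i] = prof.matrix[i][::-1]
    return prof
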