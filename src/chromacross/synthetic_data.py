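"""Ground-truth simulators for both halves of the pipeline.

Chromatin half — a partial-unwrapping generative model of CUT&RUN
fragments.  Each sampled nucleosome event either releases a wrapped
(mono-nucleosomal) fragment spanning the nucleosome's protected
footprint, or, with probability ``p_unwrap``, a sub-nucleosomal fragment
anchored at one nucleosome edge and extending toward the dyad.  Wild
type carries a fraction of short-footprint (H2A.B-type, 147 - 30 =
117 bp) nucleosomes; the knockout has none, so its mono-nucleosomal
fragments run ~30 bp larger.  Tethered MNase digestion is modeled with
two noise terms: a per-end undigested linker stub (``overhang_range``,
wrapped fragments only) that places the observed mono-nucleosome modes
above the 120-bp sub-nucleosomal cutoff, and Gaussian per-end jitter
(``mnase_jitter_sd``) for over/under-digestion.  A per-fragment truth
log (source nucleosome, wrap state, anchored edge) is attached to every
simulated sample so downstream callers can be tested against ground
truth.

Cross half — a parental-effect model of E14.5 conceptus tables.  Zygote
genotypes follow exact X-linked Punnett expectations; each cross has an
adverse-outcome (resorbed/severely delayed) probability, and normal
conceptuses get fetal and placental weights with multiplicative
paternal/maternal/zygotic deficits and lognormal biological noise.
Litter tables model sires' fertility-assay outcomes (litter sizes, pup
sexes, perinatal-death flags).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cross_effects import punnett_offspring, zygote_lacks_allele
from .fragment_io import FragmentSet, SampleMeta

__all__ = [
    "CANONICAL_FOOTPRINT",
    "H2AB_FOOTPRINT",
    "NucleosomeSpec",
    "GenomeModel",
    "GenomeConfig",
    "build_genome_model",
    "ChromatinGenParams",
    "wt_params",
    "ko_params",
    "simulate_fragments",
    "EffectParams",
    "CrossDesign",
    "simulate_conceptus_table",
    "simulate_litters",
    "write_conceptus_table",
    "read_conceptus_table",
    "synthetic_reference_conceptus_table",
    "synthetic_reference_fertility_tables",
]

CANONICAL_FOOTPRINT = 147  # bp protected by a canonical nucleosome
H2AB_FOOTPRINT = 117  # ~30 bp smaller MNase footprint of H2A.B nucleosomes
MARKS = ("H3K4me3", "H3K27me3", "H3K9me3")


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genome model


@dataclass(frozen=True)
class NucleosomeSpec:
    chrom: str
    dyad: int  # 0-based dyad position
    footprint: int  # protected length, bp
    fuzziness_sd: float  # positional SD, bp
    occupancy: float  # relative sampling weight
    mark: str  # H3K4me3 / H3K27me3 / H3K9me3 / none

    def __post_init__(self):
        if self.footprint <= 0:
            raise ValueError("footprint must be positive")
        if self.fuzziness_sd < 0:
            raise ValueError("fuzziness_sd must be >= 0")
        if self.occupancy < 0:
            raise ValueError("occupancy must be >= 0")


@dataclass
class GenomeModel:
    """Synthetic chromatin landscape with ground-truth annotations."""

    chrom_sizes: dict[str, int]
    chrom_classes: dict[str, str]  # autosome / X / Y
    nucleosomes: list[NucleosomeSpec]
    tss: list[tuple[str, int, str]]
    domains: list[tuple[str, int, int, str]]  # half-open, one mark each
    truth_peaks: list[tuple[str, int, int, str]]

    def nucleosome_frame(self) -> pd.DataFrame:
        """Nucleosome annotations as a DataFrame (cached)."""
        cached = getattr(self, "_nuc_frame", None)
        if cached is None or len(cached) != len(self.nucleosomes):
            cached = pd.DataFrame([asdict(n) for n in self.nucleosomes])
            object.__setattr__(self, "_nuc_frame", cached)
        return cached

    def peaks_for(self, mark: str):
        from .fragment_io import PeakSet

        rows = [(c, s, e) for c, s, e, m in self.truth_peaks if m == mark]
        return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), mark)

    def marks_present(self) -> set[str]:
        return {n.mark for n in self.nucleosomes}

    def to_json(self, path) -> None:
        data = {
            "chrom_sizes": self.chrom_sizes,
            "chrom_classes": self.chrom_classes,
            "nucleosomes": [asdict(n) for n in self.nucleosomes],
            "tss": [list(t) for t in self.tss],
            "domains": [list(d) for d in self.domains],
            "truth_peaks": [list(p) for p in self.truth_peaks],
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path) -> "GenomeModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            chrom_sizes={k: int(v) for k, v in data["chrom_sizes"].items()},
            chrom_classes=data["chrom_classes"],
            nucleosomes=[NucleosomeSpec(**n) for n in data["nucleosomes"]],
            tss=[(c, int(p), s) for c, p, s in data["tss"]],
            domains=[(c, int(s), int(e), m) for c, s, e, m in data["domains"]],
            truth_peaks=[(c, int(s), int(e), m) for c, s, e, m in data["truth_peaks"]],
        )


def _default_chrom_class(name: str) -> str:
    if name.lower().endswith("x"):
        return "X"
    if name.lower().endswith("y"):
        return "Y"
    return "autosome"


@dataclass
class GenomeConfig:
    """Configuration for :func:`build_genome_model`.

    Domains of different marks never overlap, so every nucleosome lies
    in at most one domain; nucleosomes outside all domains carry mark
    "none".  Fuzziness SDs and occupancies are drawn uniformly from the
    given ranges.
    """

    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 400_000, "chrX": 80_000, "chrY": 20_000})
    chrom_classes: dict[str, str] | None = None
    spacing: int = 200
    footprint: int = CANONICAL_FOOTPRINT
    domains_per_mark: dict[str, int] = field(
        default_factory=lambda: {"H3K4me3": 20, "H3K27me3": 8, "H3K9me3": 8})
    domain_width: dict[str, int] = field(
        default_factory=lambda: {"H3K4me3": 2000, "H3K27me3": 5000, "H3K9me3": 5000})
    fuzziness_range: tuple[float, float] = (4.0, 40.0)
    occupancy_range: tuple[float, float] = (0.5, 1.5)
    margin: int = 1000  # domain-free zone at chromosome ends
    seed: int = 0


def build_genome_model(config: GenomeConfig) -> GenomeModel:
    """Lay out nucleosomes, mark domains, truth peaks and TSSs.

    Nucleosome dyads are placed on a regular grid (one per ``spacing``
    bp); truth peaks coincide with the mark domains.  Every H3K4me3
    domain carries one TSS at its center (random strand), emulating
    promoter-proximal active chromatin.  Deterministic per seed.
    """
    if not config.chrom_sizes:
        raise ConfigurationError("no chromosomes configured")
    for name, size in config.chrom_sizes.items():
        if size < 10_000:
            raise ConfigurationError(f"chromosome {name} shorter than 10 kb")
    if config.spacing <= config.footprint:
        raise ConfigurationError("nucleosome spacing must exceed the footprint")

    rng = np.random.default_rng(config.seed)
    classes = dict(config.chrom_classes or {})
    for name in config.chrom_sizes:
        classes.setdefault(name, _default_chrom_class(name))

    # non-overlapping domain slots on a coarse grid across all chromosomes
    max_width = max(config.domain_width.values()) if config.domain_width else 0
    stride = max(2 * max_width, 1)
    slots = [
        (chrom, pos)
        for chrom, size in config.chrom_sizes.items()
        for pos in range(config.margin, size - config.margin - max_width, stride)
    ]
    n_needed = sum(config.domains_per_mark.values())
    if n_needed > len(slots):
        raise ConfigurationError(
            f"genome too small for {n_needed} domains ({len(slots)} slots)")
    picked = rng.permutation(len(slots))[:n_needed]
    domains: list[tuple[str, int, int, str]] = []
    i = 0
    for mark, count in config.domains_per_mark.items():
        width = config.domain_width[mark]
        for _ in range(count):
            chrom, pos = slots[picked[i]]
            domains.append((chrom, pos, pos + width, mark))
            i += 1

    tss = []
    for chrom, start, end, mark in domains:
        if mark == "H3K4me3":
            strand = "+" if rng.random() < 0.5 else "-"
            tss.append((chrom, (start + end) // 2, strand))

    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, start, end, mark in domains:
        by_chrom.setdefault(chrom, []).append((start, end, mark))

    nucleosomes: list[NucleosomeSpec] = []
    half = config.footprint / 2
    for chrom, size in config.chrom_sizes.items():
        dyads = np.arange(config.spacing // 2, size, config.spacing)
        dyads = dyads[(dyads - half >= 0) & (dyads + half <= size)]
        fuzz = rng.uniform(*config.fuzziness_range, size=len(dyads))
        occ = rng.uniform(*config.occupancy_range, size=len(dyads))
        doms = by_chrom.get(chrom, [])
        for d, f, o in zip(dyads, fuzz, occ):
            mark = "none"
            for start, end, m in doms:
                if start <= d < end:
                    mark = m
                    break
            nucleosomes.append(NucleosomeSpec(chrom, int(d), config.footprint,
                                              float(f), float(o), mark))

    return GenomeModel(chrom_sizes=dict(config.chrom_sizes),
                       chrom_classes=classes, nucleosomes=nucleosomes,
                       tss=tss, domains=domains, truth_peaks=list(domains))


# ---------------------------------------------------------------------------
# fragment simulation


@dataclass
class ChromatinGenParams:
    """Parameters of the partial-unwrapping fragment generator.

    ``h2ab_fraction`` is the probability that a WT nucleosome event uses
    the short (117 bp) footprint; knockouts must set it to 0.  The
    default 0.7 reflects that most wild-type mono-nucleosomal fragments
    run at the short-footprint size.  ``p_unwrap`` is the probability
    that an event yields an edge-anchored sub-nucleosomal fragment with
    length uniform on ``unwrap_len_range`` (<= 120 bp by definition of
    the sub-nucleosomal class).  ``overhang_range`` is the per-end
    undigested linker stub (bp, uniform integer, wrapped fragments
    only); ``mnase_jitter_sd`` is Gaussian per-end digestion noise.
    ``boost_intervals``/``p_unwrap_boost`` raise the unwrapping
    probability inside chosen regions, switching the generator from
    genome-wide ("global") to locus-specific unwrapping.
    """

    genotype: str = "WT"
    h2ab_fraction: float = 0.7
    p_unwrap: float = 0.2
    unwrap_len_range: tuple[int, int] = (30, 120)
    overhang_range: tuple[int, int] = (5, 11)
    mnase_jitter_sd: float = 3.0
    off_target_fraction: float = 0.05
    n_fragments: int = 100_000
    seed: int = 0
    p_unwrap_boost: float = 0.0
    boost_intervals: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        for name in ("h2ab_fraction", "p_unwrap", "off_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.unwrap_len_range
        if lo < 25:
            raise ConfigurationError("unwrap_len_range min must be >= 25 bp")
        if hi > 120:
            raise ConfigurationError("unwrap_len_range max must be <= 120 bp")
        if lo > hi:
            raise ConfigurationError("unwrap_len_range min > max")
        if self.genotype == "KO" and self.h2ab_fraction != 0.0:
            raise ConfigurationError("KO samples cannot carry H2A.B nucleosomes")
        if self.n_fragments < 1:
            raise ConfigurationError("n_fragments must be >= 1")


def wt_params(n_fragments: int = 100_000, seed: int = 0, **overrides) -> ChromatinGenParams:
    """Default wild-type generator configuration."""
    return ChromatinGenParams(genotype="WT", n_fragments=n_fragments,
                              seed=seed, **overrides)


def ko_params(n_fragments: int = 100_000, seed: int = 0, **overrides) -> ChromatinGenParams:
    """Default knockout configuration: no short-footprint nucleosomes and
    a higher genome-wide unwrapping probability."""
    overrides.setdefault("h2ab_fraction", 0.0)
    overrides.setdefault("p_unwrap", 0.35)
    return ChromatinGenParams(genotype="KO", n_fragments=n_fragments,
                              seed=seed, **overrides)


def _nucleosome_arrays(model: GenomeModel):
    cached = getattr(model, "_nuc_arrays", None)
    if cached is not None and len(cached[0]) == len(model.nucleosomes):
        return cached
    nf = model.nucleosome_frame()
    arrays = (nf["chrom"].to_numpy(), nf["dyad"].to_numpy(dtype=float),
              nf["footprint"].to_numpy(dtype=float),
              nf["fuzziness_sd"].to_numpy(dtype=float),
              nf["occupancy"].to_numpy(dtype=float), nf["mark"].to_numpy())
    object.__setattr__(model, "_nuc_arrays", arrays)
    return arrays


def simulate_fragments(model: GenomeModel, params: ChromatinGenParams,
                       antibody: str, replicate: int = 1,
                       max_retries: int = 100) -> FragmentSet:
    """Draw fragments from nucleosomes of the requested mark.

    Events sample nucleosomes of ``antibody``'s mark weighted by
    occupancy, plus an ``off_target_fraction`` drawn from all
    nucleosomes.  A wrapped event emits the footprint (117 or 147 bp
    per ``h2ab_fraction``) centered on Normal(dyad, fuzziness_sd), with
    per-end linker overhangs and Gaussian jitter.  An unwrapped event
    emits a fragment anchored at a uniformly chosen 5' or 3' nucleosome
    edge, extending toward the dyad, length uniform on
    ``unwrap_len_range``.  Fragments falling off the chromosome are
    redrawn (bounded retries).  The returned set carries a per-fragment
    ``truth`` frame (nucleosome index, wrap state, footprint, side,
    anchored edge).
    """
    chroms, dyads, foots, fuzz, occ, marks = _nucleosome_arrays(model)
    target = np.flatnonzero(marks == antibody)
    if len(target) == 0:
        raise ValueError(f"no nucleosomes carry mark {antibody!r} in this model")
    rng = np.random.default_rng(params.seed)
    sizes = np.array([model.chrom_sizes[c] for c in chroms], dtype=float)

    p_nuc = np.full(len(dyads), params.p_unwrap)
    for bchrom, bstart, bend in params.boost_intervals:
        inside = (chroms == bchrom) & (dyads >= bstart) & (dyads < bend)
        p_nuc[inside] = np.clip(p_nuc[inside] + params.p_unwrap_boost, 0.0, 1.0)

    w_target = occ[target] / occ[target].sum()
    w_all = occ / occ.sum()
    n = params.n_fragments

    def draw(k: int):
        off = rng.random(k) < params.off_target_fraction
        idx = np.where(
            off,
            rng.choice(len(dyads), size=k, p=w_all),
            target[rng.choice(len(target), size=k, p=w_target)],
        )
        unwrap = rng.random(k) < p_nuc[idx]
        short = rng.random(k) < params.h2ab_fraction
        foot = np.where(short, float(H2AB_FOOTPRINT), foots[idx])
        center = dyads[idx] + rng.normal(0.0, 1.0, size=k) * fuzz[idx]
        jitter = rng.normal(0.0, params.mnase_jitter_sd, size=(k, 2))
        o_lo, o_hi = params.overhang_range
        overhang = rng.integers(o_lo, o_hi + 1, size=(k, 2)).astype(float)
        side = rng.random(k) < 0.5  # True: anchored at the 5' edge
        sub_len = rng.integers(params.unwrap_len_range[0],
                               params.unwrap_len_range[1] + 1, size=k)

        # wrapped fragments: footprint + linker stubs, per-end jitter
        w_start = np.rint(center - foot / 2 - overhang[:, 0] + jitter[:, 0])
        w_len = np.rint(foot + overhang.sum(axis=1) + (jitter[:, 1] - jitter[:, 0]))
        # sub-nucleosomal: anchored at an edge, exact drawn length inward
        edge = np.where(side, center - foot / 2, center + foot / 2)
        anchor = np.rint(edge + jitter[:, 0])
        s_start = np.where(side, anchor, anchor - sub_len)
        s_len = sub_len.astype(float)

        start = np.where(unwrap, s_start, w_start)
        length = np.where(unwrap, s_len, np.maximum(w_len, 1.0))
        end = start + length
        return idx, unwrap, foot, side, edge, start.astype(np.int64), end.astype(np.int64)

    idx, unwrap, foot, side, edge, start, end = draw(n)
    bad = (start < 0) | (end > sizes[idx].astype(np.int64)) | (end <= start)
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_retries:
            raise RuntimeError(
                f"{int(bad.sum())} fragments could not be placed after "
                f"{max_retries} retries; enlarge the genome or margins")
        k = int(bad.sum())
        ridx, runw, rfoot, rside, redge, rstart, rend = draw(k)
        idx[bad], unwrap[bad], foot[bad], side[bad] = ridx, runw, rfoot, rside
        edge[bad], start[bad], end[bad] = redge, rstart, rend
        bad = (start < 0) | (end > sizes[idx].astype(np.int64)) | (end <= start)

    df = pd.DataFrame({"chrom": chroms[idx], "start": start, "end": end})
    truth = pd.DataFrame({
        "nucleosome": idx,
        "wrapped": ~unwrap,
        "footprint": foot.astype(int),
        "side": np.where(unwrap, np.where(side, "5p", "3p"), ""),
        "edge": np.rint(edge).astype(np.int64),
        "dyad": dyads[idx].astype(np.int64),
    })
    meta = SampleMeta(genotype=params.genotype, antibody=antibody, replicate=replicate)
    return FragmentSet(df, meta, truth)


# ---------------------------------------------------------------------------
# conceptus and litter simulation


@dataclass
class EffectParams:
    """Parental-effect model of conceptus outcomes and weights.

    Deficits are fractional weight reductions applied when the
    corresponding contribution of the gene is absent: paternal when the
    sire is KO, maternal when the dam is KO (or HET, if
    ``maternal_haploinsufficient``), zygotic when the zygote carries no
    functional allele.  Defaults make the two parental deficits combine
    multiplicatively to the observed ~30% reduction in fully-KO crosses:
    p = m = 1 - sqrt(0.7).  Adverse-outcome probabilities per
    (dam, sire) genotype default to the observed resorbed/delayed
    fractions: 2.3% WTxWT, 3.7% WTxKO, 1.4% KOxWT, 9.6% KOxKO.
    """

    base_fetal_weight_g: float = 0.25
    base_placental_weight_g: float = 0.09
    cv: float = 0.12
    placental_cv: float = 0.25
    sex_effect: float = 1.05  # male/female weight factor
    paternal_deficit: float = 1.0 - 0.7 ** 0.5
    maternal_deficit: float = 1.0 - 0.7 ** 0.5
    zygotic_deficit: float = 0.0
    maternal_haploinsufficient: bool = True
    resorption_probs: dict = field(default_factory=lambda: {
        ("WT", "WT"): 0.023, ("WT", "KO"): 0.037,
        ("KO", "WT"): 0.014, ("KO", "KO"): 0.096,
    })
    delayed_fraction: float = 0.5  # split of adverse outcomes into delayed vs resorbed
    litter_size: int = 8
    seed: int = 0

    def __post_init__(self):
        for name in ("paternal_deficit", "maternal_deficit", "zygotic_deficit"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        for key, p in self.resorption_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"resorption prob for {key} not in [0, 1]")

    def effective_dam(self, dam: str) -> str:
        if dam == "HET":
            return "KO" if self.maternal_haploinsufficient else "WT"
        return dam


@dataclass(frozen=True)
class CrossDesign:
    dam_genotype: str  # WT / HET / KO
    sire_genotype: str  # WT / KO (hemizygous)
    n_conceptuses: int

    def __post_init__(self):
        if self.sire_genotype not in ("WT", "KO"):
            raise ConfigurationError("sires are hemizygous: WT or KO only")
        if self.n_conceptuses < 1:
            raise ConfigurationError("n_conceptuses must be >= 1")


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-sigma * sigma / 2.0, sigma, size=size))


def simulate_conceptus_table(designs: list[CrossDesign],
                             params: EffectParams) -> pd.DataFrame:
    """Simulate per-conceptus records for a list of crosses.

    Zygote genotypes are drawn from the exact Punnett distribution; the
    outcome is adverse (split into delayed/resorbed) with the cross's
    resorption probability, else normal.  Normal conceptuses get
    weights base x sex_effect x (1 - applicable deficits) x lognormal
    noise; adverse ones carry NaN weights.  Litter ids group consecutive
    conceptuses within a cross.

    Common random numbers: the sex, outcome and noise streams are
    re-seeded identically for every design, so a null configuration
    (all deficits zero, no resorption) yields element-wise identical
    weights across crosses and cross contrasts are variance-reduced.
    """
    if not designs:
        raise ValueError("no cross designs supplied")
    frames = []
    for i, design in enumerate(designs):
        dam, sire = design.dam_genotype, design.sire_genotype
        key = (params.effective_dam(dam), sire)
        if key not in params.resorption_probs:
            raise ConfigurationError(f"no resorption probability for cross {key}")
        n = design.n_conceptuses
        rng_geno = np.random.default_rng([params.seed, 11, i])
        rng_sex = np.random.default_rng([params.seed, 101])
        rng_out = np.random.default_rng([params.seed, 102])
        rng_noise = np.random.default_rng([params.seed, 103])

        dist = punnett_offspring(dam, sire)
        sexes = np.where(rng_sex.random(n) < 0.5, "M", "F")
        zygote = np.empty(n, dtype=object)
        for sex in ("M", "F"):
            opts = [(g, p) for (s, g), p in dist.items() if s == sex]
            genos = [g for g, _ in opts]
            probs = np.array([p for _, p in opts])
            probs = probs / probs.sum()
            mask = sexes == sex
            zygote[mask] = rng_geno.choice(genos, size=int(mask.sum()), p=probs)

        adverse = rng_out.random(n) < params.resorption_probs[key]
        delayed = rng_out.random(n) < params.delayed_fraction
        outcome = np.where(adverse, np.where(delayed, "delayed", "resorbed"), "normal")

        factor = np.ones(n)
        if sire == "KO":
            factor *= 1.0 - params.paternal_deficit
        if params.effective_dam(dam) == "KO":
            factor *= 1.0 - params.maternal_deficit
        lacks = np.array([zygote_lacks_allele(g) for g in zygote])
        factor = factor * np.where(lacks, 1.0 - params.zygotic_deficit, 1.0)
        sexf = np.where(sexes == "M", params.sex_effect, 1.0)

        fetal = (params.base_fetal_weight_g * sexf * factor
                 * _lognormal_noise(rng_noise, params.cv, n))
        placental = (params.base_placental_weight_g * sexf * factor
                     * _lognormal_noise(rng_noise, params.placental_cv, n))
        fetal[adverse] = np.nan
        placental[adverse] = np.nan

        frames.append(pd.DataFrame({
            "dam_genotype": dam,
            "sire_genotype": sire,
            "sex": sexes,
            "zygote_genotype": zygote,
            "outcome": outcome,
            "fetal_weight_g": fetal,
            "placental_weight_g": placental,
            "litter_id": [f"{dam}x{sire}_{i}_{j // params.litter_size}"
                          for j in range(n)],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_litters(n_litters: dict[str, int],
                     mean_size: float = 8.0,
                     dead_prob: dict[str, float] | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate fertility-assay litters per sire genotype.

    Litter sizes are 1 + Poisson(mean_size - 1) (truncated at one live
    pup), pup sexes Bernoulli(1/2), and each litter carries a
    perinatal-death flag Bernoulli(dead_prob[sire]).  Default death
    probabilities are 10% for WT and 18% for KO sires.
    """
    dead_prob = dead_prob or {"WT": 0.10, "KO": 0.18}
    if mean_size < 1:
        raise ConfigurationError("mean litter size must be >= 1")
    for g, p in dead_prob.items():
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"dead-pup probability for {g} not in [0, 1]")
    for g, n in n_litters.items():
        if n < 1:
            raise ConfigurationError(f"n_litters for {g} must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for sire, n in n_litters.items():
        sizes = 1 + rng.poisson(mean_size - 1.0, size=n)
        males = rng.binomial(sizes, 0.5)
        dead = rng.random(n) < dead_prob.get(sire, 0.0)
        for j in range(n):
            rows.append((f"{sire}_{j}", sire, int(sizes[j]), int(males[j]),
                         int(sizes[j] - males[j]), bool(dead[j])))
    return pd.DataFrame(rows, columns=["litter_id", "sire_genotype", "size",
                                       "n_male", "n_female", "any_dead"])


CONCEPTUS_COLUMNS = ["dam_genotype", "sire_genotype", "sex", "zygote_genotype",
                     "outcome", "fetal_weight_g", "placental_weight_g", "litter_id"]


def write_conceptus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_conceptus_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(CONCEPTUS_COLUMNS[:5]) - set(table.columns)
    if missing:
        raise ValueError(f"conceptus table missing columns: {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# synthetic stand-ins for the published per-conceptus / fertility records


def _allocate(n: int, probs: dict) -> dict:
    """Largest-remainder integer allocation of n items to categories."""
    keys = sorted(probs)
    raw = {k: n * probs[k] for k in keys}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    left = n - sum(base.values())
    order = sorted(keys, key=lambda k: raw[k] - base[k], reverse=True)
    for k in order[:left]:
        base[k] += 1
    return base


def synthetic_reference_conceptus_table(seed: int = 2021) -> pd.DataFrame:
    """Synthetic reconstruction of the published E14.5 conceptus records.

    The original per-conceptus spreadsheet is not redistributable here;
    this stand-in is built from the published summary numbers instead:
    adverse-outcome counts of 3/130 (WT x WT, 2.3%), 5/135 (WT x KO,
    3.7%), 2/143 (KO x WT, 1.4%) and 12/125 (KO x KO, 9.6%), and mean
    fetal weights ~30% lower in KO x KO than WT x WT.  Zygote genotypes
    follow exact Punnett proportions (largest-remainder rounding);
    weights are drawn from the parental-effect model with a fixed seed.
    Adverse counts are exact by construction, so the printed percentages
    are reproduced to rounding precision.
    """
    counts = {("WT", "WT"): (130, 3), ("WT", "KO"): (135, 5),
              ("KO", "WT"): (143, 2), ("KO", "KO"): (125, 12)}
    params = EffectParams(seed=seed)
    rng = np.random.default_rng(seed)
    rows = []
    for (dam, sire), (n, k_adverse) in counts.items():
        dist = punnett_offspring(dam, sire)
        alloc = _allocate(n, dist)
        recs = []
        for (sex, geno), m in alloc.items():
            recs += [(sex, geno)] * m
        factor = 1.0
        if sire == "KO":
            factor *= 1.0 - params.paternal_deficit
        if dam == "KO":
            factor *= 1.0 - params.maternal_deficit
        for j, (sex, geno) in enumerate(recs):
            adverse = j < k_adverse
            outcome = ("delayed" if j % 2 == 0 else "resorbed") if adverse else "normal"
            sexf = params.sex_effect if sex == "M" else 1.0
            fw = pw = np.nan
            if not adverse:
                fw = (params.base_fetal_weight_g * sexf * factor
                      * float(_lognormal_noise(rng, params.cv, 1)[0]))
                pw = (params.base_placental_weight_g * sexf * factor
                      * float(_lognormal_noise(rng, params.placental_cv, 1)[0]))
            rows.append((dam, sire, sex, geno, outcome, fw, pw,
                         f"{dam}x{sire}_{j // params.litter_size}"))
    return pd.DataFrame(rows, columns=CONCEPTUS_COLUMNS)


def synthetic_reference_fertility_tables(seed: int = 2021) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic reconstruction of the published fertility-assay records.

    Returns ``(litters, ivf)``.  The litter table has the published
    litter counts (28 sired by WT males, 37 by KO males) with
    dead-pup flags at the published mortality fractions (10% WT, 18%
    KO, rounded to whole litters).  The IVF table uses the published
    per-replicate oocyte totals (WT 126/134/108; KO 144/141/137) with
    2-cell counts whose per-replicate percentages average 66% (WT) and
    71% (KO).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sire, n, n_dead in (("WT", 28, 3), ("KO", 37, 7)):
        sizes = 1 + rng.poisson(7.0, size=n)
        for j in range(n):
            males = int(rng.binomial(sizes[j], 0.5))
            rows.append((f"{sire}_{j}", sire, int(sizes[j]), males,
                         int(sizes[j]) - males, j < n_dead))
    litters = pd.DataFrame(rows, columns=["litter_id", "sire_genotype", "size",
                                          "n_male", "n_female", "any_dead"])
    ivf = pd.DataFrame({
        "replicate": [1, 2, 3, 1, 2, 3],
        "sperm_genotype": ["WT"] * 3 + ["KO"] * 3,
        "n_oocytes": [126, 134, 108, 144, 141, 137],
        "n_2cell": [83, 89, 71, 102, 100, 98],
        "n_blastocyst": [74, 80, 63, 91, 89, 87],
    })
    return litters, ivf
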