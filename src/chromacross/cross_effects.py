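"""X-linked parent-of-origin analysis of embryo viability and weight.

The locus under study is X-linked (the three tightly linked gene copies
are modeled as a single locus with no recombination between them): dams
are WT, HET or KO, sires hemizygous WT or KO.  Zygote genotypes follow
exact Punnett expectations.  The analyses decompose the gene's
contribution to E14.5 conceptus fitness into

* a paternal effect — same zygote genotype (X^KO Y sons), same maternal
  genotype (KO dams), different sires (WT vs KO);
* a maternal effect — same zygote genotype (XY sons), same sires (KO),
  WT vs HET/KO dams;
* a zygotic effect — genetically identical parents (HET dam x KO sire),
  zygotes with vs without a functional allele (XY vs X^KO Y, and
  XX^KO vs X^KO X^KO daughters).

Effect sizes are relative differences of median weight (robust, matching
the nonparametric testing); "adverse" outcomes pool resorbed and
severely delayed conceptuses.

Genotype vocabulary: parents WT / HET / KO; zygotes XY, XKO_Y (males),
XX, X_XKO, XKO_XKO (females).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .unwrap_stats import ChiSqResult

__all__ = [
    "punnett_offspring",
    "ViabilityResult",
    "viability_chisq",
    "WeightContrastResult",
    "weight_contrasts",
    "dunn_posthoc",
    "EffectEstimate",
    "EffectEstimates",
    "decompose_effects",
    "sex_ratio_test",
    "litter_size_tests",
    "mortality_fraction",
    "replicate_proportion_summary",
]

ADVERSE_OUTCOMES = ("resorbed", "delayed")

_DAM_GAMETES = {"WT": (("+", 1.0),), "HET": (("+", 0.5), ("KO", 0.5)), "KO": (("KO", 1.0),)}
_SIRE_X = {"WT": "+", "KO": "KO"}


def punnett_offspring(dam: str, sire: str) -> dict[tuple[str, str], float]:
    """Exact Mendelian (sex, zygote genotype) distribution for a cross.

    Sires are hemizygous, so ``sire`` must be WT or KO; a HET sire is an
    error.  Sexes segregate 1:1 with the X or Y sperm.
    """
    if dam not in _DAM_GAMETES:
        raise ValueError(f"unknown dam genotype {dam!r}")
    if sire not in _SIRE_X:
        raise ValueError(
            f"invalid sire genotype {sire!r}: males are hemizygous (WT or KO only)"
        )
    dist: dict[tuple[str, str], float] = {}
    for allele, p in _DAM_GAMETES[dam]:
        son = "XY" if allele == "+" else "XKO_Y"
        dist[("M", son)] = dist.get(("M", son), 0.0) + 0.5 * p
        alleles = frozenset_pair(allele, _SIRE_X[sire])
        dist[("F", alleles)] = dist.get(("F", alleles), 0.0) + 0.5 * p
    return dist


def frozenset_pair(maternal: str, paternal: str) -> str:
    n_ko = (maternal == "KO") + (paternal == "KO")
    return ("XX", "X_XKO", "XKO_XKO")[n_ko]


def zygote_lacks_allele(genotype: str) -> bool:
    """True when the zygote carries no functional copy (XKO_Y or XKO_XKO)."""
    return genotype in ("XKO_Y", "XKO_XKO")


# ---------------------------------------------------------------------------
# viability


@dataclass
class ViabilityResult:
    cross: tuple[str, str]
    reference_cross: tuple[str, str]
    adverse_fraction: float
    reference_fraction: float
    n: int
    reference_n: int
    chisq: ChiSqResult
    exact_fallback: bool = False


def _cross_mask(table: pd.DataFrame, cross: tuple[str, str]) -> pd.Series:
    return (table["dam_genotype"] == cross[0]) & (table["sire_genotype"] == cross[1])


def _adverse_counts(table: pd.DataFrame, cross: tuple[str, str]) -> tuple[int, int]:
    sub = table[_cross_mask(table, cross)]
    adverse = int(sub["outcome"].isin(ADVERSE_OUTCOMES).sum())
    return adverse, len(sub) - adverse


def viability_chisq(table: pd.DataFrame, cross: tuple[str, str],
                    reference_cross: tuple[str, str] = ("WT", "WT")) -> ViabilityResult:
    """Chi-squared of a cross's adverse/normal counts vs WT expectation.

    Adverse pools resorbed and severely delayed conceptuses.  Observed
    counts of ``cross`` are compared against expected counts from the
    reference cross's proportions (Pearson sum((O-E)^2/E), df=1).  If an
    expected cell is zero, Fisher's exact test on the 2x2 table is used
    instead, with a warning.
    """
    a1, n1 = _adverse_counts(table, cross)
    a0, n0 = _adverse_counts(table, reference_cross)
    tot1, tot0 = a1 + n1, a0 + n0
    if tot1 == 0 or tot0 == 0:
        raise ValueError("cross or reference has no conceptuses")
    obs = np.array([a1, n1], dtype=float)
    exp = np.array([a0, n0], dtype=float) * (tot1 / tot0)
    if (exp == 0).any():
        warnings.warn("zero expected cell; falling back to Fisher's exact test",
                      stacklevel=2)
        _, p = stats.fisher_exact([[a1, n1], [a0, n0]])
        res = ChiSqResult(statistic=float("nan"), df=1, pvalue=float(p),
                          observed=obs, expected=exp)
        fallback = True
    else:
        stat = float(((obs - exp) ** 2 / exp).sum())
        res = ChiSqResult(statistic=stat, df=1, pvalue=float(stats.chi2.sf(stat, 1)),
                          observed=obs, expected=exp)
        fallback = False
    return ViabilityResult(cross=cross, reference_cross=reference_cross,
                           adverse_fraction=a1 / tot1, reference_fraction=a0 / tot0,
                           n=tot1, reference_n=tot0, chisq=res,
                           exact_fallback=fallback)


# ---------------------------------------------------------------------------
# weight contrasts


@dataclass
class WeightContrastResult:
    statistic: float  # Kruskal-Wallis H, tie-corrected
    df: int
    pvalue: float
    groups: pd.DataFrame  # per-group n, median, mean
    posthoc: pd.DataFrame  # Dunn z, raw and adjusted p per pair


def dunn_posthoc(samples: dict[str, np.ndarray],
                 adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with the pooled tie correction T = sum(t^3 - t) / (12 (N - 1)).
    Two-sided p-values are adjusted with Holm (default) or Bonferroni.
    """
    names = list(samples)
    pooled = np.concatenate([samples[g] for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(((t ** 3 - t).sum()) / (12 * (n_total - 1))) if n_total > 1 else 0.0
    mean_ranks, sizes = {}, {}
    i = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = ranks[i:i + n].mean()
        sizes[g] = n
        i += n
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            ga, gb = names[a], names[b]
            se = np.sqrt((n_total * (n_total + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[ga] + 1.0 / sizes[gb]))
            z = (mean_ranks[ga] - mean_ranks[gb]) / se if se > 0 else 0.0
            rows.append((ga, gb, z, 2 * stats.norm.sf(abs(z))))
    out = pd.DataFrame(rows, columns=["group1", "group2", "z", "p_raw"])
    if len(out):
        out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1]
    else:
        out["p_adj"] = []
    return out


def weight_contrasts(table: pd.DataFrame, response: str = "fetal",
                     by: tuple[str, ...] = ("dam_genotype", "sire_genotype",
                                            "sex", "zygote_genotype"),
                     min_per_group: int = 3,
                     adjust: str = "holm") -> WeightContrastResult:
    """Omnibus Kruskal-Wallis on conceptus weights plus Dunn post hoc.

    Groups are cross x sex x zygote genotype by default; only
    normal-outcome conceptuses carry weights.  All-tied data returns
    H = 0, p = 1.
    """
    col = {"fetal": "fetal_weight_g", "placental": "placental_weight_g"}[response]
    sub = table[table["outcome"] == "normal"].dropna(subset=[col])
    groups: dict[str, np.ndarray] = {}
    for key, grp in sub.groupby(list(by), sort=True):
        if len(grp) >= min_per_group:
            name = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
            groups[name] = grp[col].to_numpy()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups with >= 3 observations")
    values = list(groups.values())
    pooled = np.concatenate(values)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*values)
    summary = pd.DataFrame({
        "group": list(groups),
        "n": [len(v) for v in values],
        "median": [float(np.median(v)) for v in values],
        "mean": [float(np.mean(v)) for v in values],
    })
    return WeightContrastResult(statistic=float(h), df=len(groups) - 1,
                                pvalue=float(p), groups=summary,
                                posthoc=dunn_posthoc(groups, adjust=adjust))


# ---------------------------------------------------------------------------
# paternal / maternal / zygotic decomposition


@dataclass
class EffectEstimate:
    name: str
    estimate: float  # fractional weight reduction (median-based)
    ci_low: float
    ci_high: float
    pvalue: float  # two-sided Mann-Whitney
    n_reference: int
    n_test: int


@dataclass
class EffectEstimates:
    paternal: EffectEstimate
    maternal: EffectEstimate
    zygotic: EffectEstimate
    combined_parental: EffectEstimate

    def as_dict(self) -> dict:
        return {
            e.name: {"estimate": e.estimate, "ci95": [e.ci_low, e.ci_high],
                     "pvalue": e.pvalue, "n": [e.n_reference, e.n_test]}
            for e in (self.paternal, self.maternal, self.zygotic,
                      self.combined_parental)
        }


def _weights(table: pd.DataFrame, dam: str, sire: str, zygote: str,
             col: str = "fetal_weight_g",
             litter: bool = False):
    sub = table[_cross_mask(table, (dam, sire))
                & (table["zygote_genotype"] == zygote)
                & (table["outcome"] == "normal")].dropna(subset=[col])
    if len(sub) == 0:
        raise ValueError(f"missing cross {dam} x {sire} (zygote {zygote})")
    w = sub[col].to_numpy()
    lit = sub["litter_id"].to_numpy() if litter and "litter_id" in sub else None
    return w, lit


def _boot_median_ratio(ref: np.ndarray, test: np.ndarray, n_boot: int,
                       rng: np.random.Generator,
                       ref_lit=None, test_lit=None) -> np.ndarray:
    """Bootstrap distribution of 1 - median(test)/median(ref).

    Resampling is by litter cluster when litter ids are supplied,
    otherwise by conceptus.
    """
    def resample(values, lits):
        if lits is None:
            idx = rng.integers(0, len(values), size=(n_boot, len(values)))
            return np.median(values[idx], axis=1)
        uniq = np.unique(lits)
        groups = [values[lits == u] for u in uniq]
        out = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.integers(0, len(groups), size=len(groups))
            out[b] = np.median(np.concatenate([groups[i] for i in pick]))
        return out

    return 1.0 - resample(test, test_lit) / resample(ref, ref_lit)


def _contrast(name: str, ref: np.ndarray, test: np.ndarray, n_boot: int,
              rng: np.random.Generator, ref_lit=None, test_lit=None) -> EffectEstimate:
    est = 1.0 - float(np.median(test)) / float(np.median(ref))
    boot = _boot_median_ratio(ref, test, n_boot, rng, ref_lit, test_lit)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    _, p = stats.mannwhitneyu(ref, test, alternative="two-sided")
    return EffectEstimate(name=name, estimate=est, ci_low=float(lo),
                          ci_high=float(hi), pvalue=float(p),
                          n_reference=len(ref), n_test=len(test))


def decompose_effects(table: pd.DataFrame, response: str = "fetal",
                      n_boot: int = 500, seed: int = 0,
                      stratify_by_litter: bool | None = None) -> EffectEstimates:
    """Decompose paternal, maternal and zygotic weight effects.

    Requires the crosses KO x WT and KO x KO (paternal contrast on
    X^KO Y sons), WT x KO and HET x KO (maternal contrast on XY sons)
    and HET x KO (zygotic contrasts).  Effects are relative differences
    of median weight, with percentile bootstrap 95% CIs (cluster
    bootstrap by litter when litter ids are present) and two-sided
    Mann-Whitney p-values.  ``combined_parental`` composes the paternal
    and maternal effects multiplicatively: 1 - (1-p)(1-m).
    """
    col = {"fetal": "fetal_weight_g", "placental": "placental_weight_g"}[response]
    if stratify_by_litter is None:
        stratify_by_litter = "litter_id" in table.columns
    rng = np.random.default_rng(seed)

    pat_ref, pat_ref_l = _weights(table, "KO", "WT", "XKO_Y", col, stratify_by_litter)
    pat_test, pat_test_l = _weights(table, "KO", "KO", "XKO_Y", col, stratify_by_litter)
    paternal = _contrast("paternal", pat_ref, pat_test, n_boot, rng,
                         pat_ref_l, pat_test_l)

    mat_ref, mat_ref_l = _weights(table, "WT", "KO", "XY", col, stratify_by_litter)
    mat_test, mat_test_l = _weights(table, "HET", "KO", "XY", col, stratify_by_litter)
    maternal = _contrast("maternal", mat_ref, mat_test, n_boot, rng,
                         mat_ref_l, mat_test_l)

    zyg_m_ref, zl1 = _weights(table, "HET", "KO", "XY", col, stratify_by_litter)
    zyg_m_test, zl2 = _weights(table, "HET", "KO", "XKO_Y", col, stratify_by_litter)
    zyg_f_ref, zl3 = _weights(table, "HET", "KO", "X_XKO", col, stratify_by_litter)
    zyg_f_test, zl4 = _weights(table, "HET", "KO", "XKO_XKO", col, stratify_by_litter)
    zm = _contrast("zygotic_male", zyg_m_ref, zyg_m_test, n_boot, rng, zl1, zl2)
    zf = _contrast("zygotic_female", zyg_f_ref, zyg_f_test, n_boot, rng, zl3, zl4)
    zyg_boot = 0.5 * (
        _boot_median_ratio(zyg_m_ref, zyg_m_test, n_boot, rng, zl1, zl2)
        + _boot_median_ratio(zyg_f_ref, zyg_f_test, n_boot, rng, zl3, zl4))
    zlo, zhi = np.quantile(zyg_boot, [0.025, 0.975])
    zygotic = EffectEstimate(
        name="zygotic", estimate=0.5 * (zm.estimate + zf.estimate),
        ci_low=float(zlo), ci_high=float(zhi),
        pvalue=min(1.0, 2 * min(zm.pvalue, zf.pvalue)),
        n_reference=zm.n_reference + zf.n_reference,
        n_test=zm.n_test + zf.n_test)

    comb_boot = 1.0 - (
        (1.0 - _boot_median_ratio(pat_ref, pat_test, n_boot, rng, pat_ref_l, pat_test_l))
        * (1.0 - _boot_median_ratio(mat_ref, mat_test, n_boot, rng, mat_ref_l, mat_test_l)))
    clo, chi = np.quantile(comb_boot, [0.025, 0.975])
    combined = EffectEstimate(
        name="combined_parental",
        estimate=1.0 - (1.0 - paternal.estimate) * (1.0 - maternal.estimate),
        ci_low=float(clo), ci_high=float(chi),
        pvalue=min(1.0, 2 * min(paternal.pvalue, maternal.pvalue)),
        n_reference=paternal.n_reference + maternal.n_reference,
        n_test=paternal.n_test + maternal.n_test)

    return EffectEstimates(paternal=paternal, maternal=maternal,
                           zygotic=zygotic, combined_parental=combined)


# ---------------------------------------------------------------------------
# litters, sex ratios and simple proportions


def sex_ratio_test(n_male: int, n_female: int,
                   dam: str = "WT", sire: str = "WT") -> ChiSqResult:
    """Goodness-of-fit of sexed pup counts vs Punnett sex expectations."""
    dist = punnett_offspring(dam, sire)
    p_male = sum(p for (sex, _), p in dist.items() if sex == "M")
    n = n_male + n_female
    obs = np.array([n_male, n_female], dtype=float)
    exp = np.array([p_male, 1 - p_male]) * n
    stat = float(((obs - exp) ** 2 / exp).sum())
    return ChiSqResult(statistic=stat, df=1, pvalue=float(stats.chi2.sf(stat, 1)),
                       observed=obs, expected=exp)


def litter_size_tests(wt_sizes, ko_sizes) -> dict:
    """Normality and location tests on litter-size distributions.

    Shapiro-Wilk per sire genotype plus a two-sided Mann-Whitney U
    (exact for n <= 20 without ties, else the tie-corrected normal
    approximation via scipy's automatic method selection).
    """
    wt = np.asarray(wt_sizes, dtype=float)
    ko = np.asarray(ko_sizes, dtype=float)
    if len(wt) < 3 or len(ko) < 3:
        raise ValueError("need >= 3 litters per group")
    u, p = stats.mannwhitneyu(wt, ko, alternative="two-sided", method="auto",
                              use_continuity=False)
    return {
        "shapiro_p_wt": float(stats.shapiro(wt).pvalue),
        "shapiro_p_ko": float(stats.shapiro(ko).pvalue),
        "mannwhitney_u": float(u),
        "mannwhitney_p": float(p),
        "mean_wt": float(wt.mean()),
        "mean_ko": float(ko.mean()),
    }


def mortality_fraction(litters: pd.DataFrame, group_col: str = "sire_genotype",
                       reference: str = "WT") -> pd.DataFrame:
    """Per-group fraction of litters with >= 1 dead pup, vs a reference.

    Expects a litter table with a boolean ``any_dead`` column.  Each
    non-reference group is compared to the reference by the same
    observed-vs-expected chi-squared used for viability.
    """
    rows = []
    ref = litters[litters[group_col] == reference]
    if not len(ref):
        raise ValueError(f"no reference group {reference!r}")
    ref_frac = float(ref["any_dead"].mean())
    for name, grp in litters.groupby(group_col, sort=True):
        frac = float(grp["any_dead"].mean())
        if name == reference or len(grp) == 0:
            rows.append((name, len(grp), frac, np.nan, np.nan))
            continue
        obs = np.array([grp["any_dead"].sum(), (~grp["any_dead"]).sum()], dtype=float)
        exp = np.array([ref_frac, 1 - ref_frac]) * len(grp)
        if (exp == 0).any():
            stat, p = np.nan, float(stats.fisher_exact(
                [[int(obs[0]), int(obs[1])],
                 [int(ref["any_dead"].sum()), int((~ref["any_dead"]).sum())]])[1])
        else:
            stat = float(((obs - exp) ** 2 / exp).sum())
            p = float(stats.chi2.sf(stat, 1))
        rows.append((name, len(grp), frac, stat, p))
    return pd.DataFrame(rows, columns=[group_col, "n_litters",
                                       "mortality_fraction", "chisq", "pvalue"])


def replicate_proportion_summary(successes, totals) -> dict:
    """Per-replicate percentages with unweighted mean and sample SD.

    Used for staged outcomes scored across replicate experiments (e.g.
    percentage of embryos reaching the 2-cell stage per IVF replicate).
    SD is reported as None for a single replicate.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if s.shape != t.shape:
        raise ValueError("successes and totals differ in length")
    if (s > t).any():
        raise ValueError("successes exceed totals")
    pct = 100.0 * s / t
    return {
        "percentages": pct.tolist(),
        "mean": float(pct.mean()),
        "sd": float(pct.std(ddof=1)) if len(pct) > 1 else None,
    }
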