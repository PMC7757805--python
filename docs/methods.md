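# Methods

## The partial-unwrapping fragment model

A sample is drawn from a synthetic genome (`GenomeConfig` /
`build_genome_model`): chromosomes with autosome/X/Y class labels,
nucleosome dyads on a regular grid (default spacing 200 bp), each with
a positional SD ("fuzziness", uniform 4–40 bp), a sampling weight
(occupancy, uniform 0.5–1.5), and a mark label (H3K4me3 / H3K27me3 /
H3K9me3 / none) inherited from non-overlapping mark domains. Truth
peaks coincide with the domains; each H3K4me3 domain carries one TSS at
its center, emulating promoter-proximal active chromatin.

`simulate_fragments` draws `n_fragments` events from nucleosomes of the
profiled mark (weighted by occupancy; an off-target fraction, default
5%, from all nucleosomes). Each event:

* with probability `1 − p_unwrap` releases a **wrapped** fragment: the
  nucleosome's protected footprint — 147 bp, or 117 bp with probability
  `h2ab_fraction` in wild type (the H2A.B footprint is ~30 bp shorter)
  — centered on Normal(dyad, fuzziness), extended by a per-end
  undigested **linker stub** (uniform 5–11 bp) and a per-end Gaussian
  digestion **jitter** (SD 3 bp);
* with probability `p_unwrap` releases a **sub-nucleosomal** fragment:
  anchored at a uniformly chosen 5′ or 3′ nucleosome edge and extending
  toward the dyad, length uniform on `unwrap_len_range`
  (default 30–120 bp, the defining cap of the sub-nucleosomal class).

A per-fragment truth log (source nucleosome, wrap state, anchored edge)
accompanies every sample.

Key default choices:

| parameter | default | rationale |
| --- | --- | --- |
| footprints | 147 / 117 bp | canonical vs short-variant MNase protection (~30 bp difference) |
| `h2ab_fraction` (WT) | 0.7 | most wild-type mono-nucleosomal fragments run at the short-footprint size; the in-vivo fraction is not known precisely, so this is a flagged config knob |
| `p_unwrap` | 0.20 WT / 0.35 KO | loss of the variant increases genome-wide unwrapping; magnitudes chosen to give a clearly detectable but not saturated shift |
| linker stub | U{5..11} bp per end (wrapped only) | tethered MNase leaves undigested linker, so observed mono-nucleosome modes sit above the bare footprint — at ~133 bp (WT, short footprint) and ~163 bp (KO), 30 bp apart and both above the 120-bp sub-nucleosomal cutoff, as in real size distributions. Without this term the short-footprint mode (117 bp) would fall below the cutoff and the modal-shift estimate would be truncated |
| jitter | Gaussian, SD 3 bp per end | unparameterized over/under-digestion noise |
| `unwrap_len_range` | (30, 120) bp | least-assumptive uniform on the sub-nucleosomal class; note that observed sub-nucleosomal fragments are mostly ≤80 bp, and the edge-profile analyses use that narrower regime (below) |

Locus-specific (as opposed to genome-wide) unwrapping is simulated by
raising `p_unwrap` by `p_unwrap_boost` inside `boost_intervals` — a
fixed subset of peaks — while the global mode raises it uniformly.

Fragment-length support: `unwrap_len_range[0]` to
`147 + 2·overhang_max + 6·jitter_sd` (±1 bp integer rounding).

## Fragment statistics

* **Size classes.** Small ≤120 bp, large ≥150 bp ("<121" and ">149" are
  the same bounds for integer lengths), mid in between. Samples are
  depth-matched by uniform down-sampling without replacement before any
  KO/WT comparison.
* **Small/large chi-squared.** The statistic is Pearson's
  Σ(O−E)²/E over the two reported classes only, with expected counts
  equal to the reference (WT) class proportions rescaled to the KO
  small+large total (df = 1) — the observed-vs-expected construction of
  the original analysis. Because the reference proportions are
  estimated from a finite sample of total m, Var(O−E) = (1 + n/m)·npq
  and the naive χ²₁ tail is anticonservative (by 2× at n = m); the
  reported p-value therefore refers statistic/(1 + n/m) to χ²₁, which
  simulation shows is calibrated. `expected_is_exact=True` restores the
  naive tail for an effectively infinite reference.
* **Modal mono-nucleosome size.** Argmax of the 1-bp histogram of
  lengths above 120 bp after a boundary-corrected 5-bp centered moving
  average; ties break toward the smaller length (conservative for the
  "KO larger" direction). Requires ≥1,000 qualifying fragments.
* **FRiP and per-peak ratios.** Assignment by ≥1 bp overlap (the
  bedtools-coverage convention; midpoint containment available).
  Fragments overlapping two peaks count in both. Per-peak ratio
  (small + 1)/(large + 1); the pseudocount keeps zero-count peaks
  finite, since the original handling of empty peaks is unstated.
* **Replicate concordance.** R² of OLS between replicate per-peak
  log₁₀(KO/WT ratio-of-ratios) vectors against a peak-label permutation
  null. Verdict: locus-specific iff R² exceeds the 95th null percentile
  and a minimum-signal floor (0.25); global iff within the null band;
  indeterminate otherwise. The floor and percentile are stated
  defaults formalizing a qualitative argument, not published values;
  by construction a truly global pair is mislabeled at the ~5%
  permutation type-I rate.

## Nucleosome calling and profiles

Dyads are local maxima (minimum separation one footprint) of the
Gaussian-smoothed (SD 15 bp) density of mono-nucleosomal (>120 bp)
fragment midpoints; a call's occupancy is the midpoint count within
±window/2 and its fuzziness the plain standard deviation of those
midpoints. This is a deliberately simple positioning-and-fuzziness
scorer: the analyses only need a fuzziness *ranking* to pick the
top-N best-positioned nucleosomes per sample (default 2,000; ties by
higher occupancy, then coordinate), not a full occupancy-differential
framework.

Profiles count class-filtered fragment coverage per base at offsets
±flank around each center, scaled by the sample's genome-wide mean
depth for that class (so 1 = genome average); rows are ordered by
descending occupancy, and the metaprofile is the column mean. TSS
profiles flip minus-strand rows (or restrict to + strand). No
additional per-row scaling is applied.

**Edge penetration** summarizes how deep sub-nucleosomal mass reaches:
over offsets within ±footprint//2, the coverage-weighted center of mass
of |offset| subtracted from footprint//2 — 0 when all mass sits at the
edges, footprint//2 when all mass is at the dyad. Note a geometric
subtlety: with sub-fragment lengths uniform up to 120 bp, fragments
anchored at opposite edges overlap over the dyad and the coverage
metaprofile flattens; the edge-peaked shape seen in real data
corresponds to the mostly-≤80 bp regime, which the profile-shape tests
therefore use.

## The parental-effect cross model

Zygote genotypes follow exact X-linked Punnett expectations (the three
tightly clustered gene copies are treated as one locus without
recombination; sires are hemizygous, so a HET sire is an error). Each
conceptus is adverse (resorbed or severely delayed, pooled for
probability draws and split 50/50 for table realism) with a
(dam, sire)-specific probability — defaults 2.3% WT×WT, 3.7% WT×KO,
1.4% KO×WT, 9.6% KO×KO. Normal conceptuses get weights

    base × sex_factor × (1 − paternal·[sire KO]) × (1 − maternal·[dam KO])
         × (1 − zygotic·[zygote lacks a functional allele]) × lognormal(CV)

with base fetal weight 0.25 g and placental 0.09 g (typical E14.5
values), CV 12% fetal / 25% placental, male factor 1.05. Default
deficits: paternal = maternal = 1 − √0.7 ≈ 0.163 (so both-parents-KO
combines multiplicatively to the observed ~30% reduction), zygotic = 0.
HET dams default to KO-like behavior (`maternal_haploinsufficient`),
matching the observed haploinsufficiency; overridable. The sex,
outcome and weight-noise random streams are re-seeded identically per
cross (common random numbers), so a null configuration yields
element-wise identical weights across crosses.

A caveat on model form: in the real data the reciprocal single-KO
crosses weigh close to wild type while the double-KO cross is ~30%
down, i.e. the observed effects look epistatic rather than independent.
The independent multiplicative form is kept because the decomposition
below estimates exactly its parameters; its single-parent predictions
(~16% reduction in reciprocal crosses) overstate the published
reciprocal-cross effect.

`decompose_effects` estimates each deficit as a relative difference of
median weights between groups that differ only in the targeted
contribution: paternal from X^KO Y sons of KO dams by WT vs KO sires;
maternal from XY sons of KO sires by WT vs HET dams; zygotic within
HET × KO from XY vs X^KO Y sons and XX^KO vs X^KO X^KO daughters
(averaged). CIs are percentile bootstrap (cluster-resampled by litter
when litter ids are present); p-values are two-sided Mann–Whitney.
Medians make the estimates robust and consistent with the
nonparametric testing; group means are also reported. Kruskal–Wallis
omnibus tests use SciPy's tie correction; post hocs are Dunn's test
(pooled tie correction) with Holm adjustment by default (Bonferroni
optional), since the original analysis names only "multiple
comparisons" after Kruskal–Wallis.

## Synthetic reference tables

The published per-conceptus and fertility spreadsheets are not
redistributable, so `synthetic_reference_conceptus_table` and
`synthetic_reference_fertility_tables` reconstruct stand-ins from the
published summary numbers: exact adverse counts (3/130, 5/135, 2/143,
12/125), Punnett-proportional genotypes, model-drawn weights (fixed
seed), the published litter counts (28 WT-sired, 37 KO-sired) and
per-replicate IVF oocyte totals with 2-cell percentages averaging 66%
(WT) and 71% (KO). These files exist so the summary statistics can be
recomputed end-to-end through the same code paths real tables would
take; they are synthetic and carry no information beyond the published
summaries they encode.

## What the generators do and do not emulate

Emulated: tri-modal fragment-size structure; edge-anchored
sub-nucleosomal fragments; genotype-dependent unwrapping; mark-specific
peak domains; depth imbalance between samples; cross-dependent
resorption rates, parental weight effects and litter structure.

Not emulated: sequence content (no reads, no mappability), PCR
duplicates, antibody efficiency, spike-ins, chromatin-state
autocorrelation along the genome beyond domains, litter-level
covariance of weights (litters only group records for the bootstrap),
gestational-age variation, and the epistatic parental interaction noted
above. Passing tests therefore demonstrate estimator correctness under
the stated generative model, not robustness to every artifact of real
sequencing data.

## Numerical choices and problem sizes

Coordinates are 0-based half-open throughout; lengths are end − start.
Coverage normalization scales genome-wide mean depth to 1 and omits
zero runs, so Σ(value × span) equals the genome length. Down-sampling,
permutation and bootstrap procedures take explicit seeds; generators
are deterministic per seed. Degenerate inputs are errors rather than
silent results (empty fragment sets, all-zero classes, missing
crosses), except all-tied Kruskal–Wallis input, which returns H = 0,
p = 1.

The test suite and the acceptance script run on deliberately scaled
problems — a few-hundred-kb genome, 2×10³–2×10⁵ fragments per sample,
2×10³ conceptuses per cross, 50–5,000 simulation replicates — sizes at
which every stochastic check has comfortable Monte-Carlo margins while
the whole suite stays fast on one CPU.
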