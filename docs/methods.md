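# Methods

This note documents the models, numerical choices, and design decisions
behind `breedscan`, and what the synthetic-data studies do and do not
demonstrate.

## 1. Data model

Panels are fully inbred lines; genotypes are biallelic SNP alt-dosages in
{0, 1} with missing as NaN (heterozygous diploid calls are treated as missing
by default, since a het call in a fixed line usually flags a genotyping
artifact; a `het_policy="half"` midpoint coding is available for robustness
checks). Coordinates are 1-based VCF convention on a 12-chromosome genome.

Variant QC follows the rule "minor-allele frequency below 5 % removed,
missing rate at or above 10 % removed", read literally: a variant is kept iff
MAF ≥ 0.05 (computed over non-missing calls) *and* missingness < 0.10. The
filter is idempotent and the boundary semantics are pinned by tests.

Candidate heading-date genes are declared in a YAML gene-definition file:
ordered haplotype rules (required alt-dosages at defining positions; first
full match wins), an activity map (haplotype → 0/1 code, 0 = lower activity),
and an expected DTH sign (+1 when the active haplotype delays heading, −1
when it promotes early heading). The shipped default covers Hd1 (four
haplotypes; the three characterized deletions are represented as biallelic
tag SNPs, an untagged functional pattern is Hap A), Hd2, Hd6, Hd16, Hd17 and
Hd18 as single-SNP definitions. The Hd17 defining position is set to
2,235,191 (the published digit grouping of this coordinate is ambiguous;
it is configurable).

## 2. Mixed-model association scan

Model: `y = Xβ + u + e`, `u ~ N(0, σ²_g K)`, `e ~ N(0, σ²_e I)`, with
`K = ZZᵀ / Σ_k p_k(1−p_k)`, `Z` the per-variant allele-frequency-centered
dosage matrix, missing dosages mean-imputed (hence zero after centering).

- **REML.** One eigendecomposition `K = U D Uᵀ`; profile REML over
  `log λ ∈ [−10, 10]` (`λ = σ²_g/σ²_e`) by bounded Brent search
  (`xatol 1e-8`). An optimum within 1e-3 of the bounds is flagged: with
  `K = I` the profile is exactly flat (λ unidentifiable) and any value is
  equivalent; the scan is unaffected because constant eigenvalue weights
  cancel, making the per-marker test identical to OLS (verified to 1e-8).
- **P3D/EMMAX.** Variance components are estimated once under the null design
  (intercept + covariate markers) and reused per marker; exact per-marker
  REML is available behind `ScanConfig(exact_reml=True)`. Per marker, GLS of
  the rotated, weighted data; two-sided p from t with df = n − rank(design).
  Markers with zero variance or |r| > 0.999 against a covariate yield
  missing results (a marker conditioned on itself is missing by
  construction).
- **Thresholds.** Significance 5×10⁻⁸, suggestive 1×10⁻⁵.
- **Peaks.** Greedy clumping per year among variants above the suggestive
  threshold: the top variant seeds a peak and absorbs variants within ±1 Mb
  or with r² ≥ 0.4 to the seed (both configurable); clusters overlapping in
  every scanned year are `consistent-across-years`. Peak disappearance under
  conditioning is operationalized as: maximum −log₁₀P inside the target
  interval < suggestive threshold → `LD-shadow`, else `independent`. The
  published account describes disappearance qualitatively; the suggestive
  threshold is the natural numeric cut.
- **Diagnostics.** λ_GC = median(χ²_obs)/0.4549 (the 1-df χ² median) plus
  expected-vs-observed Q–Q quantile pairs.

## 3. Correlation and partial-correlation triage

Activity codes are 0/1, so the point-biserial (code↔DTH) and phi (code↔code)
coefficients are plain Pearson correlations — which is what makes the joint
partial-correlation analysis legitimate. Within one analysis (one population
stratum × one year): listwise deletion to the complete-case set (the reported
n), genes monomorphic in the stratum dropped with a warning.

Partial correlation of gene *i* with DTH given all other genes, from the
precision matrix `P = R⁻¹` of the (k+1)×(k+1) joint correlation matrix:
`r_p = −P[i,y]/√(P[i,i]P[y,y])`; two-sided p from
`t = r_p √(df/(1−r_p²))` with `df = n − 2 − (k−1)` (k−1 conditioned
variables). A singular R raises an error naming φ = ±1 gene pairs. Holm
step-down adjustment is applied within the k genes of one analysis (the
family matching one published table column); `holm_adjust` can pad the family
to a declared m.

**Triage rule** (α = 0.05 on Holm-adjusted p, φ_min = 0.25):

1. `consistent` — marginal and partial both significant, same sign;
2. `type-I-candidate` — marginal significant, partial not, and max |φ| with a
   consistent gene ≥ φ_min (the marginal signal is plausibly borrowed
   through LD);
3. `type-II-candidate` — partial significant while marginal is not, **or**
   marginal and partial signs differ with the partial matching the gene's
   expected sign *and at least nominally significant (raw p < α)*;
4. `null` otherwise.

The nominal-significance guard on the sign-flip branch is a deliberate
design choice: without it, any near-zero pair of correlations that happens to
straddle zero in the expected direction would be flagged, and null genes
would be mislabeled at far above the tolerated rate. With the guard, a null
gene is flagged ≈2 % of the time while the planted masked gene is still
recovered in ≈99 % of panels (measured by the benchmark study). φ_min = 0.25
operationalizes "an LD relationship was observed" and is configurable.

## 4. Selection scan

Per-period haplotype (or AND-combination) carrier fractions exclude lines
with a missing call at any focal gene from numerator and denominator.
Transitions are tested by the two-sided Fisher exact test under the
probability-mass rule (sum of hypergeometric outcomes no more probable than
the observed table) — scipy's convention, verified against exhaustive
enumeration for all tables with margins ≤ 12. Zero-margin tables report
p = 1 with a warning.

Nei's normalized-identity distance is applied **per SNP** (the genome-scan
usage) between two period subpopulations:
`D = −ln(J_xy/√(J_x J_y))`. `J_xy = 0` (opposite fixation) is capped at
D = 10 and flagged — `−ln` of a machine-epsilon identity would be
meaningless. Thresholds are the 95th/90th percentiles of D within each
chromosome. Window aggregation is intentionally not implemented; per-SNP
resolution is what localizes the selected genes.

## 5. Haplotype-combination (G×G) analysis

Within a stratum fixed by a splitter gene's code (default Hd1 — strata are
defined by activity code, not by breeding-report heading class), lines are
partitioned by the code combination of the interacting genes; per-year
mean/SD/n per group. Pairwise tests are pooled-variance Student t;
Tukey–Kramer all-pairs comparisons use
`q = |m_i − m_j| / √(MSE/2 (1/n_i + 1/n_j))` with MSE pooled over all k
groups and the **exact** studentized-range distribution
(`scipy.stats.studentized_range`, k groups, N−k df). At k = 2 this reduces
exactly to the two-sided pooled t-test — a property the table-approximation
in statsmodels' `pairwise_tukeyhsd` cannot reproduce, which is why the
statistic is computed here directly. Compact letters are assigned greedily by
descending group mean; a group joins every compatible letter class, ties
resolved by label order.

## 6. The breeding-panel simulator

The simulator generates the statistical structure the analysis stack is
built to detect, with full ground truth.

**Genetic model.** DTH = μ + year offset + Σ_g β_g·c_g·m_g + ε, with c_g the
0/1 activity code, m_g the product of applicable epistasis multipliers
(1 when no rule fires), ε ~ N(0, σ²_e). Defaults: μ = 63 d, β = {Hd1 +13,
Hd16 +8, Hd17 −7, Hd18 −2, Hd2 0, Hd6 0} d, σ_e = 2.5 d, year offsets
{2019: 0, 2020: +2, 2021: +4} d; gates: Hd17's effect ×0 when Hd16 is active
(the promoter is expressed only on the inactive-repressor background) and
Hd18's effect ×2.5 when Hd16 is active. Effect sizes are sized to the
observed haplotype-group mean differences; they are defaults, not ground
truth, and fully configurable.

**Breeding mechanism.** The historical pedigree is not recorded anywhere, so
breeding is modeled as the simplest mechanism that yields co-selection LD:
per period, random biparental crosses among the previous period's lines
(founders for period I), gametes formed with Poisson crossover counts per
chromosome (Haldane map function, default 4 cM/Mb), each progeny made fully
inbred by doubling one recombinant gamete, progeny phenotyped with noise, and
survivors truncation-selected into the period's DTH window — topped up with
the nearest-to-window progeny so the output is exactly n_lines.

**Defaults as study conditions.** Four periods (93/55/54/50 lines,
~252 total), 80 founders, 60 crosses × 8 progeny per period, selection
windows narrowing (65,90) → (69,80) → (70,77.5) → (71.5,77.5) d — a breeder
homing in on the 70–80 d optimum. Founder code-1 frequencies: Hd1 fixed
functional (the panel models the functional-Hd1 stratum where the Hd16/Hd17
co-selection story plays out), Hd16 0.65, Hd17 0.55, Hd18 0.5, Hd2 0.9,
Hd6 0.25, with founder LD φ = 0.3 between Hd6 and Hd16 (they sit 1.5 Mb
apart on chromosome 3; their LD predates the program and persists, making
the effect-free Hd6 the panel's built-in Type I candidate). Under these
conditions the inactive-Hd16/late-Hd17 combination rises monotonically to
~70–95 % by period IV, panel-wide φ(Hd16, Hd17) lands around 0.3–0.45, and
the Nei scan flags both loci — the co-selection structure the analysis must
expose. Windows wider than these let the Hd18-amplified class (genetic value
≈79 d) shelter the active Hd16 allele and stall the sweep; the narrowed
defaults were fixed at design time for that reason.

**RNG.** One root seed; founder, per-period, and phenotyping streams are
derived by fixed offsets (`SeedSequence([seed, k])`), so adding a period
does not perturb earlier ones. Same config + seed ⇒ byte-identical outputs.

**Direct scenario generators.** Two benchmark scenarios plant the confounding
structure directly rather than growing it through breeding, because their
defining condition is the correlation itself:

- `sample_coded_panel` (masked-effect study): confounder (+8 d) and masked
  gene (−7 d, expressed only on the inactive-confounder background) with
  codes correlated at φ = 0.4 exactly (0.5 margins), plus independent null
  genes; n = 150, σ_e = 2.5.
- `simulate_ld_panel` (LD-shadow study): one causal locus (+8 d) and one
  unlinked zero-effect hitchhiker at φ = 0.4, embedded in a dense iid
  neutral genome — 600 lines × ~4,800 markers. The density matters: in a
  sparse synthetic genome the planted causal direction carries weight ~n/m
  in the kinship and the mixed model itself absorbs the hitchhiker's
  indirect signal (proximal contamination), so no spurious peak would form;
  a small n/m ratio reproduces the dense-genotyping regime in which
  LD-shadow peaks actually arise.

**What the simulations do not show.** The generator draws neutral variants
in linkage equilibrium within chromosomes (no local LD blocks), uses a
uniform recombination rate, one generation per breeding period, no
marker-assisted or multi-trait selection, and Gaussian residuals with a
shared σ_e. Passing benchmarks therefore demonstrate that the statistical
machinery detects breeding-induced trans-chromosomal LD and gated effects
under the stated conditions — not that it is robust to fine-scale LD
structure, G×E interaction, or phenotyping error models found in real field
data.

## 7. Benchmark studies (scripts/acceptance.py)

All studies derive their randomness from `--seed` and re-run the full public
API. Problem sizes: masked-effect recovery 100 panels × 150 lines; LD-shadow
classification 40 panels × 600 lines × ~4,800 markers; LMM calibration one
30-line K = I fixture plus 40 null panels × 120 lines × 400 markers; Fisher
enumeration all 2×2 tables with margins ≤ 12; selection scan 50 default
breeding panels; filter contract one constructed 100-line × 4-variant VCF.
The whole script runs in a few minutes on one CPU.

## 8. Known limitations

- The per-SNP kinship uses all markers including the tested one (no
  leave-one-chromosome-out); with dense markers the proximal-contamination
  bias is small, but scans on very sparse marker sets will be conservative
  near major loci.
- Multiallelic VCF records are skipped (with a count), not split.
- The pipeline's caching is seed-determinism of the run directory, not
  content-addressed staging; re-running a stage re-computes it.
- The triage rule is a decision heuristic, not an inference procedure: its
  error rates are calibrated on the simulator's conditions and should be
  re-examined before porting to panels with very different LD structure.
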