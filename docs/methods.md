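# Methods

## Model

`selscape` treats somatic mutation accumulation at each amino-acid site of a
gene as a Poisson process and asks whether the per-site missense counts are
consistent with a single passenger rate or require a minority of
recurrently hit driver sites.

**Gene level.** The selection ratio is C_N/C_S = (N/L_N)/(S/L_S). N and S
are the observed missense and synonymous substitution counts after
annotation against the selected coding transcript; stop-gain/-loss,
splice-region and other non-missense/non-synonymous classes are excluded
from both counts. L_N and L_S are rate-weighted expected site counts: every
possible single-nucleotide change in the CDS (terminal stop codon excluded)
contributes the relative rate of its trinucleotide-context class to L_N if
it is missense and to L_S if synonymous. Under a uniform spectrum this
reduces exactly to classical potential-site counting, and the ratio L_N/L_S
is invariant to the spectrum's overall scale.

The among-site heterogeneity of the latent per-site rate r is
H = 1 − (E[r])²/E[r²]. Its moment estimator from the per-codon missense
count vector z is H = (var(z) − z̄)/(var(z) + z̄(z̄−1)), with population
variance, clamped to [0, 1]; H is undefined when z̄ = 0. The interval
(1−H, 1) is the band in which positive selection at some sites coexists
with constraint at others, so each gene is tested twice with a two-cell
Pearson χ² on (N, S) — expected fractions proportional to (ρ·L_N, L_S) —
against ρ = 1 and ρ = 1−H (df = 1; directional claims use the one-sided
convention p/2 in the tested direction, 1 − p/2 otherwise, so a deviation
the wrong way is never significant).

**Site level.** Genes with C_N/C_S > 1−H pass to the mixture layer. Driver
sites occur with probability η; their excess rate λ is Gamma(α, β) with
mean m₁ − m₀, so driver counts are approximately negative binomial with
mean m₁ and shape α (exact when m₁ ≫ m₀), and

f(z) = (1−η)·Pois(z; m₀) + η·NB(z; m₁, α).

Given m₀ and α, (m₁, η) follow from the first two moments of z. The
default inversion is the closed-form approximation
m₁ = ((var−z̄)/(z̄−m₀) + z̄ + m₀/α)/(1 + 1/α), η = (z̄−m₀)/(m₁−m₀),
accurate in the m₁ ≫ m₀ regime it assumes; the exact inversion (a
quadratic in m₁ − m₀) is available as `mom_mode="exact"` and recovers the
generating parameters to machine precision on noiseless moments. η is
truncated to [0, 1] (flagged), and z̄ ≤ m₀ yields η = 0, no driver
component.

α is treated as a single cohort-wide constant: it is fitted once by
maximising the summed mixture log-likelihood over all gate-passing,
overdispersed genes, profiling (m₁, η) per gene through the moment
equations at each candidate α (bounded search on [0.05, 100] in log
space). When no gene shows excess variance the fit falls back, with a
flag, to 1.51 — the value obtained on the TCGA pan-cancer cohort — and
`fixed_alpha` can pin it explicitly.

The presence of a driver component is tested with an approximate LRT,
Λ = 2[ℓ(mixture at the moment estimates) − ℓ(Poisson(m₀))], clamped at 0,
against the boundary mixture ½χ²₀ + ½χ²₁ (χ²₂ available as a conservative
alternative).

**Decomposition.** With S_N/S_S the counts of distinct codons/CDS positions
carrying at least one missense/synonymous mutation,
Ω_pass = (S_N/S_S)/(L_N/L_S), and Ω_dri = [N/S]*/(L_N/L_S) with
[N/S]* = (N/S − (1−η)S_N/S_S)/η, so that
(1−η)Ω_pass + ηΩ_dri = C_N/C_S holds identically (negative [N/S]*, possible
at small counts, is floored at 0 and flagged, which breaks the identity for
that gene only). Negative selection on the passenger component is tested
one-sided on (S_N, S_S) against expected fractions (L_N, L_S)/(L_N+L_S).
Per-site posteriors follow Bayes' rule, Q_k = η·NB(z_k)/f(z_k), and the
site-specific ratio is the posterior mean
Ω_k = (1−Q_k)Ω_pass + Q_k[(z_k+α)/(m₁+α)]Ω_dri, a convex combination
bounded by its two component terms.

**Classification.** driver ⟺ C_N/C_S > 1 (χ² p < α-level) and a
significant driver component (η > 0, LRT p < α-level); mini-driver ⟺ ratio
in (1−H, 1) significant and a significant driver component; conserved
mini-driver ⟺ mini-driver with Ω_pass < 1 significant. The default joins
the LRT requirement to the mini-driver label
(`minidriver_rule="band_only"` relaxes it to the band test alone).
The optional dubious-gene filter drops six recurrent false positives of
mutation-based driver detection (TTN, FLG, PCLO, CSMD3, CNTN5, LRP1B) from
the driver table; the list is overridable and an empty list disables it.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha_level` | 0.05 | significance threshold, raw p-values (BH available downstream of the tables) |
| `zero_s_pseudocount` | 0.5 | substituted for S (or S_S) when zero, flagged |
| `spectrum_pseudocount` | 0.5 | regularises the 96 context-class rates |
| `m0_method` | `sites_trimmed` | passenger rate from an iteratively trimmed mean of per-codon counts (sites above the Poisson 99.9% tail of the current estimate are excluded); `synonymous` uses m₀ = S·(L_N/L_S)/n_codons |
| `mom_mode` | `printed` | closed-form moment inversion; `exact` solves the quadratic |
| `lrt_df_mode` | `half1` | ½χ²₀+½χ²₁ boundary reference; `chi2_2` for χ²₂ |
| `fixed_alpha` | None | skip the cohort α fit |
| hypermutator fence | Q3 + 1.5·IQR **and** > 1000 | per cancer type (type-7 quantiles); strata under 4 samples use the whole-cohort fence |

The trimmed-mean m₀ default matters: a synonymous-calibrated m₀ makes
z̄/m₀ coincide with C_N/C_S, so a gene below neutrality could never expose
a driver component through the moment equations — weak positive selection
would be undetectable by construction. The trimmed estimator keeps m₀
anchored to the unremarkable majority of sites instead, at the cost of a
small downward bias (~5% at z̄ ≈ 0.05) that slightly inflates η̂ at
sparsely mutated genes.

## Synthetic cohorts

The simulator realises exactly the model above: random sense-codon CDSs
(stop appended), each codon independently a driver site with probability η,
λ ~ Gamma(α, β) at driver sites, missense counts Poisson(m₀) or
Poisson(m₀+λ), individual substitutions placed within their codon in
proportion to the context-spectrum rates, and synonymous mutations at
intensity m₀·n_codons·L_S/L_N, so that a fully neutral gene has
E[C_N/C_S] = 1 by construction. An optional conserved fraction of passenger
codons produces no missense mutations at all, emulating strong negative
selection; mutations are assigned to samples uniformly (no clonal
structure, no copy number, a single static spectrum). Ground-truth tables
(per-gene parameters, per-site driver indicators and λ) are emitted
alongside the MAF/FASTA.

Reference study conditions used by the tests and `scripts/acceptance.py`,
chosen once:

- *Neutral calibration*: 2,000 genes × 500 codons at m₀ = 0.1 for both
  tests' type-I error; the LRT calibration conditions on the true m₀,
  because it checks the reference distribution of the statistic (see
  limitations for the plug-in case).
- *Equal-rate H calibration*: m₀ = 1.0 per codon. At z̄ ≪ 1 the estimator's
  denominator approaches z̄², and H becomes pure noise (mean ≈ 0.18 at
  m₀ = 0.1 despite a true value of 0); H is only informative for
  well-covered genes, which the m₀ = 1 scenario represents.
- *Two-class H*: 10,000 sites, 10% at rate 5 vs 1 (analytic H = 0.4235).
- *Recovery*: 500 genes × 500 codons at (η = 0.01, m₀ = 0.05, m₁ = 5,
  α = 1.51).
- *Planted classification cohort*: 20 drivers (η = 0.02, m₁ = 8, m₀ = 0.05),
  50 mini-drivers (η = 0.01, m₁ = 4, m₀ = 0.3, 40% of passenger sites
  conserved — placing the gene-level ratio inside (1−H, 1)), 500 neutral
  genes (m₀ = 0.05), all 500 codons.

Because the generator and the inference share the same model family,
passing these tests demonstrates internal consistency, correct formula
implementation and calibrated inference under the model — not robustness
to the things real cohorts add: signature heterogeneity between samples,
clonal structure, coverage variation, annotation errors, indels, or
selection on synonymous sites.

## Numerical choices

Quantiles use linear interpolation (type 7). Mixture probabilities are
clipped at 1e−300 before logs. The α search runs in log space with
xatol = 1e−3; estimates within 5% of the bounds are flagged as boundary
hits. Ties in transcript selection go to the lexicographically smallest
transcript id. CDS-edge changes with an unknown flank take context rate 1.
Reference-mismatch mutations are dropped with a logged count rather than
failing the run; MAF rows without a usable CDS position (or for genes
without a transcript) still count toward per-sample totals for the
hypermutator fence. All randomness flows from a single integer seed
through `numpy.random.default_rng`.

## Known limitations

- **Plug-in m₀ in the LRT.** With m₀ estimated from few synonymous events
  (E[S] ≲ 20) the boundary LRT is anti-conservative (~12% rejection at
  nominal 5% in simulation); with m₀ known it is conservative (~2.6%).
  Driver labels are protected by requiring the gene-level χ² jointly, but
  per-gene LRT p-values at poorly covered genes should be read with care.
- **Cohort α at sparse driver signal.** The profile-likelihood α̂ is
  consistent only as the number of driver sites per gene grows; with ~5
  driver sites per gene it is biased upward by roughly 60% (an
  incidental-parameters effect — each gene contributes two nuisance
  parameters). At ≥ ~25 driver sites per gene the bias is negligible.
  Downstream quantities are insensitive: η̂ and m̂₁ medians stay within
  their tolerance at the biased α̂.
- **1−H treated as known.** The second χ² test conditions on the estimated
  H without propagating its uncertainty.
- **Printed moment inversion.** The closed-form m₁ formula assumes
  m₁ ≫ m₀; near that boundary use `mom_mode="exact"`.
- The exact Poisson-gamma convolution for driver counts is not implemented;
  the negative-binomial form is the working model throughout (the
  simulator, which draws from the exact model, differs in variance by
  η(m₁² − (m₁−m₀)²)/α, under 2% at the reference conditions).
- Genomic-to-CDS projection, indels, multi-allelic sites and germline
  variants are out of scope; inputs must carry CDS positions.
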