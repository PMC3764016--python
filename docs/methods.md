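# Methods

## Model and procedure

`tfsig` treats TF target inference as two posterior-probability summaries
followed by a permutation test.

**Distance mixture.**  Every peak is paired with every gene whose TSS is
within L = 1 Mb (a peak may serve several genes; the mixture is fit on the
pooled peak–gene links).  The signed, strand-oriented distance a (negative
= upstream) follows

    f(a) = pi * (lambda/2) exp(-lambda |a|) + (1 - pi) / (2L),  a in (-L, L).

The exponential-on-signed-distance is realized as a symmetric Laplace
density: folding to |a| and halving the uniform is equivalent, and the
signed form keeps upstream/downstream reportable.  EM updates are closed
form (pi = mean posterior, lambda = sum(gamma)/sum(gamma|a|)).  The peak's
representative position is its summit when the file carries one, else the
interval midpoint.

**Gene score.**  S_g = ln(1 + sum_k gamma_k h_k) over the gene's links,
with h the peak intensity (max read depth).  The log argument is shifted
by 1 so that peakless genes score exactly 0, scores are non-negative (the
gene-level exponential component needs support [0, inf)), and a window of
all-background peaks (gamma ~ 0) scores near 0.  Two alternative readings
of the score — log1p of the gamma-weighted mean, and log1p of the
per-peak mean — are exposed as `variant=` in `binding_scores` for
sensitivity checks; only the default is used downstream.

**Score mixture.**  Scores of genes with at least one peak follow
(1-eta) psi exp(-psi S) + eta N(mu, sigma2); the normal posterior is the
binding probability p_g.  Genes with no peak are excluded from the fit and
set to p_g = 0: a point mass at S = 0 is generated by neither component
and would bias psi.  Initialization is a deterministic quantile split
(exponential moment-fit below the 75th percentile, normal above,
eta0 = 0.25), so fits need no seed.

**Concordance.**  With binding evidence u_g = p_g and expression evidence
v_g = min(-log10 p, 16), the statistic T = sum u_g v_g has exact
permutation moments E[T] = (Σu)(Σv)/G and
Var[T] = Σ(u-ū)² Σ(v-v̄)²/(G-1); the analytic p is the upper normal tail
of z = (T-E)/sqrt(Var), and a seeded explicit permutation test is
available (p = (1 + #{T_perm >= T})/(n_perm + 1)).  The per-gene null for
e_g = u_g v_g is the product u_X v_Y over independent uniform gene draws
(1e6 seeded draws by default; exact enumeration over all G² ordered pairs
for small universes), so a gene needs both strong binding and strong
expression change to score.  Testing is one-sided (concordance);
anti-concordance is not tested.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| L | 1e6 bp | half-width of the TSS window; also the uniform support |
| tol / max_iter | 1e-8 / 1000 | relative log-likelihood EM stopping rule |
| evidence cap | 16 | ceiling on -log10(p) so one gene cannot dominate T |
| n_perm | 10 000 | permutations for the explicit global test |
| n_draws | 1e6 | Monte-Carlo draws for the per-gene null |
| p_cut | 0.95 | binding-probability threshold in the Fisher alternative |
| tail mode | two | `up`/`down` convert two-tailed p with the effect sign: p/2 if concordant else 1 - p/2 |

## Numerical choices

- EM guards: pi clipped to [1e-6, 1-1e-6]; lambda bounded below by 1/(10L)
  (an exponential flatter than that is indistinguishable from the uniform);
  sigma2 floored at 1e-4; **psi capped at 50**.  The psi cap is essential,
  not cosmetic: gamma underflows for very distal peaks, giving genes scores
  like 1e-80 > 0, and the mixture likelihood is unbounded as psi chases
  that spike (observed psi ~ 1e25, with the normal component degenerating
  into a broad catch-all).  A cap at 50 (background mean score >= 0.02)
  keeps the exponential on the science it models.  None of the guards bind
  on well-separated data.
- Enrichment p-values use the signed likelihood-ratio test, not the Wald
  test (`statistic="wald"` restores it).  Near-separating scores inflate
  the Wald standard error (Hauck–Donner), so the *most* informative score
  can look the *least* significant — exactly the comparison
  `window_significance_profile` exists to make.  Under (quasi-)complete
  separation the fit is flagged and the p comes from an LRT with the
  slope capped at 20 on the standardized score.
- Expression p = 0 is clamped to 1e-300 with a warning; p outside (0, 1]
  is an error.
- Analytic concordance with one constant vector reports z = 0, p = 0.5
  (permutation mode reports 1.0 since every permutation ties); two
  constant vectors report p = 1.
- All file round-trips serialize floats to 12 significant digits.

## The simulator

`SimulationConfig` states the world the model assumes: G = 1000 genes on
synthetic chromosomes with non-overlapping ±L windows (spacing 2L + 10 kb;
an `overlapping_windows` mode stresses the pooled assignment), 20%
regulated genes carrying Poisson(3) functional peaks with |a| ~
Exp(lambda = 2e-4) and random sign, uniform background peaks in every
window, log-normal intensities (functional (1.0, 0.5) vs background
(0.0, 0.5) on the log scale — positive, right-skewed, about three-fold
brighter when functional, chosen so the functional score mode sits near
2.2 as the gene-level model expects), and regulated-gene expression
p-values ~ Beta(0.1, 1) with positive effects.  Because the config lists
both the mixture proportion `pi` and a `background_peak_density`, the
density defaults to being *derived* from pi (background count chosen so
functional links are the fraction pi of all links); an explicit density
overrides pi.

What it does **not** emulate: correlated neighbouring genes, chromatin
covariates, peak-width/intensity dependence on position, read-level noise,
or gene-density variation along real chromosomes.  A green test therefore
establishes correctness of the estimators and orderings *under the model's
own assumptions*, not performance on real ChIP-seq.

## Known limitations

- The exact weight functions of the original random-set formulation are
  not published alongside the model; the capped -log10 / probability
  evidence pair used here satisfies the documented properties (finite
  moments, Type-I calibration, weak-signal ordering) but is not guaranteed
  numerically identical to other implementations.
- Batch scanning of hundreds of profiles shares no null between runs here;
  each concordance is computed independently.
- One TSS per gene (5'-most transcript); transcript-level scoring is out
  of scope, as is peak calling itself.
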