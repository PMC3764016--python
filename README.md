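# tfsig

Genome-wide signatures of transcription-factor activity from ChIP-seq
peaks and differential gene expression.

## The problem

A ChIP-seq experiment yields thousands of called binding peaks for one
transcription factor (TF), but a peak near a gene does not make that gene
a functional target, and a differentially expressed gene is not
necessarily a *direct* target.  `tfsig` quantifies the evidence of
functional TF–gene interaction from the peaks alone, then integrates it
with a differential-expression profile to pinpoint regulated genes and to
score the TF's activity in any transcriptional profile — without
arbitrary distance windows or significance cutoffs.  It is aimed at
computational biologists who have peak calls (narrowPeak/BED), a gene
annotation (TSV/GTF) and per-gene differential-expression p-values.

## The model

**Stage 1 — peak level.**  Signed peak-to-TSS distances $a$ within
±1 Mb are modelled as a mixture of *functional* peaks, whose distance is
exponential around the TSS, and uniform background:

$$f(a) = \pi\,\tfrac{\lambda}{2}e^{-\lambda|a|} + (1-\pi)\tfrac{1}{2L},
\qquad a\in(-L,L),\; L=10^6.$$

$(\pi,\lambda)$ are fit by EM; each peak gets a posterior probability
$\gamma_i$ of being functional.  The gene-level binding score pools the
$n_g$ peaks in gene $g$'s window with their intensities $h_k$ (maximum
read depth in the peak):

$$S_g = \ln\!\Big(1 + \sum_{k=1}^{n_g}\gamma_k h_k\Big).$$

**Stage 2 — gene level.**  Across the genome the $S_g$ of peak-bearing
genes are a mixture of an exponential component near zero (non-functional)
and a normal component (functional); the posterior of the normal
component is the binding probability $p_g$.  The pairs $(S_g, p_g)$ over
all genes are the **binding profile**.

**Integration.**  Given per-gene expression evidence
$v_g=\min(-\log_{10}p^{\text{expr}}_g,16)$ and binding evidence
$u_g=p_g$, the random-set concordance statistic $T=\sum_g u_g v_g$ is
tested one-sided against permutation of gene labels (exact moments give a
closed-form z-score; an explicit seeded permutation test is also
available).  Per gene, $e_g=u_g v_g$ is compared with the null product
$u_X v_Y$ of independently drawn genes, and $t_g=-\log_{10}p(e_g)$ over
all genes is the **TF-activity signature**.

Also included: fixed-window baseline scores (MPI, UWS, LWS), logistic
regression gene-set enrichment on continuous scores, Fisher's-exact
thresholding alternative, Benjamini–Hochberg adjustment, and a seeded
generative simulator for all of the above.

## Worked example

```python
import tfsig

ds = tfsig.simulate_dataset(tfsig.SimulationConfig(seed=1))
links = tfsig.assign_peaks_to_genes(ds.peaks, ds.genes)
dmix = tfsig.fit_distance_mixture(links)
links = tfsig.peak_functional_posterior(links, dmix)
scores = tfsig.binding_scores(links, ds.genes)
profile = tfsig.build_binding_profile(
    ds.genes, tfsig.binding_probabilities(scores, tfsig.fit_score_mixture(scores)))
res = tfsig.concordance_analysis(profile, ds.expression, seed=1)
```

Running `python examples/01_fit_binding_profile.py` followed by
`python examples/02_concordance_signature.py` prints:

```
2033 peaks, 1000 genes, 2033 peak-gene links
distance mixture: pi=0.286  lambda=0.000192/bp (mean functional distance 5,205 bp)
score mixture:    eta=0.284  mu=1.84  sigma=0.81  psi=50
223 genes with binding probability p_g > 0.95 (190 of the 200 truly regulated genes)
...
global concordance: T=803.4  E[T]=261.4  z=18.02  p=7.19e-73
4 genes with concordance p_e < 0.001 (4 truly regulated)
```

Read: ~29% of peaks look TSS-targeted with a typical distance of ~5 kb
(truth: 30%, 5 kb); thresholding the binding probability at 0.95 recovers
190/200 planted target genes; and the binding profile is overwhelmingly
concordant with the simulated expression changes (z = 18, p ≈ 1e-72), as
it should be when the TF drives them.  The `examples/` directory holds
one short script per capability (profile fitting, signatures, window
comparisons, thresholding vs concordance, gene-set enrichment); file-based
pipelines with run manifests live in `tfsig.workflows`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline from scratch on a seeded synthetic dataset
(simulate → fit both mixtures → build the binding profile → concordance
against the simulated expression profile) and writes the results JSON to
`--out`.
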