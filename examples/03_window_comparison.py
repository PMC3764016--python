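"""Compare the mixture-model gene score with fixed-window baselines.

For each window size, scores genes by maximum peak intensity (MPI) and
unweighted intensity sum (UWS) within the window, measures how well each
score explains membership in the truly-regulated gene set by logistic
regression, and reports the ratio of -log10 p to that of the model-based
score.  Ratios below 1 mean the window-free model score separates
regulated genes better.
"""

import tfsig

ds = tfsig.simulate_dataset(tfsig.SimulationConfig(seed=1))
links = tfsig.assign_peaks_to_genes(ds.peaks, ds.genes)
links = tfsig.peak_functional_posterior(links, tfsig.fit_distance_mixture(links))
membership = ds.truth.regulated.to_numpy(dtype=float)

table = tfsig.window_significance_profile(
    links, ds.genes, membership,
    windows=[1_000, 10_000, 100_000, 1_000_000],
)
print(table.to_string(index=False))
print("\nratio_to_model < 1: the fixed-window score is less informative than")
print("the posterior-weighted model score at that window size.")
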