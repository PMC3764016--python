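"""End-to-end pipeline stages over files, with run manifests.

Each stage reads its inputs from disk, runs the corresponding library
functions and writes tab-separated outputs next to a flat key/value run
manifest (command, parameters, input digests, seed, version).  For seeded
stages the manifest is sufficient to reproduce the data outputs
byte-for-byte; the manifest itself carries a timestamp and is therefore
not byte-stable.  These functions — not a shell entry point — are the
intended way to script reproducible runs; see the examples/ directory.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binding import (
    DistanceMixture,
    binding_scores,
    fit_distance_mixture,
    peak_functional_posterior,
)
from .concordance import adjust_bh, concordance_analysis, threshold_enrichment
from .enrichment import gene_set_enrichment, window_significance_profile
from .genescore import ScoreMixture, binding_probabilities, build_binding_profile, fit_score_mixture
from .io import (
    DEFAULT_WINDOW_HALF_WIDTH,
    assign_peaks_to_genes,
    read_expression_profile,
    read_gene_annotation,
    read_gene_sets,
    read_peaks,
    read_table,
    write_params,
    write_table,
)
from .simulate import SimulationConfig, simulate_dataset


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, params: dict, inputs: dict) -> Path:
    manifest = {"command": command, "version": __version__, "timestamp": f"{time.time():.3f}"}
    manifest.update({f"param.{k}": v for k, v in params.items()})
    for name, path in inputs.items():
        manifest[f"input.{name}"] = str(path)
        manifest[f"sha256.{name}"] = _digest(Path(path))
    path = out_dir / f"{command}.manifest"
    write_params(manifest, path)
    return path


def fit_binding(
    peaks_path,
    annotation_path,
    out_dir,
    L: int = DEFAULT_WINDOW_HALF_WIDTH,
    annotation_format: str = "tsv",
    intensity_column: int = 6,
    score_variant: str = "log1p_sum",
):
    """Peaks + annotation -> binding profile and the two fitted mixtures.

    Writes binding_profile.tsv, distance_mixture.params and
    score_mixture.params under ``out_dir`` and returns
    (profile, distance_mixture, score_mixture).
    """
    peaks_path, annotation_path = Path(peaks_path), Path(annotation_path)
    for p in (peaks_path, annotation_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    peaks = read_peaks(peaks_path, intensity_column=intensity_column)
    genes = read_gene_annotation(annotation_path, format=annotation_format)
    links = assign_peaks_to_genes(peaks, genes, L=L)
    dmix = fit_distance_mixture(links, L=L)
    links = peak_functional_posterior(links, dmix)
    scores = binding_scores(links, genes, variant=score_variant)
    smix = fit_score_mixture(scores)
    scored = binding_probabilities(scores, smix)
    profile = build_binding_profile(genes, scored)

    write_table(profile, out_dir / "binding_profile.tsv", kind="binding_profile")
    write_params(dmix.to_dict(), out_dir / "distance_mixture.params")
    write_params(smix.to_dict(), out_dir / "score_mixture.params")
    _write_manifest(
        out_dir,
        "fit-binding",
        {"L": L, "score_variant": score_variant, "intensity_column": intensity_column},
        {"peaks": peaks_path, "annotation": annotation_path},
    )
    return profile, dmix, smix


def run_concordance(
    profile_path,
    expression_path,
    out_dir,
    tail: str = "two",
    method: str = "grs",
    mode: str = "analytic",
    n_perm: int = 10_000,
    n_draws: int = 1_000_000,
    p_cut: float = 0.95,
    fdr_cut: float = 0.01,
    seed: int = 0,
):
    """Binding profile + expression -> signature and global statistics.

    ``method='grs'`` runs the concordance analysis and writes
    signature.tsv + global_stats.params; ``method='threshold'`` instead
    thresholds the binding probability at ``p_cut``, calls DE genes at
    BH FDR < ``fdr_cut`` and writes the Fisher's-exact overlap test.
    """
    profile_path, expression_path = Path(profile_path), Path(expression_path)
    for p in (profile_path, expression_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    profile = read_table(profile_path, kind="binding_profile")
    expr = read_expression_profile(expression_path, tail_mode=tail)
    params = {
        "tail": tail, "method": method, "mode": mode, "n_perm": n_perm,
        "n_draws": n_draws, "p_cut": p_cut, "fdr_cut": fdr_cut, "seed": seed,
    }
    if method == "grs":
        result = concordance_analysis(
            profile, expr, mode=mode, n_perm=n_perm, n_draws=n_draws, seed=seed
        )
        write_table(result.per_gene, out_dir / "signature.tsv", kind="signature")
        write_params(result.global_stats(), out_dir / "global_stats.params")
    elif method == "threshold":
        expr = expr[expr["gene_id"].isin(set(profile["gene_id"]))]
        q = adjust_bh(expr["p"].to_numpy())
        de_calls = expr.loc[q < fdr_cut, "gene_id"]
        result = threshold_enrichment(profile, de_calls, p_cut=p_cut)
        write_params(
            {
                "odds_ratio": result.odds_ratio,
                "p": result.p,
                "n_regulated": result.n_regulated,
                "n_de": result.n_de,
                "table": result.table.ravel(),
            },
            out_dir / "threshold_stats.params",
        )
    else:
        raise ValueError(f"unknown concordance method: {method!r}")
    _write_manifest(
        out_dir, "concordance", params,
        {"profile": profile_path, "expression": expression_path},
    )
    return result


def score_windows(
    peaks_path,
    annotation_path,
    expression_path,
    out_dir,
    windows=(1_000, 10_000, 100_000, 1_000_000),
    methods=("mpi", "uws"),
    fdr_cut: float = 0.01,
    L: int = DEFAULT_WINDOW_HALF_WIDTH,
    annotation_format: str = "tsv",
):
    """Window-sensitivity comparison of baseline scores against the model score.

    Membership is 'differentially expressed at BH FDR < fdr_cut'; writes
    window_profile.tsv (method, window, -log10 p, ratio to the model score).
    """
    peaks_path, annotation_path, expression_path = (
        Path(peaks_path), Path(annotation_path), Path(expression_path)
    )
    for p in (peaks_path, annotation_path, expression_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    peaks = read_peaks(peaks_path)
    genes = read_gene_annotation(annotation_path, format=annotation_format)
    expr = read_expression_profile(expression_path)
    links = assign_peaks_to_genes(peaks, genes, L=L)
    dmix = fit_distance_mixture(links, L=L)
    links = peak_functional_posterior(links, dmix)
    q = pd.Series(adjust_bh(expr["p"].to_numpy()), index=expr["gene_id"])
    membership = (
        q.reindex(genes["gene_id"]).fillna(1.0).to_numpy() < fdr_cut
    ).astype(float)
    table = window_significance_profile(links, genes, membership, windows, methods=methods, L=L)
    write_table(table, out_dir / "window_profile.tsv")
    _write_manifest(
        out_dir, "score-windows",
        {"windows": list(windows), "methods": list(methods), "fdr_cut": fdr_cut, "L": L},
        {"peaks": peaks_path, "annotation": annotation_path, "expression": expression_path},
    )
    return table


def run_enrichment(sets_path, scores_path, out_dir, alternative: str = "greater"):
    """Gene sets x per-gene scores -> enrichment table (enrichment.tsv)."""
    sets_path, scores_path = Path(sets_path), Path(scores_path)
    for p in (sets_path, scores_path):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sets = read_gene_sets(sets_path)
    scores = pd.read_csv(scores_path, sep="\t", dtype={"gene_id": str})
    table = gene_set_enrichment(sets, scores, alternative=alternative)
    write_table(table, out_dir / "enrichment.tsv")
    _write_manifest(
        out_dir, "enrich", {"alternative": alternative},
        {"sets": sets_path, "scores": scores_path},
    )
    return table


def run_simulate(out_dir, seed: int = 0, **config_overrides):
    """Write a synthetic fixture bundle (annotation, peaks, expression, truth)."""
    out_dir = Path(out_dir)
    config = SimulationConfig(seed=seed, **config_overrides)
    ds = simulate_dataset(config, out_dir=out_dir)
    params = {k: v for k, v in vars(config).items() if not isinstance(v, tuple)}
    params.update(
        intensity_functional=list(config.intensity_functional),
        intensity_background=list(config.intensity_background),
    )
    _write_manifest(out_dir, "simulate", params, {})
    return ds
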