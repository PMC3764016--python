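"""Random-set concordance between a binding profile and expression evidence.

Two gene-aligned non-negative evidence vectors are compared: u_g, the
binding probability p_g, and v_g, capped -log10 expression p-values.  The
global concordance statistic is

    T = sum_g u_g v_g,

tested one-sided against the null that gene labels of one vector are
randomly permuted.  Under that null the permutation moments are exact:

    E[T]   = (sum u)(sum v) / G,
    Var[T] = sum (u - ubar)^2 * sum (v - vbar)^2 / (G - 1),

so an analytic z/p is available alongside an explicit seeded permutation
test.  Per gene, e_g = u_g v_g is the gene's contribution to T
(sum_g e_g = T); its resampling p-value compares e_g with the null product
u_X v_Y for independent uniform gene draws X, Y, so both the gene's
binding and its expression magnitude matter.  The concordance score
t_g = -log10(p_e) over all genes is the TF-activity signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("tfsig")

#: evidence cap applied to -log10(p); bounds the influence of a single gene
DEFAULT_EVIDENCE_CAP = 16.0


def expression_evidence(
    expr: pd.DataFrame,
    universe,
    cap: float = DEFAULT_EVIDENCE_CAP,
) -> pd.Series:
    """Capped -log10 p-value evidence aligned to ``universe``.

    Genes missing from the expression profile get weight 0 (their count is
    logged); p-values are assumed already one-tailed if directionality is
    wanted (see :func:`tfsig.io.read_expression_profile`).
    """
    universe = pd.Index(universe, name="gene_id")
    v = pd.Series(
        np.minimum(-np.log10(expr["p"].to_numpy(dtype=float)), cap),
        index=pd.Index(expr["gene_id"], name="gene_id"),
    )
    v = v.groupby(level=0).first().reindex(universe)
    n_missing = int(v.isna().sum())
    if n_missing:
        logger.info("expression_evidence: %d universe gene(s) missing from profile", n_missing)
    return v.fillna(0.0)


def binding_evidence(profile: pd.DataFrame, universe=None) -> pd.Series:
    """Binding probability p_g as the evidence weight (already in [0, 1])."""
    u = pd.Series(
        profile["p"].to_numpy(dtype=float),
        index=pd.Index(profile["gene_id"], name="gene_id"),
    )
    if universe is not None:
        u = u.reindex(pd.Index(universe, name="gene_id"), fill_value=0.0)
    return u


@dataclass
class ConcordanceResult:
    """Global concordance statistic with optional per-gene signature."""

    T: float
    ET: float
    VarT: float
    z: float
    p_global: float
    mode: str
    n_perm: int = 0
    seed: int | None = None
    per_gene: pd.DataFrame | None = None

    def global_stats(self) -> dict:
        return {
            "T": self.T,
            "ET": self.ET,
            "VarT": self.VarT,
            "z": self.z,
            "p_global": self.p_global,
            "mode": self.mode,
            "n_perm": self.n_perm,
            "seed": -1 if self.seed is None else self.seed,
        }


def _check_universe(u: pd.Series, v: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if len(u) != len(v) or not u.index.equals(v.index):
        raise ValueError("evidence vectors must share the same gene universe and order")
    ua, va = u.to_numpy(dtype=float), v.to_numpy(dtype=float)
    if not (np.isfinite(ua).all() and np.isfinite(va).all()):
        raise ValueError("evidence weights must be finite")
    if (ua < 0).any() or (va < 0).any():
        raise ValueError("evidence weights must be non-negative")
    return ua, va


def grs_concordance(
    u: pd.Series,
    v: pd.Series,
    mode: str = "analytic",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> ConcordanceResult:
    """Global one-sided concordance test between two evidence vectors.

    ``analytic`` standardizes T with its exact permutation moments and uses
    the upper normal tail; ``permutation`` permutes v's gene labels
    ``n_perm`` times (seeded) and reports (1 + #{T_perm >= T}) / (n_perm + 1).
    """
    ua, va = _check_universe(u, v)
    G = ua.size
    if G < 100:
        raise ValueError(f"need a universe of at least 100 genes, got {G}")
    T = float(ua @ va)
    ET = float(ua.sum() * va.sum() / G)
    var_t = float(np.sum((ua - ua.mean()) ** 2) * np.sum((va - va.mean()) ** 2) / (G - 1))
    if var_t == 0.0:
        # one constant vector: no signal is possible, T == E[T] identically
        # (z = 0, analytic p = 0.5; every permutation ties, so p_perm = 1);
        # both constant is fully degenerate and reports p = 1
        warnings.warn("degenerate concordance input: at least one vector is constant",
                      stacklevel=2)
        both = np.ptp(ua) == 0 and np.ptp(va) == 0
        p = 1.0 if (both or mode == "permutation") else 0.5
        return ConcordanceResult(T=T, ET=ET, VarT=0.0, z=0.0, p_global=p, mode=mode)
    z = (T - ET) / np.sqrt(var_t)
    if mode == "analytic":
        return ConcordanceResult(
            T=T, ET=ET, VarT=var_t, z=float(z), p_global=float(stats.norm.sf(z)), mode=mode
        )
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            count += ua @ rng.permutation(va) >= T
        p = (1.0 + count) / (n_perm + 1.0)
        return ConcordanceResult(
            T=T, ET=ET, VarT=var_t, z=float(z), p_global=float(p),
            mode=mode, n_perm=n_perm, seed=seed,
        )
    raise ValueError(f"unknown mode: {mode!r}")


def gene_concordance(
    u: pd.Series,
    v: pd.Series,
    n_draws: int = 1_000_000,
    seed: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Per-gene contributions e_g with resampling p-values and scores t_g.

    The null distribution of a contribution is the product u_X * v_Y with
    X and Y drawn independently and uniformly from the gene universe —
    Monte-Carlo with ``n_draws`` seeded draws by default, or exact over all
    G^2 ordered pairs when ``exact`` is set (small universes only).
    """
    ua, va = _check_universe(u, v)
    G = ua.size
    e = ua * va
    if exact:
        if G > 5000:
            raise ValueError("exact null enumeration is limited to universes of <= 5000 genes")
        null = np.sort(np.outer(ua, va).ravel())
        n_null = null.size
        count_ge = n_null - np.searchsorted(null, e, side="left")
        p_e = count_ge / n_null
        p_e = np.maximum(p_e, 1.0 / n_null)
    else:
        rng = np.random.default_rng(seed)
        null = np.sort(ua[rng.integers(0, G, n_draws)] * va[rng.integers(0, G, n_draws)])
        count_ge = n_draws - np.searchsorted(null, e, side="left")
        p_e = (1.0 + count_ge) / (n_draws + 1.0)
    return pd.DataFrame(
        {
            "gene_id": u.index.to_numpy(),
            "e": e,
            "p_e": p_e,
            "t": -np.log10(p_e),
        }
    )


def concordance_analysis(
    profile: pd.DataFrame,
    expr: pd.DataFrame,
    mode: str = "analytic",
    n_perm: int = 10_000,
    n_draws: int = 1_000_000,
    seed: int | None = None,
    cap: float = DEFAULT_EVIDENCE_CAP,
) -> ConcordanceResult:
    """Full concordance analysis of a binding profile against expression.

    Convenience wrapper: builds both evidence vectors over the profile's
    gene universe, runs the global test, and attaches the per-gene
    signature (gene_id, e, p_e, t).
    """
    universe = profile["gene_id"]
    u = binding_evidence(profile)
    v = expression_evidence(expr, universe, cap=cap)
    result = grs_concordance(u, v, mode=mode, n_perm=n_perm, seed=seed)
    result.per_gene = gene_concordance(u, v, n_draws=n_draws, seed=seed)
    return result


@dataclass
class ThresholdEnrichment:
    """Fisher's-exact overlap of thresholded 'regulated' genes with DE calls."""

    table: np.ndarray
    odds_ratio: float
    p: float
    n_regulated: int
    n_de: int


def threshold_enrichment(
    profile: pd.DataFrame,
    de_calls,
    p_cut: float = 0.95,
) -> ThresholdEnrichment:
    """Thresholding alternative to the concordance test.

    Genes with p_g > ``p_cut`` form the 'regulated' group; the overlap with
    the differential-expression call set is tested one-sided (enrichment)
    by Fisher's exact test on the 2x2 table.
    """
    universe = set(profile["gene_id"])
    de_calls = set(de_calls)
    if not de_calls <= universe:
        raise ValueError("de_calls contain genes outside the profile universe")
    regulated = profile["p"].to_numpy(dtype=float) > p_cut
    is_de = profile["gene_id"].isin(de_calls).to_numpy()
    a = int((regulated & is_de).sum())
    b = int((regulated & ~is_de).sum())
    c = int((~regulated & is_de).sum())
    d = int((~regulated & ~is_de).sum())
    table = np.array([[a, b], [c, d]])
    if regulated.sum() == 0 or regulated.all():
        warnings.warn("degenerate regulated group (empty or universal); p = 1", stacklevel=2)
        return ThresholdEnrichment(
            table=table, odds_ratio=np.nan, p=1.0,
            n_regulated=int(regulated.sum()), n_de=len(de_calls),
        )
    odds, p = stats.fisher_exact(table, alternative="greater")
    return ThresholdEnrichment(
        table=table, odds_ratio=float(odds), p=float(p),
        n_regulated=int(regulated.sum()), n_de=len(de_calls),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
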