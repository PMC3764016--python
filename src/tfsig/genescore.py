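"""Gene-level score mixture and binding probabilities.

Across the genome the binding scores S_g are bimodal: a spike near zero
from genes whose windows hold only background peaks, and a bell-shaped
population of genuinely bound genes.  We model scores of genes with at
least one peak as

    g(S) = (1 - eta) psi exp(-psi S) + eta N(S; mu, sigma2),

where eta is the proportion of functional (normally distributed) scores.
Note the role reversal relative to the distance mixture: here the
exponential is the *non-functional* component.  The posterior that a
gene's score came from the normal component,

    p_g = eta N(S_g) / (eta N(S_g) + (1 - eta) psi exp(-psi S_g)),

is the gene's probability of functional TF-gene interaction.  Genes with
no peak in their window (S = 0 exactly) are excluded from the fit and
assigned p = 0: the point mass at zero is produced by neither component
and would bias psi upward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_SIGMA2_FLOOR = 1e-4
# upper bound on the exponential rate: scores far below 1/psi carry no
# binding evidence anyway, and an unbounded rate lets the likelihood
# diverge on the near-zero spike produced by genes with only distal peaks
_PSI_CAP = 50.0


@dataclass
class ScoreMixture:
    """Fitted normal-exponential mixture over positive binding scores."""

    eta: float
    psi: float
    mu: float
    sigma2: float
    loglik_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    n_iter: int = 0
    converged: bool = True

    def functional_density(self, s) -> np.ndarray:
        return stats.norm.pdf(s, loc=self.mu, scale=np.sqrt(self.sigma2))

    def background_density(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return np.where(s >= 0, self.psi * np.exp(-self.psi * s), 0.0)

    def density(self, s) -> np.ndarray:
        return self.eta * self.functional_density(s) + (1.0 - self.eta) * self.background_density(s)

    def posterior(self, s) -> np.ndarray:
        fn = self.eta * self.functional_density(s)
        fb = (1.0 - self.eta) * self.background_density(s)
        total = fn + fb
        return np.divide(fn, total, out=np.zeros_like(fn), where=total > 0)

    def to_dict(self) -> dict:
        return {
            "model": "score_mixture",
            "eta": self.eta,
            "psi": self.psi,
            "mu": self.mu,
            "sigma2": self.sigma2,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreMixture":
        return cls(
            eta=float(d["eta"]),
            psi=float(d["psi"]),
            mu=float(d["mu"]),
            sigma2=float(d["sigma2"]),
            n_iter=int(d.get("n_iter", 0)),
            converged=bool(d.get("converged", True)),
        )


def fit_score_mixture(
    scores,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> ScoreMixture:
    """Fit the normal-exponential score mixture by EM.

    ``scores`` is a per-gene score table (columns gene_id, S, n) or a plain
    array of scores; only strictly positive scores enter the fit and at
    least 50 are required.  Initialization is deterministic: split at the
    75th percentile, moment-fit the exponential below and the normal above,
    eta0 = 0.25 — so repeated fits are bit-identical without a seed.
    """
    s = scores["S"].to_numpy(dtype=float) if isinstance(scores, pd.DataFrame) else np.asarray(
        scores, dtype=float
    )
    s = s[s > 0]
    if s.size < 50:
        raise ValueError(f"need at least 50 positive scores to fit, got {s.size}")

    q75 = np.quantile(s, 0.75)
    low, high = s[s <= q75], s[s > q75]
    psi = min(1.0 / max(low.mean(), 1e-12), _PSI_CAP)
    mu = high.mean() if high.size else s.mean()
    sigma2 = max(high.var() if high.size > 1 else s.var(), _SIGMA2_FLOOR)
    eta = 0.25

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        fn = eta * stats.norm.pdf(s, loc=mu, scale=np.sqrt(sigma2))
        fb = (1.0 - eta) * psi * np.exp(-psi * s)
        total = fn + fb + 1e-300
        loglik = float(np.log(total).sum())
        trace.append(loglik)
        w = fn / total  # responsibility of the normal component
        wsum = w.sum()
        eta = float(np.clip(wsum / s.size, 1e-6, 1.0 - 1e-6))
        mu = float((w @ s) / max(wsum, 1e-300))
        sigma2 = float(max((w @ (s - mu) ** 2) / max(wsum, 1e-300), _SIGMA2_FLOOR))
        bsum = s.size - wsum
        denom = float((1.0 - w) @ s)
        psi = min(float(bsum / denom), _PSI_CAP) if denom > 0 else psi
        if len(trace) > 1:
            prev = trace[-2]
            if abs(loglik - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
    if not converged:
        warnings.warn(f"score-mixture EM did not converge in {max_iter} iterations", stacklevel=2)
    return ScoreMixture(
        eta=eta,
        psi=psi,
        mu=mu,
        sigma2=sigma2,
        loglik_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )


def binding_probabilities(scores: pd.DataFrame, model: ScoreMixture) -> pd.DataFrame:
    """Per-gene probability of functional interaction.

    Genes with n = 0 get p = 0 by convention; all others get the posterior
    of the normal component evaluated at their score.
    """
    out = scores.copy()
    p = model.posterior(out["S"].to_numpy(dtype=float))
    out["p"] = np.where(out["n"].to_numpy() > 0, p, 0.0)
    return out


def build_binding_profile(
    genes: pd.DataFrame,
    scores: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the genome-wide binding profile (gene_id, S, p, n).

    Every annotated gene appears exactly once (peakless genes with
    S = 0, p = 0, n = 0); rows are sorted by gene_id.  A score for a gene
    absent from the annotation, or a duplicated gene in the score table,
    is fatal.
    """
    if scores["gene_id"].duplicated().any():
        dups = scores.loc[scores["gene_id"].duplicated(), "gene_id"].unique()
        raise ValueError(f"duplicate gene_id in score table: {list(dups[:5])}")
    unknown = set(scores["gene_id"]) - set(genes["gene_id"])
    if unknown:
        raise ValueError(f"scored gene(s) absent from annotation: {sorted(unknown)[:5]}")
    profile = (
        scores.set_index("gene_id")
        .reindex(genes["gene_id"], fill_value=0.0)
        .reset_index()
    )
    if "p" not in profile.columns:
        profile["p"] = 0.0
    profile["n"] = profile["n"].astype(np.int64)
    return profile[["gene_id", "S", "p", "n"]].sort_values("gene_id").reset_index(drop=True)
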