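"""Per-clade relaxed-clock rate summaries and artifact-control covariates.

The two clock statistics summarize how fast, and how clock-like, a
marker has evolved within a clade:

* ``weighted_mean_rate`` — the average of the per-branch substitution
  rates weighted by branch duration, i.e. the overall substitution rate
  per site per My for the clade.
* ``rate_cv`` — the branch-length-weighted coefficient of variation of
  branch rates; 0 under a strict clock, large when rates are punctuated.

``node_density`` (internal nodes per My of crown age) is the covariate
used to rule out the node-density artifact, in which densely sampled
clades appear to evolve faster only because multiple hits are better
detected.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

from .birth_death import BDFit
from .trees import DatedTree, RatedTree

__all__ = [
    "CladeEstimates",
    "weighted_mean_rate",
    "rate_cv",
    "node_density",
    "summarize_clade",
    "estimates_to_frame",
    "frame_to_estimates",
]


@dataclass
class CladeEstimates:
    """One clade's row of diversification and clock estimates."""

    clade_id: str
    lam: float
    mu: float
    epsilon: float
    mean_rate: float
    rate_cv: float
    n_tips: int
    sampling_fraction: float
    crown_age: float
    node_density: float
    lam_ci_lo: float = np.nan
    lam_ci_hi: float = np.nan
    mu_ci_lo: float = np.nan
    mu_ci_hi: float = np.nan


def _weights_and_rates(tree: RatedTree):
    pairs = list(tree.branches())
    lengths = np.array([p[0] for p in pairs], dtype=float)
    rates = np.array([p[1] for p in pairs], dtype=float)
    if not np.all(np.isfinite(lengths)) or not np.all(np.isfinite(rates)):
        raise ValueError("branch lengths and rates must be finite")
    return lengths, rates


def weighted_mean_rate(tree: RatedTree) -> float:
    """Branch-length-weighted mean substitution rate (subst/site/My)."""
    lengths, rates = _weights_and_rates(tree)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total branch length must be positive")
    return float(np.sum(rates * lengths) / total)


def rate_cv(tree: RatedTree, weighted: bool = True) -> float:
    """Coefficient of variation of branch rates (dimensionless).

    By default both the mean and the standard deviation are
    branch-length weighted (population form), consistent with
    ``weighted_mean_rate``; ``weighted=False`` gives the plain
    per-branch CV for sensitivity analysis.
    """
    lengths, rates = _weights_and_rates(tree)
    if np.ptp(rates) == 0:
        if rates[0] <= 0:
            raise ValueError("mean rate must be positive to form a CV")
        return 0.0  # strict clock, exactly
    if weighted:
        total = lengths.sum()
        if total <= 0:
            raise ValueError("total branch length must be positive")
        mean = np.sum(rates * lengths) / total
        var = np.sum(lengths * (rates - mean) ** 2) / total
    else:
        mean = rates.mean()
        var = rates.var()
    if mean <= 0:
        raise ValueError("mean rate must be positive to form a CV")
    return float(np.sqrt(var) / mean)


def node_density(tree: DatedTree) -> float:
    """Internal nodes (root included) per My of crown age."""
    if tree.crown_age <= 0:
        raise ValueError("crown age must be positive")
    return tree.n_internal_nodes / tree.crown_age


def summarize_clade(
    tree: RatedTree,
    fit: BDFit,
    sampling_fraction: float,
    clade_id: str = "clade",
    cv_weighted: bool = True,
) -> CladeEstimates:
    """Assemble one clade's estimates row from its rated tree and BD fit."""
    dated = tree.dated
    return CladeEstimates(
        clade_id=clade_id,
        lam=fit.mle.lam,
        mu=fit.mle.mu,
        epsilon=fit.epsilon,
        mean_rate=weighted_mean_rate(tree),
        rate_cv=rate_cv(tree, weighted=cv_weighted),
        n_tips=dated.n_tips,
        sampling_fraction=sampling_fraction,
        crown_age=dated.crown_age,
        node_density=node_density(dated),
        lam_ci_lo=fit.ci_lam[0],
        lam_ci_hi=fit.ci_lam[1],
        mu_ci_lo=fit.ci_mu[0],
        mu_ci_hi=fit.ci_mu[1],
    )


def estimates_to_frame(rows: list[CladeEstimates]) -> pd.DataFrame:
    """Collect estimate rows into a DataFrame with the canonical columns."""
    return pd.DataFrame([asdict(r) for r in rows])


def frame_to_estimates(frame: pd.DataFrame) -> list[CladeEstimates]:
    """Inverse of :func:`estimates_to_frame`; extra columns are ignored."""
    known = {f.name for f in fields(CladeEstimates)}
    out = []
    for _, row in frame.iterrows():
        kwargs = {k: row[k] for k in frame.columns if k in known}
        kwargs["clade_id"] = str(kwargs["clade_id"])
        kwargs["n_tips"] = int(kwargs["n_tips"])
        out.append(CladeEstimates(**kwargs))
    return out
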