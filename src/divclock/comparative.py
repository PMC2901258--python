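"""Phylogenetically independent contrasts and cross-clade regressions.

Clade-level traits (diversification rates, clock summaries) are not
statistically independent across clades because clades share ancestry.
Independent contrasts fix this: under Brownian trait evolution the
differences between sister lineages, standardized by the expected
Brownian variance (the sum of the branch lengths separating them), are
independent and identically distributed, so an ordinary regression can
be run on the contrasts — through the origin, since contrast signs are
arbitrary.

Two branch-length modes are supported on the clade backbone: "gradual"
uses the time-proportional lengths as given, while "punctuational" sets
every branch length to 1, concentrating expected change at speciation
events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .trees import BackboneTree, TreeValidationError

__all__ = [
    "ContrastSet",
    "RegressionResult",
    "DegeneratePredictorError",
    "pic_contrasts",
    "regress_through_origin",
    "regress_ols",
    "run_regression_battery",
]


class DegeneratePredictorError(ValueError):
    """The predictor has no variation (all contrasts / values equal)."""


@dataclass
class ContrastSet:
    """Standardized contrasts for one trait on a backbone tree."""

    contrasts: np.ndarray  # one per internal node, postorder
    node_ids: list[str]
    mode: str
    trait: str = ""

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass
class RegressionResult:
    """Simple-regression summary: slope, fit quality, and the F test."""

    slope: float
    r2: float
    F: float
    df: tuple[int, int]
    p_value: float
    n_points: int
    intercept: float | None = None  # None for through-origin fits
    degenerate: bool = False
    label: str = ""


def _resolve_polytomies(tree, policy: str):
    if policy == "strict":
        for node in tree.preorder_node_iter():
            if len(node.child_nodes()) > 2:
                raise TreeValidationError(
                    "backbone contains a polytomy; pass polytomy_policy="
                    "'zero_length' to resolve arbitrarily"
                )
        return tree, False
    if policy == "zero_length":
        had = any(len(nd.child_nodes()) > 2 for nd in tree.preorder_node_iter())
        tree.resolve_polytomies(limit=2, update_bipartitions=False)
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = 0.0
        return tree, had
    raise ValueError(f"unknown polytomy policy {policy!r}")


def pic_contrasts(
    backbone: BackboneTree,
    trait: dict[str, float],
    mode: str | None = None,
    polytomy_policy: str = "strict",
) -> ContrastSet:
    """Felsenstein's independent contrasts for one trait.

    At each internal node the contrast is ``(x_left - x_right) /
    sqrt(v_left + v_right)`` where ``v`` are the (recursively
    augmented) branch lengths below the node; the inferred ancestral
    value is the ``1/v``-weighted average of the daughters and the
    node's own branch is augmented by ``v_l v_r / (v_l + v_r)``.

    A binary backbone with k tips yields exactly k - 1 contrasts; a
    constant trait yields all-zero contrasts.
    """
    mode = mode or backbone.mode
    if mode not in BackboneTree.MODES:
        raise ValueError(f"mode must be one of {BackboneTree.MODES}")
    missing = [lab for lab in backbone.tip_labels if lab not in trait]
    if missing:
        raise KeyError(f"trait missing for backbone tips: {missing}")
    work = backbone.tree.clone(depth=1)
    work, _ = _resolve_polytomies(work, polytomy_policy)

    values: dict = {}
    v: dict = {}
    contrasts: list[float] = []
    node_ids: list[str] = []
    for node in work.postorder_node_iter():
        if node.is_leaf():
            values[node] = float(trait[node.taxon.label])
            v[node] = 1.0 if mode == "punctuational" else float(node.edge.length or 0.0)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise TreeValidationError("internal node is not bifurcating")
        left, right = children
        vl, vr = v[left], v[right]
        if vl + vr <= 0:
            raise TreeValidationError(
                "zero expected variance at a contrast (both daughter "
                "branches have zero length)"
            )
        diff = values[left] - values[right]
        contrasts.append(diff / np.sqrt(vl + vr))
        node_ids.append(
            "|".join(sorted(lf.taxon.label for lf in node.leaf_iter()))
        )
        # 1/v-weighted average, arranged so equal daughters reproduce
        # their shared value exactly (constant traits give zero contrasts)
        values[node] = values[right] + diff * vr / (vl + vr)
        own = 1.0 if mode == "punctuational" else float(node.edge.length or 0.0)
        v[node] = own + vl * vr / (vl + vr)
    return ContrastSet(
        contrasts=np.array(contrasts), node_ids=node_ids, mode=mode
    )


def positivize(cx: ContrastSet, cy: ContrastSet):
    """Flip each contrast pair's sign so the x-contrast is nonnegative.

    The convention for through-origin contrast plots; it changes no
    contrast magnitude and no through-origin statistic.
    """
    sign = np.where(cx.contrasts < 0, -1.0, 1.0)
    return cx.contrasts * sign, cy.contrasts * sign


def regress_through_origin(cx: ContrastSet, cy: ContrastSet) -> RegressionResult:
    """Least-squares regression of y-contrasts on x-contrasts, no intercept.

    slope = sum(cx cy) / sum(cx^2); r^2 is the uncentered
    (through-origin) coefficient ``(sum cx cy)^2 / (sum cx^2 sum cy^2)``;
    the F statistic is ``r^2 / (1 - r^2) * (n - 1)`` on (1, n - 1)
    degrees of freedom with a two-sided p-value.
    """
    if cx.node_ids != cy.node_ids:
        raise ValueError("contrast sets come from different backbones/orderings")
    n = len(cx)
    if n < 3:
        raise ValueError("need at least 3 contrasts")
    x, y = positivize(cx, cy)
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise DegeneratePredictorError("all x-contrasts are zero")
    sxy = float(np.sum(x * y))
    syy = float(np.sum(y * y))
    slope = sxy / sxx
    r2 = 0.0 if syy == 0 else sxy * sxy / (sxx * syy)
    df_den = n - 1
    F = np.inf if r2 >= 1 else r2 / (1 - r2) * df_den
    p = float(stats.f.sf(F, 1, df_den))
    return RegressionResult(
        slope=slope, r2=r2, F=float(F), df=(1, df_den), p_value=p, n_points=n
    )


def regress_ols(x, y, label: str = "") -> RegressionResult:
    """Ordinary least squares of y on x with intercept; F on (1, n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("predictor has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r2=float(model.rsquared),
        F=float(model.fvalue),
        df=(1, int(model.df_resid)),
        p_value=float(model.f_pvalue),
        n_points=len(x),
        label=label,
    )


#: response variables of the main battery, as (label, column transform)
_RESPONSES = ("log10_lam", "epsilon_sq")
_PREDICTORS = ("mean_rate", "rate_cv")


def _with_transforms(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["log10_lam"] = np.log10(out["lam"].astype(float))
    out["epsilon_sq"] = out["epsilon"].astype(float) ** 2
    return out


def run_regression_battery(
    table: pd.DataFrame,
    backbone: BackboneTree | None = None,
    polytomy_policy: str = "strict",
) -> pd.DataFrame:
    """The full cross-clade regression battery.

    For each response in {log10(lam), epsilon^2} against each predictor
    in {mean_rate, rate_cv}: a non-phylogenetic OLS and, when a backbone
    is supplied, PIC through-origin regressions under gradual and
    punctuational branch lengths.  Artifact checks regress mean_rate on
    node density, tip count (sequence sampling), and crown age
    (non-phylogenetic), when those covariates are present.

    Returns a tidy DataFrame with one row per regression.
    """
    table = _with_transforms(table)
    if backbone is not None:
        clades = set(table["clade_id"].astype(str))
        if clades != set(backbone.tip_labels):
            raise ValueError(
                "backbone tips do not match the table's clade_id values"
            )
    rows = []

    def record(kind, yname, xname, result, note=""):
        rows.append(
            {
                "analysis": kind,
                "response": yname,
                "predictor": xname,
                "slope": result.slope if result else np.nan,
                "intercept": (result.intercept if result else np.nan),
                "r2": result.r2 if result else np.nan,
                "F": result.F if result else np.nan,
                "df1": result.df[0] if result else np.nan,
                "df2": result.df[1] if result else np.nan,
                "p_value": result.p_value if result else np.nan,
                "n": result.n_points if result else len(table),
                "note": note,
            }
        )

    for yname in _RESPONSES:
        for xname in _PREDICTORS:
            try:
                res = regress_ols(table[xname], table[yname])
                record("non_pic", yname, xname, res)
            except DegeneratePredictorError:
                record("non_pic", yname, xname, None, "degenerate predictor")
            if backbone is None:
                continue
            traits_x = dict(zip(table["clade_id"].astype(str), table[xname]))
            traits_y = dict(zip(table["clade_id"].astype(str), table[yname]))
            for mode in BackboneTree.MODES:
                cx = pic_contrasts(
                    backbone, traits_x, mode=mode, polytomy_policy=polytomy_policy
                )
                cy = pic_contrasts(
                    backbone, traits_y, mode=mode, polytomy_policy=polytomy_policy
                )
                try:
                    res = regress_through_origin(cx, cy)
                    record(f"pic_{mode}", yname, xname, res)
                except DegeneratePredictorError:
                    record(
                        f"pic_{mode}", yname, xname, None, "degenerate predictor"
                    )

    for covariate in ("node_density", "n_tips", "crown_age"):
        if covariate in table.columns and table[covariate].notna().all():
            for yname in ("mean_rate", "rate_cv") if covariate == "n_tips" else ("mean_rate",):
                try:
                    res = regress_ols(table[covariate], table[yname])
                    record("artifact_check", yname, covariate, res)
                except DegeneratePredictorError:
                    record("artifact_check", yname, covariate, None,
                           "degenerate predictor")
    return pd.DataFrame(rows)
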