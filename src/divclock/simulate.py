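"""Synthetic data with the statistical structure the analyses assume.

Generators:

* crown-conditioned constant-rate birth-death chronograms (forward
  Gillespie simulation from two crown lineages, reconstructed tree of
  extant tips only);
* uniform tip subsampling (rho-sampling of the tips);
* uncorrelated lognormal relaxed-clock branch rates, parameterized by
  the *expected* rate so the generating mean is directly comparable to
  the branch-length-weighted mean rate statistic;
* Brownian traits on a clade backbone, and a full multi-clade study
  mimic in which clade-level substitution rate drives log10(speciation
  rate) with a known effect size.

All generators draw from a single :class:`numpy.random.Generator` and
are byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .birth_death import fit_bd
from .clock_summaries import estimates_to_frame, summarize_clade
from .trees import BackboneTree, DatedTree, RatedTree

__all__ = [
    "SimConfig",
    "SimulationError",
    "simulate_bd_tree",
    "subsample_tips",
    "simulate_branch_rates",
    "brownian_trait",
    "simulate_backbone",
    "simulate_study",
]


class SimulationError(RuntimeError):
    """A conditioned simulation exhausted its retry budget."""


@dataclass
class SimConfig:
    """Generating parameters for one clade's synthetic data.

    Defaults emulate a temperate angiosperm genus-level ITS study:
    speciation around 0.4 events/lineage/My with moderate relative
    extinction, a clock mean of a few 1e-3 substitutions/site/My, and
    enough log-rate spread (0.6) to give rate CVs in the 0.4-1.1 range.
    """

    lam: float = 0.4
    mu: float = 0.2
    f: float = 1.0
    n_tips: int | None = 100
    max_time: float | None = None
    clock_mean: float = 4e-3
    clock_stdev_log: float = 0.6
    bm_sigma2: float = 1e-7
    seed: int | None = None

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be nonnegative")
        if not (0 < self.f <= 1):
            raise ValueError("f must lie in (0, 1]")
        if (self.n_tips is None) == (self.max_time is None):
            raise ValueError("set exactly one of n_tips / max_time")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# -- birth-death chronograms ----------------------------------------------

_POP_CAP = 100_000


def _gillespie_crown(lam, mu, n_tips, max_time, rng):
    """One forward pass from 2 crown lineages.

    Returns (lineages, stop_time) or None if the replicate fails its
    conditioning (extinction, or n never reached).  Lineages are dicts
    with parent/birth/death/children; speciation keeps the parent alive
    and spawns one child.
    """
    lineages = [
        {"parent": None, "birth": 0.0, "death": None, "children": []},
        {"parent": None, "birth": 0.0, "death": None, "children": []},
    ]
    active = [0, 1]
    t = 0.0
    total_rate_per_lineage = lam + mu
    while True:
        k = len(active)
        if k == 0:
            return None
        if n_tips is not None and k == n_tips:
            # first passage at n: stop uniformly within the holding
            # interval before the next event, avoiding stopping-rule bias
            dt_next = rng.exponential(1.0 / (k * total_rate_per_lineage))
            return lineages, t + rng.uniform(0.0, dt_next)
        if k > _POP_CAP:
            raise SimulationError("population exceeded simulation cap")
        dt = rng.exponential(1.0 / (k * total_rate_per_lineage))
        if max_time is not None and t + dt > max_time:
            return lineages, max_time
        t += dt
        idx = active[rng.integers(k)]
        if rng.random() < lam / total_rate_per_lineage:
            lineages.append(
                {"parent": idx, "birth": t, "death": None, "children": []}
            )
            lineages[idx]["children"].append(len(lineages) - 1)
            active.append(len(lineages) - 1)
        else:
            lineages[idx]["death"] = t
            active.remove(idx)


def _reconstruct(lineages, idx, stop_time, tip_counter):
    """Reconstructed subtree descending from lineage ``idx``.

    Returns a nested tuple ('tip', label) / ('node', time, left, right),
    or None when no extant descendant survives.
    """
    line = lineages[idx]
    cur = None
    if line["death"] is None:
        tip_counter[0] += 1
        cur = ("tip", f"t{tip_counter[0]}")
    for child in sorted(
        line["children"], key=lambda c: lineages[c]["birth"], reverse=True
    ):
        sub = _reconstruct(lineages, child, stop_time, tip_counter)
        if sub is None:
            continue
        if cur is None:
            cur = sub
        else:
            cur = ("node", lineages[child]["birth"], cur, sub)
    return cur


def _to_newick(node, parent_time, stop_time, event_ages):
    if node[0] == "tip":
        return f"{node[1]}:{stop_time - parent_time!r}"
    _, t, left, right = node
    event_ages.append(stop_time - t)
    inner = (
        _to_newick(left, t, stop_time, event_ages)
        + ","
        + _to_newick(right, t, stop_time, event_ages)
    )
    return f"({inner}):{t - parent_time!r}"


def simulate_bd_tree(
    lam: float,
    mu: float = 0.0,
    n_tips: int | None = None,
    max_time: float | None = None,
    seed=None,
    max_tries: int = 1000,
) -> DatedTree:
    """Simulate a crown-conditioned reconstructed birth-death tree.

    Starts from two crown lineages and conditions on both leaving
    extant descendants at the stop condition (so the reconstructed
    crown age equals the elapsed simulation time).  When conditioning
    on ``n_tips``, the process stops at a uniform time within the first
    holding interval with n extant lineages (first passage at n among
    surviving replicates).

    The returned tree carries ``simulated_branching_times`` — the exact
    event ages, sorted descending — for verification against the tree's
    own branching-time extraction.
    """
    if (n_tips is None) == (max_time is None):
        raise ValueError("set exactly one of n_tips / max_time")
    if n_tips is not None and n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _as_rng(seed)
    for _ in range(max_tries):
        out = _gillespie_crown(lam, mu, n_tips, max_time, rng)
        if out is None:
            continue
        lineages, stop_time = out
        if stop_time <= 0:
            continue
        tip_counter = [0]
        left = _reconstruct(lineages, 0, stop_time, tip_counter)
        right = _reconstruct(lineages, 1, stop_time, tip_counter)
        if left is None or right is None:
            continue  # crown did not survive: retry
        root = ("node", 0.0, left, right)
        event_ages = []
        newick = _to_newick(root, 0.0, stop_time, event_ages)
        # _to_newick gives the root a root-edge length of 0; strip it
        newick = newick.rsplit(":", 1)[0] + ";"
        tree = DatedTree.from_string(newick, schema="newick")
        tree.simulated_branching_times = sorted(event_ages, reverse=True)
        return tree
    raise SimulationError(
        f"no replicate satisfied the conditioning in {max_tries} tries"
    )


def subsample_tips(
    tree: DatedTree, f: float, seed=None, max_tries: int = 1000
) -> DatedTree:
    """Retain each tip independently with probability ``f``.

    Conditional on at least 2 survivors (failed draws are retried); the
    pruned reconstructed tree is returned.  ``f = 1`` returns a copy of
    the input.
    """
    if not (0 < f <= 1):
        raise ValueError("f must lie in (0, 1]")
    rng = _as_rng(seed)
    labels = tree.tip_labels
    if f == 1.0:
        return DatedTree(dendropy.Tree(tree.tree))
    for _ in range(max_tries):
        keep = [lab for lab in labels if rng.random() < f]
        if len(keep) < 2:
            continue
        pruned = dendropy.Tree(tree.tree)
        pruned.retain_taxa_with_labels(keep)
        pruned.seed_node.edge.length = None  # drop any stem left by pruning
        return DatedTree(pruned)
    raise SimulationError(
        f"subsampling at f={f} kept < 2 tips in all {max_tries} tries"
    )


def simulate_branch_rates(
    tree: DatedTree,
    clock_mean: float,
    clock_stdev_log: float,
    seed=None,
) -> RatedTree:
    """Attach i.i.d. lognormal branch rates (uncorrelated relaxed clock).

    The lognormal is parameterized by its *expectation*: each branch
    rate has mean ``clock_mean`` and log-scale standard deviation
    ``clock_stdev_log`` (so the generating rate CV is
    ``sqrt(exp(s^2) - 1)``).  ``clock_stdev_log = 0`` is a strict clock.
    """
    if clock_mean <= 0:
        raise ValueError("clock_mean must be positive")
    if clock_stdev_log < 0:
        raise ValueError("clock_stdev_log must be nonnegative")
    rng = _as_rng(seed)
    s = clock_stdev_log
    mu_log = np.log(clock_mean) - 0.5 * s * s
    rates = {}
    for node, _ in tree.branches():
        rates[node] = (
            clock_mean if s == 0 else float(rng.lognormal(mu_log, s))
        )
    rated = RatedTree(tree, rates)
    rated.annotate()
    return rated


# -- backbone + study mimic ------------------------------------------------

def simulate_backbone(
    n_clades: int,
    lam: float = 0.05,
    seed=None,
    mode: str = "gradual",
) -> BackboneTree:
    """A Yule (pure-birth) clade-level backbone with tips clade_01..."""
    rng = _as_rng(seed)
    tree = simulate_bd_tree(lam=lam, mu=0.0, n_tips=n_clades, seed=rng)
    for i, leaf in enumerate(tree.tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"clade_{i:02d}"
    return BackboneTree(tree.tree, mode=mode)


def brownian_trait(
    tree: DatedTree,
    sigma2: float,
    root_value: float = 0.0,
    seed=None,
) -> dict[str, float]:
    """Brownian motion along the tree; returns tip values keyed by label.

    The change along a branch of length ``t`` is Normal(0, sigma2 * t).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be nonnegative")
    rng = _as_rng(seed)
    values = {tree.tree.seed_node: float(root_value)}
    out = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * length)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


@dataclass
class StudyTruth:
    """Generating values of one synthetic study, for recovery checks."""

    effect_size: float
    intercept: float
    clade_ids: list[str] = field(default_factory=list)
    clock_means: list[float] = field(default_factory=list)
    lams: list[float] = field(default_factory=list)
    epsilons: list[float] = field(default_factory=list)
    n_tips: list[int] = field(default_factory=list)


def simulate_study(
    n_clades: int = 13,
    effect_size: float = 91.0,
    intercept: float | None = None,
    base_config: SimConfig | None = None,
    noise_sigma2: float = 2e-3,
    backbone_lam: float = 0.05,
    n_tips_range: tuple[int, int] = (47, 304),
    epsilon_range: tuple[float, float] = (0.0, 0.9),
    seed=None,
    compute_ci: bool = False,
    keep_trees: bool = False,
):
    """End-to-end multi-clade study mimic.

    Simulates a Yule backbone over ``n_clades`` clades; evolves the
    clade-level clock mean by Brownian motion on it; sets each clade's
    true speciation rate via ``log10(lam) = intercept + effect_size *
    clock_mean + Brownian noise``; simulates each clade's chronogram
    and branch rates; and runs the birth-death fit and clock summaries
    to produce an estimates table.

    Returns ``(backbone, table, truth)`` — the estimates table is a
    DataFrame shaped like the per-clade summary table, and ``truth``
    records every generating value for recovery tests.
    """
    if n_clades < 4:
        raise ValueError("a study needs at least 4 clades")
    cfg = base_config or SimConfig()
    rng = _as_rng(seed)
    backbone = simulate_backbone(n_clades, lam=backbone_lam, seed=rng)
    clock_means = brownian_trait(
        backbone, sigma2=cfg.bm_sigma2, root_value=cfg.clock_mean, seed=rng
    )
    # rates must stay positive: reflect stray negatives back above a floor
    floor = 2e-4
    clock_means = {
        k: (floor + abs(v - floor) if v < floor else v)
        for k, v in clock_means.items()
    }
    noise = brownian_trait(backbone, sigma2=noise_sigma2, seed=rng)
    if intercept is None:
        intercept = float(np.log10(cfg.lam)) - effect_size * cfg.clock_mean
    truth = StudyTruth(effect_size=effect_size, intercept=float(intercept))
    rows = []
    trees = {}
    for clade in backbone.tip_labels:
        m = clock_means[clade]
        lam_true = 10.0 ** (intercept + effect_size * m + noise[clade])
        eps_true = float(rng.uniform(*epsilon_range))
        n_target = int(rng.integers(n_tips_range[0], n_tips_range[1] + 1))
        tree = simulate_bd_tree(
            lam=lam_true, mu=eps_true * lam_true, n_tips=n_target, seed=rng
        )
        if cfg.f < 1.0:
            tree = subsample_tips(tree, cfg.f, seed=rng)
        rated = simulate_branch_rates(
            tree, clock_mean=m, clock_stdev_log=cfg.clock_stdev_log, seed=rng
        )
        fit = fit_bd(tree, f=cfg.f, compute_ci=compute_ci)
        rows.append(
            summarize_clade(
                rated, fit, sampling_fraction=cfg.f, clade_id=clade
            )
        )
        truth.clade_ids.append(clade)
        truth.clock_means.append(m)
        truth.lams.append(lam_true)
        truth.epsilons.append(eps_true)
        truth.n_tips.append(n_target)
        if keep_trees:
            trees[clade] = rated
    table = estimates_to_frame(rows)
    if keep_trees:
        return backbone, table, truth, trees
    return backbone, table, truth
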