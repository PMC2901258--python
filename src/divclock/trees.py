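"""Dated and rate-annotated tree containers.

Trees are stored as :class:`dendropy.Tree` objects; this module wraps them
with the validation every downstream analysis assumes: an ultrametric,
rooted topology whose node ages are measured backward from the present
(tips at age 0, crown at ``crown_age``), optionally carrying one
nonnegative substitution rate per branch.

Rates can be conveyed either as BEAST-style bracketed branch comments
(``[&rate=0.005]``) or as a chronogram/phylogram pair with identical
topology, in which case each branch rate is the phylogram length divided
by the chronogram length.
"""

from __future__ import annotations

import io
from typing import Iterator, Sequence

import dendropy

__all__ = [
    "TreeError",
    "TreeValidationError",
    "TopologyMismatchError",
    "DatedTree",
    "RatedTree",
    "BackboneTree",
    "read_tree",
    "check_ultrametric",
]

#: Default ultrametricity tolerance, relative to crown age.  Calibrated
#: trees carry floating-point noise from dating software; exact equality
#: of root-to-tip path lengths is never expected.
DEFAULT_ULTRAMETRIC_RTOL = 1e-6

RATE_ANNOTATION = "rate"


class TreeError(ValueError):
    """Base class for tree input problems."""


class TreeValidationError(TreeError):
    """The tree violates a structural invariant (negative branch,
    non-ultrametric, too few tips)."""


class TopologyMismatchError(TreeError):
    """A paired chronogram/phylogram does not share the chronogram's
    topology."""


def _root_distances(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    dist: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        length = node.edge.length
        if length is None:
            length = 0.0
        if length < 0:
            raise TreeValidationError(
                f"negative branch length {length} on edge above "
                f"{node.taxon.label if node.taxon else 'an internal node'}"
            )
        parent = node.parent_node
        dist[node] = (dist[parent] if parent is not None else 0.0) + length
    return dist


class DatedTree:
    """An ultrametric, rooted tree with node ages in time units (e.g. My).

    Node ages are measured backward from the present: every tip sits at
    age 0 (within tolerance) and the root at ``crown_age``.  Branch
    lengths are parent age minus child age.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree` whose edge lengths are in time
        units.  The tree is used as-is (not copied).
    ultrametric_rtol:
        Tolerated spread of root-to-tip path lengths, relative to crown
        age.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        ultrametric_rtol: float = DEFAULT_ULTRAMETRIC_RTOL,
    ) -> None:
        tree.is_rooted = True
        self._tree = tree
        self._depths = _root_distances(tree)
        tips = [nd for nd in tree.leaf_node_iter()]
        if len(tips) < 2:
            raise TreeValidationError("a dated tree needs at least 2 tips")
        labels = [t.taxon.label if t.taxon else None for t in tips]
        if None in labels or len(set(labels)) != len(labels):
            raise TreeValidationError("tip labels must be present and unique")
        self._crown_age = max(self._depths[t] for t in tips)
        if self._crown_age <= 0:
            raise TreeValidationError("crown age must be positive")
        if not check_ultrametric(tree, self._crown_age * ultrametric_rtol):
            raise TreeValidationError(
                "tree is not ultrametric within tolerance "
                f"{ultrametric_rtol} * crown age"
            )

    # -- basic structure ---------------------------------------------------

    @property
    def tree(self) -> dendropy.Tree:
        """The underlying :class:`dendropy.Tree`."""
        return self._tree

    @property
    def crown_age(self) -> float:
        return self._crown_age

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list[str]:
        return [t.taxon.label for t in self._tree.leaf_node_iter()]

    def node_age(self, node: dendropy.Node) -> float:
        """Age of ``node``, measured back from the present (tips = 0)."""
        age = self._crown_age - self._depths[node]
        return 0.0 if node.is_leaf() else age

    def branching_times(self) -> list[float]:
        """Ages of all internal nodes, sorted descending (crown age first)."""
        ages = [
            self.node_age(nd)
            for nd in self._tree.preorder_node_iter()
            if not nd.is_leaf()
        ]
        return sorted(ages, reverse=True)

    @property
    def n_internal_nodes(self) -> int:
        """Number of internal nodes, the root included."""
        return sum(1 for nd in self._tree.preorder_node_iter() if not nd.is_leaf())

    def branches(self) -> Iterator[tuple[dendropy.Node, float]]:
        """Yield ``(child_node, branch_length)`` for every non-root branch."""
        for nd in self._tree.preorder_node_iter():
            if nd.parent_node is not None:
                yield nd, (nd.edge.length or 0.0)

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read(cls, path, schema: str = "newick", **kwargs) -> "DatedTree":
        return cls(_parse_tree(path, schema), **kwargs)

    @classmethod
    def from_string(cls, data: str, schema: str = "newick", **kwargs) -> "DatedTree":
        return cls(_parse_tree(io.StringIO(data), schema), **kwargs)

    def write(self, path, schema: str = "newick") -> None:
        with open(path, "w") as fh:
            fh.write(self.as_string(schema))

    def as_string(self, schema: str = "newick") -> str:
        return self._tree.as_string(
            schema=schema,
            suppress_annotations=False,
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )


class RatedTree:
    """A :class:`DatedTree` plus one substitution rate per branch
    (substitutions/site/My, nonnegative)."""

    def __init__(self, dated: DatedTree, rates: dict[dendropy.Node, float]):
        self.dated = dated
        for node, _ in dated.branches():
            if node not in rates:
                raise TreeValidationError("every branch needs a rate")
            if not (rates[node] >= 0):
                raise TreeValidationError("branch rates must be nonnegative")
        self._rates = dict(rates)

    def branch_rate(self, node: dendropy.Node) -> float:
        return self._rates[node]

    def branches(self) -> Iterator[tuple[float, float]]:
        """Yield ``(branch_length, branch_rate)`` over all non-root branches."""
        for node, length in self.dated.branches():
            yield length, self._rates[node]

    @classmethod
    def from_annotations(cls, dated: DatedTree) -> "RatedTree":
        """Recover per-branch rates from ``[&rate=...]`` annotations."""
        rates: dict[dendropy.Node, float] = {}
        for node, _ in dated.branches():
            value = node.annotations.get_value(RATE_ANNOTATION, None)
            if value is None:
                raise TreeValidationError(
                    "missing rate annotation on a branch; not a rated tree"
                )
            rates[node] = float(value)
        return cls(dated, rates)

    @classmethod
    def from_chronogram_phylogram(
        cls, chronogram: DatedTree, phylogram: dendropy.Tree
    ) -> "RatedTree":
        """Derive branch rates as phylogram length / chronogram length.

        The phylogram must have the same topology (same tip-label
        bipartition on every branch) as the chronogram.  A zero-length
        chronogram branch is only acceptable when the matching phylogram
        branch has zero length too; the rate is then 0.
        """
        phylo_len = _bipartition_lengths(phylogram)
        chrono_by_node: dict[dendropy.Node, frozenset[str]] = {}
        for node in chronogram.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            chrono_by_node[node] = frozenset(
                lf.taxon.label for lf in node.leaf_iter()
            )
        if set(chrono_by_node.values()) != set(phylo_len):
            raise TopologyMismatchError(
                "chronogram and phylogram do not share a topology"
            )
        rates: dict[dendropy.Node, float] = {}
        for node, t_len in chronogram.branches():
            s_len = phylo_len[chrono_by_node[node]]
            if t_len == 0:
                if s_len != 0:
                    raise TreeValidationError(
                        "zero-duration branch with nonzero substitutions"
                    )
                rates[node] = 0.0
            else:
                rates[node] = s_len / t_len
        tree = cls(chronogram, rates)
        tree.annotate()
        return tree

    def annotate(self) -> None:
        """Attach ``[&rate=...]`` annotations so writes carry the rates."""
        for node, _ in self.dated.branches():
            node.annotations.drop(name=RATE_ANNOTATION)
            node.annotations.add_new(RATE_ANNOTATION, repr(self._rates[node]))

    def write(self, path, schema: str = "newick") -> None:
        self.annotate()
        self.dated.write(path, schema=schema)

    def as_string(self, schema: str = "newick") -> str:
        self.annotate()
        return self.dated.as_string(schema)


class BackboneTree(DatedTree):
    """A clade-level dated tree: one tip per analyzed clade.

    ``mode`` selects the branch lengths used by trait-evolution models:
    ``"gradual"`` keeps the time-proportional lengths as given, while
    ``"punctuational"`` replaces every branch length with 1, modelling
    trait change as concentrated at speciation events.
    """

    MODES = ("gradual", "punctuational")

    def __init__(self, tree: dendropy.Tree, mode: str = "gradual", **kwargs):
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        super().__init__(tree, **kwargs)
        self.mode = mode

    def working_branch_lengths(self) -> dict[dendropy.Node, float]:
        """Branch lengths under the selected trait-evolution mode."""
        if self.mode == "punctuational":
            return {node: 1.0 for node, _ in self.branches()}
        return {node: length for node, length in self.branches()}


def _parse_tree(source, schema: str) -> dendropy.Tree:
    schema = schema.lower()
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported schema {schema!r}")
    kwargs = dict(schema=schema, extract_comment_metadata=True)
    try:
        if hasattr(source, "read"):
            return dendropy.Tree.get(file=source, **kwargs)
        return dendropy.Tree.get(path=str(source), **kwargs)
    except Exception as exc:  # dendropy raises schema-specific errors
        raise TreeError(f"could not parse tree: {exc}") from exc


def _bipartition_lengths(tree: dendropy.Tree) -> dict[frozenset, float]:
    lengths: dict[frozenset, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        if length < 0:
            raise TreeValidationError("negative branch length in phylogram")
        lengths[frozenset(lf.taxon.label for lf in node.leaf_iter())] = length
    return lengths


def read_tree(
    path,
    schema: str = "newick",
    phylogram_path=None,
) -> DatedTree | RatedTree:
    """Read a dated tree, recovering branch rates when available.

    If any branch carries a ``rate`` annotation the result is a
    :class:`RatedTree`; if ``phylogram_path`` is given, rates are derived
    per branch as phylogram length / chronogram length.  Otherwise a
    plain :class:`DatedTree` is returned.
    """
    dated = DatedTree.read(path, schema=schema)
    if phylogram_path is not None:
        phylogram = _parse_tree(phylogram_path, schema)
        return RatedTree.from_chronogram_phylogram(dated, phylogram)
    has_rates = any(
        node.annotations.get_value(RATE_ANNOTATION, None) is not None
        for node, _ in dated.branches()
    )
    if has_rates:
        return RatedTree.from_annotations(dated)
    return dated


def check_ultrametric(tree: dendropy.Tree | DatedTree, tolerance: float) -> bool:
    """True iff all root-to-tip path lengths agree within ``tolerance``.

    A pure predicate: it never raises, even on trees with negative
    branch lengths (which simply fail the dated-tree validation later).
    """
    if isinstance(tree, DatedTree):
        tree = tree.tree
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depths[node] = (depths[parent] if parent is not None else 0.0) + (
            node.edge.length or 0.0
        )
    tip_depths = [depths[nd] for nd in tree.leaf_node_iter()]
    return max(tip_depths) - min(tip_depths) <= tolerance
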