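"""Ultrametric chronogram handling: Newick I/O, validation, crown ages.

A chronogram is a rooted tree whose branch lengths are absolute time (here
million years, Ma).  Tips sit at the present; the age of an internal node is
its time before present.  Dated trees exported from Bayesian dating software
are ultrametric only up to print precision, so node ages are always measured
against the *mean* tip depth and ultrametricity is checked with a
configurable relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import dendropy


class ChronogramError(ValueError):
    """Invalid chronogram input (parse failure or violated invariant)."""


@dataclass(frozen=True)
class CladeSelector:
    """A named clade, pointed at by the tip set whose MRCA defines it.

    Parameters
    ----------
    name : str
        Free-text clade label.
    tips : frozenset of str
        Tip labels (at least two) whose most recent common ancestor is the
        clade's crown node.
    """

    name: str
    tips: frozenset = field()

    def __init__(self, name: str, tips: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "tips", frozenset(tips))
        if len(self.tips) < 2:
            raise ChronogramError(
                f"clade {name!r}: selector needs >= 2 tips, got {len(self.tips)}"
            )


@dataclass(frozen=True)
class UltrametricReport:
    """Outcome of an ultrametricity check."""

    passed: bool
    max_rel_deviation: float
    max_abs_deviation: float
    mean_depth: float
    rel_tol: float
    worst_tip: str


class Chronogram:
    """Rooted ultrametric tree with branch lengths in Ma.

    Wraps a :class:`dendropy.Tree`.  Construct via :func:`parse_chronogram`
    or from a simulator result; the constructor validates tip labels and
    branch lengths but does not enforce ultrametricity (use
    :func:`check_ultrametric`).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True  # chronograms are rooted by definition
        self._validate()
        self._tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        labels = [lf.taxon.label if lf.taxon else None for lf in self._tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ChronogramError(f"tree needs >= 2 tips, got {len(labels)}")
        if any(lb in (None, "") for lb in labels):
            raise ChronogramError("every tip must carry a non-empty label")
        dupes = {lb for lb in labels if labels.count(lb) > 1}
        if dupes:
            raise ChronogramError(f"duplicate tip labels: {sorted(dupes)}")
        for edge in self._tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge may be lengthless
                continue
            if edge.length is None:
                head = edge.head_node
                where = head.taxon.label if head.taxon else "an internal node"
                raise ChronogramError(f"missing branch length on the edge above {where}")
            if edge.length < 0:
                raise ChronogramError(f"negative branch length {edge.length}")

    # -- basic accessors --------------------------------------------------

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def tip_count(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def mean_tip_depth(self) -> float:
        depths = [lf.root_distance for lf in self._tree.leaf_node_iter()]
        return sum(depths) / len(depths)

    def node_age(self, node: dendropy.Node) -> float:
        """Time before present of ``node`` (mean tip depth minus its depth)."""
        return self.mean_tip_depth - node.root_distance

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Chronogram with {self.tip_count} tips, height {self.mean_tip_depth:.4g} Ma>"


def parse_chronogram(newick_text: str) -> Chronogram:
    """Parse a Newick string into a :class:`Chronogram`.

    Polytomies are preserved.  Malformed Newick, missing branch lengths and
    duplicate tip labels all raise :class:`ChronogramError`.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ChronogramError(f"Newick parse error: {exc}") from exc
    return Chronogram(tree)


def write_newick(tree: Chronogram) -> str:
    """Serialise to Newick (branch lengths after colons)."""
    return tree.as_newick()


def check_ultrametric(tree: Chronogram, rel_tol: float = 1e-6) -> UltrametricReport:
    """Report the largest root-to-tip depth deviation relative to mean depth.

    Passes iff ``max |depth(tip) - mean depth| / mean depth <= rel_tol``.
    """
    leaves = list(tree._tree.leaf_node_iter())
    mean = tree.mean_tip_depth
    worst, worst_tip = 0.0, leaves[0].taxon.label
    for lf in leaves:
        dev = abs(lf.root_distance - mean)
        if dev > worst:
            worst, worst_tip = dev, lf.taxon.label
    rel = worst / mean if mean > 0 else 0.0
    return UltrametricReport(
        passed=rel <= rel_tol,
        max_rel_deviation=rel,
        max_abs_deviation=worst,
        mean_depth=mean,
        rel_tol=rel_tol,
        worst_tip=worst_tip,
    )


def crown_age(tree: Chronogram, clade: CladeSelector) -> float:
    """Crown age (Ma) of the clade: age of the MRCA of the selector's tips.

    The MRCA is defined set-theoretically, so polytomies are fine.  Unknown
    tip labels raise with the full list of missing labels.
    """
    present = set(tree.tip_labels)
    missing = sorted(set(clade.tips) - present)
    if missing:
        raise ChronogramError(
            f"clade {clade.name!r}: tips not in tree: {missing}"
        )
    mrca = tree._tree.mrca(taxon_labels=list(clade.tips))
    return tree.node_age(mrca)


def read_clade_selectors(text: str) -> list:
    """Parse a plain-text clade definition table.

    One clade per line: ``name<TAB>tipA,tipB,...``.  Blank lines and lines
    starting with ``#`` are skipped.
    """
    out = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, tips = line.split("\t", 1)
        except ValueError as exc:
            raise ChronogramError(f"line {i}: expected 'name<TAB>tip,tip,...'") from exc
        out.append(CladeSelector(name.strip(), [t.strip() for t in tips.split(",") if t.strip()]))
    return out
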