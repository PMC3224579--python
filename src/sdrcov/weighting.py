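"""Per-sequence prior weights that counteract uneven clade representation.

An MSA drawn from public databases typically over-represents well-studied
clades. Because every information measure downstream is a weighted average
over rows, crowded clades would otherwise dominate the site distributions
and mask signal from sparsely sampled lineages. The remedy is a prior
weight per sequence: the total weight 1 enters at the root of a guide tree
and is pushed down recursively, each internal node splitting its share
among its child subtrees, so that sequences inside crowded subtrees end up
sharing a smaller allocation.

When no tree is supplied a deterministic UPGMA guide tree is built from
pairwise fractional-identity distances (1 - identity, with gapped columns
counted as mismatches).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor

from .errors import TreeError, WeightsError
from .io import DomainAlignment


@dataclasses.dataclass
class SequenceWeights:
    """Normalized non-negative weights, one per alignment row."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise WeightsError("weights must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise WeightsError("weights must be non-negative")
        total = self.values.sum()
        if total <= 0:
            raise WeightsError("at least one weight must be positive")
        self.values = self.values / total

    @property
    def n(self) -> int:
        return self.values.size

    def subset(self, indices: Sequence[int]) -> "SequenceWeights":
        """Weights for a row subset, renormalized."""
        return SequenceWeights(self.values[list(indices)].copy())


def uniform_weights(n: int) -> SequenceWeights:
    """Equal weight 1/n for each of ``n`` sequences."""
    if n < 1:
        raise WeightsError("cannot build weights for an empty alignment")
    return SequenceWeights(np.full(n, 1.0 / n))


def read_weights(path: str | Path, ids: Sequence[str]) -> SequenceWeights:
    """Read a two-column id/weight TSV and align it to ``ids`` order."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise WeightsError(
                    f"{path}:{lineno}: expected 2 fields, got {len(parts)}"
                )
            sid, val_s = parts
            if sid in table:
                raise WeightsError(f"{path}:{lineno}: duplicate id {sid!r}")
            try:
                val = float(val_s)
            except ValueError as exc:
                raise WeightsError(
                    f"{path}:{lineno}: weight {val_s!r} is not a number"
                ) from exc
            if val < 0:
                raise WeightsError(f"{path}:{lineno}: negative weight for {sid!r}")
            table[sid] = val
    missing = [i for i in ids if i not in table]
    extra = [i for i in table if i not in set(ids)]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing ids: {', '.join(missing)}")
        if extra:
            parts.append(f"unknown ids: {', '.join(extra)}")
        raise WeightsError("weight table does not match alignment (" + "; ".join(parts) + ")")
    return SequenceWeights(np.array([table[i] for i in ids]))


# ---------------------------------------------------------------------------
# tree-derived weights
# ---------------------------------------------------------------------------


def pairwise_identity_matrix(alignment: DomainAlignment) -> np.ndarray:
    """(n, n) matrix of fractional identities over full alignment length.

    A column counts as a match only when both rows carry the same non-gap
    residue; the denominator is always the alignment length m.
    """
    codes = alignment.codes()
    n, m = codes.shape
    out = np.ones((n, n))
    for i in range(n):
        match = (codes[i] == codes) & (codes[i] >= 0)
        out[i] = match.sum(axis=1) / m
    return out


def build_guide_tree(alignment: DomainAlignment) -> Tree:
    """Deterministic UPGMA guide tree from 1 - identity distances.

    Ids are fed to the constructor in lexicographic order so that ties are
    broken reproducibly regardless of input row order.
    """
    order = sorted(range(alignment.n), key=lambda i: alignment.ids[i])
    ident = pairwise_identity_matrix(alignment)
    names = [alignment.ids[i] for i in order]
    lower = [
        [float(1.0 - ident[order[i], order[j]]) for j in range(i + 1)]
        for i in range(len(order))
    ]
    dm = DistanceMatrix(names=names, matrix=lower)
    tree = DistanceTreeConstructor().upgma(dm)
    return tree


def _subtree_length(clade: Clade) -> float:
    total = clade.branch_length or 0.0
    for child in clade.clades:
        total += _subtree_length(child)
    return total


def _apportion(clade: Clade, share: float, out: dict[str, float]) -> None:
    if clade.is_terminal():
        out[clade.name] = out.get(clade.name, 0.0) + share
        return
    children = clade.clades
    lengths = np.array([_subtree_length(c) for c in children])
    if lengths.sum() > 0:
        fractions = lengths / lengths.sum()
    else:
        # zero-length subtree: fall back to leaf counts, yielding uniformity
        counts = np.array([c.count_terminals() for c in children], dtype=float)
        fractions = counts / counts.sum()
    for child, frac in zip(children, fractions):
        _apportion(child, share * frac, out)


def tree_weights(
    alignment: DomainAlignment, tree: Tree | str | Path | None = None
) -> SequenceWeights:
    """Tree-proportional sequence weights.

    The unit weight at the root is split recursively among child subtrees in
    proportion to each subtree's total branch length (own edge plus all
    descendant edges), so sequences in crowded, shallow clades share a
    smaller allocation. When every child length is zero the split falls back
    to leaf counts. ``tree`` may be a Biopython tree, a Newick path, or
    ``None`` to build the UPGMA guide tree internally.
    """
    if tree is None:
        if alignment.n == 1:
            return SequenceWeights(np.array([1.0]))
        tree = build_guide_tree(alignment)
    elif isinstance(tree, (str, Path)):
        tree = Phylo.read(str(tree), "newick")

    leaves = [t.name for t in tree.get_terminals()]
    if len(leaves) != len(set(leaves)):
        raise TreeError("tree has duplicate leaf names")
    want, have = set(alignment.ids), set(leaves)
    if want != have:
        diff = sorted(want.symmetric_difference(have))
        raise TreeError(
            "tree leaves do not match alignment ids; symmetric difference: "
            + ", ".join(diff)
        )
    if len(leaves) == 1:
        return SequenceWeights(np.array([1.0]))

    shares: dict[str, float] = {}
    _apportion(tree.root, 1.0, shares)
    return SequenceWeights(np.array([shares[i] for i in alignment.ids]))
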