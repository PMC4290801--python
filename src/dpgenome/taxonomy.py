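"""Generalization hierarchies (taxonomy trees) and the specialization cut.

Each block of SNPs has one taxonomy tree whose root ``Any_<i>`` is the
fully generalized value and whose leaves are concrete block values
(space-joined genotype runs).  A *cut* holds, per block, the frontier of
nodes currently describing the release: exactly one node on every
root-to-leaf path.  Specializing a cut node replaces it by its children,
pushing the cut downward.

Trees are either supplied by the data owner (``user_supplied`` — public
domain knowledge, free of privacy cost) or derived by scanning the data
once (``data_derived`` — one leaf per distinct observed value).  A
data-derived forest depends on the data itself, so releases built on it
are stamped as not covered by the differential-privacy guarantee.

Ordering is canonical everywhere (children are ordered, flat leaves are
sorted lexicographically, candidates are enumerated in (block, preorder)
order) so that a seed fully reproduces a randomized run.

Label rules: leaf labels are unique within a tree and shaped like block
values; non-leaf labels are unique among non-leaf nodes and are either a
single space-free token (e.g. ``Any_2``) or shaped like a block value
(a merged category named after a representative value, which may repeat
as a leaf label deeper in the same subtree).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .blocking import BlockSpec, block_values
from .errors import StateError, ValidationError
from .io_formats import GENOTYPE_RE

USER_SUPPLIED = "user_supplied"
DATA_DERIVED = "data_derived"

#: Rendered form of a root label in release rows ("Any_3" prints as "Any";
#: the block position disambiguates).
ANY = "Any"


@dataclass(eq=False)
class TaxonomyNode:
    label: str
    children: list["TaxonomyNode"] = field(default_factory=list)
    parent: "TaxonomyNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_root(self) -> bool:
        return self.parent is None

    @property
    def rendered(self) -> str:
        """Label as printed in release rows: roots print as ``Any``."""
        return ANY if self.is_root else self.label

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def structure(self):
        """Nested (label, children) form used for serialization and hashing."""
        if self.is_leaf:
            return {"label": self.label}
        return {"label": self.label, "children": [c.structure() for c in self.children]}


def leaves_under(node: TaxonomyNode) -> list[str]:
    """Left-to-right leaf labels of the subtree; a leaf returns itself."""
    return [n.label for n in node.preorder() if n.is_leaf]


def _node_from_structure(obj) -> TaxonomyNode:
    if not isinstance(obj, dict) or "label" not in obj:
        raise ValidationError(f"taxonomy node must be a dict with 'label'; got {obj!r}")
    children = [_node_from_structure(c) for c in obj.get("children", [])]
    return TaxonomyNode(str(obj["label"]), children)


class _TreeIndex:
    """Per-tree lookup tables computed once at forest construction."""

    def __init__(self, root: TaxonomyNode, block: int, width: int):
        self.root = root
        leaf_labels: list[str] = []
        nonleaf_by_label: dict[str, TaxonomyNode] = {}
        leaf_by_label: dict[str, TaxonomyNode] = {}
        self.preorder_pos: dict[int, int] = {}
        for pos, node in enumerate(root.preorder()):
            self.preorder_pos[id(node)] = pos
            _check_label_shape(node, block, width)
            if node.is_leaf:
                if node.label in leaf_by_label:
                    raise ValidationError(
                        f"duplicate leaf label {node.label!r} in block {block + 1} tree"
                    )
                leaf_by_label[node.label] = node
                leaf_labels.append(node.label)
            else:
                if node.label in nonleaf_by_label:
                    raise ValidationError(
                        f"duplicate label {node.label!r} in block {block + 1} tree"
                    )
                if not node.is_root and len(node.children) < 2:
                    raise ValidationError(
                        f"internal node {node.label!r} in block {block + 1} tree "
                        f"has {len(node.children)} child(ren); needs at least 2"
                    )
                nonleaf_by_label[node.label] = node
        if root.is_leaf:
            raise ValidationError(f"block {block + 1} root has no children")
        self.leaf_labels = leaf_labels
        self.leaf_code = {lab: i for i, lab in enumerate(leaf_labels)}
        self.nonleaf_by_label = nonleaf_by_label
        self.leaf_by_label = leaf_by_label
        # leaf codes under each node, for routing records at specialization
        self.leafcodes: dict[int, np.ndarray] = {}
        for node in root.preorder():
            self.leafcodes[id(node)] = np.array(
                [self.leaf_code[lab] for lab in leaves_under(node)], dtype=np.intp
            )


def _check_label_shape(node: TaxonomyNode, block: int, width: int) -> None:
    tokens = node.label.split(" ")
    value_shaped = len(tokens) == width and all(GENOTYPE_RE.match(t) for t in tokens)
    if node.is_leaf:
        if not value_shaped:
            raise ValidationError(
                f"leaf label {node.label!r} in block {block + 1} tree is not "
                f"{width} two-letter genotype tokens"
            )
    elif not value_shaped:
        if len(tokens) != 1 or GENOTYPE_RE.match(tokens[0]):
            raise ValidationError(
                f"non-leaf label {node.label!r} in block {block + 1} tree must be a "
                f"single non-genotype token or a {width}-genotype value shape"
            )


@dataclass(eq=False)
class TaxonomyForest:
    """One taxonomy tree per block, plus provenance and the block spec."""

    trees: list[TaxonomyNode]
    blocks: BlockSpec
    provenance: str

    def __post_init__(self):
        if self.provenance not in (USER_SUPPLIED, DATA_DERIVED):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if len(self.trees) != self.blocks.n_blocks:
            raise ValidationError(
                f"forest has {len(self.trees)} trees for {self.blocks.n_blocks} blocks"
            )
        self._index: list[_TreeIndex] = []
        for b, root in enumerate(self.trees):
            if root.label != f"Any_{b + 1}":
                raise ValidationError(
                    f"root of block {b + 1} tree must be labeled 'Any_{b + 1}'; "
                    f"got {root.label!r}"
                )
            for node in root.preorder():
                for c in node.children:
                    c.parent = node
            s, e = self.blocks.intervals[b]
            self._index.append(_TreeIndex(root, b, e - s))

    # -- lookups -----------------------------------------------------------
    def index(self, block: int) -> _TreeIndex:
        return self._index[block]

    def node(self, block: int, label: str) -> TaxonomyNode:
        """Resolve a non-leaf node by label (the form traces use)."""
        idx = self._index[block]
        if label in (ANY, f"Any_{block + 1}"):
            return idx.root
        try:
            return idx.nonleaf_by_label[label]
        except KeyError:
            raise ValidationError(
                f"no non-leaf node labeled {label!r} in block {block + 1} tree"
            ) from None

    def leaf_labels(self, block: int) -> list[str]:
        return list(self._index[block].leaf_labels)

    # -- serialization -----------------------------------------------------
    def structure(self):
        return [t.structure() for t in self.trees]

    def digest(self) -> str:
        payload = json.dumps(self.structure(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def __eq__(self, other) -> bool:
        """Structural equality (provenance is metadata, not structure)."""
        return (
            isinstance(other, TaxonomyForest)
            and self.blocks == other.blocks
            and self.structure() == other.structure()
        )


def build_flat_taxonomy(table, blocks: BlockSpec) -> TaxonomyForest:
    """Two-level forest with one leaf per distinct observed block value.

    Leaves are ordered lexicographically.  The result depends on the data,
    so its provenance is ``data_derived``.
    """
    if table.n_records == 0:
        raise ValidationError("cannot derive a taxonomy from an empty table")
    if table.n_snps != blocks.n_snps:
        raise ValidationError(
            f"block spec covers {blocks.n_snps} SNPs but table has {table.n_snps}"
        )
    trees = []
    for b, interval in enumerate(blocks.intervals):
        values = sorted(set(block_values(table, interval)))
        trees.append(
            TaxonomyNode(f"Any_{b + 1}", [TaxonomyNode(v) for v in values])
        )
    return TaxonomyForest(trees, blocks, DATA_DERIVED)


def load_taxonomy(path, blocks: BlockSpec) -> TaxonomyForest:
    """Load a user-supplied taxonomy forest from a JSON config.

    The config is either a list of nested ``{"label", "children"}`` trees
    (one per block, in block order) or ``{"trees": [...]}``.  Multilevel
    trees are allowed.
    """
    obj = json.loads(Path(path).read_text(encoding="utf-8"))
    if isinstance(obj, dict):
        obj = obj.get("trees")
    if not isinstance(obj, list):
        raise ValidationError(f"{path}: taxonomy config must be a list of trees")
    trees = [_node_from_structure(t) for t in obj]
    return TaxonomyForest(trees, blocks, USER_SUPPLIED)


def save_taxonomy(forest: TaxonomyForest, path) -> None:
    Path(path).write_text(
        json.dumps({"trees": forest.structure()}, indent=2) + "\n", encoding="utf-8"
    )


def validate_coverage(forest: TaxonomyForest, table) -> list[tuple[int, str]]:
    """Observed block values that are not leaf labels of their tree.

    Returns an empty list when the forest covers the data (a report, not
    an exception — callers that require coverage raise on a non-empty
    result).
    """
    uncovered = []
    for b, interval in enumerate(forest.blocks.intervals):
        known = set(forest.index(b).leaf_labels)
        for v in sorted(set(block_values(table, interval))):
            if v not in known:
                uncovered.append((b, v))
    return uncovered


class Cut:
    """The current specialization frontier: per block, an ordered node list.

    Holds exactly one node on each root-to-leaf path of every tree; starts
    at the roots and is pushed down by :meth:`specialize`.
    """

    def __init__(self, forest: TaxonomyForest):
        self.forest = forest
        self._nodes: list[list[TaxonomyNode]] = [[t] for t in forest.trees]

    def nodes(self, block: int) -> list[TaxonomyNode]:
        return list(self._nodes[block])

    def candidates(self) -> list[tuple[int, TaxonomyNode]]:
        """All non-leaf cut nodes, in canonical (block, preorder) order."""
        out = []
        for b, nodes in enumerate(self._nodes):
            pos = self.forest.index(b).preorder_pos
            for node in sorted(
                (n for n in nodes if not n.is_leaf), key=lambda n: pos[id(n)]
            ):
                out.append((b, node))
        return out

    def specialize(self, block: int, node: TaxonomyNode) -> None:
        """Replace ``node`` with its children in the cut."""
        nodes = self._nodes[block]
        try:
            i = next(k for k, n in enumerate(nodes) if n is node)
        except StopIteration:
            raise StateError(
                f"node {node.label!r} is not in the cut of block {block + 1}"
            ) from None
        if node.is_leaf:
            raise StateError(f"cannot specialize leaf {node.label!r}")
        self._nodes[block] = nodes[:i] + list(node.children) + nodes[i + 1:]

    def node_by_rendered_label(self, block: int, label: str) -> TaxonomyNode:
        for n in self._nodes[block]:
            if n.rendered == label:
                return n
        raise ValidationError(
            f"label {label!r} is not in the cut of block {block + 1}"
        )

    def is_valid(self) -> bool:
        """Every leaf of every tree has exactly one ancestor-or-self in the cut."""
        for b, root in enumerate(self.forest.trees):
            members = {id(n) for n in self._nodes[b]}
            for node in root.preorder():
                if node.is_leaf:
                    path_hits = 0
                    cur = node
                    while cur is not None:
                        if id(cur) in members:
                            path_hits += 1
                        cur = cur.parent
                    if path_hits != 1:
                        return False
        return True


def cut_from_trace(forest: TaxonomyForest, trace) -> Cut:
    """Replay a specialization trace (list of ``(block, label)``) on a fresh cut."""
    cut = Cut(forest)
    for block, label in trace:
        cut.specialize(int(block), forest.node(int(block), label))
    return cut
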