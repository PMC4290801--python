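"""The anonymization mechanism: random top-down specialization + Laplace noise.

The mechanism maintains a partition tree over the records.  It starts
from a single root partition in which every block is generalized to its
taxonomy root, performs ``h`` specializations — each one picks a random
non-leaf node from the current cut (a draw that consults taxonomy
structure only, never record data) and splits the affected partitions by
routing records into the chosen node's child subtrees — and finally
releases every leaf partition with a noisy count ``C + Lap(1/epsilon)``.

Privacy accounting: blocking, taxonomy handling and the ``h``
specializations are data-independent and consume no budget; the noisy
count release over the disjoint leaf partitions costs ``epsilon`` under
parallel composition, so the whole run costs exactly ``epsilon``.

Two independent RNG streams (candidate selection, Laplace noise) are
derived from the single seed, so the same specialization trace can be
replayed on a neighboring dataset while the noise stays fresh.

Empty child partitions are kept and noised by default (``keep_empty``):
suppressing them would leak the data through the released support set.
Retention makes the number of released rows the product of the child
counts of every specialized block, which is exponential in ``h`` for
diverse blocks; ``keep_empty=False`` releases only record-bearing
partitions (the tractable observed-support variant used at experimental
scale, at the cost of a data-dependent support).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .blocking import block_values
from .errors import CoverageError, StateError, ValidationError
from .taxonomy import Cut, TaxonomyForest, TaxonomyNode, validate_coverage

logger = logging.getLogger(__name__)

ROUNDING_MODES = ("raw", "rounded_nonnegative")


@dataclass(frozen=True)
class PrivacyParams:
    """Knobs of one anonymization run.

    epsilon : total privacy budget (> 0); the Laplace scale is
        ``sensitivity / epsilon``.
    h : number of specializations to attempt (>= 0).
    sensitivity : L1 sensitivity of the count vector; removing or adding
        one record changes exactly one disjoint partition count by 1, so
        this is fixed at 1.
    seed : master seed from which the selection and noise streams derive.
    rounding : ``raw`` releases real-valued counts; ``rounded_nonnegative``
        adds a presentation column ``max(0, nearest-even-int)``.
    keep_empty : keep (and noise) empty child partitions — see module note.
    """

    epsilon: float
    h: int
    sensitivity: float = 1.0
    seed: int = 0
    rounding: str = "raw"
    keep_empty: bool = True

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValidationError(f"epsilon must be > 0; got {self.epsilon}")
        if self.h < 0:
            raise ValidationError(f"h must be >= 0; got {self.h}")
        if self.sensitivity != 1:
            raise ValidationError("count-release sensitivity is fixed at 1")
        if self.rounding not in ROUNDING_MODES:
            raise ValidationError(
                f"rounding must be one of {ROUNDING_MODES}; got {self.rounding!r}"
            )


@dataclass(frozen=True)
class ReleaseRow:
    """One leaf partition of the release: rendered block labels + noisy count."""

    generalized_values: tuple[str, ...]
    noisy_count: float
    rounded: int | None = None


@dataclass(eq=True)
class AnonymizedRelease:
    """The released table: one row per leaf partition, plus run metadata."""

    rows: list[ReleaseRow]
    metadata: dict

    @property
    def trace(self) -> list[tuple[int, str]]:
        return [(int(b), str(lab)) for b, lab in self.metadata["trace"]]


def _rng_streams(seed: int):
    sel_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(sel_ss), np.random.default_rng(noise_ss)


class PartitionTree:
    """Leaf partitions of the record set under the current cut.

    Leaves are stored as a mapping from a per-block tuple of taxonomy
    nodes to the member record indices.  Records are pre-encoded once as
    integer leaf codes per block (O(n_records x m)), so each
    specialization is a vectorized bucketing of member codes.
    """

    def __init__(self, table, forest: TaxonomyForest, keep_empty: bool = True):
        uncovered = validate_coverage(forest, table)
        if uncovered:
            raise CoverageError(uncovered)
        self.table = table
        self.forest = forest
        self.keep_empty = keep_empty
        self.cut = Cut(forest)
        self.trace: list[tuple[int, str]] = []
        self.codes: list[np.ndarray] = []
        for b, interval in enumerate(forest.blocks.intervals):
            code = forest.index(b).leaf_code
            self.codes.append(
                np.array([code[v] for v in block_values(table, interval)], dtype=np.intp)
            )
        root_key = tuple(forest.trees)
        self.leaves: dict[tuple[TaxonomyNode, ...], np.ndarray] = {
            root_key: np.arange(table.n_records, dtype=np.intp)
        }

    def specialize(self, block: int, node) -> None:
        """Split every leaf partition generalized to ``node`` at ``block``."""
        if isinstance(node, str):
            node = self.forest.node(block, node)
        if node.is_leaf or not any(n is node for n in self.cut.nodes(block)):
            raise StateError(
                f"{node.label!r} is not a specializable node in the cut of "
                f"block {block + 1}"
            )
        idx = self.forest.index(block)
        child_of = np.full(len(idx.leaf_labels), -1, dtype=np.intp)
        for ci, child in enumerate(node.children):
            child_of[idx.leafcodes[id(child)]] = ci
        new_leaves: dict[tuple[TaxonomyNode, ...], np.ndarray] = {}
        codes = self.codes[block]
        empty = np.empty(0, dtype=np.intp)
        for key, members in self.leaves.items():
            if key[block] is not node:
                new_leaves[key] = members
                continue
            member_child = child_of[codes[members]]
            if self.keep_empty:
                for ci, child in enumerate(node.children):
                    new_leaves[key[:block] + (child,) + key[block + 1:]] = (
                        members[member_child == ci]
                    )
            else:
                # group members by child without touching empty children
                order = np.argsort(member_child, kind="stable")
                sorted_child = member_child[order]
                splits = np.flatnonzero(sorted_child[1:] != sorted_child[:-1]) + 1
                starts = np.concatenate(([0], splits)) if members.size else empty
                groups = np.split(members[order], splits)
                for start, sub in zip(starts, groups):
                    child = node.children[sorted_child[start]]
                    new_leaves[key[:block] + (child,) + key[block + 1:]] = sub
        self.cut.specialize(block, node)
        self.leaves = new_leaves
        self.trace.append((block, node.label))

    def leaf_items(self) -> list[tuple[tuple[str, ...], np.ndarray]]:
        """Leaf partitions as (rendered label tuple, members), canonically sorted."""
        items = [
            (tuple(n.rendered for n in key), members)
            for key, members in self.leaves.items()
        ]
        items.sort(key=lambda kv: kv[0])
        return items

    def counts(self) -> tuple[list[tuple[str, ...]], np.ndarray]:
        items = self.leaf_items()
        return [k for k, _ in items], np.array(
            [m.size for _, m in items], dtype=float
        )


def initialize_root(table, forest: TaxonomyForest, keep_empty: bool = True) -> PartitionTree:
    """Single leaf partition holding all records, generalized to every root."""
    return PartitionTree(table, forest, keep_empty=keep_empty)


def select_candidate(cut: Cut, rng: np.random.Generator):
    """Uniform draw over the non-leaf nodes of the cut; None when exhausted.

    Candidates are enumerated in canonical (block, preorder) order so a
    seeded stream reproduces the selection sequence exactly.  The draw
    never consults record data.
    """
    cands = cut.candidates()
    if not cands:
        return None
    return cands[int(rng.integers(len(cands)))]


def random_trace(forest: TaxonomyForest, h: int, seed_or_rng) -> list[tuple[int, str]]:
    """The specialization trace a seeded run would take, without any data."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else _rng_streams(int(seed_or_rng))[0]
    )
    cut = Cut(forest)
    trace = []
    for _ in range(h):
        cand = select_candidate(cut, rng)
        if cand is None:
            break
        block, node = cand
        cut.specialize(block, node)
        trace.append((block, node.label))
    return trace


def laplace_noise(scale: float, rng: np.random.Generator, size=None):
    """Draw from Laplace(0, scale); variance is ``2 * scale**2``."""
    if not scale > 0:
        raise ValidationError(f"Laplace scale must be > 0; got {scale}")
    return rng.laplace(0.0, scale, size=size)


def _round_half_even_nonneg(x: float) -> int:
    return max(0, int(np.rint(x)))


def postprocess_counts(release: AnonymizedRelease, mode: str) -> AnonymizedRelease:
    """Attach (or drop) the rounded presentation column.

    Pure post-processing of released values: consumes no privacy budget.
    ``rounded_nonnegative`` maps each count to ``max(0, nearest integer)``
    with round-half-to-even ties; ``raw`` returns the release unchanged
    apart from clearing any presentation column.
    """
    if mode not in ROUNDING_MODES:
        raise ValidationError(f"unknown rounding mode {mode!r}")
    metadata = dict(release.metadata, rounding=mode)
    if mode == "raw":
        rows = [replace(r, rounded=None) for r in release.rows]
    else:
        rows = [
            replace(r, rounded=_round_half_even_nonneg(r.noisy_count))
            for r in release.rows
        ]
    return AnonymizedRelease(rows=rows, metadata=metadata)


def anonymize(
    table,
    forest: TaxonomyForest,
    params: PrivacyParams,
    trace=None,
) -> AnonymizedRelease:
    """Run the full mechanism and return the anonymized release.

    When ``trace`` is given (a list of ``(block, label)``), those
    specializations are applied in order instead of random selection —
    used for worked examples and for replaying a run on a neighboring
    dataset.  Otherwise ``params.h`` random specializations are attempted;
    if the cut runs out of non-leaf candidates first, the run stops early
    (logged, not an error).

    The released count of each leaf partition is its true member count
    plus ``Lap(sensitivity / epsilon)`` noise; total budget spent is
    exactly ``params.epsilon``.
    """
    sel_rng, noise_rng = _rng_streams(params.seed)
    tree = PartitionTree(table, forest, keep_empty=params.keep_empty)
    early_stop = False
    if trace is not None:
        for block, label in trace:
            tree.specialize(int(block), label)
    else:
        for i in range(params.h):
            cand = select_candidate(tree.cut, sel_rng)
            if cand is None:
                early_stop = True
                logger.info(
                    "candidates exhausted after %d of %d specializations", i, params.h
                )
                break
            block, node = cand
            tree.specialize(block, node)
            logger.debug(
                "specialization %d: block %d, node %r -> %d children",
                i + 1, block + 1, node.label, len(node.children),
            )
    labels, true_counts = tree.counts()
    noise = laplace_noise(params.sensitivity / params.epsilon, noise_rng, len(labels))
    rows = [
        ReleaseRow(generalized_values=lab, noisy_count=float(c + z))
        for lab, c, z in zip(labels, true_counts, noise)
    ]
    metadata = {
        "epsilon": params.epsilon,
        "h": params.h,
        "h_performed": len(tree.trace),
        "early_stop": early_stop,
        "sensitivity": params.sensitivity,
        "seed": int(params.seed),
        "rounding": "raw",
        "keep_empty": params.keep_empty,
        "blocks": [list(iv) for iv in forest.blocks.intervals],
        "taxonomy_digest": forest.digest(),
        "taxonomy_provenance": forest.provenance,
        "taxonomy_private": forest.provenance == "user_supplied",
        "trace": [[b, lab] for b, lab in tree.trace],
        "budget": {
            "blocking": 0.0,
            "taxonomy": 0.0,
            "specialization": 0.0,
            "noisy_counts": params.epsilon,
            "total": params.epsilon,
        },
    }
    release = AnonymizedRelease(rows=rows, metadata=metadata)
    if params.rounding != "raw":
        release = postprocess_counts(release, params.rounding)
    return release
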