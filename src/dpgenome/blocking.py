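"""Partitioning of the SNP panel into contiguous blocks.

The anonymization algorithm treats groups of adjacent SNPs as single
categorical attributes.  A :class:`BlockSpec` records the half-open,
0-based index ranges of those groups; a *block value* is the space-joined
genotype string of one record restricted to one block.  Block boundaries
are a function of the panel size and the configured block size only —
they never look at genotype data, so computing them consumes no privacy
budget.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Block size used when none is given.  Six SNPs per block is a good
#: compromise between block-value diversity and granularity for panels of
#: a few hundred SNPs; the best value is data-set dependent.
DEFAULT_BLOCK_SIZE = 6


@dataclass(frozen=True)
class BlockSpec:
    """Ordered, contiguous, half-open SNP index intervals covering [0, m)."""

    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self):
        ivs = tuple((int(s), int(e)) for s, e in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        if not ivs:
            raise ValidationError("block spec must contain at least one interval")
        pos = 0
        for s, e in ivs:
            if s != pos or e <= s:
                raise ValidationError(
                    f"intervals must be contiguous, non-empty and start at 0; got {ivs}"
                )
            pos = e
        head = {e - s for s, e in ivs[:-1]}
        if len(head) > 1:
            raise ValidationError("all intervals but the last must share one length")

    @property
    def n_blocks(self) -> int:
        return len(self.intervals)

    @property
    def n_snps(self) -> int:
        return self.intervals[-1][1]

    def snps_in(self, block: int) -> range:
        s, e = self.intervals[block]
        return range(s, e)


def make_blocks(m: int, block_size: int = DEFAULT_BLOCK_SIZE) -> BlockSpec:
    """Split ``m`` SNPs into contiguous blocks of ``block_size``.

    The remainder ``m mod block_size`` is absorbed into the final block, so
    the last block may be larger than the others (never smaller).  The
    result depends only on ``m`` and ``block_size``, not on any data.
    """
    if block_size <= 0 or block_size > m:
        raise ValidationError(f"block_size must be in [1, m={m}]; got {block_size}")
    n_blocks = m // block_size
    intervals = [(i * block_size, (i + 1) * block_size) for i in range(n_blocks)]
    intervals[-1] = (intervals[-1][0], m)  # fold the remainder into the last block
    return BlockSpec(tuple(intervals))


def block_value(table, record_index: int, interval: tuple[int, int]) -> str:
    """Genotypes of one record over one interval, joined by single spaces."""
    s, e = interval
    return " ".join(table.genotypes[record_index, s:e])


def block_values(table, interval: tuple[int, int]) -> list[str]:
    """Block value of every record over one interval, in record order."""
    s, e = interval
    return [" ".join(row) for row in table.genotypes[:, s:e]]
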