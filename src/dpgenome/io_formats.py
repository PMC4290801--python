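"""Reading and writing the package's on-disk formats.

Three text formats are handled here:

* **Genotype TSV** — one header row ``ID<TAB>snp1..snpm`` followed by one
  row per individual, each cell a two-letter diploid genotype such as
  ``AG``.  Lines starting with ``#`` are comments.
* **VCF import** — biallelic SNP records with ``GT`` fields are rendered
  into the same two-letter genotype strings (import only, no export).
* **Release TSV + JSON sidecar** — an anonymized release is written as a
  TSV body (one row per leaf partition: block labels then the noisy
  count) plus a ``<path>.meta.json`` sidecar carrying the privacy
  parameters, block spec, taxonomy digest and specialization trace, so
  that reading reconstructs an equal release.

Within a genotype the two allele letters are always stored in
alphabetical order (``GA`` normalizes to ``AG``): partition labels must
be canonical strings for exact matching.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

GENOTYPE_RE = re.compile(r"^[ACGT]{2}$")


def normalize_genotype(g: str) -> str:
    """Alphabetically order the two allele letters of a genotype string."""
    return g if g[0] <= g[1] else g[1] + g[0]


@dataclass(eq=False)
class GenotypeTable:
    """A rectangular table of diploid genotypes: records x SNPs.

    ``genotypes`` is an ``(n_records, n_snps)`` array of two-letter
    strings over {A,C,G,T}, each normalized to alphabetical order.
    Record identifiers are unique.
    """

    record_ids: list[str]
    snp_ids: list[str]
    genotypes: np.ndarray

    def __post_init__(self):
        self.record_ids = [str(r) for r in self.record_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        gen = np.asarray(self.genotypes, dtype="<U2")
        if gen.ndim != 2 or gen.shape != (len(self.record_ids), len(self.snp_ids)):
            raise ValidationError(
                f"genotype matrix shape {gen.shape} does not match "
                f"{len(self.record_ids)} records x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.record_ids)) != len(self.record_ids):
            seen, dup = set(), None
            for r in self.record_ids:
                if r in seen:
                    dup = r
                    break
                seen.add(r)
            raise ValidationError(f"duplicate record id {dup!r}")
        for (i, j), g in np.ndenumerate(gen):
            if not GENOTYPE_RE.match(g):
                raise ValidationError(
                    f"invalid genotype {g!r} for record {self.record_ids[i]!r}, "
                    f"SNP {self.snp_ids[j]!r}"
                )
            gen[i, j] = normalize_genotype(g)
        self.genotypes = gen

    @property
    def n_records(self) -> int:
        return len(self.record_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def record_index(self, record_id: str) -> int:
        try:
            return self.record_ids.index(record_id)
        except ValueError:
            raise ValidationError(f"unknown record id {record_id!r}") from None

    def drop_record(self, record_id: str) -> "GenotypeTable":
        """Return a copy with one record removed (a neighboring dataset)."""
        i = self.record_index(record_id)
        keep = [k for k in range(self.n_records) if k != i]
        return GenotypeTable(
            [self.record_ids[k] for k in keep], list(self.snp_ids), self.genotypes[keep]
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeTable)
            and self.record_ids == other.record_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.genotypes, other.genotypes)
        )


# ---------------------------------------------------------------------------
# Genotype TSV
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> GenotypeTable:
    """Read a genotype TSV (``ID`` column then one column per SNP)."""
    path = Path(path)
    lines = [
        ln.rstrip("\n")
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"{path}: empty file (no header row)")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header must be 'ID<TAB>snp1...'; got {header!r}")
    snp_ids = header[1:]
    record_ids: list[str] = []
    rows: list[list[str]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(cells)} cells, expected {len(header)})"
            )
        rid, gens = cells[0], cells[1:]
        for j, g in enumerate(gens):
            if not GENOTYPE_RE.match(g):
                raise FormatError(
                    f"{path}:{lineno}: malformed genotype {g!r} "
                    f"(record {rid!r}, SNP {snp_ids[j]!r})"
                )
        record_ids.append(rid)
        rows.append(gens)
    gen = (
        np.array(rows, dtype="<U2")
        if rows
        else np.empty((0, len(snp_ids)), dtype="<U2")
    )
    return GenotypeTable(record_ids, snp_ids, gen)


def write_genotype_table(table: GenotypeTable, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("ID\t" + "\t".join(table.snp_ids) + "\n")
        for i, rid in enumerate(table.record_ids):
            fh.write(rid + "\t" + "\t".join(table.genotypes[i]) + "\n")


# ---------------------------------------------------------------------------
# VCF import
# ---------------------------------------------------------------------------

def import_vcf(path, sample_subset: list[str] | None = None) -> GenotypeTable:
    """Import biallelic SNP genotypes from a VCF file.

    Each GT pair is rendered as the two allele letters in REF/ALT space,
    alphabetically ordered (``0/1`` with REF=A, ALT=G becomes ``AG``).
    Multiallelic or non-SNP records are skipped with a logged warning;
    missing genotypes raise an error naming the sample and site.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(path))
    if sample_subset is not None:
        missing = sorted(set(sample_subset) - set(vcf.samples))
        if missing:
            raise ValidationError(f"samples not in VCF: {missing}")
        vcf.set_samples(sample_subset)
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[list[str]] = []
    n_skipped = 0
    for variant in vcf:
        alts = variant.ALT
        if len(variant.REF) != 1 or len(alts) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            logger.warning(
                "skipping non-biallelic-SNP record %s:%d (REF=%s, ALT=%s)",
                variant.CHROM, variant.POS, variant.REF, ",".join(alts) or ".",
            )
            continue
        letters = (variant.REF, alts[0])
        site = variant.ID or f"{variant.CHROM}:{variant.POS}"
        col = []
        for sample, gt in zip(samples, variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise FormatError(f"missing genotype for sample {sample!r} at {site}")
            col.append(normalize_genotype(letters[a] + letters[b]))
        snp_ids.append(site)
        columns.append(col)
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP records", n_skipped)
    gen = (
        np.array(columns, dtype="<U2").T
        if columns
        else np.empty((len(samples), 0), dtype="<U2")
    )
    return GenotypeTable(samples, snp_ids, gen)


# ---------------------------------------------------------------------------
# Release TSV + metadata sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_release(release, path) -> None:
    """Write a release body TSV and its JSON metadata sidecar.

    Body columns: one per block (the generalized label, spaces inside),
    then the noisy count in full decimal precision, then — when rounding
    is enabled — the rounded presentation count.  Counts round-trip
    bit-exactly via ``repr``/``float``.
    """
    if not release.rows:
        raise ValidationError("cannot write a release with no rows")
    path = Path(path)
    has_rounded = release.rows[0].rounded is not None
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# dpgenome anonymized release; metadata in sidecar\n")
        for row in release.rows:
            cells = [" ".join(row.generalized_values), repr(float(row.noisy_count))]
            if has_rounded:
                cells.append(str(row.rounded))
            fh.write("\t".join(cells) + "\n")
    _sidecar_path(path).write_text(
        json.dumps(release.metadata, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def _parse_labels(tokens: list[str], intervals) -> tuple[str, ...]:
    """Re-split a space-joined row of block labels using the block spec.

    A label is either a run of ``len(interval)`` two-letter genotype
    tokens (a fully specialized value, or an equally shaped internal
    label) or a single non-genotype token such as ``Any``.
    """
    labels = []
    pos = 0
    for s, e in intervals:
        if pos >= len(tokens):
            raise FormatError("row has fewer label tokens than the block spec implies")
        if GENOTYPE_RE.match(tokens[pos]):
            k = e - s
            chunk = tokens[pos:pos + k]
            if len(chunk) < k or not all(GENOTYPE_RE.match(t) for t in chunk):
                raise FormatError(f"expected {k} genotype tokens, got {chunk!r}")
            labels.append(" ".join(chunk))
            pos += k
        else:
            labels.append(tokens[pos])
            pos += 1
    if pos != len(tokens):
        raise FormatError(f"trailing label tokens {tokens[pos:]!r}")
    return tuple(labels)


def read_release(path):
    """Read a release written by :func:`write_release`."""
    from .anonymizer import AnonymizedRelease, ReleaseRow

    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    metadata = json.loads(sidecar.read_text(encoding="utf-8"))
    intervals = [tuple(iv) for iv in metadata["blocks"]]
    has_rounded = metadata.get("rounding") == "rounded_nonnegative"
    rows = []
    for lineno, ln in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not ln.strip() or ln.startswith("#"):
            continue
        cells = ln.split("\t")
        n_expected = 3 if has_rounded else 2
        if len(cells) != n_expected:
            raise FormatError(
                f"{path}:{lineno}: expected {n_expected} columns, got {len(cells)}"
            )
        labels = _parse_labels(cells[0].split(" "), intervals)
        rows.append(
            ReleaseRow(
                generalized_values=labels,
                noisy_count=float(cells[1]),
                rounded=int(cells[2]) if has_rounded else None,
            )
        )
    return AnonymizedRelease(rows=rows, metadata=metadata)
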