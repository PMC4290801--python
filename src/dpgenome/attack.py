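"""Likelihood-ratio membership attack and power estimation.

For one individual with minor-allele indicators ``x_j`` over ``m``
entries, population minor-allele frequencies ``p_j`` and pool
frequencies ``p_hat_j``, the per-individual statistic is

    L = sum_j [ x_j * log(p_hat_j / p_j)
                + (1 - x_j) * log((1 - p_hat_j) / (1 - p_j)) ]

High values indicate that the individual's alleles track the pool rather
than the population — evidence of pool membership.  Power is reported at
a fixed false-positive rate against the statistic distribution of a test
group of individuals unrelated to both case and control.

Binarization: frequencies here are *allele* frequencies, so the default
``per_allele`` mode treats each of the two allele copies at a SNP as one
Bernoulli entry (doubling m); a ``dominant`` mode (one entry per SNP,
1 iff the individual carries any minor allele) is available for
sensitivity analysis.  Frequencies are clamped inside (0, 1) at
``1/(2n+1)`` because the statistic's logs are undefined at the
boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .taxonomy import TaxonomyForest
from .utility import reconstruct_snp_counts

BINARIZE_MODES = ("per_allele", "dominant")


@dataclass(eq=False)
class FrequencyPanel:
    """Per-SNP minor/major allele letters and minor-allele frequencies."""

    snp_ids: list[str]
    minor: list[str]
    major: list[str]
    p: np.ndarray  # clamped interior minor-allele frequency
    n_reference: int  # individuals behind the estimate (sets the clamp)

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if not ((self.p > 0) & (self.p < 1)).all():
            raise ValidationError("frequencies must be strictly inside (0, 1)")


def clamp_frequencies(freq, n_individuals: int) -> np.ndarray:
    """Clamp frequencies to [1/(2n+1), 1 - 1/(2n+1)]."""
    lo = 1.0 / (2 * max(1, int(n_individuals)) + 1)
    return np.clip(np.asarray(freq, dtype=float), lo, 1.0 - lo)


def assign_minor_alleles(reference) -> FrequencyPanel:
    """Minor-allele map and population frequencies from a reference group.

    Allele copies are counted over ``2n`` chromosomes per SNP; the minor
    allele is the lower-frequency letter (ties broken toward the
    lexicographically smaller letter).  A monomorphic SNP gets the
    lexicographically smallest absent letter as its minor allele, with
    the frequency clamp keeping ``p`` interior.
    """
    if reference.n_records == 0:
        raise ValidationError("reference group must be nonempty")
    n = reference.n_records
    minor, major, p = [], [], []
    for j, sid in enumerate(reference.snp_ids):
        counts = Counter("".join(reference.genotypes[:, j]))
        if len(counts) > 2:
            raise ValidationError(
                f"SNP {sid!r} shows {len(counts)} alleles; biallelic data required"
            )
        if len(counts) == 1:
            (maj,) = counts
            mnr = next(a for a in "ACGT" if a != maj)
            cnt = 0
        else:
            (a1, c1), (a2, c2) = sorted(counts.items())
            if c1 < c2 or (c1 == c2):  # tie -> lexicographically smaller is minor
                mnr, cnt, maj = a1, c1, a2
            else:
                mnr, cnt, maj = a2, c2, a1
        minor.append(mnr)
        major.append(maj)
        p.append(cnt / (2 * n))
    return FrequencyPanel(
        list(reference.snp_ids), minor, major, clamp_frequencies(p, n), n
    )


def binarize(table, panel: FrequencyPanel, mode: str = "per_allele") -> np.ndarray:
    """Minor-allele indicator vectors, one row per individual.

    ``per_allele``: two entries per SNP, one per allele copy (x = 1 iff
    that copy is the minor allele) — row length 2m.  ``dominant``: one
    entry per SNP, x = 1 iff the individual carries at least one minor
    allele.
    """
    if mode not in BINARIZE_MODES:
        raise ValidationError(f"mode must be one of {BINARIZE_MODES}; got {mode!r}")
    if table.snp_ids != panel.snp_ids:
        raise ValidationError("table SNPs do not match the frequency panel")
    n, m = table.n_records, table.n_snps
    # split each two-letter genotype into its two allele copies, in stored order
    letters = np.ascontiguousarray(table.genotypes).view("<U1").reshape(n, m, 2)
    x = np.zeros((n, m, 2), dtype=np.int8)
    for j in range(m):
        mnr, maj = panel.minor[j], panel.major[j]
        is_minor = letters[:, j, :] == mnr
        bad = ~(is_minor | (letters[:, j, :] == maj))
        if bad.any():
            i = int(np.nonzero(bad.any(axis=1))[0][0])
            raise ValidationError(
                f"genotype {table.genotypes[i, j]!r} of record "
                f"{table.record_ids[i]!r} at SNP {panel.snp_ids[j]!r} contains "
                f"an allele outside {{{maj!r}, {mnr!r}}}"
            )
        x[:, j, :] = is_minor
    if mode == "dominant":
        return (x.sum(axis=2) >= 1).astype(np.int8)
    return x.reshape(n, 2 * m)


def expand_frequencies(freq: np.ndarray, mode: str) -> np.ndarray:
    """Match a per-SNP frequency vector to the binarization layout."""
    if mode == "dominant":
        # entry is Bernoulli(1 - (1-p)^2) under allele independence
        return 1.0 - (1.0 - np.asarray(freq)) ** 2
    return np.repeat(np.asarray(freq), 2)


def lr_statistic(x, p, p_hat) -> float:
    """The log-likelihood-ratio statistic for one binary vector."""
    return float(lr_statistics(np.atleast_2d(x), p, p_hat)[0])


def lr_statistics(x_matrix, p, p_hat) -> np.ndarray:
    """Vectorized statistic for many individuals (rows of ``x_matrix``)."""
    x = np.asarray(x_matrix, dtype=float)
    p = np.asarray(p, dtype=float)
    ph = np.asarray(p_hat, dtype=float)
    if x.shape[1] != p.shape[0] or p.shape != ph.shape:
        raise ValidationError(
            f"length mismatch: x has {x.shape[1]} entries, p {p.shape[0]}, "
            f"p_hat {ph.shape[0]}"
        )
    if not (((p > 0) & (p < 1)).all() and ((ph > 0) & (ph < 1)).all()):
        raise ValidationError("frequencies must be strictly inside (0, 1)")
    return x @ np.log(ph / p) + (1.0 - x) @ np.log((1.0 - ph) / (1.0 - p))


@dataclass(frozen=True)
class PowerResult:
    """Fraction of case individuals detectable at a fixed false-positive rate."""

    threshold: float
    power: float
    fpr: float
    n_case: int
    n_test: int


def power_at_fpr(case_stats, test_stats, fpr: float = 0.05) -> PowerResult:
    """Power at the nearest-rank (1 - fpr) percentile of the test group.

    The threshold is the test-group statistic at rank ``ceil((1-fpr) n)``
    (nearest-rank percentile, no interpolation); power is the fraction of
    case statistics *strictly* greater.
    """
    if not 0 < fpr < 1:
        raise ValidationError(f"fpr must be in (0, 1); got {fpr}")
    case = np.asarray(case_stats, dtype=float)
    test = np.sort(np.asarray(test_stats, dtype=float))
    if case.size == 0 or test.size == 0:
        raise ValidationError("case and test groups must be nonempty")
    rank = int(np.ceil((1.0 - fpr) * test.size))
    threshold = float(test[rank - 1])
    return PowerResult(
        threshold=threshold,
        power=float(np.mean(case > threshold)),
        fpr=fpr,
        n_case=case.size,
        n_test=test.size,
    )


def pool_frequencies_from_release(
    release, forest: TaxonomyForest, panel: FrequencyPanel
) -> np.ndarray:
    """Per-SNP pool minor-allele frequencies implied by a release.

    Allele masses are accumulated from the uniform-over-leaves
    reconstruction of the release (the same rule the utility evaluation
    uses, recorded in the release report metadata); the minor-allele
    share is clamped interior using the reconstructed pool size.
    """
    counts = reconstruct_snp_counts(release, forest, panel.snp_ids)
    alleles = counts.allele_counts()
    totals = counts.totals()
    freqs = np.empty(len(panel.snp_ids))
    for j, ac in enumerate(alleles):
        tot = sum(ac.values())
        freqs[j] = ac.get(panel.minor[j], 0.0) / tot if tot > 0 else 0.5
    n_pool = max(1, int(round(float(np.median(totals)))))
    return clamp_frequencies(freqs, n_pool)
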