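"""Synthetic case/control/test cohorts with a known association structure.

The generator emulates the shape of a small GWAS privacy benchmark:
three groups of individuals typed on the same SNP panel, where a chosen
subset of *effect* SNPs has its minor-allele frequency shifted upward in
the case group.  Alleles are sampled independently (Hardy-Weinberg, no
linkage disequilibrium) because the attack and utility statistics treat
SNPs independently; the effect is an additive frequency shift, the
simplest mechanism that makes "significant SNPs" a well-defined ground
truth.

Two named scenarios mirror the benchmark panels this package is
evaluated against: ``chr2_like`` (311 SNPs) and ``chr10_like``
(610 SNPs), each with 200 individuals per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_formats import GenotypeTable

GROUPS = ("case", "control", "test")

DEFAULT_MAF_RANGE = (0.05, 0.5)
DEFAULT_DELTA = 0.15

#: Named scenario shapes: (m, n_per_group, n_effect, model seed).
SCENARIOS = {
    "chr2_like": {"m": 311, "n_per_group": 200, "n_effect": 20, "model_seed": 20311},
    "chr10_like": {"m": 610, "n_per_group": 200, "n_effect": 40, "model_seed": 20610},
}


@dataclass(eq=False)
class PopulationModel:
    """Ground truth behind the simulated cohorts.

    ``p`` holds per-SNP minor-allele frequencies in (0, 0.5]; effect SNPs
    get ``p + delta`` in the case group.  ``alleles`` is the (major,
    minor) letter pair of each SNP.
    """

    m: int
    p: np.ndarray
    effect_snps: np.ndarray
    delta: float
    alleles: list[tuple[str, str]]
    snp_ids: list[str]

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.effect_snps = np.asarray(self.effect_snps, dtype=int)
        if not ((self.p > 0) & (self.p <= 0.5)).all():
            raise ValidationError("minor-allele frequencies must lie in (0, 0.5]")
        if self.effect_snps.size and not (
            (self.effect_snps >= 0) & (self.effect_snps < self.m)
        ).all():
            raise ValidationError("effect SNP indices out of range")
        if self.effect_snps.size and not (
            (self.p[self.effect_snps] + self.delta < 1)
            & (self.p[self.effect_snps] + self.delta > 0)
        ).all():
            raise ValidationError("p + delta must stay inside (0, 1) for effect SNPs")

    def case_frequencies(self) -> np.ndarray:
        q = self.p.copy()
        q[self.effect_snps] += self.delta
        return q

    def effect_snp_ids(self) -> set[str]:
        return {self.snp_ids[j] for j in self.effect_snps}

    def as_dict(self) -> dict:
        return {
            "m": self.m,
            "p": self.p.tolist(),
            "effect_snps": self.effect_snps.tolist(),
            "delta": self.delta,
            "alleles": [list(a) for a in self.alleles],
            "snp_ids": list(self.snp_ids),
        }


def generate_population(
    m: int,
    maf_range: tuple[float, float] = DEFAULT_MAF_RANGE,
    n_effect: int = 0,
    delta: float = DEFAULT_DELTA,
    rng=None,
) -> PopulationModel:
    """Draw a population model: uniform MAFs, random effect SNPs, random
    allele letter pairs."""
    rng = np.random.default_rng(rng)
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValidationError(f"maf_range must lie within (0, 0.5]; got {maf_range}")
    if not 0 <= n_effect <= m:
        raise ValidationError(f"n_effect must be in [0, m]; got {n_effect}")
    if n_effect and not 0 < hi + delta < 1:
        raise ValidationError(f"infeasible delta {delta} for maf_range {maf_range}")
    p = rng.uniform(lo, hi, size=m)
    effect = np.sort(rng.choice(m, size=n_effect, replace=False))
    letters = np.array(list("ACGT"))
    alleles = []
    for _ in range(m):
        a, b = letters[rng.choice(4, size=2, replace=False)]
        alleles.append((str(a), str(b)))  # (major, minor)
    snp_ids = [f"snp{j + 1}" for j in range(m)]
    return PopulationModel(m, p, effect, float(delta), alleles, snp_ids)


def sample_cohort(model: PopulationModel, n: int, group: str, rng=None) -> GenotypeTable:
    """Sample ``n`` individuals of one group under Hardy-Weinberg.

    Each of the two allele copies at each SNP is an independent Bernoulli
    draw of the minor allele with probability ``p_j`` (``p_j + delta`` at
    effect SNPs in the case group); genotypes are rendered as
    alphabetically ordered two-letter strings.
    """
    if group not in GROUPS:
        raise ValidationError(f"group must be one of {GROUPS}; got {group!r}")
    if n < 1:
        raise ValidationError(f"n must be >= 1; got {n}")
    rng = np.random.default_rng(rng)
    q = model.case_frequencies() if group == "case" else model.p
    dosage = (rng.random((n, model.m, 2)) < q[None, :, None]).sum(axis=2)
    gen = np.empty((n, model.m), dtype="<U2")
    for j, (maj, mnr) in enumerate(model.alleles):
        lookup = np.array(
            [maj + maj, "".join(sorted(maj + mnr)), mnr + mnr], dtype="<U2"
        )
        gen[:, j] = lookup[dosage[:, j]]
    ids = [f"{group}_{i + 1:04d}" for i in range(n)]
    return GenotypeTable(ids, list(model.snp_ids), gen)


def challenge_scenario(name: str) -> tuple[PopulationModel, dict[str, int]]:
    """A named benchmark-shaped scenario: model plus per-group cohort sizes.

    The model seed is fixed per scenario so the ground truth (frequencies,
    effect SNPs, allele letters) is reproducible; cohort sampling takes
    its own seed at :func:`sample_cohort` time.
    """
    if name not in SCENARIOS:
        raise ValidationError(f"unknown scenario {name!r}; pick from {sorted(SCENARIOS)}")
    spec = SCENARIOS[name]
    model = generate_population(
        m=spec["m"],
        maf_range=DEFAULT_MAF_RANGE,
        n_effect=spec["n_effect"],
        delta=DEFAULT_DELTA,
        rng=np.random.default_rng(spec["model_seed"]),
    )
    sizes = {g: spec["n_per_group"] for g in GROUPS}
    return model, sizes
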