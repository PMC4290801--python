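"""Case-control association utility of original and anonymized data.

The utility of a release is measured by how well the SNPs that are
significant in the original case/control data (the truth) are recovered
when the same chi-square association scan is run on data reconstructed
from the anonymized releases.

Reconstruction rule: each released leaf partition's count (clamped to be
non-negative; fractional values allowed) is distributed *uniformly* over
the concrete block values beneath each of its generalized labels — the
maximum-entropy default, recorded in report metadata so alternative
rules can be compared.  Fully specialized rows therefore contribute
exactly their count to their literal genotypes, and the total
reconstructed mass per SNP equals the sum of clamped row counts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .taxonomy import TaxonomyForest, cut_from_trace, leaves_under

RECONSTRUCTION_RULE = "uniform_over_leaves"
DEFAULT_CUTOFFS = (5e-2, 1e-2, 1e-3, 1e-5)
SCAN_MODES = ("allelic_2x2", "genotypic_2x3")


@dataclass(eq=False)
class SnpCountTable:
    """Per-SNP genotype masses (integer for raw data, fractional for
    reconstructions)."""

    snp_ids: list[str]
    genotype_counts: list[dict[str, float]]

    def allele_counts(self) -> list[dict[str, float]]:
        out = []
        for gc in self.genotype_counts:
            ac: dict[str, float] = defaultdict(float)
            for g, w in gc.items():
                ac[g[0]] += w
                ac[g[1]] += w
            out.append(dict(ac))
        return out

    def totals(self) -> np.ndarray:
        return np.array([sum(gc.values()) for gc in self.genotype_counts])


def snp_counts_from_table(table) -> SnpCountTable:
    """Direct per-SNP genotype counts of a genotype table."""
    counts = []
    for j in range(table.n_snps):
        gc: dict[str, float] = defaultdict(float)
        for g in table.genotypes[:, j]:
            gc[g] += 1.0
        counts.append(dict(gc))
    return SnpCountTable(list(table.snp_ids), counts)


def reconstruct_snp_counts(
    release, forest: TaxonomyForest, snp_ids: list[str] | None = None
) -> SnpCountTable:
    """Resolve a release's generalized rows into per-SNP genotype masses.

    Each row's clamped count is split uniformly across the leaf block
    values under its label in every block; row labels are resolved
    against the cut implied by the release's specialization trace.
    """
    blocks = forest.blocks
    meta_blocks = [tuple(iv) for iv in release.metadata["blocks"]]
    if meta_blocks != list(blocks.intervals):
        raise ValidationError("release block spec does not match the forest's")
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(blocks.n_snps)]
    cut = cut_from_trace(forest, release.trace)
    masses = np.array([max(0.0, r.noisy_count) for r in release.rows])
    genotype_counts: list[dict[str, float]] = [
        defaultdict(float) for _ in range(blocks.n_snps)
    ]
    for b, (s, e) in enumerate(blocks.intervals):
        weights: dict[str, float] = defaultdict(float)
        for row, mass in zip(release.rows, masses):
            weights[row.generalized_values[b]] += mass
        for label, w in weights.items():
            if w == 0.0:
                cut.node_by_rendered_label(b, label)  # still validate the label
                continue
            node = cut.node_by_rendered_label(b, label)
            leaves = leaves_under(node)
            share = w / len(leaves)
            for leaf in leaves:
                for off, g in enumerate(leaf.split(" ")):
                    genotype_counts[s + off][g] += share
    return SnpCountTable(list(snp_ids), [dict(gc) for gc in genotype_counts])


# ---------------------------------------------------------------------------
# Chi-square association
# ---------------------------------------------------------------------------

def chi_square(observed) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c table of (possibly fractional) counts.

    All-zero rows and columns are dropped first (reducing the degrees of
    freedom); expected counts are the usual row x column products over
    the grand total, and the p-value is the upper chi-square tail with
    ``(r-1)(c-1)`` degrees of freedom.  A table that collapses to fewer
    than two rows or columns carries no association signal: chi2 = 0,
    df = 0, p = 1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2:
        raise ValidationError("observed must be a 2-D table")
    if (obs < 0).any():
        raise ValidationError("observed counts must be non-negative")
    total = obs.sum()
    if total <= 0:
        raise ValidationError("chi-square is undefined for an all-zero table")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    r, c = obs.shape
    if r < 2 or c < 2:
        return 0.0, 0, 1.0
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    return chi2, df, float(stats.chi2.sf(chi2, df))


@dataclass(eq=False)
class AssociationResult:
    """Per-SNP chi-square statistics of a case/control scan."""

    snp_ids: list[str]
    chi2: np.ndarray
    df: np.ndarray
    p: np.ndarray
    mode: str


def association_scan(
    case_counts: SnpCountTable, control_counts: SnpCountTable, mode: str = "allelic_2x2"
) -> AssociationResult:
    """Chi-square case-vs-control test at every SNP.

    ``allelic_2x2`` tests the 2 x alleles table of allele-copy counts;
    ``genotypic_2x3`` tests the 2 x genotypes table.  Columns empty in
    both groups are dropped by :func:`chi_square`, reducing df.
    """
    if mode not in SCAN_MODES:
        raise ValidationError(f"mode must be one of {SCAN_MODES}; got {mode!r}")
    if case_counts.snp_ids != control_counts.snp_ids:
        raise ValidationError("case and control SNP panels differ")
    if mode == "allelic_2x2":
        case_cols = case_counts.allele_counts()
        ctrl_cols = control_counts.allele_counts()
    else:
        case_cols = case_counts.genotype_counts
        ctrl_cols = control_counts.genotype_counts
    chi2s, dfs = [], []
    for ca, co in zip(case_cols, ctrl_cols):
        keys = sorted(set(ca) | set(co))
        obs = np.array(
            [[ca.get(k, 0.0) for k in keys], [co.get(k, 0.0) for k in keys]]
        )
        x2, df, _ = chi_square(obs)
        chi2s.append(x2)
        dfs.append(df)
    chi2_arr = np.array(chi2s)
    df_arr = np.array(dfs, dtype=int)
    p = np.ones_like(chi2_arr)
    has_df = df_arr > 0
    p[has_df] = stats.chi2.sf(chi2_arr[has_df], df_arr[has_df])
    return AssociationResult(list(case_counts.snp_ids), chi2_arr, df_arr, p, mode)


def significant_snps(result: AssociationResult, cutoff: float) -> set[str]:
    """SNPs whose p-value is at or below the cutoff (no multiplicity
    correction — raw cutoff p-values)."""
    if not 0 < cutoff <= 1:
        raise ValidationError(f"cutoff must be in (0, 1]; got {cutoff}")
    return {sid for sid, pv in zip(result.snp_ids, result.p) if pv <= cutoff}


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtilityMetrics:
    """Significant-SNP recovery scores at one p-value cutoff."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    n_significant_truth: int
    note: str = ""

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "n_significant_truth": self.n_significant_truth,
            "note": self.note,
        }


def confusion_metrics(truth: set, predicted: set, panel, cutoff: float = float("nan")) -> UtilityMetrics:
    """Accuracy / sensitivity / precision / F1 of a predicted SNP set.

    ``panel`` is the full SNP id collection of size m.  Conventions:
    precision is 0 for an empty prediction, sensitivity is 0 for an empty
    truth (flagged in ``note``), and F1 is 0 whenever TP is 0.
    """
    panel = set(panel)
    m = len(panel)
    truth, predicted = set(truth), set(predicted)
    if not truth <= panel or not predicted <= panel:
        raise ValidationError("truth/predicted sets must lie within the SNP panel")
    tp = len(truth & predicted)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = m - tp - fp - fn
    accuracy = (tp + tn) / m if m else 0.0
    sensitivity = tp / (tp + fn) if truth else 0.0
    precision = tp / (tp + fp) if predicted else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity) if tp > 0 else 0.0
    )
    return UtilityMetrics(
        cutoff=cutoff,
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        n_significant_truth=len(truth),
        note="no significant SNPs" if not truth else "",
    )


def utility_report(
    case_table,
    control_table,
    case_release,
    control_release,
    case_forest: TaxonomyForest,
    control_forest: TaxonomyForest,
    cutoffs=DEFAULT_CUTOFFS,
    mode: str = "allelic_2x2",
) -> dict:
    """Significant-SNP recovery of a pair of releases, per cutoff.

    Truth is the association scan on the original tables; the prediction
    is the same scan on counts reconstructed from the releases (case and
    control anonymized separately).
    """
    if case_table.snp_ids != control_table.snp_ids:
        raise ValidationError("case and control tables cover different SNPs")
    snp_ids = list(case_table.snp_ids)
    truth_scan = association_scan(
        snp_counts_from_table(case_table), snp_counts_from_table(control_table), mode
    )
    pred_scan = association_scan(
        reconstruct_snp_counts(case_release, case_forest, snp_ids),
        reconstruct_snp_counts(control_release, control_forest, snp_ids),
        mode,
    )
    rows = [
        confusion_metrics(
            significant_snps(truth_scan, c), significant_snps(pred_scan, c),
            snp_ids, cutoff=c,
        )
        for c in cutoffs
    ]
    return {
        "mode": mode,
        "reconstruction": RECONSTRUCTION_RULE,
        "m": len(snp_ids),
        "metrics": rows,
    }
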