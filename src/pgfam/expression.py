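"""qPCR expression analysis: 2^-ddCt relative expression, tissue-pattern
labels, hierarchical clustering, and paralog-pair divergence categories.

Pair categories:
  I   both silent, or same expressed-tissue set at the same level (max
      per-tissue fold < f);
  II  same expressed-tissue set but some tissue diverges >= f fold;
  III different, partially/fully non-overlapping expressed-tissue sets;
  IV  one gene silent, the other expressed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._util import round_half_up

ND = "ND"  # no-amplification sentinel in Ct tables
CATEGORIES = ("I", "II", "III", "IV")


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    genes: list[str]
    tissues: list[str]
    values: np.ndarray  # genes x tissues, nonnegative

    def __post_init__(self):
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ExpressionError("matrix shape mismatch")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ExpressionError("expression values must be finite and >= 0")

    def row(self, gene: str) -> dict[str, float]:
        i = self.genes.index(gene)
        return dict(zip(self.tissues, self.values[i]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.tissues)


def _as_float_ct(raw) -> float | None:
    if isinstance(raw, str):
        if raw.strip().upper() == ND:
            return None
        return float(raw)
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    return float(raw)


def relative_expression(ct_table: pd.DataFrame, reference_gene: str,
                        calibrator_sample: str,
                        nd_baseline_ct: float = 40.0) -> ExpressionMatrix:
    """2^-ddCt relative expression from a long-format Ct table with columns
    (gene, sample, ct).  "ND" Ct values become 0; a gene not detected in the
    calibrator sample falls back to ``nd_baseline_ct`` for its calibrator
    delta-Ct so expressed tissues still yield finite values."""
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct_table.columns):
        raise ExpressionError(f"Ct table needs columns {sorted(required)}")
    samples = list(dict.fromkeys(ct_table["sample"]))
    if calibrator_sample not in samples:
        raise ExpressionError(f"calibrator sample {calibrator_sample!r} absent")
    ct: dict[tuple[str, str], float | None] = {}
    for _, row in ct_table.iterrows():
        ct[(row["gene"], row["sample"])] = _as_float_ct(row["ct"])
    genes = [g for g in dict.fromkeys(ct_table["gene"]) if g != reference_gene]
    ref_ct = {}
    for s in samples:
        if (reference_gene, s) not in ct or ct[(reference_gene, s)] is None:
            raise ExpressionError(f"missing reference Ct for sample {s!r}")
        ref_ct[s] = ct[(reference_gene, s)]
    values = np.zeros((len(genes), len(samples)))
    for i, gene in enumerate(genes):
        cal_raw = ct.get((gene, calibrator_sample))
        dct_cal = (nd_baseline_ct - ref_ct[calibrator_sample] if cal_raw is None
                   else cal_raw - ref_ct[calibrator_sample])
        for j, s in enumerate(samples):
            raw = ct.get((gene, s))
            if raw is None:
                values[i, j] = 0.0
            else:
                ddct = (raw - ref_ct[s]) - dct_cal
                values[i, j] = 2.0 ** (-ddct)
    return ExpressionMatrix(genes, samples, values)


# ---------------------------------------------------------------------------
# Tissue patterns
# ---------------------------------------------------------------------------

def classify_tissue_pattern(matrix: ExpressionMatrix, expressed_threshold: float = 0.05,
                            specificity_fraction: float = 0.8) -> dict[str, str]:
    """Label each gene: "silent", "<tissue>-specific" (one tissue holds >=
    the specificity fraction of the total), "ubiquitous" (every tissue
    expressed) or "multi:<t1+t2+...>"."""
    if expressed_threshold <= 0 or not 0.5 < specificity_fraction <= 1:
        raise ExpressionError("invalid thresholds")
    labels = {}
    for i, gene in enumerate(matrix.genes):
        row = matrix.values[i]
        expressed = [t for t, v in zip(matrix.tissues, row) if v >= expressed_threshold]
        if not expressed:
            labels[gene] = "silent"
            continue
        total = row.sum()
        top = int(np.argmax(row))
        if row[top] >= specificity_fraction * total:
            labels[gene] = f"{matrix.tissues[top]}-specific"
        elif len(expressed) == len(matrix.tissues):
            labels[gene] = "ubiquitous"
        else:
            labels[gene] = "multi:" + "+".join(expressed)
    return labels


@dataclass
class ClusterResult:
    leaf_order: list[str]
    merge_heights: list[float]
    linkage_matrix: np.ndarray


def cluster_genes(matrix: ExpressionMatrix, linkage: str = "average",
                  metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of genes on log2(x + 1) profiles."""
    if len(matrix.genes) < 2:
        raise ExpressionError("need at least two genes to cluster")
    data = np.log2(matrix.values + 1.0)
    z = hierarchy.linkage(pdist(data, metric=metric), method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusterResult([matrix.genes[i] for i in order], list(z[:, 2]), z)


# ---------------------------------------------------------------------------
# Pair categories
# ---------------------------------------------------------------------------

@dataclass
class PairCategory:
    gene_a: str
    gene_b: str
    category: str
    expressed_a: tuple[str, ...]
    expressed_b: tuple[str, ...]
    max_fold: float | None  # over shared expressed tissues, if any


def categorize_pair(expr_a: Mapping[str, float], expr_b: Mapping[str, float],
                    expressed_threshold: float = 0.05, fold: float = 2.0,
                    gene_a: str = "a", gene_b: str = "b") -> PairCategory:
    if set(expr_a) != set(expr_b):
        raise ExpressionError("pair measured on different tissue sets")
    tissues = list(expr_a)
    ea = tuple(t for t in tissues if expr_a[t] >= expressed_threshold)
    eb = tuple(t for t in tissues if expr_b[t] >= expressed_threshold)
    max_fold = None
    if ea and set(ea) == set(eb):
        folds = [max(expr_a[t], expr_b[t]) / min(expr_a[t], expr_b[t]) for t in ea]
        max_fold = max(folds)
    if not ea and not eb:
        category = "I"
    elif bool(ea) != bool(eb):
        category = "IV"
    elif set(ea) == set(eb):
        category = "I" if max_fold < fold else "II"
    else:
        category = "III"
    return PairCategory(gene_a, gene_b, category, ea, eb, max_fold)


@dataclass
class DivergenceSummary:
    counts: dict[str, int]
    total: int
    percent_divergent: float


def divergence_summary(pairs: Iterable[PairCategory] | Mapping[str, int]
                       ) -> DivergenceSummary:
    """Category counts and the percentage of divergent pairs
    (100 * (II + III + IV) / total, half-up to one decimal)."""
    if isinstance(pairs, Mapping):
        counts = {c: int(pairs.get(c, 0)) for c in CATEGORIES}
    else:
        counts = {c: 0 for c in CATEGORIES}
        for p in pairs:
            counts[p.category] += 1
    total = sum(counts.values())
    if total == 0:
        raise ExpressionError("no pairs")
    divergent = counts["II"] + counts["III"] + counts["IV"]
    return DivergenceSummary(counts, total, round_half_up(100.0 * divergent / total, 1))
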