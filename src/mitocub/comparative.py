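"""Cross-species codon-usage comparisons.

Builds the species x codon RSCU matrix, partitions codons into
frequently used (mean RSCU across species > 1) and infrequently used
sets, clusters species hierarchically on their RSCU profiles, runs
paired t-tests on codon-wise RSCU differences between species, and
tallies the per-gene / per-species outcomes of the ENC-ratio selection
screen.

Missing RSCU entries (families never observed in a species) are dropped
pairwise for distances and tests, never imputed as 0 — a 0 is a real
RSCU value (a codon absent from an observed family), not missingness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .codon_metrics import GeneBiasMetrics, CodonCountTable, count_codons, rscu
from .genetic_code import GeneticCode
from .seq_io import GeneRecord

__all__ = [
    "SpeciesRscuMatrix",
    "CodonPartition",
    "ClusterResult",
    "PairwiseRscuTest",
    "SelectionSummary",
    "build_rscu_matrix",
    "partition_codons",
    "cluster_species",
    "paired_rscu_test",
    "selection_summary",
]


@dataclass(frozen=True)
class SpeciesRscuMatrix:
    """Species x sense-codon RSCU values (NaN = family never observed).

    ``mode`` records how per-species values were aggregated over genes:
    ``concatenated`` pools codon counts over all PCGs before computing
    RSCU once (so the family-sum invariant holds per species);
    ``gene-averaged`` averages per-gene RSCU vectors, ignoring missing.
    """

    values: pd.DataFrame  # index: species, columns: codons
    codon_amino_acids: Mapping[str, str]
    mode: str

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CodonPartition:
    frequent: tuple[str, ...]  # mean RSCU across species > 1
    infrequent: tuple[str, ...]  # mean RSCU <= 1


@dataclass(frozen=True)
class ClusterResult:
    linkage_matrix: np.ndarray
    species: tuple[str, ...]  # input order, row indices of the linkage
    leaf_order: tuple[str, ...]  # dendrogram order for heatmap rows
    metric: str
    method: str


@dataclass(frozen=True)
class PairwiseRscuTest:
    species_a: str
    species_b: str
    subset_name: str
    n_pairs: int
    normality_p: float | None
    normality_ok: bool | None
    variance_test_p: float | None
    t_statistic: float | None
    p_value: float | None
    reason: str | None = None


@dataclass(frozen=True)
class SelectionSummary:
    per_gene_selected: Mapping[str, int]  # gene -> species count
    per_species_selected: Mapping[str, int]  # species -> gene count
    per_gene_mean_enc: Mapping[str, float]
    per_species_mean_enc: Mapping[str, float]


def build_rscu_matrix(
    species_cds: Mapping[str, Sequence[GeneRecord]],
    code: GeneticCode,
    mode: str = "concatenated",
) -> SpeciesRscuMatrix:
    """Per-species RSCU over all protein-coding genes.

    Concatenated mode pools codon counts over a species' genes and
    computes RSCU once; gene-averaged mode averages per-gene RSCU
    vectors, ignoring genes where a family is unobserved.
    """
    if mode not in ("concatenated", "gene-averaged"):
        raise ValueError(f"unknown mode {mode!r}")
    if not species_cds:
        raise ValueError("need at least one species")

    codons = list(code.sense_codons)
    rows: dict[str, list[float]] = {}
    for species, recs in species_cds.items():
        if mode == "concatenated":
            pooled: dict[str, int] = {}
            for rec in recs:
                t = count_codons(rec, code)
                for c, x in t.counts.items():
                    pooled[c] = pooled.get(c, 0) + x
            if not pooled:
                import warnings

                warnings.warn(f"{species}: zero countable codons; excluded")
                continue
            table = CodonCountTable(species, "ALL", pooled, 0, 0)
            vec = rscu(table, code)
            rows[species] = [
                np.nan if vec[c] is None else vec[c] for c in codons
            ]
        else:
            per_gene = []
            for rec in recs:
                vec = rscu(count_codons(rec, code), code)
                per_gene.append(
                    [np.nan if vec[c] is None else vec[c] for c in codons]
                )
            if not per_gene:
                continue
            arr = np.array(per_gene)
            with np.errstate(invalid="ignore"):
                rows[species] = list(np.nanmean(arr, axis=0))

    df = pd.DataFrame.from_dict(rows, orient="index", columns=codons)
    aa = {c: code.codon_to_aa[c] for c in codons}
    return SpeciesRscuMatrix(values=df, codon_amino_acids=aa, mode=mode)


def partition_codons(matrix: SpeciesRscuMatrix) -> CodonPartition:
    """Split codons by their mean RSCU across species (strictly > 1 is
    frequent; missing values ignored in the mean)."""
    means = matrix.values.mean(axis=0, skipna=True)
    frequent = tuple(c for c in matrix.codons if means[c] > 1.0)
    infrequent = tuple(c for c in matrix.codons if not means[c] > 1.0)
    return CodonPartition(frequent=frequent, infrequent=infrequent)


def _pairwise_distance(
    values: np.ndarray, metric: str
) -> np.ndarray:
    """Condensed distance matrix with pairwise deletion of NaNs."""
    n = values.shape[0]
    out = np.zeros(n * (n - 1) // 2)
    idx = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(values[i]) | np.isnan(values[j]))
            if not mask.any():
                raise ValueError(
                    f"species pair ({i}, {j}) share no non-missing codons"
                )
            d = values[i, mask] - values[j, mask]
            if metric == "euclidean":
                out[idx] = float(np.sqrt(np.sum(d * d)))
            elif metric == "cityblock":
                out[idx] = float(np.sum(np.abs(d)))
            elif metric == "correlation":
                a, b = values[i, mask], values[j, mask]
                out[idx] = 1.0 - float(np.corrcoef(a, b)[0, 1])
            else:
                raise ValueError(f"unsupported metric {metric!r}")
            idx += 1
    return out


def cluster_species(
    matrix: SpeciesRscuMatrix,
    subset: Sequence[str] | None = None,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusterResult:
    """Hierarchical clustering of species on (a subset of) their RSCU
    profiles.  Deterministic given metric, linkage method and input
    order; the emitted leaf order reproduces the heatmap row order."""
    species = matrix.species
    if len(species) < 2:
        raise ValueError("clustering needs at least 2 species")
    cols = list(subset) if subset is not None else matrix.codons
    values = matrix.values[cols].to_numpy(dtype=float)
    condensed = _pairwise_distance(values, metric)
    z = hierarchy.linkage(condensed, method=method)
    leaves = hierarchy.leaves_list(z)
    return ClusterResult(
        linkage_matrix=z,
        species=tuple(species),
        leaf_order=tuple(species[i] for i in leaves),
        metric=metric,
        method=method,
    )


def paired_rscu_test(
    matrix: SpeciesRscuMatrix,
    species_a: str,
    species_b: str,
    subset: Sequence[str] | None = None,
    subset_name: str = "all",
    alpha: float = 0.05,
) -> PairwiseRscuTest:
    """Paired t-test on codon-wise RSCU differences between two species.

    Codons missing in either species are dropped pairwise.  Normality of
    the paired differences is assessed first (Shapiro-Wilk) and reported;
    the t-test is still computed when normality fails, with the flag set.
    The variance-homogeneity F-ratio of the two species' RSCU variances
    is reported alongside (it is not an assumption of the paired test).
    """
    cols = list(subset) if subset is not None else matrix.codons
    a = matrix.values.loc[species_a, cols].to_numpy(dtype=float)
    b = matrix.values.loc[species_b, cols].to_numpy(dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    n = int(mask.sum())
    if n < 3:
        return PairwiseRscuTest(
            species_a, species_b, subset_name, n,
            None, None, None, None, None,
            reason=f"only {n} shared non-missing codons (need >= 3)",
        )

    d = a - b
    if np.all(np.abs(d - d[0]) < 1e-12):
        if abs(d[0]) < 1e-12:
            # identical profiles: no difference at all
            norm_p = None
            var_p = _variance_f_p(a, b)
            return PairwiseRscuTest(
                species_a, species_b, subset_name, n,
                norm_p, None, var_p, 0.0, 1.0,
            )
        return PairwiseRscuTest(
            species_a, species_b, subset_name, n,
            None, None, _variance_f_p(a, b), None, None,
            reason="zero-variance nonzero differences (degenerate t)",
        )

    norm_stat, norm_p = stats.shapiro(d)
    t_stat, p_val = stats.ttest_rel(a, b)
    return PairwiseRscuTest(
        species_a, species_b, subset_name, n,
        float(norm_p), bool(norm_p > alpha),
        _variance_f_p(a, b),
        float(t_stat), float(p_val),
    )


def _variance_f_p(a: np.ndarray, b: np.ndarray) -> float | None:
    """Two-sided p of the F-ratio of two sample variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 or vb == 0.0:
        return None
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p_one = stats.f.sf(f, dfa, dfb) if f > 1 else stats.f.cdf(f, dfa, dfb)
    return float(min(1.0, 2.0 * p_one))


def selection_summary(
    metrics: Sequence[GeneBiasMetrics],
) -> SelectionSummary:
    """Tally the selection screen by gene and by species, with mean ENC.

    Genes whose ENC is missing (too short) contribute to neither the
    tallies nor the means.
    """
    per_gene_sel: dict[str, int] = {}
    per_species_sel: dict[str, int] = {}
    gene_enc: dict[str, list[float]] = {}
    species_enc: dict[str, list[float]] = {}
    for m in metrics:
        if m.enc_obs is None:
            continue
        gene_enc.setdefault(m.gene_name, []).append(m.enc_obs)
        species_enc.setdefault(m.species_label, []).append(m.enc_obs)
        per_gene_sel.setdefault(m.gene_name, 0)
        per_species_sel.setdefault(m.species_label, 0)
        if m.selected:
            per_gene_sel[m.gene_name] += 1
            per_species_sel[m.species_label] += 1
    return SelectionSummary(
        per_gene_selected=dict(sorted(per_gene_sel.items())),
        per_species_selected=dict(sorted(per_species_sel.items())),
        per_gene_mean_enc={
            g: float(np.mean(v)) for g, v in sorted(gene_enc.items())
        },
        per_species_mean_enc={
            s: float(np.mean(v)) for s, v in sorted(species_enc.items())
        },
    )
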