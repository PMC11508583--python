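"""Per-gene codon-usage statistics: RSCU, GC3s, Wright's ENC, and the
mutation-only null curve.

RSCU (relative synonymous codon usage) of codon *j* in a synonymous
family of size *k* with counts X is::

    RSCU_j = X_j / (sum(X) / k)

so RSCU = 1 means a codon is used exactly as often as expected under
uniform synonymous usage, > 1 means over-use.  Codons of an amino acid
never observed in a gene are *missing* (no information), while an
unobserved codon inside an observed family has RSCU 0 (a real absence).

ENC (the effective number of codons, Wright 1990) summarises overall
bias.  Per amino acid observed n >= 2 times with within-family codon
frequencies p, the codon homozygosity is::

    F_hat = (n * sum(p_i^2) - 1) / (n - 1)

F_hat values are averaged inside each degeneracy class k (all the
k-fold-degenerate amino acids), and::

    ENC = N1 + sum_k N_k / Fbar_k

with N_k the code's census of k-fold families.  Under the invertebrate
mitochondrial code (N2, N4, N6, N8) = (12, 6, 1, 1), so ENC ranges from
20 (one codon per amino acid, maximal bias) to 62 (uniform usage).

The mutation-only expectation at a given GC3s is the null curve::

    ENC_exp = 2 + GC3s + 29 / (GC3s^2 + (1 - GC3s)^2)

and the ENC ratio (ENC_exp - ENC_obs)/ENC_exp > 0.15 flags genes whose
observed bias is too strong for mutation pressure alone — the natural-
selection screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .genetic_code import STOP, GeneticCode, SynonymousFamily
from .seq_io import GeneRecord

__all__ = [
    "CodonCountTable",
    "FamilyHomozygosity",
    "GeneBiasMetrics",
    "count_codons",
    "rscu",
    "gc3s",
    "family_homozygosities",
    "enc_obs",
    "enc_exp",
    "selection_flag",
    "gene_metrics",
    "DEFAULT_MIN_CODONS",
    "DEFAULT_SELECTION_THRESHOLD",
]

_VALID = frozenset("ACGT")

#: Genes with fewer counted codons return no ENC.  Mitochondrial ATP8
#: (~50-55 codons) falls under this rule, matching its customary
#: exclusion from ENC analyses as too short; every other mitochondrial
#: PCG (ND4L, ~98 codons, is the next shortest) clears it.
DEFAULT_MIN_CODONS = 60

#: ENC-ratio threshold of the selection screen (strict inequality).
DEFAULT_SELECTION_THRESHOLD = 0.15


@dataclass(frozen=True)
class CodonCountTable:
    """Sense-codon counts for one gene, with excluded-codon bookkeeping."""

    species_label: str
    gene_name: str
    counts: Mapping[str, int]
    excluded_stop: int
    excluded_ambiguous: int

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class FamilyHomozygosity:
    """Codon homozygosity F_hat of one amino acid (defined for n >= 2)."""

    amino_acid: str
    degeneracy: int
    n: int
    f_hat: float | None


@dataclass(frozen=True)
class GeneBiasMetrics:
    """All per-gene bias statistics for one coding sequence."""

    species_label: str
    gene_name: str
    total_codons: int
    rscu: Mapping[str, float | None]
    gc3s: float | None
    enc_obs: float | None
    enc_exp: float | None
    enc_ratio: float | None
    selected: bool | None


def count_codons(rec: GeneRecord, code: GeneticCode) -> CodonCountTable:
    """Count the full sense codons of a gene.

    Stop codons (terminal or internal) and codons containing ambiguity
    characters are routed to the excluded tallies; a trailing 1-2 nt
    overhang is never a codon and is ignored.
    """
    counts: dict[str, int] = {}
    n_stop = 0
    n_ambiguous = 0
    for codon in rec.codons():
        if not set(codon) <= _VALID:
            n_ambiguous += 1
        elif code.codon_to_aa[codon] == STOP:
            n_stop += 1
        else:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(
        species_label=rec.species_label,
        gene_name=rec.gene_name,
        counts=counts,
        excluded_stop=n_stop,
        excluded_ambiguous=n_ambiguous,
    )


def rscu(table: CodonCountTable, code: GeneticCode) -> dict[str, float | None]:
    """RSCU for every sense codon of the code.

    Families with zero observations yield ``None`` for all their codons;
    an unobserved codon within an observed family yields 0.0.
    """
    out: dict[str, float | None] = {}
    for fam in code.families:
        total = sum(table.counts.get(c, 0) for c in fam.codons)
        for c in fam.codons:
            if total == 0:
                out[c] = None
            else:
                out[c] = table.counts.get(c, 0) * fam.degeneracy / total
    return out


def gc3s(table: CodonCountTable, code: GeneticCode) -> float | None:
    """G+C fraction at the third position of synonymously degenerate codons.

    Single-codon families (ATG and TGG under the standard code) carry no
    synonymous information at the third position and are excluded from
    numerator and denominator; under the invertebrate mitochondrial code
    every family is degenerate, so all counted codons contribute.
    """
    num = 0
    den = 0
    for fam in code.families:
        if fam.degeneracy < 2:
            continue
        for c in fam.codons:
            x = table.counts.get(c, 0)
            den += x
            if c[2] in "GC":
                num += x
    if den == 0:
        return None
    return num / den


def family_homozygosities(
    table: CodonCountTable, code: GeneticCode
) -> list[FamilyHomozygosity]:
    """F_hat = (n * sum(p^2) - 1)/(n - 1) per amino acid; None for n < 2."""
    out = []
    for fam in code.families:
        xs = [table.counts.get(c, 0) for c in fam.codons]
        n = sum(xs)
        if n >= 2:
            sum_p2 = sum((x / n) ** 2 for x in xs)
            f_hat = (n * sum_p2 - 1) / (n - 1)
        else:
            f_hat = None
        out.append(
            FamilyHomozygosity(fam.amino_acid, fam.degeneracy, n, f_hat)
        )
    return out


def _impute_class_mean(
    k: int, available: Mapping[int, float]
) -> float:
    """Fill in Fbar for a degeneracy class with no usable family.

    The mean homozygosity of the nearest available class below and the
    nearest above are averaged (one-sided if only one side exists) —
    the interpolation customarily applied when a rare degeneracy class
    (e.g. the single 6- or 8-fold family) is absent from a short gene.
    """
    below = [kk for kk in available if kk < k]
    above = [kk for kk in available if kk > k]
    vals = []
    if below:
        vals.append(available[max(below)])
    if above:
        vals.append(available[min(above)])
    return sum(vals) / len(vals)


def enc_obs(
    table: CodonCountTable,
    code: GeneticCode,
    min_codons: int = DEFAULT_MIN_CODONS,
) -> float | None:
    """Wright's effective number of codons for one gene.

    Per degeneracy class the mean of the defined F_hat values is taken,
    excluding F_hat = 0 (a zero homozygosity would contribute an infinite
    1/Fbar); a class with no usable family is imputed from its neighbours.
    The result is capped at the code's sense-codon count.  Genes with
    fewer than ``min_codons`` counted codons return ``None``.
    """
    if table.total_codons < min_codons:
        return None

    fams = family_homozygosities(table, code)
    # class census from the code itself, not from what the gene observed
    census = code.degeneracy_census()

    class_means: dict[int, float] = {}
    for k in census:
        if k == 1:
            continue
        fh = [
            f.f_hat
            for f in fams
            if f.degeneracy == k and f.f_hat is not None and f.f_hat > 0.0
        ]
        if fh:
            class_means[k] = sum(fh) / len(fh)

    if not class_means:
        return None

    enc = float(census.get(1, 0))
    for k, n_k in census.items():
        if k == 1:
            continue
        fbar = class_means.get(k)
        if fbar is None:
            fbar = _impute_class_mean(k, class_means)
        enc += n_k / fbar

    return min(enc, float(code.n_sense_codons))


def enc_exp(gc3s_value: float) -> float:
    """Expected ENC under mutation pressure alone at a given GC3s:
    ``2 + GC3s + 29/(GC3s^2 + (1 - GC3s)^2)``."""
    if not 0.0 <= gc3s_value <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s_value}")
    s = gc3s_value
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def selection_flag(
    enc_obs_value: float,
    enc_exp_value: float,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> tuple[float, bool]:
    """ENC ratio and its strict-threshold selection call.

    ``ratio = (ENC_exp - ENC_obs)/ENC_exp``; ``selected`` is True only
    when the ratio strictly exceeds the threshold (observed ENC below
    85% of the expectation at the default 0.15).
    """
    if enc_exp_value <= 0:
        raise ValueError("enc_exp must be positive")
    ratio = (enc_exp_value - enc_obs_value) / enc_exp_value
    return ratio, ratio > threshold


def gene_metrics(
    rec: GeneRecord,
    code: GeneticCode,
    min_codons: int = DEFAULT_MIN_CODONS,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> GeneBiasMetrics:
    """Convenience: count codons and compute every per-gene statistic."""
    table = count_codons(rec, code)
    g3 = gc3s(table, code)
    obs = enc_obs(table, code, min_codons=min_codons)
    exp = enc_exp(g3) if g3 is not None else None
    if obs is not None and exp is not None:
        ratio, selected = selection_flag(obs, exp, threshold)
    else:
        ratio, selected = None, None
    return GeneBiasMetrics(
        species_label=rec.species_label,
        gene_name=rec.gene_name,
        total_codons=table.total_codons,
        rscu=rscu(table, code),
        gc3s=g3,
        enc_obs=obs,
        enc_exp=exp,
        enc_ratio=ratio,
        selected=selected,
    )
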