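"""Synthetic CDS generation with known codon-usage structure.

Three regimes cover the hypotheses the ENC-GC3s analysis distinguishes:

``uniform``
    codons drawn uniformly within each synonymous family — no bias, ENC
    near its maximum; used as the weak-bias outlier regime.
``mutation_gc3``
    within-family codon probabilities proportional to a third-base
    composition whose G+C mass equals ``gc3_target`` (split equally
    between G and C, and between A and T).  This is mutation pressure
    with no selection: genes land on the ENC_exp null curve at their
    realized GC3s.
``biased``
    per-family probability vectors drawn from a symmetric Dirichlet with
    concentration ``bias_concentration``; small concentrations give
    strongly skewed synonymous usage and depress ENC below the null
    curve, so the selection screen flags these genes by construction.

Amino acids are drawn i.i.d. from ``aa_frequencies`` (default: a
mitochondrial-like composition rich in Leu/Ser/Ile, so the 6- and 8-fold
degeneracy classes are well exercised).  Genes start with ATG and end
with an appended TAA; stop codons are never sampled internally.
Generation is fully reproducible from the integer seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genetic_code import GeneticCode, build_code
from .seq_io import GeneRecord, PCG_NAMES

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "GeneTruth",
    "MITO_GENE_CODONS",
    "DEFAULT_AA_FREQUENCIES",
    "generate",
    "make_species_panel",
    "write_truth",
]

#: Approximate codon counts of the 13 mitochondrial PCGs of an insect
#: mitogenome; ATP8 is deliberately under the default ENC length cutoff.
MITO_GENE_CODONS: dict[str, int] = {
    "ATP6": 225, "ATP8": 53, "COX1": 512, "COX2": 229, "COX3": 262,
    "CYTB": 380, "ND1": 314, "ND2": 330, "ND3": 117, "ND4": 447,
    "ND4L": 98, "ND5": 573, "ND6": 174,
}

#: Mitochondrial-like amino-acid composition (sums to 1).
DEFAULT_AA_FREQUENCIES: dict[str, float] = {
    "L": 0.15, "S": 0.11, "I": 0.09, "F": 0.08, "M": 0.06, "G": 0.06,
    "N": 0.05, "T": 0.05, "A": 0.05, "V": 0.04, "P": 0.04, "Y": 0.04,
    "K": 0.03, "W": 0.03, "E": 0.03, "D": 0.02, "Q": 0.02, "H": 0.02,
    "R": 0.02, "C": 0.01,
}

_REGIMES = ("uniform", "mutation_gc3", "biased")


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for one generated species' CDS set."""

    seed: int
    table_id: int = 5
    n_genes: int = 13
    codons_per_gene: int | Sequence[int] | None = None
    regime: str = "uniform"
    gc3_target: float = 0.5
    bias_concentration: float = 0.1
    aa_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_FREQUENCIES)
    )
    #: seed of the *generating distribution* (the per-gene Dirichlet
    #: draws of the biased regime), separable from the sampling seed so
    #: a species panel can share one codon-usage distribution while each
    #: member keeps independent sampling noise.  None: same as ``seed``.
    distribution_seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in _REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; use one of {_REGIMES}")
        if not 0.0 <= self.gc3_target <= 1.0:
            raise ValueError("gc3_target must be in [0, 1]")
        if self.bias_concentration <= 0:
            raise ValueError("bias_concentration must be positive")
        total = sum(self.aa_frequencies.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"aa_frequencies must sum to 1 (got {total})")
        if any(v < 0 for v in self.aa_frequencies.values()):
            raise ValueError("aa_frequencies must be non-negative")

    def gene_lengths(self) -> list[int]:
        """Codon count per gene (start codon included, stop excluded)."""
        if self.codons_per_gene is None:
            names = _gene_names(self.n_genes)
            return [MITO_GENE_CODONS.get(g, 300) for g in names]
        if isinstance(self.codons_per_gene, int):
            return [self.codons_per_gene] * self.n_genes
        lengths = list(self.codons_per_gene)
        if len(lengths) != self.n_genes:
            raise ValueError("codons_per_gene list length must equal n_genes")
        return lengths


@dataclass(frozen=True)
class GeneTruth:
    """Realized generating distribution of one synthetic gene."""

    gene_name: str
    #: joint sampling probability of each sense codon
    codon_probs: Mapping[str, float]
    #: within-family conditional probabilities
    family_probs: Mapping[str, float]
    realized_gc3: float
    regime: str


@dataclass(frozen=True)
class SyntheticTruth:
    species_label: str
    spec: SyntheticSpec
    genes: tuple[GeneTruth, ...]


def _gene_names(n_genes: int) -> list[str]:
    if n_genes <= len(PCG_NAMES):
        return list(PCG_NAMES[:n_genes])
    extra = [f"GENE{i:02d}" for i in range(len(PCG_NAMES), n_genes)]
    return list(PCG_NAMES) + extra


def _third_base_mass(base: str, gc3: float) -> float:
    return gc3 / 2.0 if base in "GC" else (1.0 - gc3) / 2.0


def _family_probabilities(
    code: GeneticCode, spec: SyntheticSpec, dist_rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Within-family codon probability vector per amino acid.

    For the ``biased`` regime a fresh Dirichlet draw is made per call
    (i.e. per gene) from the distribution RNG, so each gene has its own
    skew direction.
    """
    probs: dict[str, np.ndarray] = {}
    for fam in code.families:
        k = fam.degeneracy
        if spec.regime == "uniform":
            p = np.full(k, 1.0 / k)
        elif spec.regime == "mutation_gc3":
            w = np.array(
                [_third_base_mass(c[2], spec.gc3_target) for c in fam.codons]
            )
            if w.sum() == 0.0:  # all-AT or all-GC family at an extreme target
                p = np.full(k, 1.0 / k)
            else:
                p = w / w.sum()
        else:  # biased
            p = dist_rng.dirichlet(np.full(k, spec.bias_concentration))
        probs[fam.amino_acid] = p
    return probs


def _sample_gene(
    name: str,
    n_codons: int,
    code: GeneticCode,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    dist_rng: np.random.Generator,
    species_label: str,
) -> tuple[GeneRecord, GeneTruth]:
    aa_names = sorted(spec.aa_frequencies)
    aa_p = np.array([spec.aa_frequencies[a] for a in aa_names])
    fam_probs = _family_probabilities(code, spec, dist_rng)

    aa_draws = rng.choice(len(aa_names), size=n_codons - 1, p=aa_p)
    # one vectorized within-family draw per amino acid, not per codon
    body = np.empty(n_codons - 1, dtype=object)
    for i, aa in enumerate(aa_names):
        positions = np.flatnonzero(aa_draws == i)
        if positions.size == 0:
            continue
        fam = code.family_by_aa(aa)
        picks = rng.choice(fam.degeneracy, size=positions.size, p=fam_probs[aa])
        fam_arr = np.array(fam.codons, dtype=object)
        body[positions] = fam_arr[picks]
    codons = ["ATG"] + list(body)

    realized_gc3 = sum(1 for c in codons if c[2] in "GC") / len(codons)
    seq = "".join(codons) + "TAA"

    joint: dict[str, float] = {}
    family_flat: dict[str, float] = {}
    for fam in code.families:
        p = fam_probs[fam.amino_acid]
        f_aa = spec.aa_frequencies.get(fam.amino_acid, 0.0)
        for c, pc in zip(fam.codons, p):
            joint[c] = f_aa * float(pc)
            family_flat[c] = float(pc)

    rec = GeneRecord(
        species_label=species_label,
        gene_name=name,
        sequence=seq,
        source=f"synthetic:{spec.regime}:seed={spec.seed}",
    )
    truth = GeneTruth(
        gene_name=name,
        codon_probs=joint,
        family_probs=family_flat,
        realized_gc3=realized_gc3,
        regime=spec.regime,
    )
    return rec, truth


def generate(
    spec: SyntheticSpec, species_label: str = "synthetic"
) -> tuple[list[GeneRecord], SyntheticTruth]:
    """Generate a species' CDS set and its ground truth from a spec."""
    code = build_code(spec.table_id)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    dseed = spec.seed if spec.distribution_seed is None else spec.distribution_seed
    # distribution draws live on their own stream so species sharing a
    # distribution_seed get identical per-gene codon distributions
    dist_rng = np.random.default_rng(np.random.SeedSequence(dseed, spawn_key=(1,)))
    names = _gene_names(spec.n_genes)
    lengths = spec.gene_lengths()
    records: list[GeneRecord] = []
    truths: list[GeneTruth] = []
    for name, n_codons in zip(names, lengths):
        rec, truth = _sample_gene(name, n_codons, code, spec, rng, dist_rng,
                                  species_label)
        records.append(rec)
        truths.append(truth)
    return records, SyntheticTruth(
        species_label=species_label, spec=spec, genes=tuple(truths)
    )


def child_seed(parent_seed: int, index: int) -> int:
    """Deterministic, platform-stable per-species seed derivation."""
    ss = np.random.SeedSequence(parent_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0]) & 0x7FFFFFFF


def make_species_panel(
    n_species: int,
    shared_spec: SyntheticSpec,
    outlier_spec: SyntheticSpec | None = None,
) -> tuple[dict[str, list[GeneRecord]], dict[str, SyntheticTruth]]:
    """A panel of species sharing one generating spec, plus an optional
    outlier generated from a different spec (e.g. a weak-bias uniform
    species among strongly biased ones).

    The first ``n_species - 1`` (or all, without an outlier) share
    ``shared_spec`` with per-species sampling seeds derived
    deterministically from its seed, while all sharing the same
    generating distribution (``distribution_seed`` pinned to the shared
    spec's seed), so panel members are noisy replicates of one
    codon-usage profile; the last species uses ``outlier_spec`` when
    given.
    """
    if n_species < 2:
        raise ValueError("panel needs at least 2 species")
    panel: dict[str, list[GeneRecord]] = {}
    truths: dict[str, SyntheticTruth] = {}
    shared_dseed = (
        shared_spec.seed
        if shared_spec.distribution_seed is None
        else shared_spec.distribution_seed
    )
    n_shared = n_species - 1 if outlier_spec is not None else n_species
    for i in range(n_shared):
        label = f"species_{i + 1:02d}"
        sp = dataclasses.replace(
            shared_spec,
            seed=child_seed(shared_spec.seed, i),
            distribution_seed=shared_dseed,
        )
        panel[label], truths[label] = generate(sp, species_label=label)
    if outlier_spec is not None:
        label = "outlier"
        sp = dataclasses.replace(
            outlier_spec, seed=child_seed(outlier_spec.seed, n_species - 1)
        )
        panel[label], truths[label] = generate(sp, species_label=label)
    return panel, truths


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write ground truth as a plain key=value text file."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"species={truth.species_label}\n")
        fh.write(f"seed={truth.spec.seed}\n")
        fh.write(f"table_id={truth.spec.table_id}\n")
        fh.write(f"regime={truth.spec.regime}\n")
        fh.write(f"gc3_target={truth.spec.gc3_target}\n")
        fh.write(f"bias_concentration={truth.spec.bias_concentration}\n")
        for g in truth.genes:
            fh.write(f"gene={g.gene_name}\trealized_gc3={g.realized_gc3:.6f}\n")
            for codon in sorted(g.family_probs):
                fh.write(
                    f"prob\t{g.gene_name}\t{codon}\t{g.family_probs[codon]:.8f}\n"
                )
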