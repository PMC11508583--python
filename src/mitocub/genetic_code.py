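"""Genetic-code tables and their synonymous-family structure.

Every codon-bias statistic in this package (RSCU, GC3s, Wright's effective
number of codons) is defined on the partition of sense codons into
synonymous families — the sets of codons translating to the same amino
acid.  This module builds that partition from the NCBI translation tables
shipped with Biopython and exposes the degeneracy-class census that
Wright's ENC estimator averages over.

The default table is NCBI transl_table 5, the invertebrate mitochondrial
code (ATA=Met, TGA=Trp, AGA/AGG=Ser; stops TAA and TAG only), the code
used by insect mitochondrial protein-coding genes.  Table 1 (the standard
code) is also registered for generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Data import CodonTable as _NcbiCodonTable

__all__ = [
    "GeneticCode",
    "SynonymousFamily",
    "InvalidCodonError",
    "UnsupportedCodeError",
    "STOP",
    "build_code",
    "family_of",
]

#: Translation symbol used for stop codons throughout the package.
STOP = "*"

_BASES = "ACGT"
_SUPPORTED_TABLES = (1, 5)

_U_TO_T = str.maketrans("Uu", "Tt")


class UnsupportedCodeError(ValueError):
    """Raised for a translation-table id outside the registry."""


class InvalidCodonError(ValueError):
    """Raised for a string that is not an unambiguous DNA/RNA triplet."""


def normalize_codon(codon: str) -> str:
    """Return the canonical DNA-uppercase form of ``codon``.

    RNA input (U) is accepted and mapped to T.  Raises
    :class:`InvalidCodonError` for anything that is not an unambiguous
    triplet over {A, C, G, T, U}.
    """
    c = codon.strip().upper().translate(_U_TO_T)
    if len(c) != 3 or any(b not in _BASES for b in c):
        raise InvalidCodonError(f"not an unambiguous codon: {codon!r}")
    return c


@dataclass(frozen=True)
class SynonymousFamily:
    """One amino acid's set of synonymous codons.

    ``degeneracy`` is the family size k, the quantity that appears as the
    expected-uniform denominator of RSCU and indexes the degeneracy
    classes of Wright's ENC.
    """

    amino_acid: str
    codons: tuple[str, ...]
    degeneracy: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "degeneracy", len(self.codons))


@dataclass(frozen=True)
class GeneticCode:
    """A validated genetic code with derived synonymous families."""

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: frozenset[str]
    families: tuple[SynonymousFamily, ...]

    # -- derived lookups ------------------------------------------------
    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(
            sorted(c for c, aa in self.codon_to_aa.items() if aa == STOP)
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(
            sorted(c for c, aa in self.codon_to_aa.items() if aa != STOP)
        )

    @property
    def n_sense_codons(self) -> int:
        return len(self.sense_codons)

    def family_by_aa(self, amino_acid: str) -> SynonymousFamily:
        for fam in self.families:
            if fam.amino_acid == amino_acid:
                return fam
        raise KeyError(amino_acid)

    def degeneracy_census(self) -> dict[int, int]:
        """Map degeneracy k -> number of families of that size (N_k)."""
        census: dict[int, int] = {}
        for fam in self.families:
            census[fam.degeneracy] = census.get(fam.degeneracy, 0) + 1
        return dict(sorted(census.items()))

    def translate_codon(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]


def _derive_families(codon_to_aa: Mapping[str, str]) -> tuple[SynonymousFamily, ...]:
    by_aa: dict[str, list[str]] = {}
    for codon in sorted(codon_to_aa):
        aa = codon_to_aa[codon]
        if aa == STOP:
            continue
        by_aa.setdefault(aa, []).append(codon)
    return tuple(
        SynonymousFamily(aa, tuple(codons)) for aa, codons in sorted(by_aa.items())
    )


def build_code(table_id: int) -> GeneticCode:
    """Build a validated :class:`GeneticCode` from the NCBI registry.

    Parameters
    ----------
    table_id
        NCBI translation-table number.  Supported: 1 (standard) and
        5 (invertebrate mitochondrial).

    Raises
    ------
    UnsupportedCodeError
        If ``table_id`` is not in the registry.
    """
    if table_id not in _SUPPORTED_TABLES:
        raise UnsupportedCodeError(
            f"translation table {table_id} not supported "
            f"(registered tables: {_SUPPORTED_TABLES})"
        )
    ncbi = _NcbiCodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = {c: aa for c, aa in ncbi.forward_table.items()}
    for stop in ncbi.stop_codons:
        codon_to_aa[stop] = STOP
    if len(codon_to_aa) != 64:
        raise AssertionError("NCBI table does not cover all 64 codons")
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(ncbi.start_codons),
        families=_derive_families(codon_to_aa),
    )


def family_of(code: GeneticCode, codon: str) -> SynonymousFamily | None:
    """Return the synonymous family containing ``codon``.

    Stop codons return ``None`` (the distinguished STOP marker: they
    belong to no synonymous family).  Invalid or ambiguous triplets raise
    :class:`InvalidCodonError`.
    """
    c = normalize_codon(codon)
    if code.codon_to_aa[c] == STOP:
        return None
    return code.family_by_aa(code.codon_to_aa[c])
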