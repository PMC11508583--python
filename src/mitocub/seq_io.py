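"""Reading CDS sets, validating reading frames, and writing tables.

Input formats are multi-FASTA (header ``species|gene`` or a caller-supplied
species label) and GenBank flat files (CDS features; minus-strand features
are reverse-complemented into coding orientation).  Gene names are
normalized through an editable alias table so that COI/COX1, CYTB/COB,
NAD2/ND2 and similar annotation variants map onto the 13 canonical
mitochondrial protein-coding gene names.

Validation is report-only: a truncated terminal stop (1–2 nt beyond the
last full codon, completed by polyadenylation in many mitogenomes) is
flagged, not rejected, and internal stops are reported loudly but never
silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .genetic_code import STOP, GeneticCode

__all__ = [
    "GeneRecord",
    "ValidationReport",
    "PCG_NAMES",
    "DEFAULT_GENE_ALIASES",
    "read_species_cds",
    "validate_cds",
    "write_table",
    "write_fasta",
]

logger = logging.getLogger(__name__)

#: The 13 protein-coding genes of the animal mitochondrial genome.
PCG_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
)

#: Annotation variants seen in NCBI mitogenome records, mapped to the
#: canonical names above.  Keys are matched case-insensitively after
#: stripping spaces, hyphens and underscores.
DEFAULT_GENE_ALIASES: dict[str, str] = {
    "COI": "COX1", "CO1": "COX1", "COXI": "COX1",
    "COII": "COX2", "CO2": "COX2", "COXII": "COX2",
    "COIII": "COX3", "CO3": "COX3", "COXIII": "COX3",
    "COB": "CYTB", "CYB": "CYTB", "CYTOCHROMEB": "CYTB",
    "NAD1": "ND1", "NADH1": "ND1",
    "NAD2": "ND2", "NADH2": "ND2",
    "NAD3": "ND3", "NADH3": "ND3",
    "NAD4": "ND4", "NADH4": "ND4",
    "NAD4L": "ND4L", "NADH4L": "ND4L",
    "NAD5": "ND5", "NADH5": "ND5",
    "NAD6": "ND6", "NADH6": "ND6",
    "ATPASE6": "ATP6", "ATPASE8": "ATP8",
}

_VALID_BASES = frozenset("ACGT")
_U_TO_T = str.maketrans("Uu", "Tt")


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene sequence for one species."""

    species_label: str
    gene_name: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper().translate(_U_TO_T)
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 6:
            raise ValueError(
                f"{self.species_label}/{self.gene_name}: sequence shorter "
                f"than 6 nt ({len(seq)})"
            )

    @property
    def n_full_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list[str]:
        """The full triplets of the sequence (trailing 1–2 nt dropped)."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, 3 * (len(s) // 3), 3)]


@dataclass(frozen=True)
class ValidationReport:
    """Report-only frame/stop inspection of one gene.

    ``terminal_stop`` is one of ``complete`` (last full codon is a stop),
    ``truncated`` (1–2 trailing nt past the last full codon, read as a
    polyadenylation-completed stop) or ``absent``.
    ``internal_stop_positions`` are 0-based codon indices and never
    include the final codon.
    """

    frame_ok: bool
    start_codon_ok: bool
    terminal_stop: str
    internal_stop_positions: tuple[int, ...]
    ambiguous_codon_count: int

    @property
    def clean(self) -> bool:
        return (
            self.frame_ok
            and self.start_codon_ok
            and not self.internal_stop_positions
        )


def normalize_gene_name(
    raw: str, aliases: Mapping[str, str] | None = None
) -> str | None:
    """Map an annotation gene name onto a canonical PCG name.

    Returns ``None`` if the name cannot be resolved.
    """
    table = DEFAULT_GENE_ALIASES if aliases is None else dict(aliases)
    key = raw.strip().upper().replace(" ", "").replace("-", "").replace("_", "")
    if key in PCG_NAMES:
        return key
    return table.get(key)


def _records_from_fasta(
    path: Path, species_label: str | None, aliases: Mapping[str, str] | None
) -> Iterable[GeneRecord]:
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            species, raw_gene = header.split("|", 1)
        else:
            species, raw_gene = species_label or path.stem, header
        gene = normalize_gene_name(raw_gene, aliases)
        if gene is None:
            warnings.warn(
                f"{path.name}:{header}: unresolvable gene name "
                f"{raw_gene!r}; keeping raw name"
            )
            gene = raw_gene.strip()
        yield GeneRecord(
            species_label=species.strip(),
            gene_name=gene,
            sequence=str(rec.seq),
            source=f"{path.name}:{header}",
        )


def _records_from_genbank(
    path: Path, species_label: str | None, aliases: Mapping[str, str] | None
) -> Iterable[GeneRecord]:
    for rec in SeqIO.parse(str(path), "genbank"):
        species = species_label or rec.annotations.get("organism", rec.id)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            raw_gene = (quals.get("gene") or quals.get("product") or ["?"])[0]
            gene = normalize_gene_name(raw_gene, aliases)
            if gene is None:
                warnings.warn(
                    f"{path.name}:{rec.id}: unresolvable gene name "
                    f"{raw_gene!r}; keeping raw name"
                )
                gene = raw_gene.strip()
            # extract() honours strand: minus-strand CDS come back 5'->3'
            # in coding sense.
            seq = str(feat.extract(rec.seq))
            yield GeneRecord(
                species_label=str(species).strip(),
                gene_name=gene,
                sequence=seq,
                source=f"{path.name}:{rec.id}:{feat.location}",
            )


def read_species_cds(
    path: str | Path,
    fmt: str = "fasta",
    species_label: str | None = None,
    gene_aliases: Mapping[str, str] | None = None,
) -> list[GeneRecord]:
    """Read one GeneRecord per CDS from a FASTA or GenBank file.

    FASTA headers of the form ``species|gene`` carry their own species
    label; otherwise ``species_label`` (or the file stem) is used.
    GenBank CDS features are extracted in coding orientation with the
    ``/gene`` or ``/product`` qualifier as the raw gene name.
    """
    path = Path(path)
    if fmt == "fasta":
        records = list(_records_from_fasta(path, species_label, gene_aliases))
    elif fmt == "genbank":
        records = list(_records_from_genbank(path, species_label, gene_aliases))
    else:
        raise ValueError(f"unsupported format: {fmt!r} (use 'fasta' or 'genbank')")
    if not records:
        raise ValueError(f"{path}: no CDS records found")
    return records


def validate_cds(rec: GeneRecord, code: GeneticCode) -> ValidationReport:
    """Inspect start codon, terminal stop and internal stops of one CDS.

    Never mutates the sequence; downstream codon metrics consume exactly
    ``len(seq) // 3`` codons regardless of the flags raised here.
    """
    seq = rec.sequence
    codons = rec.codons()
    overhang = len(seq) % 3

    ambiguous = sum(1 for c in codons if not set(c) <= _VALID_BASES)

    def aa(c: str) -> str | None:
        if not set(c) <= _VALID_BASES:
            return None
        return code.codon_to_aa[c]

    start_ok = codons[0] in code.start_codons

    if overhang:
        # 1-2 trailing nt: mitochondrial genes completed by polyadenylation.
        terminal = "truncated"
        body = codons
    elif codons and aa(codons[-1]) == STOP:
        terminal = "complete"
        body = codons[:-1]
    else:
        terminal = "absent"
        body = codons

    internal = tuple(i for i, c in enumerate(body) if aa(c) == STOP)
    if internal:
        logger.warning(
            "%s/%s: internal stop codon(s) at codon index %s — likely "
            "annotation error; excluded from metrics",
            rec.species_label, rec.gene_name, list(internal),
        )

    return ValidationReport(
        frame_ok=True,
        start_codon_ok=start_ok,
        terminal_stop=terminal,
        internal_stop_positions=internal,
        ambiguous_codon_count=ambiguous,
    )


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
    float_precision: int = 3,
) -> None:
    """Write rows as a TSV with fixed column order and float precision.

    An empty row list yields a header-only file (``columns`` must then be
    given).  Output is UTF-8 with Unix newlines.
    """
    if columns is None:
        if not rows:
            raise ValueError("columns required when rows is empty")
        columns = list(rows[0].keys())

    def fmt(v: object) -> str:
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return str(v)
        if isinstance(v, float):
            if v != v:  # NaN
                return "NA"
            return f"{v:.{float_precision}f}"
        return str(v)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row.get(c)) for c in columns) + "\n")


def write_fasta(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords as multi-FASTA with ``species|gene`` headers."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.species_label}|{rec.gene_name}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
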