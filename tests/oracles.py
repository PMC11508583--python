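"""Independent brute-force reference implementations used only by tests.

These recompute RSCU and Wright's ENC directly from a gene's codon
string with plain dictionaries and the written formulas, sharing no code
path with the package implementation.  The codon -> amino-acid map is
taken straight from Biopython's NCBI table, not from the package's
GeneticCode object.
"""

from __future__ import annotations

from Bio.Data import CodonTable


def _aa_map(table_id: int) -> dict[str, str]:
    t = CodonTable.unambiguous_dna_by_id[table_id]
    m = dict(t.forward_table)
    for s in t.stop_codons:
        m[s] = "*"
    return m


def brute_counts(seq: str, table_id: int) -> dict[str, int]:
    """Sense-codon counts: full triplets only, stops and ambiguous dropped."""
    aa = _aa_map(table_id)
    counts: dict[str, int] = {}
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3].upper()
        if any(b not in "ACGT" for b in codon):
            continue
        if aa[codon] == "*":
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return counts


def brute_rscu(seq: str, table_id: int) -> dict[str, float | None]:
    aa = _aa_map(table_id)
    counts = brute_counts(seq, table_id)
    families: dict[str, list[str]] = {}
    for codon, a in aa.items():
        if a != "*":
            families.setdefault(a, []).append(codon)
    out: dict[str, float | None] = {}
    for a, codons in families.items():
        total = sum(counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            out[c] = None if total == 0 else counts.get(c, 0) / (total / k)
    return out


def brute_enc(seq: str, table_id: int) -> float | None:
    """Wright's ENC evaluated step by step from the definition.

    Per amino acid with n >= 2: F = (n*sum(p^2) - 1)/(n - 1).  Per
    degeneracy class: mean of defined F values excluding zeros.  A class
    with no usable mean takes the average of the nearest available class
    below and above.  ENC = N1 + sum N_k / Fbar_k, capped at the number
    of sense codons.
    """
    aa = _aa_map(table_id)
    counts = brute_counts(seq, table_id)
    families: dict[str, list[str]] = {}
    for codon, a in aa.items():
        if a != "*":
            families.setdefault(a, []).append(codon)

    f_by_class: dict[int, list[float]] = {}
    census: dict[int, int] = {}
    for a, codons in families.items():
        k = len(codons)
        census[k] = census.get(k, 0) + 1
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1) / (n - 1)
        if f > 0:
            f_by_class.setdefault(k, []).append(f)

    means = {k: sum(v) / len(v) for k, v in f_by_class.items() if k >= 2}
    if not means:
        return None

    enc = float(census.get(1, 0))
    for k, n_k in census.items():
        if k == 1:
            continue
        if k in means:
            fbar = means[k]
        else:
            below = [kk for kk in means if kk < k]
            above = [kk for kk in means if kk > k]
            vals = []
            if below:
                vals.append(means[max(below)])
            if above:
                vals.append(means[min(above)])
            fbar = sum(vals) / len(vals)
        enc += n_k / fbar

    n_sense = sum(1 for c, a in aa.items() if a != "*")
    return min(enc, float(n_sense))
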