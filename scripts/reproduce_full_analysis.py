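#!/usr/bin/env python
"""Full-scale comparative analysis of the 29 downloaded mitogenomes.

Requires the GenBank files fetched by ``scripts/fetch_accessions.py``
(network); everything else runs offline.  Prints the headline numbers of
the cross-species analysis: the frequent/infrequent codon partition
sizes, per-species mean ENC (highlighting the weak-bias outlier
Parochlus steinenii), the per-gene selection tallies of the ENC-ratio
screen, and the annotation summary of the new Conchapelopia
togamaculosa record (PP831866).

Usage:
    python scripts/reproduce_full_analysis.py --data-dir data/mitogenomes --out-dir results/full_scale
"""

from __future__ import annotations

import argparse
from pathlib import Path

from Bio import SeqIO

from mitocub import (
    build_code,
    build_rscu_matrix,
    cluster_species,
    composition_stats,
    gene_metrics,
    partition_codons,
    read_species_cds,
    selection_summary,
    write_table,
)


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, required=True)
    ap.add_argument("--out-dir", type=Path, required=True)
    args = ap.parse_args()

    code = build_code(5)
    args.out_dir.mkdir(parents=True, exist_ok=True)

    gb_files = sorted(args.data_dir.glob("*.gb"))
    if not gb_files:
        raise SystemExit(f"no GenBank files in {args.data_dir}; "
                         "run scripts/fetch_accessions.py first")

    species_cds = {}
    for path in gb_files:
        records = read_species_cds(path, fmt="genbank")
        species_cds[records[0].species_label] = records

    # annotation summary of the newly sequenced genome
    new_rec_path = args.data_dir / "PP831866.gb"
    if new_rec_path.exists():
        rec = next(SeqIO.parse(str(new_rec_path), "genbank"))
        comp = composition_stats(str(rec.seq))
        n_genes = sum(1 for f in rec.features
                      if f.type in ("CDS", "tRNA", "rRNA"))
        print(f"PP831866: length={len(rec.seq)} bp, genes={n_genes}, "
              f"AT={comp.at_content:.1f}%, AT skew={comp.at_skew:.3f}, "
              f"GC skew={comp.gc_skew:.3f}")

    matrix = build_rscu_matrix(species_cds, code, mode="concatenated")
    part = partition_codons(matrix)
    print(f"codon partition: {len(part.frequent)} frequent / "
          f"{len(part.infrequent)} infrequent")

    metrics = [
        gene_metrics(r, code)
        for recs in species_cds.values()
        for r in recs
    ]
    summary = selection_summary(metrics)
    ranked = sorted(summary.per_species_mean_enc.items(),
                    key=lambda kv: -kv[1])
    print("species mean ENC (top 5):")
    for sp, enc in ranked[:5]:
        print(f"  {sp}: {enc:.1f}")
    print("per-gene selection counts (ENC ratio > 0.15):")
    for gene, n in sorted(summary.per_gene_selected.items(),
                          key=lambda kv: -kv[1]):
        print(f"  {gene}: {n} species")

    tree = cluster_species(matrix, subset=part.frequent)
    print("heatmap leaf order (frequent codons):", ", ".join(tree.leaf_order))

    write_table(
        [{"species": s, "mean_enc": e, "n_genes_selected":
          summary.per_species_selected.get(s)}
         for s, e in ranked],
        args.out_dir / "species_summary.tsv",
        columns=["species", "mean_enc", "n_genes_selected"],
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
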