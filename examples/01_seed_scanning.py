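"""Scan 3' UTRs for miR-142 seed sites, exact and one-base-mutant.

Builds three tiny UTRs by hand, scans them with both arms' seed sets, and
classifies each gene.  ACTTTAT is the DNA reverse complement of the
miR-142-5p seed AUAAAGU, so GENE_A carries an exact 5p site; GENE_B
carries ACACTAg, one base off the 3p site ACACTAC, i.e. an inexact 3p
site; GENE_C is site-free.
"""

from coexmir import build_site_table, classify_genes, default_seed_table, scan_utr

utrs = {
    "GENE_A": "GGGACTTTATGGGACTTTATGG",   # two exact 5p sites
    "GENE_B": "TTTACACTAGTTT",            # one inexact 3p site (ACACTAG)
    "GENE_C": "CCCCCCCCCCCCCC",           # nothing
}

table = build_site_table(default_seed_table())
hits = []
for gene, seq in utrs.items():
    for hit in scan_utr(seq, table, gene_id=gene, transcript_id=f"{gene}.t1"):
        hits.append(hit)
        print(f"{gene}: {hit.quality} {hit.arm} site {hit.site_sequence} at position {hit.position}")

classes = classify_genes(hits, genes=list(utrs))
print("\nper-gene classification (exact beats inexact, arms combine to 'both'):")
for gene, cls in sorted(classes.items()):
    print(f"  {gene}: {cls}")
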