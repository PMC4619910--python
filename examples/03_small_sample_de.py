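"""Differential expression with three replicates per group.

Runs both small-sample tests on a synthetic matrix with ten planted DE
genes.  The exact rank-sum p for fully separated 3v3 groups is its floor,
2/C(6,3) = 0.1 — the reason DE filtering at alpha = 0.1 is done on raw
rank-sum p-values, while the pooled t-test can grade evidence more finely.
"""

from coexmir import SimulationConfig, call_de, simulate_expression
from coexmir.diffexp import de_table

config = SimulationConfig(
    n_genes=200, n_de_genes=10, de_shift=5.0, background_sd=0.3,
    utr_length_range=(60, 80), rng_seed=0,
)
matrix, truth = simulate_expression(config)

for test, adjust in (("wrs", "none"), ("t", "bh")):
    table = de_table(matrix, test=test, adjust=adjust)
    flagged = call_de(table, alpha=0.1)
    recovered = len(set(truth.de) & set(flagged["gene"]))
    print(
        f"{test} (adjust={adjust}): {len(flagged)} genes at p<=0.1, "
        f"{flagged.attrs['n_up']} up / {flagged.attrs['n_down']} down; "
        f"{recovered}/{len(truth.de)} planted DE genes recovered"
    )

wrs = de_table(matrix, test="wrs", adjust="none").set_index("gene")
gene = next(iter(truth.de))
print(
    f"\nexample planted gene {gene} ({truth.de[gene]}): "
    f"rank-sum W = {wrs.loc[gene, 'statistic']:.0f}, exact p = {wrs.loc[gene, 'p_raw']:.3f} "
    "(the 3v3 enumeration floor)"
)
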