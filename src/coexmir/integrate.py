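"""Network enrichment: seed classes + DE status on nodes, triad selection,
cross-tabulation, and Cytoscape-ready exports.

The node encoding follows the study's figure legend as plain string
attributes rather than rendered graphics: node *color* encodes the seed
mapping class (dark-red = exact 5p, pink = inexact 5p, dark-green = exact
3p, light-green = inexact 3p, blue = inexact both, plain = none; a
hypothetical exact-both node would be "dark-red+dark-green"), and node
*shape* encodes the DE call (down-arrow / up-arrow / ellipse).

A *triad* gene is one that is simultaneously (1) a node of the
overexpression network, (2) seed-mapped, and (3) called down-regulated —
the conjunction that singles out the genes most plausibly repressed by
the overexpressed miRNA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from coexmir.network import CoexpressionNetwork
from coexmir.reference import SEED_CLASSES

COLOR_KEYS: dict[str, str] = {
    "exact-5p": "dark-red",
    "inexact-5p": "pink",
    "exact-3p": "dark-green",
    "inexact-3p": "light-green",
    "inexact-both": "blue",
    "exact-both": "dark-red+dark-green",
    "none": "plain",
}

SHAPE_KEYS: dict[str, str] = {"down": "down-arrow", "up": "up-arrow", "ns": "ellipse"}


def annotate_network(
    networks: Mapping[str, CoexpressionNetwork],
    seed_classes: Mapping[str, str],
    de_calls: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One annotated record per gene appearing in any network.

    ``seed_classes`` maps gene -> class (genes absent default to "none");
    ``de_calls`` is a flagged DE frame with gene/direction/log2fc columns
    (genes absent default to "ns").  Columns of the result: gene,
    seed_class, color_key, de_status, shape_key, log2fc, plus one boolean
    ``in_<condition>`` column per network.
    """
    if de_calls is not None and de_calls["gene"].duplicated().any():
        dupes = de_calls.loc[de_calls["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicate gene records in DE table: {dupes}")
    de_map = (
        {r.gene: (r.direction, r.log2fc) for r in de_calls.itertuples(index=False)}
        if de_calls is not None
        else {}
    )
    all_genes = sorted(set().union(*(net.nodes for net in networks.values())) if networks else set())
    rows = []
    for gene in all_genes:
        seed_class = seed_classes.get(gene, "none")
        if seed_class not in COLOR_KEYS:
            raise ValueError(f"unknown seed class {seed_class!r} for gene {gene}")
        de_status, log2fc = de_map.get(gene, ("ns", float("nan")))
        row = {
            "gene": gene,
            "seed_class": seed_class,
            "color_key": COLOR_KEYS[seed_class],
            "de_status": de_status,
            "shape_key": SHAPE_KEYS[de_status],
            "log2fc": log2fc,
        }
        for cond, net in networks.items():
            row[f"in_{cond}"] = gene in net.nodes
        rows.append(row)
    columns = ["gene", "seed_class", "color_key", "de_status", "shape_key", "log2fc"] + [
        f"in_{cond}" for cond in networks
    ]
    return pd.DataFrame(rows, columns=columns)


def select_triad(annotated: pd.DataFrame, condition: str = "mir142") -> list[str]:
    """Genes in the condition's network that are seed-mapped and DE-down.

    Deterministically ordered by gene id.
    """
    col = f"in_{condition}"
    if col not in annotated.columns:
        raise ValueError(f"no membership column for condition {condition!r}")
    mask = annotated[col] & (annotated["seed_class"] != "none") & (annotated["de_status"] == "down")
    return sorted(annotated.loc[mask, "gene"])


def summarize_mapping_by_network(annotated: pd.DataFrame) -> pd.DataFrame:
    """Node counts per seed class and network, plus mapped fractions.

    Rows are the six mapped classes; columns one per network.  The frame's
    ``.attrs['mapped_fraction']`` maps each condition to
    (mapped nodes) / (network size); ``.attrs['n_nodes']`` gives sizes.
    """
    conditions = [c.removeprefix("in_") for c in annotated.columns if c.startswith("in_")]
    counts = pd.DataFrame(0, index=list(SEED_CLASSES), columns=conditions, dtype=int)
    sizes: dict[str, int] = {}
    fractions: dict[str, float] = {}
    for cond in conditions:
        members = annotated.loc[annotated[f"in_{cond}"]]
        sizes[cond] = len(members)
        mapped = members.loc[members["seed_class"] != "none"]
        for cls, n in mapped["seed_class"].value_counts().items():
            counts.loc[cls, cond] = int(n)
        fractions[cond] = len(mapped) / len(members) if len(members) else 0.0
    counts.attrs["n_nodes"] = sizes
    counts.attrs["mapped_fraction"] = fractions
    return counts


# ---------------------------------------------------------------------------
# Cytoscape interchange
# ---------------------------------------------------------------------------

def write_sif(network: CoexpressionNetwork, path: str | Path) -> None:
    """Simple interaction format: one ``geneA coexp geneB`` line per edge."""
    lines = [
        f"{a}\tcoexp\t{b}"
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_node_attributes(annotated: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene", "seed_class", "color_key", "de_status", "shape_key", "log2fc"]
    annotated[cols].to_csv(path, sep="\t", index=False)


def write_graphml(
    network: CoexpressionNetwork, annotated: pd.DataFrame, path: str | Path
) -> None:
    """GraphML export carrying edge r and the node display attributes."""
    graph = nx.Graph(network.graph)
    attrs = annotated.set_index("gene")
    for node in graph.nodes:
        if node in attrs.index:
            rec = attrs.loc[node]
            graph.nodes[node].update(
                seed_class=str(rec["seed_class"]),
                color_key=str(rec["color_key"]),
                de_status=str(rec["de_status"]),
                shape_key=str(rec["shape_key"]),
            )
    nx.write_graphml(graph, str(path))


def write_triad(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("gene\n" + "".join(f"{g}\n" for g in genes))
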