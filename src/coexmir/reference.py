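"""Published summary counts from the GSE50133 miR-142 overexpression study.

The raw microarray data (NCBI GEO accession GSE50133: three miR-null and
three miR-142-overexpressing neuronal clones) is not redistributed here;
what the study reports publicly are summary counts, and those are shipped
as fixtures so that the pipeline's statistics can be exercised and checked
against them:

* per-condition network sizes (nodes, edges) of the two coexpression
  networks built at the r >= 0.9998 threshold;
* counts of network nodes per seed-mapping class, plus genome-wide
  seed-mapped gene counts;
* counts of differentially expressed genes (BH-adjusted p <= 0.1; 85 in
  total, 60 down / 25 up) cross-tabulated with seed-mapping class.

The two 3x2 cross-tabulations fed to the chi-square test are the natural
collapses of these tables: arm (5p / 3p / both) against mapping quality
(exact / inexact, node counts summed over both networks), and arm against
regulation direction (down / up, exact + inexact DE counts summed per arm).
"""

from __future__ import annotations

import pandas as pd

SEED_CLASSES = (
    "exact-5p",
    "exact-3p",
    "exact-both",
    "inexact-5p",
    "inexact-3p",
    "inexact-both",
)

#: (nodes, edges) of the two published coexpression networks.
NETWORK_SIZES: dict[str, tuple[int, int]] = {
    "null": (57, 217),
    "mir142": (52, 158),
}

#: Network nodes (and genome-wide genes) per seed-mapping class.
NODE_CLASS_COUNTS = pd.DataFrame(
    {
        "null": [9, 1, 0, 7, 7, 9],
        "mir142": [6, 2, 0, 7, 8, 4],
        "genome": [2914, 720, 387, 3644, 2520, 4820],
    },
    index=list(SEED_CLASSES),
)

#: Differentially expressed genes (down / up) per seed-mapping class.
DE_CLASS_COUNTS = pd.DataFrame(
    {
        "down": [12, 3, 2, 9, 5, 12],
        "up": [12, 1, 1, 2, 1, 3],
    },
    index=list(SEED_CLASSES),
)

#: Total DE genes per direction including genes with no seed mapping.
DE_TOTALS = {"down": 60, "up": 25}


def arm_by_quality_table() -> pd.DataFrame:
    """3x2 table: arm (5p/3p/both) x mapping quality (exact/inexact).

    Node counts summed over both networks; the chi-square on this table
    asks whether exact vs inexact mapping is independent of the arm.
    """
    counts = NODE_CLASS_COUNTS[["null", "mir142"]].sum(axis=1)
    return pd.DataFrame(
        {
            "exact": [counts["exact-5p"], counts["exact-3p"], counts["exact-both"]],
            "inexact": [counts["inexact-5p"], counts["inexact-3p"], counts["inexact-both"]],
        },
        index=["5p", "3p", "both"],
    )


def arm_by_direction_table() -> pd.DataFrame:
    """3x2 table: arm (5p/3p/both) x regulation direction (down/up).

    Exact and inexact DE-gene counts summed per arm; the chi-square on this
    table asks whether up/down regulation prefers either arm.
    """
    rows = {}
    for arm, exact_cls, inexact_cls in (
        ("5p", "exact-5p", "inexact-5p"),
        ("3p", "exact-3p", "inexact-3p"),
        ("both", "exact-both", "inexact-both"),
    ):
        rows[arm] = DE_CLASS_COUNTS.loc[exact_cls] + DE_CLASS_COUNTS.loc[inexact_cls]
    return pd.DataFrame(rows).T[["down", "up"]]


def mapped_de_summary() -> dict:
    """Totals of seed-mapped DE genes and their fraction of all DE genes."""
    mapped = DE_CLASS_COUNTS.sum()
    n_total = sum(DE_TOTALS.values())
    n_mapped = int(mapped.sum())
    return {
        "n_de": n_total,
        "n_mapped": n_mapped,
        "n_mapped_down": int(mapped["down"]),
        "n_mapped_up": int(mapped["up"]),
        "mapped_fraction": n_mapped / n_total,
    }


def mapped_node_fraction(condition: str) -> dict:
    """Fraction of a network's nodes carrying any seed mapping."""
    n_nodes = NETWORK_SIZES[condition][0]
    n_mapped = int(NODE_CLASS_COUNTS[condition].sum())
    return {
        "condition": condition,
        "n_nodes": n_nodes,
        "n_mapped": n_mapped,
        "mapped_fraction": n_mapped / n_nodes,
    }
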