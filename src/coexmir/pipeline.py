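"""End-to-end pipeline: simulate (optional) -> scan seeds -> DE ->
per-condition networks -> integrate -> summary statistics.

Every run writes its artifacts plus a ``manifest.json`` listing output
files with SHA-256 checksums and the effective configuration, so repeated
runs under the same seed are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from coexmir import io as cio
from coexmir.diffexp import call_de, de_table
from coexmir.integrate import (
    annotate_network,
    select_triad,
    summarize_mapping_by_network,
    write_graphml,
    write_node_attributes,
    write_sif,
    write_triad,
)
from coexmir.network import (
    DEFAULT_R_MIN,
    compare_networks,
    coexpression_network,
    network_stats,
)
from coexmir.seeds import classify_genes, default_seed_table, scan_utrs, seed_set
from coexmir.simulate import SimulationConfig, simulate
from coexmir.stats import pearson_chisq

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run.

    Either ``simulate`` is set (inputs are generated) or all three input
    paths must point at existing files.
    """

    out_dir: str | Path = "coexmir_out"
    expression_tsv: str | Path | None = None
    conditions_yaml: str | Path | None = None
    utr_fasta: str | Path | None = None
    simulate: SimulationConfig | None = None
    seed_5p: str = "AUAAAGU"
    seed_3p: str = "GUAGUGU"
    network_mode: str = "r-threshold"
    r_min: float = DEFAULT_R_MIN
    alpha_network: float = 0.05
    de_test: str = "wrs"
    de_alpha: float = 0.1
    de_adjust: str = "none"
    conditions: tuple[str, str] = ("null", "mir142")

    def validate(self) -> None:
        if self.simulate is None:
            for name in ("expression_tsv", "conditions_yaml", "utr_fasta"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"{name} missing or not found: {path}")


@dataclass
class PipelineResult:
    networks: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)
    truth: object | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the output bundle + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    stage = "setup"
    try:
        # -- inputs -----------------------------------------------------
        if config.simulate is not None:
            stage = "simulate"
            matrix, utr_records, truth = simulate(config.simulate)
            result.truth = truth
            cio.write_expression_tsv(matrix, out / "expression.tsv", out / "conditions.yaml")
            cio.write_fasta(utr_records, out / "utrs.fasta")
            (out / "ground_truth.json").write_text(truth.to_json())
        else:
            stage = "load-inputs"
            matrix = cio.read_expression_tsv(config.expression_tsv, config.conditions_yaml)
            utr_records = cio.read_fasta(config.utr_fasta)

        # -- seed mapping ----------------------------------------------
        stage = "map-seeds"
        seeds = default_seed_table(config.seed_5p, config.seed_3p)
        hits = scan_utrs(utr_records, seeds)
        classes = classify_genes(hits, genes=[g for g, _, _ in utr_records])
        cio.write_hits_tsv(hits, out / "seed_hits.tsv")
        cio.write_classes_tsv(classes, out / "seed_classes.tsv")

        # -- differential expression -------------------------------------
        stage = "diffexp"
        table = de_table(matrix, test=config.de_test, adjust=config.de_adjust)
        flagged = call_de(table, alpha=config.de_alpha)
        cio.write_de_tsv(table, out / "de_all.tsv")
        cio.write_de_tsv(flagged, out / "de_flagged.tsv")

        # -- networks -----------------------------------------------------
        stage = "network"
        networks = {}
        for cond in config.conditions:
            net = coexpression_network(
                matrix, cond, mode=config.network_mode,
                alpha=config.alpha_network, r_min=config.r_min,
            )
            networks[cond] = net
            write_sif(net, out / f"network_{cond}.sif")
        result.networks = networks
        overlap = compare_networks(*networks.values())

        # -- integration --------------------------------------------------
        stage = "integrate"
        annotated = annotate_network(networks, classes, flagged)
        write_node_attributes(annotated, out / "node_attributes.tsv")
        for cond, net in networks.items():
            write_graphml(net, annotated, out / f"network_{cond}.graphml")
        triad = select_triad(annotated, condition=config.conditions[1])
        write_triad(triad, out / "triad_genes.tsv")
        mapping_counts = summarize_mapping_by_network(annotated)

        # -- statistics ---------------------------------------------------
        stage = "stats"
        stats: dict = {
            "network": {
                cond: dataclasses.asdict(network_stats(net)) for cond, net in networks.items()
            },
            "r_min_retained": {
                cond: net.r_min_retained for cond, net in networks.items()
            },
            "overlap": {k: v for k, v in overlap.items() if k.startswith(("n_", "node", "edge"))},
            "de": {
                "test": config.de_test,
                "alpha": config.de_alpha,
                "adjust": config.de_adjust,
                "n_flagged": int(len(flagged)),
                "n_up": flagged.attrs["n_up"],
                "n_down": flagged.attrs["n_down"],
            },
            "triad": triad,
            "mapping_counts": mapping_counts.to_dict(),
            "mapped_fraction": mapping_counts.attrs["mapped_fraction"],
        }
        arm_quality = _arm_quality_table(mapping_counts)
        if arm_quality is not None:
            chi = pearson_chisq(arm_quality)
            stats["chi2_arm_by_quality"] = {"chi2": chi.chi2, "df": chi.df, "p": chi.p}
        (out / "stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True))
        result.stats = stats

        # -- manifest -----------------------------------------------------
        stage = "manifest"
        outputs = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
        manifest = {
            "config": _config_dict(config),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        result.outputs = {p.name: p for p in outputs}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return result


def _arm_quality_table(mapping_counts):
    """Collapse per-network class counts to arm x quality; None if a margin is empty."""
    summed = mapping_counts.sum(axis=1)
    table = [
        [summed.get("exact-5p", 0), summed.get("inexact-5p", 0)],
        [summed.get("exact-3p", 0), summed.get("inexact-3p", 0)],
        [summed.get("exact-both", 0), summed.get("inexact-both", 0)],
    ]
    import numpy as np

    arr = np.asarray(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return None
    return table


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    for key, value in d.items():
        if isinstance(value, Path):
            d[key] = str(value)
    return d
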