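"""Synthetic data with planted ground truth for the full pipeline.

Emulates the statistical structure of a 3-vs-3 miRNA-overexpression
microarray study so that every downstream stage (seed scanning, network
construction, differential expression, integration) can be tested against
known truth:

* **Expression**: log2-scale values around a common baseline.  Each
  planted clique shares one latent profile within its condition plus
  independent noise of small sd (``clique_noise_sd``), giving
  within-clique correlations that approach 1 as the noise vanishes; in the
  other condition clique members are plain background.  Planted DE genes
  get an additive mean shift (log2 units) in the overexpression group.
  All remaining genes are i.i.d. background.
* **UTRs**: one record per gene.  Background sequence is rejection-sampled
  so that it contains *no* exact or one-base-mutant site of either arm;
  requested sites are then written in at recorded positions, so the
  scanner's output must equal the manifest exactly.

The generator does not attempt probe-level microarray artifacts,
normalization effects or batch structure; it produces the idealized
log-scale matrix the analysis assumes as input.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexmir.expression import ExpressionMatrix
from coexmir.seeds import Seed, build_site_table, default_seed_table, seed_set, seed_to_site

_SITE_LEN = 7
_DNA = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class PlantedSite:
    """One requested seed site: gene, arm, exact/inexact, occurrence count."""

    gene: str
    arm: str  # "5p" | "3p"
    quality: str  # "exact" | "inexact"
    count: int = 1


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror a small two-condition microarray design: 2000 genes,
    three replicates per condition, two near-perfect cliques planted in
    each condition (disjoint memberships), ten DE genes with a large
    log2 shift, and a mix of planted seed sites covering every mapping
    class.  Gene ids are ``G0000 .. G{n-1}``; clique genes are assigned
    first (null cliques, then mir142 cliques), DE genes next — overlapping
    the first mir142 clique so that network+seed+DE triad genes exist.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    modules_null: tuple[int, ...] = (8, 6)
    modules_mir142: tuple[int, ...] = (7, 5)
    n_de_genes: int = 10
    de_shift: float = 5.0
    clique_noise_sd: float = 1e-4
    background_sd: float = 0.5
    baseline_mean: float = 8.0
    utr_length_range: tuple[int, int] = (200, 400)
    planted_sites: list[PlantedSite] | None = None
    seed_5p: str = "AUAAAGU"
    seed_3p: str = "GUAGUGU"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_de_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_per_group < 3:
            raise ValueError("need at least 3 samples per group")
        if any(s <= 1 for s in (*self.modules_null, *self.modules_mir142)):
            raise ValueError("clique sizes must be >= 2")
        if self.clique_noise_sd >= self.background_sd:
            raise ValueError("clique_noise_sd must be smaller than background_sd")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        n_clique = sum(self.modules_null) + sum(self.modules_mir142)
        if n_clique > self.n_genes:
            raise ValueError("clique sizes exceed n_genes")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        lo, hi = self.utr_length_range
        if lo < _SITE_LEN or hi < lo:
            raise ValueError("invalid utr_length_range")
        if self.planted_sites is None:
            self.planted_sites = self._default_planted_sites()
        self._validate_planted()

    # -- gene id layout -------------------------------------------------
    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes - 1)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def clique_members(self) -> dict[str, list[list[str]]]:
        """Clique memberships per condition, assigned from the front."""
        ids = self.gene_ids()
        out: dict[str, list[list[str]]] = {"null": [], "mir142": []}
        cursor = 0
        for cond, sizes in (("null", self.modules_null), ("mir142", self.modules_mir142)):
            for size in sizes:
                out[cond].append(ids[cursor : cursor + size])
                cursor += size
        return out

    def de_genes(self) -> dict[str, str]:
        """Planted DE genes -> direction.

        The first min(2, n_de) DE genes are drawn from the first mir142
        clique (down-regulated), so triad genes exist by construction; the
        rest come from the background block after all cliques.  The first
        half (rounded up) is down, the remainder up.
        """
        if self.n_de_genes == 0:
            return {}
        ids = self.gene_ids()
        cliques = self.clique_members()
        n_from_clique = min(2, self.n_de_genes, len(cliques["mir142"][0]) if cliques["mir142"] else 0)
        chosen = list(cliques["mir142"][0][:n_from_clique]) if n_from_clique else []
        cursor = sum(self.modules_null) + sum(self.modules_mir142)
        while len(chosen) < self.n_de_genes:
            if cursor >= self.n_genes:
                raise ValueError("not enough background genes for n_de_genes")
            chosen.append(ids[cursor])
            cursor += 1
        n_down = (self.n_de_genes + 1) // 2
        return {g: ("down" if i < n_down else "up") for i, g in enumerate(chosen)}

    def _default_planted_sites(self) -> list[PlantedSite]:
        ids = self.gene_ids()
        cliques = self.clique_members()
        sites: list[PlantedSite] = []
        # triad candidates: mir142-clique DE-down genes get exact 5p sites
        for g in list(self.de_genes())[: min(2, self.n_de_genes)]:
            sites.append(PlantedSite(g, "5p", "exact", 1))
        # cover the remaining classes on background genes (from the back)
        tail = [g for g in reversed(ids) if g not in {s.gene for s in sites}]
        specs = [
            ("3p", "exact", 1),
            ("5p", "exact", 2),  # multiple occurrences on one gene
            ("5p", "inexact", 1),
            ("3p", "inexact", 1),
        ]
        for (arm, quality, count), gene in zip(specs, tail):
            sites.append(PlantedSite(gene, arm, quality, count))
        if len(tail) > len(specs):  # an inexact-both gene
            g = tail[len(specs)]
            sites.append(PlantedSite(g, "5p", "inexact", 1))
            sites.append(PlantedSite(g, "3p", "inexact", 1))
        if cliques["null"]:  # a null-network node with a site
            g = cliques["null"][0][0]
            if g not in {s.gene for s in sites}:
                sites.append(PlantedSite(g, "3p", "exact", 1))
        return sites

    def _validate_planted(self) -> None:
        known = set(self.gene_ids())
        for cond, sizes in (("null", self.modules_null), ("mir142", self.modules_mir142)):
            members = self.clique_members()[cond]
            flat = [g for clique in members for g in clique]
            if len(flat) != len(set(flat)):
                raise ValueError(f"gene assigned to two cliques of condition {cond}")
        for site in self.planted_sites or []:
            if site.gene not in known:
                raise ValueError(f"planted site on unknown gene {site.gene!r}")
            if site.arm not in ("5p", "3p") or site.quality not in ("exact", "inexact"):
                raise ValueError(f"invalid planted site spec {site!r}")
            if site.count < 0:
                raise ValueError("site count must be nonnegative")


@dataclass
class GroundTruth:
    """Everything the generator planted, in analysis-ready form."""

    cliques: dict[str, list[list[str]]] = field(default_factory=lambda: {"null": [], "mir142": []})
    de: dict[str, str] = field(default_factory=dict)  # gene -> "up"/"down"
    sites: list[dict] = field(default_factory=list)  # gene/transcript/arm/quality/position/site
    rng_seed: int | None = None

    def expected_classes(self, genes=None) -> dict[str, str]:
        """Per-gene seed class implied by the planted sites (manifest oracle)."""
        from coexmir.seeds import SeedHit, classify_genes

        hits = [
            SeedHit(s["gene"], s["transcript"], s["arm"], s["quality"],
                    s["position"], s["site"])
            for s in self.sites
        ]
        return classify_genes(hits, genes=genes)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the genes x (2*n_per_group) matrix and its ground truth."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_per_group
    genes = config.gene_ids()
    samples = [f"null_{i+1}" for i in range(n)] + [f"mir142_{i+1}" for i in range(n)]
    conditions = {s: ("null" if s.startswith("null") else "mir142") for s in samples}
    cols = {"null": slice(0, n), "mir142": slice(n, 2 * n)}

    values = config.baseline_mean + rng.normal(0.0, config.background_sd, (config.n_genes, 2 * n))
    index = {g: i for i, g in enumerate(genes)}

    cliques = config.clique_members()
    for cond, members in cliques.items():
        for clique in members:
            latent = config.baseline_mean + rng.normal(0.0, config.background_sd, n)
            rows = [index[g] for g in clique]
            noise = rng.normal(0.0, config.clique_noise_sd, (len(rows), n))
            values[rows, cols[cond]] = latent[None, :] + noise

    de = config.de_genes()
    for gene, direction in de.items():
        shift = config.de_shift if direction == "up" else -config.de_shift
        values[index[gene], cols["mir142"]] += shift

    matrix = ExpressionMatrix.from_arrays(values, genes, samples, conditions)
    truth = GroundTruth(cliques=cliques, de=de, rng_seed=config.rng_seed)
    return matrix, truth


# ---------------------------------------------------------------------------
# UTRs
# ---------------------------------------------------------------------------

def _forbidden_sites(config: SimulationConfig) -> set[str]:
    seeds = [*seed_set(config.seed_5p, "5p"), *seed_set(config.seed_3p, "3p")]
    return {seed_to_site(s) for s in seeds}


def _scrub(seq: np.ndarray, forbidden: set[str], protected: np.ndarray,
           rng: np.random.Generator, max_rounds: int = 10_000) -> None:
    """Resample unprotected bases until no forbidden 7-mer remains.

    ``protected`` marks planted-site bases that must not change; any
    forbidden window not fully protected has at least one free base to
    resample, so the loop terminates with probability 1.
    """
    length = seq.size
    for _ in range(max_rounds):
        dirty = False
        i = 0
        while i <= length - _SITE_LEN:
            window = seq[i : i + _SITE_LEN].tobytes().decode()
            if window in forbidden and not protected[i : i + _SITE_LEN].all():
                free = np.flatnonzero(~protected[i : i + _SITE_LEN]) + i
                seq[free] = _DNA[rng.integers(0, 4, free.size)]
                dirty = True
                i = max(0, i - _SITE_LEN + 1)
            else:
                i += 1
        if not dirty:
            return
    raise RuntimeError("site-free rejection sampling did not converge")


def _choose_positions(length: int, counts: int, occupied: list[tuple[int, int]],
                      rng: np.random.Generator) -> int:
    """Pick a 0-based start for a 7-base site, >= 1 base clear of others."""
    candidates = []
    for start in range(0, length - _SITE_LEN + 1):
        if all(start + _SITE_LEN < s or e < start - 1 for s, e in
               ((s, s + _SITE_LEN - 1) for s, _ in occupied)):
            candidates.append(start)
    if not candidates:
        raise ValueError("UTR too short to host the requested sites")
    return int(rng.choice(candidates))


def simulate_utrs(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Generate one UTR per gene plus the planted-site manifest.

    Returns ``(records, truth)`` where records are
    ``(gene_id, transcript_id, sequence)`` tuples (DNA, uppercase) and the
    manifest lists every planted site with its 1-based position.  The
    generated sequences are re-scanned defensively: their hits must equal
    the manifest exactly.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    truth = truth if truth is not None else GroundTruth(rng_seed=config.rng_seed)
    forbidden = _forbidden_sites(config)
    exact_sites = {"5p": seed_to_site(config.seed_5p), "3p": seed_to_site(config.seed_3p)}
    mutant_sites = {
        arm: [seed_to_site(s) for s in seed_set(seq, arm)[1:]]
        for arm, seq in (("5p", config.seed_5p), ("3p", config.seed_3p))
    }

    per_gene: dict[str, list[PlantedSite]] = {}
    for site in config.planted_sites or []:
        per_gene.setdefault(site.gene, []).append(site)

    lo, hi = config.utr_length_range
    records: list[tuple[str, str, str]] = []
    manifest: list[dict] = []
    for gene in config.gene_ids():
        transcript = f"{gene}.t1"
        length = int(rng.integers(lo, hi + 1))
        seq = _DNA[rng.integers(0, 4, length)].copy()
        protected = np.zeros(length, dtype=bool)
        occupied: list[tuple[int, int]] = []
        for spec in per_gene.get(gene, []):
            for _ in range(spec.count):
                if spec.quality == "exact":
                    site = exact_sites[spec.arm]
                else:
                    site = mutant_sites[spec.arm][int(rng.integers(0, len(mutant_sites[spec.arm])))]
                start = _choose_positions(length, spec.count, occupied, rng)
                seq[start : start + _SITE_LEN] = np.frombuffer(site.encode(), dtype="S1")
                protected[start : start + _SITE_LEN] = True
                occupied.append((start, spec.count))
                manifest.append(
                    {
                        "gene": gene,
                        "transcript": transcript,
                        "arm": spec.arm,
                        "quality": spec.quality,
                        "position": start + 1,
                        "site": site,
                    }
                )
        _scrub(seq, forbidden, protected, rng)
        records.append((gene, transcript, seq.tobytes().decode()))

    manifest.sort(key=lambda s: (s["gene"], s["position"]))
    truth.sites = manifest
    _check_manifest(records, manifest, config)
    return records, truth


def _check_manifest(records, manifest, config: SimulationConfig) -> None:
    """Defensive identity: scanning the emitted UTRs reproduces the manifest."""
    from coexmir.seeds import scan_utr

    table = build_site_table(default_seed_table(config.seed_5p, config.seed_3p))
    expected = {
        (s["gene"], s["arm"], s["quality"], s["position"]) for s in manifest
    }
    observed = set()
    for gene, transcript, seq in records:
        for hit in scan_utr(seq, table, gene_id=gene, transcript_id=transcript):
            observed.add((hit.gene_id, hit.arm, hit.quality, hit.position))
    if observed != expected:
        raise RuntimeError("generated UTRs do not reproduce the planted manifest")


def simulate(config: SimulationConfig) -> tuple[ExpressionMatrix, list[tuple[str, str, str]], GroundTruth]:
    """Expression + UTRs from one RNG stream seeded with ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    matrix, truth = simulate_expression(config, rng=rng)
    records, truth = simulate_utrs(config, rng=rng, truth=truth)
    return matrix, records, truth
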