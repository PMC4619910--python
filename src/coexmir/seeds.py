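"""miRNA seed derivation and complementary 3' UTR scanning.

A miRNA *seed* is the 7-nt recognition region of a mature miRNA (given here
directly as an RNA string).  A *seed site* on an mRNA is the DNA reverse
complement of the seed, read 5'->3' on the UTR sense strand; its presence
predicts targeting.  Because miRNA-target pairing tolerates single
mismatches, scanning covers both the exact seed and all 3*7 = 21 one-base
mutants per arm ("inexact" sites).

miR-142 produces two independently active arms, miR-142-5p (seed AUAAAGU)
and miR-142-3p (seed GUAGUGU); both are scanned by default.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

MIR142_5P = "AUAAAGU"
MIR142_3P = "GUAGUGU"

#: Mutually exclusive per-gene seed-mapping categories.  Exact hits take
#: precedence over inexact ones; "both" means both arms.
GENE_CLASSES = (
    "exact-5p",
    "exact-3p",
    "exact-both",
    "inexact-5p",
    "inexact-3p",
    "inexact-both",
    "none",
)


@dataclass(frozen=True)
class Seed:
    """A 7-nt RNA seed of one miR-142 arm, exact or one-base mutant."""

    arm: str  # "5p" or "3p"
    sequence: str  # RNA alphabet, length 7
    quality: str  # "exact" or "inexact"
    mutation_label: str = ""  # e.g. "2b"; empty for the exact seed

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.quality not in ("exact", "inexact"):
            raise ValueError(f"unknown quality {self.quality!r}")
        _validate_rna(self.sequence)


@dataclass(frozen=True)
class SeedHit:
    """One occurrence of a seed's complementary site on a UTR.

    ``position`` is the 1-based inclusive start of the 7-base site on the
    UTR sense strand; ``site_sequence`` is the DNA site that matched.
    """

    gene_id: str
    transcript_id: str
    arm: str
    quality: str
    position: int
    site_sequence: str


def _validate_rna(seq: str) -> None:
    if not seq:
        raise ValueError("empty seed sequence")
    bad = set(seq) - set(RNA_BASES)
    if bad:
        raise ValueError(f"non-RNA characters in seed {seq!r}: {sorted(bad)}")


def generate_mutant_seeds(exact_seed: str, arm: str = "5p") -> list[Seed]:
    """All one-base mutants of ``exact_seed`` (3 per position, 21 for a 7-mer).

    Labels follow the ``<position><variant>`` scheme, position 1-based and
    variants a/b/c in fixed A<C<G<U order of the substituted base (skipping
    the original).  The exact seed itself is never included.
    """
    _validate_rna(exact_seed)
    mutants = []
    for pos, original in enumerate(exact_seed):
        variants = [b for b in RNA_BASES if b != original]
        for letter, base in zip("abc", variants):
            seq = exact_seed[:pos] + base + exact_seed[pos + 1 :]
            mutants.append(
                Seed(arm=arm, sequence=seq, quality="inexact",
                     mutation_label=f"{pos + 1}{letter}")
            )
    return mutants


def seed_set(exact_seed: str, arm: str) -> list[Seed]:
    """The exact seed plus its 21 mutants (22 seeds for a 7-mer)."""
    exact = Seed(arm=arm, sequence=exact_seed, quality="exact")
    return [exact, *generate_mutant_seeds(exact_seed, arm)]


def default_seed_table(seed_5p: str = MIR142_5P, seed_3p: str = MIR142_3P) -> list[Seed]:
    """Exact + mutant seeds for both arms (44 seeds with the defaults)."""
    return [*seed_set(seed_5p, "5p"), *seed_set(seed_3p, "3p")]


def seed_to_site(seed: Seed | str) -> str:
    """DNA site complementary to a seed: reverse complement with U->T.

    The site is what a scanner looks for on the UTR sense strand, e.g.
    AUAAAGU -> ACTTTAT.
    """
    seq = seed.sequence if isinstance(seed, Seed) else seed
    _validate_rna(seq)
    return str(Seq(seq).back_transcribe().reverse_complement())


def build_site_table(seeds: Iterable[Seed]) -> dict[str, list[Seed]]:
    """Map DNA site 7-mer -> seeds it matches.

    Within one arm a mutant site can never coincide with the exact site
    (they differ at one position by construction), so exact-over-inexact
    precedence is resolved per arm: if the exact site of an arm appears,
    no inexact entry for that arm is kept for the same site.
    """
    table: dict[str, list[Seed]] = defaultdict(list)
    for seed in seeds:
        table[seed_to_site(seed)].append(seed)
    resolved: dict[str, list[Seed]] = {}
    for site, matched in table.items():
        exact_arms = {s.arm for s in matched if s.quality == "exact"}
        resolved[site] = [
            s for s in matched
            if s.quality == "exact" or s.arm not in exact_arms
        ]
    return resolved


def scan_utr(
    utr: str,
    site_table: Mapping[str, list[Seed]],
    gene_id: str = "",
    transcript_id: str = "",
) -> list[SeedHit]:
    """Report every overlapping 7-base window of ``utr`` matching a site.

    ``utr`` must be uppercase DNA (use :func:`coexmir.io.read_fasta` for
    normalization).  Windows containing characters outside ACGT (e.g. N)
    match nothing.  Sequences shorter than 7 yield no hits.  Positions are
    1-based; overlapping occurrences are each reported.
    """
    k = 7
    hits: list[SeedHit] = []
    for i in range(len(utr) - k + 1):
        window = utr[i : i + k]
        for seed in site_table.get(window, ()):
            hits.append(
                SeedHit(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    arm=seed.arm,
                    quality=seed.quality,
                    position=i + 1,
                    site_sequence=window,
                )
            )
    return hits


def scan_utrs(
    records: Iterable[tuple[str, str, str]],
    seeds: Iterable[Seed] | None = None,
) -> list[SeedHit]:
    """Scan ``(gene_id, transcript_id, sequence)`` records with a seed set.

    Defaults to both miR-142 arms' exact + mutant seeds.
    """
    table = build_site_table(seeds if seeds is not None else default_seed_table())
    hits: list[SeedHit] = []
    for gene_id, transcript_id, seq in records:
        hits.extend(scan_utr(seq, table, gene_id=gene_id, transcript_id=transcript_id))
    return hits


def classify_genes(
    hits: Sequence[SeedHit],
    genes: Iterable[str] | None = None,
    transcript_to_gene: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Collapse hits to one mutually exclusive class per gene.

    A gene is mapped if any of its transcripts' UTRs has a hit (logical OR
    over transcripts).  Precedence: any exact hit makes the class
    exact-5p/exact-3p/exact-both according to which arms have exact hits
    (inexact hits are then ignored); otherwise inexact-5p/-3p/-both;
    otherwise "none".  ``genes`` extends the output to unmapped genes;
    ``transcript_to_gene``, when given, re-derives gene ids from transcript
    ids and rejects hits on unknown transcripts.
    """
    per_gene: dict[str, dict[str, set[str]]] = defaultdict(
        lambda: {"exact": set(), "inexact": set()}
    )
    for hit in hits:
        if transcript_to_gene is not None:
            if hit.transcript_id not in transcript_to_gene:
                raise ValueError(f"hit references unknown transcript {hit.transcript_id!r}")
            gene = transcript_to_gene[hit.transcript_id]
        else:
            gene = hit.gene_id
        per_gene[gene][hit.quality].add(hit.arm)

    classes: dict[str, str] = {}
    for gene, arms in per_gene.items():
        for quality in ("exact", "inexact"):
            if arms[quality]:
                which = "both" if len(arms[quality]) == 2 else next(iter(arms[quality]))
                classes[gene] = f"{quality}-{which}"
                break
    if genes is not None:
        for gene in genes:
            classes.setdefault(gene, "none")
    return classes
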