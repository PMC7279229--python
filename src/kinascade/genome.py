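"""Chromosomal context: gene order, tandem duplicates and gene clusters.

Genes are ordered per chromosome by start coordinate (ties break on gene id).
A tandem pair is two same-family genes with at most ``max_intervening`` genes
of any kind between them (default 0: strict adjacency); pairs chain, so three
consecutive family members yield two pairs. A cluster is a maximal run of
>= ``min_size`` same-family genes in which consecutive members are separated
by <= ``max_intervening`` non-family genes. High protein identity within a
pair is the conventional signal of a local gene-duplication event.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import phylo


@dataclass(frozen=True)
class TandemPair:
    gene_a: str
    gene_b: str
    chromosome: str
    family: str
    intervening_gene_count: int
    identity_pct: float | None = None


@dataclass(frozen=True)
class GeneCluster:
    members: tuple[str, ...]
    chromosome: str
    family: str

    def __post_init__(self):
        if len(self.members) < 3:
            raise ValueError("a cluster has >= 3 members")


def order_genes(gene_models) -> dict[str, list[str]]:
    """Per-chromosome gene order: by start coordinate, ties by gene id.

    Stable under input permutation; duplicate gene ids are an error.
    """
    seen = set()
    per_chrom: dict[str, list] = {}
    for gm in gene_models:
        if gm.gene_id in seen:
            raise ValueError(f"duplicate gene id {gm.gene_id!r}")
        seen.add(gm.gene_id)
        per_chrom.setdefault(gm.chromosome, []).append(gm)
    return {
        chrom: [g.gene_id for g in sorted(genes, key=lambda g: (g.gene_start, g.gene_id))]
        for chrom, genes in sorted(per_chrom.items())
    }


def _family_by_gene(inventory) -> dict[str, str]:
    fams = {}
    for _, row in inventory.iterrows():
        gene = row.get("gene_id", row["id"])
        fams[gene] = row["family"]
    return fams


def find_tandem_pairs(
    inventory, order: dict[str, list[str]], max_intervening: int = 0
) -> list[TandemPair]:
    """Same-family gene pairs separated by <= max_intervening genes of any
    kind in chromosome order. Chaining is allowed (A-B and B-C)."""
    fams = _family_by_gene(inventory)
    pairs: list[TandemPair] = []
    for chrom, genes in order.items():
        for i, ga in enumerate(genes):
            fam = fams.get(ga)
            if fam in (None, "none", ""):
                continue
            for j in range(i + 1, min(i + max_intervening + 2, len(genes))):
                gb = genes[j]
                if fams.get(gb) == fam:
                    pairs.append(
                        TandemPair(ga, gb, chrom, fam, intervening_gene_count=j - i - 1)
                    )
    return pairs


def find_clusters(
    inventory,
    order: dict[str, list[str]],
    min_size: int = 3,
    max_intervening: int = 2,
) -> list[GeneCluster]:
    """Maximal runs of >= min_size same-family genes under the gap rule.

    A run extends while the next same-family gene lies within
    ``max_intervening`` non-family genes of the previous member; maximality
    guarantees a cluster of five is one object, not overlapping sub-clusters.
    """
    fams = _family_by_gene(inventory)
    clusters: list[GeneCluster] = []
    for chrom, genes in order.items():
        used: set[int] = set()
        for i, ga in enumerate(genes):
            fam = fams.get(ga)
            if i in used or fam in (None, "none", ""):
                continue
            run = [i]
            k = i
            while True:
                nxt = None
                for j in range(k + 1, min(k + max_intervening + 2, len(genes))):
                    if fams.get(genes[j]) == fam:
                        nxt = j
                        break
                if nxt is None:
                    break
                run.append(nxt)
                k = nxt
            if len(run) >= min_size:
                clusters.append(
                    GeneCluster(tuple(genes[k] for k in run), chrom, fam)
                )
                used.update(run)
    return clusters


def duplication_similarity(pair: TandemPair, proteome) -> TandemPair:
    """Attach percent protein identity (global alignment) to a tandem pair.

    Symmetric in the pair's members. Proteins are looked up by gene id.
    """
    by_gene = {getattr(r, "gene_id", r.id): r for r in proteome}
    try:
        rec_a = by_gene[pair.gene_a]
        rec_b = by_gene[pair.gene_b]
    except KeyError as e:
        raise ValueError(f"missing protein for gene {e.args[0]!r}") from e
    ident = phylo.global_align(rec_a, rec_b).identity_pct
    return TandemPair(
        pair.gene_a,
        pair.gene_b,
        pair.chromosome,
        pair.family,
        pair.intervening_gene_count,
        identity_pct=ident,
    )
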