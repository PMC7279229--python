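"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package implementation: alignment
by exhaustive enumeration, pI by pH-grid search, motif occurrence by
substring enumeration, tandem/cluster re-validation straight from gene
coordinates.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_align_score(
    a: str,
    b: str,
    matrix: str | None = "BLOSUM62",
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> float:
    """Optimal affine-gap global alignment score by exhaustive recursion.

    A gap of length L costs gap_open + (L-1) * gap_extend. Feasible for
    sequences up to ~8 residues.
    """

    def sub(x: str, y: str) -> float:
        if matrix:
            return float(_BLOSUM62[x, y])
        return match if x == y else mismatch

    @lru_cache(maxsize=None)
    def best(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(sub(a[i], b[j]) + best(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            options.append(cost + best(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            options.append(cost + best(i, j + 1, "b"))
        return max(options)

    return best(0, 0, "m")


def grid_pi(sequence: str, net_charge, step: float = 1e-4) -> float:
    """pH-grid argmin of |net charge|; the independent pI oracle."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([net_charge(sequence, ph) for ph in grid[:: 100]])
    # coarse bracket first (the charge is monotone), then fine grid inside
    k = int(np.argmin(np.abs(charges)))
    lo = max(grid[:: 100][max(k - 1, 0)], 0.0)
    hi = min(grid[:: 100][min(k + 1, len(charges) - 1)], 14.0)
    fine = np.arange(lo, hi + step, step)
    fine_charges = np.array([net_charge(sequence, ph) for ph in fine])
    return float(fine[int(np.argmin(np.abs(fine_charges)))])


def enumerate_matches(pattern, seq: str) -> set[tuple[int, int]]:
    """All (start, end) whose slice satisfies the pattern, by trying every
    substring — the completeness oracle for the scanner."""
    out = set()
    for start in range(len(seq)):
        for end in range(start + 1, len(seq) + 1):
            if pattern.matches_exact(seq[start:end]):
                out.add((start, end))
    return out


def check_tandem_pair(pair, gene_models, families, max_intervening: int) -> bool:
    """Re-validate one reported tandem pair directly from coordinates."""
    by_id = {g.gene_id: g for g in gene_models}
    ga, gb = by_id[pair.gene_a], by_id[pair.gene_b]
    if ga.chromosome != gb.chromosome:
        return False
    if families.get(pair.gene_a) != families.get(pair.gene_b):
        return False
    if families.get(pair.gene_a) in (None, "none", ""):
        return False
    chrom_genes = sorted(
        (g for g in gene_models if g.chromosome == ga.chromosome),
        key=lambda g: (g.gene_start, g.gene_id),
    )
    idx = {g.gene_id: k for k, g in enumerate(chrom_genes)}
    ia, ib = idx[pair.gene_a], idx[pair.gene_b]
    if not ia < ib:
        return False
    return (ib - ia - 1) == pair.intervening_gene_count <= max_intervening


def check_cluster(cluster, gene_models, families, min_size: int, max_intervening: int) -> bool:
    """Re-validate one reported cluster directly from coordinates."""
    if len(cluster.members) < min_size:
        return False
    fams = {families.get(m) for m in cluster.members}
    if fams != {cluster.family}:
        return False
    chrom_genes = sorted(
        (g for g in gene_models if g.chromosome == cluster.chromosome),
        key=lambda g: (g.gene_start, g.gene_id),
    )
    idx = {g.gene_id: k for k, g in enumerate(chrom_genes)}
    positions = [idx[m] for m in cluster.members]
    if positions != sorted(positions):
        return False
    for p, q in zip(positions, positions[1:]):
        gap_genes = chrom_genes[p + 1 : q]
        if any(families.get(g.gene_id) == cluster.family for g in gap_genes):
            return False
        if len(gap_genes) > max_intervening:
            return False
    return True
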