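"""Physicochemical and gene-structure properties for the inventory tables.

Molecular mass is the average (isotope-abundance-weighted) mass: the sum of
residue masses plus one water. Theoretical pI follows the Bjellqvist model
used by the Expasy ProtParam service: the pH at which the Henderson–
Hasselbalch net charge over the termini and the ionizable side chains
(D, E, C, Y acidic; H, K, R basic) is zero, found by bisection. Net charge is
strictly decreasing in pH, so the zero is unique.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

#: Expasy average residue masses, Da (monomer minus water).
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_DA = 18.02

# Bjellqvist pKa set (the ProtParam values). Terminal pKas depend on the
# terminal residue; unlisted residues take the default.
PKA_SIDECHAIN_ACIDIC = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_SIDECHAIN_BASIC = {"H": 5.98, "K": 10.0, "R": 12.0}
PKA_NTERM_DEFAULT = 7.5
PKA_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
PKA_CTERM_DEFAULT = 3.55
PKA_CTERM = {"D": 4.55, "E": 4.75}


def molecular_mass(sequence) -> float:
    """Average molecular mass in Da. Undefined when 'X' is present."""
    seq = getattr(sequence, "sequence", sequence)
    if not seq:
        raise ValueError("empty sequence")
    if "X" in seq:
        raise ValueError("mass undefined for unknown residue")
    return sum(RESIDUE_MASS_DA[c] for c in seq) + WATER_DA


def net_charge(sequence, ph: float) -> float:
    """Henderson–Hasselbalch net charge at ``ph`` (termini + side chains)."""
    seq = getattr(sequence, "sequence", sequence)
    comp = Counter(seq)

    def pos(pka: float, n: int = 1) -> float:
        return n / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float, n: int = 1) -> float:
        return -n / (1.0 + 10.0 ** (pka - ph))

    charge = pos(PKA_NTERM.get(seq[0], PKA_NTERM_DEFAULT))
    charge += neg(PKA_CTERM.get(seq[-1], PKA_CTERM_DEFAULT))
    for aa, pka in PKA_SIDECHAIN_BASIC.items():
        if comp[aa]:
            charge += pos(pka, comp[aa])
    for aa, pka in PKA_SIDECHAIN_ACIDIC.items():
        if comp[aa]:
            charge += neg(pka, comp[aa])
    return charge


def isoelectric_point(sequence, charge_tol: float = 1e-6, ph_tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14]."""
    seq = getattr(sequence, "sequence", sequence)
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > ph_tol:
        mid = 0.5 * (lo + hi)
        c = net_charge(seq, mid)
        if abs(c) < charge_tol:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gene_metrics(gene_model) -> tuple[int, int]:
    """(gene length in nt, exon count of the primary transcript)."""
    return gene_model.length_nt, len(gene_model.exons)


@dataclass(frozen=True)
class PropertySet:
    """The per-protein property row of the inventory tables."""

    protein_id: str
    length_aa: int
    mass_kda: float
    pi: float
    gene_length_nt: int | None = None
    exon_count: int | None = None
    chromosome: str | None = None


def compute_properties(record, gene_model=None) -> PropertySet:
    seq = record.sequence
    mass = molecular_mass(seq) if "X" not in seq else float("nan")
    return PropertySet(
        protein_id=record.id,
        length_aa=len(seq),
        mass_kda=mass / 1000.0,
        pi=isoelectric_point(seq),
        gene_length_nt=gene_model.length_nt if gene_model else None,
        exon_count=len(gene_model.exons) if gene_model else None,
        chromosome=gene_model.chromosome if gene_model else None,
    )


#: Columns summarized per family, -> inventory column name.
SUMMARY_FIELDS = ("length_aa", "mass_kda", "pi", "gene_length_nt", "exon_count")


def summarize_inventory(rows) -> dict[str, dict[str, dict]]:
    """Per-family extrema of the numeric property columns.

    Returns ``{family: {field: {min, min_id, max, max_id}}}``; the achieving
    protein id breaks ties lexicographically. Families with no rows are
    omitted; fields that are entirely missing for a family are omitted too.
    """
    df = rows.copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    out: dict[str, dict[str, dict]] = {}
    if df.empty or "family" not in df.columns:
        return out
    for family, sub in df.groupby("family", sort=True):
        if family in (None, "none") or (isinstance(family, float) and pd.isna(family)):
            continue
        fam_summary: dict[str, dict] = {}
        for fld in SUMMARY_FIELDS:
            if fld not in sub.columns:
                continue
            vals = sub[["id", fld]].dropna()
            if vals.empty:
                continue
            vals = vals.sort_values(["id"]).reset_index(drop=True)
            vmin = vals[fld].min()
            vmax = vals[fld].max()
            fam_summary[fld] = {
                "min": float(vmin),
                "min_id": vals.loc[vals[fld] == vmin, "id"].iloc[0],
                "max": float(vmax),
                "max_id": vals.loc[vals[fld] == vmax, "id"].iloc[0],
            }
        if fam_summary:
            out[family] = fam_summary
    return out
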