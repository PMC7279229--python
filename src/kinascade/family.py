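"""Kinase architecture detection and MAPK/MAPKK/MEKK/RAF/ZIK classification.

A eukaryotic protein kinase domain reads, N- to C-terminal: a glycine-rich
phosphate-binding loop (P-loop, consensus ``IGxGxxGxV``), a catalytic loop
(C-loop, ``HRD(L/I/V)KPxN``), and the activation segment (T-loop) carrying the
family-specific activation motif. Family assignment scans the five activation
consensus motifs and, among the motifs whose hit sits in a confirmed kinase
architecture, keeps the most specific one (highest count of fixed positions).
This precedence resolves the genuine overlaps between the ZIK/MEKK and
MEKK/RAF consensus motifs — the most constrained motif is the most
informative.

Kinase-domain confirmation is an ordered-loop heuristic: the C-loop must lie
an allowed distance upstream of the activation motif and a P-loop (strict, or
the loose ``GxGxxG`` form — some genuine MAPKs lack the strict P-loop) an
allowed distance upstream of the C-loop. The spacing windows default to
canonical ePK dimensions and are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import properties
from .motifs import (
    FAMILY_PATTERNS,
    PATTERN_FAMILY,
    MotifMatch,
    MotifPattern,
    builtin_registry,
    compile_pattern,
    scan,
)

logger = logging.getLogger(__name__)

FAMILIES = ("MAPK", "MAPKK", "MEKK", "RAF", "ZIK")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the classification pipeline.

    ``p_c_gap`` bounds the residues between the P-loop end and the C-loop
    start; ``c_t_gap`` bounds those between the C-loop end and the activation
    motif start. ``raf_tail_threshold`` is the C-terminal tail length (aa past
    the activation motif) separating RAF group A from group C.
    """

    mode: str = "confirmed"  # or "loose"
    strict_motifs: bool = False
    p_c_gap: tuple[int, int] = (40, 260)
    c_t_gap: tuple[int, int] = (5, 80)
    raf_tail_threshold: int = 150

    def __post_init__(self):
        if self.mode not in ("loose", "confirmed"):
            raise ValueError(f"mode must be 'loose' or 'confirmed', got {self.mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("p_c_gap", "c_t_gap"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class KinaseArchitecture:
    """Located loops and derived layout facts for one activation-motif hit."""

    p_loop: Optional[MotifMatch]
    c_loop: Optional[MotifMatch]
    t_loop: Optional[MotifMatch]
    txy_variant: Optional[str]
    cdd_candidate: Optional[tuple[int, int]]
    domain_position: str  # N-terminal | central | C-terminal
    p_loop_kind: Optional[str] = None  # strict | loose

    @property
    def loops_found(self) -> str:
        parts = []
        if self.p_loop:
            parts.append("P")
        if self.c_loop:
            parts.append("C")
        if self.t_loop:
            parts.append("T")
        return "".join(parts)


@dataclass(frozen=True)
class FamilyCall:
    protein_id: str
    family: Optional[str]  # MAPK|MAPKK|MEKK|RAF|ZIK|None
    evidence: tuple[str, ...]  # matching activation-pattern names, most specific first
    confirmed: bool
    mode: str
    architecture: Optional[KinaseArchitecture] = None


@dataclass(frozen=True)
class GroupCall:
    protein_id: str
    group: str
    basis: str  # rule | tree
    ambiguous_DE: bool = False


def detect_architecture(
    seq,
    activation: MotifMatch,
    registry: Optional[dict[str, MotifPattern]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> KinaseArchitecture:
    """Locate the P- and C-loops supporting one activation-motif hit.

    The C-loop is the nearest catalytic-loop match upstream of the activation
    motif within the configured spacing; the P-loop (strict preferred over
    loose at equal position) is the nearest match upstream of the C-loop
    within its spacing. Absent loops are recorded as absent, never guessed.
    """
    registry = registry or builtin_registry(config.strict_motifs)
    sequence = getattr(seq, "sequence", seq)

    c_loop = _nearest_upstream(
        scan(registry["c_loop"], sequence), activation.start, config.c_t_gap
    )
    p_loop = None
    p_kind = None
    if c_loop is not None:
        strict = _nearest_upstream(
            scan(registry["p_loop"], sequence), c_loop.start, config.p_c_gap
        )
        loose = _nearest_upstream(
            scan(registry["p_loop_loose"], sequence), c_loop.start, config.p_c_gap
        )
        if strict is not None and (loose is None or strict.end >= loose.end - 1):
            p_loop, p_kind = strict, "strict"
        elif loose is not None:
            p_loop, p_kind = loose, "loose"

    txy = None
    if activation.pattern_name == "mapk_act":
        txy = activation.matched_text[:3]

    n = len(sequence)
    cdd = (activation.end, n) if n > activation.end else None
    span_start = (p_loop or c_loop or activation).start
    midpoint = 0.5 * (span_start + activation.end)
    rel = midpoint / n
    position = "N-terminal" if rel < 0.40 else ("C-terminal" if rel > 0.60 else "central")

    return KinaseArchitecture(
        p_loop=p_loop,
        c_loop=c_loop,
        t_loop=activation,
        txy_variant=txy,
        cdd_candidate=cdd,
        domain_position=position,
        p_loop_kind=p_kind,
    )


def _nearest_upstream(matches, downstream_start: int, gap_bounds: tuple[int, int]):
    """The match ending closest below ``downstream_start`` with the gap
    (downstream_start - match.end) inside ``gap_bounds``."""
    lo, hi = gap_bounds
    best = None
    for m in matches:
        gap = downstream_start - m.end
        if lo <= gap <= hi and (best is None or m.end > best.end):
            best = m
    return best


def confirm_kinase_domain(arch: KinaseArchitecture, mode: str) -> bool:
    """Loose mode needs only the activation motif; confirmed mode needs the
    full ordered P-C-T architecture within the spacing bounds (enforced at
    detection time)."""
    if mode == "loose":
        return arch.t_loop is not None
    if mode == "confirmed":
        return arch.t_loop is not None and arch.c_loop is not None and arch.p_loop is not None
    raise ValueError(f"unknown mode {mode!r}")


def assign_family(
    seq,
    registry: Optional[dict[str, MotifPattern]] = None,
    config: PipelineConfig = PipelineConfig(),
) -> FamilyCall:
    """Scan the five activation motifs and call the family by precedence.

    Evidence lists every activation pattern with at least one hit passing the
    configured mode; the family is the evidence pattern with the highest
    fixed-position count.
    """
    registry = registry or builtin_registry(config.strict_motifs)
    protein_id = getattr(seq, "id", "")
    sequence = getattr(seq, "sequence", seq)

    passing: dict[str, KinaseArchitecture] = {}
    for name in FAMILY_PATTERNS:
        for hit in scan(registry[name], sequence):
            arch = detect_architecture(sequence, hit, registry, config)
            if confirm_kinase_domain(arch, config.mode):
                passing[name] = arch
                break

    if not passing:
        return FamilyCall(protein_id, None, (), False, config.mode, None)

    evidence = tuple(sorted(passing, key=lambda n: -registry[n].n_fixed))
    winner = evidence[0]
    arch = passing[winner]
    return FamilyCall(
        protein_id=protein_id,
        family=PATTERN_FAMILY[winner],
        evidence=evidence,
        confirmed=confirm_kinase_domain(arch, "confirmed"),
        mode=config.mode,
        architecture=arch,
    )


# --- within-family groups -------------------------------------------------

def classify_mapk_group(
    call: FamilyCall,
    arch: KinaseArchitecture,
    tree=None,
    anchors: Optional[dict[str, str]] = None,
) -> GroupCall:
    """MAPK groups: TEY -> C; the non-canonical variants (TTY/TSY/TPY...) ->
    E; TDY -> D unless a tree with D/E anchor leaves places the protein with
    an E anchor (the D/E boundary among TDY kinases is phylogenetic, so the
    rule path flags the ambiguity instead of hiding it)."""
    if call.family != "MAPK":
        raise ValueError(f"{call.protein_id}: not a MAPK ({call.family})")
    variant = arch.txy_variant
    if variant == "TEY":
        return GroupCall(call.protein_id, "C", "rule")
    if variant != "TDY":
        return GroupCall(call.protein_id, "E", "rule")
    if tree is not None and anchors:
        group = _nearest_anchor_group(tree, call.protein_id, anchors)
        if group is not None:
            return GroupCall(call.protein_id, group, "tree")
    return GroupCall(call.protein_id, "D", "rule", ambiguous_DE=True)


def _nearest_anchor_group(tree, leaf_name: str, anchors: dict[str, str]):
    """Group of the topologically nearest anchor leaf, or None if the protein
    is not in the tree."""
    try:
        tip = tree.find(leaf_name)
    except Exception:
        return None
    best = None
    best_d = None
    for anchor, group in sorted(anchors.items()):
        if anchor == leaf_name:
            continue
        try:
            d = tip.distance(tree.find(anchor))
        except Exception:
            continue
        if best_d is None or d < best_d:
            best, best_d = group, d
    return best


# RAF group signature motifs (groups B/D/E/F have heterogeneous activation
# sites and are resolvable only phylogenetically -> unassigned here).
RAF_G_ACT = compile_pattern("GTRHYMAPEV", name="raf_group_g_act")
RAF_H_ACT = compile_pattern("GTxxYMAPE(A/C/L/T)", name="raf_group_h_act")
RAF_H_PLOOP = compile_pattern("GxGxxGxV", name="raf_group_h_ploop")
RAF_AC_ACT = compile_pattern("GTxxYMAPEV", name="raf_group_ac_act")
RAF_A_PLOOP = compile_pattern("GxxSxVYxAxCxxSGxxVALK", name="raf_group_a_ploop")


def classify_raf_group(
    call: FamilyCall,
    arch: KinaseArchitecture,
    seq,
    config: PipelineConfig = PipelineConfig(),
) -> GroupCall:
    """RAF groups by activation-site signature, tried in order G, H, A/C."""
    if call.family != "RAF":
        raise ValueError(f"{call.protein_id}: not a RAF ({call.family})")
    sequence = getattr(seq, "sequence", seq)
    start = arch.t_loop.start

    if _signature_at(RAF_G_ACT, sequence, start):
        return GroupCall(call.protein_id, "G", "rule")
    if _signature_at(RAF_H_ACT, sequence, start) and any(
        m.end <= start for m in scan(RAF_H_PLOOP, sequence)
    ):
        return GroupCall(call.protein_id, "H", "rule")
    if _signature_at(RAF_AC_ACT, sequence, start) and any(
        m.end <= start for m in scan(RAF_A_PLOOP, sequence)
    ):
        tail = len(sequence) - arch.t_loop.end
        group = "C" if tail > config.raf_tail_threshold else "A"
        return GroupCall(call.protein_id, group, "rule")
    return GroupCall(call.protein_id, "unassigned", "rule")


def _signature_at(pattern: MotifPattern, sequence: str, start: int) -> bool:
    return any(m.start == start for m in scan(pattern, sequence))


# --- whole-proteome inventory --------------------------------------------

def run_inventory(
    proteome,
    gene_models=None,
    config: PipelineConfig = PipelineConfig(),
    tree=None,
    anchors=None,
) -> tuple[pd.DataFrame, dict]:
    """Classify every protein and tabulate one row per protein.

    Returns ``(table, summary)`` where the summary holds per-family counts and
    per-family property extrema. Row order equals input order. Proteins whose
    gene is absent from ``gene_models`` get empty genomic fields (warned).
    """
    registry = builtin_registry(config.strict_motifs)
    gm_by_gene = {g.gene_id: g for g in (gene_models or [])}

    rows = []
    calls: dict[str, FamilyCall] = {}
    for rec in proteome:
        call = assign_family(rec, registry, config)
        calls[rec.id] = call
        arch = call.architecture
        gm = gm_by_gene.get(rec.gene_id)
        if gene_models and gm is None:
            logger.warning("no gene model for %s (gene %s)", rec.id, rec.gene_id)

        group = ""
        ambiguous = False
        if call.family == "MAPK":
            gc = classify_mapk_group(call, arch, tree=tree, anchors=anchors)
            group, ambiguous = gc.group, gc.ambiguous_DE
        elif call.family == "RAF":
            group = classify_raf_group(call, arch, rec, config).group

        try:
            mass_kda = properties.molecular_mass(rec.sequence) / 1000.0
        except ValueError:
            mass_kda = float("nan")

        rows.append(
            {
                "id": rec.id,
                "family": call.family or "none",
                "group": group,
                "txy_variant": (arch.txy_variant or "") if arch else "",
                "loops_found": arch.loops_found if arch else "",
                "length_aa": len(rec.sequence),
                "mass_kda": round(mass_kda, 2),
                "pi": round(properties.isoelectric_point(rec.sequence), 2),
                "chromosome": gm.chromosome if gm else "",
                "exon_count": len(gm.exons) if gm else pd.NA,
                "gene_length_nt": gm.length_nt if gm else pd.NA,
                "evidence": ",".join(call.evidence),
                "confirmed": call.confirmed,
                "domain_position": arch.domain_position if arch else "",
                "ambiguous_DE": ambiguous,
                "gene_id": rec.gene_id,
            }
        )

    table = pd.DataFrame(rows)
    counts = {fam: 0 for fam in FAMILIES}
    if not table.empty:
        for fam, cnt in table["family"].value_counts().items():
            if fam in counts:
                counts[fam] = int(cnt)
    summary = {
        "n_proteins": len(rows),
        "family_counts": counts,
        "mapkkk_total": counts["MEKK"] + counts["RAF"] + counts["ZIK"],
        "property_extrema": properties.summarize_inventory(table) if rows else {},
        "mode": config.mode,
    }
    return table, summary
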