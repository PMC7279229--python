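"""Seeded synthetic proteomes with planted kinase architecture and genome
context, plus the ground-truth manifest the tests compare against.

The generator emulates the structure the pipeline assumes: kinase-like
proteins carry, N- to C-terminal, a P-loop instance, a spacer, a C-loop
instance, a spacer and a family-specific activation-motif instance, embedded
in random background sequence; decoys are either pure background or
"near-miss" kinases whose activation motif is corrupted at one fixed
position. Genes are laid out on simulated chromosomes honoring requested
tandem pairs and clusters while guaranteeing — by construction — that no
*unplanned* same-family adjacency can form a pair or cluster.

Rejection sampling keeps the planted truth exact rather than statistical: a
sampled sequence is regenerated whenever background or wildcard draws would
complete an activation motif more specific than the intended one (which would
flip the family call), or any activation motif at all in a decoy.

The default family sizes (17 MAPK / 2 MAPKK / 11 MEKK / 94 RAF / 3 ZIK, with
3 TEY + 7 TDY MAPKs, eight RAF tandem pairs and RAF clusters of five and
three on separate chromosomes, 17 chromosomes) mirror the published
C. reinhardtii inventory this pipeline re-implements the analysis for.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import seqio
from .motifs import (
    AA20,
    FAMILY_PATTERNS,
    PATTERN_FAMILY,
    MotifPattern,
    builtin_registry,
    scan,
)
from .family import RAF_AC_ACT, RAF_G_ACT, RAF_H_ACT

AA_LIST = sorted(AA20)

FAMILY_TO_PATTERN = {fam: name for name, fam in PATTERN_FAMILY.items()}


class PlacementError(RuntimeError):
    """Requested tandem/cluster structure cannot be placed."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic proteome."""

    mapk: int = 17
    mapkk: int = 2
    mekk: int = 11
    raf: int = 94
    zik: int = 3
    txy_mix: dict = field(
        default_factory=lambda: {
            "TEY": 3 / 17, "TDY": 7 / 17, "TTY": 3 / 17, "TSY": 2 / 17, "TPY": 2 / 17,
        }
    )
    decoy_random: int = 170
    decoy_near_miss: int = 30
    n_chromosomes: int = 17
    tandem_pair_count: int = 8
    tandem_family: str = "RAF"
    cluster_spec: tuple = (("RAF", 5), ("RAF", 3))
    mu: float = 0.1  # per-site substitution rate of tandem duplicates
    exon_count_range: tuple[int, int] = (1, 14)
    n_flank_range: tuple[int, int] = (5, 60)
    pc_spacer_range: tuple[int, int] = (60, 200)
    ct_spacer_range: tuple[int, int] = (10, 60)
    tail_range: tuple[int, int] = (30, 250)
    seed: int = 0

    def __post_init__(self):
        for fam in ("mapk", "mapkk", "mekk", "raf", "zik"):
            if getattr(self, fam) < 0:
                raise ValueError(f"count {fam} must be >= 0")
        if abs(sum(self.txy_mix.values()) - 1.0) > 1e-9:
            raise ValueError("txy_mix proportions must sum to 1")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError("mu must be in [0, 1)")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")

    @property
    def family_counts(self) -> dict[str, int]:
        return {
            "MAPK": self.mapk, "MAPKK": self.mapkk, "MEKK": self.mekk,
            "RAF": self.raf, "ZIK": self.zik,
        }


# --- motif instance sampling ---------------------------------------------

def sample_motif_instance(
    pattern: MotifPattern,
    rng: np.random.Generator,
    forbid: tuple[MotifPattern, ...] = (),
    max_tries: int = 10_000,
) -> str:
    """A random string satisfying ``pattern``, rejection-sampled so that no
    pattern in ``forbid`` (typically the more specific family motifs) matches
    anywhere inside it."""
    for _ in range(max_tries):
        parts = []
        for e in pattern.elements:
            if e.allowed is None:
                reps = int(rng.integers(e.min_repeat, e.max_repeat + 1))
                parts.append("".join(rng.choice(AA_LIST, size=reps)))
            else:
                parts.append(str(rng.choice(sorted(e.allowed))))
        s = "".join(parts)
        if not any(scan(q, s) for q in forbid):
            assert pattern.matches_exact(s)
            return s
    raise RuntimeError(f"could not sample an instance of {pattern.name}")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AA_LIST, size=length))


def mutate_duplicate(
    sequence: str,
    mu: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
) -> str:
    """Substitute each unprotected site independently with probability mu
    (to a uniformly chosen *different* residue)."""
    if not (0.0 <= mu < 1.0):
        raise ValueError("mu must be in [0, 1)")
    out = list(sequence)
    hits = rng.random(len(sequence)) < mu
    for i in np.flatnonzero(hits):
        if int(i) in protected:
            continue
        alternatives = [c for c in AA_LIST if c != sequence[i]]
        out[i] = str(rng.choice(alternatives))
    return "".join(out)


# --- protein construction -------------------------------------------------

def _more_specific(registry, pattern_name: str) -> tuple[MotifPattern, ...]:
    nf = registry[pattern_name].n_fixed
    return tuple(
        registry[n] for n in FAMILY_PATTERNS if registry[n].n_fixed > nf
    )


def build_kinase(
    family: str,
    rng: np.random.Generator,
    config: SimulationConfig,
    registry,
    txy_variant: str | None = None,
    raf_group: str | None = None,
    max_tries: int = 200,
) -> tuple[str, dict]:
    """One kinase-like sequence plus its truth entry.

    Layout: N-flank | P-loop | spacer | C-loop | spacer | activation | tail.
    Spacers are drawn inside the confirmed-mode spacing windows. The whole
    sequence is rejection-sampled so that no activation motif more specific
    than the intended family's matches anywhere, and (for RAF) so the
    group-signature status matches what was planted.
    """
    if family == "MAPK" and txy_variant is None:
        txy_variant = "TEY"
    pat_name = FAMILY_TO_PATTERN[family]
    pattern = registry[pat_name]
    forbid = _more_specific(registry, pat_name)

    for _ in range(max_tries):
        if family == "RAF" and raf_group == "G":
            act = "GTRHYMAPEV"
        else:
            act = sample_motif_instance(pattern, rng, forbid)
            if family == "MAPK":
                act = "T" + txy_variant[1] + "Y" + act[3:]
        p_loop = sample_motif_instance(registry["p_loop"], rng)
        c_loop = sample_motif_instance(registry["c_loop"], rng)
        n_flank = _random_peptide(rng, int(rng.integers(*_inc(config.n_flank_range))))
        sp1 = _random_peptide(rng, int(rng.integers(*_inc(config.pc_spacer_range))))
        sp2 = _random_peptide(rng, int(rng.integers(*_inc(config.ct_spacer_range))))
        tail = _random_peptide(rng, int(rng.integers(*_inc(config.tail_range))))

        seq = n_flank + p_loop + sp1 + c_loop + sp2 + act + tail
        p_start = len(n_flank)
        c_start = p_start + len(p_loop) + len(sp1)
        t_start = c_start + len(c_loop) + len(sp2)
        t_end = t_start + len(act)

        if any(scan(q, seq) for q in forbid):
            continue
        if not any(m.start == t_start for m in scan(pattern, seq)):
            continue  # variant forcing may have broken the motif (cannot for these patterns)
        if family == "RAF" and not _raf_group_ok(seq, t_start, raf_group):
            continue

        truth = {
            "family": family,
            "group": _planted_group(family, txy_variant, raf_group),
            "txy_variant": txy_variant,
            "loops": {
                "p_loop": [p_start, p_start + len(p_loop)],
                "c_loop": [c_start, c_start + len(c_loop)],
                "t_loop": [t_start, t_end],
            },
            "is_decoy": False,
            "decoy_kind": None,
        }
        return seq, truth
    raise RuntimeError(f"could not build a clean {family} kinase")


def _inc(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def _raf_group_ok(seq: str, t_start: int, raf_group: str | None) -> bool:
    """Planted RAF group must equal what the signature rules will say."""
    is_g = any(m.start == t_start for m in scan(RAF_G_ACT, seq))
    if raf_group == "G":
        return is_g
    # plain RAFs must classify as 'unassigned': no G/H/AC signature at the site
    if is_g:
        return False
    if any(m.start == t_start for m in scan(RAF_H_ACT, seq)):
        return False
    if any(m.start == t_start for m in scan(RAF_AC_ACT, seq)):
        return False
    return True


def _planted_group(family, txy_variant, raf_group):
    if family == "MAPK":
        if txy_variant == "TEY":
            return "C"
        return "D" if txy_variant == "TDY" else "E"
    if family == "RAF":
        return raf_group or "unassigned"
    return ""


def build_random_decoy(
    rng: np.random.Generator, registry, length_range=(150, 600), max_tries: int = 200
) -> tuple[str, dict]:
    """Background-only decoy: no activation motif matches anywhere."""
    fam_patterns = [registry[n] for n in FAMILY_PATTERNS]
    for _ in range(max_tries):
        seq = _random_peptide(rng, int(rng.integers(*_inc(length_range))))
        if not any(scan(p, seq) for p in fam_patterns):
            return seq, {
                "family": None, "group": "", "txy_variant": None, "loops": None,
                "is_decoy": True, "decoy_kind": "random",
            }
    raise RuntimeError("could not build a random decoy")


def build_near_miss_decoy(
    rng: np.random.Generator, config: SimulationConfig, registry, max_tries: int = 200
) -> tuple[str, dict]:
    """A full kinase whose activation motif is broken at one fixed position,
    so the loops are present but no family motif matches."""
    fam_patterns = [registry[n] for n in FAMILY_PATTERNS]
    families = sorted(FAMILY_TO_PATTERN)
    for _ in range(max_tries):
        family = str(rng.choice(families))
        txy = str(rng.choice(sorted(config.txy_mix))) if family == "MAPK" else None
        seq, truth = build_kinase(family, rng, config, registry, txy_variant=txy)
        pattern = registry[FAMILY_TO_PATTERN[family]]
        t_start = truth["loops"]["t_loop"][0]

        fixed_offsets = _fixed_offsets(pattern, truth["loops"]["t_loop"], seq)
        off = int(rng.choice(fixed_offsets))
        original = seq[t_start + off]
        replacement = str(rng.choice([c for c in AA_LIST if c != original]))
        corrupted = seq[: t_start + off] + replacement + seq[t_start + off + 1 :]
        if not any(scan(p, corrupted) for p in fam_patterns):
            return corrupted, {
                "family": None, "group": "", "txy_variant": None,
                "loops": truth["loops"], "is_decoy": True, "decoy_kind": "near_miss",
            }
    raise RuntimeError("could not build a near-miss decoy")


def _fixed_offsets(pattern: MotifPattern, t_loop: list[int], seq: str) -> list[int]:
    """Offsets (within the planted activation instance) of single-residue
    pattern positions; wildcard repeats are re-derived from the instance
    length (all fixed elements sit at determined offsets only when at most
    one variable-length wildcard precedes them, which holds for the builtin
    activation motifs — their extra length is attributed to the wildcard)."""
    length = t_loop[1] - t_loop[0]
    extra = length - pattern.min_length
    offsets = []
    pos = 0
    for e in pattern.elements:
        reps = e.min_repeat
        if e.allowed is None and e.max_repeat > e.min_repeat:
            take = min(extra, e.max_repeat - e.min_repeat)
            reps += take
            extra -= take
        if e.allowed is not None and len(e.allowed) == 1:
            offsets.append(pos)
        pos += reps
    return offsets


# --- genome layout --------------------------------------------------------

@dataclass
class _Unit:
    genes: list[str]  # gene ids, in intended adjacent order
    family: str | None  # None for decoys
    kind: str  # single | pair | cluster


def _deal_units(units: list[_Unit], n_chrom: int, rng) -> list[list[_Unit]]:
    """Deal units to chromosomes, balancing each family separately so no
    chromosome is starved of the separator genes its family units need."""
    by_family: dict[str, list[_Unit]] = {}
    for u in units:
        by_family.setdefault(u.family or "", []).append(u)
    per: list[list[_Unit]] = [[] for _ in range(n_chrom)]
    for fam in sorted(by_family):
        fam_units = list(by_family[fam])
        rng.shuffle(fam_units)
        start = int(rng.integers(0, n_chrom))
        for k, u in enumerate(fam_units):
            per[(start + k) % n_chrom].append(u)
    return per


def _order_chromosome(units: list[_Unit], sep: int, rng) -> list[_Unit]:
    """Greedy interleave: between two units of the same family, at least
    ``sep`` genes of other families must intervene. Constrained families are
    placed most-units-first; raises PlacementError when stuck."""
    remaining = list(units)
    rng.shuffle(remaining)
    placed: list[_Unit] = []
    recent: list[str | None] = []  # family of each recently placed gene
    while remaining:
        blocked = {f for f in recent[-sep:] if f is not None} if sep else set()
        candidates = [u for u in remaining if u.family is None or u.family not in blocked]
        if not candidates:
            raise PlacementError("cannot separate same-family units")
        fam_units: dict[str, int] = {}
        for u in candidates:
            if u.family is not None:
                fam_units[u.family] = fam_units.get(u.family, 0) + 1
        if fam_units:
            # most remaining constrained units first, deterministic tie-break
            target = max(sorted(fam_units), key=lambda f: fam_units[f])
            pool = [u for u in candidates if u.family == target]
        else:
            pool = candidates
        pick = pool[int(rng.integers(0, len(pool)))]
        remaining.remove(pick)
        placed.append(pick)
        recent.extend([pick.family] * len(pick.genes))
    return placed


def _layout_genome(units: list[_Unit], config: SimulationConfig, rng, sep: int = 3):
    """Assign units to chromosomes and order each one; retries re-deal."""
    for _ in range(50):
        try:
            per = _deal_units(units, config.n_chromosomes, rng)
            return [_order_chromosome(chrom_units, sep, rng) for chrom_units in per]
        except PlacementError:
            continue
    raise PlacementError(
        "infeasible placement: not enough separator genes for the requested "
        "tandem/cluster structure"
    )


def _make_gene_model(
    gene_id: str, chrom: str, start: int, protein_len: int, rng, config
) -> seqio.GeneModel:
    cds = 3 * protein_len + 3
    lo, hi = config.exon_count_range
    k = int(rng.integers(lo, hi + 1))
    k = min(k, cds // 3)  # every exon needs >= 3 nt
    cuts = sorted(rng.choice(np.arange(1, cds // 3), size=k - 1, replace=False)) if k > 1 else []
    bounds = [0] + [3 * c for c in cuts] + [cds]
    exon_lens = [bounds[i + 1] - bounds[i] for i in range(k)]
    introns = [int(rng.integers(50, 501)) for _ in range(k - 1)]
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el - 1))
        pos += el
        if i < len(introns):
            pos += introns[i]
    strand = "+" if rng.random() < 0.5 else "-"
    return seqio.GeneModel(
        gene_id=gene_id,
        chromosome=chrom,
        strand=strand,
        gene_start=start,
        gene_end=exons[-1][1],
        exons=tuple(exons),
    )


def _write_gff3(gene_models: list[seqio.GeneModel], path: Path) -> None:
    lines = ["##gff-version 3"]
    for gm in gene_models:
        mrna = f"{gm.gene_id}.t1"
        lines.append(
            f"{gm.chromosome}\tkinsim\tgene\t{gm.gene_start}\t{gm.gene_end}\t.\t"
            f"{gm.strand}\t.\tID={gm.gene_id}"
        )
        lines.append(
            f"{gm.chromosome}\tkinsim\tmRNA\t{gm.gene_start}\t{gm.gene_end}\t.\t"
            f"{gm.strand}\t.\tID={mrna};Parent={gm.gene_id}"
        )
        for i, (s, e) in enumerate(gm.exons, 1):
            lines.append(
                f"{gm.chromosome}\tkinsim\texon\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                f"ID={mrna}.exon{i};Parent={mrna}"
            )
    path.write_text("\n".join(lines) + "\n")


# --- top-level simulation -------------------------------------------------

def _variant_assignment(n: int, mix: dict[str, float], rng) -> list[str]:
    """Exact largest-remainder apportionment of TxY variants, then shuffled."""
    names = sorted(mix)
    raw = {v: n * mix[v] for v in names}
    counts = {v: int(np.floor(raw[v])) for v in names}
    short = n - sum(counts.values())
    for v in sorted(names, key=lambda v: raw[v] - counts[v], reverse=True)[:short]:
        counts[v] += 1
    out = [v for v in names for _ in range(counts[v])]
    rng.shuffle(out)
    return out


def simulate_proteome(config: SimulationConfig, out_dir) -> tuple[Path, Path, dict]:
    """Generate FASTA + GFF3 + truth manifest under ``out_dir``.

    Deterministic given ``config.seed``; the manifest covers every record
    exactly once and lists the planted tandem pairs (including the chained
    pairs a planted cluster implies), clusters and per-chromosome gene order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    registry = builtin_registry()

    fam_counts = config.family_counts
    tandem_fam = config.tandem_family
    n_pair_genes = 2 * config.tandem_pair_count
    n_cluster_genes = sum(size for fam, size in config.cluster_spec if fam == tandem_fam)
    for fam, size in config.cluster_spec:
        if fam != tandem_fam and size > fam_counts.get(fam, 0):
            raise PlacementError(f"cluster of {size} exceeds {fam} count")
    if n_pair_genes + n_cluster_genes > fam_counts.get(tandem_fam, 0):
        raise PlacementError(
            f"tandem/cluster structure needs {n_pair_genes + n_cluster_genes} "
            f"{tandem_fam} genes but only {fam_counts.get(tandem_fam, 0)} requested"
        )

    sequences: dict[str, str] = {}
    truths: dict[str, dict] = {}
    units: list[_Unit] = []
    variants = _variant_assignment(config.mapk, config.txy_mix, rng)

    def new_protein(gene_id: str, seq: str, truth: dict) -> None:
        truth = dict(truth)
        truth["gene_id"] = gene_id
        sequences[gene_id] = seq
        truths[gene_id] = truth

    counters = {fam: 0 for fam in fam_counts}

    def next_id(fam: str) -> str:
        counters[fam] += 1
        return f"{fam}{counters[fam]}"

    # clusters first (they consume tandem-family genes)
    clusters_truth = []
    cluster_units = []
    for fam, size in config.cluster_spec:
        members = []
        for _ in range(size):
            gid = next_id(fam)
            raf_group = "G" if (fam == "RAF" and size >= 5) else None
            seq, truth = build_kinase(
                fam, rng, config, registry,
                txy_variant=None if fam != "MAPK" else variants[counters[fam] - 1],
                raf_group=raf_group,
            )
            new_protein(gid, seq, truth)
            members.append(gid)
        u = _Unit(members, fam, "cluster")
        cluster_units.append(u)
        units.append(u)
        clusters_truth.append({"family": fam, "members": members})

    # tandem pairs: second member is a mutated duplicate of the first
    pairs_truth = []
    for _ in range(config.tandem_pair_count):
        ga = next_id(tandem_fam)
        seq_a, truth_a = build_kinase(tandem_fam, rng, config, registry)
        new_protein(ga, seq_a, truth_a)
        gb = next_id(tandem_fam)
        protected = frozenset(
            i for span in truth_a["loops"].values() for i in range(span[0], span[1])
        )
        forbid = _more_specific(registry, FAMILY_TO_PATTERN[tandem_fam])
        for _ in range(200):
            seq_b = mutate_duplicate(seq_a, config.mu, rng, protected)
            if not any(scan(q, seq_b) for q in forbid) and _raf_group_ok(
                seq_b, truth_a["loops"]["t_loop"][0], None
            ):
                break
        truth_b = dict(truth_a)
        truth_b["duplicate_of"] = ga
        new_protein(gb, seq_b, truth_b)
        units.append(_Unit([ga, gb], tandem_fam, "pair"))
        pairs_truth.append([ga, gb])

    # remaining family members as singletons
    for fam, total in fam_counts.items():
        while counters[fam] < total:
            gid = next_id(fam)
            txy = variants[counters[fam] - 1] if fam == "MAPK" else None
            seq, truth = build_kinase(fam, rng, config, registry, txy_variant=txy)
            new_protein(gid, seq, truth)
            units.append(_Unit([gid], fam, "single"))

    # decoys
    for k in range(config.decoy_random):
        gid = f"DECR{k + 1}"
        seq, truth = build_random_decoy(rng, registry)
        new_protein(gid, seq, truth)
        units.append(_Unit([gid], None, "single"))
    for k in range(config.decoy_near_miss):
        gid = f"DECN{k + 1}"
        seq, truth = build_near_miss_decoy(rng, config, registry)
        new_protein(gid, seq, truth)
        units.append(_Unit([gid], None, "single"))

    # genome layout
    chromosomes = _layout_genome(units, config, rng)
    gene_models: list[seqio.GeneModel] = []
    chrom_order: dict[str, list[str]] = {}
    for c, chrom_units in enumerate(chromosomes, 1):
        chrom = f"chromosome_{c:02d}"
        pos = int(rng.integers(1, 5000))
        ids: list[str] = []
        for unit in chrom_units:
            for gid in unit.genes:
                gm = _make_gene_model(gid, chrom, pos, len(sequences[gid]), rng, config)
                gene_models.append(gm)
                ids.append(gid)
                pos = gm.gene_end + int(rng.integers(200, 2001))
        chrom_order[chrom] = ids

    # expected tandem pairs = planted pairs + chained pairs inside clusters
    expected_pairs = [list(p) for p in pairs_truth]
    for cl in clusters_truth:
        m = cl["members"]
        expected_pairs.extend([m[i], m[i + 1]] for i in range(len(m) - 1))

    records = [
        seqio.ProteinRecord(id=f"{gid}.t1", gene_id=gid, sequence=seq)
        for gid, seq in sequences.items()
    ]
    fasta_path = out_dir / "proteome.fasta"
    gff_path = out_dir / "genes.gff3"
    seqio.write_fasta(records, fasta_path)
    _write_gff3(sorted(gene_models, key=lambda g: (g.chromosome, g.gene_start)), gff_path)

    manifest = {
        "config": _config_dict(config),
        "proteins": {f"{gid}.t1": truths[gid] for gid in sequences},
        "chromosome_order": chrom_order,
        "tandem_pairs": pairs_truth,
        "expected_tandem_pairs": expected_pairs,
        "clusters": clusters_truth,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return fasta_path, gff_path, manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["cluster_spec"] = [list(cs) for cs in config.cluster_spec]
    return d


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
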