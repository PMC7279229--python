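"""Degenerate amino-acid motif language and exact scanner.

The consensus notation used throughout plant/algal kinase surveys is a small
degenerate language over the 20 standard residues:

* a single letter matches exactly that residue (``G``),
* ``x`` matches any standard residue,
* ``(A/B/...)`` matches any one of the listed residues at a single position,
* ``x{m,n}`` matches between ``m`` and ``n`` arbitrary residues (``1 <= m <= n``).

The unknown residue ``X`` never satisfies any pattern position, including
``x`` — gap-filled stretches of a proteome should not produce family calls.

Patterns are compiled to an element list and scanned exactly (no mismatch
tolerance): every occurrence, including overlapping ones and every wildcard
expansion length, is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


class PatternSyntaxError(ValueError):
    """Malformed motif pattern; ``column`` is the 0-based offset of the error."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


@dataclass(frozen=True)
class Element:
    """One pattern position: an allowed-residue set with a repeat range.

    ``allowed`` of ``None`` means "any standard residue" (the ``x`` wildcard).
    Only wildcards carry a repeat range other than (1, 1).
    """

    allowed: frozenset[str] | None
    min_repeat: int = 1
    max_repeat: int = 1

    def matches(self, residue: str) -> bool:
        if residue not in AA20:
            return False
        return self.allowed is None or residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate pattern.

    ``n_fixed`` counts the single-residue (fully determined) positions and is
    the specificity score used for family precedence.
    """

    name: str
    spec: str
    elements: tuple[Element, ...]
    n_fixed: int = field(init=False)

    def __post_init__(self):
        if not self.elements:
            raise ValueError("pattern has no elements")
        nf = sum(1 for e in self.elements if e.allowed is not None and len(e.allowed) == 1)
        object.__setattr__(self, "n_fixed", nf)

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_repeat for e in self.elements)

    def matches_exact(self, text: str) -> bool:
        """True iff ``text`` in its entirety satisfies the pattern."""
        return any(end == len(text) for end in _ends_at(self.elements, text, 0))


@dataclass(frozen=True)
class MotifMatch:
    """A located occurrence; coordinates are 0-based half-open on the protein."""

    pattern_name: str
    start: int
    end: int
    matched_text: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty match")
        if len(self.matched_text) != self.end - self.start:
            raise ValueError("matched_text length disagrees with coordinates")


def compile_pattern(spec: str, name: str = "") -> MotifPattern:
    """Compile a consensus string into a :class:`MotifPattern`.

    Raises :class:`PatternSyntaxError` (with the offending column) on malformed
    alternations or quantifiers.
    """
    elements: list[Element] = []
    i = 0
    n = len(spec)
    while i < n:
        c = spec[i]
        if c == "x":
            # optional quantifier {m,n}
            if i + 1 < n and spec[i + 1] == "{":
                j = spec.find("}", i + 1)
                if j == -1:
                    raise PatternSyntaxError("unterminated quantifier", i + 1)
                body = spec[i + 2 : j]
                parts = body.split(",")
                if len(parts) != 2 or not all(p.strip().isdigit() for p in parts):
                    raise PatternSyntaxError("quantifier must be {m,n} with integers", i + 2)
                m, M = int(parts[0]), int(parts[1])
                if not (1 <= m <= M):
                    raise PatternSyntaxError("quantifier requires 1 <= m <= n", i + 2)
                elements.append(Element(None, m, M))
                i = j + 1
            else:
                elements.append(Element(None))
                i += 1
        elif c == "(":
            j = spec.find(")", i)
            if j == -1:
                raise PatternSyntaxError("unterminated alternation", i)
            alts = spec[i + 1 : j].split("/")
            if not alts or any(len(a) != 1 or a not in AA20 for a in alts):
                raise PatternSyntaxError(
                    "alternation must list single residue letters separated by '/'", i + 1
                )
            elements.append(Element(frozenset(alts)))
            i = j + 1
        elif c in AA20:
            elements.append(Element(frozenset(c)))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {c!r}", i)
    if not elements:
        raise PatternSyntaxError("empty pattern", 0)
    return MotifPattern(name=name or spec, spec=spec, elements=tuple(elements))


def _ends_at(elements: tuple[Element, ...], seq: str, start: int) -> Iterator[int]:
    """Yield every end offset of a match of ``elements`` beginning at ``start``.

    Ends are yielded shortest-first (wildcard repeats are tried ascending), and
    duplicates can arise from distinct expansions of equal total length, so
    callers dedupe.
    """

    def rec(ei: int, pos: int) -> Iterator[int]:
        if ei == len(elements):
            yield pos
            return
        e = elements[ei]
        # consume min_repeat residues unconditionally, then optional extras
        p = pos
        for _ in range(e.min_repeat):
            if p >= len(seq) or not e.matches(seq[p]):
                return
            p += 1
        yield from rec(ei + 1, p)
        for _ in range(e.max_repeat - e.min_repeat):
            if p >= len(seq) or not e.matches(seq[p]):
                return
            p += 1
            yield from rec(ei + 1, p)

    yield from rec(0, start)


def scan(pattern: MotifPattern, sequence) -> list[MotifMatch]:
    """All occurrences of ``pattern`` in ``sequence``, leftmost-first.

    ``sequence`` is a string or anything with a ``.sequence`` attribute.
    Overlapping occurrences are all reported; at a fixed start, shorter
    wildcard expansions come first.
    """
    seq = getattr(sequence, "sequence", sequence)
    out: list[MotifMatch] = []
    last = len(seq) - pattern.min_length
    for start in range(last + 1):
        seen: set[int] = set()
        for end in _ends_at(pattern.elements, seq, start):
            if end in seen:
                continue
            seen.add(end)
            out.append(MotifMatch(pattern.name, start, end, seq[start:end]))
    return out


def find_phosphosites(sequence) -> list[int]:
    """0-based positions of S or T immediately followed by P (the minimal
    MAPK substrate site)."""
    seq = getattr(sequence, "sequence", sequence)
    return [i for i in range(len(seq) - 1) if seq[i] in "ST" and seq[i + 1] == "P"]


#: Consensus strings for the five activation motifs, the kinase loops and the
#: MAPKK S/T activation site, as printed in plant/algal MAPK surveys.
BUILTIN_SPECS: dict[str, str] = {
    "mapk_act": "TxYVxTRWYRAPE(L/V)",
    "mapkk_act": "GTx{2,3}YMSPER",
    "mekk_act": "G(T/S)Px(W/Y/F)MAPEV",
    "raf_act": "GTxx(W/Y)MAPE",
    "zik_act": "GTPEFMAPE(L/V)Y",
    "p_loop": "IGxGxxGxV",
    "c_loop": "HRD(L/I/V)KPxN",
    "mapkk_st": "(S/T)xxxxx(S/T)",
    "p_loop_loose": "GxGxxG",
}

#: Strict two-wildcard MAPKK activation search string (the literature's search
#: form; the default ``GTx{2,3}YMSPER`` also accepts the printed 11-residue
#: C. reinhardtii site GTVTTYMSPER).
STRICT_MAPKK_ACT = "GTxxYMSPER"

#: Names of the five family activation motifs, most- to least-specific.
FAMILY_PATTERNS = ("mapk_act", "zik_act", "mapkk_act", "mekk_act", "raf_act")

#: Activation-motif name -> family label.
PATTERN_FAMILY = {
    "mapk_act": "MAPK",
    "mapkk_act": "MAPKK",
    "mekk_act": "MEKK",
    "raf_act": "RAF",
    "zik_act": "ZIK",
}


def builtin_registry(strict_motifs: bool = False) -> dict[str, MotifPattern]:
    """Compile and return the built-in named motif set.

    With ``strict_motifs`` the MAPKK activation motif is the two-wildcard
    search form ``GTxxYMSPER`` instead of the default ``GTx{2,3}YMSPER``.
    """
    specs = dict(BUILTIN_SPECS)
    if strict_motifs:
        specs["mapkk_act"] = STRICT_MAPKK_ACT
    return {name: compile_pattern(s, name=name) for name, s in specs.items()}


def registry_to_json(registry: dict[str, MotifPattern]) -> str:
    """Serialize a registry (name, spec, n_fixed) for provenance records."""
    return json.dumps(
        {name: {"spec": p.spec, "n_fixed": p.n_fixed} for name, p in registry.items()},
        indent=2,
        sort_keys=True,
    )
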