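"""In-silico proteolysis for the six proteases used for sample digestion,
with missed-cleavage enumeration and peptide-to-database mapping.

Specificities (all fully specific; semi-specific digestion is not modelled):

========== ==================== ==========================
name        cleaves              exception
========== ==================== ==========================
trypsin     C-term of K/R        not before P
argc        C-term of R          not before P
chymotryp.  C-term of F/W/Y/L    not before P
lysc        C-term of K          --
lysn        N-term of K          --
mirror_tr.  N-term of K/R        --
========== ==================== ==========================

``mirror_trypsin`` mirrors trypsin's specificity to the N-terminal side; it
is a named, swappable rule.  N-terminal Met clipping is not applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .sepdb import SepDatabase

__all__ = [
    "ProteaseRule",
    "DigestProduct",
    "PROTEASES",
    "get_rule",
    "cleavage_sites",
    "digest",
    "map_peptides_to_seps",
    "PeptideMapping",
]


@dataclass(frozen=True)
class ProteaseRule:
    name: str
    cleave_residues: frozenset[str]
    side: str                       # 'C' or 'N'
    blocked_by_following_proline: bool = False


PROTEASES: dict[str, ProteaseRule] = {
    "trypsin": ProteaseRule("trypsin", frozenset("KR"), "C", True),
    "argc": ProteaseRule("argc", frozenset("R"), "C", True),
    "chymotrypsin": ProteaseRule("chymotrypsin", frozenset("FWYL"), "C", True),
    "lysc": ProteaseRule("lysc", frozenset("K"), "C"),
    "lysn": ProteaseRule("lysn", frozenset("K"), "N"),
    "mirror_trypsin": ProteaseRule("mirror_trypsin", frozenset("KR"), "N"),
}


def get_rule(name: str) -> ProteaseRule:
    try:
        return PROTEASES[name]
    except KeyError:
        raise ValueError(
            f"unknown protease {name!r}; known: {', '.join(sorted(PROTEASES))}"
        ) from None


@dataclass(frozen=True)
class DigestProduct:
    parent_id: str
    peptide: str
    start: int            # 0-based, half-open in parent
    end: int
    missed_cleavages: int


def cleavage_sites(protein: str, rule: ProteaseRule) -> list[int]:
    """Inter-residue cleavage indices (between protein[i-1] and protein[i])."""
    if not protein:
        raise ValueError("empty protein")
    sites = []
    for i in range(1, len(protein)):
        if rule.side == "C":
            hit = protein[i - 1] in rule.cleave_residues
            if hit and rule.blocked_by_following_proline and protein[i] == "P":
                hit = False
        else:
            hit = protein[i] in rule.cleave_residues
        if hit:
            sites.append(i)
    return sites


def digest(
    protein: str,
    rule: ProteaseRule,
    max_missed: int = 2,
    parent_id: str = "",
) -> list[DigestProduct]:
    """All fully-specific products spanning at most ``max_missed`` internal sites."""
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    bounds = [0] + cleavage_sites(protein, rule) + [len(protein)]
    out = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + max_missed + 2, len(bounds))):
            start, end = bounds[i], bounds[j]
            out.append(DigestProduct(parent_id, protein[start:end], start, end, j - i - 1))
    return out


@dataclass
class PeptideMapping:
    """Peptide-to-database map with uniqueness flags.

    ``hits`` maps peptide -> {sep_id: [(start, end, rule name, missed)]};
    ``unique`` flags peptides that are valid digest products of exactly one
    database entry; ``unmapped`` holds query peptides found in no entry.
    """

    hits: dict[str, dict[str, list[tuple[int, int, str, int]]]]
    unique: dict[str, bool]
    unmapped: set[str]


def map_peptides_to_seps(
    peptides: Iterable[str],
    db: SepDatabase,
    rules: Sequence[ProteaseRule] | None = None,
    max_missed: int = 2,
) -> PeptideMapping:
    """Locate each query peptide among the digest products of the database."""
    if rules is None:
        rules = list(PROTEASES.values())
    queries = set(peptides)
    hits: dict[str, dict[str, list[tuple[int, int, str, int]]]] = {q: {} for q in queries}
    for entry in db:
        for rule in rules:
            for prod in digest(entry.protein, rule, max_missed, entry.sep_id):
                if prod.peptide in queries:
                    hits[prod.peptide].setdefault(entry.sep_id, []).append(
                        (prod.start, prod.end, rule.name, prod.missed_cleavages)
                    )
    unique = {q: len(h) == 1 for q, h in hits.items() if h}
    unmapped = {q for q, h in hits.items() if not h}
    return PeptideMapping(
        hits={q: h for q, h in hits.items() if h},
        unique=unique,
        unmapped=unmapped,
    )
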