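"""Protein genotype bookkeeping.

A genotype is represented relative to a wildtype protein as a set of amino-acid
substitutions ``(site, alt)`` with 1-based sites.  The canonical text form is the
field-standard ``A123T`` notation, joined by ``:`` and sorted by site
(``""`` denotes the wildtype protein itself).  Stop codons appear as ``*``.
"""

from __future__ import annotations

import re
from collections.abc import Iterable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

_MUT_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def parse_mutation(token: str) -> tuple[str, int, str]:
    """Parse ``A123T`` into ``(ref, site, alt)``."""
    m = _MUT_RE.match(token)
    if m is None:
        raise ValueError(f"malformed mutation token: {token!r}")
    return m.group(1), int(m.group(2)), m.group(3)


def parse_mutation_set(text: str) -> frozenset[tuple[int, str]]:
    """Parse ``A5T:G7D`` into ``{(5, 'T'), (7, 'D')}`` (empty string → wildtype)."""
    if not text:
        return frozenset()
    return frozenset((s, a) for _, s, a in map(parse_mutation, text.split(":")))


def format_mutation_set(wildtype: str, mutations: Iterable[tuple[int, str]]) -> str:
    """Render substitutions in canonical sorted ``ref-site-alt`` notation."""
    toks = []
    for site, alt in sorted(mutations):
        toks.append(f"{wildtype[site - 1]}{site}{alt}")
    return ":".join(toks)


def apply_mutations(wildtype: str, mutations: Iterable[tuple[int, str]]) -> str:
    seq = list(wildtype)
    for site, alt in mutations:
        if not 1 <= site <= len(seq):
            raise ValueError(f"site {site} outside 1..{len(seq)}")
        seq[site - 1] = alt
    return "".join(seq)


def mutations_between(wildtype: str, protein: str) -> frozenset[tuple[int, str]]:
    if len(protein) != len(wildtype):
        raise ValueError("genotype length differs from wildtype")
    return frozenset(
        (i + 1, a) for i, (w, a) in enumerate(zip(wildtype, protein)) if a != w
    )


def hamming(a: frozenset[tuple[int, str]], b: frozenset[tuple[int, str]]) -> int:
    """Substitution distance between two genotypes given as mutation sets.

    Two genotypes of the same wildtype differ at a site iff exactly one of them
    mutates it, or both do but to different states.
    """
    sites_a = dict(a)
    sites_b = dict(b)
    sites = set(sites_a) | set(sites_b)
    return sum(1 for s in sites if sites_a.get(s) != sites_b.get(s))


def validate_protein(seq: str, allow_stop: bool = True) -> None:
    valid = set(AMINO_ACIDS) | ({STOP} if allow_stop else set())
    for i, a in enumerate(seq):
        if a not in valid:
            raise ValueError(f"unknown amino-acid symbol {a!r} at position {i + 1}")
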