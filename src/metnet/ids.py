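"""Accession-identifier conventions for KEGG entities.

Compounds are ``C`` + 5 digits, reactions ``R`` + 5 digits, reference
pathways a bare 5-digit number (organism-independent: the same number
denotes the same metabolic function in every organism). Identifiers are
compared by exact string equality throughout.
"""

from __future__ import annotations

import re

COMPOUND_PATTERN = re.compile(r"^C\d{5}$")
REACTION_PATTERN = re.compile(r"^R\d{5}$")
PATHWAY_PATTERN = re.compile(r"^\d{5}$")

#: Near-universal metabolites excluded from shared-compound edges:
#: water, ATP, ADP and phosphate. Overridable wherever a ubiquitous
#: list is accepted, since any fixed list is a curation choice.
DEFAULT_UBIQUITOUS: frozenset[str] = frozenset(
    {"C00001", "C00002", "C00008", "C00009"}
)


def is_compound_id(accession: str) -> bool:
    return bool(COMPOUND_PATTERN.match(accession))


def is_reaction_id(accession: str) -> bool:
    return bool(REACTION_PATTERN.match(accession))


def is_pathway_number(number: str) -> bool:
    return bool(PATHWAY_PATTERN.match(number))


def validate_pathway_number(number: str) -> str:
    """Return ``number`` if it is a valid 5-digit pathway number, else raise."""
    if not is_pathway_number(number):
        raise ValueError(f"invalid pathway number: {number!r}")
    return number


def strip_prefix(accession: str) -> str:
    """Drop a KEGG database prefix such as ``cpd:`` or ``rn:``."""
    _, _, tail = accession.rpartition(":")
    return tail
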