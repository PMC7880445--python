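"""Reading KGML (KEGG Markup Language) pathway files.

A KGML file describes one pathway map of one organism: ``entry``
elements carry the map's compound inventory (among genes, orthologs and
links to other maps) and ``reaction`` elements carry the chemical
reactions. Parsing extracts exactly what the two-level reconstruction
needs — the multiset of R-number reaction accessions and the set of
C-number compound accessions — and nothing else. Maplink entries
(``type="map"``) exist for display in KEGG and are intentionally
discarded. Reaction direction/reversibility attributes are ignored:
reactions are compared downstream as unoriented set or multiset members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

from lxml import etree

from .ids import is_compound_id, is_reaction_id, strip_prefix, validate_pathway_number

logger = logging.getLogger(__name__)

__all__ = ["KGMLError", "PathwayRecord", "parse_kgml", "parse_kgml_file", "load_organism"]


class KGMLError(ValueError):
    """Malformed or invalid KGML content."""


@dataclass(frozen=True)
class PathwayRecord:
    """Parsed content of one organism-pathway KGML file.

    Attributes
    ----------
    org_code : str
        Short KEGG organism code (e.g. ``"eco"``).
    pathway_number : str
        5-digit reference-pathway number; organism-independent.
    title : str
        Display name from the root element, ``""`` if absent.
    reaction_occurrences : Mapping[str, int]
        Multiset of reaction accessions: R-number -> occurrence count
        (>= 1). Empty for a physical pathway.
    compound_set : frozenset[str]
        Distinct C-numbers of the map's compound entries, unfiltered
        (ubiquitous compounds are removed later, at network build time).
    """

    org_code: str
    pathway_number: str
    title: str
    reaction_occurrences: Mapping[str, int]
    compound_set: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        validate_pathway_number(self.pathway_number)
        for acc, count in self.reaction_occurrences.items():
            if count < 1:
                raise ValueError(f"reaction count must be >= 1: {acc} -> {count}")

    @property
    def is_physical(self) -> bool:
        """True when the KGML carried no reaction information."""
        return not self.reaction_occurrences


def parse_kgml(xml_text: str | bytes, source: str = "<string>") -> PathwayRecord:
    """Parse one KGML document into a :class:`PathwayRecord`.

    Every R-number occurrence across all ``reaction`` declarations
    increments the multiset, so a declaration naming k space-separated
    accessions contributes k increments (including repeats of the same
    accession). Compounds come from ``entry type="compound"`` elements
    only; non-C accessions there (e.g. glycans) are skipped.

    Raises
    ------
    KGMLError
        On malformed XML, a non-``pathway`` root, or missing
        ``org``/``number`` attributes. Zero reactions is *not* an
        error: that is a physical (membrane-mechanism) pathway.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise KGMLError(f"malformed XML in {source}: {exc}") from exc
    if root.tag != "pathway":
        raise KGMLError(f"root element is <{root.tag}>, expected <pathway> in {source}")
    org = root.get("org")
    number = root.get("number")
    if not org or not number:
        raise KGMLError(f"missing org/number attributes on <pathway> in {source}")

    reactions: Counter[str] = Counter()
    compounds: set[str] = set()
    for entry in root.iterfind("entry"):
        if entry.get("type") != "compound":
            continue  # genes/orthologs/maplinks: out of scope by design
        for token in (entry.get("name") or "").split():
            acc = strip_prefix(token)
            if is_compound_id(acc):
                compounds.add(acc)
    for reaction in root.iterfind("reaction"):
        for token in (reaction.get("name") or "").split():
            acc = strip_prefix(token)
            if is_reaction_id(acc):
                reactions[acc] += 1
    return PathwayRecord(
        org_code=org,
        pathway_number=validate_pathway_number(number),
        title=root.get("title") or "",
        reaction_occurrences=dict(reactions),
        compound_set=frozenset(compounds),
    )


def parse_kgml_file(path: Path | str) -> PathwayRecord:
    path = Path(path)
    return parse_kgml(path.read_bytes(), source=str(path))


def load_organism(
    directory_path: Path | str,
    universe: list[str],
) -> dict[str, Optional[PathwayRecord]]:
    """Load all cached KGML files of one organism against a pathway universe.

    Files are expected to be named ``<org><number>.xml``. The returned
    map covers *every* universe number: either a parsed record or
    ``None``, the explicit marker that the KGML file does not exist —
    which is how KEGG encodes that the organism lacks the pathway.
    Files whose pathway number falls outside the universe are skipped
    with a warning; two files for the same number are an error.
    """
    directory_path = Path(directory_path)
    universe = [validate_pathway_number(n) for n in universe]
    result: dict[str, Optional[PathwayRecord]] = {n: None for n in universe}
    seen: dict[str, Path] = {}
    for path in sorted(directory_path.glob("*.xml")):
        record = parse_kgml_file(path)
        number = record.pathway_number
        if number not in result:
            logger.warning("skipping %s: pathway %s not in universe", path.name, number)
            continue
        if number in seen:
            raise KGMLError(
                f"duplicate KGML files for pathway {number}: {seen[number].name}, {path.name}"
            )
        seen[number] = path
        result[number] = record
    return result
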