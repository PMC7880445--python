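"""Synthetic organism fixtures: KGML generation and a brute-force oracle.

A :class:`FixtureSpec` fully determines a small group of synthetic
organisms — which reference pathways each one has, the reaction
multiset of each pathway, and the compound content that wires the
structural graph (including planted ubiquitous decoys that downstream
filtering must remove). From one spec the module can

* emit the corresponding KGML files byte-deterministically
  (:func:`generate`), exercising the full parse-and-build pipeline, and
* compute every similarity index by literal enumeration straight from
  the plans (:func:`oracle`), bypassing KGML and the main code path
  entirely, so pipeline results can be checked against an independent
  implementation.

Generated accessions live in reserved high ranges (``R9xxxx``,
``C9xxxx``, pathway numbers ``9xxxx``) so fixture files can never be
mistaken for real KEGG content in a mixed cache.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .ids import DEFAULT_UBIQUITOUS

__all__ = [
    "PathwayPlan",
    "OrganismPlan",
    "FixtureSpec",
    "OracleResult",
    "random_fixture_spec",
    "generate",
    "kgml_text",
    "oracle",
]


@dataclass(frozen=True)
class PathwayPlan:
    """One organism's plan for one present pathway.

    ``reactions`` empty means a physical pathway. ``compounds`` is the
    unfiltered compound inventory the KGML will carry, possibly
    including ubiquitous decoys.
    """

    reactions: Mapping[str, int] = field(default_factory=dict)
    compounds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for acc, count in self.reactions.items():
            if count < 1:
                raise ValueError(f"reaction multiplicity must be >= 1: {acc}={count}")


@dataclass(frozen=True)
class OrganismPlan:
    org_code: str
    # pathway number -> plan; numbers missing from the map are absent
    pathways: Mapping[str, PathwayPlan] = field(default_factory=dict)


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic description of a synthetic organism group."""

    seed: int
    universe: tuple[str, ...]
    organisms: tuple[OrganismPlan, ...]
    ubiquitous: frozenset[str] = DEFAULT_UBIQUITOUS

    def __post_init__(self) -> None:
        for org in self.organisms:
            extra = set(org.pathways) - set(self.universe)
            if extra:
                raise ValueError(
                    f"organism {org.org_code!r} plans pathways outside the universe: {sorted(extra)}"
                )

    def organism(self, org_code: str) -> OrganismPlan:
        for org in self.organisms:
            if org.org_code == org_code:
                return org
        raise KeyError(org_code)


def random_fixture_spec(
    seed: int,
    n_organisms: int = 2,
    n_pathways: int = 6,
    max_reactions: int = 15,
    max_multiplicity: int = 3,
    absent_prob: float = 0.15,
    physical_prob: float = 0.15,
    reaction_keep_prob: float = 0.6,
    compound_share_prob: float = 0.5,
    ubiquitous_decoy_prob: float = 0.5,
) -> FixtureSpec:
    """Sample a random organism group with controlled overlap.

    Reaction overlap between organisms arises from a shared per-pathway
    reaction pool that each organism subsamples (``reaction_keep_prob``),
    with per-organism multiplicities. Structural edges arise from
    per-pathway-pair dedicated compounds that each organism includes
    with probability ``compound_share_prob``; ubiquitous decoys are
    planted on top and must never create edges downstream.

    All sampling runs through one seeded generator in a fixed order, so
    a (seed, parameters) pair always yields the same spec.
    """
    rng = random.Random(seed)
    universe = tuple(f"9{i:04d}" for i in range(1, n_pathways + 1))
    # Per-pathway reaction pools (shared across organisms => overlap).
    pools = {
        p: [f"R9{i:04d}" for i in range(k * 100, k * 100 + max_reactions)]
        for k, p in enumerate(universe)
    }
    # One dedicated compound per unordered pathway pair, plus one
    # private compound per pathway.
    pair_compound = {}
    for i, p in enumerate(universe):
        for j in range(i + 1, len(universe)):
            pair_compound[(p, universe[j])] = f"C9{i:02d}{j:02d}"
    private_compound = {p: f"C98{k:03d}" for k, p in enumerate(universe)}
    ubiquitous_pool = sorted(DEFAULT_UBIQUITOUS)

    organisms = []
    for o in range(n_organisms):
        code = f"sy{chr(ord('a') + o)}"
        pathways: dict[str, PathwayPlan] = {}
        for p in universe:
            roll = rng.random()
            if roll < absent_prob:
                continue
            if roll < absent_prob + physical_prob:
                reactions: dict[str, int] = {}
            else:
                reactions = {
                    acc: rng.randint(1, max_multiplicity)
                    for acc in pools[p]
                    if rng.random() < reaction_keep_prob
                }
                if not reactions:  # keep the planned status a reaction pathway
                    reactions = {pools[p][0]: 1}
            compounds = {private_compound[p]}
            for pair, acc in sorted(pair_compound.items()):
                if p in pair and rng.random() < compound_share_prob:
                    compounds.add(acc)
            if rng.random() < ubiquitous_decoy_prob:
                compounds.add(rng.choice(ubiquitous_pool))
            pathways[p] = PathwayPlan(
                reactions=reactions, compounds=frozenset(compounds)
            )
        organisms.append(OrganismPlan(org_code=code, pathways=pathways))
    return FixtureSpec(seed=seed, universe=universe, organisms=tuple(organisms))


def kgml_text(org: OrganismPlan, number: str, plan: PathwayPlan) -> str:
    """Render one pathway plan as a KGML document.

    Entries and reactions are written in sorted-accession order and a
    maplink decoy entry is always included (parsers must ignore it), so
    output is byte-deterministic for a fixed plan.
    """
    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="path:{org.org_code}{number}" org="{org.org_code}" '
        f'number="{number}" title="Synthetic pathway {number}">',
        f'  <entry id="1" name="path:{org.org_code}00000" type="map"/>',
    ]
    next_id = 2
    for acc in sorted(plan.compounds):
        lines.append(f'  <entry id="{next_id}" name="cpd:{acc}" type="compound"/>')
        next_id += 1
    for acc in sorted(plan.reactions):
        name = " ".join([f"rn:{acc}"] * plan.reactions[acc])
        lines.append(
            f'  <reaction id="{next_id}" name="{name}" type="irreversible"/>'
        )
        next_id += 1
    lines.append("</pathway>")
    return "\n".join(lines) + "\n"


def generate(spec: FixtureSpec, out_dir: Path | str) -> dict[str, Path]:
    """Write the spec's KGML files plus a manifest; returns org -> directory.

    Layout mirrors the download cache: one directory per organism
    holding ``<org><number>.xml`` files for the present pathways only
    (absence is encoded, as in KEGG, by the file not existing).
    """
    out_dir = Path(out_dir)
    dirs: dict[str, Path] = {}
    for org in spec.organisms:
        org_dir = out_dir / org.org_code
        org_dir.mkdir(parents=True, exist_ok=True)
        for number in sorted(org.pathways):
            path = org_dir / f"{org.org_code}{number}.xml"
            path.write_text(kgml_text(org, number, org.pathways[number]))
        dirs[org.org_code] = org_dir
    manifest = [
        "[pathways]",
        "universe = " + " ".join(spec.universe),
        "",
        "[compounds]",
        "ubiquitous = " + " ".join(sorted(spec.ubiquitous)),
        "",
        "[fixture]",
        f"seed = {spec.seed}",
        "organisms = " + " ".join(org.org_code for org in spec.organisms),
    ]
    (out_dir / "manifest.ini").write_text("\n".join(manifest) + "\n")
    return dirs


# ---------------------------------------------------------------------------
# Independent oracle: literal enumeration from the plans. Shares no code
# with the similarity/network modules; set and multiset operations are
# carried out on expanded element lists rather than counter arithmetic.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OracleResult:
    sim_p: Mapping[str, float]
    sim_s: Mapping[str, float]
    psim: float
    psim_w: float
    ssim: float
    csim: float

    def globals_dict(self) -> dict[str, float]:
        return {
            "psim": self.psim,
            "psim_w": self.psim_w,
            "ssim": self.ssim,
            "csim": self.csim,
        }


def _expand(reactions: Mapping[str, int], multiset: bool) -> list[str]:
    out: list[str] = []
    for acc in sorted(reactions):
        out.extend([acc] * (reactions[acc] if multiset else 1))
    return out


def _common_elements(a: list[str], b: list[str]) -> int:
    remaining = list(b)
    common = 0
    for item in a:
        if item in remaining:
            remaining.remove(item)
            common += 1
    return common


def _neighbors(org: OrganismPlan, p: str, ubiquitous: frozenset[str]) -> set[str]:
    mine = {c for c in org.pathways[p].compounds if c not in ubiquitous}
    found = set()
    for q, plan in org.pathways.items():
        if q == p:
            continue
        for c in plan.compounds:
            if c not in ubiquitous and c in mine:
                found.add(q)
                break
    return found


def oracle(
    spec: FixtureSpec,
    mode: str = "set",
    org_a: int = 0,
    org_b: int = 1,
) -> OracleResult:
    """Expected indexes for one organism pair, enumerated from the plans."""
    multiset = {"set": False, "multiset": True}[mode]
    a, b = spec.organisms[org_a], spec.organisms[org_b]
    domain = [p for p in spec.universe if p in a.pathways or p in b.pathways]
    if not domain:
        raise ValueError("no pathway present in either organism of the pair")

    sim_p: dict[str, float] = {}
    sim_s: dict[str, float] = {}
    weights: dict[str, int] = {}
    for p in domain:
        in_a, in_b = p in a.pathways, p in b.pathways
        ra = _expand(a.pathways[p].reactions, multiset) if in_a else []
        rb = _expand(b.pathways[p].reactions, multiset) if in_b else []
        common = _common_elements(ra, rb)
        weights[p] = len(ra) + len(rb) - common
        if not (in_a and in_b):
            sim_p[p] = 0.0
            sim_s[p] = 0.0
            continue
        if not ra and not rb:
            sim_p[p] = 1.0  # physical in both
        else:
            sim_p[p] = common / (len(ra) + len(rb) - common)
        na = _neighbors(a, p, spec.ubiquitous)
        nb = _neighbors(b, p, spec.ubiquitous)
        if not na and not nb:
            sim_s[p] = 1.0
        elif not na or not nb:
            sim_s[p] = 1.0 / (1.0 + len(na or nb))
        else:
            sim_s[p] = len(na & nb) / len(na | nb)

    n = len(domain)
    psim = sum(sim_p.values()) / n
    ssim = sum(sim_s.values()) / n
    csim = sum(sim_p[p] * sim_s[p] for p in domain) / n
    total = sum(weights.values())
    psim_w = (
        math.nan
        if total == 0
        else sum(sim_p[p] * weights[p] for p in domain) / total
    )
    return OracleResult(
        sim_p=sim_p, sim_s=sim_s, psim=psim, psim_w=psim_w, ssim=ssim, csim=csim
    )
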