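from __future__ import annotations

from pathlib import Path

import pytest

from metnet.fixtures import FixtureSpec, generate
from metnet.kgml_io import PathwayRecord, load_organism
from metnet.network_model import TwoLevelNetwork, build_network


def make_network(
    plans: dict[str, tuple[dict[str, int], set[str]] | None],
    org_code: str = "org",
    universe: list[str] | None = None,
    ubiquitous: frozenset[str] = frozenset(),
) -> TwoLevelNetwork:
    """Build a network straight from (reactions, compounds) plans.

    ``plans[number] = None`` marks an absent pathway; an empty reaction
    dict makes a physical pathway.
    """
    universe = universe if universe is not None else sorted(plans)
    records = {}
    for number, plan in plans.items():
        if plan is None:
            records[number] = None
        else:
            reactions, compounds = plan
            records[number] = PathwayRecord(
                org_code=org_code,
                pathway_number=number,
                title=f"pathway {number}",
                reaction_occurrences=dict(reactions),
                compound_set=frozenset(compounds),
            )
    return build_network(records, universe, ubiquitous, org_code=org_code)


def networks_from_spec(spec: FixtureSpec) -> list[TwoLevelNetwork]:
    """Build networks straight from the spec's plans, bypassing KGML I/O."""
    nets = []
    for org in spec.organisms:
        records = {}
        for number in spec.universe:
            plan = org.pathways.get(number)
            if plan is None:
                records[number] = None
            else:
                records[number] = PathwayRecord(
                    org_code=org.org_code,
                    pathway_number=number,
                    title=f"Synthetic pathway {number}",
                    reaction_occurrences=dict(plan.reactions),
                    compound_set=frozenset(plan.compounds),
                )
        nets.append(
            build_network(
                records, list(spec.universe), spec.ubiquitous, org_code=org.org_code
            )
        )
    return nets


def pipeline_networks(spec: FixtureSpec, tmp_path: Path) -> list[TwoLevelNetwork]:
    """Run a fixture spec through the full KGML write/parse/build pipeline."""
    dirs = generate(spec, tmp_path)
    nets = []
    for org in spec.organisms:
        records = load_organism(dirs[org.org_code], list(spec.universe))
        nets.append(
            build_network(
                records, list(spec.universe), spec.ubiquitous, org_code=org.org_code
            )
        )
    return nets


@pytest.fixture
def simple_pair():
    """Two small hand-built organisms over a shared 4-pathway universe.

    Pathway 00010: identical reaction pathway in both; 00020: reaction
    pathway with partial overlap; 00030: physical in both; 00040:
    present only in organism a. Compounds wire 00010-00020 in both and
    00010-00030 in b only.
    """
    universe = ["00010", "00020", "00030", "00040"]
    net_a = make_network(
        {
            "00010": ({"R00001": 1, "R00002": 1}, {"C10000", "C12000"}),
            "00020": ({"R00002": 1, "R00003": 2}, {"C12000", "C20000"}),
            "00030": ({}, {"C30000"}),
            "00040": ({"R00009": 1}, {"C40000"}),
        },
        org_code="orga",
        universe=universe,
    )
    net_b = make_network(
        {
            "00010": ({"R00001": 1, "R00002": 1}, {"C10000", "C12000", "C13000"}),
            "00020": ({"R00003": 1, "R00004": 1}, {"C12000", "C20000"}),
            "00030": ({}, {"C30000", "C13000"}),
            "00040": None,
        },
        org_code="orgb",
        universe=universe,
    )
    return net_a, net_b
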