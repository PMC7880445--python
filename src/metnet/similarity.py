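"""Case-based similarity indexes for comparing two organisms' metabolisms.

Local indexes are computed per reference pathway P_i over the domain
D = pathways present in at least one of the two organisms:

``SimP_i`` (functional level)
    * Case 1 — present in exactly one organism: 0.
    * Case 2 — physical pathway in both (no reactions anywhere): 1.
    * Case 3 — reaction pathway in both: Jaccard |R ∩ R'| / |R ∪ R'|
      over reaction accessions, as plain sets or as multisets
      (intersection = per-accession min of counts, union = max,
      cardinality = sum of counts).
    * Case 3* — KGML exists in both but reactions in only one (a case
      the original scheme leaves open): the empty-vs-nonempty Jaccard,
      i.e. 0, flagged with its own label so reports can surface it.

``SimS_i`` (structural level)
    * Case 1 — node in exactly one structural graph: 0.
    * Case 2 — isolated in both graphs: 1.
    * Case 3 — isolated in one, degree k > 0 in the other: 1/(1+k),
      k read from the connected occurrence.
    * Case 4 — connected in both: Jaccard of the incident-edge sets,
      edges identified by their far-endpoint pathway number.

Global indexes over D (n = |D|):

* ``Psim``  = mean of SimP_i — pathway similarity;
* ``PsimW`` = Σ SimP_i·|R_i ∪ R_i'| / Σ |R_i ∪ R_i'| — union-size
  weighted mean; physical pathways weigh 0, so this index considers
  reaction pathways only, and is undefined (NaN) when no reaction
  pathway exists in either organism;
* ``Ssim``  = mean of SimS_i — structure similarity;
* ``Csim``  = mean of SimS_i·SimP_i — combined similarity, which
  amplifies differences since both factors lie in [0, 1].
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Mapping

from .network_model import PathwayStatus, TwoLevelNetwork, edge_set

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonMode",
    "PathwayComparisonRow",
    "PairwiseComparison",
    "sim_pathway",
    "sim_structure",
    "reaction_union_size",
    "compare_pair",
]


class ComparisonMode(enum.Enum):
    """Whether pathway reaction content is compared as a set or multiset."""

    SET = "set"
    MULTISET = "multiset"


def _jaccard_set(a: Mapping[str, int], b: Mapping[str, int]) -> tuple[float, int]:
    keys_a, keys_b = set(a), set(b)
    union = len(keys_a | keys_b)
    if union == 0:
        return 1.0, 0
    return len(keys_a & keys_b) / union, union


def _jaccard_multiset(a: Mapping[str, int], b: Mapping[str, int]) -> tuple[float, int]:
    keys = set(a) | set(b)
    inter = sum(min(a.get(k, 0), b.get(k, 0)) for k in keys)
    union = sum(max(a.get(k, 0), b.get(k, 0)) for k in keys)
    if union == 0:
        return 1.0, 0
    return inter / union, union


def reaction_union_size(
    net_a: TwoLevelNetwork, net_b: TwoLevelNetwork, p: str, mode: ComparisonMode
) -> int:
    """|R_i ∪ R_i'| in the given mode; the PsimW weight of pathway ``p``."""
    a, b = net_a.reactions.get(p, {}), net_b.reactions.get(p, {})
    if mode is ComparisonMode.SET:
        return len(set(a) | set(b))
    keys = set(a) | set(b)
    return sum(max(a.get(k, 0), b.get(k, 0)) for k in keys)


def sim_pathway(
    net_a: TwoLevelNetwork,
    net_b: TwoLevelNetwork,
    p: str,
    mode: ComparisonMode = ComparisonMode.SET,
) -> tuple[float, str]:
    """Functional similarity SimP_i of pathway ``p``, with its case label."""
    sa, sb = net_a.status[p], net_b.status[p]
    if sa is PathwayStatus.ABSENT and sb is PathwayStatus.ABSENT:
        raise ValueError(f"pathway {p} absent from both organisms (not in D)")
    if sa is PathwayStatus.ABSENT or sb is PathwayStatus.ABSENT:
        return 0.0, "1"
    if sa is PathwayStatus.PHYSICAL and sb is PathwayStatus.PHYSICAL:
        return 1.0, "2"
    jaccard = _jaccard_set if mode is ComparisonMode.SET else _jaccard_multiset
    value, _ = jaccard(net_a.reactions[p], net_b.reactions[p])
    if sa is not sb:  # physical vs reaction: one operand empty, Jaccard = 0
        return value, "3*"
    return value, "3"


def sim_structure(
    net_a: TwoLevelNetwork, net_b: TwoLevelNetwork, p: str
) -> tuple[float, str]:
    """Structural similarity SimS_i of pathway ``p``, with its case label."""
    present_a, present_b = net_a.is_present(p), net_b.is_present(p)
    if not present_a and not present_b:
        raise ValueError(f"pathway {p} absent from both organisms (not in D)")
    if present_a != present_b:
        return 0.0, "1"
    edges_a, edges_b = edge_set(net_a, p), edge_set(net_b, p)
    if not edges_a and not edges_b:
        return 1.0, "2"
    if not edges_a or not edges_b:
        k = len(edges_a or edges_b)
        return 1.0 / (1.0 + k), "3"
    union = edges_a | edges_b
    return len(edges_a & edges_b) / len(union), "4"


@dataclass(frozen=True)
class PathwayComparisonRow:
    pathway_number: str
    title: str
    sim_s: float
    sim_p: float
    sim_s_case: str
    sim_p_case: str
    reaction_union_size: int


@dataclass(frozen=True)
class PairwiseComparison:
    """Full comparison of two organisms: per-pathway rows + global indexes."""

    org_a: str
    org_b: str
    mode: ComparisonMode
    rows: tuple[PathwayComparisonRow, ...]
    psim: float
    psim_w: float  # NaN when no reaction pathway exists in either organism
    ssim: float
    csim: float

    @property
    def n(self) -> int:
        """Number of pathways present in at least one organism."""
        return len(self.rows)

    def globals_dict(self) -> dict[str, float]:
        return {
            "psim": self.psim,
            "psim_w": self.psim_w,
            "ssim": self.ssim,
            "csim": self.csim,
        }


def compare_pair(
    net_a: TwoLevelNetwork,
    net_b: TwoLevelNetwork,
    mode: ComparisonMode = ComparisonMode.SET,
) -> PairwiseComparison:
    """Compare two organisms over their common pathway universe.

    Both networks must have been built over the same universe and
    ubiquitous list so matrix positions correspond. Universe pathways
    absent from both organisms enter no sum and no denominator.
    """
    if net_a.universe != net_b.universe:
        raise ValueError("networks were built over different pathway universes")
    domain = [
        p for p in net_a.universe if net_a.is_present(p) or net_b.is_present(p)
    ]
    if not domain:
        raise ValueError("no pathway is present in either organism")

    rows = []
    for p in domain:
        p_value, p_case = sim_pathway(net_a, net_b, p, mode)
        s_value, s_case = sim_structure(net_a, net_b, p)
        rows.append(
            PathwayComparisonRow(
                pathway_number=p,
                title=net_a.titles[p] or net_b.titles[p],
                sim_s=s_value,
                sim_p=p_value,
                sim_s_case=s_case,
                sim_p_case=p_case,
                reaction_union_size=reaction_union_size(net_a, net_b, p, mode),
            )
        )

    n = len(rows)
    psim = sum(r.sim_p for r in rows) / n
    ssim = sum(r.sim_s for r in rows) / n
    csim = sum(r.sim_s * r.sim_p for r in rows) / n
    total_weight = sum(r.reaction_union_size for r in rows)
    if total_weight == 0:
        logger.warning(
            "PsimW undefined for %s vs %s: no reaction pathway in either organism",
            net_a.org_code,
            net_b.org_code,
        )
        psim_w = math.nan
    else:
        psim_w = sum(r.sim_p * r.reaction_union_size for r in rows) / total_weight

    return PairwiseComparison(
        org_a=net_a.org_code,
        org_b=net_b.org_code,
        mode=mode,
        rows=tuple(rows),
        psim=psim,
        psim_w=psim_w,
        ssim=ssim,
        csim=csim,
    )
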