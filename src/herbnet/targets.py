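"""Compound-target mapping from likelihood scores.

Ligand-based target prediction (weighted-ensemble-similarity style) emits one
likelihood score per compound-target pair; pairs at or above a cutoff
(default 7, inclusive) are accepted as direct interactions.  Accepted pairs
are deduplicated by UniProt accession — the accession, not the gene symbol,
is the target's identity — and summarized as an interaction set with
per-compound and per-target degrees.

The module also provides a deterministic bipartite degree-sequence
realization (Gale-Ryser feasibility check plus a greedy Havel-Hakimi-style
construction).  It is used to reconstruct a concrete compound-target edge
list from the two printed degree sequences of the reference tables, since the
original study prints degrees but not edges; the resulting fixture is shipped
as ``data/ct_edges_synthetic.tsv``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import HerbnetError, NetworkBuildError

__all__ = [
    "CompoundTargetPair",
    "InteractionSet",
    "threshold_pairs",
    "dedupe_targets",
    "is_bigraphical",
    "realize_bipartite_degrees",
]

DEFAULT_LIKELIHOOD_CUTOFF = 7.0


@dataclass(frozen=True)
class CompoundTargetPair:
    """A candidate compound-target interaction with its likelihood score."""

    compound_id: str
    target_uniprot: str
    likelihood: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.likelihood):
            raise HerbnetError(
                f"likelihood must be finite for "
                f"({self.compound_id}, {self.target_uniprot})")


@dataclass(frozen=True)
class InteractionSet:
    """Accepted pairs with unique targets and both degree maps.

    Satisfies the handshake identity: the compound-degree sum and the
    target-degree sum both equal the number of accepted pairs.
    """

    pairs: tuple[CompoundTargetPair, ...]
    targets: tuple[str, ...]                      # unique, first-seen order
    compound_degree: Mapping[str, int]
    target_degree: Mapping[str, int]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def edges(self) -> list[tuple[str, str]]:
        return [(p.compound_id, p.target_uniprot) for p in self.pairs]


def threshold_pairs(pairs: Iterable[CompoundTargetPair],
                    cutoff: float = DEFAULT_LIKELIHOOD_CUTOFF
                    ) -> list[CompoundTargetPair]:
    """Keep exactly the pairs with likelihood >= cutoff, preserving order.

    The comparison is inclusive: a score of exactly ``cutoff`` is accepted.
    """
    return [p for p in pairs if p.likelihood >= cutoff]


def dedupe_targets(accepted: Sequence[CompoundTargetPair]) -> InteractionSet:
    """Collapse accepted pairs into an interaction set with unique targets.

    Duplicate (compound, target) pairs are collapsed to one interaction.
    Blank accessions are rejected with the offending pair in the message.
    """
    seen_pairs: set[tuple[str, str]] = set()
    unique_pairs: list[CompoundTargetPair] = []
    targets: list[str] = []
    cdeg: dict[str, int] = {}
    tdeg: dict[str, int] = {}
    for p in accepted:
        if not p.target_uniprot.strip():
            raise HerbnetError(
                f"blank target accession in pair ({p.compound_id!r}, "
                f"{p.target_uniprot!r}, {p.likelihood})")
        key = (p.compound_id, p.target_uniprot)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        unique_pairs.append(p)
        if p.target_uniprot not in tdeg:
            targets.append(p.target_uniprot)
        cdeg[p.compound_id] = cdeg.get(p.compound_id, 0) + 1
        tdeg[p.target_uniprot] = tdeg.get(p.target_uniprot, 0) + 1
    assert sum(cdeg.values()) == sum(tdeg.values()) == len(unique_pairs)
    return InteractionSet(pairs=tuple(unique_pairs), targets=tuple(targets),
                          compound_degree=cdeg, target_degree=tdeg)


# ---------------------------------------------------------------------------
# Bipartite degree-sequence realization


def is_bigraphical(aseq: Sequence[int], bseq: Sequence[int]) -> bool:
    """Gale-Ryser feasibility of two bipartite degree sequences.

    ``aseq`` and ``bseq`` are realizable as a simple bipartite graph iff the
    sums agree and, with ``a`` sorted non-increasingly, every prefix satisfies
    ``sum_{i<=k} a_i <= sum_j min(b_j, k)``.
    """
    if any(d < 0 for d in aseq) or any(d < 0 for d in bseq):
        return False
    if sum(aseq) != sum(bseq):
        return False
    a = sorted(aseq, reverse=True)
    b = list(bseq)
    for k in range(1, len(a) + 1):
        lhs = sum(a[:k])
        rhs = sum(min(d, k) for d in b)
        if lhs > rhs:
            return False
    return True


def realize_bipartite_degrees(left: Mapping[str, int],
                              right: Mapping[str, int]
                              ) -> list[tuple[str, str]]:
    """Deterministically realize two degree sequences as a simple bipartite graph.

    Left nodes are processed in order of decreasing degree (ties by id); each
    is connected to the right nodes with the largest remaining demand (ties by
    id).  This greedy construction succeeds exactly when the Gale-Ryser
    condition holds, so infeasible sequences raise before any work is done.
    The output edge order — and hence the realized graph — is a pure function
    of the two input mappings.
    """
    if not is_bigraphical(list(left.values()), list(right.values())):
        raise NetworkBuildError(
            "degree sequences are not bigraphical (Gale-Ryser violated): "
            f"sums {sum(left.values())} vs {sum(right.values())}")
    remaining = dict(right)
    edges: list[tuple[str, str]] = []
    for lnode, d in sorted(left.items(), key=lambda kv: (-kv[1], kv[0])):
        partners = sorted(remaining, key=lambda t: (-remaining[t], t))[:d]
        if len(partners) < d or (d > 0 and remaining[partners[-1]] <= 0):
            raise NetworkBuildError(
                f"cannot satisfy degree {d} for node {lnode!r}")
        for t in partners:
            remaining[t] -= 1
            edges.append((lnode, t))
    assert all(v == 0 for v in remaining.values())
    return edges
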