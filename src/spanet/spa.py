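"""Selective-permissibility network expansion from a core protein set.

Starting from the proteins annotated to the process of interest (the core),
the expansion repeatedly examines every interactor of the current member set
and admits those whose three-aspect GO annotations fall within the
*annotation collection* — the aspect-wise union of the core proteins' terms
plus the three root "unknown" sentinels.  The sentinels guarantee that a
protein is never excluded solely for lacking curated literature data.  The
loop stops at the fixed point where no candidate is admitted, and the
returned network is the induced subgraph of the source interactome on the
member set (all source edges among members, not just discovery edges).

Two permissibility readings are offered for multiply-annotated proteins:

``any-per-aspect`` (default)
    each aspect contributes at least one term found in the collection;
``all-terms``
    every term of every aspect must be in the collection.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .data_model import (
    ASPECTS,
    SENTINELS,
    AnnotationCollection,
    AnnotationTable,
    induced_subgraph,
    require_nodes,
)
from .errors import MissingProteinError, ParameterError

PERMISSIBILITY_MODES = ("any", "all")


@dataclass(frozen=True)
class IterationRecord:
    iteration: int
    examined: int
    admitted: int
    rejected_by_aspect: dict[str, int]
    cumulative_nodes: int


@dataclass
class ExpansionLog:
    """Per-iteration admission counts (the expansion's audit trail)."""

    iterations: list[IterationRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.iterations],
                "examined": [r.examined for r in self.iterations],
                "admitted": [r.admitted for r in self.iterations],
                **{
                    f"rejected_{a}": [r.rejected_by_aspect[a] for r in self.iterations]
                    for a in ASPECTS
                },
                "cumulative_nodes": [r.cumulative_nodes for r in self.iterations],
            }
        )


def build_collection(
    core: Sequence[str], annotations: AnnotationTable
) -> AnnotationCollection:
    """Pool the core proteins' terms aspect-wise and add the three sentinels."""
    if not core:
        raise ParameterError("core set is empty")
    pooled = {a: {SENTINELS[a]} for a in ASPECTS}
    for p in core:
        if p not in annotations:
            raise MissingProteinError(f"core protein {p!r} has no annotation record")
        ann = annotations.get(p)
        for a in ASPECTS:
            pooled[a] |= ann.aspect(a)
    return AnnotationCollection(*(frozenset(pooled[a]) for a in ASPECTS))


def is_permissible(
    protein: str,
    annotations: AnnotationTable,
    collection: AnnotationCollection,
    mode: str = "any",
) -> bool:
    """Does the protein's annotation fall within the collection?

    Sentinel terms are members of every collection, so unannotated aspects
    always match under both modes.
    """
    if mode not in PERMISSIBILITY_MODES:
        raise ParameterError(f"unknown permissibility mode {mode!r}")
    ann = annotations.get(protein)
    for a in ASPECTS:
        terms, pool = ann.aspect(a), collection.aspect(a)
        if mode == "any":
            if not terms & pool:
                return False
        else:
            if not terms <= pool:
                return False
    return True


def failing_aspects(
    protein: str,
    annotations: AnnotationTable,
    collection: AnnotationCollection,
    mode: str = "any",
) -> list[str]:
    """Aspects on which the permissibility criterion fails (for logging)."""
    ann = annotations.get(protein)
    out = []
    for a in ASPECTS:
        terms, pool = ann.aspect(a), collection.aspect(a)
        ok = bool(terms & pool) if mode == "any" else terms <= pool
        if not ok:
            out.append(a)
    return out


def expand(
    core: Sequence[str],
    g: nx.Graph,
    annotations: AnnotationTable,
    mode: str = "any",
    collection: AnnotationCollection | None = None,
) -> tuple[nx.Graph, ExpansionLog]:
    """Expand the core to the permissibility fixed point.

    Each iteration examines all non-member interactors of the current member
    set; admission depends only on the candidate's own annotation, so the
    fixed point is independent of examination order and of the core list's
    ordering.  The final iteration (zero admissions) is recorded.
    """
    require_nodes(g, core, what="core protein")
    if collection is None:
        collection = build_collection(core, annotations)

    members = set(core)
    verdict: dict[str, bool] = {}  # cache: admission depends only on the candidate
    log = ExpansionLog()
    iteration = 0
    while True:
        iteration += 1
        candidates = sorted(
            {nb for m in members for nb in g.neighbors(m)} - members
        )
        rejected_by_aspect = {a: 0 for a in ASPECTS}
        admitted = []
        for c in candidates:
            if c not in verdict:
                verdict[c] = is_permissible(c, annotations, collection, mode)
            if verdict[c]:
                admitted.append(c)
            else:
                for a in failing_aspects(c, annotations, collection, mode):
                    rejected_by_aspect[a] += 1
        members.update(admitted)
        log.iterations.append(
            IterationRecord(
                iteration=iteration,
                examined=len(candidates),
                admitted=len(admitted),
                rejected_by_aspect=rejected_by_aspect,
                cumulative_nodes=len(members),
            )
        )
        if not admitted:
            break
    return induced_subgraph(g, members), log
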