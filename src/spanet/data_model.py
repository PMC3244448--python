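"""Core graph and annotation containers plus readers/writers.

The interactome is held as an undirected :class:`networkx.Graph` whose nodes
are case-sensitive protein symbol strings.  Construction always goes through
:func:`interactome_from_edges`, which enforces the simple-graph invariants
(no self-loops, no duplicate edges, nonempty identifiers).

Annotations are per-protein term sets in the three Gene Ontology aspects
(biological process, molecular function, cellular component).  A protein
whose aspect carries no curated term is represented by that aspect's root
"unknown" sentinel — the GO root term name — so poorly annotated proteins
are never silently dropped.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .errors import EmptyInteractomeError, FormatError, MissingProteinError

logger = logging.getLogger(__name__)

#: GO aspect names, in canonical order.
ASPECTS = ("process", "function", "component")

#: Root "unknown" sentinel term per aspect.  Reserved strings: a curated term
#: must never collide with these.
SENTINELS = {
    "process": "biological_process",
    "function": "molecular_function",
    "component": "cellular_component",
}

_ASPECT_CODES = {"P": "process", "F": "function", "C": "component"}

# BioGRID TAB 2.0 column names actually consumed.
_BG_A = "Official Symbol Interactor A"
_BG_B = "Official Symbol Interactor B"
_BG_SYS = "Experimental System Type"


def interactome_from_edges(
    edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()
) -> nx.Graph:
    """Build a simple undirected graph, dropping self-loops and duplicates.

    ``nodes`` may add isolated members.  Empty identifiers are rejected.
    """
    g = nx.Graph()
    for n in nodes:
        if not n:
            raise FormatError("empty protein identifier")
        g.add_node(n)
    for a, b in edges:
        if not a or not b:
            raise FormatError("empty protein identifier in edge")
        if a == b:
            continue
        g.add_edge(a, b)
    return g


@dataclass(frozen=True)
class Annotation:
    """One protein's three aspect term sets (sentinel-filled, never empty)."""

    process: frozenset[str]
    function: frozenset[str]
    component: frozenset[str]

    def aspect(self, name: str) -> frozenset[str]:
        return getattr(self, name)

    @classmethod
    def from_sets(cls, process=(), function=(), component=()) -> "Annotation":
        sets = {}
        for name, terms in zip(ASPECTS, (process, function, component)):
            terms = frozenset(terms)
            sets[name] = terms if terms else frozenset({SENTINELS[name]})
        return cls(**sets)


#: The all-sentinel annotation given to proteins with no curated record.
UNKNOWN_ANNOTATION = Annotation.from_sets()


class AnnotationTable:
    """Mapping from protein symbol to its three-aspect :class:`Annotation`.

    Lookups for proteins without an explicit record return the all-sentinel
    annotation; ``protein in table`` reports whether an explicit record
    exists.
    """

    def __init__(self, records: Mapping[str, Annotation] | None = None):
        self._records: dict[str, Annotation] = dict(records or {})

    def get(self, protein: str) -> Annotation:
        return self._records.get(protein, UNKNOWN_ANNOTATION)

    def set(self, protein: str, annotation: Annotation) -> None:
        self._records[protein] = annotation

    def __contains__(self, protein: str) -> bool:
        return protein in self._records

    def __len__(self) -> int:
        return len(self._records)

    def proteins(self) -> list[str]:
        return sorted(self._records)

    def ensure(self, proteins: Iterable[str]) -> None:
        """Give every listed protein an explicit (sentinel) record."""
        for p in proteins:
            self._records.setdefault(p, UNKNOWN_ANNOTATION)

    @classmethod
    def from_records(cls, rows: Iterable[tuple[str, str, str]]) -> "AnnotationTable":
        """Build from (protein, aspect code P/F/C, term) triples."""
        acc: dict[str, dict[str, set[str]]] = {}
        for i, (protein, code, term) in enumerate(rows, start=1):
            aspect = _ASPECT_CODES.get(code)
            if aspect is None:
                raise FormatError(f"unknown aspect code {code!r} at row {i}")
            acc.setdefault(protein, {a: set() for a in ASPECTS})[aspect].add(term)
        return cls(
            {
                p: Annotation.from_sets(
                    sets["process"], sets["function"], sets["component"]
                )
                for p, sets in acc.items()
            }
        )


@dataclass(frozen=True)
class AnnotationCollection:
    """Aspect-wise pooled term sets of the core proteins, sentinels included."""

    process: frozenset[str]
    function: frozenset[str]
    component: frozenset[str]

    def aspect(self, name: str) -> frozenset[str]:
        return getattr(self, name)

    def __len__(self) -> int:
        return len(self.process) + len(self.function) + len(self.component)


def read_interactions(path: str | Path, physical_only: bool = True) -> nx.Graph:
    """Read an interaction file into a simple undirected graph.

    Two dialects are sniffed from the first line: a BioGRID TAB 2.0-style
    header (official symbol columns plus experimental system type) or a bare
    two-column edge list (``#`` comment lines allowed).  With
    ``physical_only`` set, rows whose system type is not ``physical`` are
    dropped from the BioGRID dialect.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        lines = [ln for ln in fh if ln.strip()]
    header_fields = lines[0].rstrip("\n").split("\t") if lines else []

    rows_read = dropped_system = dropped_self = 0
    edges: list[tuple[str, str]] = []
    if _BG_A in header_fields or _BG_B in header_fields:
        for col in (_BG_A, _BG_B, _BG_SYS):
            if col not in header_fields:
                raise FormatError(f"missing required column {col!r} in {path}")
        ia, ib = header_fields.index(_BG_A), header_fields.index(_BG_B)
        isys = header_fields.index(_BG_SYS)
        for ln in lines[1:]:
            fields = ln.rstrip("\n").split("\t")
            rows_read += 1
            a, b, system = fields[ia], fields[ib], fields[isys]
            if physical_only and system.strip().lower() != "physical":
                dropped_system += 1
                continue
            if a == b:
                dropped_self += 1
                continue
            edges.append((a, b))
    else:
        for i, ln in enumerate(lines):
            if ln.startswith("#"):
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise FormatError(f"expected 2 tab-separated columns at line {i + 1} of {path}")
            rows_read += 1
            a, b = fields[0], fields[1]
            if a == b:
                dropped_self += 1
                continue
            edges.append((a, b))

    g = interactome_from_edges(edges)
    if g.number_of_edges() == 0:
        raise EmptyInteractomeError(f"empty interactome read from {path}")
    logger.info(
        "read_interactions(%s): %d rows, %d dropped (system type), %d dropped "
        "(self-interaction), %d collapsed duplicates -> %d nodes / %d edges",
        path, rows_read, dropped_system, dropped_self,
        rows_read - dropped_system - dropped_self - g.number_of_edges(),
        g.number_of_nodes(), g.number_of_edges(),
    )
    return g


def read_annotations(
    path: str | Path, interactome: nx.Graph | None = None
) -> AnnotationTable:
    """Read a GAF-style or 3-column (protein, aspect, term) annotation table.

    Full GAF 2.x rows (>= 15 tab fields; ``!`` comments) use the DB Object
    Symbol, GO ID and Aspect columns.  When an interactome is supplied, its
    proteins missing from the file get explicit all-sentinel records.
    """
    path = Path(path)
    triples: list[tuple[str, str, str]] = []
    with path.open(newline="") as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("!", "#")):
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) >= 15:  # GAF 2.x: symbol col 3, GO ID col 5, aspect col 9
                triples.append((fields[2], fields[8], fields[4]))
            elif len(fields) >= 3:
                triples.append((fields[0], fields[1], fields[2]))
            else:
                raise FormatError(f"expected >=3 columns in annotation file {path}")
    table = AnnotationTable.from_records(triples)
    if interactome is not None:
        table.ensure(interactome.nodes)
    return table


def write_network(g: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    """Write an interactome as a 2-column TSV or GraphML; round-trip exact."""
    if g.number_of_edges() == 0:
        raise EmptyInteractomeError("refusing to write an empty interactome")
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            fh.write("#interactor_a\tinteractor_b\n")
            for a, b in sorted(tuple(sorted(e)) for e in g.edges):
                w.writerow([a, b])
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {format!r}")


def read_network(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`write_network` (either format)."""
    path = Path(path)
    if path.suffix == ".graphml":
        return nx.read_graphml(path)
    return read_interactions(path)


def induced_subgraph(g: nx.Graph, keep: Iterable[str]) -> nx.Graph:
    """Subgraph on ``keep`` ∩ nodes(g); identifiers outside g are warned about."""
    keep = set(keep)
    extra = keep - set(g.nodes)
    if extra:
        logger.warning(
            "induced_subgraph: %d identifiers not in the graph ignored (e.g. %s)",
            len(extra), sorted(extra)[:3],
        )
    return g.subgraph(keep & set(g.nodes)).copy()


def read_core_list(path: str | Path) -> list[str]:
    """Read an ordered core protein list (one symbol per line, # comments)."""
    out: list[str] = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if ln and not ln.startswith("#"):
            out.append(ln.split("\t")[0])
    if not out:
        raise FormatError(f"no core proteins found in {path}")
    return out


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read input/output protein pairs (two tab-separated columns)."""
    pairs: list[tuple[str, str]] = []
    for i, ln in enumerate(Path(path).read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FormatError(f"expected input<TAB>output at line {i} of {path}")
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise FormatError(f"no pairs found in {path}")
    return pairs


def require_nodes(g: nx.Graph, proteins: Iterable[str], what: str = "protein") -> None:
    """Raise :class:`MissingProteinError` naming the first absent protein."""
    for p in proteins:
        if p not in g:
            raise MissingProteinError(f"{what} {p!r} absent from the network")
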