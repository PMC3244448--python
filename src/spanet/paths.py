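"""Exact enumeration of fixed-length linear paths and their spectrum metrics.

A *linear path* of node-length L between an input protein (typically a
membrane sensor) and an output protein (a transcriptional regulator) is a
simple path with exactly L members — the input, L−2 intermediates and the
output — i.e. L−1 edges, every one present in the analyzed network.  The
complete duplicate-free set of such paths for one input/output pair is a
*path spectrum*; comparing spectra across inputs sharing an output gives
the standard activity metrics: path counts, protein unions, unique
proteins, and core/overall protein coverage percentages.

Enumeration is an exhaustive depth-first search with visited-set pruning
plus an exact feasibility bound (a node further from the output than the
remaining step budget can never complete a path), which keeps the search
exact while skipping dead branches.  Paths are produced in lexicographic
order, making all downstream outputs deterministic.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from functools import cached_property

import networkx as nx

from .errors import ParameterError, PathExplosionError
from .data_model import require_nodes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathSpectrum:
    """All simple paths of fixed node-length between one input and one output."""

    input: str
    output: str
    length: int  # node count L (edges: L-1)
    paths: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.paths)

    @cached_property
    def members(self) -> frozenset[str]:
        """Union of all proteins on any path (endpoints included)."""
        out: set[str] = set()
        for p in self.paths:
            out.update(p)
        return frozenset(out)

    def position_members(self, position: int) -> frozenset[str]:
        """Proteins observed at a 1-based position (1 = input, L = output)."""
        self._check_position(position)
        return frozenset(p[position - 1] for p in self.paths)

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise ParameterError(
                f"position {position} outside 1..{self.length}"
            )

    def subset(self, paths: Iterable[tuple[str, ...]]) -> "PathSpectrum":
        return PathSpectrum(self.input, self.output, self.length, tuple(paths))


@dataclass(frozen=True)
class SpectrumMetrics:
    """Per input/output pair: counts and coverage percentages."""

    path_count: int
    protein_count: int
    unique_proteins: int
    cpc: float  # % of the network's core proteins present in the spectrum
    opc: float  # % of the network's proteins present in the spectrum


def enumerate_paths(
    g: nx.Graph, input: str, output: str, length: int = 6, cap: int = 2_000_000
) -> PathSpectrum:
    """Exhaustively enumerate simple paths with exactly ``length`` nodes.

    Raises :class:`PathExplosionError` (with the partial count) as soon as
    the cap is exceeded; enumeration is streaming, so memory stays
    proportional to the cap.
    """
    if input == output:
        raise ParameterError("input and output proteins must differ")
    if length < 3:
        raise ParameterError("path node-length must be at least 3")
    require_nodes(g, (input, output))

    # exact feasibility bound: hop distance from every node to the output
    dist = nx.single_source_shortest_path_length(g, output)
    budget = length - 1  # edges available from the input
    if dist.get(input, budget + 1) > budget:
        return PathSpectrum(input, output, length, ())

    adj = {v: sorted(g.neighbors(v)) for v in g.nodes}
    paths: list[tuple[str, ...]] = []
    path = [input]
    on_path = {input}
    # stack of neighbor iterators; DFS over sorted adjacency emits paths in
    # lexicographic order
    iters = [iter(adj[input])]
    while iters:
        remaining = budget - (len(path) - 1)  # edges still usable from path end
        nb = next(iters[-1], None)
        if nb is None:
            iters.pop()
            on_path.discard(path.pop())
            continue
        if nb in on_path:
            continue
        if nb == output:
            if remaining == 1:
                paths.append(tuple(path) + (output,))
                if len(paths) > cap:
                    raise PathExplosionError(cap, len(paths))
            continue
        if remaining == 1 or dist.get(nb, length) > remaining - 1:
            continue
        path.append(nb)
        on_path.add(nb)
        iters.append(iter(adj[nb]))
    return PathSpectrum(input, output, length, tuple(paths))


def participation(
    spectrum: PathSpectrum, position: int | str = "global"
) -> dict[str, float]:
    """Participation percentages of proteins in a spectrum.

    ``"global"``: percent of paths containing the protein anywhere.
    An integer position (1-based): percent of paths carrying the protein at
    exactly that position; these positional percentages sum to 100.
    """
    total = len(spectrum)
    if total == 0:
        raise ParameterError("participation of an empty spectrum is undefined")
    counts: dict[str, int] = {}
    if position == "global":
        for p in spectrum.paths:
            for v in set(p):
                counts[v] = counts.get(v, 0) + 1
    else:
        if not isinstance(position, int):
            raise ParameterError(f"invalid position {position!r}")
        spectrum._check_position(position)
        for p in spectrum.paths:
            v = p[position - 1]
            counts[v] = counts.get(v, 0) + 1
    return {v: 100.0 * c / total for v, c in sorted(counts.items())}


def spectrum_metrics(
    spectra: Mapping[str, PathSpectrum],
    core: Iterable[str],
    network: nx.Graph,
) -> dict[str, SpectrumMetrics]:
    """Table-style metrics for all inputs sharing one output protein.

    Unique proteins (UP) for an input are those present in that input's
    spectrum union and in no other provided input's union.  CPC is the
    percentage of the network's core proteins covered by the union; OPC the
    percentage of all network proteins covered.
    """
    outputs = {s.output for s in spectra.values()}
    if len(outputs) > 1:
        raise ParameterError(f"spectra mix several outputs: {sorted(outputs)}")
    core_in_net = {c for c in core} & set(network.nodes)
    n_net = network.number_of_nodes()
    unions = {inp: set(s.members) for inp, s in spectra.items()}
    out: dict[str, SpectrumMetrics] = {}
    for inp, s in spectra.items():
        if len(s) == 0:
            warnings.warn(f"empty path spectrum for pair ({inp}, {s.output})",
                          stacklevel=2)
            out[inp] = SpectrumMetrics(0, 0, 0, 0.0, 0.0)
            continue
        union = unions[inp]
        others: set[str] = set()
        for j, u in unions.items():
            if j != inp:
                others |= u
        out[inp] = SpectrumMetrics(
            path_count=len(s),
            protein_count=len(union),
            unique_proteins=len(union - others),
            cpc=100.0 * len(union & core_in_net) / len(core_in_net)
            if core_in_net
            else 0.0,
            opc=100.0 * len(union) / n_net if n_net else 0.0,
        )
    return out
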