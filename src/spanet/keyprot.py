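"""Step-specific key-protein extraction and heart-network assembly.

The decomposition turns a set of positional participation percentages into
a small key set via a frequency histogram:

1. bin the n participation values into k = round(√n) equal-width bins over
   (0, f_max] (left-open, right-closed);
2. form the cumulative percentage curve M_i (M_0 = 0, M_k = 100) and the
   per-bin increments D_i = M_i − M_{i−1};
3. compute fold changes F_i = D_i / D_{i+1} for i = 1..k−1 (undefined when
   D_{i+1} = 0);
4. the threshold bin is the highest-fold-change bin whose strict tail (the
   proteins in bins above it) holds at most 10% of the n proteins; failing
   that, the bin with the next greater fold change, and so on;
5. the key set is every protein with participation strictly above the
   threshold bin's upper edge.

The fold change peaks where the cumulative curve flattens, separating the
low-participation bulk from the high-participation tail.  When no bin
qualifies (pathological histograms the procedure was never designed for),
the fallback takes the top ⌊0.10·n⌋ proteins by participation and flags the
decomposition.

Applied iteratively along the intermediate positions of a length-6 path
spectrum (bait-and-hit: each step's keys filter the spectrum before the
next position is decomposed), this yields the four step-specific key sets
per input/output pair; pooling all pairs' sets with the inputs and outputs
gives the condensed "heart" network.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import networkx as nx

from .data_model import induced_subgraph
from .errors import ParameterError
from .paths import PathSpectrum, participation

logger = logging.getLogger(__name__)

FOLD_MODES = ("forward", "reciprocal")


@dataclass(frozen=True)
class HistogramDecomposition:
    """Full audit trail of one histogram decomposition."""

    n: int
    k: int
    f_max: float
    bin_width: float
    m: tuple[int, ...]            # bin counts, Σm = n
    M: tuple[float, ...]          # cumulative percentages, M_k = 100
    F: tuple[float | None, ...]   # fold changes for bins 1..k-1 (None = undefined)
    threshold_bin: int | None     # 1-based; None when the fallback was taken
    key_set: frozenset[str]
    fallback: bool
    trail: tuple[dict, ...]       # candidate bins in ranking order, with verdicts


def _bin_index(f: float, width: float, k: int) -> int:
    """1-based equal-width bin over (0, f_max]; right-closed edges."""
    idx = int(math.ceil(f / width - 1e-12))
    return min(max(idx, 1), k)


def decompose(
    frequencies: Mapping[str, float],
    fold: str = "forward",
    max_key_fraction: float = 0.10,
) -> HistogramDecomposition:
    """Histogram decomposition of participation percentages into a key set.

    ``fold="forward"`` uses F_i = D_i/D_{i+1} (default); ``"reciprocal"``
    uses D_{i+1}/D_i.  ``max_key_fraction`` is the 10% rule ("did not
    exceed" read inclusively).  All ties are broken deterministically:
    equal fold changes prefer the smaller bin index; the fallback ranks by
    (participation descending, identifier ascending).
    """
    if not frequencies:
        raise ParameterError("decompose requires a nonempty frequency mapping")
    if fold not in FOLD_MODES:
        raise ParameterError(f"unknown fold-change mode {fold!r}")
    for p, f in frequencies.items():
        if not 0.0 < f <= 100.0:
            raise ParameterError(f"frequency of {p!r} outside (0, 100]: {f}")

    n = len(frequencies)
    k = max(2, int(math.floor(math.sqrt(n) + 0.5)))  # round half up, min 2
    f_max = max(frequencies.values())
    width = f_max / k
    bins = {p: _bin_index(f, width, k) for p, f in frequencies.items()}

    m = [0] * k
    for b in bins.values():
        m[b - 1] += 1
    cum = 0
    M = []
    for c in m:
        cum += c
        M.append(100.0 * cum / n)
    D = [100.0 * c / n for c in m]
    F: list[float | None] = []
    for i in range(k - 1):
        num, den = (D[i], D[i + 1]) if fold == "forward" else (D[i + 1], D[i])
        F.append(num / den if den > 0 else None)

    # rank defined fold changes descending, ties by smaller bin index
    candidates = sorted(
        ((f_val, i + 1) for i, f_val in enumerate(F) if f_val is not None),
        key=lambda t: (-t[0], t[1]),
    )
    trail: list[dict] = []
    threshold_bin: int | None = None
    key_set: frozenset[str] = frozenset()
    limit = max_key_fraction * n
    for f_val, b in candidates:
        tail = {p for p, pb in bins.items() if pb > b}
        accepted = len(tail) <= limit
        trail.append(
            {"bin": b, "fold_change": f_val, "tail_size": len(tail),
             "accepted": accepted}
        )
        if accepted:
            threshold_bin = b
            key_set = frozenset(tail)
            break

    fallback = threshold_bin is None
    if fallback:
        take = int(math.floor(max_key_fraction * n))
        ranked = sorted(frequencies.items(), key=lambda t: (-t[1], t[0]))
        key_set = frozenset(p for p, _ in ranked[:take])
        logger.info(
            "decompose: no qualifying threshold bin; fallback took top %d of %d",
            take, n,
        )
    return HistogramDecomposition(
        n=n,
        k=k,
        f_max=f_max,
        bin_width=width,
        m=tuple(m),
        M=tuple(M),
        F=tuple(F),
        threshold_bin=threshold_bin,
        key_set=key_set,
        fallback=fallback,
        trail=tuple(trail),
    )


@dataclass(frozen=True)
class StepRecord:
    """One bait-and-hit step: the position decomposed and the subset it saw."""

    step: int            # 1-based step index (1..L-2)
    position: int        # path position decomposed (step + 1)
    subset_size: int     # number of paths the decomposition saw
    decomposition: HistogramDecomposition

    @property
    def keys(self) -> frozenset[str]:
        return self.decomposition.key_set


@dataclass(frozen=True)
class StepwiseResult:
    """Step-specific key sets for one input/output pair."""

    input: str
    output: str
    steps: tuple[StepRecord, ...]

    def key_sets(self) -> list[frozenset[str]]:
        return [s.keys for s in self.steps]

    def all_keys(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.steps:
            out |= s.keys
        return frozenset(out)


def stepwise_keys(spectrum: PathSpectrum, **decompose_kwargs) -> StepwiseResult:
    """Bait-and-hit extraction of key proteins at every intermediate position.

    Step s decomposes the positional participation at position s+1 of the
    current path subset, then keeps only paths whose member at that position
    is a key ("bait") before moving to the next position.  A step whose key
    set is empty (degenerate fallback) leaves the subset unchanged, flagged
    in its record.
    """
    if len(spectrum) == 0:
        raise ParameterError("stepwise_keys requires a nonempty spectrum")
    n_steps = spectrum.length - 2
    subset = spectrum
    records: list[StepRecord] = []
    for step in range(1, n_steps + 1):
        position = step + 1
        if len(subset) == 0:
            raise ParameterError(f"path subset became empty before step {step}")
        freqs = participation(subset, position)
        dec = decompose(freqs, **decompose_kwargs)
        records.append(
            StepRecord(step=step, position=position, subset_size=len(subset),
                       decomposition=dec)
        )
        if dec.key_set:
            subset = subset.subset(
                p for p in subset.paths if p[position - 1] in dec.key_set
            )
    return StepwiseResult(input=spectrum.input, output=spectrum.output,
                          steps=tuple(records))


def global_importants(
    spectrum: PathSpectrum,
    method: str = "histogram",
    top_fraction: float = 0.10,
    **decompose_kwargs,
) -> frozenset[str]:
    """Globally important proteins of a spectrum (endpoints excluded).

    ``"histogram"`` applies :func:`decompose` to the global participation of
    all non-endpoint members; ``"top-fraction"`` takes the top share by
    participation directly.
    """
    if len(spectrum) == 0:
        raise ParameterError("global_importants requires a nonempty spectrum")
    part = participation(spectrum, "global")
    part.pop(spectrum.input, None)
    part.pop(spectrum.output, None)
    if not part:
        return frozenset()
    if method == "histogram":
        return decompose(part, **decompose_kwargs).key_set
    if method == "top-fraction":
        take = int(math.floor(top_fraction * len(part)))
        ranked = sorted(part.items(), key=lambda t: (-t[1], t[0]))
        return frozenset(p for p, _ in ranked[:take])
    raise ParameterError(f"unknown method {method!r}")


@dataclass(frozen=True)
class HeartNetwork:
    """Pooled key proteins of all branches, with inputs/outputs, as a subgraph."""

    members: frozenset[str]
    graph: nx.Graph = field(hash=False, compare=False)
    coverage: Mapping[tuple[str, str], float]  # pair -> % of paths fully inside

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def assemble_heart(
    branches: Mapping[tuple[str, str], StepwiseResult],
    inputs: Iterable[str],
    outputs: Iterable[str],
    g: nx.Graph,
    spectra: Mapping[tuple[str, str], PathSpectrum] | None = None,
) -> HeartNetwork:
    """Pool all branches' step key sets with the inputs and outputs.

    The heart network is the induced subgraph of the analyzed network on
    that pooled member set.  When the full spectra are supplied, per-pair
    path coverage is the percentage of each pair's paths whose intermediate
    members all lie inside the heart.
    """
    members: set[str] = set(inputs) | set(outputs)
    for res in branches.values():
        members |= res.all_keys()
    members &= set(g.nodes)
    heart = induced_subgraph(g, members)
    coverage: dict[tuple[str, str], float] = {}
    if spectra:
        for pair, spec in spectra.items():
            if len(spec) == 0:
                coverage[pair] = 0.0
                continue
            inside = sum(
                1 for p in spec.paths if all(v in members for v in p[1:-1])
            )
            coverage[pair] = 100.0 * inside / len(spec)
    return HeartNetwork(members=frozenset(members), graph=heart, coverage=coverage)
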