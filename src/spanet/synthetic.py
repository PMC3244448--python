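"""Seeded synthetic annotated interactomes with planted ground truth.

Real interactome releases are large, versioned and not redistributable, so
every pipeline stage is exercised against generated data with known truth:

* :func:`generate_interactome` grows a connected preferential-attachment
  graph (heavy-tailed degree distribution, the regime real interactomes
  occupy);
* :func:`generate_annotations` plants an *admissible region* around a core
  protein set by stochastic breadth-first growth, then assigns three-aspect
  GO-style annotations so that a protein passes the selective-permissibility
  check exactly when it is in the region (inadmissible proteins receive one
  out-of-vocabulary term in a randomly chosen aspect — a minimal violation
  that defeats both permissibility modes);
* :func:`plant_backbone` wires a recoverable high-participation corridor
  between an input and an output protein: a backbone chain, per-position
  decoys attached to the backbone at adjacent positions, and a
  low-participation chaff tier attached to the decoys.  The chaff pads the
  per-position participation histograms — with fewer than ~10 participating
  proteins per position the 10% rule of the histogram decomposition can
  never admit a single key, so backbone recovery would be structurally
  impossible;
* :func:`corridor_fixture` and :func:`study_fixture` compose these into
  ready-to-run test beds.

All generators are pure functions of their seeds.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .data_model import (
    ASPECTS,
    SENTINELS,
    Annotation,
    AnnotationTable,
    interactome_from_edges,
    read_annotations,
    read_interactions,
    write_network,
)
from .errors import ParameterError

TRUTH_SCHEMA_VERSION = 1

_ASPECT_PREFIX = {"process": "GO:1", "function": "GO:2", "component": "GO:3"}
_VIOLATION_PREFIX = "GO:9"


@dataclass
class BackboneRecord:
    """One planted corridor: the backbone chain and its decoy/chaff tiers."""

    input: str
    output: str
    length: int
    backbone: list[str]              # intermediates, positions 2..L-1
    decoys: dict[int, list[str]]     # position -> decoy proteins
    chaff: dict[int, list[str]]      # position -> chaff proteins

    def position_of(self, protein: str) -> int | None:
        try:
            return self.backbone.index(protein) + 2
        except ValueError:
            return None


@dataclass
class FixtureTruth:
    """Ground truth written next to every generated fixture."""

    admissible: set[str] = field(default_factory=set)
    backbones: list[BackboneRecord] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": TRUTH_SCHEMA_VERSION,
                "admissible": sorted(self.admissible),
                "backbones": [
                    {
                        "input": b.input,
                        "output": b.output,
                        "length": b.length,
                        "backbone": b.backbone,
                        "decoys": {str(k): v for k, v in b.decoys.items()},
                        "chaff": {str(k): v for k, v in b.chaff.items()},
                    }
                    for b in self.backbones
                ],
                "seeds": self.seeds,
                "params": self.params,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "FixtureTruth":
        obj = json.loads(text)
        return cls(
            admissible=set(obj["admissible"]),
            backbones=[
                BackboneRecord(
                    input=b["input"],
                    output=b["output"],
                    length=b["length"],
                    backbone=list(b["backbone"]),
                    decoys={int(k): list(v) for k, v in b["decoys"].items()},
                    chaff={int(k): list(v) for k, v in b["chaff"].items()},
                )
                for b in obj["backbones"]
            ],
            seeds=list(obj["seeds"]),
            params=dict(obj["params"]),
        )


def generate_interactome(n: int, attachment: int = 2, seed: int = 0) -> nx.Graph:
    """Connected preferential-attachment interactome with n proteins.

    Node identifiers are protein-symbol-like strings whose order is a seeded
    permutation, so identifiers carry no degree information.
    """
    if attachment < 1:
        raise ParameterError("attachment must be >= 1")
    if n < attachment + 1:
        raise ParameterError(f"n={n} too small for attachment={attachment}")
    g0 = nx.barabasi_albert_graph(n, attachment, seed=seed)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    names = {i: f"YP{perm[i]:04d}W" for i in g0.nodes}
    return interactome_from_edges(
        ((names[a], names[b]) for a, b in g0.edges), nodes=names.values()
    )


def _draw_terms(rng, pool: list[str], unknown_prob: float, aspect: str):
    if not pool or rng.random() < unknown_prob:
        return frozenset({SENTINELS[aspect]})
    n_terms = int(rng.integers(1, min(3, len(pool)) + 1))
    picked = rng.choice(len(pool), size=n_terms, replace=False)
    return frozenset(pool[i] for i in picked)


def generate_annotations(
    g: nx.Graph,
    core: Sequence[str],
    vocab_sizes: tuple[int, int, int] = (30, 20, 15),
    admit_prob: float = 0.5,
    unknown_prob: float = 0.1,
    mode: str = "any",
    seed: int = 0,
    force_admissible: frozenset[str] | set[str] = frozenset(),
) -> tuple[AnnotationTable, FixtureTruth]:
    """Annotate a graph so the permissibility check recovers a planted region.

    The admissible region grows breadth-first from the core: each frontier
    neighbor of an admitted protein is itself admitted with probability
    ``admit_prob`` (members of ``force_admissible`` always).  Admissible
    proteins draw their terms from the core-pooled vocabulary (with
    ``unknown_prob`` per aspect of being the root sentinel); every other
    protein gets a fresh out-of-vocabulary term as the *only* term of one
    randomly chosen aspect, which fails the permissibility criterion under
    both the any-per-aspect and the all-terms mode.  The returned truth is
    therefore mode-independent; ``mode`` is validated and echoed.
    """
    for p_name, p_val in (("admit_prob", admit_prob), ("unknown_prob", unknown_prob)):
        if not 0.0 <= p_val <= 1.0:
            raise ParameterError(f"{p_name} must be in [0, 1], got {p_val}")
    if mode not in ("any", "all"):
        raise ParameterError(f"unknown permissibility mode {mode!r}")
    missing = [p for p in core if p not in g]
    if missing:
        raise ParameterError(f"core proteins absent from the graph: {missing}")

    rng = np.random.default_rng(seed)
    vocab = {
        a: [f"{_ASPECT_PREFIX[a]}{i:06d}" for i in range(size)]
        for a, size in zip(ASPECTS, vocab_sizes)
    }

    # core annotations first: they define the pooled collection vocabulary
    table = AnnotationTable()
    for p in core:
        table.set(
            p,
            Annotation(
                **{a: _draw_terms(rng, vocab[a], unknown_prob, a) for a in ASPECTS}
            ),
        )
    pooled = {
        a: sorted(
            set().union(*(table.get(p).aspect(a) for p in core)) - {SENTINELS[a]}
        )
        for a in ASPECTS
    }

    # planted admissible region: stochastic BFS growth from the core
    admissible = set(core)
    visited = set(core)
    frontier = sorted(core)
    while frontier:
        nxt: list[str] = []
        for member in frontier:
            for nb in sorted(g.neighbors(member)):
                if nb in visited:
                    continue
                visited.add(nb)
                if nb in force_admissible or rng.random() < admit_prob:
                    admissible.add(nb)
                    nxt.append(nb)
        frontier = nxt

    violation_counter = 0
    for p in sorted(g.nodes):
        if p in table:  # core proteins already annotated
            continue
        if p in admissible:
            table.set(
                p,
                Annotation(
                    **{
                        a: _draw_terms(rng, pooled[a], unknown_prob, a)
                        for a in ASPECTS
                    }
                ),
            )
        else:
            bad_aspect = ASPECTS[int(rng.integers(0, 3))]
            sets = {
                a: _draw_terms(rng, pooled[a], unknown_prob, a) for a in ASPECTS
            }
            sets[bad_aspect] = frozenset(
                {f"{_VIOLATION_PREFIX}{violation_counter:06d}"}
            )
            violation_counter += 1
            table.set(p, Annotation(**sets))

    truth = FixtureTruth(
        admissible=admissible,
        seeds=[seed],
        params={
            "vocab_sizes": list(vocab_sizes),
            "admit_prob": admit_prob,
            "unknown_prob": unknown_prob,
            "mode": mode,
            "core": list(core),
        },
    )
    return table, truth


def plant_backbone(
    g: nx.Graph,
    input: str,
    output: str,
    length: int = 6,
    corridor_width: int = 2,
    chaff_per_position: int | None = None,
    seed: int = 0,
) -> tuple[nx.Graph, BackboneRecord]:
    """Wire a recoverable corridor between two existing proteins.

    The corridor has three participation tiers at every intermediate
    position:

    * the backbone chain input—b2—…—b(L-1)—output;
    * ``corridor_width`` decoys per position, each attached to the backbone
      at the two adjacent positions and (between early positions) to the
      next position's decoys — decoys ride many paths, but always fewer
      than the backbone, whose extra chaff attachments multiply its
      continuations;
    * ``chaff_per_position`` low-participation chaff proteins per position,
      each attached to the backbone at the previous position and to a
      dedicated tail chain reaching the output — one path each, surviving
      bait-and-hit filtering because its prefix is the backbone.

    The decoy→decoy links deliberately stop before the last intermediate
    position so that the backbone also dominates there.  The chaff tier
    pads each position's participation histogram to ~10(1+width) proteins;
    with fewer, the 10% rule of the histogram decomposition could never
    accept a threshold bin and key recovery would be structurally
    impossible.  ``chaff_per_position`` defaults to 9*(corridor_width+1)+3.

    The seed only shuffles protein naming; the corridor topology is a
    deterministic function of its parameters.  Returns the augmented copy
    of the graph and the planted record.
    """
    if length < 3:
        raise ParameterError("backbone length must be at least 3 nodes")
    if input == output:
        raise ParameterError("input and output must differ")
    for p in (input, output):
        if p not in g:
            raise ParameterError(f"protein {p!r} absent from the graph")
    if chaff_per_position is None:
        # width 0 plants the bare chain (exactly one input->output path)
        chaff_per_position = 0 if corridor_width == 0 else 9 * (corridor_width + 1) + 3

    rng = np.random.default_rng(seed)
    tag = f"{rng.integers(0, 16**4):04x}"
    h = g.copy()
    positions = list(range(2, length))  # intermediate positions

    def fresh(name: str) -> str:
        candidate = f"{name}.{tag}"
        suffix = 0
        while candidate in h:
            suffix += 1
            candidate = f"{name}.{tag}x{suffix}"
        return candidate

    backbone = {1: input, length: output}
    for pos in positions:
        backbone[pos] = fresh(f"B{pos}")
        h.add_node(backbone[pos])
    for pos in range(1, length):
        h.add_edge(backbone[pos], backbone[pos + 1])

    decoys: dict[int, list[str]] = {}
    for pos in positions:
        decoys[pos] = []
        for i in range(corridor_width):
            d = fresh(f"D{pos}_{i}")
            decoys[pos].append(d)
            h.add_edge(d, backbone[pos - 1])
            h.add_edge(d, backbone[pos + 1])
    # decoy->decoy links between consecutive positions, stopping before the
    # last intermediate position (keeps the backbone dominant there)
    for pos in positions[:-1]:
        if pos + 1 <= length - 2:
            for d1 in decoys[pos]:
                for d2 in decoys[pos + 1]:
                    h.add_edge(d1, d2)

    chaff: dict[int, list[str]] = {pos: [] for pos in positions}
    for pos in positions:
        for i in range(chaff_per_position):
            c = fresh(f"C{pos}_{i}")
            chaff[pos].append(c)
            h.add_edge(c, backbone[pos - 1])
            prev = c  # dedicated tail chain to the output: one path per chaff
            for tail_pos in range(pos + 1, length):
                t = fresh(f"T{pos}_{i}_{tail_pos}")
                h.add_edge(prev, t)
                prev = t
            h.add_edge(prev, output)

    record = BackboneRecord(
        input=input,
        output=output,
        length=length,
        backbone=[backbone[pos] for pos in positions],
        decoys=decoys,
        chaff=chaff,
    )
    return h, record


def corridor_fixture(
    corridor_width: int = 2,
    seed: int = 0,
    base_n: int = 40,
    length: int = 6,
    chaff_per_position: int | None = None,
) -> tuple[nx.Graph, BackboneRecord]:
    """A corridor planted between two fresh endpoints on a small background.

    The output protein touches only the corridor and the input additionally
    one background protein, so every input→output path of the planted
    length runs through the corridor — the planted record is the complete
    truth for path-spectrum tests.
    """
    g = generate_interactome(base_n, attachment=2, seed=seed)
    rng = np.random.default_rng(seed)
    anchor = sorted(g.nodes)[int(rng.integers(0, g.number_of_nodes()))]
    g.add_edge("INPUT", anchor)
    g.add_node("OUTPUT")
    return plant_backbone(
        g,
        "INPUT",
        "OUTPUT",
        length=length,
        corridor_width=corridor_width,
        chaff_per_position=chaff_per_position,
        seed=seed,
    )


@dataclass
class StudyFixture:
    """A complete synthetic study: graph, annotations, core, pairs, truth."""

    graph: nx.Graph
    annotations: AnnotationTable
    core: list[str]
    pairs: list[tuple[str, str]]
    truth: FixtureTruth


def study_fixture(
    seed: int = 0,
    n: int = 300,
    attachment: int = 3,
    core_size: int = 6,
    admit_prob: float = 0.65,
    unknown_prob: float = 0.1,
    corridor_width: int = 3,
    n_inputs: int = 2,
    mode: str = "any",
) -> StudyFixture:
    """The packaged end-to-end fixture: a scaled-down annotated interactome.

    A preferential-attachment background, a core of ``core_size`` proteins
    (high-degree, so the admissible region is sizable), corridors planted
    from ``n_inputs`` input core proteins to one output core protein, and
    annotations making corridor members admissible.  The corridors are
    planted without chaff: the organic paths of the admissible region
    already provide the low-participation tier of the histograms.
    """
    g = generate_interactome(n, attachment=attachment, seed=seed)
    rng = np.random.default_rng(seed)
    by_degree = sorted(g.degree, key=lambda nd: (-nd[1], nd[0]))
    core = sorted(v for v, _ in by_degree[: core_size + n_inputs + 1])
    # inputs and the output are core members (as in real linear-path studies)
    picks = rng.choice(len(core), size=n_inputs + 1, replace=False)
    output = core[picks[0]]
    inputs = [core[i] for i in picks[1:]]

    corridor_members: set[str] = set()
    records: list[BackboneRecord] = []
    for j, inp in enumerate(inputs):
        g, rec = plant_backbone(
            g,
            inp,
            output,
            length=6,
            corridor_width=corridor_width,
            chaff_per_position=0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records.append(rec)
        corridor_members.update(rec.backbone)
        for vs in rec.decoys.values():
            corridor_members.update(vs)
        for vs in rec.chaff.values():
            corridor_members.update(vs)

    annotations, truth = generate_annotations(
        g,
        core,
        admit_prob=admit_prob,
        unknown_prob=unknown_prob,
        mode=mode,
        seed=seed,
        force_admissible=frozenset(corridor_members),
    )
    truth.backbones = records
    truth.params.update(
        {"n": n, "attachment": attachment, "corridor_width": corridor_width}
    )
    return StudyFixture(
        graph=g,
        annotations=annotations,
        core=core,
        pairs=[(inp, output) for inp in inputs],
        truth=truth,
    )


def write_fixture(
    g: nx.Graph,
    annotations: AnnotationTable,
    truth: FixtureTruth,
    directory: str | Path,
    core: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> None:
    """Write a fixture as interactions TSV, annotations TSV and truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_network(g, directory / "interactions.tsv", format="tsv")
    with (directory / "annotations.tsv").open("w") as fh:
        code = {"process": "P", "function": "F", "component": "C"}
        for p in annotations.proteins():
            ann = annotations.get(p)
            for a in ASPECTS:
                for term in sorted(ann.aspect(a)):
                    fh.write(f"{p}\t{code[a]}\t{term}\n")
    (directory / "truth.json").write_text(truth.to_json() + "\n")
    if core is not None:
        (directory / "core.tsv").write_text("".join(f"{p}\n" for p in core))
    if pairs is not None:
        (directory / "pairs.tsv").write_text(
            "".join(f"{a}\t{b}\n" for a, b in pairs)
        )


def read_fixture(directory: str | Path) -> tuple[nx.Graph, AnnotationTable, FixtureTruth]:
    """Read back a fixture written by :func:`write_fixture`."""
    directory = Path(directory)
    g = read_interactions(directory / "interactions.tsv")
    annotations = read_annotations(directory / "annotations.tsv", interactome=g)
    truth = FixtureTruth.from_json((directory / "truth.json").read_text())
    return g, annotations, truth
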