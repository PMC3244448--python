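"""End-to-end orchestration: reconstruct → tune → topology → paths → keys → heart.

Every stage reads the previous stage's outputs from the run directory, so
each is independently re-runnable with identical results.  All randomness
flows through explicit seeds recorded in the run manifest, together with
parameters and SHA-256 digests of every output file — two runs with the
same config produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import keyprot, paths as lp, spa, synthetic, topology, tuning
from .data_model import (
    read_annotations,
    read_core_list,
    read_interactions,
    read_pairs,
    write_network,
)
from .errors import ParameterError, SpanetError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One seeded pipeline run (YAML-loadable; echoed into the manifest)."""

    interactions: str = "interactions.tsv"
    annotations: str = "annotations.tsv"
    core: str = "core.tsv"
    pairs: str = "pairs.tsv"
    outdir: str = "run"
    mode: str = "any"              # SPA permissibility mode
    alpha: float = 0.001
    n_random: int = 100
    swaps_per_edge: int = 10
    statistic: str = "paired"
    protect_core: bool = False
    length: int = 6
    cap: int = 2_000_000
    seed: int = 0
    fold: str = "forward"          # histogram fold-change reading

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(obj) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Manifest:
    config: dict
    stages: list[dict] = field(default_factory=list)
    digests: dict = field(default_factory=dict)

    def record(self, stage: str, seconds: float, outputs: dict) -> None:
        self.stages.append({"stage": stage, "wall_seconds": round(seconds, 3)})
        self.digests.update(outputs)

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {"config": self.config, "stages": self.stages, "digests": self.digests},
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )


def _digest_outputs(outdir: Path, names: list[str]) -> dict:
    return {n: _sha256(outdir / n) for n in names}


def stage_reconstruct(config: RunConfig, outdir: Path) -> nx.Graph:
    g = read_interactions(config.interactions)
    core = read_core_list(config.core)
    annotations = read_annotations(config.annotations, interactome=g)
    network, log = spa.expand(core, g, annotations, mode=config.mode)
    write_network(network, outdir / "reconstructed.tsv", format="tsv")
    write_network(network, outdir / "reconstructed.graphml", format="graphml")
    log.to_dataframe().to_csv(outdir / "expansion_log.tsv", sep="\t", index=False)
    return network

def stage_tune(config: RunConfig, outdir: Path, network: nx.Graph) -> nx.Graph:
    protect = set(read_core_list(config.core)) if config.protect_core else None
    tuned, report = tuning.tune(
        network,
        alpha=config.alpha,
        n_random=config.n_random,
        swaps_per_edge=config.swaps_per_edge,
        seed=config.seed,
        statistic=config.statistic,
        protect=protect,
    )
    write_network(tuned, outdir / "tuned.tsv", format="tsv")
    write_network(tuned, outdir / "tuned.graphml", format="graphml")
    report.table.to_csv(
        outdir / "tuning_report.tsv", sep="\t", index=False, float_format="%.10g"
    )
    (outdir / "tuning_summary.json").write_text(
        json.dumps(report.summary_dict(), indent=2, sort_keys=True) + "\n"
    )
    return tuned


def stage_topology(config: RunConfig, outdir: Path, network: nx.Graph) -> dict:
    summ = topology.summary(network).to_dict()
    (outdir / "topology.json").write_text(
        json.dumps(summ, indent=2, sort_keys=True) + "\n"
    )
    cc = nx.clustering(network)
    bc = tuning.betweenness(network)
    pd.DataFrame(
        {
            "node": sorted(network.nodes),
            "degree": [network.degree[v] for v in sorted(network.nodes)],
            "clustering": [cc[v] for v in sorted(network.nodes)],
            "betweenness": [bc[v] for v in sorted(network.nodes)],
        }
    ).to_csv(outdir / "node_stats.tsv", sep="\t", index=False, float_format="%.10g")
    return summ


def stage_paths(
    config: RunConfig, outdir: Path, network: nx.Graph
) -> dict[tuple[str, str], lp.PathSpectrum]:
    if not Path(config.pairs).exists():
        raise SpanetError(f"paths stage: pairs file {config.pairs!r} not found")
    pairs = read_pairs(config.pairs)
    core = read_core_list(config.core)
    spectra: dict[tuple[str, str], lp.PathSpectrum] = {}
    for inp, outp in pairs:
        spec = lp.enumerate_paths(network, inp, outp, length=config.length,
                                  cap=config.cap)
        spectra[(inp, outp)] = spec
        with (outdir / f"paths_{inp}_{outp}.tsv").open("w") as fh:
            for p in spec.paths:
                fh.write("\t".join(p) + "\n")
    rows = []
    for outp in sorted({o for _, o in spectra}):
        by_input = {i: s for (i, o), s in spectra.items() if o == outp}
        metrics = lp.spectrum_metrics(by_input, core, network)
        for inp in sorted(by_input):
            m = metrics[inp]
            rows.append(
                (inp, outp, m.path_count, m.protein_count, m.unique_proteins,
                 round(m.cpc, 1), round(m.opc, 1))
            )
    pd.DataFrame(
        rows,
        columns=["input", "output", "n_paths", "n_proteins", "n_unique", "cpc_pct",
                 "opc_pct"],
    ).to_csv(outdir / "path_metrics.tsv", sep="\t", index=False)
    return spectra


def stage_keyprot(
    config: RunConfig,
    outdir: Path,
    network: nx.Graph,
    spectra: dict[tuple[str, str], lp.PathSpectrum],
) -> keyprot.HeartNetwork:
    branches: dict[tuple[str, str], keyprot.StepwiseResult] = {}
    audit_rows = []
    key_rows = []
    for pair, spec in sorted(spectra.items()):
        if len(spec) == 0:
            logger.warning("keyprot: empty spectrum for pair %s skipped", pair)
            continue
        res = keyprot.stepwise_keys(spec, fold=config.fold)
        branches[pair] = res
        for rec in res.steps:
            dec = rec.decomposition
            audit_rows.append(
                (pair[0], pair[1], rec.step, rec.position, rec.subset_size, dec.n,
                 dec.k, dec.threshold_bin if dec.threshold_bin is not None else -1,
                 int(dec.fallback), len(dec.key_set))
            )
            for p in sorted(rec.keys):
                key_rows.append((pair[0], pair[1], rec.step, p))
    pd.DataFrame(
        audit_rows,
        columns=["input", "output", "step", "position", "subset_size",
                 "n_participants", "n_bins", "threshold_bin", "fallback", "n_keys"],
    ).to_csv(outdir / "keyprot_audit.tsv", sep="\t", index=False)
    pd.DataFrame(
        key_rows, columns=["input", "output", "step", "protein"]
    ).to_csv(outdir / "key_proteins.tsv", sep="\t", index=False)

    inputs = {i for i, _ in spectra}
    outputs = {o for _, o in spectra}
    heart = keyprot.assemble_heart(branches, inputs, outputs, network,
                                   spectra=spectra)
    if heart.graph.number_of_edges() > 0:
        write_network(heart.graph, outdir / "heart.tsv", format="tsv")
        write_network(heart.graph, outdir / "heart.graphml", format="graphml")
    pd.DataFrame(
        [(i, o, round(c, 2)) for (i, o), c in sorted(heart.coverage.items())],
        columns=["input", "output", "coverage_pct"],
    ).to_csv(outdir / "heart_coverage.tsv", sep="\t", index=False)
    return heart


def run_all(config: RunConfig) -> Manifest:
    """Execute all stages in order, recording the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config=config.to_dict())

    def timed(stage, fn, outputs):
        t0 = time.perf_counter()
        try:
            result = fn()
        except SpanetError as exc:
            raise SpanetError(f"stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, time.perf_counter() - t0,
                        _digest_outputs(outdir, outputs))
        return result

    network = timed(
        "reconstruct",
        lambda: stage_reconstruct(config, outdir),
        ["reconstructed.tsv", "reconstructed.graphml", "expansion_log.tsv"],
    )
    tuned = timed(
        "tune",
        lambda: stage_tune(config, outdir, network),
        ["tuned.tsv", "tuned.graphml", "tuning_report.tsv", "tuning_summary.json"],
    )
    timed(
        "topology",
        lambda: stage_topology(config, outdir, tuned),
        ["topology.json", "node_stats.tsv"],
    )
    spectra = timed(
        "paths",
        lambda: stage_paths(config, outdir, tuned),
        ["path_metrics.tsv"],
    )
    timed(
        "keyprot",
        lambda: stage_keyprot(config, outdir, tuned, spectra),
        ["keyprot_audit.tsv", "key_proteins.tsv", "heart_coverage.tsv"],
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def simulate(
    directory: str | Path,
    seed: int = 0,
    n: int = 300,
    corridor_width: int = 3,
    **fixture_kwargs,
) -> synthetic.StudyFixture:
    """Generate and write a ready-to-run synthetic study fixture."""
    fx = synthetic.study_fixture(seed=seed, n=n, corridor_width=corridor_width,
                                 **fixture_kwargs)
    synthetic.write_fixture(
        fx.graph, fx.annotations, fx.truth, directory, core=fx.core, pairs=fx.pairs
    )
    return fx


def config_for_fixture(directory: str | Path, outdir: str | Path,
                       seed: int = 0, **overrides) -> RunConfig:
    """A RunConfig pointing at a fixture directory written by :func:`simulate`."""
    d = Path(directory)
    return RunConfig(
        interactions=str(d / "interactions.tsv"),
        annotations=str(d / "annotations.tsv"),
        core=str(d / "core.tsv"),
        pairs=str(d / "pairs.tsv"),
        outdir=str(outdir),
        seed=seed,
        **overrides,
    )
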