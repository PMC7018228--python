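"""End-to-end study orchestration.

One declarative configuration drives the whole analysis: load or generate
a connectome, route greedily in its Euclidean embedding, infer a
hyperbolic map, route on the map, benchmark against randomized baselines,
and summarize the map's cartography.  Every stage writes its artifacts
under the output directory and contributes to a single consolidated study
report; the run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .cartography import (
    Partition,
    angular_localization,
    critical_gap_communities,
    nmi,
    region_angular_span,
)
from .embedding import EmbeddingConfig, embed_h2
from .generators import (
    EuclideanGeneratorConfig,
    S1GeneratorConfig,
    generate_euclidean_connectome,
    generate_s1_network,
)
from .geometry import EuclideanMetric
from .io import (
    Connectome,
    connected_components,
    read_annotations,
    read_edge_list,
    read_positions,
    write_edge_list,
    write_positions,
)
from .model import HyperbolicMap
from .nulls import (
    RewireConfig,
    rewire_cost_preserving,
    rewire_degree_preserving,
    shuffle_map,
    shuffle_positions,
)
from .routing import navigability

logger = logging.getLogger(__name__)

STAGES = ("euclidean_routing", "embed", "hyperbolic_routing", "null_models", "cartography")
NULL_MODELS = ("position_swap", "rewire", "cost_rewire")

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Declarative description of one study run."""

    stages: list[str]
    edge_list: Optional[str] = None
    positions: Optional[str] = None
    annotations: Optional[str] = None
    generator: Optional[dict] = None  # {"kind": "s1"|"euclidean", ...params}
    null_model_list: list[str] = dataclasses.field(default_factory=lambda: list(NULL_MODELS))
    replicates_per_null: int = 10
    seed: int = 0
    output_dir: str = "navmaps_out"
    embedding: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
        for m in self.null_model_list:
            if m not in NULL_MODELS:
                raise ValueError(f"unknown null model {m!r}; valid: {NULL_MODELS}")
        if (self.edge_list is None) == (self.generator is None):
            raise ValueError("exactly one of edge_list or generator must be given")
        if self.replicates_per_null <= 0:
            raise ValueError("replicates_per_null must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class StudyReport:
    """Consolidated per-stage results plus provenance."""

    network: dict
    stages: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {"network": self.network, "stages": self.stages, "provenance": self.provenance}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def _load_or_generate(config: PipelineConfig, out: Path) -> tuple[Connectome, Optional[HyperbolicMap]]:
    """Returns the connectome and, for S1-generated inputs, the planted map."""
    truth_map = None
    if config.generator is not None:
        params = dict(config.generator)
        kind = params.pop("kind")
        params.setdefault("seed", config.seed)
        if kind == "s1":
            gen_cfg = S1GeneratorConfig(**params)
            connectome, truth = generate_s1_network(gen_cfg)
            truth.write(out / "ground_truth.json")
            truth_map = truth.to_hyperbolic_map()
        elif kind == "euclidean":
            gen_cfg = EuclideanGeneratorConfig(**params)
            connectome = generate_euclidean_connectome(gen_cfg)
            write_positions(connectome, out / "positions.tsv")
        else:
            raise ValueError(f"unknown generator kind {kind!r}")
        write_edge_list(connectome, out / "edges.tsv")
    else:
        connectome = read_edge_list(config.edge_list)
        if config.positions:
            connectome = read_positions(config.positions, connectome)
        if config.annotations:
            connectome = read_annotations(config.annotations, connectome)
    return connectome, truth_map


def _null_model_sr(
    connectome: Connectome,
    hmap: Optional[HyperbolicMap],
    model: str,
    replicates: int,
    seed: int,
) -> dict:
    """Mean +/- spread of greedy-routing SR over randomized replicates.

    Randomization applies to whichever geometry drives routing: the
    hyperbolic map when one was inferred, else the Euclidean positions.
    """
    rng = np.random.default_rng(seed)
    srs = []
    for _ in range(replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if model == "position_swap":
            if hmap is not None:
                rep_map = shuffle_map(hmap, rep_seed)
                sr = navigability(connectome, rep_map.metric()).success_rate
            else:
                rep = shuffle_positions(connectome, rep_seed)
                sr = navigability(rep, EuclideanMetric(rep.positions)).success_rate
        else:
            metric = hmap.metric() if hmap is not None else EuclideanMetric(connectome.positions)
            cfg = RewireConfig(seed=rep_seed)
            if model == "rewire":
                rep = rewire_degree_preserving(connectome, cfg)
            else:
                rep = rewire_cost_preserving(connectome, metric, cfg)
            sr = navigability(rep, metric).success_rate
        srs.append(sr)
    arr = np.asarray(srs)
    return {
        "success_rate_mean": float(arr.mean()),
        "success_rate_std": float(arr.std(ddof=1)) if replicates > 1 else 0.0,
        "replicates": replicates,
        "values": [float(v) for v in arr],
    }


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute the requested stages in order and write all artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    connectome, _truth_map = _load_or_generate(config, out)
    logger.info("loaded network: N=%d, L=%d (seed=%d)", connectome.N, connectome.L, config.seed)
    if "embed" in config.stages:
        comps = connected_components(connectome)
        if len(comps) > 1:
            logger.info("restricting to the giant component (%d of %d nodes) for embedding",
                        len(comps[0]), connectome.N)
            connectome = connectome.subgraph(comps[0])

    stages: dict = {}
    hmap: Optional[HyperbolicMap] = None

    for stage in config.stages:
        logger.info("stage %s", stage)
        if stage == "euclidean_routing":
            if connectome.positions is None:
                raise ValueError("stage euclidean_routing requires node positions")
            rep = navigability(connectome, EuclideanMetric(connectome.positions))
            rep.write(out / "euclidean_routing.json")
            stages["euclidean_routing"] = rep.to_dict()
        elif stage == "embed":
            emb_cfg = EmbeddingConfig(seed=config.seed, **config.embedding)
            diag: dict = {}
            hmap = embed_h2(connectome, emb_cfg, diagnostics=diag)
            hmap.write(out / "hyperbolic_map.tsv", out / "hyperbolic_map.json")
            with (out / "likelihood_trace.tsv").open("w") as fh:
                fh.write("restart\tsweep\tlog_likelihood\n")
                for ri, trace in enumerate(diag["traces"]):
                    for si, ll in enumerate(trace):
                        fh.write(f"{ri}\t{si}\t{ll!r}\n")
            stages["embed"] = {
                "beta": diag["beta"],
                "mu": diag["mu"],
                "R": diag["R"],
                "final_log_likelihood": diag["final_log_likelihood"],
            }
        elif stage == "hyperbolic_routing":
            if hmap is None:
                raise ValueError("stage hyperbolic_routing requires the embed stage first")
            rep = navigability(connectome, hmap.metric())
            rep.write(out / "hyperbolic_routing.json")
            stages["hyperbolic_routing"] = rep.to_dict()
        elif stage == "null_models":
            if hmap is None and connectome.positions is None:
                raise ValueError("stage null_models requires positions or a prior embed stage")
            nulls_out = {}
            for k, model in enumerate(config.null_model_list):
                nulls_out[model] = _null_model_sr(
                    connectome, hmap, model, config.replicates_per_null,
                    seed=config.seed + 7919 * (k + 1),
                )
            stages["null_models"] = nulls_out
            (out / "null_models.json").write_text(json.dumps(nulls_out, indent=1))
        elif stage == "cartography":
            if hmap is None:
                raise ValueError("stage cartography requires the embed stage first")
            partition = critical_gap_communities(hmap)
            partition.write(out / "communities.tsv")
            carto: dict = {
                "n_communities": len(partition.labels),
                "community_sizes": sorted(
                    (len(m) for m in partition.communities().values()), reverse=True
                ),
            }
            if connectome.annotations:
                label_sets = sorted({ls for d in connectome.annotations.values() for ls in d})
                carto["annotations"] = {}
                for ls in label_sets:
                    ann = Partition.from_annotations(connectome, ls)
                    loc = {}
                    for name, members in sorted(ann.communities().items()):
                        if len(members) < 2:
                            continue
                        rep = angular_localization(
                            hmap, members, cluster_name=name, seed=config.seed,
                        )
                        loc[name] = {
                            "p_value": rep.p_value,
                            "ratio": rep.ratio,
                            "angular_span": region_angular_span(hmap, members),
                        }
                    carto["annotations"][ls] = {
                        "nmi_vs_communities": nmi(partition, ann),
                        "clusters": loc,
                    }
            stages["cartography"] = carto
            (out / "cartography.json").write_text(json.dumps(carto, indent=1))

    report = StudyReport(
        network={"N": connectome.N, "L": connectome.L},
        stages=stages,
        provenance={
            "seed": config.seed,
            "config": config.to_dict(),
            "navmaps_version": __version__,
        },
    )
    report.write(out / "study_report.json")
    return report
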