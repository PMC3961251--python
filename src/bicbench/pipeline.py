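"""End-to-end orchestration: simulate/load -> preprocess -> methods -> filter
-> benchmarks -> report.

Every intermediate artifact is persisted under the output directory so the
report numbers can be traced back to a bicluster file on disk, and the whole
run is reproducible from (config, seed): the only non-deterministic report
fields are the wall-clock runtimes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .benchmarks import (
    go_sig,
    mean_pairwise_gene_overlap,
    sample_dif,
    tiger_sig,
)
from .datamodel import (
    BenchmarkConfig,
    BiclusterSet,
    ExpressionMatrix,
    GeneSetCollection,
    SampleTypeLabels,
    drop_missing_genes,
    load_bicluster_set,
    load_expression_matrix,
    load_gene_sets,
    load_sample_labels,
    save_bicluster_set,
    save_expression_matrix,
    save_gene_sets,
    save_sample_labels,
    variance_filter,
)
from .methods import (
    CCParams,
    binarize_matrix,
    bimax_enumerate,
    cc_biclusters,
    constant_interval_biclusters,
    filter_bicluster_set,
    one_way_cluster_adapter,
)
from .synthetic import (
    SimulationConfig,
    generate_annotation_sets,
    generate_multitissue_dataset,
    oracle_bicluster_set,
)

logger = logging.getLogger("bicbench")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name and artifacts written so far."""

    def __init__(self, stage: str, artifacts: list[str], cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause}; "
            f"artifacts so far: {artifacts}"
        )
        self.stage = stage
        self.artifacts = artifacts


@dataclass
class PipelineConfig:
    """Full run description.

    Either ``simulation`` (synthetic data with ground truth, enabling the
    ``oracle`` method) or ``inputs`` (paths to matrix/labels/tissue GMT/
    annotation GMT files) must be given.  ``methods`` is a list of
    {"name": ..., **params} records; ``imports`` lists bicluster exchange
    files to evaluate as-is.
    """

    output_dir: str
    simulation: SimulationConfig | None = None
    inputs: dict | None = None
    methods: list[dict] = field(default_factory=list)
    imports: list[str] = field(default_factory=list)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    min_variance: float = 1.0
    annotation_dropout: float = 0.0
    annotation_spurious: float = 0.0

    def __post_init__(self):
        if self.simulation is None and self.inputs is None:
            raise ValueError("config needs either 'simulation' or 'inputs'")
        if not self.methods and not self.imports:
            raise ValueError("config needs at least one method or import")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def _rel(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        sim = doc.get("simulation")
        if sim is not None:
            sim = SimulationConfig(**sim)
        inputs = doc.get("inputs")
        if inputs is not None:
            inputs = {k: _rel(v) for k, v in inputs.items()}
        bench = BenchmarkConfig(**doc.get("benchmark", {}))
        return cls(
            output_dir=_rel(doc["output_dir"]),
            simulation=sim,
            inputs=inputs,
            methods=doc.get("methods", []),
            imports=[_rel(p) for p in doc.get("imports", [])],
            benchmark=bench,
            min_variance=doc.get("min_variance", 1.0),
            annotation_dropout=doc.get("annotation_dropout", 0.0),
            annotation_spurious=doc.get("annotation_spurious", 0.0),
        )


@dataclass
class BenchmarkReport:
    """One row per evaluated method, mirroring the three-benchmark layout."""

    rows: list[dict]
    provenance: dict

    def results_rows(self) -> list[dict]:
        """Rows with the non-deterministic timing field removed."""
        return [{k: v for k, v in r.items() if k != "runtime_s"} for r in self.rows]

    def to_tsv(self, path) -> None:
        cols = ["method", "k", "sample_dif", "tiger_sig", "go_sig",
                "mean_gene_overlap", "runtime_s"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in self.rows:
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"provenance": self.provenance, "rows": self.rows},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")


def _run_method(spec: dict, matrix: ExpressionMatrix,
                truth, labels) -> BiclusterSet:
    spec = dict(spec)
    name = spec.pop("name")
    if name == "oracle":
        if truth is None:
            raise ValueError("'oracle' method requires simulated inputs")
        return oracle_bicluster_set(truth, labels)
    if name == "cc":
        return cc_biclusters(matrix, CCParams(**spec))
    if name == "bimax":
        z = spec.pop("z_threshold", 1.0)
        return bimax_enumerate(binarize_matrix(matrix, z), **spec)
    if name == "xmotif":
        return constant_interval_biclusters(matrix, **spec)
    if name in ("kmeans", "hierarchical"):
        return one_way_cluster_adapter(matrix, method=name, **spec)
    raise ValueError(f"unknown method {name!r}")


def run_pipeline(cfg: PipelineConfig) -> BenchmarkReport:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def _save(path: Path):
        artifacts.append(str(path))

    stage = "inputs"
    try:
        truth = None
        if cfg.simulation is not None:
            matrix, labels, truth = generate_multitissue_dataset(cfg.simulation)
            tiger, go = generate_annotation_sets(
                truth, cfg.simulation,
                dropout=cfg.annotation_dropout,
                spurious=cfg.annotation_spurious,
            )
            inp = out / "inputs"
            inp.mkdir(exist_ok=True)
            save_expression_matrix(matrix, inp / "matrix.tsv")
            save_sample_labels(labels, inp / "labels.tsv")
            save_gene_sets(tiger, inp / "tissue_sets.gmt")
            save_gene_sets(go, inp / "annotation_sets.gmt")
            truth_doc = {
                "type_signatures": {
                    k: sorted(v) for k, v in truth.type_signatures.items()
                },
                "planted": [
                    {"genes": sorted(p.genes), "samples": sorted(p.samples),
                     "pattern_kind": p.pattern_kind,
                     "effect_size": p.effect_size}
                    for p in truth.planted
                ],
                "noise_sd": truth.noise_sd,
                "seed": truth.seed,
            }
            with open(inp / "truth.json", "w", encoding="utf-8") as fh:
                json.dump(truth_doc, fh, indent=1, sort_keys=True)
            for p in ("matrix.tsv", "labels.tsv", "tissue_sets.gmt",
                      "annotation_sets.gmt", "truth.json"):
                _save(inp / p)
        else:
            matrix = load_expression_matrix(cfg.inputs["matrix"])
            labels = load_sample_labels(cfg.inputs["labels"])
            tiger = load_gene_sets(cfg.inputs["tissue_sets"])
            go = load_gene_sets(cfg.inputs["annotation_sets"])

        stage = "preprocess"
        if matrix.n_missing:
            matrix = drop_missing_genes(matrix)
        if cfg.min_variance > 0:
            matrix = variance_filter(matrix, cfg.min_variance)
        save_expression_matrix(matrix, out / "preprocessed.tsv")
        _save(out / "preprocessed.tsv")
        universe = matrix.gene_ids

        rows = []
        for i, spec in enumerate(
            [dict(s) for s in cfg.methods]
            + [{"name": "import", "path": p} for p in cfg.imports]
        ):
            name = spec.get("name")
            stage = f"method:{name}"
            t0 = time.perf_counter()
            if name == "import":
                bs = load_bicluster_set(spec["path"])
                label = bs.method_name or Path(spec["path"]).stem
            else:
                bs = _run_method(spec, matrix, truth, labels)
                label = name
            runtime = time.perf_counter() - t0
            raw_path = out / f"{i:02d}_{label}.raw.json"
            save_bicluster_set(bs, raw_path)
            _save(raw_path)

            stage = f"filter:{label}"
            b = cfg.benchmark
            fbs = filter_bicluster_set(
                bs, min_genes=b.min_genes, min_samples=b.min_samples,
                top_n=b.top_n,
            )
            f_path = out / f"{i:02d}_{label}.filtered.json"
            save_bicluster_set(fbs, f_path)
            _save(f_path)

            stage = f"benchmark:{label}"
            sd = sample_dif(fbs, labels)
            tg = tiger_sig(fbs, tiger, universe, b)
            gs = go_sig(fbs, go, universe, b)
            mo = (
                mean_pairwise_gene_overlap(fbs) if fbs.k >= 2 else float("nan")
            )
            table = out / f"{i:02d}_{label}.per_bicluster.tsv"
            with open(table, "w", encoding="utf-8") as fh:
                fh.write("index\tn_genes\tn_samples\ttiger_p\tgo_min_adj_p\n")
                for j, bic in enumerate(fbs):
                    fh.write(
                        f"{j}\t{bic.n_genes}\t{bic.n_samples}\t"
                        f"{float(tg.per_bicluster_p[j])!r}\t"
                        f"{float(gs.per_bicluster_p[j])!r}\n"
                    )
            _save(table)
            rows.append({
                "method": label,
                "k": fbs.k,
                "sample_dif": sd,
                "tiger_sig": tg.significant_fraction,
                "go_sig": gs.significant_fraction,
                "mean_gene_overlap": mo,
                "runtime_s": runtime,
            })
            logger.info(
                "%s: k=%d SampleDif=%.3f TiGER-Sig=%.3f GO-Sig=%.3f (%.2fs)",
                label, fbs.k, sd, tg.significant_fraction,
                gs.significant_fraction, runtime,
            )

        stage = "report"
        provenance = {
            "version": __version__,
            "benchmark": dataclasses.asdict(cfg.benchmark),
            "min_variance": cfg.min_variance,
            "simulation": (
                dataclasses.asdict(cfg.simulation) if cfg.simulation else None
            ),
            "inputs": cfg.inputs,
        }
        report = BenchmarkReport(rows=rows, provenance=provenance)
        report.to_tsv(out / "report.tsv")
        report.to_json(out / "report.json")
        _save(out / "report.tsv")
        _save(out / "report.json")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, artifacts, exc) from exc
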