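"""End-to-end pipeline: normalize -> filter -> (group) -> network -> evaluate.

Every artifact is a TSV with a commented provenance header (parameters,
seed, package version), and identical configuration plus seed yields
byte-identical outputs.  Stage errors propagate annotated with the stage
name and the offending entity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .gba_eval import dataset_mean_auroc, filter_terms, neighbor_voting_auroc
from .io_expression import (
    AnnotationCollection,
    read_annotations,
    read_count_matrix,
    read_sample_table,
    write_annotations,
    write_matrix,
    write_network,
)
from .network_inference import build_coo_network, hrr_network_from_fpkm
from .normalize_filter import (
    filter_low_expression,
    fpkm_normalize,
    group_by_bioproject,
)
from .synthetic_data import SyntheticConfig, SyntheticTruth, simulate_dataset
from .topology import degree_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable, flags override)."""

    out_dir: str = "gcnkit_run"
    counts: str | None = None
    lengths: str | None = None
    samples: str | None = None
    annotations: list[dict[str, str]] = field(default_factory=list)
    simulate: bool = False
    simulate_params: dict[str, Any] = field(default_factory=dict)
    method: str = "COO"
    k: int = 100
    min_fpkm: float = 0.5
    min_fraction: float = 0.5
    min_libraries: int = 6
    folds: int = 3
    term_min: int = 20
    term_max: int = 1000
    genome_gene_total: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _provenance(stage: str, cfg: RunConfig, **extra: Any) -> dict[str, Any]:
    meta: dict[str, Any] = {
        "package": f"gcnkit {__version__}",
        "stage": stage,
        "method": cfg.method,
        "k": cfg.k,
        "seed": cfg.seed,
    }
    meta.update(extra)
    return meta


def _write_frame(df, path: Path, meta: dict[str, Any]) -> None:
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_simulated_inputs(out_dir: str | Path, cfg: SyntheticConfig) -> dict[str, Path]:
    """Simulate a dataset and write counts/lengths/samples/annotations/truth TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, st, ann, truth = simulate_dataset(cfg)
    paths = {
        "counts": out / "counts.tsv",
        "lengths": out / "gene_lengths.tsv",
        "samples": out / "samples.tsv",
        "annotations": out / "annotations.gmt",
        "truth": out / "truth.tsv",
    }
    write_matrix(cm.gene_ids, cm.sample_ids, cm.counts, paths["counts"],
                 header_meta={"package": f"gcnkit {__version__}", "stage": "simulate",
                              "seed": cfg.seed})
    with open(paths["lengths"], "w") as fh:
        fh.write("gene_id\tlength\n")
        for g, length in zip(cm.gene_ids, cm.gene_lengths):
            fh.write(f"{g}\t{length}\n")
    with open(paths["samples"], "w") as fh:
        fh.write("sample_id\tgroup_id\n")
        for s, g in zip(st.sample_ids, st.group_ids):
            fh.write(f"{s}\t{g}\n")
    write_annotations(ann, paths["annotations"])
    _write_truth(truth, paths["truth"])
    return paths


def _write_truth(truth: SyntheticTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tterm_id\tactive_groups\tgenes\n")
        for mid in sorted(truth.modules):
            fh.write(
                "\t".join(
                    [
                        mid,
                        truth.term_for_module[mid],
                        ",".join(sorted(truth.active_groups[mid])),
                        ",".join(sorted(truth.modules[mid])),
                    ]
                )
                + "\n"
            )
        for term in sorted(truth.decoy_terms):
            fh.write(f"-\t{term}\t-\t-\n")


def run_pipeline(cfg: RunConfig) -> list[Path]:
    """Execute the full chain and return the written artifact paths.

    Artifacts: ``fpkm.tsv`` (global normalization), ``network.tsv``,
    ``topology.tsv``, ``term_auroc.tsv``, ``dataset_auroc.tsv``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        sim_cfg = SyntheticConfig(**{"seed": cfg.seed, **cfg.simulate_params})
        inputs = write_simulated_inputs(out / "inputs", sim_cfg)
        counts_path, lengths_path, samples_path = (
            inputs["counts"], inputs["lengths"], inputs["samples"],
        )
        ann_specs = [{"path": str(inputs["annotations"]), "format": "gmt",
                      "name": "synthetic"}]
    else:
        for label, p in (("counts", cfg.counts), ("lengths", cfg.lengths),
                         ("samples", cfg.samples)):
            if p is None:
                raise ValueError(f"input stage: missing required path for {label}")
            if not Path(p).exists():
                raise FileNotFoundError(f"input stage: {label} path {p!r} does not exist")
        for spec in cfg.annotations:
            if not Path(spec["path"]).exists():
                raise FileNotFoundError(
                    f"input stage: annotation path {spec['path']!r} does not exist"
                )
        counts_path, lengths_path, samples_path = cfg.counts, cfg.lengths, cfg.samples
        ann_specs = cfg.annotations

    artifacts: list[Path] = []

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)

    _stage("read")
    cm = read_count_matrix(counts_path, lengths_path)
    st = read_sample_table(samples_path)
    collections = [
        read_annotations(s["path"], s.get("format", "gmt"), s.get("name", "annotations"))
        for s in ann_specs
    ]

    _stage("normalize")
    fm = fpkm_normalize(cm)
    fpkm_path = out / "fpkm.tsv"
    write_matrix(fm.gene_ids, fm.sample_ids, fm.fpkm, fpkm_path,
                 header_meta=_provenance("normalize", cfg))
    artifacts.append(fpkm_path)

    _stage("network")
    if cfg.method == "HRR":
        filtered = filter_low_expression(fm, cfg.min_fpkm, cfg.min_fraction)
        net = hrr_network_from_fpkm(filtered, cfg.k)
    elif cfg.method == "COO":
        ge = group_by_bioproject(
            cm, st, cfg.min_libraries, cfg.min_fpkm, cfg.min_fraction
        )
        group_nets = [
            hrr_network_from_fpkm(ge.groups[gid], cfg.k) for gid in sorted(ge.groups)
        ]
        net = build_coo_network(group_nets, cfg.k)
    else:
        raise ValueError(f"network stage: unknown method {cfg.method!r}")
    net_path = out / "network.tsv"
    write_network(net, net_path)
    artifacts.append(net_path)

    _stage("topology")
    summary = degree_stats(net, cfg.genome_gene_total)
    topo_path = out / "topology.tsv"
    _write_frame(summary.to_frame(), topo_path, _provenance("topology", cfg))
    artifacts.append(topo_path)

    _stage("evaluate")
    import pandas as pd

    tables = []
    for ann in collections:
        filtered_ann = filter_terms(ann, net, cfg.term_min, cfg.term_max)
        tables.append(
            neighbor_voting_auroc(net, filtered_ann, n_folds=cfg.folds, seed=cfg.seed)
        )
    term_table = pd.concat(tables, ignore_index=True)
    term_path = out / "term_auroc.tsv"
    _write_frame(term_table, term_path, _provenance("evaluate", cfg, folds=cfg.folds))
    artifacts.append(term_path)

    per_dataset, grand = dataset_mean_auroc(term_table)
    ds = per_dataset.reset_index().rename(columns={"auroc": "mean_auroc"})
    ds.loc[len(ds)] = ["__average__", grand]
    ds_path = out / "dataset_auroc.tsv"
    _write_frame(ds, ds_path, _provenance("evaluate", cfg, folds=cfg.folds))
    artifacts.append(ds_path)

    return artifacts
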