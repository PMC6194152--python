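"""End-to-end orchestration: simulate → screen → network → preservation → hubs.

``run_all`` wires the stages together under a single config and seed and
writes every artefact plus a manifest JSON (config hash, seed, output
paths).  Reruns with an identical config and seed reproduce byte-identical
non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .containers import ConfigurationError, ExpressionDataset, ModulePartition
from .enrichment import GeneSetCollection, hypergeometric_ora, read_gene_list
from .hubs import (
    hub_percentage_rows,
    hub_shift_report,
    kme_table,
    module_hub_partitions,
    module_list_overlap,
)
from .network import NetworkConfig, detect_modules
from .preprocess import PreprocessConfig, preprocess_pipeline
from .preservation import PreservationConfig, preservation_report
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Single-run configuration for the full pipeline.

    Either ``simulate`` is set (synthetic run) or ``expression_tsv`` +
    ``metadata_tsv`` point at real input.  The DEG screen is a probe-level
    step for real data; for synthetic runs it defaults to off because the
    generator already defines the gene universe.
    """

    output_dir: str = "coexmod_out"
    seed: int = 0
    simulate: SimulationConfig | None = None
    expression_tsv: str | None = None
    metadata_tsv: str | None = None
    probe_map_tsv: str | None = None
    gmt_files: list = field(default_factory=list)
    external_gene_list: str | None = None
    deg_screen: bool | None = None  # None -> True for real input, False for synthetic
    reference: str = "REF"
    test_conditions: tuple = ("TEST1", "TEST2")
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    preservation: PreservationConfig = field(default_factory=PreservationConfig)
    kme_threshold: float = 0.7

    def validate(self) -> None:
        if self.simulate is None and (
            self.expression_tsv is None or self.metadata_tsv is None
        ):
            raise ConfigurationError(
                "either a simulation config or expression + metadata paths required"
            )
        for path in filter(None, [self.expression_tsv, self.metadata_tsv,
                                  self.probe_map_tsv, self.external_gene_list,
                                  *self.gmt_files]):
            if not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")
        if not (0 < self.kme_threshold <= 1):
            raise ConfigurationError("kme_threshold must be in (0, 1]")


def _sanitize(obj):
    """Make a nested config JSON-serialisable (tuple keys -> 'a|b')."""
    if isinstance(obj, dict):
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _sanitize(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if hasattr(obj, "__dict__"):
        return _sanitize(vars(obj))
    return obj if isinstance(obj, (str, int, float, bool, type(None))) else str(obj)


def _config_hash(config: RunConfig) -> str:
    payload = _sanitize(asdict(config))
    payload.pop("output_dir", None)  # the analysis, not where it lands
    blob = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": {},
    }

    def _emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    # -- stage: simulate or load ------------------------------------------
    if config.simulate is not None:
        sim = config.simulate
        sim.seed = config.seed
        data, truth = generate_dataset(sim)
        data.to_tsv(out / "expression.tsv", out / "metadata.tsv")
        truth.to_json(out / "ground_truth.json")
        _emit("expression", out / "expression.tsv")
        _emit("metadata", out / "metadata.tsv")
        _emit("ground_truth", out / "ground_truth.json")
        deg_screen = config.deg_screen if config.deg_screen is not None else False
    else:
        data = ExpressionDataset.from_tsv(config.expression_tsv, config.metadata_tsv)
        deg_screen = config.deg_screen if config.deg_screen is not None else True

    # -- stage: preprocess -------------------------------------------------
    probe_map = (
        pd.read_csv(config.probe_map_tsv, sep="\t")
        if config.probe_map_tsv
        else None
    )
    if deg_screen:
        data, audit = preprocess_pipeline(
            data,
            config.preprocess,
            probe_map=probe_map,
            reference=config.reference,
            tests=tuple(config.test_conditions),
        )
    else:
        from .preprocess import detect_outlier_samples, filter_good_samples_genes

        outliers = detect_outlier_samples(data, config.preprocess.outlier_z_cut)
        if outliers:
            data = data.drop_samples(outliers)
        data = filter_good_samples_genes(data, config.preprocess.max_missing_fraction)
        audit = {"deg_screen": "skipped", "outlier_samples_removed": list(outliers)}
    with open(out / "filter_audit.json", "w") as fh:
        json.dump(audit, fh, indent=1, default=str)
    _emit("filter_audit", out / "filter_audit.json")

    # -- stage: network on the reference condition -------------------------
    ref_expr = data.condition(config.reference)
    partition, eig, summary = detect_modules(ref_expr, config.network)
    partition.to_tsv(out / "partition.tsv")
    eig.to_tsv(out / "eigengenes.tsv")
    with open(out / "network_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    _emit("partition", out / "partition.tsv")
    _emit("eigengenes", out / "eigengenes.tsv")
    _emit("network_summary", out / "network_summary.json")
    beta = summary["power"]

    # -- stage: preservation per test condition ----------------------------
    calls = {}
    pres_cfg = config.preservation
    for cond in config.test_conditions:
        cfg = PreservationConfig(
            n_permutations=pres_cfg.n_permutations,
            z_threshold=pres_cfg.z_threshold,
            rank_threshold=pres_cfg.rank_threshold,
            power=beta,
            correlation_kind=config.network.correlation_kind,
            seed=config.seed,
        )
        report = preservation_report(ref_expr, data.condition(cond), partition, cfg)
        path = out / f"preservation_{cond}.tsv"
        report.to_csv(path, sep="\t")
        _emit(f"preservation_{cond}", path)
        calls[cond] = report["call"]

    # modules non-preserved in *either* test condition are foregrounded
    combined = pd.DataFrame(calls)
    combined["non_preserved_any"] = (combined == "non-preserved").any(axis=1)
    combined.to_csv(out / "preservation_calls.tsv", sep="\t")
    _emit("preservation_calls", out / "preservation_calls.tsv")

    # -- stage: hub shift ---------------------------------------------------
    expr_by_cond = {config.reference: ref_expr}
    for cond in config.test_conditions:
        expr_by_cond[cond] = data.condition(cond)
    kme = kme_table(
        expr_by_cond,
        partition,
        kme_threshold=config.kme_threshold,
        correlation_kind=config.network.correlation_kind,
        reference=config.reference,
    )
    any_call = pd.Series(
        ["non-preserved" if v else "preserved" for v in combined["non_preserved_any"]],
        index=combined.index,
    )
    shift = hub_shift_report(kme, preservation_calls=any_call)
    shift.to_csv(out / "kme_table.tsv", sep="\t")
    _emit("kme_table", out / "kme_table.tsv")
    partitions = module_hub_partitions(kme)
    hub_percentage_rows(partitions).to_csv(out / "hub_venn.tsv", sep="\t", index=False)
    _emit("hub_venn", out / "hub_venn.tsv")

    # -- stage: external-list overlap / enrichment --------------------------
    if config.external_gene_list:
        overlap = module_list_overlap(
            partition, read_gene_list(config.external_gene_list)
        )
        overlap.to_csv(out / "external_overlap.tsv", sep="\t")
        _emit("external_overlap", out / "external_overlap.tsv")
    background = set(partition.labels.index)
    for gmt in config.gmt_files:
        collection = GeneSetCollection.from_gmt(gmt)
        name = Path(gmt).stem
        for module in partition.module_names:
            res = hypergeometric_ora(
                set(partition.genes_of(module)), collection, background
            )
            path = out / f"enrichment_{name}_{module}.tsv"
            res.to_csv(path, sep="\t")
            _emit(f"enrichment_{name}_{module}", path)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
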