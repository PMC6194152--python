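"""Three-condition expression simulator with planted module structure.

Each module is driven by a latent eigengene: one standard-normal score per
sample per (condition, module).  Gene *i* of the module is generated as

    x_i = rho_i * e + sqrt(1 - rho_i**2) * eps_i,

so the expected correlation of two module genes is ``rho_i * rho_j`` and the
expected correlation of a gene with the latent eigengene is ``rho_i``.  Genes
with ``rho_i = rho_hub`` are planted hubs (high module membership); the rest
get ``rho_nonhub``.  Background genes are independent noise everywhere.

Per-(module, condition) fates define the ground truth that downstream stages
must recover:

``preserved``
    same rho assignment as in the reference condition;
``disrupted``
    rho_i = 0 for every module gene (the module dissolves into noise);
``hub_shifted``
    the planted hubs and an equally sized subset of non-hubs swap rho values,
    so hub identity moves to different genes while the module persists.

A stated fraction of genes receives a log2 mean shift in the test conditions
(differential expression), and a configurable number of reference-condition
samples is noise-inflated to emulate outlying arrays.

Randomness is split into named substreams keyed by (condition, module), so
adding a module or condition never reshuffles the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONDITIONS,
    ConfigurationError,
    ExpressionDataset,
)

FATES = ("preserved", "disrupted", "hub_shifted")


@dataclass(frozen=True)
class ModuleSpec:
    """One planted module: size, hub fraction and the two rho levels."""

    module_id: str
    size: int
    hub_fraction: float = 0.3
    rho_hub: float = 0.9
    rho_nonhub: float = 0.5

    def __post_init__(self) -> None:
        if self.size < 3:
            raise ConfigurationError(f"module {self.module_id}: size must be >= 3")
        if not (0.0 < self.hub_fraction < 1.0):
            raise ConfigurationError(
                f"module {self.module_id}: hub_fraction must be in (0, 1)"
            )
        if not self.rho_hub > self.rho_nonhub:
            raise ConfigurationError(
                f"module {self.module_id}: rho_hub must exceed rho_nonhub"
            )

    @property
    def n_hubs(self) -> int:
        return max(1, int(round(self.size * self.hub_fraction)))


@dataclass
class SimulationConfig:
    """Study design for the synthetic three-condition dataset.

    Defaults emulate the motivating design at desk scale: three conditions
    sharing a gene universe, five modules spanning sizes 30-100, a background
    of unassigned genes, and per-stage module fates that mix preservation,
    disruption and hub shifts (including one module whose fate differs between
    the two test conditions, mirroring stage-specific non-preservation).
    """

    n_samples_per_condition: int | dict = 60
    module_specs: list = field(
        default_factory=lambda: [
            ModuleSpec("M1", 100),
            ModuleSpec("M2", 80),
            ModuleSpec("M3", 60),
            ModuleSpec("M4", 45),
            ModuleSpec("M5", 30),
        ]
    )
    n_background_genes: int = 200
    fates: dict = field(
        default_factory=lambda: {
            ("M2", "TEST1"): "disrupted",
            ("M2", "TEST2"): "disrupted",
            ("M3", "TEST1"): "hub_shifted",
            ("M3", "TEST2"): "hub_shifted",
            ("M4", "TEST1"): "disrupted",
            ("M5", "TEST2"): "disrupted",
        }
    )
    de_effect: float = 1.0
    de_fraction: float = 0.3
    n_outlier_samples: int = 0
    outlier_noise_scale: float = 5.0
    seed: int = 0

    def n_samples(self, condition: str) -> int:
        if isinstance(self.n_samples_per_condition, dict):
            return int(self.n_samples_per_condition[condition])
        return int(self.n_samples_per_condition)

    def validate(self) -> None:
        ids = [m.module_id for m in self.module_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("module ids must be unique")
        for key, fate in self.fates.items():
            mod, cond = key
            if fate not in FATES:
                raise ConfigurationError(
                    f"invalid fate {fate!r} for (module={mod}, condition={cond}); "
                    f"valid fates: {FATES}"
                )
            if mod not in ids:
                raise ConfigurationError(
                    f"fate refers to unknown module {mod!r} (condition={cond})"
                )
            if cond not in CONDITIONS:
                raise ConfigurationError(
                    f"fate refers to unknown condition {cond!r} (module={mod})"
                )
        if self.n_background_genes < 0:
            raise ConfigurationError("n_background_genes must be >= 0")
        for cond in CONDITIONS:
            if self.n_samples(cond) < 3:
                raise ConfigurationError("need >= 3 samples per condition")
        if self.n_outlier_samples > 0 and self.outlier_noise_scale <= 1.0:
            raise ConfigurationError("outlier_noise_scale must be > 1")

    @property
    def n_genes(self) -> int:
        return sum(m.size for m in self.module_specs) + self.n_background_genes


@dataclass
class GroundTruth:
    """Planted structure: membership, per-condition hub flags, fates, outliers."""

    module_of: pd.Series  # gene -> module_id or "background"
    is_hub: pd.DataFrame  # gene x condition boolean
    fates: dict  # (module_id, condition) -> fate
    outlier_samples: list

    def to_json(self, path) -> None:
        import json

        payload = {
            "module_of": self.module_of.to_dict(),
            "is_hub": {c: self.is_hub[c].to_dict() for c in self.is_hub.columns},
            "fates": {f"{m}|{c}": f for (m, c), f in self.fates.items()},
            "outlier_samples": list(self.outlier_samples),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _stream(seed: int, cond_idx: int, module_idx: int) -> np.random.Generator:
    """Counter-based substream: one generator per (condition, module) slot."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(cond_idx, module_idx))
    )


def _module_rhos(spec: ModuleSpec, fate: str) -> np.ndarray:
    """Per-gene rho for one module under one fate.

    Gene order within the module is fixed: the first ``n_hubs`` genes are the
    reference hubs.  ``hub_shifted`` swaps rho between the reference hubs and
    the next ``n_hubs`` genes.
    """
    rho = np.full(spec.size, spec.rho_nonhub)
    h = spec.n_hubs
    if fate == "preserved":
        rho[:h] = spec.rho_hub
    elif fate == "disrupted":
        rho[:] = 0.0
    elif fate == "hub_shifted":
        k = min(h, spec.size - h)  # gainer subset drawn from the non-hubs
        rho[h : h + k] = spec.rho_hub
    else:  # pragma: no cover - guarded by validate()
        raise ConfigurationError(f"invalid fate {fate!r}")
    return rho


def generate_dataset(config: SimulationConfig) -> tuple[ExpressionDataset, GroundTruth]:
    """Simulate the three-condition dataset and its ground truth.

    Deterministic given ``config.seed``; same config + seed gives bitwise
    identical matrices.
    """
    config.validate()
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    for spec in config.module_specs:
        for g in range(spec.size):
            gid = f"{spec.module_id}_g{g:04d}"
            gene_ids.append(gid)
            module_of[gid] = spec.module_id
    for b in range(config.n_background_genes):
        gid = f"BG_g{b:04d}"
        gene_ids.append(gid)
        module_of[gid] = "background"

    blocks: list[np.ndarray] = []
    sample_ids: list[str] = []
    cond_labels: list[str] = []
    is_hub = pd.DataFrame(False, index=pd.Index(gene_ids, name="gene"), columns=CONDITIONS)
    fates_full: dict = {}

    for ci, cond in enumerate(CONDITIONS):
        n = config.n_samples(cond)
        sample_ids.extend(f"{cond}_s{j:03d}" for j in range(n))
        cond_labels.extend([cond] * n)

        cond_block: list[np.ndarray] = []
        row0 = 0
        for mi, spec in enumerate(config.module_specs):
            fate = "preserved" if cond == "REF" else config.fates.get(
                (spec.module_id, cond), "preserved"
            )
            fates_full[(spec.module_id, cond)] = fate
            rng = _stream(config.seed, ci, mi)
            e = rng.standard_normal(n)
            eps = rng.standard_normal((spec.size, n))
            rho = _module_rhos(spec, fate)[:, None]
            cond_block.append(rho * e[None, :] + np.sqrt(1.0 - rho**2) * eps)
            hub_rows = np.flatnonzero(_module_rhos(spec, fate) == spec.rho_hub)
            gene_slice = gene_ids[row0 : row0 + spec.size]
            is_hub.loc[[gene_slice[i] for i in hub_rows], cond] = True
            row0 += spec.size

        # reserved substream index: background draws stay put when modules
        # are added or removed
        bg_rng = _stream(config.seed, ci, 2**20)
        if config.n_background_genes:
            cond_block.append(bg_rng.standard_normal((config.n_background_genes, n)))
        X = np.vstack(cond_block)

        if cond != "REF" and config.de_effect != 0.0 and config.de_fraction > 0.0:
            # same DE gene set in both test conditions: drawn from a dedicated
            # substream keyed off the gene universe, not the condition
            de_rng = _stream(config.seed, len(CONDITIONS), 0)
            n_de = int(round(config.de_fraction * len(gene_ids)))
            de_idx = de_rng.choice(len(gene_ids), size=n_de, replace=False)
            X[de_idx, :] += config.de_effect
        blocks.append(X)

    expr = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(gene_ids, name="gene"), columns=sample_ids
    )
    conditions = pd.Series(cond_labels, index=sample_ids)

    outliers: list[str] = []
    if config.n_outlier_samples > 0:
        ref_cols = [s for s, c in zip(sample_ids, cond_labels) if c == "REF"]
        out_rng = _stream(config.seed, len(CONDITIONS), 1)
        pick = out_rng.choice(len(ref_cols), size=config.n_outlier_samples, replace=False)
        outliers = [ref_cols[i] for i in sorted(pick)]
        # variance inflation, not mean shift: perturbs connectivity, which is
        # what the outlier detector measures
        expr.loc[:, outliers] *= config.outlier_noise_scale

    truth = GroundTruth(
        module_of=pd.Series(module_of, name="module"),
        is_hub=is_hub,
        fates=fates_full,
        outlier_samples=outliers,
    )
    return ExpressionDataset(expr, conditions), truth
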