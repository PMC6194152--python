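"""Per-condition module membership (kME), hub calls and hub-shift analysis.

kME of a gene is its correlation with the eigengene of its (reference-
defined) module, with the eigengene *recomputed on each condition's samples*
— the only reading under which a gene can gain or lose hubness between
conditions.  Genes with |kME| >= 0.7 (default) are hubs.  For each module the
hub sets of the three conditions are decomposed into the seven Venn cells
(three condition-specific, three pairwise-only, one triple), which is the
basis of the condition-specific vs. shared hub classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GREY, InputError, ModulePartition
from .correlation import correlation_matrix
from .network import module_eigengenes

logger = logging.getLogger(__name__)

#: The seven Venn cells over conditions (REF, TEST1, TEST2), as membership
#: triples (in REF?, in TEST1?, in TEST2?).
VENN_CELLS = {
    "REF_only": (True, False, False),
    "TEST1_only": (False, True, False),
    "TEST2_only": (False, False, True),
    "REF_TEST1": (True, True, False),
    "REF_TEST2": (True, False, True),
    "TEST1_TEST2": (False, True, True),
    "all_three": (True, True, True),
}


def condition_kme(
    expr_condition: pd.DataFrame,
    partition: ModulePartition,
    correlation_kind: str = "bicor",
    reference_eigengenes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """kME of every non-grey gene against its module eigengene in one condition.

    The eigengene of each reference module is recomputed on this condition's
    samples and sign-aligned to the condition's module mean profile.  If
    ``reference_eigengenes`` is given (samples × modules of the *reference*
    condition), a negative correlation between a recomputed eigengene and its
    reference counterpart is logged — it signals module inversion.

    Returns a DataFrame indexed by gene with columns ``module`` and ``kme``.
    """
    eig = module_eigengenes(expr_condition, partition.labels)
    if reference_eigengenes is not None:
        for m in eig.scores.columns:
            if m in reference_eigengenes.columns and len(reference_eigengenes) == len(
                eig.scores
            ):
                r = float(np.corrcoef(eig.scores[m], reference_eigengenes[m])[0, 1])
                if r < 0:
                    logger.warning(
                        "module %s eigengene flips sign vs reference (r=%.2f)", m, r
                    )
    rows = []
    for module in partition.module_names:
        if module not in eig.scores.columns:
            logger.warning("module %s absent from condition; skipped", module)
            continue
        genes = [g for g in partition.genes_of(module) if g in expr_condition.index]
        X = expr_condition.loc[genes].to_numpy(dtype=float)
        e = eig.scores[module].to_numpy()[None, :]
        kme = correlation_matrix(X, Y=e, kind=correlation_kind)[:, 0]
        rows.append(pd.DataFrame({"module": module, "kme": kme}, index=genes))
    if not rows:
        return pd.DataFrame(columns=["module", "kme"])
    return pd.concat(rows)


def kme_table(
    expr_by_condition: dict[str, pd.DataFrame],
    partition: ModulePartition,
    kme_threshold: float = 0.7,
    correlation_kind: str = "bicor",
    reference: str = "REF",
) -> pd.DataFrame:
    """Gene × condition kME matrix with hub flags.

    Columns: ``module``, ``kme_<COND>`` and ``hub_<COND>`` per condition
    (hub ⇔ |kME| >= threshold).
    """
    ref_eig = module_eigengenes(expr_by_condition[reference], partition.labels).scores
    out: pd.DataFrame | None = None
    for cond, expr in expr_by_condition.items():
        kt = condition_kme(
            expr,
            partition,
            correlation_kind,
            reference_eigengenes=None if cond == reference else ref_eig,
        )
        cols = kt.rename(columns={"kme": f"kme_{cond}"})
        if out is None:
            out = cols
        else:
            out = out.join(cols[f"kme_{cond}"], how="inner")
    assert out is not None
    for cond in expr_by_condition:
        out[f"hub_{cond}"] = out[f"kme_{cond}"].abs() >= kme_threshold
    return out


@dataclass
class HubPartition:
    """Seven-cell Venn decomposition of one module's hub sets.

    ``cells`` maps cell name → gene set; ``counts``/``percentages`` summarise
    (percentages relative to the number of distinct hubs across conditions);
    ``totals`` gives per-condition hub totals.
    """

    cells: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    percentages: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)


def venn_partition(hubs_ref: set, hubs_test1: set, hubs_test2: set) -> HubPartition:
    """Exact seven-cell partition of three hub sets with counts/percentages."""
    sets = (set(hubs_ref), set(hubs_test1), set(hubs_test2))
    universe = sets[0] | sets[1] | sets[2]
    cells: dict[str, set] = {name: set() for name in VENN_CELLS}
    for g in universe:
        member = (g in sets[0], g in sets[1], g in sets[2])
        for name, pattern in VENN_CELLS.items():
            if member == pattern:
                cells[name].add(g)
                break
    counts = {name: len(s) for name, s in cells.items()}
    n = len(universe)
    percentages = {
        name: round(100.0 * c / n, 2) if n else 0.0 for name, c in counts.items()
    }
    totals = {
        "REF": counts["REF_only"] + counts["REF_TEST1"] + counts["REF_TEST2"]
        + counts["all_three"],
        "TEST1": counts["TEST1_only"] + counts["REF_TEST1"] + counts["TEST1_TEST2"]
        + counts["all_three"],
        "TEST2": counts["TEST2_only"] + counts["REF_TEST2"] + counts["TEST1_TEST2"]
        + counts["all_three"],
    }
    return HubPartition(cells=cells, counts=counts, percentages=percentages, totals=totals)


def module_hub_partitions(
    kme: pd.DataFrame, conditions: tuple[str, str, str] = ("REF", "TEST1", "TEST2")
) -> dict[str, HubPartition]:
    """Venn decomposition per module from a :func:`kme_table` output."""
    out: dict[str, HubPartition] = {}
    for module, grp in kme.groupby("module"):
        hub_sets = [
            set(grp.index[grp[f"hub_{c}"]]) for c in conditions
        ]
        out[str(module)] = venn_partition(*hub_sets)
    return out


def hub_shift_report(
    kme: pd.DataFrame,
    preservation_calls: pd.Series | None = None,
    conditions: tuple[str, str, str] = ("REF", "TEST1", "TEST2"),
) -> pd.DataFrame:
    """Per-gene hub-shift classification, foregrounding non-preserved modules.

    Adds to each gene its Venn cell, a ``lost_hubness`` flag (hub in the
    reference only) and a ``gained_hubness`` flag (hub only in test
    conditions); ``non_preserved`` marks genes of modules called
    non-preserved, which are the ones the analysis interprets.
    """
    ref, t1, t2 = conditions
    out = kme.copy()
    cell = []
    for _, row in out.iterrows():
        member = (bool(row[f"hub_{ref}"]), bool(row[f"hub_{t1}"]), bool(row[f"hub_{t2}"]))
        name = next((n for n, p in VENN_CELLS.items() if p == member), "none")
        cell.append(name)
    out["cell"] = cell
    out["lost_hubness"] = out["cell"] == "REF_only"
    out["gained_hubness"] = out["cell"].isin(["TEST1_only", "TEST2_only", "TEST1_TEST2"])
    if preservation_calls is not None:
        out["non_preserved"] = out["module"].map(
            lambda m: preservation_calls.get(m, "") == "non-preserved"
        )
    return out


def hub_percentage_rows(partitions: dict[str, HubPartition]) -> pd.DataFrame:
    """Percentage-of-hub-genes rows, one per (module, cell)."""
    rows = []
    for module, hp in partitions.items():
        for name in VENN_CELLS:
            rows.append(
                {
                    "module": module,
                    "cell": name,
                    "count": hp.counts[name],
                    "percentage": hp.percentages[name],
                }
            )
    return pd.DataFrame(rows)


def module_list_overlap(
    partition: ModulePartition, external_genes: set
) -> pd.DataFrame:
    """Per-module overlap with an external gene list (count and percentage).

    Percentage is 100 * |module ∩ external| / module size, rounded to two
    decimals.  An empty external set yields zero counts with a warning.
    """
    external = set(external_genes)
    if not external:
        logger.warning("external gene list is empty; overlaps are all zero")
    rows = []
    for module in partition.module_names:
        genes = set(partition.genes_of(module))
        inter = len(genes & external)
        rows.append(
            {
                "module": module,
                "size": len(genes),
                "count": inter,
                "percentage": round(100.0 * inter / len(genes), 2) if genes else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("module")
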