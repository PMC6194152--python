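"""Hypergeometric over-representation analysis against GMT gene-set collections.

For a query gene list (a module or its hubs) and each named set of a
collection, the upper-tail hypergeometric probability P(X >= overlap) is
computed with the post-filter network genes as the default background (module
membership is only defined there), followed by Benjamini-Hochberg adjustment
within the collection.  Significance at FDR < 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .containers import InputError
from .preprocess import bh_fdr


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions (GMT content)."""

    sets: dict
    descriptions: dict

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise InputError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets: dict[str, set] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise InputError(f"malformed GMT line: {line[:80]!r}")
                name, desc, *members = fields
                if name in sets:
                    raise InputError(f"duplicate gene set name {name!r}")
                sets[name] = {m for m in members if m}
                descriptions[name] = desc
        return cls(sets=sets, descriptions=descriptions)


def hypergeometric_ora(
    query: set,
    collection: GeneSetCollection,
    background: set,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric ORA of a query against every set.

    Sets are intersected with the background before testing; the query must
    be a subset of the background.  Returns a DataFrame sorted by FDR with
    columns overlap / set_size / query_size / background_size / p_value /
    fdr / significant.
    """
    query = set(query)
    background = set(background)
    offenders = query - background
    if offenders:
        raise InputError(
            f"query genes outside the background: {sorted(offenders)[:10]}"
        )
    N = len(background)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        K = len(members & background)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set": name,
                "description": collection.descriptions.get(name, ""),
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "background_size": N,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows).set_index("set")
    result["fdr"] = bh_fdr(result["p_value"].to_numpy()) if len(result) else []
    result["significant"] = result["fdr"] < fdr_threshold
    return result.sort_values("fdr")


def read_gene_list(path: str | Path) -> set:
    """Read an external gene list, one symbol per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
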