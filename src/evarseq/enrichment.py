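"""Hypergeometric over-representation analysis against GMT gene sets.

A query gene list (e.g. the confirmed hyper-variable genes of one donor
group at one dose) is tested against each named set of a collection with
the one-sided upper-tail hypergeometric test.  The background universe
is the dose-specific list of genes retained after bimodality exclusion
— not the whole genome — following stated best practice for expression
experiments.  P-values are BH-adjusted within each query.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .classify import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_ora",
    "run_enrichment",
    "bh_adjust",
]


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets with optional descriptions."""

    sets: dict[str, set]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated name, description, members...

    Raises on duplicate set names and on lines with fewer than three
    fields (a set must have at least one member).
    """
    sets: dict[str, set] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >= 1 member")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(m for m in members if m)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in collection.sets:
            members = sorted(collection.sets[name])
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def hypergeom_ora(query, gene_set, background) -> dict:
    """Upper-tail hypergeometric test of one set against one query.

    The set is intersected with the background before testing; the query
    must be contained in the background.  Returns the counts
    (N, K, n, k), the p-value P(X >= k), and the overlapping gene ids.
    """
    query = set(query)
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not query:
        raise ValueError("empty query")
    stray = query - background
    if stray:
        raise ValueError(f"query gene(s) not in background: {sorted(stray)[:5]}")
    set_in_bg = set(gene_set) & background
    overlap = query & set_in_bg
    N, K, n, k = len(background), len(set_in_bg), len(query), len(overlap)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return {"k": k, "n": n, "K": K, "N": N, "p": p, "overlap": sorted(overlap)}


def run_enrichment(
    queries: dict[str, set],
    collection: GeneSetCollection,
    backgrounds: dict[str, set],
    query_background: dict[str, str],
    alpha: float = 0.05,
    filter_significant: bool = True,
) -> pd.DataFrame:
    """ORA of every query against every collection set.

    ``queries`` maps query ids to gene sets; ``query_background`` maps
    each query id to the key of its background in ``backgrounds`` (one
    background per dose).  BH adjustment is within each query; with
    ``filter_significant`` only rows with adjusted p < alpha are kept.
    Empty queries yield no rows.
    """
    frames = []
    for qid, genes in queries.items():
        if not genes:
            continue
        bg = backgrounds[query_background[qid]]
        rows = []
        for name in collection:
            r = hypergeom_ora(genes, collection.sets[name], bg)
            rows.append(
                (qid, name, r["k"], r["n"], r["K"], r["N"], r["p"], ",".join(r["overlap"]))
            )
        df = pd.DataFrame(
            rows, columns=["query", "set_name", "k", "n", "K", "N", "p", "overlap_ids"]
        )
        df["p_adjusted"] = bh_adjust(df["p"].to_numpy())
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["query", "set_name", "k", "n", "K", "N", "p", "overlap_ids", "p_adjusted"]
        )
    out = pd.concat(frames, ignore_index=True)
    if filter_significant:
        out = out[out["p_adjusted"] < alpha].reset_index(drop=True)
    return out
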