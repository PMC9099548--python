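"""Over-representation analysis of gene lists against GMT collections.

Given a query gene list (e.g. the genes upregulated in a cluster), each
gene set's overlap is tested with the hypergeometric upper tail
P(X >= k) over a stated gene universe, with Benjamini-Hochberg adjustment
across sets — the standard "investigate a gene list" computation for
MSigDB-style collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .dge import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions; optionally a gene universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: list[str] | None = None

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (name, description, members...).

    Empty lines are skipped; member duplicates within a line are removed
    with a warning; a line with fewer than 3 fields is an error naming the
    line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("GMT line %d (%s): %d duplicate member(s) removed",
                               lineno, name, len(members) - len(unique))
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def ora(query, universe, collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Genes outside ``universe`` are dropped from both the query and the
    sets.  Per set: overlap k, set size K (within universe), query size n,
    universe size N, p = P(X >= k) under hypergeometric(N, K, n), and BH q
    across sets; rows sorted by q then p.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query_set = set(query) & uni
    n, big_n = len(query_set), len(uni)

    rows = []
    for name, members in collection.sets.items():
        set_in_uni = set(members) & uni
        k_obs = len(query_set & set_in_uni)
        big_k = len(set_in_uni)
        p = float(hypergeom.sf(k_obs - 1, big_n, big_k, n))
        rows.append({"set": name, "overlap": k_obs, "set_size": big_k,
                     "query_size": n, "universe_size": big_n, "p": min(p, 1.0)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = []
    return result
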