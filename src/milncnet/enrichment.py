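"""Over-representation analysis of a query feature set against GMT collections."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .stats import bh_adjust, hypergeom_upper_tail

__all__ = ["GeneSetCollection", "read_gmt", "write_gmt", "ora_test"]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (the GMT payload)."""

    sets: dict[str, list[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read the standard GMT tab format: name, description, members..."""
    sets, desc = {}, {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [f for f in fields[2:] if f]
            desc[name] = fields[1]
    return GeneSetCollection(sets, desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name in collection.sets:
            desc = collection.description.get(name, "")
            handle.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def ora_test(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against each set.

    Per set the urn holds |set ∩ universe| annotated vs the rest of the
    universe, |query| features are drawn and p = P(X >= overlap) upper tail;
    the fdr column is Benjamini-Hochberg over all sets in the collection.
    Query members outside the universe are dropped (count logged).
    """
    universe = set(universe)
    query = set(query)
    outside = query - universe
    if outside:
        log.info("ora_test: dropped %d query features outside the universe", len(outside))
        query &= universe
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & universe
        overlap = len(members & query)
        p = hypergeom_upper_tail(overlap, len(universe), len(members), len(query))
        rows.append((name, overlap, len(members), len(query), len(universe), p))
    table = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size",
                       "universe_size", "p"],
    )
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    return table.sort_values(["p", "set_name"], ignore_index=True)
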