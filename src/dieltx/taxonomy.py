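"""A minimal rooted taxonomy with named ranks (NCBI nodes-like dialect)."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Rank vocabulary ordered from shallowest to deepest.
RANKS = ("root", "lineage", "class", "order", "genus", "species")

RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}


@dataclass
class TaxonomyTree:
    """taxon_id -> (parent_id, rank, name), plus the root id.

    The tree must be acyclic, every non-root parent must exist, and ranks
    must come from :data:`RANKS`.
    """

    parent: dict[str, str]
    rank: dict[str, str]
    name: dict[str, str]
    root: str

    def __post_init__(self) -> None:
        for node, r in self.rank.items():
            if r not in RANK_DEPTH:
                raise ValueError(f"unknown rank {r!r} for node {node!r}")
        for node, par in self.parent.items():
            if node == self.root:
                continue
            if par not in self.rank:
                raise ValueError(f"node {node!r} has missing parent {par!r}")
        # cycle check by walking every node to the root
        for node in self.rank:
            seen = set()
            cur = node
            while cur != self.root:
                if cur in seen:
                    raise ValueError(f"cycle in taxonomy at node {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    def __contains__(self, node: str) -> bool:
        return node in self.rank

    def ancestors(self, node: str) -> list[str]:
        """Path from node (exclusive) up to and including the root."""
        out = []
        cur = node
        while cur != self.root:
            cur = self.parent[cur]
            out.append(cur)
        return out

    def ancestor_at_rank(self, node: str, rank: str) -> str | None:
        """The node itself or its ancestor at ``rank``, if any."""
        if self.rank[node] == rank:
            return node
        for anc in self.ancestors(node):
            if self.rank[anc] == rank:
                return anc
        return None

    def nodes_at_rank(self, rank: str) -> list[str]:
        return sorted(n for n, r in self.rank.items() if r == rank)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "taxon_id": n,
                "parent_id": self.parent.get(n, n if n == self.root else ""),
                "rank": self.rank[n],
                "name": self.name.get(n, n),
            }
            for n in sorted(self.rank)
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TaxonomyTree":
        parent = dict(zip(df["taxon_id"], df["parent_id"]))
        rank = dict(zip(df["taxon_id"], df["rank"]))
        name = dict(zip(df["taxon_id"], df["name"]))
        roots = [n for n in rank if parent.get(n, n) == n or rank[n] == "root"]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {roots}")
        return cls(parent=parent, rank=rank, name=name, root=roots[0])
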