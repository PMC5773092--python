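"""Cross-species signature mapping through a user-supplied homolog table."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import GeneSet, GeneSetCollection

__all__ = ["HomologTable", "MappingReport", "map_gene_sets"]


@dataclass
class HomologTable:
    """Two-column mouse/human symbol pairs; direction-agnostic."""

    pairs: pd.DataFrame  # columns: mouse, human

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["mouse", "human"]:
            self.pairs = self.pairs.copy()
            self.pairs.columns = ["mouse", "human"]
        if (self.pairs["mouse"].str.len() == 0).any() or (
            self.pairs["human"].str.len() == 0
        ).any():
            raise ValueError("homolog table contains empty symbols")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        if len(self.pairs) == 0:
            raise ValueError("homolog table is empty")

    @classmethod
    def from_tsv(cls, path) -> "HomologTable":
        pairs = pd.read_csv(path, sep="\t", dtype=str, header=0).iloc[:, :2].dropna()
        return cls(pairs)

    def mapping(self, direction: str) -> dict[str, list[str]]:
        if direction == "mouse_to_human":
            src, dst = "mouse", "human"
        elif direction == "human_to_mouse":
            src, dst = "human", "mouse"
        else:
            raise ValueError("direction must be 'mouse_to_human' or 'human_to_mouse'")
        out: dict[str, list[str]] = {}
        for a, b in zip(self.pairs[src], self.pairs[dst]):
            out.setdefault(a, []).append(b)
        return out


@dataclass
class MappingReport:
    direction: str
    ambiguity_policy: str
    unmapped: dict[str, list[str]] = field(default_factory=dict)  # set -> genes
    expanded: dict[str, list[str]] = field(default_factory=dict)  # set -> multi-homolog genes
    dropped_ambiguous: dict[str, list[str]] = field(default_factory=dict)
    retention: dict[str, float] = field(default_factory=dict)  # set -> fraction mapped

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "set": name,
                "retention": self.retention.get(name, float("nan")),
                "n_unmapped": len(self.unmapped.get(name, [])),
                "n_expanded": len(self.expanded.get(name, [])),
                "n_dropped_ambiguous": len(self.dropped_ambiguous.get(name, [])),
            }
            for name in self.retention
        ]
        return pd.DataFrame(rows).set_index("set")


def map_gene_sets(
    c: GeneSetCollection,
    t: HomologTable,
    direction: str = "mouse_to_human",
    ambiguity_policy: str = "expand",
) -> tuple[GeneSetCollection, MappingReport]:
    """Translate every gene set through the homolog table.

    ``expand`` keeps all homologs of a many-homolog gene; ``drop`` removes
    such genes entirely.  Mapped sets are deduplicated in first-occurrence
    order.  A set whose translation comes out empty raises, naming the set.
    """
    if ambiguity_policy not in ("expand", "drop"):
        raise ValueError("ambiguity_policy must be 'expand' or 'drop'")
    lookup = t.mapping(direction)
    report = MappingReport(direction=direction, ambiguity_policy=ambiguity_policy)
    mapped_sets: dict[str, GeneSet] = {}
    for name in c.names():
        gs = c[name]
        out: list[str] = []
        seen: set[str] = set()
        unmapped: list[str] = []
        expanded: list[str] = []
        dropped: list[str] = []
        n_mapped = 0
        for g in gs.genes:
            homologs = lookup.get(g)
            if not homologs:
                unmapped.append(g)
                continue
            if len(homologs) > 1:
                if ambiguity_policy == "drop":
                    dropped.append(g)
                    continue
                expanded.append(g)
            n_mapped += 1
            for h in homologs:
                if h not in seen:
                    seen.add(h)
                    out.append(h)
        report.unmapped[name] = unmapped
        report.expanded[name] = expanded
        report.dropped_ambiguous[name] = dropped
        report.retention[name] = n_mapped / len(gs.genes)
        if not out:
            raise ValueError(f"set {name!r} is empty after homolog mapping")
        mapped_sets[name] = GeneSet(name, gs.description, out)
    return GeneSetCollection(mapped_sets), report
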