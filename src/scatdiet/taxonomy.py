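"""Seven-rank taxonomic lineages and the reference lineage table.

Taxonomic identity is carried as an ordered path over the seven classical
ranks (domain, phylum, class, order, family, genus, species). Lineages are
filled from the top down: a lineage may be truncated (deep ranks empty) but
never has gaps, so a named genus always implies a named family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import ConfigError

RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Minimum depth (number of named leading ranks) for a usable assignment:
#: anything resolving only above order is reported as unassigned.
MIN_ASSIGNABLE_DEPTH: int = RANK_INDEX["order"] + 1


@dataclass(frozen=True)
class Lineage:
    """An ordered 7-rank taxonomic path, possibly truncated at the bottom."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise ValueError(f"lineage must have {len(RANKS)} ranks, got {len(self.names)}")
        seen_empty = False
        for name in self.names:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"lineage filled with gaps: {self.names}")

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "Lineage":
        """Build from up to 7 leading names; missing deep ranks are left empty."""
        tup = tuple(names)
        return cls(tup + ("",) * (len(RANKS) - len(tup)))

    @property
    def depth(self) -> int:
        """Number of named leading ranks."""
        n = 0
        for name in self.names:
            if name == "":
                break
            n += 1
        return n

    @property
    def deepest_name(self) -> str:
        d = self.depth
        return self.names[d - 1] if d else ""

    @property
    def deepest_rank(self) -> str:
        d = self.depth
        return RANKS[d - 1] if d else ""

    @property
    def is_assignable(self) -> bool:
        """True if resolved at least to order."""
        return self.depth >= MIN_ASSIGNABLE_DEPTH

    def prefix(self, depth: int) -> "Lineage":
        return Lineage(self.names[:depth] + ("",) * (len(RANKS) - depth))

    def name_at(self, rank: str) -> str:
        return self.names[RANK_INDEX[rank]]

    def __iter__(self):
        return iter(self.names)


class Taxonomy:
    """Lineage table: taxon_id -> 7-rank lineage plus a habitat class.

    Backed by a pandas DataFrame indexed by taxon_id with one column per
    rank and an optional ``habitat_class`` column
    ({woodland, open, aquatic, none}).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [r for r in RANKS if r not in frame.columns]
        if missing:
            raise ConfigError(f"lineage table missing rank columns: {missing}")
        frame = frame.copy()
        if "habitat_class" not in frame.columns:
            frame["habitat_class"] = "none"
        self.frame = frame
        self._lineages: dict[str, Lineage] = {
            tid: Lineage(tuple(row[r] for r in RANKS))
            for tid, row in frame.iterrows()
        }
        # reverse index: rank-name -> (depth, lineage prefix); species labels
        # map to full lineages, higher-rank labels to truncated ones.
        self._label_index: dict[str, Lineage] = {}
        for lin in self._lineages.values():
            for depth in range(1, len(RANKS) + 1):
                name = lin.names[depth - 1]
                if name and name not in self._label_index:
                    self._label_index[name] = lin.prefix(depth)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._lineages

    def __len__(self) -> int:
        return len(self._lineages)

    @property
    def ids(self) -> list[str]:
        return list(self._lineages)

    def lineage(self, taxon_id: str) -> Lineage:
        try:
            return self._lineages[taxon_id]
        except KeyError:
            raise ConfigError(f"unknown taxon_id: {taxon_id!r}") from None

    def habitat(self, taxon_id: str) -> str:
        return str(self.frame.loc[taxon_id, "habitat_class"])

    def species_label(self, taxon_id: str) -> str:
        """The species name of a reference taxon (deepest rank)."""
        return self.lineage(taxon_id).deepest_name

    def lineage_for_label(self, label: str) -> Optional[Lineage]:
        """Lineage (possibly truncated) for any rank name appearing in the table.

        A species label yields the full lineage; a family label such as
        'Anatidae' yields the lineage truncated at family. Returns None for
        labels absent from the table.
        """
        return self._label_index.get(label)

    def habitat_for_label(self, label: str) -> str:
        """Habitat class for a taxon label; 'other' if unknown or unclassified."""
        lin = self.lineage_for_label(label)
        if lin is None:
            return "other"
        for tid, full in self._lineages.items():
            if full.names[: lin.depth] == lin.names[: lin.depth]:
                hab = self.habitat(tid)
                return hab if hab in ("woodland", "open", "aquatic") else "other"
        return "other"

    def to_tsv(self, path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "taxon_id"})
        if out.columns[0] != "taxon_id":
            out = out.rename(columns={out.columns[0]: "taxon_id"})
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        frame = pd.read_csv(path, sep="\t", dtype=str).set_index("taxon_id")
        return cls(frame)
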