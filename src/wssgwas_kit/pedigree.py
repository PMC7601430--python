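"""Pedigree container and topological utilities.

A pedigree is a directed acyclic parent structure: every animal has at most
one sire and one dam, and a topological order (parents before offspring)
must exist.  Unknown parents are represented as ``None`` internally and as
``"0"`` or an empty field in CSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = None


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate ids, cycles, ...)."""


@dataclass
class Pedigree:
    """Ordered pedigree records ``(animal_id, sire_id, dam_id)``.

    On construction, parents that never appear as animals are appended as
    founder records, ids are checked for uniqueness, and a topological
    order is computed (raising :class:`PedigreeError` on cycles).
    """

    records: list[tuple[str, str | None, str | None]]
    _index: dict[str, int] = field(init=False, repr=False)
    _topo: list[int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.records = [
            (str(a), _norm(s), _norm(d)) for a, s, d in self.records
        ]
        seen: set[str] = set()
        for a, _, _ in self.records:
            if a in seen:
                raise PedigreeError(f"duplicate animal id {a!r}")
            seen.add(a)
        # complete: named parents become founder records (prepended)
        missing = []
        for _, s, d in self.records:
            for p in (s, d):
                if p is not None and p not in seen:
                    seen.add(p)
                    missing.append((p, None, None))
        if missing:
            self.records = missing + self.records
        self._index = {a: i for i, (a, _, _) in enumerate(self.records)}
        self._topo = self._toposort()

    # -- basic accessors -------------------------------------------------
    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def index_of(self, animal_id: str) -> int:
        return self._index[animal_id]

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) arrays with -1 for unknown."""
        n = len(self.records)
        s = np.full(n, -1, dtype=np.int64)
        d = np.full(n, -1, dtype=np.int64)
        for i, (_, si, di) in enumerate(self.records):
            if si is not None:
                s[i] = self._index[si]
            if di is not None:
                d[i] = self._index[di]
        return s, d

    def topological_order(self) -> list[int]:
        """Indices into ``records`` with parents before offspring."""
        return list(self._topo)

    def _toposort(self) -> list[int]:
        n = len(self.records)
        s, d = (
            np.full(n, -1, dtype=np.int64),
            np.full(n, -1, dtype=np.int64),
        )
        for i, (_, si, di) in enumerate(self.records):
            s[i] = self._index[si] if si is not None else -1
            d[i] = self._index[di] if di is not None else -1
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (s[i], d[i]):
                if p >= 0:
                    indeg[i] += 1
                    children[p].append(i)
        queue = [i for i in range(n) if indeg[i] == 0]
        order: list[int] = []
        while queue:
            i = queue.pop()
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a cycle")
        return order

    def generation_of(self, animal_id: str) -> int:
        """Longest ancestral path length (founders are generation 0)."""
        s, d = self.parent_indices()
        gen = np.zeros(len(self), dtype=np.int64)
        for i in self._topo:
            g = 0
            for p in (s[i], d[i]):
                if p >= 0:
                    g = max(g, gen[p] + 1)
            gen[i] = g
        return int(gen[self._index[animal_id]])

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, s or "0", d or "0") for a, s, d in self.records],
            columns=["animal", "sire", "dam"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        recs = [
            (str(r.animal), _norm(r.sire), _norm(r.dam))
            for r in frame.itertuples()
        ]
        return cls(recs)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, dtype=str, keep_default_na=False))


def _norm(p) -> str | None:
    if p is None:
        return None
    p = str(p).strip()
    if p in ("", "0", "NA", "nan", "None"):
        return None
    return p
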