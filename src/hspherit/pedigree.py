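"""Pedigrees and the numerator (additive) relationship matrix.

The animal model treats each individual's additive genetic merit as a random
effect whose covariance is ``V_A * A``, where ``A`` is the numerator
relationship matrix implied by the pedigree.  This module parses and validates
pedigree files, orders them topologically (parents before offspring), and
builds ``A`` by the tabular method.  A slow pairwise-recursion oracle is
provided for cross-checking.

Missing parents are treated as unrelated, non-inbred founders drawn from the
base population.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Token used internally for an unknown parent.
UNKNOWN = ""

DEFAULT_MISSING_TOKENS = ("", "0", "NA", ".", "na", "nan", "NaN")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles,
    undefined parents)."""


@dataclass(frozen=True)
class Pedigree:
    """A validated pedigree in topological (parents-first) order.

    Attributes
    ----------
    animals, sires, dams :
        Parallel tuples of labels; ``UNKNOWN`` ("") marks a missing parent.
        Ordered so every known parent precedes all of its offspring.
    """

    animals: tuple[str, ...]
    sires: tuple[str, ...]
    dams: tuple[str, ...]
    index: dict[str, int] = field(repr=False, compare=False, default_factory=dict)

    def __post_init__(self):
        object.__setattr__(
            self, "index", {a: i for i, a in enumerate(self.animals)}
        )

    def __len__(self) -> int:
        return len(self.animals)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(
            a
            for a, s, d in zip(self.animals, self.sires, self.dams)
            if s == UNKNOWN and d == UNKNOWN
        )

    def parents_of(self, animal: str) -> tuple[str, str]:
        i = self.index[animal]
        return self.sires[i], self.dams[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animals, "sire": self.sires, "dam": self.dams}
        )

    @classmethod
    def from_records(
        cls,
        records: list[tuple[str, str, str]],
        *,
        auto_add_founders: bool = False,
    ) -> "Pedigree":
        """Validate and topologically order raw (animal, sire, dam) records.

        Ordering is a stable Kahn sort: among animals whose parents are all
        placed, input order is preserved, so the result is reproducible.
        """
        animals = [str(r[0]) for r in records]
        if len(set(animals)) != len(animals):
            seen: set[str] = set()
            for a in animals:
                if a in seen:
                    raise PedigreeError(f"duplicate animal id: {a!r}")
                seen.add(a)
        parent_map: dict[str, tuple[str, str]] = {}
        for a, s, d in records:
            parent_map[str(a)] = (str(s), str(d))
        defined = set(parent_map)

        referenced = {
            p for s, d in parent_map.values() for p in (s, d) if p != UNKNOWN
        }
        missing = sorted(referenced - defined)
        if missing:
            if not auto_add_founders:
                raise PedigreeError(
                    "parent(s) referenced but never defined: "
                    + ", ".join(missing[:10])
                )
            for p in missing:
                parent_map[p] = (UNKNOWN, UNKNOWN)
            order_in = missing + [str(r[0]) for r in records]
        else:
            order_in = [str(r[0]) for r in records]

        # Stable Kahn topological sort.
        placed: set[str] = set()
        ordered: list[str] = []
        pending = list(order_in)
        while pending:
            progressed = False
            remaining: list[str] = []
            for a in pending:
                s, d = parent_map[a]
                if (s == UNKNOWN or s in placed) and (d == UNKNOWN or d in placed):
                    ordered.append(a)
                    placed.add(a)
                    progressed = True
                else:
                    remaining.append(a)
            if not progressed:
                raise PedigreeError(
                    "cycle detected in pedigree involving: "
                    + ", ".join(remaining[:10])
                )
            pending = remaining

        return cls(
            animals=tuple(ordered),
            sires=tuple(parent_map[a][0] for a in ordered),
            dams=tuple(parent_map[a][1] for a in ordered),
        )


def read_pedigree(
    path: str | Path,
    *,
    animal_col: str = "animal",
    sire_col: str = "sire",
    dam_col: str = "dam",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
    auto_add_founders: bool = False,
    sep: str | None = None,
) -> Pedigree:
    """Read a delimited pedigree file (header required) into a :class:`Pedigree`.

    ``sep=None`` sniffs comma vs tab.  Tokens in ``missing_tokens`` in the
    parent columns denote unknown parents.
    """
    df = pd.read_csv(
        path, sep=sep, engine="python", dtype=str, keep_default_na=False, comment="#"
    )
    for col in (animal_col, sire_col, dam_col):
        if col not in df.columns:
            raise PedigreeError(
                f"pedigree file {path} lacks required column {col!r}; "
                f"found {list(df.columns)}"
            )
    toks = set(missing_tokens)

    def clean(v: str) -> str:
        v = v.strip()
        return UNKNOWN if v in toks else v

    records = [
        (row[animal_col].strip(), clean(row[sire_col]), clean(row[dam_col]))
        for _, row in df.iterrows()
    ]
    for a, _, _ in records:
        if a in toks or not a:
            raise PedigreeError(f"animal id {a!r} collides with a missing-value token")
    return Pedigree.from_records(records, auto_add_founders=auto_add_founders)


@dataclass(frozen=True)
class RelationshipMatrix:
    """Numerator relationship matrix ``A`` in pedigree order.

    ``A[i, j]`` is twice the kinship coefficient between animals ``i`` and
    ``j``; diagonals are ``1 + F`` with ``F`` the inbreeding coefficient.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    @property
    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0

    def loc(self, i: str, j: str) -> float:
        idx = {a: k for k, a in enumerate(self.labels)}
        return float(self.values[idx[i], idx[j]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="animal")


def additive_relationship(pedigree: Pedigree) -> RelationshipMatrix:
    """Build ``A`` by the tabular method.

    For animal ``i`` with parents ``s, d`` already processed::

        A[i, j] = 0.5 * (A[j, s] + A[j, d])   for j < i
        A[i, i] = 1 + 0.5 * A[s, d]

    with an unknown parent contributing zero relationship and no inbreeding.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    idx = pedigree.index
    for i, (a, s, d) in enumerate(
        zip(pedigree.animals, pedigree.sires, pedigree.dams)
    ):
        si = idx[s] if s != UNKNOWN else -1
        di = idx[d] if d != UNKNOWN else -1
        if si >= i or di >= i:
            raise PedigreeError(f"pedigree not parents-first ordered at {a!r}")
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        f = 0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + f
    return RelationshipMatrix(labels=pedigree.animals, values=A)


def relationship_oracle(
    pedigree: Pedigree,
    i: str,
    j: str,
    cache: dict[tuple[int, int], float] | None = None,
) -> float:
    """Additive relationship of a single pair by naive recursion.

    Independent of the tabular construction; used to cross-check it.
    Complexity is exponential without memoisation, so a cache on index
    pairs is kept; pass a dict as ``cache`` to share the memo across calls
    (e.g. when checking every pair of a pedigree).
    """
    idx = pedigree.index
    for lab in (i, j):
        if lab not in idx:
            raise KeyError(f"unknown animal id: {lab!r}")
    sires = pedigree.sires
    dams = pedigree.dams
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * len(pedigree) + 100))

    if cache is None:
        cache = {}

    def rel(p: int, q: int) -> float:
        if p < 0 or q < 0:
            return 0.0
        key = (p, q) if p >= q else (q, p)
        if key in cache:
            return cache[key]
        p, q = key  # p is the later-born of the pair
        if p == q:
            s, d = sires[p], dams[p]
            si = idx[s] if s != UNKNOWN else -1
            di = idx[d] if d != UNKNOWN else -1
            out = 1.0 + 0.5 * rel(si, di)
        else:
            s, d = sires[p], dams[p]
            si = idx[s] if s != UNKNOWN else -1
            di = idx[d] if d != UNKNOWN else -1
            out = 0.5 * (rel(si, q) + rel(di, q))
        cache[key] = out
        return out

    return rel(idx[i], idx[j])
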