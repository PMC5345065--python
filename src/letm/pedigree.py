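"""Pedigree validation and the additive genetic relationship matrix.

The animal model needs the matrix A of expected additive relatedness between
all individuals (1 on the diagonal for non-inbred individuals, 0.5 full sibs
and parent-offspring, 0.25 half sibs, ...). A is built by the standard
tabular (recursive) method over a topologically sorted pedigree:

    A_ii = 1 + 0.5 * A[dam(i), sire(i)]
    A_ij = 0.5 * (A[j, dam(i)] + A[j, sire(i)])   for j processed before i

Founders are taken as unrelated and non-inbred; an unknown single parent is
treated as an unlisted founder (its contribution to the recursion is zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: sentinels accepted for "parent unknown" in input tables
UNKNOWN_SENTINELS = {"", "0", "NA", "na", "None", None}


class PedigreeError(ValueError):
    """Raised when a pedigree violates structural invariants.

    The message lists *all* violations found, one per line.
    """


@dataclass(frozen=True)
class PedigreeTable:
    """Validated, topologically ordered pedigree.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, parents before offspring.
    dam, sire : dict
        Maps id -> parent id, or ``None`` when the parent is unknown.
    """

    ids: list[str]
    dam: dict[str, str | None]
    sire: dict[str, str | None]

    def __len__(self) -> int:
        return len(self.ids)

    def is_founder(self, individual: str) -> bool:
        return self.dam[individual] is None and self.sire[individual] is None

    @property
    def founders(self) -> list[str]:
        return [i for i in self.ids if self.is_founder(i)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "dam": [self.dam[i] or "0" for i in self.ids],
                "sire": [self.sire[i] or "0" for i in self.ids],
            }
        )


@dataclass(frozen=True)
class RelatednessMatrix:
    """Square matrix of pairwise additive relatedness, with row/column ids."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValueError("relatedness matrix must be square and match ids")

    def loc(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.values[i, j])

    def restrict(self, subset: list[str]) -> "RelatednessMatrix":
        """Principal submatrix for `subset` (order preserved).

        A principal submatrix of a PSD matrix is PSD, so the restriction is
        a valid relatedness matrix for the subset.
        """
        index = {x: k for k, x in enumerate(self.ids)}
        missing = [s for s in subset if s not in index]
        if missing:
            raise KeyError(f"ids not in relatedness matrix: {missing}")
        rows = np.array([index[s] for s in subset])
        return RelatednessMatrix(list(subset), self.values[np.ix_(rows, rows)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="id")


def _normalize_parent(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return None if text in UNKNOWN_SENTINELS else text


def validate_pedigree(table) -> PedigreeTable:
    """Validate raw parent-link records and return a topologically ordered pedigree.

    Parameters
    ----------
    table : DataFrame, mapping, or iterable of (id, dam, sire)
        Raw records. Unknown parents may be encoded as "0", "", "NA" or None.
        A DataFrame must carry columns ``id``, ``dam``, ``sire``.

    Returns
    -------
    PedigreeTable
        With ids reordered so every parent precedes its offspring.

    Raises
    ------
    PedigreeError
        Listing every violation found: duplicate ids, parents referenced but
        never defined, individuals that are their own ancestor (cycles).
    """
    if isinstance(table, pd.DataFrame):
        required = {"id", "dam", "sire"}
        if not required.issubset(table.columns):
            raise PedigreeError(f"pedigree table must have columns {sorted(required)}")
        records = list(zip(table["id"], table["dam"], table["sire"]))
    elif isinstance(table, dict):
        records = [(k, v[0], v[1]) for k, v in table.items()]
    else:
        records = [tuple(r) for r in table]

    violations: list[str] = []
    ids: list[str] = []
    dam: dict[str, str | None] = {}
    sire: dict[str, str | None] = {}
    for rid, rdam, rsire in records:
        key = str(rid).strip()
        if key in UNKNOWN_SENTINELS:
            violations.append(f"invalid individual id {rid!r}")
            continue
        if key in dam:
            violations.append(f"duplicate id {key!r}")
            continue
        ids.append(key)
        dam[key] = _normalize_parent(rdam)
        sire[key] = _normalize_parent(rsire)

    defined = set(ids)
    for i in ids:
        for role, parent in (("dam", dam[i]), ("sire", sire[i])):
            if parent is not None and parent not in defined:
                violations.append(f"undefined parent: {role} {parent!r} of {i!r}")

    # dam/sire role consistency: one id never used in both roles
    dams_used = {p for p in dam.values() if p is not None}
    sires_used = {p for p in sire.values() if p is not None}
    for both in sorted(dams_used & sires_used):
        violations.append(f"id {both!r} used as both dam and sire")

    # Kahn topological sort over the defined-parent graph; leftovers are cycles.
    order: list[str] = []
    remaining = set(ids)
    placed: set[str] = set()
    while remaining:
        ready = [
            i
            for i in ids
            if i in remaining
            and (dam[i] is None or dam[i] in placed or dam[i] not in defined)
            and (sire[i] is None or sire[i] in placed or sire[i] not in defined)
        ]
        if not ready:
            for i in sorted(remaining):
                violations.append(f"cycle: {i!r} is its own ancestor")
            break
        order.extend(ready)
        placed.update(ready)
        remaining.difference_update(ready)

    if violations:
        raise PedigreeError("invalid pedigree:\n" + "\n".join(violations))
    return PedigreeTable(order, dam, sire)


def read_pedigree(path: str | Path, sep: str | None = None) -> PedigreeTable:
    """Read a delimited pedigree file with header id,dam,sire (sentinel 0/empty)."""
    frame = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    return validate_pedigree(frame)


def build_additive_relationship(ped: PedigreeTable) -> RelatednessMatrix:
    """Construct the additive genetic relationship matrix A by the tabular method.

    Founders are unrelated and non-inbred (identity block); an unknown parent
    contributes zero relatedness. The result is symmetric, positive definite,
    with diagonal 1 + F_i (inbreeding coefficient F_i, zero when dam and sire
    are unrelated).
    """
    n = len(ped.ids)
    index = {x: k for k, x in enumerate(ped.ids)}
    a = np.zeros((n, n))
    for i_name in ped.ids:  # topological order: parents already filled
        i = index[i_name]
        d = index.get(ped.dam[i_name]) if ped.dam[i_name] else None
        s = index.get(ped.sire[i_name]) if ped.sire[i_name] else None
        a[i, i] = 1.0 + (0.5 * a[d, s] if d is not None and s is not None else 0.0)
        if i:
            rel = np.zeros(i)
            if d is not None:
                rel += 0.5 * a[:i, d]
            if s is not None:
                rel += 0.5 * a[:i, s]
            a[i, :i] = a[:i, i] = rel
    return RelatednessMatrix(list(ped.ids), a)
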