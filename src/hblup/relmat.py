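"""Shared relationship-matrix container.

A :class:`RelationshipMatrix` is a symmetric matrix of additive relationship
coefficients indexed by individual id.  The same container is used for the
pedigree matrix A and its blocks, the genomic matrix G, the tuned/blended
matrices Ga/Gw, and the combined single-step matrix H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: recognised matrix roles
ROLES = {"A", "A11", "A12", "A22", "G", "Ga", "Gw", "H", "Hinv", "generic"}


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with an individual-id index.

    Parameters
    ----------
    ids
        Ordered individual identifiers (row == column order).
    values
        ``(n, n)`` array of relationship coefficients.
    role
        One of :data:`ROLES`; purely informational.
    """

    ids: list[str]
    values: np.ndarray
    role: str = "generic"
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        # off-square roles (A12) are rectangular; skip the symmetry check
        if self.role != "A12" and n > 0:
            asym = np.max(np.abs(self.values - self.values.T))
            if asym > 1e-8:
                raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in relationship matrix")

    # -- indexing helpers -------------------------------------------------
    def loc(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def indices_of(self, ids: list[str]) -> np.ndarray:
        missing = [i for i in ids if i not in self._index]
        if missing:
            raise KeyError(f"ids not in matrix: {missing[:5]}")
        return np.array([self._index[i] for i in ids], dtype=int)

    def subset(self, ids: list[str], role: str | None = None) -> "RelationshipMatrix":
        idx = self.indices_of(ids)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)],
                                  role or self.role)

    @property
    def n(self) -> int:
        return len(self.ids)

    # -- serialisation -----------------------------------------------------
    def to_dense_csv(self, path) -> None:
        """Write a dense CSV with ids as header and first column."""
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)

    def to_triplets(self, path) -> None:
        """Write lower-triangle triplets ``rowid colid value`` (text).

        The layout follows the convention of pedigree/genomic BLUP tooling:
        one line per nonzero lower-triangle element, 17 significant digits.
        """
        with open(path, "w") as fh:
            for i in range(self.n):
                for j in range(i + 1):
                    v = self.values[i, j]
                    if v != 0.0:
                        fh.write(f"{self.ids[i]}\t{self.ids[j]}\t{v:.17g}\n")

    @classmethod
    def from_dense_csv(cls, path, role: str = "generic") -> "RelationshipMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), role)
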