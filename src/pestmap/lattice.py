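"""Areal lattice container: areas, contiguity graph, components, populations.

The lattice is the spatial skeleton shared by the synthetic generator, the
standardization step and the spatiotemporal model.  Adjacency is a symmetric
0/1 matrix with zero diagonal; connected components are labelled so that
intrinsic CAR fields can be constrained per component (a city whose
geography includes an island yields a disconnected contiguity graph).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


@dataclass
class AreaLattice:
    """Symmetric contiguity graph over administrative areas.

    Parameters
    ----------
    area_ids
        Unique string identifier per area, in matrix order.
    adjacency
        ``(n, n)`` sparse 0/1 matrix, symmetric, zero diagonal.
    population
        Persons per area (used to build expected counts).
    component
        Connected-component label per area (computed if not given).
    """

    area_ids: list[str]
    adjacency: sp.csr_matrix
    population: np.ndarray
    component: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.area_ids)
        self.adjacency = sp.csr_matrix(self.adjacency)
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"adjacency shape {self.adjacency.shape} does not match "
                f"{n} area ids"
            )
        if (self.adjacency != self.adjacency.T).nnz:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        self.population = np.asarray(self.population, dtype=float)
        if self.population.shape != (n,):
            raise ValueError("population must have one entry per area")
        if self.component is None:
            _, labels = connected_components(self.adjacency, directed=False)
            self.component = labels
        self.component = np.asarray(self.component, dtype=int)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_components(self) -> int:
        return int(self.component.max()) + 1 if self.n_areas else 0

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    # ------------------------------------------------------------------ IO

    def to_edgelist(self, path) -> None:
        """Write one undirected edge per line as two area ids."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        with open(path, "w") as fh:
            for i, j in zip(coo.row, coo.col):
                fh.write(f"{self.area_ids[i]}\t{self.area_ids[j]}\n")

    @classmethod
    def from_edgelist(
        cls,
        path,
        area_ids: list[str],
        population: np.ndarray,
    ) -> "AreaLattice":
        """Read a two-column edge list; ids absent from the list are isolates."""
        index = {a: k for k, a in enumerate(area_ids)}
        rows, cols = [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: expected two area ids")
                a, b = parts
                try:
                    i, j = index[a], index[b]
                except KeyError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unknown area id {exc.args[0]!r}"
                    ) from None
                rows += [i, j]
                cols += [j, i]
        n = len(area_ids)
        adj = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        adj.data[:] = 1.0  # collapse duplicate edges
        return cls(list(area_ids), adj, population)
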