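"""Binary haplotype datasets.

A dataset is a sample of ``n`` phased haplotypes over ``L`` discrete genome
sites, each site coded 0 (ancestral allele) / 1 (derived allele).  Under the
discretized infinite-sites model at most one mutation occurred per site, so a
dataset is fully described by its segregating sites and their derived-carrier
sets; monomorphic-ancestral sites carry no information beyond ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Dataset"]


@dataclass(frozen=True)
class Dataset:
    """A sample of ``n`` binary haplotypes over ``L`` sites.

    Parameters
    ----------
    n : int
        Number of haplotypes (samples).  Samples are labelled ``0..n-1``.
    L : int
        Number of genome sites.
    seg : dict[int, frozenset[int]]
        Maps each segregating site (0-based index) to the set of samples
        carrying the derived allele.  Carrier sets must be proper, non-empty
        subsets of the sample set: a site derived in *all* samples cannot
        arise when the ancestral allele is known.
    """

    n: int
    L: int
    seg: dict[int, frozenset[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a dataset needs at least two haplotypes")
        if self.L < 1:
            raise ValueError("L must be positive")
        full = frozenset(range(self.n))
        for site, carriers in self.seg.items():
            if not 0 <= site < self.L:
                raise ValueError(f"site {site} outside [0, {self.L})")
            if not carriers or not carriers <= full:
                raise ValueError(f"site {site}: invalid carrier set {set(carriers)}")
            if carriers == full:
                raise ValueError(
                    f"site {site} is derived in every sample; incompatible with a "
                    "known ancestral allele under the infinite-sites model"
                )

    @property
    def M(self) -> int:
        """Number of segregating sites."""
        return len(self.seg)

    @property
    def positions(self) -> list[int]:
        """Sorted segregating-site indices."""
        return sorted(self.seg)

    def matrix(self, segregating_only: bool = False) -> np.ndarray:
        """Return the haplotype matrix as a 0/1 integer array.

        With ``segregating_only`` the columns are restricted to
        :attr:`positions` (in sorted order); otherwise the full ``n x L``
        matrix is materialized.
        """
        cols = self.positions if segregating_only else range(self.L)
        out = np.zeros((self.n, len(list(cols))), dtype=np.int8)
        for j, site in enumerate(self.positions if segregating_only else range(self.L)):
            carriers = self.seg.get(site)
            if carriers:
                out[list(carriers), j] = 1
        return out

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, positions: "list[int] | None" = None,
                    L: "int | None" = None) -> "Dataset":
        """Build a dataset from an ``n x m`` 0/1 matrix.

        ``positions`` gives the genome site of each column (defaults to
        ``0..m-1``); ``L`` the genome length (defaults to ``max(position)+1``
        or the column count).  Columns with values outside {0, 1} are
        rejected: multi-allelic input is out of model.
        """
        matrix = np.asarray(matrix)
        if matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-dimensional")
        vals = np.unique(matrix)
        if not set(vals.tolist()) <= {0, 1}:
            raise ValueError(f"haplotype matrix must be binary 0/1; saw values {vals}")
        n, m = matrix.shape
        if positions is None:
            positions = list(range(m))
        if len(positions) != m:
            raise ValueError("positions length must match the column count")
        if L is None:
            L = (max(positions) + 1) if positions else m
        seg = {}
        for j, site in enumerate(positions):
            carriers = frozenset(np.flatnonzero(matrix[:, j]).tolist())
            if carriers:
                seg[int(site)] = carriers
        return cls(n=n, L=int(L), seg=seg)
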