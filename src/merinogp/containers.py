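"""In-memory containers shared across the pipeline.

Genotypes are held as an individuals x markers dosage matrix (counts of a
counted allele, 0/1/2, NaN = missing) plus a marker-metadata table; the
genomic relationship matrix carries its individual ids and the VanRaden
scaling denominator so downstream code can audit the construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_COLUMNS = ("id", "chrom", "pos", "a1", "a2")

#: sheep autosome labels; X/Y/MT recognized only for exclusion
AUTOSOMES = frozenset(str(c) for c in range(1, 27))


@dataclass
class GenotypeMatrix:
    """Dosage matrix with marker metadata.

    Parameters
    ----------
    dosages
        float array (n_individuals, n_markers); entries 0/1/2 count the
        counted allele ``a1``; NaN marks a missing genotype. Imputed
        matrices may hold fractional expected dosages.
    individual_ids
        ordered unique individual identifiers, one per row.
    markers
        DataFrame with columns ``id, chrom, pos, a1, a2`` (chromosome kept
        as a string label) and optionally ``low_panel`` (bool membership
        flag for a nested low-density panel).
    """

    dosages: np.ndarray
    individual_ids: list[str]
    markers: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x markers)")
        self.individual_ids = [str(i) for i in self.individual_ids]
        n, m = self.dosages.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids must be unique")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        if len(self.markers) != m:
            raise ValueError("marker table length does not match dosage columns")
        if self.markers["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self.markers = self.markers.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> list[str]:
        return self.markers["id"].astype(str).tolist()

    def is_complete(self) -> bool:
        return bool(np.isfinite(self.dosages).all())

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the marker positions in ``index`` (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            list(self.individual_ids),
            self.markers.iloc[index].reset_index(drop=True),
        )

    def subset_markers_by_id(self, ids: list[str]) -> "GenotypeMatrix":
        """Restrict to the named markers, in current matrix order."""
        wanted = set(str(i) for i in ids)
        mask = self.markers["id"].astype(str).isin(wanted).to_numpy()
        found = set(self.markers["id"].astype(str)[mask])
        absent = wanted - found
        if absent:
            raise KeyError(f"{len(absent)} marker ids not present, e.g. {sorted(absent)[:3]}")
        return self.subset_markers(mask)

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        ids = [self.individual_ids[i] for i in index]
        return GenotypeMatrix(self.dosages[index, :], ids, self.markers.copy())


@dataclass
class GRM:
    """Genomic relationship matrix (VanRaden method 1).

    ``denominator`` is the scalar 2*sum_f p_f(1-p_f) used to scale W W';
    keeping it allows exact conversion between marker-effect variance and
    additive genetic variance.
    """

    matrix: np.ndarray
    individual_ids: list[str]
    denominator: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]
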