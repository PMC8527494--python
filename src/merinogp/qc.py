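"""Marker quality control and sporadic-genotype imputation.

Filters follow the usual PLINK-style preprocessing of microarray data:
non-autosomal markers (sheep autosomes 1-26; X/Y/MT excluded), call rate,
minor allele frequency, and the exact Hardy-Weinberg test. Removal is by
strict inequality — a marker exactly at a threshold is kept — and the
filters run in a fixed order so the per-filter attribution in
:class:`QCReport` is deterministic. Missing genotypes that survive QC are
filled by a simple allele-frequency imputer (expected dosage 2p, or a
binomial draw), sufficient for the sporadic (<=5%) missingness these panels
show after filtering.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from merinogp.containers import AUTOSOMES, GenotypeMatrix


@dataclass
class QCThresholds:
    """Marker-retention thresholds; markers strictly below a threshold are removed."""

    min_call_rate: float = 0.95
    min_maf: float = 0.01
    min_hwe_p: float = 1e-6
    autosomes_only: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "min_hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    """Counts of markers removed per filter, applied sequentially."""

    n_markers_in: int
    removed_non_autosomal: int
    removed_call_rate: int
    removed_maf: int
    removed_hwe: int
    n_markers_out: int
    n_imputed_cells: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def marker_call_rate(dosage_column: np.ndarray) -> float:
    """Fraction of non-missing entries in one marker's dosage column."""
    col = np.asarray(dosage_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty dosage column")
    return float(np.isfinite(col).mean())


def marker_maf(dosage_column: np.ndarray) -> float:
    """Minor allele frequency min(p, 1-p), p from non-missing dosages."""
    col = np.asarray(dosage_column, dtype=float)
    obs = col[np.isfinite(col)]
    if obs.size == 0:
        raise ValueError("all-missing dosage column")
    p = obs.mean() / 2.0
    return float(min(p, 1.0 - p))


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Conditions on the allele counts and sums, over all heterozygote counts
    with the same parity, the hypergeometric null probabilities that do not
    exceed that of the observed count. Probabilities are built by the
    standard ratio recurrence, which is numerically stable for the marker
    sample sizes seen in practice.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotyped individuals")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # copies of the rarer allele
    # feasible het counts share the parity of the rare-allele count
    het_max = min(n_rare, 2 * n - n_rare)
    het_min = n_rare % 2

    probs = np.zeros(het_max + 1)
    # start at the largest feasible het count and recurse downwards:
    # P(h-2)/P(h) = h(h-1) / (4 (hom_r+1)(hom_c+1))
    h = het_max
    probs[h] = 1.0
    hom_r = (n_rare - h) // 2
    hom_c = n - h - hom_r
    while h > het_min + 1:
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    total = probs.sum()
    probs /= total

    obs = probs[n_Aa]
    p = probs[probs <= obs * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    obs = col[np.isfinite(col)]
    rounded = np.rint(obs)
    if not np.allclose(obs, rounded, atol=1e-6):
        raise ValueError("HWE test requires hard-called (integer) dosages; run QC before imputation")
    n2 = int((rounded == 2).sum())
    n1 = int((rounded == 1).sum())
    n0 = int((rounded == 0).sum())
    return n2, n1, n0


def apply_qc(gm: GenotypeMatrix, thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter markers in order: non-autosomal, call rate, MAF, HWE.

    Markers exactly at a threshold are kept; surviving markers keep their
    original order. MAF and HWE are computed from the non-missing entries
    of markers that survived the call-rate filter.
    """
    thresholds = thresholds or QCThresholds()
    n_in = gm.n_markers
    keep = np.ones(n_in, dtype=bool)

    removed_auto = 0
    if thresholds.autosomes_only:
        chrom = gm.markers["chrom"].astype(str).to_numpy()
        autosomal = np.array([c in AUTOSOMES for c in chrom])
        removed_auto = int((keep & ~autosomal).sum())
        keep &= autosomal

    removed_cr = 0
    for j in np.flatnonzero(keep):
        if marker_call_rate(gm.dosages[:, j]) < thresholds.min_call_rate:
            keep[j] = False
            removed_cr += 1

    removed_maf = 0
    for j in np.flatnonzero(keep):
        if marker_maf(gm.dosages[:, j]) < thresholds.min_maf:
            keep[j] = False
            removed_maf += 1

    removed_hwe = 0
    for j in np.flatnonzero(keep):
        n2, n1, n0 = _genotype_counts(gm.dosages[:, j])
        if hwe_exact_pvalue(n2, n1, n0) < thresholds.min_hwe_p:
            keep[j] = False
            removed_hwe += 1

    out = gm.subset_markers(keep)
    report = QCReport(
        n_markers_in=n_in,
        removed_non_autosomal=removed_auto,
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
        n_markers_out=out.n_markers,
    )
    return out, report


def impute_sporadic(
    gm: GenotypeMatrix,
    mode: str = "expected_dosage",
    seed: int | None = None,
) -> tuple[GenotypeMatrix, int]:
    """Fill missing dosages from per-marker allele frequencies.

    ``expected_dosage`` fills the continuous value 2p; ``sampled`` draws
    from Binomial(2, p) with the given seed. Non-missing cells are never
    touched. Returns the completed matrix and the number of filled cells.
    """
    if mode not in ("expected_dosage", "sampled"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    d = gm.dosages.copy()
    rng = np.random.default_rng(seed)
    n_filled = 0
    for j in range(d.shape[1]):
        col = d[:, j]
        miss = ~np.isfinite(col)
        if not miss.any():
            continue
        obs = col[~miss]
        if obs.size == 0:
            raise ValueError(f"marker {gm.markers.at[j, 'id']} is entirely missing")
        p = obs.mean() / 2.0
        if mode == "expected_dosage":
            col[miss] = 2.0 * p
        else:
            col[miss] = rng.binomial(2, p, size=int(miss.sum())).astype(float)
        n_filled += int(miss.sum())
    out = GenotypeMatrix(d, list(gm.individual_ids), gm.markers.copy())
    return out, n_filled
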