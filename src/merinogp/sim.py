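"""Synthetic genotype/phenotype generator for pipeline testing.

Emulates a fine-wool sheep genotyping study: biallelic autosomal SNPs with
a configurable allele-frequency spectrum and first-order-Markov local LD, a
low-density panel nested inside the high-density one (every k-th marker,
the way a 50K array's sites sit inside a 630K array), sporadic missing
calls, herd and sex fixed effects, and an additive architecture matched to
each prior family at a configurable heritability. Residual variance is
calibrated to the REALIZED genetic variance so the target heritability is
exact per dataset, which keeps recovery tests sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from merinogp import gio
from merinogp.containers import GenotypeMatrix

ARCHITECTURES = ("normal", "t", "point_t", "point_normal", "laplace")

#: degrees of freedom of the t-family effect draws (heavy-tailed, finite
#: fourth moment)
T_DF = 5.0


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the structure of an 821-animal, 7-herd fine-wool
    breeding population (two sexes, balanced herds) with a desk-scale
    marker panel; heritabilities of real wool traits span roughly
    0.29-0.70, so ``h2_target`` defaults to the middle of that range.
    ``herd_sd`` and ``sex_effect`` are in phenotypic-SD units.
    """

    n_individuals: int = 821
    n_markers_high: int = 5000
    n_markers_low: int = 500
    freq_beta_a: float = 1.0
    freq_beta_b: float = 1.0
    ld_rho: float = 0.85
    missing_rate: float = 0.01
    architecture: str = "normal"
    prop_qtl: float = 0.05
    h2_target: float = 0.5
    n_herds: int = 7
    herd_sd: float = 0.3
    sex_effect: float = 0.2
    mu: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.n_markers_high < 1:
            raise ValueError("need at least 1 marker")
        if self.n_markers_low > self.n_markers_high:
            raise ValueError("low panel cannot exceed the high panel")
        if not 0.0 < self.h2_target < 1.0:
            raise ValueError("h2_target must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must lie in [0, 1)")
        if not 0.0 < self.prop_qtl <= 1.0:
            raise ValueError("prop_qtl must lie in (0, 1]")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; choose from {ARCHITECTURES}"
            )


@dataclass
class TruthRecord:
    """Ground truth kept aside for recovery tests."""

    true_effects: np.ndarray
    true_bv: np.ndarray
    realized_h2: float
    sigma2_e: float = field(default=float("nan"))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Dosage matrix with Beta-spectrum frequencies and Markov LD.

    Two haplotypes per individual are built marker by marker: allele j is
    Bernoulli with a mean shifted by the previous allele so that adjacent
    alleles (hence adjacent genotypes) correlate at about ``ld_rho``.
    Frequencies are drawn from Beta(a, b) truncated to [0.01, 0.99];
    missing calls are scattered uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_markers_high

    freqs = _freq_series(rng, config.freq_beta_a, config.freq_beta_b, m, config.ld_rho)

    n_hap = 2 * n
    hap = np.empty((n_hap, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < freqs[0]
    rho = config.ld_rho
    for j in range(1, m):
        p_prev, p_j = freqs[j - 1], freqs[j]
        slope = rho * np.sqrt(p_j * (1 - p_j) / (p_prev * (1 - p_prev)))
        cond = p_j + slope * (hap[:, j - 1] - p_prev)
        cond = np.clip(cond, 0.0, 1.0)
        hap[:, j] = rng.random(n_hap) < cond

    dosages = (hap[0::2, :] + hap[1::2, :]).astype(float)

    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosages[mask] = np.nan

    chrom = (np.arange(m) % 26 + 1).astype(str)
    pos = np.arange(m) // 26 * 1000 + 1
    alleles = np.array(["A", "C", "G", "T"])
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    markers = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "a1": alleles[a_idx],
            "a2": alleles[b_idx],
            "low_panel": low_panel_mask(m, config.n_markers_low),
        }
    )
    ids = [f"ind{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, ids, markers)


def _freq_series(
    rng: np.random.Generator, a: float, b: float, size: int, rho: float,
    lo: float = 0.01, hi: float = 0.99,
) -> np.ndarray:
    """Allele frequencies with exact truncated-Beta(a, b) marginals.

    A Gaussian AR(1) copula (lag correlation ``rho``) makes adjacent
    frequencies locally similar, as on real arrays, where markers in strong
    LD necessarily share similar frequencies; for two Bernoulli alleles a
    correlation of rho is only attainable when the frequencies are close.
    With rho = 0 the frequencies are i.i.d. truncated Beta.
    """
    from scipy import stats

    z = np.empty(size)
    z[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - rho * rho)
    shocks = rng.standard_normal(size)
    for j in range(1, size):
        z[j] = rho * z[j - 1] + innov_sd * shocks[j]
    u = stats.norm.cdf(z)
    beta = stats.beta(a, b)
    f_lo, f_hi = beta.cdf(lo), beta.cdf(hi)
    return beta.ppf(f_lo + u * (f_hi - f_lo))


def low_panel_mask(n_markers_high: int, n_markers_low: int) -> np.ndarray:
    """Nested low-density panel: every k-th marker of the high panel."""
    mask = np.zeros(n_markers_high, dtype=bool)
    if n_markers_low > 0:
        idx = np.linspace(0, n_markers_high - 1, n_markers_low).round().astype(int)
        mask[np.unique(idx)] = True
    return mask


def simulate_effects(
    n_markers: int,
    architecture: str,
    prop_qtl: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """Per-marker additive effects drawn i.i.d. from the named family.

    Point-mass families place exactly round(prop_qtl * n_markers) nonzero
    effects at uniformly chosen markers; the continuous families give every
    marker an effect.
    """
    if architecture not in ARCHITECTURES:
        raise ValueError(f"unknown architecture {architecture!r}")
    rng = np.random.default_rng(seed)
    if architecture == "normal":
        return rng.standard_normal(n_markers)
    if architecture == "t":
        return rng.standard_t(T_DF, size=n_markers)
    if architecture == "laplace":
        return rng.laplace(0.0, 1.0, size=n_markers)
    n_qtl = max(1, round(prop_qtl * n_markers))
    effects = np.zeros(n_markers)
    qtl = rng.choice(n_markers, size=n_qtl, replace=False)
    if architecture == "point_t":
        effects[qtl] = rng.standard_t(T_DF, size=n_qtl)
    else:  # point_normal
        effects[qtl] = rng.standard_normal(n_qtl)
    return effects


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    config: SimConfig,
    trait_name: str = "trait1",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes y = mu + herd + sex + BV + e at the exact target h2.

    Breeding values are the centered dosages times the effects (missing
    dosages count as the mean dosage, i.e. contribute zero); the residual
    variance is then set from the realized Var(BV) so that
    Var(BV)/(Var(BV)+sigma2_e) equals ``h2_target`` exactly. Herd
    assignments are balanced and herd effects are normal draws; sex is
    Bernoulli(0.5) with an additive male offset.
    """
    effects = np.asarray(effects, dtype=float)
    if effects.size != genotypes.n_markers:
        raise ValueError("effect vector length does not match marker count")
    rng = np.random.default_rng(config.seed + 1)
    n = genotypes.n_individuals

    d = genotypes.dosages
    col_mean = np.nanmean(d, axis=0)
    w = np.where(np.isfinite(d), d, col_mean) - col_mean
    bv = w @ effects

    var_bv = float(np.var(bv))
    if var_bv > 0:
        sigma2_e = var_bv * (1.0 - config.h2_target) / config.h2_target
        realized_h2 = var_bv / (var_bv + sigma2_e)
    else:
        sigma2_e = 1.0
        realized_h2 = 0.0
    vp = var_bv + sigma2_e
    sd_p = np.sqrt(vp)

    herd_idx = rng.permutation(np.arange(n) % config.n_herds)
    herd_effects = rng.normal(0.0, config.herd_sd * sd_p, size=config.n_herds)
    sex = rng.random(n) < 0.5  # True = male
    resid = rng.normal(0.0, np.sqrt(sigma2_e), size=n)

    y = config.mu + herd_effects[herd_idx] + config.sex_effect * sd_p * sex + bv + resid

    phenos = pd.DataFrame(
        {
            "id": genotypes.individual_ids,
            "herd": pd.Categorical([f"herd{h + 1}" for h in herd_idx]),
            "sex": pd.Categorical(np.where(sex, "M", "F")),
            trait_name: y,
        }
    )
    truth = TruthRecord(effects.copy(), bv, realized_h2, sigma2_e)
    return phenos, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Genotypes, phenotypes and ground truth in one call."""
    gm = simulate_genotypes(config)
    effects = simulate_effects(
        gm.n_markers, config.architecture, config.prop_qtl, seed=config.seed + 2
    )
    phenos, truth = simulate_phenotypes(gm, effects, config)
    return gm, phenos, truth


def make_dataset(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete dataset: PED/MAP, low-panel list, phenotypes, truth.

    Files round-trip through the readers in :mod:`merinogp.gio` (pass the
    marker table's counted alleles to ``read_plink_text`` for bit-exact
    dosage recovery).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, phenos, truth = simulate_dataset(config)

    paths = {
        "ped": out / "genotypes.ped",
        "map": out / "genotypes.map",
        "low_panel": out / "low_panel_markers.txt",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.tsv",
    }
    gio.write_plink_text(gm, paths["ped"], paths["map"])
    low_ids = gm.markers.loc[gm.markers["low_panel"], "id"].tolist()
    gio.write_marker_list(low_ids, paths["low_panel"])
    gio.write_phenotypes(phenos, paths["phenotypes"])
    pd.DataFrame({"id": gm.individual_ids, "true_bv": truth.true_bv}).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths
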