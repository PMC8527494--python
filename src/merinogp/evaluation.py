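"""Cross-validated prediction accuracy.

k-fold cross-validation with replicates: each replicate draws a fresh
random partition into near-equal folds; one fold at a time becomes the
candidate population, its phenotypes are masked and ride inside the Gibbs
sampler as missing data, and accuracy is the Pearson correlation between
the candidates' genomic estimated breeding values and their phenotypes
corrected for the training-estimated fixed effects (y* = y - X b_hat).
The final accuracy of a model is the mean over all fold-replicate values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from merinogp.containers import GenotypeMatrix
from merinogp.grm import center_dosages, vanraden_grm
from merinogp.models import FixedDesign, McmcSettings, PriorSpec, build_design, fit, gebv

logger = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    k: int
    assignment: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == j) for j in range(self.k)]


def kfold_assign(ids: list[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Uniformly random split into k folds with sizes differing by <= 1."""
    ids = [str(i) for i in ids]
    n = len(ids)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    assignment: dict[str, int] = {}
    start = 0
    for fold in range(k):
        size = base + (1 if fold < extra else 0)
        for idx in perm[start:start + size]:
            assignment[ids[idx]] = fold
        start += size
    return FoldAssignment(k, assignment, seed)


def corrected_phenotype(
    y: np.ndarray, X: np.ndarray | FixedDesign, b_hat: np.ndarray
) -> np.ndarray:
    """y* = y - X b_hat, with b_hat from the training fit."""
    xmat = X.matrix if isinstance(X, FixedDesign) else np.asarray(X, float)
    return np.asarray(y, float) - xmat @ np.asarray(b_hat, float)


def accuracy(gebv_vals: np.ndarray, y_star: np.ndarray) -> float:
    """Pearson correlation between GEBV and corrected phenotype."""
    g = np.asarray(gebv_vals, float)
    ys = np.asarray(y_star, float)
    if g.size != ys.size or g.size < 3:
        raise ValueError("need vectors of equal length >= 3")
    if np.std(g) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance: accuracy undefined")
    return float(stats.pearsonr(g, ys).statistic)


@dataclass
class CVResult:
    """Per fold-replicate accuracies plus per-model summaries."""

    table: pd.DataFrame  # columns: replicate, fold, model, accuracy, n_val
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        grp = self.table.groupby("model")["accuracy"]
        out = grp.agg(["mean", "sem", "count"]).reset_index()
        return out.rename(columns={"sem": "se", "count": "n_values"})

    def mean_accuracy(self, model: str) -> float:
        vals = self.table.loc[self.table["model"] == model, "accuracy"]
        return float(vals.mean())


def cross_validate(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    trait: str,
    model_specs: dict[str, PriorSpec],
    k: int = 5,
    n_replicates: int = 3,
    seed: int = 0,
    mcmc: McmcSettings | None = None,
    correct_full_data: bool = False,
) -> CVResult:
    """k-fold cross-validation of one or more models on one trait.

    ``genotypes`` must be complete (imputed); ``phenotypes`` carries id,
    herd, sex and the trait column, row-aligned with the genotypes by id.
    Replicate r uses fold seed ``seed + r``; model fits use
    ``mcmc.seed + replicate`` so paired comparisons across datasets can
    share seeds. ``correct_full_data`` switches y* to fixed effects
    estimated once on all data (a mild leakage, offered for comparison);
    the default corrects with training-fold estimates only.
    """
    mcmc = mcmc or McmcSettings()
    if not genotypes.is_complete():
        raise ValueError("genotypes must be imputed before cross-validation")
    phen = phenotypes.set_index("id").loc[genotypes.individual_ids].reset_index()
    y_all = phen[trait].to_numpy(dtype=float)
    observed = np.isfinite(y_all)
    if observed.sum() < k:
        raise ValueError("fewer phenotyped individuals than folds")

    ids = list(genotypes.individual_ids)
    levels = {
        "herd": sorted(set(phen["herd"].astype(str))),
        "sex": sorted(set(phen["sex"].astype(str))),
    }
    need_grm = any(s.family == "gblup" for s in model_specs.values())
    grm_full = vanraden_grm(genotypes) if need_grm else None

    rows = []
    for rep in range(n_replicates):
        folds = kfold_assign(ids, k=k, seed=seed + rep)
        fold_of = np.array([folds.assignment[i] for i in ids])
        for fold in range(k):
            val = (fold_of == fold) & observed
            train = (fold_of != fold) & observed
            if val.sum() < 3:
                logger.warning("replicate %d fold %d has <3 candidates; skipped", rep, fold)
                continue
            train_levels = {
                "herd": sorted(set(phen.loc[train, "herd"].astype(str))),
                "sex": sorted(set(phen.loc[train, "sex"].astype(str))),
            }
            if train_levels != levels:
                logger.warning(
                    "replicate %d fold %d: validation factor levels unseen in "
                    "training mapped to reference", rep, fold,
                )
            design = build_design(phen, levels=train_levels, unseen="reference")
            y_masked = y_all.copy()
            y_masked[~train] = np.nan  # candidates + unphenotyped ride as missing

            train_freqs = genotypes.dosages[train].mean(axis=0) / 2.0
            w = None
            fit_mcmc = McmcSettings(
                n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                seed=mcmc.seed + 1000 * rep + fold, n_chains=mcmc.n_chains,
            )
            for name, spec in model_specs.items():
                if spec.family == "gblup":
                    res = fit(y_masked, design, G=grm_full, prior=spec, mcmc=fit_mcmc)
                else:
                    if w is None:
                        w = center_dosages(genotypes.dosages, train_freqs)
                    res = fit(y_masked, design, W=w, prior=spec, mcmc=fit_mcmc)
                g_val = gebv(res, individuals=np.flatnonzero(val))
                if correct_full_data:
                    b_ref = _full_data_bhat(y_all, observed, design)
                else:
                    b_ref = res.b_mean
                y_star = corrected_phenotype(
                    y_all[val], design.matrix[val], b_ref
                )
                rows.append(
                    {
                        "replicate": rep,
                        "fold": fold,
                        "model": name,
                        "accuracy": accuracy(g_val, y_star),
                        "n_val": int(val.sum()),
                    }
                )
    table = pd.DataFrame(rows)
    return CVResult(table, meta={"k": k, "n_replicates": n_replicates, "seed": seed,
                                 "trait": trait})


def _full_data_bhat(y: np.ndarray, observed: np.ndarray, design: FixedDesign) -> np.ndarray:
    x = design.matrix[observed]
    coef, *_ = np.linalg.lstsq(x, y[observed], rcond=None)
    return coef
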