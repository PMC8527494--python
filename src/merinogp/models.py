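"""Whole-genome regression models fitted by Gibbs sampling.

Five prior families on marker effects, the "Bayesian alphabet" plus the
equivalent mixed model:

* ``bayesA`` — scaled-t: per-marker variances with scaled-inv-chi2 priors;
* ``bayesB`` — point mass at zero with probability pi, scaled-t otherwise;
* ``bayesCpi`` — point mass plus a common normal variance, pi estimated;
* ``blasso`` — double-exponential via the Park-Casella exponential
  scale mixture (alpha_j | tau2_j ~ N(0, tau2_j), tau2_j ~ Exp(lambda2/2),
  lambda2 given a Gamma hyperprior and sampled);
* ``gblup`` — individual breeding values u ~ N(0, G sigma2_a) with the
  VanRaden G, sampled in the eigenbasis of G;
* ``ridge`` — the marker-space twin of GBLUP (common normal variance on
  effects), kept mainly for the exact GBLUP-ridge equivalence check.

The linear model is y = Xb + W alpha + e (marker families) or
y = Xb + u + e (gblup), with herd/sex dummy fixed effects, flat priors on
b, and scaled-inv-chi2 priors on all variances. Prior scales default to an
assumed-R2 heuristic: the prior mode of the genetic variance is
R2 * Var(y), spread over markers through sum of column variances of W.
Individuals with missing y (selection candidates) stay in the sampler and
have their phenotypes drawn from the model each iteration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from merinogp import _kernels
from merinogp.containers import GRM

logger = logging.getLogger(__name__)

FAMILIES = ("bayesA", "bayesB", "bayesCpi", "blasso", "gblup", "ridge")
_FAMILY_CODE = {
    "ridge": _kernels.RIDGE,
    "bayesA": _kernels.BAYES_A,
    "bayesB": _kernels.BAYES_B,
    "bayesCpi": _kernels.BAYES_CPI,
    "blasso": _kernels.BLASSO,
}


@dataclass
class PriorSpec:
    """Prior family and hyperparameters for one model fit.

    ``scale`` and ``lasso_rate`` are resolved automatically from the data
    via the ``r2`` heuristic when left None. ``pi`` is the prior
    probability that a marker effect is exactly zero (bayesB/bayesCpi);
    bayesB keeps it fixed by default, bayesCpi estimates it under a
    Beta(1,1) prior.
    """

    family: str
    df_marker: float = 5.0
    scale: Optional[float] = None
    pi: Optional[float] = None
    estimate_pi: Optional[bool] = None
    estimate_scale: Optional[bool] = None
    scale_shape: float = 1.1
    lasso_shape: float = 1.1
    lasso_rate: Optional[float] = None
    r2: float = 0.5
    df_residual: float = 5.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if not self.df_marker > 2:
            raise ValueError("df_marker must exceed 2 (finite prior variance)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 heuristic must lie in (0, 1)")
        if self.pi is None:
            self.pi = 0.95 if self.family in ("bayesB", "bayesCpi") else 0.0
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.estimate_pi is None:
            self.estimate_pi = self.family == "bayesCpi"
        if self.estimate_scale is None:
            # per-marker variance families: a fixed scale acts as a hard
            # floor on the genetic variance when m >> n, so learn it
            self.estimate_scale = self.family in ("bayesA", "bayesB")


@dataclass
class McmcSettings:
    n_iter: int = 15000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return len(range(self.burn_in, self.n_iter, self.thin))


@dataclass
class FixedDesign:
    """Full-rank fixed-effect design (intercept + reference-coded dummies)."""

    matrix: np.ndarray
    coefficient_names: list[str]
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.matrix.shape[1] != len(self.coefficient_names):
            raise ValueError("coefficient name count mismatch")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")


def build_design(
    phenos: pd.DataFrame,
    factors: tuple[str, ...] = ("herd", "sex"),
    levels: dict[str, list[str]] | None = None,
    unseen: str = "error",
) -> FixedDesign:
    """Intercept plus reference-level dummy columns for the given factors.

    ``levels`` fixes the level order (first = reference); labels absent
    from it either raise (``unseen='error'``) or fall back to the
    reference level (``unseen='reference'``, logged) — the latter is what
    cross-validation uses when a validation fold carries a level the
    training fold never saw. Single-level factors collapse into the
    intercept (logged, not an error).
    """
    n = len(phenos)
    cols = [np.ones(n)]
    names = ["intercept"]
    for fac in factors:
        vals = phenos[fac].astype(str).to_numpy()
        lev = [str(x) for x in (levels or {}).get(fac, sorted(set(vals)))]
        known = set(lev)
        missing = [v for v in vals if v not in known]
        if missing:
            if unseen == "error":
                raise ValueError(f"unknown {fac} label {missing[0]!r}")
            logger.warning(
                "%d %s labels unseen in training mapped to reference level %r",
                len(missing), fac, lev[0],
            )
            vals = np.array([v if v in known else lev[0] for v in vals])
        if len(lev) < 2:
            logger.info("factor %r has a single level; collapsed into intercept", fac)
            continue
        for level in lev[1:]:
            col = (vals == level).astype(float)
            if col.sum() == 0 and missing == []:
                # level fixed by `levels` but absent here; keep column only
                # if it adds information
                continue
            cols.append(col)
            names.append(f"{fac}[{level}]")
    x = np.column_stack(cols)
    # drop collinear columns (e.g., confounded factor levels), keep intercept
    keep = _independent_columns(x)
    dropped = [names[k] for k in range(x.shape[1]) if k not in keep]
    if dropped:
        logger.info("dropped collinear design columns: %s", dropped)
    x = x[:, keep]
    names = [names[k] for k in keep]
    ids = phenos["id"].astype(str).tolist() if "id" in phenos.columns else []
    return FixedDesign(x, names, ids)


def _independent_columns(x: np.ndarray) -> list[int]:
    keep: list[int] = []
    for k in range(x.shape[1]):
        trial = x[:, keep + [k]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(k)
    return keep


@dataclass
class FitResult:
    """Posterior draws and summaries from one model fit.

    ``draws`` holds 1-D series per stored iteration: always ``sigma2_a``
    (for marker models, the variance of the genetic values W alpha at that
    draw) and ``sigma2_e``; plus ``pi`` (bayesB/Cpi) and ``lambda2``
    (blasso). ``gebv_mean`` is the posterior-mean genetic value of every
    individual carried in the fit, candidates included.
    """

    family: str
    draws: dict[str, np.ndarray]
    b_mean: Optional[np.ndarray] = None
    b_draws: Optional[np.ndarray] = None
    alpha_mean: Optional[np.ndarray] = None
    alpha_draws: Optional[np.ndarray] = None
    u_mean: Optional[np.ndarray] = None
    u_draws: Optional[np.ndarray] = None
    gebv_mean: Optional[np.ndarray] = None
    coefficient_names: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, arr in self.draws.items():
            if arr.size:
                rows.append((name, float(np.mean(arr)), float(np.std(arr, ddof=1))))
        if self.b_draws is not None:
            for k, cname in enumerate(self.coefficient_names):
                col = self.b_draws[:, k]
                rows.append((f"b:{cname}", float(col.mean()), float(col.std(ddof=1))))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd"])


def _resolve_hyperparams(
    y_obs: np.ndarray, prior: PriorSpec, msx: float
) -> dict[str, float]:
    """Prior scales from the assumed-R2 heuristic.

    Scaled-inv-chi2(nu, S) has mode nu*S/(nu+2); S is set so the mode of
    each variance matches its heuristic target: (1-R2)Var(y) for the
    residual, R2*Var(y) for the additive variance (spread over markers via
    msx = sum of column variances of W for marker models).
    """
    vy = float(np.var(y_obs, ddof=1))
    if vy <= 0:
        raise ValueError("observed phenotypes have zero variance")
    r2 = prior.r2
    nu, nu_e = prior.df_marker, prior.df_residual
    s_e = (1.0 - r2) * vy * (nu_e + 2.0) / nu_e
    out = {"vy": vy, "s_e": s_e, "nu": nu, "nu_e": nu_e}
    if prior.family == "gblup":
        out["s_a"] = prior.scale if prior.scale is not None else r2 * vy * (nu + 2.0) / nu
        return out
    if msx <= 0:
        raise ValueError("marker matrix has zero total variance")
    target = r2 * vy / msx
    if prior.family in ("bayesB", "bayesCpi"):
        target = target / max(1.0 - prior.pi, 1e-3)
    out["s_alpha"] = prior.scale if prior.scale is not None else target * (nu + 2.0) / nu
    # Gamma hyperprior on the scale (mode at the heuristic value)
    out["s_shape"] = prior.scale_shape
    out["s_rate"] = (prior.scale_shape - 1.0) / out["s_alpha"]
    # double-exponential: Var(alpha) = 2/lambda2; match the per-marker target
    lam2_hat = 2.0 * msx / (r2 * vy)
    out["lam2_0"] = lam2_hat
    out["lam_shape"] = prior.lasso_shape
    out["lam_rate"] = (
        prior.lasso_rate
        if prior.lasso_rate is not None
        else (prior.lasso_shape - 1.0) / lam2_hat
    )
    return out


def fit(
    y: np.ndarray,
    X: FixedDesign | np.ndarray,
    W: np.ndarray | None = None,
    G: GRM | np.ndarray | None = None,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    save_effects: bool = False,
    debug: bool = False,
) -> FitResult:
    """Fit one whole-genome regression model.

    Parameters
    ----------
    y
        phenotypes, NaN for candidate individuals (kept in the sampler,
        redrawn from the model each iteration).
    X
        fixed-effect design (full rank).
    W
        column-centered dosage matrix, required for marker families.
    G
        genomic relationship matrix, required for ``gblup``.
    """
    prior = prior or PriorSpec("gblup" if G is not None and W is None else "bayesA")
    mcmc = mcmc or McmcSettings()
    design = X if isinstance(X, FixedDesign) else FixedDesign(np.asarray(X, float), [f"x{k}" for k in range(np.asarray(X).shape[1])])
    xt = np.ascontiguousarray(design.matrix.T)
    y = np.asarray(y, dtype=float).copy()
    miss = ~np.isfinite(y)
    if miss.all():
        # prior-reproduction mode: anchor the heuristic on a unit variance
        y_obs = np.array([0.0, 1.0])
    else:
        y_obs = y[~miss]
    y[miss] = 0.0

    if prior.family == "gblup":
        if G is None:
            raise ValueError("gblup requires a genomic relationship matrix")
        gmat = G.matrix if isinstance(G, GRM) else np.asarray(G, float)
        if gmat.shape[0] != y.size:
            raise ValueError("G dimension does not match y")
        hp = _resolve_hyperparams(y_obs, prior, msx=1.0)
        evals, evecs = np.linalg.eigh((gmat + gmat.T) / 2.0)
        tol = 1e-8 * max(evals.max(), 1.0)
        n_neg = int((evals < -tol).sum())
        if n_neg:
            logger.info("clamped %d negative GRM eigenvalues below tolerance", n_neg)
        evals = np.where(evals > tol, evals, 0.0)
        (b_draws, s2a, s2e, u_mean, u_draws, dev) = _kernels.gblup_gibbs(
            y, miss, xt, np.ascontiguousarray(evecs), evals,
            hp["nu"], hp["s_a"], hp["nu_e"], hp["s_e"],
            mcmc.n_iter, mcmc.burn_in, mcmc.thin, _check_seed(mcmc.seed),
            save_effects, debug,
        )
        if debug and dev > 1e-8:
            raise RuntimeError(f"residual-update drift {dev:.3g} exceeds 1e-8")
        draws = {"sigma2_a": s2a, "sigma2_e": s2e}
        ids = G.individual_ids if isinstance(G, GRM) else []
        return FitResult(
            family="gblup", draws=draws,
            b_mean=b_draws.mean(axis=0), b_draws=b_draws,
            u_mean=u_mean, u_draws=u_draws if save_effects else None,
            gebv_mean=u_mean,
            coefficient_names=design.coefficient_names,
            individual_ids=list(ids), meta={"hyperparams": hp, "mcmc": mcmc},
        )

    if W is None:
        raise ValueError(f"family {prior.family!r} requires a marker matrix W")
    W = np.asarray(W, dtype=float)
    if W.shape[0] != y.size:
        raise ValueError("W row count does not match y")
    wt = np.ascontiguousarray(W.T)
    msx = float(np.mean(W**2, axis=0).sum()) if W.shape[1] else 1.0
    hp = _resolve_hyperparams(y_obs, prior, msx)
    code = _FAMILY_CODE[prior.family]
    (
        b_draws, s2a, s2e, pi_draws, lam2_draws, alpha_mean, g_mean, alpha_draws, dev,
    ) = _kernels.marker_gibbs(
        y, miss, xt, wt, code,
        hp["nu"], hp.get("s_alpha", 1.0),
        prior.estimate_scale, hp.get("s_shape", 1.1), hp.get("s_rate", 0.1),
        prior.pi, prior.estimate_pi,
        hp.get("lam2_0", 1.0), hp.get("lam_shape", 1.1), hp.get("lam_rate", 0.1),
        hp["nu_e"], hp["s_e"],
        mcmc.n_iter, mcmc.burn_in, mcmc.thin, _check_seed(mcmc.seed),
        save_effects, debug,
    )
    if debug and dev > 1e-8:
        raise RuntimeError(f"residual-update drift {dev:.3g} exceeds 1e-8")
    draws = {"sigma2_a": s2a, "sigma2_e": s2e}
    if prior.family in ("bayesB", "bayesCpi"):
        draws["pi"] = pi_draws
    if prior.family == "blasso":
        draws["lambda2"] = lam2_draws
    return FitResult(
        family=prior.family, draws=draws,
        b_mean=b_draws.mean(axis=0), b_draws=b_draws,
        alpha_mean=alpha_mean,
        alpha_draws=alpha_draws if save_effects else None,
        gebv_mean=g_mean,
        coefficient_names=design.coefficient_names,
        individual_ids=list(design.individual_ids),
        meta={"hyperparams": hp, "mcmc": mcmc},
    )


def _check_seed(seed: int) -> int:
    seed = int(seed)
    if not 0 <= seed < 2**32:
        raise ValueError("seed must fit in an unsigned 32-bit integer")
    return seed


def gebv(
    fit_result: FitResult,
    W_new: np.ndarray | None = None,
    individuals: list[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Genomic estimated breeding values.

    Marker models: posterior-mean effects times ``W_new`` (which must be
    centered with the TRAINING allele frequencies); without ``W_new`` the
    fitted genetic values of the individuals in the fit are returned.
    GBLUP: posterior mean of the sampled u, optionally subset by row index.
    """
    if fit_result.family == "gblup":
        if W_new is not None:
            raise ValueError("gblup predicts only individuals present in G")
        vals = fit_result.u_mean
    else:
        if W_new is not None:
            W_new = np.asarray(W_new, dtype=float)
            if W_new.shape[1] != fit_result.alpha_mean.size:
                raise ValueError("marker count mismatch between W_new and fit")
            vals = W_new @ fit_result.alpha_mean
        else:
            vals = fit_result.gebv_mean
    if individuals is not None:
        vals = np.asarray(vals)[np.asarray(individuals)]
    return np.asarray(vals)


def heritability(fit_result: FitResult) -> tuple[float, float]:
    """Posterior mean and SD of h2 = sigma2_a / (sigma2_a + sigma2_e).

    The ratio is formed draw by draw, then summarized; for marker models
    sigma2_a at each draw is the realized variance of the genetic values.
    """
    try:
        s2a = np.asarray(fit_result.draws["sigma2_a"], float)
        s2e = np.asarray(fit_result.draws["sigma2_e"], float)
    except KeyError as err:
        raise ValueError("fit lacks variance draws") from err
    if s2a.size == 0 or s2a.size != s2e.size:
        raise ValueError("variance draw series empty or mismatched")
    denom = s2a + s2e
    if np.any(denom <= 0):
        raise ValueError("non-positive total variance draw")
    h2 = s2a / denom
    sd = float(np.std(h2, ddof=1)) if h2.size > 1 else 0.0
    return float(np.mean(h2)), sd
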