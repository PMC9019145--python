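"""Generalized linear mixed models by Laplace-approximated maximum
likelihood.

Used for the behavior responses: a logit-link binomial model for boldness
(did the fish emerge from the refuge within 600 s) and a Poisson-lognormal
model for activity (seconds spent moving in the 5-min window), the latter
being a Poisson GLMM with an observation-level normal random effect that
supplies lognormal overdispersion. Both carry random intercepts for source
population and holding tank.

Estimation: for candidate variance parameters the joint penalized
log-likelihood over (fixed effects, random effects) is maximized by Newton
iterations; the marginal log-likelihood is then approximated by the Laplace
method (second-order expansion around the joint mode, with the fixed
effects profiled out). The variance parameters are optimized on the log
scale by a derivative-free outer search with multiple starts. This is the
same approximation lme4's ``glmer`` uses at ``nAGQ=1``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special
from sklearn.base import BaseEstimator

_FAMILIES = ("binomial", "poisson")
_SIGMA_FLOOR = 1e-4  # variance components below this sd are treated as zero


def _loglik_terms(family: str, y: np.ndarray, eta: np.ndarray):
    """Pointwise loglik, mean and IRLS weight for a canonical-link family."""
    if family == "binomial":
        mu = special.expit(eta)
        ll = y * eta - np.logaddexp(0.0, eta)
        w = mu * (1.0 - mu)
    else:  # poisson
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        ll = y * eta - mu - special.gammaln(y + 1.0)
        w = mu
    return float(ll.sum()), mu, w


class MixedGLMM(BaseEstimator):
    """GLMM with independent random intercepts, fitted by Laplace ML.

    Parameters
    ----------
    family : {"binomial", "poisson"}
        Canonical-link response family (logit / log).
    olre : bool
        Add an observation-level random effect (Poisson-lognormal
        overdispersion term).
    n_starts : int
        Independent starting points for the outer variance search.
    beta_ridge : float
        Optional L2 penalty on fixed effects; used as the fallback under
        complete separation.

    Attributes (after ``fit``)
    --------------------------
    params_ : pd.Series           fixed-effect estimates
    bse_ : pd.Series              profile standard errors
    sigmas_ : dict[str, float]    random-effect standard deviations
    loglik_ : float               Laplace marginal log-likelihood
    k_ : int                      parameter count (fixed + active variances)
    separation_ : bool            complete-separation diagnostic (binomial)
    """

    def __init__(
        self,
        family: str = "binomial",
        olre: bool = False,
        n_starts: int = 3,
        max_inner: int = 100,
        max_iter: int = 500,
        tol: float = 1e-8,
        beta_ridge: float = 0.0,
    ):
        self.family = family
        self.olre = olre
        self.n_starts = n_starts
        self.max_inner = max_inner
        self.max_iter = max_iter
        self.tol = tol
        self.beta_ridge = beta_ridge

    # -- core numerics -------------------------------------------------------

    def _inner_mode(self, X, Z, y, dinv, beta, u):
        """Newton maximization of the joint penalized loglik over (beta, u).

        ``dinv`` is the per-random-effect prior precision vector. Returns
        the mode, the penalized loglik at the mode, and the IRLS weights.
        """
        n, p = X.shape
        q = Z.shape[1]
        A = np.hstack([X, Z])
        theta = np.concatenate([beta, u])
        pen = np.concatenate([np.full(p, self.beta_ridge), dinv])

        def objective(th):
            ll, _, _ = _loglik_terms(self.family, y, A @ th)
            return ll - 0.5 * float(pen @ (th * th))

        f = objective(theta)
        for _ in range(self.max_inner):
            eta = A @ theta
            _, mu, w = _loglik_terms(self.family, y, eta)
            grad = A.T @ (y - mu) - pen * theta
            H = (A.T * w) @ A
            H[np.diag_indices_from(H)] += pen + 1e-12
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # backtracking line search on the penalized loglik
            t = 1.0
            for _ in range(30):
                f_new = objective(theta + t * step)
                if f_new >= f - 1e-12:
                    break
                t /= 2.0
            theta = theta + t * step
            if abs(f_new - f) < self.tol * (1.0 + abs(f)):
                f = f_new
                break
            f = f_new
        eta = A @ theta
        _, _, w = _loglik_terms(self.family, y, eta)
        return theta[:p], theta[p:], f, w

    def _laplace(self, X, Z, y, sigmas, block_of, beta0=None, u0=None):
        """Laplace marginal loglik for given block sds; returns state too."""
        p = X.shape[1]
        q = Z.shape[1]
        var = np.maximum(sigmas[block_of], _SIGMA_FLOOR**2) ** 2
        active = sigmas[block_of] > _SIGMA_FLOOR
        dinv = np.where(active, 1.0 / np.maximum(var, 1e-300), 1e8)
        beta = np.zeros(p) if beta0 is None else beta0
        u = np.zeros(q) if u0 is None else u0
        beta, u, fpen, w = self._inner_mode(X, Z, y, dinv, beta, u)
        # log det (I + D^{1/2} Z' W Z D^{1/2}) over the random-effect block
        d_half = 1.0 / np.sqrt(dinv)
        M = (Z.T * w) @ Z
        M = M * d_half[:, None] * d_half[None, :]
        M[np.diag_indices_from(M)] += 1.0
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return -np.inf, beta, u, w
        ll = fpen - 0.5 * logdet
        return ll, beta, u, w

    # -- public API ----------------------------------------------------------

    def fit(self, X, y, groups: pd.DataFrame | dict | None = None):
        """Fit the model.

        ``X`` is the fixed-effect design (DataFrame or array, including the
        intercept column); ``y`` the response (0/1 for binomial, counts for
        poisson); ``groups`` a mapping of grouping-factor name → label array
        (one random intercept per factor). An observation-level effect is
        appended automatically when ``olre=True``.
        """
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}")
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            Xm = X.to_numpy(dtype=float)
        else:
            Xm = np.asarray(X, dtype=float)
            names = [f"x{j}" for j in range(Xm.shape[1])]
        yv = np.asarray(y, dtype=float)
        n = yv.size
        if self.family == "binomial" and not np.all(np.isin(yv, [0.0, 1.0])):
            raise ValueError("binomial response must be 0/1")
        if self.family == "poisson" and (np.any(yv < 0) or np.any(yv != np.round(yv))):
            raise ValueError("poisson response must be non-negative integers")

        blocks: list[tuple[str, np.ndarray]] = []
        if groups is not None:
            items = groups.items() if isinstance(groups, dict) else groups.to_dict("series").items()
            for name, labels in items:
                codes, _ = pd.factorize(np.asarray(labels))
                if codes.max() < 1:
                    warnings.warn(
                        f"grouping factor '{name}' has a single level; dropped"
                    )
                    continue
                Zk = np.zeros((n, codes.max() + 1))
                Zk[np.arange(n), codes] = 1.0
                blocks.append((name, Zk))
        if self.olre:
            blocks.append(("olre", np.eye(n)))
        if not blocks:
            blocks = [("_none", np.zeros((n, 1)))]
        Z = np.hstack([b[1] for b in blocks])
        block_of = np.concatenate(
            [np.full(b[1].shape[1], i) for i, b in enumerate(blocks)]
        )
        self.block_names_ = [b[0] for b in blocks]
        K = len(blocks)

        warm: dict[str, np.ndarray | None] = {"beta": None, "u": None}

        def negloglik(log_s):
            s = np.exp(np.clip(log_s, -12.0, 3.0))
            ll, beta, u, _ = self._laplace(
                Xm, Z, yv, s, block_of, beta0=warm["beta"], u0=warm["u"]
            )
            if np.isfinite(ll):
                warm["beta"], warm["u"] = beta, u
            return -ll

        starts = [np.full(K, np.log(0.5)), np.full(K, np.log(0.1)), np.full(K, 0.0)]
        rng = np.random.default_rng(0)
        while len(starts) < self.n_starts:
            starts.append(rng.normal(-1.0, 0.7, size=K))
        best = None
        for s0 in starts[: max(1, self.n_starts)]:
            res = optimize.minimize(
                negloglik,
                s0,
                method="Nelder-Mead",
                options={"maxiter": self.max_iter, "xatol": 1e-5, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        s_hat = np.exp(np.clip(best.x, -12.0, 3.0))
        ll, beta, u, w = self._laplace(Xm, Z, yv, s_hat, block_of)

        # profile covariance of beta: (X'WX - X'WZ (Z'WZ + D^-1)^-1 Z'WX)^-1
        var = np.maximum(s_hat[block_of], _SIGMA_FLOOR**2) ** 2
        dinv = np.where(s_hat[block_of] > _SIGMA_FLOOR, 1.0 / var, 1e8)
        XtWX = (Xm.T * w) @ Xm
        XtWZ = (Xm.T * w) @ Z
        ZtWZ = (Z.T * w) @ Z
        ZtWZ[np.diag_indices_from(ZtWZ)] += dinv
        try:
            inner = np.linalg.solve(ZtWZ, XtWZ.T)
            cov = np.linalg.inv(XtWX - XtWZ @ inner)
            bse = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            bse = np.full(len(beta), np.nan)

        self.params_ = pd.Series(beta, index=names)
        self.bse_ = pd.Series(bse, index=names)
        self.sigmas_ = {
            name: (float(s) if s > _SIGMA_FLOOR else 0.0)
            for name, s in zip(self.block_names_, s_hat)
            if name != "_none"
        }
        self.loglik_ = float(ll)
        self.n_ = int(n)
        self.k_ = len(beta) + sum(1 for s in self.sigmas_.values())
        self.converged_ = bool(best.success or best.fun < np.inf)
        self.separation_ = bool(
            self.family == "binomial" and np.max(np.abs(Xm @ beta)) > 15.0
        )
        if self.separation_ and self.beta_ridge == 0.0:
            warnings.warn(
                "complete separation detected; refitting with a small ridge "
                "penalty on fixed effects"
            )
            fallback = MixedGLMM(**{**self.get_params(), "beta_ridge": 1e-2})
            fallback.fit(X, y, groups)
            self.params_ = fallback.params_
            self.bse_ = fallback.bse_
            self.sigmas_ = fallback.sigmas_
            self.separation_ = True
        return self

    def fit_formula(
        self, data: pd.DataFrame, formula: str, groups: list[str]
    ) -> "MixedGLMM":
        """Patsy-formula front end; ``groups`` names the random-intercept
        columns in ``data``."""
        ym, Xm = patsy.dmatrices(formula, data, return_type="dataframe")
        return self.fit(Xm, ym.to_numpy().ravel(), data[groups])


# --------------------------------------------------------------------------
# behavior-model front ends


def fit_boldness_binomial(
    data: pd.DataFrame,
    rhs: str = "log10_mass + history + C(acclimation_temp_c)",
    population: str = "population",
    tank: str = "tank",
    **kwargs,
) -> MixedGLMM:
    """Mixed-effects binomial logistic model of refuge emergence.

    Response: ``emerged`` (1 = left the refuge within the 600-s limit).
    Fixed effects default to log10 mass, thermal history and acclimation
    temperature; random intercepts for population and tank.
    """
    df = data.copy()
    if "log10_mass" not in df:
        df["log10_mass"] = np.log10(df["mass_mg"])
    df["emerged"] = df["emerged"].astype(int)
    model = MixedGLMM(family="binomial", **kwargs)
    return model.fit_formula(df, f"emerged ~ {rhs}", [population, tank])


def fit_activity_pln(
    data: pd.DataFrame,
    rhs: str = "log10_mass + history + C(acclimation_temp_c)",
    population: str = "population",
    tank: str = "tank",
    activity_limit_s: float = 300.0,
    **kwargs,
) -> MixedGLMM:
    """Poisson-lognormal GLMM of activity (integer seconds moving, 0–300).

    Only fish that emerged are modelled (non-emergers have no activity
    trial). The observation-level random effect is the lognormal
    overdispersion term.
    """
    df = data.copy()
    if "emerged" in df:
        df = df[df["emerged"].astype(bool)]
    df = df.dropna(subset=["activity_s"])
    if (df["activity_s"] > activity_limit_s).any():
        raise ValueError(
            f"activity exceeds the {activity_limit_s:.0f}-s observation window"
        )
    if "log10_mass" not in df:
        df["log10_mass"] = np.log10(df["mass_mg"])
    df["activity_count"] = df["activity_s"].round().astype(int)
    model = MixedGLMM(family="poisson", olre=True, **kwargs)
    return model.fit_formula(df, f"activity_count ~ {rhs}", [population, tank])
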