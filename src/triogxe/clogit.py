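"""Conditional logistic regression on 1:3 matched case/pseudo-control sets.

The model for a case-parent trio design with additive genotype coding is

    logit P(case) = beta_g * G + sum_i beta_{g x e_i} * G * E_i

where G in {0, 1, 2} counts minor alleles and E_i are binary maternal
exposures.  Because exposures are constant within a matched set, exposure
main effects are not estimable and only genotype and genotype-by-exposure
terms enter the design.  Conditioning on the set gives the likelihood
contribution

    l_s(beta) = eta_case - log sum_{j=0..3} exp(eta_j)

over the four Mendelian transmissions of the set; sets whose four genotypes
coincide are uninformative and are excluded from both the fitted and the
null likelihood.  The null (empty) model assigns probability 1/4 to every
member, so llnull = n_informative * log(1/4).

Fitting is Newton-Raphson with step-halving from beta = 0; the conditional
log-likelihood is concave, so the iteration increases it monotonically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2, norm

LOG_QUARTER = float(np.log(0.25))

#: |beta| beyond which the likelihood is treated as monotone (separation).
SEPARATION_BOUND = 15.0


class InestimableError(ValueError):
    """A design column carries no within-set contrast (or is collinear)."""


class NoInformationError(ValueError):
    """No informative matched set to fit on."""


def design_row(genotype: int, exposures: dict[str, int],
               exposure_names: tuple[str, ...]) -> np.ndarray:
    """Covariate vector [G, G*E_1, ..., G*E_k] for one set member."""
    g = float(genotype)
    return np.array([g] + [g * exposures[name] for name in exposure_names])


def _design_cube(G: np.ndarray, E: np.ndarray | None,
                 exposure_names: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    k = len(exposure_names)
    X = np.empty((n, 4, 1 + k))
    X[:, :, 0] = G
    names = ["G"]
    if k:
        E = np.asarray(E, dtype=float)
        for j, name in enumerate(exposure_names):
            X[:, :, 1 + j] = G * E[:, [j]]
            names.append(f"G:{name}")
    return X, names


class TrioConditionalLogit:
    """Conditional logit model over 1:3 matched sets.

    Parameters
    ----------
    genotypes : (n, 4) int array
        Member dosages per set; column 0 is the observed case.
    exposures : (n, k) binary array, optional
        One exposure vector per set (shared by its four members).
    exposure_names : tuple of str
        Interaction terms to include, in order.
    design, names : optional
        A precomputed (n, 4, p) design cube and term names; overrides the
        genotype/exposure construction (used for diagnostic designs).
    """

    def __init__(self, genotypes, exposures=None, exposure_names=(),
                 design=None, names=None):
        G = np.asarray(genotypes)
        if G.ndim != 2 or G.shape[1] != 4:
            raise ValueError("genotypes must be an (n, 4) array")
        if design is not None:
            X = np.asarray(design, dtype=float)
            self.exog_names = list(names)
        else:
            X, self.exog_names = _design_cube(G, exposures, tuple(exposure_names))
        informative = (G != G[:, [0]]).any(axis=1)
        self.n_sets_total = G.shape[0]
        self.X = X[informative]
        self.genotypes = G[informative]
        self.n_sets_informative = int(informative.sum())
        self.k_params = X.shape[2]
        if self.n_sets_informative == 0:
            raise NoInformationError("no information: all matched sets uninformative")
        # a term with zero within-set spread in every informative set cannot
        # be identified against the matching
        spread = self.X.max(axis=1) - self.X.min(axis=1)  # (n, p)
        dead = ~(spread > 0).any(axis=0)
        if dead.any():
            bad = [self.exog_names[j] for j in np.flatnonzero(dead)]
            raise InestimableError(
                f"inestimable term (constant within every set): {', '.join(bad)}")

    # -- likelihood machinery -------------------------------------------------

    def _eta(self, params: np.ndarray) -> np.ndarray:
        return self.X @ params

    def loglike(self, params: np.ndarray) -> float:
        eta = self._eta(params)
        return float((eta[:, 0] - logsumexp(eta, axis=1)).sum())

    def set_probabilities(self, params: np.ndarray) -> np.ndarray:
        """Conditional probability of each member within its set (rows sum to 1)."""
        eta = self._eta(params)
        return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))

    def score(self, params: np.ndarray) -> np.ndarray:
        P = self.set_probabilities(params)
        xbar = np.einsum("nj,njp->np", P, self.X)
        return (self.X[:, 0, :] - xbar).sum(axis=0)

    def information(self, params: np.ndarray) -> np.ndarray:
        P = self.set_probabilities(params)
        xbar = np.einsum("nj,njp->np", P, self.X)
        exx = np.einsum("nj,njp,njq->pq", P, self.X, self.X)
        return exx - xbar.T @ xbar

    @property
    def llnull(self) -> float:
        return self.n_sets_informative * LOG_QUARTER

    # -- fitting --------------------------------------------------------------

    def fit(self, start_params=None, tol: float = 1e-8,
            maxiter: int = 100) -> "TrioConditionalLogitResults":
        """Newton-Raphson with step-halving; converged when max|score| < tol."""
        beta = (np.zeros(self.k_params) if start_params is None
                else np.array(start_params, dtype=float))
        ll = self.loglike(beta)
        converged = False
        separation = False
        for _ in range(maxiter):
            g = self.score(beta)
            if np.max(np.abs(g)) < tol:
                converged = True
                break
            info = self.information(beta)
            try:
                step = np.linalg.solve(info, g)
            except np.linalg.LinAlgError:
                raise InestimableError(
                    "inestimable term: singular information matrix") from None
            scale = 1.0
            for _h in range(40):
                cand = beta + scale * step
                ll_new = self.loglike(cand)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            beta, ll = cand, ll_new
            if np.max(np.abs(beta)) > SEPARATION_BOUND:
                separation = True
                break
        if separation:
            cov = np.full((self.k_params, self.k_params), np.nan)
        else:
            try:
                cov = np.linalg.inv(self.information(beta))
            except np.linalg.LinAlgError:
                raise InestimableError(
                    "inestimable term: singular information matrix") from None
        return TrioConditionalLogitResults(self, beta, cov, ll, converged,
                                           separation)


@dataclass
class TrioConditionalLogitResults:
    """Fitted conditional-logit estimates with Wald/LRT machinery."""

    model: TrioConditionalLogit
    params: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    separation: bool

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def df_model(self) -> int:
        return self.model.k_params

    @property
    def n_sets_informative(self) -> int:
        return self.model.n_sets_informative

    @property
    def llnull(self) -> float:
        return self.model.llnull

    @property
    def bse(self) -> np.ndarray:
        if self.separation:
            return np.full(self.df_model, np.inf)
        return np.sqrt(np.diag(self.cov_params))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])

    def wald_test(self, contrast) -> tuple[float, float, float]:
        """1-df Wald test of c'beta = 0.

        ``contrast`` is a coefficient index or a contrast vector c.
        Returns (z, chi2_stat, p).
        """
        c = np.zeros(self.df_model)
        if np.isscalar(contrast):
            c[int(contrast)] = 1.0
        else:
            c = np.asarray(contrast, dtype=float)
        var = float(c @ self.cov_params @ c)
        if not var > 0:
            raise ValueError("Wald test undefined: zero contrast variance")
        z = float(c @ self.params) / np.sqrt(var)
        return z, z * z, float(chi2.sf(z * z, 1))

    def summary(self) -> str:
        lines = [
            "Trio conditional logistic regression (1 case : 3 pseudo-controls)",
            f"informative sets: {self.n_sets_informative}"
            f" / {self.model.n_sets_total}",
            f"log-likelihood: {self.llf:.4f}   null: {self.llnull:.4f}",
            f"converged: {self.converged}   separation: {self.separation}",
            f"{'term':<12}{'beta':>10}{'se':>10}{'OR':>8}{'p':>12}",
        ]
        se = self.bse
        for j, name in enumerate(self.exog_names):
            p = np.nan
            if np.isfinite(se[j]) and se[j] > 0:
                p = self.wald_test(j)[2]
            lines.append(f"{name:<12}{self.params[j]:>10.4f}{se[j]:>10.4f}"
                         f"{np.exp(self.params[j]):>8.3f}{p:>12.3e}")
        stat, df, p = lrt(self)
        lines.append(f"LRT vs empty model: stat={stat:.4f} df={df} p={p:.3e}")
        return "\n".join(lines)


def lrt(fit_full: TrioConditionalLogitResults,
        fit_null: TrioConditionalLogitResults | None = None
        ) -> tuple[float, int, float]:
    """Likelihood-ratio test of a full fit against a nested null.

    ``fit_null=None`` means the empty model (no terms), whose likelihood is
    n_informative * log(1/4).  Both fits must be over the same matched sets.
    """
    if fit_null is None:
        ll0, df0 = fit_full.llnull, 0
    else:
        if (fit_null.n_sets_informative != fit_full.n_sets_informative
                or abs(fit_null.llnull - fit_full.llnull) > 1e-8):
            raise ValueError("set mismatch: LRT fits use different matched sets")
        if not set(fit_null.exog_names) <= set(fit_full.exog_names):
            raise ValueError("null model is not nested in the full model")
        ll0, df0 = fit_null.llf, fit_null.df_model
    stat = max(0.0, 2.0 * (fit_full.llf - ll0))
    df = fit_full.df_model - df0
    if df == 0:
        # degenerate comparison of a model with itself
        return stat, 0, 1.0 if stat < 1e-10 else 0.0
    return stat, df, float(chi2.sf(stat, df))
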