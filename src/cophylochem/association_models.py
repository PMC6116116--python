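"""Occurrence models and Bayesian variance partitioning of incidence data.

Two complementary analyses of host x herbivore incidence:

* **Occurrence models** — maximum-likelihood binomial regressions of the
  probability that a herbivore species occurs on a host, as a function
  of host traits and ordination axes, compared by AICc.  Effort
  (leaf flushes searched per host) can enter as a covariate.

* **Variance partitioning** — a Bernoulli generalized linear mixed
  model that decomposes variation in incidence into twelve named
  components built from the herbivore phylogeny (S), the host phylogeny
  (H) and host chemical similarity (C): main effects (S x J, J x H,
  J x C), one-sided interactions (I x H, I x C, S x I), the
  coevolutionary (S x H) and defense-tracking (S x C) interactions,
  unstructured main and interaction effects (I x J, J x I, I x I), and
  a geographic-region effect.  J is the all-ones matrix, I the
  identity; each Kronecker product acts on herbivore x host cells.

The mixed model uses a probit link with Albert-Chib latent-variable
Gibbs sampling.  Each variance component carries a parameter-expanded
prior (a standard-normal scaling times an inverse-gamma working
variance, inducing a half-Cauchy prior on the component's standard
deviation), which mixes well when components are near zero.  The
residual (probit) variance is fixed at 1, and reported proportions are
taken over the random terms only, per posterior draw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .io_core import IncidenceTable, Tree
from .phylo_stats import phylo_covariance

__all__ = [
    "OccurrenceModelResult",
    "VarpartSpec",
    "VariancePartitionResult",
    "KronTerm",
    "TermCovariances",
    "TERM_NAMES",
    "fit_occurrence_model",
    "occurrence_frame",
    "aicc",
    "build_term_covariances",
    "run_variance_partition",
    "run_variance_partition_batch",
    "compare_model_variants",
]

# The 12 named variance components, in reporting order.
TERM_NAMES = [
    "region",
    "sawfly_phylo_main",          # S x J: host range explained by sawfly phylogeny
    "host_phylo_main",            # J x H: richness explained by host phylogeny
    "host_defense_main",          # J x C: richness explained by host chemistry
    "host_phylo_interaction",     # I x H: related hosts share sawfly assemblages
    "host_defense_interaction",   # I x C: chemically similar hosts share assemblages
    "sawfly_phylo_interaction",   # S x I: related sawflies share host assemblages
    "coevolution",                # S x H: related sawflies on related hosts
    "defense_tracking",           # S x C: related sawflies on chemically similar hosts
    "sawfly_main",                # I x J
    "host_main",                  # J x I
    "interaction",                # I x I
]


# ---------------------------------------------------------------------------
# Occurrence models
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceModelResult:
    label: str
    predictors: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    odds: np.ndarray
    loglik: float
    k: int
    n: int
    aicc: float
    separation: bool = False

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": ["intercept"] + self.predictors,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "odds": self.odds,
        })


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1); requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def occurrence_frame(incidence: IncidenceTable,
                     trials: int | None = None) -> pd.DataFrame:
    """Per-host successes and trials for the occurrence model.

    ``y`` is the number of distinct herbivore species found on each
    host (zero-richness hosts included); ``n`` is the size of the
    herbivore species pool (the default number of trials for every
    host).
    """
    mat = incidence.binary_matrix()
    y = mat.sum(axis=1)
    n = trials if trials is not None else len(incidence.motus)
    df = pd.DataFrame({"y": y.astype(int), "n": int(n)})
    if incidence.effort is not None:
        df["effort"] = [incidence.effort[h] for h in df.index]
    return df


def _firth_fit(X: np.ndarray, y: np.ndarray, n: np.ndarray,
               max_iter: int = 100, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    """Firth-penalized binomial logistic fit (Jeffreys-prior score)."""
    p_dim = X.shape[1]
    beta = np.zeros(p_dim)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n * mu * (1 - mu)
        XtWX = X.T @ (w[:, None] * X)
        XtWX_inv = np.linalg.inv(XtWX)
        h = np.einsum("ij,jk,ik->i", X, XtWX_inv, X) * w
        score = X.T @ (y - n * mu + h * (0.5 - mu))
        step = XtWX_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (n - y) * np.log(1 - mu)))
    w = n * mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (w[:, None] * X))
    return beta, np.sqrt(np.diag(cov)), ll


def fit_occurrence_model(data: pd.DataFrame, predictors: list[str],
                         label: str | None = None) -> OccurrenceModelResult:
    """ML binomial occurrence model with Wald 95% intervals.

    ``data`` must have columns ``y`` (successes) and ``n`` (trials) and
    one column per predictor; an intercept is always included.  Perfect
    separation triggers a Firth-penalized refit with a warning.
    """
    import statsmodels.api as sm

    missing = [c for c in ["y", "n", *predictors] if c not in data.columns]
    if missing:
        raise ValueError(f"occurrence data missing columns {missing}")
    if (data["n"] <= 0).any():
        raise ValueError("trial counts must be positive")
    y = data["y"].to_numpy(dtype=float)
    n = data["n"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(dtype=float) for c in predictors])
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(np.column_stack([y, n - y]), X,
                       family=sm.families.Binomial())
        try:
            fit = model.fit(maxiter=200)
            beta, se, ll = fit.params, fit.bse, float(fit.llf)
            mu = fit.fittedvalues
            if (np.max(np.abs(beta)) > 15
                    or np.any((mu < 1e-8) | (mu > 1 - 1e-8))
                    or not np.all(np.isfinite(se))):
                separation = True
        except Exception:
            separation = True
    if separation:
        warnings.warn(f"possible separation in model {label!r}; "
                      "refit with Firth penalization", stacklevel=2)
        beta, se, ll = _firth_fit(X, y, n)
    # statsmodels' binomial llf omits the binomial coefficient constant the
    # same way for all models; recompute without it for AICc consistency
    mu = np.clip(1.0 / (1.0 + np.exp(-(X @ beta))), 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(mu) + (n - y) * np.log(1 - mu)))
    k = X.shape[1]
    z = 1.959963984540054
    return OccurrenceModelResult(
        label=label or "+".join(predictors) if predictors else "intercept",
        predictors=list(predictors),
        beta=np.asarray(beta), se=np.asarray(se),
        ci_low=np.asarray(beta) - z * np.asarray(se),
        ci_high=np.asarray(beta) + z * np.asarray(se),
        odds=np.exp(np.asarray(beta)),
        loglik=ll, k=k, n=len(data), aicc=aicc(ll, k, len(data)),
        separation=separation)


# ---------------------------------------------------------------------------
# Term covariances
# ---------------------------------------------------------------------------

def _cov2cor(C: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(C))
    if np.any(d <= 0):
        raise ValueError("covariance has non-positive diagonal")
    R = C / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


def nearest_psd_correlation(S: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to zero and rescale to unit diagonal."""
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    if vals.min() >= -tol:
        clipped = S
    else:
        clipped = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(clipped), 1e-12, None))
    R = clipped / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return 0.5 * (R + R.T)


@dataclass
class KronTerm:
    """A variance component's covariance, factored over sawflies x hosts."""

    name: str
    factor_s: np.ndarray  # n_s x n_s, PSD
    factor_h: np.ndarray  # n_h x n_h, PSD

    def full(self) -> np.ndarray:
        return np.kron(self.factor_s, self.factor_h)


@dataclass
class TermCovariances:
    sawfly_taxa: list[str]
    host_taxa: list[str]
    regions: list[str]
    terms: dict[str, KronTerm]

    @property
    def n_s(self) -> int:
        return len(self.sawfly_taxa)

    @property
    def n_h(self) -> int:
        return len(self.host_taxa)


def _check_psd(name: str, M: np.ndarray, tol: float = 1e-8) -> None:
    mineig = float(np.linalg.eigvalsh(0.5 * (M + M.T)).min())
    if mineig < -tol:
        raise ValueError(f"factor for term {name!r} is not PSD "
                         f"(min eigenvalue {mineig:.3e})")


def build_term_covariances(sawfly_tree: Tree, host_tree: Tree,
                           chem_similarity: np.ndarray | pd.DataFrame,
                           regions: list[str],
                           host_taxa: list[str] | None = None,
                           sawfly_taxa: list[str] | None = None
                           ) -> TermCovariances:
    """The 12 named covariance structures over sawfly x host cells.

    Phylogenies enter as tip correlation matrices (Brownian covariance
    scaled to unit diagonal); chemical similarity is projected to the
    nearest PSD matrix with unit diagonal.
    """
    s_taxa, Cs = phylo_covariance(sawfly_tree, taxa=sawfly_taxa)
    h_taxa, Ch = phylo_covariance(host_tree, taxa=host_taxa)
    S_cor = _cov2cor(Cs)
    H_cor = _cov2cor(Ch)
    if isinstance(chem_similarity, pd.DataFrame):
        chem = chem_similarity.reindex(index=h_taxa, columns=h_taxa)
        if chem.isna().any().any():
            raise ValueError("chemical similarity missing some host taxa")
        chem = chem.to_numpy(dtype=float)
    else:
        chem = np.asarray(chem_similarity, dtype=float)
        if chem.shape != (len(h_taxa), len(h_taxa)):
            raise ValueError("chemical similarity shape does not match hosts")
    C_cor = nearest_psd_correlation(chem)
    n_s, n_h = len(s_taxa), len(h_taxa)
    I_s, I_h = np.eye(n_s), np.eye(n_h)
    J_s, J_h = np.ones((n_s, n_s)), np.ones((n_h, n_h))
    spec = {
        "sawfly_phylo_main": (S_cor, J_h),
        "host_phylo_main": (J_s, H_cor),
        "host_defense_main": (J_s, C_cor),
        "host_phylo_interaction": (I_s, H_cor),
        "host_defense_interaction": (I_s, C_cor),
        "sawfly_phylo_interaction": (S_cor, I_h),
        "coevolution": (S_cor, H_cor),
        "defense_tracking": (S_cor, C_cor),
        "sawfly_main": (I_s, J_h),
        "host_main": (J_s, I_h),
        "interaction": (I_s, I_h),
    }
    terms = {"region": KronTerm("region", np.eye(len(regions)), np.eye(1))}
    for name, (Ms, Mh) in spec.items():
        _check_psd(name, Ms)
        _check_psd(name, Mh)
        terms[name] = KronTerm(name, Ms, Mh)
    return TermCovariances(list(s_taxa), list(h_taxa), list(regions), terms)


# ---------------------------------------------------------------------------
# Variance partitioning (probit PX-Gibbs)
# ---------------------------------------------------------------------------

@dataclass
class VarpartSpec:
    terms: list[str] = field(default_factory=lambda: list(TERM_NAMES))
    include_region: bool = True
    control_effort: bool = True
    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 45
    prior_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        unknown = set(self.terms) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown variance terms {sorted(unknown)}")

    def active_terms(self) -> list[str]:
        terms = [t for t in self.terms if t != "region" or self.include_region]
        return terms


@dataclass
class VariancePartitionResult:
    terms: list[str]
    proportion_mean: dict[str, float]
    proportion_ci: dict[str, tuple[float, float]]
    sigma2_samples: dict[str, np.ndarray]   # draws per term (n_draws,)
    ess: dict[str, float]
    seed: int | None
    spec: VarpartSpec
    warnings_: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.terms,
            "proportion": [self.proportion_mean[t] for t in self.terms],
            "ci_low": [self.proportion_ci[t][0] for t in self.terms],
            "ci_high": [self.proportion_ci[t][1] for t in self.terms],
            "ess": [self.ess[t] for t in self.terms],
        })


def _eig_factor(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    return vecs, np.clip(vals, 0.0, None)


def _sample_truncnorm(eta: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """z ~ N(eta, 1) truncated to z > 0 where y = 1, z <= 0 where y = 0."""
    u = rng.random(eta.shape)
    lo = np.where(y == 1, ndtr(-eta), 0.0)
    hi = np.where(y == 1, 1.0, ndtr(-eta))
    q = np.clip(lo + u * (hi - lo), 1e-15, 1 - 1e-15)
    return eta + ndtri(q)


class _PXGibbs:
    """Batched probit PX-Gibbs sampler over replicate incidence arrays.

    ``y`` has shape (chains, regions, sawflies, hosts); all chains
    share the covariance structure but carry independent data and
    states.  Kronecker eigendecompositions make every conditional
    precision diagonal, so an iteration costs a handful of small
    matrix products per term.
    """

    def __init__(self, y: np.ndarray, cov: TermCovariances, spec: VarpartSpec,
                 effort: np.ndarray | None = None, seed: int | None = None):
        self.y = np.asarray(y)
        if self.y.ndim != 4:
            raise ValueError("y must have shape (chains, regions, sawflies, hosts)")
        if self.y.min() == self.y.max():
            raise ValueError("response is constant (all 0 or all 1)")
        self.C, self.R, self.S, self.H = self.y.shape
        self.spec = spec
        self.rng = np.random.default_rng(seed)
        self.terms = [t for t in spec.active_terms() if t in cov.terms]
        self.kron = {}
        for t in self.terms:
            if t == "region":
                continue
            term = cov.terms[t]
            Qs, ls = _eig_factor(term.factor_s)
            Qh, lh = _eig_factor(term.factor_h)
            lam = np.outer(ls, lh)
            self.kron[t] = (Qs, Qh, lam, np.sqrt(lam))
        # fixed effects: intercept (+ standardized log effort per host)
        cols = [np.ones((self.R, self.S, self.H))]
        if spec.control_effort and effort is not None:
            e = np.log(np.asarray(effort, dtype=float))
            e = (e - e.mean()) / (e.std() if e.std() > 0 else 1.0)
            cols.append(np.broadcast_to(e[None, None, :], (self.R, self.S, self.H)).copy())
        self.Xcols = np.stack([c.reshape(-1) for c in cols], axis=1)  # (n_obs, p)
        self.p = self.Xcols.shape[1]
        self.XtX = self.Xcols.T @ self.Xcols
        self.prior_prec_beta = np.eye(self.p) / 100.0

    def run(self) -> dict[str, np.ndarray]:
        C, R, S, H = self.C, self.R, self.S, self.H
        rng = self.rng
        spec = self.spec
        s2_prior = spec.prior_scale ** 2
        # state
        beta = np.zeros((C, self.p))
        v = {t: np.zeros((C, S, H)) for t in self.terms if t != "region"}
        W = {t: np.zeros((C, S, H)) for t in self.terms if t != "region"}
        alpha = {t: np.full(C, 1e-3) for t in self.terms}
        psi = {t: np.ones(C) for t in self.terms}
        v_reg = np.zeros((C, R))
        has_region = "region" in self.terms
        eta = np.zeros((C, R, S, H))
        eta += (self.Xcols @ beta.T).T.reshape(C, R, S, H)
        z = np.zeros_like(eta)
        keep = [it for it in range(spec.n_iter)
                if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0]
        n_keep = len(keep)
        out = {t: np.empty((C, n_keep)) for t in self.terms}
        kidx = 0
        chol_beta = np.linalg.cholesky(
            np.linalg.inv(self.XtX + self.prior_prec_beta))
        post_prec_beta_inv = np.linalg.inv(self.XtX + self.prior_prec_beta)
        for it in range(spec.n_iter):
            # latent response
            z = _sample_truncnorm(eta, self.y, rng)
            resid = z - eta
            # fixed effects
            Xb_old = (self.Xcols @ beta.T).T.reshape(C, R, S, H)
            target = (resid + Xb_old).reshape(C, -1)
            mean_beta = target @ self.Xcols @ post_prec_beta_inv.T
            beta = mean_beta + rng.standard_normal((C, self.p)) @ chol_beta.T
            Xb_new = (self.Xcols @ beta.T).T.reshape(C, R, S, H)
            eta += Xb_new - Xb_old
            resid = z - eta
            # region effect
            if has_region:
                a = alpha["region"]
                part = resid + a[:, None, None, None] * v_reg[:, :, None, None]
                tsum = part.sum(axis=(2, 3))  # (C, R)
                prec = (S * H) * a[:, None] ** 2 + 1.0 / psi["region"][:, None]
                v_new = (a[:, None] * tsum) / prec \
                    + rng.standard_normal((C, R)) / np.sqrt(prec)
                eta += a[:, None, None, None] * (v_new - v_reg)[:, :, None, None]
                v_reg = v_new
                resid = z - eta
                # scaling parameter
                w = v_reg[:, :, None, None]
                prec_a = (S * H) * (v_reg ** 2).sum(axis=1) + 1.0 / s2_prior
                num = (resid + a[:, None, None, None] * w) * w
                mean_a = num.sum(axis=(1, 2, 3)) / prec_a
                a_new = mean_a + rng.standard_normal(C) / np.sqrt(prec_a)
                eta += (a_new - a)[:, None, None, None] * w
                alpha["region"] = a_new
                resid = z - eta
                ssq = (v_reg ** 2).sum(axis=1)
                psi["region"] = 1.0 / rng.gamma(0.5 + R / 2.0,
                                                1.0 / (0.5 + ssq / 2.0))
            # Kronecker terms
            for t in self.terms:
                if t == "region":
                    continue
                Qs, Qh, lam, sqlam = self.kron[t]
                a = alpha[t]
                part_sum = resid.sum(axis=1) + self.R * a[:, None, None] * W[t]
                proj = Qs.T @ part_sum @ Qh          # (C, S, H)
                b = a[:, None, None] * sqlam * proj
                prec = self.R * (a[:, None, None] ** 2) * lam \
                    + 1.0 / psi[t][:, None, None]
                v_new = b / prec + rng.standard_normal((C, S, H)) / np.sqrt(prec)
                W_new = Qs @ (sqlam * v_new) @ Qh.T
                eta += (a[:, None, None] * (W_new - W[t]))[:, None]
                v[t], W[t] = v_new, W_new
                resid = z - eta
                # scaling parameter
                wsq = (W[t] ** 2).sum(axis=(1, 2))
                prec_a = self.R * wsq + 1.0 / s2_prior
                num = (resid.sum(axis=1) + self.R * a[:, None, None] * W[t]) * W[t]
                mean_a = num.sum(axis=(1, 2)) / prec_a
                a_new = mean_a + rng.standard_normal(C) / np.sqrt(prec_a)
                eta += ((a_new - a)[:, None, None] * W[t])[:, None]
                alpha[t] = a_new
                resid = z - eta
                ssq = (v[t] ** 2).sum(axis=(1, 2))
                psi[t] = 1.0 / rng.gamma(0.5 + (S * H) / 2.0,
                                         1.0 / (0.5 + ssq / 2.0))
            if kidx < n_keep and it == keep[kidx]:
                for t in self.terms:
                    out[t][:, kidx] = alpha[t] ** 2 * psi[t]
                kidx += 1
        return out


def _incidence_array(incidence: IncidenceTable, cov: TermCovariances,
                     include_region: bool) -> np.ndarray:
    """(regions, sawflies, hosts) binary array aligned to the covariances."""
    if include_region:
        mats = []
        for r in cov.regions:
            m = incidence.binary_matrix(region=r)
            mats.append(m.loc[cov.host_taxa, cov.sawfly_taxa].to_numpy().T)
        return np.stack(mats)
    m = incidence.binary_matrix()
    return m.loc[cov.host_taxa, cov.sawfly_taxa].to_numpy().T[None]


def run_variance_partition(incidence: IncidenceTable | np.ndarray,
                           cov: TermCovariances, spec: VarpartSpec,
                           seed: int | None = None,
                           effort: np.ndarray | None = None
                           ) -> VariancePartitionResult:
    """Posterior variance proportions for the named components.

    ``incidence`` is an :class:`IncidenceTable` or a pre-aligned binary
    array of shape (regions, sawflies, hosts).  Proportions are
    computed per posterior draw over the included random terms (they
    sum to 1 by construction) and summarized by the mean and the 2.5
    and 97.5 percent quantiles.
    """
    if isinstance(incidence, IncidenceTable):
        y = _incidence_array(incidence, cov, spec.include_region)
        if effort is None and incidence.effort is not None:
            effort = np.array([incidence.effort[h] for h in cov.host_taxa],
                              dtype=float)
    else:
        y = np.asarray(incidence)
        if y.ndim == 2:
            y = y[None]
    samples = _PXGibbs(y[None], cov, spec, effort=effort, seed=seed).run()
    return _summarize(samples, spec, seed, chain=0)


def run_variance_partition_batch(y_batch: np.ndarray, cov: TermCovariances,
                                 spec: VarpartSpec, seed: int | None = None,
                                 effort: np.ndarray | None = None
                                 ) -> list[VariancePartitionResult]:
    """Run independent chains over a batch of replicate incidence arrays.

    ``y_batch`` has shape (replicates, regions, sawflies, hosts); one
    result per replicate.  Used by the simulation studies, where many
    replicate datasets share one covariance structure.
    """
    samples = _PXGibbs(y_batch, cov, spec, effort=effort, seed=seed).run()
    return [_summarize(samples, spec, seed, chain=c)
            for c in range(y_batch.shape[0])]


def _summarize(samples: dict[str, np.ndarray], spec: VarpartSpec,
               seed: int | None, chain: int) -> VariancePartitionResult:
    import arviz as az

    terms = list(samples)
    sig2 = np.stack([samples[t][chain] for t in terms])   # (terms, draws)
    props = sig2 / sig2.sum(axis=0, keepdims=True)
    mean = {t: float(props[i].mean()) for i, t in enumerate(terms)}
    ci = {t: (float(np.quantile(props[i], 0.025)),
              float(np.quantile(props[i], 0.975)))
          for i, t in enumerate(terms)}
    ess = {}
    warns = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, t in enumerate(terms):
            e = float(az.ess(sig2[i]))
            ess[t] = e
            if e < 10:
                warns.append(f"severe non-mixing: ESS {e:.1f} for term {t!r}")
            elif e < 100:
                warns.append(f"low effective sample size ({e:.0f}) for term {t!r}")
    return VariancePartitionResult(
        terms=terms, proportion_mean=mean, proportion_ci=ci,
        sigma2_samples={t: samples[t][chain].copy() for t in terms},
        ess=ess, seed=seed, spec=spec, warnings_=warns)


def compare_model_variants(incidence: IncidenceTable, cov: TermCovariances,
                           base_spec: VarpartSpec | None = None,
                           seed: int | None = None
                           ) -> dict[tuple[bool, bool], VariancePartitionResult]:
    """The 2 x 2 grid of model variants: with/without the region term,
    controlling or not for sampling effort.

    The unstructured interaction term is dropped from the
    without-region variants, where it is confounded with the residual.
    Keys are (include_region, control_effort).
    """
    base = base_spec or VarpartSpec()
    results = {}
    for include_region in (True, False):
        for control_effort in (True, False):
            terms = [t for t in base.terms]
            if not include_region:
                terms = [t for t in terms if t not in ("region", "interaction")]
            spec = VarpartSpec(
                terms=terms, include_region=include_region,
                control_effort=control_effort, n_iter=base.n_iter,
                burn_in=base.burn_in, thin=base.thin,
                prior_scale=base.prior_scale)
            results[(include_region, control_effort)] = run_variance_partition(
                incidence, cov, spec, seed=seed)
    return results
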