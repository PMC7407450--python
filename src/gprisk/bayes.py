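"""Bayesian whole-genome probit regression via Gibbs sampling.

Five members of the Bayesian alphabet are implemented, differing only in the
prior placed on the marker effects alpha_j:

* ``BRR``      — Gaussian with a common variance (ridge-type shrinkage);
* ``BL``       — Laplace via the exponential scale mixture (Bayesian LASSO);
* ``BayesA``   — scaled-t via per-marker inverse-chi-square variances;
* ``BayesB``   — spike at zero + scaled-t slab, mixture proportion pi sampled;
* ``BayesCpi`` — spike at zero + common-variance Gaussian slab, pi sampled.

The binary phenotype enters through probit data augmentation: a latent
liability l_i ~ Normal(eta_i, 1) truncated above (cases) or below (controls)
the threshold, with eta_i = mu + X b + sum_j m_ij alpha_j.  The residual
variance is fixed at 1 and the threshold at 0 (neither is likelihood
identified; the free intercept absorbs the threshold).  The intercept and
covariate effects carry flat priors; pi carries a Beta(P0*pi0, P0*(1-pi0))
prior where pi is the prior probability that a marker has *no* effect.

Scale hyperparameters follow the usual default rules: df = 5 for every
scaled-t / inverse-chi-square component, with the scale solved from an
R2 = 0.5 heuristic against the total marker variance, so that a priori the
markers explain about half of the unit latent variance.

Dosages are centered (not scaled) before fitting; prediction applies the
training-column means.  A fixed seed yields identical chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

MODELS = ("BRR", "BL", "BayesA", "BayesB", "BayesCpi")
_MIXTURE = ("BayesB", "BayesCpi")


@dataclass
class BayesModelSpec:
    """Prior family plus chain settings.

    ``n_iter``/``burn_in`` default to the long production chain; reduced
    values are appropriate for experimentation and testing.
    ``alpha_var_fixed`` pins the BRR marker variance (no hyperprior update),
    a validation hook that makes the posterior amenable to low-dimensional
    quadrature.
    """

    model: str = "BRR"
    n_iter: int = 52_000
    burn_in: int = 6_000
    thin: int = 5
    pi0: float = 0.5
    P0: float = 10.0
    df_prior: float = 5.0
    R2_rule: float = 0.5
    seed: int = 0
    alpha_var_fixed: float | None = None

    def validate(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if not 0.0 < self.pi0 < 1.0:
            raise ValueError("pi0 must be in (0,1)")
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class PosteriorSummary:
    """Posterior means (and dispersions) of the probit model unknowns."""

    model: str
    mu_mean: float
    mu_sd: float
    b_mean: np.ndarray
    alpha_mean: np.ndarray
    alpha_sd: np.ndarray
    inclusion_prob: np.ndarray   # posterior mean of delta_j (1.0 for non-mixture models)
    pi_mean: float               # posterior mean P(no effect); pi0 for non-mixture models
    snp_center: np.ndarray       # training column means used for centering
    fitted_prob: np.ndarray      # plug-in Phi(eta_hat) on the training samples
    prob_post_mean: np.ndarray   # posterior mean of Phi(eta) over kept draws
    n_kept: int
    mu_trace: np.ndarray = field(repr=False, default=None)

    def predict(self, M: np.ndarray | None, C: np.ndarray | None) -> np.ndarray:
        """Plug-in case probabilities Phi(mu + C b + (M - center) alpha)."""
        n = None
        eta = None
        if M is not None:
            M = np.atleast_2d(np.asarray(M, dtype=float))
            n = M.shape[0]
            if M.shape[1]:
                if M.shape[1] != len(self.alpha_mean):
                    raise ValueError(
                        f"SNP layout mismatch: fit used {len(self.alpha_mean)} "
                        f"SNPs, got {M.shape[1]}"
                    )
                eta = (M - self.snp_center) @ self.alpha_mean
        if C is not None:
            C = np.atleast_2d(np.asarray(C, dtype=float))
            n = C.shape[0]
            if C.shape[1]:
                if C.shape[1] != len(self.b_mean):
                    raise ValueError("covariate layout mismatch")
                ceta = C @ self.b_mean
                eta = ceta if eta is None else eta + ceta
        if n is None:
            raise ValueError("predict needs a SNP or covariate matrix")
        if eta is None:
            eta = np.zeros(n)
        prob = ndtr(self.mu_mean + eta)
        return np.clip(prob, 1e-12, 1.0 - 1e-12)


def _draw_truncated_latent(rng, eta, y):
    """Latent liabilities: N(eta,1) truncated to (0, inf) for cases, (-inf, 0]
    for controls (threshold fixed at 0)."""
    e = np.clip(eta, -6.0, 6.0)  # guards CDF saturation in the tails
    u = rng.random(len(e))
    lo = ndtr(-e)                # P(l <= 0 | eta)
    with np.errstate(divide="ignore"):
        z_case = ndtri(lo + u * (1.0 - lo))
        z_ctrl = ndtri(u * lo)
    z = np.where(y == 1, z_case, z_ctrl)
    return e + np.clip(z, -8.0, 8.0)


def fit_bayes(M: np.ndarray | None, C: np.ndarray | None, y: np.ndarray,
              spec: BayesModelSpec) -> PosteriorSummary:
    """Run the Gibbs sampler for ``spec.model`` and return posterior summaries.

    ``M``: imputed dosages (n x p, may be None/empty for an intercept-only or
    covariate-only fit); ``C``: covariate design (n x q) or None; ``y``: 0/1.
    """
    spec.validate()
    y = np.asarray(y).astype(int)
    n = len(y)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0, 1))):
        raise ValueError("phenotype must be coded 0/1")
    if len(classes) < 2:
        raise ValueError("both classes required to fit the probit model")
    rng = np.random.default_rng(spec.seed)

    has_snps = M is not None and np.size(M) > 0
    if has_snps:
        M = np.asarray(M, dtype=float)
        center = M.mean(axis=0)
        Mc = M - center
        p = Mc.shape[1]
        msq = np.einsum("ij,ij->j", Mc, Mc)
        msq = np.where(msq <= 0, 1e-12, msq)
        sum_var = float(np.sum(msq) / n)
    else:
        center = np.zeros(0)
        Mc = np.zeros((n, 0))
        p = 0
        msq = np.zeros(0)
        sum_var = 1.0

    has_cov = C is not None and np.size(C) > 0
    if has_cov:
        C = np.atleast_2d(np.asarray(C, dtype=float))
        q = C.shape[1]
        CtC = C.T @ C
        CtC_chol = np.linalg.cholesky(CtC + 1e-10 * np.eye(q))
    else:
        q = 0

    # default-rule hyperparameters: markers explain ~R2 of unit latent variance
    df0 = spec.df_prior
    Vy = 1.0
    S0 = Vy * spec.R2_rule * (df0 + 2.0) / max(sum_var, 1e-12)
    model = spec.model
    mixture = model in _MIXTURE
    if mixture:
        S0 = S0 / (1.0 - spec.pi0)

    # state
    mu = 0.0
    b = np.zeros(q)
    alpha = np.zeros(p)
    delta = np.ones(p, dtype=bool)
    pi = spec.pi0
    sigma2 = (spec.alpha_var_fixed if spec.alpha_var_fixed is not None
              else S0)                       # common variance (BRR / BayesCpi slab)
    sigma2_j = np.full(p, S0)                # per-marker variances (BayesA/B, BL tau^2)
    lam2 = 2.0 * (1.0 - spec.R2_rule) / spec.R2_rule * max(sum_var, 1e-12)  # BL

    eta = np.zeros(n)
    latent = _draw_truncated_latent(rng, eta, y)
    e = latent - eta  # running residual l - mu - Cb - Mc alpha

    kept = 0
    mu_acc = mu2_acc = 0.0
    b_acc = np.zeros(q)
    a_acc = np.zeros(p)
    a2_acc = np.zeros(p)
    d_acc = np.zeros(p)
    pi_acc = 0.0
    prob_acc = np.zeros(n)
    mu_trace = []

    for it in range(spec.n_iter):
        # (1) latent liabilities
        eta_cur = latent - e
        latent = _draw_truncated_latent(rng, eta_cur, y)
        e = latent - eta_cur

        # (2) intercept, flat prior
        r_mean = float(np.mean(e)) + mu
        mu_new = rng.normal(r_mean, 1.0 / np.sqrt(n))
        e += mu - mu_new
        mu = mu_new

        # covariate effects, flat prior: b | . ~ N((C'C)^-1 C'r, (C'C)^-1)
        if has_cov:
            r = e + C @ b
            mean_b = np.linalg.solve(CtC_chol.T, np.linalg.solve(CtC_chol, C.T @ r))
            b_new = mean_b + np.linalg.solve(CtC_chol.T, rng.standard_normal(q))
            e = r - C @ b_new
            b = b_new

        # (3) marker effects, single-site updates
        if p:
            if model == "BRR":
                var_slab = np.full(p, sigma2)
                _update_gaussian(rng, Mc, msq, alpha, e, var_slab)
            elif model == "BayesA":
                _update_gaussian(rng, Mc, msq, alpha, e, sigma2_j)
            elif model == "BL":
                _update_gaussian(rng, Mc, msq, alpha, e, sigma2_j)
            elif model == "BayesB":
                _update_spike_slab(rng, Mc, msq, alpha, delta, e, sigma2_j, pi)
            else:  # BayesCpi
                _update_spike_slab(rng, Mc, msq, alpha, delta, e,
                                   np.full(p, sigma2), pi)

        # (4) hyperparameters
        if p:
            if model == "BRR" and spec.alpha_var_fixed is None:
                scale = S0 * df0 + float(np.sum(alpha**2))
                sigma2 = scale / rng.chisquare(df0 + p)
            elif model == "BayesA":
                sigma2_j = (S0 * df0 + alpha**2) / rng.chisquare(df0 + 1, size=p)
            elif model == "BL":
                # 1/tau_j^2 | . ~ InverseGaussian(sqrt(lam2/alpha_j^2), lam2)
                a2 = np.maximum(alpha**2, 1e-12)
                inv_tau2 = rng.wald(np.sqrt(lam2 / a2), lam2)
                sigma2_j = 1.0 / np.maximum(inv_tau2, 1e-12)
                # lam2 | . ~ Gamma(shape0 + p, rate0 + sum(tau^2)/2)
                shape0, rate0 = 1.1, 0.1 / max(sum_var, 1e-12)
                lam2 = rng.gamma(shape0 + p, 1.0 / (rate0 + float(np.sum(sigma2_j)) / 2.0))
            elif model == "BayesB":
                d = delta.astype(float)
                sigma2_j = (S0 * df0 + d * alpha**2) / rng.chisquare(df0 + d)
            elif model == "BayesCpi":
                k_in = int(delta.sum())
                scale = S0 * df0 + float(np.sum(alpha[delta] ** 2))
                sigma2 = scale / rng.chisquare(df0 + k_in)
            if mixture:
                k_in = int(delta.sum())
                pi = rng.beta(spec.P0 * spec.pi0 + (p - k_in),
                              spec.P0 * (1.0 - spec.pi0) + k_in)

        # (5) store
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            kept += 1
            mu_acc += mu
            mu2_acc += mu * mu
            b_acc += b
            a_acc += alpha
            a2_acc += alpha**2
            d_acc += delta
            pi_acc += pi
            prob_acc += ndtr(latent - e)  # Phi(eta) at the current draw
            mu_trace.append(mu)

    if kept == 0:
        raise RuntimeError("no post-burn-in samples kept; lengthen the chain")
    mu_mean = mu_acc / kept
    mu_sd = float(np.sqrt(max(mu2_acc / kept - mu_mean**2, 0.0)))
    a_mean = a_acc / kept
    a_sd = np.sqrt(np.maximum(a2_acc / kept - a_mean**2, 0.0))
    incl = d_acc / kept if mixture else np.ones(p)
    summary = PosteriorSummary(
        model=model, mu_mean=float(mu_mean), mu_sd=mu_sd,
        b_mean=b_acc / kept, alpha_mean=a_mean, alpha_sd=a_sd,
        inclusion_prob=incl, pi_mean=float(pi_acc / kept) if mixture else spec.pi0,
        snp_center=center, fitted_prob=np.zeros(n),
        prob_post_mean=prob_acc / kept, n_kept=kept,
        mu_trace=np.asarray(mu_trace),
    )
    summary.fitted_prob = summary.predict(
        M if has_snps else np.zeros((n, 0)), C if has_cov else None)
    return summary


def _update_gaussian(rng, Mc, msq, alpha, e, var_j):
    """Single-site Gibbs updates for Gaussian-conditional effects (BRR /
    BayesA / BL all reduce to this given the current per-marker variance)."""
    p = len(alpha)
    z = rng.standard_normal(p)
    for j in range(p):
        m = Mc[:, j]
        rhs = m @ e + msq[j] * alpha[j]
        v = 1.0 / (msq[j] + 1.0 / var_j[j])
        new = v * rhs + np.sqrt(v) * z[j]
        diff = new - alpha[j]
        if diff != 0.0:
            e -= diff * m
        alpha[j] = new


def _update_spike_slab(rng, Mc, msq, alpha, delta, e, var_j, pi):
    """Spike-and-slab updates (BayesB / BayesCpi); ``pi`` = P(no effect)."""
    p = len(alpha)
    z = rng.standard_normal(p)
    u = rng.random(p)
    log_prior_odds = np.log1p(-pi) - np.log(pi)  # log P(delta=1)/P(delta=0)
    for j in range(p):
        m = Mc[:, j]
        rhs = m @ e + msq[j] * alpha[j]
        v = 1.0 / (msq[j] + 1.0 / var_j[j])
        log_odds = log_prior_odds + 0.5 * (np.log(v) - np.log(var_j[j])) \
            + 0.5 * rhs * rhs * v
        if np.log(u[j]) - np.log1p(-u[j]) < log_odds:
            new = v * rhs + np.sqrt(v) * z[j]
            delta[j] = True
        else:
            new = 0.0
            delta[j] = False
        diff = new - alpha[j]
        if diff != 0.0:
            e -= diff * m
        alpha[j] = new


class BayesModel:
    """Adapter exposing the ``fit``/``predict`` protocol used by
    :func:`gprisk.evaluate.run_cv`."""

    def __init__(self, spec: BayesModelSpec):
        spec.validate()
        self.spec = spec
        self.name = spec.model

    def fit(self, X_snps, X_cov, y, seed: int = 0) -> "BayesModel._Fitted":
        spec = BayesModelSpec(**{**self.spec.__dict__, "seed": seed})
        return BayesModel._Fitted(fit_bayes(X_snps, X_cov, y, spec))

    class _Fitted:
        def __init__(self, summary: PosteriorSummary):
            self.summary = summary

        def predict(self, X_snps, X_cov) -> np.ndarray:
            return self.summary.predict(X_snps, X_cov)
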