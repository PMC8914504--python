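"""Bayesian hierarchical logistic regression of unfavourable stroke outcome.

Model
-----
For patient i with sex s(i) in {male, female}, standardized pattern
expressions W_i (k = 10) and covariates C_i (standardized age, age squared
from centred age, female indicator, six cardiovascular risk-factor
indicators, standardized lesion volume):

    y_i ~ Bernoulli( logit^-1( alpha + sum_j beta[j, s(i)] W_ij
                               + gamma . C_i ) )

with hierarchical sex-specific pattern coefficients

    mu_j ~ Normal(0, 1),   tau_j ~ HalfNormal(1),
    beta[j, s] = mu_j + tau_j * z[j, s],   z[j, s] ~ Normal(0, 1),

an intercept alpha ~ Normal(0, 2.5) and covariate coefficients
gamma ~ Normal(0, 1).  The unfavourable outcome is mRS > 2 at 3 months.
Posterior sampling uses NUTS (non-centered parameterization, analytic
gradients); effects are judged "substantial" when the 90% highest
posterior density interval excludes zero, and sex differences are
summarized as the men - women posterior difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from ._nuts import sample_nuts
from .synthetic import RISK_FACTORS, SEX_FEMALE, SEX_MALE, VOLUME_COLUMN

logger = logging.getLogger("strokepatterns")

CONTINUOUS_COVARIATES = ("age", "age2", VOLUME_COLUMN)
COVARIATE_ORDER = ("age", "age2", "sex_female", *RISK_FACTORS,
                   VOLUME_COLUMN)


@dataclass
class PriorConfig:
    """Weakly-informative prior scales on standardized inputs."""

    hypermean_sd: float = 1.0      # mu_j ~ Normal(0, .)
    between_sex_sd: float = 1.0    # tau_j ~ HalfNormal(.)
    intercept_sd: float = 2.5      # alpha ~ Normal(0, .)
    covariate_sd: float = 1.0      # gamma ~ Normal(0, .)


@dataclass
class Standardizer:
    """Column-wise z-scoring whose parameters can be reused and inverted."""

    means: dict
    sds: dict

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: Sequence[str]) -> "Standardizer":
        means, sds = {}, {}
        for c in columns:
            x = df[c].to_numpy(dtype=float)
            sd = float(x.std(ddof=0))
            if sd == 0:
                raise ValueError(
                    f"column '{c}' has zero variance and cannot be "
                    "standardized")
            means[c], sds[c] = float(x.mean()), sd
        return cls(means, sds)

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means:
            out[c] = (df[c] - self.means[c]) / self.sds[c]
        return out

    def invert(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means:
            out[c] = df[c] * self.sds[c] + self.means[c]
        return out


@dataclass
class DesignMatrix:
    """Complete-case model inputs with stored standardization parameters."""

    patterns: np.ndarray            # n x k, standardized expressions
    covariates: np.ndarray          # n x c, standardized / indicator columns
    covariate_names: list
    y: np.ndarray                   # binary unfavourable outcome
    sex_female: np.ndarray          # boolean, True = female
    patient_ids: list
    pattern_standardizer: Standardizer
    covariate_standardizer: Standardizer
    n_dropped: int = 0

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def k(self) -> int:
        return self.patterns.shape[1]

    def subset(self, ids: Sequence[str],
               restandardize: bool = True) -> "DesignMatrix":
        """Row subset; by default restandardized on the subsample."""
        pos = [self.patient_ids.index(i) for i in ids]
        if not restandardize:
            return DesignMatrix(
                self.patterns[pos], self.covariates[pos],
                self.covariate_names, self.y[pos], self.sex_female[pos],
                [self.patient_ids[p] for p in pos],
                self.pattern_standardizer, self.covariate_standardizer,
                self.n_dropped)
        pat = pd.DataFrame(self.patterns[pos])
        pat = self.pattern_standardizer_frameless_invert(pat)
        cov = pd.DataFrame(self.covariates[pos],
                           columns=self.covariate_names)
        cov = self.covariate_standardizer.invert(cov)
        pstd = Standardizer.fit(pat, pat.columns)
        cstd = Standardizer.fit(cov, list(self.covariate_standardizer.means))
        return DesignMatrix(
            pstd.apply(pat).to_numpy(), cstd.apply(cov).to_numpy(),
            self.covariate_names, self.y[pos], self.sex_female[pos],
            [self.patient_ids[p] for p in pos], pstd, cstd, self.n_dropped)

    def pattern_standardizer_frameless_invert(self, pat: pd.DataFrame
                                              ) -> pd.DataFrame:
        pat = pat.copy()
        pat.columns = list(self.pattern_standardizer.means)
        return self.pattern_standardizer.invert(pat)


def build_design(cohort: pd.DataFrame, expressions: pd.DataFrame,
                 ) -> DesignMatrix:
    """Assemble the model inputs from a cohort table and pattern expressions.

    The outcome is 1 iff mRS > 2.  Continuous columns (pattern expressions,
    age, age squared computed from centred age, lesion volume) are z-scored
    on the fitting cohort; rows with missing fields are dropped with a
    logged count.
    """
    if not cohort.index.equals(expressions.index):
        expressions = expressions.reindex(cohort.index)
        if expressions.isna().any().any():
            raise ValueError("cohort and expressions are not aligned by "
                             "patient id")
    df = cohort.copy()
    bad_sex = ~df["sex"].isin([SEX_MALE, SEX_FEMALE])
    if bad_sex.any():
        raise ValueError(
            f"sex labels outside binary coding {SEX_MALE}/{SEX_FEMALE}: "
            f"{sorted(df.loc[bad_sex, 'sex'].unique())}")
    if ((df["mrs"] < 0) | (df["mrs"] > 6)).any():
        raise ValueError("mRS values must lie in 0..6")

    needed = ["age", "sex", "mrs", VOLUME_COLUMN, *RISK_FACTORS]
    complete = df[needed].notna().all(axis=1) & expressions.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("build_design: dropped %d incomplete rows", n_dropped)
    df = df.loc[complete]
    expressions = expressions.loc[complete]

    age_c = df["age"] - df["age"].mean()  # centre before squaring
    cov = pd.DataFrame({
        "age": df["age"].astype(float),
        "age2": age_c.astype(float) ** 2,
        "sex_female": (df["sex"] == SEX_FEMALE).astype(float),
        **{rf: df[rf].astype(float) for rf in RISK_FACTORS},
        VOLUME_COLUMN: df[VOLUME_COLUMN].astype(float),
    }, index=df.index)[list(COVARIATE_ORDER)]

    cont = ["age", "age2", VOLUME_COLUMN]
    cstd = Standardizer.fit(cov, cont)
    pstd = Standardizer.fit(expressions, expressions.columns)
    return DesignMatrix(
        patterns=pstd.apply(expressions).to_numpy(dtype=float),
        covariates=cstd.apply(cov).to_numpy(dtype=float),
        covariate_names=list(cov.columns),
        y=(df["mrs"] > 2).astype(int).to_numpy(),
        sex_female=(df["sex"] == SEX_FEMALE).to_numpy(),
        patient_ids=list(df.index),
        pattern_standardizer=pstd,
        covariate_standardizer=cstd,
        n_dropped=n_dropped)


# ----------------------------------------------------------------------
# posterior sampling
# ----------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    """Posterior samples, shaped (chains, draws[, k or c])."""

    alpha: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    beta_male: np.ndarray
    beta_female: np.ndarray
    gamma: np.ndarray
    covariate_names: list
    diagnostics: dict
    seed: int

    @property
    def k(self) -> int:
        return self.mu.shape[-1]

    def flat(self, arr: np.ndarray) -> np.ndarray:
        """Pool chains: (chains, draws, ...) -> (chains*draws, ...)."""
        return arr.reshape(-1, *arr.shape[2:])


def _make_logp_grad(design: DesignMatrix, priors: PriorConfig):
    """Joint log density and gradient (non-centered parameterization).

    Unconstrained layout:
    ``alpha | mu(k) | log_tau(k) | z_male(k) | z_female(k) | gamma(c)``
    with ``beta_sex = mu + tau * z_sex``.  The Bernoulli likelihood is
    evaluated through one stacked design matrix (single GEMV per call) and
    a numerically stable softplus/sigmoid pass.
    """
    k = design.k
    C = design.covariates
    c = C.shape[1]
    female = design.sex_female
    n = design.n
    A = np.ascontiguousarray(np.hstack([
        np.ones((n, 1)),
        design.patterns * (~female)[:, None],
        design.patterns * female[:, None],
        C]))
    y = design.y.astype(float)
    s_a, s_mu, s_tau, s_g = (priors.intercept_sd, priors.hypermean_sd,
                             priors.between_sex_sd, priors.covariate_sd)

    def logp_grad(theta):
        alpha = theta[0]
        mu = theta[1:1 + k]
        log_tau = theta[1 + k:1 + 2 * k]
        zm = theta[1 + 2 * k:1 + 3 * k]
        zf = theta[1 + 3 * k:1 + 4 * k]
        gamma = theta[1 + 4 * k:]
        tau = np.exp(log_tau)
        coef = np.empty(1 + 2 * k + c)
        coef[0] = alpha
        coef[1:1 + k] = mu + tau * zm
        coef[1 + k:1 + 2 * k] = mu + tau * zf
        coef[1 + 2 * k:] = gamma
        eta = A @ coef
        # softplus(eta) = max(eta, 0) + log1p(exp(-|eta|)), overflow-safe
        t = np.exp(-np.abs(eta))
        ll = y @ eta - (np.maximum(eta, 0.0).sum()
                        + np.log1p(t).sum())
        lp = (ll
              - 0.5 * (alpha / s_a) ** 2
              - 0.5 * (mu @ mu) / s_mu ** 2
              - 0.5 * (tau @ tau) / s_tau ** 2 + log_tau.sum()
              - 0.5 * (zm @ zm + zf @ zf)
              - 0.5 * (gamma @ gamma) / s_g ** 2)
        sig = np.where(eta >= 0.0, 1.0 / (1.0 + t), t / (1.0 + t))
        r = y - sig
        gA = r @ A
        gm = gA[1:1 + k]
        gf = gA[1 + k:1 + 2 * k]
        grad = np.empty(theta.size)
        grad[0] = gA[0] - alpha / s_a ** 2
        grad[1:1 + k] = gm + gf - mu / s_mu ** 2
        grad[1 + k:1 + 2 * k] = (tau * (zm * gm + zf * gf)
                                 - tau * tau / s_tau ** 2 + 1.0)
        grad[1 + 2 * k:1 + 3 * k] = tau * gm - zm
        grad[1 + 3 * k:1 + 4 * k] = tau * gf - zf
        grad[1 + 4 * k:] = gA[1 + 2 * k:] - gamma / s_g ** 2
        return lp, grad

    return logp_grad, k, c


def fit_hierarchical_logistic(design: DesignMatrix,
                              draws: int = 5000,
                              chains: int = 4,
                              warmup: int = 1000,
                              seed: int = 0,
                              target_accept: float = 0.9,
                              priors: Optional[PriorConfig] = None,
                              rhat_threshold: float = 1.05,
                              check_diagnostics: bool = True,
                              engine: str = "numba") -> PosteriorDraws:
    """Sample the hierarchical logistic posterior with NUTS.

    ``draws`` post-warm-up samples per chain (default mirrors the study
    setting of 5000); warm-up iterations are excluded.  Raises if both
    outcome classes or both sexes are not present, or if split-R-hat
    exceeds ``rhat_threshold`` for any parameter; a divergence rate above
    5% is logged as a warning and flagged in the diagnostics.
    """
    if priors is None:
        priors = PriorConfig()
    if len(np.unique(design.y)) < 2:
        raise ValueError("outcome has a single class; cannot fit")
    if design.sex_female.all() or (~design.sex_female).all():
        raise ValueError("both sexes must be present")

    logp_grad, k, c = _make_logp_grad(design, priors)
    dim = 1 + 4 * k + c
    ss = np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(chains)
    all_draws = np.empty((chains, draws, dim))
    divergences = 0
    for ch in range(chains):
        rng = np.random.default_rng(chain_seeds[ch])
        theta0 = 0.1 * rng.standard_normal(dim)
        theta0[1 + k:1 + 2 * k] = -1.0  # start tau below its prior scale
        if engine == "numba":
            from . import _nuts_fast as nf
            female = design.sex_female
            A = np.ascontiguousarray(np.hstack([
                np.ones((design.n, 1)),
                design.patterns * (~female)[:, None],
                design.patterns * female[:, None],
                design.covariates]))
            chain_seed = int(chain_seeds[ch].generate_state(1)[0] % (2**31))
            chain, ndiv, _, _ = nf.run_chain(
                A, design.y.astype(float), k, c,
                priors.intercept_sd, priors.hypermean_sd,
                priors.between_sex_sd, priors.covariate_sd,
                theta0, warmup, draws, chain_seed, target_accept, 10,
                nf.warmup_boundaries(warmup))
            all_draws[ch] = chain
            divergences += int(ndiv)
        elif engine == "numpy":
            chain, st = sample_nuts(logp_grad, theta0, warmup, draws, rng,
                                    target_accept=target_accept)
            all_draws[ch] = chain
            divergences += st["divergences"]
        else:
            raise ValueError(f"unknown engine '{engine}'")

    alpha = all_draws[:, :, 0]
    mu = all_draws[:, :, 1:1 + k]
    tau = np.exp(all_draws[:, :, 1 + k:1 + 2 * k])
    zm = all_draws[:, :, 1 + 2 * k:1 + 3 * k]
    zf = all_draws[:, :, 1 + 3 * k:1 + 4 * k]
    gamma = all_draws[:, :, 1 + 4 * k:]
    beta_male = mu + tau * zm
    beta_female = mu + tau * zf

    posterior = {"alpha": alpha, "mu": mu, "tau": tau,
                 "beta_male": beta_male, "beta_female": beta_female,
                 "gamma": gamma}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=posterior)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    max_rhat = float(max(np.nanmax(np.atleast_1d(rhat[v].values))
                         for v in posterior))
    min_ess = float(min(np.nanmin(np.atleast_1d(ess[v].values))
                        for v in posterior))
    div_rate = divergences / (chains * draws)
    diagnostics = {"divergences": int(divergences),
                   "divergence_rate": float(div_rate),
                   "max_rhat": max_rhat, "min_ess": min_ess,
                   "high_divergence_flag": bool(div_rate > 0.05),
                   "chains": chains, "draws": draws, "warmup": warmup}
    if div_rate > 0.05:
        logger.warning("divergence rate %.1f%% exceeds 5%%", 100 * div_rate)
        warnings.warn(f"divergence rate {100 * div_rate:.1f}% exceeds 5%",
                      RuntimeWarning)
    if check_diagnostics and max_rhat > rhat_threshold:
        raise RuntimeError(
            f"sampler did not converge: max split-R-hat {max_rhat:.3f} "
            f"> {rhat_threshold}")
    return PosteriorDraws(alpha=alpha, mu=mu, tau=tau,
                          beta_male=beta_male, beta_female=beta_female,
                          gamma=gamma,
                          covariate_names=list(design.covariate_names),
                          diagnostics=diagnostics, seed=seed)


# ----------------------------------------------------------------------
# posterior summaries
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.90

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def hpdi(samples, mass: float = 0.90) -> HPDInterval:
    """Shortest contiguous interval holding ``mass`` of the samples.

    Over the sorted samples, the window of ceil(mass * n) consecutive
    values with the smallest width; width ties resolve to the lower
    window.
    """
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 samples for an HPDI")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples must be finite")
    m = int(np.ceil(mass * n))
    if m > n:
        raise ValueError("requested mass needs more samples than provided")
    widths = x[m - 1:] - x[:n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first (lower) tie
    return HPDInterval(float(x[i]), float(x[i + m - 1]), mass)


def substantial_effect(samples, mass: float = 0.90) -> bool:
    """Decision rule: the HPDI of the posterior excludes zero."""
    return not hpdi(samples, mass).contains(0.0)


@dataclass
class SexDifference:
    pattern_id: int
    samples: np.ndarray     # per-draw beta_male - beta_female
    mean: float
    interval: HPDInterval
    substantial: bool


def sex_difference(draws: PosteriorDraws, pattern_id: int,
                   mass: float = 0.90) -> SexDifference:
    """Men - women posterior difference for one pattern (1-based id)."""
    if not 1 <= pattern_id <= draws.k:
        raise ValueError(f"pattern_id must be in 1..{draws.k}")
    j = pattern_id - 1
    diff = (draws.beta_male[:, :, j] - draws.beta_female[:, :, j]).ravel()
    interval = hpdi(diff, mass)
    return SexDifference(pattern_id, diff, float(diff.mean()), interval,
                         not interval.contains(0.0))


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted as half."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def posterior_predictive_auc(draws: PosteriorDraws, design: DesignMatrix,
                             method: str = "posterior_mean") -> float:
    """AUC of posterior-predictive outcome probabilities on the cohort.

    ``posterior_mean`` (default) scores each patient by the posterior mean
    of logit^-1(linear predictor); ``mean_auc`` instead averages per-draw
    AUCs.
    """
    Wm = design.patterns * (~design.sex_female)[:, None]
    Wf = design.patterns * design.sex_female[:, None]
    a = draws.flat(draws.alpha)           # (S,)
    bm = draws.flat(draws.beta_male)      # (S, k)
    bf = draws.flat(draws.beta_female)
    g = draws.flat(draws.gamma)
    eta = (a[None, :] + Wm @ bm.T + Wf @ bf.T
           + design.covariates @ g.T)     # (n, S)
    p = 1.0 / (1.0 + np.exp(-eta))
    if method == "posterior_mean":
        return _rank_auc(p.mean(axis=1), design.y)
    if method == "mean_auc":
        aucs = [_rank_auc(p[:, s], design.y) for s in range(p.shape[1])]
        return float(np.mean(aucs))
    raise ValueError(f"unknown method '{method}'")


# ----------------------------------------------------------------------
# baseline characteristics
# ----------------------------------------------------------------------

def compare_baseline_characteristics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sex comparison of baseline characteristics.

    Continuous variables use Welch two-sample t-tests; binary variables use
    two-sided Fisher's exact tests on the 2x2 count table.  One row per
    variable with overall / male / female summaries and the p-value.
    """
    male = cohort[cohort["sex"] == SEX_MALE]
    female = cohort[cohort["sex"] == SEX_FEMALE]
    if len(male) == 0 or len(female) == 0:
        raise ValueError("both sexes must be present")

    rows = []

    def t_row(name, col):
        a = male[col].to_numpy(float)
        b = female[col].to_numpy(float)
        flag = False
        if a.var() == 0 and b.var() == 0:
            p, flag = 1.0, True
        else:
            _, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "variable": name, "test": "welch_t",
            "overall": float(cohort[col].mean()),
            "male": float(a.mean()), "female": float(b.mean()),
            "p": float(p), "zero_variance": flag})

    def fisher_row(name, male_pos, female_pos):
        table = [[int(male_pos), len(male) - int(male_pos)],
                 [int(female_pos), len(female) - int(female_pos)]]
        _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({
            "variable": name, "test": "fisher_exact",
            "overall": float((male_pos + female_pos) / len(cohort) * 100),
            "male": float(male_pos / len(male) * 100),
            "female": float(female_pos / len(female) * 100),
            "p": float(p), "zero_variance": False})

    t_row("age", "age")
    fisher_row("unfavourable_outcome",
               (male["mrs"] > 2).sum(), (female["mrs"] > 2).sum())
    if VOLUME_COLUMN in cohort.columns:
        t_row("lesion_volume_ml", VOLUME_COLUMN)
    for rf in RISK_FACTORS:
        if rf in cohort.columns:
            fisher_row(rf, male[rf].sum(), female[rf].sum())
    return pd.DataFrame(rows).set_index("variable")
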