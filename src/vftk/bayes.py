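"""Bayesian feature-relevance framework for two-group comparisons.

For each feature the two groups are modeled independently with a normal
likelihood and a weakly-informative conjugate normal-scaled-inverse-chi^2
prior (prior mean = the group's sample mean, kappa0 = nu0 = 1e-3), which
admits exact conditional sampling: sigma^2 from its scaled-inverse-chi^2
conditional, mu from its normal conditional given sigma^2.

Summaries reported per feature:

* ``mu_h_bar`` / ``mu_s_bar`` — posterior means of the group means,
* 95% highest-density intervals of each group mean,
* ``p_mu`` — posterior probability that the first group's mean exceeds
  the second's,
* ``p_r``  — probability that a randomly drawn member of the first group
  outperforms a randomly drawn member of the second, estimated from one
  posterior-predictive draw per posterior sample, with its binomial
  Monte-Carlo standard error,
* ``dd``   — discriminative deviation |p_r - 1/2|, the distance of the
  superiority probability from chance, used to rank features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PosteriorDraws",
    "GroupComparison",
    "fit_posterior",
    "hdi",
    "prob_mean_greater",
    "prob_superiority",
    "discriminative_deviation",
    "compare_groups",
    "compare_all",
]

DEFAULT_M = 20_000
_KAPPA0 = 1e-3
_NU0 = 1e-3


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint posterior draws of one group's mean and SD."""

    mu: np.ndarray
    sigma: np.ndarray
    M: int
    n: int

    def __post_init__(self) -> None:
        if self.M < 1000:
            raise ValueError("need at least 1000 posterior draws")
        if not np.all(self.sigma > 0):
            raise ValueError("all sigma draws must be positive")


def fit_posterior(
    samples: np.ndarray,
    M: int = DEFAULT_M,
    rng: np.random.Generator | None = None,
    student_t_df: float | None = None,
) -> PosteriorDraws:
    """Draw M posterior samples of (mu, sigma) for one group.

    ``student_t_df`` switches the posterior-predictive tail behavior to a
    heavy-tailed variant (used only by the sensitivity hooks); the
    conjugate normal machinery is unchanged.

    A zero-variance sample is jittered by a tiny multiple of its mean
    scale (with a warning) so the scaled-inverse-chi^2 draw stays proper.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size < 2:
        raise ValueError("need a 1-D sample of size >= 2")
    if not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    rng = np.random.default_rng(rng)
    n = samples.size
    xbar = samples.mean()
    s2 = samples.var(ddof=1)
    if s2 == 0.0:
        import warnings

        jitter = max(abs(xbar), 1.0) * 1e-9
        warnings.warn("zero-variance sample; jittering scale for a proper posterior")
        s2 = jitter**2
    kappa_n = _KAPPA0 + n
    nu_n = _NU0 + n - 1
    # prior mean = sample mean and prior scale anchored at the sample
    # variance, so the (xbar - mu0)^2 update term vanishes
    s2_n = (_NU0 * s2 + (n - 1) * s2) / nu_n
    sigma2 = nu_n * s2_n / rng.chisquare(nu_n, size=M)
    mu = rng.normal(xbar, np.sqrt(sigma2 / kappa_n))
    return PosteriorDraws(mu=mu, sigma=np.sqrt(sigma2), M=M, n=n)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval containing ``mass`` of sorted draws.

    Sorted-window search; assumes a unimodal posterior, which holds for
    all conjugate posteriors produced here.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    draws = np.sort(np.asarray(draws, dtype=float))
    m = draws.size
    if m < 100:
        raise ValueError("need at least 100 draws for an HDI")
    k = int(np.ceil(mass * m))
    widths = draws[k - 1:] - draws[: m - k + 1]
    lo = int(np.argmin(widths))
    return float(draws[lo]), float(draws[lo + k - 1])


def _common_M(a: PosteriorDraws, b: PosteriorDraws) -> int:
    if a.M != b.M:
        raise ValueError("posterior draw counts differ; resample to a common M")
    return a.M


def prob_mean_greater(draws_h: PosteriorDraws, draws_s: PosteriorDraws) -> float:
    """Fraction of paired posterior draws with mu_h > mu_s."""
    _common_M(draws_h, draws_s)
    return float(np.mean(draws_h.mu > draws_s.mu))


def prob_superiority(
    draws_h: PosteriorDraws,
    draws_s: PosteriorDraws,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Subject-level superiority probability and its Monte-Carlo SE.

    One posterior-predictive observation is drawn per group per posterior
    draw; p_r is the fraction of pairs in which the first group's draw is
    larger, and se_r the binomial standard error sqrt(p (1-p) / M).
    """
    M = _common_M(draws_h, draws_s)
    rng = np.random.default_rng(rng)
    pred_h = rng.normal(draws_h.mu, draws_h.sigma)
    pred_s = rng.normal(draws_s.mu, draws_s.sigma)
    p_r = float(np.mean(pred_h > pred_s))
    se_r = float(np.sqrt(max(p_r * (1 - p_r), 1.0 / M) / M))
    return p_r, se_r


def discriminative_deviation(p_r: float) -> float:
    """|p_r - 0.5|: distance of the superiority probability from chance."""
    if not 0.0 <= p_r <= 1.0:
        raise ValueError(f"p_r must lie in [0, 1], got {p_r}")
    return abs(p_r - 0.5)


@dataclass(frozen=True)
class GroupComparison:
    """Bayesian summary of one feature's HC-vs-SH contrast."""

    mu_h_bar: float
    hdi_h: tuple[float, float]
    mu_s_bar: float
    hdi_s: tuple[float, float]
    p_mu: float
    p_r: float
    se_r: float
    dd: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mu_h": self.mu_h_bar,
            "hdi_h_lo": self.hdi_h[0],
            "hdi_h_hi": self.hdi_h[1],
            "mu_s": self.mu_s_bar,
            "hdi_s_lo": self.hdi_s[0],
            "hdi_s_hi": self.hdi_s[1],
            "p_mu": self.p_mu,
            "p_r": self.p_r,
            "se_r": self.se_r,
            "dd": self.dd,
        }


def compare_groups(
    samples_h: np.ndarray,
    samples_s: np.ndarray,
    M: int = DEFAULT_M,
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Full Bayesian comparison of two groups' samples of one feature."""
    rng = np.random.default_rng(rng)
    post_h = fit_posterior(samples_h, M=M, rng=rng)
    post_s = fit_posterior(samples_s, M=M, rng=rng)
    p_mu = prob_mean_greater(post_h, post_s)
    p_r, se_r = prob_superiority(post_h, post_s, rng=rng)
    return GroupComparison(
        mu_h_bar=float(post_h.mu.mean()),
        hdi_h=hdi(post_h.mu),
        mu_s_bar=float(post_s.mu.mean()),
        hdi_s=hdi(post_s.mu),
        p_mu=p_mu,
        p_r=p_r,
        se_r=se_r,
        dd=discriminative_deviation(p_r),
    )


def compare_all(
    features: pd.DataFrame,
    labels: np.ndarray,
    M: int = DEFAULT_M,
    rng: np.random.Generator | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Compare every feature column across the two groups, ranked by DD.

    ``labels`` must contain exactly the values "HC" and "SH".  The result
    is sorted by descending discriminative deviation with a stable
    feature-id tie-break; ``top_k`` truncates the ranking.
    """
    labels = np.asarray(labels)
    if not features.notna().all().all():
        raise ValueError("feature matrix contains missing values; impute upstream")
    mask_h = labels == "HC"
    mask_s = labels == "SH"
    if mask_h.sum() < 2 or mask_s.sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rng = np.random.default_rng(rng)
    rows = []
    for fid in features.columns:
        col = features[fid].to_numpy(dtype=float)
        comp = compare_groups(col[mask_h], col[mask_s], M=M, rng=rng)
        rows.append({"feature_id": fid, **comp.as_dict()})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["dd", "feature_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if top_k is not None:
        table = table.head(top_k)
    return table
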