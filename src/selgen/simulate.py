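"""Synthetic biobank-style cohort generator with known ground truth.

Real cohort data linking polygenic scores to completed fertility are access
restricted, so every downstream analysis in this package is exercised against
cohorts drawn from a generative model whose selection effects, subgroup
structure, mediation proportions and ascertainment mechanism are known by
construction.

Architecture
------------
* **Scores and human capital.**  A one-factor model: each standardized
  polygenic score ``z_k`` loads on latent human capital ``HC`` with
  correlation ``rho_k`` (``score_hc_corr``), so cross-score correlations are
  ``rho_j rho_k``.
* **Two generations.**  Midparent scores ``m_k`` are drawn first
  (``Var(m) = C/2``); respondent scores are ``m_k`` plus Mendelian segregation
  noise, which preserves the factor structure across generations.  Sibling
  counts come from parental fertility under the same link, and respondents are
  sampled *as children* — i.e. proportionally to family size — deliberately
  reproducing the size bias of a cohort recruited from offspring.
* **Fertility links.**  ``linear`` (``E[n|z] = mu (1 + eta)``), ``poisson_log``
  (``E[n|z] = mu exp(eta)``), or ``econ_model`` (expected fertility is the
  optimal ``N*`` of the two-period economic model with human capital mapped
  from ``HC``); counts are Poisson around the mean.  The linear predictor
  ``eta`` routes a fraction ``mediation_frac`` of every score's fertility
  effect through the observed education band (see below) and is scaled by
  per-stratum multipliers that create stronger selection in, by default,
  low-income strata.
* **Mediation channel.**  Latent education ``M = -u + tau nu`` (``u`` is the
  score-driven fertility predictor, so education is positively related to
  human capital) is cut into an ordinal band at fixed normal quantiles; the
  band — the *observed* mediator — re-enters the fertility predictor with a
  weight calibrated in closed form so that a product-of-coefficients mediation
  analysis on the generated data recovers exactly ``mediation_frac`` when
  scores are exchangeable (single score, or common ``|rho|`` and ``|gamma|``);
  heterogeneous configurations spread per-score proportions around that value
  (see :func:`expected_mediation_proportions`).
* **Ascertainment.**  Participation is Bernoulli with log-odds shifted by
  ``ascertainment_strength`` per standardized unit of education/human capital;
  the sampling weight is the inverse participation probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "CohortValidationError",
    "generate_cohort",
    "ground_truth_effects",
    "expected_mediation_proportions",
    "write_cohort",
    "read_cohort",
    "validate_cohort",
    "COHORT_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CohortValidationError(ValueError):
    """A cohort table violates the schema."""


_LINKS = ("linear", "poisson_log", "econ_model")

#: fixed (non-score) columns of the cohort schema, in file order
COHORT_COLUMNS = [
    "id",
    "sex",
    "birth_year",
    "n_children",
    "n_siblings",
    "income_band",
    "edu_age_band",
    "aflb",
    "n_sex_partners",
    "lives_with_partner",
    "risk_attitude",
    "weight",
]

#: latent ground-truth columns optionally appended by the generator
LATENT_COLUMNS = ["hc", "edu_latent", "p_participate", "parent_fertility_mean"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    The defaults emulate the study conditions this package targets: a cohort
    of 409,629 individuals born 1938-1968 carrying 33 standardized polygenic
    scores whose correlations with human capital span negative to strongly
    positive values, fertility effects proportional to (minus) those
    correlations, selection concentrated in low-income strata, a quarter of
    each effect mediated by educational attainment, and healthy-volunteer
    ascertainment corrected by inverse-probability weights.

    Parameters of note
    ------------------
    score_hc_corr : float | sequence
        Per-score correlation with latent human capital, in [-1, 1].
    gamma : sequence | None
        Per-score fertility coefficients (RLRS units per SD).  ``None``
        derives ``gamma_k = gamma_scale * score_hc_corr_k`` — selection
        against human-capital-increasing scores for negative ``gamma_scale``.
    mediation_frac : float
        Fraction of each score's fertility effect routed through the observed
        education band (exact for exchangeable scores).
    subgroup_multipliers : dict
        Multipliers applied to the score-driven fertility predictor by
        stratum.  Keys: ``income_band`` (one value per band, low to high),
        ``partners_high`` ((<= median, > median)), ``lives_with_partner``
        ((not cohabiting, cohabiting)).
    ascertainment_strength : float
        Log-odds shift of participation per standardized unit of the
        education/human-capital composite; 0 gives equal weights.
    """

    n: int = 409_629
    n_scores: int = 33
    birth_year_range: tuple[int, int] = (1938, 1968)
    reference_year: int = 2010
    score_hc_corr: float | tuple[float, ...] = ()
    fertility_link: str = "linear"
    gamma: tuple[float, ...] | None = None
    gamma_scale: float = -0.1
    mu: float = 1.9
    mu_parents: float = 2.3
    mediation_frac: float = 0.25
    mediation_noise_sd: float = 0.5
    edu_band_probs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    income_band_probs: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    income_hc_weight: float = 0.5
    subgroup_multipliers: dict = field(
        default_factory=lambda: {
            "income_band": (1.6, 1.3, 1.0, 0.7, 0.4),
            "partners_high": (0.8, 1.2),
            "lives_with_partner": (1.3, 0.9),
        }
    )
    parent_gamma_scale: float = 1.0
    parent_fertility_noise_sd: float = 0.25
    fertility_heritability: float = 1.0
    female_frac: float = 0.54
    cohabiting_frac: float = 0.70
    partners_nbinom_mean: float = 4.0
    partners_nbinom_k: float = 1.2
    risk_attitude_frac: float = 0.26
    risk_fertility_coef: float = 0.05
    risk_score_weight: float = 0.0
    aflb_base: float = 24.0
    aflb_edu_coef: float = 3.0
    aflb_score_coef: float = 0.0
    aflb_noise_sd: float = 3.0
    aflb_fertility_coef: float = 0.0
    ascertainment_strength: float = 0.5
    participation_base_rate: float = 0.5
    pool_factor: float = 1.25
    econ_params: dict = field(
        default_factory=lambda: {"a": 0.4, "b": 0.25, "sigma": 0.92}
    )
    econ_h_spread: float = 0.5
    include_latent: bool = False
    seed: int = 0

    # ---- derived arrays -------------------------------------------------

    def rho(self) -> np.ndarray:
        """Per-score correlation with human capital, as an array of length K."""
        if isinstance(self.score_hc_corr, (int, float)):
            return np.full(self.n_scores, float(self.score_hc_corr))
        if len(self.score_hc_corr) == 0:
            return np.round(np.linspace(-0.35, 0.5, self.n_scores), 4)
        return np.asarray(self.score_hc_corr, dtype=float)

    def gammas(self) -> np.ndarray:
        if self.gamma is None:
            return self.gamma_scale * self.rho()
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            g = np.full(self.n_scores, float(g))
        return g

    def score_names(self) -> list[str]:
        return [f"pgs_{k + 1}" for k in range(self.n_scores)]

    def score_cov(self) -> np.ndarray:
        """Implied cross-score correlation matrix C (one-factor structure)."""
        rho = self.rho()
        C = np.outer(rho, rho)
        np.fill_diagonal(C, 1.0)
        return C

    def validate(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        if self.n_scores < 1:
            raise ConfigError("n_scores must be >= 1")
        if self.fertility_link not in _LINKS:
            raise ConfigError(
                f"unknown fertility link {self.fertility_link!r}; expected one of {_LINKS}"
            )
        if not (self.mu > 0 and self.mu_parents > 0):
            raise ConfigError("baseline mean fertility mu must be > 0")
        rho = self.rho()
        if len(rho) != self.n_scores:
            raise ConfigError(
                f"score_hc_corr has length {len(rho)}, expected {self.n_scores}"
            )
        bad = np.where(np.abs(rho) > 1)[0]
        if bad.size:
            k = bad[0]
            raise ConfigError(
                "score correlation structure is not positive semidefinite: "
                f"|corr| > 1 for pair (pgs_{k + 1}, human capital): {rho[k]}"
            )
        g = self.gammas()
        if len(g) != self.n_scores:
            raise ConfigError(f"gamma has length {len(g)}, expected {self.n_scores}")
        if not 0 <= self.mediation_frac <= 1:
            raise ConfigError("mediation_frac must be in [0, 1]")
        if not math.isclose(sum(self.edu_band_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("edu_band_probs must sum to 1")
        if not math.isclose(sum(self.income_band_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("income_band_probs must sum to 1")
        if not 0 < self.participation_base_rate <= 1:
            raise ConfigError("participation_base_rate must be in (0, 1]")
        if self.birth_year_range[0] > self.birth_year_range[1]:
            raise ConfigError("birth_year_range must be (lo, hi) with lo <= hi")
        mult = self.subgroup_multipliers or {}
        unknown = set(mult) - {"income_band", "partners_high", "lives_with_partner"}
        if unknown:
            raise ConfigError(f"unknown subgroup_multipliers keys: {sorted(unknown)}")
        if "income_band" in mult and len(mult["income_band"]) != len(self.income_band_probs):
            raise ConfigError("income_band multipliers must match the number of bands")


# ---------------------------------------------------------------------------
# mediation-channel calibration (closed form)
# ---------------------------------------------------------------------------

def _band_moments(probs: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    """Thresholds and moments of an ordinal banding of a standard normal.

    Returns (standard-normal thresholds, band mean, band sd, S) where
    ``S = cov(banded code, standard normal latent)``.
    """
    probs = np.asarray(probs, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    cum[-1] = 1.0
    t = norm.ppf(cum)  # -inf ... +inf
    codes = np.arange(1, len(probs) + 1)
    mean = float(np.sum(codes * probs))
    var = float(np.sum(codes**2 * probs) - mean**2)
    pdf = norm.pdf(t)
    pdf[0] = pdf[-1] = 0.0
    # E[L * 1{t_j < L <= t_{j+1}}] = pdf(t_j) - pdf(t_{j+1}) for standard normal L
    S = float(np.sum(codes * (pdf[:-1] - pdf[1:])))
    return t, mean, math.sqrt(var), S


def _mediation_calibration(cfg: GeneratorConfig) -> dict:
    """Closed-form weights (d, g) of the direct and banded-education channels.

    The fertility predictor is ``eta = d u + g m`` with ``u = sum_k gamma_k
    z_k`` and ``m`` the standardized education band code of ``M = -u + tau
    nu``.  ``(d, g)`` solve two conditions: the marginal total effect of each
    score equals its no-mediation value ((C gamma)_k), and the per-score
    product-of-coefficients proportion mediated equals ``mediation_frac``
    (exactly for exchangeable scores; calibrated at the median of
    ``(C gamma)_k^2`` otherwise).
    """
    g_arr = cfg.gammas()
    C = cfg.score_cov()
    v = float(g_arr @ C @ g_arr)  # Var(u)
    c = C @ g_arr  # cov(z_k, u)
    tau = cfg.mediation_noise_sd
    v_M = v + tau**2
    _, _, sd_band, S = _band_moments(np.asarray(cfg.edu_band_probs))
    # phi = cov(z-standardized M, standardized band) transfer coefficient:
    # cov(z_k, m) = -c_k * phi with phi = S / (sd_M * sd_band)
    phi = S / (math.sqrt(v_M) * sd_band) if v_M > 0 else 0.0
    f = cfg.mediation_frac
    if f == 0.0 or v == 0.0 or phi == 0.0:
        return {"d": 1.0, "g": 0.0, "phi": phi, "v": v, "c": c, "v_M": v_M}
    c2 = float(np.median(c**2))
    D = 1.0 - c2 * phi**2
    Q = phi * (v - c2) / D
    g_w = (f - phi * Q) / (phi * (phi * Q - 1.0))
    d_w = 1.0 + g_w * phi
    return {"d": d_w, "g": g_w, "phi": phi, "v": v, "c": c, "v_M": v_M}


def expected_mediation_proportions(cfg: GeneratorConfig) -> np.ndarray:
    """Per-score proportion mediated implied by the generator, in closed form.

    Equals ``mediation_frac`` for every score when scores are exchangeable
    (single score, or common ``|rho|``/``|gamma|``); otherwise scores with
    stronger coupling to the shared channel sit slightly above or below it.
    Assumes subgroup multipliers are independent of scores (exact when
    ``income_hc_weight`` is 0 or multipliers are uniform).
    """
    cal = _mediation_calibration(cfg)
    d_w, g_w, phi, v = cal["d"], cal["g"], cal["phi"], cal["v"]
    c = cal["c"]
    out = np.empty(len(c))
    for k, ck in enumerate(c):
        Dk = 1.0 - ck**2 * phi**2
        bk = g_w - d_w * phi * (v - ck**2) / Dk
        tk = d_w - g_w * phi
        out[k] = -phi * bk / tk if tk != 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_scores(rng, hc_part: np.ndarray, rho: np.ndarray, resid_scale: float):
    """Scores loading on a shared factor: rho_k * factor + independent noise.

    ``resid_scale`` scales the residual variance (1 for a full generation,
    1/2 for segregation noise)."""
    n = len(hc_part)
    noise = rng.standard_normal((n, len(rho)))
    return hc_part[:, None] * rho[None, :] + noise * np.sqrt(
        resid_scale * (1.0 - rho**2)
    )[None, :]


def _fertility_counts(rng, cfg: GeneratorConfig, mean: np.ndarray) -> np.ndarray:
    mean = np.clip(mean, 0.0, None)
    return rng.poisson(mean)


def _econ_fertility_curve(cfg: GeneratorConfig):
    """Tabulate optimal fertility N*(h) and education s*(h) of the economic model."""
    from selgen.model import AgentParams, solve_two_period

    pars = cfg.econ_params
    h_grid = np.geomspace(0.2, 10.0, 257)
    N = np.empty_like(h_grid)
    s = np.empty_like(h_grid)
    for i, h in enumerate(h_grid):
        sol = solve_two_period(AgentParams(a=pars["a"], b=pars["b"], sigma=pars["sigma"], h=h))
        N[i], s[i] = sol.N_total, sol.s
    return h_grid, N, s


def generate_cohort(cfg: GeneratorConfig) -> pd.DataFrame:
    """Draw a cohort table from the generative model.

    Returns a DataFrame with the fixed schema columns plus one ``pgs_k``
    column per score (standardized in-sample over the delivered cohort, as an
    analyst would), and, when ``cfg.include_latent`` is set, the latent
    ground-truth columns.  Output is deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    rho = cfg.rho()
    gam = cfg.gammas()
    K = cfg.n_scores

    # ---- household (parental) generation --------------------------------
    p_child_zero = math.exp(-cfg.mu_parents)  # rough share of childless households
    n_resp_target = int(math.ceil(cfg.n / cfg.participation_base_rate * 1.1)) + 64
    n_pool = int(math.ceil(n_resp_target / (1.0 - p_child_zero) * cfg.pool_factor)) + 256

    hc_mid = rng.standard_normal(n_pool) * math.sqrt(0.5)
    m = _draw_scores(rng, hc_mid, rho, 0.5)  # midparent scores, Var C/2
    u_par = m @ (gam * cfg.parent_gamma_scale)
    xi = rng.standard_normal(n_pool)  # heritable non-score fertility propensity
    eta_par = u_par + cfg.parent_fertility_noise_sd * xi
    if cfg.fertility_link == "poisson_log":
        par_mean = cfg.mu_parents * np.exp(eta_par)
    elif cfg.fertility_link == "econ_model":
        h_grid, N_curve, _ = _econ_fertility_curve(cfg)
        h_par = np.exp(cfg.econ_h_spread * hc_mid * math.sqrt(2.0))
        par_mean = np.interp(h_par, h_grid, N_curve) * np.exp(
            cfg.parent_fertility_noise_sd * xi
        )
    else:
        par_mean = cfg.mu_parents * (1.0 + eta_par)
    n_par = _fertility_counts(rng, cfg, par_mean)

    # ---- respondents sampled as children (size-biased) -------------------
    has_child = n_par > 0
    n_avail = int(has_child.sum())
    if n_avail < n_resp_target:
        raise ConfigError(
            "household pool too small for the requested cohort; "
            f"increase pool_factor (have {n_avail} families with children, "
            f"need {n_resp_target})"
        )
    p_sel = np.where(has_child, n_par, 0).astype(float)
    idx = rng.choice(n_pool, size=n_resp_target, replace=False, p=p_sel / p_sel.sum())

    m_r = m[idx]
    hc_mid_r = hc_mid[idx]
    n_par_r = n_par[idx]
    xi_r = xi[idx]
    par_mean_r = par_mean[idx]

    # ---- respondent genetics: midparent + segregation noise --------------
    e_H = rng.standard_normal(n_resp_target) * math.sqrt(0.5)
    z = m_r + _draw_scores(rng, e_H, rho, 0.5)
    hc = hc_mid_r + e_H  # respondent human capital, N(0, 1)

    u = z @ gam
    cal = _mediation_calibration(cfg)
    tau = cfg.mediation_noise_sd
    nu = rng.standard_normal(n_resp_target)
    M = -u + tau * nu  # latent education, positively loaded on human capital
    sd_M = math.sqrt(cal["v_M"]) if cal["v_M"] > 0 else 1.0
    t_edu, mean_b, sd_b, _ = _band_moments(np.asarray(cfg.edu_band_probs))
    edu_band = np.searchsorted(t_edu[1:-1], M / sd_M, side="left") + 1
    m_std = (edu_band - mean_b) / sd_b

    # ---- demographics and strata -----------------------------------------
    y0, y1 = cfg.birth_year_range
    birth_year = rng.integers(y0, y1 + 1, size=n_resp_target)
    sex = np.where(rng.random(n_resp_target) < cfg.female_frac, "F", "M")

    w_inc = cfg.income_hc_weight
    income_lat = w_inc * hc + math.sqrt(max(1.0 - w_inc**2, 0.0)) * rng.standard_normal(
        n_resp_target
    )
    t_inc = norm.ppf(np.concatenate([[0.0], np.cumsum(cfg.income_band_probs)]))
    income_band = np.searchsorted(t_inc[1:-1], income_lat, side="left") + 1

    nb_mean, nb_k = cfg.partners_nbinom_mean, cfg.partners_nbinom_k
    partners = rng.negative_binomial(nb_k, nb_k / (nb_k + nb_mean), size=n_resp_target)
    cohab = (rng.random(n_resp_target) < cfg.cohabiting_frac).astype(int)

    risk_lat = cfg.risk_score_weight * _std(u) + math.sqrt(
        max(1.0 - cfg.risk_score_weight**2, 0.0)
    ) * rng.standard_normal(n_resp_target)
    risk = (risk_lat > norm.ppf(1.0 - cfg.risk_attitude_frac)).astype(int)

    # ---- respondent fertility --------------------------------------------
    mult = np.ones(n_resp_target)
    sm = cfg.subgroup_multipliers or {}
    if "income_band" in sm:
        mult *= np.asarray(sm["income_band"], dtype=float)[income_band - 1]
    if "partners_high" in sm:
        lo, hi = sm["partners_high"]
        med = np.median(partners)
        mult *= np.where(partners > med, hi, lo)
    if "lives_with_partner" in sm:
        no, yes = sm["lives_with_partner"]
        mult *= np.where(cohab == 1, yes, no)

    score_channel = cal["d"] * u + cal["g"] * m_std
    risk_c = (risk - cfg.risk_attitude_frac) / math.sqrt(
        cfg.risk_attitude_frac * (1.0 - cfg.risk_attitude_frac)
    )
    eta = (
        mult * score_channel
        + cfg.risk_fertility_coef * risk_c
        + cfg.fertility_heritability * cfg.parent_fertility_noise_sd * xi_r
    )

    if cfg.fertility_link == "econ_model":
        h_grid, N_curve, s_curve = _econ_fertility_curve(cfg)
        h_i = np.exp(cfg.econ_h_spread * hc)
        fert_mean = np.interp(h_i, h_grid, N_curve) * np.exp(
            cfg.fertility_heritability * cfg.parent_fertility_noise_sd * xi_r
        )
        # education reflects the model's optimal schooling choice
        s_i = np.interp(h_i, h_grid, s_curve)
        M_econ = _std(s_i) + tau * nu
        edu_band = np.searchsorted(t_edu[1:-1], M_econ / math.sqrt(1 + tau**2), side="left") + 1
        M = M_econ
    elif cfg.fertility_link == "poisson_log":
        fert_mean = cfg.mu * np.exp(eta)
    else:
        fert_mean = cfg.mu * (1.0 + eta)

    aflb_shift = np.zeros(n_resp_target)
    if cfg.aflb_fertility_coef != 0.0:
        # AFLB channel: fertility responds to (latent) first-birth timing
        aflb_shift = cfg.aflb_fertility_coef * _std(
            cfg.aflb_edu_coef * (M / sd_M) + rng.standard_normal(n_resp_target)
        )
        if cfg.fertility_link == "poisson_log":
            fert_mean = fert_mean * np.exp(np.where(sex == "F", aflb_shift, 0.0))
        else:
            fert_mean = fert_mean + cfg.mu * np.where(sex == "F", aflb_shift, 0.0)
    n_children = _fertility_counts(rng, cfg, fert_mean)

    # ---- age at first live birth (women with children) --------------------
    aflb = np.full(n_resp_target, np.nan)
    mothers = (sex == "F") & (n_children > 0)
    aflb_raw = (
        cfg.aflb_base
        + cfg.aflb_edu_coef * (M / sd_M)
        + cfg.aflb_score_coef * _std(u)
        + cfg.aflb_noise_sd * rng.standard_normal(n_resp_target)
    )
    aflb[mothers] = np.clip(aflb_raw[mothers], 14.0, 45.0).round(1)

    # ---- ascertainment ----------------------------------------------------
    shift = cfg.ascertainment_strength * 0.5 * (m_std + hc)
    p_part = expit(logit(cfg.participation_base_rate) + shift)
    participates = rng.random(n_resp_target) < p_part
    keep = np.flatnonzero(participates)
    if keep.size < cfg.n:
        raise ConfigError(
            f"only {keep.size} participants for requested n={cfg.n}; increase pool_factor"
        )
    keep = keep[: cfg.n]

    table = pd.DataFrame(
        {
            "id": np.arange(1, cfg.n + 1),
            "sex": sex[keep],
            "birth_year": birth_year[keep],
            "n_children": n_children[keep],
            "n_siblings": n_par_r[keep] - 1,
            "income_band": income_band[keep],
            "edu_age_band": edu_band[keep],
            "aflb": aflb[keep],
            "n_sex_partners": partners[keep],
            "lives_with_partner": cohab[keep],
            "risk_attitude": risk[keep],
            "weight": 1.0 / p_part[keep],
        }
    )
    z_kept = z[keep]
    z_kept = (z_kept - z_kept.mean(axis=0)) / z_kept.std(axis=0, ddof=0)
    for k, name in enumerate(cfg.score_names()):
        table[name] = z_kept[:, k]
    if cfg.include_latent:
        table["hc"] = hc[keep]
        table["edu_latent"] = M[keep]
        table["p_participate"] = p_part[keep]
        table["parent_fertility_mean"] = par_mean_r[keep]
    return table


def _std(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def ground_truth_effects(
    cfg: GeneratorConfig,
    n_sim: int = 2_000_000,
    by_subgroup: str | None = None,
) -> pd.DataFrame:
    """Expected selection effect per score implied by the configuration.

    For the ``linear`` link the marginal slope of RLRS on score k is
    ``(C gamma)_k`` (the direct coefficient plus correlated scores' leakage;
    equal to ``gamma_k`` for a single or uncorrelated scores), scaled by the
    subgroup multiplier within strata.  For ``poisson_log`` the slope is
    computed by Gauss-Hermite quadrature over the score-driven channel.  The
    ``econ_model`` link has no closed form: the truth is estimated by
    simulation at ``n_sim`` draws and returned with its Monte-Carlo SE.

    Subgroup strata are exact when the stratifying variable is independent of
    the scores (``income_hc_weight = 0`` for income strata).
    """
    cfg.validate()
    gam = cfg.gammas()
    C = cfg.score_cov()
    c = C @ gam
    names = cfg.score_names()

    def strata_multipliers():
        sm = cfg.subgroup_multipliers or {}
        if by_subgroup is None:
            return {"all": _mean_multiplier(cfg)}
        if by_subgroup not in sm:
            return {"all": _mean_multiplier(cfg)}
        vals = sm[by_subgroup]
        other = _mean_multiplier(cfg, exclude=by_subgroup)
        return {f"{by_subgroup}={i + 1}": v * other for i, v in enumerate(vals)}

    if cfg.fertility_link == "linear":
        base = c  # calibration keeps marginal totals at (C gamma)_k
        rows = [
            {"score_id": nm, "stratum": s_name, "beta_true": m_s * base[k], "mc_se": 0.0}
            for s_name, m_s in strata_multipliers().items()
            for k, nm in enumerate(names)
        ]
        return pd.DataFrame(rows)

    if cfg.fertility_link == "poisson_log":
        rows = []
        for s_name, m_s in strata_multipliers().items():
            slopes = _poisson_log_slopes(cfg, m_s)
            rows += [
                {"score_id": nm, "stratum": s_name, "beta_true": slopes[k], "mc_se": 0.0}
                for k, nm in enumerate(names)
            ]
        return pd.DataFrame(rows)

    # econ_model: simulate
    sim_cfg = replace(
        cfg,
        n=n_sim,
        ascertainment_strength=0.0,
        include_latent=False,
        seed=cfg.seed + 7,
    )
    table = generate_cohort(sim_cfg)
    from selgen.scan import compute_rlrs, estimate_selection

    rlrs = compute_rlrs(table, "respondents")
    rows = []
    for nm in names:
        eff = estimate_selection(table.assign(rlrs=rlrs), nm)
        rows.append(
            {"score_id": nm, "stratum": "all", "beta_true": eff.beta, "mc_se": eff.se}
        )
    return pd.DataFrame(rows)


def _mean_multiplier(cfg: GeneratorConfig, exclude: str | None = None) -> float:
    """Population-average subgroup multiplier (assumes strata independent of scores)."""
    sm = cfg.subgroup_multipliers or {}
    out = 1.0
    if "income_band" in sm and exclude != "income_band":
        out *= float(np.dot(sm["income_band"], cfg.income_band_probs))
    if "partners_high" in sm and exclude != "partners_high":
        out *= float(np.mean(sm["partners_high"]))
    if "lives_with_partner" in sm and exclude != "lives_with_partner":
        no, yes = sm["lives_with_partner"]
        out *= no * (1 - cfg.cohabiting_frac) + yes * cfg.cohabiting_frac
    return out


def _poisson_log_slopes(cfg: GeneratorConfig, mult: float = 1.0) -> np.ndarray:
    """Marginal RLRS-on-score slopes under the log link, by Gauss-Hermite quadrature.

    The fertility channel is ``eta = mult (d u + g m(M))`` with ``u`` Gaussian
    and ``m`` a banded function of ``M = -u + tau nu``; quadrature runs over
    the bivariate Gaussian (u, nu), and scores enter through the linear
    projection ``E[z_k | u] = c_k u / v``.
    """
    gam = cfg.gammas()
    C = cfg.score_cov()
    c = C @ gam
    v = float(gam @ C @ gam)
    if v == 0:
        return np.zeros(cfg.n_scores)
    cal = _mediation_calibration(cfg)
    tau = cfg.mediation_noise_sd
    t_edu, mean_b, sd_b, _ = _band_moments(np.asarray(cfg.edu_band_probs))
    sd_M = math.sqrt(cal["v_M"])

    nodes, weights = np.polynomial.hermite_e.hermegauss(81)
    wu = weights / math.sqrt(2 * math.pi)
    U, Nu = np.meshgrid(nodes * math.sqrt(v), nodes, indexing="ij")
    W = np.outer(wu, wu)
    M = -U + tau * Nu
    band = np.searchsorted(t_edu[1:-1], M / sd_M, side="left") + 1
    m_std = (band - mean_b) / sd_b
    eta = mult * (cal["d"] * U + cal["g"] * m_std)
    ex = np.exp(eta)
    denom = float(np.sum(W * ex))
    num_u = float(np.sum(W * ex * U))  # E[e^eta u]
    return c / v * (num_u / denom)


# ---------------------------------------------------------------------------
# I/O and validation
# ---------------------------------------------------------------------------

def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as UTF-8 CSV; missing AFLB becomes an empty field."""
    validate_cohort(table)
    table.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV written by :func:`write_cohort`."""
    table = pd.read_csv(
        Path(path),
        dtype={"sex": "string"},
        keep_default_na=False,
        na_values=[""],
    )
    table["sex"] = table["sex"].astype(str)
    validate_cohort(table)
    return table


def _score_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("pgs_")]


def validate_cohort(table: pd.DataFrame) -> None:
    """Check the cohort schema; raise :class:`CohortValidationError` on failure.

    Error messages list the offending rows (by ``id`` where available).
    """
    known = set(COHORT_COLUMNS) | set(LATENT_COLUMNS)
    unknown = [c for c in table.columns if c not in known and not c.startswith("pgs_")]
    if unknown:
        raise CohortValidationError(f"unknown columns: {unknown}")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    if len(table) == 0:
        return

    def _offending(mask) -> list:
        ids = table.loc[np.asarray(mask), "id"]
        return ids.head(20).tolist()

    for col in ("n_children", "n_siblings"):
        vals = table[col]
        bad = (vals != np.floor(vals)) | (vals < 0) | vals.isna()
        if bad.any():
            raise CohortValidationError(
                f"{col} must be non-negative integers; offending rows (id): {_offending(bad)}"
            )
    bad_w = ~(table["weight"] > 0)
    if bad_w.any():
        raise CohortValidationError(
            f"weights must be strictly positive; offending rows (id): {_offending(bad_w)}"
        )
    bad_sex = ~table["sex"].isin(["M", "F"])
    if bad_sex.any():
        raise CohortValidationError(
            f"sex must be 'M' or 'F'; offending rows (id): {_offending(bad_sex)}"
        )
    male_aflb = (table["sex"] == "M") & table["aflb"].notna()
    if male_aflb.any():
        raise CohortValidationError(
            f"aflb must be missing for males; offending rows (id): {_offending(male_aflb)}"
        )
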