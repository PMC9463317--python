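"""Selection-effect scans: RLRS regressions across scores, subgroups and generations.

The central quantity is relative lifetime reproductive success (RLRS): an
individual's number of children divided by the mean number of children of
their birth-year cohort, so that RLRS averages 1 within every cohort.  The
*selection effect* of a polygenic score is the slope from regressing RLRS on
the standardized score.  Because the score is standardized, that slope equals
the selection differential — and, within a cohort, the expected score among
the next generation's children (a Robertson-Price-style identity: with
in-sample standardization the OLS slope is algebraically the child-weighted
mean score).

Standard errors default to heteroskedasticity-robust (HC1): RLRS is a ratio
of counts with strongly non-constant variance.  Classic OLS/WLS standard
errors are available via ``se_type="classic"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from selgen.simulate import _score_columns

__all__ = [
    "SelectionEffect",
    "ScanReport",
    "compute_rlrs",
    "completed_fertility_filter",
    "estimate_selection",
    "scan_all",
    "subgroup_scan",
    "median_pct_difference",
    "aflb_control_contrast",
    "birth_year_trend",
    "cross_generation_compare",
    "meta_human_capital",
    "risk_attitude_robustness",
    "standardize_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionEffect:
    """One RLRS-on-score regression: beta is in expected-offspring-score units."""

    score_id: str
    subgroup: str
    weighted: bool
    controls: tuple[str, ...]
    beta: float
    se: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool | None:
        return None


@dataclass
class ScanReport:
    """A collection of selection effects plus the summaries derived from them.

    Every summary statistic in ``summary`` is recomputable from ``effects``.
    """

    effects: list[SelectionEffect] = field(default_factory=list)
    alpha: float = 0.05
    n_tests: int = 1
    summary: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests

    def significant_scores(self, subgroup: str | None = None, weighted: bool = True):
        return sorted(
            {
                e.score_id
                for e in self.effects
                if e.weighted == weighted
                and (subgroup is None or e.subgroup == subgroup)
                and e.p_value < self.threshold
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "score_id": e.score_id,
                "subgroup": e.subgroup,
                "weighted": e.weighted,
                "controls": "+".join(e.controls),
                "beta": e.beta,
                "se": e.se,
                "p_value": e.p_value,
                "n": e.n,
                "significant": e.p_value < self.threshold,
            }
            for e in self.effects
        ]
        return pd.DataFrame(rows)


def standardize_scores(table: pd.DataFrame, score_ids=None) -> pd.DataFrame:
    """Return a copy with the given score columns standardized in-sample (ddof=0)."""
    table = table.copy()
    for col in score_ids or _score_columns(table):
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"score column {col!r} has zero variance")
        table[col] = (x - x.mean()) / sd
    return table


def compute_rlrs(table: pd.DataFrame, generation: str = "respondents") -> pd.Series:
    """Relative lifetime reproductive success, normalized within birth year.

    ``respondents``: n_children / mean(n_children) over the same birth year.
    ``parents``: parental number of children is the respondent's sibship size
    (n_siblings + 1), normalized by its mean within the respondent's birth
    year.  (Respondents are sampled children, so large families are
    over-represented; see the cross-generation diagnostics.)

    Birth years whose mean fertility is zero cannot be normalized: those rows
    come back NaN and a count is logged — callers drop them explicitly.
    """
    if generation == "respondents":
        counts = table["n_children"].astype(float)
    elif generation == "parents":
        counts = table["n_siblings"].astype(float) + 1.0
    else:
        raise ValueError(f"generation must be 'respondents' or 'parents', got {generation!r}")
    if (counts < 0).any():
        raise ValueError("negative child counts")
    year_mean = counts.groupby(table["birth_year"]).transform("mean")
    rlrs = counts / year_mean.where(year_mean > 0)
    n_bad = int(rlrs.isna().sum())
    if n_bad:
        logger.warning(
            "%d rows in birth years with zero mean fertility flagged as NaN RLRS", n_bad
        )
    return rlrs.rename("rlrs")


def completed_fertility_filter(
    table: pd.DataFrame, reference_year: int = 2010
) -> tuple[pd.DataFrame, dict]:
    """Retain respondents old enough for fertility to be (near) complete.

    Males must be over 50 and females over 45 at the reference date — ages by
    which most childbearing has concluded.  Returns the retained subset and a
    dict of retained/excluded counts.
    """
    age = reference_year - table["birth_year"]
    keep = ((table["sex"] == "M") & (age > 50)) | ((table["sex"] == "F") & (age > 45))
    counts = {
        "retained": int(keep.sum()),
        "excluded": int((~keep).sum()),
        "reference_year": reference_year,
    }
    logger.info("completed-fertility filter: %(retained)d retained, %(excluded)d excluded", counts)
    return table.loc[keep].copy(), counts


def _fit_ols(y, X, weights=None, se_type: str = "robust"):
    if weights is None:
        model = sm.OLS(y, X)
    else:
        model = sm.WLS(y, X, weights=weights)
    if se_type == "robust":
        return model.fit(cov_type="HC1")
    return model.fit()


def estimate_selection(
    table: pd.DataFrame,
    score_id: str,
    weights: bool = False,
    controls: tuple[str, ...] = (),
    subgroup: str = "all",
    rlrs_col: str = "rlrs",
    se_type: str = "robust",
) -> SelectionEffect:
    """OLS (or WLS) slope of RLRS on one standardized score, with optional controls.

    With ``weights=True`` the sampling weights multiply squared residuals
    (classic WLS), correcting effect sizes for ascertainment.  Controls enter
    additively.  Raises on degenerate input: zero score variance or n < 3.
    """
    cols = [rlrs_col, score_id, *controls] + (["weight"] if weights else [])
    data = table[cols].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"insufficient data for {score_id} in {subgroup!r}: n={n} < 3")
    x = data[score_id].to_numpy(dtype=float)
    if x.std(ddof=0) == 0:
        raise ValueError(f"degenerate regressor: {score_id} has zero variance in {subgroup!r}")
    X = sm.add_constant(data[[score_id, *controls]].to_numpy(dtype=float))
    res = _fit_ols(
        data[rlrs_col].to_numpy(dtype=float),
        X,
        data["weight"].to_numpy(dtype=float) if weights else None,
        se_type,
    )
    return SelectionEffect(
        score_id=score_id,
        subgroup=subgroup,
        weighted=weights,
        controls=tuple(controls),
        beta=float(res.params[1]),
        se=float(res.bse[1]),
        p_value=float(res.pvalues[1]),
        n=n,
    )


def _with_rlrs(table: pd.DataFrame, generation: str = "respondents") -> pd.DataFrame:
    out = table.copy()
    out["rlrs"] = compute_rlrs(table, generation)
    n0 = len(out)
    out = out.dropna(subset=["rlrs"])
    if len(out) < n0:
        logger.info("dropped %d rows without defined RLRS", n0 - len(out))
    return out


def scan_all(
    table: pd.DataFrame,
    alpha: float = 0.05,
    se_type: str = "robust",
    generation: str = "respondents",
) -> ScanReport:
    """One weighted and one unweighted selection effect per score.

    Significance uses the Bonferroni threshold ``alpha / n_scores``.  The
    summary reports how much weighting changes effect sizes (mean percentage
    change in |beta|) — ascertainment corrections typically enlarge them.
    A score that fails (degenerate variance) is reported in ``exclusions``;
    the rest still compute.
    """
    scores = _score_columns(table)
    data = _with_rlrs(table, generation)
    report = ScanReport(alpha=alpha, n_tests=len(scores))
    pct_changes = []
    for sc in scores:
        try:
            unw = estimate_selection(data, sc, weights=False, se_type=se_type)
            wtd = estimate_selection(data, sc, weights=True, se_type=se_type)
        except ValueError as exc:
            report.exclusions[sc] = str(exc)
            continue
        report.effects += [unw, wtd]
        if unw.beta != 0:
            pct_changes.append(100.0 * (abs(wtd.beta) - abs(unw.beta)) / abs(unw.beta))
    report.summary["mean_pct_change_from_weighting"] = (
        float(np.mean(pct_changes)) if pct_changes else float("nan")
    )
    report.summary["n_significant_weighted"] = len(report.significant_scores(weighted=True))
    report.summary["n_significant_unweighted"] = len(report.significant_scores(weighted=False))
    return report


_SPLITS = ("income", "education", "partners", "cohabiting", "aflb-terciles")


def _strata(table: pd.DataFrame, split: str) -> list[tuple[str, pd.DataFrame]]:
    if split == "income":
        return [
            (f"income_band={b}", g) for b, g in table.groupby("income_band", sort=True)
        ]
    if split == "education":
        return [
            (f"edu_age_band={b}", g) for b, g in table.groupby("edu_age_band", sort=True)
        ]
    if split == "partners":
        med = table["n_sex_partners"].median()
        lower = table[table["n_sex_partners"] <= med]
        upper = table[table["n_sex_partners"] > med]
        return [(f"partners<={med:g}", lower), (f"partners>{med:g}", upper)]
    if split == "cohabiting":
        return [
            ("not_cohabiting", table[table["lives_with_partner"] == 0]),
            ("cohabiting", table[table["lives_with_partner"] == 1]),
        ]
    if split == "aflb-terciles":
        women = table[(table["sex"] == "F") & table["aflb"].notna()]
        q1, q2 = women["aflb"].quantile([1 / 3, 2 / 3])
        return [
            ("aflb_tercile=1", women[women["aflb"] <= q1]),
            ("aflb_tercile=2", women[(women["aflb"] > q1) & (women["aflb"] <= q2)]),
            ("aflb_tercile=3", women[women["aflb"] > q2]),
        ]
    raise ValueError(f"unknown split {split!r}; expected one of {_SPLITS}")


def subgroup_scan(
    table: pd.DataFrame,
    split: str,
    alpha: float = 0.05,
    weights: bool = False,
    se_type: str = "robust",
) -> ScanReport:
    """Selection effects per score within each stratum of a split.

    Splits: ``income`` / ``education`` (bands), ``partners`` (median split;
    ties to the lower stratum, so the upper stratum is strictly "more than
    median"), ``cohabiting``, ``aflb-terciles`` (women with non-missing age
    at first live birth only).  Strata with n < 3 are reported as
    not-estimable rather than raising.
    """
    scores = _score_columns(table)
    data = _with_rlrs(table)
    report = ScanReport(alpha=alpha, n_tests=len(scores))
    for label, grp in _strata(data, split):
        for sc in scores:
            try:
                report.effects.append(
                    estimate_selection(
                        grp, sc, weights=weights, subgroup=label, se_type=se_type
                    )
                )
            except ValueError as exc:
                report.exclusions[f"{label}:{sc}"] = str(exc)
    strata_labels = [lab for lab, _ in _strata(data, split)]
    if len(strata_labels) >= 2:
        report.summary["median_pct_difference"] = median_pct_difference(
            [e for e in report.effects if e.subgroup == strata_labels[0]],
            [e for e in report.effects if e.subgroup == strata_labels[-1]],
            sig_threshold=report.threshold,
            all_effects=report.effects,
        )
    return report


def median_pct_difference(
    effects_a: list[SelectionEffect],
    effects_b: list[SelectionEffect],
    sig_threshold: float,
    all_effects: list[SelectionEffect] | None = None,
) -> float:
    """Median percentage difference in |beta| between strata A and B.

    Restricted to scores significant in stratum A (at the multiple-testing
    threshold) whose effect keeps the same sign in every stratum; per score
    the difference is ``100 (|beta_A| - |beta_B|) / |beta_B|``.  Returns NaN
    when no score qualifies.
    """
    a = {e.score_id: e for e in effects_a}
    b = {e.score_id: e for e in effects_b}
    pool = all_effects if all_effects is not None else effects_a + effects_b
    diffs = []
    for sc, ea in a.items():
        if sc not in b or ea.p_value >= sig_threshold:
            continue
        signs = {np.sign(e.beta) for e in pool if e.score_id == sc}
        if len(signs) != 1 or b[sc].beta == 0:
            continue
        diffs.append(100.0 * (abs(ea.beta) - abs(b[sc].beta)) / abs(b[sc].beta))
    return float(np.median(diffs)) if diffs else float("nan")


def aflb_control_contrast(
    table: pd.DataFrame, alpha: float = 0.05, se_type: str = "robust"
) -> pd.DataFrame:
    """Female selection effects with and without controlling for age at first birth.

    Returns one row per score: raw beta, AFLB-controlled beta, whether the
    sign flips, plus (as attrs) the cross-score correlation between
    controlled and raw effects and the sign-change count.  Selection can run
    through two opposing channels — earlier first births and fertility after
    timing is held fixed — in which case controlling flips signs.
    """
    women = table[(table["sex"] == "F") & table["aflb"].notna()]
    data = _with_rlrs(women)
    rows = []
    for sc in _score_columns(table):
        raw = estimate_selection(data, sc, subgroup="women", se_type=se_type)
        ctl = estimate_selection(
            data, sc, controls=("aflb",), subgroup="women", se_type=se_type
        )
        rows.append(
            {
                "score_id": sc,
                "beta_raw": raw.beta,
                "se_raw": raw.se,
                "p_raw": raw.p_value,
                "beta_controlled": ctl.beta,
                "se_controlled": ctl.se,
                "p_controlled": ctl.p_value,
                "sign_changed": bool(np.sign(raw.beta) != np.sign(ctl.beta)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 3:
        out.attrs["corr_controlled_raw"] = float(
            np.corrcoef(out["beta_raw"], out["beta_controlled"])[0, 1]
        )
    out.attrs["n_sign_changed"] = int(out["sign_changed"].sum())
    return out


def birth_year_trend(
    table: pd.DataFrame, alpha: float = 0.05, bin_years: int = 5
) -> pd.DataFrame:
    """Per-score linear trend of the mean score over birth year.

    Individual-level regression of the score on birth year, with a Bonferroni
    significance flag at ``alpha / n_scores``; cohort drift of a few percent
    of an SD per generation is the magnitude of interest.  Also attaches
    ``bin_years``-wide interval means with normal-approximation 95% CIs for
    reporting (attrs["binned"]).
    """
    years = table["birth_year"]
    if years.nunique() < 2:
        raise ValueError("birth-year trend requires at least 2 distinct birth years")
    scores = _score_columns(table)
    X = sm.add_constant(years.to_numpy(dtype=float))
    rows = []
    for sc in scores:
        res = sm.OLS(table[sc].to_numpy(dtype=float), X).fit()
        rows.append(
            {
                "score_id": sc,
                "slope_per_year": float(res.params[1]),
                "se": float(res.bse[1]),
                "p_value": float(res.pvalues[1]),
                "significant": float(res.pvalues[1]) < alpha / len(scores),
            }
        )
    out = pd.DataFrame(rows)
    bins = (years // bin_years) * bin_years
    grouped = table.groupby(bins)[scores]
    mean, sd, cnt = grouped.mean(), grouped.std(ddof=1), grouped.count()
    binned = pd.concat(
        {"mean": mean, "ci_half_width": 1.96 * sd / np.sqrt(cnt)}, axis=1
    )
    out.attrs["binned"] = binned
    return out


def cross_generation_compare(
    table: pd.DataFrame, alpha: float = 0.05, se_type: str = "robust"
) -> dict:
    """Compare selection effects between respondents and their parents.

    Parental RLRS is reconstructed from sibship sizes; respondent scores act
    as proxies for (mid)parental scores.  Returns per-score effects for both
    generations, their cross-score correlation, the individual-level
    correlation between the two RLRS values (the quantity-quality check: a
    positive value means no tradeoff), and a size-bias diagnostic: the mean
    parental children count in the sample, which exceeds the population mean
    because respondents are sampled children.
    """
    scores = _score_columns(table)
    resp = _with_rlrs(table, "respondents")
    par = _with_rlrs(table, "parents")
    eff_r, eff_p = [], []
    for sc in scores:
        eff_r.append(estimate_selection(resp, sc, subgroup="respondents", se_type=se_type))
        eff_p.append(estimate_selection(par, sc, subgroup="parents", se_type=se_type))
    betas_r = np.array([e.beta for e in eff_r])
    betas_p = np.array([e.beta for e in eff_p])
    both = resp[["rlrs"]].join(par["rlrs"], rsuffix="_parents", how="inner").dropna()
    out = {
        "effects_respondents": eff_r,
        "effects_parents": eff_p,
        "effect_correlation": float(np.corrcoef(betas_r, betas_p)[0, 1])
        if len(scores) >= 3
        else float("nan"),
        "rlrs_correlation": float(both["rlrs"].corr(both["rlrs_parents"])),
        "mean_parental_children": float((table["n_siblings"] + 1).mean()),
    }
    return out


def meta_human_capital(
    effects: list[SelectionEffect], table: pd.DataFrame, hc_col: str = "edu_age_band"
) -> pd.DataFrame:
    """Cross-score meta-analysis: selection effects vs human-capital correlations.

    For each score, the correlation between the score and a human-capital
    measure (an education or earnings column); across scores, the correlation
    and OLS slope between selection effects and those correlations.  A
    strongly negative relation is the signature of substitution-dominated
    selection: scores are selected against in proportion to their link with
    human capital.
    """
    by_score = {e.score_id: e for e in effects}
    scores = [sc for sc in _score_columns(table) if sc in by_score]
    if len(scores) < 3:
        raise ValueError(f"meta-analysis requires >= 3 scores, got {len(scores)}")
    hc = table[hc_col].to_numpy(dtype=float)
    rows = [
        {
            "score_id": sc,
            "hc_correlation": float(np.corrcoef(table[sc].to_numpy(dtype=float), hc)[0, 1]),
            "beta": by_score[sc].beta,
        }
        for sc in scores
    ]
    out = pd.DataFrame(rows)
    r = float(np.corrcoef(out["hc_correlation"], out["beta"])[0, 1])
    slope = float(np.polyfit(out["hc_correlation"], out["beta"], 1)[0])
    out.attrs["cross_score_correlation"] = r
    out.attrs["cross_score_slope"] = slope
    out.attrs["hc_col"] = hc_col
    return out


def risk_attitude_robustness(
    table: pd.DataFrame, se_type: str = "robust"
) -> pd.DataFrame:
    """Selection effects with and without a binary risk-attitude control.

    Tests the externalizing/risk-seeking alternative explanation: if risk
    appetite rather than human capital drove selection, controlling for it
    would shrink effects (ratio far below 1).  Also reports whether risk
    attitude itself predicts RLRS (attrs).  A constant risk column is dropped
    with a warning, leaving controlled = raw.
    """
    data = _with_rlrs(table)
    constant_risk = data["risk_attitude"].nunique() < 2
    if constant_risk:
        logger.warning("risk_attitude is constant; control dropped")
    rows = []
    for sc in _score_columns(table):
        raw = estimate_selection(data, sc, se_type=se_type)
        if constant_risk:
            ctl = raw
        else:
            ctl = estimate_selection(data, sc, controls=("risk_attitude",), se_type=se_type)
        rows.append(
            {
                "score_id": sc,
                "beta_raw": raw.beta,
                "beta_controlled": ctl.beta,
                "ratio": ctl.beta / raw.beta if raw.beta != 0 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["median_ratio"] = float(out["ratio"].median())
    if not constant_risk:
        risk_eff = estimate_selection(
            data, "risk_attitude", subgroup="risk-only", se_type=se_type
        )
        out.attrs["risk_predicts_rlrs_p"] = risk_eff.p_value
        out.attrs["risk_beta"] = risk_eff.beta
    return out
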