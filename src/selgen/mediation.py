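"""Mediation of selection effects by educational attainment.

How much of a score's correlation with relative fertility runs through
education?  The product-of-coefficients decomposition uses two linear fits on
the same sample:

    mediator ~ score              (a-path)
    RLRS     ~ score + mediator   (b-path and direct effect)

``indirect = a * b``, ``total = direct + indirect`` (an exact identity for
nested linear models), and the proportion mediated is ``indirect / total``.
Confidence intervals come from a percentile bootstrap over individuals; the
proportion's interval is flagged unbounded when bootstrap totals cross zero
(the ratio then has no bounded interval, and displaying one would be
misleading).  The indirect effect's p-value uses the Sobel normal
approximation, which supports multiplicity thresholds far below the
resolution of a small bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from selgen.scan import ScanReport, _with_rlrs
from selgen.simulate import _score_columns

__all__ = ["MediationResult", "mediate", "mediation_panel"]


@dataclass(frozen=True)
class MediationResult:
    """Linear mediation decomposition for one score.

    ``total = direct + indirect`` to numerical tolerance.  ``proportion`` is
    only trustworthy when ``stable`` (|total| at least 5 of its SEs —
    otherwise the ratio explodes and is reported but flagged).
    """

    score_id: str
    mediator: str
    total: float
    direct: float
    indirect: float
    proportion: float
    stable: bool
    ci_indirect: tuple[float, float]
    ci_proportion: tuple[float, float]
    proportion_ci_unbounded: bool
    level: float
    n_boot: int
    n: int
    p_indirect: float
    same_sign: bool


def _ols_slope(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares coefficients for an explicit design matrix (with intercept)."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def _decompose(z: np.ndarray, med: np.ndarray, y: np.ndarray):
    one = np.ones_like(z)
    a = _ols_slope(med, np.column_stack([one, z]))[1]
    coefs = _ols_slope(y, np.column_stack([one, z, med]))
    direct, b = coefs[1], coefs[2]
    total = _ols_slope(y, np.column_stack([one, z]))[1]
    return float(total), float(direct), float(a * b)


def mediate(
    table: pd.DataFrame,
    score_id: str,
    mediator_col: str = "edu_age_band",
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    rlrs_col: str = "rlrs",
    stability_floor_se: float = 5.0,
) -> MediationResult:
    """Estimate how much of one score's selection effect is mediated.

    The mediator enters as a numeric column (an ordinal education band by
    default).  ``n_boot`` i.i.d. row resamples (>= 2) give percentile CIs for
    the indirect effect and the proportion; the proportion is additionally
    flagged unstable when |total| < ``stability_floor_se`` * SE(total), so a
    near-zero total never yields a spuriously huge ratio presented as solid.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if rlrs_col not in table.columns:
        table = _with_rlrs(table)
    data = table[[rlrs_col, score_id, mediator_col]].dropna()
    n = len(data)
    if n < 3:
        raise ValueError(f"insufficient data: n={n}")
    z = data[score_id].to_numpy(dtype=float)
    med = data[mediator_col].to_numpy(dtype=float)
    y = data[rlrs_col].to_numpy(dtype=float)
    if med.std(ddof=0) == 0:
        raise ValueError(f"mediator {mediator_col!r} has zero variance")

    total, direct, indirect = _decompose(z, med, y)

    # Sobel normal approximation for the indirect effect
    one = np.ones_like(z)
    Xa = np.column_stack([one, z])
    Xb = np.column_stack([one, z, med])
    a_coef = _ols_slope(med, Xa)[1]
    resid_a = med - Xa @ _ols_slope(med, Xa)
    se_a = np.sqrt(
        resid_a @ resid_a / (n - 2) * np.linalg.inv(Xa.T @ Xa)[1, 1]
    )
    b_all = _ols_slope(y, Xb)
    resid_b = y - Xb @ b_all
    se_b = np.sqrt(resid_b @ resid_b / (n - 3) * np.linalg.inv(Xb.T @ Xb)[2, 2])
    b_coef = b_all[2]
    sobel_se = np.sqrt(a_coef**2 * se_b**2 + b_coef**2 * se_a**2)
    p_indirect = float(2 * stats.norm.sf(abs(indirect) / sobel_se)) if sobel_se > 0 else 1.0

    # total-effect SE for the stability floor
    Xt = Xa
    resid_t = y - Xt @ _ols_slope(y, Xt)
    se_total = float(
        np.sqrt(resid_t @ resid_t / (n - 2) * np.linalg.inv(Xt.T @ Xt)[1, 1])
    )
    stable = abs(total) >= stability_floor_se * se_total

    rng = np.random.default_rng(seed)
    boot_ind = np.empty(n_boot)
    boot_tot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t_i, _, ind_i = _decompose(z[idx], med[idx], y[idx])
        boot_ind[i], boot_tot[i] = ind_i, t_i
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    ci_ind = tuple(np.quantile(boot_ind, [lo, hi]))
    crosses_zero = bool((boot_tot <= 0).any() and (boot_tot >= 0).any())
    boot_prop = boot_ind / boot_tot
    ci_prop = tuple(np.quantile(boot_prop, [lo, hi]))

    return MediationResult(
        score_id=score_id,
        mediator=mediator_col,
        total=total,
        direct=direct,
        indirect=indirect,
        proportion=indirect / total if total != 0 else float("nan"),
        stable=stable,
        ci_indirect=(float(ci_ind[0]), float(ci_ind[1])),
        ci_proportion=(float(ci_prop[0]), float(ci_prop[1])),
        proportion_ci_unbounded=crosses_zero,
        level=level,
        n_boot=n_boot,
        n=n,
        p_indirect=p_indirect,
        same_sign=bool(np.sign(indirect) == np.sign(total)),
    )


def mediation_panel(
    table: pd.DataFrame,
    scan_report: ScanReport,
    mediator_col: str = "edu_age_band",
    alpha: float = 0.05,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    weighted_selection: bool = True,
) -> tuple[list[MediationResult], dict]:
    """Mediation analysis for every score with a significant selection effect.

    Scores are selected at the scan's Bonferroni threshold (``alpha`` over the
    number of scanned scores); the indirect-effect multiplicity threshold is
    then ``alpha`` over the number of *selected* scores.  Returns per-score
    results plus a panel summary: the count of significant same-signed
    indirect effects and the median proportion mediated (over stable
    results).
    """
    selected = scan_report.significant_scores(weighted=weighted_selection)
    data = _with_rlrs(table)
    results: list[MediationResult] = []
    for i, sc in enumerate(selected):
        results.append(
            mediate(
                data,
                sc,
                mediator_col=mediator_col,
                n_boot=n_boot,
                level=level,
                seed=seed + i,
            )
        )
    threshold = alpha / len(selected) if selected else float("nan")
    sig_same_sign = sum(1 for r in results if r.same_sign and r.p_indirect < threshold)
    stable_props = [r.proportion for r in results if r.stable]
    summary = {
        "n_selected": len(selected),
        "indirect_threshold": threshold,
        "n_significant_same_sign_indirect": sig_same_sign,
        "median_proportion_mediated": float(np.median(stable_props))
        if stable_props
        else float("nan"),
    }
    if not selected:
        summary["note"] = "no scores passed the selection threshold"
    return results, summary


def panel_frame(results: list[MediationResult]) -> pd.DataFrame:
    """Tabular view of a mediation panel."""
    return pd.DataFrame(
        [
            {
                "score_id": r.score_id,
                "total": r.total,
                "direct": r.direct,
                "indirect": r.indirect,
                "proportion": r.proportion,
                "stable": r.stable,
                "ci_indirect_lo": r.ci_indirect[0],
                "ci_indirect_hi": r.ci_indirect[1],
                "ci_proportion_lo": r.ci_proportion[0],
                "ci_proportion_hi": r.ci_proportion[1],
                "proportion_ci_unbounded": r.proportion_ci_unbounded,
                "p_indirect": r.p_indirect,
                "same_sign": r.same_sign,
                "n": r.n,
            }
            for r in results
        ]
    )
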