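"""Counterfactual consequences of selection for genetic inequality.

Two computations, both built on child-count weighting of the parent
generation:

* :func:`child_mean_by_group` — the child generation's mean polygenic score
  per income band (each parent's score weighted by their number of children,
  transmission noise ignored) against the hypothetical mean if every family
  were the same size.  Where selection is stronger at the bottom of the
  income distribution, the gap between actual and hypothetical is most
  negative there, widening between-group differences.
* :func:`correlation_amplification` — the score-income correlation in the
  parent generation versus the child generation (a frequency-weighted
  correlation, each parent counted once per child), and the percentage
  change.  Selection concentrated in low-income groups *increases* the
  correlation of scores with income.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "child_mean_by_group",
    "correlation_amplification",
    "weighted_corr",
]


def child_mean_by_group(
    table: pd.DataFrame, score_id: str, group_col: str = "income_band"
) -> pd.DataFrame:
    """Actual vs equal-fertility child-generation mean score per group.

    actual = sum(n_i z_i) / sum(n_i) within the band (children inherit the
    parental score in expectation); hypothetical = unweighted mean of z.  A
    band with zero total children has no child generation: actual is NaN.
    """
    rows = []
    for band, grp in table.groupby(group_col, sort=True):
        z = grp[score_id].to_numpy(dtype=float)
        n = grp["n_children"].to_numpy(dtype=float)
        tot = n.sum()
        rows.append(
            {
                group_col: band,
                "actual": float((n * z).sum() / tot) if tot > 0 else float("nan"),
                "hypothetical": float(z.mean()),
                "n_parents": len(grp),
                "n_children": int(tot),
            }
        )
    out = pd.DataFrame(rows)
    out["gap"] = out["actual"] - out["hypothetical"]
    return out


def weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Frequency-weighted Pearson correlation (w >= 0, integer counts or not)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    mx = (w * x).sum() / tot
    my = (w * y).sum() / tot
    cov = (w * (x - mx) * (y - my)).sum() / tot
    vx = (w * (x - mx) ** 2).sum() / tot
    vy = (w * (y - my) ** 2).sum() / tot
    if vx == 0 or vy == 0:
        raise ValueError("zero weighted variance")
    return float(cov / np.sqrt(vx * vy))


def correlation_amplification(
    table: pd.DataFrame,
    score_id: str,
    income_col: str = "income_band",
    stability_floor: float = 1e-3,
) -> dict:
    """Change in the score-income correlation from parents to children.

    ``r_parents`` is the ordinary correlation over individuals;
    ``r_children`` weights each individual by their number of children (each
    child inherits its parent's score and income group in expectation).
    ``pct_change = 100 (r_children - r_parents) / |r_parents|``, flagged
    unstable when |r_parents| is below ``stability_floor``.
    """
    z = table[score_id].to_numpy(dtype=float)
    inc = table[income_col].to_numpy(dtype=float)
    n = table["n_children"].to_numpy(dtype=float)
    r_par = float(np.corrcoef(z, inc)[0, 1])
    r_chi = weighted_corr(z, inc, n)
    unstable = abs(r_par) < stability_floor
    return {
        "score_id": score_id,
        "r_parents": r_par,
        "r_children": r_chi,
        "pct_change": 100.0 * (r_chi - r_par) / abs(r_par) if not unstable else float("nan"),
        "unstable": unstable,
    }


def amplification_panel(
    table: pd.DataFrame, score_ids=None, income_col: str = "income_band"
) -> pd.DataFrame:
    """Correlation amplification for many scores, plus summary attrs.

    attrs: ``n_increased`` (scores whose |correlation with income| grows
    under child-weighting in the direction of the existing correlation — the
    amplification count) and ``median_pct_change``.
    """
    from selgen.simulate import _score_columns

    score_ids = score_ids or _score_columns(table)
    rows = [correlation_amplification(table, sc, income_col) for sc in score_ids]
    out = pd.DataFrame(rows)
    stable = out[~out["unstable"]]
    amplified = np.sign(stable["r_parents"]) * (
        stable["r_children"] - stable["r_parents"]
    ) > 0
    out.attrs["n_increased"] = int(amplified.sum())
    out.attrs["n_stable"] = int(len(stable))
    out.attrs["median_pct_change"] = (
        float(stable["pct_change"].median()) if len(stable) else float("nan")
    )
    return out
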