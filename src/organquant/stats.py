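"""Association and classification statistics for the invasion analyses.

Pearson correlation with two-sided p-values and ordinary least-squares
best-fit lines (the per-plot r/p/regression reporting), paired t-tests,
iterative Grubbs outlier flagging, TGF-β responder classification from
pSMAD3 densitometry fold changes, and the transcription-factor screen that
correlates each TF's expression with an invasion phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "ResponderCall",
    "pearson_with_regression",
    "paired_t_test",
    "grubbs_critical_value",
    "identify_outliers",
    "classify_tgfb_response",
    "tf_screen",
]


@dataclass
class AssociationResult:
    x_name: str
    y_name: str
    n: int
    r: float
    p_value: float
    slope: float
    intercept: float
    outlier_flags: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


@dataclass
class ResponderCall:
    population_id: str
    fold_change: float
    responsive: bool
    threshold: float


def pearson_with_regression(
    x, y, x_name: str = "x", y_name: str = "y"
) -> AssociationResult:
    """Pearson r with two-sided p plus the OLS best-fit line.

    The p-value comes from ``t = r*sqrt((n-2)/(1-r**2))`` against a t
    distribution with n-2 df (the exact test under bivariate normality).
    Constant input makes r undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Pearson r undefined")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return AssociationResult(
        x_name=x_name, y_name=y_name, n=n, r=float(r), p_value=float(p),
        slope=float(fit.slope), intercept=float(fit.intercept),
        outlier_flags=np.zeros(n, dtype=bool),
    )


def paired_t_test(a, b) -> tuple[float, int, float]:
    """Two-sided paired Student's t on the differences; returns (t, df, p).

    Degenerate cases are reported, not hidden: zero differences everywhere
    give (0, n-1, 1) by convention; zero-variance nonzero differences give an
    infinite t with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value G_crit at significance alpha."""
    t2 = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2) ** 2
    return (n - 1) / np.sqrt(n) * np.sqrt(t2 / (n - 2 + t2))


def identify_outliers(values, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; returns boolean flags, removal is the caller's.

    The single most extreme point is flagged if its Grubbs statistic
    ``|x - mean| / sd`` exceeds the critical value at ``alpha``; the test is
    repeated on the remaining points until nothing exceeds or fewer than 3
    points remain.  A constant vector yields no flags.
    """
    values = np.asarray(values, dtype=float)
    n0 = len(values)
    if n0 < 3:
        raise ValueError("need n >= 3 for outlier identification")
    flags = np.zeros(n0, dtype=bool)
    active = np.arange(n0)
    while len(active) >= 3:
        v = values[active]
        sd = v.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(v - v.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        if g > grubbs_critical_value(len(v), alpha):
            flags[active[i]] = True
            active = np.delete(active, i)
        else:
            break
    return flags


def classify_tgfb_response(
    densitometry: pd.DataFrame, threshold: float = 1.5
) -> list[ResponderCall]:
    """Call TGF-β responsiveness from pSMAD3 densitometry fold changes.

    ``fold = psmad3_tgfb / psmad3_ctrl``; a population is responsive iff
    fold >= threshold.  Responsive lines typically show 2–4-fold pSMAD3
    stimulation; the default 1.5 cutoff sits below that range and above the
    ~1-fold of non-responders.  Non-positive densitometry values are invalid.
    """
    calls = []
    for _, row in densitometry.iterrows():
        ctrl, tgfb = float(row["psmad3_ctrl"]), float(row["psmad3_tgfb"])
        if ctrl <= 0 or tgfb <= 0:
            raise ValueError(f"population {row['population']!r}: non-positive densitometry")
        fold = tgfb / ctrl
        calls.append(
            ResponderCall(
                population_id=str(row["population"]),
                fold_change=fold,
                responsive=fold >= threshold,
                threshold=threshold,
            )
        )
    return calls


def tf_screen(tf_expression: pd.DataFrame, phenotype, phenotype_name: str = "phenotype") -> pd.DataFrame:
    """Correlate every transcription factor with an invasion phenotype.

    For each TF column, Pearson r/p and the OLS line against the phenotype
    (rows = populations, aligned positionally).  The output is sorted by |r|
    descending with a Benjamini–Hochberg ``q_value`` column appended for
    reference; ranking uses raw |r| only.  Constant TF columns are reported
    with NaN r and excluded from the ranking (sorted last).
    """
    phenotype = np.asarray(phenotype, dtype=float)
    if len(phenotype) != len(tf_expression):
        raise ValueError("phenotype must align with the matrix rows")
    if len(phenotype) < 3:
        raise ValueError("need >= 3 populations")
    rows = []
    for tf in tf_expression.columns:
        col = tf_expression[tf].to_numpy(dtype=float)
        if np.ptp(col) == 0:
            rows.append({"tf": tf, "n": len(col), "r": np.nan, "p_value": np.nan,
                         "slope": np.nan, "intercept": np.nan})
            continue
        res = pearson_with_regression(col, phenotype, x_name=tf, y_name=phenotype_name)
        rows.append({"tf": tf, "n": res.n, "r": res.r, "p_value": res.p_value,
                     "slope": res.slope, "intercept": res.intercept})
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["q_value"] = np.nan
    if valid.any():
        out.loc[valid, "q_value"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["abs_r"] = out["r"].abs()
    out = out.sort_values("abs_r", ascending=False, na_position="last").drop(columns="abs_r")
    return out.reset_index(drop=True)
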