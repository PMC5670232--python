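"""Shared statistical machinery.

Rank-based tests, Benjamini-Hochberg FDR control, and the mixed-effects
ANOVA contract used by the group analyses. Amplitude data are assumed to be
in dB (10*log10 of an amplitude ratio) wherever a parametric test is applied,
since raw high-frequency broadband amplitudes are approximately log-normal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Parameters
    ----------
    pvals
        Raw p-values in [0, 1].
    alpha
        Target false-discovery rate.

    Returns
    -------
    reject : bool array
    qvals : monotone BH-adjusted q-values
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, qvals, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, qvals


@dataclass
class RankTestResult:
    statistic: float
    z: float
    p: float
    n: int


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None) -> RankTestResult:
    """Two-tailed Wilcoxon signed-rank test (paired or one-sample vs 0).

    Exact null enumeration is used for small samples without ties
    (n <= 25), otherwise the normal approximation with tie correction.
    Zero differences are discarded before testing.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if n < 5:
        raise ValueError("need at least 5 non-zero differences")
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    # signed-rank Z from the normal approximation (reported alongside p)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_plus - mu) / sigma if sigma > 0 else 0.0
    return RankTestResult(statistic=float(res.statistic), z=float(z), p=float(res.pvalue), n=n)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction; chi-square p-value."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # completely tied data carry no rank information
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with tie handling (t-approximation p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class MixedModelSpec:
    """Contract for the group-level mixed model.

    The response is dB amplitude; fixed factors are crossed categorical
    effects (e.g. electrode_group x recalled_category); random intercepts
    for electrode nested in patient: Y ~ X1 * X2 + (1 | patient/electrode).
    """

    response: str
    fixed: Sequence[str]
    patient: str = "patient"
    electrode: str = "electrode"


@dataclass
class AnovaEffect:
    effect: str
    f: float
    df1: float
    df2: float
    p: float


def _anova_from_ols(data: pd.DataFrame, spec: MixedModelSpec) -> list[AnovaEffect]:
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fixed_terms = " * ".join(f"C({f})" for f in spec.fixed)
    fit = smf.ols(f"{spec.response} ~ {fixed_terms}", data=data).fit()
    tab = anova_lm(fit, typ=2)
    out = []
    resid_df = float(tab.loc["Residual", "df"])
    for name, row in tab.iterrows():
        if name == "Residual":
            continue
        out.append(
            AnovaEffect(
                effect=name.replace("C(", "").replace(")", ""),
                f=float(row["F"]),
                df1=float(row["df"]),
                df2=resid_df,
                p=float(row["PR(>F)"]),
            )
        )
    return out


def mixed_anova(
    data: pd.DataFrame, spec: MixedModelSpec, method: str = "mixed"
) -> list[AnovaEffect]:
    """Random-intercept mixed model with Wald F tests per fixed effect.

    Fits Y ~ X1 * X2 [* X3] with random intercepts for patient and for
    electrode nested in patient (REML), then Wald-tests each fixed term.
    ``method="aggregate"`` collapses to per-electrode condition means and
    runs an ordinary crossed ANOVA — a deliberately simpler fallback whose
    accept/reject decisions should agree with the full model.

    The contract targets the direction and significance of effects, not
    exact F replication (degrees of freedom follow the Wald approximation).
    """
    import statsmodels.formula.api as smf

    for col in (*spec.fixed, spec.patient, spec.electrode, spec.response):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data[spec.patient].nunique() == 1 and data[spec.electrode].nunique() == 1:
        raise ValueError("unidentifiable model: single patient and single electrode")

    if method == "aggregate":
        agg = (
            data.groupby([spec.electrode, *spec.fixed], observed=True)[spec.response]
            .mean()
            .reset_index()
        )
        return _anova_from_ols(agg, spec)
    if method != "mixed":
        raise ValueError(f"unknown method {method!r}")

    import warnings

    # sum-to-zero coding so the per-term Wald tests are Type-III-style main
    # effects rather than simple effects at the reference level
    fixed_terms = " * ".join(f"C({f}, Sum)" for f in spec.fixed)
    formula = f"{spec.response} ~ {fixed_terms}"
    vc = {"electrode": f"0 + C({spec.electrode})"}
    model = smf.mixedlm(
        formula, data=data, groups=data[spec.patient], re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings():
        # boundary fits (random-effect variance -> 0) are acceptable here
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)

    # Wald chi2 per term (joint over that term's coefficients), reported as F
    exog_names = fit.model.exog_names
    terms: dict[str, list[int]] = {}
    design_info = fit.model.data.design_info
    for term, slc in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        terms[term] = list(range(slc.start, slc.stop))
    n_params = len(fit.params)  # fixed effects + variance components
    resid_df = max(float(len(data) - len(exog_names)), 1.0)
    out = []
    for term, idx in terms.items():
        contrast = np.zeros((len(idx), n_params))
        for row, j in enumerate(idx):
            contrast[row, j] = 1.0
        wt = fit.wald_test(contrast, scalar=False)
        stat = float(np.atleast_1d(wt.statistic).ravel()[0])
        df1 = float(len(idx))
        f = stat / df1
        p = float(sps.f.sf(f, df1, resid_df))
        out.append(
            AnovaEffect(
                effect=term.replace("C(", "").replace(", Sum", "").replace(")", ""),
                f=f,
                df1=df1,
                df2=resid_df,
                p=p,
            )
        )
    return out
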