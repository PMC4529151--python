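"""Mixed-effects and comparative analyses of study tables.

Measurements repeat within eyes and within subjects (two eyes of one
person are correlated), so all regressions here are linear mixed models
with random intercepts for eye nested in subject, fit with statsmodels
MixedLM. The main analyses are:

* ``fit_icd_rnfl`` — inter-capillary distance (ICD) regressed on RNFL
  thickness with region as a fixed factor;
* ``compare_techniques`` — svOCT vs histology contrasts per region and
  pooled, on log-ICD (log-transformed to attain normality);
* ``compare_arcuate`` — pooled arcuate (ST+IT) vs other-region contrast;
* ``ages_ttest`` — Welch two-sample t-test on group ages.

Estimates are REML by default; p-values are available as Wald z-tests
from the REML fit or likelihood-ratio tests from ML refits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLMParams
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .phantom import ARCUATE_REGIONS

__all__ = [
    "MixedModelFit",
    "fit_icd_rnfl",
    "compare_techniques",
    "compare_arcuate",
    "ages_ttest",
    "plot_icd_rnfl",
]


@dataclass
class MixedModelFit:
    """Summary of one mixed-model fit.

    ``fixed_effects`` maps term name to (estimate, SE, p);
    ``variance_components`` holds the subject, eye-within-subject and
    residual variances.
    """

    fixed_effects: dict = field(default_factory=dict)
    variance_components: dict = field(default_factory=dict)
    n_obs: int = 0
    converged: bool = False
    transform: str = "none"
    p_method: str = "wald"

    def effect(self, name: str) -> tuple[float, float, float]:
        return self.fixed_effects[name]

    @property
    def slope(self) -> float:
        return self.fixed_effects["rnfl_um"][0]

    @property
    def slope_se(self) -> float:
        return self.fixed_effects["rnfl_um"][1]

    @property
    def slope_p(self) -> float:
        return self.fixed_effects["rnfl_um"][2]


def _prepare(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    df["eye_uid"] = df["subject"].astype(str) + ":" + df["eye"].astype(str)
    return df


def _fit_mixed(formula: str, df: pd.DataFrame, reml: bool = True,
               zero_random_effects: bool = False):
    """MixedLM with random intercepts for eye nested in subject.

    With ``zero_random_effects`` both random-intercept variances are
    fixed at zero, which reduces the GLS fit to ordinary least squares
    on the same design.
    """
    model = smf.mixedlm(formula, df, groups=df["subject"], re_formula="1",
                        vc_formula={"eye": "0 + C(eye_uid)"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        if zero_random_effects:
            # variances pinned at a negligible value (an exact zero makes
            # the profiled-covariance solver singular); the GLS fit then
            # coincides with OLS on the same design
            k_fe, k_re, k_vc = model.k_fe, model.k_re, model.k_vc
            eps = 1e-8
            free = MixedLMParams.from_components(
                fe_params=np.ones(k_fe), cov_re=np.zeros((k_re, k_re)),
                vcomp=np.zeros(k_vc))
            start = MixedLMParams.from_components(
                fe_params=np.zeros(k_fe), cov_re=eps * np.eye(k_re),
                vcomp=eps * np.ones(k_vc))
            res = model.fit(free=free, start_params=start, reml=reml)
        else:
            res = model.fit(reml=reml)
    return model, res


def _lrt_pvalue(formula_full: str, formula_reduced: str,
                df: pd.DataFrame, df_diff: int = 1) -> float:
    """Likelihood-ratio p-value comparing nested fixed-effect
    structures, from ML (not REML) refits."""
    _, full = _fit_mixed(formula_full, df, reml=False)
    _, red = _fit_mixed(formula_reduced, df, reml=False)
    lr = 2.0 * (full.llf - red.llf)
    return float(sps.chi2.sf(max(lr, 0.0), df_diff))


def _collect_fit(res, p_method: str, transform: str,
                 lrt_p: dict | None = None) -> MixedModelFit:
    fe = {}
    # estimates that vanish relative to the response scale (degenerate
    # zero-residual fits) are exact nulls: z = 0, p = 1
    zero_tol = 1e-10 * (float(np.std(res.model.endog)) + 1e-30)
    for name in res.fe_params.index:
        est = float(res.fe_params[name])
        se = float(res.bse_fe[name]) if name in res.bse_fe else math.nan
        if lrt_p and name in lrt_p:
            p = lrt_p[name]
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                if abs(est) <= zero_tol:
                    z = 0.0
                elif se > 0:
                    z = est / se
                else:
                    z = math.inf
            p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else 0.0
            p = max(min(p, 1.0), np.nextafter(0, 1))
        fe[name] = (est, se, p)
    vc = {
        "subject": float(np.squeeze(res.cov_re)) if res.cov_re.size else 0.0,
        "eye": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        "residual": float(res.scale),
    }
    return MixedModelFit(fixed_effects=fe, variance_components=vc,
                         n_obs=int(res.nobs), converged=bool(res.converged),
                         transform=transform, p_method=p_method)


def fit_icd_rnfl(records: pd.DataFrame, transform: str = "none",
                 p_method: str = "wald",
                 zero_random_effects: bool = False) -> MixedModelFit:
    """ICD regressed on RNFL thickness with region as fixed factor.

    Response is ICD (optionally log-transformed); fixed effects are
    RNFL thickness and region; random intercepts for eye nested in
    subject. The slope of interest is the ``rnfl_um`` coefficient.
    ``p_method``: "wald" (z-test on the REML fit) or "lrt"
    (likelihood-ratio ML refit for the RNFL slope).
    """
    if transform not in ("none", "log"):
        raise ValueError("transform must be 'none' or 'log'")
    df = _prepare(records)
    if "technique" in df.columns:
        df = df[df["technique"] == "svOCT"]
    df = df.dropna(subset=["rnfl_um", "icd_um"])
    if df["subject"].nunique() < 2 or df["region"].nunique() < 2:
        raise ValueError("need at least 2 subjects and 2 regions")
    df["y"] = np.log(df["icd_um"]) if transform == "log" else df["icd_um"]
    formula = "y ~ rnfl_um + C(region)"
    _, res = _fit_mixed(formula, df, reml=True,
                        zero_random_effects=zero_random_effects)
    lrt_p = None
    if p_method == "lrt":
        lrt_p = {"rnfl_um": _lrt_pvalue(formula, "y ~ C(region)", df)}
    elif p_method != "wald":
        raise ValueError("p_method must be 'wald' or 'lrt'")
    fit = _collect_fit(res, p_method, transform, lrt_p)
    if not fit.converged:
        warnings.warn("mixed model did not fully converge; estimates are "
                      "reported with converged=False", stacklevel=2)
    return fit


def compare_techniques(records: pd.DataFrame, response: str = "icd_um",
                       by_region: bool = True, include_region: bool = True,
                       p_method: str = "wald") -> pd.DataFrame:
    """svOCT vs histology contrasts (mixed model, technique factor).

    ICD responses are log-transformed before testing. Returns a table
    with one pooled row and, if ``by_region``, one row per region
    (subset fits without the region factor); regions observed under a
    single technique are skipped with a note.
    """
    df = _prepare(records).dropna(subset=[response])
    if df["technique"].nunique() < 2:
        raise ValueError("both techniques must be present")
    log_it = response == "icd_um"
    df["y"] = np.log(df[response]) if log_it else df[response]
    tech_term = [c for c in ("C(technique)[T.svOCT]",)][0]

    def _one(sub: pd.DataFrame, formula: str, reduced: str) -> dict:
        _, res = _fit_mixed(formula, sub)
        lrt_p = None
        if p_method == "lrt":
            lrt_p = {tech_term: _lrt_pvalue(formula, reduced, sub)}
        fit = _collect_fit(res, p_method, "log" if log_it else "none", lrt_p)
        est, se, p = fit.fixed_effects[tech_term]
        return {"estimate": est, "se": se, "p": p, "n": fit.n_obs,
                "converged": fit.converged}

    rows = []
    pooled_formula = ("y ~ C(technique) + C(region)" if include_region
                      else "y ~ C(technique)")
    pooled_reduced = "y ~ C(region)" if include_region else "y ~ 1"
    rows.append({"region": "pooled", "note": "",
                 **_one(df, pooled_formula, pooled_reduced)})
    if by_region:
        for region in df["region"].unique():
            sub = df[df["region"] == region]
            if sub["technique"].nunique() < 2:
                rows.append({"region": region, "estimate": math.nan,
                             "se": math.nan, "p": math.nan, "n": len(sub),
                             "converged": False,
                             "note": "single technique only; skipped"})
                continue
            rows.append({"region": region, "note": "",
                         **_one(sub, "y ~ C(technique)", "y ~ 1")})
    return pd.DataFrame(rows)


def compare_arcuate(records: pd.DataFrame, response: str = "icd_um",
                    technique: str = "svOCT",
                    p_method: str = "wald") -> tuple[float, float]:
    """Pooled arcuate (ST, IT) vs other-region contrast.

    Mixed model of the (log-transformed, for ICD) response on a binary
    arcuate indicator; returns (estimate, p) of the arcuate effect — a
    negative ICD estimate means denser arcuate beds.
    """
    df = _prepare(records)
    if "technique" in df.columns:
        df = df[df["technique"] == technique]
    df = df.dropna(subset=[response]).copy()
    missing = set(ARCUATE_REGIONS) - set(df["region"])
    if missing:
        raise ValueError(f"arcuate regions missing from table: {missing}")
    df["y"] = np.log(df[response]) if response == "icd_um" else df[response]
    df["arcuate"] = df["region"].isin(ARCUATE_REGIONS).astype(int)
    formula = "y ~ arcuate"
    _, res = _fit_mixed(formula, df)
    lrt_p = None
    if p_method == "lrt":
        lrt_p = {"arcuate": _lrt_pvalue(formula, "y ~ 1", df)}
    fit = _collect_fit(res, p_method, "log", lrt_p)
    est, _, p = fit.fixed_effects["arcuate"]
    return est, p


def ages_ttest(group_a, group_b) -> dict:
    """Welch two-sample t-test on ages; returns t, p and group
    mean ± SD summaries."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 ages per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=False)
        if math.isnan(p):
            p = 1.0
    return {
        "t": float(t), "p": float(p),
        "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1)),
        "summary": (f"{a.mean():.1f} ± {a.std(ddof=1):.1f} vs "
                    f"{b.mean():.1f} ± {b.std(ddof=1):.1f} (P = {p:.3f})"),
    }


def plot_icd_rnfl(records: pd.DataFrame, path=None):
    """Region-colored scatter of ICD against RNFL thickness."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records.dropna(subset=["rnfl_um", "icd_um"])
    fig, ax = plt.subplots(figsize=(6, 4.5))
    for region, sub in df.groupby("region"):
        ax.scatter(sub["rnfl_um"], sub["icd_um"], s=18, label=region)
    ax.set_xlabel("RNFL thickness (μm)")
    ax.set_ylabel("ICD (μm)")
    ax.legend(title="region", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
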