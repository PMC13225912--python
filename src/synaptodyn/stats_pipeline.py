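"""Binned mixed-effects statistics and the distributional tests of the pipeline.

Time-lapse track measurements are serially correlated, so per-frame rows
would wildly overstate the effective sample size.  The pipeline therefore
(1) picks a bin width as the smallest round-number candidate at which the
lag-1 autocorrelation of the binned control-arm mean series drops below 0.3,
(2) averages each track's response within bins, and (3) fits a linear
mixed-effects model with treatment, time (minutes) and optional track
covariates as fixed effects (all interactions up to three-way) and random
intercepts for image and for track nested in image.  The headline statistic
is the time x treatment interaction: a treatment-dependent change in the
response *rate*.  Significant interactions are followed up on quintile
subsets of a baseline metric; auxiliary stages cover fold-increase
flagging, per-group slope (ANCOVA) comparison and the standard two-sample
tests (KS, binned chi-square, Fisher, Mann-Whitney).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

#: candidate bin widths in frames; round numbers in minutes at a 15 s interval
DEFAULT_BIN_CANDIDATES = (1, 2, 4, 8, 12, 20, 40)


# ---------------------------------------------------------------------------
# Bin-size selection
# ---------------------------------------------------------------------------

def _lag1_acf(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        return 1.0
    a, b = x[:-1], x[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0  # constant series: treat as perfectly correlated
    return float(np.corrcoef(a, b)[0, 1])


def binned_mean(series: np.ndarray, width: int) -> np.ndarray:
    """Block-average a series into consecutive ``width``-frame bins (remainder dropped)."""
    series = np.asarray(series, dtype=float)
    nb = len(series) // width
    return series[: nb * width].reshape(nb, width).mean(axis=1)


def select_bin_size(
    control_mean_series: np.ndarray,
    threshold: float = 0.3,
    candidates: Sequence[int] = DEFAULT_BIN_CANDIDATES,
    return_acf: bool = False,
):
    """Smallest candidate bin width whose binned lag-1 autocorrelation is below threshold.

    Computed on the control-condition across-track mean series; if no
    candidate qualifies the largest is returned with a warning.  Degenerate
    (constant or too-short) binned series count as autocorrelation 1.
    """
    series = np.asarray(control_mean_series, dtype=float)
    candidates = sorted(int(c) for c in candidates)
    if len(series) < 3 * max(candidates):
        raise ValueError(
            f"series length {len(series)} < 3 x largest candidate {max(candidates)}"
        )
    acfs = {}
    chosen = None
    for w in candidates:
        acfs[w] = _lag1_acf(binned_mean(series, w))
        if chosen is None and acfs[w] < threshold:
            chosen = w
    if chosen is None:
        chosen = candidates[-1]
        warnings.warn(
            f"no candidate bin width reached lag-1 ACF < {threshold}; using largest ({chosen})",
            stacklevel=2,
        )
    return (chosen, acfs) if return_acf else chosen


# ---------------------------------------------------------------------------
# Binned long table
# ---------------------------------------------------------------------------

def make_binned_table(
    long_df: pd.DataFrame,
    bin_frames: int,
    frame_interval_s: float,
    response: str,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Average a per-frame long table within (track, bin) cells.

    ``long_df`` needs columns ``image_id, track_id, treatment, frame`` plus
    the response and covariates.  Binning is within-track first; ``time_min``
    is the bin midpoint in minutes.
    """
    df = long_df.copy()
    df["bin_index"] = df["frame"] // bin_frames
    keys = ["image_id", "track_id", "treatment", "bin_index"]
    agg = {response: "mean", **{c: "mean" for c in covariates}}
    out = df.groupby(keys, as_index=False, observed=True).agg(agg)
    out["time_min"] = (out["bin_index"] + 0.5) * bin_frames * frame_interval_s / 60.0
    return out


# ---------------------------------------------------------------------------
# Mixed-effects model
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """Fitted treatment x time mixed model with image- and track-level intercepts."""

    fixed_effects: pd.DataFrame  # index: term; columns: coef, se, z, p
    interaction_term: str
    interaction_coef: float
    interaction_se: float
    interaction_stat: float
    interaction_p: float
    random_variances: Dict[str, float]
    llf: float
    aic: float
    bic: float
    converged: bool
    fallback_image_only: bool = False


def _interaction_formula(covariates: Sequence[str]) -> str:
    terms = ["treatment", "time_min", *covariates]
    order = min(3, len(terms))
    return "(" + " + ".join(terms) + f") ** {order}"


def fit_treatment_time_lme(
    table: pd.DataFrame,
    response: str,
    covariates: Sequence[str] = (),
    reml: bool = True,
) -> LMEFit:
    """Fit ``response ~ treatment * time (* covariates)`` with nested random intercepts.

    Random intercepts: image, and track within image (variance component).
    The headline time x treatment interaction is reported with its Wald
    z-test.  A singular or non-converging nested structure triggers a
    flagged refit with the image-level intercept only; a response with zero
    variance short-circuits to an all-zero fit.
    """
    data = table.copy()
    data["track_id"] = data["track_id"].astype(str)
    if data.groupby("treatment")["image_id"].nunique().min() < 2:
        raise ValueError("need >= 2 images per treatment arm")
    formula = f"{response} ~ {_interaction_formula(covariates)}"

    if np.allclose(np.var(data[response].to_numpy(float)), 0.0):
        # degenerate: identical response everywhere
        md = smf.ols(formula, data=data).fit()
        fe = pd.DataFrame({"coef": 0.0, "se": 0.0, "z": 0.0, "p": 1.0},
                          index=md.params.index)
        term = _find_interaction_term(md.params.index)
        return LMEFit(fe, term, 0.0, 0.0, 0.0, 1.0, {"image": 0.0, "track": 0.0},
                      llf=np.nan, aic=np.nan, bic=np.nan, converged=True)

    def _fit(nested: bool, method: str):
        kwargs = dict(groups=data["image_id"], re_formula="1")
        if nested:
            kwargs["vc_formula"] = {"track": "0 + C(track_id)"}
        md = smf.mixedlm(formula, data, **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=reml, method=method, maxiter=300)
        if not res.converged:
            raise np.linalg.LinAlgError("optimizer did not converge")
        return res

    fallback = False
    res = None
    for nested, method in ((True, "lbfgs"), (True, "powell"), (False, "powell")):
        try:
            res = _fit(nested, method)
            fallback = not nested
            break
        except (np.linalg.LinAlgError, ValueError):
            continue
    if res is None:
        logger.info("all mixed-model fits failed to converge; OLS fallback")
        res = _fit(False, "powell")  # let the exception propagate if even this fails
    if fallback:
        logger.info("nested random-effects fit failed; image-level intercept only")

    term = _find_interaction_term(res.fe_params.index)
    fe = pd.DataFrame(
        {
            "coef": res.fe_params,
            "se": res.bse_fe,
            "z": res.fe_params / res.bse_fe,
            "p": res.pvalues[res.fe_params.index],
        }
    )
    rv = {"image": float(np.asarray(res.cov_re).ravel()[0]) if res.cov_re.size else 0.0}
    rv["track"] = float(res.vcomp[0]) if (not fallback and len(res.vcomp)) else 0.0
    k = len(res.params) + 1  # fixed effects + variance parameters + residual
    nobs = res.nobs
    aic = -2 * res.llf + 2 * k
    bic = -2 * res.llf + np.log(nobs) * k
    z = float(fe.loc[term, "z"])
    return LMEFit(
        fixed_effects=fe,
        interaction_term=term,
        interaction_coef=float(fe.loc[term, "coef"]),
        interaction_se=float(fe.loc[term, "se"]),
        interaction_stat=z,
        interaction_p=float(fe.loc[term, "p"]),
        random_variances=rv,
        llf=float(res.llf),
        aic=float(aic),
        bic=float(bic),
        converged=bool(res.converged),
        fallback_image_only=fallback,
    )


def _find_interaction_term(index: Iterable[str]) -> str:
    for name in index:
        parts = name.split(":")
        if len(parts) == 2 and any("treatment" in p for p in parts) and "time_min" in parts:
            return name
    raise KeyError("treatment x time interaction term not found in design")


# ---------------------------------------------------------------------------
# Follow-up stages
# ---------------------------------------------------------------------------

def quintile_subsets(features: pd.DataFrame, baseline_metric: str) -> List[np.ndarray]:
    """Split tracks into 5 near-equal groups ranked by a baseline metric.

    Returns track-id arrays from bottom (lowest baseline) to top quintile;
    ties broken by track id so the split is deterministic.
    """
    if len(features) < 5:
        raise ValueError("need at least 5 tracks to form quintiles")
    ranked = features.sort_values([baseline_metric, "track_id"], kind="stable")
    ids = ranked["track_id"].to_numpy()
    return list(np.array_split(ids, 5))


def flag_fold_increase(
    normalized_series: Mapping, fold: float = 1.5
) -> List:
    """Track ids whose baseline-normalized series peaks at >= ``fold`` (default 1.5)."""
    return [tid for tid, s in normalized_series.items()
            if np.isfinite(s).any() and np.nanmax(s) >= fold]


@dataclass
class SlopeComparison:
    """Per-group least-squares slopes and the homogeneity-of-slopes (ANCOVA) test."""

    slopes: Dict[str, float]
    conf_ints: Dict[str, Tuple[float, float]]
    interaction_stat: float  # F statistic of the group x x interaction
    interaction_p: float
    df: Tuple[int, int]


def compare_slopes(
    x: np.ndarray, y: np.ndarray, group: np.ndarray
) -> SlopeComparison:
    """Compare regression slopes of ``y`` on ``x`` between two (or more) groups.

    Fits per-group OLS for the slopes and 95% CIs, and tests slope equality
    with the interaction F-test of ``y ~ x * group`` (classic ANCOVA
    homogeneity of slopes).
    """
    df = pd.DataFrame({"x": np.asarray(x, float), "y": np.asarray(y, float),
                       "group": np.asarray(group)})
    slopes, cis = {}, {}
    for g, sub in df.groupby("group"):
        if len(sub) < 3:
            raise ValueError(f"group {g!r}: need >= 3 points")
        if np.var(sub["x"].to_numpy()) == 0:
            raise ValueError(f"group {g!r}: degenerate x variance")
        fit = smf.ols("y ~ x", data=sub).fit()
        slopes[g] = float(fit.params["x"])
        ci = fit.conf_int().loc["x"]
        cis[g] = (float(ci[0]), float(ci[1]))
    full = smf.ols("y ~ x * C(group)", data=df).fit()
    reduced = smf.ols("y ~ x + C(group)", data=df).fit()
    ftest = full.compare_f_test(reduced)
    stat, p = float(ftest[0]), float(ftest[1])
    tss = float(np.sum((df["y"] - df["y"].mean()) ** 2))
    if not np.isfinite(stat) or reduced.ssr <= 1e-12 * max(tss, 1e-300):
        # the common-slope model already fits to numerical precision
        stat, p = 0.0, 1.0
    return SlopeComparison(
        slopes=slopes,
        conf_ints=cis,
        interaction_stat=stat,
        interaction_p=p,
        df=(int(ftest[2]), int(full.df_resid)),
    )


# ---------------------------------------------------------------------------
# Distribution tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    statistic: float
    pvalue: float
    kind: str


def distribution_tests(samples_a, samples_b, kind: str, n_bins: int = 10) -> TestResult:
    """Two-sample comparison stages: ``ks``, ``chi2_binned``, ``fisher``, ``mannwhitney``.

    ``ks``/``mannwhitney`` take raw samples; ``chi2_binned`` histograms both
    samples on shared bins over the pooled range before a contingency
    chi-square; ``fisher`` takes ``(successes, failures)`` count pairs.
    """
    if kind == "fisher":
        table = np.array([samples_a, samples_b], dtype=int)
        stat, p = sps.fisher_exact(table)
        return TestResult(float(stat), float(p), kind)
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample group")
    if kind == "ks":
        r = sps.ks_2samp(a, b)
        return TestResult(float(r.statistic), float(r.pvalue), kind)
    if kind == "mannwhitney":
        r = sps.mannwhitneyu(a, b, alternative="two-sided")
        return TestResult(float(r.statistic), float(r.pvalue), kind)
    if kind == "chi2_binned":
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        edges = np.linspace(lo, hi, n_bins + 1)
        ha, _ = np.histogram(a, bins=edges)
        hb, _ = np.histogram(b, bins=edges)
        table = np.array([ha, hb])
        table = table[:, table.sum(axis=0) > 0]
        r = sps.chi2_contingency(table)
        return TestResult(float(r.statistic), float(r.pvalue), kind)
    raise ValueError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# Optional outlier flag (not the proprietary ROUT procedure)
# ---------------------------------------------------------------------------

def mad_outlier_flag(values: np.ndarray, n_mad: float = 5.0) -> np.ndarray:
    """Boolean flag for values > ``n_mad`` median absolute deviations from the median.

    A simple robust screen, off by default in the pipeline; it is *not*
    equivalent to regression-based outlier removal used in some analysis
    suites and is provided only as an optional diagnostic.
    """
    v = np.asarray(values, dtype=float)
    med = np.nanmedian(v)
    mad = np.nanmedian(np.abs(v - med))
    if mad == 0:
        return np.zeros(len(v), dtype=bool)
    return np.abs(v - med) > n_mad * mad
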