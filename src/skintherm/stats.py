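"""Statistical layer: effect sizes, t-tests, and random-intercept mixed models.

Analyses mirror a repeated-measures cooling study: per-image median
temperatures are averaged within subject, paired/one-sample t-tests with
Cohen's d summarize the cooling response, and linear mixed-effects models
with a per-subject random intercept estimate the fixed effects of phase
(baseline vs cooled), camera, distance, posture, lighting, and melanin,
including phase interactions.

Mixed models are fitted by REML (statsmodels ``MixedLM``); denominator
degrees of freedom for the fixed-effect t-tests use Satterthwaite's
approximation, computed here from the closed-form REML likelihood of the
random-intercept model (variance of the variance components from the
numerical REML Hessian; gradient of each coefficient's sampling variance by
central differences). When the approximation is unavailable (e.g. a singular
fit with the intercept variance on the boundary) the residual-df fallback
``n_obs - rank(X)`` is used and a note is logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .colorimetry import CATEGORY_WIDTH_UNITS

__all__ = [
    "EffectSizeResult",
    "FixedEffectEstimate",
    "subject_average",
    "differential_outcome",
    "one_sample_test",
    "paired_test",
    "ThermalMixedModel",
    "ThermalMixedResults",
    "fit_lmm",
    "skin_tone_report",
]

logger = logging.getLogger(__name__)

#: Cohen's d qualitative bands: small / medium / large cutpoints.
D_BANDS = (0.2, 0.5, 0.8)

REFERENCE_LEVELS = {
    "phase": "baseline",
    "camera": "E8XT",
    "distance": 35,
    "posture": "stacked",
    "lighting": "room",
}


def d_band(d: float) -> str:
    a = abs(d)
    if a < D_BANDS[0]:
        return "negligible"
    if a < D_BANDS[1]:
        return "small"
    if a < D_BANDS[2]:
        return "medium"
    return "large"


@dataclass(frozen=True)
class EffectSizeResult:
    """t-test summary with Cohen's d.

    ``d`` standardizes by the SD of the (paired) differences; for paired
    comparisons ``d_pooled`` additionally standardizes by the pooled SD of
    the two measurement sets. ``degenerate`` flags a zero-variance input.
    """

    mean_diff: float
    sd_diff: float
    n: int
    t: float
    df: float
    p: float
    d: float
    d_pooled: float | None = None
    degenerate: bool = False

    @property
    def band(self) -> str:
        return d_band(self.d)

    def summary(self) -> str:
        lines = [
            f"mean difference = {self.mean_diff:+.3f} °C (SD {self.sd_diff:.3f}, n={self.n})",
            f"t = {self.t:.2f}, df = {self.df:.0f}, p = {self.p:.3g}",
            f"Cohen's d = {self.d:.2f} ({self.band})",
        ]
        if self.d_pooled is not None:
            lines.append(f"Cohen's d (pooled SD) = {self.d_pooled:.2f}")
        if self.degenerate:
            lines.append("warning: zero-variance differences; t/d undefined")
        return "\n".join(lines)


@dataclass(frozen=True)
class FixedEffectEstimate:
    term: str
    coef: float
    se: float
    df: float
    p: float

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        half = sps.t.ppf(1 - alpha / 2, self.df) * self.se
        return self.coef - half, self.coef + half


# --------------------------------------------------------------------------
# aggregation and t-tests

def subject_average(
    records: pd.DataFrame,
    factors: Sequence[str] = (),
    value_col: str = "median_temp_C",
) -> pd.DataFrame:
    """Within-subject arithmetic means of per-image medians.

    Averages ``value_col`` within subject x phase x region (and any extra
    ``factors``). Input rows follow the measurement-record schema.
    """
    keys = ["subject_id", "phase", "region", *factors]
    missing = set(keys + [value_col]) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    return (records.groupby(keys, observed=True)[value_col]
            .mean().reset_index())


def differential_outcome(records: pd.DataFrame,
                         value_col: str = "median_temp_C") -> pd.DataFrame:
    """Per-image ROI-minus-control difference table.

    Returns one row per image with ``diff_C = roi - control`` alongside the
    image's factor levels.
    """
    wide = records.pivot_table(index="image_id", columns="region",
                               values=value_col, aggfunc="first")
    if not {"roi", "control"} <= set(wide.columns):
        raise ValueError("records must contain both 'roi' and 'control' regions")
    meta_cols = [c for c in records.columns
                 if c not in (value_col, "region")]
    meta = records[meta_cols].drop_duplicates("image_id").set_index("image_id")
    out = meta.join((wide["roi"] - wide["control"]).rename("diff_C"), how="inner")
    return out.reset_index()


def _complete_pairs(a: pd.Series, b: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([a.rename("a"), b.rename("b")], axis=1)
    incomplete = joined.index[joined.isna().any(axis=1)]
    if len(incomplete):
        logger.warning("excluding %d subject(s) with missing cells: %s",
                       len(incomplete), list(incomplete))
        joined = joined.dropna()
    return joined["a"].to_numpy(), joined["b"].to_numpy()


def one_sample_test(deltas, popmean: float = 0.0) -> EffectSizeResult:
    """One-sample t-test of per-subject differences against ``popmean``.

    Cohen's d is the mean delta divided by the SD of the deltas.
    """
    x = np.asarray(deltas, dtype=float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 3:
        raise ValueError(f"need >= 3 finite deltas, got {n}")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in deltas; t and d are undefined")
    mean = float(np.mean(x))
    t, p = sps.ttest_1samp(x, popmean)
    return EffectSizeResult(mean_diff=mean - popmean, sd_diff=sd, n=n,
                            t=float(t), df=n - 1, p=float(p),
                            d=(mean - popmean) / sd)


def paired_test(roi_means, control_means) -> EffectSizeResult:
    """Paired t-test of ROI vs control per-subject means.

    Reports Cohen's d under both conventions: SD of the paired differences
    (``d``) and pooled SD of the two measurement sets (``d_pooled``). A
    zero-variance difference vector is flagged, not raised, so an exact
    offset between regions still reports its mean difference.
    """
    if isinstance(roi_means, pd.Series) and isinstance(control_means, pd.Series):
        a, b = _complete_pairs(roi_means, control_means)
    else:
        a = np.asarray(roi_means, dtype=float)
        b = np.asarray(control_means, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(a)
    if n < 3:
        raise ValueError(f"need >= 3 pairs, got {n}")
    diff = a - b
    mean = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    pooled = float(np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0))
    if sd <= 1e-10 * max(1.0, abs(mean)):  # constant differences
        if abs(mean) <= 1e-12:  # identical vectors: no difference at all
            return EffectSizeResult(mean_diff=0.0, sd_diff=0.0, n=n, t=0.0,
                                    df=n - 1, p=1.0, d=0.0, d_pooled=0.0,
                                    degenerate=True)
        logger.warning("paired differences have zero variance; flagging result")
        return EffectSizeResult(mean_diff=mean, sd_diff=0.0, n=n, t=np.nan,
                                df=n - 1, p=np.nan, d=np.nan,
                                d_pooled=(mean / pooled if pooled > 0 else np.nan),
                                degenerate=True)
    t, p = sps.ttest_rel(a, b)
    return EffectSizeResult(mean_diff=mean, sd_diff=sd, n=n, t=float(t),
                            df=n - 1, p=float(p), d=mean / sd,
                            d_pooled=(mean / pooled if pooled > 0 else np.nan))


# --------------------------------------------------------------------------
# random-intercept REML machinery (Satterthwaite df)

class _RandomInterceptREML:
    """Closed-form REML quantities for y = X b + Z u + e, u ~ subject intercepts."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        order = np.argsort(groups, kind="stable")
        self.X = X[order]
        self.y = y[order]
        g = np.asarray(groups)[order]
        _, counts = np.unique(g, return_counts=True)
        self.slices = []
        start = 0
        for c in counts:
            self.slices.append(slice(start, start + c))
            start += c
        self.n, self.p = X.shape

    def _blocks(self, s2e: float, s2b: float):
        """Per-group V^-1 via Sherman-Morrison; yields (Xg, yg, Vinv applied)."""
        for sl in self.slices:
            Xg, yg = self.X[sl], self.y[sl]
            ng = Xg.shape[0]
            lam = s2b / (s2e * (s2e + ng * s2b))
            yield Xg, yg, ng, lam

    def fixed_info(self, s2e: float, s2b: float) -> np.ndarray:
        """X' V^-1 X (the GLS information for the fixed effects)."""
        info = np.zeros((self.p, self.p))
        for Xg, _, ng, lam in self._blocks(s2e, s2b):
            sX = Xg.sum(axis=0)
            info += Xg.T @ Xg / s2e - lam * np.outer(sX, sX)
        return info

    def coef_cov(self, s2e: float, s2b: float) -> np.ndarray:
        return np.linalg.inv(self.fixed_info(s2e, s2b))

    def reml_loglike(self, s2e: float, s2b: float) -> float:
        if s2e <= 0 or s2b < 0:
            return -np.inf
        info = np.zeros((self.p, self.p))
        xvy = np.zeros(self.p)
        yvy = 0.0
        logdet_v = 0.0
        for Xg, yg, ng, lam in self._blocks(s2e, s2b):
            sX, sy = Xg.sum(axis=0), yg.sum()
            info += Xg.T @ Xg / s2e - lam * np.outer(sX, sX)
            xvy += Xg.T @ yg / s2e - lam * sX * sy
            yvy += yg @ yg / s2e - lam * sy * sy
            logdet_v += (ng - 1) * np.log(s2e) + np.log(s2e + ng * s2b)
        sign, logdet_i = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(info, xvy)
        rss = yvy - beta @ xvy
        return -0.5 * (logdet_v + logdet_i + rss)

    def satterthwaite_df(self, s2e: float, s2b: float,
                         contrasts: Iterable[np.ndarray]) -> list[float]:
        """df_c = 2 v_c^2 / (g_c' A g_c) per contrast c.

        v_c(theta) = c' (X'V^-1 X)^-1 c; A is the asymptotic covariance of
        the REML variance components from the numerical Hessian. Raises
        LinAlgError/ValueError when the Hessian is not usable (boundary fit).
        """
        theta = np.array([s2e, s2b], dtype=float)
        h = np.maximum(1e-7, 1e-4 * np.maximum(theta, s2e))

        def ll(t):
            # clamp at the parameter-space boundary so finite differences
            # stay defined; boundary fits use the residual-df fallback anyway
            return self.reml_loglike(max(t[0], 1e-12), max(t[1], 0.0))

        H = np.zeros((2, 2))
        f0 = ll(theta)
        if not np.isfinite(f0):
            raise ValueError("REML loglike not finite at the estimate")
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                if i == j:
                    val = (ll(theta + ei) - 2 * f0 + ll(theta - ei)) / h[i] ** 2
                else:
                    val = (ll(theta + ei + ej) - ll(theta + ei - ej)
                           - ll(theta - ei + ej) + ll(theta - ei - ej)) / (4 * h[i] * h[j])
                H[i, j] = H[j, i] = val
        if not np.all(np.isfinite(H)):
            raise ValueError("REML Hessian not finite at the estimate")
        A = np.linalg.inv(-H)
        if not np.all(np.isfinite(A)):
            raise ValueError("variance-component covariance not finite")

        dfs = []
        cov0 = self.coef_cov(s2e, s2b)
        for c in contrasts:
            grad = np.zeros(2)
            for i in range(2):
                ei = np.eye(2)[i] * h[i]
                vp = c @ self.coef_cov(*(theta + ei)) @ c
                vm = c @ self.coef_cov(*np.maximum(theta - ei, [1e-12, 0.0])) @ c
                grad[i] = (vp - vm) / (2 * h[i])
            v = c @ cov0 @ c
            denom = grad @ A @ grad
            if denom <= 0 or not np.isfinite(denom):
                raise ValueError("non-positive Satterthwaite denominator")
            dfs.append(2.0 * v ** 2 / denom)
        return dfs


# --------------------------------------------------------------------------
# model / results objects

_TERM_BUILDERS = {
    "phase": lambda d: {"phase[cooled]": (d["phase"] == "cooled").astype(float)},
    "camera": lambda d: {"camera[ONEPro]": (d["camera"] == "ONEPro").astype(float)},
    "distance": lambda d: {"distance[50]": (d["distance_cm"] == 50).astype(float)},
    "posture": lambda d: {
        "posture[knee_forward]": (d["posture"] == "knee_forward").astype(float),
        "posture[knee_behind]": (d["posture"] == "knee_behind").astype(float),
    },
    "lighting": lambda d: {"lighting[ring]": (d["lighting"] == "ring").astype(float)},
}


class ThermalMixedModel:
    """Random-intercept linear mixed model for thermal measurements.

    Parameters
    ----------
    data : DataFrame
        Modeling frame with one outcome row per image (see
        :meth:`from_measurements`).
    outcome : {"absolute", "differential"}
        Absolute ROI median temperature, or the ROI-minus-control difference
        (the clinically relevant metric; additive camera offsets cancel).
    fixed_terms : sequence of str
        Any of phase, camera, distance, posture, lighting, melanin and the
        interactions phase:camera, phase:distance, phase:melanin.
    melanin_centered : bool
        Center the converted melanin covariate at the cohort mean before
        forming its interaction. Off by default, matching the convention of
        reporting the cooling main effect at melanin zero.
    """

    def __init__(self, data: pd.DataFrame, outcome_col: str,
                 fixed_terms: Sequence[str], outcome_label: str = "absolute",
                 melanin_centered: bool = False):
        self.data = data.reset_index(drop=True)
        self.outcome_col = outcome_col
        self.outcome_label = outcome_label
        self.fixed_terms = tuple(fixed_terms)
        self.melanin_centered = melanin_centered
        if self.data["subject_id"].nunique() < 2:
            raise ValueError("need >= 2 subjects for a random-intercept model")
        self.exog = self._build_design(self.data)
        self.endog = self.data[outcome_col].astype(float)
        self.groups = self.data["subject_id"].to_numpy()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_measurements(cls, records: pd.DataFrame,
                          outcome: str = "absolute",
                          fixed_terms: Sequence[str] = ("phase", "camera", "phase:camera"),
                          melanin_centered: bool = False) -> "ThermalMixedModel":
        """Build the model from the long measurement-record table."""
        if outcome == "absolute":
            data = records[records["region"] == "roi"].copy()
            col = "median_temp_C"
        elif outcome == "differential":
            data = differential_outcome(records)
            col = "diff_C"
        else:
            raise ValueError(f"unknown outcome: {outcome!r}")
        return cls(data, col, fixed_terms, outcome_label=outcome,
                   melanin_centered=melanin_centered)

    def _melanin_column(self, d: pd.DataFrame) -> pd.Series:
        mel = d["melanin_converted"].astype(float)
        if self.melanin_centered:
            per_subject = d.groupby("subject_id")["melanin_converted"].first()
            mel = mel - per_subject.mean()
        return mel

    def _build_design(self, d: pd.DataFrame) -> pd.DataFrame:
        cols: dict[str, pd.Series] = {"Intercept": pd.Series(1.0, index=d.index)}
        mains = [t for t in self.fixed_terms if ":" not in t]
        inters = [t for t in self.fixed_terms if ":" in t]
        for term in mains:
            if term == "melanin":
                cols["melanin"] = self._melanin_column(d)
            elif term in _TERM_BUILDERS:
                cols.update(_TERM_BUILDERS[term](d))
            else:
                raise ValueError(f"unknown fixed term: {term!r}")
        for term in inters:
            left, right = term.split(":")
            if left != "phase":
                raise ValueError(f"unsupported interaction: {term!r}")
            phase = (d["phase"] == "cooled").astype(float)
            if right == "melanin":
                cols["phase[cooled]:melanin"] = phase * self._melanin_column(d)
            elif right in ("camera", "distance"):
                for name, series in _TERM_BUILDERS[right](d).items():
                    cols[f"phase[cooled]:{name}"] = phase * series
            else:
                raise ValueError(f"unsupported interaction: {term!r}")
        X = pd.DataFrame(cols)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design matrix is rank deficient for these data")
        return X

    # -- fitting ----------------------------------------------------------
    def fit(self, reml: bool = True) -> "ThermalMixedResults":
        md = sm.MixedLM(self.endog.to_numpy(), self.exog.to_numpy(),
                        groups=self.groups)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            smres = md.fit(reml=reml)
        notes = [str(wi.message) for wi in caught]

        s2e = float(smres.scale)
        s2b = float(np.asarray(smres.cov_re)[0, 0])
        singular = s2b < 1e-8 * max(s2e, 1e-12)
        if singular:
            notes.append(
                f"random-intercept variance at boundary (sigma_b^2={s2b:.3g}); "
                "fit is singular")

        engine = _RandomInterceptREML(self.exog.to_numpy(), self.endog.to_numpy(),
                                      self.groups)
        p = self.exog.shape[1]
        contrasts = list(np.eye(p))
        df_method = "satterthwaite"
        try:
            if singular:
                raise ValueError("boundary fit")
            dfs = engine.satterthwaite_df(s2e, s2b, contrasts)
        except (ValueError, np.linalg.LinAlgError) as exc:
            df_method = "residual"
            dfs = [float(len(self.endog) - p)] * p
            logger.warning("Satterthwaite df unavailable (%s); "
                           "falling back to residual df", exc)
            notes.append(f"residual-df fallback used ({exc})")

        params = pd.Series(smres.params[:p], index=list(self.exog.columns))
        bse = pd.Series(smres.bse[:p], index=list(self.exog.columns))
        return ThermalMixedResults(
            model=self, sm_result=smres, params=params, bse=bse,
            df=pd.Series(dfs, index=list(self.exog.columns)),
            sigma2_resid=s2e, sigma2_subject=s2b, df_method=df_method,
            singular=singular, notes=notes,
        )


@dataclass
class ThermalMixedResults:
    """Fixed-effect estimates with Satterthwaite-style inference."""

    model: ThermalMixedModel
    sm_result: object
    params: pd.Series
    bse: pd.Series
    df: pd.Series
    sigma2_resid: float
    sigma2_subject: float
    df_method: str
    singular: bool
    notes: list[str] = field(default_factory=list)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * sps.t.sf(np.abs(self.tvalues), self.df), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = sps.t.ppf(1 - alpha / 2, self.df) * self.bse
        return pd.DataFrame({"lower": self.params - half,
                             "upper": self.params + half})

    def fixed_effects(self) -> list[FixedEffectEstimate]:
        return [FixedEffectEstimate(term, self.params[term], self.bse[term],
                                    float(self.df[term]), float(self.pvalues[term]))
                for term in self.params.index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "df": self.df.to_numpy(),
            "p": self.pvalues.to_numpy(),
        })

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            f"Random-intercept LMM ({self.model.outcome_label} outcome, REML)",
            f"obs = {len(self.model.endog)}, "
            f"subjects = {self.model.data['subject_id'].nunique()}",
            f"sigma^2 (residual) = {self.sigma2_resid:.4f}, "
            f"sigma^2 (subject) = {self.sigma2_subject:.4f}",
            f"df method: {self.df_method}",
            "",
            f"{'term':<32}{'estimate':>10}{'se':>9}{'df':>9}{'p':>11}"
            f"{'95% CI':>22}",
        ]
        for term in self.params.index:
            lines.append(
                f"{term:<32}{self.params[term]:>10.4f}{self.bse[term]:>9.4f}"
                f"{self.df[term]:>9.1f}{self.pvalues[term]:>11.3g}"
                f"   [{ci.loc[term, 'lower']:+.3f}, {ci.loc[term, 'upper']:+.3f}]")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def fit_lmm(records: pd.DataFrame, outcome: str = "absolute",
            fixed_terms: Sequence[str] = ("phase", "camera", "phase:camera"),
            melanin_centered: bool = False) -> ThermalMixedResults:
    """Convenience wrapper: build and REML-fit a :class:`ThermalMixedModel`."""
    return ThermalMixedModel.from_measurements(
        records, outcome=outcome, fixed_terms=fixed_terms,
        melanin_centered=melanin_centered).fit()


def skin_tone_report(results: ThermalMixedResults,
                     category_width: float = CATEGORY_WIDTH_UNITS,
                     span_categories: int = 3) -> dict:
    """Translate the melanin-by-cooling interaction into category terms.

    Multiplies the per-converted-unit interaction by the nominal category
    width (25 units) and by the Intermediate-Low to Intermediate-High span
    (3 categories, 75 units).
    """
    term = "phase[cooled]:melanin"
    if term not in results.params.index:
        raise ValueError("model does not include a melanin-by-phase interaction")
    beta = float(results.params[term])
    return {
        "per_unit_C": beta,
        "per_category_C": beta * category_width,
        "across_scale_C": beta * category_width * span_categories,
        "p": float(results.pvalues[term]),
    }
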