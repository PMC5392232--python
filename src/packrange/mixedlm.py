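"""Random-intercept linear mixed models for directional overlap data,
with AICc multimodel inference.

The response is the percentage of a focal pack's 95% kernel overlapped by
a neighbour; each focal pack contributes repeated directional
observations, so focal-pack identity enters as a random intercept:

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),
                                      e_ij ~ N(0, sigma_e^2)

Fitting is by maximum likelihood (not REML, so AICc is comparable across
fixed-effect structures) via the profiled likelihood: for the variance
ratio lambda = sigma_b^2/sigma_e^2 the GLS solution and the residual
variance have closed forms, leaving a bounded one-dimensional search over
lambda.  ``dredge`` fits the marginality-respecting candidate set over
{pack-size ratio, relatedness, their interaction}; ``model_average``
produces cumulative-weight-selected, full (zero-substitution) averaged
coefficients with unconditional standard errors and relative importances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "RandomInterceptLM",
    "RandomInterceptLMResults",
    "ModelSet",
    "AveragedEstimates",
    "build_design",
    "dredge",
    "model_average",
    "predict_interaction_surface",
    "CANDIDATE_TERMS",
    "CANDIDATE_SPECS",
]

TERM_RATIO = "pack_size_ratio"
TERM_REL = "relatedness"
TERM_INT = "pack_size_ratio:relatedness"
CANDIDATE_TERMS = (TERM_RATIO, TERM_REL, TERM_INT)

#: marginality-respecting fixed-effect subsets (intercept always included)
CANDIDATE_SPECS: tuple[tuple[str, ...], ...] = (
    (),
    (TERM_RATIO,),
    (TERM_REL,),
    (TERM_RATIO, TERM_REL),
    (TERM_RATIO, TERM_REL, TERM_INT),
)

LAMBDA_UPPER = 1e4


def build_design(
    data: pd.DataFrame, terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix for a term subset.

    ``relatedness`` is coded 1 for related, 0 for unrelated (unrelated is
    the reference category); the interaction is the elementwise product.
    """
    n = len(data)
    cols = [np.ones(n)]
    names = ["Intercept"]
    if TERM_RATIO in terms:
        cols.append(data["pack_size_ratio"].to_numpy(dtype=float))
        names.append(TERM_RATIO)
    if TERM_REL in terms:
        rel = (data["relatedness"].astype(str) == "related").to_numpy(dtype=float)
        cols.append(rel)
        names.append(TERM_REL)
    if TERM_INT in terms:
        if TERM_RATIO not in terms or TERM_REL not in terms:
            raise ValueError("interaction requires both main effects")
        rel = (data["relatedness"].astype(str) == "related").to_numpy(dtype=float)
        cols.append(data["pack_size_ratio"].to_numpy(dtype=float) * rel)
        names.append(TERM_INT)
    return np.column_stack(cols), names


class RandomInterceptLM:
    """Linear model with one random intercept per group, fitted by ML.

    Parameters
    ----------
    endog : array-like
        Response vector.
    exog : array-like
        Fixed-effects design matrix (include the intercept column).
    groups : array-like
        Grouping labels, one per observation.
    exog_names : list of str, optional
        Column names for reporting.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if not np.isfinite(self.endog).all():
            raise ValueError("non-finite response")
        if not np.isfinite(self.exog).all():
            raise ValueError("non-finite design matrix")
        self.exog_names = list(
            exog_names
            if exog_names is not None
            else [f"x{i}" for i in range(self.exog.shape[1])]
        )
        groups = np.asarray(groups)
        uniq, self._group_idx = np.unique(groups, return_inverse=True)
        self.group_labels = uniq
        self.n_groups = len(uniq)
        if self.n_groups < 2:
            raise ValueError("need at least two groups for a random intercept")
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            # name the first aliased column for the error message
            q, r = np.linalg.qr(self.exog)
            bad = self.exog_names[int(np.argmin(np.abs(np.diag(r))))]
            raise ValueError(f"singular design matrix (aliased term: {bad})")
        self._group_sizes = np.bincount(self._group_idx, minlength=self.n_groups)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        terms: tuple[str, ...] = CANDIDATE_TERMS,
        response: str = "pct_of_focal",
        group: str = "focal_pack",
    ) -> "RandomInterceptLM":
        x, names = build_design(data, tuple(terms))
        return cls(data[response].to_numpy(dtype=float), x, data[group], names)

    # -- profiled likelihood machinery ------------------------------------

    def _group_sums(self, v: np.ndarray) -> np.ndarray:
        if v.ndim == 1:
            return np.bincount(self._group_idx, weights=v, minlength=self.n_groups)
        return np.column_stack(
            [
                np.bincount(self._group_idx, weights=v[:, j], minlength=self.n_groups)
                for j in range(v.shape[1])
            ]
        )

    def _profile(self, lam: float) -> tuple[float, np.ndarray, float]:
        """Profiled log-likelihood at variance ratio lam; returns
        (loglik, beta, sigma2_e)."""
        x, y = self.exog, self.endog
        n = y.size
        ni = self._group_sizes
        c = lam / (1.0 + ni * lam)  # per-group shrinkage weight
        sx = self._group_sums(x)
        sy = self._group_sums(y)
        xtvx = x.T @ x - (sx * c[:, None]).T @ sx
        xtvy = x.T @ y - (sx * c[:, None]).T @ sy
        beta = np.linalg.solve(xtvx, xtvy)
        r = y - x @ beta
        sr = self._group_sums(r)
        rss = float(r @ r - (c * sr * sr).sum())
        sigma2 = rss / n
        logdet = float(np.log1p(ni * lam).sum())
        ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n + logdet)
        return ll, beta, sigma2

    def fit(self) -> "RandomInterceptLMResults":
        """Maximise the profiled ML over lambda in [0, 1e4]."""
        grid = np.concatenate([[0.0], np.logspace(-8, math.log10(LAMBDA_UPPER), 80)])
        lls = np.array([self._profile(l)[0] for l in grid])
        i = int(np.argmax(lls))
        if i == 0:
            lam_hat = 0.0
            # polish near zero in case the maximiser sits just inside
            res = optimize.minimize_scalar(
                lambda l: -self._profile(l)[0],
                bounds=(0.0, grid[2]),
                method="bounded",
                options={"xatol": 1e-12},
            )
            if -res.fun > lls[0] + 1e-12:
                lam_hat = float(res.x)
        else:
            lo = grid[max(i - 1, 0)]
            hi = grid[min(i + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                lambda t: -self._profile(math.exp(t))[0],
                bounds=(math.log(max(lo, 1e-12)), math.log(hi)),
                method="bounded",
                options={"xatol": 1e-10},
            )
            lam_hat = float(math.exp(res.x))
        ll, beta, sigma2_e = self._profile(lam_hat)
        ni = self._group_sizes
        c = lam_hat / (1.0 + ni * lam_hat)
        sx = self._group_sums(self.exog)
        xtvx = self.exog.T @ self.exog - (sx * c[:, None]).T @ sx
        cov = sigma2_e * np.linalg.inv(xtvx)
        return RandomInterceptLMResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            cov_params=pd.DataFrame(
                cov, index=self.exog_names, columns=self.exog_names
            ),
            llf=ll,
            sigma2_e=sigma2_e,
            sigma2_b=lam_hat * sigma2_e,
            lambda_=lam_hat,
            boundary=lam_hat == 0.0,
        )


@dataclass
class RandomInterceptLMResults:
    """ML fit of a random-intercept linear model."""

    model: RandomInterceptLM
    params: pd.Series
    cov_params: pd.DataFrame
    llf: float
    sigma2_e: float
    sigma2_b: float
    lambda_: float
    boundary: bool

    @property
    def nobs(self) -> int:
        return self.model.endog.size

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def k_params(self) -> int:
        """Fixed coefficients plus the two variance components."""
        return len(self.params) + 2

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def aicc(self) -> float:
        n, k = self.nobs, self.k_params
        if n - k - 1 <= 0:
            raise ValueError(
                f"AICc undefined: n - k - 1 = {n - k - 1} for k = {k}"
            )
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def predict(self, exog) -> np.ndarray:
        """Population-level (fixed-effects) prediction."""
        return np.atleast_2d(np.asarray(exog, dtype=float)) @ self.params.to_numpy()

    def summary(self) -> str:
        lines = [
            "Random-intercept linear model (ML)",
            f"  n obs: {self.nobs}   groups: {self.model.n_groups}",
            f"  logLik: {self.llf:.4f}   AICc: {self.aicc:.3f}   k: {self.k_params}",
            f"  sigma2_b: {self.sigma2_b:.4f}   sigma2_e: {self.sigma2_e:.4f}"
            + ("   (boundary: sigma2_b = 0)" if self.boundary else ""),
            f"  {'term':<32}{'estimate':>12}{'SE':>12}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<32}{self.params[name]:>12.4f}{self.bse[name]:>12.4f}"
            )
        return "\n".join(lines)


@dataclass
class ModelSet:
    """A ranked candidate-model set with AICc deltas and Akaike weights."""

    fits: list  # [(name, terms, RandomInterceptLMResults)]
    data: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        aiccs = np.array([f.aicc for _, _, f in self.fits])
        order = np.argsort(aiccs, kind="stable")
        self.fits = [self.fits[i] for i in order]
        aiccs = aiccs[order]
        self.delta = aiccs - aiccs.min()
        w = np.exp(-0.5 * self.delta)
        self.weights = w / w.sum()

    def table(self) -> pd.DataFrame:
        rows = []
        for (name, terms, fit), d, w in zip(self.fits, self.delta, self.weights):
            rows.append(
                {
                    "model": name,
                    "terms": " + ".join(terms) if terms else "1",
                    "k": fit.k_params,
                    "logLik": fit.llf,
                    "AICc": fit.aicc,
                    "AIC": fit.aic,
                    "delta": d,
                    "weight": w,
                }
            )
        return pd.DataFrame(rows)


def _model_name(terms: tuple[str, ...]) -> str:
    if not terms:
        return "Null model"
    return " + ".join(terms)


def dredge(
    data: pd.DataFrame,
    response: str = "pct_of_focal",
    group: str = "focal_pack",
) -> ModelSet:
    """Fit the full marginality-respecting candidate set (5 models)."""
    fits = []
    for terms in CANDIDATE_SPECS:
        model = RandomInterceptLM.from_dataframe(
            data, terms, response=response, group=group
        )
        res = model.fit()
        _ = res.aicc  # raises early if N - k - 1 <= 0
        fits.append((_model_name(terms), terms, res))
    return ModelSet(fits, data=data)


@dataclass
class AveragedEstimates:
    """Cumulative-weight-selected, model-averaged coefficients.

    Full (zero-substitution) averaging is primary; conditional averages
    (over models containing each term) are reported alongside.
    Unconditional SEs follow the usual multimodel formula
    SE_j = sum_m w_m sqrt(se_mj^2 + (beta_mj - betabar_j)^2).
    """

    estimates: pd.Series
    unconditional_se: pd.Series
    conditional_estimates: pd.Series
    importance: pd.Series
    selected_models: list
    selected_weights: np.ndarray
    cum_weight: float
    ratio_range: tuple[float, float]
    ci_mult: float = 1.96

    def table(self) -> pd.DataFrame:
        lo = self.estimates - self.ci_mult * self.unconditional_se
        hi = self.estimates + self.ci_mult * self.unconditional_se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.estimates / self.unconditional_se
        p = 2.0 * sps.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "estimate": self.estimates,
                "std_error": self.unconditional_se,
                "ci_lower": lo,
                "ci_upper": hi,
                "p_value": p,
                "conditional_estimate": self.conditional_estimates,
                "relative_importance": self.importance,
            }
        )

    def predict(self, ratio, related) -> np.ndarray:
        """Averaged-coefficient prediction of percent overlap."""
        ratio = np.asarray(ratio, dtype=float)
        rel = np.asarray(related, dtype=float)
        b = self.estimates
        out = np.full(ratio.shape, b.get("Intercept", 0.0))
        out = out + b.get(TERM_RATIO, 0.0) * ratio
        out = out + b.get(TERM_REL, 0.0) * rel
        out = out + b.get(TERM_INT, 0.0) * ratio * rel
        return out

    def summary(self) -> str:
        t = self.table()
        lines = [
            f"Model-averaged effects (cumulative weight > {self.cum_weight}, "
            f"{len(self.selected_models)} models)",
            t.to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def model_average(model_set: ModelSet, cum_weight: float = 0.95) -> AveragedEstimates:
    """Average coefficients over the smallest top-ranked model prefix whose
    cumulative Akaike weight exceeds ``cum_weight`` (weights renormalised
    within the prefix)."""
    if not model_set.fits:
        raise ValueError("empty model set")
    cw = np.cumsum(model_set.weights)
    n_sel = int(np.searchsorted(cw, cum_weight) + 1)
    n_sel = min(n_sel, len(model_set.fits))
    sel = model_set.fits[:n_sel]
    w = model_set.weights[:n_sel]
    w = w / w.sum()

    all_names: list[str] = []
    for _, _, fit in sel:
        for nm in fit.params.index:
            if nm not in all_names:
                all_names.append(nm)

    est = pd.Series(0.0, index=all_names)
    for (_, _, fit), wm in zip(sel, w):
        for nm in all_names:
            if nm in fit.params.index:
                est[nm] += wm * fit.params[nm]
    se = pd.Series(0.0, index=all_names)
    for (_, _, fit), wm in zip(sel, w):
        for nm in all_names:
            b = fit.params.get(nm, 0.0)
            s = fit.bse.get(nm, 0.0)
            se[nm] += wm * math.sqrt(s * s + (b - est[nm]) ** 2)
    cond = pd.Series(np.nan, index=all_names)
    imp = pd.Series(0.0, index=all_names)
    for nm in all_names:
        wsum = 0.0
        acc = 0.0
        for (_, _, fit), wm in zip(sel, w):
            if nm in fit.params.index:
                wsum += wm
                acc += wm * fit.params[nm]
        imp[nm] = wsum
        if wsum > 0:
            cond[nm] = acc / wsum

    data = model_set.data
    if data is not None and "pack_size_ratio" in data:
        rr = (
            float(data["pack_size_ratio"].min()),
            float(data["pack_size_ratio"].max()),
        )
    else:
        rr = (0.0, 1.0)
    return AveragedEstimates(
        estimates=est,
        unconditional_se=se,
        conditional_estimates=cond,
        importance=imp,
        selected_models=[name for name, _, _ in sel],
        selected_weights=w,
        cum_weight=cum_weight,
        ratio_range=rr,
    )


def predict_interaction_surface(
    avg: AveragedEstimates,
    ratio_grid: np.ndarray | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Predicted percent overlap over the observed pack-size-ratio range
    for each relatedness level (the relatedness-by-ratio interaction
    surface).  Predictions below zero are clamped for reporting in the
    ``predicted_clamped`` column."""
    lo, hi = avg.ratio_range
    if ratio_grid is None:
        ratio_grid = np.linspace(lo, hi, n_points)
    else:
        ratio_grid = np.asarray(ratio_grid, dtype=float)
        if ratio_grid.min() < lo - 1e-9 or ratio_grid.max() > hi + 1e-9:
            warnings.warn(
                "ratio grid extends outside the observed data range",
                stacklevel=2,
            )
    rows = []
    for rel_label, rel in (("unrelated", 0.0), ("related", 1.0)):
        pred = avg.predict(ratio_grid, np.full_like(ratio_grid, rel))
        for rat, p in zip(ratio_grid, pred):
            rows.append(
                {
                    "pack_size_ratio": rat,
                    "relatedness": rel_label,
                    "predicted": p,
                    "predicted_clamped": max(p, 0.0),
                }
            )
    return pd.DataFrame(rows)
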