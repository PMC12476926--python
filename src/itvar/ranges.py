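"""Bayesian regression of across-site ITV (or mean traits) on niche breadth.

One row per species: the response is log across-site ITV* of a trait
(or the species mean of the log trait), the predictors are standardized
environmental range widths (PET, climatic water deficit, elevation,
irradiance, cloudiness, optionally MAP) plus the count of geology
classes occupied.  The model is an ordinary Gaussian linear regression

    y_sp = b1 + b2 * PETrange_sp + b3 * CWDrange_sp + ... + e_sp

fitted by Gibbs sampling with weakly-informative independent normal
priors on the slopes (sd 2.5 * sd_y on the standardized scale), a flat
prior on the intercept and a Jeffreys prior on the residual variance —
weak enough that ordinary least squares is the testable limit.

Model selection is greedy backward elimination on AIC (drop the
predictor whose removal lowers AIC most, stop when none does), with an
exhaustive all-subsets search available as a cross-check for small
predictor sets.  Collinearity among range widths is diagnosed with
variance inflation factors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from itvar.env import standardize

logger = logging.getLogger(__name__)

#: Default predictor columns of a species-ranges table used in the
#: regression.  MAP range is available but excluded by default; pass an
#: explicit predictor list to include it.
DEFAULT_PREDICTORS = (
    "pet_range",
    "cwd_range",
    "geology_count",
    "elevation_range",
    "irradiance_range",
    "cloudiness_range",
)


@dataclass
class RangeDesign:
    """Model-ready response and standardized predictor matrix."""

    y: pd.Series  # indexed by species
    X: pd.DataFrame  # standardized, same index
    std_params: pd.DataFrame | None = None  # per-column mean/sd for back-transform
    response_name: str = "log_itv_star"

    def __post_init__(self):
        if len(self.y) != len(self.X):
            raise ValueError("response and predictors differ in length")
        if len(self.y) < len(self.X.columns) + 2:
            raise ValueError(
                f"under-determined design: {len(self.y)} species for "
                f"{len(self.X.columns)} predictors (need >= predictors + 2)"
            )

    def subset(self, predictors) -> "RangeDesign":
        return RangeDesign(
            self.y, self.X.loc[:, list(predictors)], self.std_params, self.response_name
        )


def build_range_design(
    response: pd.DataFrame,
    ranges: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    response_col: str = "log_itv_star",
) -> RangeDesign:
    """Join a per-species response to a species-ranges table.

    ``response`` needs columns ``species`` and ``response_col``;
    ``ranges`` needs ``species`` and every predictor column.  Species
    missing from either side are dropped with a warning.  Predictors
    are standardized to mean 0, sd 1.
    """
    predictors = list(predictors)
    if not predictors:
        raise ValueError("empty predictor set")
    missing_cols = [c for c in predictors if c not in ranges.columns]
    if missing_cols:
        raise ValueError(f"ranges table missing predictor column(s) {missing_cols}")
    resp = response.set_index("species")[response_col].astype(float)
    rng_tab = ranges.set_index("species").loc[:, predictors].astype(float)
    common = resp.index.intersection(rng_tab.index)
    dropped = sorted(set(resp.index).symmetric_difference(rng_tab.index))
    if dropped:
        logger.warning("%d species dropped from range design (unmatched): %s",
                       len(dropped), dropped[:10])
    common = sorted(common)
    X, params = standardize(rng_tab.loc[common])
    return RangeDesign(resp.loc[common], X, params, response_col)


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 - R^2_j).

    R^2_j comes from regressing column j (with intercept) on the other
    columns.  Perfectly collinear columns yield ``inf``.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF needs >= 2 predictors")
    out = {}
    for col in X.columns:
        yj = X[col].to_numpy(float)
        others = X.drop(columns=col).to_numpy(float)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


class RangeRegression:
    """Gaussian linear model of a per-species response on range widths.

    Construct from a :class:`RangeDesign` (or via :meth:`from_frames`)
    and call :meth:`fit`.
    """

    def __init__(self, design: RangeDesign):
        self.design = design
        Xmat = np.column_stack(
            [np.ones(len(design.y)), design.X.to_numpy(float)]
        )
        if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
            corr = design.X.corr().abs()
            np.fill_diagonal(corr.values, 0)
            pairs = [
                (a, b)
                for a in corr.index
                for b in corr.columns
                if a < b and corr.loc[a, b] > 0.9999
            ]
            raise ValueError(
                f"singular design (collinear predictors): {pairs or list(design.X.columns)}"
            )
        self._Xmat = Xmat

    @classmethod
    def from_frames(cls, response, ranges, predictors=DEFAULT_PREDICTORS,
                    response_col="log_itv_star") -> "RangeRegression":
        return cls(build_range_design(response, ranges, predictors, response_col))

    def fit(
        self,
        ci_levels=(0.90, 0.95),
        draws: int = 2000,
        warmup: int = 200,
        seed: int = 0,
        prior_scale: float = 2.5,
    ) -> "RangeRegressionResults":
        """Gibbs sampling: beta | sigma^2 Gaussian, sigma^2 | beta inverse-gamma."""
        y = self.design.y.to_numpy(float)
        X = self._Xmat
        n, p = X.shape
        sd_y = y.std(ddof=1) if n > 1 else 1.0
        # flat prior on intercept, normal(0, prior_scale * sd_y) on slopes
        prior_prec = np.zeros(p)
        prior_prec[1:] = 1.0 / (prior_scale * max(sd_y, 1e-12)) ** 2
        XtX = X.T @ X
        Xty = X.T @ y

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        sig2 = max(float(resid @ resid) / max(n - p, 1), 1e-12)

        keep = np.empty((draws, p))
        keep_sig = np.empty(draws)
        for it in range(warmup + draws):
            P = XtX / sig2 + np.diag(prior_prec)
            L = np.linalg.cholesky(P)
            m = np.linalg.solve(P, Xty / sig2)
            z = rng.standard_normal(p)
            beta = m + np.linalg.solve(L.T, z)
            resid = y - X @ beta
            rss = float(resid @ resid)
            # Jeffreys prior on sigma^2: InvGamma(n/2, rss/2)
            g = rng.standard_gamma(n / 2.0)
            sig2 = (rss / 2.0) / max(g, 1e-300)
            if it >= warmup:
                keep[it - warmup] = beta
                keep_sig[it - warmup] = sig2
        return RangeRegressionResults(self, keep, keep_sig, ci_levels, seed)


@dataclass
class SelectionStep:
    predictors: tuple[str, ...]
    aic: float
    dropped: str | None  # predictor removed to *reach* this model
    candidates: dict = field(default_factory=dict)  # AIC with each predictor removed


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_predictors: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, st in enumerate(self.steps):
            rows.append(
                {
                    "step": i,
                    "predictors": "+".join(st.predictors) or "(intercept only)",
                    "aic": st.aic,
                    "dropped": st.dropped or "",
                }
            )
        return pd.DataFrame(rows)


class RangeRegressionResults:
    """Coefficient posterior, fit statistics and diagnostics."""

    def __init__(self, model, beta_draws, sig2_draws, ci_levels, seed):
        self.model = model
        self.design = model.design
        self.seed = seed
        self.ci_levels = tuple(ci_levels)
        self.terms = ["intercept"] + list(self.design.X.columns)
        self.beta_draws = beta_draws  # (draws, p)
        self.sig2_draws = sig2_draws
        self.params = pd.Series(beta_draws.mean(axis=0), index=self.terms)
        self._stats = self._fit_stats()

    def _fit_stats(self):
        y = self.design.y.to_numpy(float)
        X = self.model._Xmat
        n = len(y)
        resid = y - X @ self.params.to_numpy()
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        sig2_ml = rss / n
        loglik = -0.5 * n * (np.log(2 * np.pi * sig2_ml) + 1.0)
        k = X.shape[1] + 1  # coefficients (incl. intercept) + residual sd
        return {
            "n": n,
            "rss": rss,
            "r2": max(0.0, min(1.0, 1.0 - rss / tss)) if tss > 0 else 0.0,
            "residual_sd": float(np.sqrt(sig2_ml)),
            "loglik": float(loglik),
            "k": k,
            "aic": float(2 * k - 2 * loglik),
        }

    @property
    def aic(self) -> float:
        return self._stats["aic"]

    @property
    def loglik(self) -> float:
        return self._stats["loglik"]

    @property
    def k(self) -> int:
        return self._stats["k"]

    @property
    def r2(self) -> float:
        return self._stats["r2"]

    @property
    def residual_sd(self) -> float:
        return self._stats["residual_sd"]

    def credible_interval(self, term: str, level: float = 0.90) -> tuple[float, float]:
        j = self.terms.index(term)
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self.beta_draws[:, j], [a, 100 - a])
        return float(lo), float(hi)

    def vif(self) -> pd.Series:
        return vif(self.design.X)

    def summary(self) -> pd.DataFrame:
        """Coefficient table with posterior mean, sd and credible bounds."""
        rows = []
        for j, term in enumerate(self.terms):
            d = self.beta_draws[:, j]
            row = {"term": term, "estimate": d.mean(), "sd": d.std(ddof=1)}
            for lvl in self.ci_levels:
                a = 100 * (1 - lvl) / 2
                lo, hi = np.percentile(d, [a, 100 - a])
                tag = f"{int(round(lvl * 100))}"
                row[f"lo{tag}"] = lo
                row[f"hi{tag}"] = hi
            rows.append(row)
        return pd.DataFrame(rows).set_index("term")

    def significant_terms(self, level: float = 0.90) -> list[str]:
        """Predictors whose credible interval at ``level`` excludes zero."""
        out = []
        for term in self.terms[1:]:
            lo, hi = self.credible_interval(term, level)
            if lo > 0 or hi < 0:
                out.append(term)
        return out


def _fit_subset(design: RangeDesign, predictors, seed: int, draws: int, warmup: int,
                cache: dict) -> RangeRegressionResults:
    key = tuple(sorted(predictors))
    if key not in cache:
        sub = design.subset(list(predictors)) if predictors else RangeDesign(
            design.y, design.X.loc[:, []], design.std_params, design.response_name
        )
        # seed derived from the subset so identical subsets get identical fits
        ss = np.random.SeedSequence(seed, spawn_key=tuple(
            sorted(design.X.columns.get_loc(c) for c in predictors)
        ))
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        cache[key] = RangeRegression(sub).fit(draws=draws, warmup=warmup, seed=sub_seed)
    return cache[key]


def backward_select(
    design: RangeDesign,
    seed: int = 0,
    draws: int = 2000,
    warmup: int = 200,
) -> tuple[SelectionTrace, RangeRegressionResults]:
    """Greedy backward elimination on AIC.

    At each step every single-predictor removal is fitted; the removal
    that lowers AIC most is accepted; selection stops when no removal
    lowers AIC.  The trace records every candidate AIC, including the
    leave-one-out AICs of the final model.
    """
    cache: dict = {}
    current = tuple(design.X.columns)
    fit = _fit_subset(design, current, seed, draws, warmup, cache)
    steps = [SelectionStep(current, fit.aic, None)]
    while current:
        candidates = {}
        for drop in current:
            reduced = tuple(c for c in current if c != drop)
            candidates[drop] = _fit_subset(design, reduced, seed, draws, warmup, cache).aic
        steps[-1].candidates = dict(candidates)
        best_drop = min(candidates, key=lambda c: (candidates[c], c))
        if candidates[best_drop] >= fit.aic:
            break
        current = tuple(c for c in current if c != best_drop)
        fit = _fit_subset(design, current, seed, draws, warmup, cache)
        steps.append(SelectionStep(current, fit.aic, best_drop))
    return SelectionTrace(steps, current), fit


def exhaustive_select(
    design: RangeDesign,
    seed: int = 0,
    draws: int = 2000,
    warmup: int = 200,
) -> tuple[tuple[str, ...], float]:
    """All-subsets search for the lowest-AIC model (cross-check, <= 8 predictors)."""
    cols = list(design.X.columns)
    if len(cols) > 8:
        raise ValueError("exhaustive search limited to <= 8 predictors")
    cache: dict = {}
    best = None
    for r in range(len(cols) + 1):
        for combo in itertools.combinations(cols, r):
            aic = _fit_subset(design, combo, seed, draws, warmup, cache).aic
            if best is None or aic < best[1] - 1e-12:
                best = (combo, aic)
    return best


def mean_trait_response(observations: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean of log trait values (pooled over all retained rows).

    Returns columns ``trait``, ``species``, ``mean_log_trait``.
    """
    grp = observations.groupby(["trait", "species"], sort=True)["value"]
    out = grp.apply(lambda v: float(np.mean(np.log(v)))).rename("mean_log_trait")
    return out.reset_index()


def mean_itv_correlation(means, log_itv_star) -> tuple[float, float]:
    """Pearson correlation between species mean log trait and log ITV*.

    Returns (r, two-sided p) from the t distribution with n - 2 df.
    """
    x = np.asarray(means, dtype=float)
    y = np.asarray(log_itv_star, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired species values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
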