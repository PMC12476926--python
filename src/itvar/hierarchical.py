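"""Hierarchical Bayesian random-slope model for within-site ITV.

The response is log ITV* of species *sp* at site *si*; the predictor is
a site-level environmental-variability metric (terrain roughness or
rainfall CV).  The model is

    log ITV*_{si,sp} = beta0 + beta1_sp + beta2_sp * env_si + eps / n_{si,sp}
    beta1_sp ~ Normal(mu1, sigma1)
    beta2_sp ~ Normal(mu2, sigma2)
    eps      ~ Normal(0, tau)

so each row's residual standard deviation is tau / n (cells estimated
from more individuals are held closer to the regression line).  mu1 is
the community-average log ITV*, mu2 the community-average effect of
environmental variability on ITV — the Hypothesis-1 estimand — and the
species deviations are random intercepts and slopes.

Priors: sigma1, sigma2, tau ~ Uniform(0, 10); beta0, mu1, mu2 ~
Normal(0, 1).  As written beta0 and mu1 are jointly unidentified, so by
default beta0 is fixed at 0 and beta1_sp is parameterized as
mu1 + delta_sp with delta_sp ~ Normal(0, sigma1); the literal
double-intercept form is available via ``include_beta0`` for
sensitivity checks (beta0 + mu1 is identified either way).

Fitting is by blocked Gibbs sampling: conditional on the scale
parameters every location parameter is Gaussian, and conditional on the
locations each scale's square is truncated inverse-gamma (the uniform
prior contributes the truncation at the upper bound and a 1/sigma
Jacobian term).  The conditionals are exact, so no tuning is needed and
chains mix rapidly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from itvar.env import standardize

logger = logging.getLogger(__name__)


@dataclass
class HierModelSpec:
    """Sampler and prior settings for :class:`HierarchicalITV`.

    Parameters
    ----------
    env_variable : str
        Which site-table column is the predictor (e.g.
        ``"terrain_roughness"`` or ``"rainfall_cv"``).
    prior_sd_upper : float
        Upper bound of the Uniform(0, b) priors on sigma1, sigma2, tau.
    prior_mean_sd : float
        Standard deviation of the Normal(0, s) priors on beta0, mu1, mu2.
    error_scaling : ``"sd_over_n"`` | ``"sd_over_sqrt_n"``
        Row residual sd is tau/n (literal reading of the model) or
        tau/sqrt(n) (variance-proportional alternative).
    include_beta0 : bool
        Restore the literal double-intercept parameterization.
    standardize_env : bool
        Z-score the predictor across the distinct site values.
    """

    env_variable: str = "terrain_roughness"
    prior_sd_upper: float = 10.0
    prior_mean_sd: float = 1.0
    chains: int = 4
    iterations: int = 2000
    warmup: int | None = None  # default: iterations // 2
    seed: int = 0
    error_scaling: str = "sd_over_n"
    include_beta0: bool = False
    standardize_env: bool = True

    def __post_init__(self):
        if self.prior_sd_upper <= 0 or self.prior_mean_sd <= 0:
            raise ValueError("prior bounds must be positive")
        if self.warmup is None:
            self.warmup = self.iterations // 2
        if not self.iterations > self.warmup >= 0:
            raise ValueError("need iterations > warmup >= 0")
        if self.error_scaling not in ("sd_over_n", "sd_over_sqrt_n"):
            raise ValueError(f"unknown error_scaling {self.error_scaling!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def build_design(
    itv_within: pd.DataFrame,
    sites: pd.DataFrame,
    env_variable: str,
    standardize_env: bool = True,
) -> pd.DataFrame:
    """Join within-site ITV records to a site environment table.

    Returns a model-ready frame with columns ``log_itv_star``,
    ``species``, ``species_idx``, ``env`` (optionally standardized
    across the distinct site values, sample sd), ``site``, ``n``.
    """
    if env_variable not in sites.columns:
        raise ValueError(f"site table has no column {env_variable!r}")
    site_env = sites.set_index("site")[env_variable].astype(float)
    missing = sorted(set(itv_within["site"]) - set(site_env.index))
    if missing:
        raise ValueError(f"site(s) {missing} absent from site table")
    env_vals = site_env.loc[sorted(set(itv_within["site"]))]
    if env_vals.nunique() < 2:
        raise ValueError(f"predictor {env_variable!r} is constant across sites")
    if standardize_env:
        z, _ = standardize(env_vals.to_frame())
        site_env = z[env_variable].reindex(site_env.index).fillna(
            (site_env - env_vals.mean()) / env_vals.std(ddof=1)
        )

    df = itv_within.copy()
    undefined = ~np.isfinite(df["log_itv_star"])
    if undefined.any():
        logger.warning("dropping %d rows with undefined log ITV*", int(undefined.sum()))
        df = df[~undefined]
    df = df.reset_index(drop=True)
    if df["species"].nunique() < 2:
        raise ValueError("need >= 2 species for the hierarchical model")
    species = sorted(df["species"].unique())
    idx = {sp: i for i, sp in enumerate(species)}
    out = pd.DataFrame(
        {
            "log_itv_star": df["log_itv_star"].astype(float),
            "species": df["species"],
            "species_idx": df["species"].map(idx).astype(int),
            "site": df["site"],
            "env": df["site"].map(site_env).astype(float),
            "n": df["n"].astype(int),
        }
    )
    out.attrs["species_order"] = species
    return out


def log_likelihood(row, params: dict, error_scaling: str = "sd_over_n") -> float:
    """Normal log-density of one design row under the model.

    ``params`` needs beta0 (optional, default 0), mu-level values are
    already folded into beta1/beta2 for the row's species:
    expects keys ``beta1`` (intercept for this species, = mu1 + delta1),
    ``beta2`` and ``tau``.
    """
    tau = params["tau"]
    if tau <= 0:
        raise ValueError("tau must be positive")
    n = row["n"]
    w = n if error_scaling == "sd_over_n" else np.sqrt(n)
    mean = params.get("beta0", 0.0) + params["beta1"] + params["beta2"] * row["env"]
    return float(stats.norm.logpdf(row["log_itv_star"], loc=mean, scale=tau / w))


def _sample_trunc_invgamma(rng, a: float, b: float, upper_sq: float) -> float:
    """Draw sigma^2 ~ InvGamma(a, b) truncated to (0, upper_sq); return sigma."""
    # rejection against the untruncated draw; the bound rarely binds
    for _ in range(200):
        g = rng.standard_gamma(a)
        if g <= 0:
            continue
        sig_sq = b / g
        if sig_sq < upper_sq:
            return float(np.sqrt(sig_sq))
    # posterior mass piles up at the bound: inverse-CDF fallback
    lo = stats.gamma.cdf(b / upper_sq, a)
    u = rng.uniform(lo, 1.0)
    g = stats.gamma.ppf(min(u, 1 - 1e-12), a)
    return float(np.sqrt(b / max(g, b / upper_sq)))


class HierarchicalITV:
    """Random-intercept, random-slope model of log ITV* on site environment.

    Parameters
    ----------
    design : DataFrame from :func:`build_design`.

    Use :meth:`from_frames` to construct directly from an ITV table and
    a site table.  :meth:`fit` runs the Gibbs sampler and returns a
    :class:`HierarchicalITVResults`.
    """

    def __init__(self, design: pd.DataFrame):
        for col in ("log_itv_star", "species_idx", "env", "n"):
            if col not in design.columns:
                raise ValueError(f"design missing column {col!r}")
        self.design = design.reset_index(drop=True)
        self.species_order = design.attrs.get(
            "species_order",
            sorted(design["species"].unique()) if "species" in design else None,
        )
        self.n_species = int(design["species_idx"].max()) + 1
        if self.n_species < 2:
            raise ValueError("need >= 2 species")

    @classmethod
    def from_frames(
        cls,
        itv_within: pd.DataFrame,
        sites: pd.DataFrame,
        env_variable: str,
        standardize_env: bool = True,
    ) -> "HierarchicalITV":
        return cls(build_design(itv_within, sites, env_variable, standardize_env))

    def fit(self, spec: HierModelSpec | None = None, **kwargs) -> "HierarchicalITVResults":
        """Run the blocked Gibbs sampler.

        Any ``HierModelSpec`` field may be overridden via keyword.
        """
        if spec is None:
            spec = HierModelSpec(**kwargs)
        elif kwargs:
            spec = HierModelSpec(**{**spec.to_dict(), **kwargs})

        y = self.design["log_itv_star"].to_numpy(float)
        s = self.design["species_idx"].to_numpy(int)
        x = self.design["env"].to_numpy(float)
        n = self.design["n"].to_numpy(float)
        w = n if spec.error_scaling == "sd_over_n" else np.sqrt(n)
        S, N = self.n_species, len(y)
        U2 = spec.prior_sd_upper**2
        prior_prec = 1.0 / spec.prior_mean_sd**2

        keep = spec.iterations - spec.warmup
        store = {
            name: np.empty((spec.chains, keep))
            for name in ("beta0", "mu1", "mu2", "sigma1", "sigma2", "tau")
        }
        store["delta1"] = np.empty((spec.chains, keep, S))
        store["delta2"] = np.empty((spec.chains, keep, S))

        child_seeds = np.random.SeedSequence(spec.seed).spawn(spec.chains)
        for c in range(spec.chains):
            rng = np.random.default_rng(child_seeds[c])
            # overdispersed but data-informed start
            mu1 = y.mean() + rng.normal(0, 0.5)
            mu2 = rng.normal(0, 0.5)
            beta0 = 0.0
            d1 = np.zeros(S)
            d2 = np.zeros(S)
            resid0 = y - mu1 - mu2 * x
            tau = float(np.clip(np.std(resid0) * np.median(w) * rng.uniform(0.5, 2.0),
                                1e-3, spec.prior_sd_upper * 0.9))
            sigma1 = rng.uniform(0.1, 1.0)
            sigma2 = rng.uniform(0.1, 1.0)

            for it in range(spec.iterations):
                p = w**2 / tau**2  # row precisions

                if spec.include_beta0:
                    r = y - mu1 - d1[s] - (mu2 + d2[s]) * x
                    P = prior_prec + p.sum()
                    beta0 = (p * r).sum() / P + rng.normal() / np.sqrt(P)

                # joint (mu1, delta1) block: the conditional is Gaussian
                # with arrow-shaped precision, so draw mu1 from its
                # marginal conditional (deltas integrated out) and the
                # deltas given mu1 — exact, and avoids the slow-mixing
                # ridge between a hypermean and the mean of its deviations
                r = y - beta0 - (mu2 + d2[s]) * x
                A = np.bincount(s, weights=p, minlength=S)
                B = np.bincount(s, weights=p * r, minlength=S)
                P1 = 1.0 / sigma1**2 + A
                Pmu = prior_prec + A.sum() - (A**2 / P1).sum()
                mmu = (B.sum() - (A * B / P1).sum()) / Pmu
                mu1 = mmu + rng.normal() / np.sqrt(Pmu)
                d1 = (B - A * mu1) / P1 + rng.standard_normal(S) / np.sqrt(P1)

                # joint (mu2, delta2) block, same structure on the slope side
                r = y - beta0 - mu1 - d1[s]
                A = np.bincount(s, weights=p * x * x, minlength=S)
                B = np.bincount(s, weights=p * x * r, minlength=S)
                P2 = 1.0 / sigma2**2 + A
                Pmu = prior_prec + A.sum() - (A**2 / P2).sum()
                mmu = (B.sum() - (A * B / P2).sum()) / Pmu
                mu2 = mmu + rng.normal() / np.sqrt(Pmu)
                d2 = (B - A * mu2) / P2 + rng.standard_normal(S) / np.sqrt(P2)

                sigma1 = _sample_trunc_invgamma(rng, (S - 1) / 2.0, (d1**2).sum() / 2.0, U2)
                sigma2 = _sample_trunc_invgamma(rng, (S - 1) / 2.0, (d2**2).sum() / 2.0, U2)

                r = y - beta0 - mu1 - d1[s] - (mu2 + d2[s]) * x
                tau = _sample_trunc_invgamma(
                    rng, (N - 1) / 2.0, (w**2 * r**2).sum() / 2.0, U2
                )

                if it >= spec.warmup:
                    k = it - spec.warmup
                    store["beta0"][c, k] = beta0
                    store["mu1"][c, k] = mu1
                    store["mu2"][c, k] = mu2
                    store["sigma1"][c, k] = sigma1
                    store["sigma2"][c, k] = sigma2
                    store["tau"][c, k] = tau
                    store["delta1"][c, k] = d1
                    store["delta2"][c, k] = d2

        return HierarchicalITVResults(self, spec, store)


class HierarchicalITVResults:
    """Posterior draws and summaries from :class:`HierarchicalITV.fit`.

    Attributes
    ----------
    draws : dict of arrays
        Scalar parameters have shape (chains, draws); ``delta1``/``delta2``
        (species deviations) have shape (chains, draws, n_species).
        Derived per-species coefficients ``beta1 = beta0 + mu1 + delta1``
        and ``beta2 = mu2 + delta2`` are included.
    """

    def __init__(self, model: HierarchicalITV, spec: HierModelSpec, store: dict):
        self.model = model
        self.spec = spec
        self.draws = dict(store)
        self.draws["beta1"] = (
            store["beta0"][..., None] + store["mu1"][..., None] + store["delta1"]
        )
        self.draws["beta2"] = store["mu2"][..., None] + store["delta2"]
        self.species_order = model.species_order or [
            f"sp{i}" for i in range(model.n_species)
        ]
        self._summary = None
        self._check_convergence()

    # -- diagnostics ---------------------------------------------------
    def rhat(self) -> pd.Series:
        """Split-R-hat per scalar parameter (species parameters flattened)."""
        import arviz as az

        flat = {}
        for name in ("beta0", "mu1", "mu2", "sigma1", "sigma2", "tau"):
            if name == "beta0" and not self.spec.include_beta0:
                continue
            flat[name] = self.draws[name]
        for name in ("delta1", "delta2", "beta2"):
            for j, sp in enumerate(self.species_order):
                flat[f"{name}[{sp}]"] = self.draws[name][:, :, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rh = az.rhat(az.from_dict(posterior=flat))
        return pd.Series({k: float(rh[k].values) for k in flat})

    def _check_convergence(self):
        try:
            rh = self.rhat()
        except Exception as exc:  # diagnostics must never kill a fit
            logger.warning("R-hat computation failed: %s", exc)
            return
        bad = rh[rh > 1.01]
        if len(bad):
            warnings.warn(
                f"{len(bad)} parameter(s) with R-hat > 1.01 "
                f"(worst {bad.idxmax()}: {bad.max():.3f}); "
                "consider more iterations",
                stacklevel=3,
            )

    # -- summaries -----------------------------------------------------
    def _flat(self, name: str, j: int | None = None) -> np.ndarray:
        arr = self.draws[name]
        return (arr[:, :, j] if j is not None else arr).reshape(-1)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, central quantiles and R-hat per parameter."""
        if self._summary is not None:
            return self._summary
        try:
            rh = self.rhat()
        except Exception:
            rh = pd.Series(dtype=float)
        rows = []
        scalars = ["mu1", "mu2", "sigma1", "sigma2", "tau"]
        if self.spec.include_beta0:
            scalars = ["beta0"] + scalars
        for name in scalars:
            rows.append(self._row(name, self._flat(name), rh.get(name, np.nan)))
        for name in ("beta1", "beta2"):
            for j, sp in enumerate(self.species_order):
                label = f"{name}[{sp}]"
                rows.append(self._row(label, self._flat(name, j), rh.get(label, np.nan)))
        self._summary = pd.DataFrame(
            rows, columns=["parameter", "mean", "sd", "q2.5", "q50", "q97.5", "rhat"]
        ).set_index("parameter")
        return self._summary

    @staticmethod
    def _row(name, draws, rhat):
        q = np.percentile(draws, [2.5, 50, 97.5])
        return {
            "parameter": name,
            "mean": draws.mean(),
            "sd": draws.std(ddof=1),
            "q2.5": q[0],
            "q50": q[1],
            "q97.5": q[2],
            "rhat": rhat,
        }

    def posterior_mean(self, name: str) -> float:
        return float(self._flat(name).mean())

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        a = 100 * (1 - level) / 2
        lo, hi = np.percentile(self._flat(name), [a, 100 - a])
        return float(lo), float(hi)

    def classify_slopes(self, level: float = 0.95) -> pd.DataFrame:
        """Label mu2 and each species slope by its credible interval vs zero.

        ``positive`` when the lower bound exceeds 0, ``negative`` when
        the upper bound is below 0, otherwise ``nonsignificant``.
        """
        rows = []
        targets = [("mu2", None)] + [
            (f"beta2[{sp}]", j) for j, sp in enumerate(self.species_order)
        ]
        a = 100 * (1 - level) / 2
        for label, j in targets:
            d = self._flat("mu2") if j is None else self._flat("beta2", j)
            lo, hi = np.percentile(d, [a, 100 - a])
            cls = "positive" if lo > 0 else ("negative" if hi < 0 else "nonsignificant")
            rows.append(
                {
                    "parameter": label,
                    "species": "" if j is None else self.species_order[j],
                    "mean": d.mean(),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "level": level,
                    "label": cls,
                }
            )
        return pd.DataFrame(rows)

    def draws_frame(self) -> pd.DataFrame:
        """Long-format draws table (chain, iteration, parameter, value)."""
        recs = []
        chains, keep = self.draws["mu1"].shape
        for name in ("mu1", "mu2", "sigma1", "sigma2", "tau") + (
            ("beta0",) if self.spec.include_beta0 else ()
        ):
            arr = self.draws[name]
            for c in range(chains):
                recs.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(keep),
                            "parameter": name,
                            "value": arr[c],
                        }
                    )
                )
        return pd.concat(recs, ignore_index=True)

    def plot_slopes(self, level: float = 0.95, ax=None):
        """Forest plot of species slopes, colored by CI-vs-zero class."""
        import matplotlib.pyplot as plt

        cls = self.classify_slopes(level)
        sp = cls[cls["species"] != ""].reset_index(drop=True)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.3 * len(sp) + 1.5))
        colors = {"positive": "tab:blue", "negative": "tab:red", "nonsignificant": "0.6"}
        for i, row in sp.iterrows():
            ax.plot([row["ci_lo"], row["ci_hi"]], [i, i], color=colors[row["label"]])
            ax.plot(row["mean"], i, "o", color=colors[row["label"]], ms=4)
        ax.axvline(0, color="k", lw=0.8, ls="--")
        ax.set_yticks(range(len(sp)))
        ax.set_yticklabels(sp["species"])
        ax.set_xlabel(f"species slope (beta2), {int(level*100)}% CI")
        return ax
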