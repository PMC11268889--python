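"""Estimators for the headline quantities.

Fully implemented, simplified analogues of the study-grade mixed models:

* :func:`ratio_of_means_log` — group force ratio as the exponentiated
  difference of log-means, with a percentile bootstrap CI (optionally a
  cluster bootstrap over owls to respect repeated measures);
* :class:`HuntingSuccessModel` — fixed-effects logistic regression of
  hunting success on z-scored pre-hunt perching force, strategy, sex and
  the force x strategy interaction, fitted by IRLS with Wald CIs;
* :class:`ForceTrendModel` — penalized B-spline smooth of log landing
  force against time-to-next-hunt, with a finite-difference first
  derivative and a max-deviation bootstrap simultaneous band flagging
  intervals of significant force change;
* :func:`descriptive_tables` — tidy per-sex / per-strategy summaries
  with bootstrap CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit
from scipy.stats import norm

from .containers import G0


class SeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfect separation)."""


# --------------------------------------------------------------------------
# ratio of means on the log scale


@dataclass(frozen=True)
class RatioEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int


def _boot_indices(rng, n: int, clusters: np.ndarray | None) -> np.ndarray:
    if clusters is None:
        return rng.integers(0, n, n)
    uniq = np.unique(clusters)
    picked = rng.choice(uniq, size=len(uniq), replace=True)
    return np.concatenate([np.flatnonzero(clusters == c) for c in picked])


def ratio_of_means_log(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    clusters_a: np.ndarray | None = None,
    clusters_b: np.ndarray | None = None,
) -> RatioEstimate:
    """Ratio of group means on the log scale, with a bootstrap CI.

    ratio = exp(mean(log a) - mean(log b)); the CI is the percentile
    interval over ``n_boot`` resamples (cluster bootstrap when cluster
    labels are supplied). Both groups must be positive throughout.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("forces must be positive for a log-scale ratio")
    la, lb = np.log(a), np.log(b)
    ratio = float(np.exp(la.mean() - lb.mean()))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ia = _boot_indices(rng, a.size, clusters_a)
        ib = _boot_indices(rng, b.size, clusters_b)
        boots[i] = np.exp(la[ia].mean() - lb[ib].mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return RatioEstimate(ratio=ratio, ci_low=float(lo), ci_high=float(hi),
                         n_a=int(a.size), n_b=int(b.size))


# --------------------------------------------------------------------------
# logistic success model


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100,
    names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """IRLS for logistic regression; returns (beta, cov, deviance, n_iter).

    Raises :class:`SeparationError` when coefficients diverge, naming the
    offending predictor.
    """
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    beta = np.zeros(p)
    dev = np.inf
    for it in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix (predictor {names[int(np.argmax(np.abs(beta)))]})"
            ) from exc
        if np.max(np.abs(beta_new)) > 30.0:
            j = int(np.argmax(np.abs(beta_new)))
            raise SeparationError(
                f"coefficients diverging: perfect separation on predictor '{names[j]}'"
            )
        beta = beta_new
        dev_new = -2.0 * float(
            np.sum(y * np.log(np.clip(expit(X @ beta), 1e-12, 1))
                   + (1 - y) * np.log(np.clip(1 - expit(X @ beta), 1e-12, 1)))
        )
        if abs(dev - dev_new) < tol:
            dev = dev_new
            break
        dev = dev_new
    mu = np.clip(expit(X @ beta), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov, dev, it + 1


@dataclass
class HuntingSuccessResults:
    """Fitted logistic success model: coefficients, ORs, diagnostics."""

    params: pd.Series
    bse: pd.Series
    nobs: int
    deviance: float
    n_iter: int
    force_sd: float  # sd used to z-score the pre-hunt force (N)
    cov: np.ndarray = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.params.index)

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """exp(coefficient) per unit predictor change, with Wald CIs."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "odds_ratio": np.exp(self.params),
                "ci_low": np.exp(ci["low"]),
                "ci_high": np.exp(ci["high"]),
            }
        )

    def or_per_newton(self, strategy: str = "sit_and_wait",
                      alpha: float = 0.05) -> tuple[float, float, float]:
        """Success odds ratio per +1 N of pre-hunt force, by strategy.

        Converts the z-scale force coefficients back to newtons and adds
        the interaction for the sit-and-wait branch. Returns
        (odds_ratio, ci_low, ci_high).
        """
        idx = list(self.params.index)
        c = np.zeros(len(idx))
        c[idx.index("force_z")] = 1.0
        if strategy == "sit_and_wait" and "force_z:sit_and_wait" in idx:
            c[idx.index("force_z:sit_and_wait")] = 1.0
        beta = float(c @ self.params.values) / self.force_sd
        se = float(np.sqrt(c @ self.cov @ c)) / self.force_sd
        z = norm.ppf(1 - alpha / 2)
        return float(np.exp(beta)), float(np.exp(beta - z * se)), float(np.exp(beta + z * se))

    def summary(self) -> str:
        ors = self.odds_ratios()
        lines = [
            "Hunting success logistic model (IRLS)",
            f"n = {self.nobs}, deviance = {self.deviance:.3f}, iterations = {self.n_iter}",
            f"{'predictor':<24}{'coef':>9}{'se':>8}{'OR':>8}{'2.5%':>8}{'97.5%':>8}{'p':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<24}{self.params[name]:>9.4f}{self.bse[name]:>8.4f}"
                f"{ors.loc[name, 'odds_ratio']:>8.3f}{ors.loc[name, 'ci_low']:>8.3f}"
                f"{ors.loc[name, 'ci_high']:>8.3f}{self.pvalues[name]:>9.4f}"
            )
        orn, lo, hi = self.or_per_newton("sit_and_wait")
        lines.append(
            f"sit-and-wait success OR per +1 N pre-hunt force: "
            f"{orn:.3f} (95% CI {lo:.3f}-{hi:.3f})"
        )
        return "\n".join(lines)


class HuntingSuccessModel:
    """Logistic model of hunting success vs pre-hunt force and strategy.

    ``attempts`` needs columns: success (bool), strategy
    ('sit_and_wait' | 'on_the_wing'), prehunt_perch_force_N, and
    optionally sex. Rows with strategy 'excluded' or missing force are
    dropped (and counted in ``n_dropped``). The force is z-scored before
    fitting; the design is intercept + force_z + sit_and_wait + sex_M +
    sex_M x sit_and_wait (sex terms only when both sexes are present) +
    force_z x sit_and_wait: force x strategy plus sex and the
    sex x strategy interaction.
    """

    def __init__(self, attempts: pd.DataFrame):
        df = attempts.copy()
        n0 = len(df)
        df = df[df["strategy"].isin(["sit_and_wait", "on_the_wing"])]
        df = df[np.isfinite(df["prehunt_perch_force_N"].astype(float))]
        self.n_dropped = n0 - len(df)
        if len(df) == 0:
            raise ValueError("no usable attempts (need strategy + pre-hunt force)")
        y = df["success"].astype(float).values
        if len(np.unique(y)) < 2:
            raise SeparationError("outcome has a single class; cannot fit")
        force = df["prehunt_perch_force_N"].astype(float).values
        self.force_sd = float(force.std(ddof=0))
        if self.force_sd == 0:
            raise ValueError("pre-hunt force has zero variance")
        force_z = (force - force.mean()) / self.force_sd
        sw = (df["strategy"] == "sit_and_wait").astype(float).values
        cols = {"intercept": np.ones(len(df)), "force_z": force_z, "sit_and_wait": sw}
        if "sex" in df.columns and df["sex"].nunique() > 1:
            sex_m = (df["sex"] == "M").astype(float).values
            cols["sex_M"] = sex_m
            cols["sex_M:sit_and_wait"] = sex_m * sw
        cols["force_z:sit_and_wait"] = force_z * sw
        self.names = list(cols)
        self.X = np.column_stack(list(cols.values()))
        self.y = y

    @classmethod
    def from_dataframe(cls, attempts: pd.DataFrame) -> "HuntingSuccessModel":
        return cls(attempts)

    def fit(self, tol: float = 1e-8, max_iter: int = 100) -> HuntingSuccessResults:
        beta, cov, dev, n_iter = _irls_logistic(
            self.X, self.y, tol=tol, max_iter=max_iter, names=self.names
        )
        return HuntingSuccessResults(
            params=pd.Series(beta, index=self.names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=self.names),
            nobs=len(self.y),
            deviance=dev,
            n_iter=n_iter,
            force_sd=self.force_sd,
            cov=cov,
        )


def fit_success_glm(attempts: pd.DataFrame, **kwargs) -> HuntingSuccessResults:
    """Convenience wrapper: build and fit :class:`HuntingSuccessModel`."""
    return HuntingSuccessModel(attempts).fit(**kwargs)


# --------------------------------------------------------------------------
# penalized-spline force trend with derivative band


def _bspline_design(x: np.ndarray, k: int, xmin: float, xmax: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline design matrix with ``k`` basis functions on [xmin, xmax]."""
    degree = 3
    n_interior = k - degree - 1
    if n_interior < 0:
        raise ValueError("need at least 4 basis functions")
    interior = np.linspace(xmin, xmax, n_interior + 2)[1:-1]
    knots = np.concatenate([[xmin] * (degree + 1), interior, [xmax] * (degree + 1)])
    xc = np.clip(x, xmin, xmax)
    design = BSpline.design_matrix(xc, knots, degree).toarray()
    return design, knots


@dataclass
class ForceTrendResult:
    """Smoothed force vs time-to-hunt with a derivative significance mask."""

    perch_type: str
    grid: np.ndarray  # time to next hunt, s
    fitted: np.ndarray  # N
    band_low: np.ndarray
    band_high: np.ndarray
    derivative: np.ndarray  # N/s, w.r.t. time-to-next-hunt
    deriv_band_low: np.ndarray
    deriv_band_high: np.ndarray
    #: force declining as the hunt approaches: on a time-UNTIL-hunt axis
    #: that is a significantly positive slope (band entirely above zero)
    significant_decline_mask: np.ndarray
    n: int
    lam: float

    @property
    def significant_mask(self) -> np.ndarray:
        """Grid points where the derivative band excludes zero (either sign)."""
        return (self.deriv_band_high < 0) | (self.deriv_band_low > 0)


class ForceTrendModel:
    """Penalized B-spline smooth of log landing force on time-to-hunt.

    The smooth uses ``k`` cubic B-spline bases with a second-difference
    penalty; the penalty weight is chosen by GCV. ``fit`` evaluates the
    curve (back on the newton scale), its finite-difference first
    derivative, and max-deviation bootstrap simultaneous bands for both;
    the decline mask marks grid points whose derivative band lies
    entirely below zero.
    """

    def __init__(self, time_to_hunt: np.ndarray, force_n: np.ndarray,
                 perch_type: str = "all", min_events: int = 50):
        x = np.asarray(time_to_hunt, dtype=float)
        y = np.asarray(force_n, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y) & (y > 0)
        self.x, self.y = x[ok], y[ok]
        self.perch_type = perch_type
        self.min_events = min_events

    @staticmethod
    def _penalty(k: int) -> np.ndarray:
        d = np.diff(np.eye(k), n=2, axis=0)
        return d.T @ d

    def _solve(self, B: np.ndarray, ly: np.ndarray, lam: float, P: np.ndarray) -> np.ndarray:
        return np.linalg.solve(B.T @ B + lam * P, B.T @ ly)

    def fit(self, k: int = 9, n_boot: int = 200, seed: int = 0,
            grid_size: int = 100, lam: float | None = None) -> ForceTrendResult | None:
        if self.x.size < self.min_events:
            warnings.warn(
                f"only {self.x.size} events for perch type {self.perch_type!r}; "
                "trend not estimated", stacklevel=2,
            )
            return None
        x, y = self.x, self.y
        ly = np.log(y)
        xmin, xmax = float(x.min()), float(x.max())
        B, knots = _bspline_design(x, k, xmin, xmax)
        P = self._penalty(B.shape[1])

        if lam is None:
            lam = self._gcv(B, ly, P)
        coef = self._solve(B, ly, lam, P)

        grid = np.linspace(xmin, xmax, grid_size)
        Bg, _ = _bspline_design(grid, k, xmin, xmax)
        fitted = np.exp(Bg @ coef)
        deriv = np.gradient(fitted, grid)

        rng = np.random.default_rng(seed)
        n = x.size
        boot_fit = np.empty((n_boot, grid_size))
        boot_der = np.empty((n_boot, grid_size))
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            Bb, _ = _bspline_design(x[idx], k, xmin, xmax)
            try:
                cb = self._solve(Bb, ly[idx], lam, P)
            except np.linalg.LinAlgError:
                cb = coef
            fb = np.exp(Bg @ cb)
            boot_fit[b] = fb
            boot_der[b] = np.gradient(fb, grid)

        band_lo, band_hi = _simultaneous_band(fitted, boot_fit)
        dband_lo, dband_hi = _simultaneous_band(deriv, boot_der)
        return ForceTrendResult(
            perch_type=self.perch_type,
            grid=grid,
            fitted=fitted,
            band_low=band_lo,
            band_high=band_hi,
            derivative=deriv,
            deriv_band_low=dband_lo,
            deriv_band_high=dband_hi,
            significant_decline_mask=dband_lo > 0,
            n=int(n),
            lam=float(lam),
        )

    #: accept the smoothest lambda within this relative margin of the GCV
    #: minimum (parsimony rule; avoids spurious wiggle when GCV is flat)
    gcv_margin: float = 2e-3

    def _gcv(self, B: np.ndarray, ly: np.ndarray, P: np.ndarray) -> float:
        n = B.shape[0]
        BtB = B.T @ B
        lams = np.logspace(-2, 6, 25)
        gcvs = np.empty(len(lams))
        for i, lam in enumerate(lams):
            A = np.linalg.solve(BtB + lam * P, BtB)
            edf = np.trace(A)
            coef = np.linalg.solve(BtB + lam * P, B.T @ ly)
            rss = float(np.sum((ly - B @ coef) ** 2))
            gcvs[i] = n * rss / (n - edf) ** 2
        ok = gcvs <= gcvs.min() * (1.0 + self.gcv_margin)
        return float(lams[np.flatnonzero(ok)[-1]])


def _simultaneous_band(est: np.ndarray, boots: np.ndarray,
                       level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Max-deviation simultaneous band around ``est`` from bootstrap curves."""
    sd = boots.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.finfo(float).eps)
    dev = np.abs(boots - est) / sd
    c = np.quantile(dev.max(axis=1), level)
    return est - c * sd, est + c * sd


def trend_with_derivative(
    perch_events: pd.DataFrame,
    by_perch_type: bool = True,
    k: int = 9,
    n_boot: int = 200,
    seed: int = 0,
) -> dict[str, ForceTrendResult | None]:
    """Fit :class:`ForceTrendModel` per perch type (or pooled)."""
    out: dict[str, ForceTrendResult | None] = {}
    if by_perch_type and "perch_type" in perch_events.columns:
        groups = perch_events.groupby("perch_type")
    else:
        groups = [("all", perch_events)]
    for name, grp in groups:
        model = ForceTrendModel(
            grp["time_to_next_hunt"].values, grp["force_N"].values, perch_type=str(name)
        )
        out[str(name)] = model.fit(k=k, n_boot=n_boot, seed=seed)
    return out


# --------------------------------------------------------------------------
# descriptive tables


def _boot_ci(values: np.ndarray, stat, rng, n_boot: int,
             clusters: np.ndarray | None = None) -> tuple[float, float]:
    if len(values) < 2:
        v = float(stat(values)) if len(values) else float("nan")
        return v, v
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = _boot_indices(rng, len(values), clusters)
        boots[i] = stat(values[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(lo), float(hi)


def descriptive_tables(
    landings: pd.DataFrame | None = None,
    attempts: pd.DataFrame | None = None,
    trips: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy summary table of the headline descriptive quantities.

    One row per (metric, group) with value, bootstrap CI and n. Covers
    per-sex landing forces in N and N/kg (with the F/M ratio rows),
    body-weight multiples, per sex x strategy success rates, flight
    speeds (with the F - M gap), sit-and-wait frequency, and trip
    durations. Prey-loaded perching events are excluded from force rows.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def add(metric, group, values, stat=np.mean, clusters=None):
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if values.size == 0:
            return None
        val = float(stat(values))
        lo, hi = _boot_ci(values, stat, rng, n_boot, clusters)
        rows.append(
            {"metric": metric, "group": group, "value": val,
             "ci_low": lo, "ci_high": hi, "n": int(values.size)}
        )
        return val

    if landings is not None and len(landings):
        ld = landings
        if "loaded_with_prey" in ld.columns:
            ld = ld[~ld["loaded_with_prey"].astype(bool)]
        for subtype in ("perch", "strike"):
            sub = ld[ld["subtype"] == subtype]
            means = {}
            for sex in ("F", "M"):
                grp = sub[sub["sex"] == sex]
                cl = grp["owl_id"].values if "owl_id" in grp.columns else None
                means[sex] = add(f"{subtype}_force_N", sex, grp["force_N"].values, clusters=cl)
                if "force_per_kg" in grp.columns:
                    add(f"{subtype}_force_per_kg", sex, grp["force_per_kg"].values, clusters=cl)
                if "bw_multiple" in grp.columns:
                    add(f"{subtype}_bw_multiple", sex, grp["bw_multiple"].values, clusters=cl)
            if means.get("F") and means.get("M"):
                rows.append(
                    {"metric": f"{subtype}_force_N", "group": "F/M",
                     "value": means["F"] / means["M"], "ci_low": np.nan,
                     "ci_high": np.nan, "n": int(len(sub))}
                )
            if "bw_multiple" in sub.columns and len(sub):
                add(f"{subtype}_bw_multiple", "all", sub["bw_multiple"].values)

    if attempts is not None and len(attempts):
        att = attempts[attempts["strategy"] != "excluded"]
        for sex in ("F", "M"):
            for strat in ("sit_and_wait", "on_the_wing"):
                grp = att[(att["sex"] == sex) & (att["strategy"] == strat)]
                if len(grp):
                    add(f"success_rate_{strat}", sex, grp["success"].astype(float).values)
            sexed = att[att["sex"] == sex]
            if len(sexed):
                add("sw_frequency", sex,
                    (sexed["strategy"] == "sit_and_wait").astype(float).values)
        speeds = {}
        for sex in ("F", "M"):
            grp = att[(att["sex"] == sex) & (att["strategy"] == "on_the_wing")]
            if "flight_speed" in grp.columns and len(grp):
                speeds[sex] = add("flight_speed", sex, grp["flight_speed"].values)
        if speeds.get("F") is not None and speeds.get("M") is not None:
            rows.append(
                {"metric": "flight_speed", "group": "F-M",
                 "value": speeds["F"] - speeds["M"], "ci_low": np.nan,
                 "ci_high": np.nan, "n": int(len(att))}
            )

    if trips is not None and len(trips):
        add("trip_duration_min", "all", trips["duration_min"].values)

    return pd.DataFrame(rows, columns=["metric", "group", "value", "ci_low", "ci_high", "n"])


def bodyweight_multiple_from_force(force_n: float, body_mass: float) -> float:
    """Convenience mirror of events.bodyweight_multiple for stats callers."""
    return force_n / (body_mass * G0)
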