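"""Effect sizes, mixed models and permutation-based community analysis.

Three families of tools:

* **Paired drought effect sizes.**  The drought effect on a variable is the
  log response ratio logRR = ln(mean_drought / mean_control) of paired
  plots, with each plot first averaged over all sampling dates.  Per
  management, the mean logRR and its 95 % interval come from a mixed model
  with management as fixed effect and site as random intercept; the effect
  is called significant when the interval excludes 0.

* **Management models.**  A restricted-maximum-likelihood (REML) linear
  mixed model core supporting two presets: random site intercept with a
  separate residual variance per sampling time (for enrichment responses),
  and crossed site and time random intercepts with a common residual
  variance (for biomass responses).  The fixed effect of interest is the
  management contrast.  A singular fit (zero between-group variance) falls
  back to heteroscedastic generalized least squares with a flag.

* **Community ordination and tests.**  Hellinger transform, Bray-Curtis
  dissimilarity, principal coordinates analysis (Gower double centring),
  PERMANOVA, PERMDISP and vector fitting of environmental variables, all
  permutation-based with the (1 + #{perm >= obs}) / (1 + n_perm) p-value
  estimator and 999 permutations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "PermutationTestResult",
    "hellinger",
    "bray_curtis",
    "PCoAResult",
    "pcoa",
    "permanova",
    "permdisp",
    "fit_vectors",
    "MixedModelResult",
    "ManagementModel",
    "fit_management_model",
    "EffectSizeResult",
    "LogRRModel",
    "log_response_ratio",
]


# ===========================================================================
# REML mixed-model core
# ===========================================================================


def _codes(values) -> np.ndarray:
    return pd.Categorical(values).codes.astype(int)


def _indicator(codes: np.ndarray) -> np.ndarray:
    n_levels = codes.max() + 1
    z = np.zeros((len(codes), n_levels))
    z[np.arange(len(codes)), codes] = 1.0
    return z


def _reml_neg_loglik(theta, y, x, z_blocks, resid_codes, n_resid):
    theta = np.clip(theta, -25.0, 25.0)
    n, p = x.shape
    n_rand = len(z_blocks)
    v = np.zeros((n, n))
    for j, z in enumerate(z_blocks):
        v += np.exp(theta[j]) * (z @ z.T)
    sig2 = np.exp(theta[n_rand : n_rand + n_resid])
    v[np.diag_indices(n)] += sig2[resid_codes]
    try:
        l_chol = np.linalg.cholesky(v)
    except np.linalg.LinAlgError:
        return 1e12
    logdet_v = 2.0 * np.log(np.diag(l_chol)).sum()
    vi_y = np.linalg.solve(v, y)
    vi_x = np.linalg.solve(v, x)
    xtvx = x.T @ vi_x
    sign, logdet_xvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(xtvx, x.T @ vi_y)
    r = y - x @ beta
    quad = float(r @ np.linalg.solve(v, r))
    return 0.5 * (logdet_v + logdet_xvx + quad)


@dataclass
class MixedModelResult:
    """REML fit of a linear mixed model.

    ``params``/``bse``/CI cover the fixed effects; variance components are
    on the natural (variance) scale.  ``fallback_gls`` is set when the
    random-effect variance collapsed to the boundary and the model was
    refit as (possibly heteroscedastic) GLS.
    """

    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    variance_components: dict
    residual_variances: dict
    converged: bool
    fallback_gls: bool
    reml_criterion: float
    nobs: int
    _v: np.ndarray = field(repr=False, default=None)
    _x: np.ndarray = field(repr=False, default=None)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def predicted_mean(self, contrast: np.ndarray, alpha: float = 0.05):
        """Estimate, SE and Wald CI of a linear combination of fixed effects."""
        c = np.asarray(contrast, dtype=float)
        est = float(c @ self.params.values)
        se = float(np.sqrt(c @ self.cov_params.values @ c))
        z = sps.norm.ppf(1.0 - alpha / 2.0)
        return est, se, (est - z * se, est + z * se)

    def summary(self) -> str:
        lines = ["Mixed model (REML)", "=" * 50]
        ci = self.conf_int()
        for name in self.params.index:
            lines.append(
                f"{name:>24s} {self.params[name]:10.4f} (SE {self.bse[name]:.4f}) "
                f"[{ci.loc[name, 'lower']:.4f}, {ci.loc[name, 'upper']:.4f}]"
            )
        for name, v in self.variance_components.items():
            lines.append(f"{'var(' + name + ')':>24s} {v:10.4f}")
        for name, v in self.residual_variances.items():
            lines.append(f"{'resid var ' + str(name):>24s} {v:10.4f}")
        if self.fallback_gls:
            lines.append("note: singular random effect; heteroscedastic GLS fallback")
        return "\n".join(lines)


def _reml_fit(
    y: np.ndarray,
    x: np.ndarray,
    param_names: Sequence[str],
    random_factors: dict,
    resid_codes: np.ndarray | None,
    resid_labels: Sequence | None,
) -> MixedModelResult:
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if resid_codes is None:
        resid_codes = np.zeros(n, dtype=int)
        resid_labels = ["common"]
    n_resid = int(resid_codes.max()) + 1
    z_blocks = [_indicator(codes) for codes in random_factors.values()]

    var0 = np.log(max(np.var(y), 1e-6))
    theta0 = np.full(len(z_blocks) + n_resid, var0)
    theta0[: len(z_blocks)] -= 1.0  # start random effects below the residual

    res = optimize.minimize(
        _reml_neg_loglik,
        theta0,
        args=(y, x, z_blocks, resid_codes, n_resid),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
    )
    theta = np.clip(res.x, -25.0, 25.0)
    resid_var = np.exp(theta[len(z_blocks) :])
    rand_var = dict(zip(random_factors, np.exp(theta[: len(z_blocks)])))

    # boundary / singular detection: if a random variance is near-negligible,
    # refit without any random effect and keep the reduced model when its
    # REML criterion is not worse (the variance sat on the boundary)
    fallback = False
    if z_blocks and any(v < 1e-3 * resid_var.mean() for v in rand_var.values()):
        res_red = optimize.minimize(
            _reml_neg_loglik,
            theta[len(z_blocks) :],
            args=(y, x, [], resid_codes, n_resid),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-12},
        )
        if res_red.fun <= res.fun + 1e-6:
            fallback = True
            res = res_red
            theta = np.clip(res.x, -25.0, 25.0)
            rand_var = {k: 0.0 for k in rand_var}
            z_blocks = []
            resid_var = np.exp(theta)

    v = np.zeros((n, n))
    for var, z in zip(rand_var.values(), z_blocks):
        v += var * (z @ z.T)
    v[np.diag_indices(n)] += resid_var[resid_codes]
    vi_x = np.linalg.solve(v, x)
    xtvx = x.T @ vi_x
    cov = np.linalg.inv(xtvx)
    beta = cov @ (vi_x.T @ y)
    return MixedModelResult(
        params=pd.Series(beta, index=list(param_names)),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=list(param_names)),
        cov_params=pd.DataFrame(cov, index=list(param_names), columns=list(param_names)),
        variance_components=rand_var,
        residual_variances=dict(zip(resid_labels, resid_var)),
        converged=bool(res.success),
        fallback_gls=fallback,
        reml_criterion=float(res.fun),
        nobs=n,
        _v=v,
        _x=x,
    )


class ManagementModel:
    """Mixed model for a management effect on a per-plot response.

    preset ``"enrichment"``: random site intercept, separate residual
    variance per sampling time (enrichment variability shrinks strongly as
    the tracer dilutes).  preset ``"biomass"``: crossed site and time random
    intercepts, common residual variance.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value_col: str,
        management_col: str = "management",
        site_col: str = "site",
        time_col: str = "day",
        preset: str = "enrichment",
    ):
        if preset not in ("enrichment", "biomass"):
            raise ValueError(f"unknown preset {preset!r}")
        data = data.dropna(subset=[value_col]).reset_index(drop=True)
        if data[site_col].nunique() < 2:
            raise ValueError("need at least 2 sites")
        self.data = data
        self.preset = preset
        self.value_col = value_col
        levels = sorted(data[management_col].unique())
        if len(levels) != 2:
            raise ValueError("management must have exactly 2 levels")
        self.levels = levels
        self._y = data[value_col].to_numpy(dtype=float)
        self._x = np.column_stack(
            [np.ones(len(data)), (data[management_col] == levels[1]).astype(float)]
        )
        self._names = ["intercept", f"management[{levels[1]}]"]
        self._site = _codes(data[site_col])
        self._time = _codes(data[time_col])
        self._time_labels = sorted(data[time_col].unique())

    def fit(self) -> MixedModelResult:
        if self.preset == "enrichment":
            return _reml_fit(
                self._y, self._x, self._names,
                random_factors={"site": self._site},
                resid_codes=self._time if len(self._time_labels) > 1 else None,
                resid_labels=self._time_labels if len(self._time_labels) > 1 else None,
            )
        return _reml_fit(
            self._y, self._x, self._names,
            random_factors={"site": self._site, "time": self._time},
            resid_codes=None,
            resid_labels=None,
        )


def fit_management_model(
    data: pd.DataFrame, value_col: str, preset: str = "enrichment", **kwargs
) -> MixedModelResult:
    """Convenience wrapper: build and fit a :class:`ManagementModel`."""
    return ManagementModel(data, value_col, preset=preset, **kwargs).fit()


# ===========================================================================
# logRR effect sizes
# ===========================================================================


@dataclass
class EffectSizeResult:
    """Per-management drought effect sizes with mixed-model intervals."""

    pairs: pd.DataFrame          # one row per paired plot with its logRR
    per_management: pd.DataFrame  # logRR mean, CI and significance flag
    model: MixedModelResult | None

    def summary(self) -> str:
        lines = ["Drought logRR (paired plots, averaged over sampling dates)", "=" * 60]
        for row in self.per_management.itertuples():
            star = "*" if row.significant else " "
            lines.append(
                f"{row.management:>12s}  logRR = {row.logRR:8.4f} "
                f"[{row.ci_low:8.4f}, {row.ci_high:8.4f}] n={row.n_pairs} {star}"
            )
        return "\n".join(lines)


class LogRRModel:
    """Paired drought/control log response ratios for one variable.

    *data* is long format with site, management, treatment, replicate, day
    and the value column.  Each plot is averaged across its sampling dates,
    plots are paired by site x management x replicate, and the per-pair
    logRR = ln(drought mean / control mean).  Pairs with a non-positive
    mean are dropped with a warning flag in ``dropped_pairs``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value_col: str,
        management_col: str = "management",
        treatment_col: str = "treatment",
        site_col: str = "site",
        replicate_col: str = "replicate",
        control_label: str = "control",
        drought_label: str = "drought",
    ):
        plot_means = (
            data.dropna(subset=[value_col])
            .groupby([site_col, management_col, treatment_col, replicate_col])[value_col]
            .mean()
            .rename("mean_value")
            .reset_index()
        )
        wide = plot_means.pivot_table(
            index=[site_col, management_col, replicate_col],
            columns=treatment_col,
            values="mean_value",
        ).reset_index()
        ok = (wide.get(control_label, np.nan) > 0) & (wide.get(drought_label, np.nan) > 0)
        self.dropped_pairs = wide.loc[~ok]
        wide = wide.loc[ok].copy()
        wide["logRR"] = np.log(wide[drought_label] / wide[control_label])
        self.pairs = wide.rename(
            columns={site_col: "site", management_col: "management", replicate_col: "replicate"}
        )[["site", "management", "replicate", control_label, drought_label, "logRR"]]

    def fit(self, alpha: float = 0.05) -> EffectSizeResult:
        pairs = self.pairs
        if pairs.empty:
            raise ValueError("no usable pairs (all means non-positive or missing)")
        managements = sorted(pairs["management"].unique())
        if len(managements) == 2 and pairs["site"].nunique() >= 2:
            # cell-means coding: one predicted mean per management
            x = np.column_stack(
                [(pairs["management"] == m).astype(float) for m in managements]
            )
            fit = _reml_fit(
                pairs["logRR"].to_numpy(float), x,
                [f"mean[{m}]" for m in managements],
                random_factors={"site": _codes(pairs["site"])},
                resid_codes=None, resid_labels=None,
            )
            rows = []
            for i, m in enumerate(managements):
                contrast = np.zeros(len(managements))
                contrast[i] = 1.0
                est, se, (lo, hi) = fit.predicted_mean(contrast, alpha=alpha)
                rows.append(
                    {
                        "management": m, "logRR": est, "se": se,
                        "ci_low": lo, "ci_high": hi,
                        "n_pairs": int((pairs["management"] == m).sum()),
                        "significant": bool(lo > 0 or hi < 0),
                    }
                )
            return EffectSizeResult(pairs, pd.DataFrame(rows), fit)
        # single management level (or single site): plain t interval
        rows = []
        for m in managements:
            vals = pairs.loc[pairs["management"] == m, "logRR"].to_numpy(float)
            est = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            tq = sps.t.ppf(1 - alpha / 2, max(len(vals) - 1, 1))
            lo, hi = est - tq * se, est + tq * se
            rows.append(
                {
                    "management": m, "logRR": est, "se": se,
                    "ci_low": lo, "ci_high": hi, "n_pairs": len(vals),
                    "significant": bool(lo > 0 or hi < 0),
                }
            )
        return EffectSizeResult(pairs, pd.DataFrame(rows), None)


def log_response_ratio(data: pd.DataFrame, value_col: str, **kwargs) -> EffectSizeResult:
    """Convenience wrapper: build and fit a :class:`LogRRModel`."""
    return LogRRModel(data, value_col, **kwargs).fit()


# ===========================================================================
# community analysis
# ===========================================================================


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    permuted: np.ndarray = field(repr=False, default=None)

    def summary(self) -> str:
        return (
            f"pseudo-F = {self.statistic:.4f}, p = {self.p_value:.4f} "
            f"({self.n_permutations} permutations)"
        )


def hellinger(matrix) -> np.ndarray:
    """Hellinger transform: entry -> sqrt(value / row sum).

    Scale-invariant per row; rejects negative entries and zero rows.
    """
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("community data must be non-negative")
    row_sums = m.sum(axis=1)
    bad = np.where(row_sums <= 0)[0]
    if bad.size:
        raise ValueError(f"zero-total rows at positions {bad.tolist()}")
    return np.sqrt(m / row_sums[:, None])


def bray_curtis(matrix) -> np.ndarray:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y)."""
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise ValueError("community data must be non-negative")
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(m[i] - m[i + 1 :]).sum(axis=1)
        den = (m[i] + m[i + 1 :]).sum(axis=1)
        if np.any(den == 0):
            raise ValueError("two all-zero rows: distance undefined")
        d[i, i + 1 :] = num / den
        d[i + 1 :, i] = d[i, i + 1 :]
    return d


@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates: columns ordered by decreasing eigenvalue.

    ``coordinates`` keeps only non-negative-eigenvalue axes; the imaginary
    part of the configuration (negative eigenvalues, possible for
    non-Euclidean dissimilarities like Bray-Curtis) is kept separately for
    centroid geometry.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    imaginary_coordinates: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(distances) -> PCoAResult:
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-10 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg = vals < -tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return PCoAResult(
        coordinates=coords,
        eigenvalues=vals[pos],
        imaginary_coordinates=imag,
        negative_eigenvalues=vals[neg],
    )


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        members = np.where(codes == g)[0]
        if len(members) < 2:
            continue
        sub = d2[np.ix_(members, members)]
        ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_among = ss_total - ss_within
    df_among = n_groups - 1
    df_within = n - n_groups
    return (ss_among / df_among) / (ss_within / df_within)


def permanova(
    distances, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """One-way PERMANOVA: pseudo-F from among/within sums of squared distances.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under free
    permutation of rows.
    """
    d = np.asarray(distances, dtype=float)
    codes = _codes(groups)
    n_groups = codes.max() + 1
    counts = np.bincount(codes)
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        raise ValueError("every group needs at least 2 members")
    d2 = d**2
    f_obs = _permanova_f(d2, codes, n_groups)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = _permanova_f(d2, rng.permutation(codes), n_groups)
    p = (1.0 + np.sum(perms >= f_obs)) / (1.0 + n_permutations)
    return PermutationTestResult(float(f_obs), float(p), n_permutations, perms)


def _dispersion_distances(d: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Distance of each point to its group centroid in full PCoA space.

    Imaginary axes contribute negatively to the squared distance (Anderson's
    correction for non-Euclidean dissimilarities); small negative squared
    distances are clipped at zero.
    """
    res = pcoa(d)
    z2 = np.zeros(d.shape[0])
    for g in range(n_groups):
        members = codes == g
        c_real = res.coordinates[members].mean(axis=0)
        z2[members] = ((res.coordinates[members] - c_real) ** 2).sum(axis=1)
        if res.imaginary_coordinates.size:
            c_imag = res.imaginary_coordinates[members].mean(axis=0)
            z2[members] -= ((res.imaginary_coordinates[members] - c_imag) ** 2).sum(axis=1)
    return np.sqrt(np.clip(z2, 0.0, None))


def _anova_f(z: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = len(z)
    grand = z.mean()
    ss_among = ss_within = 0.0
    for g in range(n_groups):
        vals = z[codes == g]
        ss_among += len(vals) * (vals.mean() - grand) ** 2
        ss_within += ((vals - vals.mean()) ** 2).sum()
    if ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))


def permdisp(
    distances, groups, n_permutations: int = 999, seed: int | None = None
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Per-point centroid distances are computed in PCoA space; the F statistic
    is a one-way ANOVA on those distances and the null distribution comes
    from permuting the least-squares residuals.
    """
    d = np.asarray(distances, dtype=float)
    codes = _codes(groups)
    n_groups = codes.max() + 1
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if np.any(np.bincount(codes) < 2):
        raise ValueError("every group needs at least 2 members")
    z = _dispersion_distances(d, codes, n_groups)
    f_obs = _anova_f(z, codes, n_groups)
    group_means = np.array([z[codes == g].mean() for g in range(n_groups)])
    resid = z - group_means[codes]
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    grand = z.mean()
    for b in range(n_permutations):
        z_star = grand + rng.permutation(resid)
        perms[b] = _anova_f(z_star, codes, n_groups)
    p = (1.0 + np.sum(perms >= f_obs)) / (1.0 + n_permutations)
    return PermutationTestResult(float(f_obs), float(p), n_permutations, perms)


def fit_vectors(
    coordinates,
    variables: pd.DataFrame,
    n_permutations: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Project variables onto the first two ordination axes.

    Least-squares fit of each (centred) variable on the axis scores gives a
    direction vector and a squared correlation R²; significance is assessed
    by permuting the variable's rows.  Variables significant at *alpha* are
    flagged ``retained``; constant variables are skipped.
    """
    xy = np.asarray(coordinates, dtype=float)[:, :2]
    xy = xy - xy.mean(axis=0)
    rng = np.random.default_rng(seed)
    gram_inv = np.linalg.pinv(xy.T @ xy)

    def r2_and_b(y):
        b = gram_inv @ (xy.T @ y)
        fitted = xy @ b
        denom = float(y @ y)
        return (float(fitted @ y) / denom if denom > 0 else 0.0), b

    rows = []
    for name in variables.columns:
        y = variables[name].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.any(~np.isfinite(y)):
            continue
        y = y - y.mean()
        r2, b = r2_and_b(y)
        perms = np.empty(n_permutations)
        for k in range(n_permutations):
            perms[k] = r2_and_b(rng.permutation(y))[0]
        p = (1.0 + np.sum(perms >= r2)) / (1.0 + n_permutations)
        norm = np.linalg.norm(b)
        direction = b / norm if norm > 0 else b
        rows.append(
            {
                "variable": name, "r_squared": r2, "p_value": p,
                "axis1": direction[0] * np.sqrt(r2),
                "axis2": direction[1] * np.sqrt(r2),
                "retained": bool(p <= alpha),
            }
        )
    return pd.DataFrame(rows)
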