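"""Maximum-likelihood twin variance-component models (ACE family).

The classical twin design decomposes phenotypic variance into additive
genetic (A), dominance genetic (D), common-environment (C) and
unique-environment (E) components by contrasting monozygotic (MZ) and
dizygotic (DZ) within-pair covariance.  Each pair is modelled as an
exchangeable bivariate normal with common mean μ and variance
σ² = a² + d² + c² + e²; the within-pair covariance is

    MZ: a² + d² + c²          DZ: ½·a² + ¼·d² + c²

D and C are never co-estimated (twin-only identifiability limit), so
the fitted models are ACE, ADE, AE, CE and E, compared by AIC and
likelihood-ratio tested against a saturated per-zygosity exchangeable
model (mean, variance, covariance per zygosity; 6 parameters).

Paths enter the likelihood as squares of unconstrained reals, so
variance components are non-negative by construction and boundary
solutions (e.g. â² = 0) are attainable.  The log-likelihood is
evaluated from per-zygosity sufficient statistics, making each
evaluation O(1) in the number of pairs.

`TwinVarianceModel` follows the scikit-learn estimator protocol:
``fit(X, zygosity)`` with X of shape (n_pairs, 2), fitted attributes
with trailing underscores, `get_params`/`set_params` inherited from
``BaseEstimator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "MODELS",
    "TwinPairSet",
    "TwinModelFit",
    "DegenerateData",
    "ConvergenceFailure",
    "TwinVarianceModel",
    "twin_log_likelihood",
    "fit_twin_model",
    "fit_saturated",
    "select_model",
    "component_confidence_intervals",
    "pairwise_correlation",
]

# paths estimated by each model, beyond the mean
MODELS: dict[str, tuple[str, ...]] = {
    "E": ("e",),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "ACE": ("a", "c", "e"),
    "ADE": ("a", "d", "e"),
}
_PATHS = ("a", "d", "c", "e")


class DegenerateData(ValueError):
    """Zero phenotypic variance or too few pairs."""


class ConvergenceFailure(RuntimeError):
    """No optimizer start converged."""


@dataclass(frozen=True)
class TwinPairSet:
    """Paired phenotypes: arrays of shape (n_pairs, 2) per zygosity."""

    mz: np.ndarray
    dz: np.ndarray
    phenotype_label: str = "phenotype"

    def __post_init__(self):
        for name in ("mz", "dz"):
            x = np.asarray(getattr(self, name), dtype=float)
            if x.size and (x.ndim != 2 or x.shape[1] != 2):
                raise ValueError(f"{name} must have shape (n_pairs, 2)")
            if np.isnan(x).any():
                raise ValueError(f"missing phenotype within an included {name} pair")
            object.__setattr__(self, name, x.reshape(-1, 2))

    @classmethod
    def from_frame(cls, df, value_col: str, label: str | None = None) -> "TwinPairSet":
        """Build from a long frame with subject_id, pair_id, zygosity columns.

        Siblings are ordered within pair by subject_id (canonical
        ordering; the likelihood is exchangeable so fits do not depend
        on it, correlations are made reproducible by it).
        """
        d = (
            df[["pair_id", "zygosity", "subject_id", value_col]]
            .dropna(subset=[value_col])
            .sort_values(["pair_id", "subject_id"], kind="stable")
        )
        complete = d.groupby("pair_id")["subject_id"].transform("size") == 2
        d = d[complete]
        vals = d[value_col].to_numpy(dtype=float).reshape(-1, 2)
        zyg = d["zygosity"].to_numpy()[::2]
        return cls(
            mz=vals[zyg == "MZ"],
            dz=vals[zyg == "DZ"],
            phenotype_label=label or value_col,
        )


@dataclass
class TwinModelFit:
    model: str
    a2: float
    d2: float
    c2: float
    e2: float
    variance: float
    mean: float
    log_likelihood: float
    n_parameters: int
    aic: float
    chi2_vs_saturated: float | None = None
    p_vs_saturated: float | None = None
    df_vs_saturated: int | None = None
    ci_95: dict[str, tuple[float, float]] = field(default_factory=dict)
    paths: dict[str, float] = field(default_factory=dict)

    @property
    def standardized(self) -> dict[str, float]:
        return {"a2": self.a2, "d2": self.d2, "c2": self.c2, "e2": self.e2}


@dataclass(frozen=True)
class _SuffStats:
    """Per-zygosity sufficient statistics of the exchangeable likelihood."""

    n: int
    sum_x: float  # Σ (x1 + x2)
    sum_sq: float  # Σ (x1² + x2²)
    sum_cross: float  # Σ x1·x2

    @classmethod
    def of(cls, pairs: np.ndarray) -> "_SuffStats":
        if pairs.size == 0:
            return cls(0, 0.0, 0.0, 0.0)
        return cls(
            n=pairs.shape[0],
            sum_x=float(pairs.sum()),
            sum_sq=float((pairs**2).sum()),
            sum_cross=float((pairs[:, 0] * pairs[:, 1]).sum()),
        )

    def neg2ll(self, mu: float, var: float, cov: float) -> float:
        """−2·log-likelihood of n exchangeable bivariate normal pairs."""
        det = var * var - cov * cov
        if det <= 0 or var <= 0:
            return np.inf
        ss = self.sum_sq - 2 * mu * self.sum_x + 2 * self.n * mu * mu
        sc = self.sum_cross - mu * self.sum_x + self.n * mu * mu
        quad = (var * ss - 2 * cov * sc) / det
        return 2 * self.n * np.log(2 * np.pi) + self.n * np.log(det) + quad


def _implied_moments(params: dict[str, float]) -> tuple[float, float, float]:
    a2 = params.get("a", 0.0) ** 2
    d2 = params.get("d", 0.0) ** 2
    c2 = params.get("c", 0.0) ** 2
    e2 = params.get("e", 0.0) ** 2
    var = a2 + d2 + c2 + e2
    return var, a2 + d2 + c2, 0.5 * a2 + 0.25 * d2 + c2


def twin_log_likelihood(
    pairs: TwinPairSet, model: str, mean: float, **paths: float
) -> float:
    """Log-likelihood of a twin model at given mean and path coefficients.

    Returns −inf (never raises) when the implied pair covariance matrix
    is not positive definite.
    """
    if model == "ACDE":
        raise ValueError("ACDE is not identifiable from twin data alone")
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    extra = set(paths) - set(MODELS[model])
    if extra:
        raise ValueError(f"model {model} does not take paths {sorted(extra)}")
    var, cov_mz, cov_dz = _implied_moments(paths)
    smz, sdz = _SuffStats.of(pairs.mz), _SuffStats.of(pairs.dz)
    n2 = smz.neg2ll(mean, var, cov_mz) + sdz.neg2ll(mean, var, cov_dz)
    return -np.inf if not np.isfinite(n2) else -0.5 * n2


def fit_saturated(pairs: TwinPairSet) -> TwinModelFit:
    """Closed-form MLE of the per-zygosity exchangeable bivariate normal.

    Rotating to s = x1+x2, d = x1−x2 (independent normals) gives the
    exact MLE per zygosity: μ̂ = mean of all values, V̂s = mean (s−2μ̂)²,
    V̂d = mean d², σ̂² = (V̂s+V̂d)/4, côv = (V̂s−V̂d)/4.
    """
    ll = 0.0
    total_var = []
    means = []
    for grp in (pairs.mz, pairs.dz):
        if grp.shape[0] < 2:
            raise DegenerateData("need >=2 pairs per zygosity for the saturated model")
        mu = grp.mean()
        s = grp.sum(axis=1) - 2 * mu
        d = grp[:, 0] - grp[:, 1]
        vs = float(np.mean(s**2))
        vd = float(np.mean(d**2))
        var = (vs + vd) / 4.0
        cov = (vs - vd) / 4.0
        if var <= 0:
            raise DegenerateData("zero phenotypic variance in one zygosity group")
        ll -= 0.5 * _SuffStats.of(grp).neg2ll(mu, var, cov)
        total_var.append(var)
        means.append(mu)
    k = 6
    return TwinModelFit(
        model="saturated",
        a2=np.nan,
        d2=np.nan,
        c2=np.nan,
        e2=np.nan,
        variance=float(np.mean(total_var)),
        mean=float(np.mean(means)),
        log_likelihood=float(ll),
        n_parameters=k,
        aic=float(-2 * ll + 2 * k),
    )


def _path_starts(pairs: TwinPairSet, names: tuple[str, ...]) -> list[np.ndarray]:
    """Deterministic multi-start values from moment (Falconer) estimates
    plus fixed perturbations, for any subset of path names."""
    allv = np.concatenate([pairs.mz.ravel(), pairs.dz.ravel()])
    mu0, v0 = float(allv.mean()), float(allv.var())
    if v0 <= 0:
        raise DegenerateData("zero phenotypic variance")

    def corr(grp):
        if grp.shape[0] < 3:
            return 0.0
        r = np.corrcoef(grp[:, 0], grp[:, 1])[0, 1]
        return float(np.clip(r, -0.95, 0.95)) if np.isfinite(r) else 0.0

    rmz, rdz = corr(pairs.mz), corr(pairs.dz)
    # Falconer-style moment proportions, clipped into the simplex
    moment = {
        "a": float(np.clip(2 * (rmz - rdz), 0.02, 0.9)),
        "c": float(np.clip(2 * rdz - rmz, 0.02, 0.9)),
        "d": float(np.clip(4 * (rmz - 2 * rdz) / 3, 0.02, 0.9)),
        "e": float(np.clip(1 - rmz, 0.05, 0.95)),
    }
    k = len(names)
    prop_sets: list[dict[str, float]] = []
    total = sum(moment[p] for p in names)
    prop_sets.append({p: moment[p] / total for p in names})
    prop_sets.append({p: 1.0 / k for p in names})
    for major in names:
        prop_sets.append(
            {p: (0.75 if p == major else 0.25 / max(k - 1, 1)) for p in names}
        )
    starts = []
    for props in prop_sets:
        starts.append(
            np.array([mu0] + [np.sqrt(props[p] * v0) for p in names], dtype=float)
        )
    return starts


def _ml_fit(
    pairs: TwinPairSet,
    names: tuple[str, ...],
    smz: _SuffStats,
    sdz: _SuffStats,
    tol: float,
) -> tuple[float, dict[str, float], float]:
    """Multi-start Nelder-Mead ML over (mean, paths); returns
    (mean, path values, log-likelihood)."""

    def neg_ll(theta: np.ndarray) -> float:
        paths = dict(zip(names, theta[1:]))
        var, cov_mz, cov_dz = _implied_moments(paths)
        n2 = smz.neg2ll(theta[0], var, cov_mz) + sdz.neg2ll(theta[0], var, cov_dz)
        return np.inf if not np.isfinite(n2) else 0.5 * n2

    best = None
    for x0 in _path_starts(pairs, names):
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tol, "maxiter": 4000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise ConvergenceFailure(f"no start converged for paths {names}")
    mu = float(best.x[0])
    paths = {p: float(abs(v)) for p, v in zip(names, best.x[1:])}
    return mu, paths, -float(best.fun)


def fit_twin_model(
    pairs: TwinPairSet, model: str, tol: float = 1e-10
) -> TwinModelFit:
    """Maximum-likelihood fit of one twin model with AIC and LRT vs saturated.

    After the multi-start optimization, nested fits with each genetic or
    shared-environment path removed are compared; when a reduced fit
    attains the same likelihood (within 1e-7) the boundary solution is
    adopted exactly, so estimates such as â² = 0 are reported as 0."""
    if model == "saturated":
        return fit_saturated(pairs)
    if model == "ACDE":
        raise ValueError(
            "ACDE is not identifiable from twin data alone: D and C cannot be "
            "co-estimated with only MZ/DZ contrasts"
        )
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    names = MODELS[model]
    smz, sdz = _SuffStats.of(pairs.mz), _SuffStats.of(pairs.dz)

    mu, path_vals, ll = _ml_fit(pairs, names, smz, sdz, tol)
    free = list(names)
    improved = True
    while improved and len(free) > 1:
        improved = False
        for p in [q for q in free if q != "e"]:
            sub = tuple(q for q in free if q != p)
            mu2, paths2, ll2 = _ml_fit(pairs, sub, smz, sdz, tol)
            if ll2 >= ll - 1e-7:
                mu, ll = mu2, max(ll, ll2)
                path_vals = {**{q: 0.0 for q in free}, **paths2}
                free = list(sub)
                improved = True
                break

    comps = {p: path_vals.get(p, 0.0) ** 2 for p in _PATHS}
    var = sum(comps.values())
    std = {p: comps[p] / var for p in _PATHS}
    k = 1 + len(names)
    try:
        sat = fit_saturated(pairs)
        chi2 = max(2.0 * (sat.log_likelihood - ll), 0.0)
        df = sat.n_parameters - k
    except DegenerateData:  # e.g. a single-zygosity dataset
        chi2, df = np.nan, 0
    return TwinModelFit(
        model=model,
        a2=std["a"],
        d2=std["d"],
        c2=std["c"],
        e2=std["e"],
        variance=var,
        mean=mu,
        log_likelihood=ll,
        n_parameters=k,
        aic=-2 * ll + 2 * k,
        chi2_vs_saturated=chi2,
        p_vs_saturated=float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan,
        df_vs_saturated=df,
        paths=path_vals,
    )


def select_model(fits: list[TwinModelFit]) -> TwinModelFit:
    """Lowest AIC wins; ties broken toward the model with fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    return min(fits, key=lambda f: (f.aic, f.n_parameters))


def component_confidence_intervals(
    fit: TwinModelFit,
    pairs: TwinPairSet,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = 0,
    method: str = "bootstrap",
) -> dict[str, tuple[float, float]]:
    """CIs for the standardized components of a fitted model.

    Default: nonparametric bootstrap resampling pairs within zygosity,
    refitting, percentile interval.  Failed replicates are skipped and
    counted (`fit.ci_95` gains a '_n_failed' entry when any fail).
    ``method='delta'`` uses a finite-difference observed-information
    delta approximation instead.  Boundary components truncate at 0.
    """
    comp_names = [p + "2" for p in MODELS[fit.model]]
    if level == 0:
        return {c: (getattr(fit, c), getattr(fit, c)) for c in comp_names}
    if method == "delta":
        return _delta_cis(fit, pairs, level, comp_names)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {c: [] for c in comp_names}
    n_failed = 0
    for _ in range(n_boot):
        idx_mz = rng.integers(0, len(pairs.mz), len(pairs.mz)) if len(pairs.mz) else []
        idx_dz = rng.integers(0, len(pairs.dz), len(pairs.dz)) if len(pairs.dz) else []
        rs = TwinPairSet(pairs.mz[idx_mz], pairs.dz[idx_dz], pairs.phenotype_label)
        try:
            bfit = fit_twin_model(rs, fit.model)
        except (DegenerateData, ConvergenceFailure):
            n_failed += 1
            continue
        for c in comp_names:
            draws[c].append(getattr(bfit, c))
    q = (1 - level) / 2
    cis = {
        c: (
            max(float(np.quantile(v, q)), 0.0),
            min(float(np.quantile(v, 1 - q)), 1.0),
        )
        for c, v in draws.items()
        if v
    }
    if n_failed:
        cis["_n_failed"] = (n_failed, n_boot)  # type: ignore[assignment]
    return cis


def _delta_cis(fit, pairs, level, comp_names):
    """Delta-method CIs from a finite-difference Hessian in (mean, paths)."""
    names = MODELS[fit.model]
    theta = np.array([fit.mean] + [fit.paths[p] for p in names])

    def nll(th):
        return -twin_log_likelihood(pairs, fit.model, th[0], **dict(zip(names, th[1:])))

    h = 1e-5 * np.maximum(np.abs(theta), 1.0)
    k = len(theta)
    hess = np.zeros((k, k))
    f0 = nll(theta)
    for i in range(k):
        for j in range(i, k):
            ei, ej = np.zeros(k), np.zeros(k)
            ei[i], ej[j] = h[i], h[j]
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei) - nll(theta + ej) + f0
            ) / (h[i] * h[j])
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    var_total = fit.variance
    z = stats.norm.ppf(0.5 + level / 2)
    cis = {}
    for c in comp_names:
        p = c[0]
        i = 1 + names.index(p)
        # d(std comp)/d(path_j): quotient rule on path_p² / Σ path_j²
        grad = np.zeros(k)
        for jn, pj in enumerate(names):
            pv = fit.paths[pj]
            if pj == p:
                grad[1 + jn] = 2 * pv * (var_total - pv**2) / var_total**2
            else:
                grad[1 + jn] = -2 * pv * fit.paths[p] ** 2 / var_total**2
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        est = getattr(fit, c)
        cis[c] = (max(est - z * se, 0.0), min(est + z * se, 1.0))
    return cis


def pairwise_correlation(
    pairs: TwinPairSet, zygosity: str, level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation of (sib1, sib2) with a Fisher-z CI.

    No double entry; sibling order is the canonical (subject_id) order
    fixed when the TwinPairSet was built.
    """
    grp = pairs.mz if zygosity.upper() == "MZ" else pairs.dz
    n = grp.shape[0]
    if n < 3:
        raise ValueError(f"need >=3 {zygosity} pairs, have {n}")
    r = float(np.corrcoef(grp[:, 0], grp[:, 1])[0, 1])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zq = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    return r, (float(lo), float(hi))


class TwinVarianceModel(BaseEstimator):
    """Scikit-learn style estimator for one twin variance-component model.

    Parameters
    ----------
    model : one of 'ACE', 'ADE', 'AE', 'CE', 'E', 'saturated'
    ci : None, 'bootstrap' or 'delta' — whether/how to compute CIs in fit
    n_boot, seed : bootstrap settings
    """

    def __init__(self, model: str = "ACE", ci: str | None = None,
                 n_boot: int = 1000, seed: int = 0):
        self.model = model
        self.ci = ci
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, zygosity):
        """Fit on X of shape (n_pairs, 2) with per-pair zygosity labels."""
        X = np.asarray(X, dtype=float)
        zyg = np.asarray(zygosity)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have shape (n_pairs, 2)")
        if len(zyg) != len(X):
            raise ValueError("zygosity must have one label per pair")
        pairs = TwinPairSet(mz=X[zyg == "MZ"], dz=X[zyg == "DZ"])
        res = fit_twin_model(pairs, self.model)
        if self.ci:
            res.ci_95 = component_confidence_intervals(
                res, pairs, n_boot=self.n_boot, seed=self.seed, method=self.ci
            )
        self.result_ = res
        self.a2_, self.d2_, self.c2_, self.e2_ = res.a2, res.d2, res.c2, res.e2
        self.variance_, self.mean_ = res.variance, res.mean
        self.log_likelihood_, self.aic_ = res.log_likelihood, res.aic
        self.ci_95_ = res.ci_95
        return self

    def score(self, X=None, zygosity=None):
        """Log-likelihood of the fitted parameters (on the training set)."""
        if X is None:
            return self.log_likelihood_
        X = np.asarray(X, dtype=float)
        zyg = np.asarray(zygosity)
        pairs = TwinPairSet(mz=X[zyg == "MZ"], dz=X[zyg == "DZ"])
        if self.model == "saturated":
            raise ValueError("scoring new data is defined for path models only")
        r = self.result_
        return twin_log_likelihood(pairs, self.model, r.mean, **r.paths)
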