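"""Per-taxon count regressions and their summary machinery.

Negative binomial (NB2, log link) models each taxon's count with ln(sequencing
depth) as an offset, so coefficients are log rate ratios on relative abundance.
Beta-binomial models the taxon's reads out of the library depth with a logit
link on the mean proportion and an intra-class correlation rho, so
coefficients are log odds ratios.  Both are fit per taxon over a shared design
matrix with reference-coded categoricals (first-seen level = reference).

Non-convergence is data, not an exception: failed taxa are listed separately
and can be routed to rank-sum / chi-squared fallback tests.  Summaries follow
the two standard tables: per-coefficient estimates with profile-likelihood CIs
and per-covariate likelihood-ratio tests, and an estimate table of
exponentiated (contrast) coefficients with Wald CIs and BH-adjusted p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .io_core import MicroSet

logger = logging.getLogger("microtide")

__all__ = [
    "FitControl",
    "ModelSpec",
    "DesignInfo",
    "TaxaModelFit",
    "TaxaModelSet",
    "build_design",
    "fit_nb",
    "fit_bb",
    "taxa_models",
    "covariate_lrt",
    "profile_ci",
    "profile_interval",
    "bh_adjust",
    "estimate_table",
    "summary_table",
    "rank_taxa_test",
    "presence_chisq",
]

INTERCEPT = "(Intercept)"


@dataclass
class FitControl:
    """Optimizer settings shared by the NB and BB fitters."""

    maxiter: int = 200
    tol: float = 1e-8
    theta_bounds: tuple[float, float] = (1e-4, 1e6)


@dataclass
class ModelSpec:
    """Which table to model, with which terms and family.

    ``terms`` are covariate names; ``"A:B"`` is an interaction (both main
    effects must be declared), ``"A*B"`` expands to ``A, B, A:B``.  ``offset``
    adds ln(depth) to the linear predictor (NB only).
    """

    table: str
    terms: list[str]
    offset: bool = True
    family: str = "negbin"

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("model terms must be non-empty")
        if self.family not in ("negbin", "betabin"):
            raise ValueError(f"family must be 'negbin' or 'betabin', got {self.family!r}")

    def expanded_terms(self) -> list[str]:
        out: list[str] = []
        for t in self.terms:
            t = t.replace(" ", "")
            if "*" in t:
                parts = t.split("*")
                for p in parts:
                    if p not in out:
                        out.append(p)
                inter = ":".join(parts)
                if inter not in out:
                    out.append(inter)
            elif t not in out:
                out.append(t)
        for t in out:
            if ":" in t:
                for comp in t.split(":"):
                    if comp not in out:
                        raise ValueError(
                            f"interaction {t!r} references undeclared main effect {comp!r}"
                        )
        return out


@dataclass
class DesignInfo:
    """Everything needed to rebuild design rows at arbitrary covariate profiles."""

    terms: list[str]
    column_names: list[str]
    term_columns: dict[str, list[str]]
    variables: dict[str, dict]  # name -> {"kind": "categorical", "levels": [...]} | {"kind": "numeric", "mean": float}

    def columns_for_term_family(self, term: str) -> list[str]:
        """Columns of `term` plus of every interaction involving it."""
        cols = list(self.term_columns[term])
        for t, tc in self.term_columns.items():
            if ":" in t and term in t.split(":"):
                cols += tc
        return cols

    def make_row(self, settings: dict | None = None) -> np.ndarray:
        """One design row at a covariate profile.

        Unspecified categoricals sit at their reference level and numerics at
        their observed mean.
        """
        settings = settings or {}
        vals: dict[str, float] = {INTERCEPT: 1.0}
        base: dict[str, dict[str, float]] = {}
        for var, info in self.variables.items():
            if info["kind"] == "categorical":
                lvl = settings.get(var, info["levels"][0])
                if lvl not in info["levels"]:
                    raise ValueError(f"unknown level {lvl!r} for {var!r}")
                base[var] = {f"{var}{l}": float(lvl == l) for l in info["levels"][1:]}
            else:
                base[var] = {var: float(settings.get(var, info["mean"]))}
        for term in self.terms:
            comps = term.split(":")
            combos: list[tuple[str, float]] = [("", 1.0)]
            for comp in comps:
                combos = [
                    (f"{nm}:{cn}" if nm else cn, v * cv)
                    for nm, v in combos
                    for cn, cv in base[comp].items()
                ]
            for nm, v in combos:
                vals[nm] = v
        return np.array([vals[c] for c in self.column_names])


def build_design(frame: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix from a per-library covariate frame (reference coding)."""
    terms = spec.expanded_terms()
    for t in terms:
        for comp in t.split(":"):
            if comp not in frame.columns:
                raise KeyError(f"covariate {comp!r} not found in clinical data")
    var_cols: dict[str, dict[str, np.ndarray]] = {}
    variables: dict[str, dict] = {}
    for t in terms:
        for var in t.split(":"):
            if var in var_cols:
                continue
            ser = frame[var]
            if isinstance(ser.dtype, pd.CategoricalDtype) or ser.dtype == object:
                cat = ser if isinstance(ser.dtype, pd.CategoricalDtype) else pd.Categorical(ser)
                levels = list(cat.cat.categories if hasattr(cat, "cat") else cat.categories)
                codes = (cat.cat.codes if hasattr(cat, "cat") else cat.codes).to_numpy()
                var_cols[var] = {
                    f"{var}{lvl}": (codes == k).astype(float)
                    for k, lvl in enumerate(levels) if k > 0
                }
                variables[var] = {"kind": "categorical", "levels": levels}
            else:
                x = ser.to_numpy(dtype=float)
                var_cols[var] = {var: x}
                variables[var] = {
                    "kind": "numeric", "mean": float(np.nanmean(x)),
                    "min": float(np.nanmin(x)), "max": float(np.nanmax(x)),
                }
    column_names = [INTERCEPT]
    columns = [np.ones(len(frame))]
    term_columns: dict[str, list[str]] = {}
    for term in terms:
        comps = term.split(":")
        combo: list[tuple[str, np.ndarray]] = [("", np.ones(len(frame)))]
        for comp in comps:
            combo = [
                (f"{nm}:{cn}" if nm else cn, v * cv)
                for nm, v in combo
                for cn, cv in var_cols[comp].items()
            ]
        term_columns[term] = [nm for nm, _ in combo]
        for nm, v in combo:
            column_names.append(nm)
            columns.append(v)
    X = np.column_stack(columns)
    return X, DesignInfo(terms=terms, column_names=column_names,
                         term_columns=term_columns, variables=variables)


@dataclass
class TaxaModelFit:
    """One taxon's fitted model, with the data kept for refits (LRT, profiling)."""

    taxon: str
    family: str
    coef_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    dispersion: float  # theta for NB, rho for BB
    loglik: float
    converged: bool
    n_obs: int
    reason: str = ""
    y: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)
    offset: np.ndarray = field(default=None, repr=False)   # NB linear-predictor offset
    trials: np.ndarray = field(default=None, repr=False)   # BB denominators

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


@dataclass
class TaxaModelSet:
    """All per-taxon fits of one table under one model spec."""

    spec: ModelSpec
    design: DesignInfo
    fits: list[TaxaModelFit]
    failed: list[TaxaModelFit]
    libraries: list[str]
    mean_log_depth: float = 0.0

    @property
    def converged_taxa(self) -> list[str]:
        return [f.taxon for f in self.fits]

    @property
    def failed_taxa(self) -> list[str]:
        return [f.taxon for f in self.failed]

    def fit_for(self, taxon: str) -> TaxaModelFit:
        for f in self.fits + self.failed:
            if f.taxon == taxon:
                return f
        raise KeyError(f"no fit for taxon {taxon!r}")


def _failed_fit(taxon, family, names, y, X, reason, offset=None, trials=None) -> TaxaModelFit:
    p = len(names)
    return TaxaModelFit(
        taxon=taxon, family=family, coef_names=list(names),
        beta=np.full(p, np.nan), cov=np.full((p, p), np.nan),
        dispersion=np.nan, loglik=np.nan, converged=False,
        n_obs=len(y), reason=reason, y=y, X=X, offset=offset, trials=trials,
    )


def _nb_loglik_fixed_mu(y: np.ndarray, mu: np.ndarray, control: FitControl) -> float:
    """Max NB2 log-likelihood over theta with the mean vector held fixed."""
    lo, hi = np.log(control.theta_bounds[0]), np.log(control.theta_bounds[1])

    def nll(log_theta: float) -> float:
        th = np.exp(log_theta)
        return -stats.nbinom.logpmf(y, th, th / (th + mu)).sum()

    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    return -res.fun


def fit_nb(
    y,
    X,
    offset=None,
    control: FitControl | None = None,
    coef_names: list[str] | None = None,
    taxon: str = "",
) -> TaxaModelFit:
    """Negative binomial (NB2) maximum-likelihood fit of one taxon.

    Rank-deficient designs and degenerate responses (all zero) are flagged as
    non-converged rather than raised.  The covariance is the inverse observed
    information at the optimum, for the regression coefficients only.
    """
    from statsmodels.discrete.discrete_model import NegativeBinomial

    control = control or FitControl()
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    names = coef_names or [f"x{j}" for j in range(X.shape[1])]
    off = None if offset is None else np.asarray(offset, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _failed_fit(taxon, "negbin", names, y, X, "rank-deficient", offset=off)
    if not (y > 0).any():
        return _failed_fit(taxon, "negbin", names, y, X, "all-zero counts", offset=off)
    beta = cov = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NegativeBinomial(y, X, offset=off, loglike_method="nb2")
            res = model.fit(disp=0, maxiter=control.maxiter, gtol=control.tol,
                            method="bfgs")
            converged = bool(res.mle_retvals.get("converged", False))
            if not converged:
                res = model.fit(disp=0, maxiter=4 * control.maxiter, method="nm",
                                start_params=res.params)
                converged = bool(res.mle_retvals.get("converged", False))
            params = np.asarray(res.params)
            with np.errstate(all="ignore"):
                cov_full = np.asarray(res.cov_params())
            beta, alpha = params[:-1], params[-1]
            cov = cov_full[:-1, :-1]
            llf = float(res.llf)
    except Exception:
        beta = None
    # equidispersion boundary: alpha -> 0 degenerates the joint Hessian, so
    # take the Poisson solution for beta with theta pinned at its upper bound
    at_boundary = beta is None or not (
        np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))
    ) or alpha < 1.0 / control.theta_bounds[1]
    if at_boundary:
        import statsmodels.api as sm

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = sm.GLM(y, X, offset=off, family=sm.families.Poisson()).fit()
            beta = np.asarray(glm.params)
            cov = np.asarray(glm.cov_params())
            alpha = 1.0 / control.theta_bounds[1]
            th = control.theta_bounds[1]
            llf = float(stats.nbinom.logpmf(y, th, th / (th + glm.mu)).sum())
            converged = bool(glm.converged)
        except Exception as exc:
            return _failed_fit(taxon, "negbin", names, y, X,
                               f"fit error: {exc}", offset=off)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(cov)):
        return _failed_fit(taxon, "negbin", names, y, X, "non-finite estimates", offset=off)
    theta = 1.0 / alpha if alpha > 0 else np.inf
    theta = float(np.clip(theta, *control.theta_bounds))
    if np.any(np.diag(cov) <= 0):
        converged = False
    return TaxaModelFit(
        taxon=taxon, family="negbin", coef_names=names, beta=beta, cov=cov,
        dispersion=theta, loglik=llf, converged=converged, n_obs=len(y),
        reason="" if converged else "no convergence", y=y, X=X, offset=off,
    )


def _bb_nll(params: np.ndarray, y, n, X, offset) -> float:
    beta, r = params[:-1], params[-1]
    eta = X @ beta
    if offset is not None:
        eta = eta + offset
    mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
    rho = np.clip(expit(r), 1e-10, 1 - 1e-7)
    s = (1.0 - rho) / rho
    ll = stats.betabinom.logpmf(y, n, mu * s, (1.0 - mu) * s).sum()
    return np.inf if not np.isfinite(ll) else -ll


def fit_bb(
    y,
    n,
    X,
    control: FitControl | None = None,
    coef_names: list[str] | None = None,
    taxon: str = "",
    offset=None,
) -> TaxaModelFit:
    """Beta-binomial maximum-likelihood fit: logit link on the mean proportion.

    The intra-class correlation rho is parameterized on the logit scale so the
    optimizer is unconstrained.  Starting values come from a plain binomial
    GLM.  The covariance of beta is taken from the inverse numerical Hessian.
    """
    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess

    control = control or FitControl()
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.asarray(X, dtype=float)
    if (y < 0).any():
        raise ValueError("negative counts")
    if (y > n).any():
        raise ValueError("counts exceed trials (y > n)")
    names = coef_names or [f"x{j}" for j in range(X.shape[1])]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return _failed_fit(taxon, "betabin", names, y, X, "rank-deficient", trials=n)
    if not (y > 0).any():
        return _failed_fit(taxon, "betabin", names, y, X, "all-zero counts", trials=n)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(np.column_stack([y, n - y]), X, offset=offset,
                         family=sm.families.Binomial()).fit()
            start = np.append(np.asarray(glm.params), logit(0.05))
            res = optimize.minimize(
                _bb_nll, start, args=(y, n, X, offset), method="BFGS",
                options={"maxiter": control.maxiter, "gtol": 1e-6},
            )
            if not res.success:
                res2 = optimize.minimize(
                    _bb_nll, res.x, args=(y, n, X, offset), method="Nelder-Mead",
                    options={"maxiter": 200 * (X.shape[1] + 1), "fatol": control.tol},
                )
                if res2.fun <= res.fun:
                    res = res2
            hess = approx_hess(res.x, _bb_nll, args=(y, n, X, offset))
            cov_full = np.linalg.inv(hess)
            converged = bool(np.all(np.isfinite(res.x))) and np.all(
                np.diag(cov_full)[:-1] > 0
            )
    except Exception as exc:
        return _failed_fit(taxon, "betabin", names, y, X, f"fit error: {exc}", trials=n)
    beta = res.x[:-1]
    rho = float(expit(res.x[-1]))
    cov = cov_full[:-1, :-1]
    if not (np.all(np.isfinite(beta)) and np.all(np.isfinite(cov))):
        return _failed_fit(taxon, "betabin", names, y, X, "non-finite estimates", trials=n)
    return TaxaModelFit(
        taxon=taxon, family="betabin", coef_names=names, beta=beta, cov=cov,
        dispersion=rho, loglik=float(-res.fun),
        converged=converged, n_obs=len(y),
        reason="" if converged else "no convergence", y=y, X=X, trials=n, offset=offset,
    )


def taxa_models(
    micro_set: MicroSet,
    spec: ModelSpec,
    control: FitControl | None = None,
) -> TaxaModelSet:
    """Fit the spec's model to every taxon of one table.

    Libraries with missing covariate values are dropped with a warning.
    Non-converged taxa land in ``failed`` and flow to the fallback tests.
    """
    control = control or FitControl()
    clin = micro_set.clinical_frame(spec.table)
    needed = sorted({c for t in spec.expanded_terms() for c in t.split(":")})
    for c in needed:
        if c not in clin.columns:
            raise KeyError(f"covariate {c!r} not found in clinical data")
    ok = ~clin[needed].isna().any(axis=1)
    if not ok.all():
        dropped = clin.index[~ok].tolist()
        logger.warning("taxa_models: dropping %d libraries with missing covariates: %s",
                       len(dropped), dropped)
    libs = clin.index[ok].tolist()
    if not libs:
        raise ValueError("no libraries with complete covariates")
    X, design = build_design(clin.loc[libs], spec)
    cts = micro_set.wide(spec.table, "cts").loc[libs]
    depths = cts.sum(axis=1).to_numpy(dtype=float)
    log_depth = np.log(depths)
    fits: list[TaxaModelFit] = []
    failed: list[TaxaModelFit] = []
    for taxon in micro_set.tables[spec.table]:
        y = cts[taxon].to_numpy(dtype=float)
        if spec.family == "negbin":
            fit = fit_nb(y, X, offset=log_depth if spec.offset else None,
                         control=control, coef_names=design.column_names,
                         taxon=taxon)
        else:
            fit = fit_bb(y, depths, X, control=control,
                         coef_names=design.column_names, taxon=taxon)
        (fits if fit.converged else failed).append(fit)
        if not fit.converged:
            logger.info("taxa_models: %s did not converge (%s)", taxon, fit.reason)
    logger.info("taxa_models %s/%s: %d converged, %d failed",
                spec.table, spec.family, len(fits), len(failed))
    return TaxaModelSet(spec=spec, design=design, fits=fits, failed=failed,
                        libraries=libs, mean_log_depth=float(log_depth.mean()))


def _refit_loglik(fit: TaxaModelFit, X: np.ndarray, extra_offset=None,
                  control: FitControl | None = None) -> float:
    """Max log-likelihood of fit's family on a modified design (for LRT/profiling)."""
    control = control or FitControl()
    off = fit.offset
    if extra_offset is not None:
        off = extra_offset if off is None else off + extra_offset
    if fit.family == "negbin":
        if X.shape[1] == 0:
            mu = np.exp(off) if off is not None else np.ones_like(fit.y)
            return _nb_loglik_fixed_mu(fit.y, mu, control)
        sub = fit_nb(fit.y, X, offset=off, control=control)
    else:
        if X.shape[1] == 0:
            def nll(r):
                return _bb_nll(np.array([r]), fit.y, fit.trials,
                               np.zeros((len(fit.y), 0)), off)
            res = optimize.minimize_scalar(nll, bounds=(-15, 15), method="bounded")
            return -res.fun
        sub = fit_bb(fit.y, fit.trials, X, control=control, offset=off)
    if not sub.converged:
        raise RuntimeError(f"refit failed: {sub.reason}")
    return sub.loglik


def covariate_lrt(models: TaxaModelSet, fit: TaxaModelFit, term: str,
                  control: FitControl | None = None) -> float:
    """Likelihood-ratio p-value for an entire covariate (all its columns and
    interactions) in one taxon's converged fit."""
    if term not in models.design.term_columns:
        raise KeyError(f"term {term!r} not in model; terms are {models.design.terms}")
    if not fit.converged:
        return np.nan
    drop = set(models.design.columns_for_term_family(term))
    keep_idx = [j for j, c in enumerate(fit.coef_names) if c not in drop]
    df = len(fit.coef_names) - len(keep_idx)
    try:
        ll_red = _refit_loglik(fit, fit.X[:, keep_idx], control=control)
    except RuntimeError as exc:
        logger.warning("covariate_lrt %s/%s: reduced fit failed (%s)",
                       fit.taxon, term, exc)
        return np.nan
    lr = max(2.0 * (fit.loglik - ll_red), 0.0)
    return float(stats.chi2.sf(lr, df))


def profile_interval(
    pl_fun, mle: float, se: float, ll_max: float, level: float = 0.95,
) -> tuple[float, float]:
    """Profile-likelihood interval by root-finding on the signed LR statistic.

    `pl_fun(b)` must return the log-likelihood maximized over all other
    parameters with the focal coefficient fixed at b.  Raises RuntimeError
    when a bracket cannot be established.
    """
    q = stats.chi2.ppf(level, 1)

    def g(b: float) -> float:
        return 2.0 * (ll_max - pl_fun(b)) - q

    bounds = []
    for sign in (-1.0, 1.0):
        step = max(se, 1e-6)
        lo_b, hi_b = mle, mle
        found = False
        for k in range(1, 31):
            b = mle + sign * step * (1.5 ** k)
            val = g(b)
            if np.isfinite(val) and val > 0:
                hi_b = b
                found = True
                break
            lo_b = b
        if not found:
            raise RuntimeError("no bracket for profile limit")
        lo, hi = (hi_b, lo_b) if sign < 0 else (lo_b, hi_b)
        root = optimize.brentq(g, min(lo, hi), max(lo, hi), xtol=1e-8)
        bounds.append(root)
    return min(bounds), max(bounds)


def profile_ci(
    models: TaxaModelSet, fit: TaxaModelFit, level: float = 0.95,
    control: FitControl | None = None,
) -> pd.DataFrame:
    """Per-coefficient profile-likelihood CIs, falling back to Wald on failure."""
    if not fit.converged:
        raise ValueError(f"taxon {fit.taxon!r} did not converge")
    z = stats.norm.ppf(0.5 + level / 2.0)
    rows = []
    for j, name in enumerate(fit.coef_names):
        mle, se = fit.beta[j], fit.se[j]
        keep = [k for k in range(len(fit.coef_names)) if k != j]
        xj = fit.X[:, j]

        def pl(b, _keep=keep, _xj=xj):
            try:
                return _refit_loglik(fit, fit.X[:, _keep], extra_offset=b * _xj,
                                     control=control)
            except RuntimeError:
                return np.nan

        try:
            lo, hi = profile_interval(pl, mle, se, fit.loglik, level)
            method = "profile"
        except (RuntimeError, ValueError):
            logger.warning("profile_ci %s/%s: profiling failed, Wald fallback",
                           fit.taxon, name)
            lo, hi = mle - z * se, mle + z * se
            method = "wald"
        rows.append({"Coefficient": name, "ci_low": lo, "ci_high": hi,
                     "method": method})
    return pd.DataFrame(rows)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def _contrast_rows(fit: TaxaModelFit, design: DesignInfo) -> list[dict]:
    """Estimate-table rows: plain coefficients plus interaction contrasts.

    For every interaction column ``A<l>:B<m>`` two within-stratum contrasts
    are emitted: ``A<l> | B<m>`` (main + interaction) and ``B<m> | A<l>``,
    with variance summed over the contrast's covariance terms.
    """
    names = fit.coef_names
    idx = {c: j for j, c in enumerate(names)}
    rows = []
    for j, name in enumerate(names):
        rows.append({"Coefficient": name, "est": fit.beta[j],
                     "var": fit.cov[j, j]})
    for name in names:
        if ":" not in name:
            continue
        comps = name.split(":")
        for comp in comps:
            if comp not in idx:
                continue  # e.g. numeric-by-numeric component absent as a column
            others = [c for c in comps if c != comp]
            j, k = idx[comp], idx[name]
            est = fit.beta[j] + fit.beta[k]
            var = fit.cov[j, j] + fit.cov[k, k] + 2.0 * fit.cov[j, k]
            rows.append({"Coefficient": f"{comp} | {':'.join(others)}",
                         "est": est, "var": var})
    return rows


def estimate_table(models: TaxaModelSet, level: float = 0.95) -> pd.DataFrame:
    """Exponentiated (contrast) coefficients with Wald CIs and BH-FDR p-values.

    Rate ratios for NB models, odds ratios for BB.  FDR adjustment pools
    across taxa separately within each coefficient label.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    if not models.fits:
        raise ValueError("no converged fits to summarize")
    if models.failed:
        logger.info("estimate_table: omitting non-converged taxa: %s",
                    models.failed_taxa)
    rows = []
    for fit in models.fits:
        for r in _contrast_rows(fit, models.design):
            se = np.sqrt(r["var"])
            zstat = r["est"] / se if se > 0 else np.nan
            rows.append({
                "Taxa": fit.taxon,
                "Coefficient": r["Coefficient"],
                "ratio": np.exp(r["est"]),
                "ci_low": np.exp(r["est"] - z * se),
                "ci_high": np.exp(r["est"] + z * se),
                "z": zstat,
                "p": 2.0 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else np.nan,
            })
    df = pd.DataFrame(rows)
    df["fdr_p"] = np.nan
    for _, g in df.groupby("Coefficient"):
        df.loc[g.index, "fdr_p"] = bh_adjust(g["p"].to_numpy())
    return df


def summary_table(
    models: TaxaModelSet, level: float = 0.95, profile: bool = True,
    control: FitControl | None = None,
) -> pd.DataFrame:
    """Per-coefficient model summary: estimates, profile CIs, Wald tests,
    FDR-adjusted p-values, and per-covariate likelihood-ratio tests."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    if not models.fits:
        raise ValueError("no converged fits to summarize")
    rows = []
    for fit in models.fits:
        if profile:
            ci = profile_ci(models, fit, level, control).set_index("Coefficient")
        lrt_by_term = {
            t: covariate_lrt(models, fit, t, control) for t in models.design.terms
        }
        for j, name in enumerate(fit.coef_names):
            se = fit.se[j]
            zstat = fit.beta[j] / se if se > 0 else np.nan
            if profile:
                lo, hi = ci.loc[name, "ci_low"], ci.loc[name, "ci_high"]
            else:
                lo, hi = fit.beta[j] - z * se, fit.beta[j] + z * se
            term = next(
                (t for t, cols in models.design.term_columns.items() if name in cols),
                None,
            )
            rows.append({
                "Taxa": fit.taxon, "Coefficient": name,
                "Estimate": fit.beta[j], "ci_low": lo, "ci_high": hi,
                "z": zstat,
                "wald_p": 2.0 * stats.norm.sf(abs(zstat)) if np.isfinite(zstat) else np.nan,
                "lrt_p": lrt_by_term.get(term, np.nan) if term else np.nan,
            })
    df = pd.DataFrame(rows)
    df["fdr_p"] = np.nan
    for _, g in df.groupby("Coefficient"):
        df.loc[g.index, "fdr_p"] = bh_adjust(g["wald_p"].to_numpy())
    return df[["Taxa", "Coefficient", "Estimate", "ci_low", "ci_high",
               "z", "wald_p", "fdr_p", "lrt_p"]]


def _group_values(micro_set: MicroSet, table: str, group: str):
    clin = micro_set.clinical_frame(table)
    if group not in clin.columns:
        raise KeyError(f"group column {group!r} not found")
    g = clin[group]
    if isinstance(g.dtype, pd.CategoricalDtype):
        levels = [l for l in g.cat.categories]
    else:
        levels = list(pd.unique(g.dropna()))
    counts = g.value_counts()
    empty = [l for l in levels if counts.get(l, 0) == 0]
    if empty:
        raise ValueError(f"group level(s) with zero observations: {empty}")
    if len(levels) < 2:
        raise ValueError("group must have at least 2 levels")
    return g, levels


def rank_taxa_test(
    micro_set: MicroSet,
    table: str,
    group: str,
    on: str = "ra",
    failed_only: TaxaModelSet | None = None,
) -> pd.DataFrame:
    """Per-taxon rank tests of abundance across groups.

    Two groups: Wilcoxon rank-sum (exact when both groups have <= 8
    observations and no ties, otherwise the tie-corrected normal
    approximation).  More groups: Kruskal-Wallis.  BH adjustment across the
    tested taxa.  `failed_only` restricts to the non-converged taxa of a
    model set.
    """
    if on not in ("ra", "clr"):
        raise ValueError("on must be 'ra' or 'clr'")
    g, levels = _group_values(micro_set, table, group)
    vals = micro_set.wide(table, on)
    taxa = micro_set.tables[table]
    if failed_only is not None:
        taxa = [t for t in taxa if t in failed_only.failed_taxa]
    rows = []
    for taxon in taxa:
        v = vals[taxon]
        samples = [v[g == lvl].to_numpy() for lvl in levels]
        if len(levels) == 2:
            x, y = samples
            pooled = np.concatenate([x, y])
            exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method="exact" if exact else "asymptotic",
                use_continuity=False,
            )
            stat, p = float(res.statistic), float(res.pvalue)
            kind = "wilcoxon-exact" if exact else "wilcoxon-normal"
        else:
            try:
                res = stats.kruskal(*samples)
                stat, p = float(res.statistic), float(res.pvalue)
            except ValueError:  # all values identical
                stat, p = 0.0, 1.0
            kind = "kruskal-wallis"
        rows.append({"Taxa": taxon, "test": kind, "statistic": stat, "p": p})
    df = pd.DataFrame(rows, columns=["Taxa", "test", "statistic", "p"])
    df["fdr_p"] = bh_adjust(df["p"].to_numpy()) if len(df) else np.nan
    return df


def presence_chisq(
    micro_set: MicroSet,
    table: str,
    group: str,
    failed_only: TaxaModelSet | None = None,
) -> pd.DataFrame:
    """Per-taxon Pearson chi-squared test of presence/absence by group.

    No continuity correction.  Tables with an all-present or all-absent margin
    are flagged undefined rather than raised; cells with expected count < 5
    set the ``low_expected`` flag.
    """
    g, levels = _group_values(micro_set, table, group)
    bins = micro_set.wide(table, "bin")
    taxa = micro_set.tables[table]
    if failed_only is not None:
        taxa = [t for t in taxa if t in failed_only.failed_taxa]
    rows = []
    for taxon in taxa:
        b = bins[taxon]
        tab = np.array([
            [(b[g == lvl] == 0).sum(), (b[g == lvl] == 1).sum()] for lvl in levels
        ], dtype=float)
        if (tab.sum(axis=0) == 0).any():
            rows.append({"Taxa": taxon, "statistic": np.nan, "df": np.nan,
                         "p": np.nan, "low_expected": False, "degenerate": True})
            continue
        chi2_res = stats.chi2_contingency(tab, correction=False)
        rows.append({
            "Taxa": taxon, "statistic": float(chi2_res.statistic),
            "df": int(chi2_res.dof), "p": float(chi2_res.pvalue),
            "low_expected": bool((chi2_res.expected_freq < 5).any()),
            "degenerate": False,
        })
    df = pd.DataFrame(rows)
    ok = df["p"].notna()
    df["fdr_p"] = np.nan
    if ok.any():
        df.loc[ok, "fdr_p"] = bh_adjust(df.loc[ok, "p"].to_numpy())
    return df
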