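"""REML variance components, BLUEs, LRT, and heritability for factorial trials.

The observation model for a combined multi-environment factorial trial is

    y = mu + f + m + fm + s + fs + ms + fms + r(s) + e

with every term an independent zero-mean Gaussian random effect: female GCA
(f), male GCA (m), SCA (fm), environment (s), the three G-by-E interactions,
replicate nested in environment, and the plot residual.  The single-
environment model drops the environment terms and keeps f, m, fm, r, e.

Variance components are estimated by REML under non-negativity bounds.  Two
routes share one surface:

* a *spectral* route for balanced complete designs — every covariance term
  is a tensor product of identity and all-ones blocks over the
  (female, male, environment, replicate) grid, so all terms diagonalize in
  one fixed orthogonal basis and the restricted likelihood factorizes over
  a handful of eigen-classes (O(1) per likelihood evaluation after one
  pass over the data);
* a *dense* generic route for unbalanced data (profiled Gaussian REML with
  analytic gradients on the full n x n covariance).

The spectral route is exact REML, not an approximation; the two routes are
cross-checked against each other in the test suite.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "PlotRecordTable",
    "VarianceDecomposition",
    "HeritabilityReport",
    "FactorialREML",
    "fit_blues",
    "reml_single_env",
    "reml_combined",
    "lrt_term",
    "lrt_all_terms",
    "heritability_single",
    "heritability_combined",
    "cve",
    "spectra_band_decomposition",
    "significance_stars",
]

logger = logging.getLogger(__name__)

# random terms as (name, grouping factor columns); residual is implicit
COMBINED_TERMS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("f", ("female",)),
    ("m", ("male",)),
    ("fm", ("female", "male")),
    ("s", ("environment",)),
    ("fs", ("female", "environment")),
    ("ms", ("male", "environment")),
    ("fms", ("female", "male", "environment")),
    ("r_s", ("environment", "replicate")),
)
SINGLE_TERMS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("f", ("female",)),
    ("m", ("male",)),
    ("fm", ("female", "male")),
    ("r", ("replicate",)),
)

DISPLAY_NAMES = {
    "f": "GCA_f",
    "m": "GCA_m",
    "fm": "SCA",
    "s": "Env",
    "fs": "GCA_f x Env",
    "ms": "GCA_m x Env",
    "fms": "SCA x Env",
    "r_s": "Rep(Env)",
    "r": "Rep",
    "e": "Residual",
}


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Star coding at the 0.05 / 0.01 / 0.001 levels; 'NS' above alpha."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "NS"


# ---------------------------------------------------------------------------
# record table


@dataclass
class PlotRecordTable:
    """Validated long-format plot observations.

    One row per (environment, replicate, hybrid) with female/male parent
    labels and one column per trait.
    """

    frame: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    REQUIRED = ("environment", "replicate", "female", "male", "hybrid")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise KeyError(f"record table lacks columns: {missing}")
        if not self.traits:
            self.traits = [
                c
                for c in self.frame.columns
                if c not in self.REQUIRED and pd.api.types.is_numeric_dtype(self.frame[c])
            ]
        dup = self.frame.duplicated(subset=["environment", "replicate", "hybrid"])
        if dup.any():
            rows = self.frame.index[dup].tolist()[:5]
            raise ValueError(
                f"duplicate (environment, replicate, hybrid) rows at index {rows}"
            )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


def _frame(records) -> pd.DataFrame:
    return records.frame if isinstance(records, PlotRecordTable) else records


# ---------------------------------------------------------------------------
# results


@dataclass
class VarianceDecomposition:
    """REML estimates for one response, with optional LRT annotations."""

    estimates: dict[str, float]
    loglik: float
    converged: bool
    n_records: int
    model: str  # "single" or "combined"
    lrt_pvalues: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, term: str) -> float:
        return self.estimates[term]

    @property
    def total(self) -> float:
        return float(sum(self.estimates.values()))

    @property
    def percents(self) -> dict[str, float]:
        tot = self.total
        if tot <= 0:
            return {k: 0.0 for k in self.estimates}
        return {k: 100.0 * v / tot for k, v in self.estimates.items()}

    def stars(self) -> dict[str, str]:
        return {k: significance_stars(p) for k, p in self.lrt_pvalues.items()}

    def to_frame(self) -> pd.DataFrame:
        pct = self.percents
        rows = []
        for term, est in self.estimates.items():
            rows.append(
                {
                    "term": DISPLAY_NAMES.get(term, term),
                    "estimate": est,
                    "percent": pct[term],
                    "stars": significance_stars(self.lrt_pvalues[term])
                    if term in self.lrt_pvalues
                    else "",
                }
            )
        return pd.DataFrame(rows)


@dataclass
class HeritabilityReport:
    """Entry-mean heritabilities and the residual coefficient of variation."""

    H2: float
    h2: float | None
    h2_f: float | None
    h2_m: float | None
    cve_percent: float | None = None
    t: int | None = None
    r: int | None = None


# ---------------------------------------------------------------------------
# balanced spectral REML route


def _group_index(frame: pd.DataFrame, cols: tuple[str, ...]) -> np.ndarray:
    key = frame[list(cols)].apply(tuple, axis=1)
    codes, _ = pd.factorize(key)
    return codes


def _is_balanced(frame: pd.DataFrame, combined: bool) -> bool:
    """Complete factorial crossing with a constant replicate count."""
    axes = ["female", "male"] + (["environment"] if combined else [])
    sizes = [frame[a].nunique() for a in axes]
    counts = frame.groupby(axes, observed=True).size()
    if len(counts) != int(np.prod(sizes)):
        return False
    return counts.nunique() == 1


def _tensor_layout(frame: pd.DataFrame, response: str, combined: bool):
    """Reshape responses onto the (F, M, [S,] R) grid of a balanced design."""
    axes = ["female", "male"] + (["environment"] if combined else [])
    levels = [np.sort(frame[a].unique()) for a in axes]
    dims = [len(lv) for lv in levels]
    reps = len(frame) // int(np.prod(dims))
    idx = [
        pd.Categorical(frame[a], categories=lv).codes for a, lv in zip(axes, levels)
    ]
    # order replicates within cell by replicate label for determinism
    order = np.lexsort(
        (frame["replicate"].to_numpy(),) + tuple(reversed([i for i in idx]))
    )
    tensor = np.empty(dims + [reps])
    flat = frame[response].to_numpy(dtype=float)[order]
    tensor[...] = flat.reshape(dims + [reps])
    return tensor, dims + [reps]


def _balanced_classes(dims: list[int], terms, combined: bool):
    """Eigen-classes of the balanced-design covariance.

    Every random term's covariance is a tensor product of I (axes the term
    distinguishes) and all-ones J blocks (axes it averages over).  The
    common eigenbasis splits each axis into its mean direction and the
    contrast space; a *class* is one choice of mean/contrast per axis.
    Within class c the covariance is delta_c * I with

        delta_c = sigma2_e + sum_k lambda_{k,c} sigma2_k,
        lambda_{k,c} = prod(dims of the term's J-axes) if c is 'mean' on
                       all J-axes of term k, else 0.
    """
    n_axes = len(dims)
    if combined:
        axis_of = {"female": 0, "male": 1, "environment": 2, "replicate": 3}
    else:
        axis_of = {"female": 0, "male": 1, "replicate": 2}
    term_I_axes = []
    for _, cols in terms:
        term_I_axes.append({axis_of[c] for c in cols})
    classes = []
    for c in itertools.product((1, 0), repeat=n_axes):  # 1 = mean, 0 = contrast
        mult = 1
        for a, flag in enumerate(c):
            mult *= 1 if flag else dims[a] - 1
        if mult == 0:
            continue
        lam = []
        for I_axes in term_I_axes:
            J_axes = [a for a in range(n_axes) if a not in I_axes]
            if all(c[a] == 1 for a in J_axes):
                lam.append(float(np.prod([dims[a] for a in J_axes])))
            else:
                lam.append(0.0)
        classes.append((c, mult, np.array(lam)))
    return classes


def _class_ss(tensor: np.ndarray, c: tuple[int, ...]) -> float:
    """Squared norm of the projection of y onto eigen-class c."""
    proj = tensor
    scale = 1.0
    for axis, flag in enumerate(c):
        mean = proj.mean(axis=axis, keepdims=True)
        if flag:
            # mean axes collapse to length 1; the broadcast projection's
            # squared norm carries one factor of the axis length each
            proj = mean
            scale *= tensor.shape[axis]
        else:
            proj = proj - mean
    return scale * float((proj**2).sum())


def _reml_spectral(tensor: np.ndarray, dims: list[int], terms, combined: bool):
    n = int(np.prod(dims))
    classes = _balanced_classes(dims, terms, combined)
    # drop the grand-mean class (absorbed by the fixed intercept)
    grand = tuple([1] * len(dims))
    info = []
    for c, mult, lam in classes:
        if c == grand:
            continue
        info.append((mult, lam, _class_ss(tensor, c)))
    mults = np.array([m for m, _, _ in info], dtype=float)
    lams = np.stack([l for _, l, _ in info])  # classes x terms
    sss = np.array([s for _, _, s in info])
    k = lams.shape[1]

    vary = float(np.var(tensor))
    if vary == 0.0:
        est = np.zeros(k + 1)
        ll = _spectral_loglik(est, mults, lams, sss, n, floor=1e-12)
        return est, ll, True

    floor = max(vary, 1.0) * 1e-10

    def negll_grad(theta):
        delta = theta[-1] + lams @ theta[:-1]
        delta = np.maximum(delta, floor)
        nll = 0.5 * float(mults @ np.log(delta) + sss @ (1.0 / delta))
        common = mults / delta - sss / delta**2
        grad = np.empty(k + 1)
        grad[:-1] = 0.5 * (lams.T @ common)
        grad[-1] = 0.5 * common.sum()
        return nll, grad

    bounds = [(0.0, None)] * k + [(floor, None)]
    starts = [
        np.full(k + 1, vary / (k + 1)),
        np.concatenate([np.full(k, vary / (10 * k)), [0.9 * vary]]),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    est = np.asarray(best.x)
    est[:-1][est[:-1] < floor] = 0.0
    ll = _spectral_loglik(est, mults, lams, sss, n, floor)
    return est, ll, bool(best.success)


def _spectral_loglik(theta, mults, lams, sss, n, floor):
    delta = np.maximum(theta[-1] + lams @ theta[:-1], floor)
    ll = -0.5 * float(mults @ np.log(delta) + sss @ (1.0 / delta))
    # match the dense route's normalization (intercept-only fixed part)
    return ll - 0.5 * np.log(n) - 0.5 * (n - 1) * np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# dense generic REML route


def _reml_dense(
    y: np.ndarray,
    X: np.ndarray,
    groups: list[np.ndarray],
    tol: float = 1e-8,
    max_starts: int = 3,
):
    """Bounded REML on the full covariance V = sum_k s2_k Z_k Z_k' + s2_e I."""
    n = len(y)
    p = X.shape[1]
    k = len(groups)
    Zs = []
    for g in groups:
        q = g.max() + 1
        Z = np.zeros((n, q))
        Z[np.arange(n), g] = 1.0
        Zs.append(Z)
    vary = float(np.var(y))
    if vary == 0.0:
        est = np.zeros(k + 1)
        return est, _dense_loglik(est, y, X, Zs), True
    floor = max(vary, 1.0) * 1e-10

    def negll_grad(theta):
        V = np.eye(n) * max(theta[-1], floor)
        for s2, Z in zip(theta[:-1], Zs):
            if s2 > 0:
                V += s2 * (Z @ Z.T)
        L = np.linalg.cholesky(V)
        Vinv = np.linalg.inv(V)
        XtVinv = X.T @ Vinv
        A = XtVinv @ X
        Ainv = np.linalg.inv(A)
        P = Vinv - XtVinv.T @ Ainv @ XtVinv
        Py = P @ y
        ld_V = 2.0 * np.log(np.diag(L)).sum()
        sign, ld_A = np.linalg.slogdet(A)
        nll = 0.5 * (ld_V + ld_A + float(y @ Py))
        grad = np.empty(k + 1)
        for j, Z in enumerate(Zs):
            PZ = P @ Z
            tr = float(np.einsum("iq,iq->", PZ, Z))
            quad = float((Z.T @ Py) @ (Z.T @ Py))
            grad[j] = 0.5 * (tr - quad)
        grad[-1] = 0.5 * (np.trace(P) - float(Py @ Py))
        return nll, grad

    bounds = [(0.0, None)] * k + [(floor, None)]
    rng = np.random.default_rng(0)
    starts = [np.full(k + 1, vary / (k + 1))]
    for _ in range(max_starts - 1):
        w = rng.dirichlet(np.ones(k + 1))
        starts.append(np.maximum(w * vary, floor))
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                negll_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 300, "ftol": tol * 1e-4, "gtol": tol},
            )
        except np.linalg.LinAlgError:
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if best is not None and best.success:
            break
    if best is None:
        raise RuntimeError("REML failed to converge from every start")
    est = np.asarray(best.x)
    est[:-1][est[:-1] < floor] = 0.0
    return est, _dense_loglik(est, y, X, Zs), bool(best.success)


def _dense_loglik(theta, y, X, Zs):
    n, p = X.shape
    floor = max(float(np.var(y)), 1.0) * 1e-10
    V = np.eye(n) * max(theta[-1], floor)
    for s2, Z in zip(theta[:-1], Zs):
        if s2 > 0:
            V += s2 * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    Vinv = np.linalg.inv(V)
    XtVinv = X.T @ Vinv
    A = XtVinv @ X
    P = Vinv - XtVinv.T @ np.linalg.inv(A) @ XtVinv
    ld_V = 2.0 * np.log(np.diag(L)).sum()
    _, ld_A = np.linalg.slogdet(A)
    return (
        -0.5 * (ld_V + ld_A + float(y @ (P @ y)))
        - 0.5 * (n - p) * np.log(2.0 * np.pi)
    )


# ---------------------------------------------------------------------------
# estimator


class FactorialREML(BaseEstimator):
    """REML variance components for a factorial trial response.

    Parameters
    ----------
    model : {"combined", "single"}
        "combined" fits the multi-environment model (female, male, SCA,
        environment, the three G-by-E interactions, replicate-in-
        environment, residual); "single" fits the within-environment model
        (female, male, SCA, replicate, residual).
    drop : sequence of term names to exclude (for nested LRT refits).
    force_dense : skip the balanced spectral route even when applicable.
    tol : optimizer gradient tolerance for the dense route.

    Attributes
    ----------
    decomposition_ : VarianceDecomposition
    components_ : dict of term name -> REML estimate (includes "e")
    loglik_ : restricted log-likelihood at the optimum
    converged_ : bool
    """

    def __init__(
        self,
        model: str = "combined",
        drop: tuple[str, ...] = (),
        force_dense: bool = False,
        tol: float = 1e-8,
    ):
        self.model = model
        self.drop = drop
        self.force_dense = force_dense
        self.tol = tol

    def _terms(self):
        base = COMBINED_TERMS if self.model == "combined" else SINGLE_TERMS
        unknown = set(self.drop) - {t for t, _ in base} - {"e"}
        if unknown:
            raise KeyError(f"cannot drop unknown terms: {sorted(unknown)}")
        if "e" in self.drop:
            raise ValueError("the residual cannot be dropped")
        return tuple((t, c) for t, c in base if t not in self.drop)

    def fit(self, records, response: str):
        frame = _frame(records)
        if self.model not in ("combined", "single"):
            raise ValueError("model must be 'combined' or 'single'")
        if self.model == "combined" and frame["environment"].nunique() < 2:
            raise ValueError(
                "combined model needs >= 2 environments; use model='single'"
            )
        terms = self._terms()
        for t, cols in terms:
            for c in cols:
                if frame[c].nunique() < 2 and c != "replicate":
                    raise ValueError(f"factor {c!r} needs >= 2 levels")
        y = frame[response].to_numpy(dtype=float)
        if np.isnan(y).any():
            raise ValueError(f"response {response!r} contains missing values")
        combined = self.model == "combined"
        if not self.force_dense and _is_balanced(frame, combined):
            tensor, dims = _tensor_layout(frame, response, combined)
            est, ll, ok = _reml_spectral(tensor, dims, terms, combined)
        else:
            groups = [_group_index(frame, cols) for _, cols in terms]
            X = np.ones((len(frame), 1))
            est, ll, ok = _reml_dense(y, X, groups, tol=self.tol)
        if not ok:
            logger.warning("REML optimizer did not report convergence")
        names = [t for t, _ in terms] + ["e"]
        self.components_ = dict(zip(names, (float(v) for v in est)))
        self.loglik_ = float(ll)
        self.converged_ = bool(ok)
        self.n_records_ = len(frame)
        self.decomposition_ = VarianceDecomposition(
            estimates=dict(self.components_),
            loglik=self.loglik_,
            converged=self.converged_,
            n_records=self.n_records_,
            model=self.model,
        )
        return self


# ---------------------------------------------------------------------------
# functional surface


def reml_single_env(records, response: str, **kwargs) -> VarianceDecomposition:
    """Within-environment variance components (female, male, SCA, rep, residual)."""
    return FactorialREML(model="single", **kwargs).fit(records, response).decomposition_


def reml_combined(records, response: str, **kwargs) -> VarianceDecomposition:
    """Multi-environment variance components with G-by-E terms.

    Routes to :func:`reml_single_env` if only one environment is present.
    """
    frame = _frame(records)
    if frame["environment"].nunique() < 2:
        return reml_single_env(records, response, **kwargs)
    return FactorialREML(model="combined", **kwargs).fit(records, response).decomposition_


def lrt_term(full, reduced) -> tuple[float, float]:
    """Likelihood-ratio test of one variance term: chi2(1) on -2 delta logREL.

    ``full`` and ``reduced`` are fitted :class:`VarianceDecomposition` (or
    FactorialREML) objects; the reduced model must drop exactly one random
    term of the full model.
    """
    fl = full.decomposition_ if isinstance(full, FactorialREML) else full
    rd = reduced.decomposition_ if isinstance(reduced, FactorialREML) else reduced
    full_terms = set(fl.estimates) - {"e"}
    red_terms = set(rd.estimates) - {"e"}
    if not (red_terms < full_terms and len(full_terms - red_terms) == 1):
        raise ValueError("reduced model must be nested with exactly one term removed")
    stat = max(0.0, 2.0 * (fl.loglik - rd.loglik))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def lrt_all_terms(records, response: str, model: str = "combined", **kwargs) -> VarianceDecomposition:
    """Fit the full model plus one reduced model per term; attach LRT p-values."""
    est = FactorialREML(model=model, **kwargs).fit(records, response)
    vc = est.decomposition_
    for term in [t for t in vc.estimates if t != "e"]:
        red = FactorialREML(model=model, drop=(term,), **kwargs).fit(records, response)
        _, p = lrt_term(est, red)
        vc.lrt_pvalues[term] = p
    return vc


def fit_blues(records, env: str, response: str) -> pd.Series:
    """Per-hybrid BLUEs within one environment (hybrid fixed, replicate random).

    Returns estimable hybrid means (intercept plus effect) indexed by hybrid.
    For balanced data with homoscedastic replicates this reduces to the plot
    mean per hybrid; in general it is the GLS solution under the REML
    replicate/residual variance estimates.
    """
    frame = _frame(records)
    sub = frame[frame["environment"] == env]
    if sub.empty:
        raise KeyError(f"environment {env!r} has no records")
    all_hybrids = np.sort(frame["hybrid"].unique())
    hybrids = np.sort(sub["hybrid"].unique())
    if len(hybrids) < 2:
        raise ValueError("need >= 2 hybrids for BLUE extraction")
    empty = sorted(set(all_hybrids) - set(hybrids))
    if empty:
        raise ValueError(f"hybrid(s) without observations in {env!r}: {empty}")
    y = sub[response].to_numpy(dtype=float)
    hcodes = pd.Categorical(sub["hybrid"], categories=hybrids).codes
    X = np.zeros((len(sub), len(hybrids)))
    X[np.arange(len(sub)), hcodes] = 1.0
    rcodes, _ = pd.factorize(sub["replicate"])
    if rcodes.max() == 0:  # single replicate: no replicate variance estimable
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        return pd.Series(beta, index=hybrids, name=response)
    est, _, _ = _reml_dense(y, X, [rcodes])
    s2r, s2e = est[0], est[1]
    n = len(sub)
    V = np.eye(n) * max(s2e, 1e-12)
    if s2r > 0:
        Zr = np.zeros((n, rcodes.max() + 1))
        Zr[np.arange(n), rcodes] = 1.0
        V += s2r * (Zr @ Zr.T)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    return pd.Series(beta, index=hybrids, name=response)


def blues_table(records, response: str) -> pd.DataFrame:
    """Per-environment hybrid BLUEs stacked into a long (hybrid, env) table.

    The returned frame carries hybrid, female, male, environment, and the
    BLUE in column ``value`` — the record layout the prediction models and
    cross-validation consume.
    """
    frame = _frame(records)
    parent_of = (
        frame[["hybrid", "female", "male"]].drop_duplicates().set_index("hybrid")
    )
    rows = []
    for env in sorted(frame["environment"].unique()):
        blues = fit_blues(frame, env, response)
        for hyb, val in blues.items():
            rows.append(
                {
                    "hybrid": hyb,
                    "female": parent_of.loc[hyb, "female"],
                    "male": parent_of.loc[hyb, "male"],
                    "environment": env,
                    "value": float(val),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heritability and CV


def _component(comp, keys, parts) -> float | None:
    """Aggregated component: direct key if present, else sum of its parts."""
    for k in keys:
        if k in comp and comp[k] is not None:
            return float(comp[k])
    if all(p in comp for p in parts):
        return float(sum(comp[p] for p in parts))
    return None


def _as_components(vc) -> dict:
    if isinstance(vc, FactorialREML):
        return dict(vc.components_)
    if isinstance(vc, VarianceDecomposition):
        return dict(vc.estimates)
    return dict(vc)


def heritability_single(vc, r: int) -> HeritabilityReport:
    """Entry-mean heritabilities for a single environment with r replicates.

    H2 = s2_g / (s2_g + s2_e / r) with s2_g the total hybrid variance
    (f + m + fm); h2 uses the additive numerator f + m; the female and male
    narrow-sense components use f and m alone over the same denominator.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    comp = _as_components(vc)
    g = _component(comp, ("g",), ("f", "m", "fm"))
    e = comp.get("e")
    if g is None or e is None:
        raise KeyError("need hybrid components (f, m, fm or g) and residual e")
    denom = g + e / r
    if denom <= 0:
        raise ZeroDivisionError("zero total variance: heritability undefined")
    f, m = comp.get("f"), comp.get("m")
    a = f + m if f is not None and m is not None else None
    return HeritabilityReport(
        H2=g / denom,
        h2=a / denom if a is not None else None,
        h2_f=f / denom if f is not None else None,
        h2_m=m / denom if m is not None else None,
        t=1,
        r=r,
    )


def heritability_combined(vc, t: int, r: int) -> HeritabilityReport:
    """Entry-mean heritabilities across t environments with r replicates each.

    The denominator is s2_g* + s2_gxe*/t + s2_e/(t*r), where s2_g* is the
    total hybrid variance (f + m + fm) and s2_gxe* the total hybrid-by-
    environment variance (fs + ms + fms).  Numerators: s2_g* for H2,
    f + m for h2, f for the female and m for the male narrow-sense parts.

    Accepts a fitted decomposition or a plain mapping; aggregated keys
    ("g" or "hybrid", "gs" or "hybrid_env", "e") may stand in for the
    fine-grained terms — useful when only report-level components are
    available.
    """
    if t < 1 or r < 1:
        raise ValueError("t and r must be >= 1")
    comp = _as_components(vc)
    g = _component(comp, ("g", "hybrid"), ("f", "m", "fm"))
    gs = _component(comp, ("gs", "hybrid_env"), ("fs", "ms", "fms"))
    e = comp.get("e", comp.get("residual"))
    if g is None or gs is None or e is None:
        raise KeyError(
            "need hybrid, hybrid-by-environment, and residual components "
            "(fine-grained or aggregated)"
        )
    denom = g + gs / t + e / (t * r)
    if denom <= 0:
        raise ZeroDivisionError("zero total variance: heritability undefined")
    f, m = comp.get("f"), comp.get("m")
    a = f + m if f is not None and m is not None else None
    return HeritabilityReport(
        H2=g / denom,
        h2=a / denom if a is not None else None,
        h2_f=f / denom if f is not None else None,
        h2_m=m / denom if m is not None else None,
        t=t,
        r=r,
    )


def cve(vc, mean: float) -> float:
    """Residual coefficient of variation, percent: 100 * sqrt(s2_e) / mean."""
    if mean == 0:
        raise ZeroDivisionError("trait mean is zero: CVe undefined")
    comp = _as_components(vc)
    e = comp.get("e", comp.get("residual"))
    if e is None:
        raise KeyError("need residual component 'e'")
    return 100.0 * float(np.sqrt(e)) / abs(mean)


# ---------------------------------------------------------------------------
# per-band spectral decomposition


def spectra_band_decomposition(
    records: pd.DataFrame,
    band_columns: list[str] | None = None,
    t: int | None = None,
    r: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Variance decomposition and heritability profile across spectral bands.

    Fits the combined-environment model independently to every band column
    of ``records`` (which must carry the factor columns female, male,
    hybrid, environment, replicate).  Returns percent-of-total profiles,
    heritability curves, and per-band convergence flags.
    """
    if band_columns is None:
        band_columns = [
            c
            for c in records.columns
            if c not in PlotRecordTable.REQUIRED and pd.api.types.is_numeric_dtype(records[c])
        ]
    if not band_columns:
        raise ValueError("no band columns to decompose")
    if t is None:
        t = records["environment"].nunique()
    if r is None:
        r = int(records.groupby(["environment", "hybrid"], observed=True).size().max())
    pct_rows, herit_rows, flags = [], [], []
    for band in band_columns:
        try:
            vc = reml_combined(records, band)
            hr = heritability_combined(vc, t=t, r=r)
            pct_rows.append(vc.percents)
            herit_rows.append(
                {"H2": hr.H2, "h2": hr.h2, "h2_f": hr.h2_f, "h2_m": hr.h2_m}
            )
            flags.append(vc.converged)
        except Exception as exc:  # pragma: no cover - surfaced per band
            logger.warning("band %s failed: %s", band, exc)
            pct_rows.append({})
            herit_rows.append({})
            flags.append(False)
    return {
        "percents": pd.DataFrame(pct_rows, index=band_columns),
        "heritability": pd.DataFrame(herit_rows, index=band_columns),
        "converged": pd.Series(flags, index=band_columns, name="converged"),
    }
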