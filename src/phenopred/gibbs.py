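"""Multi-kernel Bayesian RKHS regression by Gibbs sampling.

Fits models of the form

    y = 1*mu + sum_j u_j + e,    u_j ~ N(0, sigma2_j K_j),   e ~ N(0, sigma2_e I)

where each K_j is a record-level PSD kernel: GCA kernels expanded from the
parent relationship matrices, the SCA Kronecker kernel, the phenomic
relationship, the environment block (a ridge on environment indicators,
i.e. an identity kernel over environment levels), and Hadamard-product
G-by-E / NIR-by-E interaction kernels.

Each kernel effect is sampled in the kernel's eigenbasis: with
K_j = U_j D_j U_j' and u_j = U_j D_j^(1/2) b_j, the full conditional of
b_j is Gaussian with *diagonal* precision D_j / sigma2_e + I / sigma2_j,
so one sweep costs O(n * rank) per kernel after a single eigendecomposition.
Variance components get scaled-inverse-chi-square conditionals; missing
responses are imputed by data augmentation each sweep, which yields
predictions for unobserved records for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import IncidenceMap
from .kernels import (
    RelationshipKernel,
    expand_to_records,
    interaction_hadamard,
)
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelSpec",
    "PosteriorSummary",
    "MultiKernelGibbs",
    "build_model",
    "gibbs_fit",
    "predict_records",
]

GP_ROLES_SINGLE = ("f-GCA", "m-GCA", "SCA")
GP_ROLES_COMBINED = GP_ROLES_SINGLE + ("environment", "fxE", "mxE", "SCAxE")
PP_ROLES_SINGLE = ("phenomic",)
PP_ROLES_COMBINED = ("phenomic", "environment", "NIRxE")


@dataclass(frozen=True)
class ModelSpec:
    """Which kernels enter the model, plus MCMC settings.

    ``model`` is one of "GP", "PP", "GP+PP"; ``scope`` is "single" (one
    environment, no interaction kernels) or "combined" (environment main
    effect plus the matching interaction kernels).  Chain defaults follow
    the standard 5000 / 1000 / 10 iteration / burn-in / thinning setup.
    """

    model: str = "GP"
    scope: str = "combined"
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 10
    df0: float = 5.0
    r2: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in ("GP", "PP", "GP+PP"):
            raise ValueError("model must be GP, PP, or GP+PP")
        if self.scope not in ("single", "combined"):
            raise ValueError("scope must be 'single' or 'combined'")
        if not (0 < self.burn_in < self.n_iter):
            raise ValueError("need 0 < burn_in < n_iter")

    @property
    def roles(self) -> tuple[str, ...]:
        gp = GP_ROLES_COMBINED if self.scope == "combined" else GP_ROLES_SINGLE
        pp = PP_ROLES_COMBINED if self.scope == "combined" else PP_ROLES_SINGLE
        if self.model == "GP":
            return gp
        if self.model == "PP":
            return pp
        merged = list(gp)
        for role in pp:
            if role not in merged:
                merged.append(role)
        return tuple(merged)


@dataclass
class PosteriorSummary:
    """Posterior means from a Gibbs fit."""

    mu: float
    effects: dict[str, np.ndarray]  # record-level posterior-mean effects
    variance_means: dict[str, float]
    variance_sds: dict[str, float]
    fitted: np.ndarray
    record_ids: list
    n_samples: int
    rhat: dict[str, float] = field(default_factory=dict)

    def predictions(self) -> pd.Series:
        return pd.Series(self.fitted, index=self.record_ids, name="predicted")


def build_model(
    spec: ModelSpec,
    kernels: dict[str, np.ndarray | RelationshipKernel],
    incidence: IncidenceMap,
) -> dict[str, np.ndarray]:
    """Assemble the record-level kernel stack for a model class and scope.

    ``kernels`` maps entity-level inputs: "f-GCA" (females), "m-GCA"
    (males), "SCA" (hybrids), "phenomic" (records).  Environment and
    interaction kernels are constructed here from the incidence map; the
    environment main effect is an identity kernel over environment levels
    (a ridge on environment indicators).
    """
    n = incidence.n_records
    stack: dict[str, np.ndarray] = {}
    roles = spec.roles
    entity_factor = {"f-GCA": "female", "m-GCA": "male", "SCA": "hybrid"}
    for role in ("f-GCA", "m-GCA", "SCA"):
        if role in roles:
            if role not in kernels:
                raise KeyError(f"model {spec.model} requires a {role!r} kernel")
            K = kernels[role]
            if not isinstance(K, RelationshipKernel):
                raise TypeError(f"{role!r} kernel must be a RelationshipKernel")
            stack[role] = expand_to_records(K, incidence, entity_factor[role])
    if "phenomic" in roles:
        if "phenomic" not in kernels:
            raise KeyError(f"model {spec.model} requires a 'phenomic' kernel")
        P = kernels["phenomic"]
        P = P.matrix if isinstance(P, RelationshipKernel) else np.asarray(P, float)
        if P.shape != (n, n):
            raise ValueError(
                f"phenomic kernel must be record-level ({n} x {n}), got {P.shape}"
            )
        stack["phenomic"] = P
    if "environment" in roles:
        Ze = incidence.Z("environment")
        stack["environment"] = Ze @ Ze.T
    for role, base in (("fxE", "f-GCA"), ("mxE", "m-GCA"), ("SCAxE", "SCA")):
        if role in roles:
            stack[role] = interaction_hadamard(stack[base], incidence)
    if "NIRxE" in roles:
        stack["NIRxE"] = interaction_hadamard(stack["phenomic"], incidence)
    return stack


class MultiKernelGibbs(BaseEstimator, RegressorMixin):
    """Bayesian multi-kernel (RKHS) regressor fitted by Gibbs sampling.

    Parameters
    ----------
    kernels : dict of name -> record-level PSD kernel matrix
        Aligned to the record ordering of the training response.
    n_iter, burn_in, thin : chain settings (defaults 5000 / 1000 / 10).
    df0, r2 : scaled-inverse-chi-square hyperprior degrees of freedom and
        the prior share of response variance split equally among kernels.
    fixed_variances : optional dict name -> variance (plus "e") to hold
        variance components fixed (no variance sampling) — used for
        BLUP-equivalence checks.
    seed : RNG seed; fits are reproducible given the seed.

    Attributes (fitted)
    -------------------
    posterior_ : PosteriorSummary
    mu_, fitted_, variance_components_ : convenience views.
    """

    def __init__(
        self,
        kernels: dict[str, np.ndarray] | None = None,
        n_iter: int = 5000,
        burn_in: int = 1000,
        thin: int = 10,
        df0: float = 5.0,
        r2: float = 0.5,
        fixed_variances: dict[str, float] | None = None,
        seed: int | None = None,
        record_ids: list | None = None,
    ):
        self.kernels = kernels
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.df0 = df0
        self.r2 = r2
        self.fixed_variances = fixed_variances
        self.seed = seed
        self.record_ids = record_ids

    def fit(self, X, y=None):
        """Fit to a response vector with NaN marking records to predict.

        ``X`` is the response (records aligned to the kernel matrices); an
        explicit ``y`` overrides it for sklearn-style calls where ``X`` is
        ignored.
        """
        y = np.asarray(X if y is None else y, dtype=float).ravel()
        if self.kernels is None or len(self.kernels) == 0:
            raise ValueError("at least one kernel is required")
        names = list(self.kernels)
        n = len(y)
        obs = ~np.isnan(y)
        if not obs.any():
            raise ValueError("response is entirely missing")
        rng = np.random.default_rng(self.seed)

        # eigendecompose kernels once; keep numerically nonzero eigenpairs
        bases, eigs = {}, {}
        for name in names:
            K = np.asarray(self.kernels[name], dtype=float)
            if K.shape != (n, n):
                raise ValueError(f"kernel {name!r} misaligned: {K.shape} vs n={n}")
            w, V = np.linalg.eigh(0.5 * (K + K.T))
            if w[0] < -1e-8 * max(1.0, abs(w[-1])):
                raise ValueError(f"kernel {name!r} is not PSD (min eig {w[0]:.3g})")
            keep = w > max(w[-1], 0.0) * 1e-10
            if not keep.any():
                raise ValueError(f"kernel {name!r} is numerically zero")
            bases[name] = V[:, keep]
            eigs[name] = w[keep]

        vy = float(np.nanvar(y[obs]))
        vy = vy if vy > 0 else 1.0
        fixed = self.fixed_variances or {}
        # scaled-inv-chi2 prior: mode = S0 / (df0 + 2)
        mean_diag = {
            name: float(np.mean(np.diag(np.asarray(self.kernels[name])))) or 1.0
            for name in names
        }
        S0 = {
            name: self.r2 * vy / len(names) / mean_diag[name] * (self.df0 + 2.0)
            for name in names
        }
        S0["e"] = (1.0 - self.r2) * vy * (self.df0 + 2.0)

        sigma2 = {name: fixed.get(name, S0[name] / (self.df0 + 2.0)) for name in names}
        sigma2_e = fixed.get("e", S0["e"] / (self.df0 + 2.0))
        mu = float(np.nanmean(y[obs]))
        ycur = np.where(obs, y, mu)
        b = {name: np.zeros(len(eigs[name])) for name in names}
        u = {name: np.zeros(n) for name in names}

        n_keep = (self.n_iter - self.burn_in) // self.thin
        sum_mu = 0.0
        sum_u = {name: np.zeros(n) for name in names}
        sum_fit = np.zeros(n)
        var_draws = {name: [] for name in (*names, "e")}
        kept = 0

        total_u = np.zeros(n)
        for it in range(self.n_iter):
            # intercept
            resid = ycur - total_u
            mu = rng.normal(resid.mean(), np.sqrt(sigma2_e / n))
            # kernel effects in their eigenbases
            for name in names:
                V, d = bases[name], eigs[name]
                total_u -= u[name]
                r = ycur - mu - total_u
                rt = V.T @ r
                prec = d / sigma2_e + 1.0 / sigma2[name]
                mean_b = (np.sqrt(d) / sigma2_e) * rt / prec
                b[name] = mean_b + rng.standard_normal(len(d)) / np.sqrt(prec)
                u[name] = V @ (np.sqrt(d) * b[name])
                total_u += u[name]
                if name not in fixed:
                    ssq = float(b[name] @ b[name])
                    df = self.df0 + len(d)
                    sigma2[name] = (S0[name] + ssq) / rng.chisquare(df)
            # residual variance
            resid = ycur - mu - total_u
            if "e" not in fixed:
                sse = float(resid @ resid)
                sigma2_e = (S0["e"] + sse) / rng.chisquare(self.df0 + n)
            # impute missing responses
            fitted = mu + total_u
            if (~obs).any():
                ycur[~obs] = fitted[~obs] + rng.standard_normal(
                    (~obs).sum()
                ) * np.sqrt(sigma2_e)
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0:
                kept += 1
                sum_mu += mu
                sum_fit += fitted
                for name in names:
                    sum_u[name] += u[name]
                    var_draws[name].append(sigma2[name])
                var_draws["e"].append(sigma2_e)

        kept = max(kept, 1)
        var_arr = {k: np.asarray(v) for k, v in var_draws.items()}
        rhat = {k: _split_rhat(v) for k, v in var_arr.items() if len(v) >= 4}
        ids = (
            list(self.record_ids)
            if self.record_ids is not None
            else list(range(n))
        )
        self.posterior_ = PosteriorSummary(
            mu=sum_mu / kept,
            effects={name: sum_u[name] / kept for name in names},
            variance_means={k: float(v.mean()) for k, v in var_arr.items()},
            variance_sds={k: float(v.std(ddof=1)) if len(v) > 1 else 0.0 for k, v in var_arr.items()},
            fitted=sum_fit / kept,
            record_ids=ids,
            n_samples=kept,
            rhat=rhat,
        )
        self.mu_ = self.posterior_.mu
        self.fitted_ = self.posterior_.fitted
        self.variance_components_ = self.posterior_.variance_means
        return self

    def predict(self, X=None):
        """Posterior-mean fitted values; ``X`` may index a record subset."""
        check_is_fitted(self, "posterior_")
        if X is None:
            return self.fitted_.copy()
        idx = np.asarray(X)
        return self.fitted_[idx]


def _split_rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction on one parameter's draws."""
    m = len(draws) // 2
    a, b = draws[:m], draws[m : 2 * m]
    W = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    B = m * np.var([a.mean(), b.mean()], ddof=1)
    if W <= 0:
        return 1.0
    return float(np.sqrt((W * (m - 1) / m + B / m) / W))


def gibbs_fit(
    model: dict[str, np.ndarray],
    y: np.ndarray | pd.Series,
    spec: ModelSpec | None = None,
    record_ids: list | None = None,
    fixed_variances: dict[str, float] | None = None,
) -> PosteriorSummary:
    """Fit an assembled kernel stack to a response (NaN = predict).

    Thin functional wrapper over :class:`MultiKernelGibbs`.
    """
    if spec is None:
        spec = ModelSpec()
    if isinstance(y, pd.Series):
        if record_ids is None:
            record_ids = list(y.index)
        y = y.to_numpy(dtype=float)
    est = MultiKernelGibbs(
        kernels=model,
        n_iter=spec.n_iter,
        burn_in=spec.burn_in,
        thin=spec.thin,
        df0=spec.df0,
        r2=spec.r2,
        fixed_variances=fixed_variances,
        seed=spec.seed,
        record_ids=record_ids,
    )
    est.fit(y)
    return est.posterior_


def predict_records(fit: PosteriorSummary, targets: list) -> pd.Series:
    """Posterior-mean predictions for target record ids (observed or masked)."""
    pos = {rid: i for i, rid in enumerate(fit.record_ids)}
    missing = [t for t in targets if t not in pos]
    if missing:
        raise KeyError(f"unknown record ids: {missing[:5]}")
    idx = [pos[t] for t in targets]
    return pd.Series(fit.fitted[idx], index=targets, name="predicted")
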