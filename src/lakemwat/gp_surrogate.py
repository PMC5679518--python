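"""Exact Gaussian Process regression of normalized MWAT on lake/climate
predictors: kernels, marginal-likelihood fitting, AIC kernel selection,
bootstrap cross-validation and predictive intervals.

The response X_i (MWAT, degC) is normalized to a zero-mean unit-variance
process Y_i = (X_i - Xbar) / sigma before fitting; features are
standardized per column. Kernels use ARD (one lengthscale per feature)
since the predictors carry heterogeneous units. Hyperparameters (including
the observation-noise variance) are optimized on the log scale by
multi-restart L-BFGS-B on the exact log marginal likelihood

    log L = -1/2 y^T (K + s_n^2 I)^{-1} y - 1/2 log|K + s_n^2 I| - n/2 log 2pi

via a Cholesky factorization with an escalating-jitter fallback. Candidate
kernel forms are ranked by AIC = 2k - 2 log L with k the number of
optimized hyperparameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

LEAF_FORMS = ("squared_exponential", "rational_quadratic", "matern32",
              "matern52", "linear")
COMPOSITE_FORMS = ("sum", "product")

_JITTERS = (0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)


# ---------------------------------------------------------------------------
# kernel specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """A kernel form with its hyperparameters; composites hold children."""

    form: str
    children: tuple = ()
    signal_variance: float = 1.0
    lengthscales: tuple | None = None   # per-feature; None for 'linear'
    rq_alpha: float = 1.0               # rational quadratic shape only

    def __post_init__(self):
        if self.form in COMPOSITE_FORMS:
            if len(self.children) < 2:
                raise ValueError(f"{self.form} kernel needs >= 2 children")
        elif self.form not in LEAF_FORMS:
            raise ValueError(f"unknown kernel form {self.form!r}")
        if self.signal_variance <= 0 or self.rq_alpha <= 0:
            raise ValueError("variances and rq_alpha must be positive")
        if self.lengthscales is not None and any(l <= 0 for l in self.lengthscales):
            raise ValueError("lengthscales must be positive")

    @property
    def n_params(self) -> int:
        if self.form in COMPOSITE_FORMS:
            return sum(c.n_params for c in self.children)
        if self.form == "linear":
            return 1
        n = 1 + len(self.lengthscales)
        return n + 1 if self.form == "rational_quadratic" else n

    def to_dict(self) -> dict:
        d = {"form": self.form}
        if self.form in COMPOSITE_FORMS:
            d["children"] = [c.to_dict() for c in self.children]
        else:
            d["signal_variance"] = self.signal_variance
            if self.lengthscales is not None:
                d["lengthscales"] = list(self.lengthscales)
            if self.form == "rational_quadratic":
                d["rq_alpha"] = self.rq_alpha
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KernelSpec":
        if d["form"] in COMPOSITE_FORMS:
            return cls(d["form"], tuple(cls.from_dict(c) for c in d["children"]))
        return cls(d["form"],
                   signal_variance=d.get("signal_variance", 1.0),
                   lengthscales=tuple(d["lengthscales"]) if "lengthscales" in d else None,
                   rq_alpha=d.get("rq_alpha", 1.0))


def se_kernel(d: int, v: float = 1.0) -> KernelSpec:
    return KernelSpec("squared_exponential", signal_variance=v,
                      lengthscales=(1.0,) * d)


def rq_kernel(d: int, v: float = 1.0, alpha: float = 1.0) -> KernelSpec:
    return KernelSpec("rational_quadratic", signal_variance=v,
                      lengthscales=(1.0,) * d, rq_alpha=alpha)


def default_kernel_candidates(d: int) -> dict:
    """The seven candidate covariance forms ranked during model selection."""
    return {
        "se": se_kernel(d),
        "rq": rq_kernel(d),
        "matern32": KernelSpec("matern32", lengthscales=(1.0,) * d),
        "matern52": KernelSpec("matern52", lengthscales=(1.0,) * d),
        "linear": KernelSpec("linear"),
        "se_plus_rq": KernelSpec("sum", (se_kernel(d), rq_kernel(d))),
        "se_times_rq": KernelSpec("product", (se_kernel(d), rq_kernel(d))),
    }


# --- hyperparameter packing (log scale) ------------------------------------

def pack_params(spec: KernelSpec) -> np.ndarray:
    if spec.form in COMPOSITE_FORMS:
        return np.concatenate([pack_params(c) for c in spec.children])
    out = [math.log(spec.signal_variance)]
    if spec.form != "linear":
        out.extend(math.log(l) for l in spec.lengthscales)
    if spec.form == "rational_quadratic":
        out.append(math.log(spec.rq_alpha))
    return np.array(out)


def unpack_params(spec: KernelSpec, theta: np.ndarray) -> KernelSpec:
    spec2, rest = _unpack(spec, np.asarray(theta, dtype=float))
    if len(rest):
        raise ValueError("parameter vector longer than kernel spec")
    return spec2


def _unpack(spec, theta):
    if spec.form in COMPOSITE_FORMS:
        children = []
        for c in spec.children:
            c2, theta = _unpack(c, theta)
            children.append(c2)
        return replace(spec, children=tuple(children)), theta
    v = math.exp(theta[0])
    theta = theta[1:]
    ls = None
    if spec.form != "linear":
        d = len(spec.lengthscales)
        ls = tuple(np.exp(theta[:d]))
        theta = theta[d:]
    alpha = spec.rq_alpha
    if spec.form == "rational_quadratic":
        alpha = math.exp(theta[0])
        theta = theta[1:]
    return replace(spec, signal_variance=v, lengthscales=ls, rq_alpha=alpha), theta


# --- Gram matrices and gradients -------------------------------------------

def _sqdist_per_dim(X1, X2, lengthscales):
    """Per-dimension squared scaled differences d_j^2 / l_j^2, list of (n1,n2)."""
    out = []
    for j, l in enumerate(lengthscales):
        diff = (X1[:, j:j + 1] - X2[None, :, j]) / l
        out.append(diff * diff)
    return out


def kernel_eval(spec: KernelSpec, x1, x2):
    """Covariance between two feature vectors (or Gram matrix of two sets)."""
    X1 = np.atleast_2d(np.asarray(x1, dtype=float))
    X2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError("feature dimension mismatch")
    K = _gram(spec, X1, X2)
    if np.asarray(x1).ndim == 1 and np.asarray(x2).ndim == 1:
        return float(K[0, 0])
    return K


def _check_dim(spec, d):
    if spec.form in COMPOSITE_FORMS:
        for c in spec.children:
            _check_dim(c, d)
    elif spec.lengthscales is not None and len(spec.lengthscales) != d:
        raise ValueError("feature dimension mismatch with kernel lengthscales")


def _gram(spec, X1, X2):
    _check_dim(spec, X1.shape[1])
    if spec.form == "sum":
        return sum(_gram(c, X1, X2) for c in spec.children)
    if spec.form == "product":
        K = _gram(spec.children[0], X1, X2)
        for c in spec.children[1:]:
            K = K * _gram(c, X1, X2)
        return K
    if spec.form == "linear":
        return spec.signal_variance * (1.0 + X1 @ X2.T)
    s = sum(_sqdist_per_dim(X1, X2, spec.lengthscales))
    v = spec.signal_variance
    if spec.form == "squared_exponential":
        return v * np.exp(-0.5 * s)
    if spec.form == "rational_quadratic":
        return v * (1.0 + s / (2.0 * spec.rq_alpha)) ** (-spec.rq_alpha)
    r = np.sqrt(np.maximum(s, 0.0))
    if spec.form == "matern32":
        a = math.sqrt(3.0) * r
        return v * (1.0 + a) * np.exp(-a)
    # matern52
    a = math.sqrt(5.0) * r
    return v * (1.0 + a + 5.0 * s / 3.0) * np.exp(-a)


def _gram_with_grads(spec, X):
    """Symmetric Gram matrix and dK/d(log theta_i) in packing order."""
    if spec.form in COMPOSITE_FORMS:
        parts = [_gram_with_grads(c, X) for c in spec.children]
        if spec.form == "sum":
            K = sum(p[0] for p in parts)
            grads = [g for p in parts for g in p[1]]
            return K, grads
        Ks = [p[0] for p in parts]
        K = np.prod(Ks, axis=0)
        grads = []
        for i, p in enumerate(parts):
            others = np.prod([Ks[j] for j in range(len(Ks)) if j != i], axis=0) \
                if len(Ks) > 1 else 1.0
            grads.extend(g * others for g in p[1])
        return K, grads

    v = spec.signal_variance
    if spec.form == "linear":
        K = v * (1.0 + X @ X.T)
        return K, [K.copy()]

    d2 = _sqdist_per_dim(X, X, spec.lengthscales)
    s = sum(d2)
    if spec.form == "squared_exponential":
        K = v * np.exp(-0.5 * s)
        return K, [K.copy()] + [K * d2j for d2j in d2]
    if spec.form == "rational_quadratic":
        alpha = spec.rq_alpha
        B = 1.0 + s / (2.0 * alpha)
        K = v * B ** (-alpha)
        base = v * B ** (-alpha - 1.0)
        grads = [K.copy()] + [base * d2j for d2j in d2]
        with np.errstate(divide="ignore", invalid="ignore"):
            dlogK_dalpha = -np.log(B) + s / (2.0 * alpha * B)
        grads.append(K * alpha * dlogK_dalpha)
        return K, grads
    r = np.sqrt(np.maximum(s, 0.0))
    if spec.form == "matern32":
        e = np.exp(-math.sqrt(3.0) * r)
        K = v * (1.0 + math.sqrt(3.0) * r) * e
        return K, [K.copy()] + [3.0 * v * e * d2j for d2j in d2]
    e = np.exp(-math.sqrt(5.0) * r)
    K = v * (1.0 + math.sqrt(5.0) * r + 5.0 * s / 3.0) * e
    base = (5.0 * v / 3.0) * (1.0 + math.sqrt(5.0) * r) * e
    return K, [K.copy()] + [base * d2j for d2j in d2]


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _chol_with_jitter(A):
    for jitter in _JITTERS:
        try:
            M = A if jitter == 0.0 else A + jitter * np.eye(len(A))
            return cholesky(M, lower=True), jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance factorization failed even with jitter up to 1e-4; "
        "check hyperparameters and duplicated inputs")


def log_marginal_likelihood(features, responses, spec: KernelSpec,
                            noise_variance: float) -> float:
    """Exact GP log marginal likelihood on the given (already scaled) data."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(responses, dtype=float).ravel()
    n = len(y)
    K = _gram(spec, X, X)
    L, _ = _chol_with_jitter(K + noise_variance * np.eye(n))
    a = solve_triangular(L, y, lower=True)
    return float(-0.5 * a @ a - np.log(np.diag(L)).sum() - 0.5 * n * math.log(2.0 * math.pi))


def _neg_lml_and_grad(theta, spec_template, X, y):
    """Negative log marginal likelihood and gradient w.r.t. log-parameters.

    ``theta`` is [kernel log-params..., log noise_variance]. Gradient uses
    d logL / d theta_i = 1/2 ( a^T dK a - tr(K^{-1} dK) ), a = K^{-1} y.
    """
    spec = unpack_params(spec_template, theta[:-1])
    noise = math.exp(theta[-1])
    n = len(y)
    K, grads = _gram_with_grads(spec, X)
    A = K + noise * np.eye(n)
    try:
        L, _ = _chol_with_jitter(A)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros_like(theta)
    alpha = cho_solve((L, True), y)
    lml = (-0.5 * y @ alpha - np.log(np.diag(L)).sum()
           - 0.5 * n * math.log(2.0 * math.pi))
    Kinv = cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    g = np.empty_like(theta)
    for i, dK in enumerate(grads):
        g[i] = 0.5 * np.sum(W * dK)
    g[-1] = 0.5 * noise * np.trace(W)
    return -lml, -g


# ---------------------------------------------------------------------------
# trained model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationConstants:
    """Response normalization Y = (X - mean) / sd."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("normalization sd must be positive")

    def normalize(self, x):
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def denormalize(self, y):
        return np.asarray(y, dtype=float) * self.sd + self.mean


@dataclass
class PredictionDistribution:
    """Denormalized predictive distribution with 95% limits (mean +- 1.96 sd)."""

    mean: np.ndarray
    sd: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray


@dataclass
class TrainedGP:
    """A fitted exact GP with its factorized training covariance."""

    features: np.ndarray                  # standardized, (n, d)
    responses: np.ndarray                 # normalized, (n,)
    kernel: KernelSpec
    noise_variance: float                 # normalized scale
    norm: NormalizationConstants
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    log_marginal_likelihood: float
    n_hyperparameters: int
    feature_names: tuple | None = None
    chol: np.ndarray = field(default=None, repr=False)
    alpha: np.ndarray = field(default=None, repr=False)
    jitter: float = 0.0

    @property
    def n_train(self) -> int:
        return len(self.responses)

    def standardize(self, X) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.feature_mean) / self.feature_sd


def _factorize(gp: TrainedGP) -> TrainedGP:
    K = _gram(gp.kernel, gp.features, gp.features)
    L, jitter = _chol_with_jitter(K + gp.noise_variance * np.eye(gp.n_train))
    gp.chol = L
    gp.alpha = cho_solve((L, True), gp.responses)
    gp.jitter = jitter
    return gp


def fit(features, responses, spec_template: KernelSpec, restarts: int = 5,
        seed: int = 0, noise_init: float = 0.1) -> TrainedGP:
    """Fit a GP by multi-restart maximum marginal likelihood.

    Responses (degC) are normalized to zero mean / unit sd; features are
    standardized per column. Restart initializations draw lengthscales
    log-uniform in [0.1, 10] of the standardized feature scale; the restart
    sequence is fully determined by ``seed``.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y_raw = np.asarray(responses, dtype=float).ravel()
    n, d = X.shape
    if len(y_raw) != n:
        raise ValueError("features and responses disagree on n")
    if n < d + 2:
        raise ValueError("need at least d + 2 training points")
    y_sd = float(y_raw.std())
    if y_sd == 0.0:
        raise ValueError("constant responses: normalization sd would be zero")
    norm = NormalizationConstants(float(y_raw.mean()), y_sd)
    y = norm.normalize(y_raw)
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd[x_sd == 0.0] = 1.0
    Xs = (X - x_mean) / x_sd

    k_kernel = spec_template.n_params
    theta0 = np.append(pack_params(spec_template), math.log(noise_init))
    rng = np.random.default_rng(seed)
    inits = [theta0]
    for _ in range(max(restarts - 1, 0)):
        t = theta0.copy()
        t[:k_kernel] = _random_log_params(spec_template, rng)
        t[-1] = math.log(10 ** rng.uniform(-2.0, -0.3))
        inits.append(t)

    bounds = _param_bounds(spec_template) + [(math.log(1e-8), math.log(10.0))]
    best, diagnostics = None, []
    for i, t0 in enumerate(inits):
        res = minimize(_neg_lml_and_grad, t0, args=(spec_template, Xs, y),
                       jac=True, method="L-BFGS-B", bounds=bounds)
        diagnostics.append((i, res.fun, res.message))
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None or best.fun >= 1e24:
        raise RuntimeError(f"all optimizer restarts failed: {diagnostics}")

    spec_opt = unpack_params(spec_template, best.x[:-1])
    gp = TrainedGP(
        features=Xs, responses=y, kernel=spec_opt,
        noise_variance=math.exp(best.x[-1]), norm=norm,
        feature_mean=x_mean, feature_sd=x_sd,
        log_marginal_likelihood=float(-best.fun),
        n_hyperparameters=k_kernel + 1,
    )
    return _factorize(gp)


def _random_log_params(spec, rng):
    """Restart draw in packing order: v, lengthscales, (alpha) per leaf."""
    if spec.form in COMPOSITE_FORMS:
        return np.concatenate([_random_log_params(c, rng) for c in spec.children])
    out = [math.log(10 ** rng.uniform(-0.5, 0.5))]
    if spec.form != "linear":
        out.extend(np.log(10 ** rng.uniform(-1.0, 1.0, size=len(spec.lengthscales))))
    if spec.form == "rational_quadratic":
        out.append(math.log(10 ** rng.uniform(-0.3, 0.7)))
    return np.array(out)


def _param_bounds(spec):
    if spec.form in COMPOSITE_FORMS:
        return [b for c in spec.children for b in _param_bounds(c)]
    out = [(math.log(1e-6), math.log(1e3))]
    if spec.form != "linear":
        out.extend([(math.log(1e-2), math.log(1e3))] * len(spec.lengthscales))
    if spec.form == "rational_quadratic":
        out.append((math.log(1e-2), math.log(1e3)))
    return out


def predict(gp: TrainedGP, x) -> PredictionDistribution:
    """Predictive distribution at query features (degC, denormalized).

    Mean k*^T (K + s_n^2 I)^{-1} y and variance
    k** - k*^T (K + s_n^2 I)^{-1} k* + s_n^2 on the normalized scale,
    then denormalized; 95% limits are mean +- 1.96 sd.
    """
    single = np.asarray(x, dtype=float).ndim == 1
    Xq = gp.standardize(x)
    if Xq.shape[1] != gp.features.shape[1]:
        raise ValueError("feature dimension mismatch")
    Ks = _gram(gp.kernel, Xq, gp.features)
    mean_n = Ks @ gp.alpha
    V = solve_triangular(gp.chol, Ks.T, lower=True)
    kss = np.diag(_gram(gp.kernel, Xq, Xq)).copy()
    var_n = np.maximum(kss - np.sum(V * V, axis=0), 0.0) + gp.noise_variance
    mean = gp.norm.denormalize(mean_n)
    sd = np.sqrt(var_n) * gp.norm.sd
    if single:
        mean, sd = float(mean[0]), float(sd[0])
    return PredictionDistribution(mean=mean, sd=sd,
                                  lower95=mean - 1.96 * sd,
                                  upper95=mean + 1.96 * sd)


def aic(gp: TrainedGP) -> float:
    """Akaike Information Criterion, 2k - 2 log L (k = optimized hyperparameters)."""
    return 2.0 * gp.n_hyperparameters - 2.0 * gp.log_marginal_likelihood


# ---------------------------------------------------------------------------
# model selection, validation, statistics
# ---------------------------------------------------------------------------

def select_kernel(features, responses, candidates: dict | None = None,
                  restarts: int = 5, seed: int = 0):
    """Fit each candidate kernel and rank by ascending AIC.

    Returns ``(ranking, fits)``: a DataFrame with columns kernel, aic,
    log_marginal_likelihood, n_hyperparameters, error (empty on success),
    sorted by AIC, and a dict of the fitted models. Individual candidate
    failures are recorded, not fatal, provided at least one succeeds.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if candidates is None:
        candidates = default_kernel_candidates(X.shape[1])
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    rows, fits = [], {}
    for name, spec in candidates.items():
        try:
            gp = fit(X, responses, spec, restarts=restarts, seed=seed)
            fits[name] = gp
            rows.append({"kernel": name, "aic": aic(gp),
                         "log_marginal_likelihood": gp.log_marginal_likelihood,
                         "n_hyperparameters": gp.n_hyperparameters, "error": ""})
        except Exception as exc:  # noqa: BLE001 - candidate failures are data
            rows.append({"kernel": name, "aic": np.nan,
                         "log_marginal_likelihood": np.nan,
                         "n_hyperparameters": spec.n_params + 1,
                         "error": str(exc)})
    if not fits:
        raise RuntimeError("every kernel candidate failed to fit")
    ranking = pd.DataFrame(rows).sort_values("aic", na_position="last",
                                             ignore_index=True)
    return ranking, fits


@dataclass
class BootstrapResult:
    """Pooled out-of-bag error summary of bootstrap cross-validation."""

    mean_error: float          # degC, pooled mean (prediction - truth)
    mean_absolute_error: float  # degC
    replicates: pd.DataFrame   # per-replicate mean error / MAE / n_oob
    errors: np.ndarray         # pooled out-of-bag errors


def bootstrap_cv(features, responses, spec: KernelSpec, B: int = 50,
                 seed: int = 0, restarts: int = 2) -> BootstrapResult:
    """Bootstrap cross-validation: resample rows, refit, score out-of-bag.

    Each replicate draws n rows with replacement, fits the kernel on the
    resample and predicts the out-of-bag rows; denormalized errors are
    pooled across replicates. Replicates with no out-of-bag rows are
    redrawn.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(responses, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    rows, pooled = [], []
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) == 0:
            continue
        gp = fit(X[idx], y[idx], spec, restarts=restarts,
                 seed=int(rng.integers(0, 2 ** 31 - 1)))
        pred = predict(gp, X[oob]).mean
        err = pred - y[oob]
        pooled.append(err)
        rows.append({"replicate": b + 1, "mean_error": float(err.mean()),
                     "mean_absolute_error": float(np.abs(err).mean()),
                     "n_oob": len(oob)})
        b += 1
    errors = np.concatenate(pooled)
    return BootstrapResult(mean_error=float(errors.mean()),
                           mean_absolute_error=float(np.abs(errors).mean()),
                           replicates=pd.DataFrame(rows), errors=errors)


@dataclass
class FitStatistics:
    r_squared: float
    rmse: float   # degC
    mae: float    # degC


def fit_statistics(gp: TrainedGP, features, responses) -> FitStatistics:
    """Denormalized R^2, RMSE and MAE of the GP on the given rows."""
    y = np.asarray(responses, dtype=float).ravel()
    pred = predict(gp, np.atleast_2d(np.asarray(features, dtype=float))).mean
    resid = y - pred
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / sst if sst > 0 else 1.0
    return FitStatistics(r_squared=r2,
                         rmse=float(np.sqrt((resid ** 2).mean())),
                         mae=float(np.abs(resid).mean()))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def gp_to_dict(gp: TrainedGP) -> dict:
    return {
        "kernel": gp.kernel.to_dict(),
        "noise_variance": gp.noise_variance,
        "norm": {"mean": gp.norm.mean, "sd": gp.norm.sd},
        "feature_mean": gp.feature_mean.tolist(),
        "feature_sd": gp.feature_sd.tolist(),
        "features": gp.features.tolist(),
        "responses": gp.responses.tolist(),
        "log_marginal_likelihood": gp.log_marginal_likelihood,
        "n_hyperparameters": gp.n_hyperparameters,
        "feature_names": list(gp.feature_names) if gp.feature_names else None,
    }


def gp_from_dict(d: dict) -> TrainedGP:
    gp = TrainedGP(
        features=np.array(d["features"]),
        responses=np.array(d["responses"]),
        kernel=KernelSpec.from_dict(d["kernel"]),
        noise_variance=d["noise_variance"],
        norm=NormalizationConstants(d["norm"]["mean"], d["norm"]["sd"]),
        feature_mean=np.array(d["feature_mean"]),
        feature_sd=np.array(d["feature_sd"]),
        log_marginal_likelihood=d["log_marginal_likelihood"],
        n_hyperparameters=d["n_hyperparameters"],
        feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
    )
    return _factorize(gp)


def save_gp(gp: TrainedGP, path) -> None:
    with open(path, "w") as fh:
        json.dump(gp_to_dict(gp), fh)


def load_gp(path) -> TrainedGP:
    with open(path) as fh:
        return gp_from_dict(json.load(fh))
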