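"""Three-component bivariate Gaussian-mixture EM with a bespoke restart rule.

The clustering stage models the 2-D trial features as a mixture of three full
covariance Gaussians: one "no-decision" cluster near the origin and one
cluster for reactions to each side.  The fitting protocol is:

1. *Exhaustive initialisation* — several short randomly-initialised EM runs
   (means drawn from the data, pooled covariance, uniform weights, capped
   burn-in); the highest-log-likelihood candidate wins.
2. *Short EM* — run to a loose relative log-likelihood tolerance (1e-4).
3. *Sign-opposition restart criterion* — accept the short-EM solution only if
   the most positive of the six mean coordinates is at least half the
   magnitude of the most negative and vice versa (so two clusters sit on
   opposite sides of the origin, in whatever dimension); otherwise restart
   from step 1 with a fresh seed, up to ``max_restarts`` times.  The
   criterion is skipped for the PCA feature set.
4. *Final EM* — run the accepted solution to a tight tolerance.

Everything is deterministic given (data, config.seed).  Covariances are kept
positive-definite by flooring eigenvalues at a small fraction of the data
variance.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import logsumexp

log = logging.getLogger(__name__)


@dataclass
class MixtureModel3:
    """Weights, means and covariances of the three Gaussian clusters."""

    weights: np.ndarray       # (3,) nonnegative, sums to 1
    means: np.ndarray         # (3, 2)
    covariances: np.ndarray   # (3, 2, 2) symmetric positive-definite
    loglik: float = float("nan")
    n_restarts_used: int = 0
    criterion_satisfied: bool | None = None

    def copy(self) -> "MixtureModel3":
        return MixtureModel3(self.weights.copy(), self.means.copy(),
                             self.covariances.copy(), self.loglik,
                             self.n_restarts_used, self.criterion_satisfied)


@dataclass
class EMConfig:
    """Fitting protocol parameters (defaults follow the pipeline's protocol)."""

    n_components: int = 3
    n_exhaust_starts: int = 5
    exhaust_iter: int = 200       # EM iteration cap per candidate start
    short_em_tol: float = 1e-4    # relative loglik tolerance of the short EM
    final_tol: float = 1e-6
    max_iter: int = 1000
    max_restarts: int = 100
    apply_sign_criterion: bool = True
    exclude_centre_from_criterion: bool = False
    cov_floor_frac: float = 1e-8  # eigenvalue floor, x mean data variance
    seed: int = 0

    def validate(self) -> None:
        if self.n_components != 3:
            raise ValueError("this pipeline uses exactly 3 components")
        for name in ("short_em_tol", "final_tol", "cov_floor_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if min(self.n_exhaust_starts, self.max_iter, self.max_restarts) < 1:
            raise ValueError("counts must be >= 1")


# ---------------------------------------------------------------------------
# densities

def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a d-variate Gaussian at each row of X."""
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    dev = X - mean
    sol = np.linalg.solve(L, dev.T)        # (d, n)
    maha = np.sum(sol * sol, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def log_likelihood(X: np.ndarray, weights, means, covariances) -> float:
    """Total log-likelihood of X under a Gaussian mixture."""
    lp = _weighted_log_prob(X, weights, means, covariances)
    return float(np.sum(logsumexp(lp, axis=1)))


def _weighted_log_prob(X, weights, means, covariances) -> np.ndarray:
    K = len(weights)
    lp = np.empty((X.shape[0], K))
    for k in range(K):
        lp[:, k] = np.log(weights[k] + 1e-300) + _log_gauss(
            X, means[k], covariances[k])
    return lp


def responsibilities(X: np.ndarray, model: MixtureModel3) -> np.ndarray:
    """E-step posteriors: (n, 3), rows sum to 1."""
    lp = _weighted_log_prob(X, model.weights, model.means, model.covariances)
    return np.exp(lp - logsumexp(lp, axis=1, keepdims=True))


def posterior(model: MixtureModel3, point) -> np.ndarray:
    """Cluster responsibilities for a single 2-D point."""
    return responsibilities(np.atleast_2d(np.asarray(point, float)), model)[0]


# ---------------------------------------------------------------------------
# EM steps

def _cov_floor(X: np.ndarray, frac: float) -> float:
    v = float(np.mean(np.var(X, axis=0)))
    return max(frac * v, 1e-12)


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= floor:
        return cov
    warnings.warn("covariance eigenvalue floored to keep the component "
                  "positive-definite")
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def em_iterate(X: np.ndarray, model: MixtureModel3,
               cov_floor: float | None = None) -> MixtureModel3:
    """One E-step + M-step; the returned model's loglik is evaluated at the
    updated parameters."""
    X = np.asarray(X, float)
    if cov_floor is None:
        cov_floor = _cov_floor(X, EMConfig.cov_floor_frac)
    R = responsibilities(X, model)
    nk = R.sum(axis=0)
    nk = np.maximum(nk, 1e-300)
    weights = nk / nk.sum()
    means = (R.T @ X) / nk[:, None]
    covs = np.empty_like(model.covariances)
    for k in range(len(weights)):
        dev = X - means[k]
        covs[k] = _floor_cov((R[:, k, None] * dev).T @ dev / nk[k], cov_floor)
    ll = log_likelihood(X, weights, means, covs)
    return MixtureModel3(weights, means, covs, ll,
                         model.n_restarts_used, model.criterion_satisfied)


def _run_em(X, model, tol, max_iter, cov_floor) -> MixtureModel3:
    """Iterate EM until the relative loglik change drops below tol."""
    prev = (model.loglik if np.isfinite(model.loglik)
            else log_likelihood(X, model.weights, model.means, model.covariances))
    for _ in range(max_iter):
        model = em_iterate(X, model, cov_floor)
        if abs(model.loglik - prev) <= tol * abs(prev):
            break
        prev = model.loglik
    return model


# ---------------------------------------------------------------------------
# initialisation / restart protocol

def exhaustive_init(X: np.ndarray, config: EMConfig,
                    rng: np.random.Generator,
                    return_candidates: bool = False):
    """Best of ``n_exhaust_starts`` randomly-initialised EM runs.

    Each candidate draws its means from distinct data points, starts from the
    pooled covariance and uniform weights, and runs EM to the short-EM
    tolerance (capped at ``exhaust_iter`` iterations); the candidate with the
    highest log-likelihood is returned (with all candidates, if
    ``return_candidates``).
    """
    X = np.asarray(X, float)
    K = config.n_components
    if X.shape[0] < K:
        raise ValueError(f"need at least {K} points")
    floor = _cov_floor(X, config.cov_floor_frac)
    pooled = _floor_cov(np.cov(X.T, ddof=0), floor)
    candidates = []
    for _ in range(config.n_exhaust_starts):
        idx = rng.choice(X.shape[0], size=K, replace=False)
        cand = MixtureModel3(np.full(K, 1.0 / K), X[idx].astype(float).copy(),
                             np.stack([pooled] * K))
        candidates.append(
            _run_em(X, cand, config.short_em_tol, config.exhaust_iter, floor))
    best = max(candidates, key=lambda m: m.loglik)
    return (best, candidates) if return_candidates else best


def sign_opposition_criterion(means: np.ndarray,
                              exclude_centre: bool = False) -> bool:
    """True iff the extreme mean coordinates straddle zero within a factor 2.

    Over all mean coordinates (all three clusters, both axes, unless the
    smallest-norm "centre" cluster is excluded): the maximum M and minimum m
    must satisfy m < 0 < M, M >= |m|/2 and |m| >= M/2.
    """
    means = np.asarray(means, float)
    if exclude_centre:
        centre = int(np.argmin(np.linalg.norm(means, axis=1)))
        means = np.delete(means, centre, axis=0)
    M = float(means.max())
    m = float(means.min())
    return (m < 0.0 < M) and (M >= -m / 2.0) and (-m >= M / 2.0)


def fit(X: np.ndarray, config: EMConfig | None = None) -> MixtureModel3:
    """Full fitting protocol: init -> short EM -> restart criterion -> final EM.

    Deterministic given (X, config.seed); restart r uses seed + r.  If no
    restart satisfies the sign-opposition criterion, the highest-likelihood
    short-EM solution is used and flagged (``criterion_satisfied=False``).
    """
    config = config or EMConfig()
    config.validate()
    X = np.asarray(X, float)
    if X.shape[0] < config.n_components or len(np.unique(X, axis=0)) < config.n_components:
        raise ValueError("need at least 3 distinct points to fit 3 clusters")
    floor = _cov_floor(X, config.cov_floor_frac)

    n_attempts = config.max_restarts if config.apply_sign_criterion else 1
    chosen = best = None
    restarts_used = n_attempts
    satisfied = False
    for r in range(n_attempts):
        rng = np.random.default_rng(config.seed + r)
        cand = exhaustive_init(X, config, rng)
        cand = _run_em(X, cand, config.short_em_tol, config.max_iter, floor)
        if best is None or cand.loglik > best.loglik:
            best = cand
        if (not config.apply_sign_criterion) or sign_opposition_criterion(
                cand.means, config.exclude_centre_from_criterion):
            chosen, restarts_used, satisfied = cand, r, True
            break
    if chosen is None:
        chosen = best
        log.info("sign-opposition criterion unmet after %d restarts; using "
                 "highest-likelihood solution", n_attempts)
    final = _run_em(X, chosen, config.final_tol, config.max_iter, floor)
    final.n_restarts_used = restarts_used
    final.criterion_satisfied = satisfied if config.apply_sign_criterion else None
    final.weights = final.weights / final.weights.sum()
    return final


# ---------------------------------------------------------------------------
# serialisation

def model_to_dict(model: MixtureModel3, config: EMConfig | None = None) -> dict:
    d = {
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "loglik": model.loglik,
        "n_restarts_used": model.n_restarts_used,
        "criterion_satisfied": model.criterion_satisfied,
    }
    if config is not None:
        d["config"] = asdict(config)
    return d


def model_from_dict(d: dict) -> MixtureModel3:
    return MixtureModel3(
        weights=np.asarray(d["weights"], float),
        means=np.asarray(d["means"], float),
        covariances=np.asarray(d["covariances"], float),
        loglik=float(d["loglik"]),
        n_restarts_used=int(d.get("n_restarts_used", 0)),
        criterion_satisfied=d.get("criterion_satisfied"),
    )


def save_model(model: MixtureModel3, path, config: EMConfig | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, config), fh, indent=1, sort_keys=True)


def load_model(path) -> MixtureModel3:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
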