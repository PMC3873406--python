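"""Maximum-entropy presence-background modelling (linear/quadratic/product).

The model estimates a Gibbs distribution over the landscape,

    q(x) = exp(sum_j lambda_j f_j(x)) / Z,

where the f_j are min-max-scaled linear, quadratic and pairwise-product
transforms of the predictors (27 features for 6 predictors) and Z
normalizes over the modelling landscape (background cells plus presence
cells).  The weights maximize the penalized presence log-likelihood

    mean_presence(lambda . f) - log Z(lambda) - sum_j beta_j |lambda_j|,

an L1-regularized convex problem.  At the optimum the KKT conditions
pin each feature's landscape expectation to within beta_j of its
presence mean, with equality whenever the weight is active — the
characteristic "relaxed moment matching" of this model family.

Per-feature penalties follow the published feature-class default
schedule: beta_j = beta_multiplier * b(m) * sqrt(var_presence(f_j) / m),
with b(m) interpolated from a sample-size table for the
linear/quadratic/product class (``BETA_TABLE``, configurable).

The solver splits lambda into positive and negative parts and runs
box-constrained L-BFGS-B on the smooth equivalent problem; convergence
is declared when the projected (KKT) gradient drops below 1e-6 in the
max norm, with a 500-iteration cap.  Optimizer choice is not normative
— any method meeting the KKT contract would do.

Outputs: the raw relative-occurrence rate exp(lambda.f - log Z), its
normalization over the projection grid, and the logistic transform
c*raw/(1 + c*raw) with c = exp(H), H the entropy of the fitted
distribution (the standard prevalence-0.5 calibration).  Thresholding at
fixed sensitivity is rank-invariant to this choice.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .climate import BIOCLIM_NAMES, BioclimStack
from .grid import GridSpec

logger = logging.getLogger(__name__)

#: sample-size -> base regularization for the linear/quadratic/product class
BETA_TABLE = ((0, 2.6), (10, 1.6), (17, 0.9), (30, 0.55), (100, 0.05))

KKT_TOL = 1e-6
MAX_ITER = 500
ZERO_LAMBDA = 1e-6


@dataclass
class FeatureSet:
    """Feature definitions over named predictors plus training scaling."""

    predictor_names: tuple[str, ...]
    definitions: list[tuple]  # ("linear", i) | ("quadratic", i) | ("product", i, j)
    lo: np.ndarray  # per-feature training minimum
    hi: np.ndarray  # per-feature training maximum

    @property
    def n_features(self) -> int:
        return len(self.definitions)

    def labels(self) -> list[str]:
        out = []
        for d in self.definitions:
            if d[0] == "linear":
                out.append(self.predictor_names[d[1]])
            elif d[0] == "quadratic":
                out.append(f"{self.predictor_names[d[1]]}^2")
            else:
                out.append(f"{self.predictor_names[d[1]]}*{self.predictor_names[d[2]]}")
        return out

    def raw_features(self, X: np.ndarray) -> np.ndarray:
        cols = []
        for d in self.definitions:
            if d[0] == "linear":
                cols.append(X[:, d[1]])
            elif d[0] == "quadratic":
                cols.append(X[:, d[1]] ** 2)
            else:
                cols.append(X[:, d[1]] * X[:, d[2]])
        return np.column_stack(cols)

    def transform(self, X: np.ndarray, clamp: bool = False) -> tuple[np.ndarray, int]:
        """Scaled feature matrix and the count of rows needing clamping.

        Scaling maps the training minimum to 0 and maximum to 1.  With
        ``clamp=True`` (projection onto new climates) out-of-range
        values are clipped to [0, 1].
        """
        F = (self.raw_features(X) - self.lo) / (self.hi - self.lo)
        n_clamped = int(np.sum(np.any((F < 0) | (F > 1), axis=1)))
        if clamp:
            F = np.clip(F, 0.0, 1.0)
        return F, n_clamped


def build_features(
    X_presence: np.ndarray,
    X_background: np.ndarray,
    predictor_names=BIOCLIM_NAMES,
) -> tuple[FeatureSet, np.ndarray, np.ndarray]:
    """Linear + quadratic + pairwise-product features, scaled on training data.

    Constant features (training max == min) are dropped with a warning;
    a constant predictor therefore loses its linear, quadratic and all
    product features.  Returns the feature set and the scaled design
    matrices for presences and background.
    """
    if X_presence.shape[0] < 2:
        raise ValueError("need at least 2 presence cells with valid predictors")
    p = X_presence.shape[1]
    train = np.vstack([X_presence, X_background])
    # a predictor constant on the training data carries no information:
    # drop its linear and quadratic features and every product touching
    # it (those are collinear with the partner's linear feature)
    varying = np.ptp(train, axis=0) > 0
    defs: list[tuple] = [("linear", i) for i in range(p)]
    defs += [("quadratic", i) for i in range(p)]
    defs += [("product", i, j) for i, j in itertools.combinations(range(p), 2)]

    fs = FeatureSet(tuple(predictor_names), defs, np.zeros(len(defs)), np.ones(len(defs)))
    raw = fs.raw_features(train)
    lo, hi = raw.min(axis=0), raw.max(axis=0)
    keep = hi > lo
    keep &= np.array([all(varying[i] for i in d[1:]) for d in defs])
    if not keep.all():
        dropped = [lab for lab, k in zip(fs.labels(), keep) if not k]
        logger.warning("dropping constant feature(s): %s", ", ".join(dropped))
    fs = FeatureSet(
        tuple(predictor_names),
        [d for d, k in zip(defs, keep) if k],
        lo[keep],
        hi[keep],
    )
    if fs.n_features == 0:
        raise ValueError("all candidate features are constant on the training data")
    F_pres, _ = fs.transform(X_presence)
    F_bg, _ = fs.transform(X_background)
    return fs, F_pres, F_bg


def default_betas(F_presence: np.ndarray, beta_multiplier: float, table=BETA_TABLE) -> np.ndarray:
    """Per-feature L1 penalties from the feature-class default schedule."""
    m = F_presence.shape[0]
    sizes = np.array([t[0] for t in table], dtype=float)
    vals = np.array([t[1] for t in table], dtype=float)
    b = float(np.interp(m, sizes, vals))
    sd = np.maximum(F_presence.std(axis=0, ddof=0), 1e-3)
    return beta_multiplier * b * sd / np.sqrt(m)


@dataclass
class MaxEntModel:
    """A fitted model: weights, penalties, normalizer, entropy, metadata."""

    feature_set: FeatureSet
    lambdas: np.ndarray
    betas: np.ndarray
    beta_multiplier: float
    normalizer: float  # log Z over the training landscape
    entropy: float  # of the fitted distribution
    converged: bool
    training_meta: dict = field(default_factory=dict)

    def scores(self, F: np.ndarray) -> np.ndarray:
        """Raw relative occurrence rate exp(lambda.f - log Z) per row."""
        return np.exp(F @ self.lambdas - self.normalizer)

    def logistic(self, F: np.ndarray) -> np.ndarray:
        c = np.exp(self.entropy)
        r = self.scores(F)
        return c * r / (1.0 + c * r)

    def to_json(self) -> str:
        fs = self.feature_set
        return json.dumps(
            {
                "predictors": list(fs.predictor_names),
                "features": [list(d) for d in fs.definitions],
                "lo": fs.lo.tolist(),
                "hi": fs.hi.tolist(),
                "lambdas": self.lambdas.tolist(),
                "betas": self.betas.tolist(),
                "beta_multiplier": self.beta_multiplier,
                "normalizer": self.normalizer,
                "entropy": self.entropy,
                "converged": self.converged,
                "training_meta": self.training_meta,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        fs = FeatureSet(
            tuple(d["predictors"]),
            [tuple(x) for x in d["features"]],
            np.array(d["lo"]),
            np.array(d["hi"]),
        )
        return cls(
            fs,
            np.array(d["lambdas"]),
            np.array(d["betas"]),
            d["beta_multiplier"],
            d["normalizer"],
            d["entropy"],
            d["converged"],
            d["training_meta"],
        )


def penalized_loglik(
    lambdas: np.ndarray, F_presence: np.ndarray, F_landscape: np.ndarray, betas: np.ndarray
) -> float:
    """The objective being maximized (per-presence average)."""
    pbar = F_presence.mean(axis=0)
    return float(
        pbar @ lambdas - logsumexp(F_landscape @ lambdas) - np.abs(lambdas) @ betas
    )


def kkt_residual(
    lambdas: np.ndarray, F_presence: np.ndarray, F_landscape: np.ndarray, betas: np.ndarray
) -> float:
    """Max-norm violation of the L1 stationarity conditions.

    For active weights: |E_q[f] - mean_pres[f] + sign(lambda)*beta|.
    For zero weights: max(0, |E_q[f] - mean_pres[f]| - beta).
    """
    pbar = F_presence.mean(axis=0)
    s = F_landscape @ lambdas
    q = np.exp(s - logsumexp(s))
    g = q @ F_landscape - pbar
    active = lambdas != 0
    res = np.where(
        active, np.abs(g + np.sign(lambdas) * betas), np.maximum(0.0, np.abs(g) - betas)
    )
    return float(res.max(initial=0.0))


def fit(
    feature_set: FeatureSet,
    F_presence: np.ndarray,
    F_background: np.ndarray,
    beta_multiplier: float = 1.0,
    betas: np.ndarray | None = None,
    max_iter: int = MAX_ITER,
    training_meta: dict | None = None,
) -> MaxEntModel:
    """Fit the L1-penalized Gibbs model over background + presence cells.

    ``F_presence`` rows should be one per presence *cell* (duplicates
    collapsed upstream); the modelling landscape is their union with the
    background rows.  A model that fails the KKT tolerance within the
    iteration cap is still returned, flagged ``converged=False``.
    """
    if beta_multiplier < 0:
        raise ValueError("beta_multiplier must be >= 0")
    if betas is None:
        betas = default_betas(F_presence, beta_multiplier)
    betas = np.asarray(betas, dtype=float)
    F_land = np.vstack([F_presence, F_background])
    pbar = F_presence.mean(axis=0)
    J = feature_set.n_features

    def objective(z):
        lam = z[:J] - z[J:]
        s = F_land @ lam
        logz = logsumexp(s)
        f = logz - pbar @ lam + betas @ (z[:J] + z[J:])
        q = np.exp(s - logz)
        e = q @ F_land
        grad = np.concatenate([e - pbar + betas, -(e - pbar) + betas])
        return f, grad

    # L-BFGS-B with cold restarts: a restart resets the Hessian estimate,
    # which reliably pushes past premature ftol-based stalls; the total
    # iteration budget stays capped at max_iter.
    z = np.zeros(2 * J)
    iters_left = max_iter
    lam = z[:J] - z[J:]
    while iters_left > 0:
        res = minimize(
            objective,
            z,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * J),
            options={
                "maxiter": iters_left,
                "maxfun": 20 * max_iter,
                "ftol": 1e-15,
                "gtol": 1e-9,
            },
        )
        z = res.x
        iters_left -= max(res.nit, 1)
        lam = z[:J] - z[J:]
        if kkt_residual(lam, F_presence, F_land, betas) <= KKT_TOL:
            break
    lam[np.abs(lam) < ZERO_LAMBDA] = 0.0

    s = F_land @ lam
    logz = float(logsumexp(s))
    q = np.exp(s - logz)
    entropy = float(-(q * (s - logz)).sum())
    residual = kkt_residual(lam, F_presence, F_land, betas)
    converged = residual <= KKT_TOL
    if not converged:
        logger.warning("maxent fit did not reach KKT tolerance (residual %.2e)", residual)
    meta = dict(training_meta or {})
    meta.update(n_presence=int(F_presence.shape[0]), n_background=int(F_background.shape[0]))
    return MaxEntModel(
        feature_set, lam, betas, beta_multiplier, logz, entropy, converged, meta
    )


@dataclass
class SuitabilitySurface:
    """Continuous model output on a grid: normalized raw + logistic."""

    grid: GridSpec
    raw: np.ndarray  # normalized over valid cells (sums to 1)
    logistic: np.ndarray  # in (0, 1)
    species_id: str = ""
    scenario: str = ""
    n_clamped_cells: int = 0

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.logistic)


def predict(model: MaxEntModel, predictors: BioclimStack, scenario: str = "") -> SuitabilitySurface:
    """Project a fitted model onto a predictor stack.

    Features are rebuilt with the training scaling and clamped to the
    training [0, 1] range (the count of affected cells is recorded); the
    raw channel renormalizes over the valid cells of this grid, the
    logistic channel uses the training entropy calibration.
    """
    valid = predictors.valid
    rows, cols = np.nonzero(valid)
    X = predictors.matrix(rows, cols)
    F, n_clamped = model.feature_set.transform(X, clamp=True)
    s = F @ model.lambdas
    raw = np.full(predictors.grid.shape, np.nan)
    raw[rows, cols] = np.exp(s - logsumexp(s))
    logis = np.full(predictors.grid.shape, np.nan)
    c = np.exp(model.entropy)
    rel = np.exp(s - model.normalizer)
    logis[rows, cols] = c * rel / (1.0 + c * rel)
    return SuitabilitySurface(
        predictors.grid,
        raw,
        logis,
        species_id=model.training_meta.get("species_id", ""),
        scenario=scenario,
        n_clamped_cells=n_clamped,
    )


def cross_validate(
    feature_set: FeatureSet,
    F_presence: np.ndarray,
    F_background: np.ndarray,
    k: int = 5,
    seed: int = 0,
    beta_multiplier: float = 1.0,
):
    """k-fold cross-validation over presence cells with a shared background.

    Presences are partitioned into k seeded folds; each model trains on
    the other k-1 folds.  Yields (model, test_indices) pairs.
    """
    m = F_presence.shape[0]
    if k < 2 or k > m:
        raise ValueError(f"k must be in [2, n_presences={m}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    out = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        model = fit(
            feature_set,
            F_presence[train_idx],
            F_background,
            beta_multiplier=beta_multiplier,
            training_meta={"fold": i, "k": k, "seed": seed},
        )
        out.append((model, np.sort(test_idx)))
    return out
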