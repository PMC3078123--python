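"""Presence-only maximum-entropy habitat model.

The model estimates a Gibbs distribution q(x) ∝ exp(λ·f(x)) over a finite
set of background cells, where f are features built from the environmental
covariates (linear, quadratic, pairwise-product and hinge transforms of
each variable scaled to [0, 1]).  The weights λ maximise the L1-regularised
log-likelihood of the presence sample under q — equivalently, q is the
maximum-entropy distribution satisfying the feature-expectation constraints
implied by the presences.  The fit is run with the classic defaults:
convergence threshold 1e-5 on the per-iteration gain change, at most 500
iterations, regularisation multiplier 1.

Feature classes switch on with presence count m, mirroring the reference
Maxent auto-feature rule: linear always, quadratic at m >= 10, hinge at
m >= 15, product at m >= 80.  Per-feature regularisation is
``beta_class(m) * std_j / sqrt(m)`` with the published default beta tables
(linear/quadratic/product interpolated on m; hinge 0.5), times the
regularisation multiplier.

The reported habitat suitability index is the v3.2-era logistic output
``HSI = c q(x) / (1 + c q(x))`` with ``c = exp(H)``, H the entropy of the
fitted distribution over the background; a featureless (uniform) model
yields HSI = 0.5 everywhere.

The optimiser is proximal gradient descent (ISTA) with backtracking line
search on the regularised objective, which guarantees a monotone
non-decreasing gain trace — the contract the rest of the pipeline relies
on; the gain trace is stored on the fitted model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .grid import Grid, LayerStack

__all__ = [
    "MaxentConfig",
    "FeatureSet",
    "NicheModel",
    "JackknifeRow",
    "sample_background",
    "fit",
    "predict_logistic",
    "jackknife",
    "binary_map",
]

log = logging.getLogger(__name__)

# Published default beta tables: (presence count, beta) breakpoints.
_BETA_LQP = ([0, 10, 30, 100], [1.0, 1.0, 0.2, 0.05])
_BETA_HINGE = 0.5
_MIN_FEATURE_STD = 1e-4


@dataclass(frozen=True)
class MaxentConfig:
    """Fit configuration; defaults are the reference implementation's."""

    convergence_threshold: float = 1e-5
    max_iterations: int = 500
    regularization_multiplier: float = 1.0
    n_background: int = 10_000
    seed: int = 0
    n_hinge_knots: int = 50

    def __post_init__(self):
        if self.convergence_threshold <= 0 or self.max_iterations <= 0:
            raise ValueError("convergence_threshold and max_iterations must be positive")
        if self.regularization_multiplier <= 0 or self.n_background <= 0:
            raise ValueError("regularization_multiplier and n_background must be positive")


class FeatureSet:
    """Feature expansion of raw covariates, with [0, 1] scaling.

    Scaling min/max come from the presence + background pool; prediction
    inputs outside that range are clamped to the boundary before feature
    evaluation (Maxent's "clamping").
    """

    def __init__(
        self,
        variables: list[str],
        vmin: np.ndarray,
        vmax: np.ndarray,
        use_quadratic: bool,
        use_hinge: bool,
        use_product: bool,
        n_hinge_knots: int = 50,
    ):
        self.variables = list(variables)
        self.vmin = np.asarray(vmin, dtype=float)
        self.vmax = np.asarray(vmax, dtype=float)
        self.use_quadratic = use_quadratic
        self.use_hinge = use_hinge
        self.use_product = use_product
        self.n_hinge_knots = n_hinge_knots
        self._knots = (np.arange(n_hinge_knots) + 0.5) / n_hinge_knots

    @classmethod
    def from_pool(
        cls,
        pool: np.ndarray,
        variables: list[str],
        n_presences: int,
        n_hinge_knots: int = 50,
    ) -> "FeatureSet":
        """Build scaling from the presence+background pool and select
        feature classes from the presence count."""
        pool = np.asarray(pool, dtype=float)
        if not np.isfinite(pool).all():
            raise ValueError("non-finite covariates in feature pool")
        return cls(
            variables,
            pool.min(axis=0),
            pool.max(axis=0),
            use_quadratic=n_presences >= 10,
            use_hinge=n_presences >= 15,
            use_product=n_presences >= 80,
            n_hinge_knots=n_hinge_knots,
        )

    # -- evaluation --------------------------------------------------------
    def scale(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = np.where(self.vmax > self.vmin, self.vmax - self.vmin, 1.0)
        Z = (np.clip(X, self.vmin, self.vmax) - self.vmin) / span
        return Z

    def transform(self, X: np.ndarray) -> np.ndarray:
        """(n, V) raw covariates -> (n, F) feature matrix, values in [0, 1]."""
        Z = self.scale(X)
        cols = [Z]
        if self.use_quadratic:
            cols.append(Z ** 2)
        if self.use_product:
            V = Z.shape[1]
            iu, ju = np.triu_indices(V, k=1)
            cols.append(Z[:, iu] * Z[:, ju])
        if self.use_hinge:
            k = self._knots
            fwd = np.clip((Z[:, :, None] - k) / (1.0 - k), 0.0, None)
            rev = np.clip((k - Z[:, :, None]) / k, 0.0, None)
            n = Z.shape[0]
            cols.append(fwd.reshape(n, -1))
            cols.append(rev.reshape(n, -1))
        return np.concatenate(cols, axis=1)

    @property
    def feature_names(self) -> list[str]:
        names = list(self.variables)
        if self.use_quadratic:
            names += [f"{v}^2" for v in self.variables]
        if self.use_product:
            V = len(self.variables)
            iu, ju = np.triu_indices(V, k=1)
            names += [f"{self.variables[i]}*{self.variables[j]}" for i, j in zip(iu, ju)]
        if self.use_hinge:
            for tag in ("hinge", "rhinge"):
                names += [
                    f"{tag}({v},{k:.3f})" for v in self.variables for k in self._knots
                ]
        return names

    def feature_classes(self) -> np.ndarray:
        """Per-feature class label: 'lqp' or 'hinge' (drives beta)."""
        V = len(self.variables)
        n_lqp = V + (V if self.use_quadratic else 0)
        if self.use_product:
            n_lqp += V * (V - 1) // 2
        n_hinge = 2 * V * self.n_hinge_knots if self.use_hinge else 0
        return np.array(["lqp"] * n_lqp + ["hinge"] * n_hinge)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "vmin": self.vmin.tolist(),
            "vmax": self.vmax.tolist(),
            "use_quadratic": self.use_quadratic,
            "use_hinge": self.use_hinge,
            "use_product": self.use_product,
            "n_hinge_knots": self.n_hinge_knots,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            d["variables"], np.array(d["vmin"]), np.array(d["vmax"]),
            d["use_quadratic"], d["use_hinge"], d["use_product"], d["n_hinge_knots"],
        )


@dataclass
class NicheModel:
    """A fitted maximum-entropy niche model."""

    features: FeatureSet
    weights: np.ndarray
    log_partition: float  # log sum over background of exp(lambda . f)
    entropy: float  # entropy of the fitted distribution over background
    training_gain: float  # regularised gain at convergence
    n_background: int
    gain_trace: list[float] = field(default_factory=list)

    def log_density(self, X_raw: np.ndarray) -> np.ndarray:
        """log q(x): log Gibbs density normalised over the background
        (sums to 1 across the background sample)."""
        F = self.features.transform(np.asarray(X_raw, dtype=float))
        return F @ self.weights - self.log_partition

    def hsi(self, X_raw: np.ndarray) -> np.ndarray:
        """Logistic habitat suitability index in [0, 1]."""
        t = self.entropy + self.log_density(X_raw)
        return 1.0 / (1.0 + np.exp(-t))

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": self.features.to_dict(),
                "weights": self.weights.tolist(),
                "log_partition": self.log_partition,
                "entropy": self.entropy,
                "training_gain": self.training_gain,
                "n_background": self.n_background,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NicheModel":
        d = json.loads(text)
        return cls(
            FeatureSet.from_dict(d["features"]),
            np.array(d["weights"]),
            d["log_partition"],
            d["entropy"],
            d["training_gain"],
            d["n_background"],
        )


@dataclass(frozen=True)
class JackknifeRow:
    variable: str
    gain_without: float
    gain_only: float
    test_auc_only: float


# -- background sampling ---------------------------------------------------

def sample_background(
    stack: LayerStack, config: MaxentConfig, return_cells: bool = False
):
    """Draw background covariate vectors uniformly, without replacement,
    from the cells valid in every layer (seeded).  If fewer valid cells
    exist than requested, all are taken with a warning."""
    rows, cols = stack.valid_cells()
    n_valid = rows.size
    if n_valid == 0:
        raise ValueError("no valid cells to sample background from")
    n = config.n_background
    if n > n_valid:
        warnings.warn(
            f"requested {n} background points but only {n_valid} valid cells; using all"
        )
        sel = np.arange(n_valid)
    else:
        rng = np.random.default_rng(config.seed)
        sel = rng.choice(n_valid, size=n, replace=False)
    r, c = rows[sel], cols[sel]
    X = stack.covariates_at_cells(r, c)
    if return_cells:
        return X, r, c
    return X


# -- fitting ---------------------------------------------------------------

def _beta_vector(features: FeatureSet, P: np.ndarray, multiplier: float) -> np.ndarray:
    m = P.shape[0]
    classes = features.feature_classes()
    beta_lqp = np.interp(m, *_BETA_LQP)
    beta = np.where(classes == "hinge", _BETA_HINGE, beta_lqp)
    std = np.maximum(P.std(axis=0), _MIN_FEATURE_STD)
    return multiplier * beta * std / np.sqrt(m)


def fit(
    presences: np.ndarray,
    background: np.ndarray,
    config: MaxentConfig | None = None,
    variables: list[str] | None = None,
) -> NicheModel:
    """Fit the maximum-entropy model.

    Parameters
    ----------
    presences, background
        (m, V) and (N, V) raw covariate matrices.
    config
        Fit settings; defaults used when omitted.
    variables
        Covariate names (defaults to ``x0..x{V-1}``).
    """
    config = config or MaxentConfig()
    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if presences.shape[0] < 2:
        raise ValueError("need at least 2 presence samples")
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    if not (np.isfinite(presences).all() and np.isfinite(background).all()):
        raise ValueError("non-finite covariates")
    V = presences.shape[1]
    if variables is None:
        variables = [f"x{i}" for i in range(V)]

    pool = np.vstack([presences, background])
    features = FeatureSet.from_pool(
        pool, variables, presences.shape[0], config.n_hinge_knots
    )
    P = features.transform(presences)
    B = features.transform(background)
    beta = _beta_vector(features, P, config.regularization_multiplier)
    p_mean = P.mean(axis=0)
    N = B.shape[0]
    logN = np.log(N)

    def smooth_neg(lam):
        # -(mean presence log-lik relative to uniform), up to the logN shift
        return -(p_mean @ lam) + logsumexp(B @ lam)

    def gain_of(lam, sneg):
        return -sneg + logN - beta @ np.abs(lam)

    lam = np.zeros(P.shape[1])
    sneg = smooth_neg(lam)  # = logN at lam = 0
    gain = gain_of(lam, sneg)  # = 0
    trace = [gain]
    step = 1.0
    for _ in range(config.max_iterations):
        eta = B @ lam
        q = np.exp(eta - logsumexp(eta))
        grad = -p_mean + q @ B
        # backtracking proximal step
        while True:
            cand = np.sign(lam - step * grad) * np.maximum(
                np.abs(lam - step * grad) - step * beta, 0.0
            )
            d = cand - lam
            sneg_cand = smooth_neg(cand)
            if sneg_cand <= sneg + grad @ d + (d @ d) / (2.0 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                cand, sneg_cand = lam, sneg
                break
        lam, sneg = cand, sneg_cand
        new_gain = gain_of(lam, sneg)
        trace.append(new_gain)
        if abs(new_gain - gain) < config.convergence_threshold:
            gain = new_gain
            break
        gain = new_gain
        step *= 1.2  # allow the step to recover after backtracking

    eta = B @ lam
    log_partition = float(logsumexp(eta))
    logq = eta - log_partition
    q = np.exp(logq)
    entropy = float(-(q @ logq))
    model = NicheModel(
        features=features,
        weights=lam,
        log_partition=log_partition,
        entropy=entropy,
        training_gain=float(gain),
        n_background=N,
        gain_trace=[float(g) for g in trace],
    )
    log.info(
        "maxent fit: %d presences, %d background, %d features, gain %.4f, %d iterations",
        P.shape[0], N, P.shape[1], gain, len(trace) - 1,
    )
    return model


# -- prediction ------------------------------------------------------------

def predict_logistic(model: NicheModel, stack: LayerStack) -> Grid:
    """Per-cell HSI grid in [0, 1]; nodata wherever any layer is nodata."""
    if model.features.variables != stack.names:
        raise KeyError(
            f"stack variables {stack.names} do not match model "
            f"variables {model.features.variables}"
        )
    ref = stack.reference
    rows, cols = stack.valid_cells()
    X = stack.covariates_at_cells(rows, cols)
    vals = model.hsi(X)
    out = np.full(ref.values.shape, ref.nodata, dtype=float)
    out[rows, cols] = vals
    return ref.copy(values=out)


def binary_map(hsi: Grid, threshold: float) -> Grid:
    """Threshold an HSI grid into predicted presence (1) / absence (0);
    HSI exactly at the threshold counts as presence."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    out = np.full(hsi.values.shape, hsi.nodata, dtype=float)
    m = hsi.mask
    out[m] = (hsi.values[m] >= threshold).astype(float)
    return hsi.copy(values=out)


# -- variable importance ---------------------------------------------------

def jackknife(
    presences: np.ndarray,
    background: np.ndarray,
    variables: list[str],
    config: MaxentConfig | None = None,
    test_presences: np.ndarray | None = None,
) -> tuple[list[JackknifeRow], float]:
    """Leave-one-out / only-one variable importance.

    For every variable, fits a model without it (``gain_without``) and a
    model with only it (``gain_only``), and scores the only-it model by
    presence-background AUC on ``test_presences`` (training presences when
    no test set is given).  Returns the rows plus the full-model gain.
    """
    from .evaluate import auc_presence_background

    presences = np.atleast_2d(np.asarray(presences, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    if test_presences is None:
        test_presences = presences
    full = fit(presences, background, config, variables)
    rows = []
    for i, name in enumerate(variables):
        keep = [j for j in range(len(variables)) if j != i]
        m_wo = fit(
            presences[:, keep], background[:, keep], config, [variables[j] for j in keep]
        )
        m_only = fit(presences[:, [i]], background[:, [i]], config, [name])
        auc = auc_presence_background(
            m_only.log_density(test_presences[:, [i]]),
            m_only.log_density(background[:, [i]]),
        )
        rows.append(
            JackknifeRow(
                variable=name,
                gain_without=m_wo.training_gain,
                gain_only=m_only.training_gain,
                test_auc_only=float(auc),
            )
        )
    return rows, full.training_gain
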