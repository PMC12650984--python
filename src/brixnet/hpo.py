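"""Bayesian hyperparameter optimisation: GP surrogate + probability of improvement.

The mixed categorical/continuous search space (conv filter counts, FC widths,
log-uniform learning rate, batch size, activation, optimizer) is encoded into
the unit hypercube (integers min-max scaled, learning rates in log10,
categoricals one-hot).  A Gaussian-process surrogate (Matern 5/2, jitter 1e-6)
is fitted to the evaluated configurations and the next point maximises the
probability of improvement

    PI(x) = Phi((mu(x) - f_best - xi) / sigma(x))

over a random candidate pool.  The first ``n_init`` points are quasi-random
(Sobol).  The optimisation objective is the mean validation-fold R² of a
fruit-level five-fold cross-validation.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

from .evaluation import r_squared
from .models import ModelSpec, build_model, train
from .preprocess import FruitPatchDataset

logger = logging.getLogger(__name__)

__all__ = [
    "Dim",
    "SearchSpace",
    "BoaTrace",
    "IterationRecord",
    "encode",
    "decode",
    "suggest_next",
    "run_boa",
    "cv_objective",
    "fold_assignments",
    "probability_of_improvement",
    "fit_gp",
    "ca_cnn_space",
    "sa_cnn_space",
    "ma_cnn_space",
]

ACTIVATIONS = ["relu", "softmax", "sigmoid", "elu"]
OPTIMIZERS = ["sgd", "adam", "adabound", "rmsprop"]


@dataclass(frozen=True)
class Dim:
    name: str
    kind: str  # "int" | "log" | "cat"
    domain: tuple

    def __post_init__(self):
        if self.kind not in ("int", "log", "cat"):
            raise ValueError(f"unknown dim kind {self.kind!r}")
        if len(self.domain) == 0:
            raise ValueError(f"dim {self.name}: empty domain")
        if self.kind in ("int", "log") and not self.domain[0] < self.domain[1]:
            raise ValueError(f"dim {self.name}: empty range {self.domain}")

    @property
    def width(self) -> int:
        return len(self.domain) if self.kind == "cat" else 1


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple[Dim, ...]

    @property
    def n_encoded(self) -> int:
        return sum(d.width for d in self.dims)

    def validate(self, config: dict) -> None:
        for d in self.dims:
            if d.name not in config:
                raise ValueError(f"config missing dimension {d.name!r}")
            v = config[d.name]
            if d.kind == "cat":
                if v not in d.domain:
                    raise ValueError(f"{d.name}={v!r} not in {d.domain}")
            elif not (d.domain[0] <= v <= d.domain[1]):
                raise ValueError(f"{d.name}={v} outside {d.domain}")


def encode(config: dict, space: SearchSpace) -> np.ndarray:
    """Map a configuration into the unit hypercube."""
    space.validate(config)
    out = []
    for d in space.dims:
        v = config[d.name]
        if d.kind == "int":
            lo, hi = d.domain
            out.append((float(v) - lo) / (hi - lo))
        elif d.kind == "log":
            lo, hi = np.log10(d.domain[0]), np.log10(d.domain[1])
            out.append((np.log10(v) - lo) / (hi - lo))
        else:
            onehot = [0.0] * len(d.domain)
            onehot[d.domain.index(v)] = 1.0
            out.extend(onehot)
    return np.array(out)


def decode(vector: np.ndarray, space: SearchSpace) -> dict:
    """Inverse of :func:`encode`; fractional one-hot blocks decode by argmax."""
    vector = np.asarray(vector, dtype=float)
    if vector.shape != (space.n_encoded,):
        raise ValueError(f"expected vector of length {space.n_encoded}")
    config = {}
    i = 0
    for d in space.dims:
        if d.kind == "int":
            lo, hi = d.domain
            config[d.name] = int(round(lo + np.clip(vector[i], 0, 1) * (hi - lo)))
            i += 1
        elif d.kind == "log":
            lo, hi = np.log10(d.domain[0]), np.log10(d.domain[1])
            config[d.name] = float(10 ** (lo + np.clip(vector[i], 0, 1) * (hi - lo)))
            i += 1
        else:
            block = vector[i : i + len(d.domain)]
            config[d.name] = d.domain[int(np.argmax(block))]
            i += len(d.domain)
    return config


def ca_cnn_space() -> SearchSpace:
    """Spectral-branch network search space (filters, FC widths, lr, batch, act, opt)."""
    return SearchSpace(
        (
            Dim("filters1", "int", (4, 64)),
            Dim("filters2", "int", (8, 128)),
            Dim("filters3", "int", (16, 256)),
            Dim("fc1", "int", (32, 128)),
            Dim("fc2", "int", (32, 128)),
            Dim("learning_rate", "log", (1e-4, 1e-1)),
            Dim("batch_size", "int", (2, 128)),
            Dim("activation", "cat", tuple(ACTIVATIONS)),
            Dim("optimizer", "cat", tuple(OPTIMIZERS)),
        )
    )


def sa_cnn_space() -> SearchSpace:
    return SearchSpace(
        (
            Dim("filters1", "int", (4, 64)),
            Dim("filters2", "int", (16, 256)),
            Dim("filters3", "int", (8, 128)),
            Dim("fc1", "int", (64, 256)),
            Dim("fc2", "int", (64, 256)),
            Dim("learning_rate", "log", (1e-4, 1e-2)),
            Dim("batch_size", "int", (2, 128)),
            Dim("activation", "cat", tuple(ACTIVATIONS)),
            Dim("optimizer", "cat", tuple(OPTIMIZERS)),
        )
    )


def ma_cnn_space() -> SearchSpace:
    """Dual-branch space: branch filters are inherited from the single-branch optima."""
    return SearchSpace(
        (
            Dim("fc1", "int", (64, 256)),
            Dim("fc2", "int", (64, 256)),
            Dim("learning_rate", "log", (1e-5, 1e-1)),
            Dim("batch_size", "int", (4, 128)),
            Dim("activation", "cat", tuple(ACTIVATIONS)),
            Dim("optimizer", "cat", tuple(OPTIMIZERS)),
        )
    )


@dataclass
class IterationRecord:
    config: dict
    objective: float
    duration: float
    fold_scores: list[float] | None = None
    failed: bool = False


@dataclass
class BoaTrace:
    iterations: list[IterationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.iterations)

    @property
    def best_so_far(self) -> np.ndarray:
        vals = [r.objective for r in self.iterations]
        return np.maximum.accumulate(vals) if vals else np.array([])

    def evaluated(self) -> tuple[list[dict], np.ndarray]:
        recs = [r for r in self.iterations if np.isfinite(r.objective)]
        return [r.config for r in recs], np.array([r.objective for r in recs])


def probability_of_improvement(mu, sigma, f_best: float, xi: float = 0.01) -> np.ndarray:
    """PI(x) = Phi((mu - f_best - xi)/sigma); zero where sigma is 0."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    out = np.zeros_like(mu)
    ok = sigma > 0
    out[ok] = norm.cdf((mu[ok] - f_best - xi) / sigma[ok])
    return out


def fit_gp(X: np.ndarray, y: np.ndarray, jitter: float = 1e-6) -> GaussianProcessRegressor:
    """Matern-5/2 GP surrogate with a small jitter; length scale fitted by ML."""
    gp = GaussianProcessRegressor(
        kernel=Matern(nu=2.5, length_scale=0.3, length_scale_bounds=(1e-2, 1e2)),
        alpha=jitter,
        normalize_y=True,
        n_restarts_optimizer=0,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs may stop early; the fit is still usable
        gp.fit(X, y)
    return gp


def _sobol_point(space: SearchSpace, seed: int, index: int) -> dict:
    sob = qmc.Sobol(space.n_encoded, scramble=True, seed=seed & 0x7FFFFFFF)
    n = 1 << (index + 1).bit_length()  # power of two keeps the sequence balanced
    pts = sob.random(n)
    return decode(pts[index], space)


def suggest_next(
    trace: BoaTrace,
    space: SearchSpace,
    seed: int,
    n_init: int = 5,
    xi: float = 0.01,
    pool: int = 512,
) -> dict:
    """Next configuration: quasi-random during warm-up, then PI-optimal."""
    configs, y = trace.evaluated()
    if len(configs) < n_init:
        return _sobol_point(space, seed, len(trace))
    rng = np.random.default_rng([seed & 0x7FFFFFFF, len(trace)])
    if np.ptp(y) == 0:
        logger.info("degenerate BOA history (all objectives equal); sampling at random")
        return decode(rng.uniform(size=space.n_encoded), space)
    X = np.stack([encode(c, space) for c in configs])
    gp = fit_gp(X, y)
    # snap candidates onto the valid grid before scoring so PI is evaluated
    # at points that decode to themselves
    cand_cfgs = [decode(v, space) for v in rng.uniform(size=(pool, space.n_encoded))]
    cand = np.stack([encode(c, space) for c in cand_cfgs])
    mu, sigma = gp.predict(cand, return_std=True)
    pi = probability_of_improvement(mu, sigma, float(y.max()), xi=xi)
    return cand_cfgs[int(np.argmax(pi))]


def run_boa(
    space: SearchSpace,
    objective,
    n_iter: int = 30,
    seed: int = 0,
    n_init: int = 5,
    xi: float = 0.01,
    pool: int = 512,
) -> tuple[BoaTrace, dict]:
    """Sequential BOA loop; returns the trace and the selected best configuration.

    ``objective`` maps a config dict to a scalar (or a (scalar, fold-scores)
    tuple).  A raising objective records that iteration as failed with -inf and
    the loop continues.  Among iterations tied at the maximum objective, the
    one with the lowest fold-score variance wins (earliest on remaining ties) —
    stability operationalised as cross-validation spread.
    """
    trace = BoaTrace()
    for _ in range(n_iter):
        config = suggest_next(trace, space, seed, n_init=n_init, xi=xi, pool=pool)
        t0 = time.perf_counter()
        folds = None
        failed = False
        try:
            res = objective(config)
            if isinstance(res, tuple):
                value, folds = float(res[0]), list(res[1])
            else:
                value = float(res)
        except Exception as exc:  # noqa: BLE001 - any model failure is a failed trial
            logger.warning("objective failed for %s: %s", config, exc)
            value, failed = float("-inf"), True
        trace.iterations.append(
            IterationRecord(
                config=config,
                objective=value,
                duration=time.perf_counter() - t0,
                fold_scores=folds,
                failed=failed,
            )
        )
    finite = [r for r in trace.iterations if np.isfinite(r.objective)]
    if not finite:
        raise RuntimeError("all BOA iterations failed")
    best_val = max(r.objective for r in finite)
    tied = [r for r in finite if r.objective == best_val]

    def _stability(rec: IterationRecord) -> float:
        return float(np.var(rec.fold_scores)) if rec.fold_scores else 0.0

    best = min(tied, key=lambda r: (_stability(r), trace.iterations.index(r)))
    return trace, best.config


def _default_trainer(xs, xp, y, spec: ModelSpec, n_bands: int, seed: int):
    model = build_model(spec, n_bands, seed=seed)
    trained = train(
        model,
        xs if spec.spectral_branch is not None else None,
        xp if spec.spatial_branch is not None else None,
        y,
        spec,
        seed=seed,
    )
    return trained


def fold_assignments(ids: list[str], folds: int, seed: int) -> list[list[str]]:
    """Random partition of fruit ids into ``folds`` disjoint, exhaustive folds."""
    ids = list(ids)
    if len(ids) < folds:
        raise ValueError(f"{len(ids)} fruits cannot fill {folds} folds")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    perm = rng.permutation(len(ids))
    parts = np.array_split(perm, folds)
    if any(len(p) == 0 for p in parts):
        raise ValueError("empty cross-validation fold")
    return [[ids[i] for i in part] for part in parts]


def cv_objective(
    dataset: FruitPatchDataset,
    spec_template: ModelSpec,
    folds: int = 5,
    seed: int = 0,
    trainer=None,
    augment: bool = False,
    return_folds: bool = False,
):
    """Mean validation-fold R² of a fruit-level k-fold cross-validation.

    Folds partition fruit ids (never patches); augmentation, when enabled, is
    applied to training folds only.  ``trainer(xs, xp, y, spec, n_bands, seed)``
    may be injected to replace network training (it must return an object with
    ``predict_brix``); fold scores are fruit-level R² of patch-averaged
    predictions.
    """
    fold_ids = fold_assignments(list(dataset.sample_ids), folds, seed)
    trainer = trainer or _default_trainer
    n_bands = dataset.cubes[0].shape[2]
    scores = []
    for k in range(folds):
        val_ids = fold_ids[k]
        train_ids = [i for j in range(folds) if j != k for i in fold_ids[j]]
        xs, xp, y, _ = dataset.patch_arrays(train_ids, seed=seed * folds + k, augment_data=augment)
        trained = trainer(xs, xp, y, spec_template, n_bands, seed + k)
        vxs, vxp, vy, vpids = dataset.patch_arrays(val_ids, seed=seed * folds + k + 1)
        patch_preds = trained.predict_brix(vxs, vxp)
        order: list[str] = []
        bucket: dict[str, list[float]] = {}
        for pid, p in zip(vpids, patch_preds):
            if pid not in bucket:
                bucket[pid] = []
                order.append(pid)
            bucket[pid].append(float(p))
        preds = np.array([np.mean(bucket[pid]) for pid in order])
        truth = {pid: dataset.labels[dataset.subset_indices([pid])[0]] for pid in order}
        scores.append(r_squared([truth[pid] for pid in order], preds))
    mean_score = float(np.mean(scores))
    return (mean_score, scores) if return_folds else mean_score
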