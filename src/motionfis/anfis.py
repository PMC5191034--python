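"""Zero-order Sugeno fuzzy system with hybrid (neuro-fuzzy) training.

Walk/run discrimination uses the three per-axis acceleration deviations of
the thigh sensor (σ_gBx, σ_gBy, σ_gBz) as inputs.  The model has three
Gaussian membership functions per input and one constant consequent per
rule; rules enumerate every MF combination (grid partition), giving
3³ = 27 rules.  The crisp output is the firing-strength-weighted average
of the consequents, interpreted as a motion index: walk in [1, 2], run in
[3, 4], uncertain in (2, 3), anything else out of range.

Hybrid learning alternates, per epoch, a batch least-squares solve for the
27 consequents (the output is linear in them given the normalized firing
strengths) with a normalized gradient-descent step on all Gaussian centers
and widths, using an adaptive step size.  The per-epoch training RMSE is
recorded.

Rule order is lexicographic with the first input most significant: rule
r = 9(i−1) + 3(j−1) + k for MF indices (i, j, k); the convention is carried
on the model as ``rule_order`` so alternative orderings can be compared
(see :mod:`motionfis.diagnostics`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

WALK_BAND = (1.0, 2.0)
RUN_BAND = (3.0, 4.0)
N_INPUTS = 3
N_MFS = 3
N_RULES = N_MFS**N_INPUTS

RULE_ORDER_DEFAULT = "first_input_most_significant"

_SIGMA_FLOOR = 1e-4  # prevents MF collapse during gradient descent

#: Width of the three initial Gaussians on the canonical [0, 2] input range.
INIT_SIGMA = 0.3397


@dataclass
class GaussianMF:
    """Gaussian membership f(x; σ, μ) = exp(−(x−μ)² / (2σ²))."""

    sigma: float
    mu: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("Gaussian MF width must be positive")

    def __call__(self, x):
        return np.exp(-((np.asarray(x, dtype=float) - self.mu) ** 2) / (2 * self.sigma**2))


@dataclass
class SugenoModel:
    """3-input, 27-rule zero-order Sugeno system."""

    mfs: list[list[GaussianMF]]  # [input][mf]
    consequents: np.ndarray  # (27,)
    rule_order: str = RULE_ORDER_DEFAULT

    def __post_init__(self) -> None:
        self.consequents = np.asarray(self.consequents, dtype=float)
        if len(self.mfs) != N_INPUTS or any(len(m) != N_MFS for m in self.mfs):
            raise ValueError(f"model requires {N_MFS} MFs for each of {N_INPUTS} inputs")
        if self.consequents.shape != (N_RULES,):
            raise ValueError(f"model requires {N_RULES} consequents")

    def copy(self) -> "SugenoModel":
        return SugenoModel(
            mfs=[[GaussianMF(m.sigma, m.mu) for m in row] for row in self.mfs],
            consequents=self.consequents.copy(),
            rule_order=self.rule_order,
        )


@dataclass(frozen=True)
class MotionIndex:
    """Crisp output with its band: walk [1,2], run [3,4], uncertain (2,3)."""

    value: float
    band: str  # walk | run | uncertain | out_of_range


@dataclass
class TrainingConfig:
    epochs: int = 40
    step_size: float = 0.01
    step_decrease: float = 0.9
    step_increase: float = 1.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be ≥ 1")


@dataclass
class TrainingTrace:
    rmse: np.ndarray  # per-epoch training RMSE, length = epochs
    model: SugenoModel


def init_grid(
    input_ranges: Sequence[tuple[float, float]] = ((0.0, 2.0),) * 3,
) -> SugenoModel:
    """Grid-partition initialization.

    Per input, three Gaussians centered at the range's endpoints and
    midpoint; on the canonical [0, 2] range the centers are {0, 1, 2} with
    width 0.3397, and widths scale with the half-range otherwise.  The 26
    in-band consequents split the walk band [1, 2] and the run band [3, 4]
    into 13 equal steps of 1/13 ≈ 0.0769 each; the 27th consequent sits at
    2.5, the middle of the uncertain gap, catching combinations matching
    neither motion.
    """
    if len(input_ranges) != N_INPUTS:
        raise ValueError(f"need {N_INPUTS} input ranges")
    mfs: list[list[GaussianMF]] = []
    for lo, hi in input_ranges:
        if not hi > lo:
            raise ValueError(f"degenerate input range ({lo}, {hi})")
        scale = (hi - lo) / 2.0
        sigma = INIT_SIGMA * scale
        mfs.append([GaussianMF(sigma, lo), GaussianMF(sigma, lo + scale), GaussianMF(sigma, hi)])
    walk = WALK_BAND[0] + np.arange(1, 14) / 13.0
    run = RUN_BAND[0] + np.arange(1, 14) / 13.0
    consequents = np.concatenate([walk, run, [2.5]])
    return SugenoModel(mfs=mfs, consequents=consequents)


def _memberships(model: SugenoModel, X: np.ndarray) -> np.ndarray:
    """(n, 3 inputs, 3 MFs) membership grid for an (n, 3) input matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], N_INPUTS, N_MFS))
    for f in range(N_INPUTS):
        for j in range(N_MFS):
            out[:, f, j] = model.mfs[f][j](X[:, f])
    return out


def rule_weights(model: SugenoModel, X: np.ndarray) -> np.ndarray:
    """(n, 27) rule firing strengths: product conjunction, lexicographic order."""
    M = _memberships(model, X)
    W = np.einsum("ni,nj,nk->nijk", M[:, 0], M[:, 1], M[:, 2])
    return W.reshape(-1, N_RULES)


def forward(model: SugenoModel, x: np.ndarray) -> float:
    """Crisp output Σ wᵢcᵢ / Σ wᵢ for one 3-vector input."""
    w = rule_weights(model, np.atleast_2d(x))[0]
    s = w.sum()
    if s <= 0.0 or not np.isfinite(s):
        raise FloatingPointError("all rule weights vanished; output undefined")
    return float(w @ model.consequents / s)


def forward_batch(model: SugenoModel, X: np.ndarray) -> np.ndarray:
    W = rule_weights(model, X)
    s = W.sum(axis=1)
    if np.any(s <= 0.0) or not np.all(np.isfinite(s)):
        raise FloatingPointError("all rule weights vanished for some input")
    return (W @ model.consequents) / s


def classify_index(value: float) -> MotionIndex:
    """Band assignment of a crisp motion index."""
    if WALK_BAND[0] <= value <= WALK_BAND[1]:
        band = "walk"
    elif RUN_BAND[0] <= value <= RUN_BAND[1]:
        band = "run"
    elif WALK_BAND[1] < value < RUN_BAND[0]:
        band = "uncertain"
    else:
        band = "out_of_range"
    return MotionIndex(value=float(value), band=band)


def label_training_data(
    activities: Sequence[str], seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw a target motion index per label, uniform within the label's band."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(len(activities))
    for i, act in enumerate(activities):
        if act == "walk":
            out[i] = rng.uniform(*WALK_BAND)
        elif act == "run":
            out[i] = rng.uniform(*RUN_BAND)
        else:
            raise ValueError(f"motion-index labels must be walk or run, got {act!r}")
    return out


#: Condition-number threshold above which the consequent design matrix is
#: treated as numerically singular (rules fired by almost no record would
#: otherwise receive arbitrarily large constants).
_COND_LIMIT = 1e8


def _solve_consequents(Wn: np.ndarray, y: np.ndarray, warn: bool = True) -> np.ndarray:
    """Least-squares consequents given normalized firing strengths.

    Falls back to a ridge-regularized solve when the design is rank
    deficient or numerically singular (condition number beyond
    ``_COND_LIMIT``): corner rules fired by almost no training record have
    no usable signal and pure least squares would assign them runaway
    constants.
    """
    c, _, rank, sv = np.linalg.lstsq(Wn, y, rcond=None)
    cond = sv[0] / sv[-1] if rank == N_RULES and sv[-1] > 0 else np.inf
    if rank < N_RULES or cond > _COND_LIMIT:
        lam = 1e-6 * float(np.trace(Wn.T @ Wn)) / N_RULES
        logger.log(
            logging.WARNING if warn else logging.DEBUG,
            "consequent design matrix rank %d, cond %.2g; using ridge (λ=%g)",
            rank, cond, lam,
        )
        c = np.linalg.solve(Wn.T @ Wn + lam * np.eye(N_RULES), Wn.T @ y)
    return c


def hybrid_train(
    model: SugenoModel,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig | None = None,
) -> TrainingTrace:
    """Hybrid learning: per epoch, LS consequents then a gradient step.

    Each epoch (a) solves the 27 consequents by batch least squares at the
    current antecedents, records the training RMSE, then (b) takes one
    normalized full-batch gradient-descent step on every Gaussian (σ, μ).
    The step size decreases ×``step_decrease`` when the RMSE rose and
    increases ×``step_increase`` after two consecutive falls.  The input
    model is not modified.
    """
    config = config or TrainingConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape != (y.size, N_INPUTS):
        raise ValueError(f"X must be (n, {N_INPUTS}) matching y")
    if X.shape[0] < N_RULES:
        logger.warning(
            "only %d records for %d consequents; solve is underdetermined",
            X.shape[0], N_RULES,
        )
    m = model.copy()
    eta = config.step_size
    rmses: list[float] = []
    for epoch in range(config.epochs):
        W = rule_weights(m, X)
        S = W.sum(axis=1, keepdims=True)
        if np.any(S <= 0.0):
            raise FloatingPointError("a training record fires no rule")
        Wn = W / S
        m.consequents = _solve_consequents(Wn, y, warn=epoch == 0)
        pred = Wn @ m.consequents
        err = pred - y
        rmses.append(float(np.sqrt(np.mean(err**2))))

        if eta > 0.0:
            g_sigma, g_mu = _antecedent_gradients(m, X, W, S, pred, err)
            norm = float(np.sqrt(np.sum(g_sigma**2) + np.sum(g_mu**2)))
            if norm > 0.0:
                for f in range(N_INPUTS):
                    for j in range(N_MFS):
                        mf = m.mfs[f][j]
                        mf.sigma = max(
                            mf.sigma - eta * g_sigma[f, j] / norm, _SIGMA_FLOOR
                        )
                        mf.mu = mf.mu - eta * g_mu[f, j] / norm
        # adaptive step size on the RMSE history
        if len(rmses) >= 2 and rmses[-1] > rmses[-2]:
            eta *= config.step_decrease
        elif len(rmses) >= 3 and rmses[-1] < rmses[-2] < rmses[-3]:
            eta *= config.step_increase
    return TrainingTrace(rmse=np.array(rmses), model=m)


def _antecedent_gradients(m, X, W, S, pred, err):
    """∂SSE/∂σ and ∂SSE/∂μ for all 9 Gaussians (analytic, full batch)."""
    # G[n, r] = w_nr (c_r − pred_n) / S_n ;  A[n, f, j] sums G over rules
    # whose antecedent on input f is MF j.
    G = W * (m.consequents[None, :] - pred[:, None]) / S
    G3 = G.reshape(-1, N_MFS, N_MFS, N_MFS)
    A = np.stack(
        [G3.sum(axis=(2, 3)), G3.sum(axis=(1, 3)), G3.sum(axis=(1, 2))], axis=1
    )  # (n, input, mf)
    g_sigma = np.zeros((N_INPUTS, N_MFS))
    g_mu = np.zeros((N_INPUTS, N_MFS))
    for f in range(N_INPUTS):
        for j in range(N_MFS):
            mf = m.mfs[f][j]
            d = X[:, f] - mf.mu
            common = 2.0 * err * A[:, f, j]
            g_mu[f, j] = np.sum(common * d / mf.sigma**2)
            g_sigma[f, j] = np.sum(common * d**2 / mf.sigma**3)
    return g_sigma, g_mu


@dataclass
class RecognitionReport:
    """Per-class tallies mirroring the walk/run evaluation layout."""

    correct: dict[str, int]
    total: dict[str, int]
    uncertain: dict[str, int]
    rate_including: dict[str, float]
    rate_excluding: dict[str, float | None]
    rmse_excluding: float | None

    def as_dict(self) -> dict:
        return {
            "correct": self.correct,
            "total": self.total,
            "uncertain": self.uncertain,
            "rate_including": self.rate_including,
            "rate_excluding": self.rate_excluding,
            "rmse_excluding": self.rmse_excluding,
        }


def evaluate(
    model: SugenoModel,
    X: np.ndarray,
    labels: Sequence[str],
    targets: np.ndarray | None = None,
) -> RecognitionReport:
    """Score walk/run recognition, tallying uncertain outputs separately.

    Rates are reported in percent, per class, both including uncertain
    outputs (counted as misses) and excluding them from the denominator.
    The RMSE against target indices, when given, also excludes uncertain
    outputs.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    outputs = forward_batch(model, X)
    bands = [classify_index(v).band for v in outputs]
    classes = sorted(set(labels))
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    uncertain = {c: 0 for c in classes}
    keep = np.ones(len(labels), dtype=bool)
    for i, (lab, band) in enumerate(zip(labels, bands)):
        total[lab] += 1
        if band == lab:
            correct[lab] += 1
        elif band in ("uncertain", "out_of_range"):
            uncertain[lab] += 1
            keep[i] = False
    rate_inc = {c: 100.0 * correct[c] / total[c] if total[c] else 0.0 for c in classes}
    rate_exc: dict[str, float | None] = {}
    for c in classes:
        denom = total[c] - uncertain[c]
        rate_exc[c] = 100.0 * correct[c] / denom if denom else None
    rmse = None
    if targets is not None and np.any(keep):
        t = np.asarray(targets, dtype=float).ravel()
        rmse = float(np.sqrt(np.mean((outputs[keep] - t[keep]) ** 2)))
    return RecognitionReport(
        correct=correct,
        total=total,
        uncertain=uncertain,
        rate_including=rate_inc,
        rate_excluding=rate_exc,
        rmse_excluding=rmse,
    )


# --- serialization ---------------------------------------------------------

def to_json(model: SugenoModel) -> str:
    doc = {
        "rule_order": model.rule_order,
        "mfs": [[{"sigma": m.sigma, "mu": m.mu} for m in row] for row in model.mfs],
        "consequents": model.consequents.tolist(),
    }
    return json.dumps(doc, indent=2)


def from_json(text: str) -> SugenoModel:
    doc = json.loads(text)
    return SugenoModel(
        mfs=[[GaussianMF(m["sigma"], m["mu"]) for m in row] for row in doc["mfs"]],
        consequents=np.array(doc["consequents"]),
        rule_order=doc["rule_order"],
    )


def save(model: SugenoModel, path: str | Path) -> None:
    Path(path).write_text(to_json(model))


def load(path: str | Path) -> SugenoModel:
    return from_json(Path(path).read_text())
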