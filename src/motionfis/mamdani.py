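"""Mamdani fuzzy inference system for five-activity recognition.

The classifier maps a five-feature input vector (SET-1 or SET-2, see
:mod:`motionfis.features`) to one of {stand, sit, lie, walk, run}:

1. fuzzification — each feature is evaluated against piecewise-linear
   (trapezoidal) membership functions with the published boundary cuts;
2. rule firing — each if-then rule's strength is the minimum of its
   antecedent memberships (don't-care antecedents are skipped);
3. implication/aggregation — each rule's output triangle is clipped at the
   rule strength (min implication) and the clipped shapes are combined by
   pointwise maximum;
4. defuzzification — the crisp output is the centroid (center-of-mass
   abscissa) of the aggregated shape, computed analytically from the
   clipped-triangle polygon.

The five output membership functions are symmetric triangles on the motor
index axis with peaks {0.5, 1, 1.5, 2, 2.5} (stand, sit, lie, walk, run)
and half-width 0.5, so a single rule firing at full strength defuzzifies
exactly to its activity's peak.  A crisp output is mapped back to an
activity by the nearest peak; if no rule fires the input is unrecognized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

ACTIVITIES = ("stand", "sit", "lie", "walk", "run")
OUTPUT_PEAKS = {"stand": 0.5, "sit": 1.0, "lie": 1.5, "walk": 2.0, "run": 2.5}
OUTPUT_HALF_WIDTH = 0.5

UNRECOGNIZED = "unrecognized"


@dataclass(frozen=True)
class PiecewiseLinearMF:
    """Membership function as ordered (domain value, strength) breakpoints.

    Between breakpoints the strength is linearly interpolated; outside the
    first/last breakpoint it is 0.  Plateaus and ramps of the published
    trapezoids are expressed directly as breakpoints.
    """

    name: str
    breakpoints: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        xs = [b[0] for b in self.breakpoints]
        ys = [b[1] for b in self.breakpoints]
        if len(xs) < 2:
            raise ValueError("membership function needs at least 2 breakpoints")
        if np.any(np.diff(xs) <= 0):
            raise ValueError(f"breakpoint abscissae must strictly increase: {xs}")
        if min(ys) < 0 or max(ys) > 1:
            raise ValueError("membership strengths must lie in [0, 1]")

    def __call__(self, x: float) -> float:
        xs = np.array([b[0] for b in self.breakpoints])
        ys = np.array([b[1] for b in self.breakpoints])
        if x < xs[0] or x > xs[-1]:
            return 0.0
        return float(np.interp(x, xs, ys))


def mf_eval(mf: PiecewiseLinearMF, x: float) -> float:
    """Evaluate a membership function at x (0 outside its support)."""
    return mf(x)


@dataclass(frozen=True)
class TriangularOutputMF:
    """Symmetric output triangle: height 1 at peak, 0 at peak ± half_width."""

    activity: str
    peak: float
    half_width: float = OUTPUT_HALF_WIDTH


@dataclass(frozen=True)
class FuzzyRule:
    """Antecedent (feature name → MF label; missing = don't care) and activity."""

    antecedent: Mapping[str, str]
    consequent: str

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ValueError("rule needs at least one non-don't-care antecedent")
        if self.consequent not in ACTIVITIES:
            raise ValueError(f"unknown activity {self.consequent!r}")


@dataclass
class MamdaniModel:
    feature_set_id: int
    feature_names: tuple[str, ...]
    variables: dict[str, dict[str, PiecewiseLinearMF]]
    output_mfs: dict[str, TriangularOutputMF]
    rules: list[FuzzyRule]

    def __post_init__(self) -> None:
        for rule in self.rules:
            for name, label in rule.antecedent.items():
                if name not in self.variables or label not in self.variables[name]:
                    raise ValueError(
                        f"rule references undeclared membership {name}/{label}"
                    )


# Published boundary cuts of the input trapezoids, expressed as breakpoints.
# Angles in degrees; accelerations in g; angular velocities in °/s;
# gradients in °/s² (chest gyro) and g/s (thigh acc).
_THETA_LOW = ((0.0, 1.0), (16.0, 1.0), (36.0, 0.0))
_THETA_HIGH = ((0.0, 0.0), (30.0, 0.0), (60.0, 1.0), (90.0, 1.0))

_SET1_MFS: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    "theta_A": {"low": _THETA_LOW, "high": _THETA_HIGH},
    "theta_B": {"low": _THETA_LOW, "high": _THETA_HIGH},
    # Only the plateaus are published for omega_BRx; the transition across
    # the (25, 60) gap is linear, keeping both functions continuous.
    "omega_BRx": {
        "low": ((0.0, 1.0), (25.0, 1.0), (60.0, 0.0)),
        "high": ((25.0, 0.0), (60.0, 1.0), (300.0, 1.0)),
    },
    "g_BRx": {
        "low": ((0.0, 0.0), (0.08, 1.0), (0.28, 1.0), (0.4, 0.0)),
        "high": ((0.28, 0.0), (0.38, 1.0), (1.35, 1.0)),
    },
    "sigma_gBx": {
        "low": ((0.0, 0.0), (0.07, 1.0), (0.28, 1.0), (0.32, 0.0)),
        "high": ((0.28, 0.0), (0.4, 1.0), (1.0, 1.0)),
    },
}

_SET2_MFS: dict[str, dict[str, tuple[tuple[float, float], ...]]] = {
    "theta_A": {"low": _THETA_LOW, "high": _THETA_HIGH},
    "theta_B": {"low": _THETA_LOW, "high": _THETA_HIGH},
    "gamma_wAx": {
        "low": ((0.0, 1.0), (15.0, 1.0), (22.0, 0.0)),
        "high": ((15.0, 0.0), (30.0, 1.0), (60.0, 1.0)),
    },
    "gamma_gBx": {
        "low": ((0.0, 1.0), (0.02, 1.0), (0.03, 0.0)),
        "medium": ((0.0, 0.0), (0.02, 1.0), (0.18, 1.0), (0.2, 0.0)),
        "high": ((0.18, 0.0), (0.23, 1.0), (1.0, 1.0)),
    },
    "sigma_gAx": {
        "low": ((0.0, 0.0), (0.02, 1.0), (0.2, 1.0), (0.23, 0.0)),
        "high": ((0.2, 0.0), (0.3, 1.0), (1.0, 1.0)),
    },
}

_SET1_RULES = [
    ({"theta_A": "low", "theta_B": "low", "omega_BRx": "low"}, "stand"),
    ({"theta_A": "low", "theta_B": "high", "omega_BRx": "low"}, "sit"),
    ({"theta_A": "high", "theta_B": "high", "omega_BRx": "low"}, "lie"),
    ({"omega_BRx": "high", "g_BRx": "low", "sigma_gBx": "low"}, "walk"),
    ({"omega_BRx": "high", "g_BRx": "high", "sigma_gBx": "high"}, "run"),
]

_SET2_RULES = [
    ({"theta_A": "low", "theta_B": "low", "gamma_wAx": "low", "gamma_gBx": "low"}, "stand"),
    ({"theta_A": "low", "theta_B": "high", "gamma_wAx": "low", "gamma_gBx": "low"}, "sit"),
    ({"theta_A": "high", "theta_B": "high", "gamma_wAx": "low", "gamma_gBx": "low"}, "lie"),
    ({"gamma_wAx": "high", "gamma_gBx": "medium", "sigma_gAx": "low"}, "walk"),
    ({"gamma_wAx": "high", "gamma_gBx": "high", "sigma_gAx": "high"}, "run"),
]


def _build(set_id: int, names, mfs, rules) -> MamdaniModel:
    variables = {
        name: {label: PiecewiseLinearMF(label, bps) for label, bps in labels.items()}
        for name, labels in mfs.items()
    }
    outputs = {
        act: TriangularOutputMF(act, OUTPUT_PEAKS[act]) for act in ACTIVITIES
    }
    return MamdaniModel(
        feature_set_id=set_id,
        feature_names=tuple(names),
        variables=variables,
        output_mfs=outputs,
        rules=[FuzzyRule(ant, cons) for ant, cons in rules],
    )


def build_set1() -> MamdaniModel:
    """The SET-1 model: {θ_A, θ_B, ω_BRx, g_BRx, σ_gBx} → activity."""
    return _build(1, _SET1_MFS.keys(), _SET1_MFS, _SET1_RULES)


def build_set2() -> MamdaniModel:
    """The SET-2 model: {θ_A, θ_B, γ_ωAx, γ_gBx, σ_gAx} → activity."""
    return _build(2, _SET2_MFS.keys(), _SET2_MFS, _SET2_RULES)


def _as_mapping(model: MamdaniModel, x) -> dict[str, float]:
    if isinstance(x, Mapping):
        missing = set(model.feature_names) - set(x)
        if missing:
            raise ValueError(f"input missing features {sorted(missing)}")
        return {k: float(x[k]) for k in model.feature_names}
    arr = np.asarray(x, dtype=float).ravel()
    if arr.shape != (len(model.feature_names),):
        raise ValueError(
            f"expected {len(model.feature_names)} features "
            f"({', '.join(model.feature_names)}), got shape {arr.shape}"
        )
    return dict(zip(model.feature_names, arr))


def variable_domain(model: MamdaniModel, name: str) -> tuple[float, float]:
    """Overall domain of a linguistic variable (union of its MF supports)."""
    los = [mf.breakpoints[0][0] for mf in model.variables[name].values()]
    his = [mf.breakpoints[-1][0] for mf in model.variables[name].values()]
    return min(los), max(his)


def fire(model: MamdaniModel, x) -> np.ndarray:
    """Firing strength of every rule: min of antecedent memberships.

    ``x`` is a mapping feature-name → value or an array in the model's
    feature order.  Inputs are saturated to each variable's domain before
    fuzzification (a value beyond the top plateau still counts as fully
    "high", a tilt a shade over 90° as fully tilted).  Don't-care
    antecedents are skipped in the min.
    """
    xm = _as_mapping(model, x)
    for name in xm:
        lo, hi = variable_domain(model, name)
        xm[name] = float(np.clip(xm[name], lo, hi))
    strengths = np.empty(len(model.rules))
    for r, rule in enumerate(model.rules):
        strengths[r] = min(
            model.variables[name][label](xm[name])
            for name, label in rule.antecedent.items()
        )
    return strengths


def _clipped_trapezoid(mf: TriangularOutputMF, w: float):
    """Vertices of the output triangle clipped at strength w (a trapezoid)."""
    p, h = mf.peak, mf.half_width
    return [(p - h, 0.0), (p - h + w * h, w), (p + h - w * h, w), (p + h, 0.0)]


def _aggregate_eval(traps, x: float) -> float:
    best = 0.0
    for verts in traps:
        xs = [v[0] for v in verts]
        ys = [v[1] for v in verts]
        if xs[0] <= x <= xs[-1]:
            best = max(best, float(np.interp(x, xs, ys)))
    return best


def _segment_intersections(traps) -> list[float]:
    segs = []
    for verts in traps:
        for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
            if x1 > x0:
                segs.append((x0, y0, x1, y1))
    pts: list[float] = []
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            ax0, ay0, ax1, ay1 = segs[i]
            bx0, by0, bx1, by1 = segs[j]
            lo, hi = max(ax0, bx0), min(ax1, bx1)
            if lo >= hi:
                continue
            sa = (ay1 - ay0) / (ax1 - ax0)
            sb = (by1 - by0) / (bx1 - bx0)
            if sa == sb:
                continue
            # ay0 + sa (x - ax0) = by0 + sb (x - bx0)
            x = (by0 - ay0 + sa * ax0 - sb * bx0) / (sa - sb)
            if lo < x < hi:
                pts.append(x)
    return pts


def aggregate_centroid(
    clip_levels: Mapping[str, float], output_mfs: Mapping[str, TriangularOutputMF]
) -> float | None:
    """Centroid abscissa of the max-aggregated clipped output triangles.

    Computed analytically: the aggregate is piecewise linear, so its two
    moments are integrated exactly over each linear piece.  Returns None
    when no triangle is clipped above 0.
    """
    traps = [
        _clipped_trapezoid(output_mfs[act], w)
        for act, w in clip_levels.items()
        if w > 0.0
    ]
    if not traps:
        return None
    xs = sorted(
        {v[0] for verts in traps for v in verts} | set(_segment_intersections(traps))
    )
    area = 0.0
    moment = 0.0
    for x0, x1 in zip(xs[:-1], xs[1:]):
        h = x1 - x0
        if h <= 0:
            continue
        # the aggregate is linear inside the subinterval; sample it at two
        # interior points (endpoints can be degenerate collapsed vertices)
        xa, xb = x0 + 0.25 * h, x1 - 0.25 * h
        fa = _aggregate_eval(traps, xa)
        fb = _aggregate_eval(traps, xb)
        fmid = 0.5 * (fa + fb)
        slope = (fb - fa) / (xb - xa)
        mid = 0.5 * (x0 + x1)
        area += fmid * h
        moment += fmid * mid * h + slope * h**3 / 12.0
    if area <= 0.0:
        return None
    return moment / area


def infer(model: MamdaniModel, x) -> float | None:
    """Crisp motor-index output (centroid defuzzification), or None.

    None is the distinguished "unrecognized" result: no rule fired above 0.
    """
    strengths = fire(model, x)
    clip: dict[str, float] = {}
    for rule, w in zip(model.rules, strengths):
        clip[rule.consequent] = max(clip.get(rule.consequent, 0.0), float(w))
    return aggregate_centroid(clip, model.output_mfs)


def classify(crisp: float | None) -> str:
    """Map a crisp motor index to the activity with the nearest output peak.

    The published per-class index ranges overlap, so classification is by
    nearest peak; ties break toward the lower peak.  None → "unrecognized".
    """
    if crisp is None or not np.isfinite(crisp):
        return UNRECOGNIZED
    best = UNRECOGNIZED
    best_d = np.inf
    for act in ACTIVITIES:
        d = abs(crisp - OUTPUT_PEAKS[act])
        if d < best_d - 1e-12:
            best, best_d = act, d
    return best


def infer_batch(model: MamdaniModel, X: np.ndarray) -> list[str]:
    """Classify each row of an (n, 5) feature matrix."""
    return [classify(infer(model, row)) for row in np.atleast_2d(X)]


# --- serialization ---------------------------------------------------------

def to_json(model: MamdaniModel) -> str:
    """Human-readable structured-text form of the model."""
    doc = {
        "feature_set_id": model.feature_set_id,
        "feature_names": list(model.feature_names),
        "variables": {
            name: {label: list(map(list, mf.breakpoints)) for label, mf in labels.items()}
            for name, labels in model.variables.items()
        },
        "output_mfs": {
            act: {"peak": mf.peak, "half_width": mf.half_width}
            for act, mf in model.output_mfs.items()
        },
        "rules": [
            {"if": dict(r.antecedent), "then": r.consequent} for r in model.rules
        ],
    }
    return json.dumps(doc, indent=2)


def from_json(text: str) -> MamdaniModel:
    doc = json.loads(text)
    variables = {
        name: {
            label: PiecewiseLinearMF(label, tuple(map(tuple, bps)))
            for label, bps in labels.items()
        }
        for name, labels in doc["variables"].items()
    }
    outputs = {
        act: TriangularOutputMF(act, d["peak"], d["half_width"])
        for act, d in doc["output_mfs"].items()
    }
    return MamdaniModel(
        feature_set_id=doc["feature_set_id"],
        feature_names=tuple(doc["feature_names"]),
        variables=variables,
        output_mfs=outputs,
        rules=[FuzzyRule(r["if"], r["then"]) for r in doc["rules"]],
    )


def save(model: MamdaniModel, path: str | Path) -> None:
    Path(path).write_text(to_json(model))


def load(path: str | Path) -> MamdaniModel:
    return from_json(Path(path).read_text())
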