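"""Diagnostic for the published trained walk/run Sugeno parameters.

The published trained system lists 9 Gaussian antecedents and 27 constant
consequents, but not the convention mapping consequent index to rule
(combination of per-input MFs).  This module rebuilds the trained system
under several candidate orderings and evaluates the two published probe
inputs — (0.4235, 0.3412, 0.7224) and (0.9595, 1.3726, 1.3168), reported
to return 1.61 (walk) and 3.31 (run) — so the ambiguity can be inspected.
It is a diagnostic, not part of recognition.
"""

from __future__ import annotations

import itertools

import numpy as np

from motionfis.anfis import GaussianMF, N_RULES, SugenoModel, classify_index, forward

# Trained antecedents: per input, three (sigma, mu) pairs.
TRAINED_MFS = [
    [(0.1941, -0.0506), (0.1736, 1.0145), (0.4448, 1.9665)],
    [(0.2840, -0.0230), (0.2951, 0.9999), (0.3830, 1.9823)],
    [(0.4087, 0.0492), (0.2451, 1.0645), (0.3420, 1.9982)],
]

# Trained consequents mf1..mf27, in published index order.
TRAINED_CONSEQUENTS = np.array([
    1.6017, 1.0093, 171.5, 2.1715, 2.8963, -242.3, 4.5227, 3.4755, 3.5141,
    -38.4, 187.5, 11.7, 3.1452, 3.6483, -0.9198, -1.855, 0.9098, 3.6164,
    3.3686, 4.1074, 2.7958, -10.763, 28.7, 3.7789, 2.1909, 15.8998, -28.038,
])

# The blind-test probe inputs and the outputs reported for them.
PROBE_INPUTS = np.array([
    [0.4235, 0.3412, 0.7224],
    [0.9595, 1.3726, 1.3168],
])
REPORTED_OUTPUTS = (1.61, 3.31)


def _permuted_consequents(axis_order: tuple[int, int, int]) -> np.ndarray:
    """Reindex the published consequents assuming they enumerate the rule
    grid with ``axis_order`` from most to least significant input."""
    grid = TRAINED_CONSEQUENTS.reshape(3, 3, 3)
    # rule r (our convention) has MF indices (i, j, k); under the candidate
    # ordering the published list index is the lexicographic rank of the
    # indices arranged in axis_order.
    out = np.empty(N_RULES)
    for r, (i, j, k) in enumerate(itertools.product(range(3), repeat=3)):
        idx = (i, j, k)
        pub = (idx[axis_order[0]], idx[axis_order[1]], idx[axis_order[2]])
        out[r] = grid[pub]
    return out


def evaluate_orderings() -> dict[str, dict]:
    """Evaluate the probe inputs under every input-significance ordering.

    Returns, per ordering tag, the two crisp outputs, their bands, and the
    absolute errors against the reported values.
    """
    mfs = [[GaussianMF(s, m) for s, m in row] for row in TRAINED_MFS]
    results: dict[str, dict] = {}
    for order in itertools.permutations(range(3)):
        tag = "order_" + "".join(str(o + 1) for o in order)
        model = SugenoModel(
            mfs=[[GaussianMF(m.sigma, m.mu) for m in row] for row in mfs],
            consequents=_permuted_consequents(order),
            rule_order=tag,
        )
        outs = [forward(model, x) for x in PROBE_INPUTS]
        results[tag] = {
            "outputs": outs,
            "bands": [classify_index(v).band for v in outs],
            "abs_error_vs_reported": [
                abs(o - r) for o, r in zip(outs, REPORTED_OUTPUTS)
            ],
        }
    return results


def format_report(results: dict[str, dict] | None = None) -> str:
    """Plain-text table of the ordering diagnostic."""
    results = results if results is not None else evaluate_orderings()
    lines = [
        "Trained-parameter ordering diagnostic",
        f"probe inputs: {PROBE_INPUTS.tolist()}",
        f"reported outputs: {REPORTED_OUTPUTS}",
        "",
        f"{'ordering':<12} {'out1':>10} {'out2':>10} {'band1':>12} {'band2':>12} {'|err1|':>8} {'|err2|':>8}",
    ]
    for tag, r in sorted(results.items()):
        o1, o2 = r["outputs"]
        b1, b2 = r["bands"]
        e1, e2 = r["abs_error_vs_reported"]
        lines.append(
            f"{tag:<12} {o1:>10.4f} {o2:>10.4f} {b1:>12} {b2:>12} {e1:>8.3f} {e2:>8.3f}"
        )
    lines.append("")
    lines.append(
        "No ordering is asserted correct; the published consequent-to-rule "
        "mapping is ambiguous and this table only documents the candidates."
    )
    return "\n".join(lines)
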