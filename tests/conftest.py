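"""Shared fixtures and independent metric oracles.

The oracles here deliberately avoid the package's own sweep/integration
code paths: the ROC oracle counts concordant positive-negative pairs
directly, and the PR oracle rebuilds the threshold sweep by brute force
and integrates the interpolated precision numerically on a fine recall
grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from donorpred.sequence_io import SpliceWindow, WindowGeometry
from donorpred.synthetic import GeneratorConfig, generate


def mann_whitney_auc(scores, labels) -> float:
    """Fraction of (positive, negative) pairs ranked concordantly, ties 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def davis_goadrich_auc_grid(scores, labels, recall_step: float = 1e-4) -> float:
    """Numerically integrated interpolated PR area.

    Rebuilds the achievable (tp, fp) points by scanning every distinct
    threshold with explicit counting, then integrates precision over a
    fine recall grid with linear-in-TP false-positive interpolation.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    P = int(y.sum())
    assert P > 0
    pts = [(0.0, 0.0)]
    for t in sorted(set(s), reverse=True):
        keep = s >= t
        pts.append((float((y & keep).sum()), float((~y & keep).sum())))
    area = 0.0
    for (tp_a, fp_a), (tp_b, fp_b) in zip(pts, pts[1:]):
        if tp_b == tp_a:
            continue
        slope = (fp_b - fp_a) / (tp_b - tp_a)
        n_steps = max(2, int(np.ceil((tp_b - tp_a) / (recall_step * P))))
        xs = np.linspace(tp_a, tp_b, n_steps + 1)
        fps = fp_a + slope * (xs - tp_a)
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = xs / (xs + fps)
        if xs[0] == 0.0:  # limit at recall 0: constant segment precision
            prec[0] = 1.0 / (1.0 + slope)
        area += np.trapezoid(prec, xs / P)
    return float(area)


def random_scored_instance(rng: np.random.Generator, n_max: int = 200):
    """A random (scores, labels) instance with both classes present."""
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=bool)
    labels[: int(rng.integers(1, n))] = True
    rng.shuffle(labels)
    scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n) if rng.random() < 0.3 \
        else rng.random(n)
    return scores, labels


@pytest.fixture(scope="session")
def strong_signal_windows() -> list[SpliceWindow]:
    """400 true + 400 false windows with high conservation (clear signal)."""
    return generate(GeneratorConfig(n_true=400, n_false=400, conservation=0.9, seed=11))


@pytest.fixture(scope="session")
def default_geometry() -> WindowGeometry:
    return WindowGeometry(15, 9)
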