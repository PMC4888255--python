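"""Numeric encoding of splice-site windows.

Each window is mapped to a feature vector drawn from three families:

* **Positional** (f1--f4): log-probability of the window under the
  true-site per-position frequency matrix (f1, the weight-matrix-model
  score), its contrast against the false-site matrix (f2), and a min--max
  normalized sum of the observed per-position frequencies (f3, the
  Shapiro--Senapathy family) plus its true-vs-false contrast (f4).
* **Dependency** (f5--f8): the same pattern built on pairwise conditional
  frequencies over all L(L-1) ordered position pairs -- f5 is the
  weight-array-model style log score, f7 the sum-of-absolute-error style
  score 2L(L-1) - 2*sum(q), with f6/f8 the true-vs-false contrasts.
* **Compositional** (k-mer blocks): the fraction of overlapping k-length
  substrings equal to each k-mer, for k = 2, 3, 4 -- 16 + 64 + 256 = 336
  values, giving 344 features in total with the eight scores above.

The reduced 49-feature set (``TABLE1_49``) is the frozen result of
F-score filtering at threshold 1.25 on the human benchmark data: all
eight positional/dependency scores plus 14 di-, 15 tri- and 12
tetra-nucleotide compositions.  It ships as the default manifest so
predictions are reproducible without re-running selection.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .frequency_models import (
    NUCLEOTIDES,
    DependencyFrequencyModel,
    PositionalFrequencyModel,
    encode_sequences,
)
from .sequence_io import SpliceWindow

SCORE_FEATURES = ("f1", "f2", "f3", "f4", "f5", "f6", "f7", "f8")

_KMER_PREFIX = {2: "di", 3: "tri", 4: "tet"}


def kmer_feature_names(k: int) -> list[str]:
    """All 4**k k-mer feature names in lexicographic A<C<G<T order."""
    prefix = _KMER_PREFIX[k]
    return [prefix + "_" + "".join(t) for t in itertools.product(NUCLEOTIDES, repeat=k)]


@dataclass(frozen=True)
class FeatureSetManifest:
    """An ordered, named feature list identifying one encoding layout."""

    id: str
    names: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"manifest '{self.id}' contains duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    def to_text(self) -> str:
        lines = [f"# feature set {self.id}: {self.provenance}"]
        lines.extend(self.names)
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str, id: str = "custom") -> "FeatureSetManifest":
        lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
        provenance = ""
        if lines and lines[0].startswith("#"):
            provenance = lines[0].lstrip("# ")
            lines = lines[1:]
        return cls(id=id, names=tuple(lines), provenance=provenance)


FULL344 = FeatureSetManifest(
    id="full344",
    names=tuple(SCORE_FEATURES)
    + tuple(kmer_feature_names(2))
    + tuple(kmer_feature_names(3))
    + tuple(kmer_feature_names(4)),
    provenance="all 4 positional + 4 dependency + 336 compositional features",
)

# The frozen reduced feature set: survivors of F-score filtering at
# threshold 1.25 on the human benchmark windows.  14 dimers, 15 trimers,
# 12 tetramers plus all eight probabilistic scores.
_TABLE1_DI = ("AA", "AC", "AG", "CA", "CC", "CT", "GA",
              "GC", "GG", "GT", "TA", "TC", "TG", "TT")
_TABLE1_TRI = ("AAG", "AGG", "AGT", "CAG", "GAG", "GGG", "GGT", "GTA",
               "GTC", "GTG", "TAA", "TGA", "TGC", "TGG", "TGT")
_TABLE1_TET = ("AAGG", "AGGT", "CAGG", "GAGG", "GGGT", "GGTA",
               "GGTG", "GTAA", "GTGA", "GTGG", "TAAG", "TGAG")

TABLE1_49 = FeatureSetManifest(
    id="table1_49",
    names=tuple(SCORE_FEATURES)
    + tuple("di_" + m for m in _TABLE1_DI)
    + tuple("tri_" + m for m in _TABLE1_TRI)
    + tuple("tet_" + m for m in _TABLE1_TET),
    provenance="49 features retained at F-score >= 1.25 on human benchmark data",
)

MANIFESTS: dict[str, FeatureSetManifest] = {m.id: m for m in (FULL344, TABLE1_49)}


class DegenerateModelError(ValueError):
    """A frequency model cannot support the requested score (M == N)."""


def _check_lengths(L: int, *models) -> None:
    for m in models:
        if m.L != L:
            raise ValueError(
                f"model fitted at L={m.L} applied to windows of length {L}"
            )


def _positional_block(
    X: np.ndarray,
    true_model: PositionalFrequencyModel,
    false_model: PositionalFrequencyModel,
) -> np.ndarray:
    """(n, 4) array of f1..f4 for integer-encoded windows X."""
    n, L = X.shape
    _check_lengths(L, true_model, false_model)
    cols = np.arange(L)
    out = np.empty((n, 4))
    sums = {}
    for tag, model in (("t", true_model), ("f", false_model)):
        if model.M - model.N <= 0:
            raise DegenerateModelError(
                f"positional model '{model.class_tag}': M == N, "
                "min-max normalized score undefined"
            )
        probs = model.p[cols, X]  # (n, L)
        if np.any(probs <= 0):
            raise ValueError(
                f"zero frequency in positional model '{model.class_tag}'; "
                "log-score undefined -- estimate with a positive pseudocount"
            )
        sums[tag + "_log"] = np.log2(probs).sum(axis=1)
        sums[tag + "_ss"] = 100.0 * (probs.sum(axis=1) - model.M) / (model.M - model.N)
    out[:, 0] = sums["t_log"]
    out[:, 1] = sums["t_log"] - sums["f_log"]
    out[:, 2] = sums["t_ss"]
    out[:, 3] = sums["t_ss"] - sums["f_ss"]
    return out


def _dependency_block(
    X: np.ndarray,
    true_dep: DependencyFrequencyModel,
    false_dep: DependencyFrequencyModel,
) -> np.ndarray:
    """(n, 4) array of f5..f8 for integer-encoded windows X."""
    n, L = X.shape
    _check_lengths(L, true_dep, false_dep)
    ii, jj = np.where(~np.eye(L, dtype=bool))  # all L(L-1) ordered pairs
    two_LL1 = 2.0 * L * (L - 1)
    out = np.empty((n, 4))
    sums = {}
    for tag, model in (("t", true_dep), ("f", false_dep)):
        vals = model.q[ii[None, :], jj[None, :], X[:, ii], X[:, jj]]  # (n, P)
        if np.any(vals <= 0):
            raise ValueError(
                f"zero frequency in dependency model '{model.class_tag}'; "
                "log-score undefined -- estimate with a positive pseudocount"
            )
        sums[tag + "_log"] = np.log2(vals).sum(axis=1)
        sums[tag + "_q"] = vals.sum(axis=1)
    out[:, 0] = sums["t_log"]
    out[:, 1] = sums["t_log"] - sums["f_log"]
    out[:, 2] = two_LL1 - 2.0 * sums["t_q"]
    out[:, 3] = 2.0 * sums["f_q"] - 2.0 * sums["t_q"]
    return out


def _composition_block(X: np.ndarray, k: int) -> np.ndarray:
    """(n, 4**k) overlapping k-mer fractions, lexicographic order."""
    n, L = X.shape
    if L < k:
        raise ValueError(f"window length {L} < k={k}")
    n_windows = L - k + 1
    ids = np.zeros((n, n_windows), dtype=np.int64)
    for t in range(k):
        ids = ids * 4 + X[:, t : t + n_windows]
    flat = (np.arange(n)[:, None] * 4**k + ids).ravel()
    counts = np.bincount(flat, minlength=n * 4**k).reshape(n, 4**k)
    return counts / n_windows


def positional_features(
    w: SpliceWindow,
    true_model: PositionalFrequencyModel,
    false_model: PositionalFrequencyModel,
) -> dict[str, float]:
    """f1..f4 for a single window."""
    X = encode_sequences([w])
    vals = _positional_block(X, true_model, false_model)[0]
    return dict(zip(("f1", "f2", "f3", "f4"), map(float, vals)))


def dependency_features(
    w: SpliceWindow,
    true_dep: DependencyFrequencyModel,
    false_dep: DependencyFrequencyModel,
) -> dict[str, float]:
    """f5..f8 for a single window."""
    X = encode_sequences([w])
    vals = _dependency_block(X, true_dep, false_dep)[0]
    return dict(zip(("f5", "f6", "f7", "f8"), map(float, vals)))


def compositional_features(w: SpliceWindow, k: int) -> dict[str, float]:
    """Overlapping k-mer composition (k in {2, 3, 4}) of a single window."""
    if k not in _KMER_PREFIX:
        raise ValueError(f"k must be 2, 3 or 4, got {k}")
    X = encode_sequences([w])
    vals = _composition_block(X, k)[0]
    return dict(zip(kmer_feature_names(k), map(float, vals)))


@dataclass
class FrequencyModelBundle:
    """The four class-conditional models every full encoding needs."""

    true_positional: PositionalFrequencyModel
    false_positional: PositionalFrequencyModel
    true_dependency: DependencyFrequencyModel
    false_dependency: DependencyFrequencyModel

    @property
    def L(self) -> int:
        return self.true_positional.L


def encode(
    windows: SpliceWindow | Sequence[SpliceWindow],
    models: FrequencyModelBundle,
    manifest: FeatureSetManifest = TABLE1_49,
) -> pd.DataFrame:
    """Encode one or many windows into a feature matrix.

    Returns a DataFrame with one row per window and columns exactly in
    manifest order.  Unknown feature names in the manifest raise.
    """
    if isinstance(windows, SpliceWindow):
        windows = [windows]
    unknown = set(manifest.names) - set(FULL344.names)
    if unknown:
        raise ValueError(
            f"manifest '{manifest.id}' references unknown features: {sorted(unknown)}"
        )
    X = encode_sequences(windows)
    blocks = [
        _positional_block(X, models.true_positional, models.false_positional),
        _dependency_block(X, models.true_dependency, models.false_dependency),
    ]
    needed_ks = {
        k for k, pre in _KMER_PREFIX.items()
        if any(name.startswith(pre + "_") for name in manifest.names)
    }
    for k in (2, 3, 4):
        if k in needed_ks:
            blocks.append(_composition_block(X, k))
    computed = pd.DataFrame(
        np.hstack(blocks),
        columns=list(SCORE_FEATURES)
        + [name for k in (2, 3, 4) if k in needed_ks for name in kmer_feature_names(k)],
    )
    out = computed[list(manifest.names)].copy()
    out.index = pd.Index([w.source_id or str(i) for i, w in enumerate(windows)], name="window")
    return out
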