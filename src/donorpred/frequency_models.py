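"""Per-position and pairwise conditional nucleotide frequency models.

Two probabilistic summaries of a labelled window collection drive the
positional and dependency scores:

* :class:`PositionalFrequencyModel` -- p(alpha at i), the per-position
  nucleotide frequency matrix, plus the extremal column sums M (sum of
  per-position maxima) and N (sum of per-position minima) used by the
  min--max normalized positional score.
* :class:`DependencyFrequencyModel` -- q(alpha at i | beta at j), the
  conditional frequency of each nucleotide at position i given the
  nucleotide observed at every other position j, over all L(L-1) ordered
  position pairs.

Both are estimated with an additive pseudocount (Laplace smoothing by
default) so the log-scores built on top of them stay finite; with
pseudocount 0 the estimates are the raw empirical frequencies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sequence_io import SpliceWindow

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


def encode_sequences(windows: Sequence[SpliceWindow]) -> np.ndarray:
    """Windows -> integer matrix (n, L) with A,C,G,T -> 0..3.

    Raises on empty input or mixed lengths.
    """
    if not windows:
        raise ValueError("at least one window is required")
    lengths = {len(w.sequence) for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"mixed window lengths {sorted(lengths)}")
    L = lengths.pop()
    X = np.empty((len(windows), L), dtype=np.int8)
    for r, w in enumerate(windows):
        for c, ch in enumerate(w.sequence):
            try:
                X[r, c] = _NT_INDEX[ch]
            except KeyError:
                raise ValueError(
                    f"window '{w.source_id}': invalid character {ch!r}"
                ) from None
    return X


@dataclass
class PositionalFrequencyModel:
    """Smoothed per-position nucleotide frequencies for one class."""

    class_tag: str
    p: np.ndarray  # (L, 4), rows sum to 1
    pseudocount: float
    n_train: int

    @property
    def L(self) -> int:
        return self.p.shape[0]

    @property
    def M(self) -> float:
        """Sum over positions of the highest per-position frequency."""
        return float(self.p.max(axis=1).sum())

    @property
    def N(self) -> float:
        """Sum over positions of the lowest per-position frequency."""
        return float(self.p.min(axis=1).sum())

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# positional\tclass={self.class_tag}\tL={self.L}\t"
            f"pseudocount={self.pseudocount!r}\tn_train={self.n_train}\n"
        )
        buf.write("position\t" + "\t".join(NUCLEOTIDES) + "\n")
        for i in range(self.L):
            row = "\t".join(repr(float(v)) for v in self.p[i])
            buf.write(f"{i + 1}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "PositionalFrequencyModel":
        lines = text.strip().splitlines()
        meta = _parse_header(lines[0], "positional")
        L = int(meta["L"])
        p = np.array(
            [[float(v) for v in line.split("\t")[1:]] for line in lines[2 : 2 + L]]
        )
        return cls(
            class_tag=meta["class"],
            p=p,
            pseudocount=float(meta["pseudocount"]),
            n_train=int(meta["n_train"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "PositionalFrequencyModel":
        return cls.from_text(Path(path).read_text())


@dataclass
class DependencyFrequencyModel:
    """Smoothed pairwise conditional frequencies for one class.

    ``q[i, j, a, b]`` is the frequency of nucleotide ``a`` at position ``i``
    given nucleotide ``b`` at position ``j`` (i != j; the diagonal is
    filled with 1 and never consulted).  Conditioning cells with zero
    support at pseudocount 0 fall back to the uniform 1/4 distribution.
    """

    class_tag: str
    q: np.ndarray  # (L, L, 4, 4)
    pseudocount: float
    n_train: int

    @property
    def L(self) -> int:
        return self.q.shape[0]

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(
            f"# dependency\tclass={self.class_tag}\tL={self.L}\t"
            f"pseudocount={self.pseudocount!r}\tn_train={self.n_train}\n"
        )
        buf.write("i\tj\tgiven\t" + "\t".join(NUCLEOTIDES) + "\n")
        L = self.L
        for i in range(L):
            for j in range(L):
                if i == j:
                    continue
                for b in range(4):
                    row = "\t".join(repr(float(v)) for v in self.q[i, j, :, b])
                    buf.write(f"{i + 1}\t{j + 1}\t{NUCLEOTIDES[b]}\t{row}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "DependencyFrequencyModel":
        lines = text.strip().splitlines()
        meta = _parse_header(lines[0], "dependency")
        L = int(meta["L"])
        q = np.ones((L, L, 4, 4))
        for line in lines[2:]:
            parts = line.split("\t")
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            b = _NT_INDEX[parts[2]]
            q[i, j, :, b] = [float(v) for v in parts[3:]]
        return cls(
            class_tag=meta["class"],
            q=q,
            pseudocount=float(meta["pseudocount"]),
            n_train=int(meta["n_train"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path: str | Path) -> "DependencyFrequencyModel":
        return cls.from_text(Path(path).read_text())


def _parse_header(line: str, expected_kind: str) -> dict:
    if not line.startswith(f"# {expected_kind}"):
        raise ValueError(f"expected a {expected_kind} model header, got: {line!r}")
    meta = {}
    for field in line.split("\t")[1:]:
        key, _, value = field.partition("=")
        meta[key] = value
    return meta


def estimate_positional(
    windows: Sequence[SpliceWindow],
    pseudocount: float = 1.0,
    class_tag: Optional[str] = None,
) -> PositionalFrequencyModel:
    """Estimate p(alpha at i) = (count + pc) / (n + 4*pc) from one class."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    X = encode_sequences(windows)
    n, L = X.shape
    counts = np.zeros((L, 4))
    for i in range(L):
        counts[i] = np.bincount(X[:, i], minlength=4)
    p = (counts + pseudocount) / (n + 4 * pseudocount)
    tag = class_tag if class_tag is not None else _infer_tag(windows)
    return PositionalFrequencyModel(class_tag=tag, p=p, pseudocount=pseudocount, n_train=n)


def estimate_dependency(
    windows: Sequence[SpliceWindow],
    pseudocount: float = 1.0,
    class_tag: Optional[str] = None,
) -> DependencyFrequencyModel:
    """Estimate q(alpha at i | beta at j) over all ordered pairs i != j.

    q = (count(alpha at i AND beta at j) + pc) / (count(beta at j) + 4*pc).
    At pseudocount 0, a conditioning nucleotide never seen at j yields the
    uniform 1/4 distribution (maximum-entropy fallback).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    X = encode_sequences(windows)
    n, L = X.shape
    onehot = np.zeros((n, L, 4))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], X] = 1.0
    # pair[i, j, a, b] = number of windows with a at i and b at j
    pair = np.einsum("nia,njb->ijab", onehot, onehot)
    col = onehot.sum(axis=0)  # (L, 4) marginal counts

    denom = col[None, :, None, :] + 4 * pseudocount  # (1, j, 1, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (pair + pseudocount) / denom
    # zero conditioning support at pseudocount 0 -> uniform
    zero_support = np.broadcast_to(denom == 0, q.shape)
    q = np.where(zero_support, 0.25, q)
    idx = np.arange(L)
    q[idx, idx] = 1.0  # diagonal unused; keep logs finite if ever touched
    tag = class_tag if class_tag is not None else _infer_tag(windows)
    return DependencyFrequencyModel(class_tag=tag, q=q, pseudocount=pseudocount, n_train=n)


def _infer_tag(windows: Sequence[SpliceWindow]) -> str:
    labels = {w.label for w in windows}
    if len(labels) == 1 and (tag := labels.pop()) is not None:
        return tag
    return "unlabelled"
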