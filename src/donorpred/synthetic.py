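"""Synthetic donor splice-site benchmarks with controllable signal.

True sites are drawn position-independently from a position weight matrix
built around a consensus window: at each non-GT position the consensus
nucleotide receives probability mass ``conservation`` and the remaining
mass is split over the other nucleotides in proportion to the background
distribution.  False sites are pure background.  Both classes carry the
conserved GT, so the only discriminative signal is the partial
conservation around the junction -- the situation real donor-site
classifiers face.  At ``conservation = 0.25`` with a uniform background
the two classes are distributionally identical (the null case); at 1.0
every true site equals the consensus.

An optional dependent-pair mode plants a correlated pair of positions in
the true class so that pairwise-dependency scores carry signal beyond
what the per-position matrix explains.

The default consensus ``AAGCCCAGGTAAGTA`` embeds the canonical donor
context (exon ...CAG | GTAAGT intron...) at the default (15, 9) geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .frequency_models import NUCLEOTIDES, _NT_INDEX
from .sequence_io import (
    DEFAULT_GEOMETRY,
    LABEL_FALSE,
    LABEL_TRUE,
    SpliceWindow,
    WindowGeometry,
    write_windows_fasta,
)

DEFAULT_CONSENSUS_15_9 = "AAGCCCAGGTAAGTA"


def default_consensus(geometry: WindowGeometry) -> str:
    """A canonical-donor-like consensus for an arbitrary geometry."""
    if (geometry.window_length, geometry.gt_offset) == (15, 9):
        return DEFAULT_CONSENSUS_15_9
    core = "CAG"  # exon tail
    intron = "AAGT"  # intron start after GT
    up = ("A" * geometry.upstream + core)[-geometry.upstream:] if geometry.upstream else ""
    down = (intron + "A" * geometry.downstream)[: geometry.downstream]
    return up + "GT" + down


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic benchmark generator."""

    geometry: WindowGeometry = DEFAULT_GEOMETRY
    n_true: int = 1000
    n_false: int = 1000
    conservation: float = 0.85
    consensus: Optional[str] = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    dependent_pair: Optional[tuple[int, int]] = None  # 1-based positions, true class
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.25 <= self.conservation <= 1.0):
            raise ValueError(
                f"conservation must lie in [0.25, 1], got {self.conservation}"
            )
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or bg.min() < 0 or abs(bg.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 non-negative values summing to 1")
        consensus = self.consensus or default_consensus(self.geometry)
        SpliceWindow(sequence=consensus, source_id="consensus").validate(self.geometry)
        self.consensus = consensus


def _true_pwm(config: GeneratorConfig) -> np.ndarray:
    """(L, 4) sampling matrix for the true class."""
    L = config.geometry.window_length
    bg = np.asarray(config.background, dtype=float)
    pwm = np.empty((L, 4))
    for i, ch in enumerate(config.consensus):
        c = _NT_INDEX[ch]
        others = bg.copy()
        others[c] = 0.0
        total = others.sum()
        if total > 0:
            others *= (1.0 - config.conservation) / total
        row = others
        row[c] = config.conservation
        pwm[i] = row
    g, t = config.geometry.gt_offset - 1, config.geometry.gt_offset
    pwm[g] = [0.0, 0.0, 1.0, 0.0]
    pwm[t] = [0.0, 0.0, 0.0, 1.0]
    return pwm


def generate(config: GeneratorConfig) -> list[SpliceWindow]:
    """Draw ``n_true`` true and ``n_false`` false windows, labelled.

    Deterministic given ``config.seed``.  True windows precede false
    windows in the returned list; class counts are exact.
    """
    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    L = geom.window_length
    g, t = geom.gt_offset - 1, geom.gt_offset

    def draw(n: int, pwm: np.ndarray) -> np.ndarray:
        cum = np.cumsum(pwm, axis=1)
        u = rng.random((n, L))
        return (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)

    true_pwm = _true_pwm(config)
    X_true = draw(config.n_true, true_pwm)
    if config.dependent_pair is not None:
        i, j = (p - 1 for p in config.dependent_pair)
        if i in (g, t) or j in (g, t) or i == j:
            raise ValueError("dependent_pair must name two distinct non-GT positions")
        # plant a deterministic copy: position i mirrors position j in the
        # true class, creating pure pairwise signal invisible to the
        # per-position matrix when j is drawn from a symmetric background
        X_true[:, i] = X_true[:, j]

    bg = np.asarray(config.background, dtype=float)
    bg_pwm = np.tile(bg, (L, 1))
    bg_pwm[g] = [0.0, 0.0, 1.0, 0.0]
    bg_pwm[t] = [0.0, 0.0, 0.0, 1.0]
    X_false = draw(config.n_false, bg_pwm)

    windows = []
    for r in range(config.n_true):
        seq = "".join(NUCLEOTIDES[c] for c in X_true[r])
        windows.append(SpliceWindow(sequence=seq, label=LABEL_TRUE, source_id=f"syn_t{r + 1}"))
    for r in range(config.n_false):
        seq = "".join(NUCLEOTIDES[c] for c in X_false[r])
        windows.append(SpliceWindow(sequence=seq, label=LABEL_FALSE, source_id=f"syn_f{r + 1}"))
    return windows


def generate_eval_suite(
    out_dir: str | Path,
    ratios: Sequence[tuple[int, int]] = ((1, 1), (1, 5), (1, 19)),
    n_true: int = 500,
    geometry: WindowGeometry = DEFAULT_GEOMETRY,
    conservation: float = 0.85,
    seed: int = 0,
) -> list[Path]:
    """Write one labelled FASTA benchmark per class ratio.

    Mirrors the balanced (1:1) and imbalanced (1:5, 1:19) evaluation
    designs: each file holds ``n_true`` true windows and ``n_true * f/t``
    false windows.  A manifest table listing the files is written
    alongside.  Reproducible by seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest_lines = ["file\tratio\tn_true\tn_false\tconservation\tseed"]
    for idx, (t, f) in enumerate(ratios):
        if n_true % t:
            raise ValueError(f"n_true={n_true} not divisible by ratio part {t}")
        n_false = (n_true // t) * f
        config = GeneratorConfig(
            geometry=geometry,
            n_true=n_true,
            n_false=n_false,
            conservation=conservation,
            seed=seed + idx,
        )
        windows = generate(config)
        path = out_dir / f"synthetic_{t}to{f}.fasta"
        write_windows_fasta(windows, path)
        paths.append(path)
        manifest_lines.append(
            f"{path.name}\t{t}:{f}\t{n_true}\t{n_false}\t{conservation}\t{seed + idx}"
        )
    (out_dir / "manifest.tsv").write_text("\n".join(manifest_lines) + "\n")
    return paths
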