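"""Reading, validating and assembling donor splice-site windows.

A donor (5') splice site is the exon--intron boundary; introns almost always
begin with the dinucleotide GT.  All downstream feature extraction operates
on fixed-length windows around a conserved GT, described by a
:class:`WindowGeometry` (window length and the 1-based position of the
conserved G).  This module reads labelled window files in the common
benchmark layouts, scans arbitrary FASTA for candidate GT sites, and builds
the repeated balanced / imbalanced cross-validation sets used to evaluate a
classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

VALID_NT = frozenset("ACGT")
# IUPAC nucleotide codes tolerated in input records; windows overlapping a
# non-ACGT code are rejected rather than imputed.
IUPAC_NT = frozenset("ACGTURYSWKMBDHVN")

LABEL_TRUE = "true"
LABEL_FALSE = "false"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed as sequence records."""


class GeometryError(ValueError):
    """Raised when a window or record is incompatible with the geometry."""


@dataclass(frozen=True)
class WindowGeometry:
    """Fixed window shape: total length and 1-based offset of the conserved G.

    The conserved T sits at ``gt_offset + 1``.  The default (15, 9) places
    8 nt of exon upstream of the GT and 5 nt of intron downstream, the
    geometry of the NN269 benchmark windows.
    """

    window_length: int = 15
    gt_offset: int = 9

    def __post_init__(self) -> None:
        if self.window_length < 4:
            raise GeometryError(f"window_length must be >= 4, got {self.window_length}")
        if not (2 <= self.gt_offset <= self.window_length - 1):
            raise GeometryError(
                f"gt_offset must lie in [2, window_length-1]; "
                f"got gt_offset={self.gt_offset}, window_length={self.window_length}"
            )

    @property
    def upstream(self) -> int:
        """Number of nucleotides before the conserved G."""
        return self.gt_offset - 1

    @property
    def downstream(self) -> int:
        """Number of nucleotides after the conserved T."""
        return self.window_length - self.gt_offset - 1


DEFAULT_GEOMETRY = WindowGeometry(15, 9)


@dataclass(frozen=True)
class SpliceWindow:
    """One candidate window: sequence, optional label, provenance.

    ``source_coord`` is the 1-based inclusive start of the window on its
    source sequence (forward strand unless ``strand == '-'``, in which case
    coordinates are in the reverse-complement frame).
    """

    sequence: str
    label: Optional[str] = None  # "true" | "false" | None
    source_id: str = ""
    source_coord: Optional[int] = None
    strand: str = "+"

    def validate(self, geometry: WindowGeometry) -> None:
        seq = self.sequence
        if len(seq) != geometry.window_length:
            raise GeometryError(
                f"window '{self.source_id}': length {len(seq)} != "
                f"geometry window_length {geometry.window_length}"
            )
        if not set(seq) <= VALID_NT:
            bad = sorted(set(seq) - VALID_NT)
            raise GeometryError(
                f"window '{self.source_id}': non-ACGT characters {bad}"
            )
        g, t = geometry.gt_offset - 1, geometry.gt_offset
        if seq[g] != "G" or seq[t] != "T":
            raise GeometryError(
                f"window '{self.source_id}': expected GT at positions "
                f"{geometry.gt_offset}-{geometry.gt_offset + 1}, found "
                f"{seq[g]}{seq[t]}"
            )


@dataclass
class Rejection:
    """A skipped record and the reason it was skipped."""

    record_id: str
    reason: str


@dataclass
class DatasetSplit:
    """One cross-validation fold of one evaluation set."""

    set_index: int
    fold_index: int
    train: list[SpliceWindow]
    test: list[SpliceWindow]
    ratio: tuple[int, int]
    seed: int


# Format profiles: where the conserved G sits in each record layout.
# `None` means "at the geometry's own gt_offset" (records are bare windows).
_PROFILE_GT_POS: dict[str, Optional[int]] = {
    "fasta": None,
    "plain": None,
    "nn269": 9,   # 15 nt records, GT at 9-10
    "hs3d": 71,   # 140 nt records, GT at 71-72
    "ucsc": 9,    # 38 nt records, GT at 9-10
}


def _iter_records(path: Path) -> Iterator[tuple[str, str]]:
    """Yield (record_id, sequence) pairs from FASTA or one-seq-per-line text.

    The layout is sniffed from the first non-blank character: '>' means
    FASTA; anything else is treated as one sequence per line.
    """
    with open(path) as fh:
        head = ""
        for line in fh:
            if line.strip():
                head = line.lstrip()[0]
                break
    if head == ">":
        for rec in SeqIO.parse(str(path), "fasta"):
            yield rec.id, str(rec.seq).upper()
        return
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            seq = line.strip().upper()
            if not seq:
                continue
            if not set(seq) <= IUPAC_NT:
                bad = sorted(set(seq) - IUPAC_NT)
                raise ParseError(
                    f"{path}: line {lineno}: not a nucleotide sequence "
                    f"(unexpected characters {bad})"
                )
            yield f"line{lineno}", seq


def _label_from_header(record_id: str) -> Optional[str]:
    """Extract a label from a ``source|start|label`` style FASTA id."""
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[-1] in (LABEL_TRUE, LABEL_FALSE):
        return parts[-1]
    return None


def read_windows(
    path: str | Path,
    geometry: WindowGeometry = DEFAULT_GEOMETRY,
    format_profile: str = "fasta",
    label: Optional[str] = None,
    return_rejections: bool = False,
):
    """Read splice-site windows from *path* under a named format profile.

    Long-record profiles (``hs3d``, ``ucsc``) carry the conserved GT at a
    fixed record position; the window of ``geometry.window_length`` is cut
    so that position lands on ``geometry.gt_offset``.  Bare-window profiles
    (``fasta``, ``plain``, ``nn269``) expect records that already match the
    geometry.  Records violating the GT invariant, containing ambiguity
    codes inside the window, or too short for the cut are logged and
    skipped, never silently dropped.

    Parameters
    ----------
    label:
        Class label to attach to every accepted window.  For FASTA input a
        ``>source|start|label`` header overrides this.
    return_rejections:
        Also return the list of :class:`Rejection` records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_profile not in _PROFILE_GT_POS:
        raise ValueError(
            f"unknown format_profile '{format_profile}'; "
            f"expected one of {sorted(_PROFILE_GT_POS)}"
        )
    record_gt_pos = _PROFILE_GT_POS[format_profile]

    windows: list[SpliceWindow] = []
    rejections: list[Rejection] = []
    for rec_id, seq in _iter_records(path):
        gt_pos = record_gt_pos if record_gt_pos is not None else geometry.gt_offset
        start = gt_pos - geometry.gt_offset  # 0-based window start in record
        end = start + geometry.window_length
        if start < 0 or end > len(seq):
            rejections.append(
                Rejection(rec_id, f"record too short for window cut ({len(seq)} nt)")
            )
            continue
        window_seq = seq[start:end]
        win = SpliceWindow(
            sequence=window_seq,
            label=_label_from_header(rec_id) or label,
            source_id=rec_id,
            source_coord=start + 1,
        )
        try:
            win.validate(geometry)
        except GeometryError as exc:
            rejections.append(Rejection(rec_id, str(exc)))
            continue
        windows.append(win)

    for rej in rejections:
        logger.warning("rejected record %s: %s", rej.record_id, rej.reason)
    if return_rejections:
        return windows, rejections
    return windows


def scan_candidates(
    fasta_path: str | Path,
    geometry: WindowGeometry = DEFAULT_GEOMETRY,
    both_strands: bool = False,
) -> list[SpliceWindow]:
    """Scan a FASTA file for candidate donor windows around every GT dimer.

    A window is emitted for each forward-strand occurrence of "GT" with at
    least ``geometry.upstream`` nt before the G and ``geometry.downstream``
    nt after the T.  Windows overlapping a non-ACGT character are skipped
    with a log entry.  With ``both_strands`` the reverse complement is also
    scanned and its windows reported in the reverse-complement coordinate
    frame (``strand == '-'``).

    Output is ordered by record, then coordinate.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    windows: list[SpliceWindow] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs = [(str(rec.seq).upper(), "+")]
        if both_strands:
            seqs.append((str(Seq(str(rec.seq)).reverse_complement()).upper(), "-"))
        for seq, strand in seqs:
            windows.extend(_scan_one(seq, rec.id, strand, geometry))
    return windows


def _scan_one(
    seq: str, source_id: str, strand: str, geometry: WindowGeometry
) -> Iterator[SpliceWindow]:
    L, up = geometry.window_length, geometry.upstream
    pos = seq.find("GT")
    while pos != -1:
        start = pos - up  # 0-based window start
        if start >= 0 and start + L <= len(seq):
            window_seq = seq[start : start + L]
            if set(window_seq) <= VALID_NT:
                yield SpliceWindow(
                    sequence=window_seq,
                    source_id=source_id,
                    source_coord=start + 1,
                    strand=strand,
                )
            else:
                logger.warning(
                    "skipped candidate at %s:%d (%s): ambiguity code in window",
                    source_id, start + 1, strand,
                )
        pos = seq.find("GT", pos + 1)


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into n_folds near-equal folds."""
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, n_folds)]


def assemble_eval_sets(
    true_windows: Sequence[SpliceWindow],
    false_windows: Sequence[SpliceWindow],
    ratio: tuple[int, int] = (1, 1),
    n_sets: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    n_true: Optional[int] = None,
) -> list[DatasetSplit]:
    """Build the repeated-subsampling cross-validation design.

    ``n_sets`` independent sets are drawn without replacement, each holding
    true and false windows in exactly ``ratio`` (true:false).  Within each
    set the two classes are independently partitioned into ``n_folds``
    random folds (stratified, so every fold preserves the set's class
    ratio) and each fold serves once as the test partition.  Deterministic
    given ``seed``.

    ``n_true`` caps the number of true windows per set; by default as many
    as the ratio and the available windows allow.
    """
    t_ratio, f_ratio = ratio
    if t_ratio < 1 or f_ratio < 1:
        raise ValueError(f"ratio parts must be positive, got {ratio}")
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    unit = min(len(true_windows) // t_ratio, len(false_windows) // f_ratio)
    if n_true is not None:
        if n_true % t_ratio:
            raise ValueError(f"n_true={n_true} not divisible by ratio part {t_ratio}")
        unit = min(unit, n_true // t_ratio)
    n_t, n_f = unit * t_ratio, unit * f_ratio
    if unit == 0 or n_t < n_folds or n_f < n_folds:
        raise ValueError(
            f"insufficient windows for ratio {t_ratio}:{f_ratio} with "
            f"{len(true_windows)} true / {len(false_windows)} false available "
            f"and {n_folds} folds (would give {n_t} true + {n_f} false per set)"
        )

    rng = np.random.default_rng(seed)
    splits: list[DatasetSplit] = []
    for set_index in range(1, n_sets + 1):
        t_sel = [true_windows[i] for i in rng.choice(len(true_windows), n_t, replace=False)]
        f_sel = [false_windows[i] for i in rng.choice(len(false_windows), n_f, replace=False)]
        t_folds = _fold_indices(n_t, n_folds, rng)
        f_folds = _fold_indices(n_f, n_folds, rng)
        for fold_index in range(1, n_folds + 1):
            test = [t_sel[i] for i in t_folds[fold_index - 1]] + [
                f_sel[i] for i in f_folds[fold_index - 1]
            ]
            train = [
                t_sel[i]
                for k in range(n_folds)
                if k != fold_index - 1
                for i in t_folds[k]
            ] + [
                f_sel[i]
                for k in range(n_folds)
                if k != fold_index - 1
                for i in f_folds[k]
            ]
            splits.append(
                DatasetSplit(
                    set_index=set_index,
                    fold_index=fold_index,
                    train=train,
                    test=test,
                    ratio=(t_ratio, f_ratio),
                    seed=seed,
                )
            )
    return splits


def write_windows_fasta(windows: Iterable[SpliceWindow], path: str | Path) -> None:
    """Serialize windows as FASTA with ``>source_id|start|label`` headers."""
    with open(path, "w") as fh:
        for i, w in enumerate(windows):
            coord = w.source_coord if w.source_coord is not None else ""
            label = w.label if w.label is not None else ""
            sid = w.source_id or f"window{i + 1}"
            fh.write(f">{sid}|{coord}|{label}\n{w.sequence}\n")


def write_split_manifest(splits: Sequence[DatasetSplit], path: str | Path) -> None:
    """Write a plain-text table describing a cross-validation design."""
    with open(path, "w") as fh:
        fh.write("set\tfold\trole\twindow_id\tlabel\n")
        for sp in splits:
            for role, group in (("train", sp.train), ("test", sp.test)):
                for w in group:
                    fh.write(
                        f"{sp.set_index}\t{sp.fold_index}\t{role}\t"
                        f"{w.source_id}\t{w.label or ''}\n"
                    )
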