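"""Quality and complexity filtering of candidate reads.

Two per-read scores drive the filters:

* mean Q — the probability-domain mean of per-base Phred scores,
  ``-10*log10(mean(10^(-q/10)))``.  Averaging error probabilities (the ONT
  reporting convention) weights bad bases more heavily than an arithmetic
  mean of Phred values would; reads below Q 9 are discarded.
* DUST — a windowed triplet-frequency statistic.  Within each 64-base
  window (step 32) every overlapping 3-mer is counted and the window
  scores ``sum(c*(c-1)/2) / (n_triplets - 1)``; the read's score is the
  maximum over windows.  A 64-base homopolymer scores 31.0, typical
  non-repetitive sequence ~2; reads above the screening default of 7 are
  discarded as low-complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import ReadRecord

__all__ = [
    "QcMetrics",
    "QcConfig",
    "ClassifiedRead",
    "PIPELINE_LABELS",
    "mean_qscore",
    "dust_score",
    "compute_metrics",
    "apply_qc",
]

#: Single-assignment pipeline fates, in the order stages assign them.
PIPELINE_LABELS = ("carrier", "low_quality", "low_complexity", "hqnr", "target")

PHRED_OFFSET = 33


@dataclass(frozen=True)
class QcMetrics:
    length: int
    mean_q: float
    dust: float


@dataclass(frozen=True)
class QcConfig:
    """Filter thresholds: reject Q < q_threshold, then DUST > dust_threshold."""

    q_threshold: float = 9.0
    dust_threshold: float = 7.0
    dust_window: int = 64

    def __post_init__(self) -> None:
        if self.q_threshold < 0 or self.dust_threshold < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass
class ClassifiedRead:
    """A read plus its (eventual) pipeline label and QC metrics."""

    read: ReadRecord
    label: str | None = None
    metrics: QcMetrics | None = None


def mean_qscore(quality: str) -> float:
    """Probability-domain mean quality of a Phred+33 string."""
    if not quality:
        raise ValueError("cannot compute mean quality of an empty string")
    q = np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.float64)
    q -= PHRED_OFFSET
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


_TRIPLET_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _TRIPLET_CODE[ord(_b)] = _i
    _TRIPLET_CODE[ord(_b.lower())] = _i


def dust_score(sequence: str, window: int = 64) -> float:
    """Maximum windowed triplet-repetition score; 0 for sequences < 4 bases.

    Windows slide by ``window // 2``; triplets containing an ambiguous base
    are skipped.  Windows with fewer than two countable triplets contribute
    nothing (the normalisation ``n_triplets - 1`` would degenerate).
    """
    n = len(sequence)
    if n < 4:
        return 0.0
    codes = _TRIPLET_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    safe = np.where(valid, codes, 0).astype(np.int64)
    triplets = safe[:-2] * 16 + safe[1:-1] * 4 + safe[2:]
    trip_valid = valid[:-2] & valid[1:-1] & valid[2:]
    step = max(1, window // 2)
    best = 0.0
    for start in range(0, n, step):
        stop = min(start + window, n)
        t = triplets[start : max(stop - 2, start)]
        v = trip_valid[start : max(stop - 2, start)]
        t = t[v]
        if t.size >= 2:
            counts = np.bincount(t, minlength=64)
            score = float(np.sum(counts * (counts - 1) / 2) / (t.size - 1))
            best = max(best, score)
        if stop >= n:
            break
    return best


def compute_metrics(read: ReadRecord, window: int = 64) -> QcMetrics:
    """Annotate one read; zero-length reads get mean_q = 0 (and fail QC)."""
    mean_q = mean_qscore(read.quality) if read.quality else 0.0
    return QcMetrics(length=len(read.bases), mean_q=mean_q, dust=dust_score(read.bases, window))


def _as_classified(read: ReadRecord | ClassifiedRead) -> ClassifiedRead:
    return read if isinstance(read, ClassifiedRead) else ClassifiedRead(read=read)


def apply_qc(
    candidates: Sequence[ReadRecord | ClassifiedRead],
    config: QcConfig | None = None,
) -> tuple[list[ClassifiedRead], list[ClassifiedRead], list[ClassifiedRead]]:
    """Split candidates into (low_quality, low_complexity, survivors).

    The quality filter runs first; complexity is only judged on
    quality-passers, so a read failing both is labelled ``low_quality``.
    Every read is annotated with its metrics regardless of fate.  The
    quality rejection is strict (Q < threshold): a read at exactly the
    threshold survives.
    """
    config = config or QcConfig()
    low_quality: list[ClassifiedRead] = []
    low_complexity: list[ClassifiedRead] = []
    survivors: list[ClassifiedRead] = []
    for item in candidates:
        cr = _as_classified(item)
        cr.metrics = compute_metrics(cr.read, config.dust_window)
        if cr.metrics.mean_q < config.q_threshold:
            cr.label = "low_quality"
            low_quality.append(cr)
        elif cr.metrics.dust > config.dust_threshold:
            cr.label = "low_complexity"
            low_complexity.append(cr)
        else:
            survivors.append(cr)
    return low_quality, low_complexity, survivors
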