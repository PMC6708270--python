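"""Per-channel Poisson test for high-quality noise reads (HQNRs).

HQNRs are artifact reads that survive quality and complexity filtering yet
map to no organism; they are attributed to malfunctioning ("bad") pores.
Because a genuine low-input candidate read is a rare event, the candidate
reads surviving QC should scatter thinly and uniformly over the flowcell's
512 channels.  A channel emitting improbably many candidates under a
Poisson null with rate ``lambda = total_candidates / n_channels`` is
flagged, and every candidate read it produced is discarded — a deliberate
conservative choice that sacrifices a true detection sitting on a bad pore.

The rate is estimated from the post-QC candidate population itself (the
population the test is applied to), not from the full run.  The test is
one-sided with no multiple-testing correction by default, matching common
screening practice; Bonferroni is available as a config option.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import poisson

from .read_qc import ClassifiedRead
from .sequence_io import ReadRecord

__all__ = [
    "ChannelTally",
    "HqnrConfig",
    "tally_channels",
    "poisson_upper_tail",
    "flag_hqnr_channels",
    "label_hqnrs",
]

DEFAULT_N_CHANNELS = 512


@dataclass
class ChannelTally:
    """Candidate-read counts per flowcell channel (1-based indexing)."""

    n_channels: int
    counts: np.ndarray  # length n_channels + 1; slot 0 unused
    n_unknown: int = 0  # reads without a parseable channel, excluded

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class HqnrConfig:
    p_threshold: float = 0.05
    n_channels: int = DEFAULT_N_CHANNELS
    correction: str = "none"  # or "bonferroni"

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.correction not in ("none", "bonferroni"):
            raise ValueError(f"unknown correction {self.correction!r}")


def _channel_of(item: ReadRecord | ClassifiedRead) -> int | None:
    return item.read.channel if isinstance(item, ClassifiedRead) else item.channel


def tally_channels(
    reads: Sequence[ReadRecord | ClassifiedRead],
    n_channels: int = DEFAULT_N_CHANNELS,
) -> ChannelTally:
    """Count candidate reads per channel; unknown channels are set aside."""
    counts = np.zeros(n_channels + 1, dtype=np.int64)
    n_unknown = 0
    for item in reads:
        channel = _channel_of(item)
        if channel is None:
            n_unknown += 1
            continue
        if not 1 <= channel <= n_channels:
            raise ValueError(f"channel {channel} outside [1, {n_channels}]")
        counts[channel] += 1
    return ChannelTally(n_channels=n_channels, counts=counts, n_unknown=n_unknown)


def poisson_upper_tail(x: int, lam: float) -> float:
    """P(X >= x) for X ~ Poisson(lam), via the survival function."""
    if x < 0 or lam < 0:
        raise ValueError("x and lam must be non-negative")
    return float(poisson.sf(x - 1, lam))


def flag_hqnr_channels(tally: ChannelTally, config: HqnrConfig | None = None) -> set[int]:
    """Channels whose candidate count is improbable under the uniform null."""
    config = config or HqnrConfig(n_channels=tally.n_channels)
    if tally.total == 0:
        return set()
    lam = tally.total / config.n_channels
    threshold = config.p_threshold
    if config.correction == "bonferroni":
        threshold /= config.n_channels
    occupied = np.nonzero(tally.counts)[0]
    tails = poisson.sf(tally.counts[occupied] - 1, lam)
    return {int(c) for c, tail in zip(occupied, tails) if tail < threshold}


def label_hqnrs(
    reads: Sequence[ReadRecord | ClassifiedRead],
    flagged_channels: set[int],
) -> tuple[list, list]:
    """Partition surviving candidates into (hqnr_reads, target_reads).

    Reads with no channel attribution cannot be blamed on a pore and pass
    through to the target set.
    """
    hqnr: list = []
    target: list = []
    for item in reads:
        channel = _channel_of(item)
        if channel is not None and channel in flagged_channels:
            if isinstance(item, ClassifiedRead):
                item.label = "hqnr"
            hqnr.append(item)
        else:
            if isinstance(item, ClassifiedRead):
                item.label = "target"
            target.append(item)
    return hqnr, target
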