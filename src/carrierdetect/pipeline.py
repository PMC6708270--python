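"""End-to-end carrier-sequencing read filtering.

Stage order, each read receiving exactly one label:

1. carrier subtraction (canonical k-mer shared fraction vs the carrier index)
2. quality filter (probability-domain mean Q < 9 rejected)
3. complexity filter (windowed DUST score > 7 rejected)
4. per-channel Poisson noise test on the survivors; reads on flagged
   channels become ``hqnr``, the rest are the run's ``target`` reads —
   the candidate detections handed to downstream identification.

Reads whose IDs carry no parseable channel skip stage 4 (they cannot be
attributed to a pore) and, if they survive QC, land in the target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .carrier_filter import (
    DEFAULT_K,
    DEFAULT_THRESHOLD,
    CarrierIndex,
    build_carrier_index,
    partition_reads,
)
from .hqnr_detect import ChannelTally, HqnrConfig, flag_hqnr_channels, label_hqnrs, tally_channels
from .read_qc import ClassifiedRead, QcConfig, apply_qc
from .sequence_io import GenomeSequence, ReadRecord

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    carrier_k: int = DEFAULT_K
    carrier_threshold: float = DEFAULT_THRESHOLD
    qc: QcConfig = field(default_factory=QcConfig)
    hqnr: HqnrConfig = field(default_factory=HqnrConfig)


@dataclass
class PipelineResult:
    """Disjoint partitions plus the channel-test internals."""

    partitions: dict[str, list[ClassifiedRead]]
    flagged_channels: set[int]
    tally: ChannelTally | None  # None when no candidate survived QC
    config: PipelineConfig

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.partitions.values())


def run_pipeline(
    reads: Sequence[ReadRecord],
    carrier_genome: GenomeSequence,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    config = config or PipelineConfig()
    index = build_carrier_index(carrier_genome, config.carrier_k)
    carrier_reads, candidates = partition_reads(reads, index, config.carrier_threshold)

    low_quality, low_complexity, survivors = apply_qc(candidates, config.qc)

    known = [cr for cr in survivors if cr.read.channel is not None]
    unknown = [cr for cr in survivors if cr.read.channel is None]
    if known:
        tally = tally_channels(known, config.hqnr.n_channels)
        flagged = flag_hqnr_channels(tally, config.hqnr)
        hqnr, target = label_hqnrs(known, flagged)
    else:
        tally, flagged, hqnr, target = None, set(), [], []
    for cr in unknown:  # unattributable reads fail open into the target set
        cr.label = "target"
    target = target + unknown

    carrier_classified = [ClassifiedRead(read=r, label="carrier") for r in carrier_reads]
    return PipelineResult(
        partitions={
            "carrier": carrier_classified,
            "low_quality": low_quality,
            "low_complexity": low_complexity,
            "hqnr": hqnr,
            "target": target,
        },
        flagged_channels=flagged,
        tally=tally,
        config=config,
    )
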