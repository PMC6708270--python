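"""Synthetic nanopore-like runs with ground-truth labels.

The generator reproduces the statistical structure a carrier-sequencing
analysis assumes, at desk scale: a dominant carrier read population, a
handful of spiked target reads (parts-per-million relative abundance at
full scale), trace contamination drawn from unrelated genomes, and a few
designated "bad pore" channels emitting random-sequence noise reads at
elevated rates.  Every emitted read carries a truth label so filtering
stages can be scored exactly.

What is emulated: read-length log-normality (median ~6.5 kb for carrier
fragments), a substitution/insertion/deletion error process at nominal
R9.4-like rates (6/3/4%), per-read mean quality in the Phred 6-14 band,
channel attribution in the ``channel_<N>_<uuid>_template`` ID format, and
ddPCR droplet partitioning.  What is not: signal-level behaviour,
homopolymer-biased errors, pore death over time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .sequence_io import GenomeSequence, ReadRecord

__all__ = [
    "FragmentModel",
    "ErrorModel",
    "QualityModel",
    "RunConfig",
    "TruthLabel",
    "SimulatedRun",
    "generate_genome",
    "simulate_read",
    "simulate_bad_pore_read",
    "simulate_run",
    "simulate_ddpcr",
    "write_run",
    "load_config",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class FragmentModel:
    """Log-normal fragment lengths parameterised by their median (bp)."""

    median_bp: float
    sigma: float  # log-scale spread

    def draw(self, rng: np.random.Generator, max_length: int, min_length: int = 100) -> int:
        length = int(round(rng.lognormal(np.log(self.median_bp), self.sigma)))
        return max(min_length, min(length, max_length))


@dataclass(frozen=True)
class ErrorModel:
    substitution: float = 0.06
    insertion: float = 0.03
    deletion: float = 0.04

    def __post_init__(self) -> None:
        for r in (self.substitution, self.insertion, self.deletion):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class QualityModel:
    """Per-read mean Phred ~ Normal(loc, scale) truncated to [low, high],
    with per-base jitter; the emitted string is calibrated so its
    probability-domain mean matches the drawn per-read mean."""

    mean_loc: float = 10.5
    mean_scale: float = 1.0
    mean_low: float = 6.0
    mean_high: float = 14.0
    base_jitter: float = 1.5

    def draw_mean(self, rng: np.random.Generator) -> float:
        a = (self.mean_low - self.mean_loc) / self.mean_scale
        b = (self.mean_high - self.mean_loc) / self.mean_scale
        return float(truncnorm.rvs(a, b, loc=self.mean_loc, scale=self.mean_scale, random_state=rng))


@dataclass(frozen=True)
class TruthLabel:
    read_id: str
    origin: str  # carrier | target | contaminant | bad_pore


@dataclass(frozen=True)
class RunConfig:
    """Full parameterization of one synthetic run.

    Defaults are desk-scale: 5,000 carrier reads instead of the ~1.3e6 of
    a real 48 h run, and a 100 kb target-genome stand-in instead of a
    4.2 Mb bacterial chromosome; both are plain fields for full-scale use.
    """

    seed: int = 0
    carrier_genome_length: int = 48_502
    target_genome_length: int = 100_000
    contam_genome_length: int = 50_000
    n_carrier_reads: int = 5_000
    n_target_reads: int = 5
    n_contam_reads: int = 3
    n_channels: int = 512
    bad_pore_channels: tuple[int, ...] = (7, 99)
    bad_pore_reads_per_channel: int = 10
    bad_pore_length_range: tuple[int, int] = (267, 865)
    carrier_fragment: FragmentModel = field(default_factory=lambda: FragmentModel(6_493, 1.0))
    target_fragment: FragmentModel = field(default_factory=lambda: FragmentModel(900, 0.4))
    contam_fragment: FragmentModel = field(default_factory=lambda: FragmentModel(700, 0.4))
    errors: ErrorModel = field(default_factory=ErrorModel)
    quality: QualityModel = field(default_factory=QualityModel)
    gc: float = 0.5

    def __post_init__(self) -> None:
        for n in (self.n_carrier_reads, self.n_target_reads, self.n_contam_reads,
                  self.bad_pore_reads_per_channel):
            if n < 0:
                raise ValueError("read counts must be non-negative")
        if any(not 1 <= c <= self.n_channels for c in self.bad_pore_channels):
            raise ValueError("bad_pore_channels must lie in [1, n_channels]")

    @property
    def total_reads(self) -> int:
        return (self.n_carrier_reads + self.n_target_reads + self.n_contam_reads
                + len(self.bad_pore_channels) * self.bad_pore_reads_per_channel)


@dataclass
class SimulatedRun:
    reads: list[ReadRecord]
    truth: list[TruthLabel]  # row-for-row aligned with reads
    carrier_genome: GenomeSequence
    target_genome: GenomeSequence
    contam_genomes: list[GenomeSequence]
    config: RunConfig


def generate_genome(length: int, gc: float = 0.5, seed: int | np.random.Generator = 0,
                    label: str = "synthetic_genome") -> GenomeSequence:
    """i.i.d. random genome with the requested GC fraction."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    rng = _as_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = _BASES[rng.choice(4, size=length, p=p)]
    return GenomeSequence(label, bases.tobytes().decode("ascii"))


def _uuid_like(rng: np.random.Generator) -> str:
    hexdigits = "0123456789abcdef"
    digits = "".join(hexdigits[i] for i in rng.integers(0, 16, size=32))
    return f"{digits[:8]}-{digits[8:12]}-{digits[12:16]}-{digits[16:20]}-{digits[20:]}"


def _quality_string(n: int, mean_q: float, jitter: float, rng: np.random.Generator) -> str:
    """Phred+33 string whose probability-domain mean tracks ``mean_q``.

    Shifting every Phred value by a constant d multiplies every error
    probability by 10^(-d/10), so one additive correction makes the
    probability-domain mean exact before integer rounding.
    """
    q = rng.normal(mean_q, jitter, size=n)
    achieved = -10.0 * np.log10(np.mean(10.0 ** (-q / 10.0)))
    q += mean_q - achieved
    q = np.clip(np.rint(q), 2, 41).astype(np.uint8)
    return (q + 33).tobytes().decode("ascii")


def _apply_errors(fragment: np.ndarray, errors: ErrorModel, rng: np.random.Generator) -> np.ndarray:
    """Substitutions, then deletions, then single-base insertions."""
    out = fragment.copy()
    if errors.substitution > 0:
        sub_mask = rng.random(out.size) < errors.substitution
        offsets = rng.integers(1, 4, size=int(sub_mask.sum()))
        out[sub_mask] = (out[sub_mask] + offsets) % 4
    if errors.deletion > 0:
        out = out[rng.random(out.size) >= errors.deletion]
    if errors.insertion > 0 and out.size:
        ins_mask = rng.random(out.size) < errors.insertion
        positions = np.nonzero(ins_mask)[0]
        inserted = rng.integers(0, 4, size=positions.size)
        out = np.insert(out, positions, inserted)
    return out


_CODE_OF = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_OF[ord(_b)] = _i


def simulate_read(
    genome: GenomeSequence,
    fragment_length: int,
    channel: int,
    seed: int | np.random.Generator,
    errors: ErrorModel | None = None,
    quality: QualityModel | None = None,
    origin: str = "carrier",
) -> tuple[ReadRecord, TruthLabel]:
    """One read from a uniformly placed, uniformly stranded genome fragment."""
    rng = _as_rng(seed)
    errors = errors or ErrorModel()
    quality = quality or QualityModel()
    if fragment_length > len(genome):
        raise ValueError(
            f"fragment ({fragment_length} bp) longer than genome ({len(genome)} bp)"
        )
    start = int(rng.integers(0, len(genome) - fragment_length + 1))
    codes = _CODE_OF[np.frombuffer(
        genome.bases[start : start + fragment_length].encode("ascii"), dtype=np.uint8
    )]
    if rng.random() < 0.5:  # reverse strand
        codes = (3 - codes)[::-1]
    codes = _apply_errors(codes, errors, rng)
    bases = _BASES[codes].tobytes().decode("ascii")
    mean_q = quality.draw_mean(rng)
    qual = _quality_string(len(bases), mean_q, quality.base_jitter, rng)
    read_id = f"channel_{channel}_{_uuid_like(rng)}_template"
    record = ReadRecord(read_id, bases, qual, channel=channel, uuid=read_id.split("_", 2)[2][:-9])
    return record, TruthLabel(read_id, origin)


def simulate_bad_pore_read(
    channel: int,
    seed: int | np.random.Generator,
    length_range: tuple[int, int] = (267, 865),
) -> tuple[ReadRecord, TruthLabel]:
    """A noise read from a malfunctioning pore: random bases unrelated to
    any genome, length in the short HQNR band, quality above the Q 9
    filter so only the channel-level Poisson test can remove it."""
    rng = _as_rng(seed)
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    bases = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    mean_q = float(rng.uniform(9.5, 12.7))
    qual = _quality_string(length, mean_q, 0.8, rng)
    read_id = f"channel_{channel}_{_uuid_like(rng)}_template"
    return ReadRecord(read_id, bases, qual, channel=channel), TruthLabel(read_id, "bad_pore")


def simulate_run(config: RunConfig) -> SimulatedRun:
    """Generate a full labelled run; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    carrier = generate_genome(config.carrier_genome_length, config.gc, rng, "carrier")
    target = generate_genome(config.target_genome_length, config.gc, rng, "target")
    contams = [
        generate_genome(config.contam_genome_length, config.gc, rng, f"contaminant_{i + 1}")
        for i in range(max(config.n_contam_reads, 0))
    ]

    bad = set(config.bad_pore_channels)
    good_channels = np.array([c for c in range(1, config.n_channels + 1) if c not in bad])

    reads: list[ReadRecord] = []
    truth: list[TruthLabel] = []

    def emit(genome: GenomeSequence, fragment: FragmentModel, origin: str) -> None:
        channel = int(rng.choice(good_channels))
        length = fragment.draw(rng, max_length=len(genome))
        read, label = simulate_read(
            genome, length, channel, rng, config.errors, config.quality, origin
        )
        reads.append(read)
        truth.append(label)

    for _ in range(config.n_carrier_reads):
        emit(carrier, config.carrier_fragment, "carrier")
    for _ in range(config.n_target_reads):
        emit(target, config.target_fragment, "target")
    for i in range(config.n_contam_reads):
        emit(contams[i], config.contam_fragment, "contaminant")
    for channel in config.bad_pore_channels:
        for _ in range(config.bad_pore_reads_per_channel):
            read, label = simulate_bad_pore_read(channel, rng, config.bad_pore_length_range)
            reads.append(read)
            truth.append(label)

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = [truth[i] for i in order]
    return SimulatedRun(reads, truth, carrier, target, contams, config)


def simulate_ddpcr(
    copies: float, n_droplets: int, seed: int | np.random.Generator
) -> tuple[int, int]:
    """Partition ``copies`` molecules over droplets: each droplet is
    positive with probability 1 - exp(-copies/n_droplets)."""
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if copies < 0:
        raise ValueError("copies must be non-negative")
    rng = _as_rng(seed)
    p_positive = 1.0 - np.exp(-copies / n_droplets)
    return int(rng.binomial(n_droplets, p_positive)), n_droplets


def write_run(run: SimulatedRun, fastq_path: str | Path, truth_path: str | Path) -> None:
    """FASTQ plus a tab-separated truth-label sidecar (read_id, origin)."""
    from .sequence_io import write_fastq

    write_fastq(run.reads, fastq_path)
    with open(truth_path, "w") as handle:
        handle.write("read_id\torigin\n")
        for label in run.truth:
            handle.write(f"{label.read_id}\t{label.origin}\n")


def load_config(path: str | Path) -> RunConfig:
    """RunConfig from a YAML file; nested models accept plain mappings."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    for key, cls in (("carrier_fragment", FragmentModel), ("target_fragment", FragmentModel),
                     ("contam_fragment", FragmentModel), ("errors", ErrorModel),
                     ("quality", QualityModel)):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    for key in ("bad_pore_channels", "bad_pore_length_range"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
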