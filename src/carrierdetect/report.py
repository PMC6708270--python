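"""Reporting surfaces: read-set summary metrics and per-read feature tables.

Two tables mirror how carrier-sequencing results are conventionally
presented: a summary of each read partition (count, min/max/median length,
total bases) and a per-read table of length, mean quality and DUST score
for every non-carrier read.  The run-level report adds the observed (and,
when library stoichiometry is supplied, expected) target reads per million
carrier reads.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantitation import observed_reads_per_million
from .read_qc import ClassifiedRead
from .sequence_io import ReadRecord

__all__ = [
    "ReadSetSummary",
    "summarize_reads",
    "per_read_report",
    "run_report",
    "format_run_report",
]


@dataclass(frozen=True)
class ReadSetSummary:
    n_reads: int
    min_length: int | None
    max_length: int | None
    median_length: int | None
    total_bases: int


def _length_of(item) -> int:
    if isinstance(item, numbers.Integral):
        return int(item)
    if isinstance(item, ClassifiedRead):
        return len(item.read.bases)
    if isinstance(item, ReadRecord):
        return len(item.bases)
    raise TypeError(f"cannot take a read length from {type(item).__name__}")


def summarize_reads(reads: Sequence) -> ReadSetSummary:
    """Exact integer length metrics for a read set (or raw length list).

    The median of an even-sized set is the mean of the two middle values
    rounded half-up to an integer; an empty set yields n = 0 with absent
    length fields.
    """
    lengths = sorted(_length_of(r) for r in reads)
    n = len(lengths)
    if n == 0:
        return ReadSetSummary(0, None, None, None, 0)
    if n % 2 == 1:
        median = lengths[n // 2]
    else:
        median = (lengths[n // 2 - 1] + lengths[n // 2] + 1) // 2  # half-up
    return ReadSetSummary(n, lengths[0], lengths[-1], median, sum(lengths))


def per_read_report(reads: Sequence[ClassifiedRead]) -> pd.DataFrame:
    """One row per read, input order: read_id, label, length, mean_q, dust.

    Scores are rounded to one decimal, the precision the summary tables
    are conventionally printed at.
    """
    rows = []
    for cr in reads:
        if cr.metrics is None:
            raise ValueError(f"read {cr.read.read_id!r} has no QC metrics")
        rows.append(
            {
                "read_id": cr.read.read_id,
                "label": cr.label,
                "length": cr.metrics.length,
                "mean_q": round(cr.metrics.mean_q, 1),
                "dust": round(cr.metrics.dust, 1),
            }
        )
    return pd.DataFrame(rows, columns=["read_id", "label", "length", "mean_q", "dust"])


def run_report(
    partitions: Mapping[str, Sequence],
    quant: Mapping[str, float] | None = None,
) -> dict:
    """Machine-readable run verdict.

    ``partitions`` maps the five pipeline labels to their read lists.  The
    observed target-reads-per-million uses the carrier partition as the
    denominator and is absent when no carrier reads exist; ``quant`` may
    carry an ``expected_reads_per_million`` to print alongside.
    """
    summaries = {label: asdict(summarize_reads(reads)) for label, reads in partitions.items()}
    n_total = sum(s["n_reads"] for s in summaries.values())
    n_carrier = summaries.get("carrier", {"n_reads": 0})["n_reads"]
    n_target = summaries.get("target", {"n_reads": 0})["n_reads"]
    candidate_total = n_total - n_carrier
    report = {
        "n_reads": n_total,
        "partitions": summaries,
        "observed_reads_per_million": (
            observed_reads_per_million(n_target, n_carrier) if n_carrier > 0 else None
        ),
        "hqnr_test_performed": candidate_total > 0,
    }
    if quant:
        report.update(quant)
    return report


def format_run_report(report: Mapping) -> str:
    """Human-readable rendering of :func:`run_report` output."""
    lines = [f"total reads\t{report['n_reads']}"]
    lines.append("partition\tn_reads\tmin\tmax\tmedian\ttotal_bases")
    for label, s in report["partitions"].items():
        lines.append(
            f"{label}\t{s['n_reads']}\t{s['min_length']}\t{s['max_length']}"
            f"\t{s['median_length']}\t{s['total_bases']}"
        )
    orpm = report.get("observed_reads_per_million")
    lines.append(
        "observed target reads per 10^6 carrier reads\t"
        + (f"{orpm:.2f}" if orpm is not None else "n/a (no carrier reads)")
    )
    erpm = report.get("expected_reads_per_million")
    if erpm is not None:
        lines.append(f"expected target reads per 10^6 carrier reads\t{erpm:.2f}")
    if not report.get("hqnr_test_performed", True):
        lines.append("channel noise test\tnot applicable (no candidate reads)")
    return "\n".join(lines) + "\n"


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(report, handle, indent=2)
        handle.write("\n")
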