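"""Quantitation arithmetic for low-input detection experiments.

Covers droplet digital PCR (ddPCR) Poisson copy estimation, genome
copy-number correction, DNA yield, parts-per-billion sensitivity, and the
expected/observed target-read stoichiometry of a carrier library.

ddPCR fractionates one reaction into ~20,000 droplets; with the positive
fraction p the mean copies per droplet is lambda = -ln(1 - p) and copies
per reaction is n_droplets * lambda.  A fully saturated plate carries no
information about concentration and is treated as an error (real practice
re-dilutes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "DdpcrResult",
    "SaturationError",
    "ddpcr_copies",
    "copies_per_cell",
    "genome_mass_fg",
    "dna_yield",
    "sensitivity_ppb",
    "expected_reads_per_million",
    "observed_reads_per_million",
]

#: Average mass of one double-stranded base pair, daltons.
DALTONS_PER_BP = 650.0
AVOGADRO = 6.022e23


class SaturationError(ValueError):
    """All droplets positive: sample too concentrated to quantify."""


@dataclass(frozen=True)
class DdpcrResult:
    n_droplets: int
    n_positive: int
    lam_hat: float  # mean copies per droplet
    copies: float  # copies per reaction
    lam_ci95: tuple[float, float]  # Wilson interval on p, transformed


def ddpcr_copies(n_positive: int, n_droplets: int) -> DdpcrResult:
    """Poisson copy estimate from droplet counts, with a 95% interval.

    The interval is a Wilson score interval on the positive fraction,
    pushed through ``-ln(1 - p)`` (monotone, so endpoints map directly);
    Wilson is stable near p = 0 where low-input samples live.
    """
    if n_droplets <= 0:
        raise ValueError("n_droplets must be positive")
    if not 0 <= n_positive <= n_droplets:
        raise ValueError("n_positive must be in [0, n_droplets]")
    if n_positive == n_droplets:
        raise SaturationError(
            f"{n_positive}/{n_droplets} droplets positive: "
            "sample too concentrated to quantify, re-dilute"
        )
    p_hat = n_positive / n_droplets
    lam_hat = -math.log1p(-p_hat)
    lo, hi = proportion_confint(n_positive, n_droplets, alpha=0.05, method="wilson")
    ci = (-math.log1p(-float(lo)), -math.log1p(-float(hi)))
    return DdpcrResult(
        n_droplets=n_droplets,
        n_positive=n_positive,
        lam_hat=lam_hat,
        copies=n_droplets * lam_hat,
        lam_ci95=ci,
    )


def copies_per_cell(genome_copies: float, cells: float) -> float:
    """Genome copy-number correction factor (e.g. 2000 copies / 1000 cells -> 2)."""
    if cells <= 0:
        raise ValueError("cells must be positive")
    return genome_copies / cells


def genome_mass_fg(length_bp: float) -> float:
    """Mass in femtograms of one double-stranded genome of the given length."""
    if length_bp < 0:
        raise ValueError("length must be non-negative")
    return length_bp * DALTONS_PER_BP / AVOGADRO * 1e15


def dna_yield(copies_out: float, cells_in: float, cpc: float) -> float:
    """Extraction yield DNA_out / DNA_in as a fraction of input genome copies."""
    if cells_in <= 0 or cpc <= 0:
        raise ValueError("cells_in and copies-per-cell must be positive")
    return copies_out / (cells_in * cpc)


def sensitivity_ppb(cells: float, genome_length_bp: float, soil_mass_mg: float) -> float:
    """Input DNA mass over sample mass, in parts per billion.

    ~1e4 single-copy cells of a 4.2 Mb organism in 50 mg of soil is the
    canonical ~1 ppb life-detection benchmark.
    """
    if soil_mass_mg <= 0:
        raise ValueError("soil mass must be positive")
    dna_mass_g = cells * genome_mass_fg(genome_length_bp) * 1e-15
    soil_mass_g = soil_mass_mg * 1e-3
    return dna_mass_g / soil_mass_g * 1e9


def expected_reads_per_million(
    target_mass_pg: float,
    carrier_mass_pg: float,
    target_mean_fragment: float = 1.0,
    carrier_mean_fragment: float = 1.0,
) -> float:
    """Expected target reads per 10^6 carrier reads from library stoichiometry.

    Read counts follow molecule counts, i.e. mass over mean fragment
    length: ``(m_t / m_c) * (L_c / L_t) * 1e6``.
    """
    if min(target_mass_pg, carrier_mass_pg, target_mean_fragment, carrier_mean_fragment) <= 0:
        raise ValueError("masses and fragment lengths must be positive")
    return (target_mass_pg / carrier_mass_pg) * (carrier_mean_fragment / target_mean_fragment) * 1e6


def observed_reads_per_million(target_reads: float, carrier_reads: float) -> float:
    if carrier_reads <= 0:
        raise ValueError("carrier_reads must be positive")
    return 1e6 * target_reads / carrier_reads
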