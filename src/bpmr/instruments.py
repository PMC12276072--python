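"""Selection of independent, strongly associated genetic proxies.

Implements the standard instrument-selection funnel for two-sample MR:
genome-wide significance filtering (P < 5e-8 by convention), exclusion of
problem regions such as the APOE locus, greedy LD clumping (keep the most
significant variant per LD region), and instrument-strength diagnostics
(per-variant F statistics and variance explained, with F < 10 the
conventional weak-instrument bar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import (
    GenomicRegion,
    LDReference,
    SummaryStats,
    VariantAssociation,
    in_region,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0


@dataclass
class InstrumentSet:
    """Clumped exposure-side instruments plus per-variant diagnostics."""

    stats: SummaryStats
    provenance: dict[str, list[str]] = field(default_factory=dict)
    f_stats: dict[str, float] = field(default_factory=dict)
    r2_contributions: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.stats)

    @property
    def rsids(self) -> list[str]:
        return list(self.stats.df["rsid"])


@dataclass(frozen=True)
class InstrumentStrength:
    mean_f: float
    min_f: float
    max_f: float
    total_r2: float

    def __post_init__(self) -> None:
        assert self.mean_f >= self.min_f >= 0
        assert 0.0 <= self.total_r2 <= 1.0


def select_significant(stats: SummaryStats, threshold: float = 5e-8) -> SummaryStats:
    """Retain rows with pvalue strictly below ``threshold``; order preserved."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    mask = stats.df["pvalue"] < threshold
    if not mask.any():
        logger.warning(
            "%s: no variants below p < %g", stats.trait_name, threshold
        )
    return stats.subset(mask)


def exclude_regions(
    stats: SummaryStats, regions: list[GenomicRegion]
) -> SummaryStats:
    """Drop variants inside any of the supplied closed regions."""
    if not regions:
        return stats.subset(np.ones(len(stats), dtype=bool))
    chrom = stats.df["chrom"].map(normalize_chrom)
    pos = stats.df["pos"]
    drop = np.zeros(len(stats), dtype=bool)
    for r in regions:
        drop |= (
            (chrom == normalize_chrom(r.chrom)) & (pos >= r.start) & (pos <= r.end)
        ).to_numpy()
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("%s: excluded %d variants in masked regions", stats.trait_name, n_drop)
    return stats.subset(~drop)


def clump(
    stats: SummaryStats,
    ld: LDReference,
    r2_threshold: float = 0.001,
    window_bp: int = 1_000_000,
) -> InstrumentSet:
    """Greedy LD clumping keeping the most significant variant per region.

    Candidates are sorted by ascending p-value, ties broken by (chrom, pos).
    The best remaining variant becomes an index; every remaining variant
    within ``window_bp`` of it (± window, so a 1 Mb window spans 2 Mb) with
    r² >= ``r2_threshold`` against it is removed.  Indices are returned in
    the sort order they were chosen.  Variants absent from the LD position
    index are treated as independent of everything, with a warning.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValueError("r2_threshold must be in (0, 1)")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")

    df = stats.df
    order = df.sort_values(
        ["pvalue", "chrom", "pos"], kind="mergesort"
    ).index.to_numpy()

    missing = [r for r in df["rsid"] if r not in ld.positions]
    if missing:
        logger.warning(
            "%d variants absent from LD position index; treated as independent",
            len(missing),
        )

    chroms = df["chrom"].map(normalize_chrom).to_numpy()
    poss = df["pos"].to_numpy()
    rsids = df["rsid"].to_numpy()

    alive = np.ones(len(df), dtype=bool)
    kept_positions: list[int] = []
    pos_of = {idx: k for k, idx in enumerate(df.index)}
    for idx in order:
        k = pos_of[idx]
        if not alive[k]:
            continue
        alive[k] = False
        kept_positions.append(k)
        near = (
            alive
            & (chroms == chroms[k])
            & (np.abs(poss - poss[k]) <= window_bp)
        )
        for j in np.flatnonzero(near):
            if ld.r2(rsids[k], rsids[j]) >= r2_threshold:
                alive[j] = False

    mask = np.zeros(len(df), dtype=bool)
    mask[kept_positions] = True
    kept = stats.subset(mask)
    inst = InstrumentSet(stats=kept)
    for v in kept.records():
        inst.provenance[v.rsid] = ["significant", "clump_index"]
        inst.f_stats[v.rsid] = f_statistic(v)
        try:
            inst.r2_contributions[v.rsid] = variance_explained(v, method="f_based")
        except ValueError:
            pass
    return inst


def f_statistic(v: VariantAssociation) -> float:
    """Per-variant instrument-strength F, the squared Wald z: (beta/se)**2."""
    return (v.beta / v.se) ** 2


def variance_explained(
    v: VariantAssociation,
    method: str = "f_based",
    phenotypic_sd: float | None = None,
) -> float:
    """Fraction of exposure variance explained by one variant.

    ``f_based``: R² = F / (F + n - 2), from the identity between the
    one-degree F statistic and the partial R² of a simple regression.
    ``freq_beta``: R² = 2 f (1-f) beta_std², requiring the effect on the
    SD-of-trait scale (either unit 'SD' inputs or a supplied phenotypic SD
    to standardize an mm Hg beta).  Both are clamped to [0, 1].
    """
    if method == "f_based":
        if not v.n or v.n <= 2:
            raise ValueError("f_based variance explained requires n > 2")
        F = f_statistic(v)
        return float(np.clip(F / (F + v.n - 2), 0.0, 1.0))
    if method == "freq_beta":
        if v.eaf is None:
            raise ValueError("freq_beta variance explained requires eaf")
        beta_std = v.beta if phenotypic_sd is None else v.beta / phenotypic_sd
        return float(np.clip(2 * v.eaf * (1 - v.eaf) * beta_std**2, 0.0, 1.0))
    raise ValueError(f"unknown method {method!r}")


def instrument_strength(inst: InstrumentSet) -> InstrumentStrength:
    """Summarize F statistics and total variance explained for a set."""
    fs = np.array([f_statistic(v) for v in inst.stats.records()])
    r2s = np.array(
        [variance_explained(v, method="f_based") for v in inst.stats.records()]
    )
    return InstrumentStrength(
        mean_f=float(fs.mean()),
        min_f=float(fs.min()),
        max_f=float(fs.max()),
        total_r2=float(np.clip(r2s.sum(), 0.0, 1.0)),
    )
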