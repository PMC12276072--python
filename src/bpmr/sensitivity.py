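"""Robustness analyses beyond estimator swaps.

Two checks from the study design: (i) reverse-causality guarding — drop
genetic proxies lying within a flanking window (500 kb by default) of lead
variants from the outcome GWAS, then re-estimate; (ii) an alternate-exposure
rerun, e.g. a BP GWAS without BMI adjustment whose betas are on the
inverse-normal SD scale, routed through half-SD effect scaling so the two
runs are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .harmonize import HarmonizedInstrument
from .sumstats import SummaryStats, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 500_000


@dataclass
class ExclusionSpec:
    """Lead variants and the flanking half-width within which instruments
    are considered at risk of proxying the outcome itself."""

    lead_variants: list[tuple[str, str, int]]  # (rsid, chrom, pos)
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")


@dataclass
class ExclusionReport:
    removed: dict[str, list[str]] = field(default_factory=dict)  # lead -> rsids
    unresolvable: list[str] = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len({r for rs in self.removed.values() for r in rs} | set(self.unresolvable))


def exclude_near_leads(
    hs: list[HarmonizedInstrument],
    positions: dict[str, tuple[str, int]],
    spec: ExclusionSpec,
) -> tuple[list[HarmonizedInstrument], ExclusionReport]:
    """Remove instruments within ``flank_bp`` (closed, |Δpos| <= flank) of
    any lead variant on the same chromosome.  Instruments whose rsid is not
    in the position lookup are dropped conservatively, with a warning."""
    report = ExclusionReport()
    kept: list[HarmonizedInstrument] = []
    leads = [(r, normalize_chrom(c), int(p)) for r, c, p in spec.lead_variants]
    for h in hs:
        loc = positions.get(h.rsid)
        if loc is None:
            logger.warning("%s: no position; conservatively excluded", h.rsid)
            report.unresolvable.append(h.rsid)
            continue
        chrom, pos = normalize_chrom(loc[0]), int(loc[1])
        hit = None
        for lead_rsid, lead_chrom, lead_pos in leads:
            if chrom == lead_chrom and abs(pos - lead_pos) <= spec.flank_bp:
                hit = lead_rsid
                break
        if hit is None:
            kept.append(h)
        else:
            report.removed.setdefault(hit, []).append(h.rsid)
    for lead, rsids in report.removed.items():
        logger.info("excluded %d instruments near %s", len(rsids), lead)
    return kept, report


def rerun_with_exposure(alt_exposure: SummaryStats, pipeline_config):
    """Re-run the full select → clump → harmonize → estimate pipeline with a
    different exposure GWAS (e.g. the BMI-unadjusted, SD-scale rerun).

    SD-unit exposures are scaled per half-SD decrease (k = 0.5) so results
    are comparable to mm Hg runs scaled per 10/5 mm Hg decrease.  Returns
    the pipeline's results table.
    """
    from .pipeline import run_analysis  # local import to avoid a cycle

    cfg = pipeline_config.replace_exposure(alt_exposure)
    if alt_exposure.unit == "SD":
        cfg.scale_k = 0.5
    return run_analysis(cfg)
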