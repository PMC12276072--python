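"""End-to-end orchestration: select → clump → harmonize → estimate → report.

One run takes a single exposure GWAS and any number of outcome GWAS (the
emulated study used seven autopsy phenotypes, four tagged vascular brain
injury and three tagged Alzheimer's pathology), produces one results row per
(outcome × method), flags Bonferroni-significant primary (random-effects
IVW) rows, and renders a forest-style text table of odds ratios per k-unit
exposure decrease.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import mr
from .harmonize import harmonize_set
from .instruments import (
    InstrumentSet,
    clump,
    exclude_regions,
    instrument_strength,
    select_significant,
)
from .sensitivity import ExclusionSpec, exclude_near_leads
from .sumstats import (
    GenomicRegion,
    LDReference,
    SummaryStats,
    read_ld,
    read_sumstats,
)

logger = logging.getLogger(__name__)

PRIMARY_METHOD = "ivw_mre"
#: Bonferroni threshold used when exactly seven outcomes are configured,
#: matching the convention of correcting 0.05 across seven phenotypes.
SEVEN_OUTCOME_ALPHA = 0.007

RESULT_COLUMNS = [
    "outcome", "category", "method", "n_variants", "theta", "se", "p",
    "OR", "CI_low", "CI_high", "Q", "Q_df", "Q_p",
    "egger_intercept", "egger_intercept_se", "egger_intercept_p",
    "significant_bonferroni",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything one run needs; paths or in-memory objects both accepted."""

    exposure: SummaryStats | str | Path
    outcomes: dict  # label -> SummaryStats | path
    ld: LDReference | str | Path | None = None
    categories: dict = field(default_factory=dict)  # label -> "VBI" | "AD" | ...
    exposure_unit: str = "mmHg"
    scale_k: float = 10.0
    selection_threshold: float = 5e-8
    exclusion_regions: list = field(default_factory=list)  # GenomicRegion | "chr:a-b"
    clump_r2: float = 0.001
    clump_window_bp: int = 1_000_000
    palindrome_maf: float = 0.42
    methods: tuple = (PRIMARY_METHOD, "egger", "weighted_median")
    bonferroni_alpha: float | None = None
    n_boot: int = 1000
    seed: int = 0
    sensitivity: ExclusionSpec | None = None
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.scale_k <= 0:
            raise ValueError("scale_k must be > 0")
        if self.bonferroni_alpha is not None and not (0 < self.bonferroni_alpha < 1):
            raise ValueError("bonferroni_alpha must be in (0, 1)")
        self.exclusion_regions = [
            r if isinstance(r, GenomicRegion) else GenomicRegion.parse(r)
            for r in self.exclusion_regions
        ]

    @property
    def alpha(self) -> float:
        if self.bonferroni_alpha is not None:
            return self.bonferroni_alpha
        if len(self.outcomes) == 7:
            return SEVEN_OUTCOME_ALPHA
        return 0.05 / max(1, len(self.outcomes))

    def replace_exposure(self, alt_exposure: SummaryStats) -> "AnalysisConfig":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs["exposure"] = alt_exposure
        kwargs["exposure_unit"] = alt_exposure.unit
        cfg = AnalysisConfig(**kwargs)
        return cfg


def _load_exposure(cfg: AnalysisConfig) -> SummaryStats:
    if isinstance(cfg.exposure, SummaryStats):
        return cfg.exposure
    return read_sumstats(cfg.exposure, unit=cfg.exposure_unit)


def _load_outcome(obj) -> SummaryStats:
    if isinstance(obj, SummaryStats):
        return obj
    return read_sumstats(obj, unit="logOR")


def _load_ld(cfg: AnalysisConfig) -> LDReference:
    if cfg.ld is None:
        return LDReference(window_bp=cfg.clump_window_bp)
    if isinstance(cfg.ld, LDReference):
        return cfg.ld
    return read_ld(cfg.ld, window_bp=cfg.clump_window_bp)


def _checksum(obj) -> str:
    if isinstance(obj, (str, Path)) and Path(obj).exists():
        return hashlib.sha256(Path(obj).read_bytes()).hexdigest()[:16]
    if isinstance(obj, SummaryStats):
        payload = pd.util.hash_pandas_object(obj.df, index=False).to_numpy().tobytes()
        return hashlib.sha256(payload).hexdigest()[:16]
    return "n/a"


def select_instruments(cfg: AnalysisConfig, exposure: SummaryStats,
                       ld: LDReference) -> tuple[InstrumentSet, dict]:
    """Instrument-selection stage shared by every outcome."""
    sig = select_significant(exposure, cfg.selection_threshold)
    if len(sig) == 0:
        raise PipelineError("instruments", "no genome-wide-significant variants")
    masked = exclude_regions(sig, cfg.exclusion_regions)
    if len(masked) == 0:
        raise PipelineError("instruments", "all significant variants in excluded regions")
    inst = clump(masked, ld, cfg.clump_r2, cfg.clump_window_bp)
    if len(inst) == 0:
        raise PipelineError("instruments", "clumping retained no variants")
    strength = instrument_strength(inst)
    counts = {
        "candidates": len(exposure),
        "significant": len(sig),
        "after_region_exclusion": len(masked),
        "clumped": len(inst),
        "mean_f": strength.mean_f,
        "min_f": strength.min_f,
        "total_r2": strength.total_r2,
    }
    logger.info("instrument selection: %s", counts)
    return inst, counts


def _estimate_rows(hs, cfg: AnalysisConfig, label: str, category: str) -> list[dict]:
    if len(hs) < 2:
        raise PipelineError("estimate", f"{label}: fewer than 2 harmonized instruments")
    rows = []
    est_ivw, het = mr.ivw(hs, random_effects=True)
    egg = mr.egger(hs) if len(hs) >= 3 else None
    for method in cfg.methods:
        if method in ("ivw_mre", "ivw"):
            est = est_ivw
        elif method == "ivw_fe":
            est, _ = mr.ivw(hs, random_effects=False)
        elif method == "egger":
            if egg is None:
                continue
            est = egg.slope
        elif method in ("weighted_median", "wmedian"):
            if len(hs) < 3:
                continue
            est = mr.weighted_median(hs, n_boot=cfg.n_boot, seed=cfg.seed)
        else:
            raise PipelineError("estimate", f"unknown method {method!r}")
        scaled = mr.scale_to_or(est, cfg.scale_k)
        rows.append({
            "outcome": label,
            "category": category,
            "method": est.method,
            "n_variants": est.n_variants,
            "theta": est.theta_hat,
            "se": est.se,
            "p": est.pvalue,
            "OR": scaled.or_point,
            "CI_low": scaled.or_low,
            "CI_high": scaled.or_high,
            "Q": het.Q,
            "Q_df": het.df,
            "Q_p": het.pvalue,
            "egger_intercept": egg.intercept if egg else np.nan,
            "egger_intercept_se": egg.intercept_se if egg else np.nan,
            "egger_intercept_p": egg.intercept_p if egg else np.nan,
            "significant_bonferroni": False,
        })
    return rows


def run_analysis(cfg: AnalysisConfig) -> dict:
    """Run the full pipeline; returns results table, reports and manifest.

    The returned dict has keys ``results`` (DataFrame, one row per outcome ×
    method), ``harmonization`` (per-outcome report dicts), ``instrument_counts``,
    ``manifest`` and ``forest`` (rendered text table).  When ``cfg.out_dir``
    is set, each stage output is also written as it completes.
    """
    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    try:
        exposure = _load_exposure(cfg)
        ld = _load_ld(cfg)
        outcomes = {lbl: _load_outcome(o) for lbl, o in cfg.outcomes.items()}
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage labelling
        raise PipelineError("load", str(e)) from e

    inst, counts = select_instruments(cfg, exposure, ld)
    if out_dir:
        inst.stats.df.to_csv(out_dir / "instruments.tsv", sep="\t", index=False)

    all_rows: list[dict] = []
    harmonization: dict[str, dict] = {}
    for label, outcome in outcomes.items():
        try:
            hs, report = harmonize_set(inst, outcome, cfg.palindrome_maf)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("harmonize", f"{label}: {e}") from e
        harmonization[label] = report.to_dict()
        if cfg.sensitivity is not None:
            hs, excl = exclude_near_leads(hs, ld.positions, cfg.sensitivity)
            harmonization[label]["lead_exclusion_removed"] = excl.n_removed
        category = cfg.categories.get(label, "")
        all_rows.extend(_estimate_rows(hs, cfg, label, category))

    results = pd.DataFrame(all_rows, columns=RESULT_COLUMNS)

    primary = results["method"] == PRIMARY_METHOD
    flags = mr.bonferroni_flag(results.loc[primary, "p"].tolist(), cfg.alpha)
    results.loc[primary, "significant_bonferroni"] = flags

    manifest = {
        "seed": cfg.seed,
        "selection_threshold": cfg.selection_threshold,
        "exclusion_regions": [
            f"{r.chrom}:{r.start}-{r.end}" for r in cfg.exclusion_regions
        ],
        "clump_r2": cfg.clump_r2,
        "clump_window_bp": cfg.clump_window_bp,
        "palindrome_maf": cfg.palindrome_maf,
        "scale_k": cfg.scale_k,
        "bonferroni_alpha": cfg.alpha,
        "methods": list(cfg.methods),
        "n_boot": cfg.n_boot,
        "exposure_checksum": _checksum(cfg.exposure),
        "outcome_checksums": {lbl: _checksum(o) for lbl, o in cfg.outcomes.items()},
        "instrument_counts": counts,
        "harmonization": harmonization,
    }

    forest = forest_table(results, alpha=cfg.alpha)
    if out_dir:
        results.to_csv(out_dir / "results.tsv", sep="\t", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out_dir / "report.md").write_text(forest)
        (out_dir / "report.json").write_text(
            results.to_json(orient="records", indent=2)
        )

    return {
        "results": results,
        "instruments": inst,
        "instrument_counts": counts,
        "harmonization": harmonization,
        "manifest": manifest,
        "forest": forest,
    }


def forest_table(results: pd.DataFrame, method: str = PRIMARY_METHOD,
                 alpha: float | None = None) -> str:
    """Text rendition of the forest plot: one line per outcome, vascular
    rows first, ``OR (low–high)`` to two decimals, an asterisk marking
    Bonferroni-significant rows."""
    if results.empty:
        raise ValueError("empty results")
    sub = results[results["method"] == method].copy()
    if sub.empty:
        sub = results.copy()
    order = {"VBI": 0, "AD": 1}
    sub["_ord"] = sub["category"].map(lambda c: order.get(c, 2))
    sub = sub.sort_values(["_ord"], kind="mergesort")
    width = max((len(str(o)) for o in sub["outcome"]), default=10)
    lines = [f"{'Outcome':<{width}}  Category  OR (95% CI)        P"]
    for row in sub.itertuples(index=False):
        star = " *" if row.significant_bonferroni else ""
        cell = f"{row.OR:.2f} ({row.CI_low:.2f}–{row.CI_high:.2f}){star}"
        lines.append(
            f"{row.outcome:<{width}}  {row.category:<8}  {cell:<18} {row.p:.3g}"
        )
    return "\n".join(lines) + "\n"
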