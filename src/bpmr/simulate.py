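"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the statistical structure the MR pipeline assumes: a
very large continuous-trait exposure GWAS (blood pressure in mm Hg, or on
the SD scale after inverse-normal transformation) and a much smaller
binary/ordinal outcome GWAS reporting per-allele log odds ratios, sharing a
set of variants with block-structured LD, palindromic alleles, and
configurable horizontal pleiotropy.

Generative model, per candidate variant j:

    f_j ~ Uniform(0.05, 0.5)                    effect-allele frequency
    γ_j   true per-allele effect on the exposure (mm Hg), scaled so that
          Σ 2 f_j (1−f_j) γ_j² / SD² equals the target variance explained
    se_Xj = SD / sqrt(2 f_j (1−f_j) n_X)
    β̂_Xj ~ Normal(γ_j, se_Xj²)
    α_j ~ Normal(μ_α, σ_α²), correlated (inside_rho) with |γ_j| when the
          InSIDE assumption is being deliberately violated
    se_Yj = 1 / sqrt(2 f_j (1−f_j) n_Y φ (1−φ))   for case fraction φ
    β̂_Yj ~ Normal(θ γ_j + α_j, se_Yj²)

Outcome summary statistics are generated directly on the log-OR scale —
exactly the scale the pipeline consumes — rather than by simulating
individual-level ordinal phenotypes.  All randomness flows from one seeded
generator, so outputs are bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import LDReference, SummaryStats

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

GENOME_WIDE_P = 5e-8
#: chi-square(1) critical value for P < 5e-8
_GW_CHI2 = sps.chi2.isf(GENOME_WIDE_P, 1)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic two-sample study.

    Defaults mirror the study design being emulated: a ~1M-participant BP
    exposure GWAS, a ~7,400-participant autopsy outcome GWAS, 4.4% exposure
    variance explained by the instruments, and a 20 mm Hg phenotypic SD so
    that a 10 mm Hg change is half a standard deviation.
    """

    n_variants: int = 200
    n_exposure: int = 1_028_980
    n_outcome: int = 7_400
    case_fraction: float = 0.5
    theta: float = 0.0            # true causal effect, log-OR per mm Hg
    total_r2: float = 0.044       # exposure variance explained by all variants
    pleiotropy_mean: float = 0.0  # directional pleiotropy, log-OR per allele
    pleiotropy_sd: float = 0.0
    inside_rho: float = 0.0       # corr(α_j, |γ_j|); nonzero violates InSIDE
    frac_pleiotropic: float = 1.0  # fraction of variants carrying α_j
    # orient effect alleles to be exposure-increasing (γ_j >= 0); directional
    # pleiotropy is defined relative to this orientation
    gamma_positive: bool = False
    frac_palindromic: float = 0.10
    frac_missing_outcome: float = 0.0
    ld_blocks: list = field(default_factory=list)  # (n_satellites, r2) per block
    exposure_sd_mmHg: float = 20.0
    exposure_unit: str = "mmHg"
    trait_name: str = "SBP"
    outcome_name: str = "outcome"
    # Optional alternative effect-size model: per-variant noncentrality
    # λ_j = ncp_min + Exponential(ncp_mean_excess).  When set, γ_j is derived
    # from λ_j and total_r2 becomes a realized (reported) rather than an
    # imposed quantity.  Used by the study-mimic preset to reproduce a
    # realistic skewed F distribution.
    ncp_min: float | None = None
    ncp_mean_excess: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("case_fraction", "frac_palindromic", "frac_missing_outcome",
                     "frac_pleiotropic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (-1.0 <= self.inside_rho <= 1.0):
            raise ValueError("inside_rho must be in [-1, 1]")
        if min(self.n_variants, self.n_exposure, self.n_outcome) <= 0:
            raise ValueError("sizes must be positive")
        if not (0.0 < self.total_r2 <= 1.0):
            raise ValueError("total_r2 must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated study."""

    theta: float
    gamma: dict[str, float]        # true exposure effects, mm Hg per allele
    alpha: dict[str, float]        # pleiotropic outcome effects, log-OR per allele
    eaf: dict[str, float]
    blocks: dict[str, str]         # satellite rsid -> index rsid
    config: SimulationConfig


def _layout(rng: np.random.Generator, cfg: SimulationConfig):
    """Chromosome/position layout: loci spaced 3 Mb apart so distinct loci
    never fall in the same clumping window; alleles with the configured
    palindromic fraction."""
    J = cfg.n_variants
    chroms = np.array([str(1 + (j % 22)) for j in range(J)])
    pos = np.array([1_000_000 + 3_000_000 * (j // 22) for j in range(J)])
    is_pal = rng.random(J) < cfg.frac_palindromic
    alleles = []
    for p in is_pal:
        pool = _PALINDROMIC if p else _NONPALINDROMIC
        alleles.append(pool[rng.integers(len(pool))])
    ea = np.array([a for a, _ in alleles])
    oa = np.array([b for _, b in alleles])
    return chroms, pos, ea, oa


def _draw_gamma(rng: np.random.Generator, cfg: SimulationConfig, f: np.ndarray,
                se_x: np.ndarray) -> np.ndarray:
    if cfg.ncp_min is not None:
        lam = cfg.ncp_min + rng.exponential(cfg.ncp_mean_excess or 0.0, len(f))
        signs = np.ones(len(f)) if cfg.gamma_positive else rng.choice([-1.0, 1.0], len(f))
        return signs * np.sqrt(lam) * se_x
    raw = rng.normal(0.0, 1.0, len(f))
    if cfg.gamma_positive:
        raw = np.abs(raw)
    denom = np.sum(2 * f * (1 - f) * raw**2) / cfg.exposure_sd_mmHg**2
    scale = np.sqrt(cfg.total_r2 / denom)
    return raw * scale


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig,
                gamma: np.ndarray) -> np.ndarray:
    J = len(gamma)
    if cfg.pleiotropy_mean == 0.0 and cfg.pleiotropy_sd == 0.0:
        return np.zeros(J)
    g = np.abs(gamma)
    gs = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(J)
    z = rng.normal(size=J)
    rho = cfg.inside_rho
    mix = rho * gs + np.sqrt(max(0.0, 1 - rho**2)) * z
    alpha = cfg.pleiotropy_mean + cfg.pleiotropy_sd * mix
    if cfg.frac_pleiotropic < 1.0:
        carrier = rng.random(J) < cfg.frac_pleiotropic
        alpha = np.where(carrier, alpha, 0.0)
    return alpha


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, LDReference, SimulationTruth]:
    """Generate one exposure/outcome summary-statistics pair plus LD and truth."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.n_variants
    rsids = np.array([f"rs{j + 1}" for j in range(J)])
    chroms, pos, ea, oa = _layout(rng, cfg)
    f = rng.uniform(0.05, 0.5, J)

    sd = cfg.exposure_sd_mmHg if cfg.exposure_unit == "mmHg" else 1.0
    se_x = sd / np.sqrt(2 * f * (1 - f) * cfg.n_exposure)
    gamma = _draw_gamma(rng, cfg, f, se_x)
    alpha = _draw_alpha(rng, cfg, gamma)

    phi = cfg.case_fraction
    se_y = 1.0 / np.sqrt(2 * f * (1 - f) * cfg.n_outcome * phi * (1 - phi))

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(cfg.theta * gamma + alpha, se_y)

    # frequency estimates carry their own (small) sampling noise per study
    eaf_x = np.clip(rng.normal(f, np.sqrt(f * (1 - f) / (2 * cfg.n_exposure))), 0.001, 0.999)
    eaf_y = np.clip(rng.normal(f, np.sqrt(f * (1 - f) / (2 * cfg.n_outcome))), 0.001, 0.999)

    ld = LDReference(window_bp=1_000_000)
    blocks: dict[str, str] = {}
    gamma_sat: dict[str, float] = {}
    alpha_sat: dict[str, float] = {}
    rows_extra = []
    # LD blocks: satellites of the first len(ld_blocks) index variants, with
    # stored within-block r² and attenuated (correlated) effect estimates.
    for b, (n_sat, r2) in enumerate(cfg.ld_blocks):
        if b >= J:
            break
        r = np.sqrt(r2)
        for s in range(int(n_sat)):
            rsid = f"rs{b + 1}_{s + 1}"
            blocks[rsid] = str(rsids[b])
            # a satellite correlated r with the index variant tags an
            # attenuated effect r·γ on both sides of the design
            gamma_sat[rsid] = float(r * gamma[b])
            alpha_sat[rsid] = float(r * alpha[b])
            sat_pos = int(pos[b]) + 10_000 * (s + 1)
            sat_bx = rng.normal(r * gamma[b], se_x[b])
            sat_by = rng.normal(r * (cfg.theta * gamma[b] + alpha[b]), se_y[b])
            rows_extra.append((str(chroms[b]), sat_pos, rsid, str(ea[b]), str(oa[b]),
                               float(eaf_x[b]), float(eaf_y[b]),
                               float(sat_bx), float(se_x[b]),
                               float(sat_by), float(se_y[b])))
            ld.set_r2(str(rsids[b]), rsid, r2)
            ld.add_position(rsid, str(chroms[b]), sat_pos)
            for s2 in range(s):
                ld.set_r2(f"rs{b + 1}_{s2 + 1}", rsid, r2)
    for j in range(J):
        ld.add_position(str(rsids[j]), str(chroms[j]), int(pos[j]))

    def frame(bx, sx, eaf, n):
        return pd.DataFrame({
            "chrom": chroms, "pos": pos, "rsid": rsids,
            "effect_allele": ea, "other_allele": oa,
            "eaf": eaf, "beta": bx, "se": sx,
            "pvalue": _wald_p(bx, sx), "n": float(n),
        })

    exp_df = frame(beta_x, se_x, eaf_x, cfg.n_exposure)
    out_df = frame(beta_y, se_y, eaf_y, cfg.n_outcome)
    if rows_extra:
        extra = pd.DataFrame(
            rows_extra,
            columns=["chrom", "pos", "rsid", "effect_allele", "other_allele",
                     "eaf_x", "eaf_y", "beta_x", "se_x", "beta_y", "se_y"],
        )
        exp_extra = extra.rename(columns={"eaf_x": "eaf", "beta_x": "beta", "se_x": "se"})
        exp_extra["pvalue"] = _wald_p(exp_extra["beta"].to_numpy(), exp_extra["se"].to_numpy())
        exp_extra["n"] = float(cfg.n_exposure)
        out_extra = extra.rename(columns={"eaf_y": "eaf", "beta_y": "beta", "se_y": "se"})
        out_extra["pvalue"] = _wald_p(out_extra["beta"].to_numpy(), out_extra["se"].to_numpy())
        out_extra["n"] = float(cfg.n_outcome)
        cols = list(exp_df.columns)
        exp_df = pd.concat([exp_df, exp_extra[cols]], ignore_index=True)
        out_df = pd.concat([out_df, out_extra[cols]], ignore_index=True)

    if cfg.frac_missing_outcome > 0:
        keep = rng.random(len(out_df)) >= cfg.frac_missing_outcome
        out_df = out_df[keep].reset_index(drop=True)

    exposure = SummaryStats(cfg.trait_name, cfg.exposure_unit, exp_df,
                            default_n=cfg.n_exposure)
    outcome = SummaryStats(cfg.outcome_name, "logOR", out_df,
                           default_n=cfg.n_outcome)
    truth = SimulationTruth(
        theta=cfg.theta,
        gamma={**{str(r): float(g) for r, g in zip(rsids, gamma)}, **gamma_sat},
        alpha={**{str(r): float(a) for r, a in zip(rsids, alpha)}, **alpha_sat},
        eaf={str(r): float(x) for r, x in zip(rsids, f)},
        blocks=blocks,
        config=cfg,
    )
    return exposure, outcome, ld, truth


def paired_frame(exposure: SummaryStats, outcome: SummaryStats) -> pd.DataFrame:
    """Inner-join simulated exposure and outcome stats on rsid into the
    (beta_exp, se_exp, beta_out, se_out) frame the estimators accept.

    Valid for simulator output, where both sides already share effect
    alleles; real data must go through harmonization instead.
    """
    e = exposure.df[["rsid", "beta", "se"]].rename(
        columns={"beta": "beta_exp", "se": "se_exp"})
    o = outcome.df[["rsid", "beta", "se"]].rename(
        columns={"beta": "beta_out", "se": "se_out"})
    return e.merge(o, on="rsid", how="inner")


#: outcome labels of the emulated study: four vascular-brain-injury and
#: three Alzheimer's-pathology phenotypes, with their GWAS sample sizes.
STUDY_OUTCOMES = [
    ("Arteriolosclerosis", "VBI", 6668, 0.75),
    ("Atherosclerosis in circle of Willis", "VBI", 7340, 0.79),
    ("Gross infarcts", "VBI", 7398, 0.76),
    ("Microinfarcts", "VBI", 7480, 0.75),
    ("Braak NFT stage", "AD", 7776, 0.69),
    ("CERAD score", "AD", 7786, 0.87),
    ("Diffuse plaques", "AD", 6363, 0.89),
]


def simulate_study(
    cfg: SimulationConfig,
    outcomes: list[tuple[str, str, float]] | None = None,
) -> dict:
    """Simulate one exposure GWAS against several outcome GWAS.

    ``outcomes`` is a list of (label, category, true_theta); sample sizes
    and case fractions come from :data:`STUDY_OUTCOMES` when the label
    matches, else from the config.  The same exposure draw and instruments
    underlie every outcome (the two-sample design shares the exposure side).
    """
    if outcomes is None:
        outcomes = [(lbl, cat, cfg.theta) for lbl, cat, _, _ in STUDY_OUTCOMES]
    meta = {lbl: (n, phi) for lbl, _, n, phi in STUDY_OUTCOMES}
    rng = np.random.default_rng(cfg.seed)
    base_seed = int(rng.integers(2**31 - 1))
    exposure, _, ld, truth = simulate_pair(replace(cfg, seed=base_seed))

    out_stats: dict[str, SummaryStats] = {}
    categories: dict[str, str] = {}
    thetas: dict[str, float] = {}
    for k, (label, category, theta) in enumerate(outcomes):
        n_out, phi = meta.get(label, (cfg.n_outcome, cfg.case_fraction))
        sub = replace(cfg, seed=base_seed, theta=theta, n_outcome=n_out,
                      case_fraction=phi, outcome_name=label)
        # redraw only the outcome side: same exposure randomness via the
        # shared base seed, fresh outcome noise via a per-outcome stream
        out_rng = np.random.default_rng((base_seed, k))
        _, outcome, _, _ = simulate_pair(sub)
        out_stats[label] = _redraw_outcome_noise(outcome, truth, sub, out_rng)
        categories[label] = category
        thetas[label] = theta
    return {
        "exposure": exposure,
        "outcomes": out_stats,
        "categories": categories,
        "thetas": thetas,
        "ld": ld,
        "truth": truth,
    }


def _redraw_outcome_noise(outcome: SummaryStats, truth: SimulationTruth,
                          cfg: SimulationConfig, rng: np.random.Generator) -> SummaryStats:
    """Give each outcome an independent noise realization around its own
    true means (θ·γ + α), keeping variant layout and standard errors."""
    df = outcome.df.copy()
    gamma = df["rsid"].map(truth.gamma)
    alpha = df["rsid"].map(truth.alpha)
    mean = cfg.theta * gamma.to_numpy(float) + alpha.to_numpy(float)
    se = df["se"].to_numpy(float)
    beta = rng.normal(mean, se)
    df["beta"] = beta
    df["pvalue"] = _wald_p(beta, se)
    return SummaryStats(outcome.trait_name, "logOR", df, default_n=outcome.default_n)


def simulate_study_mimic(seed: int, outcomes_spec=None, **overrides) -> dict:
    """Preset emulating the scale of the SBP analysis: ~1000 candidate loci
    with a skewed strength distribution calibrated so that the selected
    instrument count, mean F and variance explained land near the study's
    reported values (831 instruments, mean F 70, R² ≈ 4–6%).

    Returns the ``simulate_study`` bundle plus a ``manifest`` of realized
    instrument diagnostics.
    """
    from .instruments import clump, instrument_strength, select_significant

    cfg = SimulationConfig(
        n_variants=1000,
        ncp_min=26.0,
        ncp_mean_excess=36.0,
        frac_palindromic=0.10,
        theta=0.0,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    bundle = simulate_study(cfg, outcomes=outcomes_spec)
    sig = select_significant(bundle["exposure"], GENOME_WIDE_P)
    inst = clump(sig, bundle["ld"])
    strength = instrument_strength(inst)
    bundle["instruments"] = inst
    bundle["manifest"] = {
        "n_candidates": cfg.n_variants,
        "n_significant": len(sig),
        "n_instruments": len(inst),
        "mean_f": strength.mean_f,
        "min_f": strength.min_f,
        "max_f": strength.max_f,
        "total_r2": strength.total_r2,
        "note": ("antihypertensive-medication correction of the source BP "
                 "phenotype is upstream of summary statistics and not simulated"),
    }
    return bundle
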