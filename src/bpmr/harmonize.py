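"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires each variant's exposure and outcome betas to refer to
the same effect allele.  Allele labels can differ between studies in two
gauge ways — swapped effect/other orientation, and opposite-strand reporting
— and in one irreducible way: palindromic SNPs (A/T or C/G), for which the
two gauges coincide and strand must be inferred from allele frequency, or
the variant dropped when the minor-allele frequency is too close to 0.5 to
call (the conventional cutoff excludes MAF > 0.42).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

from .instruments import InstrumentSet
from .sumstats import SummaryStats, VariantAssociation

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})

PALINDROME_MAF_LIMIT = 0.42


class Action(str, Enum):
    """What harmonization did to (or why it dropped) an instrument."""

    kept_as_is = "kept_as_is"
    sign_flipped = "sign_flipped"
    strand_flipped = "strand_flipped"
    strand_flipped_and_sign_flipped = "strand_flipped_and_sign_flipped"
    dropped_palindromic_high_maf = "dropped_palindromic_high_maf"
    dropped_palindromic_ambiguous = "dropped_palindromic_ambiguous"
    dropped_allele_mismatch = "dropped_allele_mismatch"
    dropped_missing_in_outcome = "dropped_missing_in_outcome"

    @property
    def dropped(self) -> bool:
        return self.value.startswith("dropped")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """An exposure/outcome-aligned variant: the (β_X, β_Y) pair the
    estimators consume, expressed per copy of the shared effect allele."""

    rsid: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: float | None
    eaf_out: float | None
    action: Action

    @property
    def dropped(self) -> bool:
        return self.action.dropped


@dataclass
class HarmonizationReport:
    counts: Counter = field(default_factory=Counter)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def record(self, h: HarmonizedInstrument) -> None:
        self.counts[h.action.value] += 1
        if h.dropped:
            self.dropped.append((h.rsid, h.action.value))

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "counts": {a.value: self.counts.get(a.value, 0) for a in Action},
            "dropped": [{"rsid": r, "reason": why} for r, why in self.dropped],
        }


def _is_snv(ea: str, oa: str) -> bool:
    return ea in _COMPLEMENT and oa in _COMPLEMENT and ea != oa


def _is_palindromic(ea: str, oa: str) -> bool:
    return {ea, oa} in _PALINDROMIC_PAIRS


def _dropped(exp: VariantAssociation, out: VariantAssociation | None, action: Action) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        rsid=exp.rsid,
        beta_exp=exp.beta,
        se_exp=exp.se,
        beta_out=float("nan") if out is None else out.beta,
        se_out=float("nan") if out is None else out.se,
        eaf_exp=exp.eaf,
        eaf_out=None if out is None else out.eaf,
        action=action,
    )


def harmonize_pair(
    exp: VariantAssociation,
    out: VariantAssociation,
    palindrome_maf_limit: float = PALINDROME_MAF_LIMIT,
) -> HarmonizedInstrument:
    """Align one outcome association to the exposure's effect allele.

    Non-palindromic SNVs: resolve orientation swaps (flip the outcome beta
    sign and replace eaf by 1-eaf) and strand flips (relabel alleles by
    their complements, then resolve orientation).  Palindromic SNVs: drop
    when the exposure-side MAF exceeds ``palindrome_maf_limit`` (strict);
    otherwise infer strand by frequency concordance — the outcome EAF is
    compared against eaf_exp and 1-eaf_exp and the closer match decides the
    sign.  Missing outcome EAF or an exact frequency tie makes a palindrome
    unresolvable and it is dropped.  Indels, multi-allelic records and
    irreconcilable allele pairs are dropped as mismatches.
    """
    if exp.rsid != out.rsid:
        raise ValueError(f"rsid mismatch: {exp.rsid} vs {out.rsid}")
    e_ea, e_oa = exp.effect_allele, exp.other_allele
    o_ea, o_oa = out.effect_allele, out.other_allele
    if not (_is_snv(e_ea, e_oa) and _is_snv(o_ea, o_oa)):
        return _dropped(exp, out, Action.dropped_allele_mismatch)

    def aligned(beta_out: float, eaf_out: float | None, action: Action) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=exp.rsid,
            beta_exp=exp.beta,
            se_exp=exp.se,
            beta_out=beta_out,
            se_out=out.se,
            eaf_exp=exp.eaf,
            eaf_out=eaf_out,
            action=action,
        )

    def flip(eaf: float | None) -> float | None:
        return None if eaf is None else 1.0 - eaf

    if _is_palindromic(e_ea, e_oa):
        # For a palindrome the outcome labels must be the same unordered
        # pair (complementing maps it to itself); anything else mismatches.
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return _dropped(exp, out, Action.dropped_allele_mismatch)
        if exp.eaf is None:
            return _dropped(exp, out, Action.dropped_palindromic_ambiguous)
        maf = min(exp.eaf, 1.0 - exp.eaf)
        if maf > palindrome_maf_limit:
            return _dropped(exp, out, Action.dropped_palindromic_high_maf)
        if out.eaf is None:
            return _dropped(exp, out, Action.dropped_palindromic_ambiguous)
        # Nominal label alignment first (orientation swap), then decide the
        # hidden strand from frequency concordance.
        if (o_ea, o_oa) == (e_ea, e_oa):
            beta, eaf = out.beta, out.eaf
        else:
            beta, eaf = -out.beta, flip(out.eaf)
        d_same = abs(eaf - exp.eaf)
        d_flip = abs(eaf - (1.0 - exp.eaf))
        if d_same == d_flip:
            return _dropped(exp, out, Action.dropped_palindromic_ambiguous)
        if d_flip < d_same:
            beta, eaf = -beta, flip(eaf)
        # Net action: did the final sign convention differ from the
        # outcome's reported orientation?
        flipped = ((o_ea, o_oa) != (e_ea, e_oa)) ^ (d_flip < d_same)
        action = Action.sign_flipped if flipped else Action.kept_as_is
        return aligned(beta, eaf, action)

    # non-palindromic
    if (o_ea, o_oa) == (e_ea, e_oa):
        return aligned(out.beta, out.eaf, Action.kept_as_is)
    if (o_ea, o_oa) == (e_oa, e_ea):
        return aligned(-out.beta, flip(out.eaf), Action.sign_flipped)
    c_ea, c_oa = _COMPLEMENT[o_ea], _COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (e_ea, e_oa):
        return aligned(out.beta, out.eaf, Action.strand_flipped)
    if (c_ea, c_oa) == (e_oa, e_ea):
        return aligned(-out.beta, flip(out.eaf), Action.strand_flipped_and_sign_flipped)
    return _dropped(exp, out, Action.dropped_allele_mismatch)


def harmonize_set(
    instruments: InstrumentSet | SummaryStats,
    outcome: SummaryStats,
    palindrome_maf_limit: float = PALINDROME_MAF_LIMIT,
) -> tuple[list[HarmonizedInstrument], HarmonizationReport]:
    """Harmonize every instrument against the outcome summary statistics.

    Instruments absent from the outcome are reported as
    ``dropped_missing_in_outcome``.  Output order follows instrument order;
    the report's counts sum to the number of input instruments.  Only
    non-dropped rows are returned in the harmonized list.
    """
    stats = instruments.stats if isinstance(instruments, InstrumentSet) else instruments
    out_by_rsid = {}
    for v in outcome.records():
        out_by_rsid.setdefault(v.rsid, v)
    report = HarmonizationReport()
    kept: list[HarmonizedInstrument] = []
    for v in stats.records():
        out = out_by_rsid.get(v.rsid)
        if out is None:
            h = _dropped(v, None, Action.dropped_missing_in_outcome)
        else:
            h = harmonize_pair(v, out, palindrome_maf_limit)
        report.record(h)
        if not h.dropped:
            kept.append(h)
    n_drop = len(report.dropped)
    if n_drop:
        logger.info("harmonization dropped %d of %d instruments", n_drop, report.n_total)
    return kept, report
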