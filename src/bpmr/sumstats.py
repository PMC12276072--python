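"""GWAS summary-statistics data model and readers/writers.

The in-memory container for a trait's summary statistics is a pandas
DataFrame with canonical columns, wrapped in :class:`SummaryStats` together
with trait metadata (name, unit, fallback sample size).  Units distinguish
continuous exposures measured in mm Hg, inverse-normal-transformed exposures
on the standard-deviation (SD) scale, and binary/ordinal outcomes whose betas
are log odds ratios.

Genomic coordinates are 1-based and intervals are closed on both ends, which
is how region bounds such as the APOE exclusion window are printed in the
GWAS literature.  The genome build is whatever the input files use; it is
carried as opaque metadata and never lifted over.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order of the backing frame
COLUMNS = [
    "chrom",
    "pos",
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: default header names expected in delimited files (file -> canonical)
DEFAULT_COLUMN_MAP = {
    "CHR": "chrom",
    "POS": "pos",
    "RSID": "rsid",
    "EA": "effect_allele",
    "OA": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
}

VALID_UNITS = ("mmHg", "SD", "logOR")


class SumstatsError(ValueError):
    """Configuration or content problem in a summary-statistics file."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele effect in the trait's unit (mm Hg
    change per allele for a blood-pressure exposure, log odds ratio per
    allele for a binary or ordinal outcome).
    """

    chrom: str
    pos: int
    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pvalue: float
    n: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.rsid}: se must be > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.rsid}: eaf outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: pos must be >= 1")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.rsid}: pvalue outside (0, 1]")
        if not self.n > 0:
            raise ValueError(f"{self.rsid}: n must be > 0")


@dataclass
class SummaryStats:
    """A trait-labelled table of variant associations.

    ``df`` holds one row per variant with the canonical :data:`COLUMNS`.
    rsIDs are unique (the reader deduplicates, keeping the smallest p-value).
    """

    trait_name: str
    unit: str
    df: pd.DataFrame
    default_n: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise SumstatsError(
                f"unit must be one of {VALID_UNITS}, got {self.unit!r}"
            )
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        self.df = self.df[COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def records(self) -> Iterator[VariantAssociation]:
        for row in self.df.itertuples(index=False):
            eaf = None if pd.isna(row.eaf) else float(row.eaf)
            yield VariantAssociation(
                chrom=str(row.chrom),
                pos=int(row.pos),
                rsid=str(row.rsid),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=eaf,
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                n=float(row.n),
            )

    def subset(self, mask) -> "SummaryStats":
        """New SummaryStats with rows where ``mask`` is True; order kept."""
        return SummaryStats(
            trait_name=self.trait_name,
            unit=self.unit,
            df=self.df.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            default_n=self.default_n,
            metadata=dict(self.metadata),
        )

    def lookup(self, rsid: str) -> VariantAssociation | None:
        hit = self.df[self.df["rsid"] == rsid]
        if hit.empty:
            return None
        return next(SummaryStats(self.trait_name, self.unit, hit).records())


@dataclass(frozen=True)
class GenomicRegion:
    """A closed 1-based interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "GenomicRegion":
        """Parse ``chr19:45116911-46318605`` (commas in numbers allowed)."""
        m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}")
        chrom, start, end = m.groups()
        return cls(
            chrom=normalize_chrom(chrom),
            start=int(start.replace(",", "")),
            end=int(end.replace(",", "")),
        )


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so 'chr19' and '19' compare equal."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def in_region(v: VariantAssociation, region: GenomicRegion) -> bool:
    """True iff the variant lies inside the closed interval of ``region``."""
    return (
        normalize_chrom(v.chrom) == normalize_chrom(region.chrom)
        and region.start <= v.pos <= region.end
    )


class LDReference:
    """Pairwise r² lookups backed by a sparse table plus a position index.

    Pairs absent from the table are r² = 0; r²(v, v) = 1; pairs separated by
    more than ``window_bp`` (or on different chromosomes) are treated as 0.
    """

    def __init__(
        self,
        pairs: Mapping[tuple[str, str], float] | Iterable[tuple[str, str, float]] = (),
        positions: Mapping[str, tuple[str, int]] | None = None,
        window_bp: int = 1_000_000,
    ) -> None:
        self.window_bp = int(window_bp)
        self._r2: dict[frozenset, float] = {}
        self.positions: dict[str, tuple[str, int]] = {
            r: (normalize_chrom(c), int(p))
            for r, (c, p) in (positions or {}).items()
        }
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        for entry in items:
            if isinstance(entry, tuple) and len(entry) == 2 and not isinstance(entry[0], str):
                raise TypeError("pairs must be (a, b) -> r2 or (a, b, r2) rows")
            if len(entry) == 2:  # mapping item: ((a, b), r2)
                (a, b), r2 = entry
            else:
                a, b, r2 = entry
            self.set_r2(a, b, float(r2))

    def set_r2(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a != b:
            self._r2[frozenset((a, b))] = r2

    def add_position(self, rsid: str, chrom: str, pos: int) -> None:
        self.positions[rsid] = (normalize_chrom(chrom), int(pos))

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        pa, pb = self.positions.get(a), self.positions.get(b)
        if pa is not None and pb is not None:
            if pa[0] != pb[0]:  # cross-chromosome pairs are independent
                return 0.0
            if abs(pa[1] - pb[1]) > self.window_bp:
                return 0.0
        return self._r2.get(frozenset((a, b)), 0.0)


# ---------------------------------------------------------------------------
# file IO


def _opener(path, mode="rt"):
    return gzip.open(path, mode) if str(path).endswith(".gz") else open(path, mode)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    unit: str = "mmHg",
    trait_name: str | None = None,
    default_n: float | None = None,
    sep: str | None = None,
) -> SummaryStats:
    """Read delimited summary statistics into a :class:`SummaryStats`.

    ``column_map`` maps file header names to canonical field names; the
    default expects CHR/POS/RSID/EA/OA/EAF/BETA/SE/P/N.  Rows violating the
    per-variant invariants (se <= 0, p outside (0,1], identical alleles, ...)
    are dropped with a logged count.  Alleles are upper-cased.  Duplicate
    rsIDs keep the row with the smallest p-value.  ``# key=value`` header
    lines written by :func:`write_sumstats` are honoured for metadata.
    """
    cmap = dict(column_map or DEFAULT_COLUMN_MAP)
    meta: dict[str, str] = {}
    with _opener(path) as fh:
        text_lines = []
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            text_lines.append(line)
    if not text_lines:
        raise SumstatsError(f"{path}: no data rows")
    df = pd.read_csv(
        io.StringIO("".join(text_lines)),
        sep=sep if sep is not None else r"\s+|,|\t",
        engine="python",
    )
    # canonical field names are accepted directly as a fallback spelling
    for src in list(cmap):
        if src not in df.columns and cmap[src] in df.columns:
            cmap.pop(src)
    missing = [src for src in cmap if src not in df.columns]
    # N may legitimately be absent when a default is supplied
    if "N" in missing and (default_n is not None or "default_n" in meta):
        cmap.pop("N", None)
        missing.remove("N")
    if missing:
        raise SumstatsError(f"{path}: mapped columns absent from header: {missing}")
    df = df.rename(columns=cmap)
    df = df[[c for c in COLUMNS if c in df.columns]]

    if default_n is None and "default_n" in meta:
        default_n = float(meta["default_n"])
    if "n" not in df.columns:
        if default_n is None:
            raise SumstatsError(f"{path}: no N column and no default_n")
        df["n"] = default_n
    df["n"] = pd.to_numeric(df["n"], errors="coerce").fillna(
        default_n if default_n is not None else np.nan
    )

    for col in ("pos", "eaf", "beta", "se", "pvalue"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["rsid"] = df["rsid"].astype(str)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    n_in = len(df)
    ok = (
        df["se"].gt(0)
        & df["pvalue"].gt(0)
        & df["pvalue"].le(1)
        & df["pos"].ge(1)
        & df["n"].gt(0)
        & df["beta"].notna()
        & (df["effect_allele"] != df["other_allele"])
        & (df["eaf"].isna() | (df["eaf"].ge(0) & df["eaf"].le(1)))
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.info("%s: dropped %d invalid rows of %d", path, dropped, n_in)
    df = df[ok]

    dups = df["rsid"].duplicated(keep=False)
    if dups.any():
        logger.info("%s: deduplicating %d duplicate rsid rows", path, int(dups.sum()))
        df = (
            df.sort_values("pvalue", kind="mergesort")
            .drop_duplicates("rsid", keep="first")
            .sort_index()
        )
    if df.empty:
        raise SumstatsError(f"{path}: zero valid rows retained")

    return SummaryStats(
        trait_name=trait_name or meta.get("trait_name", "trait"),
        unit=unit if "unit" not in meta else meta["unit"],
        df=df.reset_index(drop=True),
        default_n=default_n,
        metadata={k: v for k, v in meta.items() if k not in ("trait_name", "unit", "default_n")},
    )


def write_sumstats(stats: SummaryStats, path) -> None:
    """Write TSV with ``# key=value`` metadata header; round-trips exactly."""
    if len(stats) == 0:
        raise SumstatsError("refusing to write empty SummaryStats")
    out = stats.df.rename(columns={v: k for k, v in DEFAULT_COLUMN_MAP.items()})
    with _opener(path, "wt") as fh:
        fh.write(f"# trait_name={stats.trait_name}\n")
        fh.write(f"# unit={stats.unit}\n")
        if stats.default_n is not None:
            fh.write(f"# default_n={stats.default_n}\n")
        for k, v in stats.metadata.items():
            fh.write(f"# {k}={v}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_regions(path, zero_based: bool = False) -> list[GenomicRegion]:
    """Read a BED-like three-column region file.

    By default columns are interpreted as 1-based closed intervals (matching
    how region bounds are printed in GWAS papers); pass ``zero_based=True``
    for true BED semantics (0-based half-open), which shifts start by +1.
    """
    regions = []
    with _opener(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            s, e = int(start), int(end)
            if zero_based:
                s += 1
            regions.append(GenomicRegion(normalize_chrom(chrom), s, e))
    return regions


def read_ld(path, window_bp: int = 1_000_000) -> LDReference:
    """Read an LD table: rsid_a, rsid_b, r2 rows, with optional position
    index rows of the form ``rsid  chrom:pos  POS`` marked by a third column
    'POS'?  Simpler contract: lines are either

        A<TAB>B<TAB>r2           (a pairwise entry)
        #pos<TAB>rsid<TAB>chrom<TAB>pos   (a position-index entry)

    gzip is transparent via the filename.
    """
    ld = LDReference(window_bp=window_bp)
    with _opener(path) as fh:
        header_skipped = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#pos"):
                _, rsid, chrom, pos = line.split("\t")
                ld.add_position(rsid, chrom, int(pos))
                continue
            if line.startswith("#"):
                continue
            parts = re.split(r"[\t,]| +", line)
            if not header_skipped and parts[-1].lower() in ("r2", "r^2"):
                header_skipped = True
                continue
            a, b, r2 = parts[0], parts[1], float(parts[2])
            ld.set_r2(a, b, r2)
    return ld


def write_ld(ld: LDReference, path) -> None:
    with _opener(path, "wt") as fh:
        fh.write("rsid_a\trsid_b\tr2\n")
        for key, r2 in sorted(ld._r2.items(), key=lambda kv: sorted(kv[0])):
            a, b = sorted(key)
            fh.write(f"{a}\t{b}\t{r2:.6g}\n")
        for rsid, (chrom, pos) in sorted(ld.positions.items()):
            fh.write(f"#pos\t{rsid}\t{chrom}\t{pos}\n")
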