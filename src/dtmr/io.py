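"""Reading, validating and writing GWAS summary statistics, region
catalogs and LD matrices.

All in-memory coordinates are 1-based inclusive; BED input (0-based,
half-open) is converted on read and back on write.  Summary statistics
are tab- or comma-delimited text with a header, transparently gzipped.
Floats survive a write/read round trip to at least 12 significant
digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ConfigurationError,
    LDMatrixError,
    RegionValidationError,
    SumStatsValidationError,
)

VALID_ALLELES = frozenset("ACGT")
VALID_ELEMENTS = frozenset({"gene", "promoter", "enhancer"})

#: Default header names, matching common GWAS catalog exports.  Sources
#: with other dialects supply a ``column_map`` of {canonical: actual}.
DEFAULT_COLUMNS = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_REQUIRED = ("rsid", "chrom", "pos", "effect_allele", "other_allele",
             "beta", "se", "pval")
_OPTIONAL = ("eaf", "n")


@dataclass
class VariantAssociation:
    """One variant's summary association with one trait.

    ``beta`` is the per-effect-allele effect: log-CRP units for the
    exposure, log-odds for a binary outcome.  ``eaf`` and ``n`` are
    optional — the analysis never needs them once palindromic variants
    are excluded unconditionally.
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self):
        self.effect_allele = str(self.effect_allele).strip().upper()
        self.other_allele = str(self.other_allele).strip().upper()
        self.chrom = str(self.chrom).strip()
        self.pos = int(self.pos)
        if self.effect_allele not in VALID_ALLELES:
            raise SumStatsValidationError(
                f"{self.rsid}: malformed effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise SumStatsValidationError(
                f"{self.rsid}: malformed other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise SumStatsValidationError(
                f"{self.rsid}: effect and other allele identical")
        if not np.isfinite(self.beta):
            raise SumStatsValidationError(f"{self.rsid}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise SumStatsValidationError(f"{self.rsid}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise SumStatsValidationError(
                f"{self.rsid}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumStatsValidationError(
                f"{self.rsid}: eaf must be in [0, 1]")

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))


@dataclass(frozen=True)
class GenomicRegion:
    """A gene/promoter/enhancer interval for one drug-target gene.

    ``start``/``end`` are 1-based inclusive.
    """

    target_gene: str
    element: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.element not in VALID_ELEMENTS:
            raise RegionValidationError(
                f"{self.target_gene}: element {self.element!r} not in "
                f"{sorted(VALID_ELEMENTS)}")
        if self.start > self.end:
            raise RegionValidationError(
                f"{self.target_gene}: start {self.start} > end {self.end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass
class LDMatrix:
    """Pairwise squared correlations (r²) between candidate variants.

    Pairs absent from the matrix are treated as unlinked (r² = 0) in
    lenient mode — reference panels never cover every variant.
    """

    rsids: list
    r2: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if self.r2.shape != (k, k):
            raise LDMatrixError(
                f"matrix shape {self.r2.shape} does not match {k} rsids")
        if len(set(self.rsids)) != k:
            raise LDMatrixError("duplicate rsids in LD matrix")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise LDMatrixError("r2 entries must lie in [0, 1]")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise LDMatrixError("LD matrix is not symmetric (tol 1e-8)")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise LDMatrixError("LD matrix diagonal must be 1")
        # enforce exact symmetry after the tolerance check
        self.r2 = (self.r2 + self.r2.T) / 2.0
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def lookup(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two variants; ``default`` when either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])


# ---------------------------------------------------------------------------
# summary statistics

def _resolve_columns(header: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict:
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigurationError(
                f"unknown canonical field(s) in column_map: {sorted(unknown)}")
        cmap.update(column_map)
    missing = [cmap[f] for f in _REQUIRED if cmap[f] not in header]
    if missing:
        raise ConfigurationError(
            f"required column(s) missing from header: {missing}")
    return cmap


def _sniff_sep(path: Path) -> str:
    """Tab or comma, judged from the header line (gzip-aware)."""
    import gzip
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_table(path: Path) -> pd.DataFrame:
    # round_trip parsing so written floats survive bit-identically
    return pd.read_csv(path, sep=_sniff_sep(path),
                       float_precision="round_trip")


def read_sumstats(path, column_map: Mapping[str, str] | None = None
                  ) -> list[VariantAssociation]:
    """Read a delimited summary-statistics file into validated records.

    Row order is preserved; duplicate rsids are rejected.  Row-level
    validation failures name the offending 1-based data row.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    df = _read_table(path)
    cmap = _resolve_columns(df.columns, column_map)
    out: list[VariantAssociation] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        kwargs = {}
        for f in _REQUIRED:
            kwargs[f] = rec[cmap[f]]
        for f in _OPTIONAL:
            col = cmap[f]
            if col in df.columns and pd.notna(rec[col]):
                kwargs[f] = float(rec[col])
        try:
            va = VariantAssociation(
                rsid=str(kwargs.pop("rsid")),
                chrom=kwargs.pop("chrom"),
                pos=kwargs.pop("pos"),
                effect_allele=kwargs.pop("effect_allele"),
                other_allele=kwargs.pop("other_allele"),
                beta=float(kwargs.pop("beta")),
                se=float(kwargs.pop("se")),
                pval=float(kwargs.pop("pval")),
                **kwargs,
            )
        except SumStatsValidationError as e:
            raise SumStatsValidationError(str(e), row=i) from None
        except (TypeError, ValueError) as e:
            raise SumStatsValidationError(f"malformed value ({e})", row=i) \
                from None
        if va.rsid in seen:
            raise SumStatsValidationError(
                f"duplicate rsid {va.rsid}", row=i)
        seen.add(va.rsid)
        out.append(va)
    return out


def write_sumstats(path, assocs: Iterable[VariantAssociation],
                   column_map: Mapping[str, str] | None = None) -> None:
    """Write records as tab-delimited text (gzip if the path ends .gz)."""
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    rows = []
    for a in assocs:
        rows.append({
            cmap["rsid"]: a.rsid, cmap["chrom"]: a.chrom, cmap["pos"]: a.pos,
            cmap["effect_allele"]: a.effect_allele,
            cmap["other_allele"]: a.other_allele,
            cmap["eaf"]: a.eaf, cmap["beta"]: a.beta, cmap["se"]: a.se,
            cmap["pval"]: a.pval, cmap["n"]: a.n,
        })
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def sumstats_to_frame(assocs: Iterable[VariantAssociation]) -> pd.DataFrame:
    """Tidy DataFrame view of a collection of associations."""
    return pd.DataFrame([vars(a) for a in assocs])


# ---------------------------------------------------------------------------
# region catalogs

def read_regions(path) -> list[GenomicRegion]:
    """Read a BED3+2 region catalog (chrom, start, end, target, element).

    BED coordinates are 0-based half-open on disk and converted to
    1-based inclusive in memory.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise RegionValidationError(
                    f"line {ln}: expected 5 columns "
                    "(chrom start end target element)")
            chrom, start, end, target, element = fields[:5]
            try:
                start0, end0 = int(start), int(end)
            except ValueError:
                raise RegionValidationError(
                    f"line {ln}: non-integer coordinates") from None
            regions.append(GenomicRegion(
                target_gene=target, element=element.lower(), chrom=chrom,
                start=start0 + 1, end=end0))
    return regions


def write_regions(path, regions: Iterable[GenomicRegion]) -> None:
    """Write a catalog back out as BED3+2 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                     f"{r.target_gene}\t{r.element}\n")


# ---------------------------------------------------------------------------
# LD matrices

def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix: square with rsid header, or long 3-column.

    The long format lists ``rsid_a rsid_b r2`` pairs; unlisted pairs are
    zero and the diagonal is implied.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header or "," in header:
        df = _read_table(path)
    else:  # whitespace-delimited
        df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] == 3 and not _looks_square(df):
        return _ld_from_long(df)
    rsids = [str(c) for c in df.columns]
    if df.shape[0] != df.shape[1]:
        raise LDMatrixError(
            f"matrix is {df.shape[0]}×{df.shape[1]}, expected square")
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as e:
        raise LDMatrixError(f"non-numeric entry: {e}") from None
    return LDMatrix(rsids=rsids, r2=mat)


def _looks_square(df: pd.DataFrame) -> bool:
    return df.shape[0] == df.shape[1] and all(
        pd.api.types.is_numeric_dtype(df[c]) for c in df.columns)


def _ld_from_long(df: pd.DataFrame) -> LDMatrix:
    a_col, b_col, r_col = df.columns
    rsids = sorted(set(df[a_col].astype(str)) | set(df[b_col].astype(str)))
    idx = {r: i for i, r in enumerate(rsids)}
    mat = np.eye(len(rsids))
    for a, b, r2 in zip(df[a_col].astype(str), df[b_col].astype(str),
                        df[r_col]):
        r2 = float(r2)
        if not 0 <= r2 <= 1:
            raise LDMatrixError(f"r2 {r2} out of [0, 1] for pair {a},{b}")
        mat[idx[a], idx[b]] = r2
        mat[idx[b], idx[a]] = r2
    return LDMatrix(rsids=rsids, r2=mat)


def write_ld_matrix(path, ld: LDMatrix) -> None:
    pd.DataFrame(ld.r2, columns=ld.rsids).to_csv(
        path, sep="\t", index=False, float_format="%.17g")
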