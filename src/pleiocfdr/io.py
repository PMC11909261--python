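"""Readers, writers and variant alignment for P-value-only GWAS summary statistics.

Conventions used throughout the package:

* variant positions are 1-based base pairs;
* genomic intervals are BED-style 0-based half-open, so a variant at ``pos``
  lies inside ``(start, end)`` iff ``start < pos <= end``;
* chromosome labels are normalized by stripping a leading ``chr`` so that
  mixed dialects join cleanly;
* strand and alleles are ignored — the target trait is a multivariate-shape
  GWAS that reports P values only.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, RecordError

logger = logging.getLogger(__name__)

#: default column names for summary-statistic files
DEFAULT_COLUMNS = {"variant_id": "SNP", "chrom": "CHR", "pos": "BP", "p": "P"}

#: smallest representable P value after flooring; keeps -log10 finite
DEFAULT_P_FLOOR = 1e-300


def normalize_chrom(labels: Iterable) -> pd.Series:
    """Strip a leading ``chr`` (any case) and return string labels."""
    s = pd.Series(labels, dtype="object").astype(str)
    return s.str.replace(r"^[Cc][Hh][Rr]", "", regex=True)


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric chromosomes first in numeric order, then others lexicographically."""
    num = pd.to_numeric(chrom, errors="coerce")
    return pd.Series(
        [(0, int(v), "") if not np.isnan(v) else (1, 0, c) for v, c in zip(num, chrom)],
        index=chrom.index,
    )


def _sort_by_position(df: pd.DataFrame) -> pd.DataFrame:
    key = _chrom_sort_key(df["chrom"])
    order = sorted(df.index, key=lambda i: (key[i], df.at[i, "pos"]))
    return df.loc[order].reset_index(drop=True)


@dataclass
class SummaryStats:
    """Per-variant association results for one trait (P values only)."""

    df: pd.DataFrame  # columns: variant_id, chrom, pos, p
    trait_name: str = "trait"
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["variant_id", "chrom", "pos", "p"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"SummaryStats missing columns: {missing}")
        p = self.df["p"].to_numpy(dtype=float)
        if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
            raise RecordError("all P values must lie in (0, 1]")
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise ConsistencyError(
                f"duplicate variant ids in {self.trait_name}: {sorted(set(dup))[:5]}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Series:
        return self.df["variant_id"]

    def write(self, path: str | Path, column_map: Mapping[str, str] | None = None) -> None:
        """Write a tab-separated file; P serialized with 17 significant digits."""
        cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
        out = self.df.rename(
            columns={k: v for k, v in cols.items() if k in self.df.columns}
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    p_floor: float | None = DEFAULT_P_FLOOR,
    trait_name: str | None = None,
    sep: str = "\t",
) -> SummaryStats:
    """Load one trait's summary statistics from delimited text (optionally gzipped).

    P values of exactly 0 are raised to ``p_floor`` (rejected if ``p_floor`` is
    None); missing P values are dropped; non-numeric or out-of-range P values
    raise :class:`RecordError` with the offending line number.
    """
    cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
    raw = pd.read_csv(path, sep=sep, dtype={cols["p"]: object})
    for key in ("variant_id", "chrom", "pos", "p"):
        if cols[key] not in raw.columns:
            raise FormatError(
                f"column {cols[key]!r} (mapped from {key!r}) not found in {path}"
            )
    n_read = len(raw)
    df = pd.DataFrame(
        {
            "variant_id": raw[cols["variant_id"]].astype(str),
            "chrom": normalize_chrom(raw[cols["chrom"]]),
            "pos": pd.to_numeric(raw[cols["pos"]]).astype(np.int64),
        }
    )
    p_raw = raw[cols["p"]]
    missing = p_raw.isna() | (p_raw.astype(str).str.strip() == "")
    p = pd.to_numeric(p_raw.mask(missing), errors="coerce")
    bad = (~missing) & (p.isna() | (p > 1) | (p < 0))
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 one-based
        raise RecordError(
            f"invalid P value {p_raw[bad].iloc[0]!r} at line {line} of {path}"
        )
    zero = (~missing) & (p == 0)
    if zero.any():
        if p_floor is None:
            line = int(np.flatnonzero(zero.to_numpy())[0]) + 2
            raise RecordError(f"P value of exactly 0 at line {line}; set a p_floor")
        p = p.mask(zero, p_floor)
    elif p_floor is not None:
        below = (~missing) & (p < p_floor) & (p > 0)
        p = p.mask(below, p_floor)
        zero = zero | below
    df["p"] = p.astype(float)
    df = df.loc[~missing.to_numpy()]
    df = _sort_by_position(df)
    name = trait_name or Path(str(path)).name.split(".")[0]
    report = {
        "n_read": n_read,
        "n_floored": int(zero.sum()),
        "n_dropped": int(missing.sum()),
    }
    logger.info("read %s: %s", name, report)
    return SummaryStats(df, trait_name=name, report=report)


# ---------------------------------------------------------------------------
# genomic intervals


@dataclass
class AnnotationSet:
    """A named collection of genomic intervals (0-based half-open)."""

    name: str
    intervals: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        iv = self.intervals
        if not len(iv):
            self.intervals = pd.DataFrame(columns=["chrom", "start", "end"])
            self._merged = {}
            return
        if (iv["start"] >= iv["end"]).any():
            bad = iv[iv["start"] >= iv["end"]].iloc[0]
            raise RecordError(
                f"interval with start >= end in {self.name!r}: "
                f"{bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        self._merged = None  # built lazily

    def __len__(self) -> int:
        return len(self.intervals)

    def _merged_index(self) -> dict:
        """Per-chromosome merged (start, end) arrays for membership queries."""
        if self._merged is None:
            merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            for chrom, grp in self.intervals.groupby("chrom", sort=False):
                iv = grp.sort_values("start")[["start", "end"]].to_numpy(dtype=np.int64)
                starts, ends = [], []
                cs, ce = iv[0]
                for s, e in iv[1:]:
                    if s <= ce:
                        ce = max(ce, e)
                    else:
                        starts.append(cs)
                        ends.append(ce)
                        cs, ce = s, e
                starts.append(cs)
                ends.append(ce)
                merged[str(chrom)] = (np.asarray(starts), np.asarray(ends))
            self._merged = merged
        return self._merged

    def contains(self, chrom: Sequence, pos: Sequence) -> np.ndarray:
        """Membership of 1-based positions; a variant in overlapping intervals counts once."""
        chrom = normalize_chrom(chrom).to_numpy()
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # to 0-based
        out = np.zeros(len(pos0), dtype=bool)
        merged = self._merged_index()
        for c in np.unique(chrom):
            if c not in merged:
                continue
            starts, ends = merged[c]
            sel = chrom == c
            idx = np.searchsorted(starts, pos0[sel], side="right") - 1
            ok = idx >= 0
            ok[ok] = pos0[sel][ok] < ends[idx[ok]]
            out[sel] = ok
        return out

    def write(self, path: str | Path) -> None:
        iv = self.intervals.copy()
        iv["chrom"] = "chr" + normalize_chrom(iv["chrom"]).astype(str)
        iv.to_csv(path, sep="\t", header=False, index=False)


def read_intervals(
    path: str | Path, margin: int = 0, name: str | None = None
) -> AnnotationSet:
    """Read a BED3(+) file, extending each interval by ``margin`` bp (clipped at 0)."""
    iv = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    iv["chrom"] = normalize_chrom(iv["chrom"])
    iv["start"] = np.maximum(iv["start"].astype(np.int64) - margin, 0)
    iv["end"] = iv["end"].astype(np.int64) + margin
    return AnnotationSet(name or Path(str(path)).name.split(".")[0], iv)


def default_exclusions() -> AnnotationSet:
    """Long-range-LD exclusion regions: MHC (chr6) and chr8p23.1, GRCh37."""
    ref = importlib.resources.files("pleiocfdr") / "data" / "exclusion_regions_grch37.bed"
    with importlib.resources.as_file(ref) as p:
        return read_intervals(p, name="long_range_ld")


# ---------------------------------------------------------------------------
# linkage disequilibrium


@dataclass
class LDModel:
    """Block assignments plus sparse pairwise r² between nearby variants.

    Absent pairs are treated as r² = 0; r² is symmetric and r²(a, a) = 1
    implicitly. Every variant appearing in a pair must have a block.
    """

    block_of: dict  # variant_id -> block index
    pairs: pd.DataFrame  # columns: a, b, r2

    def __post_init__(self) -> None:
        if not len(self.pairs):
            self.pairs = pd.DataFrame(columns=["a", "b", "r2"])
        else:
            unknown = set(self.pairs["a"]) | set(self.pairs["b"])
            unknown -= set(self.block_of)
            if unknown:
                raise ConsistencyError(
                    f"variants in r2 pairs without a block: {sorted(unknown)[:5]}"
                )
        self._pair_map = None

    def _pairs_dict(self) -> dict:
        if self._pair_map is None:
            self._pair_map = {}
            for a, b, r2 in self.pairs.itertuples(index=False):
                key = (a, b) if a <= b else (b, a)
                self._pair_map[key] = float(r2)
        return self._pair_map

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        key = (a, b) if a <= b else (b, a)
        return self._pairs_dict().get(key, 0.0)

    def edges_over(self, variant_ids: Sequence[str], min_r2: float) -> tuple[np.ndarray, np.ndarray]:
        """Index pairs (into ``variant_ids``) with r² >= ``min_r2``."""
        index = {v: i for i, v in enumerate(variant_ids)}
        if not len(self.pairs):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        sel = self.pairs["r2"].to_numpy() >= min_r2
        a = self.pairs["a"].to_numpy()[sel]
        b = self.pairs["b"].to_numpy()[sel]
        ia = np.array([index.get(x, -1) for x in a], dtype=np.int64)
        ib = np.array([index.get(x, -1) for x in b], dtype=np.int64)
        keep = (ia >= 0) & (ib >= 0)
        return ia[keep], ib[keep]

    def write_pairs(self, path: str | Path) -> None:
        self.pairs.rename(columns={"a": "SNP_A", "b": "SNP_B", "r2": "R2"}).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )


def read_ld_pairs(path: str | Path, block_of: Mapping[str, int]) -> LDModel:
    """Read a tab-separated SNP_A/SNP_B/R2 pair table (optionally gzipped)."""
    pairs = pd.read_csv(path, sep="\t")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in pairs.columns:
            raise FormatError(f"column {col!r} not found in {path}")
    pairs = pairs.rename(columns={"SNP_A": "a", "SNP_B": "b", "R2": "r2"})
    bad = (pairs["r2"] < 0) | (pairs["r2"] > 1)
    if bad.any():
        raise RecordError(f"r2 outside [0, 1] at line {int(np.flatnonzero(bad)[0]) + 2}")
    return LDModel(dict(block_of), pairs[["a", "b", "r2"]])


def read_ld_blocks(path: str | Path) -> AnnotationSet:
    """LD blocks as BED3; the block index is the row order."""
    return read_intervals(path, margin=0, name="ld_blocks")


def assign_blocks(ss: SummaryStats, blocks: AnnotationSet) -> dict:
    """Map each variant to the index of the first block interval containing it."""
    out: dict[str, int] = {}
    chrom = normalize_chrom(ss.df["chrom"]).to_numpy()
    pos0 = ss.df["pos"].to_numpy() - 1
    ids = ss.df["variant_id"].to_numpy()
    iv = blocks.intervals
    bc = normalize_chrom(iv["chrom"]).to_numpy()
    bs = iv["start"].to_numpy()
    be = iv["end"].to_numpy()
    for i in range(len(iv)):
        sel = (chrom == bc[i]) & (pos0 >= bs[i]) & (pos0 < be[i])
        for v in ids[sel]:
            out.setdefault(v, i)
    return out


# ---------------------------------------------------------------------------
# alignment and exclusion


def align_variants(stats: Sequence[SummaryStats]) -> pd.DataFrame:
    """Inner-join several traits on variant id.

    Returns a table with columns ``variant_id, chrom, pos`` (taken from the
    first input) and one ``p_<trait>`` column per input, sorted by (chrom, pos).
    The joined variant set is independent of input order.
    """
    if len(stats) < 2:
        raise ValueError("align_variants needs at least two SummaryStats")
    names = [s.trait_name for s in stats]
    if len(set(names)) != len(names):
        raise ConsistencyError(f"duplicate trait names: {names}")
    base = stats[0].df.rename(columns={"p": f"p_{names[0]}"})
    joined = base
    for s in stats[1:]:
        other = s.df.rename(columns={"p": f"p_{s.trait_name}"})
        merged = joined.merge(
            other[["variant_id", "chrom", "pos", f"p_{s.trait_name}"]],
            on="variant_id",
            suffixes=("", "_other"),
        )
        conflict = (merged["chrom"] != merged["chrom_other"]) | (
            merged["pos"] != merged["pos_other"]
        )
        if conflict.any():
            ids = sorted(merged.loc[conflict, "variant_id"])[:10]
            raise ConsistencyError(f"conflicting chrom/pos for variants: {ids}")
        joined = merged.drop(columns=["chrom_other", "pos_other"])
    for s in stats:
        dropped = len(s) - len(joined)
        logger.info("align_variants: dropped %d of %d from %s", dropped, len(s), s.trait_name)
    return _sort_by_position(joined)


def trait_columns(joined: pd.DataFrame) -> list[str]:
    """The ``p_<trait>`` columns of an aligned table, in input order."""
    return [c for c in joined.columns if c.startswith("p_")]


def apply_exclusions(ss: SummaryStats, regions: AnnotationSet) -> SummaryStats:
    """Drop variants falling inside any exclusion region."""
    if not len(regions):
        return ss
    inside = regions.contains(ss.df["chrom"], ss.df["pos"])
    out = ss.df.loc[~inside].reset_index(drop=True)
    if not len(out):
        logger.warning("apply_exclusions removed every variant of %s", ss.trait_name)
    return SummaryStats(out, trait_name=ss.trait_name, report=dict(ss.report))


def exclude_rows(df: pd.DataFrame, regions: AnnotationSet | None) -> pd.DataFrame:
    """Row-filter any table with chrom/pos columns by exclusion regions."""
    if regions is None or not len(regions):
        return df
    inside = regions.contains(df["chrom"], df["pos"])
    return df.loc[~inside].reset_index(drop=True)
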