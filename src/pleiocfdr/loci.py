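"""Independent genomic loci from per-variant cFDR/FDR values.

Mirrors the FUMA-style procedure: lead variants are identified greedily in
increasing value order subject to pairwise r² < ``clump_r2``; leads within
``merge_kb`` on the same chromosome are then merged (transitively) into one
locus represented by its most significant lead. Expected false discoveries at
a threshold are the sum of lead values below it — valid because the cFDR is a
posterior null probability — summed across analyses without deduplication,
which is deliberately conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .io import LDModel, _chrom_sort_key
from .simulate import Truth

logger = logging.getLogger(__name__)

LOCUS_COLUMNS = [
    "lead_variant_id",
    "chrom",
    "lead_pos",
    "start",
    "end",
    "lead_value",
    "source",
    "sources",
    "member_count",
]

#: LD lookups beyond this distance are assumed r² = 0
MAX_LD_DISTANCE = 1_000_000


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=LOCUS_COLUMNS)


def clump(
    scored: pd.DataFrame,
    ld: LDModel,
    clump_r2: float = 0.1,
    merge_kb: int = 250,
    threshold: float = 0.01,
    value_col: str = "cfdr",
    source: str = "analysis",
) -> pd.DataFrame:
    """Call independent loci from per-variant values below ``threshold``.

    ``scored`` needs columns variant_id, chrom, pos and ``value_col``. Ties in
    value are broken by (chrom, pos) so the result is independent of input row
    order. The locus span covers all clumped member variants.
    """
    sig = scored.loc[scored[value_col].to_numpy() < threshold].reset_index(drop=True)
    if not len(sig):
        return _empty_table()
    key = _chrom_sort_key(sig["chrom"])
    order = sorted(
        range(len(sig)),
        key=lambda i: (sig[value_col].iat[i], key.iat[i], int(sig["pos"].iat[i])),
    )
    ids = sig["variant_id"].to_numpy()
    chroms = sig["chrom"].astype(str).to_numpy()
    pos = sig["pos"].to_numpy(dtype=np.int64)
    vals = sig[value_col].to_numpy(dtype=float)

    lead_idx: list[int] = []
    members: list[list[int]] = []
    for i in order:
        attached = False
        for k, j in enumerate(lead_idx):
            if chroms[j] != chroms[i] or abs(int(pos[j]) - int(pos[i])) > MAX_LD_DISTANCE:
                continue
            if ld.r2(ids[j], ids[i]) >= clump_r2:
                members[k].append(i)
                attached = True
                break
        if not attached:
            lead_idx.append(i)
            members.append([i])

    # transitive distance merge of leads on the same chromosome
    window = merge_kb * 1000
    by_pos = sorted(range(len(lead_idx)), key=lambda k: (_ck(chroms[lead_idx[k]]), pos[lead_idx[k]]))
    groups: list[list[int]] = []
    for k in by_pos:
        j = lead_idx[k]
        if groups:
            last = groups[-1][-1]
            jl = lead_idx[last]
            if chroms[jl] == chroms[j] and pos[j] - pos[jl] <= window:
                groups[-1].append(k)
                continue
        groups.append([k])

    rows = []
    for grp in groups:
        all_members = [m for k in grp for m in members[k]]
        best = min(grp, key=lambda k: (vals[lead_idx[k]], _ck(chroms[lead_idx[k]]), pos[lead_idx[k]]))
        j = lead_idx[best]
        rows.append(
            {
                "lead_variant_id": ids[j],
                "chrom": chroms[j],
                "lead_pos": int(pos[j]),
                "start": int(pos[all_members].min()),
                "end": int(pos[all_members].max()),
                "lead_value": float(vals[j]),
                "source": source,
                "sources": source,
                "member_count": len(all_members),
            }
        )
    out = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    return out.sort_values(["lead_value", "chrom", "lead_pos"], ignore_index=True)


def _ck(chrom: str):
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


def merge_across(tables: Sequence[pd.DataFrame], merge_kb: int = 250) -> pd.DataFrame:
    """Merge lead variants across analyses into a final locus set.

    Leads within ``merge_kb`` (transitively, same chromosome) collapse into
    one locus represented by the most significant lead; each merged locus
    records the set of contributing source analyses.
    """
    if not len(tables):
        raise ValueError("merge_across needs at least one table")
    pool = pd.concat(list(tables), ignore_index=True)
    if not len(pool):
        return _empty_table()
    order = sorted(
        range(len(pool)),
        key=lambda i: (_ck(str(pool["chrom"].iat[i])), int(pool["lead_pos"].iat[i])),
    )
    window = merge_kb * 1000
    groups: list[list[int]] = []
    for i in order:
        if groups:
            j = groups[-1][-1]
            if str(pool["chrom"].iat[j]) == str(pool["chrom"].iat[i]) and (
                int(pool["lead_pos"].iat[i]) - int(pool["lead_pos"].iat[j]) <= window
            ):
                groups[-1].append(i)
                continue
        groups.append([i])
    rows = []
    for grp in groups:
        sub = pool.iloc[grp]
        best = sub.sort_values(["lead_value", "chrom", "lead_pos"]).iloc[0]
        sources = sorted({s for row in sub["sources"] for s in str(row).split(",")})
        rows.append(
            {
                "lead_variant_id": best["lead_variant_id"],
                "chrom": best["chrom"],
                "lead_pos": int(best["lead_pos"]),
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "lead_value": float(best["lead_value"]),
                "source": best["source"],
                "sources": ",".join(sources),
                "member_count": int(sub["member_count"].sum()),
            }
        )
    out = pd.DataFrame(rows, columns=LOCUS_COLUMNS)
    return out.sort_values(["lead_value", "chrom", "lead_pos"], ignore_index=True)


def expected_false_discoveries(
    tables: Sequence[pd.DataFrame], threshold: float = 0.01
) -> float:
    """Sum of lead values below ``threshold``, totalled across analyses.

    Shared leads are counted once per analysis, which over-counts under
    dependence — a deliberately conservative bound on false-positive loci.
    """
    total = 0.0
    for t in tables:
        v = t["lead_value"].to_numpy(dtype=float) if len(t) else np.empty(0)
        total += float(v[v < threshold].sum())
    return total


@dataclass
class LocusScore:
    """Locus calls scored against simulation ground truth."""

    n_loci: int
    n_true: int
    n_false: int
    fdp: float
    power: float
    n_causal_blocks: int
    n_detected_blocks: int


def score_against_truth(table: pd.DataFrame, truth: Truth) -> LocusScore:
    """FDP and block-level power of a locus table on the simulated universe.

    A locus is a true positive iff its span contains at least one variant that
    is causal for the target trait; power is the fraction of causal blocks
    containing at least one lead variant.
    """
    tdf = truth.df
    known = set(tdf["variant_id"])
    leads = list(table["lead_variant_id"]) if len(table) else []
    missing = [v for v in leads if v not in known]
    if missing:
        raise ConsistencyError(f"lead variants not in truth universe: {missing[:5]}")
    causal = tdf.loc[tdf["causal_target"], ["chrom", "pos"]]
    cc = causal["chrom"].astype(str).to_numpy()
    cp = causal["pos"].to_numpy()
    n_true = 0
    for _, row in table.iterrows():
        hit = (cc == str(row["chrom"])) & (cp >= row["start"]) & (cp <= row["end"])
        n_true += bool(hit.any())
    n_loci = len(table)
    n_false = n_loci - n_true
    block_of = dict(zip(tdf["variant_id"], tdf["block"]))
    detected = {block_of[v] for v in leads}
    signal_blocks = np.flatnonzero(truth.block_has_target_signal)
    n_detected = sum(1 for b in signal_blocks if b in detected)
    n_causal_blocks = len(signal_blocks)
    return LocusScore(
        n_loci=n_loci,
        n_true=n_true,
        n_false=n_false,
        fdp=n_false / max(1, n_loci),
        power=n_detected / n_causal_blocks if n_causal_blocks else 0.0,
        n_causal_blocks=n_causal_blocks,
        n_detected_blocks=n_detected,
    )


def write_locus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_locus_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sources": str})
    missing = [c for c in LOCUS_COLUMNS if c not in df.columns]
    if missing:
        raise ConsistencyError(f"locus table missing columns: {missing}")
    return df


def loci_bed(table: pd.DataFrame) -> pd.DataFrame:
    """BED3 of locus spans (0-based half-open)."""
    if not len(table):
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(
        {
            "chrom": "chr" + table["chrom"].astype(str),
            "start": table["start"].astype(int) - 1,
            "end": table["end"].astype(int),
        }
    )
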