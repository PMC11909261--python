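"""Synthetic two-trait GWAS summary statistics with block LD and shared causals.

The generator emulates the statistical structure a pleiotropy-informed
analysis relies on: two traits measured in independent cohorts whose causal
variants partially overlap, marginal association statistics smeared across
block-structured LD, and interval annotations enriched for the shared causal
variants. The target trait is P-value-only (a multivariate-shape GWAS whose
per-variant statistic is a chi-square with ``target_df`` degrees of freedom);
the auxiliary trait is an ordinary signed-z GWAS reported as two-sided P.

Model
-----
Variants live in ``n_blocks`` blocks of ``block_size`` variants. Within a
block the signed correlation between variants at lag ``d`` is
``within_block_r ** d`` (AR(1)); blocks are separated by more than 1 Mb and
are independent. Each variant is null, causal for one trait, or causal for
both (fractions ``pi_*``); causal effects are i.i.d. normal, with correlation
``rho_shared`` between the two traits' effects at shared causals, and are
scaled so the expected per-causal non-centrality is ``h2 * n / m_causal``.
Marginal z statistics are ``sqrt(n) * R @ beta`` plus correlated noise with
the block covariance ``R``. The target statistic sums ``target_df``
independent such z's squared, with the non-centrality split across the df so
the total is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .errors import ConfigError
from .io import DEFAULT_P_FLOOR, AnnotationSet, LDModel, SummaryStats

#: number of autosomes over which blocks are laid out
_N_CHROM = 22
#: spacing between adjacent variants within a block (bp)
_SPACING = 5_000
#: minimum gap between consecutive blocks (bp); keeps blocks clumping-independent
_GAP = 1_100_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic two-trait GWAS.

    Defaults mirror a vault-shape-style target GWAS (n ≈ 6.8k, multivariate
    chi-square statistic) conditioned on a larger brain-shape-style auxiliary
    GWAS (n ≈ 19.6k), over 1725 approximately independent LD blocks.
    """

    n_blocks: int = 1725
    block_size: int = 12
    within_block_r: float = 0.9
    n_target: int = 6772
    n_aux: int = 19644
    pi_shared: float = 0.02
    pi_target_only: float = 0.01
    pi_aux_only: float = 0.01
    h2_target: float = 0.5
    h2_aux: float = 0.5
    rho_shared: float = 0.8
    target_df: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.within_block_r < 1):
            raise ConfigError(f"within_block_r must be in [0, 1): {self.within_block_r}")
        fracs = (self.pi_shared, self.pi_target_only, self.pi_aux_only)
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ConfigError(f"causal fractions invalid: {fracs}")
        if not -1 <= self.rho_shared <= 1:
            raise ConfigError(f"rho_shared must be in [-1, 1]: {self.rho_shared}")
        if self.target_df < 1:
            raise ConfigError(f"target_df must be >= 1: {self.target_df}")
        if min(self.n_blocks, self.block_size, self.n_target, self.n_aux) < 1:
            raise ConfigError("sizes must be positive")
        if not (0 <= self.h2_target < 1 and 0 <= self.h2_aux < 1):
            raise ConfigError("h2 must be in [0, 1)")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class Truth:
    """Ground-truth causal labels for scoring discoveries."""

    df: pd.DataFrame  # variant_id, chrom, pos, block, causal_target, causal_aux
    block_has_target_signal: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.block_has_target_signal is None:
            n_blocks = int(self.df["block"].max()) + 1 if len(self.df) else 0
            flags = np.zeros(n_blocks, dtype=bool)
            causal = self.df.loc[self.df["causal_target"], "block"].unique()
            flags[causal] = True
            self.block_has_target_signal = flags

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _layout(cfg: SimulationConfig) -> pd.DataFrame:
    """Variant ids, chromosomes, positions and block indices."""
    m = cfg.n_variants
    block = np.repeat(np.arange(cfg.n_blocks), cfg.block_size)
    lag = np.tile(np.arange(cfg.block_size), cfg.n_blocks)
    per_chrom = -(-cfg.n_blocks // _N_CHROM)  # ceil
    chrom_idx = block // per_chrom
    local_block = block % per_chrom
    span = (cfg.block_size - 1) * _SPACING
    pos = 1 + local_block * (span + _GAP) + lag * _SPACING
    return pd.DataFrame(
        {
            "variant_id": [f"snp{i:07d}" for i in range(m)],
            "chrom": (chrom_idx + 1).astype(str),
            "pos": pos.astype(np.int64),
            "block": block,
        }
    )


def simulate_ld_model(cfg: SimulationConfig) -> LDModel:
    """Block-diagonal LD: signed r decays geometrically with lag, r² = r^(2d)."""
    layout = _layout(cfg)
    block_of = dict(zip(layout["variant_id"], layout["block"].astype(int)))
    r = cfg.within_block_r
    if r == 0.0 or cfg.block_size == 1:
        return LDModel(block_of, pd.DataFrame(columns=["a", "b", "r2"]))
    ids = layout["variant_id"].to_numpy()
    k = cfg.block_size
    offs_a, offs_b = np.triu_indices(k, 1)
    r2_lag = r ** (2.0 * (offs_b - offs_a))
    base = np.arange(cfg.n_blocks) * k
    a_idx = (base[:, None] + offs_a[None, :]).ravel()
    b_idx = (base[:, None] + offs_b[None, :]).ravel()
    pairs = pd.DataFrame(
        {"a": ids[a_idx], "b": ids[b_idx], "r2": np.tile(r2_lag, cfg.n_blocks)}
    )
    return LDModel(block_of, pairs)


def _ar1_noise(rng: np.random.Generator, n_blocks: int, k: int, r: float) -> np.ndarray:
    """AR(1)-correlated standard normal noise, shape (n_blocks, k)."""
    z = rng.standard_normal((n_blocks, k))
    if r == 0.0 or k == 1:
        return z
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - r * r)
    for j in range(1, k):
        out[:, j] = r * out[:, j - 1] + c * z[:, j]
    return out


def _ld_smear(beta: np.ndarray, r: float) -> np.ndarray:
    """R @ beta for AR(1) correlation R, vectorized over blocks (rows)."""
    if r == 0.0 or beta.shape[1] == 1:
        return beta
    k = beta.shape[1]
    left = np.empty_like(beta)
    right = np.empty_like(beta)
    left[:, 0] = beta[:, 0]
    for j in range(1, k):
        left[:, j] = r * left[:, j - 1] + beta[:, j]
    right[:, -1] = 0.0
    for j in range(k - 2, -1, -1):
        right[:, j] = r * (right[:, j + 1] + beta[:, j + 1])
    return left + right


def simulate_sumstats(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, Truth]:
    """Draw one replicate of the two-trait study. Bit-identical for a given seed."""
    layout = _layout(cfg)
    m = cfg.n_variants
    shape = (cfg.n_blocks, cfg.block_size)
    r = cfg.within_block_r

    rng_lab = substream(cfg.seed, "causal_labels")
    u = rng_lab.random(m)
    shared = u < cfg.pi_shared
    t_only = (~shared) & (u < cfg.pi_shared + cfg.pi_target_only)
    a_only = (~shared) & (~t_only) & (
        u < cfg.pi_shared + cfg.pi_target_only + cfg.pi_aux_only
    )
    causal_t = shared | t_only
    causal_a = shared | a_only

    rng_eff = substream(cfg.seed, "effect_sizes")
    beta_t = np.zeros(m)
    beta_a = np.zeros(m)
    m_ct = max(int(causal_t.sum()), 1)
    m_ca = max(int(causal_a.sum()), 1)
    sd_t = np.sqrt(cfg.h2_target / m_ct)
    sd_a = np.sqrt(cfg.h2_aux / m_ca)
    if not (np.isfinite(sd_t) and np.isfinite(sd_a)):
        raise ConfigError("per-causal effect variance is non-finite")
    n_sh = int(shared.sum())
    z1 = rng_eff.standard_normal(n_sh)
    z2 = rng_eff.standard_normal(n_sh)
    rho = cfg.rho_shared
    beta_t[shared] = sd_t * z1
    beta_a[shared] = sd_a * (rho * z1 + np.sqrt(1.0 - rho * rho) * z2)
    beta_t[t_only] = sd_t * rng_eff.standard_normal(int(t_only.sum()))
    beta_a[a_only] = sd_a * rng_eff.standard_normal(int(a_only.sum()))

    mu_t = np.sqrt(cfg.n_target) * _ld_smear(beta_t.reshape(shape), r)
    mu_a = np.sqrt(cfg.n_aux) * _ld_smear(beta_a.reshape(shape), r)

    rng_t = substream(cfg.seed, "target_noise")
    df = cfg.target_df
    stat = np.zeros(shape)
    mu_rep = mu_t / np.sqrt(df)  # split non-centrality across replicates
    for _ in range(df):
        stat += (mu_rep + _ar1_noise(rng_t, cfg.n_blocks, cfg.block_size, r)) ** 2
    p_t = stats.chi2.sf(stat.ravel(), df)

    rng_a = substream(cfg.seed, "aux_noise")
    z_a = mu_a + _ar1_noise(rng_a, cfg.n_blocks, cfg.block_size, r)
    p_a = 2.0 * stats.norm.sf(np.abs(z_a.ravel()))

    p_t = np.clip(p_t, DEFAULT_P_FLOOR, 1.0)
    p_a = np.clip(p_a, DEFAULT_P_FLOOR, 1.0)

    base = layout[["variant_id", "chrom", "pos"]]
    target = SummaryStats(base.assign(p=p_t), trait_name="target")
    aux = SummaryStats(base.assign(p=p_a), trait_name="aux")
    truth = Truth(
        layout.assign(causal_target=causal_t, causal_aux=causal_a)
    )
    return target, aux, truth


def simulate_annotation(
    cfg: SimulationConfig,
    truth: Truth,
    hit_rate: float,
    decoy_rate: float,
    name: str = "synthetic_peaks",
    half_width: int = 500,
) -> AnnotationSet:
    """Intervals covering ``hit_rate`` of shared-causal variants plus random decoys.

    Each selected variant contributes one interval of ±``half_width`` bp around
    its position, emulating a TF-binding-site / ATAC-peak track enriched for
    the shared causal architecture.
    """
    if not (0 <= hit_rate <= 1 and 0 <= decoy_rate <= 1):
        raise ConfigError("rates must lie in [0, 1]")
    rng = substream(cfg.seed, "annotation")
    df = truth.df
    shared = df["causal_target"].to_numpy() & df["causal_aux"].to_numpy()
    hits = np.flatnonzero(shared)
    n_hit = int(round(hit_rate * len(hits)))
    chosen_hits = rng.choice(hits, size=n_hit, replace=False) if n_hit else np.empty(0, int)
    decoys = np.flatnonzero(~shared)
    n_decoy = int(round(decoy_rate * len(decoys)))
    chosen_dec = rng.choice(decoys, size=n_decoy, replace=False) if n_decoy else np.empty(0, int)
    idx = np.sort(np.concatenate([chosen_hits, chosen_dec]))
    if not len(idx):
        return AnnotationSet(name, pd.DataFrame(columns=["chrom", "start", "end"]))
    pos = df["pos"].to_numpy()[idx]
    iv = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy()[idx],
            "start": np.maximum(pos - 1 - half_width, 0),
            "end": pos + half_width,
        }
    )
    return AnnotationSet(name, iv)


def write_simulation(
    cfg: SimulationConfig,
    outdir,
    hit_rate: float = 0.5,
    decoy_rate: float = 0.15,
) -> Mapping[str, str]:
    """Run one replicate and write every artifact as plain text; returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    target, aux, truth = simulate_sumstats(cfg)
    ld = simulate_ld_model(cfg)
    ann = simulate_annotation(cfg, truth, hit_rate, decoy_rate)
    paths = {
        "target": outdir / "target.sumstats.tsv",
        "aux": outdir / "aux.sumstats.tsv",
        "ld_pairs": outdir / "ld_pairs.tsv",
        "blocks": outdir / "ld_blocks.bed",
        "annotation": outdir / "annotation.bed",
        "truth": outdir / "truth.tsv",
    }
    target.write(paths["target"])
    aux.write(paths["aux"])
    ld.write_pairs(paths["ld_pairs"])
    blocks_bed(cfg).write(paths["blocks"])
    ann.write(paths["annotation"])
    truth.write(paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def blocks_bed(cfg: SimulationConfig) -> AnnotationSet:
    """One BED interval per LD block, spanning its variants."""
    layout = _layout(cfg)
    grp = layout.groupby("block", sort=True)
    iv = pd.DataFrame(
        {
            "chrom": grp["chrom"].first(),
            "start": grp["pos"].min() - 1,
            "end": grp["pos"].max(),
        }
    ).reset_index(drop=True)
    return AnnotationSet("ld_blocks", iv)
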