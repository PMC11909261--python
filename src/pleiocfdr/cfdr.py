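"""Conservative empirical-Bayes conditional FDR from two P-value vectors.

The conditional FDR of a variant is the posterior probability that it is null
for the target trait given that its target and auxiliary P values are at most
the observed values::

    cFDR(p_t | p_a) = pi0(p_a) * F0(p_t | p_a) / F(p_t | p_a)

Estimated conservatively: pi0 is set to 1, F0(p_t | p_a) = p_t under
independence of null variants from the auxiliary trait, and F is the
empirical conditional CDF. With an uninformative auxiliary trait this reduces
exactly to the empirical-Bayes (rank-based) FDR, p * n / rank.

Model fitting averages empirical counts over many random LD-pruning
iterations (r² below a threshold) so that LD does not over-weight long
haplotypes, and excludes long-range-LD regions (MHC, 8p23.1) first. The
fitted surface lives on a -log10 grid, is capped at 1, monotonized along the
target axis, and queried per variant by bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from ._rng import substream
from .errors import ConfigError, DomainError, ModelError
from .io import AnnotationSet, LDModel, exclude_rows, trait_columns


def _check_domain(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1)):
        raise DomainError(f"{name} values must lie in (0, 1]")
    return p


def unconditioned_fdr(p) -> np.ndarray:
    """Empirical-Bayes FDR: min(1, p * n / rank(p)) with max-rank for ties."""
    p = _check_domain(p, "p")
    rank = stats.rankdata(p, method="max")
    return np.minimum(1.0, p * len(p) / rank)


def brute_force_cfdr(p_target, p_aux) -> np.ndarray:
    """Direct double-count evaluation of the conservative cFDR estimator.

    cFDR_i = p_t,i * #{j: p_a,j <= p_a,i} / #{j: p_t,j <= p_t,i and
    p_a,j <= p_a,i}, capped at 1. Quadratic in n; intended as the exact
    reference for small inputs and for per-variant estimation without a grid.
    """
    pt = _check_domain(p_target, "p_target")
    pa = _check_domain(p_aux, "p_aux")
    if pt.shape != pa.shape:
        raise DomainError("p_target and p_aux must have equal length")
    n = len(pt)
    out = np.empty(n)
    chunk = max(1, 10_000_000 // max(n, 1))
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        le_a = pa[None, :] <= pa[lo:hi, None]
        n_aux = le_a.sum(axis=1)
        n_both = (le_a & (pt[None, :] <= pt[lo:hi, None])).sum(axis=1)
        out[lo:hi] = pt[lo:hi] * n_aux / n_both
    return np.minimum(1.0, out)


# ---------------------------------------------------------------------------
# random LD pruning


def _random_maximal_independent_set(
    n: int, ea: np.ndarray, eb: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Greedy maximal independent set under a random visiting order.

    Implemented as priority-based parallel selection (equivalent to the
    sequential greedy keep-if-no-kept-neighbor rule over a random
    permutation, but vectorized): repeatedly keep every undecided vertex
    whose priority beats all undecided neighbors, then drop its neighbors.
    """
    prio = rng.random(n)
    status = np.zeros(n, dtype=np.int8)  # 0 undecided, 1 kept, 2 removed
    while True:
        und = status == 0
        if not und.any():
            break
        live = und[ea] & und[eb]
        ea, eb = ea[live], eb[live]
        min_nb = np.full(n, np.inf)
        np.minimum.at(min_nb, ea, prio[eb])
        np.minimum.at(min_nb, eb, prio[ea])
        keep = und & (prio < min_nb)
        status[keep] = 1
        drop = np.zeros(n, dtype=bool)
        drop[ea[keep[eb]]] = True
        drop[eb[keep[ea]]] = True
        status[drop & (status == 0)] = 2
    return status == 1


# ---------------------------------------------------------------------------
# gridded surface


def default_grid(grid_step: float = 0.1) -> np.ndarray:
    """-log10 P breakpoints: dense (``grid_step``) up to 10, step 1 up to 300."""
    if grid_step <= 0:
        raise ConfigError(f"grid_step must be positive: {grid_step}")
    return np.concatenate([np.arange(0.0, 10.0, grid_step), np.arange(10.0, 301.0, 1.0)])


@dataclass
class CfdrSurface:
    """Gridded conservative cFDR estimate over (-log10 P_target, -log10 P_aux)."""

    grid_target: np.ndarray
    grid_aux: np.ndarray
    cfdr_values: np.ndarray  # shape (len(grid_target), len(grid_aux))
    n_prune_iterations: int
    prune_r2: float
    seed: int

    def lookup(self, p_target, p_aux) -> np.ndarray:
        return lookup_cfdr(self, p_target, p_aux)

    def write(self, path: str | Path) -> None:
        """Portable text dump: meta header, then a matrix with grid margins."""
        with open(path, "w") as fh:
            fh.write(f"# n_prune_iterations={self.n_prune_iterations}\n")
            fh.write(f"# prune_r2={self.prune_r2!r}\n")
            fh.write(f"# seed={self.seed}\n")
            fh.write(
                "\t".join(["target\\aux"] + [repr(float(g)) for g in self.grid_aux]) + "\n"
            )
            for gt, row in zip(self.grid_target, self.cfdr_values):
                fh.write(
                    "\t".join([repr(float(gt))] + [repr(float(v)) for v in row]) + "\n"
                )

    @classmethod
    def read(cls, path: str | Path) -> "CfdrSurface":
        meta = {}
        with open(path) as fh:
            lines = fh.read().splitlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                k, v = ln[1:].strip().split("=", 1)
                meta[k] = v
            else:
                body.append(ln.split("\t"))
        grid_aux = np.array([float(x) for x in body[0][1:]])
        grid_target = np.array([float(r[0]) for r in body[1:]])
        values = np.array([[float(x) for x in r[1:]] for r in body[1:]])
        return cls(
            grid_target,
            grid_aux,
            values,
            int(meta["n_prune_iterations"]),
            float(meta["prune_r2"]),
            int(meta["seed"]),
        )


def build_cfdr_surface(
    joined: pd.DataFrame,
    ld: LDModel,
    n_iter: int = 500,
    prune_r2: float = 0.2,
    exclusions: AnnotationSet | None = None,
    grid_step: float = 0.1,
    seed: int = 0,
    target: str | None = None,
    aux: str | None = None,
    monotonize: bool = True,
) -> CfdrSurface:
    """Fit the cFDR surface from randomly LD-pruned empirical counts.

    Each iteration keeps a random maximal subset with pairwise r² below
    ``prune_r2``; the bivariate histogram of (-log10 P_target, -log10 P_aux)
    over kept variants is averaged across iterations, and the conservative
    estimator is evaluated exactly at every grid node from the suffix-
    cumulated average counts. Values are capped at 1 and (by default) made
    non-increasing along the target axis by a cumulative minimum.
    """
    if grid_step <= 0:
        raise ConfigError(f"grid_step must be positive: {grid_step}")
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1: {n_iter}")
    cols = trait_columns(joined)
    t = target or cols[0]
    a = aux or cols[1]
    df = exclude_rows(joined, exclusions)
    if not len(df):
        raise ModelError("no variants left after exclusions")
    pt = _check_domain(df[t].to_numpy(), t)
    pa = _check_domain(df[a].to_numpy(), a)
    lt = np.minimum(-np.log10(pt), 300.0)
    la = np.minimum(-np.log10(pa), 300.0)

    grid = default_grid(grid_step)
    edges = np.append(grid, np.inf)
    it_b = np.clip(np.searchsorted(edges, lt, side="right") - 1, 0, len(grid) - 1)
    ia_b = np.clip(np.searchsorted(edges, la, side="right") - 1, 0, len(grid) - 1)

    ids = df["variant_id"].to_numpy()
    ea, eb = ld.edges_over(ids, prune_r2)
    rng = substream(seed, "prune")
    hist = np.zeros((len(grid), len(grid)))
    flat = it_b * len(grid) + ia_b
    for _ in range(n_iter):
        kept = _random_maximal_independent_set(len(df), ea, eb, rng)
        if not kept.any():
            raise ModelError("LD pruning produced an empty set")
        hist += np.bincount(flat[kept], minlength=len(grid) ** 2).reshape(
            len(grid), len(grid)
        )
    avg = hist / n_iter

    # suffix-cumulated counts: S[k, l] = average number of kept variants with
    # -log10 p_t >= grid[k] and -log10 p_a >= grid[l]; exact at grid nodes
    s = avg[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]
    n_aux = s[0, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (10.0 ** -grid)[:, None] * n_aux[None, :] / s
    ratio[s == 0] = np.inf
    values = np.minimum(ratio, 1.0)
    if monotonize:
        values = np.minimum.accumulate(values, axis=0)
    return CfdrSurface(grid.copy(), grid.copy(), values, n_iter, prune_r2, int(seed))


def lookup_cfdr(surface: CfdrSurface, p_target, p_aux) -> np.ndarray:
    """Per-variant cFDR by bilinear interpolation; queries beyond the grid clamp."""
    pt = _check_domain(p_target, "p_target")
    pa = _check_domain(p_aux, "p_aux")
    lt = np.clip(-np.log10(pt), surface.grid_target[0], surface.grid_target[-1])
    la = np.clip(-np.log10(pa), surface.grid_aux[0], surface.grid_aux[-1])
    interp = RegularGridInterpolator(
        (surface.grid_target, surface.grid_aux),
        surface.cfdr_values,
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    out = interp(np.column_stack([lt, la]))
    return np.clip(out, np.nextafter(0.0, 1.0), 1.0)


def per_snp_cfdr(
    joined: pd.DataFrame,
    surface: CfdrSurface,
    target: str | None = None,
    aux: str | None = None,
) -> pd.DataFrame:
    """Aligned table plus a ``cfdr`` column from the fitted surface."""
    cols = trait_columns(joined)
    t = target or cols[0]
    a = aux or cols[1]
    out = joined.copy()
    out["cfdr"] = lookup_cfdr(surface, out[t].to_numpy(), out[a].to_numpy())
    return out
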