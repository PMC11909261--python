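import numpy as np
import pandas as pd
import pytest

from pleiocfdr.io import LDModel, SummaryStats


def make_joined(p_target, p_aux, chrom="1", spacing=2_000_000):
    """Aligned two-trait table with variants far apart (no LD, no merging)."""
    n = len(p_target)
    return pd.DataFrame(
        {
            "variant_id": [f"s{i:05d}" for i in range(n)],
            "chrom": chrom,
            "pos": np.arange(1, n + 1, dtype=np.int64) * spacing,
            "p_target": np.asarray(p_target, dtype=float),
            "p_aux": np.asarray(p_aux, dtype=float),
        }
    )


def empty_ld(variant_ids):
    """LD model with every variant independent."""
    return LDModel(
        {v: i for i, v in enumerate(variant_ids)},
        pd.DataFrame(columns=["a", "b", "r2"]),
    )


@pytest.fixture
def toy_enrichment_table():
    """20 variants: 10 aux-significant, 4 of which are also target-significant,
    and 5 target-significant overall -> fold = (4/10)/(5/20) = 1.6."""
    p_aux = [0.01] * 10 + [0.5] * 10
    p_target = [0.01] * 4 + [0.5] * 6 + [0.01] + [0.5] * 9
    return make_joined(p_target, p_aux)


@pytest.fixture
def toy_cfdr_pairs():
    """Hand-evaluated 5-variant brute-force example."""
    p_target = np.array([0.001, 0.02, 0.5, 0.9, 0.04])
    p_aux = np.array([0.01, 0.02, 0.03, 0.5, 0.9])
    expected = np.array([0.001, 0.02, 0.5, 0.9, 0.04 * 5 / 3])
    return p_target, p_aux, expected


def write_sumstats_file(path, rows, header="SNP\tCHR\tBP\tP"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def scaled_sim_config(n_blocks, block_size, seed, **kw):
    """Scaled-down simulation preserving the default per-causal non-centrality.

    Shrinking the variant count while keeping h2 fixed concentrates the same
    heritability in far fewer causals, inflating per-variant signal ~30x past
    the default study conditions; instead h2 is rescaled so that
    h2 * n / m_causal matches the default configuration.
    """
    from pleiocfdr.simulate import SimulationConfig

    ref = SimulationConfig()
    m_ref = (ref.pi_shared + ref.pi_target_only) * ref.n_variants
    ncp_t = ref.h2_target * ref.n_target / m_ref
    m_ref_a = (ref.pi_shared + ref.pi_aux_only) * ref.n_variants
    ncp_a = ref.h2_aux * ref.n_aux / m_ref_a
    pi_shared = kw.get("pi_shared", ref.pi_shared)
    pi_t = kw.get("pi_target_only", ref.pi_target_only)
    pi_a = kw.get("pi_aux_only", ref.pi_aux_only)
    m = n_blocks * block_size
    kw.setdefault("h2_target", min(0.99, ncp_t * max((pi_shared + pi_t) * m, 1) / ref.n_target))
    kw.setdefault("h2_aux", min(0.99, ncp_a * max((pi_shared + pi_a) * m, 1) / ref.n_aux))
    return SimulationConfig(n_blocks=n_blocks, block_size=block_size, seed=seed, **kw)
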