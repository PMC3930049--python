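import numpy as np
import pytest

from mhcpop import amplicon, simulate


@pytest.fixture(scope="session")
def default_run():
    """One default-condition synthetic run pushed through the full variant
    filter, shared across tests (seed 0 throughout)."""
    cfg = simulate.SimConfig(seed=0)
    alleles = simulate.simulate_allele_pool(cfg)
    pools = simulate.assign_pool_alleles(cfg, alleles)
    tags = simulate.default_tag_map(cfg)
    reads, truth = simulate.simulate_pool_reads(cfg, pools, alleles, tags)
    specs = [
        amplicon.PoolSpec(p, tags[p], simulate._FWD_PRIMER, simulate._REV_PRIMER)
        for p in cfg.pop_labels
    ]
    result = amplicon.run_filter(reads, specs, alleles["A001"])
    return {
        "cfg": cfg,
        "alleles": alleles,
        "pools": pools,
        "tags": tags,
        "reads": reads,
        "truth": truth,
        "specs": specs,
        "result": result,
    }


@pytest.fixture()
def toy_alignment():
    """Build a small in-frame codon alignment from ungapped or gapped rows."""

    def build(rows, n_codons=None):
        n = n_codons or len(rows[0]) // 3
        return amplicon.CodonAlignment(
            [f"V{i}" for i in range(len(rows))], list(rows), n
        )

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
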