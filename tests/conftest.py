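import numpy as np
import pytest

from ectocage import Chain, ChainSet, CtssLibrary, CtssRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_chain():
    """One chain mapping chrA:[0,1000) onto chrB:[0,1000) unchanged."""
    return ChainSet([Chain(
        score=100, source_name="chrA", source_size=1000,
        source_start=0, source_end=1000,
        target_name="chrB", target_size=1000, target_strand="+",
        target_start=0, target_end=1000, chain_id="1",
        blocks=[(1000, 0, 0)],
    )])


@pytest.fixture
def random_library(rng):
    """1000 random CTSS records on two chromosomes and both strands."""
    recs = [
        CtssRecord(
            chrom=rng.choice(["chr1", "chr2"]),
            pos=int(rng.integers(0, 5000)),
            strand=rng.choice(["+", "-"]),
            count=int(rng.integers(1, 50)),
        )
        for _ in range(1000)
    ]
    return CtssLibrary("rand", recs)


def random_chain_set(rng, n_chains=5, max_blocks=8) -> ChainSet:
    """Random well-formed chains on one source chromosome.

    Chains sit on disjoint source ranges; strands, gaps and scores vary.
    """
    chains = []
    cursor = 0
    tgt_cursor = 0
    target_size = 500_000
    for ci in range(n_chains):
        cursor += int(rng.integers(50, 500))
        blocks = []
        n_blocks = int(rng.integers(1, max_blocks + 1))
        for bi in range(n_blocks):
            size = int(rng.integers(1, 200))
            if bi == n_blocks - 1:
                blocks.append((size, 0, 0))
            else:
                blocks.append((size, int(rng.integers(0, 60)),
                               int(rng.integers(0, 60))))
        t_span = sum(s + dt for s, dt, _ in blocks)
        q_span = sum(s + dq for s, _, dq in blocks)
        tgt_cursor += int(rng.integers(50, 500))
        strand = "+" if rng.random() < 0.5 else "-"
        chains.append(Chain(
            score=int(rng.integers(1, 10_000)),
            source_name="chrA", source_size=1_000_000,
            source_start=cursor, source_end=cursor + t_span,
            target_name="chrB", target_size=target_size,
            target_strand=strand,
            target_start=tgt_cursor, target_end=tgt_cursor + q_span,
            chain_id=str(ci + 1),
            blocks=blocks,
        ))
        cursor += t_span
        tgt_cursor += q_span
    return ChainSet(chains)
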