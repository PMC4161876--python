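"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate, at desk scale, the data the screen runs on in the
field: a source genome carrying annotated receptor loci with known TSSs, a
target genome reachable through an alignment chain file (with indel gaps,
strand flips, a configurable unmapped subset and deliberately colliding
lifts), per-library CAGE tag tables with planted sharp and broad promoters
over expressed loci plus pseudogene decoys accumulating spurious tags,
qPCR Ct tables with reference genes and calibrator samples, and two-channel
ratiometric calcium traces with a configurable responder fraction.

Everything is deterministic under a fixed seed, and every generated file
parses cleanly through the formats_io readers.  The accompanying truth
tables record, per entity, what was planted, so recovery can be scored
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import (
    Chain,
    ChainSet,
    CtssLibrary,
    CtssRecord,
    GenomicInterval,
    LocusAnnotation,
)
from .parsimony_phylo import Msa, Tree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults are the conditions the screen is exercised under: three
    planted collision pairs, five pseudogene decoys, promoter spread of
    about one hundred bases for broad promoters, calcium responder
    amplitudes of 80.5 +/- 26 % dR/R0, and a responder fraction of 11/37.
    """

    seed: int = 0
    # genomes / screen
    n_receptors: int = 20
    n_pseudogenes: int = 5
    n_libraries: int = 3
    depth_per_library: int = 1_000_000
    sharp_fraction: float = 0.5
    broad_width: int = 100            # bp of dispersed initiation
    background_rate: float = 0.005    # tags per bp per library over annotated space
    collision_pairs: int = 3
    n_unmapped: int = 2
    expressed_fraction: float = 0.6
    expression_tpm: float = 400.0     # planted TPM per expressed receptor
    decoy_tpm: float = 400.0          # spurious pile-up on pseudogene decoys
    decoy_library_fraction: float = 1.0
    window_width: int = 200
    locus_length: int = 2_000
    # qPCR
    planted_folds: tuple = (4.0, 1.0, 0.25)
    ct_noise_sd: float = 0.2
    n_ct_replicates: int = 3
    n_calibrators: int = 3
    n_test_samples: int = 3
    # calcium
    n_traces: int = 37
    responder_fraction: float = 11 / 37
    response_mean: float = 80.5       # % dR/R0
    response_sd: float = 26.0
    trace_duration: float = 300.0     # s
    sampling_interval: float = 3.0    # s
    stimulus_window: tuple = (60.0, 90.0)
    channel_noise_sd: float = 8.0     # fluorescence units per channel

    def __post_init__(self) -> None:
        for name in ("n_receptors", "n_pseudogenes", "n_libraries",
                     "depth_per_library", "collision_pairs", "n_unmapped",
                     "n_traces"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("sharp_fraction", "expressed_fraction",
                     "responder_fraction", "decoy_library_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.window_width % 2 or self.window_width < 2:
            raise ValueError("window_width must be even and >= 2")


@dataclass
class Entity:
    """One simulated locus: a receptor or a pseudogene decoy."""

    entity_id: str
    kind: str                 # receptor | pseudogene
    source_tss: int
    source_locus: GenomicInterval
    target_tss: int | None
    target_locus: GenomicInterval | None
    target_strand: str
    unmapped: bool = False
    collision_partner: str | None = None
    collision_discard: bool = False
    expressed: bool = False
    shape: str | None = None  # sharp | broad
    decoy: bool = False


@dataclass
class TruthTable:
    """Planted ground truth for every simulated entity."""

    loci: pd.DataFrame = field(default_factory=pd.DataFrame)
    expected_tags_per_library: dict = field(default_factory=dict)
    traces: pd.DataFrame = field(default_factory=pd.DataFrame)
    ct_folds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Genomes and chains
# ---------------------------------------------------------------------------

_SRC_CHROM = "chrS"
_TGT_CHROM = "chrT"
_SPACING_SRC = 10_000
_SPACING_TGT = 12_000
_FLANK = 3_000


def _entity_layout(config: SimulationConfig) -> list[Entity]:
    """Assign roles deterministically: unmapped first, collisions last."""
    n_r, n_p = config.n_receptors, config.n_pseudogenes
    need = config.n_unmapped + 2 * config.collision_pairs + 4
    if n_r < need:
        raise ValueError(
            f"infeasible geometry: need >= {need} receptors for "
            f"{config.n_unmapped} unmapped + {config.collision_pairs} "
            f"collision pairs + 4 plain windows, got {n_r}"
        )
    entities: list[Entity] = []
    for i in range(n_r + n_p):
        kind = "receptor" if i < n_r else "pseudogene"
        prefix = "R" if kind == "receptor" else "P"
        idx = i if kind == "receptor" else i - n_r
        s0 = 5_000 + i * _SPACING_SRC
        src = GenomicInterval(_SRC_CHROM, s0, s0 + config.locus_length, "+")
        entities.append(Entity(
            entity_id=f"{prefix}{idx:03d}", kind=kind,
            source_tss=s0, source_locus=src,
            target_tss=None, target_locus=None,
            target_strand="-" if i % 3 == 2 else "+",
            decoy=(kind == "pseudogene"),
        ))
    for j in range(config.n_unmapped):
        entities[j].unmapped = True
    # collision pairs occupy the last receptors; second member is discarded
    for k in range(config.collision_pairs):
        a = entities[n_r - 2 * config.collision_pairs + 2 * k]
        b = entities[n_r - 2 * config.collision_pairs + 2 * k + 1]
        a.collision_partner, b.collision_partner = b.entity_id, a.entity_id
        b.collision_discard = True
    return entities


def _make_chain(entity_index: int, entity: Entity, config: SimulationConfig,
                target_region_start: int, target_size: int) -> Chain:
    """One chain per entity: three blocks with small indel gaps placed
    downstream of the TSS window so the window itself lifts contiguously."""
    src_start = entity.source_locus.start - _FLANK
    sizes_gaps = [(4_000, 20, 10), (2_000, 0, 30),
                  (config.locus_length + 2 * _FLANK - 6_000 - 20, 0, 0)]
    t_span = sum(s + dt for s, dt, _ in sizes_gaps)
    q_span = sum(s + dq for s, _, dq in sizes_gaps)
    strand = entity.target_strand
    t_start, t_end = target_region_start, target_region_start + q_span
    return Chain(
        score=1_000 + entity_index,
        source_name=_SRC_CHROM, source_size=2_000_000,
        source_start=src_start, source_end=src_start + t_span,
        target_name=_TGT_CHROM, target_size=target_size,
        target_strand=strand,
        target_start=t_start, target_end=t_end,
        chain_id=str(entity_index + 1),
        blocks=list(sizes_gaps),
    )


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[list[LocusAnnotation], list[LocusAnnotation], ChainSet, list[Entity]]:
    """Source and target annotations plus the chain set connecting them.

    Every source receptor locus reaches a designated homolog region on the
    target through its own chain, except the configured unmapped subset;
    exactly `collision_pairs` pairs of source TSS windows lift to identical
    target coordinates; pseudogene entities map onto target loci marked
    biotype=pseudogene.
    """
    entities = _entity_layout(config)
    target_size = 5_000 + (len(entities) + 2) * _SPACING_TGT
    chains: list[Chain] = []
    for i, e in enumerate(entities):
        if e.unmapped:
            continue
        if e.collision_discard:
            # reuse the partner's target region: identical lifted coordinates
            partner = next(x for x in entities if x.entity_id == e.collision_partner)
            region_start = 5_000 + entities.index(partner) * _SPACING_TGT
            e.target_strand = partner.target_strand
        else:
            region_start = 5_000 + i * _SPACING_TGT
        chains.append(_make_chain(i, e, config, region_start, target_size))
        chain = chains[-1]
        mapped = chain.map_position(e.source_tss)
        assert mapped is not None, "source TSS must fall inside an aligned block"
        _, t_tss, t_strand = mapped
        e.target_tss = t_tss
        L = config.locus_length
        if t_strand == "+":
            iv = GenomicInterval(_TGT_CHROM, t_tss, t_tss + L, "+")
        else:
            iv = GenomicInterval(_TGT_CHROM, t_tss - L + 1, t_tss + 1, "-")
        e.target_locus = iv

    # one target locus per non-discarded mapped entity (discarded collision
    # members share their partner's locus)
    target_ann = [
        LocusAnnotation(e.entity_id, e.target_locus, e.target_tss,
                        "pseudogene" if e.decoy else "gene")
        for e in entities
        if e.target_locus is not None and not e.collision_discard
    ]
    # geometry check: target loci must not overlap
    ivs = sorted(target_ann, key=lambda l: l.interval.start)
    for a, b in zip(ivs, ivs[1:]):
        if a.interval.overlaps(b.interval):
            raise ValueError(
                f"infeasible geometry: target loci {a.locus_id} and "
                f"{b.locus_id} overlap"
            )
    source_ann = [
        LocusAnnotation(e.entity_id, e.source_locus, e.source_tss, "gene")
        for e in entities
    ]
    return source_ann, target_ann, ChainSet(chains), entities


# ---------------------------------------------------------------------------
# CAGE libraries
# ---------------------------------------------------------------------------

def _assign_expression(entities: list[Entity], config: SimulationConfig,
                       rng: np.random.Generator) -> None:
    eligible = [
        e for e in entities
        if e.kind == "receptor" and not e.unmapped
        and e.collision_partner is None
    ]
    n_expr = round(config.expressed_fraction * len(eligible))
    order = rng.permutation(len(eligible))
    chosen = [eligible[i] for i in order[:n_expr]]
    n_sharp = round(config.sharp_fraction * len(chosen))
    for j, e in enumerate(chosen):
        e.expressed = True
        e.shape = "sharp" if j < n_sharp else "broad"


def simulate_ctss(
    config: SimulationConfig,
    entities: list[Entity],
    rng: np.random.Generator,
) -> tuple[list[CtssLibrary], TruthTable]:
    """Per-library CAGE tag tables over the target genome.

    Expressed sharp receptors put >= 90% of locus tags at the planted TSS;
    broad receptors spread tags over `broad_width` bp around it; every
    annotated base receives Poisson-rate background; pseudogene decoys get
    a localised spurious pile-up in a subset of libraries.  Library depth
    is exact: one multinomial draw of `depth_per_library` tags per library
    over all tag-emitting positions (a distant bulk-transcription block
    absorbs the non-receptor mass of the library).
    """
    if config.depth_per_library == 0 and any(e.expressed for e in entities):
        raise ValueError("depth 0 with nonzero expression request")

    expected_tags = config.expression_tpm / 1e6 * config.depth_per_library
    decoy_tags = config.decoy_tpm / 1e6 * config.depth_per_library
    n_decoy_libs = math.ceil(config.decoy_library_fraction * config.n_libraries)

    positions: list[tuple[int, str]] = []   # (pos, strand)
    weights_base: list[float] = []
    per_entity_slices: dict[str, slice] = {}

    def add_entity_positions(e: Entity) -> None:
        start = len(positions)
        strand = e.target_locus.strand
        tss = e.target_tss
        sense = 1 if strand == "+" else -1
        if e.shape == "sharp":
            # dominant TSS plus a minor downstream shoulder, kept inside the locus
            spread = [tss + sense * k for k in range(1, 11)]
            positions.append((tss, strand))
            weights_base.append(0.95)
            for p in spread:
                positions.append((p, strand))
                weights_base.append(0.05 / len(spread))
        else:  # broad: uniform initiation over broad_width from the TSS inward
            span = [tss + sense * k for k in range(config.broad_width)]
            for p in span:
                positions.append((p, strand))
                weights_base.append(1.0 / config.broad_width)
        per_entity_slices[e.entity_id] = slice(start, len(positions))

    expressed = [e for e in entities if e.expressed and e.target_locus is not None]
    decoys = [e for e in entities if e.decoy and e.target_locus is not None]
    for e in expressed:
        add_entity_positions(e)
    decoy_slices: dict[str, slice] = {}
    for e in decoys:
        start = len(positions)
        strand = e.target_locus.strand
        # localised pile-up: 30 bp of dispersed spurious starts at the decoy TSS
        for p in range(e.target_tss - 15, e.target_tss + 15):
            positions.append((p, strand))
            weights_base.append(1.0 / 30)
        decoy_slices[e.entity_id] = slice(start, len(positions))

    # background over annotated target space only
    bg_slices: list[tuple[slice, float]] = []
    for e in entities:
        if e.target_locus is None or e.collision_discard:
            continue
        start = len(positions)
        iv = e.target_locus
        for p in range(iv.start, iv.end):
            positions.append((p, iv.strand))
        bg_slices.append((slice(start, len(positions)), config.background_rate))

    # distant bulk-transcription block soaking up the rest of each library
    bulk_start = len(positions)
    bulk_origin = 5_000 + (len(entities) + 1) * _SPACING_TGT
    for p in range(bulk_origin, bulk_origin + 50):
        positions.append((p, "+"))

    pos_arr = np.array([p for p, _ in positions], dtype=np.int64)
    strand_arr = np.array([s for _, s in positions])

    libraries: list[CtssLibrary] = []
    expected: dict[str, dict[str, float]] = {}
    for li in range(config.n_libraries):
        lib_id = f"LIB{li:02d}"
        w = np.zeros(len(positions))
        for e in expressed:
            sl = per_entity_slices[e.entity_id]
            w[sl] = expected_tags * np.asarray(weights_base[sl])
        for e in decoys:
            if li < n_decoy_libs:
                sl = decoy_slices[e.entity_id]
                w[sl] = decoy_tags * np.asarray(weights_base[sl])
        for sl, rate in bg_slices:
            w[sl] = rate
        allocated = w.sum()
        if allocated > config.depth_per_library:
            raise ValueError(
                "planted expression exceeds library depth; raise "
                "depth_per_library or lower expression_tpm"
            )
        w[bulk_start:] = (config.depth_per_library - allocated) / (
            len(positions) - bulk_start
        )
        p = w / w.sum()
        counts = rng.multinomial(config.depth_per_library, p)
        nz = counts > 0
        # merge duplicate (pos, strand) positions if any
        df = pd.DataFrame({
            "pos": pos_arr[nz], "strand": strand_arr[nz], "count": counts[nz],
        })
        df = df.groupby(["pos", "strand"], as_index=False)["count"].sum()
        recs = [
            CtssRecord(_TGT_CHROM, int(r.pos), str(r.strand), int(r.count))
            for r in df.itertuples(index=False)
        ]
        libraries.append(CtssLibrary(lib_id, recs))
        expected[lib_id] = {
            e.entity_id: expected_tags for e in expressed
        }
        if li < n_decoy_libs:
            expected[lib_id].update({e.entity_id: decoy_tags for e in decoys})

    truth = TruthTable(
        loci=pd.DataFrame([{
            "entity_id": e.entity_id,
            "kind": e.kind,
            "source_tss": e.source_tss,
            "target_tss": e.target_tss if e.target_tss is not None else -1,
            "unmapped": e.unmapped,
            "collision_partner": e.collision_partner or "",
            "collision_discard": e.collision_discard,
            "expressed": e.expressed,
            "shape": e.shape or "",
            "decoy": e.decoy,
            "expected_tpm": (
                config.expression_tpm if e.expressed
                else (config.decoy_tpm if e.decoy else 0.0)
            ),
        } for e in entities]),
        expected_tags_per_library=expected,
    )
    return libraries, truth


def simulate_screen_inputs(config: SimulationConfig):
    """Convenience: genomes + chains + expression + libraries + truth."""
    rng = np.random.default_rng(config.seed)
    source_ann, target_ann, chains, entities = simulate_genomes(config)
    _assign_expression(entities, config, rng)
    libraries, truth = simulate_ctss(config, entities, rng)
    return source_ann, target_ann, chains, entities, libraries, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def simulate_ct_table(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[str], list[str], dict[str, float]]:
    """Ct table with reference genes, calibrators and planted fold changes.

    Returns (long-format table, reference gene names, calibrator sample
    names, {target gene: planted fold}).  Reference genes sit at Ct ~ 20;
    target genes carry a baseline dCt of 5 in calibrators and a dCt shifted
    by -log2(fold) in test samples.  Gaussian cycle noise of `ct_noise_sd`
    is added to every well.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    refs = ["REF1", "REF2", "REF3"]
    targets = {f"TGT{i}": f for i, f in enumerate(config.planted_folds)}
    calibrators = [f"CAL{i}" for i in range(config.n_calibrators)]
    tests = [f"TEST{i}" for i in range(config.n_test_samples)]
    base_dct = 5.0
    rows = []
    for sample in calibrators + tests:
        for rep in range(config.n_ct_replicates):
            for g in refs:
                rows.append((sample, g, rep, 20.0 + rng.normal(0, config.ct_noise_sd)))
            for g, fold in targets.items():
                dct = base_dct - (math.log2(fold) if sample in tests else 0.0)
                rows.append((sample, g, rep,
                             20.0 + dct + rng.normal(0, config.ct_noise_sd)))
    df = pd.DataFrame(rows, columns=["sample", "gene", "replicate", "ct"])
    return df, refs, calibrators, targets


# ---------------------------------------------------------------------------
# Calcium traces
# ---------------------------------------------------------------------------

def simulate_calcium(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-channel fura-2 traces with a planted responder subset.

    Responder amplitudes are drawn Normal(response_mean, response_sd) % and
    floored at 30% so planted responders stay separable from channel noise;
    onsets fall within the first 9 s of the stimulus window and responses
    last 60-120 s.  Gaussian noise is applied to each channel before
    ratioing, so ratio artifacts emerge the way they do in real recordings.

    Returns (traces long-format table, truth table with responder flags).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = np.arange(0.0, config.trace_duration + 1e-9, config.sampling_interval)
    t_on, t_off = config.stimulus_window
    n_resp = round(config.responder_fraction * config.n_traces)
    responder_idx = set(rng.permutation(config.n_traces)[:n_resp].tolist())

    f340_base, f380_base = 800.0, 1000.0
    rows, truth_rows = [], []
    for i in range(config.n_traces):
        trace_id = f"T{i:03d}"
        is_resp = i in responder_idx
        g = np.zeros_like(t)
        amp = onset = dur = 0.0
        if is_resp:
            amp = max(float(rng.normal(config.response_mean, config.response_sd)), 30.0)
            onset = float(t_on + rng.uniform(0.0, 9.0))
            dur = float(rng.uniform(60.0, 120.0))
            rise, fall = 6.0, 15.0
            g = np.clip((t - onset) / rise, 0.0, 1.0) * np.clip(
                1.0 - (t - onset - dur) / fall, 0.0, 1.0
            )
        f340 = f340_base * (1.0 + amp / 100.0 * g)
        f340 = f340 + rng.normal(0, config.channel_noise_sd, size=t.shape)
        f380 = f380_base + rng.normal(0, config.channel_noise_sd, size=t.shape)
        f380 = np.maximum(f380, 1.0)
        for ti, a, b in zip(t, f340, f380):
            rows.append((trace_id, float(ti), float(a), float(b)))
        truth_rows.append({
            "trace_id": trace_id, "responder": is_resp,
            "amplitude": amp, "onset": onset, "duration": dur,
        })
    traces = pd.DataFrame(rows, columns=["trace_id", "time", "f340", "f380"])
    truth = pd.DataFrame(truth_rows)
    return traces, truth


# ---------------------------------------------------------------------------
# Protein families for the parsimony stage
# ---------------------------------------------------------------------------

def simulate_protein_family(
    n_taxa: int,
    n_columns: int,
    seed: int,
    substitution_prob: float = 0.05,
) -> tuple[Msa, Tree]:
    """Evolve a protein alignment on a random tree; returns (Msa, true tree).

    A random unrooted binary topology is grown by seeded stepwise addition;
    each column starts from a uniform random residue at an arbitrary root
    and mutates with probability `substitution_prob` per edge.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    labels = [f"T{i}" for i in range(n_taxa)]
    tree = Tree.star3(labels[0], labels[1], labels[2])
    for label in labels[3:]:
        edges = tree.edges()
        tree = tree.insert_leaf(edges[rng.integers(len(edges))], label)

    aa = np.array(list(AMINO_ACIDS))
    # root at an internal node and evolve down every edge
    internal = [n for n in tree.adj if n not in tree.labels]
    root = internal[0]
    seqs: dict[int, np.ndarray] = {
        root: rng.integers(0, len(aa), size=n_columns)
    }
    stack = [(root, None)]
    while stack:
        node, parent = stack.pop()
        for nb in tree.adj[node]:
            if nb == parent:
                continue
            s = seqs[node].copy()
            mut = rng.random(n_columns) < substitution_prob
            s[mut] = rng.integers(0, len(aa), size=int(mut.sum()))
            seqs[nb] = s
            stack.append((nb, node))
    rows = ["".join(aa[seqs[n]]) for n in sorted(tree.labels)]
    names = [tree.labels[n] for n in sorted(tree.labels)]
    msa = Msa(names, rows)
    return msa, tree
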