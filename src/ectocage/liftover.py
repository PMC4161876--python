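"""Cross-genome projection of TSS windows through alignment chains.

Implements the window lift used by the ectopic-expression screen: fixed-width
windows centred on source-genome transcription start sites are mapped to the
target genome through UCSC-style chains, and windows whose lifted coordinates
collide are deduplicated by keeping the first window in input order.

Mapping uses the single highest-scoring chain overlapping the window; the
lifted interval is the hull of the mapped bases on the target.  Failure modes
are statuses, never exceptions: `unmapped` (no base maps), `low_coverage`
(mapped fraction below `min_match`), `split` (mapped bases land in
non-contiguous target runs with more internal gap than the window's unmapped
allowance).
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import Chain, ChainSet, GenomicInterval

MIN_MATCH_DEFAULT = 0.95  # conventional liftOver remap threshold


@dataclass(frozen=True)
class TssWindow:
    receptor_id: str
    interval: GenomicInterval
    tss: int


@dataclass(frozen=True)
class LiftResult:
    source: GenomicInterval
    status: str  # mapped | unmapped | split | low_coverage
    target: GenomicInterval | None = None
    chain_id: str | None = None
    mapped_fraction: float = 0.0
    receptor_id: str | None = None


def build_tss_windows(
    tss_list: list[tuple[str, str, int, str]], width: int = 200
) -> list[TssWindow]:
    """Build one window of `width` bp per TSS, centred on it, clipped at 0.

    `tss_list` holds (receptor_id, chrom, tss_position, strand) in a defined
    input order; ids are carried onto the windows for collision reporting.
    """
    if width < 2 or width % 2 != 0:
        raise ValueError(f"window width must be even and >= 2, got {width}")
    half = width // 2
    windows = []
    for receptor_id, chrom, tss, strand in tss_list:
        start = max(0, tss - half)
        end = tss + half
        windows.append(TssWindow(receptor_id, GenomicInterval(chrom, start, end, strand), tss))
    return windows


def _map_through_chain(
    interval: GenomicInterval, chain: Chain
) -> tuple[int, int | None, int | None]:
    """Map the interval block-wise through one chain.

    Returns (n_mapped_bases, min_target_pos, max_target_pos) with target
    positions on the plus strand.  Block-offset arithmetic only — the
    per-base check lives in the test oracle.
    """
    n_mapped = 0
    t_min: int | None = None
    t_max: int | None = None
    for bs, be, t0 in chain.aligned_blocks():
        lo = max(interval.start, bs)
        hi = min(interval.end, be)
        if lo >= hi:
            continue
        n_mapped += hi - lo
        ts = t0 + (lo - bs)
        te = t0 + (hi - bs) - 1  # inclusive, target-strand coords
        if chain.target_strand == "+":
            lo_t, hi_t = ts, te
        else:
            lo_t = chain.target_size - 1 - te
            hi_t = chain.target_size - 1 - ts
        t_min = lo_t if t_min is None else min(t_min, lo_t)
        t_max = hi_t if t_max is None else max(t_max, hi_t)
    return n_mapped, t_min, t_max


def lift_interval(
    interval: GenomicInterval,
    chains: ChainSet,
    min_match: float = MIN_MATCH_DEFAULT,
) -> LiftResult:
    """Lift one interval through the best overlapping chain.

    The target interval is the hull [min, max] of mapped bases on one target
    chromosome and strand.  Internal unmapped gap inside the hull is
    tolerated up to the window's unmapped allowance, `(1 - min_match) *
    len(interval)`; beyond that the lift is reported as `split`.
    """
    overlapping = chains.overlapping(interval)
    if not overlapping:
        return LiftResult(interval, "unmapped")
    best = max(overlapping, key=lambda c: (c.score, c.chain_id))
    n_mapped, t_min, t_max = _map_through_chain(interval, best)
    if n_mapped == 0:
        return LiftResult(interval, "unmapped")
    frac = n_mapped / len(interval)
    assert t_min is not None and t_max is not None
    hull_len = t_max - t_min + 1
    allowance = (1.0 - min_match) * len(interval)
    target = GenomicInterval(
        best.target_name,
        t_min,
        t_max + 1,
        "+" if best.target_strand == "+" else "-",
    )
    if hull_len - n_mapped > allowance:
        return LiftResult(interval, "split", target, best.chain_id, frac)
    if frac < min_match:
        return LiftResult(interval, "low_coverage", target, best.chain_id, frac)
    return LiftResult(interval, "mapped", target, best.chain_id, frac)


def lift_windows_dedup(
    windows: list[TssWindow],
    chains: ChainSet,
    min_match: float = MIN_MATCH_DEFAULT,
    keep_split: bool = False,
) -> tuple[list[LiftResult], list[str]]:
    """Lift all windows, then discard later members of coordinate collisions.

    Among windows whose lifted target coordinates are exactly identical
    (chrom, start, end, strand), the first in input order is kept and every
    subsequent one is discarded and its receptor id reported.
    """
    results: list[LiftResult] = []
    for w in windows:
        r = lift_interval(w.interval, chains, min_match)
        if r.status == "split" and keep_split:
            r = LiftResult(r.source, "mapped", r.target, r.chain_id, r.mapped_fraction, w.receptor_id)
        else:
            r = LiftResult(r.source, r.status, r.target, r.chain_id, r.mapped_fraction, w.receptor_id)
        results.append(r)

    seen: dict[tuple[str, int, int, str], str] = {}
    discarded: list[str] = []
    kept: list[LiftResult] = []
    for r in results:
        if r.status != "mapped" or r.target is None:
            kept.append(r)
            continue
        key = (r.target.chrom, r.target.start, r.target.end, r.target.strand)
        if key in seen:
            discarded.append(r.receptor_id or "?")
        else:
            seen[key] = r.receptor_id or "?"
            kept.append(r)
    return kept, discarded
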