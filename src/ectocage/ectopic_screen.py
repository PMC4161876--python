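"""The candidate-screening cascade for ectopic receptor expression.

Lifted promoter windows are scored by pooled CAGE tag counts across a
chosen library subset, then passed through two filters — more tags than
the third quartile of all windows in the screen, and more tags than an
absolute cutoff (default 100) — before artifact flagging and TSS-position
classification against the target annotation.

Both filters are strict ("more tags than"), and both flags are always
reported; the verdict `candidate` requires passing the absolute cutoff.
Windows whose dominant TSS sits more than 5 kb upstream of the annotated
gene are set aside as `discarded_far_upstream`; windows overlapping no
receptor locus (or only pseudogene loci, when pseudogenes count as
artifactual) are `artifact`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cage_quant import count_tags_starting_in, promoter_profile, tpm
from .formats_io import CtssLibrary, GenomicInterval, LocusAnnotation
from .liftover import LiftResult

ABS_CUTOFF_DEFAULT = 100  # tags; the screen's arbitrary absolute cutoff
AT_START_TOL_DEFAULT = 50        # bp around the annotated start
UPSTREAM_PROXIMAL_RANGE = (500, 2000)   # bp upstream of the annotated start
FAR_UPSTREAM_DISCARD = 5000      # bp; beyond this the window is not pursued
THREE_PRIME_TOL_DEFAULT = 500    # bp around the locus 3' end


def pool_counts(counts_per_library: dict[str, int], library_subset: list[str]) -> int:
    """Sum window counts over the selected libraries."""
    if not library_subset:
        raise ValueError("library_subset must be non-empty")
    missing = [l for l in library_subset if l not in counts_per_library]
    if missing:
        raise KeyError(f"libraries missing from counts: {missing}")
    return int(sum(counts_per_library[l] for l in library_subset))


def quartile_filter(
    pooled_counts: np.ndarray | list[int], method: str = "linear"
) -> tuple[float, np.ndarray]:
    """Q3 over ALL windows in the screen; flag = strictly more tags than Q3."""
    counts = np.asarray(pooled_counts, dtype=float)
    if counts.size < 4:
        raise ValueError(f"quartile filter needs >= 4 windows, got {counts.size}")
    if method == "linear":
        q3 = float(np.percentile(counts, 75))
    elif method == "nearest-rank":
        q3 = float(np.percentile(counts, 75, method="inverted_cdf"))
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    return q3, counts > q3


def absolute_cutoff_filter(
    pooled_counts: np.ndarray | list[int], abs_cutoff: int = ABS_CUTOFF_DEFAULT
) -> np.ndarray:
    """Strictly more tags than the absolute cutoff."""
    if abs_cutoff < 0:
        raise ValueError("abs_cutoff must be >= 0")
    return np.asarray(pooled_counts) > abs_cutoff


def flag_artifacts(
    target_windows: list[GenomicInterval | None],
    annotation: list[LocusAnnotation],
    pseudogene_is_artifact: bool = True,
) -> list[bool]:
    """Artifact iff a window overlaps no receptor gene locus.

    A window overlapping only pseudogene loci counts as an artifact when
    `pseudogene_is_artifact` is set (mechanising the screen's manual
    inspection, which found spurious tag accumulation near pseudogenes).
    """
    flags = []
    for w in target_windows:
        if w is None:
            flags.append(False)
            continue
        overlapping = [l for l in annotation if l.interval.overlaps(
            GenomicInterval(w.chrom, w.start, w.end, l.interval.strand))]
        if not overlapping:
            flags.append(True)
        elif pseudogene_is_artifact and all(
            l.biotype == "pseudogene" for l in overlapping
        ):
            flags.append(True)
        else:
            flags.append(False)
    return flags


def classify_tss_position(
    dominant_tss: int,
    locus: LocusAnnotation,
    at_start_tol: int = AT_START_TOL_DEFAULT,
    three_prime_tol: int = THREE_PRIME_TOL_DEFAULT,
) -> str:
    """Place a dominant TSS relative to its annotated locus.

    The signed distance d = annotated start - TSS, measured in transcription
    orientation (positive = upstream of the gene).  Classes, checked in
    order: at the annotated start (|d| <= tol), upstream proximal
    (500 <= d <= 2000), far upstream discard (d > 5000), inside the gene
    body, near the 3' end, else unclassified.
    """
    iv = locus.interval
    if iv.strand == "+":
        d = iv.start - dominant_tss
        three_prime = iv.end - 1
    else:
        d = dominant_tss - (iv.end - 1)
        three_prime = iv.start
    lo, hi = UPSTREAM_PROXIMAL_RANGE
    if abs(d) <= at_start_tol:
        return "at_annotated_start"
    if lo <= d <= hi:
        return "upstream_proximal"
    if d > FAR_UPSTREAM_DISCARD:
        return "upstream_far_discard"
    if iv.start < dominant_tss < iv.end - 1:
        return "intragenic"
    if abs(dominant_tss - three_prime) <= three_prime_tol:
        return "three_prime_end"
    return "unclassified"


@dataclass
class ScreenConfig:
    library_subset: list[str]                 # pooling is over an explicit subset
    abs_cutoff: int = ABS_CUTOFF_DEFAULT
    pseudogene_is_artifact: bool = True
    percentile_method: str = "linear"
    at_start_tol: int = AT_START_TOL_DEFAULT
    three_prime_tol: int = THREE_PRIME_TOL_DEFAULT
    metadata: dict = field(default_factory=dict)


def run_screen(
    lift_results: list[LiftResult],
    libraries: list[CtssLibrary],
    annotation: list[LocusAnnotation],
    config: ScreenConfig,
) -> tuple[pd.DataFrame, dict]:
    """Run the full cascade; returns (candidate table, run metadata).

    Verdict precedence: discarded_far_upstream, then artifact, then
    filtered (below the absolute cutoff), then candidate.  The table is
    ordered by receptor id and fully determined by inputs and config.
    """
    lib_by_id = {l.library_id: l for l in libraries}
    unknown = [l for l in config.library_subset if l not in lib_by_id]
    if not config.library_subset:
        raise ValueError("library_subset must be non-empty")
    if unknown:
        raise KeyError(f"unknown libraries in subset: {unknown}")

    mapped = [r for r in lift_results if r.status == "mapped" and r.target is not None]
    rows = []
    pooled_all = []
    for r in mapped:
        per_lib = {
            lid: count_tags_starting_in(lib_by_id[lid], r.target)
            for lid in config.library_subset
        }
        pooled = pool_counts(per_lib, config.library_subset)
        pooled_all.append(pooled)
        rows.append((r, per_lib, pooled))

    if len(pooled_all) >= 4:
        q3, q3_flags = quartile_filter(pooled_all, config.percentile_method)
    else:
        q3, q3_flags = float("nan"), np.zeros(len(pooled_all), dtype=bool)
    abs_flags = absolute_cutoff_filter(pooled_all, config.abs_cutoff)
    artifact_flags = flag_artifacts(
        [r.target for r, _, _ in rows], annotation, config.pseudogene_is_artifact
    )

    pooled_total = sum(lib_by_id[lid].total_tags for lid in config.library_subset)
    records = []
    for (r, per_lib, pooled), q3f, absf, art in zip(
        rows, q3_flags, abs_flags, artifact_flags
    ):
        # dominant TSS within the lifted window, pooled over the subset
        merged_counts: dict[int, int] = {}
        for lid in config.library_subset:
            prof = promoter_profile(
                lib_by_id[lid], r.receptor_id or "?", r.target, strand_aware=False,
            )
            for p, c in zip(prof.positions, prof.counts):
                merged_counts[int(p)] = merged_counts.get(int(p), 0) + int(c)
        if merged_counts:
            dom = max(sorted(merged_counts), key=lambda p: (merged_counts[p], -p))
        else:
            dom = None

        overlapping = [
            l for l in annotation
            if l.interval.chrom == r.target.chrom
            and l.interval.start < r.target.end
            and r.target.start < l.interval.end
        ]
        gene_loci = [l for l in overlapping if l.biotype == "gene"]
        ref_locus = gene_loci[0] if gene_loci else (overlapping[0] if overlapping else None)
        if dom is not None and ref_locus is not None:
            tss_class = classify_tss_position(
                dom, ref_locus, config.at_start_tol, config.three_prime_tol
            )
        else:
            tss_class = "unclassified"

        if tss_class == "upstream_far_discard":
            verdict = "discarded_far_upstream"
        elif art:
            verdict = "artifact"
        elif not absf:
            verdict = "filtered"
        else:
            verdict = "candidate"

        rec = {
            "receptor_id": r.receptor_id,
            "source_chrom": r.source.chrom,
            "source_start": r.source.start,
            "source_end": r.source.end,
            "lift_status": r.status,
            "target_chrom": r.target.chrom,
            "target_start": r.target.start,
            "target_end": r.target.end,
            "target_strand": r.target.strand,
            "pooled_count": pooled,
            "pooled_tpm": tpm(pooled, pooled_total) if pooled_total else float("nan"),
            "above_q3": bool(q3f),
            "above_abs_cutoff": bool(absf),
            "artifact": bool(art),
            "dominant_tss": dom if dom is not None else -1,
            "tss_position_class": tss_class,
            "verdict": verdict,
        }
        for lid in config.library_subset:
            rec[f"count_{lid}"] = per_lib[lid]
        records.append(rec)

    # unmapped / split / low-coverage windows still appear, verdict 'filtered'
    for r in lift_results:
        if r.status != "mapped" or r.target is None:
            records.append({
                "receptor_id": r.receptor_id,
                "source_chrom": r.source.chrom,
                "source_start": r.source.start,
                "source_end": r.source.end,
                "lift_status": r.status,
                "target_chrom": "", "target_start": -1, "target_end": -1,
                "target_strand": "",
                "pooled_count": 0, "pooled_tpm": 0.0,
                "above_q3": False, "above_abs_cutoff": False,
                "artifact": False, "dominant_tss": -1,
                "tss_position_class": "unclassified",
                "verdict": "filtered",
                **{f"count_{lid}": 0 for lid in config.library_subset},
            })

    table = pd.DataFrame.from_records(records)
    table = table.sort_values("receptor_id", kind="mergesort").reset_index(drop=True)
    meta = {
        "q3": q3,
        "abs_cutoff": config.abs_cutoff,
        "library_subset": list(config.library_subset),
        "pooled_total_tags": pooled_total,
        "n_windows": len(lift_results),
        "n_mapped": len(mapped),
        "n_above_q3": int(np.sum(q3_flags)) if len(pooled_all) else 0,
        "n_above_abs_cutoff": int(np.sum(abs_flags)) if len(pooled_all) else 0,
        "n_artifacts": int(np.sum(artifact_flags)) if len(pooled_all) else 0,
        "n_candidates": int((table["verdict"] == "candidate").sum()),
        "artifact_rule": "window overlaps no receptor gene locus"
        + ("; pseudogene-only overlap counts as artifact"
           if config.pseudogene_is_artifact else ""),
        "note": "artifact flagging mechanises what was a manual inspection step",
    }
    return table, meta
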