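"""qPCR relative quantification (double-delta-Ct) and reporter fold-increase.

A Ct value is the PCR cycle at which a gene's amplification signal crosses
threshold; lower Ct means more template.  dCt normalises a target gene to
the arithmetic mean Ct of the reference genes within the same sample
(equivalent to a geometric mean on the expression scale).  ddCt subtracts
the mean dCt of designated calibrator samples, and the fold change is
2^(-ddCt).  Technical replicates are collapsed by mean Ct before any
differencing.

`rescale_heatmap` divides a ddCt matrix by its maximum absolute entry so
the most extreme value maps to +/-1, the convention used for heat-map
display of normalised fold expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CtTable:
    """Long-format Ct measurements with designated references and calibrators."""

    data: pd.DataFrame  # columns: sample, gene, replicate, ct
    reference_genes: list[str]
    calibrator_samples: list[str]

    def __post_init__(self) -> None:
        needed = {"sample", "gene", "replicate", "ct"}
        if not needed.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(needed)}")
        if not self.reference_genes:
            raise ValueError("reference_genes must be non-empty")
        if not self.calibrator_samples:
            raise ValueError("calibrator_samples must be non-empty")
        genes = set(self.data["gene"])
        samples = set(self.data["sample"])
        missing_g = set(self.reference_genes) - genes
        missing_s = set(self.calibrator_samples) - samples
        if missing_g:
            raise ValueError(f"reference genes absent from table: {sorted(missing_g)}")
        if missing_s:
            raise ValueError(f"calibrator samples absent from table: {sorted(missing_s)}")
        ct = self.data["ct"]
        if not (np.isfinite(ct).all() and (ct > 0).all()):
            raise ValueError("Ct values must be finite and > 0")

    def mean_ct(self) -> pd.DataFrame:
        """Collapse technical replicates: sample x gene matrix of mean Ct."""
        return self.data.pivot_table(
            index="sample", columns="gene", values="ct", aggfunc="mean"
        )


def delta_ct(ct_target: float, ct_references) -> float:
    """dCt = Ct(target) - arithmetic mean Ct of the reference genes."""
    refs = np.asarray(ct_references, dtype=float).ravel()
    if refs.size == 0 or not np.isfinite(refs).all():
        raise ValueError("need at least one finite reference Ct")
    return float(ct_target - refs.mean())


def delta_delta_ct(dct_sample: float, dct_calibrators) -> float:
    """ddCt = sample dCt minus mean calibrator dCt."""
    cal = np.asarray(dct_calibrators, dtype=float).ravel()
    if cal.size == 0:
        raise ValueError("calibrator set must be non-empty")
    return float(dct_sample - cal.mean())


def fold_change(ddct: float) -> float:
    """Relative expression: 2 to the power of minus ddCt."""
    return float(2.0 ** (-ddct))


def rescale_heatmap(ddct_matrix) -> np.ndarray:
    """Divide by the maximum |ddCt| so the extreme entry maps to +/-1."""
    m = np.asarray(ddct_matrix, dtype=float)
    peak = np.max(np.abs(m))
    if peak == 0:
        raise ValueError("all-zero ddCt matrix cannot be rescaled")
    return m / peak


def fold_increase(signal: float, control_signal: float) -> float:
    """Reporter-assay response as fold over the control signal."""
    if control_signal <= 0:
        raise ValueError("control signal must be > 0")
    return float(signal / control_signal)


def relative_expression(table: CtTable) -> pd.DataFrame:
    """Full ddCt pipeline over a Ct table.

    Returns one row per (sample, target gene) with dCt, ddCt and fold
    change; reference genes are excluded from the target set.
    """
    mean_ct = table.mean_ct()
    refs = mean_ct[table.reference_genes].mean(axis=1)
    targets = [g for g in mean_ct.columns if g not in table.reference_genes]
    rows = []
    for gene in targets:
        dct = mean_ct[gene] - refs
        cal_mean = dct.loc[table.calibrator_samples].mean()
        for sample in mean_ct.index:
            ddct = float(dct.loc[sample] - cal_mean)
            rows.append({
                "sample": sample,
                "gene": gene,
                "delta_ct": float(dct.loc[sample]),
                "delta_delta_ct": ddct,
                "fold_change": fold_change(ddct),
            })
    return pd.DataFrame(rows)


def fold_increase_summary(signals, control_signals) -> dict[str, float]:
    """Per-replicate fold increases, reported as mean +/- SD.

    `signals` and `control_signals` are paired replicate measurements.
    """
    s = np.asarray(signals, dtype=float)
    c = np.asarray(control_signals, dtype=float)
    if s.shape != c.shape or s.size == 0:
        raise ValueError("paired non-empty replicate arrays required")
    folds = np.array([fold_increase(x, y) for x, y in zip(s, c)])
    return {
        "mean_fold": float(folds.mean()),
        "sd_fold": float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
        "n": int(folds.size),
    }
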