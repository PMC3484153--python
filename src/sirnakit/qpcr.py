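"""Knockdown quantification from qPCR cycle-threshold data.

Relative expression follows the comparative threshold-cycle method with
per-gene amplification efficiencies (the Pfaffl-style generalisation of
2^-ddCt): the target's efficiency raised to the calibrator-minus-sample
cycle difference, divided by the same ratio for a reference gene.  With
two reference genes the per-normalizer ratios are pooled by geometric
mean; replicates are averaged on the log2 scale, on which Ct noise is
additive.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Role(str, enum.Enum):
    TARGET = "TARGET"
    NORMALIZER = "NORMALIZER"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well: a (sample, gene, replicate) cycle-threshold reading.

    ``efficiency`` is the amplification rate per cycle in (1, 2],
    2.0 = perfect doubling."""

    run_id: str
    sample: str
    gene: str
    role: Role
    replicate: int
    ct: float
    efficiency: float = 2.0

    def __post_init__(self):
        if self.ct <= 0:
            raise ValueError(f"ct must be positive, got {self.ct}")
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(f"efficiency must lie in (1, 2], got {self.efficiency}")


@dataclass
class ExtinctionEstimate:
    """Relative expression ratio Q of a target after siRNA treatment and the
    derived knockdown percentage 100 x (1 - Q)."""

    sirna_id: str
    q: float
    knockdown_pct: float
    log2_sd: float
    n_reps: int
    normalizers: list[str] = field(default_factory=list)


def relative_quantity(
    ct_target_sample: float,
    ct_target_calibrator: float,
    e_target: float,
    ct_ref_sample: float,
    ct_ref_calibrator: float,
    e_ref: float,
) -> float:
    """Efficiency-corrected expression ratio.

    q = e_t^(Ct_t,cal - Ct_t,sample) / e_ref^(Ct_ref,cal - Ct_ref,sample);
    with both efficiencies equal to 2 this is exactly 2^-ddCt.
    """
    if e_target <= 1.0 or e_ref <= 1.0:
        raise ValueError("amplification efficiencies must exceed 1")
    return e_target ** (ct_target_calibrator - ct_target_sample) / e_ref ** (
        ct_ref_calibrator - ct_ref_sample
    )


def _mean_ct(df: pd.DataFrame, sample: str, gene: str) -> tuple[float, float]:
    """(mean Ct, efficiency) for a sample x gene cell; error if absent."""
    sub = df[(df["sample"] == sample) & (df["gene"] == gene)]
    if sub.empty:
        raise ValueError(f"no Ct records for sample {sample!r}, gene {gene!r}")
    return float(sub["ct"].mean()), float(sub["efficiency"].iloc[0])


def estimate_extinction(
    records: list[CtRecord] | pd.DataFrame,
    sirna_id: str,
    target_gene: str,
    normalizer_genes: list[str],
    calibrator: str = "mock",
) -> ExtinctionEstimate:
    """Pooled extinction estimate for one siRNA from replicate Ct readings.

    Per normalizer, a ratio q is computed for every sample replicate
    (against the replicate-averaged calibrator Ct) and averaged on the
    log2 scale; per-normalizer results are pooled by geometric mean.
    ``log2_sd`` is the dispersion of per-replicate log2 q pooled across
    normalizers (NaN with a single replicate).
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if not (df["sample"] == calibrator).any():
        raise ValueError(f"calibrator sample {calibrator!r} absent from records")

    ct_t_cal, e_t = _mean_ct(df[df["sample"] == calibrator], calibrator, target_gene)
    sample_target = df[(df["sample"] == sirna_id) & (df["gene"] == target_gene)]
    if sample_target.empty:
        raise ValueError(f"no target-gene records for siRNA {sirna_id!r}")

    per_norm_log2q = []
    all_rep_log2q = []
    for norm in normalizer_genes:
        ct_n_cal, e_n = _mean_ct(df[df["sample"] == calibrator], calibrator, norm)
        rep_log2q = []
        for _, row in sample_target.iterrows():
            rep = row["replicate"]
            norm_row = df[
                (df["sample"] == sirna_id)
                & (df["gene"] == norm)
                & (df["replicate"] == rep)
            ]
            if norm_row.empty:
                raise ValueError(
                    f"replicate {rep} of {sirna_id!r} lacks a {norm!r} reading"
                )
            q = relative_quantity(
                ct_target_sample=float(row["ct"]),
                ct_target_calibrator=ct_t_cal,
                e_target=float(row["efficiency"]),
                ct_ref_sample=float(norm_row["ct"].iloc[0]),
                ct_ref_calibrator=ct_n_cal,
                e_ref=float(norm_row["efficiency"].iloc[0]),
            )
            rep_log2q.append(math.log2(q))
        per_norm_log2q.append(float(np.mean(rep_log2q)))
        all_rep_log2q.extend(rep_log2q)

    log2q = float(np.mean(per_norm_log2q))  # geometric mean on the q scale
    n_reps = len(sample_target)
    if len(all_rep_log2q) > 1 and n_reps > 1:
        log2_sd = float(np.std(all_rep_log2q, ddof=1))
    else:
        log2_sd = float("nan")
        logger.warning("siRNA %s: single replicate, dispersion undefined", sirna_id)
    q = 2.0 ** log2q
    return ExtinctionEstimate(
        sirna_id=sirna_id,
        q=q,
        knockdown_pct=100.0 * (1.0 - q),
        log2_sd=log2_sd,
        n_reps=n_reps,
        normalizers=list(normalizer_genes),
    )


@dataclass
class RunValidation:
    passed: bool
    reason: str
    control_knockdown_pct: float | None = None


def validate_run(
    records: list[CtRecord] | pd.DataFrame,
    positive_control_id: str,
    target_gene: str,
    normalizer_genes: list[str],
    calibrator: str = "mock",
    threshold_pct: float = 80.0,
) -> RunValidation:
    """A run passes when the positive-control siRNA knocks its target down
    by at least ``threshold_pct`` percent (default 80; some screens use 70).
    Failing runs should be excluded from downstream tables."""
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    if not (df["sample"] == positive_control_id).any():
        return RunValidation(False, f"positive control {positive_control_id!r} absent")
    est = estimate_extinction(
        df, positive_control_id, target_gene, normalizer_genes, calibrator
    )
    if est.knockdown_pct >= threshold_pct:
        return RunValidation(True, "control knockdown above threshold",
                             est.knockdown_pct)
    return RunValidation(
        False,
        f"control knockdown {est.knockdown_pct:.1f}% below {threshold_pct}%",
        est.knockdown_pct,
    )


def records_to_frame(records: list[CtRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "run_id": [r.run_id for r in records],
            "sample": [r.sample for r in records],
            "gene": [r.gene for r in records],
            "role": [str(r.role) for r in records],
            "replicate": [r.replicate for r in records],
            "ct": [r.ct for r in records],
            "efficiency": [r.efficiency for r in records],
        }
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns run_id, sample, gene, role, replicate, ct,
    efficiency (efficiency defaults to 2.0 when absent)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    required = {"run_id", "sample", "gene", "role", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df
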