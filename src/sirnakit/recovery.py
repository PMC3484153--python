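"""Monte-Carlo parameter-recovery and calibration studies.

These wrap the synthetic generator and the covariate models into the two
simulation studies the toolkit uses to validate itself: refitting the
reduced gene + location + position model on repeated synthetic screens
(parameter recovery), and fitting the full thirteen-covariate model on
pure-noise responses (type-I error calibration).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import fit_full_model, refit_reduced
from .synthetic import EfficacyGenParams, simulate_covariate_table


def reduced_model_recovery(
    n_reps: int = 200,
    base_seed: int = 1,
    params: EfficacyGenParams | None = None,
) -> pd.DataFrame:
    """Refit the reduced model on ``n_reps`` synthetic 88-siRNA screens.

    Each repetition draws a fresh transcriptome, target sites and
    efficacies (seeds ``base_seed, base_seed+1, ...``), then fits
    efficacy ~ gene + location + position with the 5' UTR and BCL2L1 as
    reference levels.  Returns one row per repetition with the recovered
    positional slope (per 100 bp) and the CDS / 3'UTR location contrasts.
    Repetitions whose random layout misses a location level are skipped.
    """
    rows = []
    for i in range(n_reps):
        seed = base_seed + i
        table = simulate_covariate_table(
            seed=seed,
            params=EfficacyGenParams(seed=seed) if params is None else _reseed(params, seed),
        )
        present = set(table["location"])
        if "FIVE_UTR" not in present or "CDS" not in present:
            continue
        fit = refit_reduced(table, gene_reference="BCL2L1",
                            location_reference="FIVE_UTR")
        rows.append(
            {
                "seed": seed,
                "slope_per_100bp": fit.slope_per_100bp,
                "cds_offset": fit.location_offsets.get("CDS", np.nan),
                "utr3_offset": fit.location_offsets.get("THREE_UTR", np.nan),
            }
        )
    return pd.DataFrame(rows)


def _reseed(params: EfficacyGenParams, seed: int) -> EfficacyGenParams:
    return EfficacyGenParams(
        gene_offsets=dict(params.gene_offsets),
        location_offsets=dict(params.location_offsets),
        slope_per_100bp=params.slope_per_100bp,
        noise_sd=params.noise_sd,
        baseline=params.baseline,
        seed=seed,
    )


def recovery_summary(recovery: pd.DataFrame) -> dict[str, float]:
    """Mean and Monte-Carlo standard error of each recovered quantity."""
    out: dict[str, float] = {"n_reps": float(len(recovery))}
    for col in ("slope_per_100bp", "cds_offset", "utr3_offset"):
        vals = recovery[col].dropna().to_numpy()
        out[f"{col}_mean"] = float(np.mean(vals))
        out[f"{col}_se"] = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    return out


def full_model_type1_rates(
    n_reps: int = 1000,
    base_seed: int = 1,
    alpha: float = 0.05,
    noise_sd: float = 10.0,
) -> pd.Series:
    """Per-term rejection rate of the full-model sequential ANOVA when the
    response is pure noise.  A calibrated test rejects each term at
    roughly ``alpha``."""
    counts: dict[str, int] = {}
    tested: dict[str, int] = {}
    for i in range(n_reps):
        table = simulate_covariate_table(
            seed=base_seed + i, pure_noise=True, noise_sd=noise_sd
        )
        _, anova = fit_full_model(table)
        for term in anova.index:
            if term == "Residual":
                continue
            tested[term] = tested.get(term, 0) + 1
            if anova.loc[term, "PR(>F)"] < alpha:
                counts[term] = counts.get(term, 0) + 1
    return pd.Series(
        {term: counts.get(term, 0) / n for term, n in tested.items()},
        name="rejection_rate",
    )
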