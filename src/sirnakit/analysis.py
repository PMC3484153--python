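"""Covariate analysis of measured siRNA efficacy.

Assembles one row per siRNA holding thirteen candidate predictors —
predicted score, target gene, position and region of the target site,
off-target and seed-match counts, polynucleotide tract, exon context and
target-site accessibility — and fits least-squares linear models of the
measured knockdown percentage on them.  Term significance is judged by
sequential (type-I) ANOVA in the documented covariate order; a reduced
gene + location + position model is refit for effect estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .design import SiRNACandidate, has_polyn_tract
from .offtarget import MismatchHit, SeedMatchProfile

logger = logging.getLogger(__name__)

# Fixed covariate order for sequential ANOVA.  Covariates 8-10 (3'UTR seed
# matches) expand to four numeric fields; accessibility is optional.
COVARIATE_TERMS: list[str] = [
    "dsir_score",
    "gene",
    "position_bp",
    "location",
    "n_offtargets",
    "polyn",
    "n_transcriptome_hits",
    "seed_n_seqs",
    "seed_hit1",
    "seed_hit2",
    "seed_hit3plus",
    "target_exon_length",
    "spans_junction",
    "accessibility",
]

CATEGORICAL_TERMS = {"gene", "location"}

# seed_n_seqs is the sum of the three hit-class counts and therefore exactly
# aliased with them in a linear model; it stays in the table as a derived
# total but enters the fit only through the three class counts.
MODEL_TERMS: list[str] = [t for t in COVARIATE_TERMS if t != "seed_n_seqs"]

TABLE_COLUMNS = ["sirna_id"] + COVARIATE_TERMS + ["efficacy_pct"]


def build_covariate_table(
    candidates: list[SiRNACandidate],
    offtarget_results: dict[str, tuple[int, list[MismatchHit]]],
    seed_profiles: dict[str, SeedMatchProfile],
    exon_contexts: dict[str, tuple[int | None, int | None]],
    accessibility: dict[str, float] | None,
    efficacies: dict[str, float],
) -> pd.DataFrame:
    """One complete covariate row per siRNA, keyed by sirna_id.

    Missing accessibility propagates as NaN (never silently imputed);
    an efficacy for an unknown siRNA id is a hard error.
    """
    by_id = {c.sirna_id: c for c in candidates}
    unknown = set(efficacies) - set(by_id)
    if unknown:
        raise ValueError(f"efficacies for unknown siRNA ids: {sorted(unknown)}")
    rows = []
    for sid, eff in efficacies.items():
        if not (-50.0 <= eff <= 100.0):
            raise ValueError(f"{sid}: efficacy {eff} outside [-50, 100]")
        c = by_id[sid]
        n_ot, hits = offtarget_results.get(sid, (0, []))
        prof = seed_profiles.get(sid, SeedMatchProfile(0, 0, 0, 0))
        exon_len, junction = exon_contexts.get(sid, (None, None))
        acc = accessibility.get(sid, math.nan) if accessibility else math.nan
        rows.append(
            {
                "sirna_id": sid,
                "dsir_score": c.base_score,
                "gene": c.symbol,
                "position_bp": c.start,
                "location": str(c.location),
                "n_offtargets": n_ot,
                "polyn": int(has_polyn_tract(c.sense)),
                "n_transcriptome_hits": len(hits),
                "seed_n_seqs": prof.n_seqs,
                "seed_hit1": prof.hit1,
                "seed_hit2": prof.hit2,
                "seed_hit3plus": prof.hit3plus,
                "target_exon_length": exon_len,
                "spans_junction": junction,
                "accessibility": acc,
                "efficacy_pct": eff,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _term_formula(term: str) -> str:
    return f"C({term})" if term in CATEGORICAL_TERMS else term


def _available_terms(table: pd.DataFrame) -> list[str]:
    terms = []
    for term in MODEL_TERMS:
        if term not in table.columns or table[term].isna().all():
            logger.info("covariate %r absent or all-missing; dropped from model", term)
            continue
        col = table[term]
        if term not in CATEGORICAL_TERMS and col.nunique(dropna=True) < 2:
            logger.info("covariate %r is constant; dropped from model", term)
            continue
        if term in CATEGORICAL_TERMS and col.nunique(dropna=True) < 2:
            logger.info("factor %r has a single level; dropped from model", term)
            continue
        terms.append(term)
    return terms


def fit_full_model(
    table: pd.DataFrame, anova: str = "sequential"
) -> tuple[pd.Series, pd.DataFrame]:
    """Least-squares fit of efficacy on all available covariates, with a
    per-term ANOVA table (sequential type-I by default, ``anova="marginal"``
    for drop-one type-II sums of squares).

    A rank-deficient design is an error listing the aliased columns.
    """
    if len(table) < 20:
        raise ValueError(f"need >= 20 records to fit the full model, got {len(table)}")
    if "efficacy_pct" not in table.columns or table["efficacy_pct"].isna().any():
        raise ValueError("response efficacy_pct must be present and complete")
    terms = _available_terms(table)
    formula = "efficacy_pct ~ " + " + ".join(_term_formula(t) for t in terms)
    model = smf.ols(formula, data=table)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        aliased = _aliased_columns(model.exog, model.exog_names)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    fit = model.fit()
    typ = 1 if anova == "sequential" else 2
    anova_table = sm.stats.anova_lm(fit, typ=typ)
    return fit.params, anova_table


def _aliased_columns(exog: np.ndarray, names: list[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(exog.shape[1]):
        cols = kept + [j]
        if np.linalg.matrix_rank(exog[:, cols]) == len(cols):
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


@dataclass
class ReducedFit:
    """The three-covariate model efficacy ~ gene + location + position.

    Offsets are reported against the chosen reference levels; the positional
    slope is expressed per 100 bp of distance from the transcript 5' end.
    """

    gene_offsets: dict[str, float]
    location_offsets: dict[str, float]
    slope_per_100bp: float
    p_values: dict[str, float]
    fitted_values: pd.DataFrame
    gene_reference: str
    location_reference: str
    intercept: float = 0.0


def refit_reduced(
    table: pd.DataFrame,
    gene_reference: str = "BCL2L1",
    location_reference: str = "FIVE_UTR",
) -> ReducedFit:
    """Refit efficacy on the three informative covariates only:
    target gene, target-site location and target-site position."""
    for col in ("gene", "location", "position_bp", "efficacy_pct"):
        if col not in table.columns:
            raise ValueError(f"covariate table lacks column {col!r}")
    gene_counts = table["gene"].value_counts()
    for gene, n in gene_counts.items():
        if n < 2:
            logger.warning("gene %s has only %d record(s); kept in fit", gene, n)

    if gene_reference not in set(table["gene"]):
        gene_reference = sorted(set(table["gene"]))[0]
    if location_reference not in set(table["location"]):
        location_reference = sorted(set(table["location"]))[0]

    terms = []
    if table["gene"].nunique() > 1:
        terms.append(f"C(gene, Treatment(reference='{gene_reference}'))")
    if table["location"].nunique() > 1:
        terms.append(f"C(location, Treatment(reference='{location_reference}'))")
    terms.append("position_bp")
    formula = "efficacy_pct ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(fit, typ=1)

    gene_offsets, location_offsets = {}, {}
    for name, value in fit.params.items():
        if name.startswith("C(gene"):
            gene_offsets[name.split("[T.")[1].rstrip("]")] = float(value)
        elif name.startswith("C(location"):
            location_offsets[name.split("[T.")[1].rstrip("]")] = float(value)
    p_values = {}
    for row_name in anova.index:
        if row_name.startswith("C(gene"):
            p_values["gene"] = float(anova.loc[row_name, "PR(>F)"])
        elif row_name.startswith("C(location"):
            p_values["location"] = float(anova.loc[row_name, "PR(>F)"])
        elif row_name == "position_bp":
            p_values["position"] = float(anova.loc[row_name, "PR(>F)"])

    fitted = table[["sirna_id"]].copy() if "sirna_id" in table.columns else pd.DataFrame(index=table.index)
    fitted["measured"] = table["efficacy_pct"].to_numpy()
    fitted["fitted"] = fit.fittedvalues.to_numpy()

    return ReducedFit(
        gene_offsets=gene_offsets,
        location_offsets=location_offsets,
        slope_per_100bp=float(fit.params["position_bp"]) * 100.0,
        p_values=p_values,
        fitted_values=fitted,
        gene_reference=gene_reference,
        location_reference=location_reference,
        intercept=float(fit.params["Intercept"]),
    )


@dataclass
class PositionTest:
    gene: str
    testable: bool
    n_records: int
    slope_per_100bp: float | None = None
    p_value: float | None = None
    reason: str = ""


def per_gene_position_test(
    table: pd.DataFrame, gene: str, cds_only: bool = True, min_records: int = 4
) -> PositionTest:
    """Within one gene (CDS sites only by default), is position a significant
    predictor of efficacy?  Simple regression with a two-sided slope test;
    fewer than ``min_records`` usable rows is declared not-testable."""
    sub = table[table["gene"] == gene]
    if cds_only:
        sub = sub[sub["location"] == "CDS"]
    n = len(sub)
    if n < min_records:
        return PositionTest(
            gene=gene, testable=False, n_records=n,
            reason=f"only {n} usable records (need >= {min_records})",
        )
    fit = smf.ols("efficacy_pct ~ position_bp", data=sub).fit()
    return PositionTest(
        gene=gene,
        testable=True,
        n_records=n,
        slope_per_100bp=float(fit.params["position_bp"]) * 100.0,
        p_value=float(fit.pvalues["position_bp"]),
    )
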