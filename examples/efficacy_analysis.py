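"""Covariate analysis of a simulated 88-siRNA screen.

Builds the full thirteen-covariate table for one synthetic screen, asks
the sequential ANOVA which covariates predict measured efficacy, refits
the reduced gene + location + position model, and runs the within-gene
positional test for the gene with the strongest planted decay.
"""

from sirnakit import fit_full_model, per_gene_position_test, refit_reduced, simulate_covariate_table

table = simulate_covariate_table(seed=42)
print(f"covariate table: {len(table)} siRNAs, "
      f"{table['gene'].nunique()} genes, locations "
      f"{table['location'].value_counts().to_dict()}\n")

_, anova = fit_full_model(table)
print("sequential ANOVA (significant terms at 5%):")
for term in anova.index:
    if term != "Residual" and anova.loc[term, "PR(>F)"] < 0.05:
        print(f"  {term:<14} F = {anova.loc[term, 'F']:>7.2f}  "
              f"p = {anova.loc[term, 'PR(>F)']:.2e}")

fit = refit_reduced(table)
print(f"\nreduced model (refs: gene {fit.gene_reference}, "
      f"location {fit.location_reference}):")
print(f"  positional slope: {fit.slope_per_100bp:+.2f}% per 100 bp "
      f"(p = {fit.p_values['position']:.1e})")
print(f"  CDS vs 5'UTR:     {fit.location_offsets['CDS']:+.1f}% "
      f"(location p = {fit.p_values['location']:.1e})")
print(f"  3'UTR vs 5'UTR:   {fit.location_offsets['THREE_UTR']:+.1f}%")
print("  gene offsets vs BCL2L1: "
      + ", ".join(f"{g} {v:+.1f}" for g, v in sorted(fit.gene_offsets.items())))

res = per_gene_position_test(table, "HDAC6")
print(f"\nwithin-gene positional test, HDAC6 CDS sites (n={res.n_records}): "
      f"slope {res.slope_per_100bp:+.2f}%/100bp, p = {res.p_value:.3f}")
print("\nOnly gene, location and position carry signal in the generator; "
      "the other ten covariates should (and do) come out non-significant "
      "in most runs.")
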