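"""Design siRNA candidates for a synthetic transcript.

Trains the guide-strand scoring model on simulated (guide, efficacy)
pairs, enumerates every 21-nt window of one transcript, scores each
window, applies the positional correction, then filters (score > 80,
CDS only, no polynucleotide tracts) and picks well-spaced candidates.
"""

from sirnakit import (
    EfficacyGenParams,
    FilterRules,
    apply_positional_correction,
    enumerate_candidates,
    filter_candidates,
    make_study_transcriptome,
    predict_efficacy,
    sample_study_candidates,
    select_spaced,
    simulate_efficacies,
    train_model,
)
from sirnakit.transcripts import to_rna

# training data: a simulated screen of 88 guides with measured efficacies
train_cands = sample_study_candidates(seed=7)
measured = simulate_efficacies(train_cands, EfficacyGenParams(seed=7, noise_sd=5.0))
pairs = [(c.guide, min(max(measured[c.sirna_id], 0.0), 100.0)) for c in train_cands]
model = train_model(pairs, regularization=10.0)

# design against one transcript
target = make_study_transcriptome(seed=7)[3]  # CSNK2B-like, 1128 nt
candidates = enumerate_candidates(target)
for c in candidates:
    c.base_score = predict_efficacy(model, c.guide)
    c.corrected_score = apply_positional_correction(c.base_score, c.location, c.start)

retained, rejected = filter_candidates(
    candidates, FilterRules(min_score=80.0, cds_only=True, no_polyn=True)
)
picked = select_spaced(retained, k=5, min_gap=42)

print(f"target {target.symbol}: {len(candidates)} windows, "
      f"{len(retained)} pass filters, {len(picked)} selected\n")
print(f"{'start':>6} {'loc':>4} {'base':>6} {'corr':>6}  guide (5'->3')")
for c in picked:
    print(f"{c.start:>6} {c.location.value[:4]:>4} {c.base_score:>6.1f} "
          f"{c.corrected_score:>6.1f}  {to_rna(c.guide)}")
print("\nbase = predicted extinction %; corr = after the location/position "
      "correction (CDS sites near the 5' end keep their score).")
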