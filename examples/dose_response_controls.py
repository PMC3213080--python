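"""Estimate control-strain GI50s from simulated noiseless plates.

Simulates two replicate 96-well plates carrying only the four control
strains (WT at B11/D3/F5, rad14 at B12, rev1 at D4, mag1 at G5, blanks at
A1/H12), blank-corrects them, computes per-dose growth AUCs, and fits the
normalized AUC vs dose line whose slope gives GI50 = -0.5/slope.
"""

from phenoscreen import SimConfig, simulate_plate, summarize_all
from phenoscreen.plate_io import assemble_curves, blank_correct

config = SimConfig(noise_sigma_mult=0.0, noise_sd_add=0.0, n_replicates=2, seed=1)
curves = []
for r in range(config.n_replicates):
    layout, plates = simulate_plate([], config, replicate_id=f"R{r + 1}")
    curves += assemble_curves([blank_correct(p, layout) for p in plates], layout)

fits, summaries = summarize_all(curves)

print("strain   GI50 (%MMS)   sem        passing/total replicates")
for strain in ("WT", "rad14", "rev1", "mag1"):
    s = summaries[strain]
    print(f"{strain:<8} {s.gi50_mean:<13.6g} {s.gi50_sem:<10.2g} {s.n_pass}/{s.n_total}")

# WT (0.01) and rad14 (0.008) are exact: their simulated dose response is
# linear by construction.  rev1 and mag1 carry configured steep profiles;
# their GI50s (~0.0071, ~0.0069) anchor the intermediate/severe boundaries
# of this batch but sit above the strains' true sensitivities, because
# -0.5/slope cannot reach below ~0.0067 once growth hits zero within the
# dose range.
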