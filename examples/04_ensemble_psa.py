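"""3D polar surface area over a conformer ensemble.

Each conformer's exposed polar van-der-Waals surface (probe radius 0) is
integrated by spiral-point sampling; the ensemble is summarised by median,
quartiles and Tukey adjacent limits — the whisker bounds of a violin plot.
A flexible degrader samples conformers of widely differing polarity, so
the spread between the adjacent limits can span tens of Å²."""

from protacsol import ensemble_psa, generate_toy_ensemble, summarize_ensemble

ensemble = generate_toy_ensemble(n_conformers=50, seed=3, jitter=0.4)
values = ensemble_psa(ensemble)
dist = summarize_ensemble(values)

print(f"conformers      : {len(values)}")
print(f"lower adjacent  : {dist.lower_adjacent:6.2f} Å²")
print(f"Q1              : {dist.q1:6.2f} Å²")
print(f"median          : {dist.median:6.2f} Å²")
print(f"Q3              : {dist.q3:6.2f} Å²")
print(f"upper adjacent  : {dist.upper_adjacent:6.2f} Å²")
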