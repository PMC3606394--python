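"""Screen sampled flux distributions against AngII/PMA observations.

Samples 1000 independent flux bases log10-uniformly on [0.01, 100],
screens each against the three experimental observations (4-hour Nox1
protein stability under AngII, 30-minute up-regulated quasi-steady
state under AngII, 30-minute up-regulation under PMA) and summarizes
the surviving recycling-vs-proteolysis flux split.
"""

from nox1sim import flux_distribution_summary, screening_ensemble

df = screening_ensemble(n=1000, seed=11)
retained = df[df.combined]
print(f"samples: {len(df)}, pass condition 1: {df.cond1.sum()}, "
      f"condition 2: {df.cond2.sum()}, condition 3: {df.cond3.sum()}, "
      f"all three: {len(retained)}")

summary = flux_distribution_summary(retained)
print(f"retained proteolytic flux f14: max {retained.f14.max():.3g}")
print(f"retained recycling flux f2+f3+f4: min {retained.recycling.min():.3g}")
print(f"mean log10 separation: {summary['log10_separation']:.2f} decades")
print(f"mean recycling / mean proteolysis: "
      f"{summary['mean_flux_ratio']:.0f}-fold")
print(
    "\nThe screens eliminate the large-proteolysis / small-recycling "
    "corner: surviving parameter sets disassemble the active complex "
    "almost entirely through subunit recycling."
)
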