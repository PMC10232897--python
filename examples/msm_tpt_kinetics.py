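"""Kinetic model of a state-switching system: tICA -> MSM -> transition paths.

Emits collective-variable time series from a known 3-state Markov chain,
recovers the slow coordinates with tICA, discretizes them with k-means,
builds a symmetrized transition probability matrix, checks the implied
timescales, coarse-grains with PCCA+, and decomposes the 0 -> 2 transition
flux into pathways.
"""

import numpy as np

from allokit import msm, synthetic, tica, tpt

tpm_true = np.array(
    [[0.95, 0.05, 0.00],
     [0.03, 0.92, 0.05],
     [0.00, 0.04, 0.96]]
)
spec = synthetic.MarkovEmissionSpec(
    tpm=tpm_true, means=np.eye(3) * 5.0, noise_std=0.4, n_frames=200_000, seed=0
)
segments, _, _ = synthetic.gen_markov_cv(spec)

model = tica.fit_tica(segments, lag_frames=5)
projections = [tica.project(model, seg, k=2) for seg in segments]
print(f"tICA eigenvalues: {np.round(model.eigenvalues, 3)}")
print(f"kinetic content of first 2 modes: {tica.kinetic_content(model, 2):.3f}")

clustering = msm.cluster_microstates(projections, k=30, seed=0)
markov = msm.build_tpm(clustering.assignments, lag_frames=1)
table = msm.implied_timescales(clustering.assignments, lags=[1, 2, 5, 10], n_timescales=2)
print("\nimplied timescales (frames) vs lag -- flat means Markovian:")
print(table.round(1).to_string(index=False))

macro = msm.pcca_macrostates(markov, m=3)
print(f"\nmacrostate populations: {np.round(macro.populations, 3)}")

result = tpt.tpt_analysis(macro.macro_tpm, macro.populations, source=[0], target=[2])
print("\ntransition pathways 0 -> 2 (flux fractions):")
print(result.pathway_table().to_string(index=False))
print(
    "\nThe committor-weighted flux decomposition shows which macrostate routes\n"
    "carry the transition; cumulative_flux reaching ~1 means the listed paths\n"
    "account for the whole reactive current."
)
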