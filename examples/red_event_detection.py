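"""Detect a rare contact-pattern change in a trajectory's contact map.

Builds a 200-pair contact time series with 8 pairs that switch occupancy at
frame 500 (a planted conformational event), then runs the event-detection
protocol: smoothing, non-negative matrix factorization into 2 components,
normalization by the constitutive pairs, and extraction of the
structure-differentiating contact pairs (SDCPs) at the 4-sigma level.
"""

from allokit import contacts, red, synthetic

cts, truth = synthetic.gen_contact_fixture(
    n_frames=1000, n_pairs=200, n_switching=8, n_constitutive=32,
    event_frame=500, seed=0,
)
smoothed = contacts.smooth(cts, window_frames=25)

model = red.fit_red(smoothed, c=2, seed=0)
constitutive = red.identify_constitutive_pairs(model)
model = red.normalize_components(model, constitutive)

weights, labels, transitions = red.dominance_timeline(model)
table = red.extract_sdcps(model, int(labels[0]), int(labels[-1]), k_sigma=4.0)

print(f"planted event frame:   {truth.event_frames[0]}")
print(f"detected transition(s): {transitions}")
print(f"constitutive pairs used for normalization: {len(constitutive)}")
print(f"\nSDCP table ({len(table)} pairs beyond 4 sigma):")
print(table[["res_i", "res_j", "delta", "direction"]].to_string(index=False))
print(
    "\nEach row is a residue pair whose contact weight differs between the two\n"
    "components by more than 4 standard deviations: 'formed' pairs appear during\n"
    "the event, 'broken' pairs are lost. Planted ground truth:",
    sorted(truth.switching_pairs),
)
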