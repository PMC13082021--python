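"""Recover ordered ciliary subzones from noisy per-particle class labels.

Generates a nine-filament synthetic ciliary barrel with 20% of particle
labels flipped, sharpens them by neighbor voting, enforces the
proximal-to-distal zone order, and reports the recovered boundaries.
"""

import ciliabase as cb

ps = cb.gen_cilium(cb.CiliumModel(label_noise=0.2, jitter_sigma=1.0, seed=42))
print(f"{len(ps)} particles on 9 filaments; "
      f"{(ps.labels != ps.true_labels).mean():.0%} of input labels are wrong")

voted = cb.vote_reassign(ps, cb.VotingConfig(window=24.0))
ordered = cb.enforce_ordering(voted, cb.ZoneOrdering())
print(f"after voting + ordering: {(ordered.labels == ordered.true_labels).mean():.1%} "
      "of labels match ground truth")

print("contiguous zones per filament:", sorted(set(cb.count_segments(ordered).values())))
summary = cb.boundary_summary(cb.boundaries(ordered))
print(summary.to_string(index=False))
print("Each row is one zone transition: its mean arc position (nm) across the")
print("nine filaments and the filament-to-filament spread. The generator's true")
print("boundaries sit at 205, 435, 465 and 718 nm.")
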