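"""Normalize DMS structure-probing counts and locate the structure dip.

Simulates DMS-like counts with a planted inaccessible (structured) band
downstream of the start codon, normalizes them to [0, 1] reactivities,
builds the cross-gene sliding-window profile, and finds the first dip.
"""

import numpy as np

import riboflow as rf

rng = np.random.default_rng(41)
tracks, offsets = {}, {}
for i in range(40):
    gene = f"g{i:02d}"
    n = 400
    seq = "".join(rng.choice(list("ACGT"), size=n))
    accessibility = np.clip(rng.normal(0.8, 0.05, n), 0, 1)
    accessibility[90:130] = 0.15   # structured band at +60..+100 from start
    counts = rf.synthdata.simulate_dms_counts(seq, accessibility,
                                              depth=200.0, seed=100 + i)
    reactivity = rf.normalize_dms(counts, seq, window=n)
    tracks[gene] = np.where(reactivity.mask, np.nan, reactivity.values)
    offsets[gene] = 30             # 30-nt 5' UTR before the start codon

profile, per_gene = rf.window_profile(tracks, offsets, width=40,
                                      upstream=30, downstream=250)
dip = rf.find_energy_dip(profile)
print(f"window profile over {len(tracks)} genes, "
      f"positions {profile.positions[0]}..{profile.positions[-1]} nt")
print(f"first signal dip downstream of the start codon: +{dip} nt "
      f"(planted structured band spans +60..+100)")

te = {g: float(np.exp(rng.normal())) for g in tracks}
corr = rf.te_window_correlation(per_gene, te, profile, n_windows=280)
n_sig = int(np.nansum(corr.p_corr < 0.05))
print(f"windows significantly correlated with (independent) TE after "
      f"Bonferroni x280: {n_sig} (expected 0 under this null)")
# Low reactivity means protected/paired bases; the dip marks where mRNA
# structure is strongest relative to its surroundings.
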