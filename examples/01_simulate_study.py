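"""Generate a synthetic two-brand NIR study and look at its structure.

The generator emulates a smoking-machine quality-control campaign: product
batches on a timeline, pads split between two container cups (paired
measurements), standard-sample batches per brand, and empty-pad background
spectra.  Same seed, same study, bit for bit.
"""

import nirstab as ns

config = ns.scaled_study_config(seed=1)
study = ns.simulate_study(config)

meta = study.metadata_frame()
print(f"total spectra: {len(study)} on grid "
      f"{study.grid.start:.0f}..{study.grid.stop:.0f} cm^-1, step {study.grid.step:.0f}")
print(meta.groupby(["role", "brand"], dropna=False).size().rename("n").reset_index()
      .to_string(index=False))

pairs, remainder = ns.pair_up(study.select(role="product"))
print(f"measurement pairs (classical vs self-made cup): {len(pairs)}, "
      f"unpaired spectra: {len(remainder)}")
# Every product pad is measured once per cup, so pair count is half the
# product spectra; standards are scanned in the classical cup only.
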