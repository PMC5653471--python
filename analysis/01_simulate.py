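"""Simulate the study population and write its genotypes, pedigree,
phenotypes and true allele origins under results/simdata/."""

import os

from crossblup.pipeline import cmd_simulate

from common import STUDY, scratch_dir

outdir = os.path.join(scratch_dir(), "simdata")
ds, log = cmd_simulate(STUDY, outdir)

print(f"wrote {outdir}")
print(f"individuals: {ds.panel.n_ind} ({len(ds.cb_ids)} crossbred, "
      f"{len(ds.genotyped)} genotyped)")
for pair, v in ds.realized_fst.items():
    print(f"realized F_ST {pair[0]}-{pair[1]}: {v:.3f}")
tr = ds.truths["ADG"]
for b, K in tr.K2.items():
    rpc = K[0, 1] / (K[0, 0] * K[1, 1]) ** 0.5
    print(f"generating r_pc[{b}] = {rpc:.2f}")
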