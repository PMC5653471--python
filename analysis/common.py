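"""Shared study conditions for the analysis scripts.

One synthetic three-way cross stands in for the proprietary pig data:
three drifted purebred lines at pairwise F_ST ~ 0.15, a sire line (S)
crossed onto F1 (LR x LW) dams with litter structure, one daily-gain-like
trait with purebred h2 0.30, crossbred h2 0.35, and purebred-crossbred
genetic correlations 0.5 (S), 0.3 (LR), 0.6 (LW) - the LR value mirrors
the regime where breed-specific crossbred effects matter most.  A large
block of phenotyped-but-ungenotyped crossbreds feeds the pedigree-based
validation step only.
"""

import os

from crossblup import SimConfig

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
SCRATCH = os.path.join(os.path.dirname(__file__), "..", "scratch")

STUDY = SimConfig(
    n_pb=150, n_cb=400, n_cb_extra=400, n_loci=900, n_chromosomes=3,
    n_dams_f1=60, n_sires_s=60, n_f1_grandsires=20, n_f1_granddams=30,
    litter_size=5, qtl_count=200, target_fst=0.15, seed=101,
)


def results_dir():
    os.makedirs(RESULTS, exist_ok=True)
    return RESULTS


def scratch_dir():
    """Bulk outputs (VCF, full matrices) that no downstream step re-reads."""
    os.makedirs(SCRATCH, exist_ok=True)
    return SCRATCH
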