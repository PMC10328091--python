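"""Design an in-frame deletion using a validated 5' CCA PAM.

Builds a synthetic target genome with a CCA-preceded protospacer inside the
gene to delete, then designs: a spacer, a synthetic CRISPR array
(leader + repeat + spacer + repeat), homology arms, and the edited locus,
with validation flags and predicted screening amplicons.
"""

import tempfile

import numpy as np

from pamflow import DesignRequest, check_amplicons, run_design_pipeline
from pamflow.model import GenomeRecord
from pamflow.simulate import DEFAULT_DIRECT_REPEAT

rng = np.random.default_rng(0)
protospacer = "ACGTTGCAGGCTAATCGTCAGGCATTGACTAATGCA"  # 36 nt, 50% GC
seq = ("".join(rng.choice(np.array(list("ACGT")), size=2000))
       + "CCA" + protospacer
       + "".join(rng.choice(np.array(list("ACGT")), size=2000)))
genome = GenomeRecord(id="target", sequence=seq)

request = DesignRequest(
    leader="A" * 100,
    direct_repeat=DEFAULT_DIRECT_REPEAT,
    lha_len=471, rha_len=491,          # arm lengths of the first knock-out
    deletion=(2000, 2300),             # 300 bp, in-frame
    spacer_region=(1995, 2300),
    cds_intervals=[(1900, 2500)],
    pam_patterns=("CCA",),
)

with tempfile.TemporaryDirectory() as tmp:
    design, paths = run_design_pipeline(genome, request, tmp)

print(f"edit              : {design.kind} of {design.edit_size} bp")
print(f"spacer            : {design.spacer.sequence} ({design.spacer.strand})")
print(f"PAM used          : {design.spacer.pam}")
print(f"spacer GC         : {design.spacer.gc:.2f}")
print(f"synthetic array   : {len(design.synthetic_array)} bp "
      f"(leader 100 + 2x repeat 30 + spacer 36)")
print(f"homology arms     : {len(design.lha)} / {len(design.rha)} bp")
print(f"flags             : {design.flags}")
amp = check_amplicons(design, wt_len=1262, edited_len=962)
print(f"amplicons         : WT {amp['wt_len']} bp vs edited {amp['edited_len']} bp "
      f"-> delta {amp['delta']} (consistent={amp['consistent']})")
# in_frame=True because 300 is divisible by 3 and the deletion sits inside
# the annotated CDS; target_destroyed=True because the deleted region carries
# the PAM+protospacer, so the edited chromosome escapes self-targeting.
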