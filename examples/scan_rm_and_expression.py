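"""Scan a plasmid for restriction-modification sites; compute expression ratios.

A Type I R-M system recognizing 5'-TAAGN5TCC-3' cleaves incoming plasmids, so
editing vectors should be screened for the motif on both strands. The qPCR
utility computes the efficiency-corrected (Pfaffl) relative expression used
to characterize leader-driven transcription.
"""

import numpy as np

from pamflow import QuantInput, pfaffl_expression, scan_rm_sites

rng = np.random.default_rng(5)
backbone = "".join(rng.choice(np.array(list("ACGT")), size=4000))
site = "TAAGACGTATCC"
plasmid = backbone[:1000] + site + backbone[1000:2500] + site + backbone[2500:]

scan = scan_rm_sites(plasmid)  # default motif TAAGNNNNNTCC
print(f"plasmid length : {len(plasmid)} bp")
print(f"R-M sites      : {scan.count}")
for pos, strand in zip(scan.positions, scan.strands):
    print(f"  position {pos:>5}  strand {strand}")
# each site found raises the chance the host restriction system destroys the
# vector before editing can occur; redesign or methylate to remove them

q = QuantInput(E_target=1.95, E_reference=1.98, Cp_target=24.1, Cp_reference=18.7)
ratio = pfaffl_expression(q)
print(f"\nPfaffl expression ratio: {ratio:.4g}")
print("(< 1: the target transcript is rarer than the reference, here the "
      "low-but-functional leader-driven array transcription)")
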