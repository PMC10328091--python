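"""Decide which end of a CRISPR array is leader-proximal.

The leader contains the promoter that transcribes the array, so a
sigma70-like -35/-10 signal in one genomic flank reveals the orientation.
Downstream stages require crRNA orientation, so resolving "reverse" also
reverse-complements the repeat and spacers and inverts spacer order.
"""

from pamflow import CrisprArray, orient_array, score_promoter_signal
from pamflow._seq import revcomp

array = CrisprArray(
    array_id="array2", host_id="host",
    interval=(1000, 1400),
    direct_repeat="ATTTACATTCCAATATGGATCTACTCAAAT",
    spacers=["GATTTAGGCAACACTTGCGGAATTCTGGGTATCAAG",
             "CCTTATCAAGAGTGGTAGCAACTTGTGCTAATGTCA"],
    orientation="unknown",
)

promoter = "TTGACA" + "C" * 17 + "TATAAT"       # perfect -35/-10, spacer 17
upstream = "G" * 12 + promoter + "G" * 12       # leader side
downstream = "G" * 53                            # no signal

print(f"upstream flank score   : {score_promoter_signal(upstream)} / 12")
print(f"downstream flank score : {score_promoter_signal(revcomp(downstream))} / 12")

oriented = orient_array(array, upstream, downstream)
print(f"orientation call       : {oriented.orientation}")
print(f"leader-proximal spacer : {oriented.spacers[0][:12]}...")
# with the promoter in the upstream flank the array reads left-to-right
# (forward); an external prediction can always override via external_call
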