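"""Build paired interference-assay constructs for candidate PAM validation.

A candidate PAM is validated in vivo by comparing transformation efficiency
of a plasmid carrying (candidate PAM + protospacer + native 3' repeat flank)
against the neutral control (native 5' repeat flank + the same protospacer):
a functional PAM triggers interference and depresses transformation.
"""

from pamflow import build_interference_construct, derive_native_flanks

direct_repeat = "ATTTACATTCCAATATGGATCTACTCAAAT"
five_native, three_native = derive_native_flanks(direct_repeat, 5)
print(f"direct repeat        : {direct_repeat}")
print(f"native 5' flank      : {five_native}   (last 5 nt of the repeat)")
print(f"native 3' flank      : {three_native}   (first 5 nt of the repeat)")

protospacer = "GATTTAGGCAACACTTGCGGAATTCTGGGTATCAAG"
for pam in ("CCA", "GCC", "TCA"):
    control = build_interference_construct(protospacer, five_native, three_native)
    test = build_interference_construct(protospacer, pam + five_native[len(pam):],
                                        three_native)
    print(f"\ncandidate PAM {pam}:")
    print(f"  control insert : {control[:20]}...")
    print(f"  test insert    : {test[:20]}...")
    # the pair differs only in its leading bases, so any drop in
    # transformation efficiency is attributable to the candidate PAM
    assert control[5:] == test[5:]
print("\nEach pair differs only 5' of the protospacer, isolating the PAM effect.")
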