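"""Array orientation from promoter-like signal in the flanking sequence.

The leader that drives transcription of a CRISPR array carries a sigma70-style
promoter. The original workflow delegated this call to an external promoter
predictor; here a deterministic consensus-hexamer scorer stands in, and an
explicit external call (e.g. a CRISPRFinder orientation) always takes
precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from ._seq import revcomp
from .model import CrisprArray, canonicalized

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"
MIN_FLANK_LEN = 40
SPACER_RANGE = range(15, 20)  # allowed -35/-10 separation, inclusive 15..19
DEFAULT_MARGIN = 2.0


@dataclass(frozen=True)
class PromoterScore:
    """Scores for the two possible leader placements and the resulting call."""

    forward_score: float
    reverse_score: float
    call: str
    margin_threshold: float


def score_promoter_signal(flank: str) -> float:
    """Best sigma70-like promoter score over all placements in ``flank``.

    The model is a pair of consensus hexamers (-35 TTGACA, -10 TATAAT)
    separated by 15-19 nt; each matching base scores +1, so the maximum is 12.
    All placements and spacer widths are enumerated exhaustively.
    """
    flank = flank.upper()
    if len(flank) < MIN_FLANK_LEN:
        raise ValueError(
            f"flank length {len(flank)} < minimum {MIN_FLANK_LEN} nt"
        )
    best = 0
    n = len(flank)
    for i in range(n - 6 + 1):
        hex35 = flank[i:i + 6]
        s35 = sum(a == b for a, b in zip(hex35, MINUS35))
        for gap in SPACER_RANGE:
            j = i + 6 + gap
            if j + 6 > n:
                break
            hex10 = flank[j:j + 6]
            score = s35 + sum(a == b for a, b in zip(hex10, MINUS10))
            if score > best:
                best = score
    return float(best)


def score_orientation(
    upstream_flank: str,
    downstream_flank: str,
    margin_threshold: float = DEFAULT_MARGIN,
) -> PromoterScore:
    """Score both leader placements; call unknown when within the margin.

    ``forward`` means the leader (promoter) sits in the upstream flank read on
    the + strand; ``reverse`` means it sits in the downstream flank read on
    the - strand (the array is transcribed leftwards).
    """
    fwd = score_promoter_signal(upstream_flank)
    rev = score_promoter_signal(revcomp(downstream_flank))
    if abs(fwd - rev) < margin_threshold:
        call = "unknown"
    elif fwd > rev:
        call = "forward"
    else:
        call = "reverse"
    return PromoterScore(fwd, rev, call, margin_threshold)


def orient_array(
    array: CrisprArray,
    upstream_flank: str | None = None,
    downstream_flank: str | None = None,
    external_call: str | None = None,
    margin_threshold: float = DEFAULT_MARGIN,
) -> CrisprArray:
    """Resolve array orientation and canonicalize into crRNA orientation.

    Precedence: an ``external_call`` wins; otherwise promoter scoring of the
    two genomic flanks decides; if neither is conclusive the array is returned
    with orientation ``unknown`` and the caller must supply a call.

    Arrays whose orientation is already known are returned unchanged
    (idempotent): their sequences are taken to be in crRNA orientation
    already, as in CRISPRFinder-style locus files.
    """
    if external_call == "unknown":
        raise ValueError("external_call must be 'forward' or 'reverse', not 'unknown'")
    if array.orientation != "unknown":
        return array
    if external_call is not None:
        if external_call not in ("forward", "reverse"):
            raise ValueError(f"invalid external_call {external_call!r}")
        call = external_call
    elif upstream_flank is not None and downstream_flank is not None:
        call = score_orientation(
            upstream_flank, downstream_flank, margin_threshold
        ).call
    else:
        call = "unknown"
    if call == "unknown":
        return array
    oriented = replace(array, orientation=call)
    # sequences were given on the genome + strand; flip into crRNA orientation
    return replace(canonicalized(oriented), orientation=call)
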