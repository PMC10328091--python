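"""Genome-editing design for endogenous Type I-B CRISPR systems.

Once a functional 5' PAM is known, editing a locus requires:

* an interference construct (candidate PAM or native repeat flank + the
  protospacer + the native 3' repeat flank) for in vivo PAM validation;
* a spacer chosen 3' of a PAM occurrence in the target window, with GC
  content inside 40-60% by default;
* a synthetic CRISPR array (leader + direct repeat + spacer + direct repeat)
  expressing that spacer from the native leader;
* an editing template of two homology arms flanking the edit, whose product
  must no longer carry PAM + protospacer (escape from self-targeting);
* predicted screening-amplicon sizes, whose WT-edited difference must equal
  the edit size;
* a scan for restriction-modification recognition sites (TAAGN5TCC by
  default) that would impair plasmid transfer.

A qPCR utility computes the efficiency-corrected (Pfaffl) expression ratio
used to characterize leader activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._seq import find_motif, gc_fraction, revcomp, validate_dna
from .model import GenomeRecord

DEFAULT_RM_MOTIF = "TAAGNNNNNTCC"
DEFAULT_GC_BOUNDS = (0.40, 0.60)
DEFAULT_SPACER_LENGTH = 36


@dataclass(frozen=True)
class SpacerCandidate:
    """A protospacer candidate: the bases immediately 3' of a PAM match."""

    sequence: str
    strand: str
    start: int          # protospacer interval on the + strand
    end: int
    pam: str
    pam_start: int
    gc: float


@dataclass(frozen=True)
class RmScan:
    """Degenerate-motif scan result over both strands."""

    count: int
    positions: tuple[int, ...]   # match start on the + strand
    strands: tuple[str, ...]


@dataclass(frozen=True)
class QuantInput:
    """qPCR crossing points and primer efficiencies for the Pfaffl ratio."""

    E_target: float
    E_reference: float
    Cp_target: float
    Cp_reference: float

    def __post_init__(self):
        for name, e in (("E_target", self.E_target), ("E_reference", self.E_reference)):
            if not (1.0 < e <= 2.0):
                raise ValueError(f"{name} must be in (1, 2], got {e}")
        if self.Cp_target < 0 or self.Cp_reference < 0:
            raise ValueError("crossing points must be >= 0")


@dataclass
class EditDesign:
    """A deletion or insertion design with its template, spacer and checks."""

    genome_id: str
    kind: str                                  # deletion | insertion
    lha: str
    rha: str
    lha_interval: tuple[int, int]
    rha_interval: tuple[int, int]
    edited_locus: str
    deletion_interval: tuple[int, int] | None = None
    insertion_point: int | None = None
    cargo: str | None = None
    spacer: SpacerCandidate | None = None
    synthetic_array: str = ""
    flags: dict = field(default_factory=dict)
    predicted_amplicons: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"invalid design kind {self.kind!r}")
        if self.kind == "deletion":
            if self.deletion_interval is None:
                raise ValueError("deletion design requires deletion_interval")
            if self.cargo:
                raise ValueError("deletion design must not carry cargo")
        else:
            if self.cargo is None:
                raise ValueError("insertion design requires cargo")

    @property
    def edit_size(self) -> int:
        """Deletion length, or cargo length net of any replaced bases."""
        if self.kind == "deletion":
            s, e = self.deletion_interval
            return e - s
        removed = 0
        if self.deletion_interval is not None:
            s, e = self.deletion_interval
            removed = e - s
        return len(self.cargo) - removed


def derive_native_flanks(direct_repeat: str, n: int = 5) -> tuple[str, str]:
    """The repeat-derived sequences flanking a spacer in the native array.

    5' side = last n bases of the direct repeat (precedes each spacer),
    3' side = first n bases (follows it).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n > len(direct_repeat):
        raise ValueError(
            f"n={n} exceeds direct repeat length {len(direct_repeat)}"
        )
    if n == 0:
        return "", ""
    return direct_repeat[-n:], direct_repeat[:n]


def build_interference_construct(
    protospacer: str, five_prime: str, three_prime: str
) -> str:
    """Assemble a test insert: 5' flank (native or candidate PAM) + protospacer + 3' flank."""
    return (
        validate_dna(five_prime, where="5' flank")
        + validate_dna(protospacer, where="protospacer")
        + validate_dna(three_prime, where="3' flank")
    )


def find_candidate_spacers(
    genome: GenomeRecord,
    region: tuple[int, int],
    pam_patterns: Sequence[str],
    length: int = DEFAULT_SPACER_LENGTH,
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS,
) -> list[SpacerCandidate]:
    """Scan both strands of ``region`` for PAM matches and their 3' spacers.

    The PAM lies 5' of the protospacer; both PAM and protospacer must fall
    inside the region. GC bounds are inclusive. Sorted by position then
    strand; an empty result is not an error (relax the PAM patterns).
    """
    start, end = region
    if not (0 <= start < end <= len(genome.sequence)):
        raise ValueError(f"region [{start},{end}) outside genome {genome.id!r}")
    window = genome.sequence[start:end]
    lo, hi = gc_bounds
    out = []
    for pattern in pam_patterns:
        plen = len(pattern)
        # + strand
        for m in find_motif(window, pattern):
            sp_start = start + m + plen
            sp_end = sp_start + length
            if sp_end > end:
                continue
            seq = genome.sequence[sp_start:sp_end]
            gc = gc_fraction(seq)
            if lo <= gc <= hi:
                out.append(SpacerCandidate(
                    sequence=seq, strand="+", start=sp_start, end=sp_end,
                    pam=genome.sequence[start + m:sp_start],
                    pam_start=start + m, gc=gc,
                ))
        # - strand: scan the reverse complement of the window
        rc = revcomp(window)
        wlen = end - start
        for m in find_motif(rc, pattern):
            sp_rc_start = m + plen
            sp_rc_end = sp_rc_start + length
            if sp_rc_end > wlen:
                continue
            seq = rc[sp_rc_start:sp_rc_end]
            gc = gc_fraction(seq)
            if lo <= gc <= hi:
                sp_start = end - sp_rc_end
                out.append(SpacerCandidate(
                    sequence=seq, strand="-", start=sp_start, end=end - sp_rc_start,
                    pam=rc[m:sp_rc_start],
                    pam_start=end - sp_rc_start, gc=gc,
                ))
    # dedupe (same site may match several patterns), deterministic order
    seen = set()
    unique = []
    for c in sorted(out, key=lambda c: (c.start, c.strand, c.pam)):
        key = (c.start, c.end, c.strand)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    return unique


def build_synthetic_array(leader: str, direct_repeat: str, spacer: str) -> str:
    """Leader + DR + spacer + DR, mimicking a one-spacer native array."""
    import logging

    if not spacer:
        raise ValueError("spacer must be non-empty")
    if not leader or not direct_repeat:
        raise ValueError("leader and direct repeat must be non-empty")
    if spacer == direct_repeat:
        logging.getLogger(__name__).warning(
            "spacer identical to direct repeat: recombination between the "
            "flanking repeats is likely to excise it"
        )
    return leader + direct_repeat + spacer + direct_repeat


def build_editing_template(
    genome: GenomeRecord,
    *,
    deletion: tuple[int, int] | None = None,
    insertion: tuple[int, str] | None = None,
    replacement: tuple[tuple[int, int], str] | None = None,
    lha_len: int,
    rha_len: int,
) -> EditDesign:
    """Homology arms around an edit and the resulting edited locus.

    Exactly one of ``deletion`` (interval to remove), ``insertion``
    ((point, cargo)), or ``replacement`` ((interval, cargo), e.g. a knock-in
    in place of the PAM) must be given. The edited locus is LHA + cargo (if
    any) + RHA; arms running off the contig are an error.
    """
    seq = genome.sequence
    given = [x is not None for x in (deletion, insertion, replacement)]
    if sum(given) != 1:
        raise ValueError("specify exactly one of deletion/insertion/replacement")
    if deletion is not None:
        s, e = deletion
        if s >= e:
            raise ValueError(f"empty deletion interval [{s},{e})")
        kind, cargo, del_interval, ins_point = "deletion", None, (s, e), None
    elif insertion is not None:
        p, cargo = insertion
        cargo = validate_dna(cargo, where="cargo")
        if not cargo:
            raise ValueError("insertion cargo must be non-empty")
        kind, del_interval, ins_point = "insertion", None, p
        s = e = p
    else:
        (s, e), cargo = replacement
        if s >= e:
            raise ValueError(f"empty replacement interval [{s},{e})")
        cargo = validate_dna(cargo, where="cargo")
        kind, del_interval, ins_point = "insertion", (s, e), None
    if s - lha_len < 0 or e + rha_len > len(seq):
        raise ValueError(
            f"homology arms [{s - lha_len},{e + rha_len}) run off contig "
            f"{genome.id!r} (length {len(seq)})"
        )
    lha = seq[s - lha_len:s]
    rha = seq[e:e + rha_len]
    edited = lha + (cargo or "") + rha
    return EditDesign(
        genome_id=genome.id,
        kind=kind,
        lha=lha, rha=rha,
        lha_interval=(s - lha_len, s),
        rha_interval=(e, e + rha_len),
        edited_locus=edited,
        deletion_interval=del_interval,
        insertion_point=ins_point,
        cargo=cargo,
    )


def predicted_amplicon_delta(wt_len: int, edited_len: int) -> int:
    """Absolute WT vs edited screening-amplicon size difference."""
    if wt_len <= 0 or edited_len <= 0:
        raise ValueError("amplicon lengths must be positive")
    return abs(wt_len - edited_len)


def check_amplicons(design: EditDesign, wt_len: int, edited_len: int) -> dict:
    """Record predicted amplicon sizes and flag disagreement with the edit size."""
    delta = predicted_amplicon_delta(wt_len, edited_len)
    design.predicted_amplicons = {
        "wt_len": wt_len,
        "edited_len": edited_len,
        "delta": delta,
        "consistent": delta == design.edit_size,
    }
    return design.predicted_amplicons


def scan_rm_sites(seq: str, motif: str = DEFAULT_RM_MOTIF) -> RmScan:
    """Find a degenerate recognition motif on both strands.

    Overlapping matches are all reported; positions are + strand starts,
    ordered by (position, strand).
    """
    seq = validate_dna(seq, where="scanned sequence")
    fwd = [(p, "+") for p in find_motif(seq, motif)]
    rc_motif = revcomp(motif)
    rev = [(p, "-") for p in find_motif(seq, rc_motif)]
    matches = sorted(fwd + rev)
    return RmScan(
        count=len(matches),
        positions=tuple(p for p, _ in matches),
        strands=tuple(s for _, s in matches),
    )


def validate_design(
    design: EditDesign,
    genome: GenomeRecord | None = None,
    cds_intervals: Sequence[tuple[int, int]] | None = None,
    rm_motif: str = DEFAULT_RM_MOTIF,
) -> dict:
    """Compute the design's validation flags (never raises on a bad design).

    * ``in_frame``: deletion length divisible by 3 when the deletion lies
      within a supplied CDS interval, else "n/a";
    * ``target_destroyed``: the edited locus contains neither PAM+protospacer
      nor its reverse complement (interference needs both, so removing or
      splitting either lets the edited chromosome escape self-targeting);
    * ``spacer_to_arm_distance``: nearest distance from the spacer to a
      homology arm (reported, not constrained);
    * ``rm_site_count``: recognition sites in the edited locus and in the
      whole cassette (synthetic array + template).
    """
    flags: dict = {}
    if design.kind == "deletion" and cds_intervals:
        s, e = design.deletion_interval
        inside = any(cs <= s and e <= ce for cs, ce in cds_intervals)
        flags["in_frame"] = ((e - s) % 3 == 0) if inside else "n/a"
    else:
        flags["in_frame"] = "n/a"

    if design.spacer is not None:
        target = design.spacer.pam + design.spacer.sequence
        flags["target_destroyed"] = (
            target not in design.edited_locus
            and revcomp(target) not in design.edited_locus
        )
        ls, le = design.lha_interval
        rs, re_ = design.rha_interval
        ss, se = design.spacer.start, design.spacer.end
        # distance from the spacer's near edge to the nearest arm edge
        def _dist(a0, a1):
            if se <= a0:
                return a0 - se
            if ss >= a1:
                return ss - a1
            return 0
        flags["spacer_to_arm_distance"] = min(_dist(ls, le), _dist(rs, re_))
    else:
        flags["target_destroyed"] = None
        flags["spacer_to_arm_distance"] = None

    cassette = design.synthetic_array + design.edited_locus
    flags["rm_site_count"] = {
        "edited_locus": scan_rm_sites(design.edited_locus, rm_motif).count,
        "cassette": scan_rm_sites(cassette, rm_motif).count if cassette else 0,
    }
    design.flags.update(flags)
    return flags


def pfaffl_expression(q: QuantInput) -> float:
    """Efficiency-corrected relative expression: E_t^(-Cp_t) / E_r^(-Cp_r)."""
    return (q.E_target ** -q.Cp_target) / (q.E_reference ** -q.Cp_reference)
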