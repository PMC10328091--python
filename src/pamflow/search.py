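"""Spacer -> protospacer search with the seed/global mismatch filters.

The search replaces the original BLASTn call with an exhaustive windowed
Hamming scan of both strands (vectorized with numpy), applying the published
filter: global mismatch fraction strictly below ``max_mismatch_fraction``
(default 20%) and at most ``max_seed_mismatches`` (default 1) within the
``seed_length`` (default 7) PAM-proximal nucleotides. Externally computed
12-column tabular alignments can be imported through the same filters.

Conventions
-----------
* Spacers are in crRNA orientation (apply ``orient_array`` first).
* ``interval`` is always on the subject's + strand, 0-based half-open.
* Mismatch positions are 1-based from the PAM-proximal (5') end of the
  protospacer, i.e. position 1 is the base right next to the PAM.
* ``upstream_flank`` is read in protospacer orientation and is the PAM side
  for the 5'-PAM Type I-B convention used throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import N_CODE, encode, revcomp
from .model import GenomeRecord, SearchParams

log = logging.getLogger(__name__)


@dataclass
class MgeEvidence:
    """Why a hit is attributed to a mobile genetic element."""

    category: str  # title_keyword | prophage_interval | feature_keyword | none
    detail: str = ""
    keyword_set_version: str = "default"

    def __post_init__(self):
        if self.category not in (
            "title_keyword", "prophage_interval", "feature_keyword", "none"
        ):
            raise ValueError(f"invalid MGE category {self.category!r}")
        if self.category == "none" and self.detail:
            raise ValueError("category 'none' must carry no detail")


@dataclass
class SpacerHit:
    """One spacer->protospacer match with its mismatch geometry and flanks."""

    spacer_id: str
    spacer_seq: str
    subject_id: str
    subject_title: str
    strand: str
    interval: tuple[int, int]
    mismatch_count: int
    mismatch_positions: list[int]
    gap_count: int = 0
    upstream_flank: str = ""
    downstream_flank: str = ""
    flank_truncated: bool = False
    mge: MgeEvidence | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.mismatch_count != len(self.mismatch_positions):
            raise ValueError("mismatch_count disagrees with mismatch_positions")

    def sort_key(self):
        return (self.spacer_id, self.subject_id, self.strand, self.interval[0])


def count_mismatches(spacer: str, window: str, n_policy: str = "mismatch"):
    """Compare equal-length strings; positions are 1-based from the 5' end.

    Under ``n_policy='mismatch'`` an N in either string is a mismatch; under
    ``'wildcard'`` it matches anything.
    """
    if len(spacer) != len(window):
        raise ValueError(
            f"length mismatch: spacer {len(spacer)} vs window {len(window)}"
        )
    positions = []
    for i, (a, b) in enumerate(zip(spacer.upper(), window.upper()), start=1):
        if a == "N" or b == "N":
            if n_policy == "mismatch":
                positions.append(i)
            continue
        if a != b:
            positions.append(i)
    return len(positions), positions


def extract_flanks(
    subject: GenomeRecord,
    interval: tuple[int, int],
    strand: str,
    up_len: int,
    down_len: int,
):
    """Flanks of a protospacer, read in protospacer orientation.

    ``upstream`` is the PAM side (5' of the protospacer). Flanks shortened by
    a contig edge come back truncated with ``truncated=True``.
    """
    seq = subject.sequence
    s, e = interval
    if not (0 <= s < e <= len(seq)):
        raise ValueError(f"interval [{s},{e}) outside subject {subject.id!r}")
    if strand == "+":
        up = seq[max(0, s - up_len):s]
        down = seq[e:e + down_len]
    else:
        up = revcomp(seq[e:e + up_len])
        down = revcomp(seq[max(0, s - down_len):s])
    truncated = len(up) < up_len or len(down) < down_len
    return up, down, truncated


def _as_spacer_items(spacers) -> list[tuple[str, str]]:
    if isinstance(spacers, Mapping):
        return [(str(k), v) for k, v in spacers.items()]
    items = []
    for i, s in enumerate(spacers):
        if isinstance(s, tuple):
            items.append((str(s[0]), s[1]))
        else:
            items.append((f"spacer_{i + 1}", s))
    return items


def _overlaps_any(interval, intervals) -> bool:
    s, e = interval
    return any(s < b and a < e for a, b in intervals)


def _scan_one_strand(enc_subject, enc_spacer, params, seed_slice, n_mask_policy):
    """Vectorized window scan; returns (indices, mismatch matrix rows)."""
    L = enc_spacer.size
    if enc_subject.size < L:
        return np.empty(0, dtype=int), None
    windows = sliding_window_view(enc_subject, L)
    neq = windows != enc_spacer
    n_mask = (windows == N_CODE) | (enc_spacer == N_CODE)
    if n_mask_policy == "mismatch":
        neq = neq | n_mask
    else:  # wildcard: N matches anything
        neq = neq & ~n_mask
    mm = neq.sum(axis=1)
    seed_mm = neq[:, seed_slice].sum(axis=1)
    keep = (mm / L < params.max_mismatch_fraction) & (
        seed_mm <= params.max_seed_mismatches
    )
    idx = np.nonzero(keep)[0]
    return idx, neq


def _dedup_overlapping(hits: list[SpacerHit]) -> list[SpacerHit]:
    """Reduce overlapping same-spacer/same-strand hits to the best one.

    Within a chain of mutually overlapping windows, keep the lowest-mismatch
    hit, ties broken leftmost.
    """
    out = []
    by_group: dict[tuple, list[SpacerHit]] = {}
    for h in hits:
        by_group.setdefault((h.spacer_id, h.subject_id, h.strand), []).append(h)
    for group in by_group.values():
        group.sort(key=lambda h: h.interval)
        cluster: list[SpacerHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.interval[0] < cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.interval[1])
            else:
                if cluster:
                    out.append(min(cluster, key=lambda x: (x.mismatch_count, x.interval[0])))
                cluster = [h]
                cluster_end = h.interval[1]
        if cluster:
            out.append(min(cluster, key=lambda x: (x.mismatch_count, x.interval[0])))
    out.sort(key=SpacerHit.sort_key)
    return out


def search_spacers(
    spacers,
    subjects: Sequence[GenomeRecord],
    params: SearchParams = SearchParams(),
    exclude: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[SpacerHit]:
    """Exhaustive both-strand search of every subject for every spacer.

    A window is a hit iff its global mismatch fraction is strictly below
    ``params.max_mismatch_fraction`` and it has at most
    ``params.max_seed_mismatches`` mismatches within the ``seed_length``
    PAM-proximal positions. Hits overlapping an ``exclude`` interval (e.g.
    the source array locus) are dropped; overlapping same-spacer same-strand
    windows are reduced to the best one.
    """
    items = _as_spacer_items(spacers)
    exclude = exclude or {}
    for sid, seq in items:
        if len(seq) < params.seed_length:
            raise ValueError(
                f"spacer {sid!r} shorter ({len(seq)}) than seed_length "
                f"({params.seed_length})"
            )
    hits: list[SpacerHit] = []
    for subject in subjects:
        enc_subj = encode(subject.sequence)
        excl = exclude.get(subject.id, ())
        for sid, sseq in items:
            L = len(sseq)
            # + strand: window index == protospacer 5' end; mismatch matrix
            # column j is protospacer position j+1
            enc_sp = encode(sseq)
            idx, neq = _scan_one_strand(
                enc_subj, enc_sp, params, slice(0, params.seed_length), params.n_policy
            )
            for i in idx:
                interval = (int(i), int(i) + L)
                if _overlaps_any(interval, excl):
                    continue
                positions = [int(j) + 1 for j in np.nonzero(neq[i])[0]]
                up, down, trunc = extract_flanks(
                    subject, interval, "+",
                    params.upstream_flank_len, params.downstream_flank_len,
                )
                hits.append(SpacerHit(
                    spacer_id=sid, spacer_seq=sseq,
                    subject_id=subject.id, subject_title=subject.title,
                    strand="+", interval=interval,
                    mismatch_count=len(positions), mismatch_positions=positions,
                    upstream_flank=up, downstream_flank=down,
                    flank_truncated=trunc,
                ))
            # - strand: scan + strand with the reverse complement; window
            # column j corresponds to protospacer position L - j
            enc_rc = encode(revcomp(sseq))
            idx, neq = _scan_one_strand(
                enc_subj, enc_rc, params,
                slice(L - params.seed_length, L), params.n_policy,
            )
            for i in idx:
                interval = (int(i), int(i) + L)
                if _overlaps_any(interval, excl):
                    continue
                positions = sorted(L - int(j) for j in np.nonzero(neq[i])[0])
                up, down, trunc = extract_flanks(
                    subject, interval, "-",
                    params.upstream_flank_len, params.downstream_flank_len,
                )
                hits.append(SpacerHit(
                    spacer_id=sid, spacer_seq=sseq,
                    subject_id=subject.id, subject_title=subject.title,
                    strand="-", interval=interval,
                    mismatch_count=len(positions), mismatch_positions=positions,
                    upstream_flank=up, downstream_flank=down,
                    flank_truncated=trunc,
                ))
    return _dedup_overlapping(hits)


# ---------------------------------------------------------------------------
# Tabular (BLAST outfmt-6 style) import


def _gapped_compare(spacer: str, window: str):
    """Global re-alignment of spacer vs protospacer-oriented window.

    Returns (mismatch_count, positions, gap_count) with every gap column
    counted as a mismatch at the nearest spacer position.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(spacer, window)[0]
    a, b = str(aln[0]), str(aln[1])
    positions = []
    gap_count = 0
    spacer_pos = 0
    for ca, cb in zip(a, b):
        if ca != "-":
            spacer_pos += 1
        if ca == "-" or cb == "-":
            gap_count += 1
            positions.append(max(spacer_pos, 1))
        elif ca != cb or ca == "N" or cb == "N":
            positions.append(spacer_pos)
    positions = sorted(set(positions))
    return len(positions), positions, gap_count


def import_tabular_hits(
    path,
    spacers,
    subjects: Sequence[GenomeRecord],
    params: SearchParams = SearchParams(),
) -> list[SpacerHit]:
    """Convert 12-column tabular alignment rows into filtered SpacerHits.

    Mismatch geometry is recomputed by re-comparing the spacer to the subject
    window, so the same seed/global filters as ``search_spacers`` apply.
    Partial-query rows are rejected; gapped rows follow ``params.gap_policy``.
    """
    items = dict(_as_spacer_items(spacers))
    by_id = {r.id: r for r in subjects}
    hits = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(fields)}")
        try:
            (qid, sid, _pident, length, _mism, gaps,
             qstart, qend, sstart, send, _evalue, _bits) = fields
            length, gaps = int(length), int(gaps)
            qstart, qend, sstart, send = map(int, (qstart, qend, sstart, send))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
        if qid not in items:
            raise ValueError(f"{path}:{lineno}: unknown spacer id {qid!r}")
        if sid not in by_id:
            raise ValueError(f"{path}:{lineno}: unknown subject id {sid!r}")
        sseq = items[qid]
        L = len(sseq)
        if qstart > 1 or qend < L:
            log.info("%s:%d dropped: partial (qstart=%d qend=%d)", path, lineno, qstart, qend)
            continue
        if gaps > 0 and params.gap_policy == "forbid":
            log.info("%s:%d dropped: gap_policy forbid (gaps=%d)", path, lineno, gaps)
            continue
        subject = by_id[sid]
        if sstart <= send:
            strand, interval = "+", (sstart - 1, send)
        else:
            strand, interval = "-", (send - 1, sstart)
        window = subject.sequence[interval[0]:interval[1]]
        if strand == "-":
            window = revcomp(window)
        if len(window) == L and gaps == 0:
            count, positions = count_mismatches(sseq, window, params.n_policy)
            gap_count = 0
        else:
            count, positions, gap_count = _gapped_compare(sseq, window)
        if count / L >= params.max_mismatch_fraction:
            log.info("%s:%d dropped: global_mismatch (%d/%d)", path, lineno, count, L)
            continue
        seed_mm = sum(1 for p in positions if p <= params.seed_length)
        if seed_mm > params.max_seed_mismatches:
            log.info("%s:%d dropped: seed_mismatch (%d)", path, lineno, seed_mm)
            continue
        up, down, trunc = extract_flanks(
            subject, interval, strand,
            params.upstream_flank_len, params.downstream_flank_len,
        )
        hits.append(SpacerHit(
            spacer_id=qid, spacer_seq=sseq,
            subject_id=sid, subject_title=subject.title,
            strand=strand, interval=interval,
            mismatch_count=count, mismatch_positions=positions,
            gap_count=gap_count,
            upstream_flank=up, downstream_flank=down, flank_truncated=trunc,
        ))
    hits.sort(key=SpacerHit.sort_key)
    return hits
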