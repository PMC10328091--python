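"""PAM consensus from the 5' flanks of MGE-retained hits.

Given the upstream (PAM-side) flanks of the retained hits, this module builds
a position frequency matrix over the k PAM-proximal positions (columns
indexed -k..-1, -1 adjacent to the protospacer), derives a degenerate IUPAC
consensus, computes the per-position information content used by sequence
logos, and enumerates short candidate motifs (default trinucleotides, the
length of every PAM validated in the source system).

A report is only issued when at least ``min_mge_hits`` (default 2) hits
contribute; fewer yields status ``insufficient_mge_hits``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import IUPAC_BY_BASES
from .search import SpacerHit

DEFAULT_K = 5
DEFAULT_CANDIDATE_K = 3
DEFAULT_MIN_MGE_HITS = 2


@dataclass
class PamReport:
    """Frequency matrix, consensus, information content and candidate motifs."""

    k: int
    pfm: pd.DataFrame | None
    consensus: str
    information_content: list[float]
    candidates: list[tuple[str, int]]
    dinucleotide_counts: dict[str, dict[str, int]]
    n_contributing_hits: int
    status: str = "ok"

    def top_candidate(self) -> tuple[str, int] | None:
        return self.candidates[0] if self.candidates else None


def build_pfm(flanks: Sequence[str], k: int) -> pd.DataFrame:
    """Base counts over the k PAM-proximal flank positions.

    Rows A/C/G/T, columns -k..-1. Bases outside {A,C,G,T} (e.g. N) are
    excluded from their column's counts. Flanks shorter than k must be
    filtered out by the caller.
    """
    if not flanks:
        raise ValueError("no flanks to tally")
    for f in flanks:
        if len(f) < k:
            raise ValueError(
                f"flank {f!r} shorter than k={k}; exclude truncated flanks first"
            )
    cols = list(range(-k, 0))
    pfm = pd.DataFrame(0, index=list("ACGT"), columns=cols, dtype=int)
    for flank in flanks:
        tail = flank[-k:]
        for col, base in zip(cols, tail):
            if base in "ACGT":
                pfm.loc[base, col] += 1
    return pfm


def consensus_iupac(pfm: pd.DataFrame, mode: str = "covering") -> str:
    """Degenerate consensus from a PFM.

    ``covering``: per column, the IUPAC code of every base observed at least
    once. ``majority``: the single base if its frequency exceeds 0.5, else
    the code of all bases with frequency >= 0.25, else N.
    """
    if mode not in ("covering", "majority"):
        raise ValueError(f"unknown consensus mode {mode!r}")
    out = []
    for col in pfm.columns:
        counts = pfm[col]
        total = counts.sum()
        if total == 0:
            raise ValueError(f"PFM column {col} is empty")
        if mode == "covering":
            bases = frozenset(counts.index[counts > 0])
        else:
            freqs = counts / total
            top = freqs.idxmax()
            if freqs[top] > 0.5:
                bases = frozenset(top)
            else:
                bases = frozenset(freqs.index[freqs >= 0.25])
                if not bases:
                    bases = frozenset("ACGT")
        out.append(IUPAC_BY_BASES[bases])
    return "".join(out)


def information_content(
    pfm: pd.DataFrame,
    small_sample_correction: bool = False,
) -> list[float]:
    """Per-column information content in bits: IC = 2 + sum p*log2(p).

    The optional small-sample correction subtracts the standard
    e(n) = 3 / (2 ln2 n) term per column.
    """
    out = []
    for col in pfm.columns:
        counts = pfm[col].to_numpy(dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"PFM column {col} is empty")
        p = counts[counts > 0] / total
        ic = 2.0 + float(np.sum(p * np.log2(p)))
        if small_sample_correction:
            ic -= 3.0 / (2.0 * np.log(2) * total)
        out.append(max(ic, 0.0))
    return out


def call_pam(
    hits: Sequence[SpacerHit],
    k: int = DEFAULT_K,
    min_mge_hits: int = DEFAULT_MIN_MGE_HITS,
    candidate_k: int = DEFAULT_CANDIDATE_K,
    mode: str = "covering",
) -> PamReport:
    """Compile the PAM report from MGE-retained hits.

    Truncated flanks (shorter than k) are excluded rather than padded. With
    fewer than ``min_mge_hits`` usable flanks the report carries status
    ``insufficient_mge_hits`` and no consensus — the published rule requires
    at least two phage-region hits before a consensus is drawn.
    """
    flanks = [h.upstream_flank for h in hits if len(h.upstream_flank) >= k]
    n = len(flanks)
    if n < min_mge_hits:
        return PamReport(
            k=k, pfm=None, consensus="", information_content=[],
            candidates=[], dinucleotide_counts={},
            n_contributing_hits=n, status="insufficient_mge_hits",
        )
    flanks = sorted(flanks)  # hit order must not matter
    pfm = build_pfm(flanks, k)
    cand = Counter(f[-candidate_k:] for f in flanks)
    candidates = sorted(cand.items(), key=lambda kv: (-kv[1], kv[0]))
    dinucs = {
        "-3:-2": dict(sorted(Counter(f[-3:-1] for f in flanks).items())),
        "-2:-1": dict(sorted(Counter(f[-2:] for f in flanks).items())),
    }
    return PamReport(
        k=k,
        pfm=pfm,
        consensus=consensus_iupac(pfm, mode),
        information_content=information_content(pfm),
        candidates=candidates,
        dinucleotide_counts=dinucs,
        n_contributing_hits=n,
        status="ok",
    )
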