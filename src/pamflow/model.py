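"""Domain types and file I/O for the PAM-prediction pipeline.

All genomic coordinates in this package are 0-based half-open; 1-based
coordinates appear only as extra presentation columns in the written report.

Formats handled here:

* FASTA subject/genome records (via Biopython).
* CRISPR locus files — a small key/value dialect carrying what a
  CRISPRFinder-style record provides (direct repeat, ordered spacers,
  coordinates, orientation, leader). See ``read_crispr_locus``.
* BED3 prophage intervals.
* A delimited feature table (record_id/start/end/strand/kind/label).
* The tabular hit + consensus report (TSV/CSV, or spreadsheet export).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_dna

ORIENTATIONS = ("forward", "reverse", "unknown")

REPORT_COLUMNS = [
    "spacer_id",
    "spacer_seq",
    "subject_id",
    "subject_title",
    "strand",
    "start",
    "end",
    "start_1based",
    "end_1based",
    "mismatch_count",
    "mismatch_positions",
    "gap_count",
    "upstream_flank",
    "downstream_flank",
    "flank_truncated",
    "mge_category",
    "mge_detail",
]


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature on a subject record (half-open coordinates)."""

    start: int
    end: int
    strand: str = "+"
    label: str = ""
    kind: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class GenomeRecord:
    """A subject sequence with the annotation the MGE filter consumes."""

    id: str
    sequence: str
    title: str = ""
    features: list[FeatureAnnotation] = field(default_factory=list)
    prophage_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = validate_dna(self.sequence, where=f"record {self.id!r}")
        for s, e in self.prophage_intervals:
            self._check_interval(s, e)
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature [{f.start},{f.end}) exceeds length of record {self.id!r}"
                )

    def _check_interval(self, start: int, end: int):
        if not (0 <= start < end <= len(self.sequence)):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for record "
                f"{self.id!r} (length {len(self.sequence)})"
            )

    def __len__(self):
        return len(self.sequence)


@dataclass
class CrisprArray:
    """A CRISPR locus: direct repeat, ordered spacers, placement on the host.

    Spacer index 1 is the leader-proximal (most recently acquired) spacer.
    When ``orientation`` is known, sequences are stored in crRNA orientation.
    """

    array_id: str
    host_id: str
    interval: tuple[int, int]
    direct_repeat: str
    spacers: list[str]
    orientation: str = "unknown"
    leader: str | None = None
    evidence_level: int | None = None

    def __post_init__(self):
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"invalid orientation {self.orientation!r}")
        self.direct_repeat = validate_dna(self.direct_repeat, where="direct repeat")
        if len(self.direct_repeat) < 18:
            raise ValueError(
                f"direct repeat length {len(self.direct_repeat)} < 18 nt"
            )
        if not self.spacers:
            raise ValueError("CRISPR array must contain at least one spacer")
        self.spacers = [
            validate_dna(s, where=f"spacer {i + 1}") for i, s in enumerate(self.spacers)
        ]
        if any(not s for s in self.spacers):
            raise ValueError("empty spacer sequence")
        if self.leader is not None:
            self.leader = validate_dna(self.leader, where="leader")
        s, e = self.interval
        if not (0 <= s < e):
            raise ValueError(f"invalid array interval [{s},{e})")

    def spacer_items(self) -> list[tuple[str, str]]:
        """(spacer_id, sequence) pairs; ids are 1-based, leader-proximal first."""
        width = len(str(len(self.spacers)))
        return [
            (f"{self.array_id}_sp{str(i + 1).zfill(width)}", s)
            for i, s in enumerate(self.spacers)
        ]


@dataclass(frozen=True)
class SearchParams:
    """Filtering parameters for the spacer->protospacer search.

    Defaults implement the published filter: global mismatch fraction
    strictly below 0.20 and at most one mismatch within the seven
    PAM-proximal (seed) nucleotides.
    """

    max_mismatch_fraction: float = 0.20
    seed_length: int = 7
    max_seed_mismatches: int = 1
    upstream_flank_len: int = 5
    downstream_flank_len: int = 5
    gap_policy: str = "forbid"
    n_policy: str = "mismatch"

    def __post_init__(self):
        if not (0 < self.max_mismatch_fraction < 1):
            raise ValueError("max_mismatch_fraction must be in (0,1)")
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if self.max_seed_mismatches < 0:
            raise ValueError("max_seed_mismatches must be >= 0")
        if self.upstream_flank_len < 0 or self.downstream_flank_len < 0:
            raise ValueError("flank lengths must be >= 0")
        if self.gap_policy not in ("forbid", "count_as_mismatch"):
            raise ValueError(f"invalid gap_policy {self.gap_policy!r}")
        if self.n_policy not in ("mismatch", "wildcard"):
            raise ValueError(f"invalid n_policy {self.n_policy!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeRecord]:
    """Read subject records; header text after the id token becomes the title."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            GenomeRecord(
                id=rec.id,
                title=rec.description[len(rec.id):].strip(),
                sequence=str(rec.seq),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.title) for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# CRISPR locus dialect
#
#   array_id      aw_array2
#   host_id       CP002987.1
#   start         1234
#   end           5678
#   direct_repeat ATTTACATT...
#   orientation   forward          (optional; default unknown)
#   leader        ACGT...          (optional)
#   evidence_level 4               (optional)
#   spacer        GCTTACCAAT...    (one line per spacer, in array order)

_LOCUS_KEYS = {
    "array_id", "host_id", "start", "end", "direct_repeat",
    "orientation", "leader", "evidence_level", "spacer",
}


def read_crispr_locus(path) -> CrisprArray:
    """Parse the documented key/value locus dialect into a CrisprArray."""
    path = Path(path)
    kv: dict[str, str] = {}
    spacers: list[str] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'key value', got {line!r}")
        key, value = parts[0].lower(), parts[1].strip()
        if key not in _LOCUS_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if key == "spacer":
            spacers.append(value)
        else:
            kv[key] = value
    if "direct_repeat" not in kv:
        raise ValueError(f"{path}: missing direct_repeat")
    if not spacers:
        raise ValueError(f"{path}: locus file lists no spacers")
    return CrisprArray(
        array_id=kv.get("array_id", path.stem),
        host_id=kv.get("host_id", ""),
        interval=(int(kv.get("start", 0)), int(kv.get("end", 1))),
        direct_repeat=kv["direct_repeat"],
        spacers=spacers,
        orientation=kv.get("orientation", "unknown"),
        leader=kv.get("leader"),
        evidence_level=int(kv["evidence_level"]) if "evidence_level" in kv else None,
    )


def write_crispr_locus(array: CrisprArray, path) -> None:
    lines = [
        f"array_id\t{array.array_id}",
        f"host_id\t{array.host_id}",
        f"start\t{array.interval[0]}",
        f"end\t{array.interval[1]}",
        f"direct_repeat\t{array.direct_repeat}",
        f"orientation\t{array.orientation}",
    ]
    if array.leader is not None:
        lines.append(f"leader\t{array.leader}")
    if array.evidence_level is not None:
        lines.append(f"evidence_level\t{array.evidence_level}")
    lines += [f"spacer\t{s}" for s in array.spacers]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED3 prophage intervals and the feature table


def read_prophage_bed(path, records: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Attach BED3 intervals to matching records; unknown ids are skipped.

    Returns the same record objects (mutated in place) for convenience.
    """
    import logging

    log = logging.getLogger(__name__)
    by_id = {r.id: r for r in records}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
        rid, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
        rec = by_id.get(rid)
        if rec is None:
            log.warning("%s:%d: unknown record id %r, interval skipped", path, lineno, rid)
            continue
        rec._check_interval(start, end)
        rec.prophage_intervals.append((start, end))
    return list(records)


def read_feature_table(path, records: Sequence[GenomeRecord]) -> list[GenomeRecord]:
    """Attach features from a TSV with columns record_id/start/end/strand/kind/label."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"record_id", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    by_id = {r.id: r for r in records}
    for row in df.itertuples(index=False):
        rec = by_id.get(row.record_id)
        if rec is None:
            continue
        feat = FeatureAnnotation(
            start=int(row.start),
            end=int(row.end),
            strand=getattr(row, "strand", "+") or "+",
            kind=getattr(row, "kind", ""),
            label=getattr(row, "label", ""),
        )
        if feat.end > len(rec.sequence):
            raise ValueError(
                f"feature [{feat.start},{feat.end}) exceeds record {rec.id!r}"
            )
        rec.features.append(feat)
    return list(records)


def write_feature_table(records: Iterable[GenomeRecord], path) -> None:
    rows = [
        {
            "record_id": r.id,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "kind": f.kind,
            "label": f.label,
        }
        for r in records
        for f in r.features
    ]
    pd.DataFrame(rows, columns=["record_id", "start", "end", "strand", "kind", "label"]).to_csv(
        path, sep="\t", index=False
    )


def write_prophage_bed(records: Iterable[GenomeRecord], path) -> None:
    lines = [
        f"{r.id}\t{s}\t{e}"
        for r in records
        for (s, e) in r.prophage_intervals
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Report


def hits_to_frame(hits) -> pd.DataFrame:
    """Tabulate SpacerHit objects into the report schema (deterministic order)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "spacer_id": h.spacer_id,
                "spacer_seq": h.spacer_seq,
                "subject_id": h.subject_id,
                "subject_title": h.subject_title,
                "strand": h.strand,
                "start": h.interval[0],
                "end": h.interval[1],
                "start_1based": h.interval[0] + 1,
                "end_1based": h.interval[1],
                "mismatch_count": h.mismatch_count,
                "mismatch_positions": ",".join(map(str, h.mismatch_positions)),
                "gap_count": h.gap_count,
                "upstream_flank": h.upstream_flank,
                "downstream_flank": h.downstream_flank,
                "flank_truncated": h.flank_truncated,
                "mge_category": h.mge.category if h.mge else "",
                "mge_detail": h.mge.detail if h.mge else "",
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return df.sort_values(
        ["spacer_id", "subject_id", "strand", "start"], kind="mergesort"
    ).reset_index(drop=True)


def _consensus_block(pam_report) -> list[str]:
    lines = [f"# status\t{pam_report.status}",
             f"# n_contributing_hits\t{pam_report.n_contributing_hits}"]
    if pam_report.status == "ok":
        lines.append(f"# consensus\t{pam_report.consensus}")
        cols = "\t".join(str(c) for c in pam_report.pfm.columns)
        lines.append(f"# pfm_position\t{cols}")
        for base in "ACGT":
            vals = "\t".join(str(int(v)) for v in pam_report.pfm.loc[base])
            lines.append(f"# pfm_{base}\t{vals}")
        ic = "\t".join(f"{v:.4f}" for v in pam_report.information_content)
        lines.append(f"# information_content_bits\t{ic}")
        for kmer, count in pam_report.candidates:
            lines.append(f"# candidate\t{kmer}\t{count}")
    return lines


def write_report(hits, pam_report, path, format: str = "tsv", header_lines=()) -> None:
    """Write the hit table plus consensus block; tsv/csv output is byte-stable.

    ``header_lines`` are emitted first as '# '-prefixed comments (used by the
    pipeline to record the run seed and configuration).
    """
    if format not in ("tsv", "csv", "spreadsheet"):
        raise ValueError(f"unknown report format {format!r}")
    df = hits_to_frame(hits)
    if format == "spreadsheet":
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            df.to_excel(xw, sheet_name="hits", index=False)
            meta = pd.DataFrame(
                {"line": _consensus_block(pam_report)} if pam_report else {"line": []}
            )
            meta.to_excel(xw, sheet_name="consensus", index=False)
        return
    sep = "\t" if format == "tsv" else ","
    buf = io.StringIO()
    df.to_csv(buf, sep=sep, index=False)
    text = "".join(f"# {line}\n" for line in header_lines) + buf.getvalue()
    if pam_report is not None:
        text += "\n" + "\n".join(_consensus_block(pam_report)) + "\n"
    Path(path).write_text(text)


def parse_report(path, format: str = "tsv") -> pd.DataFrame:
    """Re-parse the tabular section of a written report (consensus block skipped)."""
    sep = "\t" if format == "tsv" else ","
    lines = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(lines)), sep=sep, keep_default_na=False)
    for col in ("mismatch_positions", "upstream_flank", "downstream_flank",
                "mge_category", "mge_detail", "subject_title"):
        df[col] = df[col].astype(str).replace("nan", "")
    if df["flank_truncated"].dtype == object:
        df["flank_truncated"] = df["flank_truncated"].map(
            {"True": True, "False": False}
        )
    return df


def canonicalized(array: CrisprArray) -> CrisprArray:
    """Flip an array whose sequences are on the genome + strand into crRNA
    orientation (reverse-complement, spacer order inverted). No-op unless the
    orientation is "reverse". Locus files with a stated orientation already
    carry crRNA-oriented sequences and must not be passed through this."""
    from ._seq import revcomp

    if array.orientation != "reverse":
        return array
    return replace(
        array,
        direct_repeat=revcomp(array.direct_repeat),
        spacers=[revcomp(s) for s in reversed(array.spacers)],
        leader=revcomp(array.leader) if array.leader else None,
    )
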