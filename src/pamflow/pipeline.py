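"""End-to-end orchestration: PAM prediction runs and edit-design runs.

Stages run in the original workflow's order: orient the array, find or
import spacer hits, keep MGE-attributable hits, compile the PAM report,
write the report files. Identical inputs and configuration produce
byte-identical TSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .consensus import (
    DEFAULT_CANDIDATE_K,
    DEFAULT_K,
    DEFAULT_MIN_MGE_HITS,
    PamReport,
    call_pam,
)
from .design import (
    DEFAULT_GC_BOUNDS,
    DEFAULT_SPACER_LENGTH,
    EditDesign,
    build_editing_template,
    build_synthetic_array,
    check_amplicons,
    find_candidate_spacers,
    validate_design,
)
from .mge import FEATURE_KEYWORDS, TITLE_KEYWORDS, filter_mge_hits
from .model import (
    GenomeRecord,
    SearchParams,
    read_crispr_locus,
    read_fasta,
    read_feature_table,
    read_prophage_bed,
    write_fasta,
    write_report,
)
from .orientation import orient_array
from .search import SpacerHit, import_tabular_hits, search_spacers

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or contradictory run configuration."""


class DesignError(ValueError):
    """A design request that cannot be fulfilled (e.g. no candidate spacer)."""


class DesignValidationError(ValueError):
    """A completed design that fails validation (target not destroyed)."""


@dataclass
class RunConfig:
    """Configuration of a PAM-prediction run (YAML-loadable)."""

    locus_path: str
    subject_fasta: Sequence[str] | str = ()
    feature_table: str | None = None
    prophage_bed: str | None = None
    tabular_hits: str | None = None
    internal_search: bool | None = None   # None = auto from tabular_hits
    params: SearchParams = field(default_factory=SearchParams)
    keywords_title: Sequence[str] = tuple(sorted(TITLE_KEYWORDS))
    keywords_feature: Sequence[str] = tuple(sorted(FEATURE_KEYWORDS))
    consensus_mode: str = "covering"
    k: int = DEFAULT_K
    candidate_k: int = DEFAULT_CANDIDATE_K
    min_mge_hits: int = DEFAULT_MIN_MGE_HITS
    orientation: str | None = None        # external orientation override
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"
    report_format: str = "tsv"

    def __post_init__(self):
        if isinstance(self.subject_fasta, (str, Path)):
            self.subject_fasta = [str(self.subject_fasta)]
        if self.internal_search is None:
            self.internal_search = self.tabular_hits is None
        if self.internal_search and self.tabular_hits is not None:
            raise ConfigError(
                "exactly one hit source allowed: internal search and a "
                "tabular-hit file were both selected"
            )
        if not self.internal_search and self.tabular_hits is None:
            raise ConfigError("tabular_hits required when internal search is off")
        if self.orientation not in (None, "forward", "reverse"):
            raise ConfigError(f"invalid orientation override {self.orientation!r}")
        if not self.subject_fasta:
            raise ConfigError("at least one subject FASTA is required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "params" in data and isinstance(data["params"], dict):
            data["params"] = SearchParams(**data["params"])
        return cls(**data)


@dataclass
class PipelineResult:
    report: PamReport
    kept_hits: list[SpacerHit]
    discarded_hits: list[SpacerHit]
    report_path: Path


def run_pam_pipeline(config: RunConfig) -> PipelineResult:
    """Execute orient -> search/import -> MGE filter -> PAM call -> report.

    An array with unknown orientation and no override is a configuration
    error (the non-interactive replacement for the original console prompt).
    Insufficient MGE hits is a reported status, not a failure.
    """
    logging.getLogger("pamflow").setLevel(config.log_level.upper())
    array = read_crispr_locus(config.locus_path)
    subjects: list[GenomeRecord] = []
    for fp in config.subject_fasta:
        subjects.extend(read_fasta(fp))
    if config.feature_table:
        read_feature_table(config.feature_table, subjects)
    if config.prophage_bed:
        read_prophage_bed(config.prophage_bed, subjects)

    array = orient_array(array, external_call=config.orientation)
    if array.orientation == "unknown":
        raise ConfigError(
            "array orientation is unknown; supply an orientation override "
            "('forward' or 'reverse') in the run configuration"
        )
    spacers = array.spacer_items()
    log.info("stage array: %d spacers, orientation %s", len(spacers), array.orientation)

    exclude = {array.host_id: [array.interval]} if array.host_id else {}
    if config.internal_search:
        hits = search_spacers(spacers, subjects, config.params, exclude=exclude)
    else:
        hits = import_tabular_hits(
            config.tabular_hits, spacers, subjects, config.params
        )
    log.info("stage search: %d filtered hits", len(hits))

    kept, discarded = filter_mge_hits(
        hits, subjects, config.keywords_title, config.keywords_feature
    )
    log.info("stage mge: %d kept, %d discarded", len(kept), len(discarded))

    report = call_pam(
        kept,
        k=config.k,
        min_mge_hits=config.min_mge_hits,
        candidate_k=config.candidate_k,
        mode=config.consensus_mode,
    )
    log.info("stage pam: status %s, %d contributing hits",
             report.status, report.n_contributing_hits)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report_path = out_dir / f"pam_report.{'xlsx' if config.report_format == 'spreadsheet' else config.report_format}"
    header = [
        f"seed\t{config.seed}",
        f"locus\t{Path(config.locus_path).name}",
        f"hit_source\t{'internal_search' if config.internal_search else 'tabular'}",
    ]
    write_report(kept, report, report_path, config.report_format, header_lines=header)
    return PipelineResult(report, kept, discarded, report_path)


@dataclass
class DesignRequest:
    """A deletion/insertion request plus the sequences needed to express it."""

    leader: str
    direct_repeat: str
    lha_len: int
    rha_len: int
    deletion: tuple[int, int] | None = None
    insertion: tuple[int, str] | None = None
    replacement: tuple[tuple[int, int], str] | None = None
    pam_patterns: Sequence[str] = ("CCA",)
    spacer_length: int = DEFAULT_SPACER_LENGTH
    gc_bounds: tuple[float, float] = DEFAULT_GC_BOUNDS
    spacer_region: tuple[int, int] | None = None  # default: the edited interval
    cds_intervals: Sequence[tuple[int, int]] | None = None
    wt_amplicon_len: int | None = None
    edited_amplicon_len: int | None = None


def run_design_pipeline(
    genome: GenomeRecord,
    request: DesignRequest,
    out_dir,
    strict: bool = True,
) -> tuple[EditDesign, dict]:
    """Design an edit end to end and write its FASTA + design sheet.

    Raises DesignError when no spacer candidate matches the requested PAM
    patterns (suggesting pattern relaxation, mirroring the CCA -> CCG
    fallback used for the knock-in), and, under ``strict``,
    DesignValidationError when the edited locus would not escape
    self-targeting (target not destroyed).
    """
    if request.spacer_region is not None:
        region = request.spacer_region
    elif request.deletion is not None:
        region = request.deletion
    elif request.replacement is not None:
        region = request.replacement[0]
    else:
        p = request.insertion[0]
        region = (max(0, p - 200), min(len(genome.sequence), p + 200))

    candidates = find_candidate_spacers(
        genome, region, request.pam_patterns,
        length=request.spacer_length, gc_bounds=request.gc_bounds,
    )
    if not candidates:
        raise DesignError(
            f"no candidate spacer with PAM patterns {list(request.pam_patterns)} "
            f"in region {region}; consider relaxing the pattern "
            "(e.g. CCA -> CCN or an alternative double-cytosine PAM)"
        )
    spacer = candidates[0]

    design = build_editing_template(
        genome,
        deletion=request.deletion,
        insertion=request.insertion,
        replacement=request.replacement,
        lha_len=request.lha_len,
        rha_len=request.rha_len,
    )
    design.spacer = spacer
    design.synthetic_array = build_synthetic_array(
        request.leader, request.direct_repeat, spacer.sequence
    )
    flags = validate_design(design, genome, request.cds_intervals)
    if request.wt_amplicon_len and request.edited_amplicon_len:
        check_amplicons(design, request.wt_amplicon_len, request.edited_amplicon_len)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    parts = [
        GenomeRecord(id="LHA", sequence=design.lha),
        GenomeRecord(id="RHA", sequence=design.rha),
        GenomeRecord(id="spacer", sequence=spacer.sequence),
        GenomeRecord(id="synthetic_array", sequence=design.synthetic_array),
        GenomeRecord(id="edited_locus", sequence=design.edited_locus),
    ]
    if design.cargo:
        parts.insert(2, GenomeRecord(id="cargo", sequence=design.cargo))
    fasta_path = out_dir / "design.fasta"
    write_fasta(parts, fasta_path)

    sheet = {
        "genome_id": design.genome_id,
        "kind": design.kind,
        "deletion_interval": design.deletion_interval,
        "insertion_point": design.insertion_point,
        "edit_size": design.edit_size,
        "lha_interval": design.lha_interval,
        "rha_interval": design.rha_interval,
        "spacer": spacer.sequence,
        "spacer_strand": spacer.strand,
        "spacer_interval": (spacer.start, spacer.end),
        "pam": spacer.pam,
        "spacer_gc": round(spacer.gc, 4),
        **{f"flag_{k}": v for k, v in flags.items()},
        **{f"amplicon_{k}": v for k, v in design.predicted_amplicons.items()},
    }
    sheet_path = out_dir / "design_sheet.tsv"
    sheet_path.write_text(
        "".join(f"{k}\t{v}\n" for k, v in sheet.items())
    )

    if strict and flags.get("target_destroyed") is False:
        raise DesignValidationError(
            "edited locus still contains PAM + protospacer: the design would "
            "not escape self-targeting"
        )
    return design, {"fasta": fasta_path, "sheet": sheet_path}
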