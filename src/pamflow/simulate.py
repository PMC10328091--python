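"""Synthetic invader pools with planted protospacers and a known 5' PAM.

The generator emulates the immunization history the method assumes: a host
array whose spacers derive from mobile genetic elements, so that each spacer
has a protospacer somewhere in the invader pool, preceded by the system's
PAM. Subjects are random background sequence with protospacers planted at
non-overlapping positions on random strands; a configurable fraction of
subjects is labeled as MGE through the three evidence routes in round-robin
(title keyword, prophage interval, feature annotation).

Everything is driven by one seeded numpy generator, so a fixture is fully
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .model import CrisprArray, FeatureAnnotation, GenomeRecord

# the direct repeat of the A. woodii array the workflow was developed on
DEFAULT_DIRECT_REPEAT = "ATTTACATTCCAATATGGATCTACTCAAAT"
_BASES = np.array(list("ACGT"))
_EDGE_MARGIN = 10  # keeps planted flanks clear of contig edges (no truncation)


@dataclass(frozen=True)
class PlantedProtospacer:
    """Ground truth for one planted protospacer."""

    spacer_id: str
    subject_id: str
    interval: tuple[int, int]   # protospacer interval on the + strand
    strand: str
    mutation_positions: tuple[int, ...]  # 1-based, PAM-proximal end
    violation: str | None = None        # None, or why this plant breaks the filters


@dataclass
class FixtureTruth:
    """What was planted where, and how each subject is MGE-labeled."""

    pam: str
    plants: list[PlantedProtospacer] = field(default_factory=list)
    mge_routes: dict[str, str] = field(default_factory=dict)  # subject_id -> route


def _random_seq(rng, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng, seq: str, positions_1based) -> str:
    chars = list(seq)
    for p in positions_1based:
        old = chars[p - 1]
        choices = [b for b in "ACGT" if b != old]
        chars[p - 1] = choices[rng.integers(0, 3)]
    return "".join(chars)


def generate_invader_set(
    pam: str = "CCA",
    n_protospacers: int = 20,
    spacer_len: int = 36,
    n_subjects: int = 5,
    mutation_counts=0,
    seed_mutation_counts=0,
    mge_fraction: float = 1.0,
    subject_len: int = 3000,
    direct_repeat: str = DEFAULT_DIRECT_REPEAT,
    seed: int = 0,
    seed_length: int = 7,
    max_retries: int = 100,
) -> tuple[list[GenomeRecord], CrisprArray, FixtureTruth]:
    """Build (subjects, host array, truth) for a planted-PAM fixture.

    ``mutation_counts`` (scalar or per-protospacer list) substitutions are
    injected into the planted copy outside the seed region, so that by
    default every plant passes the filters; ``seed_mutation_counts`` places
    additional substitutions inside the seed to deliberately violate the
    seed rule (recorded as a violation in the truth).
    """
    rng = np.random.default_rng(seed)
    pam = pam.upper()

    def _as_list(x):
        if np.isscalar(x):
            return [int(x)] * n_protospacers
        if len(x) != n_protospacers:
            raise ValueError("per-protospacer list length mismatch")
        return [int(v) for v in x]

    muts = _as_list(mutation_counts)
    seed_muts = _as_list(seed_mutation_counts)

    subjects_chars = [list(_random_seq(rng, subject_len)) for _ in range(n_subjects)]
    used: list[list[tuple[int, int]]] = [[] for _ in range(n_subjects)]
    subject_ids = [f"contig_{i + 1:02d}" for i in range(n_subjects)]

    truth = FixtureTruth(pam=pam)
    spacers: list[str] = []
    plen = len(pam)
    span = plen + spacer_len

    width = len(str(n_protospacers))
    for i in range(n_protospacers):
        spacer = _random_seq(rng, spacer_len)
        spacers.append(spacer)
        sp_id = f"sim_array_sp{str(i + 1).zfill(width)}"
        subj = int(rng.integers(0, n_subjects))

        # injected substitutions on the planted copy (spacer stays clean)
        non_seed = list(range(seed_length + 1, spacer_len + 1))
        in_seed = list(range(1, seed_length + 1))
        positions = sorted(
            list(rng.choice(non_seed, size=muts[i], replace=False))
            + list(rng.choice(in_seed, size=seed_muts[i], replace=False))
        )
        planted_copy = _mutate(rng, spacer, positions)
        violation = None
        if seed_muts[i] > 1:
            violation = "seed_mismatch"
        elif (muts[i] + seed_muts[i]) / spacer_len >= 0.20:
            violation = "global_mismatch"

        for attempt in range(max_retries):
            pos = int(rng.integers(_EDGE_MARGIN, subject_len - span - _EDGE_MARGIN))
            window = (pos - _EDGE_MARGIN, pos + span + _EDGE_MARGIN)
            if any(window[0] < e and s < window[1] for s, e in used[subj]):
                continue
            break
        else:
            raise RuntimeError(
                f"could not place protospacer {sp_id} after {max_retries} tries"
            )
        used[subj].append(window)

        strand = "+" if rng.integers(0, 2) == 0 else "-"
        insert = pam + planted_copy
        if strand == "+":
            interval = (pos + plen, pos + span)
            subjects_chars[subj][pos:pos + span] = list(insert)
        else:
            interval = (pos, pos + spacer_len)
            subjects_chars[subj][pos:pos + span] = list(revcomp(insert))
        truth.plants.append(PlantedProtospacer(
            spacer_id=sp_id, subject_id=subject_ids[subj],
            interval=interval, strand=strand,
            mutation_positions=tuple(int(p) for p in positions),
            violation=violation,
        ))

    # MGE labeling: round-robin across the three evidence routes
    n_mge = int(round(mge_fraction * n_subjects))
    routes = ("title_keyword", "prophage_interval", "feature_keyword")
    records = []
    for i, sid in enumerate(subject_ids):
        seq = "".join(subjects_chars[i])
        title = f"synthetic contig {i + 1}"
        features: list[FeatureAnnotation] = []
        prophages: list[tuple[int, int]] = []
        if i < n_mge:
            route = routes[i % 3]
            truth.mge_routes[sid] = route
            if route == "title_keyword":
                title = f"synthetic phage contig {i + 1}"
            elif route == "prophage_interval":
                prophages = [(0, subject_len)]
            else:
                features = [FeatureAnnotation(
                    0, subject_len, "+", label="putative transposase", kind="CDS"
                )]
        else:
            truth.mge_routes[sid] = "none"
        records.append(GenomeRecord(
            id=sid, title=title, sequence=seq,
            features=features, prophage_intervals=prophages,
        ))

    array = CrisprArray(
        array_id="sim_array",
        host_id="sim_host",
        interval=(0, len(direct_repeat) * (n_protospacers + 1)
                  + sum(len(s) for s in spacers)),
        direct_repeat=direct_repeat,
        spacers=spacers,
        orientation="forward",
    )
    return records, array, truth
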