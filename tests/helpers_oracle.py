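"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive pure Python (character loops, O(n^2)
clustering) and shares no code path with the package's vectorized search.
"""

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq):
    return "".join(COMP[b] for b in reversed(seq))


def naive_mismatches(a, b):
    """1-based positions where the equal-length strings differ (N = mismatch)."""
    return [
        i + 1
        for i in range(len(a))
        if a[i] != b[i] or a[i] == "N" or b[i] == "N"
    ]


def brute_force_search(spacer_items, subjects, params, exclude=None):
    """All windows, both strands, naive counting; returns comparable tuples.

    Each hit is (spacer_id, subject_id, strand, start, end, mismatch_count,
    positions, upstream_flank, downstream_flank). Applies the same filters,
    exclusion and best-of-overlap reduction as the specification describes,
    implemented independently.
    """
    exclude = exclude or {}
    raw = []
    for subject in subjects:
        seq = subject.sequence
        n = len(seq)
        excl = exclude.get(subject.id, [])
        for sid, spacer in spacer_items:
            L = len(spacer)
            for start in range(n - L + 1):
                end = start + L
                if any(start < b and a < end for a, b in excl):
                    continue
                window = seq[start:end]
                for strand in "+-":
                    proto = window if strand == "+" else rc(window)
                    positions = naive_mismatches(spacer, proto)
                    mm = len(positions)
                    if mm / L >= params.max_mismatch_fraction:
                        continue
                    seed_mm = sum(1 for p in positions if p <= params.seed_length)
                    if seed_mm > params.max_seed_mismatches:
                        continue
                    if strand == "+":
                        up = seq[max(0, start - params.upstream_flank_len):start]
                        down = seq[end:end + params.downstream_flank_len]
                    else:
                        up = rc(seq[end:end + params.upstream_flank_len])
                        down = rc(seq[max(0, start - params.downstream_flank_len):start])
                    raw.append(
                        (sid, subject.id, strand, start, end, mm,
                         tuple(positions), up, down)
                    )
    return _reduce_overlaps(raw)


def _reduce_overlaps(raw):
    """Keep the lowest-mismatch (ties: leftmost) hit of each overlap chain."""
    from collections import defaultdict

    groups = defaultdict(list)
    for h in raw:
        groups[(h[0], h[1], h[2])].append(h)
    out = []
    for hits in groups.values():
        hits = sorted(hits, key=lambda h: h[3])
        # union-find-free chaining: assign cluster ids by sweeping
        clusters = []
        for h in hits:
            placed = False
            for cl in clusters:
                if any(h[3] < o[4] and o[3] < h[4] for o in cl):
                    cl.append(h)
                    placed = True
                    break
            if not placed:
                clusters.append([h])
        for cl in clusters:
            out.append(min(cl, key=lambda h: (h[5], h[3])))
    return sorted(out)


def hit_tuples(hits):
    """Project package SpacerHit objects onto the oracle tuple schema."""
    return sorted(
        (h.spacer_id, h.subject_id, h.strand, h.interval[0], h.interval[1],
         h.mismatch_count, tuple(h.mismatch_positions),
         h.upstream_flank, h.downstream_flank)
        for h in hits
    )


def random_fixture(rng, n_subjects=2, subject_len=2000, spacer_lens=(30, 36),
                   n_spacers=3, plant=True):
    """A random subject set plus spacers, some planted with mutations."""
    import numpy as np

    from pamflow.model import GenomeRecord

    bases = np.array(list("ACGT"))
    subjects = []
    for i in range(n_subjects):
        seq = "".join(rng.choice(bases, size=subject_len))
        subjects.append(GenomeRecord(id=f"s{i}", title=f"random subject {i}",
                                     sequence=seq))
    spacer_items = []
    for j in range(n_spacers):
        L = int(rng.choice(spacer_lens))
        spacer = "".join(rng.choice(bases, size=L))
        if plant and j % 2 == 0:
            # plant a mutated copy (possibly filter-violating) somewhere
            subj = subjects[int(rng.integers(0, n_subjects))]
            pos = int(rng.integers(0, subject_len - L))
            copy = list(spacer)
            for p in rng.choice(L, size=int(rng.integers(0, 8)), replace=False):
                copy[p] = "ACGT"[int(rng.integers(0, 4))]
            if rng.integers(0, 2):
                copy = list(rc("".join(copy)))
            seq = subj.sequence
            subj.sequence = seq[:pos] + "".join(copy) + seq[pos + L:]
        spacer_items.append((f"sp{j}", spacer))
    return spacer_items, subjects
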