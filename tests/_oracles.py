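"""Independent brute-force oracles used by the test suite.

These deliberately use different algorithms from the package (exhaustive
enumeration, per-residue boolean sets, connected components) so agreement
is meaningful.
"""

from math import comb


def hypergeometric_tail(a, b, c, d):
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] with both margins fixed."""
    row1, col1, total = a + b, a + c, a + b + c + d
    num = 0
    for k in range(a, min(row1, col1) + 1):
        if row1 - k <= total - col1:
            num += comb(col1, k) * comb(total - col1, row1 - k)
    return num / comb(total, row1)


def brute_force_epitopes(
    calls, mapped_peptides, tcell_genotypes, mapps_genotypes, pools, min_length=9
):
    """Exhaustive enumeration of the four-step assay merge; returns sorted spans.

    Enumerates every (match, identification, pool) triple with explicit
    residue sets, decomposes the union into runs by scanning positions, and
    merges MAPPs identifications into regions via connected components of
    the span-overlap graph.
    """
    # donor positivity per stimulus (OR over markers), pools only
    positive = {}
    for c in calls:
        key = (c.donor_id, c.stimulus)
        positive[key] = positive.get(key, False) or c.positive
    pool_span = {f"pool_{q.pool_id}": (q.span_start, q.span_end) for q in pools}

    matches = []
    for m in mapps_genotypes:
        for t in tcell_genotypes:
            shared = set(m.drb1_alleles) & set(t.drb1_alleles)
            if shared:
                matches.append((m.donor_id, t.donor_id))

    combined = set()
    for mdonor, tdonor in matches:
        for p in mapped_peptides:
            if p.donor_id != mdonor:
                continue
            for stim, (qs, qe) in pool_span.items():
                if not positive.get((tdonor, stim), False):
                    continue
                for r in range(max(p.start, qs), min(p.end, qe) + 1):
                    combined.add(r)

    # maximal runs by scanning every position
    runs, cur = [], None
    limit = max([p.end for p in mapped_peptides], default=0) + 2
    for pos in range(1, limit):
        if pos in combined:
            cur = (cur[0], pos) if cur else (pos, pos)
        elif cur:
            runs.append(cur)
            cur = None
    intervals = [(a, b) for a, b in runs if b - a + 1 >= min_length]

    # cohort regions via connected components of the overlap graph
    peps = list(mapped_peptides)
    parent = list(range(len(peps)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(peps)):
        for j in range(i + 1, len(peps)):
            if min(peps[i].end, peps[j].end) >= max(peps[i].start, peps[j].start):
                parent[find(i)] = find(j)
    components = {}
    for i, p in enumerate(peps):
        components.setdefault(find(i), []).append(p)
    regions = [
        (min(p.start for p in ps), max(p.end for p in ps))
        for ps in components.values()
    ]

    spans = set()
    for rs, re_ in regions:
        for a, b in intervals:
            lo, hi = max(rs, a), min(re_, b)
            if hi - lo + 1 >= min_length:
                spans.add((lo, hi))
    return sorted(spans)
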