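"""Brute-force reference implementations used only to check the package.

Deliberately naive (quadratic scans, union-find over all pairs, per-base
sums) and independent of the library's data structures.
"""

from __future__ import annotations


def brute_stitch(peaks, max_gap):
    """Transitive merge over ALL peak pairs via union-find.

    peaks: list of (chrom, start, end).  Two peaks are linked when they are
    on the same chromosome and the gap between them is <= max_gap (overlap
    counts as gap 0).  Returns sorted merged spans with constituent indices.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = peaks[i]
            cj, sj, ej = peaks[j]
            if ci != cj:
                continue
            gap = max(si, sj) - min(ei, ej)
            if gap <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged = []
    for members in groups.values():
        chrom = peaks[members[0]][0]
        start = min(peaks[i][1] for i in members)
        end = max(peaks[i][2] for i in members)
        merged.append((chrom, start, end, sorted(members)))
    merged.sort()
    return merged


def brute_cutoff(signals):
    """Tangent-line elbow threshold by exhaustive enumeration.

    signals: ascending-sorted values s_1..s_n.  Global slope
    m = (s_n - s_1)/(n - 1); for each candidate tangent index i, count the
    points lying strictly above the slope-m line through (i, s_i); the
    winner maximises that count, ties resolved to the largest index.
    Returns (threshold, i*, counts).
    """
    n = len(signals)
    assert n >= 2
    m = (signals[-1] - signals[0]) / (n - 1)
    counts = []
    for i in range(n):
        c = 0
        for j in range(n):
            line = signals[i] + m * (j - i)
            if signals[j] > line:
                c += 1
        counts.append(c)
    best = max(range(n), key=lambda i: (counts[i], i))
    return signals[best], best, counts


def brute_associate(regions, genes, max_distance):
    """All-pairs center-to-TSS distance filter.

    regions: list of (region_id, chrom, center); genes: list of
    (gene_id, chrom, tss).  Returns the set of associated
    (region_id, gene_id, distance) triples (inclusive threshold).
    """
    out = set()
    for rid, rc, center in regions:
        for gid, gc, tss in genes:
            if rc == gc and abs(tss - center) <= max_distance:
                out.add((rid, gid, abs(tss - center)))
    return out


def brute_region_signal(steps, start, end):
    """Per-base sum of step values over [start, end)."""
    total = 0.0
    for pos in range(start, end):
        for s, e, v in steps:
            if s <= pos < e:
                total += v
                break
    return total


def brute_components(intervals):
    """Connected components of interval overlap-or-adjacency (same chrom).

    intervals: list of (chrom, start, end).  Returns a frozenset of
    frozensets of indices: the union-connectivity structure that stitching
    with max_gap=0 must reproduce.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, si, ei = intervals[i]
            cj, sj, ej = intervals[j]
            if ci == cj and si <= ej and sj <= ei:  # overlap or adjacency
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())
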