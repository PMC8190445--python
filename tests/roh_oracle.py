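"""Brute-force reference implementation of the windowed ROH definition.

Deliberately naive (pure-python O(M*W) window scans and exhaustive interval
enumeration) and independent of the vectorized caller: used only as a test
oracle.  Interval selection keeps every *maximal* interval satisfying the
segment constraints; fixtures used with this oracle are restricted to
settings (zero heterozygote/missing allowance, spacing below the density
bound) where maximal valid intervals cannot overlap, so the result is a
unique, well-defined segment set.
"""

from rohload.roh import ROHParams


def oracle_segments(calls, cm, params: ROHParams):
    """Return [(start_idx, end_idx)] of ROH for one individual, one chromosome."""
    p = params
    g = list(calls)
    ppos = [round(c * 1e6) for c in cm]
    m = len(g)
    w = p.window_snps
    if m < w:
        return []
    hits = []
    for i in range(m - w + 1):
        window = g[i:i + w]
        n_het = sum(1 for x in window if x == 1)
        n_mis = sum(1 for x in window if x == -1)
        hits.append(n_het <= p.window_het and n_mis <= p.window_missing)
    eligible = []
    for j in range(m):
        cov = range(max(0, j - w + 1), min(j, m - w) + 1)
        n_hit = sum(1 for i in cov if hits[i])
        eligible.append(n_hit >= p.window_hit_threshold * len(cov))
    # maximal eligible runs, split at oversized gaps
    runs, cur = [], []
    gap = round(p.max_gap_cm * 1e6)
    for j in range(m):
        if eligible[j]:
            if cur and ppos[j] - ppos[cur[-1]] > gap:
                runs.append(cur)
                cur = []
            cur.append(j)
        else:
            if cur:
                runs.append(cur)
                cur = []
    if cur:
        runs.append(cur)
    # exhaustive enumeration of valid intervals inside each run (prefix sums
    # keep the per-interval check O(1); every interval is still visited)
    candidates = []
    min_len = round(p.min_length_cm * 1e6)
    chet = [0]
    for x in g:
        chet.append(chet[-1] + (1 if x == 1 else 0))
    for run in runs:
        for a in range(len(run)):
            for b in range(a, len(run)):
                i, j = run[a], run[b]
                if g[i] in (1, -1) or g[j] in (1, -1):
                    continue
                if chet[j + 1] - chet[i] > p.segment_het:
                    continue
                n = j - i + 1
                length = ppos[j] - ppos[i]
                if (n >= p.min_snps and length >= min_len
                        and length <= p.max_avg_spacing_cm_per_snp * 1e6 * n):
                    candidates.append((i, j))
    maximal = [c for c in candidates
               if not any(o != c and o[0] <= c[0] and c[1] <= o[1]
                          for o in candidates)]
    maximal.sort()
    for (a, b), (c, d) in zip(maximal, maximal[1:]):
        assert b < c, "oracle fixture produced overlapping maximal intervals"
    return maximal
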