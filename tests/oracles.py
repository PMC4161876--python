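"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity along a deliberately different path:
per-base chain walking instead of block-interval arithmetic, Sankoff
dynamic programming instead of Fitch set operations, a full
Needleman-Wunsch matrix instead of the library aligner.
"""

from __future__ import annotations


def map_base_through_chain(chain, pos: int):
    """Map one source base by walking the raw (size, dt, dq) triples."""
    t = chain.source_start
    q_off = 0
    for size, dt, dq in chain.blocks:
        if t <= pos < t + size:
            q_stranded = q_off + (pos - t)
            if chain.target_strand == "+":
                return chain.target_start + q_stranded
            return chain.target_end - 1 - q_stranded
        t += size + dt
        q_off += size + dq
    return None


def brute_force_lift(interval, chains, min_match=0.95):
    """Status + target hull from independently mapping every single base."""
    overlapping = [
        c for c in chains.chains
        if c.source_name == interval.chrom
        and c.source_start < interval.end and interval.start < c.source_end
    ]
    if not overlapping:
        return ("unmapped", None)
    best = max(overlapping, key=lambda c: (c.score, c.chain_id))
    mapped = [
        q for q in (
            map_base_through_chain(best, p)
            for p in range(interval.start, interval.end)
        ) if q is not None
    ]
    if not mapped:
        return ("unmapped", None)
    lo, hi = min(mapped), max(mapped)
    strand = best.target_strand
    hull = (best.target_name, lo, hi + 1, strand)
    width = interval.end - interval.start
    frac = len(mapped) / width
    if (hi - lo + 1) - len(mapped) > (1.0 - min_match) * width:
        return ("split", hull)
    if frac < min_match:
        return ("low_coverage", hull)
    return ("mapped", hull)


def sankoff_score(tree, msa) -> int:
    """Minimum state changes per column by cost-vector dynamic programming."""
    alphabet = sorted({ch for row in msa.rows for ch in row})
    inf = 10 ** 9
    rows = dict(zip(msa.labels, msa.rows))
    total = 0
    leaf = next(iter(tree.labels))
    root_nb = tree.adj[leaf][0]
    for j in range(msa.n_columns):

        def cost(node, parent):
            if node in tree.labels:
                ch = rows[tree.labels[node]][j]
                return {a: (0 if a == ch else inf) for a in alphabet}
            kids = [nb for nb in tree.adj[node] if nb != parent]
            kid_costs = [cost(k, node) for k in kids]
            return {
                a: sum(
                    min(c[b] + (0 if a == b else 1) for b in alphabet)
                    for c in kid_costs
                )
                for a in alphabet
            }

        c = cost(root_nb, leaf)
        ch = rows[tree.labels[leaf]][j]
        total += min(c[b] + (0 if b == ch else 1) for b in alphabet)
    return total


def nw_align(a: str, b: str, match=1.0, mismatch=0.0, gap=-1.0):
    """Full-matrix global alignment; returns (score, row_a, row_b)."""
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = i * gap
    for j in range(1, m + 1):
        score[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            score[i][j] = max(
                score[i - 1][j - 1] + sub,
                score[i - 1][j] + gap,
                score[i][j - 1] + gap,
            )
    # traceback, diagonal preferred
    ra, rb = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if score[i][j] == score[i - 1][j - 1] + sub:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i, j = i - 1, j - 1
                continue
        if i > 0 and score[i][j] == score[i - 1][j] + gap:
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            continue
        ra.append("-")
        rb.append(b[j - 1])
        j -= 1
    return score[n][m], "".join(reversed(ra)), "".join(reversed(rb))


def identity_from_rows(row_a: str, row_b: str) -> float:
    """Percent identity excluding terminal-gap columns."""
    n = len(row_a)
    lead = 0
    while lead < n and (row_a[lead] == "-" or row_b[lead] == "-"):
        lead += 1
    trail = n
    while trail > lead and (row_a[trail - 1] == "-" or row_b[trail - 1] == "-"):
        trail -= 1
    core_a, core_b = row_a[lead:trail], row_b[lead:trail]
    if not core_a:
        return 0.0
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    return matches / len(core_a) * 100.0
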