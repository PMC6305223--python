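"""Independent brute-force oracles used by the test suite.

These deliberately re-derive everything from first principles (direct
column scans, exhaustive recursion, a second plain NW implementation) and
share no scoring or search code with the package.
"""

from __future__ import annotations

GAP = "-"


# ---------------------------------------------------------------------------
# exhaustive traversal enumeration (chaining oracle)
# ---------------------------------------------------------------------------

def _diagonal_states(diag):
    """Per column: (state_before, state_after, column_score), consumed-state
    coordinates recomputed directly from the gapped rows."""
    r = diag.d1 - 1
    c = diag.d2 - 1
    out = []
    for a, b in zip(diag.aligned_ref, diag.aligned_contig):
        before = (r, c)
        if a != GAP:
            r += 1
        if b != GAP:
            c += 1
        score = 1 if (a == b and a != GAP) else -1
        out.append((before, (r, c), score))
    return out


def brute_force_points(diagonals):
    """Entry and exit points per the printed iff-condition, scanning every
    column of every diagonal (all qualifying columns, not just the first).

    Returns (entries, exits) as lists of (diag_id, state, col)."""
    states = {d.id: _diagonal_states(d) for d in diagonals}
    entries, exits = [], []
    for d in diagonals:
        cols = states[d.id]
        entries.append((d.id, cols[0][0], 0))
        exits.append((d.id, cols[-1][1], len(cols) - 1))
        for g in diagonals:
            if g.id == d.id:
                continue
            g_start = (g.d1 - 1, g.d2 - 1)
            g_end = (g.d3, g.d4)
            for j, (before, after, _s) in enumerate(cols):
                if j < len(cols) - 1 and (after[0] == g_start[0] or after[1] == g_start[1]):
                    exits.append((d.id, after, j))
                if j > 0 and (before[0] == g_end[0] or before[1] == g_end[1]):
                    entries.append((d.id, before, j))
    return sorted(set(entries)), sorted(set(exits))


def enumerate_traversal_scores(
    diagonals, ref_len, contig_len, gap_score=-1, max_nodes=500_000
):
    """Scores of ALL valid traversals (ORIGIN..TERMINUS), by exhaustive
    recursion over alternating exit/entry sequences satisfying coordinate
    monotonicity, same-diagonal pairing, and element uniqueness.

    Raises RuntimeError past ``max_nodes`` recursion steps."""
    entries, exits = brute_force_points(diagonals)
    states = {d.id: _diagonal_states(d) for d in diagonals}
    exits_by_diag = {}
    for x in exits:
        exits_by_diag.setdefault(x[0], []).append(x)
    scores = []
    count = [0]

    def segment(diag_id, col_from, col_to):
        return sum(s for _b, _a, s in states[diag_id][col_from : col_to + 1])

    def rec(state, from_origin, used, score):
        count[0] += 1
        if count[0] > max_nodes:
            raise RuntimeError("enumeration too large")
        # close with TERMINUS: reference jump free
        scores.append(score + gap_score * (contig_len - state[1]))
        for e in entries:
            if e in used:
                continue
            (did, est, ecol) = e
            if est[0] < state[0] or est[1] < state[1]:
                continue
            jump = (
                gap_score * (est[1] - state[1])
                if from_origin
                else gap_score * ((est[0] - state[0]) + (est[1] - state[1]))
            )
            for x in exits_by_diag.get(did, []):
                if x in used or x[2] < ecol:
                    continue
                xst = x[1]
                if xst[0] < est[0] or xst[1] < est[1]:
                    continue
                rec(
                    xst,
                    False,
                    used | {e, x},
                    score + jump + segment(did, ecol, x[2]),
                )

    rec((0, 0), True, frozenset(), 0)
    return scores


def best_traversal_score(diagonals, ref_len, contig_len, gap_score=-1):
    return max(enumerate_traversal_scores(diagonals, ref_len, contig_len, gap_score))


# ---------------------------------------------------------------------------
# plain quadratic semi-global NW (second, independent implementation)
# ---------------------------------------------------------------------------

def nw_semiglobal_plain(ref, contig, match=1, mismatch=-1, gap=-1):
    """Textbook O(nm) DP with python loops: reference end gaps free, contig
    end gaps penalized. For small instances only."""
    n, m = len(ref), len(contig)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i * gap] + [0] * n
        for j in range(1, n + 1):
            sub = match if ref[j - 1] == contig[i - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return max(prev)


# ---------------------------------------------------------------------------
# brute maximal exact matches
# ---------------------------------------------------------------------------

def brute_force_mems(ref, query, k):
    """All maximal exact matches >= k by direct scanning of every start pair."""
    out = set()
    for j in range(len(ref)):
        for i in range(len(query)):
            if ref[j] != query[i]:
                continue
            if j > 0 and i > 0 and ref[j - 1] == query[i - 1]:
                continue  # not left-maximal
            length = 0
            while (
                j + length < len(ref)
                and i + length < len(query)
                and ref[j + length] == query[i + length]
            ):
                length += 1
            if length >= k:
                out.add((j, i, length))
    return sorted(out)
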