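"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (full matrices, quadratic scans,
cell-by-cell sums) and shares no code with the package internals it
checks.
"""

from __future__ import annotations

import math


def naive_smith_waterman(a, b, match=2.0, mismatch=-1.0, gap=-1.0):
    """Full-matrix Smith-Waterman over token lists.

    Returns (score, matched_tokens) of the single best local alignment,
    with the diagonal-first / up / left tie-break convention on the
    traceback.
    """
    n, m = len(a), len(b)
    h = [[0.0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            v = max(0.0, h[i - 1][j - 1] + s, h[i - 1][j] + gap, h[i][j - 1] + gap)
            h[i][j] = v
            if v > best:
                best, bi, bj = v, i, j
    matched = 0
    i, j = bi, bj
    while h[i][j] > 0.0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if abs(h[i][j] - (h[i - 1][j - 1] + s)) < 1e-9:
                if a[i - 1] == b[j - 1]:
                    matched += 1
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(h[i][j] - (h[i - 1][j] + gap)) < 1e-9:
            i -= 1
            continue
        j -= 1
    return best, matched


def substring_set(doc_lines, n, scheme):
    """Unhashed fingerprint set of a document built line by line."""
    out = set()
    for line in doc_lines:
        m = len(line)
        if m < n:
            continue
        if scheme == "full":
            out.update(line[i : i + n] for i in range(m - n + 1))
        else:
            out.update(line[i : i + n] for i in range(0, (m // n) * n, n))
    return out


def sequential_reduction(doc_lines_by_id, n, scheme, cutoff):
    """Quadratic greedy reduction: rescans every retained document per candidate.

    ``doc_lines_by_id`` is an ordered mapping doc_id -> raw lines (visit
    order).  Returns the list of retained doc_ids.
    """
    retained = []  # (doc_id, fingerprint set)
    for doc_id, lines in doc_lines_by_id.items():
        fps = substring_set(lines, n, scheme)
        ok = True
        for _, other in retained:
            shared = len(fps & other)
            if fps and shared / len(fps) > cutoff:
                ok = False
                break
            if other and shared / len(other) > cutoff:
                ok = False
                break
        if ok:
            retained.append((doc_id, fps))
    return [doc_id for doc_id, _ in retained]


def tmi_cell_sum(n11, n1p, np1, npp):
    """True mutual information summed explicitly over the four cells."""
    cells = [
        (n11, n1p, np1),
        (n1p - n11, n1p, npp - np1),
        (np1 - n11, npp - n1p, np1),
        (npp - n1p - np1 + n11, npp - n1p, npp - np1),
    ]
    total = 0.0
    for nij, ni, nj in cells:
        if nij > 0:
            total += (nij / npp) * math.log2(nij * npp / (ni * nj))
    return total
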