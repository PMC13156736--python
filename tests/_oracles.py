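"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: structure
MFE by exhaustive enumeration of all admissible pair sets scored by a
standalone scorer; off-target counts by an all-substring Hamming scan;
homology by an exhaustive offset scan.
"""

from __future__ import annotations

from functools import lru_cache

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
MIN_LOOP = 3


def enumerate_structures(seq: str):
    """All non-crossing pair sets with hairpin loops >= 3 and no
    multibranch loops (each closing pair has at most one inner branch)."""
    n = len(seq)

    @lru_cache(maxsize=None)
    def closed(i, j):
        if j - i - 1 < MIN_LOOP or (seq[i], seq[j]) not in _WC:
            return ()
        out = [((i, j),)]
        for k in range(i + 1, j - MIN_LOOP):
            for l in range(k + MIN_LOOP + 1, j):
                for inner in closed(k, l):
                    out.append(((i, j),) + inner)
        return tuple(out)

    @lru_cache(maxsize=None)
    def exterior(i, j):
        if i > j:
            return ((),)
        out = [()]
        # decompose by the leftmost closing pair (k, l)
        for k in range(i, j - MIN_LOOP):
            for l in range(k + MIN_LOOP + 1, j + 1):
                for c in closed(k, l):
                    for e in exterior(l + 1, j):
                        out.append(c + e)
        return tuple(out)

    return exterior(0, n - 1)


def score_structure(seq: str, pairs, table) -> int | None:
    """Energy in tenths of a kcal/mol of one pair set; None if the pair
    set falls outside the model (multibranch, oversized loop)."""
    total = 0
    pairs = sorted(pairs)
    for (i, j) in pairs:
        inside = [(k, l) for (k, l) in pairs if i < k < l < j]
        direct = [c for c in inside
                  if not any(k2 < c[0] and c[1] < l2
                             for (k2, l2) in inside if (k2, l2) != c)]
        if not direct:
            total += table.hairpin_penalty(j - i - 1)
        elif len(direct) == 1:
            k, l = direct[0]
            b1, b2 = k - i - 1, j - l - 1
            if b1 == 0 and b2 == 0:
                total += table.stack[seq[i] + seq[i + 1]]
            else:
                size = b1 + b2
                loops = table.bulge if (b1 == 0 or b2 == 0) else table.internal
                if size not in loops:
                    return None
                total += loops[size]
        else:
            return None
    return total


def brute_mfe(seq: str, table) -> float:
    """Exhaustive-enumeration MFE in kcal/mol."""
    seq = seq.upper()
    best = 0
    for pairs in enumerate_structures(seq):
        if not pairs:
            continue
        e = score_structure(seq, pairs, table)
        if e is not None and e < best:
            best = e
    return best / 10.0


def best_hamming(site: str, transcript: str) -> int | None:
    """Minimum Hamming distance of ``site`` over every same-length
    substring of ``transcript`` (None when the transcript is shorter)."""
    w = len(site)
    if len(transcript) < w:
        return None
    return min(sum(a != b for a, b in zip(site, transcript[p:p + w]))
               for p in range(len(transcript) - w + 1))


def brute_offtarget_counts(site: str, transcriptome, target_ids, max_mm=4):
    """All-substring Hamming bucket counts, one bucket per transcript."""
    counts = {k: 0 for k in range(max_mm + 1)}
    for tid, seq in transcriptome:
        if tid in target_ids:
            continue
        d = best_hamming(site, seq.upper())
        if d is not None and d <= max_mm:
            counts[d] += 1
    return counts


def brute_identity(site: str, ortholog: str) -> float | None:
    """Exhaustive-offset ungapped identity."""
    w = len(site)
    if len(ortholog) < w:
        return None
    best = max(sum(a == b for a, b in zip(site, ortholog[p:p + w]))
               for p in range(len(ortholog) - w + 1))
    return best / w
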