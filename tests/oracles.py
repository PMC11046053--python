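"""Independent brute-force oracles shared by the test modules."""


def nw_global(a: str, b: str, match: int, mismatch: int, gap: int) -> int:
    """Needleman-Wunsch global alignment score (linear gap penalty)."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0] * m
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def sw_bruteforce(q: str, t: str, match: int, mismatch: int, gap: int) -> int:
    """Best local alignment score by exhaustion: the maximum global score
    over all substring pairs (empty alignment scores 0)."""
    best = 0
    for i1 in range(len(q)):
        for i2 in range(i1 + 1, len(q) + 1):
            for j1 in range(len(t)):
                for j2 in range(j1 + 1, len(t) + 1):
                    best = max(best, nw_global(q[i1:i2], t[j1:j2], match, mismatch, gap))
    return best
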