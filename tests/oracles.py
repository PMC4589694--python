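"""Independent brute-force oracles for the test suite.

Everything here is written as plainly as possible and independently of
the package's implementation: per-start full dynamic programming for
primer windows, tuple-valued Gotoh local alignment for probe counts, and
an exhaustive cross-product for primer-pairing geometry. Oracles trade
speed for obvious correctness and are only run at small problem sizes.
"""

from __future__ import annotations

from itertools import product

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
        "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
        "D": "H", "H": "D", "N": "N"}

BIG = 10 ** 9


def rc(seq: str) -> str:
    return "".join(COMP[b] for b in reversed(seq))


def base_matches(primer_base: str, target_base: str) -> bool:
    """Target base set must be a subset of the primer's; target N never matches."""
    if target_base == "N":
        return False
    return IUPAC_SETS[target_base] <= IUPAC_SETS[primer_base]


def _anchored_dp(primer: str, seq: str, start: int, g_max: int):
    """Global alignments of the full primer against seq[start:start+k].

    Returns ``final[k][g]`` = minimal mismatches aligning the whole
    primer to exactly k target bases from ``start`` using at most ``g``
    indels (BIG when impossible). Plain O(m * k * g) table.
    """
    m = len(primer)
    kmax = min(m + g_max, len(seq) - start)
    # dp[i][k][g]
    dp = [[[BIG] * (g_max + 1) for _ in range(kmax + 1)] for _ in range(m + 1)]
    for g in range(g_max + 1):
        for k in range(min(g, kmax) + 1):
            dp[0][k][g] = 0
    for i in range(1, m + 1):
        for k in range(kmax + 1):
            for g in range(g_max + 1):
                best = BIG
                if k >= 1:
                    cost = 0 if base_matches(primer[i - 1], seq[start + k - 1]) else 1
                    if dp[i - 1][k - 1][g] < BIG:
                        best = dp[i - 1][k - 1][g] + cost
                if g >= 1:
                    best = min(best, dp[i - 1][k][g - 1], dp[i][k - 1][g - 1] if k >= 1 else BIG)
                dp[i][k][g] = best
    return [dp[m][k] for k in range(kmax + 1)]


def oracle_tables(seq: str, primer: str, g_cap: int):
    """Per-start anchored DP tables, computed once at indel capacity
    ``g_cap`` so hit sets for any g_max <= g_cap can be derived."""
    return [_anchored_dp(primer, seq, s, g_cap) for s in range(len(seq))]


def oracle_sites(seq: str, primer: str, n_max: int, g_max: int, tables=None):
    """All primer hits on the given (already oriented) sequence.

    Per window: minimal-edit alignment with at most g_max indels, ranked
    by (mismatches + gaps, gaps); candidates costlier than n_max + g_max
    total are discarded outright; a candidate whose overlapping neighbour
    has a strictly lex-smaller (total, gaps) is suppressed; the survivors
    with mismatches <= n_max are the hits, as (start0, length, mm, gaps).

    ``tables`` may carry precomputed :func:`oracle_tables` output built
    with ``g_cap >= g_max``.
    """
    m, n = len(primer), len(seq)
    if tables is None:
        tables = oracle_tables(seq, primer, g_max)
    cands = []
    for s in range(n):
        final = tables[s]
        for k in range(max(1, m - g_max), min(m + g_max, n - s) + 1):
            best = None  # (total, gaps, mm)
            prev_mm = BIG
            for g in range(g_max + 1):
                mm = final[k][g]
                if mm >= BIG or mm >= prev_mm:
                    prev_mm = min(prev_mm, mm)
                    continue
                prev_mm = mm
                cand = (mm + g, g, mm)
                if best is None or cand[:2] < best[:2]:
                    best = cand
            if best is not None and best[0] <= n_max + g_max:
                cands.append((s, k, best[2], best[1]))
    hits = []
    for s, k, mm, gp in cands:
        dominated = False
        for so, ko, mo, go in cands:
            if (so, ko) == (s, k):
                continue
            if so < s + k and s < so + ko and (mo + go, go) < (mm + gp, gp):
                dominated = True
                break
        if not dominated and mm <= n_max:
            hits.append((s, k, mm, gp))
    hits.sort()
    return hits


def oracle_simulate_tables(seq: str, fw: str, rv: str, g_cap: int):
    """Precompute the four orientation table sets for oracle_simulate."""
    rseq = rc(seq)
    return {
        ("fw", "+"): oracle_tables(seq, fw, g_cap),
        ("fw", "-"): oracle_tables(rseq, fw, g_cap),
        ("rv", "+"): oracle_tables(seq, rv, g_cap),
        ("rv", "-"): oracle_tables(rseq, rv, g_cap),
    }


def oracle_simulate(seq: str, fw: str, rv: str, d_min: int, d_max: int,
                    n_max: int, g_max: int, total_max: int, tables=None):
    """Brute-force amplicon prediction on one target sequence.

    Returns a sorted list of (start0, end0_exclusive, strand, fw_mm,
    fw_gaps, rv_mm, rv_gaps); duplicate products keep the minimal
    (total, gaps) supporting pair.
    """
    n = len(seq)
    rseq = rc(seq)
    if tables is None:
        tables = oracle_simulate_tables(seq, fw, rv, g_max)

    def fwd_coords(h):  # hit on '+': coordinates already forward
        s, k, mm, gp = h
        return (s, s + k, mm, gp)

    def rev_coords(h):  # hit found on rc(seq) mapped to forward coords
        s, k, mm, gp = h
        return (n - (s + k), n - s, mm, gp)

    products = {}
    for fw_strand in ("+", "-"):
        if fw_strand == "+":
            fw_hits = [fwd_coords(h) for h in
                       oracle_sites(seq, fw, n_max, g_max, tables[("fw", "+")])]
            rv_hits = [rev_coords(h) for h in
                       oracle_sites(rseq, rv, n_max, g_max, tables[("rv", "-")])]
        else:
            fw_hits = [rev_coords(h) for h in
                       oracle_sites(rseq, fw, n_max, g_max, tables[("fw", "-")])]
            rv_hits = [fwd_coords(h) for h in
                       oracle_sites(seq, rv, n_max, g_max, tables[("rv", "+")])]
        for (fs, fe, fmm, fgp), (rs, re, rmm, rgp) in product(fw_hits, rv_hits):
            if fw_strand == "+":
                if rs < fe:
                    continue
                span = re - fs
                key = (fs, re, "+")
            else:
                if fs < re:
                    continue
                span = fe - rs
                key = (rs, fe, "-")
            total = fmm + fgp + rmm + rgp
            if not (d_min <= span <= d_max) or total > total_max:
                continue
            entry = (total, fgp + rgp, fmm, fgp, rmm, rgp)
            if key not in products or entry[:2] < products[key][:2]:
                products[key] = entry
    out = []
    for (a, b, strand), (_, _, fmm, fgp, rmm, rgp) in products.items():
        out.append((a, b, strand, fmm, fgp, rmm, rgp))
    out.sort()
    return out


def _tadd(t, ds, dg, dm, di):
    return (t[0] + ds, t[1] + dg, t[2] + dm, t[3] + di)


def oracle_local_align(query: str, subject: str,
                       match=1, mismatch=-2, gap_open=-2, gap_extend=-1):
    """Exhaustive Gotoh local alignment with tuple-valued cells.

    Cells hold (score, -gaps, -mismatches, identities) maximised
    lexicographically, so the returned optimum carries the same
    deterministic tie-break the package documents. Returns
    (score, gaps, mismatches, identities) or None.
    """
    lq, ls = len(query), len(subject)
    NEG = (-BIG, 0, 0, 0)
    ZERO = (0, 0, 0, 0)
    M = [[NEG] * (ls + 1) for _ in range(lq + 1)]
    X = [[NEG] * (ls + 1) for _ in range(lq + 1)]
    Y = [[NEG] * (ls + 1) for _ in range(lq + 1)]
    best = ZERO
    for i in range(1, lq + 1):
        for j in range(1, ls + 1):
            matched = base_matches(query[i - 1], subject[j - 1])
            base = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], ZERO)
            if matched:
                M[i][j] = _tadd(base, match, 0, 0, 1)
            else:
                M[i][j] = _tadd(base, mismatch, 0, -1, 0)
            X[i][j] = max(_tadd(M[i - 1][j], gap_open, -1, 0, 0),
                          _tadd(X[i - 1][j], gap_extend, -1, 0, 0),
                          _tadd(Y[i - 1][j], gap_open, -1, 0, 0))
            Y[i][j] = max(_tadd(M[i][j - 1], gap_open, -1, 0, 0),
                          _tadd(Y[i][j - 1], gap_extend, -1, 0, 0),
                          _tadd(X[i][j - 1], gap_open, -1, 0, 0))
            if M[i][j] > best:
                best = M[i][j]
    if best[0] <= 0:
        return None
    score, neg_gaps, neg_mm, ident = best
    return (score, -neg_gaps, -neg_mm, ident)
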