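"""TaqMan probe verification by local alignment.

After amplicon extraction, each method's probe (when present) is aligned
against the amplicon sequence to annotate how well it would anneal,
emulating the pairwise sequence-comparison step of the original screening
pipelines. The alignment is a Smith-Waterman/Gotoh local alignment with
affine gaps (match +1, mismatch -2, gap open -2, gap extend -1; the open
score applies to the first gapped position of a run). TaqMan probes may
be designed on either strand, so both amplicon strands are tried.

Co-optimal local alignments can differ in their edit composition; to keep
the annotation deterministic the optimum is ranked lexicographically by
(score desc, gap positions asc, mismatches asc, identities desc). The
four-level objective is packed into one integer so the DP stays in plain
int arithmetic; the weight separation is valid for sequences up to ~500
nt per side. An alignment is reported only when it covers at least half
of the probe (``min_coverage``); below that floor, or when no alignment
scores positive, the probe is annotated as not found.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .io_formats import DetectionMethod
from .pcr_engine import Amplicon, iupac_match, revcomp

MATCH = 1
MISMATCH = -2
GAP_OPEN = -2    # score of the first position of a gap run
GAP_EXTEND = -1  # score of each further gapped position

_W_SCORE = 1 << 30
_W_GAP = 1 << 20
_W_MM = 1 << 10

_D_MATCH = MATCH * _W_SCORE + 1
_D_MISMATCH = MISMATCH * _W_SCORE - _W_MM
_D_OPEN = GAP_OPEN * _W_SCORE - _W_GAP
_D_EXT = GAP_EXTEND * _W_SCORE - _W_GAP

_NEG = -(1 << 60)


@dataclass(frozen=True)
class ProbeAlignment:
    """Best local alignment of a probe inside an amplicon.

    Coordinates are 1-based inclusive: ``probe_start/probe_end`` on the
    probe, ``amp_start/amp_end`` on the amplicon sequence as stored
    (forward-primer -> reverse-primer orientation). ``strand`` is '+'
    when the probe anneals to the amplicon sequence as stored and '-'
    when it anneals to its reverse complement; minus-strand coordinates
    are reported on the stored sequence. ``covered_fraction`` is aligned
    probe bases / probe length, in (0, 1].
    """

    probe_start: int
    probe_end: int
    amp_start: int
    amp_end: int
    strand: str
    identities: int
    mismatches: int
    gaps: int
    score: int
    covered_fraction: float


def local_align(query: str, subject: str) -> Optional[tuple]:
    """Gotoh local alignment under the composite lexicographic objective.

    Returns ``(composite, q_start, q_end, s_start, s_end, identities,
    mismatches, gaps)`` with 1-based inclusive coordinates, or ``None``
    when no alignment has positive score. Among co-optimal composites the
    smallest ``(q_end, s_end)`` end cell wins; gap runs are scored
    open + (L-1) * extend. Shared by probe verification and greedy
    clustering.
    """
    lq, ls = len(query), len(subject)
    if lq == 0 or ls == 0:
        return None
    # M: alignment ends in an aligned column; X: ends with query base vs
    # gap; Y: ends with gap vs subject base. Full matrices are kept for
    # the traceback.
    M = [[_NEG] * (ls + 1) for _ in range(lq + 1)]
    X = [[_NEG] * (ls + 1) for _ in range(lq + 1)]
    Y = [[_NEG] * (ls + 1) for _ in range(lq + 1)]
    best = 0
    best_pos = None
    for i in range(1, lq + 1):
        qb = query[i - 1]
        m_prev, x_prev, y_prev = M[i - 1], X[i - 1], Y[i - 1]
        m_row, x_row, y_row = M[i], X[i], Y[i]
        for j in range(1, ls + 1):
            sub = _D_MATCH if iupac_match(qb, subject[j - 1]) else _D_MISMATCH
            base = m_prev[j - 1]
            if x_prev[j - 1] > base:
                base = x_prev[j - 1]
            if y_prev[j - 1] > base:
                base = y_prev[j - 1]
            if base < 0:
                base = 0          # local alignment: start fresh
            m_val = base + sub
            x_val = max(m_prev[j] + _D_OPEN, x_prev[j] + _D_EXT, y_prev[j] + _D_OPEN)
            y_val = max(m_row[j - 1] + _D_OPEN, y_row[j - 1] + _D_EXT, x_row[j - 1] + _D_OPEN)
            m_row[j] = m_val
            x_row[j] = x_val
            y_row[j] = y_val
            if m_val > best:      # strict: earliest (i, j) wins ties
                best = m_val
                best_pos = (i, j)
    if best_pos is None:
        return None

    # Traceback from the best cell, replaying forward decisions. Ties in
    # predecessor values carry identical (score, gaps, mm, id) prefix
    # totals, so any consistent choice yields the same counts.
    i, j = best_pos
    q_end, s_end = i, j
    identities = mismatches = gaps = 0
    state = "M"
    while True:
        if state == "M":
            matched = iupac_match(query[i - 1], subject[j - 1])
            if matched:
                identities += 1
            else:
                mismatches += 1
            base = M[i][j] - (_D_MATCH if matched else _D_MISMATCH)
            i -= 1
            j -= 1
            if base == 0:
                break
            if M[i][j] == base:
                state = "M"
            elif X[i][j] == base:
                state = "X"
            elif Y[i][j] == base:
                state = "Y"
            else:  # pragma: no cover - DP consistency
                raise AssertionError("traceback failure in M")
        elif state == "X":
            gaps += 1
            val = X[i][j]
            if M[i - 1][j] + _D_OPEN == val:
                state = "M"
            elif X[i - 1][j] + _D_EXT == val:
                state = "X"
            elif Y[i - 1][j] + _D_OPEN == val:
                state = "Y"
            else:  # pragma: no cover
                raise AssertionError("traceback failure in X")
            i -= 1
        else:  # "Y"
            gaps += 1
            val = Y[i][j]
            if M[i][j - 1] + _D_OPEN == val:
                state = "M"
            elif Y[i][j - 1] + _D_EXT == val:
                state = "Y"
            elif X[i][j - 1] + _D_OPEN == val:
                state = "X"
            else:  # pragma: no cover
                raise AssertionError("traceback failure in Y")
            j -= 1
    return (best, i + 1, q_end, j + 1, s_end, identities, mismatches, gaps)


def decode_score(composite: int) -> int:
    """Recover the plain alignment score from a composite value."""
    id_ = composite % _W_MM
    c = (composite - id_) // _W_MM
    mm = (-c) % _W_MM
    c = (c + mm) // _W_MM
    gp = (-c) % _W_MM
    c = (c + gp) // _W_MM
    return c


def align_probe(
    probe: str,
    amplicon_seq: str,
    min_coverage: float = 0.5,
) -> Optional[ProbeAlignment]:
    """Best local alignment of a probe over both strands of an amplicon.

    Returns ``None`` when no positive-scoring alignment covers at least
    ``min_coverage`` of the probe. Strand ties break toward '+'.
    """
    if len(probe) < 10:
        raise ValueError("probe shorter than 10 nt")
    results = []
    for strand, subject in (("+", amplicon_seq), ("-", revcomp(amplicon_seq))):
        res = local_align(probe, subject)
        if res is not None:
            results.append((res[0], strand, res))
    if not results:
        return None
    # max returns the first maximal element, so '+' wins exact ties
    _, strand, res = max(results, key=lambda r: r[0])
    comp, q_start, q_end, s_start, s_end, ident, mm, gaps = res
    covered = (q_end - q_start + 1) / len(probe)
    if covered < min_coverage:
        return None
    if strand == "-":
        # map coordinates back to the stored amplicon orientation
        n = len(amplicon_seq)
        s_start, s_end = n - s_end + 1, n - s_start + 1
    return ProbeAlignment(
        probe_start=q_start, probe_end=q_end,
        amp_start=s_start, amp_end=s_end,
        strand=strand,
        identities=ident, mismatches=mm, gaps=gaps,
        score=decode_score(comp),
        covered_fraction=covered,
    )


def annotate_probe(
    amplicon: Amplicon,
    method: DetectionMethod,
    min_coverage: float = 0.5,
) -> Amplicon:
    """Fill the probe fields of an amplicon.

    ``probe_status`` becomes ``no_probe`` (method has none), ``perfect``
    (full probe coverage with zero mismatches and gaps), ``mismatched``
    (an alignment was found but carries edits or partial coverage) or
    ``not_found`` (no acceptable alignment). Annotation never removes an
    amplicon; filtering on probe quality happens downstream in the
    screening-matrix strict mode.
    """
    if method.probe is None:
        return replace(amplicon, probe_status="no_probe",
                       probe_mismatches=0, probe_gaps=0)
    aln = align_probe(method.probe, amplicon.sequence, min_coverage=min_coverage)
    if aln is None:
        return replace(amplicon, probe_status="not_found",
                       probe_mismatches=0, probe_gaps=0)
    perfect = (aln.covered_fraction == 1.0 and aln.mismatches == 0 and aln.gaps == 0)
    return replace(
        amplicon,
        probe_status="perfect" if perfect else "mismatched",
        probe_mismatches=aln.mismatches,
        probe_gaps=aln.gaps,
    )
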