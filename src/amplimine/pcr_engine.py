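"""Core in-silico PCR engine.

The engine predicts PCR amplification by (1) locating primer binding sites
on both strands of a target under per-primer mismatch and indel bounds,
(2) pairing sites of the forward and reverse primer in convergent
orientation within the product-size window, and (3) applying a combined
mismatches+gaps cap over both primers before an amplicon is reported.

Site-finding semantics
----------------------
A candidate site is a target window aligned to the *full* primer
(end-to-end primer coverage, target ends free). For each window the engine
computes the minimal-edit alignment among alignments using at most
``g_max`` indel positions, ranking alignments by (mismatches + gaps)
first and gap count second. The window is a hit when that minimal-edit
alignment satisfies ``mismatches <= n_max`` (gaps are within ``g_max`` by
construction); a window whose *best* alignment is over budget is not
rescued by a worse-but-within-bounds alignment.

Every clean site is surrounded by shadow windows (the same alignment
padded by one extra target base at either end, costing one gap). A window
is therefore suppressed when an overlapping candidate window — of the
same primer and strand — achieves a strictly smaller (total edits, gaps)
pair. Overlapping candidates of equal cost (e.g. tandem repeats of the
primer sequence) are all reported, as genuinely distinct loci.

IUPAC ambiguity codes in primers match their base sets at zero cost; an
``N`` in the target never matches (this suppresses hits inside the N-runs
of draft records).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import DetectionMethod, PcrParams, SequenceRecord, IUPAC_LETTERS

# 4-bit encoding of IUPAC base sets: A=1, C=2, G=4, T=8.
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_INF = 1 << 14  # larger than any attainable mismatch count

_BITS_LUT = np.zeros(128, dtype=np.int32)
for _letter, _bits in IUPAC_BITS.items():
    _BITS_LUT[ord(_letter)] = _bits


def revcomp(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, N<->N, ...)."""
    bad = set(seq) - IUPAC_LETTERS
    if bad:
        raise ValueError(f"non-IUPAC character(s) {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer_base: str, target_base: str) -> bool:
    """True iff the target base set is a subset of the primer's ambiguity set.

    A target ``N`` never matches (counted as a mismatch), even against a
    primer ``N``.
    """
    p = IUPAC_BITS[primer_base]
    t = IUPAC_BITS[target_base]
    return t != 15 and (t & ~p) == 0


@dataclass(frozen=True)
class PrimerHit:
    """One primer binding site.

    ``start``/``end`` are 1-based inclusive forward-strand coordinates of
    the matched target window; ``strand`` is the strand the primer
    annealed to. ``total_edits`` = mismatches + gaps.
    """

    record_id: str
    primer_role: str  # "forward" | "reverse"
    strand: str       # "+" | "-"
    start: int
    end: int
    mismatches: int
    gaps: int

    @property
    def total_edits(self) -> int:
        return self.mismatches + self.gaps


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product.

    ``strand`` is the orientation of the forward primer's match; ``start``
    and ``end`` are 1-based inclusive forward-strand coordinates spanning
    outermost primer bases. ``sequence`` is the extracted target
    subsequence, reverse-complemented for minus-strand products so that it
    always reads forward-primer -> reverse-primer.
    """

    record_id: str
    dataset_label: str
    method_id: str
    specificity: str
    strand: str
    start: int
    end: int
    product_length: int
    fw_mismatches: int
    fw_gaps: int
    rv_mismatches: int
    rv_gaps: int
    total_edits: int
    sequence: str
    probe_status: str = "no_probe"
    probe_mismatches: int = 0
    probe_gaps: int = 0
    species: str = "unknown"


def _scan_forward(seq: str, primer: str, g_max: int) -> np.ndarray:
    """Anchored banded DP over all window starts simultaneously.

    Returns ``G`` of shape ``(kmax+1, g_max+1, n)`` where
    ``G[k, g, s]`` is the minimal number of mismatches over alignments of
    the full primer to ``seq[s : s+k]`` using at most ``g`` indel
    positions (``_INF`` when impossible). Only the final primer row is
    returned; the band ``|k - i| <= g_max`` restricts intermediate work.
    """
    n = len(seq)
    m = len(primer)
    gm = g_max
    kmax = m + gm

    # mismatch cost of primer base i against every target position,
    # padded with _INF beyond the sequence end so overruns stay infeasible.
    tbits = _BITS_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    mm = np.full((m, n + kmax), _INF, dtype=np.int32)
    for i, pb in enumerate(primer):
        pbits = IUPAC_BITS[pb]
        mm[i, :n] = (((tbits & ~pbits & 15) != 0) | (tbits == 15)).astype(np.int32)

    prev = np.full((kmax + 2, gm + 1, n), _INF, dtype=np.int32)
    for k in range(0, gm + 1):          # row i=0: k target bases as gaps
        for g in range(k, gm + 1):
            prev[k, g, :] = 0

    for i in range(1, m + 1):
        cur = np.full((kmax + 2, gm + 1, n), _INF, dtype=np.int32)
        klo, khi = max(0, i - gm), min(kmax, i + gm)
        for k in range(klo, khi + 1):
            for g in range(gm + 1):
                if k >= 1:
                    # diagonal: primer base i vs target base s+k-1
                    best = prev[k - 1, g, :] + mm[i - 1, k - 1:k - 1 + n]
                else:
                    best = np.full(n, _INF, dtype=np.int32)
                if g >= 1:
                    np.minimum(best, prev[k, g - 1, :], out=best)       # primer base vs gap
                    if k >= 1:
                        np.minimum(best, cur[k - 1, g - 1, :], out=best)  # target base vs gap
                cur[k, g, :] = best
        prev = cur
    return prev[:kmax + 1, :, :]


def _candidates(seq: str, primer: str, params: PcrParams) -> list[tuple[int, int, int, int]]:
    """Candidate windows ``(start0, length, mismatches, gaps)`` on one strand.

    Candidates carry the minimal-edit alignment's counts and are kept when
    total edits <= n_max + g_max (anything costlier can neither pass the
    per-primer bounds nor suppress a window that does).
    """
    n, m, gm = len(seq), len(primer), params.g_max
    if n < m - gm:
        return []
    G = _scan_forward(seq, primer, gm)
    out: list[tuple[int, int, int, int]] = []
    cap = params.n_max + params.g_max
    starts = np.arange(n)
    for k in range(max(1, m - gm), min(m + gm, n) + 1):
        best_mm = G[k, 0, :].copy()
        best_gaps = np.zeros(n, dtype=np.int32)
        best_total = best_mm + 0
        for g in range(1, gm + 1):
            mm_g = G[k, g, :]
            total_g = mm_g + g
            better = total_g < best_total      # lexicographic: ties keep fewer gaps
            best_total = np.where(better, total_g, best_total)
            best_mm = np.where(better, mm_g, best_mm)
            best_gaps = np.where(better, g, best_gaps)
        valid = (starts + k <= n) & (best_total <= cap)
        for s in np.nonzero(valid)[0]:
            out.append((int(s), k, int(best_mm[s]), int(best_gaps[s])))
    return out


def _suppress(cands: list[tuple[int, int, int, int]]) -> list[tuple[int, int, int, int]]:
    """Drop windows dominated by a strictly cheaper overlapping candidate."""
    if not cands:
        return []
    cands = sorted(cands, key=lambda c: (c[0], c[0] + c[1]))
    maxk = max(c[1] for c in cands)
    keep = []
    for idx, (s, k, mm, gp) in enumerate(cands):
        t = mm + gp
        dominated = False
        # overlap only possible within one window width in either direction
        j = idx - 1
        while j >= 0 and cands[j][0] > s - maxk:
            so, ko, mo, go = cands[j]
            if so + ko > s and (mo + go, go) < (t, gp):
                dominated = True
                break
            j -= 1
        if not dominated:
            j = idx + 1
            while j < len(cands) and cands[j][0] < s + k:
                so, ko, mo, go = cands[j]
                if (mo + go, go) < (t, gp):
                    dominated = True
                    break
                j += 1
        if not dominated:
            keep.append((s, k, mm, gp))
    return keep


def find_primer_sites(
    target: SequenceRecord,
    primer: str,
    params: PcrParams,
    strand: str,
    primer_role: str = "forward",
) -> list[PrimerHit]:
    """Find binding sites of ``primer`` on one strand of ``target``.

    ``strand='+'`` matches the primer against the forward sequence,
    ``strand='-'`` against its reverse complement; coordinates are always
    reported on the forward strand. See the module docstring for the hit
    semantics (minimal-edit window alignment, bounds, shadow suppression).
    """
    if len(primer) < 10:
        raise ValueError(f"primer shorter than 10 nt: {primer!r}")
    if strand not in "+-" or len(strand) != 1:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = target.sequence if strand == "+" else revcomp(target.sequence)
    n = len(seq)
    cands = _suppress(_candidates(seq, primer, params))
    hits = []
    for s, k, mm, gp in cands:
        if mm > params.n_max:
            continue
        if strand == "+":
            start, end = s + 1, s + k
        else:
            start, end = n - (s + k) + 1, n - s
        hits.append(PrimerHit(
            record_id=target.record_id, primer_role=primer_role, strand=strand,
            start=start, end=end, mismatches=mm, gaps=gp,
        ))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def pair_hits(
    fw_hits: list[PrimerHit],
    rv_hits: list[PrimerHit],
    params: PcrParams,
) -> list[tuple[PrimerHit, PrimerHit]]:
    """Pair forward/reverse primer sites in convergent orientation.

    ``fw_hits`` must lie on one strand and ``rv_hits`` on the opposite
    strand of the same record. A pair is kept when the primer footprints
    do not overlap, the forward match lies strictly upstream of the
    reverse match in amplicon orientation (3' ends facing inward), and the
    outer-to-outer span is within ``[d_min, d_max]``.
    """
    pairs = []
    for fw in fw_hits:
        for rv in rv_hits:
            if fw.record_id != rv.record_id or fw.strand == rv.strand:
                continue
            if fw.strand == "+":
                if rv.start <= fw.end:   # overlap or wrong geometry
                    continue
                span = rv.end - fw.start + 1
            else:
                if fw.start <= rv.end:
                    continue
                span = fw.end - rv.start + 1
            if params.d_min <= span <= params.d_max:
                pairs.append((fw, rv))
    return pairs


def simulate_pcr(
    target: SequenceRecord,
    method: DetectionMethod,
    params: PcrParams = PcrParams(),
) -> list[Amplicon]:
    """Predict the amplicons of one detection method on one target record.

    Both product orientations are considered (forward primer annealing to
    either strand). Products whose summed primer edits exceed
    ``total_edit_max`` are discarded; duplicate coordinate/strand products
    are reported once with the minimal-edit supporting pair. Probe fields
    are initialised to ``no_probe`` and filled by
    :func:`amplimine.probe_align.annotate_probe`.
    """
    products: dict[tuple[int, int, str], Amplicon] = {}
    for fw_strand in ("+", "-"):
        rv_strand = "-" if fw_strand == "+" else "+"
        fw_hits = find_primer_sites(target, method.fw_primer, params, fw_strand, "forward")
        rv_hits = find_primer_sites(target, method.rv_primer, params, rv_strand, "reverse")
        for fw, rv in pair_hits(fw_hits, rv_hits, params):
            total = fw.total_edits + rv.total_edits
            if total > params.total_edit_max:
                continue
            if fw_strand == "+":
                start, end = fw.start, rv.end
                seq = target.sequence[start - 1:end]
            else:
                start, end = rv.start, fw.end
                seq = revcomp(target.sequence[start - 1:end])
            key = (start, end, fw_strand)
            amp = Amplicon(
                record_id=target.record_id,
                dataset_label=target.dataset_label,
                method_id=method.method_id,
                specificity=method.specificity,
                strand=fw_strand,
                start=start, end=end,
                product_length=end - start + 1,
                fw_mismatches=fw.mismatches, fw_gaps=fw.gaps,
                rv_mismatches=rv.mismatches, rv_gaps=rv.gaps,
                total_edits=total,
                sequence=seq,
            )
            prior = products.get(key)
            if prior is None or (total, fw.gaps + rv.gaps) < (
                    prior.total_edits, prior.fw_gaps + prior.rv_gaps):
                products[key] = amp
    return sorted(products.values(), key=lambda a: (a.start, a.end, a.strand))
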