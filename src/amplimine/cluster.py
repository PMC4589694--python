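"""Non-redundant amplicon set construction.

Two grouping modes are provided:

* **exact** — partition by identical sequence string, the grouping behind
  "distinct groups of 100% identical sequences";
* **approximate** — greedy incremental clustering in the cd-hit style:
  sequences are visited longest first and join the first established
  representative they align to at or above an identity threshold with
  sufficient bidirectional coverage, else they found a new cluster.

The approximate mode is defined by explicit pairwise local alignment
(same scoring as the probe step: match +1, mismatch -2, gap open -2,
extend -1) rather than cd-hit's word-filter heuristics; identity is
matches / alignment columns, and coverage is the aligned span on each
sequence divided by its length. Defaults are 90% identity with 90%
coverage of both the longer (aL) and the shorter (aS) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import SequenceRecord
from .pcr_engine import Amplicon
from .probe_align import local_align


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for approximate clustering (all fractions in (0, 1])."""

    identity_min: float = 0.9
    aL: float = 0.9  # alignment coverage of the longer sequence
    aS: float = 0.9  # alignment coverage of the shorter sequence

    def __post_init__(self) -> None:
        for name in ("identity_min", "aL", "aS"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class Cluster:
    representative: Amplicon
    members: list[Amplicon]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """A partition of the input amplicon multiset into clusters."""

    clusters: list[Cluster]
    mode: str  # "exact" | "approximate"

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]


def dedup_identical(amplicons: list[Amplicon]) -> ClusterSet:
    """Group amplicons whose sequences are string-identical.

    The representative is the first member in input order; clusters are
    ordered by first occurrence. The cluster count equals the number of
    distinct sequence strings.
    """
    by_seq: dict[str, Cluster] = {}
    for amp in amplicons:
        cl = by_seq.get(amp.sequence)
        if cl is None:
            by_seq[amp.sequence] = Cluster(representative=amp, members=[amp])
        else:
            cl.members.append(amp)
    return ClusterSet(clusters=list(by_seq.values()), mode="exact")


def _joins(seq: str, rep: str, params: ClusterParams) -> bool:
    """Does ``seq`` meet the identity/coverage thresholds against ``rep``?"""
    if seq == rep:
        return True
    res = local_align(seq, rep)
    if res is None:
        return False
    _, q_start, q_end, s_start, s_end, ident, mm, gaps = res
    columns = ident + mm + gaps
    identity = ident / columns
    span_q = q_end - q_start + 1
    span_s = s_end - s_start + 1
    if len(seq) >= len(rep):
        cov_long, cov_short = span_q / len(seq), span_s / len(rep)
    else:
        cov_long, cov_short = span_s / len(rep), span_q / len(seq)
    return identity >= params.identity_min and cov_long >= params.aL and cov_short >= params.aS


def greedy_cluster(
    amplicons: list[Amplicon],
    params: ClusterParams = ClusterParams(),
) -> ClusterSet:
    """Greedy incremental clustering, longest sequence first.

    Length ties keep input order (the documented tie-break source: the
    cluster count of equal-length permutations may vary only through this
    greedy visiting order). Each sequence joins the first representative
    it satisfies :func:`_joins` against, else founds a new cluster.
    """
    order = sorted(range(len(amplicons)),
                   key=lambda i: (-len(amplicons[i].sequence), i))
    clusters: list[Cluster] = []
    for idx in order:
        amp = amplicons[idx]
        for cl in clusters:
            if _joins(amp.sequence, cl.representative.sequence, params):
                cl.members.append(amp)
                break
        else:
            clusters.append(Cluster(representative=amp, members=[amp]))
    return ClusterSet(clusters=clusters, mode="approximate")


def export_nonredundant(clusters: ClusterSet) -> list[SequenceRecord]:
    """One FASTA record per cluster representative.

    The record ID combines the representative's record and method IDs
    with a cluster ordinal (guaranteeing uniqueness); the description
    carries the cluster size, so member counts survive the FASTA export.
    """
    records = []
    for i, cl in enumerate(clusters.clusters, start=1):
        rep = cl.representative
        records.append(SequenceRecord(
            record_id=f"{rep.record_id}|{rep.method_id}|c{i}",
            description=f"cluster_size={cl.size}",
            sequence=rep.sequence,
            dataset_label=rep.dataset_label,
        ))
    return records
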