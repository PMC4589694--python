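"""Screening matrices and consistency summaries.

A screening matrix counts predicted amplicons per (record, dataset) x
method cell. In *strict* mode only perfect predictions are counted:
amplicons with zero primer mismatches and gaps whose probe (when the
method has one) anneals perfectly — the filter used when judging whether
a method "detects" a record.

Consistency summaries aggregate the matrix per dataset and method
specificity class: the fraction of methods of a class producing at least
one amplicon in a dataset, the fraction of records detected, and the
amplicon:record ratio (event-specific assays target unique integration
junctions, so on transgenic-like data this ratio is expected to be 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .io_formats import DetectionMethod, SequenceRecord, SPECIFICITY_CLASSES
from .pcr_engine import Amplicon


@dataclass
class ScreeningMatrix:
    """Amplicon counts per (record_id, dataset_label) x method_id."""

    detection: dict[tuple[str, str, str], int]
    strict_mode: bool
    specificity: dict[str, str] = field(default_factory=dict)  # method_id -> class

    def count(self, record_id: str, dataset_label: str, method_id: str) -> int:
        return self.detection.get((record_id, dataset_label, method_id), 0)


@dataclass(frozen=True)
class ConsistencySummary:
    """Aggregates for one (dataset_label, specificity) pair.

    Fractions are ``None`` (reported as absent, not zero) when their
    denominator is empty. ``record_count`` is the number of distinct
    records of the dataset detected by methods of the class;
    ``records_detected_fraction`` divides it by the dataset size.
    """

    dataset_label: str
    specificity: str
    methods_detecting_fraction: Optional[float]
    records_detected_fraction: Optional[float]
    amplicon_count: int
    record_count: int
    amplicons_per_record: Optional[float]


def is_strict(amplicon: Amplicon) -> bool:
    """Perfect prediction: no primer edits, probe perfect or absent."""
    return amplicon.total_edits == 0 and amplicon.probe_status in ("perfect", "no_probe")


def build_matrix(amplicons: list[Amplicon], strict: bool) -> ScreeningMatrix:
    """Count amplicons per record x method, optionally strict-filtered."""
    detection: dict[tuple[str, str, str], int] = {}
    specificity: dict[str, str] = {}
    for amp in amplicons:
        if strict and not is_strict(amp):
            continue
        key = (amp.record_id, amp.dataset_label, amp.method_id)
        detection[key] = detection.get(key, 0) + 1
        specificity[amp.method_id] = amp.specificity
    return ScreeningMatrix(detection=detection, strict_mode=strict,
                           specificity=specificity)


def summarize(
    matrix: ScreeningMatrix,
    records: list[SequenceRecord],
    methods: list[DetectionMethod],
) -> list[ConsistencySummary]:
    """One summary per dataset x specificity class.

    ``records`` must include undetected records — they provide the
    denominators of the per-dataset detection fractions.
    """
    datasets: dict[str, int] = {}
    for rec in records:
        datasets[rec.dataset_label] = datasets.get(rec.dataset_label, 0) + 1
    methods_by_class: dict[str, list[str]] = {c: [] for c in SPECIFICITY_CLASSES}
    for m in methods:
        methods_by_class[m.specificity].append(m.method_id)

    # per (dataset, method): amplicon count and detected record sets
    amp_count: dict[tuple[str, str], int] = {}
    detected: dict[tuple[str, str], set[str]] = {}
    for (rid, dlabel, mid), n in matrix.detection.items():
        amp_count[(dlabel, mid)] = amp_count.get((dlabel, mid), 0) + n
        detected.setdefault((dlabel, mid), set()).add(rid)

    summaries = []
    for dlabel in sorted(datasets):
        n_records = datasets[dlabel]
        for cls in SPECIFICITY_CLASSES:
            mids = methods_by_class[cls]
            n_amps = sum(amp_count.get((dlabel, mid), 0) for mid in mids)
            recs: set[str] = set()
            for mid in mids:
                recs |= detected.get((dlabel, mid), set())
            n_detecting = sum(1 for mid in mids if amp_count.get((dlabel, mid), 0) > 0)
            summaries.append(ConsistencySummary(
                dataset_label=dlabel,
                specificity=cls,
                methods_detecting_fraction=(n_detecting / len(mids)) if mids else None,
                records_detected_fraction=(len(recs) / n_records) if n_records else None,
                amplicon_count=n_amps,
                record_count=len(recs),
                amplicons_per_record=(n_amps / len(recs)) if recs else None,
            ))
    return summaries


def write_summary_table(summaries: list[ConsistencySummary], path: str | Path) -> None:
    """Write summaries as TSV; absent fractions become empty fields."""
    df = pd.DataFrame([
        {
            "dataset_label": s.dataset_label,
            "specificity": s.specificity,
            "methods_detecting_fraction": s.methods_detecting_fraction,
            "records_detected_fraction": s.records_detected_fraction,
            "amplicon_count": s.amplicon_count,
            "record_count": s.record_count,
            "amplicons_per_record": s.amplicons_per_record,
        }
        for s in summaries
    ])
    df.to_csv(path, sep="\t", index=False)


def candidate_events(
    matrix: ScreeningMatrix,
    observed: dict[str, bool],
) -> list[tuple[str, str]]:
    """Triage records consistent with a set of screening calls.

    ``observed`` maps method_id -> positive/negative laboratory call. A
    record is a candidate when its (strict-mode) detection pattern covers
    every observed positive; candidates are ranked by how many observed
    negatives they also satisfy (i.e. methods called negative that do not
    detect the record), ties broken by (record_id, dataset_label). This
    supports the unauthorized-GMO workflow: shortlist sequences that
    explain all positive screening signals.
    """
    pattern: dict[tuple[str, str], set[str]] = {}
    for (rid, dlabel, mid), n in matrix.detection.items():
        if n > 0:
            pattern.setdefault((rid, dlabel), set()).add(mid)
    positives = {m for m, call in observed.items() if call}
    negatives = {m for m, call in observed.items() if not call}
    ranked = []
    for key, mids in pattern.items():
        if positives <= mids:
            neg_ok = len(negatives - mids)
            ranked.append((-neg_ok, key))
    ranked.sort()
    return [key for _, key in ranked]
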