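"""Readers and writers for the pipeline's external formats.

Four formats cross the package boundary:

* FASTA target datasets (plain or line-wrapped), each file carrying a
  user-supplied *dataset label* so downstream summaries can be broken down
  by collection of origin;
* a TSV table of PCR detection methods (primer pair, optional probe,
  specificity class);
* a TSV record-to-species mapping;
* the 18-column TAB-delimited amplicon table that the pipeline emits and
  that the clustering / matrix stages re-read.

Coordinates in the amplicon table are 1-based inclusive on the forward
strand of the input record, regardless of amplicon orientation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# IUPAC nucleotide alphabet (no U: DNA only).
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")

SPECIFICITY_CLASSES = ("event", "construct", "element", "taxon")

#: Column order of the TAB-delimited amplicon table.
AMPLICON_COLUMNS = (
    "record_id", "dataset_label", "method_id", "specificity", "strand",
    "start", "end", "product_length",
    "fw_mismatches", "fw_gaps", "rv_mismatches", "rv_gaps", "total_edits",
    "probe_status", "probe_mismatches", "probe_gaps",
    "species", "amplicon_sequence",
)

PROBE_STATUSES = ("perfect", "mismatched", "not_found", "no_probe")


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


class MethodsTableError(ValueError):
    """Invalid detection-methods table row."""


@dataclass(frozen=True)
class SequenceRecord:
    """One target sequence with its dataset provenance.

    ``record_id`` is the first whitespace-delimited token of the FASTA
    header (the position database record IDs occupy in public FASTA dumps);
    ``description`` is the remainder of the header line.
    """

    record_id: str
    description: str
    sequence: str
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_LETTERS
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DetectionMethod:
    """One PCR detection method: primer pair, optional TaqMan probe.

    ``specificity`` follows the four-class scheme used for GMO reference
    methods: *event* (integration-junction assays, the most specific),
    *construct* (junctions between elements of a transgenic construct),
    *element* (single genetic elements such as promoters or markers) and
    *taxon* (endogenous species genes).
    """

    method_id: str
    specificity: str
    target_name: str
    fw_primer: str
    rv_primer: str
    probe: Optional[str] = None

    def __post_init__(self) -> None:
        if self.specificity not in SPECIFICITY_CLASSES:
            raise MethodsTableError(
                f"method {self.method_id!r}: unknown specificity "
                f"{self.specificity!r} (expected one of {SPECIFICITY_CLASSES})"
            )
        for role, primer in (("fw_primer", self.fw_primer), ("rv_primer", self.rv_primer)):
            if len(primer) < 10:
                raise MethodsTableError(
                    f"method {self.method_id!r}: {role} shorter than 10 nt"
                )
            _check_iupac(primer, f"method {self.method_id!r} {role}")
        if self.probe is not None:
            _check_iupac(self.probe, f"method {self.method_id!r} probe")


@dataclass(frozen=True)
class PcrParams:
    """In-silico PCR tolerances.

    Defaults mirror the canonical e-PCR invocation for GMO screening:
    product size window 50-500 bp, at most 2 mismatches and 2 indels per
    primer, and at most 2 mismatches+gaps summed over both primers for an
    amplicon to be retained.
    """

    d_min: int = 50
    d_max: int = 500
    n_max: int = 2
    g_max: int = 2
    total_edit_max: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.d_min <= self.d_max):
            raise ValueError(f"require 0 < d_min <= d_max, got {self.d_min}..{self.d_max}")
        if min(self.n_max, self.g_max, self.total_edit_max) < 0:
            raise ValueError("edit bounds must be non-negative")


def _check_iupac(seq: str, what: str) -> None:
    bad = set(seq) - IUPAC_LETTERS
    if bad:
        raise MethodsTableError(f"{what}: non-IUPAC character(s) {sorted(bad)!r}")


def read_fasta(path: str | Path, dataset_label: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; input order is preserved. Raises
    :class:`FastaParseError` on sequence data before the first header and
    on duplicate record IDs within the file.
    """
    path = Path(path)
    # Biopython silently ignores junk before the first '>', so pre-check.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first FASTA header"
                )
            break

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate record ID {entry.id!r}")
        seen.add(entry.id)
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        records.append(
            SequenceRecord(
                record_id=entry.id,
                description=desc,
                sequence=str(entry.seq).upper(),
                dataset_label=dataset_label,
            )
        )
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA (header = id + ' ' + description)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")


def read_methods_table(path: str | Path) -> list[DetectionMethod]:
    """Read the TSV detection-methods table.

    Expected header columns: ``method_id``, ``specificity``, ``target_name``,
    ``fw_primer``, ``rv_primer``, ``probe`` (the probe field may be empty).
    Primers and probes are uppercased. Validation failures name the row.
    """
    path = Path(path)
    methods: list[DetectionMethod] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"method_id", "specificity", "target_name", "fw_primer", "rv_primer", "probe"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise MethodsTableError(f"{path}: missing column(s) {sorted(missing)}")
        for rownum, row in enumerate(reader, start=2):
            mid = row["method_id"].strip()
            if mid in seen:
                raise MethodsTableError(f"{path}: row {rownum}: duplicate method_id {mid!r}")
            seen.add(mid)
            probe = row["probe"].strip().upper() or None
            try:
                methods.append(
                    DetectionMethod(
                        method_id=mid,
                        specificity=row["specificity"].strip(),
                        target_name=row["target_name"].strip(),
                        fw_primer=row["fw_primer"].strip().upper(),
                        rv_primer=row["rv_primer"].strip().upper(),
                        probe=probe,
                    )
                )
            except MethodsTableError as exc:
                raise MethodsTableError(f"{path}: row {rownum}: {exc}") from exc
    return methods


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read the two-column TSV record→species mapping (header: record_id, species)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"record_id", "species"}.issubset(reader.fieldnames):
            raise ValueError(f"{path}: expected columns record_id, species")
        for rownum, row in enumerate(reader, start=2):
            rid = row["record_id"].strip()
            if rid in mapping:
                raise ValueError(f"{path}: row {rownum}: duplicate record_id {rid!r}")
            mapping[rid] = row["species"].strip()
    return mapping


def write_amplicon_table(amplicons, path: str | Path) -> None:
    """Write the 18-column TAB-delimited amplicon table (header + one row each)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(AMPLICON_COLUMNS)
        for a in amplicons:
            writer.writerow([
                a.record_id, a.dataset_label, a.method_id, a.specificity, a.strand,
                a.start, a.end, a.product_length,
                a.fw_mismatches, a.fw_gaps, a.rv_mismatches, a.rv_gaps, a.total_edits,
                a.probe_status, a.probe_mismatches, a.probe_gaps,
                a.species, a.sequence,
            ])


def read_amplicon_table(path: str | Path):
    """Re-parse a table written by :func:`write_amplicon_table`.

    Returns a list of :class:`~amplimine.pcr_engine.Amplicon`; the
    round-trip reproduces every field.
    """
    from .pcr_engine import Amplicon  # local import to avoid a cycle

    path = Path(path)
    amplicons = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or tuple(header) != AMPLICON_COLUMNS:
            raise ValueError(f"{path}: unexpected amplicon table header")
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(AMPLICON_COLUMNS):
                raise ValueError(f"{path}: row {rownum}: expected {len(AMPLICON_COLUMNS)} columns")
            d = dict(zip(AMPLICON_COLUMNS, row))
            amplicons.append(
                Amplicon(
                    record_id=d["record_id"],
                    dataset_label=d["dataset_label"],
                    method_id=d["method_id"],
                    specificity=d["specificity"],
                    strand=d["strand"],
                    start=int(d["start"]),
                    end=int(d["end"]),
                    product_length=int(d["product_length"]),
                    fw_mismatches=int(d["fw_mismatches"]),
                    fw_gaps=int(d["fw_gaps"]),
                    rv_mismatches=int(d["rv_mismatches"]),
                    rv_gaps=int(d["rv_gaps"]),
                    total_edits=int(d["total_edits"]),
                    probe_status=d["probe_status"],
                    probe_mismatches=int(d["probe_mismatches"]),
                    probe_gaps=int(d["probe_gaps"]),
                    species=d["species"],
                    sequence=d["amplicon_sequence"],
                )
            )
    return amplicons
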