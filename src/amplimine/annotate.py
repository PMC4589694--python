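"""Species and provenance annotation of amplicons.

The original screening workflow resolves species by querying a taxonomy
service with the target record ID; this package replaces that with an
offline record->species TSV mapping so runs are fully reproducible and
download-free. When no mapping is supplied, a fallback extracts an
``[organism]``-style bracketed token from the FASTA description, a
convention common in public sequence dumps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .io_formats import SequenceRecord
from .pcr_engine import Amplicon

_BRACKET = re.compile(r"\[([^\[\]]+)\]")


@dataclass(frozen=True)
class SpeciesMap:
    """Immutable record_id -> species lookup."""

    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "SpeciesMap":
        """Fallback map built from ``[organism]`` tokens in FASTA descriptions."""
        entries = {}
        for rec in records:
            m = _BRACKET.search(rec.description)
            if m:
                entries[rec.record_id] = m.group(1).strip()
        return cls(entries)


def assign_species(amplicon: Amplicon, species_map: SpeciesMap) -> Amplicon:
    """Set the species field from the map; ``"unknown"`` when absent.

    Total and idempotent; no other field is touched.
    """
    species = species_map.entries.get(amplicon.record_id, "unknown")
    return replace(amplicon, species=species)
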