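"""Synthetic datasets with planted primer/probe sites.

Real screening runs operate on public sequence collections (patent
divisions, transgenic divisions, plant contigs) that are far too large to
ship; this module emulates their composition with three record classes:

* ``transgenic_like`` — records carrying GM-specific planted sites
  (event / construct / element methods), like public transgene entries;
* ``plant_like`` — plant-genomic decoys carrying at most taxon-specific
  sites, like whole-genome contig divisions;
* ``patent_like`` — constructs emitted in several near-identical copies
  (background-only substitutions between copies), reproducing the heavy
  redundancy of patent sequence divisions.

Every planted site comes with an analytically derived ground-truth
amplicon (coordinates, edit counts, probe status), so the in-silico PCR
engine can be validated field-for-field against what was planted. The
random background is screened for unintended primer sites (an ungapped
sliding similarity check with a conservative margin) and redrawn when one
appears, which keeps the ground truth exhaustive; generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .io_formats import (
    DetectionMethod,
    PcrParams,
    SequenceRecord,
    write_fasta,
)
from .pcr_engine import Amplicon, IUPAC_BITS, revcomp

_BASES = "ACGT"

_CROPS = ("Zea mays", "Glycine max", "Oryza sativa", "Brassica napus", "Gossypium hirsutum")
_PLANTS = ("Arabidopsis thaliana", "Solanum lycopersicum", "Triticum aestivum")


@dataclass(frozen=True)
class SiteSpec:
    """One planted amplification site.

    ``*_subs`` are substitutions, ``*_dels``/``*_ins`` indel edits placed
    mid-primer (end placement would make the ground-truth alignment
    ambiguous). ``spacer_len`` is the distance between the primer
    footprints and controls the product length; ``strand`` plants the
    site on the forward or reverse strand of the record.
    """

    method_id: str
    fw_subs: int = 0
    fw_dels: int = 0
    fw_ins: int = 0
    rv_subs: int = 0
    rv_dels: int = 0
    rv_ins: int = 0
    probe_subs: int = 0
    spacer_len: int = 64
    strand: str = "+"


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site: the expected amplicon (exact
    coordinates, lengths, edit counts, probe annotation) and whether the
    site is recoverable under the generation-time PCR parameters."""

    expected: Amplicon
    recoverable: bool


@dataclass(frozen=True)
class FixtureSpec:
    """Composition of a synthetic corpus (defaults: a desk-scale mix of
    the three record classes with five-fold patent redundancy)."""

    seed: int = 0
    n_transgenic: int = 20
    n_plant: int = 12
    n_patent_constructs: int = 3
    redundancy: int = 5
    background_gc: float = 0.44
    params: PcrParams = PcrParams()


@dataclass
class FixtureBundle:
    records: dict[str, list[SequenceRecord]]  # dataset_label -> records
    species_map: dict[str, str]
    truth: list[PlantedSite]

    @property
    def all_records(self) -> list[SequenceRecord]:
        return [r for recs in self.records.values() for r in recs]


def make_panel(
    seed: int = 0,
    n_event: int = 6,
    n_construct: int = 2,
    n_element: int = 3,
    n_taxon: int = 4,
) -> list[DetectionMethod]:
    """A synthetic detection-method panel (random 20-mer primers, 24-mer
    probes). The class mix mirrors, at reduced scale, reference-method
    catalogues dominated by event-specific assays. One element and one
    taxon method are probe-less to exercise the ``no_probe`` path."""
    rng = np.random.default_rng(seed)
    methods = []
    specs = (
        [("event", "QT-EVE")] * n_event
        + [("construct", "QL-CON")] * n_construct
        + [("element", "QT-ELE")] * n_element
        + [("taxon", "QT-TAX")] * n_taxon
    )
    counters: dict[str, int] = {}
    for cls, prefix in specs:
        counters[cls] = counters.get(cls, 0) + 1
        idx = counters[cls]
        fw = "".join(rng.choice(list(_BASES), size=20))
        rv = "".join(rng.choice(list(_BASES), size=20))
        probe: Optional[str] = "".join(rng.choice(list(_BASES), size=24))
        if (cls == "element" and idx == n_element) or (cls == "taxon" and idx == n_taxon):
            probe = None
        methods.append(DetectionMethod(
            method_id=f"{prefix}-{idx:02d}",
            specificity=cls,
            target_name=f"synthetic {cls} target {idx}",
            fw_primer=fw, rv_primer=rv, probe=probe,
        ))
    return methods


def _random_bg(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list(_BASES), size=length, p=p))


def _screen_bg(segment: str, primers: list[str], margin: int = 4) -> bool:
    """True when the segment is free of near-matches to any primer.

    Ungapped sliding comparison on both strands; a window with at least
    ``len(primer) - margin`` matching positions triggers a redraw. The
    margin conservatively covers what the engine could accept under its
    mismatch/indel bounds.
    """
    if not segment:
        return True
    seg = np.frombuffer(segment.encode("ascii"), dtype=np.uint8)
    for primer in primers:
        for p in (primer, revcomp(primer)):
            m = len(p)
            if len(seg) < m - margin:
                continue
            parr = np.frombuffer(p.encode("ascii"), dtype=np.uint8)
            nwin = len(seg) - m + 1
            if nwin <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(seg, m)
            matches = (windows == parr).sum(axis=1)
            if matches.max() >= m - margin:
                return False
    return True


def _draw_bg(rng, length: int, gc: float, primers: list[str], what: str) -> str:
    for _ in range(100):
        seg = _random_bg(rng, length, gc)
        if _screen_bg(seg, primers):
            return seg
    raise RuntimeError(f"could not draw clean background for {what}")


def _concretize(base: str, rng) -> str:
    """Pick a concrete base compatible with an IUPAC primer base."""
    bits = IUPAC_BITS[base]
    options = [b for b in _BASES if IUPAC_BITS[b] & bits]
    return options[rng.integers(len(options))]


def _pick_positions(rng, m: int, count: int, forbidden: set[int]) -> list[int]:
    """Interior positions (>=2 from each end), pairwise >=3 apart."""
    positions: list[int] = []
    eligible = [i for i in range(2, m - 2) if i not in forbidden]
    rng.shuffle(eligible)
    for pos in eligible:
        if all(abs(pos - q) >= 3 for q in positions):
            positions.append(pos)
            if len(positions) == count:
                return sorted(positions)
    raise ValueError(f"cannot place {count} edits in a {m} nt primer")


def _mutate_site(primer: str, subs: int, dels: int, ins: int, rng) -> str:
    """Target-side copy of a primer binding site with planted edits.

    Substitutions go to interior positions; indels are applied at the
    primer midpoint (deletions remove target bases, insertions add
    random ones).
    """
    m = len(primer)
    if subs + dels + ins > 0 and m < 12:
        raise ValueError("primer too short for planted edits")
    if subs > 0 and subs + dels + ins >= m:
        raise ValueError("edit budget exceeds primer length")
    site = [_concretize(b, rng) for b in primer]
    mid = m // 2
    forbidden = set(range(mid - 2, mid + 3)) if (dels or ins) else set()
    for pos in _pick_positions(rng, m, subs, forbidden) if subs else []:
        bits = IUPAC_BITS[primer[pos]]
        bad = [b for b in _BASES if not (IUPAC_BITS[b] & ~bits == 0)]
        site[pos] = bad[rng.integers(len(bad))]
    if dels:
        del site[mid:mid + dels]
    if ins:
        for k in range(ins):
            site.insert(mid + k, _BASES[rng.integers(4)])
    return "".join(site)


def _mutate_probe(probe: str, subs: int, rng) -> str:
    site = list(probe)
    if subs:
        # keep substitutions >=4 from the probe ends so the best local
        # alignment still spans the full probe and counts them all
        positions = []
        eligible = list(range(4, len(probe) - 4))
        rng.shuffle(eligible)
        for pos in eligible:
            if all(abs(pos - q) >= 4 for q in positions):
                positions.append(pos)
                if len(positions) == subs:
                    break
        if len(positions) < subs:
            raise ValueError(f"cannot place {subs} probe edits")
        for pos in positions:
            bits = IUPAC_BITS[probe[pos]]
            bad = [b for b in _BASES if not (IUPAC_BITS[b] & ~bits == 0)]
            site[pos] = bad[rng.integers(len(bad))]
    return "".join(site)


def _build_block(method: DetectionMethod, spec: SiteSpec, rng,
                 gc: float, primers: list[str]) -> tuple[str, dict]:
    """Assemble fw_site + spacer(+probe) + revcomp(rv_site); return the
    block and the per-primer edit bookkeeping."""
    fw_site = _mutate_site(method.fw_primer, spec.fw_subs, spec.fw_dels, spec.fw_ins, rng)
    rv_site = _mutate_site(method.rv_primer, spec.rv_subs, spec.rv_dels, spec.rv_ins, rng)
    if method.probe is not None:
        probe_var = _mutate_probe(method.probe, spec.probe_subs, rng)
        if spec.spacer_len < len(probe_var) + 6:
            raise ValueError(
                f"spacer_len {spec.spacer_len} too short for probe of "
                f"{len(probe_var)} nt (need >= {len(probe_var) + 6})")
        left = (spec.spacer_len - len(probe_var)) // 2
        right = spec.spacer_len - len(probe_var) - left
        spacer = (_draw_bg(rng, left, gc, primers, "spacer") + probe_var
                  + _draw_bg(rng, right, gc, primers, "spacer"))
    else:
        spacer = _draw_bg(rng, spec.spacer_len, gc, primers, "spacer")
    block = fw_site + spacer + revcomp(rv_site)
    info = {
        "fw_mm": spec.fw_subs, "fw_gaps": spec.fw_dels + spec.fw_ins,
        "rv_mm": spec.rv_subs, "rv_gaps": spec.rv_dels + spec.rv_ins,
        "probe_subs": spec.probe_subs,
    }
    return block, info


def generate_construct(
    methods: list[DetectionMethod],
    site_specs: list[SiteSpec],
    seed: int,
    record_id: str = "construct_1",
    dataset_label: str = "transgenic_like",
    species: str = "Zea mays",
    params: PcrParams = PcrParams(),
    background_gc: float = 0.44,
    flank: int = 60,
    spacing: int = 80,
) -> tuple[SequenceRecord, list[PlantedSite]]:
    """One synthetic record embedding the requested sites, plus ground truth.

    Sites are laid out left to right with clean background flanks and
    spacers; a spec with ``strand='-'`` embeds the reverse complement of
    its block. The returned :class:`PlantedSite` rows give the exact
    amplicon each site should produce and whether it is within the edit
    and product-size bounds of ``params``.
    """
    rng = np.random.default_rng(seed)
    by_id = {m.method_id: m for m in methods}
    for spec in site_specs:
        if spec.method_id not in by_id:
            raise ValueError(f"unknown method {spec.method_id!r}")
    seen_methods = [s.method_id for s in site_specs]
    if len(seen_methods) != len(set(seen_methods)):
        raise ValueError("each method may be planted at most once per record")
    primers = [p for m in methods for p in (m.fw_primer, m.rv_primer)]

    parts: list[str] = [_draw_bg(rng, flank, background_gc, primers, record_id)]
    offset = flank
    truth: list[PlantedSite] = []
    for i, spec in enumerate(site_specs):
        method = by_id[spec.method_id]
        block, info = _build_block(method, spec, rng, background_gc, primers)
        plen = len(block)
        start = offset + 1                       # 1-based inclusive
        end = offset + plen
        total = info["fw_mm"] + info["fw_gaps"] + info["rv_mm"] + info["rv_gaps"]
        if method.probe is None:
            probe_status, probe_mm = "no_probe", 0
        elif info["probe_subs"] == 0:
            probe_status, probe_mm = "perfect", 0
        else:
            probe_status, probe_mm = "mismatched", info["probe_subs"]
        recoverable = (
            info["fw_mm"] <= params.n_max and info["rv_mm"] <= params.n_max
            and info["fw_gaps"] <= params.g_max and info["rv_gaps"] <= params.g_max
            and total <= params.total_edit_max
            and params.d_min <= plen <= params.d_max
        )
        truth.append(PlantedSite(
            expected=Amplicon(
                record_id=record_id, dataset_label=dataset_label,
                method_id=method.method_id, specificity=method.specificity,
                strand=spec.strand, start=start, end=end, product_length=plen,
                fw_mismatches=info["fw_mm"], fw_gaps=info["fw_gaps"],
                rv_mismatches=info["rv_mm"], rv_gaps=info["rv_gaps"],
                total_edits=total, sequence=block,
                probe_status=probe_status, probe_mismatches=probe_mm,
                probe_gaps=0, species=species,
            ),
            recoverable=recoverable,
        ))
        parts.append(block if spec.strand == "+" else revcomp(block))
        offset = end
        gap = spacing if i < len(site_specs) - 1 else flank
        parts.append(_draw_bg(rng, gap, background_gc, primers, record_id))
        offset += gap
    record = SequenceRecord(
        record_id=record_id,
        description=f"synthetic construct [{species}]",
        sequence="".join(parts),
        dataset_label=dataset_label,
    )
    return record, truth


def generate_dataset(
    spec: FixtureSpec,
    methods: Optional[list[DetectionMethod]] = None,
) -> FixtureBundle:
    """Generate the full mixed-class corpus described by ``spec``.

    Deterministic for a fixed seed. Transgenic-like records each carry
    one event-specific site (a 1:1 amplicon:record design) plus element /
    construct sites on alternating records and never a taxon site;
    plant-like records carry at most one taxon site; patent-like
    constructs are emitted in ``redundancy`` copies differing only in
    background positions, so all copies yield identical amplicons.
    """
    if methods is None:
        methods = make_panel(seed=spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    by_class: dict[str, list[DetectionMethod]] = {}
    for m in methods:
        by_class.setdefault(m.specificity, []).append(m)
    for cls in ("event", "element", "construct", "taxon"):
        if not by_class.get(cls):
            raise ValueError(f"panel must contain at least one {cls} method")

    records: dict[str, list[SequenceRecord]] = {
        "transgenic_like": [], "plant_like": [], "patent_like": [],
    }
    species_map: dict[str, str] = {}
    truth: list[PlantedSite] = []

    def _sub_seed() -> int:
        return int(rng.integers(1 << 31))

    for i in range(spec.n_transgenic):
        sites = [SiteSpec(method_id=by_class["event"][i % len(by_class["event"])].method_id)]
        if i % 2 == 0:
            sites.append(SiteSpec(
                method_id=by_class["element"][i % len(by_class["element"])].method_id))
        if i % 3 == 0:
            sites.append(SiteSpec(
                method_id=by_class["construct"][i % len(by_class["construct"])].method_id))
        species = _CROPS[i % len(_CROPS)]
        rid = f"TGN{i + 1:04d}"
        rec, t = generate_construct(
            methods, sites, _sub_seed(), record_id=rid,
            dataset_label="transgenic_like", species=species,
            params=spec.params, background_gc=spec.background_gc)
        records["transgenic_like"].append(rec)
        species_map[rid] = species
        truth.extend(t)

    primers = [p for m in methods for p in (m.fw_primer, m.rv_primer)]
    for i in range(spec.n_plant):
        species = _PLANTS[i % len(_PLANTS)]
        rid = f"PLN{i + 1:04d}"
        if i % 3 != 2:
            sites = [SiteSpec(
                method_id=by_class["taxon"][i % len(by_class["taxon"])].method_id)]
            rec, t = generate_construct(
                methods, sites, _sub_seed(), record_id=rid,
                dataset_label="plant_like", species=species,
                params=spec.params, background_gc=spec.background_gc)
            truth.extend(t)
        else:
            sub_rng = np.random.default_rng(_sub_seed())
            rec = SequenceRecord(
                record_id=rid, description=f"plant contig [{species}]",
                sequence=_draw_bg(sub_rng, 400, spec.background_gc, primers, rid),
                dataset_label="plant_like")
        records["plant_like"].append(rec)
        species_map[rid] = species

    for c in range(spec.n_patent_constructs):
        species = _CROPS[c % len(_CROPS)]
        method = by_class["event"][c % len(by_class["event"])]
        base_id = f"PAT{c + 1:04d}"
        master, t_master = generate_construct(
            methods, [SiteSpec(method_id=method.method_id)], _sub_seed(),
            record_id=f"{base_id}_1", dataset_label="patent_like",
            species=species, params=spec.params, background_gc=spec.background_gc)
        records["patent_like"].append(master)
        species_map[master.record_id] = species
        truth.extend(t_master)
        amp = t_master[0].expected
        for copy in range(2, spec.redundancy + 1):
            rid = f"{base_id}_{copy}"
            seq = list(master.sequence)
            # mutate a few background positions outside the amplicon span
            bg_pos = [p for p in range(len(seq))
                      if p < amp.start - 1 or p >= amp.end]
            for p in rng.choice(bg_pos, size=min(5, len(bg_pos)), replace=False):
                alt = [b for b in _BASES if b != seq[p]]
                seq[p] = alt[rng.integers(3)]
            rec = SequenceRecord(
                record_id=rid, description=master.description,
                sequence="".join(seq), dataset_label="patent_like")
            records["patent_like"].append(rec)
            species_map[rid] = species
            truth.append(PlantedSite(
                expected=replace(amp, record_id=rid),
                recoverable=t_master[0].recoverable))
    return FixtureBundle(records=records, species_map=species_map, truth=truth)


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as FASTA files, a species map and a ground-truth
    table (the 18 amplicon columns plus ``recoverable``)."""
    from .io_formats import AMPLICON_COLUMNS

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for label, recs in bundle.records.items():
        p = outdir / f"{label}.fasta"
        write_fasta(recs, p)
        paths[label] = p
    sp = outdir / "species_map.tsv"
    with open(sp, "w") as fh:
        fh.write("record_id\tspecies\n")
        for rid, species in bundle.species_map.items():
            fh.write(f"{rid}\t{species}\n")
    paths["species_map"] = sp
    gt = outdir / "ground_truth.tsv"
    with open(gt, "w") as fh:
        fh.write("\t".join(AMPLICON_COLUMNS) + "\trecoverable\n")
        for site in bundle.truth:
            a = site.expected
            fh.write("\t".join(str(v) for v in (
                a.record_id, a.dataset_label, a.method_id, a.specificity,
                a.strand, a.start, a.end, a.product_length,
                a.fw_mismatches, a.fw_gaps, a.rv_mismatches, a.rv_gaps,
                a.total_edits, a.probe_status, a.probe_mismatches,
                a.probe_gaps, a.species, a.sequence,
            )) + f"\t{int(site.recoverable)}\n")
    paths["ground_truth"] = gt
    return paths
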