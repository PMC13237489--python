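"""UniProt-style FASTA I/O, weak-label annotation, and dataset curation.

The curation pipeline mirrors how a homolog family is assembled for
classifier training: parse FASTA with species taken from the ``OS=`` header
field, attach putative activity + temperature labels through a pluggable
annotator (an LLM in production; a deterministic mock here), drop exact
duplicate sequences and non-mesophilic organisms, and append the artificial
no-activity penalty set.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ActivityLabel

logger = logging.getLogger(__name__)

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = set(CANONICAL_AA)

__all__ = [
    "CANONICAL_AA",
    "SequenceRecord",
    "TemperatureClass",
    "classify_temperature",
    "CuratedDataset",
    "parse_fasta",
    "write_fasta",
    "Annotator",
    "MockAnnotator",
    "AnnotationError",
    "annotate_records",
    "curate_dataset",
]


class TemperatureClass(Enum):
    THERMOPHILIC = "thermophilic"
    MESOPHILIC = "mesophilic"
    PSYCHROPHILIC = "psychrophilic"


def classify_temperature(celsius: float) -> TemperatureClass:
    """Growth-temperature class: >45 thermophilic, <=15 psychrophilic."""
    if celsius > 45.0:
        return TemperatureClass.THERMOPHILIC
    if celsius <= 15.0:
        return TemperatureClass.PSYCHROPHILIC
    return TemperatureClass.MESOPHILIC


@dataclass(frozen=True)
class SequenceRecord:
    """One protein entry with species metadata."""

    record_id: str
    sequence: str
    species: str = ""
    accession: str = ""

    def __post_init__(self):
        bad = set(self.sequence) - _CANONICAL_SET
        if bad:
            raise ValueError(
                f"record {self.record_id}: non-canonical residues {sorted(bad)}")
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")

    @property
    def genus(self) -> str:
        return self.species.split()[0] if self.species else ""

    @property
    def length(self) -> int:
        return len(self.sequence)


_OS_RE = re.compile(r"\bOS=(.*?)(?:\s+[A-Z]{2}=|$)")


def _species_from_description(description: str) -> str:
    m = _OS_RE.search(description)
    return m.group(1).strip() if m else ""


def _accession_from_id(record_id: str) -> str:
    parts = record_id.split("|")
    return parts[1] if len(parts) >= 3 else ""


def parse_fasta(stream) -> list[SequenceRecord]:
    """Parse UniProt-dialect FASTA into records, in file order.

    Records containing non-canonical residues (B, J, O, U, X, Z or gaps) are
    excluded with a logged count.  A sequence line appearing before any
    header is a parse error naming the offending line.
    """
    if isinstance(stream, str):
        text = stream
    else:
        text = stream.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(
                f"malformed FASTA: sequence data before any header at line {lineno}")
        break
    records: list[SequenceRecord] = []
    n_noncanonical = 0
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper()
        if set(seq) - _CANONICAL_SET or not seq:
            n_noncanonical += 1
            continue
        records.append(SequenceRecord(
            record_id=rec.id,
            sequence=seq,
            species=_species_from_description(rec.description),
            accession=_accession_from_id(rec.id),
        ))
    if n_noncanonical:
        logger.warning("excluded %d records with non-canonical residues",
                       n_noncanonical)
    return records


def write_fasta(records, handle) -> None:
    """Write records with the species restated in an ``OS=`` field."""
    out = []
    for r in records:
        desc = f"OS={r.species}" if r.species else ""
        out.append(SeqRecord(Seq(r.sequence), id=r.record_id, description=desc))
    SeqIO.write(out, handle, "fasta")


class AnnotationError(Exception):
    """Raised by an annotator that cannot label a record."""


class Annotator:
    """Annotation contract: species/sequence metadata in, labels out.

    Implementations must be deterministic for fixed inputs and return an
    ``(ActivityLabel in {HIGH, LOW}, TemperatureClass)`` pair, raising
    :class:`AnnotationError` for records they cannot label.
    """

    def annotate(self, record: SequenceRecord) -> tuple[ActivityLabel, TemperatureClass]:
        raise NotImplementedError


_LABEL_STRINGS = {"High activity": ActivityLabel.HIGH,
                  "Low activity": ActivityLabel.LOW}


class MockAnnotator(Annotator):
    """Deterministic table-lookup annotator over genus lists.

    Emulates the production annotator's bounded response schema: the
    activity output is restricted to the strings "High activity" /
    "Low activity", mapped onto the label enumeration.  Records without a
    species are refused (only a sequence-aware annotator could label them).
    """

    def __init__(self, high_genera=(), thermophilic_genera=(),
                 psychrophilic_genera=()):
        self.high_genera = frozenset(high_genera)
        self.thermophilic_genera = frozenset(thermophilic_genera)
        self.psychrophilic_genera = frozenset(psychrophilic_genera)

    def annotate(self, record: SequenceRecord) -> tuple[ActivityLabel, TemperatureClass]:
        if not record.species:
            raise AnnotationError(
                f"record {record.record_id} lacks an OS= species field")
        genus = record.genus
        activity = "High activity" if genus in self.high_genera else "Low activity"
        if genus in self.thermophilic_genera:
            temp = TemperatureClass.THERMOPHILIC
        elif genus in self.psychrophilic_genera:
            temp = TemperatureClass.PSYCHROPHILIC
        else:
            temp = TemperatureClass.MESOPHILIC
        return _LABEL_STRINGS[activity], temp


def annotate_records(records, annotator: Annotator):
    """Annotate every record, caching by species.

    Returns ``(annotations, failed_ids)`` where ``annotations`` maps
    record_id -> (ActivityLabel, TemperatureClass).  Failed records are
    excluded downstream with a logged count.
    """
    cache: dict[str, tuple[ActivityLabel, TemperatureClass]] = {}
    annotations: dict[str, tuple[ActivityLabel, TemperatureClass]] = {}
    failed: list[str] = []
    for rec in records:
        key = rec.species
        try:
            if key and key in cache:
                result = cache[key]
            else:
                result = annotator.annotate(rec)
                if result[0] not in (ActivityLabel.HIGH, ActivityLabel.LOW):
                    raise AnnotationError(
                        f"annotator returned non-training label {result[0]}")
                if key:
                    cache[key] = result
        except AnnotationError as exc:
            logger.warning("annotation failed: %s", exc)
            failed.append(rec.record_id)
            continue
        annotations[rec.record_id] = result
    if failed:
        logger.warning("%d records could not be annotated and are dropped",
                       len(failed))
    return annotations, failed


@dataclass
class CuratedDataset:
    """Curation output: ordered records, labels, and provenance counters."""

    records: list[SequenceRecord]
    labels: list[ActivityLabel]
    temperatures: list[TemperatureClass | None]
    sources: list[str]                       # "natural" | "penalty"
    n_input: int = 0
    n_deduplicated: int = 0
    n_temperature_removed: int = 0
    n_final: int = 0
    n_penalty_added: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self):
        for rec, lab, temp, src in zip(self.records, self.labels,
                                       self.temperatures, self.sources):
            yield {
                "record_id": rec.record_id,
                "accession": rec.accession,
                "species": rec.species,
                "genus": rec.genus,
                "length": rec.length,
                "activity": lab.name,
                "temperature": temp.value if temp is not None else "",
                "source": src,
            }

    def to_tsv(self, handle) -> None:
        import csv
        cols = ["record_id", "accession", "species", "genus", "length",
                "activity", "temperature", "source"]
        w = csv.DictWriter(handle, fieldnames=cols, delimiter="\t",
                           lineterminator="\n")
        w.writeheader()
        for row in self.to_rows():
            w.writerow(row)


def curate_dataset(records, annotations, penalty_records=()) -> CuratedDataset:
    """Deduplicate, drop non-mesophilic records, append the penalty set.

    Duplicate = identical amino-acid string, first occurrence kept.  Records
    missing from ``annotations`` (annotator failures) are dropped before
    deduplication with a logged count.  Penalty records receive the
    no-activity label; a penalty sequence duplicating a natural one is kept
    but logged as a collision.
    """
    n_input = len(records)
    annotated = [r for r in records if r.record_id in annotations]
    n_unannotated = n_input - len(annotated)
    if n_unannotated:
        logger.info("dropping %d unannotated records", n_unannotated)

    seen: set[str] = set()
    deduped: list[SequenceRecord] = []
    for rec in annotated:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        deduped.append(rec)
    n_deduplicated = len(deduped)

    kept: list[SequenceRecord] = []
    for rec in deduped:
        if annotations[rec.record_id][1] is TemperatureClass.MESOPHILIC:
            kept.append(rec)
    n_temperature_removed = n_deduplicated - len(kept)
    n_final = len(kept)

    out_records = list(kept)
    out_labels = [annotations[r.record_id][0] for r in kept]
    out_temps: list[TemperatureClass | None] = [
        annotations[r.record_id][1] for r in kept]
    out_sources = ["natural"] * len(kept)

    natural_seqs = {r.sequence for r in kept}
    n_collisions = 0
    for rec in penalty_records:
        if rec.sequence in natural_seqs:
            n_collisions += 1
        out_records.append(rec)
        out_labels.append(ActivityLabel.NONE)
        out_temps.append(None)
        out_sources.append("penalty")
    if n_collisions:
        logger.warning("%d penalty sequences collide with natural sequences",
                       n_collisions)

    return CuratedDataset(
        records=out_records, labels=out_labels, temperatures=out_temps,
        sources=out_sources, n_input=n_input, n_deduplicated=n_deduplicated,
        n_temperature_removed=n_temperature_removed, n_final=n_final,
        n_penalty_added=len(out_records) - n_final,
    )
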