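"""Data model, curation and I/O for site-level cysteine ligandability records.

A *site* is a cysteine position in a protein; a :class:`SiteRecord` is one
source-level ligandability observation for that site (``pos`` for liganded,
``neg`` for unliganded).  ``unquantified`` records are synthesized for
cysteines that no probe detected in otherwise-quantified proteins; they carry
no source and act only as default negative votes during cluster labeling.

Positions are 1-based over the full curated sequence.  Records whose position
does not index a 'C' are rejected during loading (logged, never remapped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .errors import FormatError, PositionBoundsError, UnresolvedReferenceError

POS = "pos"
NEG = "neg"
UNQUANTIFIED = "unquantified"
LABELS = (POS, NEG, UNQUANTIFIED)

MIN_LENGTH = 30
MAX_LENGTH = 2046

RECORD_COLUMNS = ["uid", "position", "label", "source_id", "record_id"]


@dataclass(frozen=True)
class ProteinEntry:
    uid: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.uid}")

    @property
    def cysteine_positions(self) -> tuple[int, ...]:
        """1-based positions of every 'C' in the sequence."""
        return tuple(i + 1 for i, aa in enumerate(self.sequence) if aa == "C")


@dataclass(frozen=True)
class SiteRecord:
    uid: str
    position: int  # 1-based
    label: str
    source_id: str | None = None
    record_id: str | None = None
    meta: tuple = ()

    @property
    def site(self) -> tuple[str, int]:
        return (self.uid, self.position)

    @property
    def observed(self) -> bool:
        return self.label != UNQUANTIFIED


@dataclass
class CuratedDB:
    """Proteins plus their site records plus a curation log."""

    proteins: dict[str, ProteinEntry] = field(default_factory=dict)
    records: list[SiteRecord] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def log(self, event: str, **detail) -> None:
        self.provenance.append({"event": event, **detail})

    def protein_of(self, record: SiteRecord) -> ProteinEntry:
        return self.proteins[record.uid]

    def observed_records(self) -> list[SiteRecord]:
        return [r for r in self.records if r.observed]

    def sites(self) -> list[tuple[str, int]]:
        """All distinct (uid, position) sites, sorted."""
        return sorted({r.site for r in self.records})

    def records_by_site(self) -> dict[tuple[str, int], list[SiteRecord]]:
        out: dict[tuple[str, int], list[SiteRecord]] = {}
        for r in self.records:
            out.setdefault(r.site, []).append(r)
        return out

    def validate(self) -> None:
        for r in self.records:
            if r.uid not in self.proteins:
                raise UnresolvedReferenceError([r.uid])
            seq = self.proteins[r.uid].sequence
            if not (1 <= r.position <= len(seq)) or seq[r.position - 1] != "C":
                raise PositionBoundsError(f"{r.uid}:{r.position} is not a Cys site")


def _validate_record(row_uid, position, label, proteins) -> str | None:
    """Return a rejection reason, or None if the record is valid."""
    if row_uid not in proteins:
        return "unknown-uid"
    if label not in LABELS:
        return "bad-label"
    seq = proteins[row_uid].sequence
    if not (1 <= position <= len(seq)):
        return "position-out-of-bounds"
    if seq[position - 1] != "C":
        return "position-not-cysteine"
    return None


def load_fasta(fasta_path) -> dict[str, ProteinEntry]:
    """Read a FASTA file; uid is the first whitespace-delimited header token."""
    proteins: dict[str, ProteinEntry] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        uid = rec.id.split()[0]
        proteins[uid] = ProteinEntry(uid=uid, sequence=str(rec.seq).upper())
    return proteins


def consolidate_identical_sequences(
    proteins: dict[str, ProteinEntry],
) -> tuple[dict[str, ProteinEntry], dict[str, str]]:
    """Merge uids referring to identical sequences.

    The lexicographically smallest uid becomes canonical; the returned alias
    map sends every uid (including canonical ones) to its canonical uid.
    """
    by_seq: dict[str, list[str]] = {}
    for uid in sorted(proteins):
        by_seq.setdefault(proteins[uid].sequence, []).append(uid)
    merged: dict[str, ProteinEntry] = {}
    aliases: dict[str, str] = {}
    for seq, uids in by_seq.items():
        canon = min(uids)
        merged[canon] = ProteinEntry(uid=canon, sequence=seq)
        for uid in uids:
            aliases[uid] = canon
    return merged, aliases


def load_database(records_path, fasta_path) -> CuratedDB:
    """Load a record table (TSV) and sequence FASTA into a :class:`CuratedDB`.

    Malformed rows are logged and counted in provenance, not silently
    dropped.  Uids in the record table that are absent from the FASTA raise
    :class:`UnresolvedReferenceError` listing the offenders.
    """
    table = pd.read_csv(records_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS[:4] if c not in table.columns]
    if missing:
        raise FormatError(f"record table missing required columns: {missing}")

    raw_proteins = load_fasta(fasta_path)
    proteins, aliases = consolidate_identical_sequences(raw_proteins)

    unknown = sorted(set(table["uid"]) - set(aliases))
    if unknown:
        raise UnresolvedReferenceError(unknown)

    db = CuratedDB(proteins=proteins)
    for uid, canon in sorted(aliases.items()):
        if uid != canon:
            db.log("uid-consolidated", uid=uid, canonical=canon)

    rejected: dict[str, int] = {}
    n_auto = 0
    for i, row in enumerate(table.itertuples(index=False)):
        uid = aliases[row.uid]
        try:
            position = int(row.position)
        except ValueError:
            rejected["bad-position"] = rejected.get("bad-position", 0) + 1
            db.log("record-rejected", row=i, reason="bad-position")
            continue
        reason = _validate_record(uid, position, row.label, proteins)
        if reason is not None:
            rejected[reason] = rejected.get(reason, 0) + 1
            db.log("record-rejected", row=i, reason=reason, uid=uid, position=position)
            continue
        record_id = getattr(row, "record_id", "") or None
        if record_id is None:
            n_auto += 1
            record_id = f"R{n_auto:06d}"
        source_id = row.source_id or None
        if row.label == UNQUANTIFIED:
            source_id = None
        db.records.append(
            SiteRecord(uid=uid, position=position, label=row.label,
                       source_id=source_id, record_id=record_id)
        )
    if rejected:
        db.log("rejection-summary", counts=rejected)
    return db


def apply_length_filter(db: CuratedDB) -> CuratedDB:
    """Drop proteins with length outside [30, 2046] and their records."""
    keep = {u: p for u, p in db.proteins.items()
            if MIN_LENGTH <= len(p.sequence) <= MAX_LENGTH}
    dropped = sorted(set(db.proteins) - set(keep))
    out = CuratedDB(
        proteins=keep,
        records=[r for r in db.records if r.uid in keep],
        provenance=list(db.provenance),
    )
    for uid in dropped:
        out.log("protein-length-filtered", uid=uid, length=len(db.proteins[uid].sequence))
    out.log("length-filter-summary", n_dropped=len(dropped), n_kept=len(keep))
    return out


def add_unquantified_sites(db: CuratedDB) -> CuratedDB:
    """Synthesize one ``unquantified`` record per undetected cysteine.

    Only proteins with at least one observed record gain records; every
    cysteine position of such a protein with zero observed records receives
    exactly one ``unquantified`` record.  Idempotent.
    """
    observed_by_uid: dict[str, set[int]] = {}
    existing_unq: set[tuple[str, int]] = set()
    for r in db.records:
        if r.observed:
            observed_by_uid.setdefault(r.uid, set()).add(r.position)
        else:
            existing_unq.add(r.site)

    new_records = list(db.records)
    n_added = 0
    for uid in sorted(observed_by_uid):
        seen = observed_by_uid[uid]
        for pos in db.proteins[uid].cysteine_positions:
            if pos not in seen and (uid, pos) not in existing_unq:
                new_records.append(
                    SiteRecord(uid=uid, position=pos, label=UNQUANTIFIED,
                               source_id=None, record_id=f"U:{uid}:{pos}")
                )
                n_added += 1
    out = CuratedDB(proteins=dict(db.proteins), records=new_records,
                    provenance=list(db.provenance))
    out.log("unquantified-added", n=n_added)
    return out


def curate(db: CuratedDB) -> CuratedDB:
    """Full curation chain: length filter then unquantified augmentation."""
    return add_unquantified_sites(apply_length_filter(db))


# ---------------------------------------------------------------------------
# writing

def write_database(db: CuratedDB, records_path, fasta_path, log_path=None) -> None:
    """Write the record table (TSV), sequences (FASTA) and curation log (JSONL)."""
    rows = [
        {"uid": r.uid, "position": r.position, "label": r.label,
         "source_id": r.source_id or "", "record_id": r.record_id or ""}
        for r in sorted(db.records, key=lambda r: (r.uid, r.position, r.label,
                                                   r.source_id or "", r.record_id or ""))
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(records_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for uid in sorted(db.proteins):
            fh.write(f">{uid}\n{db.proteins[uid].sequence}\n")
    if log_path is not None:
        with open(log_path, "w") as fh:
            for event in db.provenance:
                fh.write(json.dumps(event, sort_keys=True) + "\n")


__all__ = [
    "POS", "NEG", "UNQUANTIFIED", "LABELS", "MIN_LENGTH", "MAX_LENGTH",
    "ProteinEntry", "SiteRecord", "CuratedDB",
    "load_fasta", "consolidate_identical_sequences", "load_database",
    "apply_length_filter", "add_unquantified_sites", "curate", "write_database",
]
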