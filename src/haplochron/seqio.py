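"""Alignment I/O, replicate-aware masking, haplotype collapsing and counting.

The input is an aligned set of mitochondrial control-region sequences with
per-sample collection metadata (year, site, basin region) and, for museum
specimens, a per-column replication mask recording which positions were
confirmed by at least two independent sequencing reads.  The module turns
such an alignment into a catalog of unique haplotypes and a
haplotype-by-temporal-period count table, the central exchange object of
the downstream analyses.

Alignment gaps can additionally be recoded as binary presence/absence
characters (simple indel coding sensu Simmons & Ochoterena), so that
shared deletions carry phylogenetic signal without each gap column being
treated as an independent change.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide ambiguity codes mapped to the base sets they denote.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: base set -> single-letter code.
CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_CODES.items()}

AMBIGUITY_CODES = frozenset(IUPAC_CODES) - frozenset("ACGT")
ALPHABET = frozenset(IUPAC_CODES) | {"-"}

REGIONS = ("northern", "southern", "unknown")


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (length mismatch etc.)."""


class InputError(ValueError):
    """Malformed or inconsistent user input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One aligned sequence with its sampling metadata.

    ``replicated`` is a per-column boolean mask; ``True`` means the base
    call was confirmed by two or more independent reads.  Modern samples
    default to all-``True``.
    """

    id: str
    year: int
    site: str
    region: str
    seq: str
    replicated: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.replicated):
            raise AlignmentError(
                f"record {self.id!r}: sequence length {len(self.seq)} != "
                f"replication-mask length {len(self.replicated)}"
            )
        bad = set(self.seq.upper()) - ALPHABET
        if bad:
            raise InputError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )
        if self.region not in REGIONS:
            raise InputError(
                f"record {self.id!r}: region {self.region!r} not in {REGIONS}"
            )
        if not 1800 <= self.year <= date.today().year:
            raise InputError(
                f"record {self.id!r}: year {self.year} outside [1800, today]"
            )

    @classmethod
    def make(
        cls,
        id: str,
        seq: str,
        year: int,
        site: str = "",
        region: str = "unknown",
        replicated: Sequence[bool] | None = None,
    ) -> "SequenceRecord":
        if replicated is None:
            replicated = (True,) * len(seq)
        return cls(id, year, site, region, seq.upper(), tuple(replicated))


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length collection of :class:`SequenceRecord`."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment is empty")
        length = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != length:
                raise AlignmentError(
                    f"record {rec.id!r} has length {len(rec.seq)}, "
                    f"expected {length}"
                )

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)


@dataclass(frozen=True)
class TemporalGrouping:
    """Ordered, non-overlapping periods of inclusive calendar-year ranges.

    Gaps between consecutive periods are allowed; years falling in a gap
    are assignable to no period.
    """

    periods: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.periods:
            if start > end:
                raise InputError(f"period {label!r}: start {start} > end {end}")
            if prev_end is not None and start <= prev_end:
                raise InputError(
                    f"period {label!r} overlaps or is out of order"
                )
            prev_end = end

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _, _ in self.periods)


@dataclass(frozen=True)
class HaplotypeCatalog:
    """Unique haplotype sequences and the sample -> haplotype partition."""

    haplotypes: tuple[tuple[str, str], ...]  # (label, sequence)
    membership: dict[str, str]  # sample id -> haplotype label
    excluded: tuple[tuple[str, str], ...] = ()  # (sample id, reason)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.haplotypes)

    def sequence(self, label: str) -> str:
        for lab, seq in self.haplotypes:
            if lab == label:
                return seq
        raise KeyError(label)

    def members(self, label: str) -> list[str]:
        return [sid for sid, lab in self.membership.items() if lab == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "haplotypes": [{"label": l, "sequence": s} for l, s in self.haplotypes],
            "membership": self.membership,
            "excluded": [{"id": i, "reason": r} for i, r in self.excluded],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


class HaplotypeTable:
    """Haplotype x temporal-period count matrix.

    Thin wrapper around a pandas DataFrame (rows = haplotype labels,
    columns = period labels, integer counts).
    """

    def __init__(self, counts: pd.DataFrame):
        if (counts.to_numpy() < 0).any():
            raise InputError("negative count in haplotype table")
        if counts.index.has_duplicates:
            raise InputError("duplicate haplotype labels")
        self.counts = counts.astype(int)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    @property
    def period_labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def period_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def column(self, period: str) -> pd.Series:
        return self.counts[period]

    def frequencies(self, period: str) -> pd.Series:
        col = self.counts[period]
        total = col.sum()
        if total == 0:
            raise InputError(f"period {period!r} has no samples")
        return col / total

    def __eq__(self, other) -> bool:
        return isinstance(other, HaplotypeTable) and self.counts.equals(other.counts)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.loc["Total"] = out.sum(axis=0)
        out["Total"] = out.sum(axis=1)
        out.to_csv(path, sep="\t", index_label="haplotype")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df = df.drop(index="Total", errors="ignore")
        df = df.drop(columns="Total", errors="ignore")
        return cls(df)


@dataclass(frozen=True)
class GapCharacterMatrix:
    """Binary gap presence/absence characters from simple indel coding.

    ``characters`` are half-open 0-based column intervals; ``states`` maps
    each sequence id to a tuple over ``{"present", "absent", "missing"}``
    aligned with ``characters``.  User-facing output converts intervals to
    1-based inclusive coordinates.
    """

    characters: tuple[tuple[int, int], ...]
    states: dict[str, tuple[str, ...]]

    def to_tsv(self, path: str | Path) -> None:
        cols = [f"gap_{s + 1}_{e}" for s, e in self.characters]
        df = pd.DataFrame.from_dict(
            {sid: list(st) for sid, st in self.states.items()},
            orient="index",
            columns=cols,
        )
        df.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# Operations


def _parse_unreplicated_ranges(spec: str, length: int) -> tuple[bool, ...]:
    """Parse '12-40,100-120' (1-based inclusive UNreplicated columns)."""
    mask = [True] * length
    spec = spec.strip()
    if not spec:
        return tuple(mask)
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if "-" in chunk:
            lo_s, hi_s = chunk.split("-", 1)
            lo, hi = int(lo_s), int(hi_s)
        else:
            lo = hi = int(chunk)
        if not 1 <= lo <= hi <= length:
            raise InputError(f"unreplicated range {chunk!r} outside alignment")
        for col in range(lo - 1, hi):
            mask[col] = False
    return tuple(mask)


def read_alignment(fasta_path: str | Path, metadata_path: str | Path) -> Alignment:
    """Read an aligned FASTA plus a sample-metadata TSV into an Alignment.

    The metadata table must have columns ``id``, ``year``, ``site``,
    ``region`` and may have ``replicated_ranges`` (comma-separated 1-based
    inclusive ranges of *unreplicated* columns; empty = fully replicated).
    FASTA ids and metadata ids must match one-to-one.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise InputError(f"no sequences in {fasta_path}")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str})
    for col in ("id", "year"):
        if col not in meta.columns:
            raise InputError(f"metadata missing required column {col!r}")
    meta = meta.set_index("id")
    if meta.index.has_duplicates:
        raise InputError("duplicate ids in metadata")

    missing = set(seqs) - set(meta.index)
    if missing:
        raise InputError(f"FASTA ids absent from metadata: {sorted(missing)}")
    extra = set(meta.index) - set(seqs)
    if extra:
        raise InputError(f"metadata ids absent from FASTA: {sorted(extra)}")

    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        offender = next(
            rid for rid, s in seqs.items()
            if len(s) != len(next(iter(seqs.values())))
        )
        raise AlignmentError(
            f"unequal sequence lengths {sorted(lengths)}; e.g. record {offender!r}"
        )
    length = lengths.pop()

    records = []
    for rid, seq in seqs.items():
        row = meta.loc[rid]
        if pd.isna(row["year"]):
            raise InputError(f"record {rid!r}: missing year")
        if "replicated_ranges" in meta.columns and not pd.isna(row["replicated_ranges"]):
            mask = _parse_unreplicated_ranges(str(row["replicated_ranges"]), length)
        else:
            mask = (True,) * length
        records.append(
            SequenceRecord(
                id=rid,
                year=int(row["year"]),
                site=str(row.get("site", "")) if not pd.isna(row.get("site")) else "",
                region=str(row.get("region", "unknown")) if not pd.isna(row.get("region")) else "unknown",
                seq=seq,
                replicated=mask,
            )
        )
    return Alignment(tuple(records))


def mask_unreplicated(record: SequenceRecord, alignment: Alignment) -> SequenceRecord:
    """Replace unique SNPs in unreplicated stretches with ambiguity codes.

    At each column where the record is unreplicated and its base differs
    from the base shared by *all* other fully-replicated records at that
    column, the base becomes the IUPAC code covering both the observed and
    the consensus base (e.g. an unreplicated T where everyone else has C
    becomes Y).  Columns where the other records disagree among themselves
    carry a genuine polymorphism and are left untouched.
    """
    if all(record.replicated):
        return record
    if len(record.seq) != alignment.length:
        raise AlignmentError(
            f"record {record.id!r} not in alignment coordinate system"
        )
    others = [r for r in alignment if r.id != record.id]
    seq = list(record.seq)
    for col, ok in enumerate(record.replicated):
        if ok:
            continue
        base = seq[col]
        if base == "-" or base in AMBIGUITY_CODES:
            continue
        consensus = {
            r.seq[col]
            for r in others
            if r.replicated[col] and r.seq[col] not in AMBIGUITY_CODES
        }
        consensus.discard("-")
        if len(consensus) != 1:
            continue  # column polymorphic (or uninformative) among others
        shared = consensus.pop()
        if base != shared:
            seq[col] = CODE_FOR_SET[frozenset({base, shared})]
    return replace(record, seq="".join(seq))


def trim_alignment(aln: Alignment, head: int, tail: int) -> Alignment:
    """Drop ``head`` columns from the start and ``tail`` from the end."""
    if head < 0 or tail < 0:
        raise InputError("head and tail must be non-negative")
    if head + tail >= aln.length:
        raise InputError(
            f"cannot trim {head}+{tail} columns from alignment of length {aln.length}"
        )
    stop = aln.length - tail
    return Alignment(
        tuple(
            replace(r, seq=r.seq[head:stop], replicated=r.replicated[head:stop])
            for r in aln
        )
    )


def assign_period(year: int, grouping: TemporalGrouping) -> str | None:
    """Return the label of the period containing ``year``, or None."""
    for label, start, end in grouping.periods:
        if start <= year <= end:
            return label
    return None


def _polymorphic_columns(sequences: Iterable[str]) -> set[int]:
    """Columns with >1 distinct unambiguous character across sequences."""
    poly: set[int] = set()
    seqs = list(sequences)
    if not seqs:
        return poly
    for col in range(len(seqs[0])):
        seen = {
            s[col] for s in seqs if s[col] not in AMBIGUITY_CODES
        }
        if len(seen) > 1:
            poly.add(col)
    return poly


def collapse_haplotypes(
    aln: Alignment,
    policy: Literal["strict_remove", "gap_fifth_state"] = "gap_fifth_state",
) -> HaplotypeCatalog:
    """Collapse identical sequences into haplotypes.

    ``gap_fifth_state``: '-' is a fifth symbol; exact string identity
    defines a haplotype (ambiguous sequences are kept as-is).
    ``strict_remove``: sequences with an ambiguity code at any column that
    is polymorphic among the unambiguous sequences are excluded first,
    then identity collapsing is applied.

    Labels are H1, H2, ... by decreasing total frequency, ties broken by
    first occurrence in the alignment.
    """
    excluded: list[tuple[str, str]] = []
    kept: list[SequenceRecord] = []
    if policy == "strict_remove":
        clean = [
            r.seq for r in aln
            if not (set(r.seq) & AMBIGUITY_CODES)
        ]
        poly = _polymorphic_columns(clean)
        for rec in aln:
            bad_cols = [
                c for c, ch in enumerate(rec.seq)
                if ch in AMBIGUITY_CODES and c in poly
            ]
            if bad_cols:
                excluded.append(
                    (rec.id, f"ambiguity at polymorphic column(s) {bad_cols[:5]}")
                )
            else:
                kept.append(rec)
    elif policy == "gap_fifth_state":
        kept = list(aln)
    else:
        raise InputError(f"unknown collapse policy {policy!r}")

    if not kept:
        raise InputError("no sequences left after ambiguity exclusion")

    groups: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for idx, rec in enumerate(kept):
        groups.setdefault(rec.seq, []).append(rec.id)
        order.setdefault(rec.seq, idx)
    ranked = sorted(groups, key=lambda s: (-len(groups[s]), order[s]))
    haplotypes = tuple((f"H{i + 1}", seq) for i, seq in enumerate(ranked))
    label_of = {seq: lab for lab, seq in haplotypes}
    membership = {
        sid: label_of[seq] for seq, sids in groups.items() for sid in sids
    }
    return HaplotypeCatalog(haplotypes, membership, tuple(excluded))


def simple_indel_coding(aln: Alignment) -> GapCharacterMatrix:
    """Recode alignment gaps as binary presence/absence characters.

    Each distinct maximal gap interval (same start and end across
    sequences) becomes one character.  A sequence scores ``present`` if it
    has exactly that gap, ``absent`` if it has residues anywhere in the
    interval, and ``missing`` if one of its own gaps strictly contains the
    interval (the longer deletion makes the shorter one unobservable).
    """
    def gap_runs(seq: str) -> list[tuple[int, int]]:
        runs, start = [], None
        for i, ch in enumerate(seq):
            if ch == "-" and start is None:
                start = i
            elif ch != "-" and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, len(seq)))
        return runs

    per_seq = {rec.id: gap_runs(rec.seq) for rec in aln}
    characters = sorted({iv for runs in per_seq.values() for iv in runs})

    states: dict[str, tuple[str, ...]] = {}
    for rec in aln:
        runs = per_seq[rec.id]
        row = []
        for iv in characters:
            if iv in runs:
                row.append("present")
            elif any(s < iv[0] and iv[1] <= e or s <= iv[0] and iv[1] < e
                     for s, e in runs):
                row.append("missing")  # strictly contained in a longer gap
            else:
                row.append("absent")
        states[rec.id] = tuple(row)
    return GapCharacterMatrix(tuple(characters), states)


def haplotype_table(
    catalog: HaplotypeCatalog,
    aln: Alignment,
    grouping: TemporalGrouping,
) -> HaplotypeTable:
    """Count catalog members per haplotype and temporal period.

    Samples whose collection year falls outside every period are dropped
    with a warning; excluded samples never appear.
    """
    years = {rec.id: rec.year for rec in aln}
    counts = pd.DataFrame(
        0, index=list(catalog.labels), columns=list(grouping.labels), dtype=int
    )
    dropped = []
    for sid, hap in catalog.membership.items():
        period = assign_period(years[sid], grouping)
        if period is None:
            dropped.append(sid)
            continue
        counts.loc[hap, period] += 1
    if dropped:
        msg = f"{len(dropped)} sample(s) outside all periods dropped: {dropped[:10]}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return HaplotypeTable(counts)
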