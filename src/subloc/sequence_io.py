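"""Reading, validating and normalizing transcript sequences and labels.

Transcripts are handled on the DNA alphabet: RNA input (U) is accepted and
mapped to T, because every downstream encoder operates on the DNA sequence of
the corresponding mRNA. Ambiguous IUPAC codes (N, R, Y, ...) are retained at
I/O level so no information is lost; the encoders decide how windows that
touch them are treated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

#: IUPAC nucleotide one-letter codes (DNA), including ambiguity codes.
IUPAC_CODES = frozenset("ACGTNRYSWKMBDHV")

#: Unambiguous bases; encoders count windows drawn from this alphabet only.
UNAMBIGUOUS = frozenset("ACGT")


def sanitize_sequence(raw: str) -> str:
    """Normalize a raw sequence string to uppercase DNA.

    Whitespace is stripped, letters uppercased and U mapped to T. Characters
    outside the IUPAC nucleotide codes raise :class:`ValidationError`. The
    function is idempotent.
    """
    if not raw or not raw.strip():
        raise ValidationError("empty sequence string")
    cleaned = "".join(raw.split()).upper().replace("U", "T")
    bad = set(cleaned) - IUPAC_CODES
    if bad:
        raise ValidationError(
            f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return cleaned


@dataclass(frozen=True)
class NucleotideSequence:
    """A named transcript sequence on the DNA alphabet.

    ``seq`` is expected to be sanitized (uppercase, T not U). Ambiguity codes
    are permitted here; length limits are enforced by the encoders, which know
    their own window sizes.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} has non-IUPAC characters {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def is_unambiguous(self) -> bool:
        return set(self.seq) <= UNAMBIGUOUS


@dataclass(frozen=True)
class LabeledCorpus:
    """Sequences paired with single-location labels.

    Multi-location mRNAs are out of scope: each id carries exactly one label,
    drawn from the declared ``locations``.
    """

    records: tuple[tuple[NucleotideSequence, str], ...]
    locations: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        locs = self.locations or tuple(
            dict.fromkeys(label for _, label in self.records))
        object.__setattr__(self, "locations", locs)
        seen: set[str] = set()
        for seq, label in self.records:
            if seq.id in seen:
                raise ValidationError(f"duplicate sequence id {seq.id!r}")
            seen.add(seq.id)
            if label not in self.locations:
                raise ValidationError(
                    f"label {label!r} for {seq.id!r} not in declared locations")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> tuple[NucleotideSequence, ...]:
        return tuple(seq for seq, _ in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(seq.id for seq, _ in self.records)

    @property
    def labels(self) -> dict[str, str]:
        return {seq.id: label for seq, label in self.records}

    def subset(self, ids: Iterable[str]) -> "LabeledCorpus":
        wanted = set(ids)
        recs = tuple(r for r in self.records if r[0].id in wanted)
        return LabeledCorpus(recs, self.locations)


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into sanitized :class:`NucleotideSequence` records.

    The first whitespace-delimited token of each header is the id. Input
    order is preserved; duplicate ids and empty files are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append(NucleotideSequence(rec.id, sanitize_sequence(str(rec.seq))))
    if not out:
        raise FormatError(f"no FASTA records found in {path}")
    return out


def write_fasta(records: Sequence[NucleotideSequence], path: str | Path) -> None:
    """Write records as single-line FASTA (round-trips with read_fasta)."""
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def read_labels(path: str | Path,
                known_locations: Sequence[str]) -> dict[str, str]:
    """Read a two-column (id, location) TSV into an id -> location map.

    A header row reading ``id<TAB>location`` (any case) is skipped. An id
    listed twice with different labels is rejected: multi-location transcripts
    are out of scope.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = list(known_locations)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(parts)}")
            sid, loc = parts[0].strip(), parts[1].strip()
            if lineno == 1 and sid.lower() == "id" and loc.lower() == "location":
                continue
            if loc not in known:
                raise ValidationError(
                    f"{path}:{lineno}: unknown location {loc!r} "
                    f"(known: {known})")
            if sid in out and out[sid] != loc:
                raise ValidationError(
                    f"{path}:{lineno}: id {sid!r} labeled both "
                    f"{out[sid]!r} and {loc!r}; multi-location transcripts "
                    "are not supported")
            out[sid] = loc
    if not out:
        raise FormatError(f"no label rows found in {path}")
    return out


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlocation\n")
        for sid, loc in labels.items():
            fh.write(f"{sid}\t{loc}\n")


def corpus_from_files(fasta_path: str | Path, labels_path: str | Path,
                      known_locations: Sequence[str]) -> LabeledCorpus:
    """Assemble a LabeledCorpus from a FASTA file and a label TSV."""
    seqs = read_fasta(fasta_path)
    labels = read_labels(labels_path, known_locations)
    missing = [s.id for s in seqs if s.id not in labels]
    if missing:
        raise ValidationError(
            f"{len(missing)} sequences lack labels, e.g. {missing[:3]}")
    records = tuple((s, labels[s.id]) for s in seqs)
    return LabeledCorpus(records, tuple(known_locations))


def write_corpus(corpus: LabeledCorpus, fasta_path: str | Path,
                 labels_path: str | Path) -> None:
    write_fasta(corpus.sequences, fasta_path)
    write_labels(corpus.labels, labels_path)
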