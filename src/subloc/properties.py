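"""Physicochemical constant tables for the property-weighted encoders.

The electron-ion interaction pseudopotential (EIIP) assigns each nucleotide a
dimensionless energy of delocalized electrons; the di-/trinucleotide tables
hold one real value per (property, word) cell and parameterize the DPCP/TPCP
descriptors and the PseKNC sequence-order correlation factors.

The bundled di-/trinucleotide tables are synthetic stand-ins (see the file
headers): they preserve the layout, naming and dimensions of the conventional
148-property dinucleotide and 12-property trinucleotide compendia, but their
numeric values are deterministic placeholders. Pass a TSV path to the loaders
to substitute published values; the TSV dialect is one header row of
alphabetically ordered words and one row per property, first column the
property name.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")
TRINUCLEOTIDES: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT")

#: EIIP energies of the four nucleotides (dimensionless).
EIIP_VALUES: Mapping[str, float] = {
    "A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335,
}

#: Default property names for the PseKNC correlation factors: the six
#: conventional helical parameters of B-DNA dinucleotide steps.
HELICAL_PROPERTIES: tuple[str, ...] = (
    "Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")

_DINUC_FILE = "dinucleotide_properties_synthetic.tsv"
_TRINUC_FILE = "trinucleotide_properties_synthetic.tsv"


@dataclass(frozen=True)
class EIIPTable:
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set("ACGT"):
            raise ValidationError("EIIP table must have exactly A, C, G, T")


@dataclass(frozen=True)
class PropertyTable:
    """A complete (property x word) matrix of real values.

    ``table`` is indexed by property name with one column per word in
    alphabetical order; ``standardized`` records whether each property row
    has been scaled to mean 0 / population SD 1.
    """

    table: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        words = DINUCLEOTIDES if self.table.shape[1] == 16 else TRINUCLEOTIDES
        if tuple(self.table.columns) != words:
            raise ValidationError(
                "property table columns must be the alphabetically ordered "
                f"{len(words)} words")
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate property names: {dup}")
        if not np.isfinite(self.table.to_numpy()).all():
            raise ValidationError("property table contains non-finite cells")

    @property
    def properties(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    @property
    def n_properties(self) -> int:
        return self.table.shape[0]

    def values_for(self, names: tuple[str, ...] | list[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.table.index]
        if missing:
            raise ValidationError(f"unknown properties: {missing}")
        return self.table.loc[list(names)].to_numpy(dtype=float)


def load_eiip() -> EIIPTable:
    """Return the EIIP nucleotide energies (A 0.1260, C 0.1340, G 0.0806, T 0.1335)."""
    return EIIPTable(dict(EIIP_VALUES))


def _bundled(name: str) -> Path:
    return Path(str(resources.files("subloc").joinpath("data", name)))


def verify_bundled_checksums() -> dict[str, bool]:
    """Check bundled table files against their recorded SHA-256 digests."""
    recorded = json.loads(_bundled("checksums.json").read_text())
    out = {}
    for fname, digest in recorded.items():
        actual = hashlib.sha256(_bundled(fname).read_bytes()).hexdigest()
        out[fname] = actual == digest
    return out


def _read_property_tsv(path: str | Path, n_words: int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, list[float]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts[1:]]
                if len(header) != n_words:
                    raise FormatError(
                        f"{path}:{lineno}: header must list {n_words} words, "
                        f"got {len(header)}")
                continue
            if len(parts) != n_words + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_words + 1} cells, "
                    f"got {len(parts)}")
            try:
                values = [float(v) for v in parts[1:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric cell") from exc
            rows.append((parts[0], values))
    if header is None or not rows:
        raise FormatError(f"no property rows found in {path}")
    df = pd.DataFrame([v for _, v in rows],
                      index=[n for n, _ in rows], columns=header)
    expect = DINUCLEOTIDES if n_words == 16 else TRINUCLEOTIDES
    df = df.reindex(columns=list(expect))
    if df.isna().any().any():
        raise FormatError(
            f"{path}: header words must be exactly the {n_words} "
            "alphabetically ordered words")
    return df


def load_dinucleotide_properties(path: str | Path | None = None) -> PropertyTable:
    """Load the dinucleotide property table (bundled synthetic default: 148 x 16)."""
    return PropertyTable(_read_property_tsv(path or _bundled(_DINUC_FILE), 16))


def load_trinucleotide_properties(path: str | Path | None = None) -> PropertyTable:
    """Load the trinucleotide property table (bundled default: 12 x 64)."""
    return PropertyTable(_read_property_tsv(path or _bundled(_TRINUC_FILE), 64))


def standardize_properties(table: PropertyTable) -> PropertyTable:
    """Scale each property row to mean 0 and population SD 1.

    Zero-variance properties cannot be standardized and raise
    :class:`ValidationError` naming the offender. Idempotent up to 1e-12.
    """
    values = table.table.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD
    flat = np.isclose(sd[:, 0], 0.0)
    if flat.any():
        name = table.table.index[int(np.argmax(flat))]
        raise ValidationError(f"zero-variance property {name!r}")
    out = pd.DataFrame((values - mean) / sd, index=table.table.index,
                       columns=table.table.columns)
    return PropertyTable(out, standardized=True)
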