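"""Numeric feature encoders for transcript sequences.

Seven feature blocks are produced, in four groups:

========== ===================================================== =====
group      block                                                 width
========== ===================================================== =====
kmer       k-mer frequencies, k = 2..5 (counts / L)               1360
pseknc     pseudo k-tuple composition, k = 2..5 + lambda factors  1370
physico-   EIIP-weighted trinucleotide frequencies (PseEIIP)        64
chemical   dinucleotide property x frequency products (DPCP)      2368
           trinucleotide property x frequency products (TPCP)      768
zcurve     phase-independent trinucleotide Z-curve descriptor       48
           phase-specific trinucleotide Z-curve descriptor         144
========== ===================================================== =====

Normalization follows two conventions, both deliberate: plain k-mer
frequencies divide counts by the sequence length L, while every other block
divides by the number of valid windows (L - k + 1 on unambiguous sequences)
so that the frequencies of each word length sum to one — which is what the
Z-curve bounds and the "normalized frequency" in the property-weighted
descriptors require.

Windows that overlap ambiguous IUPAC codes contribute to no count; the other
blocks then normalize by the count of valid windows. ``policy='strict'``
rejects ambiguous sequences outright. Coordinates are 0-based with half-open
windows, and codon phases are counted from the first base of the transcript
(no reading-frame annotation is attempted).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import LengthError, ValidationError
from .properties import (DINUCLEOTIDES, TRINUCLEOTIDES, EIIPTable,
                         HELICAL_PROPERTIES, PropertyTable, load_eiip,
                         load_dinucleotide_properties,
                         load_trinucleotide_properties,
                         standardize_properties)
from .sequence_io import LabeledCorpus, NucleotideSequence

GROUP_KMER = "kmer"
GROUP_PSEKNC = "pseknc"
GROUP_PHYSICOCHEMICAL = "physicochemical"
GROUP_ZCURVE = "zcurve"
#: Canonical assembly order of the feature groups.
CANONICAL_GROUPS: tuple[str, ...] = (
    GROUP_KMER, GROUP_PSEKNC, GROUP_PHYSICOCHEMICAL, GROUP_ZCURVE)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with group provenance for each column."""

    names: tuple[str, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.groups):
            raise ValidationError("names and groups must align")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def columns_in_groups(self, groups: Iterable[str]) -> np.ndarray:
        wanted = set(groups)
        return np.array([i for i, g in enumerate(self.groups) if g in wanted])

    @staticmethod
    def concat(schemas: Sequence["FeatureSchema"]) -> "FeatureSchema":
        names = tuple(n for s in schemas for n in s.names)
        groups = tuple(g for s in schemas for g in s.groups)
        return FeatureSchema(names, groups)

    def to_json_dict(self) -> dict:
        return {"names": list(self.names), "groups": list(self.groups)}

    @staticmethod
    def from_json_dict(d: dict) -> "FeatureSchema":
        return FeatureSchema(tuple(d["names"]), tuple(d["groups"]))


@dataclass(frozen=True)
class FeatureVector:
    schema: FeatureSchema
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.schema),):
            raise ValidationError("value vector does not match schema width")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature values must be finite")


@dataclass(frozen=True)
class FeatureMatrix:
    """Rows = sequences (indexed by id), columns = named features."""

    data: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self) -> None:
        if tuple(self.data.columns) != self.schema.names:
            raise ValidationError("matrix columns do not match schema")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="id")

    @staticmethod
    def from_csv(path: str | Path, schema: FeatureSchema) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="id")
        return FeatureMatrix(df[list(schema.names)], schema)

    def select(self, ids: Sequence[str], groups: Iterable[str]) -> "FeatureMatrix":
        cols = self.schema.columns_in_groups(groups)
        names = tuple(self.schema.names[i] for i in cols)
        grps = tuple(self.schema.groups[i] for i in cols)
        sub = self.data.loc[list(ids), list(names)]
        return FeatureMatrix(sub, FeatureSchema(names, grps))


@dataclass(frozen=True)
class PseKNCConfig:
    """Configuration of the pseudo k-tuple nucleotide composition encoder.

    ``ks`` are the k-tuple sizes whose normalized frequencies form the
    leading blocks; ``lam`` sequence-order correlation factors computed from
    standardized dinucleotide properties are appended, weighted by
    ``weight``.  Defaults give the 1360 + 10 = 1370-dimensional descriptor.
    """

    ks: tuple[int, ...] = (2, 3, 4, 5)
    lam: int = 10
    weight: float = 0.1
    property_names: tuple[str, ...] = HELICAL_PROPERTIES

    def __post_init__(self) -> None:
        if not self.ks or any(k < 1 or k > 6 for k in self.ks):
            raise ValidationError("ks must be non-empty with each k in 1..6")
        if self.lam < 1:
            raise ValidationError("lam must be >= 1")
        if self.weight < 0:
            raise ValidationError("weight must be >= 0")

    @property
    def dimension(self) -> int:
        return sum(4 ** k for k in self.ks) + self.lam


@dataclass(frozen=True)
class EncoderTables:
    """Bundle of constant tables shared by the encoders.

    ``dinuc_standardized`` is derived from ``dinuc`` and feeds the PseKNC
    correlation factors; ``dinuc``/``trinuc`` are used raw by DPCP/TPCP.
    """

    eiip: EIIPTable
    dinuc: PropertyTable
    trinuc: PropertyTable
    dinuc_standardized: PropertyTable = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dinuc_standardized is None:
            object.__setattr__(self, "dinuc_standardized",
                               standardize_properties(self.dinuc))


def default_tables(dinuc_path: str | Path | None = None,
                   trinuc_path: str | Path | None = None) -> EncoderTables:
    return EncoderTables(
        eiip=load_eiip(),
        dinuc=load_dinucleotide_properties(dinuc_path),
        trinuc=load_trinucleotide_properties(trinuc_path))


# ---------------------------------------------------------------------------
# low-level counting

def _codes(seq: NucleotideSequence, policy: str = "skip") -> np.ndarray:
    """Map a sequence to integer codes; ambiguous bases become -1."""
    arr = np.array([_CODE.get(ch, -1) for ch in seq.seq], dtype=np.int64)
    if policy == "strict" and (arr < 0).any():
        raise ValidationError(
            f"sequence {seq.id!r} contains ambiguous bases (strict policy)")
    return arr


def _word_counts(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Counts of the 4**k words over valid (unambiguous) windows.

    Returns (counts, number of valid windows).
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64), 0
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for off in range(k):
        window = codes[off:off + n]
        idx = idx * 4 + np.where(window < 0, 0, window)
        valid &= window >= 0
    counts = np.bincount(idx[valid], minlength=4 ** k)
    return counts, int(valid.sum())


def _require_length(seq: NucleotideSequence, minimum: int, what: str) -> None:
    if seq.length < minimum:
        raise LengthError(
            f"sequence {seq.id!r} has length {seq.length} < {minimum} "
            f"required by {what}")


def _words(k: int) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


# ---------------------------------------------------------------------------
# schemas

def kmer_schema(ks: Sequence[int] = (2, 3, 4, 5)) -> FeatureSchema:
    names = tuple(f"kmer.k{k}.{w}" for k in ks for w in _words(k))
    return FeatureSchema(names, (GROUP_KMER,) * len(names))

def pseknc_schema(cfg: PseKNCConfig) -> FeatureSchema:
    names = tuple(f"pseknc.k{k}.{w}" for k in cfg.ks for w in _words(k))
    names += tuple(f"pseknc.lambda.{j}" for j in range(1, cfg.lam + 1))
    return FeatureSchema(names, (GROUP_PSEKNC,) * len(names))

def eiip_schema() -> FeatureSchema:
    names = tuple(f"eiip.{w}" for w in TRINUCLEOTIDES)
    return FeatureSchema(names, (GROUP_PHYSICOCHEMICAL,) * 64)

def dpcp_schema(props: PropertyTable) -> FeatureSchema:
    names = tuple(f"dpcp.{p}.{w}" for p in props.properties
                  for w in DINUCLEOTIDES)
    return FeatureSchema(names, (GROUP_PHYSICOCHEMICAL,) * len(names))

def tpcp_schema(props: PropertyTable) -> FeatureSchema:
    names = tuple(f"tpcp.{p}.{w}" for p in props.properties
                  for w in TRINUCLEOTIDES)
    return FeatureSchema(names, (GROUP_PHYSICOCHEMICAL,) * len(names))

def zcurve48_schema() -> FeatureSchema:
    names = tuple(f"zc48.{ax}.{w}" for w in DINUCLEOTIDES for ax in _AXES)
    return FeatureSchema(names, (GROUP_ZCURVE,) * 48)

def zcurve144_schema() -> FeatureSchema:
    names = tuple(f"zc144.p{ph}.{ax}.{w}"
                  for ph in (1, 2, 3) for w in DINUCLEOTIDES for ax in _AXES)
    return FeatureSchema(names, (GROUP_ZCURVE,) * 144)


# ---------------------------------------------------------------------------
# encoders

def encode_kmer(seq: NucleotideSequence,
                ks: Sequence[int] = (2, 3, 4, 5),
                policy: str = "skip") -> FeatureVector:
    """k-mer count / L for each k, blocks concatenated in ascending word size.

    The denominator is the full sanitized length L (not the window count), so
    each k block sums to (L - k + 1) / L on unambiguous sequences.
    """
    ks = tuple(ks)
    _require_length(seq, max(ks), f"k-mer (k={max(ks)})")
    codes = _codes(seq, policy)
    parts = []
    for k in ks:
        counts, _ = _word_counts(codes, k)
        parts.append(counts / seq.length)
    return FeatureVector(kmer_schema(ks), np.concatenate(parts))


def _correlation_factors(codes: np.ndarray, cfg: PseKNCConfig,
                         props: PropertyTable) -> np.ndarray:
    """theta_1..theta_lam: mean squared property difference of dinucleotide
    pairs at gap j, averaged over valid positions."""
    if not props.standardized:
        raise ValidationError(
            "PseKNC correlation requires a standardized property table")
    pmat = props.values_for(cfg.property_names)  # (n_props, 16)
    n = codes.size - 1
    di = codes[:-1] * 4 + codes[1:]
    di_valid = (codes[:-1] >= 0) & (codes[1:] >= 0)
    theta = np.zeros(cfg.lam)
    for j in range(1, cfg.lam + 1):
        a, b = di[:n - j], di[j:]
        ok = di_valid[:n - j] & di_valid[j:]
        if not ok.any():
            raise LengthError(
                f"no valid dinucleotide pairs at correlation rank {j}")
        diff = pmat[:, a[ok]] - pmat[:, b[ok]]
        theta[j - 1] = np.mean(np.mean(diff ** 2, axis=0))
    return theta


def encode_pseknc(seq: NucleotideSequence, cfg: PseKNCConfig | None = None,
                  props: PropertyTable | None = None,
                  policy: str = "skip") -> FeatureVector:
    """Type-I pseudo k-tuple nucleotide composition.

    Per k the 4**k normalized word frequencies are scaled by
    1 / (1 + w * sum(theta)); the lam correlation factors, scaled by
    w / (1 + w * sum(theta)), are appended after all k blocks. With w = 0 the
    frequency blocks reduce to plain normalized frequencies and the lam
    components vanish.
    """
    cfg = cfg or PseKNCConfig()
    if props is None:
        props = standardize_properties(load_dinucleotide_properties())
    _require_length(seq, cfg.lam + 2, f"PseKNC (lambda={cfg.lam})")
    _require_length(seq, max(cfg.ks), "PseKNC k-tuples")
    codes = _codes(seq, policy)
    theta = _correlation_factors(codes, cfg, props)
    denom = 1.0 + cfg.weight * theta.sum()
    parts = []
    for k in cfg.ks:
        counts, nwin = _word_counts(codes, k)
        if nwin == 0:
            raise LengthError(f"no valid {k}-mer windows in {seq.id!r}")
        parts.append(counts / nwin / denom)
    parts.append(cfg.weight * theta / denom)
    return FeatureVector(pseknc_schema(cfg), np.concatenate(parts))


def eiip_indicator(seq: NucleotideSequence, eiip: EIIPTable | None = None,
                   policy: str = "error") -> np.ndarray:
    """Per-position EIIP energies of the sequence (the indicator sequence).

    Ambiguous bases raise by default; ``policy='skip'`` drops them from the
    output instead.
    """
    eiip = eiip or load_eiip()
    values = []
    for ch in seq.seq:
        if ch in eiip.values:
            values.append(eiip.values[ch])
        elif policy == "skip":
            continue
        else:
            raise ValidationError(
                f"ambiguous base {ch!r} in {seq.id!r}; use policy='skip'")
    return np.array(values)


def encode_pseeiip(seq: NucleotideSequence, eiip: EIIPTable | None = None,
                   policy: str = "skip") -> FeatureVector:
    """EIIP-weighted trinucleotide frequencies, 64 components.

    Component xyz = (EIIP_x + EIIP_y + EIIP_z) * f_xyz with f the
    window-count-normalized trinucleotide frequency (sums to 1 on
    unambiguous sequences).
    """
    eiip = eiip or load_eiip()
    _require_length(seq, 3, "PseEIIP")
    counts, nwin = _word_counts(_codes(seq, policy), 3)
    if nwin == 0:
        raise LengthError(f"no valid trinucleotide windows in {seq.id!r}")
    e = np.array([eiip.values[b] for b in "ACGT"])
    weights = e[:, None, None] + e[None, :, None] + e[None, None, :]
    return FeatureVector(eiip_schema(), weights.ravel() * counts / nwin)


def _property_weighted(seq: NucleotideSequence, props: PropertyTable, k: int,
                       policy: str) -> np.ndarray:
    counts, nwin = _word_counts(_codes(seq, policy), k)
    if nwin == 0:
        raise LengthError(f"no valid {k}-mer windows in {seq.id!r}")
    freqs = counts / nwin
    return (props.table.to_numpy(dtype=float) * freqs[None, :]).ravel()


def encode_dpcp(seq: NucleotideSequence, props: PropertyTable | None = None,
                policy: str = "skip") -> FeatureVector:
    """Dinucleotide property x frequency products, property-major order."""
    props = props or load_dinucleotide_properties()
    _require_length(seq, 2, "DPCP")
    return FeatureVector(dpcp_schema(props),
                         _property_weighted(seq, props, 2, policy))


def encode_tpcp(seq: NucleotideSequence, props: PropertyTable | None = None,
                policy: str = "skip") -> FeatureVector:
    """Trinucleotide property x frequency products, property-major order."""
    props = props or load_trinucleotide_properties()
    _require_length(seq, 3, "TPCP")
    return FeatureVector(tpcp_schema(props),
                         _property_weighted(seq, props, 3, policy))


def _zcurve_from_freqs(freqs: np.ndarray) -> np.ndarray:
    """Map 64 trinucleotide frequencies to 16 (x, y, z) triplets.

    For each two-base prefix XY, with p the frequency of XYN:
    x contrasts purines vs pyrimidines (A+G vs C+T), y amino vs keto
    (A+C vs G+T), z weak vs strong hydrogen bonding (A+T vs C+G).
    """
    p = freqs.reshape(16, 4)  # columns: A, C, G, T
    x = (p[:, 0] + p[:, 2]) - (p[:, 1] + p[:, 3])
    y = (p[:, 0] + p[:, 1]) - (p[:, 2] + p[:, 3])
    z = (p[:, 0] + p[:, 3]) - (p[:, 1] + p[:, 2])
    return np.stack([x, y, z], axis=1).ravel()


def encode_zcurve_independent(seq: NucleotideSequence,
                              policy: str = "skip") -> FeatureVector:
    """Phase-independent trinucleotide Z-curve descriptor (48 components)."""
    _require_length(seq, 3, "Z-curve (48)")
    counts, nwin = _word_counts(_codes(seq, policy), 3)
    if nwin == 0:
        raise LengthError(f"no valid trinucleotide windows in {seq.id!r}")
    return FeatureVector(zcurve48_schema(), _zcurve_from_freqs(counts / nwin))


def encode_zcurve_phase(seq: NucleotideSequence,
                        policy: str = "skip") -> FeatureVector:
    """Phase-specific trinucleotide Z-curve descriptor (144 components).

    Phase k in {1, 2, 3} takes trinucleotide windows starting at 0-based
    positions congruent to k - 1 mod 3, counted from the first base of the
    transcript; frequencies are normalized within each phase.
    """
    _require_length(seq, 5, "Z-curve (144)")
    codes = _codes(seq, policy)
    n = codes.size - 2
    idx = codes[:n] * 16 + codes[1:n + 1] * 4 + codes[2:n + 2]
    valid = (codes[:n] >= 0) & (codes[1:n + 1] >= 0) & (codes[2:n + 2] >= 0)
    parts = []
    for phase in range(3):
        sel = valid & (np.arange(n) % 3 == phase)
        if not sel.any():
            raise LengthError(
                f"phase {phase + 1} has no valid windows in {seq.id!r}")
        counts = np.bincount(idx[sel], minlength=64)
        parts.append(_zcurve_from_freqs(counts / sel.sum()))
    return FeatureVector(zcurve144_schema(), np.concatenate(parts))


# ---------------------------------------------------------------------------
# assembly

def group_min_length(group: str, cfg: PseKNCConfig) -> int:
    if group == GROUP_KMER:
        return max(cfg.ks)
    if group == GROUP_PSEKNC:
        return max(cfg.lam + 2, max(cfg.ks))
    if group == GROUP_PHYSICOCHEMICAL:
        return 3
    if group == GROUP_ZCURVE:
        return 5
    raise ValidationError(f"unknown feature group {group!r}")


def encode_group(seq: NucleotideSequence, group: str, cfg: PseKNCConfig,
                 tables: EncoderTables, policy: str = "skip") -> FeatureVector:
    """Encode one feature group (physicochemical = EIIP + DPCP + TPCP;
    zcurve = 48- then 144-component block)."""
    if group == GROUP_KMER:
        return encode_kmer(seq, cfg.ks, policy)
    if group == GROUP_PSEKNC:
        return encode_pseknc(seq, cfg, tables.dinuc_standardized, policy)
    if group == GROUP_PHYSICOCHEMICAL:
        blocks = [encode_pseeiip(seq, tables.eiip, policy),
                  encode_dpcp(seq, tables.dinuc, policy),
                  encode_tpcp(seq, tables.trinuc, policy)]
    elif group == GROUP_ZCURVE:
        blocks = [encode_zcurve_independent(seq, policy),
                  encode_zcurve_phase(seq, policy)]
    else:
        raise ValidationError(f"unknown feature group {group!r}")
    return FeatureVector(FeatureSchema.concat([b.schema for b in blocks]),
                         np.concatenate([b.values for b in blocks]))


def battery_schema(groups: Sequence[str], cfg: PseKNCConfig,
                   tables: EncoderTables) -> FeatureSchema:
    ordered = [g for g in CANONICAL_GROUPS if g in set(groups)]
    unknown = set(groups) - set(CANONICAL_GROUPS)
    if unknown:
        raise ValidationError(f"unknown feature groups {sorted(unknown)}")
    schemas = []
    for g in ordered:
        if g == GROUP_KMER:
            schemas.append(kmer_schema(cfg.ks))
        elif g == GROUP_PSEKNC:
            schemas.append(pseknc_schema(cfg))
        elif g == GROUP_PHYSICOCHEMICAL:
            schemas.extend([eiip_schema(), dpcp_schema(tables.dinuc),
                            tpcp_schema(tables.trinuc)])
        else:
            schemas.extend([zcurve48_schema(), zcurve144_schema()])
    return FeatureSchema.concat(schemas)


def encode_sequence(seq: NucleotideSequence, groups: Sequence[str],
                    cfg: PseKNCConfig, tables: EncoderTables,
                    policy: str = "skip") -> FeatureVector:
    ordered = [g for g in CANONICAL_GROUPS if g in set(groups)]
    blocks = [encode_group(seq, g, cfg, tables, policy) for g in ordered]
    return FeatureVector(FeatureSchema.concat([b.schema for b in blocks]),
                         np.concatenate([b.values for b in blocks]))


def build_feature_matrix(corpus: LabeledCorpus | Sequence[NucleotideSequence],
                         groups: Sequence[str] = CANONICAL_GROUPS,
                         cfg: PseKNCConfig | None = None,
                         tables: EncoderTables | None = None,
                         policy: str = "skip") -> FeatureMatrix:
    """Encode a corpus into a named feature matrix, rows in corpus order.

    Columns are the requested group blocks concatenated in canonical order
    (kmer, pseknc, physicochemical, zcurve). A sequence violating any
    requested group's length precondition fails the whole build with an
    error naming it.
    """
    cfg = cfg or PseKNCConfig()
    tables = tables or default_tables()
    seqs = corpus.sequences if isinstance(corpus, LabeledCorpus) else tuple(corpus)
    if not seqs:
        raise ValidationError("cannot encode an empty corpus")
    minimum = max(group_min_length(g, cfg) for g in groups)
    short = [s.id for s in seqs if s.length < minimum]
    if short:
        raise LengthError(
            f"sequences shorter than {minimum} nt for requested groups: "
            f"{short[:5]}")
    schema = battery_schema(groups, cfg, tables)
    rows = np.empty((len(seqs), len(schema)))
    for i, s in enumerate(seqs):
        rows[i] = encode_sequence(s, groups, cfg, tables, policy).values
    df = pd.DataFrame(rows, index=[s.id for s in seqs],
                      columns=list(schema.names))
    return FeatureMatrix(df, schema)
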