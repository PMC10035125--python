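"""One-off generator for the bundled synthetic property tables.

Run from the repo root:  python scripts/make_property_tables.py
Writes src/subloc/data/*.tsv and data/checksums.json.
"""
import hashlib
import json
from pathlib import Path

import numpy as np

DATA = Path(__file__).resolve().parents[1] / "src" / "subloc" / "data"
DINUCS = [a + b for a in "ACGT" for b in "ACGT"]
TRINUCS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]

HELICAL = ["Twist", "Tilt", "Roll", "Shift", "Slide", "Rise"]
TRI_NAMES = [
    "Bendability (DNase)", "Bendability (consensus)", "Consensus rigid",
    "Consensus roll", "DNase I", "DNase I rigid", "Nucleosome",
    "Nucleosome Rigid", "Nucleosome positioning", "MW Daltons", "MW-kg",
    "Trinucleotide GC content",
]
# approximate nucleotide-monophosphate residue masses (Da)
RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}

DINUC_HEADER = """\
# Synthetic dinucleotide physicochemical property table (stand-in).
# 148 properties x 16 dinucleotides. Values are deterministic pseudo-random
# placeholders at realistic scales, NOT measured physicochemical constants;
# the first six rows reuse the conventional helical-parameter names so the
# default PseKNC correlation property set has stable identifiers. Supply your
# own TSV (same layout) to use a published compendium.
"""

TRINUC_HEADER = """\
# Synthetic trinucleotide physicochemical property table (stand-in).
# 12 properties x 64 trinucleotides. Property names follow the conventional
# trinucleotide descriptor set; 'Trinucleotide GC content' and the molecular
# weights are computed from the word, the remaining values are deterministic
# pseudo-random placeholders, NOT measured constants. Supply your own TSV
# (same layout) to use published values.
"""


def fmt(x: float) -> str:
    return f"{x:.6g}"


def synth_rows(rng: np.random.Generator, n_rows: int, n_cols: int) -> np.ndarray:
    out = np.empty((n_rows, n_cols))
    for i in range(n_rows):
        scale = 10.0 ** rng.uniform(-1.0, 1.5)
        offset = rng.normal(0.0, scale)
        out[i] = np.round(offset + scale * rng.standard_normal(n_cols), 4)
    return out


def write_table(path: Path, header: str, names: list[str], cols: list[str],
                values: np.ndarray) -> None:
    lines = [header.rstrip("\n"), "property\t" + "\t".join(cols)]
    for name, row in zip(names, values):
        lines.append(name + "\t" + "\t".join(fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def main() -> None:
    rng = np.random.default_rng(12345)

    di_names = HELICAL + [f"Synthetic dinucleotide property {i:03d}"
                          for i in range(7, 149)]
    di_values = synth_rows(rng, 148, 16)
    write_table(DATA / "dinucleotide_properties_synthetic.tsv",
                DINUC_HEADER, di_names, DINUCS, di_values)

    tri_values = synth_rows(rng, 12, 64)
    gc = np.array([sum(ch in "GC" for ch in w) / 3.0 for w in TRINUCS])
    mw = np.array([sum(RESIDUE_MASS[ch] for ch in w) for w in TRINUCS])
    tri_values[TRI_NAMES.index("Trinucleotide GC content")] = np.round(gc, 6)
    tri_values[TRI_NAMES.index("MW Daltons")] = np.round(mw, 2)
    tri_values[TRI_NAMES.index("MW-kg")] = mw * 1.66054e-27
    write_table(DATA / "trinucleotide_properties_synthetic.tsv",
                TRINUC_HEADER, TRI_NAMES, TRINUCS, tri_values)

    sums = {}
    for f in sorted(DATA.glob("*.tsv")):
        sums[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (DATA / "checksums.json").write_text(json.dumps(sums, indent=2) + "\n")
    for k, v in sums.items():
        print(k, v)


if __name__ == "__main__":
    main()
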