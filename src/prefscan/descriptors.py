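"""Amino acid descriptor catalog.

Thirty 20-valued scales organised in four sets:

* Set 1 — eight basic physicochemical descriptors (volume, log solubility,
  hydrophobicity, isoelectric point, helix propensity, steric hindrance,
  sheet propensity, flexibility);
* Set 2 — two metabolic descriptors (in vivo decay time, synthesis cost);
* Set 3 — sixteen composites derived arithmetically from Set 1 scales;
* Set 4 — four discrete side-chain composition counts.

Each scale ships with an explicit provenance string naming the published
source of its numbers.  Any scale can be overridden through a custom
tab-delimited file, so exact alternative numbers can always be substituted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class DescriptorTable:
    """One named amino acid scale.

    Parameters
    ----------
    descriptor_id : str
        Short stable token, e.g. ``"hydrophobicity"``.
    display_name : str
        Human-readable name, e.g. ``"Hydrophobicity"``.
    set_id : int
        Which set (1-4) the descriptor belongs to.
    values : dict
        Mapping of each canonical 1-letter amino acid code to a real number.
    provenance : str
        Citation of the numeric scale's source.
    """

    descriptor_id: str
    display_name: str
    set_id: int
    values: dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - set(self.values))
            extra = sorted(set(self.values) - set(AMINO_ACIDS))
            raise ValueError(
                f"descriptor {self.display_name!r}: must map exactly the 20 "
                f"canonical amino acids (missing {missing}, unexpected {extra})"
            )
        vals = np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"descriptor {self.display_name!r}: non-finite value")
        if np.ptp(vals) == 0:
            raise ValueError(
                f"descriptor {self.display_name!r}: constant scale cannot be fit"
            )
        if self.set_id == 4:
            if np.any(vals < 0) or np.any(vals != np.round(vals)):
                raise ValueError(
                    f"descriptor {self.display_name!r}: Set 4 values must be "
                    "non-negative integers"
                )

    def as_array(self) -> np.ndarray:
        """Values in canonical (alphabetical 1-letter) amino acid order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)


@dataclass
class DescriptorCatalog:
    """Ordered collection of descriptor tables, Set 1 first.

    ``selected_sets`` restricts which sets participate in a screen; the scan
    order (Set 1 → 4, table order within a set) is preserved so that simple
    descriptors are seeded before composites and discrete counts.
    """

    tables: list[DescriptorTable] = field(default_factory=list)
    selected_sets: frozenset[int] = frozenset({1, 2, 3, 4})

    def __post_init__(self) -> None:
        ids = [t.descriptor_id for t in self.tables]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate descriptor ids: {dup}")

    def restrict(self, sets: set[int] | frozenset[int]) -> "DescriptorCatalog":
        return DescriptorCatalog(
            tables=[t for t in self.tables if t.set_id in sets],
            selected_sets=frozenset(sets),
        )

    def get(self, descriptor_id: str) -> DescriptorTable:
        for t in self.tables:
            if t.descriptor_id == descriptor_id:
                return t
        raise KeyError(f"unknown descriptor_id {descriptor_id!r}")

    def by_set(self, set_id: int) -> list[DescriptorTable]:
        return [t for t in self.tables if t.set_id == set_id]

    def __iter__(self):
        return iter(self.tables)

    def __len__(self) -> int:
        return len(self.tables)


# ---------------------------------------------------------------------------
# Built-in scales.  The screen is affine-invariant in r and p, so the exact
# units of each scale do not affect which sites are explained, only the
# magnitude of the reported slope.


def _scale(vals: str) -> dict[str, float]:
    numbers = [float(x) for x in vals.split()]
    assert len(numbers) == 20
    return dict(zip(AMINO_ACIDS, numbers))


# Residue volumes, A^3 (Zamyatnin, Prog Biophys Mol Biol 1972).
_VOLUME = _scale(
    "88.6 108.5 111.1 138.4 189.9 60.1 153.2 166.7 168.6 166.7 "
    "162.9 114.1 112.7 143.8 173.4 89.0 116.1 140.0 227.8 193.6"
)

# Solubility in water, g/100 g at 25 C (CRC Handbook of Chemistry and
# Physics); stored already log10-transformed below.
_SOLUBILITY = _scale(
    "16.65 16.0 0.778 0.864 2.965 24.99 4.19 4.117 58.5 2.426 "
    "3.381 3.53 162.3 2.5 18.6 5.023 9.0 8.85 1.136 0.0453"
)
_LOG_SOLUBILITY = {a: math.log10(v) for a, v in _SOLUBILITY.items()}

# Octanol/water side-chain hydrophobicity, pi scale (Fauchere & Pliska,
# Eur J Med Chem 1983).
_HYDROPHOBICITY = _scale(
    "0.31 1.54 -0.77 -0.64 1.79 0.00 0.13 1.80 -0.99 1.70 "
    "1.23 -0.60 0.72 -0.22 -1.01 -0.04 0.26 1.22 2.25 0.96"
)

# Isoelectric point of the free amino acid (standard pK tables).
_ISOELECTRIC = _scale(
    "6.00 5.07 2.77 3.22 5.48 5.97 7.59 6.02 9.74 5.98 "
    "5.74 5.41 6.30 5.65 10.76 5.68 5.60 5.96 5.89 5.66"
)

# Alpha-helix propensity P_alpha (Chou & Fasman, Biochemistry 1974).
_P_HELIX = _scale(
    "1.42 0.70 1.01 1.51 1.13 0.57 1.00 1.08 1.16 1.21 "
    "1.45 0.67 0.57 1.11 0.98 0.77 0.83 1.06 1.08 0.69"
)

# Steric parameter of the side chain (Charton, J Theor Biol 1981).
_STERIC = _scale(
    "0.52 0.62 0.76 0.68 0.70 0.00 0.70 1.02 0.68 0.98 "
    "0.78 0.76 0.64 0.68 0.68 0.53 0.70 0.76 0.70 0.70"
)

# Beta-sheet propensity P_beta (Chou & Fasman, Biochemistry 1974).
_P_SHEET = _scale(
    "0.83 1.19 0.54 0.37 1.38 0.75 0.87 1.60 0.74 1.30 "
    "1.05 0.89 0.55 1.10 0.93 0.75 1.19 1.70 1.37 1.47"
)

# Average side-chain flexibility from B-factor statistics (Bhaskaran &
# Ponnuswamy, Int J Pept Protein Res 1988).
_FLEXIBILITY = _scale(
    "0.357 0.346 0.511 0.497 0.314 0.544 0.323 0.462 0.466 0.365 "
    "0.295 0.463 0.509 0.493 0.529 0.507 0.444 0.386 0.305 0.420"
)

# N-end rule in vivo half-life in yeast, minutes (Bachmair, Finley &
# Varshavsky, Science 1986).
_DECAY_TIME = _scale(
    "1200 1200 3 30 3 1200 10 30 3 3 "
    "1200 3 1200 10 2 1200 1200 1200 3 10"
)

# Biosynthetic cost in high-energy phosphate bonds, E. coli (Akashi &
# Gojobori, PNAS 2002).
_SYNTHESIS_COST = _scale(
    "11.7 24.7 12.7 15.3 52.0 11.7 38.3 32.3 30.3 27.3 "
    "34.3 14.7 20.3 16.3 27.3 11.7 18.7 23.3 74.3 50.0"
)

# Side-chain heavy-atom composition (counted from chemical structure;
# H-bond donors/acceptors count each side-chain heavy atom once per role,
# Asp/Glu/Lys/Arg in their charged forms, His neutral).
_N_OXYGEN = _scale("0 0 2 2 0 0 0 0 0 0 0 1 0 1 0 1 1 0 0 1")
_N_NITROGEN = _scale("0 0 0 0 0 0 2 0 1 0 0 1 0 1 3 0 0 0 1 0")
_N_SULFUR = _scale("0 1 0 0 0 0 0 0 0 0 1 0 0 0 0 0 0 0 0 0")
_N_HBOND = _scale("0 1 2 2 0 0 2 0 1 0 1 2 0 2 3 2 2 0 1 2")


_SET1_SPECS = [
    ("volume", "Volume", _VOLUME, "Residue volume (Zamyatnin 1972)"),
    ("log_solubility", "Log(solubility)", _LOG_SOLUBILITY,
     "log10 solubility in water, g/100 g at 25 C (CRC Handbook)"),
    ("hydrophobicity", "Hydrophobicity", _HYDROPHOBICITY,
     "Octanol/water pi scale (Fauchere & Pliska 1983)"),
    ("isoelectric_point", "Isoelectric point", _ISOELECTRIC,
     "pI of the free amino acid (standard pK tables)"),
    ("p_helix", "P(helix)", _P_HELIX, "Helix propensity (Chou & Fasman 1974)"),
    ("steric_hindrance", "Steric hindrance", _STERIC,
     "Side-chain steric parameter (Charton 1981)"),
    ("p_sheet", "P(sheet)", _P_SHEET, "Sheet propensity (Chou & Fasman 1974)"),
    ("flexibility", "Flexibility", _FLEXIBILITY,
     "Average flexibility from B-factors (Bhaskaran & Ponnuswamy 1988)"),
]

_SET2_SPECS = [
    ("decay_time", "In vivo decay time", _DECAY_TIME,
     "N-end rule half-life in yeast, min (Bachmair et al. 1986)"),
    ("synthesis_cost", "Cost for synthesis", _SYNTHESIS_COST,
     "Biosynthetic cost in ~P bonds, E. coli (Akashi & Gojobori 2002)"),
]

# Composite formulas in catalog order: operand display names joined by the
# operator; parsed against Set 1 display names at build time.
_SET3_FORMULAS = [
    "Volume / P(helix)",
    "Volume / P(sheet)",
    "Volume / Log(solubility)",
    "Log(solubility) x Flexibility",
    "Steric hindrance x Flexibility",
    "P(helix) + P(sheet)",
    "Log(solubility) x Hydrophobicity",
    "Hydrophobicity x Flexibility",
    "Volume / (P(helix) + P(sheet))",
    "Steric hindrance / P(helix)",
    "Isoelectric point / P(sheet)",
    "Volume x Isoelectric point",
    "Isoelectric point / P(helix)",
    "P(helix) / P(sheet)",
    "Steric hindrance / P(sheet)",
    "P(helix) x Flexibility",
]

_SET4_SPECS = [
    ("n_oxygen", "Number of Oxygen atoms in side chain", _N_OXYGEN),
    ("n_nitrogen", "Number of Nitrogen atoms in side chain", _N_NITROGEN),
    ("n_sulfur", "Number of Sulfur atoms in side chain", _N_SULFUR),
    ("n_hbond", "Number of H-bond donors and acceptors in side chain", _N_HBOND),
]


def _slug(name: str) -> str:
    s = name.lower()
    s = s.replace("/", "_per_").replace(" x ", "_times_").replace(" + ", "_plus_")
    s = re.sub(r"[()]", "", s)
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    return s


def derive_composites(set1: list[DescriptorTable]) -> list[DescriptorTable]:
    """Build the 16 Set-3 composite scales from the 8 Set-1 scales.

    Each composite is elementwise arithmetic on its parent scales: ``/`` is a
    ratio, ``x`` a product, ``+`` a sum.  A custom Set-1 scale that puts a
    zero in a ratio denominator is rejected rather than propagated as
    infinity.
    """
    by_name = {t.display_name: t for t in set1}
    out: list[DescriptorTable] = []
    for formula in _SET3_FORMULAS:
        values = _eval_formula(formula, by_name)
        out.append(
            DescriptorTable(
                descriptor_id=_slug(formula),
                display_name=formula.replace(" / ", "/"),
                set_id=3,
                values=values,
                provenance=f"Composite of Set 1 scales: {formula}",
            )
        )
    return out


def _eval_formula(formula: str, by_name: dict[str, DescriptorTable]) -> dict[str, float]:
    # Grammar is tiny: either "A op B" or "A / (B + C)".
    m = re.fullmatch(r"(.+?) / \((.+?) \+ (.+?)\)", formula)
    if m:
        a, b, c = (_parent(by_name, g) for g in m.groups())
        denom = {aa: b[aa] + c[aa] for aa in AMINO_ACIDS}
        _check_denominator(formula, denom)
        return {aa: a[aa] / denom[aa] for aa in AMINO_ACIDS}
    for op in (" / ", " x ", " + "):
        if op in formula:
            left, right = formula.split(op, 1)
            a, b = _parent(by_name, left), _parent(by_name, right)
            if op == " / ":
                _check_denominator(formula, b)
                return {aa: a[aa] / b[aa] for aa in AMINO_ACIDS}
            if op == " x ":
                return {aa: a[aa] * b[aa] for aa in AMINO_ACIDS}
            return {aa: a[aa] + b[aa] for aa in AMINO_ACIDS}
    raise ValueError(f"unparseable composite formula {formula!r}")


def _parent(by_name: dict[str, DescriptorTable], name: str) -> dict[str, float]:
    name = name.strip()
    if name not in by_name:
        raise ValueError(f"missing parent scale {name!r} for composite derivation")
    return by_name[name].values


def _check_denominator(formula: str, denom: dict[str, float]) -> None:
    zeros = sorted(aa for aa, v in denom.items() if v == 0)
    if zeros:
        raise ValueError(
            f"composite {formula!r}: zero denominator for amino acid(s) {zeros}"
        )


def _builtin_tables() -> list[DescriptorTable]:
    set1 = [
        DescriptorTable(did, name, 1, vals, prov)
        for did, name, vals, prov in _SET1_SPECS
    ]
    set2 = [
        DescriptorTable(did, name, 2, vals, prov)
        for did, name, vals, prov in _SET2_SPECS
    ]
    set3 = derive_composites(set1)
    set4 = [
        DescriptorTable(did, name, 4, vals,
                        "Counted from side-chain chemical structure")
        for did, name, vals in _SET4_SPECS
    ]
    return set1 + set2 + set3 + set4


def load_catalog(custom_table_path: str | None = None) -> DescriptorCatalog:
    """Return the built-in descriptor catalog, or one read from a custom file.

    The custom file is tab-delimited: first column descriptor name, second
    column set id (1-4), then 20 columns headed by 1-letter amino acid codes.
    Rows with missing amino acids, non-numeric cells or duplicate names are
    rejected with the offending row named.
    """
    if custom_table_path is None:
        return DescriptorCatalog(tables=_builtin_tables())
    return _load_custom(custom_table_path)


def _load_custom(path: str) -> DescriptorCatalog:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty descriptor file")
    header = lines[0].split("\t")
    if len(header) < 3:
        raise ValueError(
            f"{path}: header must have descriptor name, set id and 20 amino "
            f"acid columns (got {len(header)} fields)"
        )
    aa_cols = [h.strip() for h in header[2:]]
    missing = sorted(set(AMINO_ACIDS) - set(aa_cols))
    if missing:
        raise ValueError(f"{path}: header omits amino acid(s) {missing}")
    unknown = sorted(set(aa_cols) - set(AMINO_ACIDS))
    if unknown:
        raise ValueError(f"{path}: unknown amino acid column(s) {unknown}")

    tables: list[DescriptorTable] = []
    seen: set[str] = set()
    for idx, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 2 + len(aa_cols):
            raise ValueError(f"{path} row {idx}: expected {2 + len(aa_cols)} fields, "
                             f"got {len(fields)}")
        name = fields[0].strip()
        if name in seen:
            raise ValueError(f"{path} row {idx}: duplicate descriptor name {name!r}")
        seen.add(name)
        try:
            set_id = int(fields[1])
        except ValueError:
            raise ValueError(f"{path} row {idx}: non-integer set id {fields[1]!r}") from None
        if set_id not in (1, 2, 3, 4):
            raise ValueError(f"{path} row {idx}: set id must be 1-4, got {set_id}")
        values: dict[str, float] = {}
        for aa, cell in zip(aa_cols, fields[2:]):
            try:
                values[aa] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path} row {idx} ({name}): non-numeric value {cell!r} "
                    f"for amino acid {aa}"
                ) from None
        tables.append(DescriptorTable(_slug(name), name, set_id, values,
                                      provenance=f"user-supplied ({path})"))
    return DescriptorCatalog(tables=tables)
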