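"""Text-format I/O: ITP nonbonded sections, GRO/PDB coordinates, XVG tables.

All quantities are stored internally in nm / kJ/mol / amu / e.  Two nonbonded
dialects are understood: sigma-epsilon (``sigma-eps``) and the dispersion /
repulsion coefficients ``C6``/``C12`` (``c6c12``), related by

    eps = C6^2 / (4 C12),   sigma = (C12 / C6)^(1/6)

and the exact inverses C6 = 4 eps sigma^6, C12 = 4 eps sigma^12.
"""

from __future__ import annotations

import math
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "BeadType",
    "NonbondedTable",
    "Frame",
    "TimeSeriesTable",
    "read_nonbond_params",
    "write_nonbond_params",
    "read_coordinates",
    "read_xvg",
    "write_xvg",
    "sigma_eps_to_c6c12",
    "c6c12_to_sigma_eps",
]


class ParseError(ValueError):
    """Raised when a text input cannot be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# ---------------------------------------------------------------------------
# Lennard-Jones parameter conversions
# ---------------------------------------------------------------------------

def sigma_eps_to_c6c12(sigma: float, eps: float) -> tuple[float, float]:
    """Convert (sigma [nm], eps [kJ/mol]) to (C6 [kJ mol^-1 nm^6], C12 [kJ mol^-1 nm^12])."""
    c6 = 4.0 * eps * sigma**6
    c12 = 4.0 * eps * sigma**12
    return c6, c12


def c6c12_to_sigma_eps(c6: float, c12: float) -> tuple[float, float]:
    """Convert (C6, C12) to (sigma, eps).  Requires strictly positive coefficients."""
    if c6 <= 0.0 or c12 <= 0.0:
        raise ValueError(
            f"cannot convert C6={c6}, C12={c12} to sigma/epsilon: "
            "both coefficients must be positive"
        )
    eps = c6 * c6 / (4.0 * c12)
    sigma = (c12 / c6) ** (1.0 / 6.0)
    return sigma, eps


# ---------------------------------------------------------------------------
# Nonbonded table
# ---------------------------------------------------------------------------

def _is_small_bead_name(name: str) -> bool:
    # Martini ring beads are prefixed 'S' (SP1, SC4, SNd, ...).
    return len(name) >= 2 and name[0] == "S" and name[1] in "PNCQ"


@dataclass
class BeadType:
    """Per-type metadata for one coarse-grained bead type."""

    name: str
    mass: float = 72.0
    charge: float = 0.0
    small: bool = False
    category: str | None = None  # protein/lipid/water/ion tag; not written to ITP


@dataclass
class NonbondedTable:
    """Symmetric per-pair Lennard-Jones table keyed by bead-type names.

    ``pairs`` maps a lexicographically sorted name tuple to ``(eps, sigma)``
    in kJ/mol and nm.  The table is complete when every unordered pair of
    declared types (including self pairs) has an entry.
    """

    types: list[str] = field(default_factory=list)
    meta: dict[str, BeadType] = field(default_factory=dict)
    pairs: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    dialect: str = "sigma-eps"  # source dialect tag: 'sigma-eps' or 'c6c12'

    # -- construction -----------------------------------------------------
    def add_type(
        self,
        name: str,
        mass: float = 72.0,
        charge: float = 0.0,
        small: bool | None = None,
        category: str | None = None,
    ) -> None:
        if name in self.meta:
            raise ValueError(f"duplicate bead type {name!r}")
        if small is None:
            small = _is_small_bead_name(name)
        self.types.append(name)
        self.meta[name] = BeadType(name, mass, charge, small, category)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set_pair(self, a: str, b: str, eps: float, sigma: float) -> None:
        if a not in self.meta or b not in self.meta:
            missing = a if a not in self.meta else b
            raise KeyError(f"unknown bead type {missing!r}")
        if eps < 0.0:
            raise ValueError(f"eps must be >= 0, got {eps} for pair ({a}, {b})")
        if sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {sigma} for pair ({a}, {b})")
        self.pairs[self._key(a, b)] = (float(eps), float(sigma))

    # -- queries -----------------------------------------------------------
    def eps(self, a: str, b: str) -> float:
        return self.pairs[self._key(a, b)][0]

    def sigma(self, a: str, b: str) -> float:
        return self.pairs[self._key(a, b)][1]

    def has_pair(self, a: str, b: str) -> bool:
        return self._key(a, b) in self.pairs

    def all_pair_keys(self) -> list[tuple[str, str]]:
        """Every unordered pair (incl. self pairs) of declared types, sorted."""
        n = len(self.types)
        keys = []
        for i in range(n):
            for j in range(i, n):
                keys.append(self._key(self.types[i], self.types[j]))
        return sorted(keys)

    def missing_pairs(self) -> list[tuple[str, str]]:
        return [k for k in self.all_pair_keys() if k not in self.pairs]

    def is_complete(self) -> bool:
        return not self.missing_pairs()

    def validate(self) -> None:
        for (a, b), (eps, sigma) in self.pairs.items():
            if a not in self.meta or b not in self.meta:
                raise ValueError(f"pair ({a}, {b}) refers to undeclared type")
            if eps < 0.0 or sigma <= 0.0:
                raise ValueError(f"invalid (eps, sigma)=({eps}, {sigma}) for ({a}, {b})")

    def copy(self) -> "NonbondedTable":
        out = NonbondedTable(dialect=self.dialect)
        out.types = list(self.types)
        out.meta = {k: BeadType(v.name, v.mass, v.charge, v.small, v.category) for k, v in self.meta.items()}
        out.pairs = dict(self.pairs)
        return out

    def types_of_category(self, category: str) -> list[str]:
        return [t for t in self.types if self.meta[t].category == category]

    # -- comparisons -------------------------------------------------------
    def equals(self, other: "NonbondedTable", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Structural equality; category tags are ignored (they do not survive ITP I/O)."""
        if sorted(self.types) != sorted(other.types):
            return False
        for name in self.types:
            a, b = self.meta[name], other.meta[name]
            if a.small != b.small:
                return False
            if not (math.isclose(a.mass, b.mass, rel_tol=rtol, abs_tol=atol or 1e-12)
                    and math.isclose(a.charge, b.charge, rel_tol=rtol, abs_tol=atol or 1e-12)):
                return False
        if set(self.pairs) != set(other.pairs):
            return False
        for k, (e1, s1) in self.pairs.items():
            e2, s2 = other.pairs[k]
            if not (math.isclose(e1, e2, rel_tol=rtol, abs_tol=atol)
                    and math.isclose(s1, s2, rel_tol=rtol, abs_tol=atol)):
                return False
        return True


# ---------------------------------------------------------------------------
# ITP nonbonded-section parsing
# ---------------------------------------------------------------------------

def _strip_comment(line: str) -> str:
    idx = line.find(";")
    return line[:idx] if idx >= 0 else line


def read_nonbond_params(text: str, form: str | None = None) -> NonbondedTable:
    """Parse ``[ defaults ]`` / ``[ atomtypes ]`` / ``[ nonbond_params ]`` sections.

    ``form`` forces the dialect ('sigma-eps' or 'c6c12'); when omitted it is
    taken from the ``[ defaults ]`` comb-rule (1 -> c6c12, 2/3 -> sigma-eps),
    defaulting to sigma-eps if no defaults section is present.

    Self interactions may come either from the trailing V/W columns of
    ``[ atomtypes ]`` or from explicit ``[ nonbond_params ]`` entries;
    conflicting duplicates raise.
    """
    if form not in (None, "sigma-eps", "c6c12"):
        raise ValueError(f"unknown form {form!r}")
    table = NonbondedTable()
    section = None
    dialect = form
    pending: list[tuple[int, str, str, float, float]] = []  # lineno, a, b, v, w

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw).strip()
        if not line:
            continue
        if line.startswith("["):
            if not line.endswith("]"):
                raise ParseError(f"malformed section header {raw.strip()!r}", lineno)
            section = line[1:-1].strip().lower()
            continue
        fields = line.split()
        if section == "defaults":
            # nbfunc comb-rule [gen-pairs fudgeLJ fudgeQQ]
            if len(fields) < 2:
                raise ParseError("defaults section needs nbfunc and comb-rule", lineno)
            if form is None:
                dialect = "c6c12" if fields[1] == "1" else "sigma-eps"
        elif section == "atomtypes":
            # name [at.num] mass charge ptype [V W]
            if len(fields) not in (4, 5, 6, 7):
                raise ParseError(f"malformed atomtypes line {raw.strip()!r}", lineno)
            offset = 1 if len(fields) in (5, 7) else 0
            name = fields[0]
            try:
                mass = float(fields[1 + offset])
                charge = float(fields[2 + offset])
            except ValueError as exc:
                raise ParseError(f"non-numeric mass/charge: {exc}", lineno) from None
            if name in table.meta:
                raise ParseError(f"duplicate atomtype {name!r}", lineno)
            table.add_type(name, mass=mass, charge=charge)
            if len(fields) >= 6:
                try:
                    v, w = float(fields[-2]), float(fields[-1])
                except ValueError as exc:
                    raise ParseError(f"non-numeric V/W: {exc}", lineno) from None
                pending.append((lineno, name, name, v, w))
        elif section == "nonbond_params":
            if len(fields) != 5:
                raise ParseError(f"malformed nonbond_params line {raw.strip()!r}", lineno)
            a, b, func = fields[0], fields[1], fields[2]
            if func != "1":
                raise ParseError(f"unsupported function type {func!r} (only LJ func 1)", lineno)
            try:
                v, w = float(fields[3]), float(fields[4])
            except ValueError as exc:
                raise ParseError(f"non-numeric parameter: {exc}", lineno) from None
            pending.append((lineno, a, b, v, w))
        elif section is None:
            raise ParseError(f"data outside any section: {raw.strip()!r}", lineno)
        # other sections silently skipped (moleculetype etc. are out of scope)

    if dialect is None:
        dialect = "sigma-eps"
    table.dialect = dialect

    for lineno, a, b, v, w in pending:
        for name in (a, b):
            if name not in table.meta:
                raise ParseError(f"pair references undeclared type {name!r}", lineno)
        if dialect == "c6c12":
            try:
                sigma, eps = c6c12_to_sigma_eps(v, w)
            except ValueError as exc:
                raise ParseError(str(exc), lineno) from None
        else:
            sigma, eps = v, w
        key = table._key(a, b)
        if key in table.pairs:
            e0, s0 = table.pairs[key]
            if not (math.isclose(e0, eps, rel_tol=1e-9, abs_tol=1e-12)
                    and math.isclose(s0, sigma, rel_tol=1e-9, abs_tol=1e-12)):
                raise ParseError(
                    f"duplicate conflicting entry for pair ({a}, {b}): "
                    f"({e0}, {s0}) vs ({eps}, {sigma})",
                    lineno,
                )
            continue
        table.set_pair(a, b, eps, sigma)
    return table


def write_nonbond_params(table: NonbondedTable, form: str | None = None) -> str:
    """Emit ``[ defaults ]`` + ``[ atomtypes ]`` + ``[ nonbond_params ]`` text.

    Pairs are written in lexicographic order with 6 significant digits, which
    is the round-trip precision contract of this writer.  Raises if the pair
    table is incomplete.
    """
    table.validate()
    missing = table.missing_pairs()
    if missing:
        raise ValueError(f"incomplete pair table; missing pairs: {missing}")
    dialect = form or table.dialect
    if dialect not in ("sigma-eps", "c6c12"):
        raise ValueError(f"unknown form {dialect!r}")

    comb_rule = "1" if dialect == "c6c12" else "2"
    lines = ["[ defaults ]", "; nbfunc  comb-rule", f"  1  {comb_rule}", ""]
    lines.append("[ atomtypes ]")
    lines.append("; name  mass  charge  ptype")
    for name in table.types:
        bt = table.meta[name]
        lines.append(f"  {name}  {bt.mass:.6g}  {bt.charge:.6g}  A")
    lines.append("")
    lines.append("[ nonbond_params ]")
    header = "; i  j  func  C6  C12" if dialect == "c6c12" else "; i  j  func  sigma  eps"
    lines.append(header)
    for a, b in sorted(table.pairs):
        eps, sigma = table.pairs[(a, b)]
        if dialect == "c6c12":
            v, w = sigma_eps_to_c6c12(sigma, eps)
        else:
            v, w = sigma, eps
        lines.append(f"  {a}  {b}  1  {v:.6g}  {w:.6g}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Coordinate frames
# ---------------------------------------------------------------------------

WATER_RESNAMES = {"W", "WF", "PW", "SOL", "HOH"}
ION_RESNAMES = {"ION", "NA", "CL", "NA+", "CL-", "K", "K+", "CA", "CA2+", "MG"}
LIPID_RESNAMES = {
    "DPPC", "DMPC", "DLPC", "DOPC", "POPC", "POPE", "DOPE", "DSPC", "DAPC",
    "POPG", "DOPG", "POPS", "DOPS", "CHOL", "CHL1", "DIPC",
}


@dataclass
class Frame:
    """One coordinate frame: bead positions (nm), categories, ids, orthorhombic box.

    ``categories`` holds one of ``protein``/``lipid``/``water``/``ion`` per
    bead; ``resids`` are 1-based; ``peptide_ids`` are 1-based for protein
    beads and 0 otherwise.
    """

    coords: np.ndarray
    categories: np.ndarray
    resids: np.ndarray
    peptide_ids: np.ndarray
    box: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.categories = np.asarray(self.categories, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.peptide_ids = np.asarray(self.peptide_ids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        n = len(self.coords)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for arr, label in ((self.categories, "categories"), (self.resids, "resids"),
                           (self.peptide_ids, "peptide_ids")):
            if len(arr) != n:
                raise ValueError(f"{label} length {len(arr)} != {n} beads")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths (nm)")
        bad = set(self.categories) - {"protein", "lipid", "water", "ion"}
        if bad:
            raise ValueError(f"unknown bead categories: {sorted(bad)}")

    def select(self, category: str) -> np.ndarray:
        return np.flatnonzero(self.categories == category)

    @property
    def n_beads(self) -> int:
        return len(self.coords)


def _categorize(resname: str) -> str:
    rn = resname.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES:
        return "ion"
    if rn in LIPID_RESNAMES:
        return "lipid"
    return "protein"


def read_coordinates(text: str, format: str = "GRO") -> Frame:
    """Read a single GRO or PDB frame into a :class:`Frame` (coordinates in nm).

    Bead categories are inferred from residue names (Martini water ``W``/``PW``,
    ``ION``-style ions, common phospholipid residue names; everything else is
    protein).  Peptide ids come from PDB chains, or from residue-number resets
    for GRO input.  A box (GRO box vector line / PDB CRYST1) is required;
    triclinic boxes are rejected.
    """
    import MDAnalysis as mda

    fmt = format.upper()
    if fmt not in ("GRO", "PDB"):
        raise ValueError(f"unsupported format {format!r}")
    suffix = ".gro" if fmt == "GRO" else ".pdb"
    tmp = tempfile.NamedTemporaryFile("w", suffix=suffix, delete=False)
    try:
        tmp.write(text)
        tmp.close()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(tmp.name)
        dims = u.dimensions
        if dims is None or np.all(dims[:3] == 0):
            raise ValueError("missing box (required for periodic-boundary-aware metrics)")
        if not np.allclose(dims[3:], 90.0, atol=1e-3):
            raise ValueError(f"triclinic box unsupported (angles {dims[3:]})")
        coords = u.atoms.positions / 10.0  # Angstrom -> nm
        resnames = [r for r in u.atoms.resnames]
        resids = np.asarray(u.atoms.resids, dtype=int)
        categories = np.array([_categorize(r) for r in resnames], dtype=object)
        if fmt == "PDB":
            chain_ids = u.atoms.chainIDs if hasattr(u.atoms, "chainIDs") else u.atoms.segids
            chain_order: list[str] = []
            pep = np.zeros(len(coords), dtype=int)
            for i, (cat, cid) in enumerate(zip(categories, chain_ids)):
                if cat != "protein":
                    continue
                if cid not in chain_order:
                    chain_order.append(cid)
                pep[i] = chain_order.index(cid) + 1
        else:
            # GRO has no chain records: a drop in residue number starts a new peptide
            pep = np.zeros(len(coords), dtype=int)
            current, last_resid = 0, None
            for i, cat in enumerate(categories):
                if cat != "protein":
                    last_resid = None
                    continue
                if last_resid is None or resids[i] < last_resid:
                    current += 1
                pep[i] = current
                last_resid = resids[i]
        box = np.asarray(dims[:3], dtype=float) / 10.0
        return Frame(coords=coords, categories=categories, resids=resids,
                     peptide_ids=pep, box=box)
    finally:
        os.unlink(tmp.name)


# ---------------------------------------------------------------------------
# XVG time series
# ---------------------------------------------------------------------------

@dataclass
class TimeSeriesTable:
    """Plain numeric table with a strictly increasing time column."""

    columns: list[str]
    data: np.ndarray  # (n_rows, n_cols)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.columns):
            raise ValueError(
                f"{self.data.shape[1]} data columns vs {len(self.columns)} names")
        t = self.data[:, 0]
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time column must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data[:, 0]

    def values(self, column: int | str = 1) -> np.ndarray:
        if isinstance(column, str):
            column = self.columns.index(column)
        return self.data[:, column]


def read_xvg(text: str) -> TimeSeriesTable:
    """Parse an XVG-like table: '@'/'#' lines are headers, rows are floats."""
    rows: list[list[float]] = []
    names: list[str] = []
    ncol: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(("#", "@")):
            if line.startswith("@") and "legend" in line and '"' in line:
                names.append(line.split('"')[1])
            continue
        fields = line.split()
        try:
            row = [float(f) for f in fields]
        except ValueError:
            bad = next(f for f in fields if not _is_float(f))
            raise ParseError(f"non-numeric data token {bad!r}", lineno) from None
        if ncol is None:
            ncol = len(row)
        elif len(row) != ncol:
            raise ParseError(f"expected {ncol} columns, got {len(row)}", lineno)
        rows.append(row)
    if not rows:
        raise ParseError("no data rows")
    data = np.asarray(rows, dtype=float)
    columns = ["time"] + (names if len(names) == data.shape[1] - 1
                          else [f"value{i}" for i in range(1, data.shape[1])])
    return TimeSeriesTable(columns=columns, data=data)


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_xvg(table: TimeSeriesTable, title: str = "") -> str:
    lines = []
    if title:
        lines.append(f"@ title \"{title}\"")
    for i, name in enumerate(table.columns[1:]):
        lines.append(f"@ s{i} legend \"{name}\"")
    for row in table.data:
        lines.append("  ".join(f"{v:.10g}" for v in row))
    lines.append("")
    return "\n".join(lines)
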