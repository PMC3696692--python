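"""Readers, writers and in-memory containers for structural ensembles,
DEER dipolar traces, sequence alignments and atom selections.

A multi-MODEL PDB file stands in for a molecular-dynamics trajectory:
each MODEL is one frame, and every frame must carry an identical atom
roster in identical order.  All downstream analytics consume only the
types defined here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

# IUPAC 2021 standard atomic weights, amu (abridged to the elements that
# occur in protein/lipid structures and common ions).
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06,
    "CL": 35.45, "K": 39.098, "CA": 40.078, "MN": 54.938, "FE": 55.845,
    "CO": 58.933, "NI": 58.693, "CU": 63.546, "ZN": 65.38, "SE": 78.971,
    "BR": 79.904, "I": 126.904,
}

_DEFAULT_ELEMENT = "C"


def element_mass(element: str) -> float:
    """Atomic mass for *element*; unknown elements fall back to carbon
    with a logged warning (they still contribute plausibly to a CoM)."""
    key = element.strip().upper()
    if key in ATOMIC_MASSES:
        return ATOMIC_MASSES[key]
    logger.warning("unknown element %r: defaulting to carbon mass", element)
    return ATOMIC_MASSES[_DEFAULT_ELEMENT]


def _infer_element(atom_name: str) -> str:
    """Element from an atom name when the element columns are blank.

    PDB atom names put a one-letter element in column 14 ("CA ", "N  ");
    two-letter elements occupy columns 13-14.  Heuristic: strip digits,
    then prefer a single leading letter unless the two-letter prefix is a
    known element that is not a carbon/nitrogen/oxygen/... ambiguity.
    """
    name = atom_name.strip()
    letters = re.sub(r"[^A-Za-z]", "", name).upper()
    if not letters:
        return _DEFAULT_ELEMENT
    if len(letters) >= 2 and letters[:2] in ATOMIC_MASSES and letters[:2] not in (
        "CA", "CD", "CE", "CO", "ND", "NE", "NI", "OD", "OE", "SE",
    ):
        # CA/CD/... are far more likely protein carbon/nitrogen names.
        return letters[:2]
    return letters[0]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's metadata; coordinates live in the ensemble array."""

    serial: int
    name: str
    resname: str
    resid: int
    chain: str
    element: str
    mass: float


@dataclass
class StructureEnsemble:
    """F frames x N atoms with coordinates in Å.

    Atom metadata is shared across frames; ``coords`` has shape (F, N, 3).
    ``frame_times`` is an optional per-frame time stamp in ns.
    """

    atoms: List[AtomRecord]
    coords: np.ndarray
    frame_times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coords second axis ({self.coords.shape[1]}) does not match "
                f"atom count ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.coords.shape[0],):
                raise ValueError("frame_times length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass(frozen=True)
class AtomSelection:
    """An ordered, duplicate-free set of atom indices into an ensemble."""

    label: str
    indices: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.indices) == 0:
            raise ValueError(f"selection {self.label!r} is empty")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError(f"selection {self.label!r} has duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class DeerTrace:
    """A dipolar evolution signal: times in µs, real echo amplitudes
    normalized so v(0) = 1."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be 1-D arrays of equal length")
        if self.t[0] != 0.0:
            raise ValueError("trace must start at t = 0")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class AlignmentBlock:
    """A gapped alignment plus named column spans marking TMD regions.

    ``region_spans`` maps region name -> (start, stop) half-open 0-based
    column interval.
    """

    ids: List[str]
    rows: List[str]
    region_spans: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("alignment has no sequences")
        ncol = len(self.rows[0])
        for sid, row in zip(self.ids, self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {ncol}"
                )
        for name, (lo, hi) in self.region_spans.items():
            if not (0 <= lo <= hi <= ncol):
                raise ValueError(f"region {name!r} span ({lo}, {hi}) outside [0, {ncol})")

    @property
    def ncol(self) -> int:
        return len(self.rows[0])


# ---------------------------------------------------------------------------
# PDB ensembles
# ---------------------------------------------------------------------------

def read_pdb_ensemble(path: str) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a StructureEnsemble.

    One frame per MODEL; a file without MODEL records yields F = 1.  ATOM
    and HETATM records are both retained.  The element is taken from
    columns 77-78 when present, otherwise inferred from the atom name.
    Raises a ValueError naming the offending MODEL if atom counts differ
    between frames.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ens", path)
    except Exception as exc:  # Biopython raises several exception types
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no coordinate records found")

    atoms0 = list(models[0].get_atoms())
    if not atoms0:
        raise ValueError(f"{path}: first MODEL contains no atoms")

    records: List[AtomRecord] = []
    for atom in atoms0:
        residue = atom.get_parent()
        chain = residue.get_parent().id or " "
        element = (atom.element or "").strip()
        if not element:
            element = _infer_element(atom.get_name())
        records.append(
            AtomRecord(
                serial=int(atom.get_serial_number() or 0),
                name=atom.get_name(),
                resname=residue.get_resname().strip(),
                resid=int(residue.id[1]),
                chain=str(chain),
                element=element,
                mass=element_mass(element),
            )
        )

    n = len(records)
    coords = np.empty((len(models), n, 3), dtype=float)
    for f, model in enumerate(models):
        frame_atoms = list(model.get_atoms())
        if len(frame_atoms) != n:
            raise ValueError(
                f"{path}: MODEL {model.id + 1} has {len(frame_atoms)} atoms, "
                f"expected {n} (as in MODEL {models[0].id + 1})"
            )
        for a, atom in enumerate(frame_atoms):
            coords[f, a] = atom.get_coord()
    return StructureEnsemble(atoms=records, coords=coords)


def write_pdb_ensemble(ensemble: StructureEnsemble, path: str) -> None:
    """Write an ensemble as a multi-MODEL PDB file (fixed 8.3 coordinate
    columns, hence round-trip precision 1e-3 Å)."""
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for a, rec in enumerate(ensemble.atoms):
                x, y, z = ensemble.coords[f, a]
                name = rec.name
                # Column 13 is reserved for 2-letter elements; 1-letter
                # element names start in column 14.
                if len(name) < 4 and len(rec.element) == 1:
                    name_field = f" {name:<3s}"
                else:
                    name_field = f"{name:<4s}"
                fh.write(
                    f"ATOM  {rec.serial % 100000:5d} {name_field} "
                    f"{rec.resname:>3s} {rec.chain:1s}{rec.resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {rec.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# DEER traces
# ---------------------------------------------------------------------------

_TIME_FACTORS = {"us": 1.0, "µs": 1.0, "ns": 1e-3, "ms": 1e3, "s": 1e6}


def read_deer_trace(path: str, time_unit: Optional[str] = None) -> DeerTrace:
    """Read a two-column ASCII dipolar-evolution trace.

    Columns are time and echo amplitude, whitespace- or comma-delimited;
    lines starting with ``#`` are comments.  A ``# time_unit: <unit>``
    comment (or the *time_unit* argument, which wins) declares the time
    unit; default µs.  The amplitude is renormalized so v(0) = 1.
    """
    declared_unit = None
    rows: List[Tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                m = re.search(r"time_unit\s*[:=]\s*(\S+)", stripped)
                if m:
                    declared_unit = m.group(1)
                continue
            parts = re.split(r"[,\s]+", stripped)
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {stripped!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparsable numeric data") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    unit = (time_unit or declared_unit or "us").lower().lstrip("μµ") or "us"
    if time_unit is None and declared_unit is not None:
        unit = declared_unit.lower()
    if unit in ("μs", "µs"):
        unit = "us"
    if unit not in _TIME_FACTORS:
        raise ValueError(f"{path}: unknown time unit {unit!r}")
    t = np.array([r[0] for r in rows]) * _TIME_FACTORS[unit]
    v = np.array([r[1] for r in rows])
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: times are not strictly increasing")
    if t[0] != 0.0:
        raise ValueError(
            f"{path}: first time point is {t[0]:g} µs, not 0; zero-time "
            "correction is out of scope — supply a trace starting at t = 0"
        )
    if v[0] == 0:
        raise ValueError(f"{path}: v(0) = 0, cannot normalize")
    return DeerTrace(t=t, v=v / v[0])


def write_deer_trace(trace: DeerTrace, path: str, header: str = "") -> None:
    """Write a trace as two-column ASCII (time µs, amplitude), full
    double precision so a read-back is bitwise equal."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# time_unit: us\n")
        for ti, vi in zip(trace.t, trace.v):
            fh.write(f"{float(ti)!r} {float(vi)!r}\n")


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def read_alignment(
    path: str,
    format: str = "fasta",
    region_spans: Optional[Dict[str, Tuple[int, int]]] = None,
) -> AlignmentBlock:
    """Read an aligned FASTA or Stockholm file.

    Rows are uppercased and Stockholm ``.`` gaps are normalized to ``-``.
    A ragged alignment raises a ValueError naming the offending id.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    seqs = list(SeqIO.parse(path, format))
    if not seqs:
        raise ValueError(f"{path}: no sequences found")
    ids = [s.id for s in seqs]
    rows = [str(s.seq).upper().replace(".", "-") for s in seqs]
    block = AlignmentBlock(ids=ids, rows=rows, region_spans=region_spans or {})
    return block


def read_region_table(path: str) -> Dict[str, Tuple[int, int]]:
    """Read a TSV of (region, col_start, col_end) half-open 0-based
    alignment-column spans."""
    spans: Dict[str, Tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, lo, hi = parts[0], int(parts[1]), int(parts[2])
            spans[name] = (lo, hi)
    return spans


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def resolve_selection(ensemble: StructureEnsemble, spec: str) -> AtomSelection:
    """Resolve a selection expression against an ensemble.

    Grammar: clauses joined by ``and`` (or commas), each one of

    * ``chain A``
    * ``resid 423-431`` or ``resid 613`` or ``resid 5,9,12``
    * ``name CA`` or ``name N,O``

    The result is ordered by atom index (file order) and deterministic.
    An empty result is an error, as is a chain/resid token that matches
    nothing anywhere in the structure.
    """
    clauses = [c.strip() for c in re.split(r"\band\b|,(?=\s*(?:chain|resid|name)\b)", spec) if c.strip()]
    if not clauses:
        raise ValueError(f"empty selection expression: {spec!r}")

    mask = np.ones(ensemble.n_atoms, dtype=bool)
    chains = np.array([a.chain for a in ensemble.atoms])
    resids = np.array([a.resid for a in ensemble.atoms])
    names = np.array([a.name for a in ensemble.atoms])

    for clause in clauses:
        parts = clause.split(None, 1)
        if len(parts) != 2:
            raise ValueError(f"cannot parse selection clause {clause!r}")
        keyword, arg = parts[0].lower(), parts[1].strip()
        if keyword == "chain":
            wanted = [c.strip() for c in arg.split(",")]
            for c in wanted:
                if not np.any(chains == c):
                    raise ValueError(f"unknown chain {c!r} in selection {spec!r}")
            mask &= np.isin(chains, wanted)
        elif keyword == "resid":
            wanted_ids: List[int] = []
            for token in arg.split(","):
                token = token.strip()
                m = re.fullmatch(r"(-?\d+)\s*[-:]\s*(-?\d+)", token)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    wanted_ids.extend(range(lo, hi + 1))
                else:
                    wanted_ids.append(int(token))
            present = set(resids[mask].tolist()) if mask.any() else set()
            all_present = set(resids.tolist())
            missing = [r for r in wanted_ids if r not in all_present]
            # Only individual resids (not range interiors) must exist.
            if missing and not any(re.search(r"[-:]", tok) for tok in arg.split(",")):
                raise ValueError(f"unknown resid {missing[0]} in selection {spec!r}")
            mask &= np.isin(resids, wanted_ids)
            del present
        elif keyword == "name":
            wanted = [n.strip() for n in arg.split(",")]
            mask &= np.isin(names, wanted)
        else:
            raise ValueError(f"unknown selection keyword {keyword!r} in {spec!r}")

    indices = tuple(int(i) for i in np.flatnonzero(mask))
    if not indices:
        raise ValueError(f"selection {spec!r} matched no atoms")
    return AtomSelection(label=spec, indices=indices)


def selection_union(a: AtomSelection, b: AtomSelection) -> AtomSelection:
    """Ordered union of two selections (duplicates collapse)."""
    merged = tuple(sorted(set(a.indices) | set(b.indices)))
    return AtomSelection(label=f"({a.label}) or ({b.label})", indices=merged)
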