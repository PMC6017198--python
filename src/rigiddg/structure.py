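"""PDB structure I/O, glycine-truncation mutagenesis, SASA and secondary
structure.

The mutation model is side-chain truncation: mutating a residue to glycine
removes every side-chain atom, and with it all stabilizing interactions that
those atoms participate in.  Mutations to targets other than glycine require
rotamer placement, which is delegated to an external tool hook.
"""

from __future__ import annotations

import copy
import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topology import (BACKBONE_ATOMS, MAX_SASA, ONE_TO_THREE, STANDARD_AA1,
                       THREE_TO_ONE, vdw_radius)

logger = logging.getLogger(__name__)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBFormatError(ValueError):
    """Raised on malformed or empty PDB content."""


class ResidueNotFoundError(KeyError):
    """Raised when a (chain, position) has no residue in the structure."""


class MutationMismatchError(ValueError):
    """Raised when the wild-type code of a mutation does not match the
    structure (signals a mis-specified mutation)."""


class ExternalToolRequiredError(RuntimeError):
    """Raised for non-glycine target residues when no external side-chain
    placement tool is configured."""


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if not self.atom_name:
            raise ValueError("empty atom name")
        self.residue_name = self.residue_name.upper()

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.insertion_code)

    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class SSRecord:
    """A HELIX/SHEET/TURN header record (one residue range on one chain)."""
    kind: str  # helix | sheet | turn
    chain_id: str
    start_seq: int
    end_seq: int

    def covers(self, chain: str, seq: int) -> bool:
        return self.chain_id == chain and self.start_seq <= seq <= self.end_seq


@dataclass
class Structure:
    atoms: list[AtomRecord]
    id: str = ""
    ss_records: list[SSRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(atoms=[copy.deepcopy(a) for a in self.atoms],
                         id=self.id, ss_records=list(self.ss_records))

    def residues(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Residues in order of first appearance, keyed by
        (chain, seq, insertion code)."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def get_residue(self, chain: str, position: int,
                    insertion_code: str = "") -> list[AtomRecord]:
        atoms = [a for a in self.atoms
                 if a.chain_id == chain and a.residue_seq == position
                 and a.insertion_code == insertion_code]
        if not atoms:
            raise ResidueNotFoundError(
                f"no residue at chain {chain!r} position {position}")
        return atoms

    def chains(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class MutationSpec:
    chain: str
    position: int
    wt_code: str
    target_code: str

    def __post_init__(self):
        for code in (self.wt_code, self.target_code):
            if code not in STANDARD_AA1:
                raise ValueError(f"unknown amino-acid code {code!r}")

    def __str__(self) -> str:
        return f"{self.chain}:{self.wt_code}{self.position}{self.target_code}"


# ---------------------------------------------------------------------------
# PDB reading and writing (fixed-column format)
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2] in ("SE", "CL", "BR", "FE", "ZN"):
        return stripped[:2]
    return stripped[0]


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip() or " "
        resseq = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ = float(line[54:60]) if line[54:60].strip() else 1.0
        bfac = float(line[60:66]) if line[60:66].strip() else 0.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBFormatError(f"malformed ATOM record at line {lineno}: {exc}") from exc
    if not element:
        element = _infer_element(name)
    rec = AtomRecord(serial=serial, atom_name=name, element=element,
                     residue_name=resname, chain_id=chain, residue_seq=resseq,
                     insertion_code=icode, coords=np.array([x, y, z]),
                     occupancy=occ, b_factor=bfac)
    return rec, altloc


def _parse_ss_line(line: str) -> SSRecord | None:
    rec_type = line[:6].strip()
    try:
        if rec_type == "HELIX":
            return SSRecord("helix", line[19].strip() or " ",
                            int(line[21:25]), int(line[33:37]))
        if rec_type == "SHEET":
            return SSRecord("sheet", line[21].strip() or " ",
                            int(line[22:26]), int(line[33:37]))
        if rec_type == "TURN":
            return SSRecord("turn", line[19].strip() or " ",
                            int(line[20:24]), int(line[31:35]))
    except (ValueError, IndexError):
        logger.warning("skipping malformed %s record: %r", rec_type, line.rstrip())
    return None


def read_pdb(path, model_index: int = 0, include_hetatm: bool = False) -> Structure:
    """Parse a PDB file into a Structure.

    Only ATOM records of the selected model are kept (HETATM and waters are
    excluded by default); for alternate locations the highest-occupancy
    conformer is retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    atoms: list[AtomRecord] = []
    ss_records: list[SSRecord] = []
    # (residue_key, atom_name) -> index into atoms, for altloc resolution
    seen: dict[tuple, int] = {}
    current_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec_type = line[:6].strip()
            if rec_type == "MODEL":
                try:
                    current_model = int(line[10:14]) - 1
                except ValueError:
                    raise PDBFormatError(f"malformed MODEL record at line {lineno}")
                continue
            if rec_type in ("HELIX", "SHEET", "TURN"):
                ss = _parse_ss_line(line)
                if ss is not None:
                    ss_records.append(ss)
                continue
            if rec_type not in ("ATOM", "HETATM"):
                continue
            if current_model != model_index:
                continue
            if rec_type == "HETATM" and not include_hetatm:
                continue
            rec, altloc = _parse_atom_line(line, lineno)
            if rec.residue_name in WATER_NAMES:
                continue
            key = (rec.residue_key, rec.atom_name)
            if key in seen:
                if altloc and rec.occupancy > atoms[seen[key]].occupancy:
                    atoms[seen[key]] = rec
                continue
            seen[key] = len(atoms)
            atoms.append(rec)
    if not atoms:
        raise PDBFormatError(f"no ATOM records in {path}")
    return Structure(atoms=atoms, id=path.stem, ss_records=ss_records)


def _format_atom_name(name: str, element: str) -> str:
    # Single-letter elements start in column 14; longer names fill col 13.
    if len(name) < 4 and len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(s: Structure, path) -> None:
    """Write ATOM records (8.3 fixed-point coordinates), a TER per chain and
    a final END terminator."""
    if not s.atoms:
        raise ValueError("cannot write an empty Structure")
    lines = []
    for ss in s.ss_records:
        if ss.kind == "helix":
            lines.append(f"HELIX    1   1 AAA {ss.chain_id} {ss.start_seq:4d}  "
                         f"AAA {ss.chain_id} {ss.end_seq:4d}  1{'':30s}")
        elif ss.kind == "sheet":
            lines.append(f"SHEET    1   A 1 AAA {ss.chain_id}{ss.start_seq:4d} "
                         f" AAA {ss.chain_id}{ss.end_seq:4d}  0")
        else:
            lines.append(f"TURN     1  T1 AAA {ss.chain_id}{ss.start_seq:4d} "
                         f" AAA {ss.chain_id}{ss.end_seq:4d}")
    prev_chain = None
    last = None
    for a in s.atoms:
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append(_ter_line(last))
        name = _format_atom_name(a.atom_name, a.element)
        lines.append(
            f"ATOM  {a.serial:5d} {name}"
            f" {a.residue_name:>3s} {a.chain_id}{a.residue_seq:4d}"
            f"{a.insertion_code or ' '}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.b_factor:6.2f}{'':10s}{a.element:>2s}"
        )
        prev_chain = a.chain_id
        last = a
    lines.append(_ter_line(last))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _ter_line(a: AtomRecord) -> str:
    return (f"TER   {a.serial + 1:5d}      {a.residue_name:>3s} "
            f"{a.chain_id}{a.residue_seq:4d}{a.insertion_code or ' '}")


# ---------------------------------------------------------------------------
# Mutagenesis by side-chain truncation
# ---------------------------------------------------------------------------

def truncate_to_glycine(s: Structure, m: MutationSpec) -> Structure:
    """Return a new Structure with the mutated residue's side chain removed
    and the residue renamed GLY.  The input structure is not modified."""
    residue = s.get_residue(m.chain, m.position)
    resname = residue[0].residue_name
    expected = ONE_TO_THREE[m.wt_code]
    if resname != expected:
        raise MutationMismatchError(
            f"residue at {m.chain}:{m.position} is {resname}, "
            f"mutation says {expected}")
    if m.target_code != "G":
        raise ExternalToolRequiredError(
            f"target {m.target_code!r} requires side-chain placement by an "
            "external tool; only truncation to glycine is built in")
    key = residue[0].residue_key
    out_atoms = []
    for a in s.atoms:
        if a.residue_key == key and a.atom_name not in BACKBONE_ATOMS:
            continue
        b = copy.deepcopy(a)
        if b.residue_key == key:
            b.residue_name = "GLY"
        out_atoms.append(b)
    return Structure(atoms=out_atoms, id=s.id, ss_records=list(s.ss_records))


def mutate(s: Structure, m: MutationSpec, external_cmd: str | None = None) -> Structure:
    """Apply a mutation.  Glycine targets use built-in truncation; any other
    target shells out to `external_cmd` (a template with {pdb_in} {pdb_out}
    {chain} {pos} {target} placeholders) when provided."""
    if m.target_code == "G":
        return truncate_to_glycine(s, m)
    if external_cmd is None:
        raise ExternalToolRequiredError(
            f"target {m.target_code!r} requires an external tool "
            "(pass external_cmd)")
    tmpdir = Path(tempfile.mkdtemp(prefix="rigiddg_mut_"))
    try:
        pdb_in = tmpdir / "in.pdb"
        pdb_out = tmpdir / "out.pdb"
        write_pdb(s, pdb_in)
        cmd = external_cmd.format(pdb_in=pdb_in, pdb_out=pdb_out,
                                  chain=m.chain, pos=m.position,
                                  target=m.target_code)
        subprocess.run(cmd, shell=True, check=True)
        return read_pdb(pdb_out)
    finally:
        shutil.rmtree(tmpdir, ignore_errors=True)


# ---------------------------------------------------------------------------
# Solvent accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit-sphere points (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(coords: np.ndarray, radii: np.ndarray,
                  probe_radius: float = 1.4, n_points: int = 3840) -> np.ndarray:
    """Per-atom solvent accessible surface areas (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    sphere = fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    areas = np.zeros(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * sphere
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.where((d < ri + expanded) & (np.arange(n) != i))[0]
        free = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * ri * ri * free.mean()
    return areas


def compute_sasa(s: Structure, site: tuple[str, int],
                 probe_radius: float = 1.4, n_points: int = 3840,
                 include_hydrogens: bool = True) -> tuple[float, float]:
    """Absolute (A^2) and relative (%) SASA of the residue at `site`.

    Relative SASA is 100 * absolute / theoretical-maximum of the residue
    type, clipped to [0, 100].
    """
    chain, position = site
    residue = s.get_residue(chain, position)
    atoms = [a for a in s.atoms if include_hydrogens or not a.is_hydrogen()]
    coords = np.array([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) for a in atoms])
    areas = shrake_rupley(coords, radii, probe_radius, n_points)
    key = residue[0].residue_key
    absolute = float(sum(area for a, area in zip(atoms, areas)
                         if a.residue_key == key))
    code = THREE_TO_ONE.get(residue[0].residue_name)
    ref = MAX_SASA.get(code)
    if ref is None:
        logger.warning("no reference max SASA for residue %s; relative SASA "
                       "clipped from absolute only", residue[0].residue_name)
        ref = max(absolute, 1.0)
    relative = float(np.clip(100.0 * absolute / ref, 0.0, 100.0))
    return absolute, relative


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees for four points."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(s: Structure, chain: str, position: int
                       ) -> tuple[float | None, float | None]:
    """(phi, psi) in degrees; None at chain termini or on missing atoms."""
    res_keys = [k for k in s.residues() if k[0] == chain]
    order = {k: i for i, k in enumerate(res_keys)}
    residues = s.residues()

    def atom(key, name):
        for a in residues[key]:
            if a.atom_name == name:
                return a.coords
        return None

    this_key = None
    for k in res_keys:
        if k[1] == position:
            this_key = k
            break
    if this_key is None:
        raise ResidueNotFoundError(f"no residue at {chain}:{position}")
    i = order[this_key]
    phi = psi = None
    n, ca, c = (atom(this_key, x) for x in ("N", "CA", "C"))
    if i > 0 and n is not None and ca is not None and c is not None:
        c_prev = atom(res_keys[i - 1], "C")
        if c_prev is not None:
            phi = dihedral(c_prev, n, ca, c)
    if i < len(res_keys) - 1 and n is not None and ca is not None and c is not None:
        n_next = atom(res_keys[i + 1], "N")
        if n_next is not None:
            psi = dihedral(n, ca, c, n_next)
    return phi, psi


SS_LABELS = ("helix", "sheet", "turn", "coil")


def assign_secondary_structure(s: Structure, site: tuple[str, int],
                               dihedral_fallback: bool = True) -> str:
    """Label a residue helix/sheet/turn/coil.

    HELIX/SHEET/TURN header records take precedence when present; otherwise
    a phi/psi window classifier is used (helix: phi in [-100,-30] and psi in
    [-80,-5]; sheet: phi in [-180,-90] and psi in [90,180]; else coil).
    """
    chain, position = site
    s.get_residue(chain, position)  # raise if absent
    for ss in s.ss_records:
        if ss.covers(chain, position):
            return ss.kind
    if not dihedral_fallback:
        return "coil"
    phi, psi = backbone_dihedrals(s, chain, position)
    if phi is None or psi is None:
        return "coil"
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "helix"
    if -180 <= phi <= -90 and 90 <= psi <= 180:
        return "sheet"
    return "coil"
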