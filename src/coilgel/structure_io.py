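"""Sequence/structure data model and standard-format I/O.

The central objects are :class:`HeptadSequence` — a one-letter sequence with a
periodic heptad register (a–g) and 1-based residue numbering — and
:class:`StructureModel`, a thin wrapper around a biotite ``AtomArray`` that
adds coiled-coil bookkeeping (symmetry order, per-residue α-carbons).

An ideal Crick-parametrized pentamer generator is included as a deterministic
geometric fixture standing in for a relaxed/predicted pentamer structure; it
is not a structure predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
import biotite.sequence.io.fasta as fasta_io

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
HEPTAD_LABELS = "abcdefg"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class RegisterError(ValueError):
    """Unknown or inconsistent heptad register label."""


class PDBParseError(ValueError):
    """Malformed PDB record; message carries the offending line number."""


@dataclass(frozen=True)
class HeptadSequence:
    """Amino-acid sequence with heptad register and residue numbering.

    Parameters
    ----------
    residues : str
        One-letter amino-acid string (canonical 20 alphabet).
    register : str
        Per-residue heptad label in ``a``–``g``; must cycle with period 7.
    numbering_offset : int
        Residue number of string index 0 (1-based by convention, so the
        default 1 makes residue numbers equal index + 1).
    """

    residues: str
    register: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 7:
            raise ValueError("sequence must be at least one heptad (7 residues)")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residues: {sorted(bad)}")
        if len(self.register) != len(self.residues):
            raise RegisterError("register length must match sequence length")
        if set(self.register) - set(HEPTAD_LABELS):
            raise RegisterError("register labels must be in a-g")
        start = HEPTAD_LABELS.index(self.register[0])
        expected = "".join(
            HEPTAD_LABELS[(start + i) % 7] for i in range(len(self.register)))
        if self.register != expected:
            raise RegisterError("register must cycle a-g with period 7")

    def __len__(self) -> int:
        return len(self.residues)

    def residue_numbers(self) -> np.ndarray:
        return np.arange(len(self)) + self.numbering_offset

    def label_of(self, residue_number: int) -> str:
        idx = residue_number - self.numbering_offset
        if not 0 <= idx < len(self):
            raise IndexError(f"residue {residue_number} out of range")
        return self.register[idx]

    def select(self, labels: Iterable[str],
               window: tuple[int, int] | None = None) -> np.ndarray:
        """0-based string indices whose register label is in ``labels``.

        ``window`` restricts the selection to residue numbers
        ``window[0] <= n <= window[1]`` (inclusive, 1-based convention).
        """
        labels = set(labels)
        if labels - set(HEPTAD_LABELS):
            raise RegisterError(f"unknown labels: {labels - set(HEPTAD_LABELS)}")
        nums = self.residue_numbers()
        mask = np.array([c in labels for c in self.register])
        if window is not None:
            lo, hi = window
            mask &= (nums >= lo) & (nums <= hi)
        return np.nonzero(mask)[0]

    def mutated(self, index: int, new_residue: str) -> "HeptadSequence":
        if new_residue not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {new_residue!r}")
        res = self.residues[:index] + new_residue + self.residues[index + 1:]
        return replace(self, residues=res)


def assign_heptad(residues: str, first_label: str,
                  numbering_offset: int = 1) -> HeptadSequence:
    """Assign a periodic heptad register starting at ``first_label``."""
    if first_label not in HEPTAD_LABELS:
        raise RegisterError(f"unknown heptad label {first_label!r}")
    start = HEPTAD_LABELS.index(first_label)
    register = "".join(
        HEPTAD_LABELS[(start + i) % 7] for i in range(len(residues)))
    return HeptadSequence(residues, register, numbering_offset)


# The b/c/f surface windows of the 54-residue Q-family coiled coil.  With the
# default register origin (residue 1 = 'a') the N-terminal window AA17-28
# contains exactly 5 surface (b/c/f) residues and the C-terminal window
# AA29-54 exactly 11.
N_WINDOW = (17, 28)
C_WINDOW = (29, 54)
SURFACE_LABELS = ("b", "c", "f")
DEFAULT_REGISTER_ORIGIN = "a"


def example_sequence() -> HeptadSequence:
    """A synthetic 54-residue Q-like coiled-coil sequence (fixture).

    Hydrophobic a/d core (L/I), charged e/g flanks, and a terminal-patch
    surface: b/c/f positions are basic (K/R) up to residue 28 and acidic
    (E/D) from residue 29 on, mimicking the positive-N/negative-C surface
    patch pattern of the Q-family hydrogel variants.  Register origin is
    the default 'a' at residue 1.
    """
    by_label_n = {"a": "L", "b": "K", "c": "R", "d": "I", "e": "E",
                  "f": "K", "g": "Q"}
    by_label_c = {"a": "L", "b": "E", "c": "D", "d": "I", "e": "K",
                  "f": "E", "g": "Q"}
    residues = "".join(
        (by_label_n if i < 28 else by_label_c)[HEPTAD_LABELS[i % 7]]
        for i in range(54))
    return assign_heptad(residues, DEFAULT_REGISTER_ORIGIN)


@dataclass(frozen=True)
class CrickParams:
    """Crick-style parametrization of an ideal coiled-coil pentamer.

    Defaults approximate COMPcc-like dimensions (~7 nm long for ~50
    residues).  All lengths in Å.
    """

    superhelix_radius: float = 8.6
    helix_radius: float = 2.26
    rise_per_residue: float = 1.51
    residues_per_turn: float = 3.62
    superhelix_pitch: float = 200.0
    minor_phase: float = 0.0
    superhelix_phase: float = 0.0

    def __post_init__(self) -> None:
        for name in ("superhelix_radius", "helix_radius", "rise_per_residue",
                     "residues_per_turn", "superhelix_pitch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class StructureModel:
    """A (possibly multi-chain) structure with coiled-coil bookkeeping."""

    atoms: struc.AtomArray
    symmetry_order: int = 1

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.atoms.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def alpha_carbons(self, chain: str | None = None) -> np.ndarray:
        """(n_res, 3) α-carbon coordinates, optionally for one chain."""
        mask = self.atoms.atom_name == "CA"
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        return np.asarray(self.atoms.coord[mask], dtype=float)

    def residue_numbers(self, chain: str | None = None) -> np.ndarray:
        mask = self.atoms.atom_name == "CA"
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        return np.asarray(self.atoms.res_id[mask], dtype=int)

    def validate(self) -> None:
        """Check one α-carbon per residue and equal chain lengths."""
        lengths = []
        for ch in self.chain_ids:
            sel = self.atoms[self.atoms.chain_id == ch]
            res_ids = np.unique(sel.res_id)
            ca = sel[sel.atom_name == "CA"]
            if len(ca) != len(res_ids):
                raise ValueError(
                    f"chain {ch}: {len(res_ids)} residues but {len(ca)} "
                    "alpha-carbons (expect exactly one per residue)")
            lengths.append(len(res_ids))
        if len(set(lengths)) > 1:
            raise ValueError(f"unequal chain lengths: {lengths}")


def read_pdb(path: str | Path) -> StructureModel:
    """Read an ATOM/TER/END-subset PDB file.

    Raises :class:`PDBParseError` naming the 1-based line number of the
    first malformed ATOM record.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise PDBParseError(
                    f"{path.name}:{lineno}: truncated ATOM record")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise PDBParseError(
                    f"{path.name}:{lineno}: unparseable coordinate field"
                ) from exc
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    return StructureModel(atoms=atoms)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    pdb = PDBFile()
    pdb.set_structure(model.atoms)
    pdb.write(str(path))


def _ca_atom_array(chains: Sequence[np.ndarray], residues: str,
                   numbering_offset: int = 1) -> struc.AtomArray:
    n_res = len(residues)
    n = len(chains) * n_res
    arr = struc.AtomArray(n)
    coords = np.concatenate(chains, axis=0)
    arr.coord = coords.astype(np.float32)
    arr.chain_id = np.repeat([chr(ord("A") + k) for k in range(len(chains))],
                             n_res)
    arr.res_id = np.tile(np.arange(n_res) + numbering_offset, len(chains))
    arr.res_name = np.tile([THREE_LETTER[c] for c in residues], len(chains))
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.full(n, False)
    return arr


def build_ideal_pentamer(sequence: HeptadSequence,
                         params: CrickParams | None = None) -> StructureModel:
    """Deterministic ideal pentamer (α-carbon resolution) from Crick geometry.

    Chain ``k`` is chain 0 rotated by ``72°·k`` about the superhelix (z)
    axis, so the construction is exactly 5-fold symmetric.  Consecutive
    α-carbons are ~3.8 Å apart for the default parameters.
    """
    params = params or CrickParams()
    n = len(sequence)
    i = np.arange(n, dtype=float)
    omega0 = 2.0 * np.pi * params.rise_per_residue / params.superhelix_pitch
    omega1 = 2.0 * np.pi / params.residues_per_turn
    t = omega0 * i + params.superhelix_phase
    alpha = omega1 * i + params.minor_phase

    def chain(phi: float) -> np.ndarray:
        u = np.stack([np.cos(t + phi), np.sin(t + phi), np.zeros(n)], axis=1)
        axis = params.superhelix_radius * u
        axis[:, 2] = params.rise_per_residue * i
        # tangent of the superhelical curve, then the in-helix normal frame
        tang = np.stack([
            -params.superhelix_radius * omega0 * np.sin(t + phi),
            params.superhelix_radius * omega0 * np.cos(t + phi),
            np.full(n, params.rise_per_residue),
        ], axis=1)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        b = np.cross(tang, u)
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        offset = params.helix_radius * (
            -np.cos(alpha)[:, None] * u + np.sin(alpha)[:, None] * b)
        return axis + offset

    chains = [chain(2.0 * np.pi * k / 5.0) for k in range(5)]
    atoms = _ca_atom_array(chains, sequence.residues,
                           sequence.numbering_offset)
    return StructureModel(atoms=atoms, symmetry_order=5)


# ---------------------------------------------------------------------------
# multi-frame XYZ trajectories

def write_xyz_frames(path: str | Path, frames: np.ndarray | Sequence[np.ndarray],
                     names: Sequence[str] | None = None,
                     comment: str = "", decimals: int = 6) -> None:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or (frames.size and frames.shape[2] != 3):
        raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
    n_atoms = frames.shape[1] if frames.size else 0
    if names is None:
        names = ["X"] * n_atoms
    fmt = f"%s %.{decimals}f %.{decimals}f %.{decimals}f"
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{n_atoms}\n{comment}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(fmt % (name, x, y, z) + "\n")


def read_xyz_frames(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a multi-frame XYZ file -> ((n_frames, n_atoms, 3) array, names).

    All frames must share the same atom count; an empty file yields an
    empty (0, 0, 3) trajectory.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    names: list[str] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n_atoms = int(lines[pos])
        block = lines[pos + 2: pos + 2 + n_atoms]
        if len(block) < n_atoms:
            raise ValueError(f"truncated frame at line {pos + 1}")
        coords = np.empty((n_atoms, 3))
        frame_names = []
        for j, line in enumerate(block):
            parts = line.split()
            frame_names.append(parts[0])
            coords[j] = [float(v) for v in parts[1:4]]
        if frames and n_atoms != frames[0].shape[0]:
            raise ValueError(
                f"inconsistent atom count at line {pos + 1}: "
                f"{n_atoms} != {frames[0].shape[0]}")
        frames.append(coords)
        names = frame_names
        pos += 2 + n_atoms
    if not frames:
        return np.empty((0, 0, 3)), []
    return np.stack(frames), names


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {header: sequence} dict."""
    return dict(fasta_io.FastaFile.read(str(path)).items())


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    ff = fasta_io.FastaFile()
    for name, seq in sequences.items():
        ff[name] = seq
    ff.write(str(path))
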