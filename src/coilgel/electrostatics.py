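"""Surface electrostatic energies and the NEE/CEE/ΔEE_bcf statistics.

The gelation predictor ΔEE_bcf is the difference between the summed
electrostatic energies of the solvent-exposed b/c/f residues in the
N-terminal window (AA17–28, 5 residues for the Q-family register) and the
C-terminal window (AA29–54, 11 residues).

Two backends provide the per-residue energies:

* a built-in Debye–Hückel screened-Coulomb surrogate on residue α-carbon
  centroids with rule-based integer charges at pH 8 (D/E → −1, K/R → +1,
  H → 0), standing in for a Poisson–Boltzmann solver;
* externally computed per-residue energy tables (TSV interop).

Only the summed window magnitudes are consumed downstream, so the
surrogate needs to rank surface-charge patterns, not reproduce solver
absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (AMINO_ACIDS, C_WINDOW, HeptadSequence, N_WINDOW,
                           SURFACE_LABELS, StructureModel)
from .units import COULOMB_K, WATER_DIELECTRIC, debye_kappa

#: Rule-based integer side-chain charges (elementary charges) at pH 8.
CHARGE_AT_PH8 = {aa: 0.0 for aa in AMINO_ACIDS}
CHARGE_AT_PH8.update({"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": 0.0})

DELTA_CONVENTIONS = ("abs", "N-C", "C-N")


@dataclass(frozen=True)
class ChargeAssignment:
    """Per-residue net charges, indexed by residue number."""

    charges: dict[int, float]
    source: str = "rule_pH8"

    def __post_init__(self) -> None:
        vals = np.array(list(self.charges.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError("charges must be finite")

    @classmethod
    def from_sequence(cls, sequence: HeptadSequence) -> "ChargeAssignment":
        nums = sequence.residue_numbers()
        return cls({int(n): CHARGE_AT_PH8[aa]
                    for n, aa in zip(nums, sequence.residues)})


@dataclass(frozen=True)
class ElectrostaticParams:
    """Debye–Hückel medium parameters.

    ``dielectric`` is the effective medium dielectric entering as a 1/ϵ
    energy prefactor.  The screening constant κ is derived from the ionic
    strength and temperature with the fixed water dielectric, so scanning
    ``dielectric`` rescales energies without changing the screening length.
    """

    dielectric: float = WATER_DIELECTRIC
    ionic_strength: float = 0.5  # mol/L
    temperature: float = 277.0  # K

    def __post_init__(self) -> None:
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be >= 0")

    @property
    def kappa(self) -> float:
        """Inverse Debye length, Å⁻¹."""
        return debye_kappa(self.ionic_strength, self.temperature)


def screened_pair_energy(q1: float, q2: float, r: float | np.ndarray,
                         params: ElectrostaticParams) -> float | np.ndarray:
    """Screened Coulomb energy U = k q₁q₂ e^{−κr} / (ϵ r) in kJ/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be > 0")
    u = COULOMB_K * q1 * q2 * np.exp(-params.kappa * r) / (
        params.dielectric * r)
    return float(u) if u.ndim == 0 else u


def per_residue_potential(structure: StructureModel,
                          charges: ChargeAssignment,
                          params: ElectrostaticParams | None = None,
                          chain: str | None = None) -> pd.Series:
    """Per-residue screened-Coulomb interaction energies (kJ/mol).

    Residue positions are α-carbon coordinates; residue i's energy is the
    sum of its screened pair energies with every other residue, so the
    total pairwise energy equals half the sum of the per-residue values.
    """
    params = params or ElectrostaticParams()
    coords = structure.alpha_carbons(chain)
    res_ids = structure.residue_numbers(chain)
    try:
        q = np.array([charges.charges[int(n)] for n in res_ids])
    except KeyError as exc:
        raise KeyError(f"no charge defined for residue {exc.args[0]}") from exc
    return _pair_sum_energies(coords, q, res_ids, params)


def _pair_sum_energies(coords: np.ndarray, q: np.ndarray,
                       res_ids: np.ndarray,
                       params: ElectrostaticParams) -> pd.Series:
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(r, np.inf)
    u = COULOMB_K * np.outer(q, q) * np.exp(-params.kappa * r) / (
        params.dielectric * r)
    energies = u.sum(axis=1)
    out = pd.Series(0.0, index=pd.Index(np.unique(res_ids), name="residue"))
    for rid, e in zip(res_ids, energies):
        out[int(rid)] += e
    return out


def compute_ee_bcf(energies: pd.Series, sequence: HeptadSequence,
                   n_window: tuple[int, int] = N_WINDOW,
                   c_window: tuple[int, int] = C_WINDOW) -> tuple[float, float]:
    """Summed b/c/f-surface energies of the two terminal windows.

    Returns ``(NEE_bcf, CEE_bcf)`` on the magnitude scale (absolute value
    of each window sum), in the units of ``energies``.
    """
    sums = []
    for window in (n_window, c_window):
        idx = sequence.select(SURFACE_LABELS, window)
        if idx.size == 0:
            raise ValueError(
                f"no b/c/f residues inside window {window}: "
                "register misconfigured?")
        nums = idx + sequence.numbering_offset
        missing = [int(n) for n in nums if n not in energies.index]
        if missing:
            raise KeyError(f"missing energies for residues {missing}")
        sums.append(abs(float(energies.loc[nums].sum())))
    return sums[0], sums[1]


def delta_ee_bcf(nee: float, cee: float, convention: str = "abs") -> float:
    """ΔEE_bcf from the two window magnitudes.

    The default convention ``abs`` returns |CEE − NEE|, which reproduces
    the published consistency check (targets 27 and 80 ×10⁴ kJ/mol giving
    53 ×10⁴, inside the targeted 45–64 ×10⁴ band).  ``N-C`` and ``C-N``
    are signed alternatives.
    """
    if convention not in DELTA_CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "N-C":
        return nee - cee
    if convention == "C-N":
        return cee - nee
    return abs(cee - nee)


@dataclass
class ElectrostaticProfile:
    """Per-residue energies plus the derived window statistics (kJ/mol)."""

    per_residue_energy: pd.Series
    nee_bcf: float
    cee_bcf: float
    delta: float
    convention: str = "abs"

    @classmethod
    def from_energies(cls, energies: pd.Series, sequence: HeptadSequence,
                      convention: str = "abs") -> "ElectrostaticProfile":
        nee, cee = compute_ee_bcf(energies, sequence)
        return cls(energies, nee, cee,
                   delta_ee_bcf(nee, cee, convention), convention)


def read_external_potentials(path: str | Path) -> pd.Series:
    """Read a (residue_number, energy_kJ_per_mol) TSV of external energies."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue_number", "energy_kJ_per_mol"}
    if not required <= set(df.columns):
        raise ValueError(f"TSV must have columns {sorted(required)}")
    if df["residue_number"].duplicated().any():
        dups = df.loc[df["residue_number"].duplicated(), "residue_number"]
        raise ValueError(f"duplicate residue rows: {sorted(set(dups))}")
    s = pd.Series(df["energy_kJ_per_mol"].to_numpy(dtype=float),
                  index=pd.Index(df["residue_number"].astype(int),
                                 name="residue"))
    return s.sort_index()


def write_external_potentials(energies: pd.Series, path: str | Path) -> None:
    pd.DataFrame({
        "residue_number": energies.index.to_numpy(),
        "energy_kJ_per_mol": energies.to_numpy(),
    }).to_csv(path, sep="\t", index=False)
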