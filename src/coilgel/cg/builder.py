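"""Coarse-grained coiled-coil model construction.

One CG site per residue at the α-carbon.  Two families of massless virtual
sites encode anisotropic interactions:

* 10 *intra*-CC virtual sites per adjacent monomer pair, anchored midway
  between the paired sites of residues 16, 18, 21, 22, 25, 28, 31, 33, 36
  and 38 (knob-in-hole packing that keeps the pentamer together);
* *inter*-CC virtual sites at the coiled-coil ends, anchored at residues 12
  (N end) and 50 (C end), mediating end-to-end stacking within protofibrils.

Intramolecular structure is maintained by a heteroelastic network model
(HENM): harmonic bonds between all site pairs (virtual sites included)
whose mean distance lies within a 19.0 Å cutoff, with per-bond spring
constants iteratively matched to trajectory distance fluctuations.

The CG Hamiltonian has exactly four term families: HENM bonded springs,
Debye-screened Coulomb point-charge electrostatics (intermolecular),
purely repulsive WCA excluded volume (intermolecular) and bounded Gaussian
virtual-site attractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from ..structure_io import StructureModel
from ..units import COULOMB_K, KB, WATER_DIELECTRIC, debye_kappa

INTRA_ANCHOR_RESIDUES = (16, 18, 21, 22, 25, 28, 31, 33, 36, 38)
INTER_ANCHOR_RESIDUES = (12, 50)

#: Average residue masses (amu) for CG site masses.
AA_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}
DEFAULT_SITE_MASS = 110.0


class HENMConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class VirtualSite:
    """Massless site placed as a fixed linear combination of real sites."""

    kind: str                 # "intra" | "inter_n" | "inter_c"
    anchors: tuple[int, ...]  # real-site indices
    weights: tuple[float, ...]
    cc: int = 0

    def __post_init__(self) -> None:
        if len(self.anchors) != len(self.weights):
            raise ValueError("anchors and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-12:
            raise ValueError("placement weights must sum to 1")


@dataclass
class BondTable:
    """HENM bonds over extended (real + virtual) site indices."""

    i: np.ndarray
    j: np.ndarray
    k: np.ndarray   # kJ/mol/Å²
    r0: np.ndarray  # Å

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class CGTopology:
    """Sites, virtual sites and bonds of a CG system."""

    residue: np.ndarray            # residue number per real site
    monomer: np.ndarray            # monomer index within its coiled coil
    cc: np.ndarray                 # coiled-coil index per real site
    charge: np.ndarray             # e
    mass: np.ndarray               # amu
    virtual_sites: list[VirtualSite] = field(default_factory=list)
    bonds: BondTable | None = None
    #: Optional explicit list of attracting virtual-site index pairs.
    #: None means every (inter_c, inter_n) pair of distinct coiled coils
    #: attracts; fibril builders narrow this to consecutive CCs within a
    #: protofibril so the bounded well encodes end-to-end stacking only.
    attraction_pairs: list[tuple[int, int]] | None = None
    #: CC-index pairs excluded from non-bonded terms (the analog of bonded
    #: exclusions: consecutive CCs in a protofibril interact through the
    #: end-to-end well, not through excluded volume/electrostatics).
    nonbonded_exclusions: set[frozenset] | None = None

    @property
    def n_real(self) -> int:
        return len(self.residue)

    @property
    def n_virtual(self) -> int:
        return len(self.virtual_sites)

    @property
    def n_extended(self) -> int:
        return self.n_real + self.n_virtual

    def virtual_cc(self) -> np.ndarray:
        return np.array([v.cc for v in self.virtual_sites], dtype=int)

    def extension_matrix(self) -> sparse.csr_matrix:
        """Sparse J with extended = J @ real (per coordinate axis)."""
        rows, cols, vals = [], [], []
        for i in range(self.n_real):
            rows.append(i), cols.append(i), vals.append(1.0)
        for vi, v in enumerate(self.virtual_sites):
            for a, w in zip(v.anchors, v.weights):
                rows.append(self.n_real + vi), cols.append(a), vals.append(w)
        return sparse.csr_matrix((vals, (rows, cols)),
                                 shape=(self.n_extended, self.n_real))

    def extended_coords(self, x: np.ndarray) -> np.ndarray:
        J = self.extension_matrix()
        return np.asarray(J @ x)


def map_structure_to_cg(model: StructureModel, cc_index: int = 0,
                        sequence: str | None = None
                        ) -> tuple[CGTopology, np.ndarray]:
    """One CG site per residue at its α-carbon coordinate."""
    model.validate()
    coords, residue, monomer, mass = [], [], [], []
    for m, chain in enumerate(model.chain_ids):
        ca = model.alpha_carbons(chain)
        nums = model.residue_numbers(chain)
        coords.append(ca)
        residue.extend(int(n) for n in nums)
        monomer.extend([m] * len(nums))
        if sequence is not None:
            mass.extend(AA_MASS.get(aa, DEFAULT_SITE_MASS) for aa in sequence)
        else:
            mass.extend([DEFAULT_SITE_MASS] * len(nums))
    n = len(residue)
    topo = CGTopology(
        residue=np.array(residue), monomer=np.array(monomer),
        cc=np.full(n, cc_index), charge=np.zeros(n),
        mass=np.array(mass))
    return topo, np.concatenate(coords, axis=0)


def map_frames_to_cg(frames: np.ndarray) -> np.ndarray:
    """α-carbon frames are already at CG resolution; validate and pass through."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_frames, n_sites, 3)")
    return frames


def add_virtual_sites(topology: CGTopology,
                      intra_residues=INTRA_ANCHOR_RESIDUES,
                      inter_residues=INTER_ANCHOR_RESIDUES) -> CGTopology:
    """Attach intra- and inter-CC virtual-site definitions to a topology.

    Intra sites: for each cyclically adjacent monomer pair within a CC, one
    midpoint site per anchor residue.  Inter sites: one site per CC end,
    placed at the centroid of the end-anchor residue (12 at the N end, 50
    at the C end) across all monomers of the CC.
    """
    virtual: list[VirtualSite] = []
    for cc in np.unique(topology.cc):
        in_cc = np.nonzero(topology.cc == cc)[0]
        monomers = np.unique(topology.monomer[in_cc])
        index_of = {(int(topology.monomer[i]), int(topology.residue[i])): int(i)
                    for i in in_cc}
        n_mon = len(monomers)
        for mi, m in enumerate(monomers):
            m_next = monomers[(mi + 1) % n_mon]
            if n_mon < 2:
                break
            for res in intra_residues:
                try:
                    a = index_of[(int(m), res)]
                    b = index_of[(int(m_next), res)]
                except KeyError as exc:
                    raise KeyError(
                        f"anchor residue {res} missing in monomer pair "
                        f"({m}, {m_next}) of CC {cc}") from exc
                virtual.append(VirtualSite("intra", (a, b), (0.5, 0.5),
                                           cc=int(cc)))
        for res, kind in zip(inter_residues, ("inter_n", "inter_c")):
            anchors = []
            for m in monomers:
                if (int(m), res) not in index_of:
                    raise KeyError(
                        f"inter anchor residue {res} missing in monomer {m}")
                anchors.append(index_of[(int(m), res)])
            w = 1.0 / len(anchors)
            virtual.append(VirtualSite(kind, tuple(anchors),
                                       (w,) * len(anchors), cc=int(cc)))
    return replace(topology, virtual_sites=virtual)


# ---------------------------------------------------------------------------
# heteroelastic network model (fluctuation matching)

def _network_hessian(x0: np.ndarray, i: np.ndarray, j: np.ndarray,
                     k: np.ndarray) -> np.ndarray:
    """3n×3n Hessian of a harmonic distance network at its rest geometry."""
    n = len(x0)
    H = np.zeros((3 * n, 3 * n))
    d = x0[j] - x0[i]
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    for b in range(len(i)):
        block = k[b] * np.outer(u[b], u[b])
        ii, jj = i[b], j[b]
        H[3 * ii:3 * ii + 3, 3 * ii:3 * ii + 3] += block
        H[3 * jj:3 * jj + 3, 3 * jj:3 * jj + 3] += block
        H[3 * ii:3 * ii + 3, 3 * jj:3 * jj + 3] -= block
        H[3 * jj:3 * jj + 3, 3 * ii:3 * ii + 3] -= block
    return H


def model_distance_fluctuations(x0: np.ndarray, i: np.ndarray, j: np.ndarray,
                                k: np.ndarray, temperature: float
                                ) -> np.ndarray:
    """Closed-form Gaussian-network pair-distance variances (Å²)."""
    H = _network_hessian(x0, i, j, k)
    evals, evecs = np.linalg.eigh(H)
    tol = max(evals.max(), 1.0) * 1e-9
    keep = evals > tol
    inv = evecs[:, keep] / evals[keep]
    cov = inv @ evecs[:, keep].T * (KB * temperature)
    d = x0[j] - x0[i]
    u = d / np.linalg.norm(d, axis=1, keepdims=True)
    sig = np.empty(len(i))
    for b in range(len(i)):
        v = np.zeros(3 * len(x0))
        v[3 * i[b]:3 * i[b] + 3] = -u[b]
        v[3 * j[b]:3 * j[b] + 3] = u[b]
        sig[b] = v @ cov @ v
    return sig


def fit_henm(frames: np.ndarray, cutoff: float = 19.0,
             temperature: float = 277.0, tol: float = 0.01,
             max_iter: int = 500, damping: float = 0.5) -> BondTable:
    """Fit HENM spring constants by iterative fluctuation matching.

    Pairs whose trajectory-mean distance is within ``cutoff`` become bonds
    with rest length equal to the trajectory-mean distance.  Spring
    constants are updated multiplicatively,
    ``k ← k · (σ²_model/σ²_traj)^damping``, until the Gaussian-network
    closed-form fluctuations match the trajectory fluctuations within
    ``tol`` (max relative deviation).  Raises
    :class:`HENMConvergenceError` with the residual on failure.
    """
    frames = map_frames_to_cg(frames)
    n = frames.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    dists = np.linalg.norm(frames[:, ju] - frames[:, iu], axis=2)
    mean_d = dists.mean(axis=0)
    within = mean_d <= cutoff
    i, j = iu[within], ju[within]
    if i.size == 0:
        raise ValueError("no pairs within cutoff")
    r0 = mean_d[within]
    sig_traj = dists.var(axis=0)[within]
    if np.any(sig_traj <= 0):
        raise ValueError("zero distance fluctuation: trajectory too short")
    x0 = frames.mean(axis=0)
    k = KB * temperature / sig_traj
    residual = np.inf
    for _ in range(max_iter):
        sig_model = model_distance_fluctuations(x0, i, j, k, temperature)
        ratio = sig_model / sig_traj
        residual = float(np.abs(ratio - 1.0).max())
        if residual < tol:
            return BondTable(i=i, j=j, k=k, r0=r0)
        k = k * (sig_model / sig_traj) ** damping
    raise HENMConvergenceError(
        f"fluctuation matching did not converge in {max_iter} iterations "
        f"(max relative residual {residual:.3g})")


def augmented_frames(topology: CGTopology, frames: np.ndarray) -> np.ndarray:
    """Append virtual-site positions to real-site frames."""
    J = topology.extension_matrix().toarray()
    return np.einsum("er,fri->fei", J, map_frames_to_cg(frames))


# ---------------------------------------------------------------------------
# Hamiltonian

@dataclass(frozen=True)
class HamiltonianParams:
    """Parameters of the non-bonded term families.

    ``sigma``/``eps_rep`` set the WCA purely repulsive excluded volume;
    ``attraction_depth``/``attraction_width``/``attraction_r0`` set the
    bounded Gaussian well between inter-CC virtual sites; κ for the
    screened Coulomb term derives from the ionic strength and temperature
    at the fixed water dielectric, so the medium dielectric ϵ acts purely
    as a 1/ϵ prefactor.
    """

    sigma: float = 4.0                 # Å
    eps_rep: float = 2.0               # kJ/mol
    attraction_depth: float = 8.0      # kJ/mol
    attraction_width: float = 1.5      # Å
    attraction_r0: float = 6.0         # Å
    elec_cutoff: float = 30.0          # Å
    ionic_strength: float = 0.5        # mol/L
    temperature: float = 277.0         # K

    @property
    def kappa(self) -> float:
        return debye_kappa(self.ionic_strength, self.temperature)


@dataclass
class HamiltonianSpec:
    """The four term families of the CG Hamiltonian."""

    bonds: BondTable
    dielectric: float
    params: HamiltonianParams


class Hamiltonian:
    """Energy/force evaluator for a CG system.

    Non-bonded terms (electrostatics, excluded volume) act only between
    sites of *different* coiled coils; intramolecular structure is entirely
    HENM springs.  Virtual sites are massless geometry followers: their
    forces are redistributed to anchors through the placement weights.
    """

    def __init__(self, topology: CGTopology, dielectric: float,
                 params: HamiltonianParams | None = None) -> None:
        if topology.bonds is None:
            raise ValueError("topology has no HENM bonds: fit or assign first")
        self.topology = topology
        self.dielectric = float(dielectric)
        self.params = params or HamiltonianParams()
        self.spec = HamiltonianSpec(topology.bonds, self.dielectric,
                                    self.params)
        self._J = topology.extension_matrix()
        n = topology.n_real
        # intermolecular real-site pairs
        iu, ju = np.triu_indices(n, k=1)
        inter = topology.cc[iu] != topology.cc[ju]
        if topology.nonbonded_exclusions:
            excl = topology.nonbonded_exclusions
            cci, ccj = topology.cc[iu], topology.cc[ju]
            keep = np.array([frozenset((int(a), int(b))) not in excl
                             for a, b in zip(cci, ccj)])
            inter &= keep
        self._nb_i, self._nb_j = iu[inter], ju[inter]
        self._qq = (topology.charge[self._nb_i]
                    * topology.charge[self._nb_j]) * COULOMB_K / self.dielectric
        # attraction pairs: inter_c of one CC with inter_n of another
        if topology.attraction_pairs is not None:
            pairs = [(n + a, n + b) for a, b in topology.attraction_pairs]
        else:
            vcc = topology.virtual_cc()
            kinds = [v.kind for v in topology.virtual_sites]
            c_idx = [vi for vi, kk in enumerate(kinds) if kk == "inter_c"]
            n_idx = [vi for vi, kk in enumerate(kinds) if kk == "inter_n"]
            pairs = [(n + a, n + b) for a in c_idx for b in n_idx
                     if vcc[a] != vcc[b]]
        self._attr = (np.array([p[0] for p in pairs], dtype=int),
                      np.array([p[1] for p in pairs], dtype=int))
        self._kappa = self.params.kappa
        rc = self.params.elec_cutoff
        self._elec_shift = np.exp(-self._kappa * rc) / rc
        self._JT = self._J.T.tocsr()

    # -- term evaluators -----------------------------------------------------
    def _pair_terms(self, xe: np.ndarray):
        """Yield (i, j, energy, dU/dr, r, diff) for each term family."""
        p = self.params
        terms = []
        b = self.topology.bonds
        if len(b):
            diff = xe[b.j] - xe[b.i]
            d = np.sqrt((diff * diff).sum(axis=1))
            stretch = d - b.r0
            terms.append((b.i, b.j, 0.5 * b.k * stretch**2, b.k * stretch,
                          d, diff))
        if len(self._nb_i):
            i, j = self._nb_i, self._nb_j
            diff = xe[j] - xe[i]
            r = np.sqrt((diff * diff).sum(axis=1))
            e = np.zeros_like(r)
            de = np.zeros_like(r)
            # screened Coulomb, energy-shifted at the cutoff
            inside = np.nonzero(r < p.elec_cutoff)[0]
            if inside.size:
                ri = r[inside]
                expf = np.exp(-self._kappa * ri)
                qq = self._qq[inside]
                e[inside] = qq * (expf / ri - self._elec_shift)
                de[inside] = -qq * expf * (self._kappa * ri + 1.0) / ri**2
            # WCA purely repulsive
            rmin = p.sigma * 2.0 ** (1.0 / 6.0)
            core = np.nonzero(r < rmin)[0]
            if core.size:
                rc = np.maximum(r[core], 1e-6)
                sr6 = (p.sigma / rc)**6
                e[core] += 4.0 * p.eps_rep * (sr6**2 - sr6) + p.eps_rep
                de[core] += 4.0 * p.eps_rep * (-12.0 * sr6**2 + 6.0 * sr6) / rc
            terms.append((i, j, e, de, r, diff))
        ai, aj = self._attr
        if len(ai) and p.attraction_depth > 0:
            diff = xe[aj] - xe[ai]
            r = np.sqrt((diff * diff).sum(axis=1))
            z = (r - p.attraction_r0) / p.attraction_width
            e = -p.attraction_depth * np.exp(-0.5 * z**2)
            de = -e * z / p.attraction_width
            terms.append((ai, aj, e, de, r, diff))
        return terms

    def energy(self, x: np.ndarray) -> float:
        return self.energy_forces(x)[0]

    def energy_forces(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        xe = np.asarray(self._J @ x)
        total = 0.0
        n_ext = len(xe)
        grad_e = np.zeros_like(xe)
        for i, j, e, dudr, r, diff in self._pair_terms(xe):
            total += float(e.sum())
            g = (dudr / r)[:, None] * diff
            for c in range(3):
                grad_e[:, c] += np.bincount(j, weights=g[:, c],
                                            minlength=n_ext)
                grad_e[:, c] -= np.bincount(i, weights=g[:, c],
                                            minlength=n_ext)
        grad = np.asarray(self._JT @ grad_e)
        return total, -grad

    def energy_terms(self, x: np.ndarray) -> dict[str, float]:
        x = np.asarray(x, dtype=float).reshape(-1, 3)
        xe = np.asarray(self._J @ x)
        names = iter(["bonded", "nonbonded", "attraction"])
        return {next(names): float(e.sum())
                for _, _, e, _, _, _ in self._pair_terms(xe)}


def assemble_hamiltonian(topology: CGTopology, dielectric: float,
                         params: HamiltonianParams | None = None
                         ) -> Hamiltonian:
    """Build the four-term CG Hamiltonian evaluator."""
    return Hamiltonian(topology, dielectric, params)
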