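"""Metropolis Monte-Carlo mutational search for coiled-coil variants.

Single-point mutations are proposed at core/flank heptad positions
(a, d, e, g by default) and accepted with Metropolis probabilities

* score criterion:  P = min(1, exp(−C_score · ΔRS)), ΔRS the change in a
  stability score in J/mol (lower is more stable; published constant
  C = 3.93×10⁻⁵ mol/J);
* electrostatic-target criteria: P = min(1, exp(−C · Δ|EE − EE*|)) for the
  N- and C-terminal surface energies (C = 1.31×10⁻⁴ and 1.96×10⁻⁴ mol/J).

The trimodal search combines the three criteria as the product of their
acceptance probabilities.  Restart-best sequences are aggregated into a
position-probability matrix whose per-column argmax is the consensus.

The built-in stability scorer is a deterministic, additive
helix-propensity + heptad-compatibility surrogate standing in for an
external structure-based score; additivity makes small search landscapes
exhaustively enumerable in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .electrostatics import (CHARGE_AT_PH8, ElectrostaticParams,
                             compute_ee_bcf)
from .structure_io import (AMINO_ACIDS, HeptadSequence, StructureModel,
                           build_ideal_pentamer)
from .units import KB

GAS_CONSTANT = KB * 1000.0  # J/(mol K)

#: Helix propensities, kcal/mol relative to alanine (higher = destabilizing).
HELIX_PROPENSITY = {
    "A": 0.0, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26, "Q": 0.39,
    "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50, "Y": 0.53, "F": 0.54,
    "H": 0.61, "V": 0.61, "N": 0.65, "T": 0.66, "C": 0.68, "D": 0.69,
    "G": 1.0, "P": 3.16,
}

_HYDROPHOBIC = set("LIVMFAW")
_POLAR = set("DEKRNQHSTY")
_CHARGED = set("DEKR")
_KCAL_TO_J = 4184.0


@dataclass(frozen=True)
class MCConfig:
    """Search hyperparameters.

    ``RT`` (J/mol) is carried for completeness — the empirical constants C
    already render the Metropolis exponents dimensionless, so RT does not
    enter the default acceptance forms.
    """

    c_score: float = 3.93e-5       # mol/J
    c_nee: float = 1.31e-4         # mol/J
    c_cee: float = 1.96e-4         # mol/J
    iterations: int = 1000
    restarts: int = 60
    mutable_labels: tuple[str, ...] = ("a", "d", "e", "g")
    temperature: float = 277.0
    exclude_residues: tuple[str, ...] = ()
    combine: str = "product"       # {"product", "all_gates"}

    def __post_init__(self) -> None:
        if min(self.c_score, self.c_nee, self.c_cee) <= 0:
            raise ValueError("acceptance constants must be > 0")
        if self.iterations < 1 or self.restarts < 1:
            raise ValueError("iterations and restarts must be >= 1")
        if not self.mutable_labels:
            raise ValueError("mutable positions must be non-empty")
        if self.combine not in ("product", "all_gates"):
            raise ValueError(f"unknown combine rule {self.combine!r}")

    @property
    def rt(self) -> float:
        """Gas constant × temperature, J/mol."""
        return GAS_CONSTANT * self.temperature


def acceptance_probability_score(delta_rs: float, c_score: float) -> float:
    """P = min(1, exp(−C·ΔRS)); improving moves (ΔRS ≤ 0) are certain."""
    if c_score <= 0:
        raise ValueError("c_score must be > 0")
    if delta_rs <= 0:
        return 1.0
    return float(np.exp(-min(c_score * delta_rs, 700.0)))


def acceptance_probability_ee(delta_distance: float, c_ee: float) -> float:
    """P = min(1, exp(−C·Δ|EE − EE*|)); target-approaching moves are certain."""
    if c_ee <= 0:
        raise ValueError("c_ee must be > 0")
    if delta_distance <= 0:
        return 1.0
    return float(np.exp(-min(c_ee * delta_distance, 700.0)))


def propose_mutation(seq: HeptadSequence, rng: np.random.Generator,
                     mutable_labels: Iterable[str] = ("a", "d", "e", "g"),
                     exclude_residues: Iterable[str] = ()) -> HeptadSequence:
    """Mutate one uniformly chosen mutable position to a uniform alternative."""
    idx = seq.select(mutable_labels)
    if idx.size == 0:
        raise ValueError("sequence has no mutable positions")
    pos = int(rng.choice(idx))
    current = seq.residues[pos]
    alternatives = [aa for aa in AMINO_ACIDS
                    if aa != current and aa not in set(exclude_residues)]
    new = alternatives[int(rng.integers(len(alternatives)))]
    return seq.mutated(pos, new)


def surrogate_score(seq: HeptadSequence) -> float:
    """Deterministic additive stability score in J/mol (lower = more stable)."""
    return sum(_position_term(aa, lab)
               for aa, lab in zip(seq.residues, seq.register))


def _position_term(aa: str, label: str) -> float:
    term = HELIX_PROPENSITY[aa]
    if label in "ad":
        term += -0.5 if aa in _HYDROPHOBIC else (0.5 if aa in _POLAR else 0.0)
    elif label in "eg":
        term += -0.3 if aa in _CHARGED else 0.0
    else:  # surface b/c/f: mild preference for polar residues
        term += -0.1 if aa in _POLAR else 0.0
    return term * _KCAL_TO_J


class PentamerEEEvaluator:
    """NEE/CEE evaluator on a fixed pentamer geometry.

    Distances are precomputed from the structure (default: the ideal
    pentamer of the initial sequence); only charges change per candidate
    sequence, so each evaluation is a vectorized pair sum.
    """

    def __init__(self, template: HeptadSequence,
                 structure: StructureModel | None = None,
                 params: ElectrostaticParams | None = None,
                 scale: float = 1.0) -> None:
        structure = structure or build_ideal_pentamer(template)
        self.params = params or ElectrostaticParams()
        self.scale = scale
        coords = structure.alpha_carbons()
        self.res_ids = structure.residue_numbers()
        r = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(r, np.inf)
        from .units import COULOMB_K
        self._weights = (COULOMB_K * np.exp(-self.params.kappa * r)
                         / (self.params.dielectric * r))
        self._template = template

    def __call__(self, seq: HeptadSequence) -> tuple[float, float]:
        charge_by_res = {int(n): CHARGE_AT_PH8[aa]
                         for n, aa in zip(seq.residue_numbers(), seq.residues)}
        q = np.array([charge_by_res[int(n)] for n in self.res_ids])
        site_e = (self._weights * q[None, :]).sum(axis=1) * q
        energies = pd.Series(site_e).groupby(self.res_ids).sum()
        energies.index.name = "residue"
        nee, cee = compute_ee_bcf(energies * self.scale, seq)
        return nee, cee


@dataclass
class MCStep:
    restart: int
    step: int
    sequence: str
    score: float
    nee: float | None
    cee: float | None
    accepted: bool
    p_accept: float


@dataclass
class SearchTrace:
    """Full record of a Monte-Carlo search."""

    steps: list[MCStep]
    restart_best: list[tuple[str, float]]  # (sequence, score) per restart
    mode: str
    config: MCConfig

    @property
    def best(self) -> tuple[str, float]:
        """Overall best (sequence, score) across restarts."""
        return min(self.restart_best, key=lambda t: t[1])

    def best_sequences(self) -> list[str]:
        """Restart-best sequences ranked by score (best first)."""
        return [s for s, _ in sorted(self.restart_best, key=lambda t: t[1])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def run_search(initial: HeptadSequence,
               scorer: Callable[[HeptadSequence], float] | None = None,
               config: MCConfig | None = None,
               mode: str = "score_only",
               targets: tuple[float, float] | None = None,
               ee_evaluator: Callable[[HeptadSequence],
                                      tuple[float, float]] | None = None,
               seed: int | np.random.SeedSequence | None = 0) -> SearchTrace:
    """Run the restarted Metropolis search.

    ``mode="score_only"`` accepts on the stability score alone;
    ``mode="trimodal"`` additionally gates on distance to the NEE/CEE
    targets, combining criteria by probability product (or, with
    ``config.combine == "all_gates"``, by three independent Bernoulli
    gates).  Every proposal counts as one iteration; each restart begins
    from ``initial``.  The trace is reproducible from ``seed``.
    """
    config = config or MCConfig()
    scorer = scorer or surrogate_score
    if mode not in ("score_only", "trimodal"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "trimodal":
        if targets is None or ee_evaluator is None:
            raise ValueError("trimodal mode requires targets and ee_evaluator")
        nee_target, cee_target = targets
    rng = np.random.default_rng(seed)

    steps: list[MCStep] = []
    restart_best: list[tuple[str, float]] = []
    for restart in range(config.restarts):
        current = initial
        score = float(scorer(current))
        if mode == "trimodal":
            nee, cee = ee_evaluator(current)
        else:
            nee = cee = None
        best_seq, best_score = current.residues, score
        for step in range(config.iterations):
            try:
                proposal = propose_mutation(current, rng,
                                            config.mutable_labels,
                                            config.exclude_residues)
                new_score = float(scorer(proposal))
            except Exception as exc:  # scorer failure aborts with context
                raise RuntimeError(
                    f"scorer failed at restart {restart} step {step}"
                ) from exc
            p_score = acceptance_probability_score(new_score - score,
                                                   config.c_score)
            if mode == "trimodal":
                new_nee, new_cee = ee_evaluator(proposal)
                p_nee = acceptance_probability_ee(
                    abs(new_nee - nee_target) - abs(nee - nee_target),
                    config.c_nee)
                p_cee = acceptance_probability_ee(
                    abs(new_cee - cee_target) - abs(cee - cee_target),
                    config.c_cee)
                if config.combine == "product":
                    p = p_score * p_nee * p_cee
                    accepted = rng.random() < p
                else:
                    gates = [rng.random() < pi for pi in (p_score, p_nee, p_cee)]
                    p = p_score * p_nee * p_cee
                    accepted = all(gates)
            else:
                new_nee = new_cee = None
                p = p_score
                accepted = rng.random() < p
            if accepted:
                current, score = proposal, new_score
                nee, cee = new_nee, new_cee
                if score < best_score:
                    best_seq, best_score = current.residues, score
            steps.append(MCStep(restart, step, proposal.residues, new_score,
                                new_nee, new_cee, accepted, p))
        restart_best.append((best_seq, best_score))
    return SearchTrace(steps, restart_best, mode, config)


@dataclass
class ConsensusProfile:
    """Position × amino-acid probability matrix with its consensus sequence."""

    matrix: pd.DataFrame  # rows: positions, columns: amino acids, sums to 1
    consensus: str

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def build_consensus(sequences: Sequence[str]) -> ConsensusProfile:
    """Column frequencies of equal-length sequences; argmax consensus.

    Ties are broken by alphabetical amino-acid order (the matrix columns
    are alphabetical and the first maximum wins).
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    length = lengths.pop()
    counts = np.zeros((length, len(AMINO_ACIDS)))
    col = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for s in sequences:
        for i, aa in enumerate(s):
            counts[i, col[aa]] += 1
    matrix = pd.DataFrame(counts / len(sequences),
                          columns=list(AMINO_ACIDS))
    matrix.index.name = "position"
    consensus = "".join(AMINO_ACIDS[j] for j in counts.argmax(axis=1))
    return ConsensusProfile(matrix, consensus)
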