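"""Synthetic MSA + profile datasets with planted covarying site pairs.

The generator emulates the evolutionary-covariation premise the scoring
method is built on: when the residue at a domain site changes, binding is
restored by a compensating change in the bound-peptide preference, so the
domain site and the peptide position covary across the family. Each
planted pair (j, k) assigns every sequence a hidden state; the state fixes
the residue written at MSA site j and biases the PWM column k toward a
state-specific target residue. ``coupling`` interpolates between a fully
state-determined column (1.0) and the shared background column (0.0), and
``pwm_sharpness`` controls how peaked the state-specific column is.

States are assigned in balanced, shuffled blocks rather than i.i.d., so a
two-state planted site splits the family evenly (as a clean clade split
would) and its most frequent residue holds exactly half of the sequence
weight — the boundary the conservation filter keeps.

Non-planted MSA sites are drawn i.i.d. from a small per-site residue
repertoire (``background_support`` residues, consensus drawn with the
per-site conservation probability) — alignment columns of real domain
families tolerate a handful of residues, not all 20. Non-planted PWM
columns are Dirichlet draws around a shared per-site background,
independent of the sequences, so they carry no covariation signal.

A companion helper emits a minimal toy structure (single-CA residues in
PDB format) in which planted pairs sit close together and all other mapped
pairs are far apart, for exercising the structure-based evaluation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .alphabet import AMINO_ACIDS, N_RESIDUES
from .errors import GeneratorSpecError
from .io import DomainAlignment, ProfileSet, SiteMap


@dataclasses.dataclass
class PlantedPair:
    """One planted covarying (MSA site, PWM site) pair."""

    j: int
    k: int
    coupling: float = 0.9
    n_states: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling <= 1.0:
            raise GeneratorSpecError(f"coupling {self.coupling} outside [0, 1]")
        if not 2 <= self.n_states <= N_RESIDUES:
            raise GeneratorSpecError(
                f"n_states must be in [2, {N_RESIDUES}], got {self.n_states}"
            )


@dataclasses.dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a modest domain family: 30 sequences, 10 alignment
    sites, 5 peptide positions, one strongly coupled planted pair, moderate
    background conservation (0.3) and fairly peaked profile columns.
    """

    n_sequences: int = 30
    m_sites: int = 10
    w_sites: int = 5
    planted_pairs: Sequence[PlantedPair] = dataclasses.field(
        default_factory=lambda: [PlantedPair(j=3, k=2, coupling=0.9)]
    )
    background_conservation: float | Sequence[float] = 0.3
    background_support: int = 4
    pwm_sharpness: float = 8.0
    duplications: dict[int, int] | None = None  # 0-based row -> extra copies
    seed: int = 0

    def conservation_vector(self) -> np.ndarray:
        c = self.background_conservation
        if np.isscalar(c):
            vec = np.full(self.m_sites, float(c))
        else:
            vec = np.asarray(c, dtype=float)
            if vec.shape != (self.m_sites,):
                raise GeneratorSpecError(
                    "per-site conservation must have one entry per MSA site"
                )
        if np.any(vec < 0) or np.any(vec > 1):
            raise GeneratorSpecError("conservation must lie in [0, 1]")
        return vec

    def validate(self) -> None:
        if self.n_sequences < 2:
            raise GeneratorSpecError("need at least 2 sequences")
        if self.m_sites < 1 or self.w_sites < 1:
            raise GeneratorSpecError("site counts must be >= 1")
        if self.pwm_sharpness < 0:
            raise GeneratorSpecError("pwm_sharpness must be >= 0")
        if not 2 <= self.background_support <= N_RESIDUES:
            raise GeneratorSpecError(
                f"background_support must be in [2, {N_RESIDUES}]"
            )
        seen_j, seen_k = set(), set()
        cons = self.conservation_vector()
        for p in self.planted_pairs:
            if not 1 <= p.j <= self.m_sites:
                raise GeneratorSpecError(f"planted MSA site {p.j} out of bounds")
            if not 1 <= p.k <= self.w_sites:
                raise GeneratorSpecError(f"planted PWM site {p.k} out of bounds")
            if p.j in seen_j or p.k in seen_k:
                raise GeneratorSpecError(
                    "each MSA/PWM site may appear in at most one planted pair"
                )
            if cons[p.j - 1] >= 1.0:
                raise GeneratorSpecError(
                    f"conservation 1.0 at planted MSA site {p.j}: a fully "
                    "conserved site cannot covary"
                )
            seen_j.add(p.j)
            seen_k.add(p.k)
        if self.duplications:
            for idx, copies in self.duplications.items():
                if not 0 <= idx < self.n_sequences:
                    raise GeneratorSpecError(f"duplication row {idx} out of bounds")
                if copies < 1:
                    raise GeneratorSpecError("duplication count must be >= 1")


@dataclasses.dataclass
class GroundTruth:
    """What was planted, for downstream checks."""

    planted: list[PlantedPair]
    m_sites: int
    w_sites: int
    state_residues: dict[int, list[int]]  # MSA site j -> state residue codes
    target_residues: dict[int, list[int]]  # PWM site k -> per-state targets
    states: np.ndarray  # (n_base, n_planted) hidden state per sequence/pair


def _keyed_column(target: int, sharpness: float) -> np.ndarray:
    """A column peaked at ``target``: delta at infinite sharpness, uniform
    at sharpness 0."""
    if np.isinf(sharpness):
        col = np.zeros(N_RESIDUES)
        col[target] = 1.0
        return col
    col = np.full(N_RESIDUES, 1.0 / N_RESIDUES)
    col[target] += sharpness
    return col / (1.0 + sharpness)


def generate(spec: GeneratorSpec) -> tuple[DomainAlignment, ProfileSet, GroundTruth]:
    """Draw one dataset; byte-identical for identical spec + seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m, w = spec.n_sequences, spec.m_sites, spec.w_sites
    cons = spec.conservation_vector()
    planted_by_j = {p.j: p for p in spec.planted_pairs}
    planted_by_k = {p.k: p for p in spec.planted_pairs}

    # balanced hidden states per sequence for each planted pair: every state
    # holds an (almost) equal share, shuffled across rows
    def _balanced_states(n_states: int) -> np.ndarray:
        reps = -(-n // n_states)  # ceil
        pool = np.tile(np.arange(n_states), reps)[:n]
        return rng.permutation(pool)

    states = np.column_stack(
        [_balanced_states(p.n_states) for p in spec.planted_pairs]
    ) if spec.planted_pairs else np.zeros((n, 0), dtype=int)

    state_residues: dict[int, list[int]] = {}
    target_residues: dict[int, list[int]] = {}
    codes = np.empty((n, m), dtype=np.int64)
    for j in range(1, m + 1):
        if j in planted_by_j:
            p = planted_by_j[j]
            col_idx = list(spec.planted_pairs).index(p)
            res = rng.permutation(N_RESIDUES)[: p.n_states]
            state_residues[j] = [int(r) for r in res]
            codes[:, j - 1] = res[states[:, col_idx]]
        else:
            support = rng.permutation(N_RESIDUES)[: spec.background_support]
            consensus, others = support[0], support[1:]
            draw = rng.random(n)
            codes[:, j - 1] = np.where(
                draw < cons[j - 1], consensus, rng.choice(others, size=n)
            )

    matrices = np.empty((n, w, N_RESIDUES))
    for k in range(1, w + 1):
        background = rng.dirichlet(np.ones(N_RESIDUES))
        if k in planted_by_k:
            p = planted_by_k[k]
            col_idx = list(spec.planted_pairs).index(p)
            targets = rng.permutation(N_RESIDUES)[: p.n_states]
            target_residues[k] = [int(t) for t in targets]
            keyed = np.stack(
                [_keyed_column(int(t), spec.pwm_sharpness) for t in targets]
            )
            for i in range(n):
                matrices[i, k - 1] = (
                    p.coupling * keyed[states[i, col_idx]]
                    + (1.0 - p.coupling) * background
                )
        else:
            conc = background * N_RESIDUES * (1.0 + spec.pwm_sharpness)
            for i in range(n):
                matrices[i, k - 1] = rng.dirichlet(conc)

    ids = [f"seq{i + 1:03d}" for i in range(n)]
    rows = ["".join(AMINO_ACIDS[c] for c in codes[i]) for i in range(n)]

    if spec.duplications:
        for idx in sorted(spec.duplications):
            for c in range(spec.duplications[idx]):
                ids.append(f"{ids[idx]}_dup{c + 1}")
                rows.append(rows[idx])
                matrices = np.concatenate([matrices, matrices[idx : idx + 1]])

    alignment = DomainAlignment(ids=ids, rows=rows)
    profiles = ProfileSet(ids=list(ids), matrices=matrices)
    truth = GroundTruth(
        planted=list(spec.planted_pairs),
        m_sites=m,
        w_sites=w,
        state_residues=state_residues,
        target_residues=target_residues,
        states=states,
    )
    return alignment, profiles, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:>5d}  CA  GLY {chain:1s}{resnum:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
)


def generate_toy_structure(
    truth: GroundTruth, near: float = 4.0, far: float = 15.0
) -> tuple[str, SiteMap]:
    """Minimal PDB text + site map realizing the planted geometry.

    Domain sites become single-CA residues on chain A arranged on a ring in
    the xy-plane; non-planted peptide sites sit on the ring's axis, so they
    are essentially equidistant (the ring radius) from every domain
    residue, and a peptide site planted against domain site j sits ``near``
    Å radially inside residue j. The ring radius is grown until every
    non-planted mapped pair is at least ``far`` Å apart, keeping the
    near/far contrast sharp rather than spreading background distances.
    """
    if not near < far:
        raise GeneratorSpecError("near distance must be smaller than far")
    m, w = truth.m_sites, truth.w_sites
    planted_k_to_j = {p.k: p.j for p in truth.planted}
    angles = 2.0 * np.pi * np.arange(m) / max(m, 2)
    # smallest radius keeping a planted peptide >= far from neighbouring
    # domain residues (and the ring itself >= far from its axis)
    radius = far
    if m > 1:
        gap = 2.0 * np.sin(np.pi / m)
        while True:
            d2 = radius**2 + (radius - near) ** 2 \
                - 2.0 * radius * (radius - near) * np.cos(2.0 * np.pi / m)
            if d2 >= far**2:
                break
            radius *= 1.1
        radius = max(radius, far / gap if gap > 0 else far)

    domain_xyz = {
        j: np.array([radius * np.cos(angles[j - 1]),
                     radius * np.sin(angles[j - 1]), 0.0])
        for j in range(1, m + 1)
    }
    peptide_xyz: dict[int, np.ndarray] = {}
    for k in range(1, w + 1):
        if k in planted_k_to_j:
            j = planted_k_to_j[k]
            a = angles[j - 1]
            peptide_xyz[k] = np.array(
                [(radius - near) * np.cos(a), (radius - near) * np.sin(a), 0.0]
            )
        else:
            # on the ring axis, 1 A apart so residues stay distinct
            peptide_xyz[k] = np.array([0.0, 0.0, float(k)])

    lines = []
    serial = 0
    domain_map: dict[int, tuple[str, int]] = {}
    peptide_map: dict[int, tuple[str, int]] = {}
    for j in range(1, m + 1):
        serial += 1
        x, y, z = domain_xyz[j]
        lines.append(
            _PDB_ATOM.format(serial=serial, chain="A", resnum=j, x=x, y=y, z=z)
        )
        domain_map[j] = ("A", j)
    for k in range(1, w + 1):
        serial += 1
        x, y, z = peptide_xyz[k]
        lines.append(
            _PDB_ATOM.format(serial=serial, chain="B", resnum=k, x=x, y=y, z=z)
        )
        peptide_map[k] = ("B", k)
    lines.append("END\n")
    return "".join(lines), SiteMap(domain_map=domain_map, peptide_map=peptide_map)
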