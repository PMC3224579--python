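"""Readers and writers for all external representations.

Formats handled here:

* aligned FASTA for the domain MSA (gap ``-``; ``.`` accepted as an alias),
* a multi-PWM text container: per-domain blocks introduced by ``>id`` lines
  followed by a whitespace-delimited probability table with a residue
  header, in either orientation (residues as rows or as columns),
* two-column TSV for explicit sequence weights (parsed in
  :mod:`sdrcov.weighting`),
* a three-column TSV site map (role, site index, chain:resnum),
* coordinates in PDB format (heavy atoms only, via Biopython).

Site indices are 1-based in every file and report.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

from .alphabet import (
    AA_TO_INDEX,
    AMINO_ACIDS,
    GAP,
    GAP_ALIASES,
    GAP_CODE,
    N_RESIDUES,
)
from .errors import AlignmentError, MappingError, ProfileError

_AA_SET = set(AMINO_ACIDS)

#: per-site probability sums farther than this from 1 are rejected
PROFILE_SUM_TOLERANCE = 1e-3


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DomainAlignment:
    """A multiple sequence alignment of peptide-recognition domains.

    ``rows`` are aligned strings over the 20 canonical amino acids plus the
    gap character; ``ids`` are unique, non-empty identifiers in row order.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        m = len(self.rows[0])
        if m < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if not sid:
                raise AlignmentError("empty sequence identifier")
            if len(row) != m:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(row)}, expected {m}"
                )
            for pos, c in enumerate(row, start=1):
                if c not in _AA_SET and c != GAP:
                    raise AlignmentError(
                        f"illegal character {c!r} in sequence {sid!r} "
                        f"at column {pos}"
                    )
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            dup = next(s for s in self.ids if s in seen or seen.add(s))
            raise AlignmentError(f"duplicate sequence identifier {dup!r}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def m(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """(n, m) int array of residue indices; gaps are ``GAP_CODE``."""
        out = np.empty((self.n, self.m), dtype=np.int64)
        for i, row in enumerate(self.rows):
            out[i] = [GAP_CODE if c == GAP else AA_TO_INDEX[c] for c in row]
        return out

    def column(self, j: int) -> str:
        """Alignment column at 1-based site index ``j``."""
        if not 1 <= j <= self.m:
            raise AlignmentError(f"site index {j} outside [1, {self.m}]")
        return "".join(row[j - 1] for row in self.rows)

    def subset(self, indices: Sequence[int]) -> "DomainAlignment":
        """New alignment keeping the given 0-based row indices, in order."""
        return DomainAlignment(
            ids=[self.ids[i] for i in indices],
            rows=[self.rows[i] for i in indices],
        )


@dataclasses.dataclass
class ProfileSet:
    """One aligned PWM per domain, row-aligned to a :class:`DomainAlignment`.

    ``matrices`` has shape (n, w, 20); ``matrices[i, k]`` is the probability
    distribution over residues at peptide position ``k`` of domain ``i``'s
    binding profile. Optional ``site_labels`` carry display names such as
    ``-1`` or ``P+2``.
    """

    ids: list[str]
    matrices: np.ndarray
    site_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[2] != N_RESIDUES:
            raise ProfileError(
                f"profile array must be (n, w, {N_RESIDUES}), "
                f"got {self.matrices.shape}"
            )
        if self.matrices.shape[0] != len(self.ids):
            raise ProfileError("number of PWMs does not match number of ids")
        if np.any(self.matrices < 0):
            raise ProfileError("negative probability in PWM")
        sums = self.matrices.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = np.argwhere(np.abs(sums - 1.0) > 1e-6)[0]
            raise ProfileError(
                f"PWM site does not sum to 1 (id {self.ids[bad[0]]!r}, "
                f"site {bad[1] + 1}, sum {sums[tuple(bad)]:.6g})"
            )
        if self.site_labels is not None and len(self.site_labels) != self.w:
            raise ProfileError("site_labels length does not match site count")

    @property
    def n(self) -> int:
        return self.matrices.shape[0]

    @property
    def w(self) -> int:
        return self.matrices.shape[1]

    def labels(self) -> list[str]:
        return self.site_labels or [str(k) for k in range(1, self.w + 1)]

    def subset(self, indices: Sequence[int]) -> "ProfileSet":
        return ProfileSet(
            ids=[self.ids[i] for i in indices],
            matrices=self.matrices[list(indices)].copy(),
            site_labels=self.site_labels,
        )


@dataclasses.dataclass
class SiteMap:
    """Mapping between analysis site indices and structure residues.

    ``domain_map`` sends 1-based MSA site indices to ``(chain, resnum)``;
    ``peptide_map`` does the same for PWM sites.
    """

    domain_map: dict[int, tuple[str, int]]
    peptide_map: dict[int, tuple[str, int]]

    def __post_init__(self) -> None:
        for name, mp in (("domain", self.domain_map), ("peptide", self.peptide_map)):
            for j in mp:
                if j < 1:
                    raise MappingError(f"{name} site index {j} must be >= 1")
            if len(set(mp.values())) != len(mp):
                raise MappingError(
                    f"a structure residue appears twice in the {name} map"
                )

    def validate_bounds(self, m: int, w: int) -> None:
        for j in self.domain_map:
            if j > m:
                raise MappingError(f"domain site {j} outside [1, {m}]")
        for k in self.peptide_map:
            if k > w:
                raise MappingError(f"peptide site {k} outside [1, {w}]")


@dataclasses.dataclass
class Residue:
    """Heavy atoms of one structure residue."""

    chain: str
    resnum: int
    name: str
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3)


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------


def read_alignment(path: str | Path) -> DomainAlignment:
    """Read an aligned FASTA file into a :class:`DomainAlignment`.

    Lowercase residues are upper-cased and ``.`` gaps normalized to ``-``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = []
    for r in records:
        seq = str(r.seq).upper()
        seq = "".join(GAP if c in GAP_ALIASES else c for c in seq)
        rows.append(seq)
    return DomainAlignment(ids=ids, rows=rows)


def write_alignment(path: str | Path, alignment: DomainAlignment) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


# ---------------------------------------------------------------------------
# PWM container I/O
# ---------------------------------------------------------------------------


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _parse_block(block_id: str, lines: list[list[str]]) -> tuple[np.ndarray, list[str] | None]:
    """Parse one PWM block into a (w, 20) matrix plus optional site labels.

    Orientation is auto-detected from the residue header: a header row made
    of the 20 one-letter codes means sites-as-rows; residue letters leading
    each data row means sites-as-columns.
    """
    if not lines:
        raise ProfileError(f"empty PWM block for id {block_id!r}")
    header = lines[0]
    header_res = [t for t in header if t in _AA_SET and len(t) == 1]

    if len(header_res) == N_RESIDUES:
        # residues across the columns, one row per site
        res_order = [t for t in header if t in _AA_SET and len(t) == 1]
        cols = [AA_TO_INDEX[r] for r in res_order]
        site_labels: list[str] = []
        rows = []
        for ln in lines[1:]:
            if len(ln) == N_RESIDUES + 1 and not _is_number(ln[0]):
                site_labels.append(ln[0])
                vals = ln[1:]
            elif len(ln) == N_RESIDUES + 1:
                site_labels.append(ln[0])
                vals = ln[1:]
            elif len(ln) == N_RESIDUES:
                vals = ln
            else:
                raise ProfileError(
                    f"PWM block {block_id!r}: row with {len(ln)} fields, "
                    f"expected {N_RESIDUES} or {N_RESIDUES + 1}"
                )
            row = np.empty(N_RESIDUES)
            for c, v in zip(cols, vals):
                row[c] = float(v)
            rows.append(row)
        if not rows:
            raise ProfileError(f"PWM block {block_id!r} has a header but no sites")
        mat = np.vstack(rows)
        return mat, (site_labels if len(site_labels) == len(rows) else None)

    # residues down the rows: optional label header, then 20 residue rows
    data_lines = lines
    site_labels = None
    if header and header[0] not in _AA_SET or (header and len(header[0]) > 1):
        site_labels = header[1:] if not _is_number(header[0]) else header
        data_lines = lines[1:]
    elif header and header[0] in _AA_SET and not all(_is_number(t) for t in header[1:]):
        raise ProfileError(f"PWM block {block_id!r}: cannot parse header row")

    by_res: dict[int, np.ndarray] = {}
    w = None
    for ln in data_lines:
        if not ln:
            continue
        res = ln[0]
        if res not in _AA_SET or len(res) != 1:
            raise ProfileError(
                f"PWM block {block_id!r}: expected a residue letter, got {res!r}"
            )
        vals = np.array([float(v) for v in ln[1:]])
        if w is None:
            w = vals.size
        elif vals.size != w:
            raise ProfileError(
                f"PWM block {block_id!r}: ragged table at residue {res}"
            )
        by_res[AA_TO_INDEX[res]] = vals
    if len(by_res) != N_RESIDUES:
        missing = sorted(set(range(N_RESIDUES)) - set(by_res))
        raise ProfileError(
            f"PWM block {block_id!r}: missing residue rows "
            f"{''.join(AMINO_ACIDS[i] for i in missing)}"
        )
    mat = np.vstack([by_res[i] for i in range(N_RESIDUES)]).T  # (w, 20)
    if site_labels is not None and len(site_labels) != mat.shape[0]:
        site_labels = None
    return mat, site_labels


def read_profiles(path: str | Path, ids: Iterable[str] | None = None) -> ProfileSet:
    """Read the multi-PWM block container.

    Per-site probabilities whose sum deviates from 1 by at most
    ``PROFILE_SUM_TOLERANCE`` are renormalized; larger deviations are
    rejected. When ``ids`` is given the blocks are matched and re-ordered
    against it, and absent ids are an error.
    """
    blocks: dict[str, list[list[str]]] = {}
    order: list[str] = []
    current: list[list[str]] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                bid = line[1:].split()[0]
                if bid in blocks:
                    raise ProfileError(f"duplicate PWM block id {bid!r}")
                current = []
                blocks[bid] = current
                order.append(bid)
            else:
                if current is None:
                    raise ProfileError(f"data before first '>' header in {path}")
                current.append(line.split())
    if not blocks:
        raise ProfileError(f"no PWM blocks in {path}")

    wanted = list(ids) if ids is not None else order
    missing = [i for i in wanted if i not in blocks]
    if missing:
        raise ProfileError(f"PWM file lacks blocks for ids: {', '.join(missing)}")

    mats = []
    labels = None
    w = None
    for bid in wanted:
        mat, blabels = _parse_block(bid, blocks[bid])
        if np.any(mat < 0):
            raise ProfileError(f"negative probability in PWM block {bid!r}")
        sums = mat.sum(axis=1)
        bad = np.abs(sums - 1.0) > PROFILE_SUM_TOLERANCE
        if np.any(bad):
            k = int(np.argmax(bad))
            raise ProfileError(
                f"PWM block {bid!r} site {k + 1} sums to {sums[k]:.6g}; "
                f"outside tolerance {PROFILE_SUM_TOLERANCE}"
            )
        mat = mat / sums[:, None]
        if w is None:
            w = mat.shape[0]
        elif mat.shape[0] != w:
            raise ProfileError(
                f"PWM block {bid!r} has {mat.shape[0]} sites, expected {w}"
            )
        if labels is None and blabels is not None:
            labels = blabels
        mats.append(mat)
    return ProfileSet(ids=wanted, matrices=np.stack(mats), site_labels=labels)


def write_profiles(path: str | Path, profiles: ProfileSet, precision: int = 10) -> None:
    """Write the residues-as-rows block format read by :func:`read_profiles`."""
    labels = profiles.labels()
    with open(path, "w") as fh:
        for i, pid in enumerate(profiles.ids):
            fh.write(f">{pid}\n")
            fh.write("site\t" + "\t".join(labels) + "\n")
            for r, aa in enumerate(AMINO_ACIDS):
                vals = "\t".join(
                    f"{profiles.matrices[i, k, r]:.{precision}g}"
                    for k in range(profiles.w)
                )
                fh.write(f"{aa}\t{vals}\n")


# ---------------------------------------------------------------------------
# site maps and structures
# ---------------------------------------------------------------------------


def _parse_residue_ref(tok: str) -> tuple[str, int]:
    if ":" not in tok:
        raise MappingError(f"residue reference {tok!r} is not chain:resnum")
    chain, _, num = tok.partition(":")
    if not chain:
        raise MappingError(f"residue reference {tok!r} has an empty chain")
    try:
        return chain, int(num)
    except ValueError as exc:
        raise MappingError(f"residue number in {tok!r} is not an integer") from exc


def read_site_map(path: str | Path) -> SiteMap:
    """Read the site-map TSV: columns role (domain|peptide), site, chain:resnum."""
    domain: dict[int, tuple[str, int]] = {}
    peptide: dict[int, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MappingError(
                    f"{path}:{lineno}: expected 3 fields, got {len(parts)}"
                )
            role, site_s, ref = parts
            try:
                site = int(site_s)
            except ValueError as exc:
                raise MappingError(
                    f"{path}:{lineno}: site index {site_s!r} is not an integer"
                ) from exc
            target = {"domain": domain, "peptide": peptide}.get(role.lower())
            if target is None:
                raise MappingError(
                    f"{path}:{lineno}: role must be 'domain' or 'peptide', "
                    f"got {role!r}"
                )
            if site in target:
                raise MappingError(f"{path}:{lineno}: duplicate {role} site {site}")
            target[site] = _parse_residue_ref(ref)
    return SiteMap(domain_map=domain, peptide_map=peptide)


def write_site_map(path: str | Path, site_map: SiteMap) -> None:
    with open(path, "w") as fh:
        fh.write("# role\tsite\tresidue\n")
        for j, (chain, num) in sorted(site_map.domain_map.items()):
            fh.write(f"domain\t{j}\t{chain}:{num}\n")
        for k, (chain, num) in sorted(site_map.peptide_map.items()):
            fh.write(f"peptide\t{k}\t{chain}:{num}\n")


def read_structure(path: str | Path) -> dict[tuple[str, int], Residue]:
    """Read heavy-atom coordinates from a PDB file, grouped by residue.

    Hydrogens are dropped; for disordered atoms the highest-occupancy
    conformer (Biopython's selected child, ties favouring altloc 'A') is
    used.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure("s", str(path))[0]
    out: dict[tuple[str, int], Residue] = {}
    for chain in model:
        for res in chain:
            names, elements, coords = [], [], []
            for atom in res.get_atoms():  # selected altloc for disordered
                element = (atom.element or "").strip().upper()
                if element in ("H", "D"):
                    continue
                names.append(atom.get_name())
                elements.append(element or atom.get_name()[0].upper())
                coords.append(atom.get_coord())
            if not coords:
                continue
            key = (chain.id, res.id[1])
            out[key] = Residue(
                chain=chain.id,
                resnum=res.id[1],
                name=res.get_resname(),
                atom_names=names,
                elements=elements,
                coords=np.asarray(coords, dtype=float),
            )
    return out


def read_structure_distances_input(
    path: str | Path, map_path: str | Path
) -> tuple[dict[tuple[str, int], Residue], SiteMap]:
    """Load a coordinate file plus its site map and cross-validate them."""
    structure = read_structure(path)
    site_map = read_site_map(map_path)
    for role, mp in (
        ("domain", site_map.domain_map),
        ("peptide", site_map.peptide_map),
    ):
        for site, (chain, num) in mp.items():
            if (chain, num) not in structure:
                raise MappingError(
                    f"{role} site {site} maps to residue {chain}:{num}, "
                    f"which is absent from the structure"
                )
    return structure, site_map
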