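"""Read, clean, conventionalize, transform and write PDB structures.

Structures are held in a deliberately small object model (Atom / Residue /
Complex) indexed by author chain ID and residue number.  Reading goes
through gemmi; writing emits fixed-column ATOM records directly.

The pipeline works on TCR-pMHC complexes under the benchmark chain
convention: MHC chains ``A`` and ``B`` (for MHC class I, ``B`` is the
beta-2-microglobulin chain), peptide ``C``, TCR alpha ``D`` and TCR beta
``E``.  ``apply_convention`` relabels arbitrary author chain IDs into this
scheme; ``clean`` strips solvent, small molecules, hydrogens and disorder
the way structures are prepared before docking.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import EmptyStructureError, MappingError, MissingChainError
from .geometry import RigidTransform

ROLES = ("mhc_a", "mhc_b", "peptide", "tcr_alpha", "tcr_beta")
CONVENTIONAL_CHAIN: dict[str, str] = {
    "mhc_a": "A",
    "mhc_b": "B",
    "peptide": "C",
    "tcr_alpha": "D",
    "tcr_beta": "E",
}
TCR_ROLES = ("tcr_alpha", "tcr_beta")
PMHC_ROLES = ("mhc_a", "mhc_b", "peptide")

#: residue names treated as solvent at clean time
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: three-letter codes accepted as polymer residues when they appear as
#: HETATM records (modified amino acids commonly kept in docking inputs)
POLYMER_HET = {"MSE", "SEC", "PYL", "CSO", "PTR", "SEP", "TPO"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    """One atom: PDB name, element symbol, position (Angstrom), occupancy, altloc."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    """One residue under author numbering; ``het`` marks HETATM provenance."""

    chain_id: str
    seq_id: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_polymer(self) -> bool:
        return self.res_name in STANDARD_AA or self.res_name in POLYMER_HET

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Complex:
    """A multi-chain structure plus a role map onto the docking convention.

    ``chains`` preserves file order; ``role_map`` assigns each biological
    role (mhc_a, mhc_b, peptide, tcr_alpha, tcr_beta) to a chain ID.
    """

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    role_map: dict[str, str] = field(default_factory=dict)

    # -- access -----------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise MissingChainError(f"{self.id}: no chain {chain_id!r}") from None

    def role_chain(self, role: str) -> list[Residue]:
        if role not in self.role_map:
            raise MissingChainError(f"{self.id}: role {role!r} not assigned")
        return self.chain(self.role_map[role])

    def residues(self) -> Iterator[Residue]:
        for res_list in self.chains.values():
            yield from res_list

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def coords(self) -> np.ndarray:
        """All atomic coordinates as an (N, 3) array, in file order."""
        return np.array([a.position for _, a in self.atoms()], dtype=float).reshape(-1, 3)

    def copy(self) -> "Complex":
        return _copy.deepcopy(self)

    def transform(self, t: RigidTransform) -> "Complex":
        """Return a copy with every atom moved by the rigid transform."""
        out = self.copy()
        for _, atom in out.atoms():
            atom.position = t.rotation @ atom.position + t.translation
        return out

    def subset(self, chain_ids: Iterable[str], new_id: str | None = None) -> "Complex":
        """Copy retaining only the given chains (role map restricted to them)."""
        keep = list(chain_ids)
        chains = {cid: _copy.deepcopy(self.chains[cid]) for cid in keep if cid in self.chains}
        role_map = {r: c for r, c in self.role_map.items() if c in chains}
        return Complex(new_id or self.id, chains, role_map)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, structure_id: str | None = None) -> Complex:
    """Parse a PDB file into a :class:`Complex` (model 1 only).

    Every ATOM/HETATM record of the first model is represented; chain order
    is preserved.  The role map is left empty — assign it (or call
    ``apply_convention``) before running role-aware operations.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinates found")
    model = st[0]

    cx = Complex(structure_id or path.stem)
    n_atoms = 0
    for g_chain in model:
        residues = cx.chains.setdefault(g_chain.name, [])
        for g_res in g_chain:
            res = Residue(
                chain_id=g_chain.name,
                seq_id=g_res.seqid.num,
                icode=g_res.seqid.icode.strip(),
                res_name=g_res.name,
                het=(g_res.het_flag == "H"),
            )
            for g_atom in g_res:
                altloc = g_atom.altloc if g_atom.altloc not in ("\x00", " ") else ""
                res.atoms.append(
                    Atom(
                        name=g_atom.name,
                        element=g_atom.element.name,
                        position=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                        occupancy=min(max(g_atom.occ, 0.0), 1.0),
                        altloc=altloc,
                    )
                )
                n_atoms += 1
            residues.append(res)
    if n_atoms == 0:
        raise EmptyStructureError(f"{path}: zero ATOM records")
    return cx


# ---------------------------------------------------------------------------
# cleaning
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: Residue) -> None:
    """Keep the highest-occupancy altloc per atom name (alphabetical on tie)."""
    by_name: dict[str, list[Atom]] = {}
    for atom in res.atoms:
        by_name.setdefault(atom.name, []).append(atom)
    kept: list[Atom] = []
    for atoms in by_name.values():
        best = min(atoms, key=lambda a: (-a.occupancy, a.altloc))
        best.altloc = ""
        kept.append(best)
    # preserve original atom order
    order = {a.name: i for i, a in enumerate(res.atoms)}
    res.atoms = sorted(kept, key=lambda a: order[a.name])


def clean(cx: Complex, keep_roles: Iterable[str] | None = None) -> Complex:
    """Prepare a structure for docking evaluation.

    Removes solvent, non-polymer heteroatoms and hydrogens; collapses
    disordered atoms to the highest-occupancy alternate location (first
    altloc alphabetically on an occupancy tie); and drops every chain not
    claimed by ``keep_roles`` — reducing the file to a single TCR-pMHC, TCR
    or pMHC when several copies were crystallised together.

    ``keep_roles=None`` keeps all roles currently in the role map.
    """
    roles = set(keep_roles) if keep_roles is not None else set(cx.role_map)
    missing = [r for r in roles if r not in cx.role_map or cx.role_map[r] not in cx.chains]
    if missing:
        raise MissingChainError(f"{cx.id}: kept role(s) map to absent chains: {sorted(missing)}")
    keep_chains = {cx.role_map[r] for r in roles}

    out = Complex(cx.id, role_map={r: cx.role_map[r] for r in roles})
    for cid, residues in cx.chains.items():
        if cid not in keep_chains:
            continue
        new_residues = []
        for res in residues:
            if res.is_water or (res.het and not res.is_polymer):
                continue
            r = _copy.deepcopy(res)
            r.atoms = [a for a in r.atoms if a.element not in ("H", "D")]
            _resolve_altlocs(r)
            if r.atoms:
                new_residues.append(r)
        if new_residues:
            out.chains[cid] = new_residues
    return out


# ---------------------------------------------------------------------------
# chain convention
# ---------------------------------------------------------------------------

def apply_convention(cx: Complex, role_map: Mapping[str, str]) -> Complex:
    """Relabel chains to the benchmark convention A/B/C/D/E.

    ``role_map`` maps each role to the *source* chain ID.  Every chain in
    the structure must be covered, and no two roles may claim the same
    source chain.  A two-phase rename makes the operation safe when source
    IDs collide with target IDs (e.g. swapped D/E chains).
    """
    sources = list(role_map.values())
    if len(set(sources)) != len(sources):
        raise MappingError(f"{cx.id}: two roles map to the same source chain")
    unknown = [r for r in role_map if r not in ROLES]
    if unknown:
        raise MappingError(f"{cx.id}: unknown role(s) {unknown}")
    missing = [c for c in sources if c not in cx.chains]
    if missing:
        raise MissingChainError(f"{cx.id}: role map names absent chain(s) {missing}")
    uncovered = [c for c in cx.chains if c not in sources]
    if uncovered:
        raise MappingError(f"{cx.id}: chains {uncovered} not covered by role map")

    target = {role_map[role]: CONVENTIONAL_CHAIN[role] for role in role_map}
    out = Complex(cx.id)
    # phase one: move to private temporary IDs so renames cannot collide
    staged: dict[str, list[Residue]] = {}
    for cid, residues in cx.chains.items():
        staged[f"\x00{target[cid]}"] = _copy.deepcopy(residues)
    # phase two: assign final IDs in conventional order
    for final in sorted(t.lstrip("\x00") for t in staged):
        residues = staged[f"\x00{final}"]
        for res in residues:
            res.chain_id = final
        out.chains[final] = residues
    out.role_map = {role: CONVENTIONAL_CHAIN[role] for role in role_map}
    return out


# ---------------------------------------------------------------------------
# random pose
# ---------------------------------------------------------------------------

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via the normalized-quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def random_pose(cx: Complex, seed: int, max_translation: float = 20.0) -> Complex:
    """Apply one uniform random rotation (about the centroid) and translation.

    Used to scrub any initial-orientation bias from docking inputs.  Each
    translation component is uniform in ``[-max_translation,
    +max_translation]`` Angstroms; internal geometry is exactly preserved.
    Deterministic for a given seed.
    """
    if max_translation <= 0:
        raise ValueError("max_translation must be positive")
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    shift = rng.uniform(-max_translation, max_translation, size=3)
    centroid = cx.coords().mean(axis=0)
    # rotate about the centroid, then translate
    t = RigidTransform(rot, centroid - rot @ centroid + shift)
    return cx.transform(t)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_name(name: str, element: str) -> str:
    # columns 13-16: 1-letter elements start in column 14
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_pdb(cx: Complex, path: str | Path) -> None:
    """Write standard fixed-column ATOM records, TER between chains, END."""
    if cx.n_atoms == 0:
        raise EmptyStructureError(f"{cx.id}: refusing to write empty structure")
    lines: list[str] = []
    serial = 0
    for cid, residues in cx.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.position
                lines.append(
                    "ATOM  {serial:>5d} {name} {res:<3s} {chain}{seq:>4d}{icode}"
                    "   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                        serial=serial,
                        name=_format_atom_name(atom.name, atom.element),
                        res=res.res_name[:3],
                        chain=cid[:1],
                        seq=res.seq_id,
                        icode=(res.icode or " ")[:1],
                        x=x, y=y, z=z,
                        occ=atom.occupancy,
                        b=0.0,
                        el=atom.element[:2],
                    )
                )
        serial += 1
        last = residues[-1]
        lines.append(
            "TER   {serial:>5d}      {res:<3s} {chain}{seq:>4d}{icode}".format(
                serial=serial, res=last.res_name[:3], chain=cid[:1],
                seq=last.seq_id, icode=(last.icode or " ")[:1],
            )
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
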