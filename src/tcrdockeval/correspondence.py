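"""Residue correspondence between structures and IMGT loop selection.

Docked models, unbound components and the bound reference of a docking case
rarely share author residue numbering.  This module pairs residues across
structures by global sequence alignment of each shared chain role, and
selects CDR loop / framework residues from IMGT numbering.

Under the IMGT scheme the three complementarity-determining loops of a TCR
variable domain occupy fixed residue ranges: CDR1 27-38, CDR2 56-65 and
CDR3 105-117; positions 1-128 span the whole variable domain.  Structures
are expected to be IMGT-numbered already (or accompanied by an explicit
numbering map); this module does not renumber.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.PDB.Polypeptide import protein_letters_3to1_extended as _3TO1

from .errors import ChainIdentityError, MissingRoleError
from .structio import Complex, Residue, TCR_ROLES


class ResidueKey(NamedTuple):
    """Hashable residue identifier: (chain_id, author seq_id, insertion code)."""

    chain_id: str
    seq_id: int
    icode: str = ""


def key_of(res: Residue) -> ResidueKey:
    return ResidueKey(res.chain_id, res.seq_id, res.icode or "")


@dataclass(frozen=True)
class LoopDefinition:
    """A CDR loop as an inclusive IMGT residue-number interval."""

    loop_id: str
    imgt_range: tuple[int, int]

    def __contains__(self, seq_id: int) -> bool:
        lo, hi = self.imgt_range
        return lo <= seq_id <= hi


CDR1 = LoopDefinition("CDR1", (27, 38))
CDR2 = LoopDefinition("CDR2", (56, 65))
CDR3 = LoopDefinition("CDR3", (105, 117))
CDR_LOOPS: dict[str, LoopDefinition] = {"CDR1": CDR1, "CDR2": CDR2, "CDR3": CDR3}
VARIABLE_DOMAIN = (1, 128)


# ---------------------------------------------------------------------------
# sequences and alignment
# ---------------------------------------------------------------------------

def sequence_of(chain: Sequence[Residue]) -> str:
    """One-letter sequence of a chain; unknown residue names become ``X``."""
    if not chain:
        raise ValueError("empty chain")
    letters = []
    for res in chain:
        one = _3TO1.get(res.res_name, "X")
        letters.append(one if len(one) == 1 else "X")
    return "".join(letters)


@dataclass(frozen=True)
class AlignmentResult:
    """Aligned index pairs of a pairwise global alignment plus summary stats.

    ``identity`` is the fraction of aligned (non-gap) columns that match;
    columns opposite a gap do not count against identity, so residues
    unresolved in one structure do not fail the identity filter.
    """

    pairs: tuple[tuple[int, int], ...]
    identity: float
    score: float


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_global(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Optimal global alignment (affine gaps); deterministic traceback.

    Among co-optimal alignments the first traceback reported by the
    aligner is taken, which is deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    # BLOSUM matrices carry 'X'; translate anything else unknown to X
    allowed = set(str(substitution_matrices.load(matrix).alphabet))
    sa = "".join(c if c in allowed else "X" for c in seq_a.upper())
    sb = "".join(c if c in allowed else "X" for c in seq_b.upper())
    aln = _aligner(matrix, gap_open, gap_extend).align(sa, sb)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            pairs.append((i, j))
            if sa[i] == sb[j]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentResult(tuple(pairs), identity, float(aln.score))


# ---------------------------------------------------------------------------
# complex-level correspondence
# ---------------------------------------------------------------------------

@dataclass
class Correspondence:
    """One-to-one residue pairing between two structures, by chain role."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    identity: dict[str, float]  # role -> fraction of matching aligned columns

    def __post_init__(self):
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("correspondence is not one-to-one")
        self._a2b = dict(self.pairs)
        self._b2a = {b: a for a, b in self.pairs}

    def to_ref(self, key: ResidueKey) -> ResidueKey | None:
        """Map an A-side (model/unbound) key to its B-side (reference) partner."""
        return self._a2b.get(key)

    def to_model(self, key: ResidueKey) -> ResidueKey | None:
        return self._b2a.get(key)

    @property
    def a_keys(self) -> set[ResidueKey]:
        return set(self._a2b)

    @property
    def b_keys(self) -> set[ResidueKey]:
        return set(self._b2a)


def identity_correspondence(cx: Complex, roles: Iterable[str] | None = None) -> Correspondence:
    """Self-correspondence (every residue paired with itself, identity 1)."""
    roles = list(roles) if roles is not None else list(cx.role_map)
    pairs = []
    for role in roles:
        for res in cx.role_chain(role):
            k = key_of(res)
            pairs.append((k, k))
    return Correspondence(pairs, {role: 1.0 for role in roles})


def map_complex(
    model: Complex,
    reference: Complex,
    min_identity: float = 0.9,
    roles: Iterable[str] | None = None,
    **align_kwargs,
) -> Correspondence:
    """Pair residues of ``model`` with ``reference`` role by role.

    Each chain role present in both structures is globally aligned and its
    residues paired at aligned (match or mismatch) columns; gap columns stay
    unpaired.  A chain pair whose identity falls below ``min_identity``
    raises :class:`ChainIdentityError` naming the role.

    ``roles`` restricts the mapping; by default all shared roles are mapped
    (so a TCR-only unbound structure maps cleanly against a full complex).
    """
    if not 0.0 < min_identity <= 1.0:
        raise ValueError("min_identity must be in (0, 1]")
    if roles is None:
        shared = [r for r in model.role_map if r in reference.role_map]
        if not shared:
            raise MissingRoleError(
                f"{model.id} and {reference.id} share no chain roles"
            )
    else:
        shared = list(roles)
        for r in shared:
            if r not in model.role_map or r not in reference.role_map:
                raise MissingRoleError(f"role {r!r} absent from one structure")

    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    identities: dict[str, float] = {}
    for role in shared:
        res_a = model.role_chain(role)
        res_b = reference.role_chain(role)
        aln = align_global(sequence_of(res_a), sequence_of(res_b), **align_kwargs)
        if aln.identity < min_identity:
            raise ChainIdentityError(role, aln.identity, min_identity)
        identities[role] = aln.identity
        for i, j in aln.pairs:
            pairs.append((key_of(res_a[i]), key_of(res_b[j])))
    return Correspondence(pairs, identities)


# ---------------------------------------------------------------------------
# IMGT selection
# ---------------------------------------------------------------------------

def _tcr_roles_or_raise(cx: Complex, roles: Iterable[str] | None) -> list[str]:
    requested = list(roles) if roles is not None else list(TCR_ROLES)
    for role in requested:
        if role not in TCR_ROLES:
            raise MissingRoleError(f"{role!r} is not a TCR role")
        if role not in cx.role_map:
            raise MissingRoleError(f"{cx.id}: role {role!r} not assigned")
    return requested


def select_cdr(
    cx: Complex,
    roles: Iterable[str] | None = None,
    loops: Iterable[LoopDefinition] | None = None,
) -> set[ResidueKey]:
    """Residues of the requested TCR chains inside the requested CDR ranges.

    Assumes IMGT numbering on the TCR variable domains.  Insertion-coded
    residues whose number falls in a loop range (e.g. 111A in CDR3) are
    included.  Empty loops are not an error.
    """
    loops = list(loops) if loops is not None else list(CDR_LOOPS.values())
    selected: set[ResidueKey] = set()
    for role in _tcr_roles_or_raise(cx, roles):
        for res in cx.role_chain(role):
            if any(res.seq_id in loop for loop in loops):
                selected.add(key_of(res))
    return selected


def select_framework(cx: Complex, roles: Iterable[str] | None = None) -> set[ResidueKey]:
    """Variable-domain residues (IMGT 1-128) outside every CDR range.

    The constant domain (IMGT > 128) is excluded so framework superposition
    is not distorted by variation in the TCR elbow angle.
    """
    lo, hi = VARIABLE_DOMAIN
    selected: set[ResidueKey] = set()
    for role in _tcr_roles_or_raise(cx, roles):
        for res in cx.role_chain(role):
            if lo <= res.seq_id <= hi and not any(
                res.seq_id in loop for loop in CDR_LOOPS.values()
            ):
                selected.add(key_of(res))
    return selected


# ---------------------------------------------------------------------------
# optional author->IMGT numbering maps
# ---------------------------------------------------------------------------

def read_numbering_map(path: str | Path) -> dict[ResidueKey, int]:
    """Read a TSV numbering map: chain, author_seq_id, icode, imgt_seq_id.

    For structures that are not already IMGT-numbered; apply with
    :func:`renumber`.
    """
    mapping: dict[ResidueKey, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{line_no}: expected 4 tab-separated fields")
        chain, seq_id, icode, imgt = fields
        mapping[ResidueKey(chain, int(seq_id), icode.strip())] = int(imgt)
    return mapping


def renumber(cx: Complex, mapping: Mapping[ResidueKey, int]) -> Complex:
    """Return a copy with author numbering replaced where the map covers it."""
    out = cx.copy()
    for res in out.residues():
        new = mapping.get(ResidueKey(res.chain_id, res.seq_id, res.icode or ""))
        if new is not None:
            res.seq_id = new
            res.icode = ""
    return out
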