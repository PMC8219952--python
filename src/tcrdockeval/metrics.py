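"""Contacts, docking scenarios, CAPRI model-quality metrics and difficulty.

The evaluation follows the CAPRI community criteria.  For a docked model
compared against the bound reference complex, with the TCR as receptor and
the pMHC as ligand:

* ``F_nat``   — fraction of the reference's receptor-ligand residue
  contacts (heavy atoms within the contact cutoff) reproduced by the model;
* ``F_non-nat`` — fraction of the model's contacts absent from the
  reference set;
* ``L-RMSD``  — backbone RMSD of the ligand after superposing the model on
  the reference receptor backbone;
* ``I-RMSD``  — backbone RMSD over the reference-defined interface residues
  after superposing on those same interface backbones.

Models are classed incorrect / acceptable / medium / high from
(F_nat, L-RMSD, I-RMSD); docking cases are classed rigid / medium /
difficult from the bound-unbound interface I-RMSD and F_non-nat.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .correspondence import (
    Correspondence,
    ResidueKey,
    key_of,
    map_complex,
    select_cdr,
)
from .errors import (
    InvalidReferenceError,
    MissingReferenceError,
    MissingStructureError,
)
from .geometry import CoordSet, kabsch, rmsd_fixed
from .structio import Complex, PMHC_ROLES, TCR_ROLES

logger = logging.getLogger(__name__)

#: backbone atom names used for all RMSD calculations
BACKBONE_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactSet:
    """Residue-residue contacts at a heavy-atom distance cutoff.

    Pairs are stored directionally as (group-A key, group-B key); for
    receptor-ligand contacts group A is the TCR and group B the pMHC.
    """

    cutoff: float
    pairs: frozenset[tuple[ResidueKey, ResidueKey]]

    def __len__(self) -> int:
        return len(self.pairs)


def _heavy_positions(
    cx: Complex, keys: Iterable[ResidueKey]
) -> tuple[list[ResidueKey], np.ndarray]:
    wanted = set(keys)
    owners: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    for res in cx.residues():
        k = key_of(res)
        if k in wanted:
            for atom in res.atoms:
                if atom.element not in ("H", "D"):
                    owners.append(k)
                    coords.append(atom.position)
    return owners, np.asarray(coords, dtype=float).reshape(-1, 3)


def contacts(
    cx: Complex,
    group_a: Iterable[ResidueKey],
    group_b: Iterable[ResidueKey],
    cutoff: float = 5.0,
) -> ContactSet:
    """All residue pairs with any heavy-atom distance strictly below cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    owners_a, xa = _heavy_positions(cx, group_a)
    owners_b, xb = _heavy_positions(cx, group_b)
    if len(xa) == 0 or len(xb) == 0:
        return ContactSet(cutoff, frozenset())
    tree = cKDTree(xb)
    pairs: set[tuple[ResidueKey, ResidueKey]] = set()
    for ia, neighbours in enumerate(tree.query_ball_point(xa, r=cutoff)):
        for ib in neighbours:
            # query_ball_point is inclusive of r; the contact rule is strict
            if np.linalg.norm(xa[ia] - xb[ib]) < cutoff:
                pairs.add((owners_a[ia], owners_b[ib]))
    return ContactSet(cutoff, frozenset(pairs))


def role_keys(cx: Complex, roles: Sequence[str]) -> set[ResidueKey]:
    """All residue keys of the chains holding the given roles."""
    out: set[ResidueKey] = set()
    for role in roles:
        out.update(key_of(r) for r in cx.role_chain(role))
    return out


def interface_contacts(cx: Complex, cutoff: float = 5.0) -> ContactSet:
    """Receptor-ligand contacts of a complex: TCR (D/E) vs pMHC (A/B/C)."""
    return contacts(cx, role_keys(cx, TCR_ROLES), role_keys(cx, PMHC_ROLES), cutoff)


# ---------------------------------------------------------------------------
# quality / difficulty vocabulary and thresholds
# ---------------------------------------------------------------------------

class QualityClass(enum.IntEnum):
    """CAPRI model quality, ordered incorrect < acceptable < medium < high."""

    INCORRECT = 0
    ACCEPTABLE = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "QualityClass":
        return cls[label.upper()]


class DifficultyClass(enum.Enum):
    RIGID = "rigid"
    MEDIUM = "medium"
    DIFFICULT = "difficult"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class CapriThresholds:
    """Cut-points of the CAPRI quality table, ordered (acceptable, medium, high)."""

    f_nat: tuple[float, float, float] = (0.1, 0.3, 0.5)
    l_rmsd: tuple[float, float, float] = (10.0, 5.0, 1.0)
    i_rmsd: tuple[float, float, float] = (4.0, 2.0, 1.0)


@dataclass(frozen=True)
class DifficultyThresholds:
    """Cut-points of the benchmark difficulty table."""

    i_rmsd_rigid: float = 1.5
    i_rmsd_difficult: float = 2.2
    f_nonnat_rigid: float = 0.4


@dataclass(frozen=True)
class ScenarioSpec:
    """Cutoffs governing interface-residue selection and metric evaluation.

    ``mhc_shell_cutoff`` (9 A) selects MHC surface residues near the peptide
    or TCR for the vague-information scenarios; ``real_interface_cutoff``
    (4.5 A) defines the true-interface selection of scenario 4.  The contact
    cutoff for F_nat (5 A) and the interface-residue cutoff for I-RMSD
    (10 A) follow CAPRI convention.
    """

    scenario: int = 1
    mhc_shell_cutoff: float = 9.0
    real_interface_cutoff: float = 4.5
    native_contact_cutoff: float = 5.0
    interface_cutoff: float = 10.0

    def __post_init__(self):
        for name in ("mhc_shell_cutoff", "real_interface_cutoff",
                     "native_contact_cutoff", "interface_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")


@dataclass(frozen=True)
class InterfaceMetrics:
    """CAPRI metrics of one model against its reference."""

    f_nat: float
    f_nonnat: float
    l_rmsd: float
    i_rmsd: float
    n_native_contacts: int = 0
    n_model_contacts: int = 0


@dataclass
class DockingCase:
    """A benchmark docking case: bound reference, unbound components, models."""

    case_id: str
    reference: Complex | None = None
    tcr_unbound: Complex | None = None
    pmhc_unbound: Complex | None = None
    metadata: dict = field(default_factory=dict)
    models: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# scenario residue selection
# ---------------------------------------------------------------------------

def _map_keys(
    keys: Iterable[ResidueKey], corr: Correspondence, direction: str
) -> set[ResidueKey]:
    convert = corr.to_model if direction == "to_model" else corr.to_ref
    out = set()
    dropped = 0
    for k in keys:
        mapped = convert(k)
        if mapped is None:
            dropped += 1
        else:
            out.add(mapped)
    if dropped:
        logger.info("dropped %d residues without correspondence", dropped)
    return out


def scenario_residues(
    case: DockingCase,
    spec: ScenarioSpec,
    min_identity: float = 0.9,
) -> tuple[set[ResidueKey], set[ResidueKey]]:
    """Interface-residue selection for one docking scenario.

    Returns ``(tcr_selection, pmhc_selection)`` as residue keys of the
    *unbound* structures (the form submitted to a docking server).

    Scenario 1: CDR loops of the unbound TCR; all peptide residues.
    Scenario 2: as 1, plus unbound MHC residues within the 9 A shell of the
    peptide.
    Scenario 3: CDR loops; pMHC residues within 9 A of the TCR in the bound
    reference, mapped back to unbound numbering.
    Scenario 4: the true interface — residues of each partner within 4.5 A
    of the other partner in the bound reference, mapped back to unbound
    numbering.
    """
    s = spec.scenario
    if case.tcr_unbound is None or case.pmhc_unbound is None:
        raise MissingStructureError(f"{case.case_id}: unbound structures required")
    if s in (3, 4) and case.reference is None:
        raise MissingReferenceError(
            f"{case.case_id}: scenario {s} needs the bound reference"
        )

    cdr_keys = select_cdr(case.tcr_unbound)
    peptide_keys = role_keys(case.pmhc_unbound, ("peptide",))

    if s == 1:
        return cdr_keys, set(peptide_keys)

    if s == 2:
        mhc_keys = role_keys(case.pmhc_unbound, ("mhc_a", "mhc_b"))
        shell = contacts(case.pmhc_unbound, mhc_keys, peptide_keys, spec.mhc_shell_cutoff)
        near = {a for a, _ in shell.pairs}
        return cdr_keys, peptide_keys | near

    ref = case.reference
    ref_tcr = role_keys(ref, TCR_ROLES)
    ref_pmhc = role_keys(ref, PMHC_ROLES)

    if s == 3:
        shell = contacts(ref, ref_pmhc, ref_tcr, spec.mhc_shell_cutoff)
        near_ref = {a for a, _ in shell.pairs}
        corr = map_complex(case.pmhc_unbound, ref, min_identity=min_identity)
        return cdr_keys, _map_keys(near_ref, corr, "to_model")

    # scenario 4: true interface at the real-interface cutoff
    true_iface = contacts(ref, ref_tcr, ref_pmhc, spec.real_interface_cutoff)
    tcr_ref = {a for a, _ in true_iface.pairs}
    pmhc_ref = {b for _, b in true_iface.pairs}
    corr_tcr = map_complex(case.tcr_unbound, ref, min_identity=min_identity)
    corr_pmhc = map_complex(case.pmhc_unbound, ref, min_identity=min_identity)
    return (
        _map_keys(tcr_ref, corr_tcr, "to_model"),
        _map_keys(pmhc_ref, corr_pmhc, "to_model"),
    )


# ---------------------------------------------------------------------------
# paired coordinate extraction
# ---------------------------------------------------------------------------

def _atom_index(cx: Complex) -> dict[ResidueKey, dict[str, np.ndarray]]:
    index: dict[ResidueKey, dict[str, np.ndarray]] = {}
    for res in cx.residues():
        index[key_of(res)] = {a.name: a.position for a in res.atoms if a.element not in ("H", "D")}
    return index


def paired_coordsets(
    model: Complex,
    reference: Complex,
    corr: Correspondence,
    ref_keys: Iterable[ResidueKey],
    atom_names: Sequence[str] | None = BACKBONE_ATOMS,
) -> tuple[CoordSet, CoordSet]:
    """Matched coordinate sets over reference residues and their model partners.

    Atoms are matched by (mapped residue, atom name); atoms missing on
    either side are dropped pairwise (a count is logged).  ``atom_names``
    of None selects all heavy atoms.
    """
    model_index = _atom_index(model)
    ref_index = _atom_index(reference)
    labels: list[tuple[ResidueKey, str]] = []
    xm: list[np.ndarray] = []
    xr: list[np.ndarray] = []
    dropped = 0
    for rk in sorted(ref_keys):
        mk = corr.to_model(rk)
        if mk is None or mk not in model_index or rk not in ref_index:
            dropped += 1
            continue
        m_atoms = model_index[mk]
        r_atoms = ref_index[rk]
        names = atom_names if atom_names is not None else sorted(r_atoms)
        for name in names:
            if name in m_atoms and name in r_atoms:
                labels.append((rk, name))
                xm.append(m_atoms[name])
                xr.append(r_atoms[name])
            else:
                dropped += 1
    if dropped:
        logger.debug("paired_coordsets: dropped %d unmatched residues/atoms", dropped)
    if not labels:
        raise InvalidReferenceError("no atoms could be paired between structures")
    return CoordSet(labels, np.array(xm)), CoordSet(labels, np.array(xr))


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def evaluate_model(
    model: Complex,
    reference: Complex,
    corr: Correspondence | None = None,
    spec: ScenarioSpec = ScenarioSpec(),
) -> InterfaceMetrics:
    """CAPRI metrics of a docked model against the bound reference.

    ``corr`` maps model residues onto reference residues; if omitted it is
    computed by global sequence alignment of each shared chain role.
    """
    if corr is None:
        corr = map_complex(model, reference)

    ref_tcr = role_keys(reference, TCR_ROLES)
    ref_pmhc = role_keys(reference, PMHC_ROLES)
    native = contacts(reference, ref_tcr, ref_pmhc, spec.native_contact_cutoff)
    if len(native) == 0:
        raise InvalidReferenceError(
            f"{reference.id}: no receptor-ligand contacts at "
            f"{spec.native_contact_cutoff} A — not a valid bound reference"
        )

    # model contacts over residues with a correspondence, in reference key space
    mapped_model_keys = corr.a_keys
    model_tcr = role_keys(model, TCR_ROLES) & mapped_model_keys
    model_pmhc = role_keys(model, PMHC_ROLES) & mapped_model_keys
    model_contacts = contacts(model, model_tcr, model_pmhc, spec.native_contact_cutoff)
    mapped_pairs = {
        (corr.to_ref(a), corr.to_ref(b)) for a, b in model_contacts.pairs
    }
    f_nat = len(mapped_pairs & native.pairs) / len(native)
    f_nonnat = (
        len(mapped_pairs - native.pairs) / len(mapped_pairs) if mapped_pairs else 0.0
    )

    # L-RMSD: fit on receptor backbone, measure ligand backbone unrefit
    rec_m, rec_r = paired_coordsets(model, reference, corr, ref_tcr)
    fit, _ = kabsch(rec_m, rec_r)
    lig_m, lig_r = paired_coordsets(model, reference, corr, ref_pmhc)
    l_rmsd = rmsd_fixed(CoordSet(lig_m.labels, fit.apply(lig_m.coords)), lig_r)

    # I-RMSD: fit and measure on the reference interface backbone
    iface = contacts(reference, ref_tcr, ref_pmhc, spec.interface_cutoff)
    iface_keys = {a for a, _ in iface.pairs} | {b for _, b in iface.pairs}
    int_m, int_r = paired_coordsets(model, reference, corr, iface_keys)
    _, i_rmsd = kabsch(int_m, int_r)

    return InterfaceMetrics(
        f_nat=f_nat,
        f_nonnat=f_nonnat,
        l_rmsd=l_rmsd,
        i_rmsd=i_rmsd,
        n_native_contacts=len(native),
        n_model_contacts=len(mapped_pairs),
    )


def classify(
    metrics: InterfaceMetrics, thresholds: CapriThresholds = CapriThresholds()
) -> QualityClass:
    """CAPRI quality class from (F_nat, L-RMSD, I-RMSD).

    High:       F_nat >= 0.5 and (L-RMSD <= 1.0 or I-RMSD <= 1.0)
    Medium:     F_nat >= 0.3 and (L-RMSD <= 5.0 or I-RMSD <= 2.0)
    Acceptable: F_nat >= 0.1 and (L-RMSD <= 10.0 or I-RMSD <= 4.0)
    Incorrect:  otherwise (always when F_nat < 0.1).
    """
    for value in (metrics.f_nat, metrics.l_rmsd, metrics.i_rmsd):
        if not np.isfinite(value):
            raise ValueError("metrics must be finite")
    fn_a, fn_m, fn_h = thresholds.f_nat
    l_a, l_m, l_h = thresholds.l_rmsd
    i_a, i_m, i_h = thresholds.i_rmsd
    f, l, i = metrics.f_nat, metrics.l_rmsd, metrics.i_rmsd
    if f >= fn_h and (l <= l_h or i <= i_h):
        return QualityClass.HIGH
    if f >= fn_m and (l <= l_m or i <= i_m):
        return QualityClass.MEDIUM
    if f >= fn_a and (l <= l_a or i <= i_a):
        return QualityClass.ACCEPTABLE
    return QualityClass.INCORRECT


# ---------------------------------------------------------------------------
# bound/unbound difficulty
# ---------------------------------------------------------------------------

def classify_difficulty(
    i_rmsd: float,
    f_nonnat: float,
    thresholds: DifficultyThresholds = DifficultyThresholds(),
) -> DifficultyClass:
    """Benchmark difficulty from bound-unbound I-RMSD and F_non-nat.

    Rigid:     I-RMSD <= 1.5 and F_non-nat <= 0.4
    Medium:    1.5 < I-RMSD <= 2.2, or I-RMSD <= 1.5 with F_non-nat > 0.4
    Difficult: I-RMSD > 2.2
    """
    if i_rmsd > thresholds.i_rmsd_difficult:
        return DifficultyClass.DIFFICULT
    if i_rmsd > thresholds.i_rmsd_rigid:
        return DifficultyClass.MEDIUM
    if f_nonnat > thresholds.f_nonnat_rigid:
        return DifficultyClass.MEDIUM
    return DifficultyClass.RIGID


def difficulty(
    case: DockingCase,
    spec: ScenarioSpec = ScenarioSpec(),
    thresholds: DifficultyThresholds = DifficultyThresholds(),
    min_identity: float = 0.9,
) -> tuple[DifficultyClass, float, float]:
    """Classify a docking case from its bound-unbound conformational change.

    The unbound TCR and unbound pMHC are each superposed onto their bound
    counterparts over all mapped backbone atoms; the I-RMSD is then measured
    over the mapped backbone atoms of the bound interface residues, and
    F_non-nat from the contacts of the superposed-unbound pseudo-complex
    against the native contact set.

    Returns ``(class, i_rmsd, f_nonnat)``.
    """
    if case.reference is None:
        raise MissingReferenceError(f"{case.case_id}: bound reference required")
    if case.tcr_unbound is None or case.pmhc_unbound is None:
        raise MissingStructureError(f"{case.case_id}: both unbound structures required")
    ref = case.reference

    ref_tcr = role_keys(ref, TCR_ROLES)
    ref_pmhc = role_keys(ref, PMHC_ROLES)
    native = contacts(ref, ref_tcr, ref_pmhc, spec.native_contact_cutoff)
    if len(native) == 0:
        raise InvalidReferenceError(f"{ref.id}: reference has no interface contacts")

    iface = contacts(ref, ref_tcr, ref_pmhc, spec.interface_cutoff)
    iface_keys = {a for a, _ in iface.pairs} | {b for _, b in iface.pairs}

    pieces: list[tuple[Complex, Correspondence, set[ResidueKey]]] = []
    for unbound, ref_side in ((case.tcr_unbound, ref_tcr), (case.pmhc_unbound, ref_pmhc)):
        corr = map_complex(unbound, ref, min_identity=min_identity)
        all_m, all_r = paired_coordsets(unbound, ref, corr, ref_side)
        fit, _ = kabsch(all_m, all_r)
        pieces.append((unbound.transform(fit), corr, ref_side))

    # I-RMSD over the bound interface backbone, without re-fitting
    labels, xm, xr = [], [], []
    for moved, corr, ref_side in pieces:
        cs_m, cs_r = paired_coordsets(moved, ref, corr, iface_keys & ref_side)
        labels.extend(cs_m.labels)
        xm.append(cs_m.coords)
        xr.append(cs_r.coords)
    i_rmsd = rmsd_fixed(
        CoordSet(labels, np.vstack(xm)), CoordSet(labels, np.vstack(xr))
    )

    # F_non-nat of the superposed-unbound pseudo-complex
    (tcr_moved, corr_tcr, _), (pmhc_moved, corr_pmhc, _) = pieces
    pseudo = Complex(f"{case.case_id}-unbound-superposed")
    for part in (tcr_moved, pmhc_moved):
        for cid, residues in part.chains.items():
            pseudo.chains[f"{cid}"] = residues
        pseudo.role_map.update(part.role_map)
    u_contacts = contacts(
        pseudo,
        role_keys(pseudo, [r for r in TCR_ROLES if r in pseudo.role_map]),
        role_keys(pseudo, [r for r in PMHC_ROLES if r in pseudo.role_map]),
        spec.native_contact_cutoff,
    )
    mapped = set()
    for a, b in u_contacts.pairs:
        ra = corr_tcr.to_ref(a)
        rb = corr_pmhc.to_ref(b)
        if ra is not None and rb is not None:
            mapped.add((ra, rb))
    f_nonnat = len(mapped - native.pairs) / len(mapped) if mapped else 0.0

    return classify_difficulty(i_rmsd, f_nonnat, thresholds), i_rmsd, f_nonnat
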