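"""Synthetic TCR-pMHC docking cases with analytically known metric values.

The generator builds toy complexes that satisfy every structural assumption
the pipeline makes — conventional A/B/C/D/E chains, IMGT-numbered TCR
variable domains with all three CDR loops present, a peptide lying in the
MHC groove with the CDR3 tips at a controlled closest-approach distance —
while remaining small enough that brute-force oracles can verify every
metric.  Residues carry backbone atoms (N, CA, C, O) plus CB; all metrics
in the pipeline are heavy-atom, so nothing more is needed.

Three layers of synthesis mirror a real benchmark:

* :func:`make_reference` — a bound reference complex;
* :func:`make_unbound`   — unbound components, optionally with Gaussian
  perturbation of the interface residues (emulating bound/unbound
  conformational change) and a random re-pose;
* :func:`make_decoy` / :func:`make_decoy_set` — rigid-body decoys and
  rank-ordered decoy sets with a planted mixture of CAPRI quality classes,
  verified by evaluation and re-drawn until the mixture is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .clustering import ModelRecord
from .correspondence import identity_correspondence, key_of, select_cdr
from .errors import GenerationError
from .geometry import RigidTransform
from .metrics import (
    DockingCase,
    QualityClass,
    ScenarioSpec,
    classify,
    contacts,
    evaluate_model,
    interface_contacts,
    role_keys,
)
from .structio import (
    Atom,
    Complex,
    CONVENTIONAL_CHAIN,
    PMHC_ROLES,
    Residue,
    TCR_ROLES,
    random_pose,
)

CA_SPACING = 3.8

# planar heavy-atom offsets relative to CA; keeping z = 0 makes the
# closest TCR-peptide approach exactly the CA-plane separation
_ATOM_OFFSETS: dict[str, tuple[str, np.ndarray]] = {
    "N": ("N", np.array([-1.46, 0.35, 0.0])),
    "CA": ("C", np.array([0.0, 0.0, 0.0])),
    "C": ("C", np.array([1.52, 0.35, 0.0])),
    "O": ("O", np.array([2.12, 1.45, 0.0])),
    "CB": ("C", np.array([0.0, -1.20, 0.0])),
}

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

# IMGT numbers given to the synthetic TCR variable domain
_FRAMEWORK_NUMBERS = (
    1, 4, 7, 10, 13, 16, 19, 22, 25,
    40, 43, 46, 49, 52,
    68, 71, 74, 77, 80, 85, 90, 95, 100,
    120, 123, 126, 128,
)
_CDR1_NUMBERS = (27, 28, 29, 30, 31, 32)
_CDR2_NUMBERS = (56, 57, 58, 59, 60, 61)
_CDR3_NUMBERS = (105, 106, 107, 108, 109, 110, 111, 112)


@dataclass(frozen=True)
class ToyCaseParams:
    """Knobs of the toy complex.

    ``interface_gap`` is the closest CDR3-tip-to-peptide heavy-atom
    distance before jitter; keeping it below the 4.5 A real-interface
    cutoff guarantees non-empty scenario-4 selections, and below the 5 A
    contact cutoff a non-empty native contact set.  ``jitter_sigma`` adds a
    small seeded Gaussian to every atom so different seeds give genuinely
    different (but reproducible) cases.
    """

    seed: int = 0
    peptide_length: int = 9
    mhc_helix_length: int = 12
    interface_gap: float = 4.0
    jitter_sigma: float = 0.08

    def __post_init__(self):
        if self.peptide_length < 1:
            raise ValueError("peptide_length must be >= 1")
        if self.interface_gap <= 0:
            raise ValueError("interface_gap must be positive")


@dataclass(frozen=True)
class DecoySpec:
    """One rigid-body decoy: ligand translation/rotation plus CDR loop noise.

    The rotation is applied about ``axis`` through the centroid of the
    ligand's interface atoms, so small angles perturb the interface
    smoothly; the translation is applied afterwards.  With no rotation and
    no noise, the ligand RMSD equals exactly the translation magnitude.
    """

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_angle: float = 0.0  # degrees
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    loop_noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class DecoyModel:
    """A generated decoy with its platform-style rank, score and true class."""

    model_id: str
    rank: int
    score: float
    quality: QualityClass
    complex: Complex
    spec: DecoySpec


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

def _residue(chain_id: str, seq_id: int, res_name: str, ca: np.ndarray) -> Residue:
    res = Residue(chain_id=chain_id, seq_id=seq_id, icode="", res_name=res_name)
    for name, (element, offset) in _ATOM_OFFSETS.items():
        if name == "CB" and res_name == "GLY":
            continue
        res.atoms.append(Atom(name=name, element=element, position=ca + offset))
    return res


def _strand(
    chain_id: str, numbers: Sequence[int], names: Sequence[str],
    start: np.ndarray, step: np.ndarray,
) -> list[Residue]:
    return [
        _residue(chain_id, num, name, start + i * step)
        for i, (num, name) in enumerate(zip(numbers, names))
    ]


def _tcr_chain(
    chain_id: str, names: Sequence[str], center_x: float,
    tip_xs: Sequence[float], gap: float,
) -> list[Residue]:
    """One TCR variable domain: framework block, CDR1/2 arcs, CDR3 dipping
    to the peptide plane with its three tip residues at height ``gap``."""
    residues: list[Residue] = []
    it = iter(names)

    for j, num in enumerate(_FRAMEWORK_NUMBERS):
        ca = np.array([
            center_x + CA_SPACING * ((j % 3) - 1),
            -4.0 + 4.0 * ((j // 3) % 3),
            14.0 + 3.5 * (j // 9),
        ])
        residues.append(_residue(chain_id, num, next(it), ca))

    for num_set, y in ((_CDR1_NUMBERS, -6.0), (_CDR2_NUMBERS, 6.0)):
        for j, num in enumerate(num_set):
            ca = np.array([center_x + CA_SPACING * (j - 2.5), y, 10.0])
            residues.append(_residue(chain_id, num, next(it), ca))

    # CDR3: 105,106 descend, 107 shoulders, 108-110 tips, 111-112 ascend
    heights = [10.0, 7.5, 5.8, gap, gap, gap, 5.8, 8.5]
    xs = [tip_xs[0] - 3 * CA_SPACING, tip_xs[0] - 2 * CA_SPACING, tip_xs[0] - CA_SPACING,
          tip_xs[0], tip_xs[1], tip_xs[2],
          tip_xs[2] + CA_SPACING, tip_xs[2] + 2 * CA_SPACING]
    for num, x, z in zip(_CDR3_NUMBERS, xs, heights):
        residues.append(_residue(chain_id, num, next(it), np.array([x, 0.0, z])))

    return sorted(residues, key=lambda r: r.seq_id)


def make_reference(params: ToyCaseParams = ToyCaseParams()) -> DockingCase:
    """Build a bound toy TCR-pMHC complex as a docking case.

    Chains follow the benchmark convention: MHC helix pair and floor on
    chain A, a beta-2-microglobulin stand-in on chain B, the peptide on
    chain C between the helices, TCR alpha/beta variable domains on D/E
    with CDR3 tips over the first/last thirds of the peptide.
    """
    rng = np.random.default_rng(params.seed)
    P = params.peptide_length
    L = params.mhc_helix_length

    def names(n: int) -> list[str]:
        return [str(_AA20[i]) for i in rng.integers(0, 20, size=n)]

    cx = Complex(f"toycase-{params.seed}")

    # MHC chain A: two flanking helices plus a groove floor out of the 9 A shell
    a_res: list[Residue] = []
    start_x = -CA_SPACING
    for block, (y, z) in enumerate(((-7.0, -1.0), (7.0, -1.0), (0.0, -11.0))):
        nums = range(block * L + 1, block * L + L + 1)
        a_res.extend(
            _strand("A", list(nums), names(L), np.array([start_x, y, z]),
                    np.array([CA_SPACING, 0.0, 0.0]))
        )
    cx.chains["A"] = a_res

    cx.chains["B"] = _strand(
        "B", list(range(1, 9)), names(8),
        np.array([start_x, 0.0, -20.0]), np.array([CA_SPACING, 0.0, 0.0]),
    )

    pep_x = [i * CA_SPACING for i in range(P)]
    cx.chains["C"] = _strand(
        "C", list(range(1, P + 1)), names(P),
        np.array([0.0, 0.0, 0.0]), np.array([CA_SPACING, 0.0, 0.0]),
    )

    # TCR tips sit over peptide residues; alpha takes the N-terminal third,
    # beta the C-terminal third
    def tip_window(offset: int) -> list[float]:
        mid = max(1, min(P - 2, offset))
        return [pep_x[mid - 1], pep_x[mid], pep_x[mid + 1]]

    tips_d = tip_window(P // 3)
    tips_e = tip_window(2 * P // 3)
    n_tcr = len(_FRAMEWORK_NUMBERS) + len(_CDR1_NUMBERS) + len(_CDR2_NUMBERS) + len(_CDR3_NUMBERS)
    cx.chains["D"] = _tcr_chain("D", names(n_tcr), tips_d[1], tips_d, params.interface_gap)
    cx.chains["E"] = _tcr_chain("E", names(n_tcr), tips_e[1], tips_e, params.interface_gap)

    cx.role_map = dict(CONVENTIONAL_CHAIN)

    if params.jitter_sigma > 0:
        for _, atom in cx.atoms():
            atom.position = atom.position + rng.normal(0.0, params.jitter_sigma, size=3)

    case = DockingCase(
        case_id=cx.id,
        reference=cx,
        metadata={"mhc_class": "I", "species": "human"},
    )
    if len(interface_contacts(cx)) == 0:
        raise GenerationError(f"{cx.id}: parameters produced an empty interface")
    return case


# ---------------------------------------------------------------------------
# unbound components
# ---------------------------------------------------------------------------

def make_unbound(
    case: DockingCase,
    interface_noise_sigma: float = 0.0,
    seed: int = 0,
    interface_cutoff: float = 10.0,
    max_translation: float = 20.0,
) -> tuple[Complex, Complex]:
    """Split a bound reference into unbound TCR and pMHC components.

    Gaussian noise of the stated sigma (per coordinate) is added to the
    atoms of interface residues only — emulating binding-site conformational
    change — before each component is randomly re-posed.  The correspondence
    to the bound form stays residue-identical.
    """
    if interface_noise_sigma < 0:
        raise ValueError("interface_noise_sigma must be >= 0")
    ref = case.reference
    if ref is None:
        raise ValueError(f"{case.case_id}: case has no reference")
    rng = np.random.default_rng(seed)

    iface = contacts(
        ref, role_keys(ref, TCR_ROLES), role_keys(ref, PMHC_ROLES), interface_cutoff
    )
    iface_keys = {a for a, _ in iface.pairs} | {b for _, b in iface.pairs}

    out = []
    for roles, tag in ((TCR_ROLES, "tcr"), (PMHC_ROLES, "pmhc")):
        chains = [ref.role_map[r] for r in roles]
        part = ref.subset(chains, new_id=f"{case.case_id}-{tag}-unbound")
        if interface_noise_sigma > 0:
            for res in part.residues():
                if key_of(res) in iface_keys:
                    for atom in res.atoms:
                        atom.position = atom.position + rng.normal(
                            0.0, interface_noise_sigma, size=3
                        )
        pose_seed = int(rng.integers(0, 2**31 - 1))
        out.append(random_pose(part, seed=pose_seed, max_translation=max_translation))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

def _ligand_interface_centroid(reference: Complex, cutoff: float = 5.0) -> np.ndarray:
    native = interface_contacts(reference, cutoff)
    lig_keys = {b for _, b in native.pairs}
    if not lig_keys:  # fall back to the whole ligand
        lig_keys = role_keys(reference, PMHC_ROLES)
    pts = [
        a.position
        for res in reference.residues()
        if key_of(res) in lig_keys
        for a in res.atoms
    ]
    return np.mean(pts, axis=0)


def make_decoy(reference: Complex, spec: DecoySpec) -> Complex:
    """Apply a decoy specification to a copy of the reference.

    The ligand chains (A/B/C) are rotated about the stated axis through the
    ligand interface centroid, then translated; the receptor is untouched.
    Optional Gaussian noise is then added to the CDR loop atoms.
    """
    out = reference.copy()
    axis = np.asarray(spec.axis, dtype=float)
    if np.linalg.norm(axis) == 0:
        raise ValueError("rotation axis must be non-zero")
    rot = Rotation.from_rotvec(
        np.deg2rad(spec.rotation_angle) * axis / np.linalg.norm(axis)
    ).as_matrix()
    center = _ligand_interface_centroid(reference)
    shift = np.asarray(spec.translation, dtype=float)
    transform = RigidTransform(rot, center - rot @ center + shift)

    lig_chains = {reference.role_map[r] for r in PMHC_ROLES}
    for cid, residues in out.chains.items():
        if cid in lig_chains:
            for res in residues:
                for atom in res.atoms:
                    atom.position = transform.rotation @ atom.position + transform.translation

    if spec.loop_noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        loop_keys = select_cdr(out)
        for res in out.residues():
            if key_of(res) in loop_keys:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(
                        0.0, spec.loop_noise_sigma, size=3
                    )
    return out


#: frozen per-class sampling ranges for planted decoys; the verification
#: loop below makes the exact magnitudes non-critical
_CLASS_DRAWS = {
    QualityClass.HIGH: dict(shift=(0.2, 0.6), angle=(0.0, 0.0)),
    QualityClass.MEDIUM: dict(shift=(2.3, 3.2), angle=(0.0, 6.0)),
    QualityClass.ACCEPTABLE: dict(shift=(0.0, 1.0), angle=(28.0, 45.0)),
    QualityClass.INCORRECT: dict(shift=(20.0, 35.0), angle=(120.0, 240.0)),
}


def _draw_spec(target: QualityClass, rng: np.random.Generator) -> DecoySpec:
    d = _CLASS_DRAWS[target]
    shift = rng.uniform(*d["shift"]) * rng.choice((-1.0, 1.0))
    angle = rng.uniform(*d["angle"]) * rng.choice((-1.0, 1.0))
    if target is QualityClass.INCORRECT:
        translation = (rng.uniform(-5, 5), rng.uniform(-5, 5), abs(shift))
    else:
        translation = (0.0, shift, 0.0)
    return DecoySpec(
        translation=translation,
        rotation_angle=angle,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def make_decoy_set(
    reference: Complex,
    n_models: int,
    planted_mixture: Mapping[QualityClass, int],
    seed: int = 0,
    spec: ScenarioSpec = ScenarioSpec(),
    max_retries: int = 80,
) -> list[DecoyModel]:
    """A rank-ordered decoy set realising an exact quality-class mixture.

    Decoys are drawn from per-class magnitude ranges, evaluated against the
    reference, and re-drawn until each model's CAPRI class matches its
    planted label (bounded retries).  Rank order is then randomised and
    synthetic scores are assigned so that better classes receive better
    (lower) mean scores with Gaussian noise.
    """
    counts = dict(planted_mixture)
    if sum(counts.values()) != n_models:
        raise ValueError("planted mixture must sum to n_models")
    rng = np.random.default_rng(seed)
    corr = identity_correspondence(reference)
    score_base = {
        QualityClass.HIGH: -150.0,
        QualityClass.MEDIUM: -120.0,
        QualityClass.ACCEPTABLE: -90.0,
        QualityClass.INCORRECT: -40.0,
    }

    planted: list[tuple[QualityClass, Complex, DecoySpec]] = []
    for target, n_of_class in sorted(counts.items(), key=lambda kv: -kv[0]):
        for _ in range(n_of_class):
            for _attempt in range(max_retries):
                d_spec = _draw_spec(target, rng)
                decoy = make_decoy(reference, d_spec)
                achieved = classify(evaluate_model(decoy, reference, corr, spec))
                if achieved == target:
                    planted.append((target, decoy, d_spec))
                    break
            else:
                raise GenerationError(
                    f"could not realise class {target} after {max_retries} draws"
                )

    order = rng.permutation(len(planted))
    models: list[DecoyModel] = []
    for rank, idx in enumerate(order, start=1):
        target, decoy, d_spec = planted[idx]
        decoy.id = f"{reference.id}-model-{rank:04d}"
        models.append(
            DecoyModel(
                model_id=decoy.id,
                rank=rank,
                score=float(score_base[target] + rng.normal(0.0, 8.0)),
                quality=target,
                complex=decoy,
                spec=d_spec,
            )
        )
    return models


def to_model_records(decoys: Sequence[DecoyModel], cutoff: float = 5.0) -> list[ModelRecord]:
    """Contact-set records for clustering, one per decoy, in rank order."""
    return [
        ModelRecord(
            model_id=d.model_id,
            rank=d.rank,
            score=d.score,
            contact_set=interface_contacts(d.complex, cutoff),
        )
        for d in sorted(decoys, key=lambda d: d.rank)
    ]
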