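import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import brute_force_contacts
from tcrdockeval import errors
from tcrdockeval.correspondence import identity_correspondence, key_of, select_cdr
from tcrdockeval.metrics import (
    BACKBONE_ATOMS,
    CapriThresholds,
    DifficultyClass,
    DockingCase,
    InterfaceMetrics,
    QualityClass,
    ScenarioSpec,
    classify,
    classify_difficulty,
    contacts,
    difficulty,
    evaluate_model,
    interface_contacts,
    role_keys,
    scenario_residues,
)
from tcrdockeval.structio import Atom, Complex, PMHC_ROLES, Residue, TCR_ROLES
from tcrdockeval.synthetic import DecoySpec, make_decoy, make_unbound


def _metrics(f_nat, l_rmsd, i_rmsd, f_nonnat=0.0):
    return InterfaceMetrics(f_nat=f_nat, f_nonnat=f_nonnat, l_rmsd=l_rmsd, i_rmsd=i_rmsd)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def _two_atom_complex(distance):
    cx = Complex("two")
    cx.chains["D"] = [Residue("D", 1, "", "GLY", [Atom("CA", "C", [0, 0, 0])])]
    cx.chains["C"] = [Residue("C", 1, "", "GLY", [Atom("CA", "C", [distance, 0, 0])])]
    cx.role_map = {"tcr_alpha": "D", "peptide": "C"}
    return cx


def test_contact_below_cutoff_found():
    cx = _two_atom_complex(4.9)
    cs = contacts(cx, {key_of(cx.chains["D"][0])}, {key_of(cx.chains["C"][0])}, 5.0)
    assert len(cs) == 1


def test_cutoff_is_strict():
    cx = _two_atom_complex(4.5)
    cs = contacts(cx, {key_of(cx.chains["D"][0])}, {key_of(cx.chains["C"][0])}, 4.5)
    assert len(cs) == 0


def test_empty_group_gives_empty_set(reference):
    assert len(contacts(reference, set(), role_keys(reference, PMHC_ROLES), 5.0)) == 0


@pytest.mark.parametrize("cutoff", [4.5, 5.0, 9.0])
def test_contacts_match_all_pairs_oracle(reference, cutoff):
    tcr = role_keys(reference, TCR_ROLES)
    pmhc = role_keys(reference, PMHC_ROLES)
    fast = contacts(reference, tcr, pmhc, cutoff).pairs
    assert fast == brute_force_contacts(reference, tcr, pmhc, cutoff)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def test_scenario1_is_cdrs_plus_peptide(full_case):
    tcr_sel, pmhc_sel = scenario_residues(full_case, ScenarioSpec(scenario=1))
    assert tcr_sel == select_cdr(full_case.tcr_unbound)
    assert pmhc_sel == role_keys(full_case.pmhc_unbound, ("peptide",))


def test_scenario2_adds_mhc_shell_and_contains_peptide(full_case):
    _, s1_pmhc = scenario_residues(full_case, ScenarioSpec(scenario=1))
    _, s2_pmhc = scenario_residues(full_case, ScenarioSpec(scenario=2))
    assert s1_pmhc <= s2_pmhc
    # every added residue verified within the shell by brute force
    unbound = full_case.pmhc_unbound
    pep = role_keys(unbound, ("peptide",))
    mhc = role_keys(unbound, ("mhc_a", "mhc_b"))
    shell = {a for a, _ in brute_force_contacts(unbound, mhc, pep, 9.0)}
    assert s2_pmhc - s1_pmhc == shell
    assert shell < mhc  # the groove floor stays outside the 9 A shell


def test_scenario4_matches_distance_oracle_and_shrinks(full_case):
    spec = ScenarioSpec(scenario=4)
    tcr_sel, pmhc_sel = scenario_residues(full_case, spec)
    assert tcr_sel and pmhc_sel
    ref = full_case.reference
    oracle = brute_force_contacts(
        ref, role_keys(ref, TCR_ROLES), role_keys(ref, PMHC_ROLES), 4.5
    )
    # unbound components are residue-identical to the bound reference here
    assert tcr_sel == {a for a, _ in oracle}
    assert pmhc_sel == {b for _, b in oracle}

    tighter_t, tighter_p = scenario_residues(
        full_case, dataclasses.replace(spec, real_interface_cutoff=4.2)
    )
    assert tighter_t <= tcr_sel and tighter_p <= pmhc_sel


def test_scenario34_need_reference(full_case):
    case = DockingCase(
        "no-ref", reference=None,
        tcr_unbound=full_case.tcr_unbound, pmhc_unbound=full_case.pmhc_unbound,
    )
    with pytest.raises(errors.MissingReferenceError):
        scenario_residues(case, ScenarioSpec(scenario=3))


# ---------------------------------------------------------------------------
# evaluate_model, with an independent straight-line recomputation
# ---------------------------------------------------------------------------

def straight_line_metrics(model, reference, spec=ScenarioSpec()):
    """Brute-force CAPRI metrics assuming residue-identical numbering."""
    def backbone(cx, keys):
        out = []
        for res in cx.residues():
            if key_of(res) in keys:
                for name in BACKBONE_ATOMS:
                    atom = res.atom(name)
                    if atom is not None:
                        out.append(((key_of(res), name), atom.position))
        out.sort(key=lambda kv: kv[0])
        return np.array([p for _, p in out])

    tcr = role_keys(reference, TCR_ROLES)
    pmhc = role_keys(reference, PMHC_ROLES)
    native = brute_force_contacts(reference, tcr, pmhc, spec.native_contact_cutoff)
    model_c = brute_force_contacts(model, tcr, pmhc, spec.native_contact_cutoff)
    f_nat = len(native & model_c) / len(native)
    f_nonnat = len(model_c - native) / len(model_c) if model_c else 0.0

    def fit(mob, tgt):
        mc, tc = mob.mean(0), tgt.mean(0)
        r, _ = Rotation.align_vectors(tgt - tc, mob - mc)
        return lambda pts: (pts - mc) @ r.as_matrix().T + tc

    rec_fit = fit(backbone(model, tcr), backbone(reference, tcr))
    dl = rec_fit(backbone(model, pmhc)) - backbone(reference, pmhc)
    l_rmsd = np.sqrt((dl**2).sum() / len(dl))

    iface_pairs = brute_force_contacts(reference, tcr, pmhc, spec.interface_cutoff)
    iface = {a for a, _ in iface_pairs} | {b for _, b in iface_pairs}
    mi, ri = backbone(model, iface), backbone(reference, iface)
    di = fit(mi, ri)(mi) - ri
    i_rmsd = np.sqrt((di**2).sum() / len(di))
    return f_nat, f_nonnat, l_rmsd, i_rmsd


def test_reference_against_itself_is_perfect(reference, ref_corr):
    m = evaluate_model(reference, reference, ref_corr)
    assert (m.f_nat, m.f_nonnat) == (1.0, 0.0)
    assert m.l_rmsd == pytest.approx(0.0, abs=1e-9)
    assert m.i_rmsd == pytest.approx(0.0, abs=1e-9)
    assert classify(m) is QualityClass.HIGH


def test_pure_translation_l_rmsd_exact(reference, ref_corr):
    d = make_decoy(reference, DecoySpec(translation=(0, 3.0, 0)))
    m = evaluate_model(d, reference, ref_corr)
    assert m.l_rmsd == pytest.approx(3.0, abs=1e-6)


def test_far_translation_destroys_interface(reference, ref_corr):
    d = make_decoy(reference, DecoySpec(translation=(50.0, 0, 0)))
    m = evaluate_model(d, reference, ref_corr)
    assert m.f_nat == 0.0
    assert classify(m) is QualityClass.INCORRECT


def test_rotated_decoy_matches_brute_force_recomputation(reference, ref_corr):
    d = make_decoy(reference, DecoySpec(rotation_angle=15.0, axis=(0.3, 0.2, 1.0)))
    m = evaluate_model(d, reference, ref_corr)
    f_nat, f_nonnat, l_rmsd, i_rmsd = straight_line_metrics(d, reference)
    assert m.f_nat == pytest.approx(f_nat)
    assert m.f_nonnat == pytest.approx(f_nonnat)
    assert m.l_rmsd == pytest.approx(l_rmsd, abs=1e-6)
    assert m.i_rmsd == pytest.approx(i_rmsd, abs=1e-6)


def test_contactless_reference_rejected(reference, ref_corr):
    far = make_decoy(reference, DecoySpec(translation=(200.0, 0, 0)))
    with pytest.raises(errors.InvalidReferenceError):
        evaluate_model(reference, far, ref_corr)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "f_nat, l_rmsd, i_rmsd, expected",
    [
        (0.6, 0.9, 1.8, QualityClass.HIGH),       # high via L-RMSD branch
        (0.35, 6.0, 1.9, QualityClass.MEDIUM),    # medium via I-RMSD branch
        (0.15, 12.0, 3.5, QualityClass.ACCEPTABLE),  # acceptable via I-RMSD
        (0.05, 0.5, 0.5, QualityClass.INCORRECT),  # F_nat below 0.1 dominates
    ],
)
def test_capri_table_branches(f_nat, l_rmsd, i_rmsd, expected):
    assert classify(_metrics(f_nat, l_rmsd, i_rmsd)) is expected


def test_thresholds_are_inclusive():
    assert classify(_metrics(0.5, 1.0, 9.9)) is QualityClass.HIGH
    assert classify(_metrics(0.3, 5.0, 9.9)) is QualityClass.MEDIUM
    assert classify(_metrics(0.1, 10.0, 9.9)) is QualityClass.ACCEPTABLE


def test_classify_monotone_under_improvement():
    rng = np.random.default_rng(2024)
    for _ in range(300):
        f, l, i = rng.uniform(0, 1), rng.uniform(0, 15), rng.uniform(0, 6)
        base = classify(_metrics(f, l, i))
        assert classify(_metrics(min(1.0, f + rng.uniform(0, 0.5)), l, i)) >= base
        assert classify(_metrics(f, max(0.0, l - rng.uniform(0, 5)), i)) >= base
        assert classify(_metrics(f, l, max(0.0, i - rng.uniform(0, 2)))) >= base


def test_nonfinite_metrics_rejected():
    with pytest.raises(ValueError):
        classify(_metrics(float("nan"), 1.0, 1.0))


@pytest.mark.parametrize(
    "i_rmsd, f_nonnat, expected",
    [
        (0.0, 0.0, DifficultyClass.RIGID),
        (1.8, 0.1, DifficultyClass.MEDIUM),   # middle I-RMSD band
        (1.2, 0.5, DifficultyClass.MEDIUM),   # low I-RMSD but many non-native contacts
        (2.5, 0.0, DifficultyClass.DIFFICULT),
    ],
)
def test_difficulty_table_branches(i_rmsd, f_nonnat, expected):
    assert classify_difficulty(i_rmsd, f_nonnat) is expected


def test_difficulty_boundaries_inclusive():
    assert classify_difficulty(1.5, 0.4) is DifficultyClass.RIGID
    assert classify_difficulty(2.2, 0.0) is DifficultyClass.MEDIUM


def test_identical_unbound_is_rigid(full_case):
    cls, i_rmsd, f_nonnat = difficulty(full_case)
    assert cls is DifficultyClass.RIGID
    assert i_rmsd == pytest.approx(0.0, abs=1e-9)
    assert f_nonnat == 0.0


def test_perturbed_unbound_increases_i_rmsd(ref_case):
    gentle = DockingCase("gentle", reference=ref_case.reference)
    gentle.tcr_unbound, gentle.pmhc_unbound = make_unbound(ref_case, 0.4, seed=5)
    harsh = DockingCase("harsh", reference=ref_case.reference)
    harsh.tcr_unbound, harsh.pmhc_unbound = make_unbound(ref_case, 2.5, seed=5)
    _, i_gentle, _ = difficulty(gentle)
    cls_harsh, i_harsh, _ = difficulty(harsh)
    assert i_gentle < i_harsh
    assert cls_harsh is DifficultyClass.DIFFICULT


def test_missing_unbound_raises(reference):
    with pytest.raises(errors.MissingStructureError):
        difficulty(DockingCase("partial", reference=reference))


def test_interface_contacts_equal_role_contacts(reference):
    direct = contacts(
        reference, role_keys(reference, TCR_ROLES), role_keys(reference, PMHC_ROLES), 5.0
    )
    assert interface_contacts(reference).pairs == direct.pairs
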