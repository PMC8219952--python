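import numpy as np
import pytest

from tcrdockeval.analysis import (
    CaseResult,
    LoopRmsdRecord,
    benchmark_summary,
    best_in_top,
    cluster_success,
    loop_rmsd,
    loop_table,
    sampling_fraction,
    success_rate,
    success_table,
)
from tcrdockeval.clustering import ModelRecord
from tcrdockeval.correspondence import CDR_LOOPS, key_of, select_cdr
from tcrdockeval.errors import MissingLoopError
from tcrdockeval.metrics import ContactSet, DockingCase, QualityClass
from tcrdockeval.synthetic import ToyCaseParams, make_reference, make_unbound

Q = QualityClass


def _result(case_id, qualities):
    return CaseResult(case_id=case_id, qualities=list(qualities))


# ---------------------------------------------------------------------------
# success rates
# ---------------------------------------------------------------------------

class TestBestInTop:
    def test_top_one(self):
        assert best_in_top(_result("c", [Q.INCORRECT, Q.MEDIUM, Q.INCORRECT]), 1) is Q.INCORRECT

    def test_top_two_sees_medium(self):
        assert best_in_top(_result("c", [Q.INCORRECT, Q.MEDIUM, Q.INCORRECT]), 2) is Q.MEDIUM

    def test_n_beyond_length_truncates(self):
        qualities = [Q.INCORRECT] * 39 + [Q.HIGH]
        assert best_in_top(_result("c", qualities), 100) is Q.HIGH

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            best_in_top(_result("c", []), 1)


class TestSuccessRate:
    def test_matches_direct_count(self):
        rng = np.random.default_rng(0)
        results = []
        for i in range(44):
            qualities = [Q(rng.integers(0, 4)) for _ in range(10)]
            results.append(_result(f"case{i}", qualities))
        for n in (1, 5, 10):
            expected = 100.0 * sum(
                1 for r in results if any(q >= Q.ACCEPTABLE for q in r.qualities[:n])
            ) / 44
            assert success_rate(results, n) == pytest.approx(expected)

    def test_fifteen_of_fortyfour(self):
        results = [_result(f"c{i}", [Q.ACCEPTABLE]) for i in range(15)]
        results += [_result(f"c{i + 15}", [Q.INCORRECT]) for i in range(29)]
        assert round(success_rate(results, 1), 1) == 34.1

    def test_all_incorrect_is_zero(self):
        results = [_result(f"c{i}", [Q.INCORRECT] * 5) for i in range(10)]
        assert success_rate(results, 5) == 0.0

    def test_monotone_in_n_and_min_class(self):
        rng = np.random.default_rng(3)
        results = [
            _result(f"c{i}", [Q(rng.integers(0, 4)) for _ in range(20)])
            for i in range(25)
        ]
        rates = [success_rate(results, n) for n in (1, 2, 5, 10, 20, 50)]
        assert rates == sorted(rates)
        by_class = [
            success_rate(results, 5, min_class=c)
            for c in (Q.ACCEPTABLE, Q.MEDIUM, Q.HIGH)
        ]
        assert by_class == sorted(by_class, reverse=True)

    def test_duplicate_case_ids_rejected(self):
        results = [_result("same", [Q.HIGH]), _result("same", [Q.HIGH])]
        with pytest.raises(ValueError):
            success_rate(results, 1)


class TestSamplingFraction:
    def test_all_models_acceptable(self):
        assert sampling_fraction(_result("c", [Q.ACCEPTABLE] * 200)) == 100.0

    def test_none_acceptable(self):
        assert sampling_fraction(_result("c", [Q.INCORRECT] * 50)) == 0.0

    def test_quarter(self):
        qualities = [Q.MEDIUM] * 50 + [Q.INCORRECT] * 150
        assert sampling_fraction(_result("c", qualities)) == 25.0


def _cluster_case(quality_by_position):
    """One case: clusters of 4 records each; qualities placed by (cluster, member)."""
    clusters = []
    qualities = {}
    contact = ContactSet(5.0, frozenset())
    rank = 1
    for ci in range(6):
        members = []
        for mi in range(4):
            mid = f"c{ci}m{mi}"
            members.append(ModelRecord(model_id=mid, rank=rank, contact_set=contact))
            qualities[mid] = quality_by_position.get((ci, mi), Q.INCORRECT)
            rank += 1
        clusters.append(members)
    return clusters, qualities


class TestClusterSuccess:
    def test_hit_in_first_cluster_second_member(self):
        case = _cluster_case({(0, 1): Q.ACCEPTABLE})
        assert cluster_success([case], n_clusters=1) == 100.0

    def test_hit_only_in_sixth_cluster_fails_at_five(self):
        case = _cluster_case({(5, 0): Q.HIGH})
        assert cluster_success([case], n_clusters=5) == 0.0
        assert cluster_success([case], n_clusters=6) == 100.0

    def test_member_beyond_top_four_not_counted(self):
        clusters, qualities = _cluster_case({})
        clusters[0].append(
            ModelRecord(model_id="extra", rank=99, contact_set=ContactSet(5.0, frozenset()))
        )
        qualities["extra"] = Q.HIGH
        assert cluster_success([(clusters, qualities)], n_clusters=5) == 0.0

    def test_caseless_cluster_counts_as_failure(self):
        good = _cluster_case({(0, 0): Q.MEDIUM})
        empty = ([], {})
        assert cluster_success([good, empty], n_clusters=5) == 50.0

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(9)
        cases = []
        expected_hits = 0
        for _ in range(20):
            placed = {}
            if rng.random() < 0.5:
                ci, mi = int(rng.integers(0, 6)), int(rng.integers(0, 4))
                placed[(ci, mi)] = Q.ACCEPTABLE
                if ci < 5:
                    expected_hits += 1
            cases.append(_cluster_case(placed))
        assert cluster_success(cases, n_clusters=5) == pytest.approx(100.0 * expected_hits / 20)


# ---------------------------------------------------------------------------
# loop RMSD
# ---------------------------------------------------------------------------

class TestLoopRmsd:
    def test_reference_against_itself_zero(self, full_case):
        for role in ("tcr_alpha", "tcr_beta"):
            for loop in CDR_LOOPS.values():
                assert loop_rmsd(
                    full_case.tcr_unbound, full_case.reference,
                    loop=loop, chain_role=role,
                ) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_displaced_loop_reads_displacement(self, full_case):
        subject = full_case.tcr_unbound.copy()
        keys = select_cdr(subject, ["tcr_beta"], [CDR_LOOPS["CDR3"]])
        for res in subject.residues():
            if key_of(res) in keys:
                for atom in res.atoms:
                    atom.position = atom.position + np.array([0.0, 2.0, 0.0])
        value = loop_rmsd(
            subject, full_case.reference, loop=CDR_LOOPS["CDR3"], chain_role="tcr_beta"
        )
        assert value == pytest.approx(2.0, abs=1e-9)

    def test_matches_brute_force_on_noisy_loop(self, full_case):
        from scipy.spatial.transform import Rotation

        from tcrdockeval.correspondence import select_framework
        from tcrdockeval.metrics import BACKBONE_ATOMS

        rng = np.random.default_rng(21)
        subject = full_case.tcr_unbound.copy()
        keys = select_cdr(subject, ["tcr_alpha"], [CDR_LOOPS["CDR3"]])
        for res in subject.residues():
            if key_of(res) in keys:
                for atom in res.atoms:
                    atom.position = atom.position + rng.normal(0, 0.8, size=3)

        value = loop_rmsd(
            subject, full_case.reference, loop=CDR_LOOPS["CDR3"], chain_role="tcr_alpha"
        )

        # independent recomputation from raw coordinates
        ref = full_case.reference
        fw = select_framework(ref)
        atoms = {key_of(r): {a.name: a.position for a in r.atoms} for r in subject.residues()}
        ref_atoms = {key_of(r): {a.name: a.position for a in r.atoms} for r in ref.residues()}
        mob, tgt = [], []
        for k in sorted(fw):
            for name in BACKBONE_ATOMS:
                mob.append(atoms[k][name])
                tgt.append(ref_atoms[k][name])
        mob, tgt = np.array(mob), np.array(tgt)
        mc, tc = mob.mean(0), tgt.mean(0)
        rot, _ = Rotation.align_vectors(tgt - tc, mob - mc)
        deltas = []
        for k in sorted(keys):
            for name in sorted(atoms[k]):
                moved = rot.as_matrix() @ (atoms[k][name] - mc) + tc
                deltas.append(moved - ref_atoms[k][name])
        expected = np.sqrt((np.array(deltas) ** 2).sum() / len(deltas))
        assert value == pytest.approx(expected, abs=1e-9)

    def test_missing_loop_raises(self, full_case):
        subject = full_case.tcr_unbound.copy()
        keys = select_cdr(subject, ["tcr_alpha"], [CDR_LOOPS["CDR3"]])
        for cid in list(subject.chains):
            subject.chains[cid] = [
                r for r in subject.chains[cid] if key_of(r) not in keys
            ]
        with pytest.raises(MissingLoopError):
            loop_rmsd(
                subject, full_case.reference,
                loop=CDR_LOOPS["CDR3"], chain_role="tcr_alpha",
            )


# ---------------------------------------------------------------------------
# benchmark summary and tables
# ---------------------------------------------------------------------------

class TestBenchmarkSummary:
    def test_single_case_totals(self, ref_case):
        counts = benchmark_summary([ref_case])
        assert counts["total_cases"] == 1
        assert counts["unique_tcrs"] == 1
        assert counts["unique_pmhcs"] == 1
        assert counts["mhc_class_i"] == 1
        assert counts["human_tcr"] == 1

    def test_shared_tcr_detected(self):
        a = make_reference(ToyCaseParams(seed=1))
        b = make_reference(ToyCaseParams(seed=2))
        # same TCR (chains D/E copied from a), different pMHC
        for cid in ("D", "E"):
            b.reference.chains[cid] = a.reference.chains[cid]
        b.metadata["species"] = "mouse"
        b.metadata["mhc_class"] = "II"
        counts = benchmark_summary([a, b])
        assert counts == {
            "mhc_class_i": 1, "mhc_class_ii": 1,
            "human_tcr": 1, "mouse_tcr": 1,
            "unique_tcrs": 1, "unique_pmhcs": 2,
            "max_tcr_sharing": 2, "max_pmhc_sharing": 1,
            "total_cases": 2,
        }

    def test_missing_metadata_raises(self, ref_case):
        bare = DockingCase("bare", reference=ref_case.reference, metadata={})
        with pytest.raises(ValueError):
            benchmark_summary([bare])


def test_success_table_shape_and_rounding():
    results = [
        CaseResult(f"c{i}", platform="haddock", scenario=1,
                   qualities=[Q.ACCEPTABLE if i < 15 else Q.INCORRECT])
        for i in range(44)
    ]
    table = success_table(results, tops=(1, 5))
    assert list(table["top_n"]) == [1, 5]
    assert table.loc[table.top_n == 1, "success_pct"].item() == 34.1


def test_loop_table_improvement_flag():
    rec = LoopRmsdRecord("c", "tcr_alpha", "CDR3", baseline_rmsd=2.0,
                         model_rmsd=1.0, model_quality=Q.MEDIUM)
    table = loop_table([rec])
    assert bool(table["improved"].item()) is True
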