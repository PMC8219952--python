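"""Cohort-level analytics: success rates, sampling, clusters, loops, summary.

The central quantity is the *success rate*: the percentage of docking cases
with at least one model of a minimum quality among the top N ranked models.
Sampling performance asks instead what fraction of all models produced for
a case reach that quality, and cluster success applies the top-N logic to a
ranked cluster list.  The loop analysis measures how far a CDR loop sits
from its bound conformation once the TCR frameworks are superposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import ModelRecord
from .correspondence import (
    CDR_LOOPS,
    Correspondence,
    LoopDefinition,
    map_complex,
    select_cdr,
    select_framework,
)
from .errors import MissingLoopError
from .geometry import CoordSet, kabsch, rmsd_fixed
from .metrics import (
    DifficultyClass,
    DockingCase,
    QualityClass,
    paired_coordsets,
)
from .structio import Complex, PMHC_ROLES, TCR_ROLES

TOP_N_DEFAULT = (1, 5, 10, 20, 50, 100)


@dataclass
class CaseResult:
    """Rank-ordered model qualities for one case on one platform/scenario."""

    case_id: str
    platform: str = ""
    scenario: int = 1
    qualities: list[QualityClass] = field(default_factory=list)
    difficulty: DifficultyClass | None = None
    mhc_class: str | None = None


@dataclass(frozen=True)
class LoopRmsdRecord:
    """Baseline (unbound) and model loop RMSD for one CDR loop of one case."""

    case_id: str
    chain_role: str
    loop_id: str
    baseline_rmsd: float
    model_rmsd: float
    model_quality: QualityClass


# ---------------------------------------------------------------------------
# success rates
# ---------------------------------------------------------------------------

def best_in_top(result: CaseResult, n: int) -> QualityClass:
    """Best CAPRI class among the first ``n`` ranked models (or all, if fewer)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not result.qualities:
        raise ValueError(f"{result.case_id}: empty quality list")
    return max(result.qualities[:n])


def success_rate(
    results: Sequence[CaseResult],
    n: int,
    min_class: QualityClass = QualityClass.ACCEPTABLE,
) -> float:
    """Percentage of cases with a model of at least ``min_class`` in the top n."""
    if not results:
        raise ValueError("no case results")
    ids = [r.case_id for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case_ids in results")
    hits = sum(1 for r in results if best_in_top(r, n) >= min_class)
    return 100.0 * hits / len(results)


def sampling_fraction(
    result: CaseResult, min_class: QualityClass = QualityClass.ACCEPTABLE
) -> float:
    """Models of at least ``min_class`` as a percentage of all models of a case."""
    if not result.qualities:
        raise ValueError(f"{result.case_id}: empty quality list")
    hits = sum(1 for q in result.qualities if q >= min_class)
    return 100.0 * hits / len(result.qualities)


def cluster_success(
    case_clusterings: Sequence[
        tuple[Sequence[Sequence[ModelRecord]], Mapping[str, QualityClass]]
    ],
    n_clusters: int,
    members_per_cluster: int = 4,
    min_class: QualityClass = QualityClass.ACCEPTABLE,
) -> float:
    """Success rate of the top members of the top ranked clusters.

    Each element of ``case_clusterings`` is ``(ranked_clusters, qualities)``
    for one case, where ``qualities`` maps model_id to its CAPRI class.  A
    case succeeds if any of the first ``members_per_cluster`` members of
    any of the first ``n_clusters`` clusters reaches ``min_class``; cases
    with no clusters count as failures.
    """
    if not case_clusterings:
        raise ValueError("no cases given")
    hits = 0
    for ranked, qualities in case_clusterings:
        found = False
        for members in list(ranked)[:n_clusters]:
            for record in list(members)[:members_per_cluster]:
                if qualities.get(record.model_id, QualityClass.INCORRECT) >= min_class:
                    found = True
                    break
            if found:
                break
        hits += found
    return 100.0 * hits / len(case_clusterings)


# ---------------------------------------------------------------------------
# CDR loop flexibility
# ---------------------------------------------------------------------------

def loop_rmsd(
    subject_tcr: Complex,
    reference: Complex,
    corr: Correspondence | None = None,
    loop: LoopDefinition = CDR_LOOPS["CDR3"],
    chain_role: str = "tcr_alpha",
) -> float:
    """Loop RMSD after framework superposition.

    The framework residues (IMGT 1-128 outside the CDRs, both TCR chains)
    of ``subject_tcr`` are superposed onto the reference over backbone
    atoms; the RMSD of the requested loop is then measured over all heavy
    atoms without re-fitting.  ``subject_tcr`` may be an unbound TCR (the
    baseline measure) or the TCR component of a docked model.
    """
    roles = [r for r in TCR_ROLES if r in subject_tcr.role_map and r in reference.role_map]
    if chain_role not in roles:
        raise MissingLoopError(f"chain role {chain_role!r} absent from both structures")
    if corr is None:
        corr = map_complex(subject_tcr, reference, roles=roles)

    framework_ref = select_framework(reference, roles)
    fw_subj, fw_ref = paired_coordsets(subject_tcr, reference, corr, framework_ref)
    fit, _ = kabsch(fw_subj, fw_ref)

    loop_ref_keys = select_cdr(reference, [chain_role], [loop])
    if not loop_ref_keys:
        raise MissingLoopError(
            f"{reference.id}: no {loop.loop_id} residues on {chain_role}"
        )
    try:
        lp_subj, lp_ref = paired_coordsets(
            subject_tcr, reference, corr, loop_ref_keys, atom_names=None
        )
    except Exception as exc:
        raise MissingLoopError(
            f"{subject_tcr.id}: {loop.loop_id} of {chain_role} missing"
        ) from exc
    return rmsd_fixed(CoordSet(lp_subj.labels, fit.apply(lp_subj.coords)), lp_ref)


# ---------------------------------------------------------------------------
# benchmark summary
# ---------------------------------------------------------------------------

def _concat_sequence(cx: Complex, roles: Sequence[str]) -> str:
    from .correspondence import sequence_of

    return "|".join(sequence_of(cx.role_chain(r)) for r in roles if r in cx.role_map)


def benchmark_summary(cases: Sequence[DockingCase]) -> dict[str, int]:
    """Biological feature counts of a benchmark set.

    Counts MHC class I/II and human/mouse TCR cases, unique TCRs and pMHCs
    (exact match of concatenated chain sequences) and the maximum number of
    cases sharing one TCR (resp. pMHC).
    """
    if not cases:
        raise ValueError("no cases")
    class_i = class_ii = human = mouse = 0
    tcr_seqs: list[str] = []
    pmhc_seqs: list[str] = []
    for case in cases:
        meta = case.metadata
        if "mhc_class" not in meta or "species" not in meta or case.reference is None:
            raise ValueError(f"{case.case_id}: metadata (mhc_class, species) and reference required")
        mhc_class = str(meta["mhc_class"]).upper()
        if mhc_class in ("I", "1"):
            class_i += 1
        elif mhc_class in ("II", "2"):
            class_ii += 1
        else:
            raise ValueError(f"{case.case_id}: unknown MHC class {meta['mhc_class']!r}")
        species = str(meta["species"]).lower()
        if species == "human":
            human += 1
        elif species == "mouse":
            mouse += 1
        tcr_seqs.append(_concat_sequence(case.reference, TCR_ROLES))
        pmhc_seqs.append(_concat_sequence(case.reference, PMHC_ROLES))

    def sharing(seqs: list[str]) -> int:
        return max(seqs.count(s) for s in set(seqs))

    return {
        "mhc_class_i": class_i,
        "mhc_class_ii": class_ii,
        "human_tcr": human,
        "mouse_tcr": mouse,
        "unique_tcrs": len(set(tcr_seqs)),
        "unique_pmhcs": len(set(pmhc_seqs)),
        "max_tcr_sharing": sharing(tcr_seqs),
        "max_pmhc_sharing": sharing(pmhc_seqs),
        "total_cases": len(cases),
    }


# ---------------------------------------------------------------------------
# tabular reports
# ---------------------------------------------------------------------------

def success_table(
    results: Sequence[CaseResult],
    tops: Iterable[int] = TOP_N_DEFAULT,
) -> pd.DataFrame:
    """Success-rate table by platform/scenario/N with a best-class breakdown.

    ``success_pct`` counts acceptable-or-better; the breakdown columns give
    the percentage of cases whose *best* top-N model lands in each class.
    Percentages are rounded to one decimal in the table; use the functions
    above for raw values.
    """
    rows = []
    groups: dict[tuple[str, int], list[CaseResult]] = {}
    for r in results:
        groups.setdefault((r.platform, r.scenario), []).append(r)
    for (platform, scenario), group in sorted(groups.items()):
        for n in tops:
            best = [best_in_top(r, n) for r in group]
            row = {
                "platform": platform,
                "scenario": scenario,
                "top_n": n,
                "n_cases": len(group),
                "success_pct": round(success_rate(group, n), 1),
            }
            for quality in QualityClass:
                row[f"best_{quality}"] = round(
                    100.0 * sum(1 for b in best if b == quality) / len(group), 1
                )
            rows.append(row)
    return pd.DataFrame(rows)


def loop_table(records: Sequence[LoopRmsdRecord]) -> pd.DataFrame:
    """Loop-flexibility records as a flat table (one row per model and loop)."""
    return pd.DataFrame(
        {
            "case_id": r.case_id,
            "chain_role": r.chain_role,
            "loop_id": r.loop_id,
            "baseline_rmsd": r.baseline_rmsd,
            "model_rmsd": r.model_rmsd,
            "model_quality": str(r.model_quality),
            "improved": r.model_rmsd < r.baseline_rmsd,
        }
        for r in records
    )
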