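"""Machine-readable outputs: metric CSVs, selection lists, cluster JSON."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .clustering import ClusterParams, ModelRecord
from .correspondence import ResidueKey
from .metrics import InterfaceMetrics, QualityClass


def metrics_table(
    rows: Iterable[tuple[str, str, int, InterfaceMetrics, QualityClass]],
) -> pd.DataFrame:
    """Flat table of per-model CAPRI metrics.

    Each row is ``(case_id, model_id, rank, metrics, quality)``.
    """
    return pd.DataFrame(
        {
            "case": case_id,
            "model_id": model_id,
            "rank": rank,
            "f_nat": m.f_nat,
            "f_nonnat": m.f_nonnat,
            "l_rmsd": m.l_rmsd,
            "i_rmsd": m.i_rmsd,
            "quality": str(quality),
        }
        for case_id, model_id, rank, m, quality in rows
    )


def write_selection(keys: Iterable[ResidueKey], path: str | Path) -> None:
    """Selected residues as whitespace-separated ``chain seq_id icode`` lines.

    This is the plain-text form in which interface selections are handed to
    docking servers; residues are sorted for reproducible output.
    """
    lines = [
        f"{k.chain_id}\t{k.seq_id}\t{k.icode or '-'}"
        for k in sorted(keys)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_selection(path: str | Path) -> set[ResidueKey]:
    keys = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chain, seq, icode = line.split("\t")
        keys.add(ResidueKey(chain, int(seq), "" if icode == "-" else icode))
    return keys


def cluster_report(
    ranked_clusters: Sequence[Sequence[ModelRecord]],
    unclustered: Sequence[str],
    params: ClusterParams = ClusterParams(),
) -> dict:
    """JSON-serialisable cluster summary with per-cluster mean scores."""
    k = params.top_k_for_score
    clusters = []
    for idx, members in enumerate(ranked_clusters, start=1):
        scores = sorted(m.score for m in members)
        clusters.append(
            {
                "cluster_rank": idx,
                "size": len(members),
                "mean_best_score": sum(scores[:k]) / min(k, len(scores)),
                "members": [
                    {"model_id": m.model_id, "rank": m.rank, "score": m.score}
                    for m in members
                ],
            }
        )
    return {
        "params": {
            "fcc_cutoff": params.fcc_cutoff,
            "min_size": params.min_size,
            "top_k_for_score": params.top_k_for_score,
        },
        "clusters": clusters,
        "unclustered": list(unclustered),
    }


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
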