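"""Benchmark-shaped directory trees for docking cases.

A case directory holds ``reference.pdb``, ``tcr_unbound.pdb``,
``pmhc_unbound.pdb``, a ``models/`` folder of ranked model PDBs and a
``metadata.json`` describing the case and the model ranking — the layout
the synthetic generator writes and every CLI subcommand reads.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .metrics import DockingCase
from .structio import CONVENTIONAL_CHAIN, Complex, read_pdb, write_pdb
from .synthetic import DecoyModel
from .metrics import QualityClass


def assign_conventional_roles(cx: Complex) -> Complex:
    """Fill the role map of a structure already on A/B/C/D/E chain IDs."""
    inverse = {v: k for k, v in CONVENTIONAL_CHAIN.items()}
    cx.role_map = {inverse[c]: c for c in cx.chains if c in inverse}
    return cx


def save_case(
    case: DockingCase,
    out_dir: str | Path,
    decoys: Sequence[DecoyModel] = (),
) -> Path:
    """Write a docking case (and optionally its decoy set) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if case.reference is not None:
        write_pdb(case.reference, out / "reference.pdb")
    if case.tcr_unbound is not None:
        write_pdb(case.tcr_unbound, out / "tcr_unbound.pdb")
    if case.pmhc_unbound is not None:
        write_pdb(case.pmhc_unbound, out / "pmhc_unbound.pdb")

    model_entries = []
    if decoys:
        models_dir = out / "models"
        models_dir.mkdir(exist_ok=True)
        for d in sorted(decoys, key=lambda d: d.rank):
            fname = f"rank_{d.rank:04d}.pdb"
            write_pdb(d.complex, models_dir / fname)
            model_entries.append(
                {
                    "model_id": d.model_id,
                    "rank": d.rank,
                    "score": d.score,
                    "file": f"models/{fname}",
                    "planted_quality": str(d.quality),
                }
            )
    meta = {"case_id": case.case_id, **case.metadata, "models": model_entries}
    (out / "metadata.json").write_text(json.dumps(meta, indent=1))
    return out


def load_case(case_dir: str | Path, load_models: bool = True) -> DockingCase:
    """Read a case directory back into a :class:`DockingCase`.

    ``case.models`` is filled with dicts carrying model_id, rank, score and
    (when ``load_models``) the parsed ``Complex``.
    """
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "metadata.json").read_text())
    case = DockingCase(
        case_id=meta.get("case_id", case_dir.name),
        metadata={k: v for k, v in meta.items() if k not in ("case_id", "models")},
    )
    for attr, fname in (
        ("reference", "reference.pdb"),
        ("tcr_unbound", "tcr_unbound.pdb"),
        ("pmhc_unbound", "pmhc_unbound.pdb"),
    ):
        path = case_dir / fname
        if path.exists():
            setattr(case, attr, assign_conventional_roles(read_pdb(path)))
    for entry in meta.get("models", []):
        record = dict(entry)
        if "planted_quality" in record:
            record["planted_quality"] = QualityClass.from_label(record["planted_quality"])
        if load_models:
            record["complex"] = assign_conventional_roles(
                read_pdb(case_dir / entry["file"], structure_id=entry["model_id"])
            )
        case.models.append(record)
    case.models.sort(key=lambda m: m["rank"])
    return case
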