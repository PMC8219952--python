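"""Interface-residue selections for the four docking information scenarios.

Scenario 1 uses only what IMGT numbering gives for free: the six CDR loops
plus the peptide.  Scenario 2 adds unbound MHC residues within 9 A of the
peptide.  Scenarios 3 and 4 borrow from the bound reference: the pMHC
9 A shell around the TCR, and the true 4.5 A interface on both sides.
"""

from tcrdockeval import ScenarioSpec, make_reference, make_unbound, scenario_residues

case = make_reference()
case.tcr_unbound, case.pmhc_unbound = make_unbound(case, 0.0, seed=2)

for n in (1, 2, 3, 4):
    tcr_sel, pmhc_sel = scenario_residues(case, ScenarioSpec(scenario=n))
    needs_ref = "bound reference" if n >= 3 else "unbound only"
    print(
        f"scenario {n} ({needs_ref}): "
        f"{len(tcr_sel)} TCR residues, {len(pmhc_sel)} pMHC residues"
    )

# Selections shrink from the vague scenarios to the true interface of
# scenario 4; these are the residue lists a docking server would receive
# as restraints for each information level.
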