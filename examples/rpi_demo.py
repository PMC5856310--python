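"""Score one patient's three technique plans with the RPI.

The Radiation Planning Index condenses each plan into one number in
[0, 1] from normalized DVH areas: OARs should have small areas, targets
large ones, and a homogeneous target dose is rewarded.  All plans of one
patient share each structure's maximum dose across plans, so the three
techniques are scored on a common dose axis.
"""

from srsqa import default_profiles, render_dose, sample_cohort
from srsqa.compare import plan_rpi_inputs
from srsqa.rpi import RPIStructureTerm, compute_rpi, cross_plan_dmax

cohort = sample_cohort(1, seed=42, lesion_counts=[3])
spec = cohort[0]

plans = {}
for tech, profile in default_profiles().items():
    grid, structures = render_dose(spec, profile)
    plans[tech] = plan_rpi_inputs(grid, structures)

dmax = cross_plan_dmax([(t, dvhs) for t, (dvhs, _) in plans.items()])

print(f"patient {spec.patient_id}, weights all 1.0")
print(f"{'technique':<12}{'RPI (all OARs)':>16}{'RPI (brain only)':>18}")
for tech, (dvhs, sdev) in plans.items():
    target = RPIStructureTerm("total_target", "target", dvhs["total_target"],
                              dmax["total_target"], 1.0, sdev)
    oars = [RPIStructureTerm(n, "oar", d, dmax[n])
            for n, d in dvhs.items() if n != "total_target"]
    brain_only = [o for o in oars if o.name == "healthy_brain"]
    rpi_all = compute_rpi([target], oars).rpi
    rpi_brain = compute_rpi([target], brain_only).rpi
    print(f"{tech:<12}{rpi_all:>16.3f}{rpi_brain:>18.3f}")
print()
print("Scores near 1 mean the plan approaches the ideal (full homogeneous")
print("target coverage, unirradiated OARs); differences between the two")
print("columns show how much the small OARs move the composite score.")
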