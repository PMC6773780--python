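"""Build a biconcave-cell phantom and print its analytic ground truth.

The phantom is the study's reference cell: a discocyte whose projected
surface area, mean optical path difference, dry mass (MCH) and sphericity
match the magnitudes of a healthy red blood cell imaged at 666 nm.
"""

from holocyte import phantom

scenario = phantom.sealed_scenario()
params = phantom.scenario_base_params(scenario)
gt = phantom.ground_truth_record(params)

print(f"cell radius        : {gt.radius_um:.3f} um")
print(f"projected area PSA : {gt.psa_um2:.1f} um^2")
print(f"mean OPD           : {gt.mean_opd_nm:.1f} nm")
print(f"dry mass MCH       : {gt.mch_pg:.1f} pg")
print(f"sphericity k       : {gt.sphericity_k:.2f}")
print()
print("morphing the same cell across the sealed temperature sweep")
print("(dry mass is conserved; area grows, the dimple deepens):")
for t in scenario.temperatures_c:
    m = phantom.morph_for_temperature(params, scenario, t)
    g = phantom.ground_truth_record(m)
    print(
        f"  {t:4.0f} C  PSA {g.psa_um2:5.1f} um^2   k {g.sphericity_k:.3f}"
        f"   MCH {g.mch_pg:.2f} pg"
    )
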