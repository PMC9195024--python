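"""Closed-loop recovery on fully synthetic inputs.

Generates a random valid composition, draws budget-calibrated triplicate
readings around a known true dose ratio, and checks that the measured
ratio recovers the truth within its propagated uncertainty — the
end-to-end consistency argument behind the pipeline's error bars.
"""

from radequiv import markus_ic_budget, measured_ratio, radiological_profile, water
from radequiv.synthetic_data import random_material, synthetic_readings

mat = random_material(seed=2024, n_elements=4)
p = radiological_profile(mat, water())
print(f"random material {mat.name}: elements {dict(mat.fractions)}")
print(f"  density {mat.density:.3f} g/cm^3, Z_eff {p.z_eff:.2f}, "
      f"RED {p.red:.3f}, I {p.mean_excitation:.1f} eV")
print()

budget = markus_ic_budget()
true_ratio = 0.950
num = synthetic_readings(95.0, budget, n=3, seed=1)
den = synthetic_readings(100.0, budget, n=3, seed=2)
res = measured_ratio(num, den, budget, budget)
pull = (res.ratio - true_ratio) / res.u_k1
print(f"true ratio {true_ratio:.3f}; recovered {res} (pull {pull:+.2f} sigma)")
print()
print("Over many seeds the recovered ratio lands within 3 sigma of the truth")
print(">= 99% of the time (see the coverage tests).")
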