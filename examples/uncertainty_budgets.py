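"""Uncertainty budgets and measured dose-ratio propagation.

Combines the bundled ionization-chamber and radiochromic-film budgets in
quadrature and propagates them through a measured dose ratio, reproducing
the +-u (k=1) form in which interface dose ratios are reported.
"""

from radequiv import (
    ReadingSet,
    combine_budget,
    film_budget_co60,
    markus_ic_budget,
    measured_ratio,
)

ic = markus_ic_budget()
film = film_budget_co60()
print(f"Markus chamber combined uncertainty: {combine_budget(ic, 1):.2f}% (k=1), "
      f"{combine_budget(ic, 2):.2f}% (k=2)")
print(f"EBT3 film (Co-60) combined uncertainty: {combine_budget(film, 1):.2f}% (k=1)")
print()

# a film-measured interface ratio: silicone-over-SW vs all-SW readings
num = ReadingSet((95.0,), configuration="MS-SW")
den = ReadingSet((100.0,), configuration="SW-SW")
res = measured_ratio(num, den, film, film, method="film", depth=1.5)
print(f"film dose ratio at 1.5 cm: {res}")
print()
print("The +-0.028 combines both readings' film budgets in quadrature; with")
print("triplicate readings the standard error of each mean would be added too.")
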