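"""Spectrum-averaged coefficient and stopping-power ratios.

Averages the mass energy-absorption coefficient and the restricted
(Delta = 10 keV) collision stopping power of silicone relative to water
over a Co-60 source (two gamma lines) and over a synthetic 6 MV-like
bremsstrahlung spectrum. Ratios below 1 mean silicone absorbs/stops
slightly less than the same mass of water.
"""

from radequiv import mean_stopping_power_ratio, spectrum_averaged_ratio, silicone, water
from radequiv.spectra import co60, mean_energy
from radequiv.synthetic_data import synthetic_6mv_spectrum

si, w = silicone(), water()
for spec in (co60(), synthetic_6mv_spectrum()):
    muen = spectrum_averaged_ratio(si, w, spec, "muen_rho")
    l10 = mean_stopping_power_ratio(si, w, spec, cutoff=0.010)
    s_col = mean_stopping_power_ratio(si, w, spec, cutoff=None)
    print(f"{spec.label} (mean energy {mean_energy(spec):.2f} MeV):")
    print(f"  mass energy-absorption ratio (si/w):     {muen:.4f}")
    print(f"  restricted stopping-power ratio (10 keV): {l10:.4f}")
    print(f"  unrestricted stopping-power ratio:        {s_col:.4f}")
print()
print("The ~0.97 energy-absorption ratio tracks the electrons-per-gram ratio")
print("(Compton dominance); the ~0.94-0.95 stopping ratios additionally feel")
print("silicone's higher mean excitation energy.")
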