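"""Synthetic inputs with known ground truth for every pipeline stage.

Provides random valid compositions, triplicate dosimeter reading sets
whose noise follows a stated uncertainty budget, an analytic depth-dose
stand-in for the Monte Carlo with a closed-form configuration ratio, a
synthetic 6 MV-like bremsstrahlung spectrum, and the bundled reference
fixture set (materials, slab setups, budgets, Co-60 lines). All
generators are pure functions of their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import (
    MaterialComposition,
    silicone,
    silicone_e10,
    silicone_e50,
    solid_water,
    water,
)
from .photon_interactions import compound_coefficients
from .ratio_analysis import (
    ReadingSet,
    UncertaintyBudget,
    combine_budget,
    film_budget_co60,
    film_budget_linac,
    markus_ic_budget,
)
from .slab_transport import SlabPhantom, TransportResult, figure_setups
from .spectra import PhotonSpectrum, co60

DEFAULT_POOL = ("H", "C", "N", "O", "Si", "Cl", "Ca")

#: buildup depth constant (cm) of the analytic depth-dose ramp; Co-60-like.
#: Cancels exactly in same-depth configuration ratios.
BUILDUP_D0_CM = 0.3


def random_material(
    seed: int,
    n_elements: int = 3,
    pool=DEFAULT_POOL,
    density_range: tuple[float, float] = (0.9, 1.2),
    name: str | None = None,
) -> MaterialComposition:
    """Draw a random valid composition.

    Mass fractions are Dirichlet(1) over ``n_elements`` symbols sampled
    without replacement from ``pool``; density is uniform in
    ``density_range``. Always passes composition validation.
    """
    if not pool:
        raise ValueError("element pool is empty")
    if n_elements < 1 or n_elements > len(pool):
        raise ValueError("n_elements must be in [1, len(pool)]")
    rng = np.random.default_rng(seed)
    symbols = [str(s) for s in rng.choice(list(pool), size=n_elements, replace=False)]
    fracs = rng.dirichlet(np.ones(n_elements))
    density = float(rng.uniform(*density_range))
    return MaterialComposition(
        name or f"synthetic-{seed}",
        density,
        dict(zip(symbols, map(float, fracs))),
    )


def synthetic_readings(
    true_dose: float,
    budget: UncertaintyBudget,
    n: int = 3,
    seed: int = 0,
    configuration: str = "synthetic",
) -> ReadingSet:
    """Draw n readings around a true dose with budget-driven noise.

    Readings are normal with mean ``true_dose`` and relative standard
    deviation equal to the budget's combined k=1 percent; non-positive
    draws are rejected and redrawn (relevant only for absurd budgets).
    """
    if true_dose <= 0:
        raise ValueError("true_dose must be positive")
    if n < 1:
        raise ValueError("need n >= 1 readings")
    rng = np.random.default_rng(seed)
    sd = true_dose * combine_budget(budget) / 100.0
    values = []
    while len(values) < n:
        v = float(rng.normal(true_dose, sd))
        if v > 0:
            values.append(v)
    return ReadingSet(tuple(values), configuration=configuration)


def synthetic_6mv_spectrum(n_bins: int = 60, filtration_cm: float = 25.0) -> PhotonSpectrum:
    """Synthetic filtered-bremsstrahlung 6 MV-like spectrum (binned).

    Thin-target bremsstrahlung fluence ~ (E_max - E)/E with E_max = 6 MeV,
    hardened by ``filtration_cm`` of water-equivalent attenuation. The
    default filtration puts the mean energy near 1.8 MeV, typical of
    clinical 6 MV beams. This is a synthetic stand-in, not a measured
    linac spectrum; spectrum-conditional results quoted against it carry
    that caveat.
    """
    e_max = 6.0
    edges = np.linspace(0.05, e_max, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0
    w = water()
    mu = compound_coefficients(w, mids).mu_rho * w.density
    fluence = (e_max - mids) / mids * np.exp(-mu * filtration_cm)
    return PhotonSpectrum(
        "synthetic-6mv", "binned", edges[1:], fluence, e_min=float(edges[0])
    )


@dataclass(frozen=True)
class FixtureSet:
    """The bundled reference fixtures for the slab-interface study."""

    materials: dict[str, MaterialComposition]
    phantoms: dict[str, SlabPhantom]
    budgets: dict[str, UncertaintyBudget]
    spectra: dict[str, PhotonSpectrum]


def paper_fixture_set() -> FixtureSet:
    """Materials, six slab setups, budgets, and the Co-60 two-line source."""
    return FixtureSet(
        materials={
            "water": water(),
            "solid_water": solid_water(),
            "silicone": silicone(),
            "silicone_e10": silicone_e10(),
            "silicone_e50": silicone_e50(),
        },
        phantoms=figure_setups(),
        budgets={
            "markus_ic": markus_ic_budget(),
            "film_co60": film_budget_co60(),
            "film_linac": film_budget_linac(),
        },
        spectra={"co60": co60()},
    )


# ---------------------------------------------------------------------------
# analytic depth-dose stand-in

def _primary_kerma_curve(phantom: SlabPhantom, spec: PhotonSpectrum) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free primary collision-kerma curve on the phantom's bins.

    Exponential attenuation of each spectral line through the layer
    stack, converted with the local mass energy-absorption coefficient,
    inverse-square corrected to the source, with a 1 - exp(-d/d0) buildup
    ramp (the ramp cancels in same-depth ratios).
    """
    e_lines, w_lines = spec.as_lines()
    n_bins = int(round(phantom.total_thickness / phantom.bin_cm))
    centers = (np.arange(n_bins) + 0.5) * phantom.bin_cm
    edges = phantom.layer_edges()
    dose = np.zeros(n_bins)
    for e, wgt in zip(e_lines, w_lines):
        mu_layers = np.array(
            [
                float(compound_coefficients(mat, [e]).mu_rho[0]) * mat.density
                for mat, _ in phantom.layers
            ]
        )
        muen_layers = np.array(
            [float(compound_coefficients(mat, [e]).muen_rho[0]) for mat, _ in phantom.layers]
        )
        layer_idx = np.searchsorted(edges, centers, side="right") - 1
        # optical depth from surface to each bin center
        thick = np.diff(edges)
        cum = np.concatenate([[0.0], np.cumsum(mu_layers * thick)])
        depth_in_layer = centers - edges[layer_idx]
        tau = cum[layer_idx] + mu_layers[layer_idx] * depth_in_layer
        src = phantom.axis_depth_cm - phantom.sad_cm
        invsq = (phantom.sad_cm / (centers - src)) ** 2
        buildup = 1.0 - np.exp(-centers / BUILDUP_D0_CM)
        dose += wgt * e * muen_layers[layer_idx] * np.exp(-tau) * invsq * buildup
    return centers, dose


def synthetic_depth_dose(
    phantom: SlabPhantom,
    spec: PhotonSpectrum,
    noise_relative: float = 0.0,
    seed: int = 0,
) -> TransportResult:
    """Fast analytic stand-in for :func:`radequiv.slab_transport.simulate`.

    Returns a TransportResult-shaped curve built from the closed-form
    primary kerma model, with optional Gaussian relative noise. The
    closed-form configuration ratio for any two phantoms is
    :func:`closed_form_ratio`.
    """
    centers, dose = _primary_kerma_curve(phantom, spec)
    rng = np.random.default_rng(seed)
    if noise_relative > 0:
        noisy = dose * (1.0 + noise_relative * rng.standard_normal(dose.size))
        noisy = np.maximum(noisy, 0.0)
        stderr = dose * noise_relative
    else:
        noisy = dose
        stderr = np.zeros_like(dose)
    return TransportResult(
        depth_bins=centers,
        dose=noisy,
        stderr=stderr,
        histories=0,
        seed=seed,
        phantom=phantom,
        spectrum=spec.label,
        estimator="analytic",
    )


def closed_form_ratio(
    phantom_a: SlabPhantom, phantom_b: SlabPhantom, depth: float, spec: PhotonSpectrum
) -> float:
    """True dose ratio A/B at a depth under the analytic kerma model."""
    ca, da = _primary_kerma_curve(phantom_a, spec)
    cb, db = _primary_kerma_curve(phantom_b, spec)
    return float(np.interp(depth, ca, da) / np.interp(depth, cb, db))
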