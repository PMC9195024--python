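"""Elemental compositions and stoichiometric radiological quantities.

A material is a named vector of elemental mass fractions plus a bulk
density. From that alone (no interaction data) one can derive the
quantities that drive megavoltage water-equivalence: electron densities,
relative electron density (RED), the Mayneord effective atomic number,
and the Bragg-additivity mean excitation energy.

The three reference materials of the slab-interface study — water,
Gammex/RMI-457 solid water, and generic polydimethylsiloxane silicone
(C2H6OSi) — ship as named constructors.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .constants import N_AVOGADRO, element

#: tolerance on |sum of mass fractions - 1|; admits published compositions
#: whose printed fractions sum to 0.999 without renormalization.
FRACTION_SUM_TOL = 0.002


@dataclass(frozen=True)
class MaterialComposition:
    """A named elemental mass-fraction vector with bulk density.

    Parameters
    ----------
    name : material identifier.
    density : bulk mass density rho (g/cm^3).
    fractions : element symbol -> mass fraction w_i. Must be non-negative
        and sum to 1 within :data:`FRACTION_SUM_TOL`.
    mean_excitation_override_eV : if set, :func:`mean_excitation_energy`
        returns this instead of the Bragg-additivity value. Used for
        pre-defined materials with an ICRU-recommended I (water: 75 eV).
    original_fraction_sum : sum of the fractions as supplied, recorded
        before any renormalization.
    """

    name: str
    density: float
    fractions: Mapping[str, float]
    mean_excitation_override_eV: float | None = None
    original_fraction_sum: float = field(default=float("nan"), compare=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive, got {self.density}")
        if not self.fractions:
            raise ValueError(f"{self.name}: composition has no elements")
        for sym, w in self.fractions.items():
            element(sym)  # raises on unknown symbol
            if w < 0:
                raise ValueError(f"{self.name}: negative mass fraction {w} for {sym}")
        s = sum(self.fractions.values())
        if abs(s - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"{self.name}: mass fractions sum to {s:.4f}, outside "
                f"1 +- {FRACTION_SUM_TOL}; pass renormalize=True to parse_material"
            )
        if math.isnan(self.original_fraction_sum):
            object.__setattr__(self, "original_fraction_sum", s)

    @property
    def symbols(self) -> list[str]:
        return list(self.fractions)

    def electrons_per_gram_mol(self) -> float:
        """Sum_i w_i Z_i / A_i (mol electrons per gram, times 1/N_A)."""
        return sum(w * element(s).Z / element(s).A for s, w in self.fractions.items())


@dataclass(frozen=True)
class RadiologicalProfile:
    """Derived per-material radiological quantities (one summary-table row)."""

    material: MaterialComposition
    z_eff: float
    electrons_per_gram: float
    electrons_per_cm3: float
    red: float
    mean_excitation: float

    def __post_init__(self) -> None:
        zs = [element(s).Z for s in self.material.fractions]
        if not (min(zs) <= self.z_eff <= max(zs) + 1e-9):
            raise ValueError("z_eff outside constituent Z range")
        if self.red <= 0:
            raise ValueError("red must be positive")


# ---------------------------------------------------------------------------
# parsing

def parse_material(source, *, renormalize: bool = False) -> MaterialComposition:
    """Parse a material document into a validated composition.

    ``source`` may be a mapping with keys ``name``, ``density_g_cm3`` and
    ``elements`` (symbol -> mass fraction), a path to a YAML/JSON file with
    those keys, or a path to a tab-separated file with header
    ``symbol<TAB>mass_fraction`` and a ``#density=`` comment line.

    With ``renormalize=True`` the fractions are scaled to sum exactly to 1;
    the original sum is recorded on the returned composition either way.
    """
    if isinstance(source, (str, os.PathLike)):
        doc = _read_material_file(os.fspath(source))
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        raise TypeError(f"cannot parse material from {type(source).__name__}")

    for key in ("name", "density_g_cm3", "elements"):
        if key not in doc:
            raise ValueError(f"material document missing key {key!r}")
    fractions = {str(k): float(v) for k, v in doc["elements"].items()}
    for sym, w in fractions.items():
        element(sym)
        if w < 0:
            raise ValueError(f"negative mass fraction {w} for {sym}")
    original_sum = sum(fractions.values())
    if renormalize:
        if original_sum <= 0:
            raise ValueError("cannot renormalize: fractions sum to zero")
        fractions = {s: w / original_sum for s, w in fractions.items()}
    return MaterialComposition(
        name=str(doc["name"]),
        density=float(doc["density_g_cm3"]),
        fractions=fractions,
        mean_excitation_override_eV=doc.get("mean_excitation_override_eV"),
        original_fraction_sum=original_sum,
    )


def _read_material_file(path: str) -> dict:
    with open(path) as fh:
        text = fh.read()
    # try structured formats first, fall back to the TSV dialect
    for loader in (json.loads, yaml.safe_load):
        try:
            doc = loader(text)
        except Exception:
            continue
        if isinstance(doc, dict) and "elements" in doc:
            return doc
    return _parse_material_tsv(text, default_name=os.path.splitext(os.path.basename(path))[0])


def _parse_material_tsv(text: str, default_name: str) -> dict:
    density = None
    name = default_name
    rows: dict[str, float] = {}
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    for ln in lines:
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if body.startswith("density="):
                density = float(body.split("=", 1)[1])
            elif body.startswith("name="):
                name = body.split("=", 1)[1].strip()
            continue
        parts = ln.split("\t")
        if parts[0].lower() == "symbol":
            continue
        if len(parts) != 2:
            raise ValueError(f"malformed TSV material line: {ln!r}")
        rows[parts[0]] = float(parts[1])
    if density is None:
        raise ValueError("TSV material file lacks a '#density=' line")
    return {"name": name, "density_g_cm3": density, "elements": rows}


# ---------------------------------------------------------------------------
# stoichiometric quantities

def electron_density(
    mat: MaterialComposition, reference: MaterialComposition
) -> tuple[float, float, float]:
    """Electron densities and RED of ``mat`` relative to ``reference``.

    Returns ``(electrons_per_gram, electrons_per_cm3, red)`` with
    electrons_per_gram = N_A * sum_i w_i Z_i / A_i,
    electrons_per_cm3 = rho * electrons_per_gram, and
    red = electrons_per_cm3(mat) / electrons_per_cm3(reference).
    """
    epg = N_AVOGADRO * mat.electrons_per_gram_mol()
    epcm3 = mat.density * epg
    ref_epcm3 = reference.density * N_AVOGADRO * reference.electrons_per_gram_mol()
    return epg, epcm3, epcm3 / ref_epcm3


def effective_atomic_number(
    mat: MaterialComposition,
    exponent: float = 2.94,
    weighting: str = "electron_fraction",
) -> float:
    """Mayneord power-law effective atomic number.

    Z_eff = (sum_i a_i Z_i^m)^(1/m) with exponent m (default 2.94).
    With ``weighting="electron_fraction"`` (the classic form) the weights
    are a_i = w_i Z_i/A_i normalized to unit sum; with
    ``weighting="mass_fraction"`` the normalized mass fractions are used
    directly. The two variants differ noticeably for silicon-rich media;
    both are exposed because published tabulations mix them.
    """
    if exponent <= 0:
        raise ValueError("Mayneord exponent must be positive")
    if weighting == "electron_fraction":
        raw = {s: w * element(s).Z / element(s).A for s, w in mat.fractions.items()}
    elif weighting == "mass_fraction":
        raw = dict(mat.fractions)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    total = sum(raw.values())
    return sum(a / total * element(s).Z ** exponent for s, a in raw.items()) ** (1.0 / exponent)


def mean_excitation_energy(mat: MaterialComposition) -> float:
    """Mean excitation energy I (eV) by Bragg additivity.

    ln I = [sum w_i (Z_i/A_i) ln I_adj,i] / [sum w_i (Z_i/A_i)], using the
    compound-adjusted elemental constants of the bundled table. Materials
    carrying ``mean_excitation_override_eV`` (pre-defined media with an
    ICRU-recommended I, e.g. water at 75 eV) return the override.
    """
    if mat.mean_excitation_override_eV is not None:
        return float(mat.mean_excitation_override_eV)
    num = 0.0
    den = 0.0
    for s, w in mat.fractions.items():
        rec = element(s)
        t = w * rec.Z / rec.A
        num += t * math.log(rec.I_adj)
        den += t
    return math.exp(num / den)


def radiological_profile(
    mat: MaterialComposition,
    reference: MaterialComposition,
    exponent: float = 2.94,
    weighting: str = "electron_fraction",
) -> RadiologicalProfile:
    """Aggregate Z_eff, electron densities, RED and I into one record."""
    epg, epcm3, red = electron_density(mat, reference)
    return RadiologicalProfile(
        material=mat,
        z_eff=effective_atomic_number(mat, exponent, weighting),
        electrons_per_gram=epg,
        electrons_per_cm3=epcm3,
        red=red,
        mean_excitation=mean_excitation_energy(mat),
    )


# ---------------------------------------------------------------------------
# reference materials

def water() -> MaterialComposition:
    """Liquid water, I overridden to the ICRU value of 75 eV."""
    return MaterialComposition(
        "water", 1.00, {"H": 0.112, "O": 0.888}, mean_excitation_override_eV=75.0
    )


def solid_water() -> MaterialComposition:
    """Gammex/RMI-457 epoxy-based solid water (printed fractions sum 0.999)."""
    return MaterialComposition(
        "solid_water",
        1.03,
        {"H": 0.081, "C": 0.672, "N": 0.024, "O": 0.198, "Cl": 0.001, "Ca": 0.023},
    )


def silicone(density: float = 1.01) -> MaterialComposition:
    """Generic polydimethylsiloxane (C2H6OSi) moldable silicone."""
    return MaterialComposition(
        "silicone", density, {"H": 0.081, "C": 0.324, "O": 0.216, "Si": 0.379}
    )


def silicone_e10() -> MaterialComposition:
    """Soft commercial silicone variant (shore 00-10), density 1.04 g/cm^3."""
    m = silicone(1.04)
    return MaterialComposition("silicone_e10", 1.04, m.fractions)


def silicone_e50() -> MaterialComposition:
    """Firm commercial silicone variant (shore 00-50), density 1.07 g/cm^3."""
    m = silicone(1.07)
    return MaterialComposition("silicone_e50", 1.07, m.fractions)


REFERENCE_MATERIALS = {
    "water": water,
    "solid_water": solid_water,
    "silicone": silicone,
    "silicone_e10": silicone_e10,
    "silicone_e50": silicone_e50,
}


def get_material(name: str) -> MaterialComposition:
    """Resolve a named reference material."""
    try:
        return REFERENCE_MATERIALS[name]()
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; known: {sorted(REFERENCE_MATERIALS)}"
        ) from None
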