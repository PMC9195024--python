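"""Layered slab phantoms and the analog photon Monte Carlo driver.

The geometry emulates the slab-interface study: a point source at
source-to-axis distance (SAD) upstream, a divergent square field defined
at the axis plane, a stack of homogeneous material slabs, and
collision-kerma scoring in 0.1 cm axial bins over a centered square
scoring area. Electron transport is not modeled: collision kerma equals
dose at charged-particle-equilibrium depths, which is where the interface
ratios are compared; the sub-millimetre electron-fluence perturbation at
material interfaces is explicitly outside this model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import yaml

from . import _kernel
from .materials import MaterialComposition, get_material
from .photon_interactions import compound_coefficients
from .spectra import PhotonSpectrum

#: photons below this energy are absorbed on the spot (their range is far
#: below the bin width in these media)
PHOTON_CUTOFF_MEV = 0.010


@dataclass(frozen=True)
class SlabPhantom:
    """Layered slab geometry with scoring protocol.

    Depth is measured from the beam-entry surface; layer boundaries must
    align with scoring-bin edges. The axis plane (100 cm SAD in the
    reference setups) sits at ``axis_depth_cm`` below the entry surface.
    """

    name: str
    layers: tuple[tuple[MaterialComposition, float], ...]
    axis_depth_cm: float
    sad_cm: float = 100.0
    field_cm: float = 10.0
    lateral_extent_cm: float = 15.0
    bin_cm: float = 0.1
    scoring_area_cm: float = 1.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError(f"{self.name}: phantom needs at least one layer")
        for mat, t in self.layers:
            if t <= 0:
                raise ValueError(f"{self.name}: non-positive layer thickness {t}")
        if not (0 < self.axis_depth_cm <= self.total_thickness + 1e-9):
            raise ValueError(
                f"{self.name}: axis depth {self.axis_depth_cm} outside stack "
                f"of {self.total_thickness} cm"
            )
        if self.scoring_area_cm > self.lateral_extent_cm:
            raise ValueError(f"{self.name}: scoring area exceeds lateral extent")
        for _, t in self.layers:
            if abs(round(t / self.bin_cm) - t / self.bin_cm) > 1e-9:
                raise ValueError(
                    f"{self.name}: layer thickness {t} not a multiple of the "
                    f"{self.bin_cm} cm bin width"
                )

    @property
    def total_thickness(self) -> float:
        return sum(t for _, t in self.layers)

    def layer_edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([t for _, t in self.layers])])


@dataclass(frozen=True)
class TransportResult:
    """Depth-binned collision-kerma dose with per-bin statistical error.

    ``dose`` is mean energy imparted per unit mass per history (MeV/g);
    ``stderr`` the history-by-history batch standard error of that mean.
    """

    depth_bins: np.ndarray
    dose: np.ndarray
    stderr: np.ndarray
    histories: int
    seed: int
    phantom: SlabPhantom
    spectrum: str
    estimator: str
    emitted_energy: float = 0.0
    deposited_energy: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.stderr < 0) or np.any(self.dose < 0):
            raise ValueError("dose and stderr must be non-negative")


# ---------------------------------------------------------------------------
# construction

def build_phantom(config, name: str = "phantom") -> SlabPhantom:
    """Build a validated phantom from a config mapping or YAML/JSON file.

    Expected keys: ``layers`` (list of {material, thickness_cm}),
    ``axis_depth_cm``; optional ``sad_cm``, ``field_cm``, ``bin_cm``,
    ``lateral_extent_cm``, ``scoring_area_cm``, ``name``. Material entries
    may be names of bundled reference materials or inline material
    documents.
    """
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise TypeError("phantom config must be a mapping or a path to one")
    layers = []
    for entry in config["layers"]:
        spec = entry["material"]
        if isinstance(spec, str):
            mat = get_material(spec)
        else:
            from .materials import parse_material

            mat = parse_material(spec)
        layers.append((mat, float(entry["thickness_cm"])))
    return SlabPhantom(
        name=str(config.get("name", name)),
        layers=tuple(layers),
        axis_depth_cm=float(config["axis_depth_cm"]),
        sad_cm=float(config.get("sad_cm", 100.0)),
        field_cm=float(config.get("field_cm", 10.0)),
        lateral_extent_cm=float(config.get("lateral_extent_cm", 15.0)),
        bin_cm=float(config.get("bin_cm", 0.1)),
        scoring_area_cm=float(config.get("scoring_area_cm", 1.0)),
    )


def figure_setups() -> dict[str, SlabPhantom]:
    """The six reference slab configurations of the interface study.

    Upper slab of 1.5 cm (bolus-like) or 5.0 cm (phantom-like) over a
    5.0 cm backing, in the combinations SW-SW, MS-SW, MS-MS, with the
    axis plane at the slab interface.
    """
    combos = {"SWSW": ("solid_water", "solid_water"),
              "MSSW": ("silicone", "solid_water"),
              "MSMS": ("silicone", "silicone")}
    out = {}
    for depth in (1.5, 5.0):
        for i, (tag, (upper, lower)) in enumerate(combos.items(), start=1):
            key = f"setup-{i}-{tag}-{depth}"
            out[key] = SlabPhantom(
                name=key,
                layers=((get_material(upper), depth), (get_material(lower), 5.0)),
                axis_depth_cm=depth,
            )
    return out


# ---------------------------------------------------------------------------
# simulation

def simulate(
    phantom: SlabPhantom,
    spec: PhotonSpectrum,
    histories: int,
    seed: int,
    estimator: str = "track_length",
    primary_only: bool = False,
    batches: int = 10,
) -> TransportResult:
    """Run the analog photon MC and return the depth-dose tally.

    ``estimator`` selects the collision-kerma tally: ``"track_length"``
    (expected-value, the default — every flight segment crossing the
    scoring column contributes) or ``"collision"`` (the sampled energy
    transferred to electrons is deposited at each interaction point).
    ``primary_only`` terminates histories at their first interaction,
    banking the full photon energy there; the track-length tally then
    measures the primary collision kerma (an exponential-attenuation
    oracle exists for homogeneous phantoms).

    Statistics are history-by-history over ``batches`` equal batches; the
    result is bitwise-reproducible for a given (seed, histories, batches).
    """
    if histories < 1:
        raise ValueError("histories must be >= 1")
    if estimator not in ("track_length", "collision"):
        raise ValueError(f"unknown estimator {estimator!r}")
    e_lines, w_lines = spec.as_lines()
    e_grid = np.geomspace(PHOTON_CUTOFF_MEV, float(e_lines[-1]), 160)

    z_edges = phantom.layer_edges()
    n_bins = int(round(phantom.total_thickness / phantom.bin_cm))
    bin_centers = (np.arange(n_bins) + 0.5) * phantom.bin_cm
    bin_layer = (np.searchsorted(z_edges, bin_centers, side="right") - 1).astype(np.int64)
    bin_rho = np.array([phantom.layers[l][0].density for l in bin_layer])

    n_layers = len(phantom.layers)
    log_mu_incoh = np.empty((n_layers, e_grid.size))
    log_mu_pe = np.empty_like(log_mu_incoh)
    log_mu_pair = np.empty_like(log_mu_incoh)
    log_mutr_mass = np.empty_like(log_mu_incoh)
    for l, (mat, _) in enumerate(phantom.layers):
        cs = compound_coefficients(mat, e_grid)
        rho = mat.density
        log_mu_incoh[l] = np.log(np.maximum(cs.incoherent * rho, 1e-300))
        log_mu_pe[l] = np.log(np.maximum(cs.photoelectric * rho, 1e-300))
        log_mu_pair[l] = np.log(np.maximum(cs.pair * rho, 1e-300))
        log_mutr_mass[l] = np.log(np.maximum(cs.mutr_rho, 1e-300))

    line_cumw = np.cumsum(np.asarray(w_lines, dtype=float))
    line_cumw /= line_cumw[-1]

    batches = max(1, min(batches, histories))
    batch_sizes = np.full(batches, histories // batches, dtype=np.int64)
    batch_sizes[: histories % batches] += 1

    v_bin = phantom.scoring_area_cm**2 * phantom.bin_cm
    batch_dose = np.empty((batches, n_bins))
    emitted = 0.0
    deposited = 0.0
    for b in range(batches):
        bin_edep = np.zeros(n_bins)
        em, dep = _kernel.run_batch(
            int(batch_sizes[b]),
            int((seed + 7919 * b) % 2**31),
            np.asarray(e_lines, dtype=float),
            line_cumw,
            float(phantom.axis_depth_cm - phantom.sad_cm),
            float(phantom.axis_depth_cm),
            float(phantom.field_cm / 2.0),
            z_edges,
            float(phantom.lateral_extent_cm / 2.0),
            float(phantom.scoring_area_cm / 2.0),
            float(phantom.bin_cm),
            n_bins,
            bin_layer,
            bin_rho,
            float(np.log(e_grid[0])),
            float(np.log(e_grid[1]) - np.log(e_grid[0])),
            e_grid.size,
            log_mu_incoh,
            log_mu_pe,
            log_mu_pair,
            log_mutr_mass,
            PHOTON_CUTOFF_MEV,
            0 if estimator == "track_length" else 1,
            1 if primary_only else 0,
            bin_edep,
        )
        emitted += em
        deposited += dep
        if estimator == "track_length":
            batch_dose[b] = bin_edep / v_bin / batch_sizes[b]
        else:
            batch_dose[b] = bin_edep / (bin_rho * v_bin) / batch_sizes[b]

    dose = batch_dose.mean(axis=0)
    if batches > 1:
        stderr = batch_dose.std(axis=0, ddof=1) / np.sqrt(batches)
    else:
        stderr = np.zeros(n_bins)
    return TransportResult(
        depth_bins=bin_centers,
        dose=dose,
        stderr=stderr,
        histories=histories,
        seed=seed,
        phantom=phantom,
        spectrum=spec.label,
        estimator=estimator,
        emitted_energy=emitted,
        deposited_energy=deposited,
    )


# ---------------------------------------------------------------------------
# post-processing

def dose_at_depth(result: TransportResult, depth: float) -> tuple[float, float]:
    """Dose and statistical error at a depth, interpolated between bins.

    Linear interpolation between bin centers; the error is taken
    conservatively as the larger of the two neighbouring bins'.
    """
    bins = result.depth_bins
    if not (bins[0] - 1e-9 <= depth <= bins[-1] + 1e-9):
        raise ValueError(
            f"depth {depth} outside scored range [{bins[0]}, {bins[-1]}] cm"
        )
    d = float(np.interp(depth, bins, result.dose))
    i = int(np.clip(np.searchsorted(bins, depth), 1, bins.size - 1))
    err = float(max(result.stderr[i - 1], result.stderr[i]))
    return d, err


def dose_at_interface(result: TransportResult, side: str = "upper") -> tuple[float, float]:
    """Scoring-bin dose adjacent to the axis-plane interface.

    ``side="upper"`` returns the last bin of the upper slab (the film
    position between slabs, the reference convention); ``side="lower"``
    the first bin of the lower slab.
    """
    axis = result.phantom.axis_depth_cm
    half = result.phantom.bin_cm / 2.0
    depth = axis - half if side == "upper" else axis + half
    idx = int(np.argmin(np.abs(result.depth_bins - depth)))
    return float(result.dose[idx]), float(result.stderr[idx])


def configuration_ratio(
    result_a: TransportResult, result_b: TransportResult, depth: float
) -> tuple[float, float]:
    """Dose ratio A/B at a depth with independent-error propagation."""
    if result_a.spectrum != result_b.spectrum:
        raise ValueError("configuration ratio requires a shared source spectrum")
    da, ea = dose_at_depth(result_a, depth)
    db, eb = dose_at_depth(result_b, depth)
    if db == 0:
        raise ZeroDivisionError("denominator dose is zero at the requested depth")
    ratio = da / db
    err = ratio * float(np.hypot(ea / da if da else 0.0, eb / db))
    return ratio, err


def write_result_csv(result: TransportResult, path) -> None:
    """Write `depth_cm, dose_per_history, stderr` columns."""
    arr = np.column_stack([result.depth_bins, result.dose, result.stderr])
    header = "depth_cm,dose_per_history,stderr"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
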