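"""Photon spectra: weighting kernels for mean ratios and MC sources.

Two kinds are supported: discrete line spectra (e.g. the two Co-60 gamma
lines) and binned fluence spectra read from the EGSnrc-style text dialect
(title line; ``N E_min MODE`` header with MODE 0 = fluence per bin; then
N rows of ``E_top weight``). Binned spectra are treated as discrete lines
at bin midpoints for all weighting integrals.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhotonSpectrum",
    "make_line_spectrum",
    "read_spectrum",
    "write_spectrum",
    "mean_energy",
    "co60",
]


@dataclass(frozen=True)
class PhotonSpectrum:
    """A normalized photon fluence spectrum.

    ``entries`` are (energy MeV, weight) pairs with strictly increasing,
    positive energies; weights are fluence per line/bin, normalized to unit
    sum. For ``kind="binned"`` the energies are bin top edges and ``e_min``
    is the declared bottom edge of the first bin.
    """

    label: str
    kind: str  # "discrete_lines" | "binned"
    energies: np.ndarray
    weights: np.ndarray
    e_min: float | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if self.kind not in ("discrete_lines", "binned"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if e.size == 0:
            raise ValueError("spectrum has no entries")
        if e.size != w.size:
            raise ValueError("energies and weights differ in length")
        if np.any(e <= 0) or np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing and positive")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 with at least one positive")
        if self.kind == "binned":
            if self.e_min is None:
                raise ValueError("binned spectrum requires e_min")
            if not (0 <= self.e_min < e[0]):
                raise ValueError("e_min must lie in [0, first bin top)")
        total = w.sum()
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w / total)

    def as_lines(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (energies, weights) as effective discrete lines.

        Binned spectra are collapsed to bin midpoints (first bin midpoint
        uses the declared minimum energy as its lower edge).
        """
        if self.kind == "discrete_lines":
            return self.energies, self.weights
        lower = np.concatenate([[self.e_min], self.energies[:-1]])
        return (lower + self.energies) / 2.0, self.weights

    @property
    def max_energy(self) -> float:
        return float(self.energies[-1])


def make_line_spectrum(lines, label: str = "lines") -> PhotonSpectrum:
    """Build a normalized discrete spectrum from (energy, weight) pairs.

    Entries are re-sorted in ascending energy; weights of duplicate
    energies are not merged (duplicates raise, as for any non-increasing
    grid).
    """
    arr = np.asarray(list(lines), dtype=float)
    if arr.size == 0:
        raise ValueError("empty line list")
    order = np.argsort(arr[:, 0], kind="stable")
    return PhotonSpectrum(label, "discrete_lines", arr[order, 0], arr[order, 1])


def co60() -> PhotonSpectrum:
    """Co-60 modeled as two equal-weight lines at 1.17 and 1.33 MeV."""
    return make_line_spectrum([(1.17, 1.0), (1.33, 1.0)], label="co60")


def read_spectrum(source, label: str | None = None) -> PhotonSpectrum:
    """Read a binned spectrum in the EGSnrc-style text dialect.

    Layout: line 1 free-text title; line 2 ``N E_min MODE`` with MODE 0
    (fluence per bin) the only supported mode; then N lines ``E_top weight``
    with strictly increasing top edges.
    """
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            text = fh.read()
        default_label = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    else:
        text = source.read()
        default_label = "spectrum"
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ValueError("spectrum file too short: need title and header")
    header = lines[1].split()
    if len(header) != 3:
        raise ValueError(f"malformed spectrum header {lines[1]!r}: need 'N E_min MODE'")
    try:
        n = int(header[0])
        e_min = float(header[1])
        mode = int(float(header[2]))
    except ValueError as exc:
        raise ValueError(f"malformed spectrum header {lines[1]!r}") from exc
    if mode != 0:
        raise ValueError(f"unsupported spectrum MODE {mode}; only 0 (fluence per bin)")
    rows = lines[2:]
    if len(rows) != n:
        raise ValueError(f"declared {n} bins but found {len(rows)} data rows")
    data = np.array([[float(tok) for tok in row.split()[:2]] for row in rows])
    if data.shape[1] != 2:
        raise ValueError("each spectrum row must hold 'E_top weight'")
    return PhotonSpectrum(
        label or lines[0].strip() or default_label, "binned", data[:, 0], data[:, 1], e_min=e_min
    )


def write_spectrum(spec: PhotonSpectrum, path) -> None:
    """Write a binned spectrum in the dialect read by :func:`read_spectrum`.

    Round-trips exactly: read(write(s)) reproduces entries bit-for-bit
    (weights are stored normalized).
    """
    if spec.kind != "binned":
        raise ValueError("only binned spectra have a file representation")
    buf = io.StringIO()
    buf.write(f"{spec.label}\n")
    buf.write(f"{spec.energies.size} {float(spec.e_min)!r} 0\n")
    for e, w in zip(spec.energies, spec.weights):
        buf.write(f"{float(e)!r} {float(w)!r}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def mean_energy(spec: PhotonSpectrum) -> float:
    """Fluence-weighted mean energy (MeV); binned spectra use midpoints."""
    e, w = spec.as_lines()
    return float(np.sum(e * w))
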