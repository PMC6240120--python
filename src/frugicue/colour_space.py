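"""Avian tetrahedral colour space.

Transforms fruit reflectance spectra into the colour coordinates used by
tetrachromatic birds: quantum catches of the four single cones (UVS, SWS,
MWS, LWS), their projection into a regular tetrahedron whose vertices
represent sole excitation of a single cone class, and an achromatic
brightness value from the double cone.

Coordinates follow the convention that the achromatic point (equal
stimulation of all four cones) sits at the origin, red reflectance pulls
``x`` positive and blue pulls it negative, green pulls ``y`` positive,
and UV reflectance pulls ``z`` positive.  Chromaticity is the Euclidean
distance to the origin and is bounded by the tetrahedron circumradius
0.75.

Receptor sensitivities are generated from visual-pigment templates
(Govardovskii A1 nomogram by default) with configurable peak wavelengths;
defaults approximate the ultraviolet-sensitive (UVS) passerine retina of
the blue tit.  Oil-droplet filtering is not modelled separately: the
effective sensitivity of a cone is represented by its pigment template
alone (users may supply measured, droplet-corrected curves instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WAVELENGTH_GRID",
    "TETRA_VERTICES",
    "ReflectanceSpectrum",
    "ReceptorSet",
    "ConeCatch",
    "TetraColour",
    "make_receptors",
    "quantum_catches",
    "to_tetra",
    "brightness",
    "spectrum_to_colour",
    "read_spectra_csv",
    "write_colours_csv",
]

#: standard wavelength grid, nm (5-nm steps, 300-700 inclusive)
WAVELENGTH_GRID = np.arange(300.0, 705.0, 5.0)
GRID_STEP = 5.0

#: blue-tit-like single-cone peaks (nm), UVS < SWS < MWS < LWS, and double cone
DEFAULT_LAMBDA_MAX = {"uvs": 371.0, "sws": 449.0, "mws": 502.0, "lws": 563.0}
DEFAULT_DOUBLE_LAMBDA_MAX = 563.0

#: regular tetrahedron, circumradius 0.75.  Rotation chosen so that the
#: LWS (red) vertex lies at +x, MWS (green) toward +y, SWS (blue) toward
#: -x, and UVS at +z; other published variants differ only by rotation.
TETRA_VERTICES = {
    "uvs": np.array([0.0, 0.0, 0.75]),
    "lws": np.array([np.sqrt(0.5), 0.0, -0.25]),
    "mws": np.array([-np.sqrt(0.125), np.sqrt(0.375), -0.25]),
    "sws": np.array([-np.sqrt(0.125), -np.sqrt(0.375), -0.25]),
}

_CONE_ORDER = ("uvs", "sws", "mws", "lws")


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Reflectance on the standard 300-700 nm grid (unitless fraction)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.shape != refl.shape:
            raise ValueError("wavelengths and reflectance must have equal length")
        if not np.array_equal(wl, WAVELENGTH_GRID):
            raise ValueError(
                "spectrum must be on the 300-700 nm grid with 5-nm steps"
            )
        if np.any(refl < 0) or not np.all(np.isfinite(refl)):
            raise ValueError("reflectance values must be finite and >= 0")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", refl)

    @classmethod
    def flat(cls, level: float) -> "ReflectanceSpectrum":
        return cls(WAVELENGTH_GRID, np.full_like(WAVELENGTH_GRID, float(level)))


@dataclass(frozen=True)
class ReceptorSet:
    """Four unit-area single-cone curves plus the double-cone curve."""

    wavelengths: np.ndarray
    single: dict  # name -> curve, keys uvs/sws/mws/lws
    double: np.ndarray
    lambda_max: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        if not np.array_equal(wl, WAVELENGTH_GRID):
            raise ValueError("receptor curves must be on the standard grid")
        for name in _CONE_ORDER:
            if name not in self.single:
                raise ValueError(f"missing single-cone curve: {name}")
        curves = {k: np.asarray(v, float) for k, v in self.single.items()}
        dbl = np.asarray(self.double, float)
        for name, c in list(curves.items()) + [("double", dbl)]:
            if c.shape != wl.shape:
                raise ValueError(f"curve {name} not on the grid")
            if np.any(c < 0):
                raise ValueError(f"curve {name} has negative sensitivity")
            area = float(np.sum(c) * GRID_STEP)
            if abs(area - 1.0) > 1e-6:
                raise ValueError(f"curve {name} area {area:.8f} != 1")
        peaks = [wl[np.argmax(curves[n])] for n in _CONE_ORDER]
        if not all(a < b for a, b in zip(peaks, peaks[1:])):
            raise ValueError("single-cone peaks must be ordered uvs<sws<mws<lws")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "single", curves)
        object.__setattr__(self, "double", dbl)


@dataclass(frozen=True)
class ConeCatch:
    """Raw and simplex-normalized quantum catches."""

    raw: dict            # name -> raw catch (arbitrary units)
    relative: dict       # name -> relative catch, sums to 1
    double_raw: float
    illuminant_total: dict | None = None  # raw catches of a perfect reflector

    def __post_init__(self):
        rel = np.array([self.relative[n] for n in _CONE_ORDER])
        if abs(rel.sum() - 1.0) > 1e-9:
            raise ValueError("relative catches must sum to 1")
        if np.any(rel < -1e-12) or np.any(rel > 1 + 1e-12):
            raise ValueError("relative catches must lie in [0, 1]")
        if any(self.raw[n] < 0 for n in _CONE_ORDER):
            raise ValueError("raw catches must be >= 0")


@dataclass(frozen=True)
class TetraColour:
    """Cartesian colour point (x, y, z), brightness a, chromaticity r."""

    x: float
    y: float
    z: float
    a: float

    def __post_init__(self):
        if self.r > 0.75 + 1e-9:
            raise ValueError("colour point outside the tetrahedron circumsphere")

    @property
    def r(self) -> float:
        return float(np.sqrt(self.x**2 + self.y**2 + self.z**2))


# ---------------------------------------------------------------------------
# receptor templates


def _govardovskii_a1(wl: np.ndarray, lmax: float) -> np.ndarray:
    """A1 visual pigment nomogram (alpha plus beta band), un-normalized."""
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lmax
    b = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    return alpha + beta


def _gaussian_template(wl: np.ndarray, lmax: float, width: float = 40.0) -> np.ndarray:
    return np.exp(-0.5 * ((wl - lmax) / width) ** 2)


_TEMPLATES = {"govardovskii": _govardovskii_a1, "gaussian": _gaussian_template}


def make_receptors(
    lambda_max: dict | None = None,
    template: str = "govardovskii",
    double_lambda_max: float | None = None,
) -> ReceptorSet:
    """Build a receptor set from a pigment template.

    Parameters
    ----------
    lambda_max
        Mapping cone name (uvs, sws, mws, lws) -> peak wavelength in nm.
        Defaults to blue-tit-like peaks (371, 449, 502, 563).
    template
        "govardovskii" (A1 nomogram, default) or "gaussian".
    double_lambda_max
        Peak of the double cone; defaults to the LWS peak.
    """
    lmax = dict(DEFAULT_LAMBDA_MAX if lambda_max is None else lambda_max)
    if double_lambda_max is None:
        double_lambda_max = lmax.get("lws", DEFAULT_DOUBLE_LAMBDA_MAX)
    try:
        fn = _TEMPLATES[template]
    except KeyError:
        raise ValueError(f"unknown template {template!r}") from None
    for name in _CONE_ORDER:
        if name not in lmax:
            raise ValueError(f"missing lambda_max for receptor {name}")
        if not (WAVELENGTH_GRID[0] <= lmax[name] <= WAVELENGTH_GRID[-1]):
            raise ValueError(
                f"lambda_max for receptor {name} ({lmax[name]} nm) outside the "
                "300-700 nm grid"
            )
    vals = [lmax[n] for n in _CONE_ORDER]
    if not all(a < b for a, b in zip(vals, vals[1:])):
        raise ValueError("lambda_max must increase uvs < sws < mws < lws")

    def unit(curve: np.ndarray) -> np.ndarray:
        return curve / (curve.sum() * GRID_STEP)

    single = {n: unit(fn(WAVELENGTH_GRID, lmax[n])) for n in _CONE_ORDER}
    double = unit(fn(WAVELENGTH_GRID, float(double_lambda_max)))
    return ReceptorSet(WAVELENGTH_GRID, single, double, lambda_max=lmax)


# ---------------------------------------------------------------------------
# catches and colour coordinates


def quantum_catches(
    spectrum: ReflectanceSpectrum,
    receptors: ReceptorSet,
    illuminant: np.ndarray | None = None,
) -> ConeCatch:
    """Quantum catch of each receptor: sum of R * S_i * I * d-lambda.

    ``illuminant`` is a per-wavelength irradiance on the standard grid;
    ``None`` means the ideal flat illuminant (1 everywhere).
    """
    if illuminant is None:
        illum = np.ones_like(WAVELENGTH_GRID)
    else:
        illum = np.asarray(illuminant, dtype=float)
        if illum.shape != WAVELENGTH_GRID.shape:
            raise ValueError("illuminant must be on the standard grid")
        if np.any(illum < 0) or not np.any(illum > 0):
            raise ValueError("illuminant must be >= 0 and not all zero")
    prod = spectrum.reflectance * illum
    raw = {
        n: float(np.sum(prod * receptors.single[n]) * GRID_STEP)
        for n in _CONE_ORDER
    }
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("degenerate spectrum: zero total quantum catch")
    relative = {n: raw[n] / total for n in _CONE_ORDER}
    double_raw = float(np.sum(prod * receptors.double) * GRID_STEP)
    perfect = {
        n: float(np.sum(illum * receptors.single[n]) * GRID_STEP)
        for n in _CONE_ORDER
    }
    perfect["double"] = float(np.sum(illum * receptors.double) * GRID_STEP)
    return ConeCatch(raw=raw, relative=relative, double_raw=double_raw,
                     illuminant_total=perfect)


def to_tetra(catch: ConeCatch, a: float | None = None) -> TetraColour:
    """Map simplex catches to the Cartesian tetrahedron point.

    The point is the catch-weighted mixture of the four cone vertices, so
    equal catches land exactly on the origin (the achromatic point).
    """
    rel = np.array([catch.relative[n] for n in _CONE_ORDER])
    if abs(rel.sum() - 1.0) > 1e-6 or np.any(rel < -1e-6):
        raise ValueError("relative catches are off the simplex")
    pt = sum(catch.relative[n] * TETRA_VERTICES[n] for n in _CONE_ORDER)
    if a is None:
        a = brightness(catch)
    return TetraColour(x=float(pt[0]), y=float(pt[1]), z=float(pt[2]), a=a)


def brightness(catch: ConeCatch) -> float:
    """Double-cone catch normalized by a perfect (R == 1) reflector.

    The normalization makes ``a`` scale-free and confined to (0, 1] for
    physical reflectances, with high values perceived as bright.
    """
    if catch.illuminant_total is None:
        raise ValueError("catch lacks the perfect-reflector normalization")
    denom = catch.illuminant_total["double"]
    if denom <= 0:
        raise ValueError("degenerate illuminant for brightness normalization")
    return float(catch.double_raw / denom)


def spectrum_to_colour(
    spectrum: ReflectanceSpectrum,
    receptors: ReceptorSet | None = None,
    illuminant: np.ndarray | None = None,
) -> TetraColour:
    """Convenience: spectrum -> (x, y, z, a) in one call."""
    if receptors is None:
        receptors = make_receptors()
    catch = quantum_catches(spectrum, receptors, illuminant)
    return to_tetra(catch)


# ---------------------------------------------------------------------------
# I/O


def read_spectra_csv(path) -> dict:
    """Read spectra from long (species, wavelength_nm, reflectance) or wide
    (species x wavelength-columns) CSV; returns {species: ReflectanceSpectrum}.
    """
    df = pd.read_csv(path)
    out = {}
    cols = {c.lower(): c for c in df.columns}
    if "wavelength_nm" in cols and "reflectance" in cols and "species" in cols:
        for sp, grp in df.groupby(cols["species"]):
            grp = grp.sort_values(cols["wavelength_nm"])
            out[str(sp)] = ReflectanceSpectrum(
                grp[cols["wavelength_nm"]].to_numpy(float),
                grp[cols["reflectance"]].to_numpy(float),
            )
    else:
        if "species" not in cols:
            raise ValueError("spectra CSV needs a 'species' column")
        wl_cols = [c for c in df.columns if c != cols["species"]]
        wl = np.array([float(c) for c in wl_cols])
        order = np.argsort(wl)
        for _, row in df.iterrows():
            out[str(row[cols["species"]])] = ReflectanceSpectrum(
                wl[order], row[wl_cols].to_numpy(float)[order]
            )
    return out


def write_colours_csv(colours: dict, path) -> pd.DataFrame:
    """Write {species: TetraColour} as CSV with columns species, x, y, z, a."""
    df = pd.DataFrame(
        [(sp, c.x, c.y, c.z, c.a) for sp, c in sorted(colours.items())],
        columns=["species", "x", "y", "z", "a"],
    )
    df.to_csv(path, index=False)
    return df
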