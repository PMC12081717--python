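"""Core in-memory containers for multimodal kidney microscopy data.

Conventions used throughout the package:

* arrays are indexed ``(z, y, x)`` (volumes) or ``(y, x)`` (planes) or
  ``(y, x, wavenumber)`` (hyperspectral stacks), 0-based, y increasing
  downward;
* physical calibration is carried as ``pixel_size_um`` (in-plane) and
  ``z_spacing_um`` (axial), and every micron/pixel conversion goes through
  these fields;
* wavenumber axes are strictly increasing, in cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, Mapping

import numpy as np

from .exceptions import AxisMismatchError, FormatError, InvalidAxisError

#: canonical channel names of the co-registered label-free modalities:
#: four SRS bands, the two autofluorescence channels, SHG collagen and a
#: nuclei channel (Hoechst or lipid:protein-derived).
CHANNEL_NAMES = (
    "lipid_2850",
    "sat_2880",
    "protein_2940",
    "unsat_3011",
    "nadh",
    "flavin",
    "shg",
    "nuclei",
)


def _check_wavenumbers(wavenumbers: np.ndarray) -> np.ndarray:
    wn = np.asarray(wavenumbers, dtype=float)
    if wn.ndim != 1 or wn.size < 2:
        raise InvalidAxisError("wavenumber axis must be 1-D with at least 2 samples")
    if not np.all(np.diff(wn) > 0):
        raise InvalidAxisError("wavenumber axis must be strictly increasing")
    return wn


@dataclass
class HyperspectralStack:
    """A hyperspectral SRS image: one C-H-region spectrum per pixel.

    Parameters
    ----------
    data : ndarray, shape (y, x, n_wavenumbers)
        Non-negative SRS intensities.
    wavenumbers : ndarray, shape (n_wavenumbers,)
        Strictly increasing Raman shift axis in cm^-1.
    pixel_size_um : float
        In-plane pixel pitch in microns.
    meta : dict
        Free-form acquisition metadata; carried, never interpreted.
    """

    data: np.ndarray
    wavenumbers: np.ndarray
    pixel_size_um: float = 1.0
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavenumbers = _check_wavenumbers(self.wavenumbers)
        if self.data.ndim != 3:
            raise FormatError("stack data must be 3-D (y, x, wavenumber)")
        if self.data.shape[2] != self.wavenumbers.size:
            raise FormatError(
                f"stack has {self.data.shape[2]} spectral planes but "
                f"{self.wavenumbers.size} listed wavenumbers"
            )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("stack data must be finite")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self):
        return self.data.shape

    def band(self, wavenumber_cm1: float, tol_cm1: float = 5.0) -> np.ndarray:
        """Return the image plane at the axis sample nearest ``wavenumber_cm1``.

        Raises :class:`InvalidAxisError` if the nearest sample is further
        than ``tol_cm1`` away.
        """
        idx = int(np.argmin(np.abs(self.wavenumbers - wavenumber_cm1)))
        if abs(self.wavenumbers[idx] - wavenumber_cm1) > tol_cm1:
            raise InvalidAxisError(
                f"no axis sample within {tol_cm1} cm^-1 of {wavenumber_cm1}"
            )
        return self.data[:, :, idx]


@dataclass
class ReferenceSpectrum:
    """A named reference spectrum for one lipid subtype (e.g. cholesterol, TAG)."""

    name: str
    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _check_wavenumbers(self.wavenumbers)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != self.wavenumbers.shape:
            raise FormatError("reference axes and intensities differ in length")
        if np.any(self.intensities < 0):
            raise ValueError("reference intensities must be non-negative")
        if self.intensities.max() <= 0:
            raise ValueError("reference must have positive maximum intensity")

    def resample(self, axis: np.ndarray, shift_cm1: float = 0.0) -> np.ndarray:
        """Linearly interpolate the (optionally shifted) spectrum onto ``axis``.

        A positive ``shift_cm1`` evaluates r(nu - shift): the reference is
        displaced toward higher wavenumbers. Out-of-range values are extended
        with the edge values.
        """
        axis = np.asarray(axis, dtype=float)
        return np.interp(axis - shift_cm1, self.wavenumbers, self.intensities)


@dataclass
class MultimodalVolume:
    """Co-registered (z, y, x) channel set from one imaging session."""

    channels: Dict[str, np.ndarray]
    z_spacing_um: float = 1.0
    pixel_size_um: float = 1.0
    meta: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("volume must contain at least one channel")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise FormatError(f"channels disagree in shape: {sorted(shapes)}")
        (shape,) = shapes
        if len(shape) != 3:
            raise FormatError("channels must be 3-D (z, y, x)")
        if self.z_spacing_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("voxel spacings must be positive")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class PhasorCoordinates:
    """Per-pixel spectral phasor (G, S) coordinates at one harmonic."""

    G: np.ndarray
    S: np.ndarray
    harmonic: int
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.harmonic < 1:
            raise ValueError("harmonic must be a positive integer")
        if not (self.G.shape == self.S.shape == self.valid_mask.shape):
            raise FormatError("phasor component shapes differ")


def common_axis(refs) -> np.ndarray:
    """Return the shared wavenumber axis of several references, or raise."""
    axis = refs[0].wavenumbers
    for ref in refs[1:]:
        if ref.wavenumbers.shape != axis.shape or not np.allclose(
            ref.wavenumbers, axis
        ):
            raise AxisMismatchError(
                f"reference {ref.name!r} is not on the common wavenumber axis"
            )
    return axis


def as_channel_dict(obj) -> Mapping[str, np.ndarray]:
    """Accept a MultimodalVolume or a plain name->array mapping."""
    if isinstance(obj, MultimodalVolume):
        return obj.channels
    return obj
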