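"""Shared spectral utilities: phasor transform, 3-peak linear unmixing,
per-label channel fractions.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datatypes import (
    HyperspectralStack,
    MultimodalVolume,
    PhasorCoordinates,
    as_channel_dict,
)
from .exceptions import InvalidAxisError

#: default endmember intensities at (2850, 2880, 2940) cm^-1 for the
#: two-component lipid/protein unmix; overridable from measured references.
LIPID_ENDMEMBER = (1.0, 0.7, 0.3)
PROTEIN_ENDMEMBER = (0.2, 0.5, 1.0)
UNMIX_PEAKS = (2850.0, 2880.0, 2940.0)


def phasor_transform(
    stack: HyperspectralStack,
    harmonic: int = 1,
    window: Optional[Tuple[float, float]] = None,
) -> PhasorCoordinates:
    """Spectral phasor coordinates of every pixel.

    Over the spectral window [nu0, nu0 + dnu] (default: the full axis),

        G = sum_i I(nu_i) cos(2 pi n (nu_i - nu0) / dnu) / sum_i I(nu_i)
        S = sum_i I(nu_i) sin(2 pi n (nu_i - nu0) / dnu) / sum_i I(nu_i)

    at harmonic n. Pixels whose total intensity in the window is zero are
    flagged invalid (G = S = 0 there) rather than propagating NaN.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    wn = stack.wavenumbers
    if window is None:
        lo, hi = wn[0], wn[-1]
    else:
        lo, hi = window
    sel = (wn >= lo) & (wn <= hi)
    if sel.sum() < 2:
        raise InvalidAxisError("spectral window contains fewer than 2 samples")
    nu = wn[sel]
    data = stack.data[:, :, sel]
    phase = 2.0 * np.pi * harmonic * (nu - nu[0]) / (nu[-1] - nu[0])
    total = data.sum(axis=2)
    valid = total > 0
    safe_total = np.where(valid, total, 1.0)
    G = np.where(valid, (data * np.cos(phase)).sum(axis=2) / safe_total, 0.0)
    S = np.where(valid, (data * np.sin(phase)).sum(axis=2) / safe_total, 0.0)
    return PhasorCoordinates(G=G, S=S, harmonic=harmonic, valid_mask=valid)


def _nnls2(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares for a 2-column design, vectorized.

    For two variables the NNLS solution is either the unconstrained
    least-squares solution (when it is non-negative) or lies on one of the
    axes; all three candidates are enumerated per pixel.
    """
    # unconstrained solution via normal equations
    AtA = A.T @ A
    AtY = Y @ A  # (N, 2)
    inv = np.linalg.inv(AtA)
    X0 = AtY @ inv.T  # (N, 2)

    a0, a1 = A[:, 0], A[:, 1]
    x_only0 = np.clip(AtY[:, 0] / (a0 @ a0), 0.0, None)
    x_only1 = np.clip(AtY[:, 1] / (a1 @ a1), 0.0, None)

    def _resid(x0, x1):
        pred = np.outer(x0, a0) + np.outer(x1, a1)
        return ((Y - pred) ** 2).sum(axis=1)

    zeros = np.zeros(Y.shape[0])
    r_axis0 = _resid(x_only0, zeros)
    r_axis1 = _resid(zeros, x_only1)
    use_axis0 = r_axis0 <= r_axis1
    X = np.where(
        use_axis0[:, None],
        np.stack([x_only0, zeros], axis=1),
        np.stack([zeros, x_only1], axis=1),
    )
    interior = (X0 >= 0).all(axis=1)
    X[interior] = X0[interior]
    return X


def linear_unmix(
    stack: HyperspectralStack,
    peaks: Sequence[float] = UNMIX_PEAKS,
    lipid_endmember: Sequence[float] = LIPID_ENDMEMBER,
    protein_endmember: Sequence[float] = PROTEIN_ENDMEMBER,
) -> Tuple[np.ndarray, np.ndarray]:
    """Unmix the three dominant C-H peaks into lipid and protein images.

    The intensities at 2850, 2880 and 2940 cm^-1 (the peaks carrying most
    of the C-H-region variance) are solved per pixel as a non-negative
    least-squares mixture of a pure-lipid and a pure-protein 3-vector.
    Returns the two coefficient images, clipped at zero.
    """
    bands = np.stack([stack.band(p) for p in peaks], axis=2)  # (y, x, 3)
    A = np.stack(
        [np.asarray(lipid_endmember, float), np.asarray(protein_endmember, float)],
        axis=1,
    )  # (3, 2)
    ny, nx, _ = bands.shape
    X = _nnls2(A, bands.reshape(-1, len(peaks)))
    lipid = np.clip(X[:, 0].reshape(ny, nx), 0.0, None)
    protein = np.clip(X[:, 1].reshape(ny, nx), 0.0, None)
    return lipid, protein


def channel_fractions(
    volume: Union[MultimodalVolume, Mapping[str, np.ndarray]],
    labels: np.ndarray,
) -> pd.DataFrame:
    """Simplex-normalized mean channel intensity per label.

    For each label present in ``labels`` (0 treated as background and
    omitted), the mean intensity of every channel over the label's pixels
    is divided by the sum over channels, so each row sums to 1.
    """
    channels: Dict[str, np.ndarray] = dict(as_channel_dict(volume))
    labels = np.asarray(labels)
    first = next(iter(channels.values()))
    if labels.shape != first.shape:
        raise ValueError("labels shape must match channel shape")
    ids = [int(i) for i in np.unique(labels) if i != 0]
    rows = {}
    for lab in ids:
        sel = labels == lab
        means = np.array([channels[name][sel].mean() for name in channels])
        total = means.sum()
        rows[lab] = means / total if total > 0 else means
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(channels))
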