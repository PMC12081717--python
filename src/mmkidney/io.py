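"""TIFF / OME-TIFF file I/O with YAML sidecars.

Layout conventions:

* a :class:`~mmkidney.datatypes.HyperspectralStack` is a multi-page TIFF
  with one page per wavenumber; the axis lives in the sidecar (inline list
  or a two-column CSV referenced via ``wavenumbers_csv``), never implied by
  page order alone;
* a :class:`~mmkidney.datatypes.MultimodalVolume` is a multi-page TIFF
  ordered channel-major (all z-planes of channel 0, then channel 1, ...)
  with the channel order listed in the sidecar;
* the sidecar schema is
  ``{channels: [...], wavenumbers: [...] | wavenumbers_csv: path,
  pixel_size_um: float, z_spacing_um: float}``;
* OME-TIFF channel names, when present, substitute for a sidecar.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import HyperspectralStack, MultimodalVolume, ReferenceSpectrum
from .exceptions import FormatError, InvalidAxisError

PathLike = Union[str, Path]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: HyperspectralStack, path: PathLike) -> Path:
    """Write a hyperspectral stack as multi-page float32 TIFF + YAML sidecar."""
    path = Path(path)
    pages = np.moveaxis(stack.data, 2, 0).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "wavenumbers": [float(w) for w in stack.wavenumbers],
        "pixel_size_um": float(stack.pixel_size_um),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return path


def write_volume(volume: MultimodalVolume, path: PathLike) -> Path:
    """Write a multimodal volume channel-major as multi-page float32 TIFF."""
    path = Path(path)
    names = sorted(volume.channels)
    pages = np.concatenate([volume.channels[n] for n in names], axis=0).astype(
        np.float32
    )
    tifffile.imwrite(path, pages)
    sidecar = {
        "channels": names,
        "pixel_size_um": float(volume.pixel_size_um),
        "z_spacing_um": float(volume.z_spacing_um),
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(sidecar, fh)
    return path


def _ome_channel_names(tif: tifffile.TiffFile) -> Optional[List[str]]:
    xmlstr = tif.ome_metadata
    if not xmlstr:
        return None
    try:
        root = ET.fromstring(xmlstr)
    except ET.ParseError:
        return None
    names = [
        ch.get("Name")
        for ch in root.iter()
        if ch.tag.endswith("Channel") and ch.get("Name")
    ]
    return names or None


def read_stack(
    path: PathLike, sidecar: Optional[PathLike] = None
) -> Union[HyperspectralStack, MultimodalVolume]:
    """Read a phantom or acquisition TIFF back into its typed container.

    The wavenumber axis (stacks) or channel list (volumes) comes from the
    YAML sidecar, or from OME metadata for OME-TIFF volumes; a file without
    either is rejected rather than silently indexed by plane number.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        ome_names = _ome_channel_names(tif)
    if pages.ndim == 2:
        pages = pages[None]
    elif pages.ndim == 4:
        # OME CZYX array: flatten to channel-major pages
        pages = pages.reshape(-1, *pages.shape[-2:])

    sidecar_file = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta = None
    if sidecar_file.exists():
        with open(sidecar_file) as fh:
            meta = yaml.safe_load(fh) or {}

    if meta is not None and ("wavenumbers" in meta or "wavenumbers_csv" in meta):
        if "wavenumbers" in meta:
            wn = np.asarray(meta["wavenumbers"], dtype=float)
        else:
            csv = pd.read_csv(Path(sidecar_file).parent / meta["wavenumbers_csv"])
            wn = csv.iloc[:, 0].to_numpy(dtype=float)
        if wn.size != pages.shape[0]:
            raise FormatError(
                f"TIFF has {pages.shape[0]} pages but {wn.size} listed wavenumbers"
            )
        return HyperspectralStack(
            data=np.moveaxis(pages, 0, 2).astype(float),
            wavenumbers=wn,
            pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        )

    if meta is not None and "channels" in meta:
        names = list(meta["channels"])
    elif ome_names:
        names = ome_names
        meta = meta or {}
    else:
        raise InvalidAxisError(
            f"{path}: no sidecar wavenumber axis or channel list, and no OME "
            "channel metadata; refusing to guess plane identities"
        )

    if pages.shape[0] % len(names) != 0:
        raise FormatError(
            f"{pages.shape[0]} pages do not divide evenly into "
            f"{len(names)} channels"
        )
    nz = pages.shape[0] // len(names)
    channels = {
        name: pages[i * nz : (i + 1) * nz].astype(float)
        for i, name in enumerate(names)
    }
    return MultimodalVolume(
        channels=channels,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        z_spacing_um=float(meta.get("z_spacing_um", 1.0)),
    )


def write_ome_volume(volume: MultimodalVolume, path: PathLike) -> Path:
    """Write a volume as OME-TIFF with channel names in the OME metadata."""
    path = Path(path)
    names = sorted(volume.channels)
    data = np.stack([volume.channels[n] for n in names], axis=0).astype(np.float32)
    # OME axes: CZYX
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",  # a trailing dim of <=4 is not samples
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": volume.pixel_size_um,
            "PhysicalSizeY": volume.pixel_size_um,
            "PhysicalSizeZ": volume.z_spacing_um,
        },
    )
    return path


def read_reference_csv(path: PathLike, name: Optional[str] = None) -> ReferenceSpectrum:
    """Read a two-column (wavenumber_cm1, intensity) reference spectrum CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("reference CSV needs two columns (wavenumber, intensity)")
    return ReferenceSpectrum(
        name=name or path.stem,
        wavenumbers=df.iloc[:, 0].to_numpy(dtype=float),
        intensities=df.iloc[:, 1].to_numpy(dtype=float),
    )


def write_reference_csv(ref: ReferenceSpectrum, path: PathLike) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"wavenumber_cm1": ref.wavenumbers, "intensity": ref.intensities}
    ).to_csv(path, index=False)
    return path


def write_float_tiff(image: np.ndarray, path: PathLike) -> Path:
    """Write a float map (similarity score, ratio image, RGB) as 32-bit TIFF."""
    path = Path(path)
    image = np.asarray(image, dtype=np.float32)
    photometric = "rgb" if image.ndim == 3 and image.shape[2] == 3 else "minisblack"
    tifffile.imwrite(path, image, photometric=photometric)
    return path


def write_label_tiff(labels: np.ndarray, path: PathLike) -> Path:
    """Write a label image as 16-bit TIFF (warns above 65535 labels)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:  # pragma: no cover
        warnings.warn("label image exceeds 16-bit range; clipping")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path
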