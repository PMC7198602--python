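"""Image stacks, ROI masks and the file formats that carry them.

The package works on 3D fluorescence stacks in (Z, Y, X) axis order with
physical voxel sizes in nanometres; a voxel's physical position is the
position of its centre, ``index * voxel_size``.  OME-TIFF is the canonical
interchange format (voxel sizes live in the OME metadata); plain multi-page
TIFFs are accepted when the caller supplies the voxel size.  Nested region
masks (cell ⊃ nucleus ⊃ nucleolus) travel as a single 8-bit label TIFF where
the label encodes the deepest compartment a voxel belongs to.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile
import yaml

logger = logging.getLogger("nucleoring")

#: nm per unit, for the OME PhysicalSize* units we are willing to read.
_UNIT_TO_NM = {
    "nm": 1.0,
    "µm": 1000.0,  # µm, the OME default
    "um": 1000.0,
    "μm": 1000.0,  # GREEK SMALL LETTER MU variant
    "mm": 1.0e6,
}


@dataclass
class ImageStack:
    """A 3D intensity array with physical voxel sizes.

    Parameters
    ----------
    data:
        Array of shape (Z, Y, X); any real dtype, all values finite.
    voxel_size:
        Physical size of one voxel along (Z, Y, X), in nanometres.
    channel_name:
        Free-text channel label (e.g. ``"UBF"``); purely informational.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D stack (Z, Y, X), got {self.data.ndim}D data"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive numbers, got {vs}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, channel_name: str | None = None) -> "ImageStack":
        """Same geometry, new pixel data."""
        return ImageStack(
            data=data,
            voxel_size=self.voxel_size,
            channel_name=self.channel_name if channel_name is None else channel_name,
        )


@dataclass
class RoiSet:
    """Nested binary regions of interest: nucleolus ⊆ nucleus ⊆ cell."""

    cell: np.ndarray
    nucleus: np.ndarray
    nucleolus: np.ndarray

    def __post_init__(self) -> None:
        self.cell = np.asarray(self.cell, dtype=bool)
        self.nucleus = np.asarray(self.nucleus, dtype=bool)
        self.nucleolus = np.asarray(self.nucleolus, dtype=bool)
        if not (self.cell.shape == self.nucleus.shape == self.nucleolus.shape):
            raise ValueError(
                "ROI masks must be congruent: "
                f"cell {self.cell.shape}, nucleus {self.nucleus.shape}, "
                f"nucleolus {self.nucleolus.shape}"
            )
        bad = int(np.count_nonzero(self.nucleolus & ~self.nucleus))
        if bad:
            raise ValueError(
                f"ROI nesting violation: {bad} nucleolus voxel(s) outside the nucleus"
            )
        bad = int(np.count_nonzero(self.nucleus & ~self.cell))
        if bad:
            raise ValueError(
                f"ROI nesting violation: {bad} nucleus voxel(s) outside the cell"
            )
        if not self.nucleolus.any():
            warnings.warn("RoiSet has an empty nucleolus mask", stacklevel=2)
            logger.warning("RoiSet has an empty nucleolus mask")

    @property
    def extranucleolar(self) -> np.ndarray:
        """Nuclear voxels outside the nucleolus (nucleus ∖ nucleolus)."""
        return self.nucleus & ~self.nucleolus

    def named_masks(self) -> dict[str, np.ndarray]:
        """The four analysis regions in reporting order."""
        return {
            "cell": self.cell,
            "nucleus": self.nucleus,
            "nucleolus": self.nucleolus,
            "extranucleolar": self.extranucleolar,
        }

    def to_label_image(self) -> np.ndarray:
        """8-bit label image: 0 outside, 1 cell, 2 nucleus, 3 nucleolus."""
        lbl = np.zeros(self.cell.shape, dtype=np.uint8)
        lbl[self.cell] = 1
        lbl[self.nucleus] = 2
        lbl[self.nucleolus] = 3
        return lbl


# ---------------------------------------------------------------------------
# stack I/O


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack as OME-TIFF with voxel-size metadata (in nm)."""
    path = Path(path)
    vz, vy, vx = stack.voxel_size
    metadata = {
        "axes": "ZYX",
        "PhysicalSizeZ": vz,
        "PhysicalSizeZUnit": "nm",
        "PhysicalSizeY": vy,
        "PhysicalSizeYUnit": "nm",
        "PhysicalSizeX": vx,
        "PhysicalSizeXUnit": "nm",
    }
    if stack.channel_name:
        metadata["Channel"] = {"Name": [stack.channel_name]}
    tifffile.imwrite(
        path, stack.data, ome=True, metadata=metadata, photometric="minisblack"
    )
    return path


def _parse_ome_metadata(ome_xml: str) -> tuple[tuple[float, float, float] | None, str]:
    """Extract (Z, Y, X) voxel size in nm and the first channel name."""
    try:
        root = ElementTree.fromstring(ome_xml)
    except ElementTree.ParseError:
        return None, ""
    pixels = None
    channel_name = ""
    for elem in root.iter():
        tag = elem.tag.rsplit("}", 1)[-1]
        if tag == "Pixels" and pixels is None:
            pixels = elem
        elif tag == "Channel" and not channel_name:
            channel_name = elem.get("Name", "") or ""
    if pixels is None:
        return None, channel_name
    sizes = []
    for axis in ("Z", "Y", "X"):
        raw = pixels.get(f"PhysicalSize{axis}")
        if raw is None:
            return None, channel_name
        unit = pixels.get(f"PhysicalSize{axis}Unit", "µm")
        factor = _UNIT_TO_NM.get(unit)
        if factor is None:
            raise ValueError(f"unsupported OME physical-size unit {unit!r}")
        sizes.append(float(raw) * factor)
    return (sizes[0], sizes[1], sizes[2]), channel_name


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_name: str | None = None,
) -> ImageStack:
    """Read a 3D TIFF / OME-TIFF stack.

    Voxel sizes come from the OME metadata when present; metadata always wins
    over the ``voxel_size`` argument, which is the fallback for plain TIFFs.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For non-3D data, or when no voxel size is available from either
        metadata or the argument.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.series[0].asarray()
        ome_xml = tf.ome_metadata
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"expected 3D stack in {path.name}, got {data.ndim}D data of shape "
            f"{data.shape}"
        )
    meta_vs: tuple[float, float, float] | None = None
    meta_channel = ""
    if ome_xml:
        meta_vs, meta_channel = _parse_ome_metadata(ome_xml)
    if meta_vs is not None:
        vs = meta_vs
    elif voxel_size is not None:
        vs = tuple(float(v) for v in voxel_size)  # type: ignore[assignment]
    else:
        raise ValueError(
            f"{path.name} carries no voxel-size metadata; pass voxel_size=(z, y, x) "
            "in nanometres (e.g. from the run configuration)"
        )
    name = channel_name if channel_name is not None else meta_channel
    return ImageStack(data=data, voxel_size=vs, channel_name=name or "")


# ---------------------------------------------------------------------------
# ROI I/O


def write_roiset(rois: RoiSet, path: str | Path) -> Path:
    """Write nested masks as one 8-bit label TIFF (0/1/2/3)."""
    path = Path(path)
    tifffile.imwrite(path, rois.to_label_image(), photometric="minisblack")
    return path


def read_roiset(source) -> RoiSet:
    """Load nested ROI masks.

    ``source`` is either a single label-image TIFF (labels 1/2/3 for
    cell/nucleus/nucleolus, cumulative) or a mapping with ``cell``,
    ``nucleus`` and ``nucleolus`` paths to binary mask TIFFs.  Nesting is
    validated; a violation raises (no silent repair), naming the number of
    offending voxels.
    """
    if isinstance(source, (str, Path)):
        lbl = np.squeeze(tifffile.imread(source))
        if lbl.ndim != 3:
            raise ValueError(f"expected 3D label image, got {lbl.ndim}D")
        return RoiSet(cell=lbl >= 1, nucleus=lbl >= 2, nucleolus=lbl >= 3)
    try:
        paths = {k: source[k] for k in ("cell", "nucleus", "nucleolus")}
    except (TypeError, KeyError) as exc:
        raise TypeError(
            "source must be a label-image path or a mapping with keys "
            "'cell', 'nucleus', 'nucleolus'"
        ) from exc
    masks = {k: np.squeeze(tifffile.imread(p)) > 0 for k, p in paths.items()}
    return RoiSet(**masks)


# ---------------------------------------------------------------------------
# configuration and run logging


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration root in {path} must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable sha256 of a configuration dict (canonical JSON)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(outdir: str | Path, seed: int, config: dict) -> Path:
    """Write the reproducibility manifest for one run."""
    import scipy
    import skimage

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": int(seed),
        "config_sha256": config_hash(config),
        "versions": {
            "nucleoring": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
            "tifffile": tifffile.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
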