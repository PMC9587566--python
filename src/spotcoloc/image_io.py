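"""Reading, validation and channel-role assignment for multi-channel z-stacks.

The analysis operates on 3-channel, 8-bit confocal z-stacks: two signal
channels carrying the fluorescent labels to be co-localized plus one nuclear
counterstain.  Stacks are held in a single canonical layout — ``(z, channel,
row, col)`` — regardless of how the container on disk orders its axes.
Coordinates throughout the package are 0-based ``(row, col)`` with pixel
centers at integer positions; sub-pixel positions are floats in this frame.

Supported containers are TIFF/OME-TIFF (via :mod:`tifffile`) and LIF via the
optional ``readlif`` package.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

#: The three channel roles every stack must cover.
ROLES = ("signal_a", "signal_b", "nuclear")

#: Maximum number of focal planes accepted per stack.
MAX_Z_PLANES = 30

#: Required number of channels.
N_CHANNELS = 3

#: Maximum representable intensity (8-bit acquisition).
MAX_INTENSITY = 255


class FormatError(ValueError):
    """Raised when a file cannot be read as a supported 3-channel stack."""


class StackValidationError(ValueError):
    """Raised when a stack violates the input prerequisites."""


class ChannelMappingError(ValueError):
    """Raised when a channel-role mapping is not a bijection onto valid indices."""


@dataclass(frozen=True)
class ImageStack:
    """A validated multi-channel z-stack.

    Parameters
    ----------
    voxels
        4-D intensity array indexed ``(z, channel, row, col)``, 8-bit range.
    channel_roles
        Mapping from role name (``signal_a``, ``signal_b``, ``nuclear``) to
        channel index.
    source
        Origin of the data (file path or ``"<memory>"``).
    series
        Series index within a multi-series container.
    pixel_size_um
        Physical pixel size, if known.  Annotates outputs only.
    """

    voxels: np.ndarray
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"signal_a": 0, "signal_b": 1, "nuclear": 2}
    )
    source: str = "<memory>"
    series: int = 0
    pixel_size_um: float | None = None

    @property
    def n_z(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[1]

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(rows, cols) of a single plane."""
        return self.voxels.shape[2], self.voxels.shape[3]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, row, col)`` sub-stack for a channel role."""
        if role not in self.channel_roles:
            raise ChannelMappingError(f"unassigned channel role: {role!r}")
        return self.voxels[:, self.channel_roles[role]]

    def checksum(self) -> str:
        """SHA-1 of the voxel data; role reassignment must not change it."""
        return hashlib.sha1(np.ascontiguousarray(self.voxels).tobytes()).hexdigest()


def validate_stack(stack: ImageStack) -> ImageStack:
    """Check a stack against the input prerequisites and return it unchanged.

    The prerequisites: at most :data:`MAX_Z_PLANES` focal planes, exactly
    three channels, intensities within the 8-bit range, and a channel-role
    mapping that is a bijection onto the channel indices.

    Raises
    ------
    StackValidationError
        If any prerequisite is violated.
    """
    v = stack.voxels
    if v.ndim != 4:
        raise StackValidationError(
            f"expected 4-D (z, channel, row, col) voxels, got {v.ndim}-D"
        )
    if not 1 <= stack.n_z <= MAX_Z_PLANES:
        raise StackValidationError(
            f"too many z-planes: {stack.n_z} (limit {MAX_Z_PLANES})"
        )
    if stack.n_channels != N_CHANNELS:
        raise StackValidationError(
            f"not a 3-channel (RGB-like) stack: {stack.n_channels} channels"
        )
    if np.issubdtype(v.dtype, np.floating):
        raise StackValidationError(f"depth error: floating-point voxels ({v.dtype})")
    if v.dtype.itemsize > 1:
        # >8-bit containers are rejected, not rescaled: silent rescaling
        # would shift every percentile threshold downstream.
        if v.min() < 0 or v.max() > MAX_INTENSITY:
            raise StackValidationError(
                f"depth error: intensities outside [0, {MAX_INTENSITY}] "
                f"(dtype {v.dtype}, max {v.max()})"
            )
    _check_mapping(stack.channel_roles)
    return stack


def _check_mapping(mapping: dict[str, int]) -> None:
    if set(mapping) != set(ROLES):
        raise ChannelMappingError(
            f"mapping must cover exactly {set(ROLES)}, got {set(mapping)}"
        )
    indices = sorted(mapping.values())
    if indices != list(range(N_CHANNELS)):
        raise ChannelMappingError(
            f"mapping must be a bijection onto channel indices 0..2, got {mapping}"
        )


def assign_channels(stack: ImageStack, mapping: dict[str, int] | None = None) -> ImageStack:
    """Return a stack carrying the given role→index mapping; voxels untouched.

    With ``mapping=None`` the identity assignment
    ``{signal_a: 0, signal_b: 1, nuclear: 2}`` is used.
    """
    if mapping is None:
        mapping = {"signal_a": 0, "signal_b": 1, "nuclear": 2}
    _check_mapping(mapping)
    return replace(stack, channel_roles=dict(mapping))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_image(path: str | Path, series: int = 0) -> ImageStack:
    """Read a LIF or TIFF/OME-TIFF file into a validated :class:`ImageStack`.

    Axis order on disk is normalized to ``(z, channel, row, col)``; a
    single-plane image gets ``n_z = 1``.  The returned stack carries the
    identity channel assignment; use :func:`assign_channels` to override.

    Parameters
    ----------
    path
        Input file.  ``.tif``/``.tiff`` are read with tifffile; ``.lif``
        requires the optional ``readlif`` dependency.
    series
        Series index for multi-series containers (OME-TIFF, LIF).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        voxels = _read_tiff(path, series)
    elif suffix == ".lif":
        voxels = _read_lif(path, series)
    else:
        raise FormatError(f"unsupported format: {path.name!r} (expected LIF or TIFF)")
    stack = ImageStack(voxels=voxels, source=str(path), series=series)
    return validate_stack(stack)


def _read_tiff(path: Path, series: int) -> np.ndarray:
    with tifffile.TiffFile(path) as tf:
        if not 0 <= series < len(tf.series):
            raise IndexError(
                f"series {series} out of range: file has {len(tf.series)} series"
            )
        s = tf.series[series]
        return _normalize_axes(s.asarray(), s.axes, path)


def _read_lif(path: Path, series: int) -> np.ndarray:
    try:
        from readlif.reader import LifFile
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading .lif files requires the optional 'readlif' package "
            "(pip install spotcoloc[lif])"
        ) from exc
    lif = LifFile(str(path))  # pragma: no cover
    images = list(lif.get_iter_image())  # pragma: no cover
    if not 0 <= series < len(images):  # pragma: no cover
        raise IndexError(f"series {series} out of range ({len(images)} series)")
    img = images[series]  # pragma: no cover
    planes = [  # pragma: no cover
        [np.asarray(img.get_frame(z=z, c=c)) for c in range(img.channels)]
        for z in range(img.nz)
    ]
    return np.asarray(planes)  # pragma: no cover


def _normalize_axes(arr: np.ndarray, axes: str, path: Path) -> np.ndarray:
    """Transpose an on-disk array with tifffile axis labels to (Z, C, Y, X)."""
    axes = axes.upper()
    # Samples-per-pixel ('S') acts as the channel axis when no 'C' exists
    # (plain RGB TIFF pages).
    if "C" not in axes and "S" in axes:
        axes = axes.replace("S", "C")
    # Squeeze singleton axes outside the canonical set (T, Q, S, ...).
    for ax in list(axes):
        if ax not in "ZCYX":
            pos = axes.index(ax)
            if arr.shape[pos] != 1:
                raise FormatError(
                    f"{path.name}: unsupported non-singleton axis {ax!r} "
                    f"(axes {axes}, shape {arr.shape})"
                )
            arr = np.squeeze(arr, axis=pos)
            axes = axes[:pos] + axes[pos + 1 :]
    if "Y" not in axes or "X" not in axes:
        raise FormatError(f"{path.name}: no image plane axes found ({axes})")
    if "C" not in axes:
        raise FormatError(
            f"{path.name}: not a 3-channel (RGB-like) image (axes {axes})"
        )
    if "Z" not in axes:
        arr = arr[np.newaxis]
        axes = "Z" + axes
    order = [axes.index(ax) for ax in "ZCYX"]
    return np.transpose(arr, order)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with explicit ZCYX axes (lossless round-trip)."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.ascontiguousarray(stack.voxels),
        metadata={"axes": "ZCYX"},
        ome=True,
    )
    return path
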