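"""Binary mask I/O, morphological cleaning and connected-component extraction.

Masks are 2-D ``uint8`` arrays over {0, 1} with 1 = cellular foreground,
indexed (row, col) from the top-left corner.  Cleaning applies the standard
morphological pipeline used before analysing segmented cellular regions:
hole filling, then an opening that deletes small noise specks, then a
closing that smooths the contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "CellObject",
    "read_mask",
    "write_mask",
    "validate_mask",
    "clean_mask",
    "label_components",
]

#: 3x3 structuring element giving 8-connectivity for foreground components.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class MaskError(ValueError):
    """Raised for invalid binary masks or unreadable mask files."""


@dataclass
class CellObject:
    """One 8-connected foreground component of a binary mask.

    Attributes
    ----------
    id : int
        Positive component label (1..N within an image).
    rows, cols : ndarray of int
        Pixel coordinates of the component, same length, global frame.
    area : int
        Pixel count ``A_i``.
    bbox : tuple of int
        ``(rmin, rmax, cmin, cmax)`` inclusive bounds.
    hull_area : int
        Pixel count of the filled convex hull, set by the stage-1 features.
    de : float
        Diameter-equality ratio (minor / major diameter), in [0, 1].
    cx : float
        Concavity, normalised convex-hull deficit, in [0, 1).
    stage1_label : str
        One of ``PS``, ``PO``, ``SC``, ``OC`` once labels are assigned.
    """

    id: int
    rows: np.ndarray
    cols: np.ndarray
    hull_area: int = 0
    de: float = float("nan")
    cx: float = float("nan")
    stage1_label: str = ""
    _hull_window: np.ndarray | None = field(default=None, repr=False)
    _hull_origin: tuple[int, int] | None = field(default=None, repr=False)

    @property
    def area(self) -> int:
        return int(self.rows.size)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (
            int(self.rows.min()),
            int(self.rows.max()),
            int(self.cols.min()),
            int(self.cols.max()),
        )

    def window_mask(self, pad: int = 0, shape: tuple[int, int] | None = None):
        """Boolean window containing this object, padded by ``pad`` pixels.

        Returns ``(window, (row_origin, col_origin))``.  If ``shape`` is
        given the window is clipped to the image bounds.
        """
        rmin, rmax, cmin, cmax = self.bbox
        r0, c0 = rmin - pad, cmin - pad
        r1, c1 = rmax + pad + 1, cmax + pad + 1
        if shape is not None:
            r0, c0 = max(r0, 0), max(c0, 0)
            r1, c1 = min(r1, shape[0]), min(c1, shape[1])
        win = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        win[self.rows - r0, self.cols - c0] = True
        return win, (r0, c0)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check the {0,1} contract and return the mask as ``uint8``."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise MaskError(f"mask must be a non-empty 2-D array, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise MaskError("mask values must be exactly 0 or 1")
    return arr.astype(np.uint8)


def read_mask(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG image as a binary mask (any nonzero pixel -> 1)."""
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("L"))
    except FileNotFoundError:
        raise MaskError(f"cannot read mask file: {path}") from None
    except OSError as exc:
        raise MaskError(f"cannot read mask file: {path} ({exc})") from None
    if arr.ndim != 2 or arr.size == 0:
        raise MaskError(f"image at {path} is empty or not 2-D")
    return (arr != 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = validate_mask(mask)
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


def clean_mask(
    mask: np.ndarray,
    opening_radius: int = 2,
    closing_radius: int = 2,
) -> np.ndarray:
    """Fill interior holes, then open, then close the foreground.

    The opening uses a disc structuring element of the given radius and
    removes components smaller than the element (isolated noise pixels);
    the closing smooths small contour indentations.  Order follows the
    conventional fill / open / close sequence for segmented cell masks.
    """
    from skimage.morphology import disk

    arr = validate_mask(mask).astype(bool)
    filled = ndimage.binary_fill_holes(arr)
    opened = ndimage.binary_opening(filled, structure=disk(opening_radius))
    closed = ndimage.binary_closing(opened, structure=disk(closing_radius))
    return closed.astype(np.uint8)


def label_components(mask: np.ndarray) -> list[CellObject]:
    """Extract 8-connected foreground components as :class:`CellObject`.

    Components are labelled 1..N in scan order; the background is never
    labelled.  An empty mask yields an empty list.
    """
    arr = validate_mask(mask)
    labels, n = ndimage.label(arr, structure=EIGHT_CONNECTED)
    objects: list[CellObject] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        rr, cc = np.nonzero(labels[sl] == i)
        objects.append(
            CellObject(id=i, rows=rr + sl[0].start, cols=cc + sl[1].start)
        )
    return objects


def labelled_array(objects: list[CellObject], shape: tuple[int, int]) -> np.ndarray:
    """Paint object ids into an integer label image (0 = background)."""
    out = np.zeros(shape, dtype=np.int32)
    for obj in objects:
        out[obj.rows, obj.cols] = obj.id
    return out
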