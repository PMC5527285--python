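"""DNA-damage and compartment-mislocalisation marker quantification.

Three read-outs:

* per-nucleus mean intensity of a pan-nuclear damage marker (gamma-H2AX
  style), background-subtracted and normalised so the control-group mean is
  exactly 1;
* counts of punctate repair foci (53BP1 style) inside each nucleus, with a
  cell scored positive when it carries more than five foci (strictly more,
  i.e. six or above);
* counts of small cytoplasmic aggregates (PML-body style, 0.1-1 um) in the
  cytoplasm - inside the cell mask but outside the nucleus - where their
  presence indicates that nuclear content has escaped the compartment.

Focus and aggregate detection use Laplacian-of-Gaussian blob detection over
a physical diameter window, so the pixel size is mandatory for those
operations.  Prominence is measured relative to the local background, which
makes the counts invariant to a constant intensity offset.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import blob_log

__all__ = [
    "FocusParams",
    "nuclear_intensity",
    "normalize_to_control",
    "detect_foci",
    "cytoplasmic_aggregates",
    "estimate_background",
]

#: strict "more than five foci" positivity cutoff
FOCUS_POSITIVITY_THRESHOLD = 5


def estimate_background(image: np.ndarray, mask: np.ndarray, bins: int = 256) -> float:
    """Background level as the intensity mode outside ``mask``.

    The histogram mode is robust to the fraction of marker-positive area,
    unlike a mean or median over a background that still contains dim
    objects.
    """
    outside = np.asarray(image, float)[~np.asarray(mask, bool)]
    if outside.size == 0:
        return 0.0
    hist, edges = np.histogram(outside, bins=bins)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1]))


def nuclear_intensity(
    marker_channel: np.ndarray,
    label_mask: np.ndarray,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Background-subtracted mean marker intensity per nucleus.

    Background is the mode of the non-nucleus pixels; negative means after
    subtraction are floored at 0.  Returns columns (nucleus_id,
    mean_intensity).  An empty label set yields an empty table.
    """
    marker = np.asarray(marker_channel, float)
    labels = np.asarray(label_mask)
    if marker.shape != labels.shape:
        raise ValueError(
            f"geometry mismatch: marker {marker.shape} vs labels {labels.shape}"
        )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return pd.DataFrame(columns=["nucleus_id", "mean_intensity"])
    bg = estimate_background(marker, labels > 0) if subtract_background else 0.0
    means = ndi.mean(marker, labels=labels, index=ids)
    vals = np.maximum(np.asarray(means) - bg, 0.0)
    return pd.DataFrame({"nucleus_id": ids.astype(int), "mean_intensity": vals})


def normalize_to_control(values, control_values) -> np.ndarray:
    """Divide ``values`` by the mean of ``control_values``.

    By construction the control group's normalised mean is exactly 1.
    """
    control = np.asarray(control_values, float)
    if control.size == 0:
        raise ValueError("control_values must be non-empty")
    m = control.mean()
    if m <= 0:
        raise ValueError(f"control mean must be positive (got {m})")
    return np.asarray(values, float) / m


@dataclass(frozen=True)
class FocusParams:
    """Blob-detection window and sensitivity for focus counting.

    Diameters are physical (um); the LoG threshold is relative to the
    median absolute deviation of the intensity inside the nucleus, so a
    constant offset added to the image changes nothing.
    """

    min_diameter_um: float = 0.3
    max_diameter_um: float = 1.2
    threshold_snr: float = 6.0
    num_sigma: int = 6

    def __post_init__(self):
        if not 0 < self.min_diameter_um < self.max_diameter_um:
            raise ValueError(
                "need 0 < min_diameter_um < max_diameter_um "
                f"(got {self.min_diameter_um}, {self.max_diameter_um})"
            )


def _blob_count_in_region(
    marker: np.ndarray,
    region: np.ndarray,
    pixel_size: float,
    params: FocusParams,
) -> int:
    """LoG blobs inside one region, counted offset-invariantly."""
    if not region.any():
        return 0
    sl = ndi.find_objects(region.astype(np.int8), max_label=1)[0]
    pad = int(np.ceil(params.max_diameter_um / pixel_size)) + 2
    rs = slice(max(sl[0].start - pad, 0), sl[0].stop + pad)
    cs = slice(max(sl[1].start - pad, 0), sl[1].stop + pad)
    crop = marker[rs, cs].astype(float)
    reg = region[rs, cs]

    inside = crop[reg]
    med = float(np.median(inside))
    mad = float(np.median(np.abs(inside - med)))
    noise = 1.4826 * mad if mad > 0 else float(inside.std()) or 1.0
    work = (crop - med).clip(min=0.0)
    work[~reg] = 0.0

    # blob radius ~ sqrt(2)*sigma  =>  sigma = diameter / (2*sqrt(2))
    min_sigma = max(params.min_diameter_um / (2.0 * np.sqrt(2.0)) / pixel_size, 0.5)
    max_sigma = max(params.max_diameter_um / (2.0 * np.sqrt(2.0)) / pixel_size, min_sigma + 0.25)
    blobs = blob_log(
        work,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=params.num_sigma,
        threshold=params.threshold_snr * noise,
        overlap=0.5,
    )
    count = 0
    for y, x, _s in blobs:
        yi, xi = int(round(y)), int(round(x))
        if 0 <= yi < reg.shape[0] and 0 <= xi < reg.shape[1] and reg[yi, xi]:
            count += 1
    return count


def detect_foci(
    marker_channel: np.ndarray,
    label_mask: np.ndarray,
    pixel_size: float,
    params: FocusParams | None = None,
) -> pd.DataFrame:
    """Count repair foci per nucleus and call positivity at > 5 foci.

    Returns columns (nucleus_id, focus_count, positive); the positivity
    cutoff is strict, so exactly five foci is negative.
    """
    p = params or FocusParams()
    marker = np.asarray(marker_channel, float)
    labels = np.asarray(label_mask)
    if marker.shape != labels.shape:
        raise ValueError(
            f"geometry mismatch: marker {marker.shape} vs labels {labels.shape}"
        )
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    rows = []
    for obj_id in ids:
        count = _blob_count_in_region(marker, labels == obj_id, pixel_size, p)
        rows.append(
            {
                "nucleus_id": int(obj_id),
                "focus_count": count,
                "positive": count > FOCUS_POSITIVITY_THRESHOLD,
            }
        )
    return pd.DataFrame(rows, columns=["nucleus_id", "focus_count", "positive"])


def cytoplasmic_aggregates(
    marker_channel: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    params: FocusParams | None = None,
) -> pd.DataFrame:
    """Count small cytoplasmic aggregates per cell.

    ``nucleus_mask``/``cell_mask`` are label images with matching ids; every
    nucleus must lie inside its cell.  Blobs are detected in the cytoplasmic
    band (cell minus nucleus) over a 0.1-1 um diameter window; a cell is
    aggregate-positive when at least one is found.  Returns columns
    (cell_id, aggregate_count, positive).
    """
    p = params or FocusParams(min_diameter_um=0.1, max_diameter_um=1.0)
    marker = np.asarray(marker_channel, float)
    nuc = np.asarray(nucleus_mask)
    cell = np.asarray(cell_mask)
    if marker.shape != nuc.shape or marker.shape != cell.shape:
        raise ValueError("geometry mismatch between marker and masks")
    ids = np.unique(cell)
    ids = ids[ids > 0]
    rows = []
    for obj_id in ids:
        nuc_obj = nuc == obj_id
        cell_obj = cell == obj_id
        if (nuc_obj & ~cell_obj).any():
            raise ValueError(f"nucleus {obj_id} extends outside its cell mask")
        band = cell_obj & ~nuc_obj
        count = _blob_count_in_region(marker, band, pixel_size, p)
        rows.append(
            {"cell_id": int(obj_id), "aggregate_count": count, "positive": count >= 1}
        )
    return pd.DataFrame(rows, columns=["cell_id", "aggregate_count", "positive"])
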