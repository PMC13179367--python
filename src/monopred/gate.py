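"""Multi-channel logical gating of positive cells in multiplex IF images.

Nuclei are segmented on the DAPI channel; each marker channel (CD14 = ch1,
CD16 = ch2, APOBEC3A = ch3) gets a global positivity mask built by
rolling-ball-style background correction, a global percentile threshold on
the corrected intensity distribution (default: 50th percentile, strict >),
removal of small objects and optional morphological closing.  Per nucleus j
and channel c two binary predicates are evaluated:

* ``O_c`` — perinuclear ring positivity: the annulus between a dilation and
  an erosion of the nucleus is sampled into angular bins about the nucleus
  centroid; O_c = 1 iff enough bins contain positive pixels AND the largest
  contiguous negative angular gap (circular) stays below a preset maximum.
* ``N_c`` — nuclear overlap: the fraction of nuclear pixels positive for
  channel c is strictly greater than a minimal fraction (default 0.5).

Boolean aggregation rules gate cell phenotypes:

    A1 = O2 & ~(O1 | N1)          (CD16 ring without CD14: non-classical)
    A2 = O2 | O1 | N1             (any monocyte marker: monocyte)
    A3 = (N3 & O3) & A2           (APOBEC3A+ monocyte)
    A4 = N3 & O3                  (APOBEC3A+ cell)

so A1 implies A2 and A3 = A4 & A2.  Phenotype labels for the summary are a
configurable mapping; "classical monocyte" defaults to (O1|N1) & ~O2
(CD14+CD16-, the immunophenotype convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology, segmentation

__all__ = [
    "MaskParams",
    "RingParams",
    "GateConfig",
    "background_correct",
    "channel_mask",
    "segment_nuclei",
    "outer_ring_predicate",
    "nuclear_overlap_predicate",
    "apply_rules",
    "gate_image",
    "summarize",
    "GateResults",
    "MARKER_CHANNELS",
]

#: marker channel order in a stack after the DAPI page
MARKER_CHANNELS = ("CD14", "CD16", "APOBEC3A")


@dataclass(frozen=True)
class MaskParams:
    """Positivity-mask construction parameters (pixel units)."""

    background_radius: int | None = 30
    percentile: float = 50.0
    min_object_size: int = 9
    closing: bool = False
    closing_radius: int = 1
    noise_floor_mads: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.background_radius is not None and self.background_radius < 1:
            raise ValueError("background_radius must be >= 1")
        if self.noise_floor_mads < 0:
            raise ValueError("noise_floor_mads must be >= 0")


@dataclass(frozen=True)
class RingParams:
    """Perinuclear ring geometry and angular-bin positivity parameters."""

    dilation: int = 4
    erosion: int = 1
    n_bins: int = 36
    coverage: float = 0.5
    max_gap_deg: float = 90.0
    min_positive_px: int = 1

    def __post_init__(self) -> None:
        if not self.dilation > self.erosion >= 0:
            raise ValueError("need dilation > erosion >= 0")
        if self.n_bins < 8:
            raise ValueError("need at least 8 angular bins")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not 0 < self.max_gap_deg <= 360:
            raise ValueError("max_gap_deg must be in (0, 360]")


@dataclass(frozen=True)
class GateConfig:
    """Full gating configuration."""

    nucleus_mask: MaskParams = field(default_factory=lambda: MaskParams(min_object_size=30))
    marker_mask: MaskParams = field(default_factory=MaskParams)
    ring: RingParams = field(default_factory=RingParams)
    nuclear_min_frac: float = 0.5
    watershed: bool = False
    watershed_min_distance: int = 5


def background_correct(image: np.ndarray, radius: int | None) -> np.ndarray:
    """Rolling-ball-style background subtraction via grayscale opening.

    The background is estimated with a flat structuring element of width
    2*radius+1 (separable min/max filters); the corrected image is the
    original minus that estimate.  Exact no-op on a zero background.
    """
    img = np.asarray(image, dtype=float)
    if radius is None:
        return img
    size = 2 * int(radius) + 1
    background = ndimage.grey_opening(img, size=(size, size))
    return img - background


def channel_mask(image: np.ndarray, params: MaskParams) -> np.ndarray:
    """Binary positivity mask of one channel.

    Threshold = the configured percentile of the background-corrected
    intensity distribution over the whole image; comparison is strict, so a
    constant image yields an empty mask.
    """
    corrected = background_correct(image, params.background_radius)
    if params.noise_floor_mads > 0:
        # zero out pixels within the robust noise band so the percentile
        # threshold sees a background quantized at 0; exact no-op on
        # noiseless images (MAD = 0)
        med = np.median(corrected)
        mad = np.median(np.abs(corrected - med))
        floor = med + params.noise_floor_mads * 1.4826 * mad
        corrected = np.where(corrected > floor, corrected, 0.0)
    threshold = np.percentile(corrected, params.percentile)
    mask = corrected > threshold
    if params.min_object_size > 1:
        # drop objects strictly smaller than min_object_size
        mask = morphology.remove_small_objects(mask, max_size=params.min_object_size - 1)
    if params.closing:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    return mask


def segment_nuclei(
    dapi: np.ndarray,
    params: MaskParams | None = None,
    watershed: bool = False,
    min_distance: int = 5,
) -> np.ndarray:
    """Integer-labeled nucleus mask from the DAPI channel.

    Background-corrected global threshold + connected components; objects
    below ``min_object_size`` are removed.  Optional distance-transform
    watershed splits touching nuclei.  An all-zero image yields zero labels.
    """
    if params is None:
        params = MaskParams(min_object_size=30)
    mask = channel_mask(dapi, params)
    if not mask.any():
        return np.zeros_like(mask, dtype=np.int32)
    if watershed:
        distance = ndimage.distance_transform_edt(mask)
        peaks = morphology.local_maxima(
            ndimage.grey_dilation(distance, size=(2 * min_distance + 1,) * 2)
            == distance
        ) & mask
        markers, _ = ndimage.label(peaks)
        labels = segmentation.watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    return labels.astype(np.int32)


def _circular_max_gap(negative: np.ndarray) -> int:
    """Longest run of True in a circular boolean sequence."""
    if negative.all():
        return negative.size
    if not negative.any():
        return 0
    doubled = np.concatenate([negative, negative])
    best = run = 0
    for v in doubled:
        run = run + 1 if v else 0
        best = max(best, run)
    return min(best, negative.size)


def _ring_geometry(labels, label_id, params: RingParams):
    """Ring mask (excluding other nuclei), nucleus centroid, and crop origin."""
    obj = ndimage.find_objects((labels == label_id).astype(np.int8))
    if not obj or obj[0] is None:
        raise ValueError(f"label {label_id} not found")
    pad = params.dilation + 1
    (r_sl, c_sl) = obj[0]
    r0 = max(0, r_sl.start - pad)
    r1 = min(labels.shape[0], r_sl.stop + pad)
    c0 = max(0, c_sl.start - pad)
    c1 = min(labels.shape[1], c_sl.stop + pad)
    local = labels[r0:r1, c0:c1]
    nucleus = local == label_id
    dilated = morphology.dilation(nucleus, morphology.disk(params.dilation))
    eroded = (
        morphology.erosion(nucleus, morphology.disk(params.erosion))
        if params.erosion > 0
        else nucleus
    )
    ring = dilated & ~eroded & ((local == 0) | nucleus)
    cy, cx = ndimage.center_of_mass(nucleus)
    return ring, nucleus, (cy, cx), (r0, r1, c0, c1)


def outer_ring_predicate(
    labels: np.ndarray, label_id: int, mask: np.ndarray, params: RingParams | None = None
) -> int:
    """O_c for one nucleus: angular-bin positivity of the perinuclear ring.

    The ring is dilate(nucleus) minus erode(nucleus), excluding other
    nuclei; ring pixels fall into ``n_bins`` half-open angular bins about
    the nucleus centroid.  A bin is positive when it holds at least
    ``min_positive_px`` mask-positive pixels.  O_c = 1 iff the positive-bin
    fraction reaches ``coverage`` and the largest circular run of negative
    bins spans strictly less than ``max_gap_deg`` degrees.
    """
    if params is None:
        params = RingParams()
    ring, _, (cy, cx), (r0, r1, c0, c1) = _ring_geometry(labels, label_id, params)
    if not ring.any():
        warnings.warn(f"label {label_id}: degenerate (empty) ring")
        return 0
    rr, cc = np.nonzero(ring)
    angles = np.mod(np.arctan2(rr - cy, cc - cx), 2 * np.pi)
    bins = np.minimum((angles / (2 * np.pi) * params.n_bins).astype(int),
                      params.n_bins - 1)
    pos = mask[r0:r1, c0:c1][rr, cc]
    pos_counts = np.bincount(bins[pos], minlength=params.n_bins)
    positive_bins = pos_counts >= params.min_positive_px
    frac = positive_bins.mean()
    gap_bins = _circular_max_gap(~positive_bins)
    gap_deg = gap_bins * 360.0 / params.n_bins
    return int(frac >= params.coverage and gap_deg < params.max_gap_deg)


def nuclear_overlap_predicate(
    labels: np.ndarray, label_id: int, mask: np.ndarray, min_frac: float = 0.5
) -> int:
    """N_c for one nucleus: 1 iff the positive nuclear-pixel fraction is
    strictly greater than ``min_frac``."""
    nucleus = labels == label_id
    n = nucleus.sum()
    if n == 0:
        raise ValueError(f"label {label_id} has no pixels")
    return int((mask & nucleus).sum() / n > min_frac)


def apply_rules(predicates: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the Boolean gating rules A1..A4 from O1..O3, N1..N3."""
    df = predicates.copy()
    o1, o2, o3 = (df[c].astype(bool) for c in ("O1", "O2", "O3"))
    n1, n3 = df["N1"].astype(bool), df["N3"].astype(bool)
    df["A1"] = (o2 & ~(o1 | n1)).astype(int)
    df["A2"] = (o2 | o1 | n1).astype(int)
    df["A4"] = (n3 & o3).astype(int)
    df["A3"] = (df["A4"].astype(bool) & df["A2"].astype(bool)).astype(int)
    return df[[*predicates.columns, "A1", "A2", "A3", "A4"]]


@dataclass
class GateResults:
    """Per-cell predicates/rules and image-level summary."""

    cells: pd.DataFrame
    summary: dict

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary])


def gate_image(stack: np.ndarray, config: GateConfig | None = None) -> GateResults:
    """Run the full gating pipeline on a (4, H, W) channel stack.

    Page order: DAPI, CD14 (ch1), CD16 (ch2), APOBEC3A (ch3).
    """
    if config is None:
        config = GateConfig()
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] != 4:
        raise ValueError("stack must be (4, H, W): DAPI, CD14, CD16, APOBEC3A")
    labels = segment_nuclei(
        stack[0], config.nucleus_mask, watershed=config.watershed,
        min_distance=config.watershed_min_distance,
    )
    masks = [channel_mask(stack[i + 1], config.marker_mask) for i in range(3)]
    rows = []
    ids = np.unique(labels)
    ids = ids[ids > 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for lab in ids:
            nucleus = labels == lab
            cy, cx = ndimage.center_of_mass(nucleus)
            row = {"label": int(lab), "row": cy, "col": cx,
                   "area": int(nucleus.sum())}
            for c, mask in enumerate(masks, start=1):
                row[f"O{c}"] = outer_ring_predicate(labels, lab, mask, config.ring)
                row[f"N{c}"] = nuclear_overlap_predicate(
                    labels, lab, mask, config.nuclear_min_frac
                )
            rows.append(row)
    cols = ["label", "row", "col", "area", "O1", "N1", "O2", "N2", "O3", "N3"]
    cells = pd.DataFrame(rows, columns=cols)
    cells = apply_rules(cells)
    return GateResults(cells=cells, summary=summarize(cells))


def summarize(cells: pd.DataFrame) -> dict:
    """Image-level counts and ratios from gated cells.

    Phenotype mapping: monocyte = A2; APOBEC3A+ monocyte = A3; APOBEC3A+
    cell = A4; non-classical monocyte = A1; classical monocyte =
    (O1 | N1) & ~O2.  Ratios with zero denominators are None (unavailable).
    """
    n = len(cells)
    counts = {f"A{k}": int(cells[f"A{k}"].sum()) if n else 0 for k in (1, 2, 3, 4)}
    classical = (
        int(((cells["O1"].astype(bool) | cells["N1"].astype(bool))
             & ~cells["O2"].astype(bool)).sum())
        if n
        else 0
    )

    def ratio(num, den):
        return num / den if den else None

    return {
        "n_cells": n,
        **counts,
        "n_monocytes": counts["A2"],
        "n_classical": classical,
        "n_non_classical": counts["A1"],
        "apobec3a_monocyte_ratio": ratio(counts["A3"], counts["A2"]),
        "apobec3a_cell_ratio": ratio(counts["A4"], n),
        "monocyte_share_of_apobec3a": ratio(counts["A3"], counts["A4"]),
    }
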