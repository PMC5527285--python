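"""Synthetic microscopy data with known ground truth.

Every assay quantified by this package has a generator here that emulates it
well enough to verify the measurement code end to end:

``generate_nucleus_image``
    Multi-channel 2-D field of nuclei.  Channel 0 is a DNA stain (filled
    shapes, blurred, Poisson-Gaussian noise), channel 1 a nuclear-envelope
    marker rendered as a rim along each nucleus boundary.  Normal nuclei are
    near-circular ellipses; deformed nuclei are ellipses warped by low-order
    Fourier modes; fragmented nuclei are a main body plus an extruded lobe
    joined by a thin chromatin bridge, with the envelope rim omitted over
    the lobe - the hallmark of chromatin escaping the lamina.

``generate_reporter_traces``
    Dual-reporter (NLS / NES) nuclear and cytoplasmic intensities from a
    two-compartment exchange model.  The closed state holds the NLS
    nuclear/cytoplasmic ratio at an import-leak balance; rupture events
    (Poisson arrivals) let both reporters equilibrate with a fast time
    constant; after resealing the baseline re-accumulates.  Reporter amount
    is conserved exactly before noise.

``generate_shape_trajectories``
    Per-cell shape tuples over k timepoints, in a quiescent preset (small
    jitter around a base shape) or a dynamic preset (large frame-to-frame
    excursions), emulating nuclei traced in time-lapse/intravital movies.

``generate_focus_image`` / ``generate_intensity_image`` /
``generate_aggregate_image``
    DNA-damage-marker assays: punctate repair foci inside nuclei, uniform
    per-nucleus marker intensity with a group effect, and small cytoplasmic
    aggregates outside the nucleus but inside the cell.

All generators are deterministic given their seed (one seeded random stream
per call, no global state) and return ground-truth tables describing each
object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage.filters import gaussian

from . import shape as shape_metrics
from .rupture import ReporterTrace

__all__ = [
    "match_labels",
    "ImageSpec",
    "TraceSpec",
    "SyntheticImage",
    "DEPLETED_EVENT_RATE",
    "depleted_trace_spec",
    "control_trace_spec",
    "generate_nucleus_image",
    "generate_reporter_traces",
    "generate_shape_trajectories",
    "generate_focus_image",
    "generate_intensity_image",
    "generate_aggregate_image",
]

_EIGHT = np.ones((3, 3), bool)

#: Rupture incidence of the myosin-phosphatase-depleted cohort: 56 exchange
#: events in 292 cells over 4 h of imaging, in events per cell-hour.
DEPLETED_EVENT_RATE = 56.0 / (292.0 * 4.0)

PHENOTYPES = ("normal", "deformed", "fragmented")


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic multi-channel nucleus image."""

    width: int = 512
    height: int = 512
    pixel_size: float = 0.25  # um per pixel
    n_nuclei: int = 20
    phenotype_mix: Mapping[str, float] = field(
        default_factory=lambda: {"normal": 1.0, "deformed": 0.0, "fragmented": 0.0}
    )
    snr: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 64 or self.height < 64:
            raise ValueError("image must be at least 64x64 pixels")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        mix = dict(self.phenotype_mix)
        unknown = set(mix) - set(PHENOTYPES)
        if unknown:
            raise ValueError(f"unknown phenotypes in mix: {sorted(unknown)}")
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phenotype_mix must sum to 1 (got {total})")
        object.__setattr__(
            self, "phenotype_mix", {k: mix.get(k, 0.0) for k in PHENOTYPES}
        )


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a simulated dual-reporter barrier-assay cohort.

    Defaults mirror the imaging protocol being emulated: 4-h recordings
    sampled every 2 min, a closed-state N/C ratio of 3, rupture events with
    a 15-min mean duration.  ``event_rate`` is in events per cell-hour.
    """

    n_cells: int = 10
    duration: float = 240.0  # min
    frame_interval: float = 2.0  # min
    event_rate: float = 0.0  # events per cell-hour
    open_ratio_baseline: float = 3.0
    mean_event_duration: float = 15.0  # min
    noise_cv: float = 0.03
    mitosis_rate: float = 0.0  # events per cell-hour
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration must cover at least one frame interval")
        if self.event_rate < 0 or self.mitosis_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.mean_event_duration < self.frame_interval:
            raise ValueError("mean_event_duration must be at least one frame interval")
        if self.open_ratio_baseline <= 1.0:
            raise ValueError("open_ratio_baseline must exceed 1 (nuclear enrichment)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        # Poisson arrivals with mean busy length L: the chance a drawn event
        # overlaps another is about 1 - exp(-2*lambda*L).
        lam_per_min = self.event_rate / 60.0
        p_overlap = 1.0 - math.exp(-2.0 * lam_per_min * self.mean_event_duration)
        if p_overlap > 0.05:
            raise ValueError(
                "event_rate too high: expected overlap fraction "
                f"{p_overlap:.3f} exceeds 5% of draws"
            )


def depleted_trace_spec(n_cells: int = 292, seed: int = 0, **overrides) -> TraceSpec:
    """Preset matching the depleted cohort: 56 events / 292 cells / 4 h."""
    kw = dict(
        n_cells=n_cells,
        duration=240.0,
        frame_interval=2.0,
        event_rate=DEPLETED_EVENT_RATE,
        noise_cv=0.03,
        seed=seed,
    )
    kw.update(overrides)
    return TraceSpec(**kw)


def control_trace_spec(n_cells: int = 83, seed: int = 0, **overrides) -> TraceSpec:
    """Preset matching the control cohort: no events in 83 cells over 4 h."""
    kw = dict(
        n_cells=n_cells,
        duration=240.0,
        frame_interval=2.0,
        event_rate=0.0,
        noise_cv=0.03,
        seed=seed,
    )
    kw.update(overrides)
    return TraceSpec(**kw)


# --------------------------------------------------------------------------
# nucleus image generation
# --------------------------------------------------------------------------


def _polar_contour(rng: np.random.Generator, phenotype: str, pixel_size: float):
    """Sub-pixel outline(s) of one nucleus in local coordinates.

    Returns (polygons, lobe_info) where polygons is a list of (rows, cols)
    closed outlines (main body first) and lobe_info is None except for
    fragmented nuclei, where it carries the lobe centre/radius and bridge
    geometry used to join lobe and body.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 1024, endpoint=False)
    r_eq = rng.uniform(4.5, 7.0) / pixel_size  # equivalent radius, px
    q = rng.uniform(1.0, 1.3)  # axis ratio
    a, b = r_eq * math.sqrt(q), r_eq / math.sqrt(q)
    phi = rng.uniform(0.0, np.pi)
    r = a * b / np.sqrt((b * np.cos(theta - phi)) ** 2 + (a * np.sin(theta - phi)) ** 2)

    if phenotype == "deformed":
        # low-order Fourier warp; amplitudes sized to reproduce the grossly
        # lobulated outlines of contractility-deregulated nuclei
        # (circularity mostly 0.45-0.65); resample if the radius pinches
        base = r.copy()
        for _ in range(50):
            warp = np.zeros_like(theta)
            for m in (2, 3, 4, 5):
                amp = rng.uniform(0.15, 0.25)
                warp = warp + amp * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
            r = base * (1.0 + warp)
            if r.min() > 0.2 * base.min():
                break

    rows = r * np.sin(theta)
    cols = r * np.cos(theta)
    if phenotype != "fragmented":
        return [(rows, cols)], None

    # fragmented: main body + extruded lobe + thin bridge
    direction = rng.uniform(0.0, 2.0 * np.pi)
    r_main = a * b / math.sqrt(
        (b * math.cos(direction - phi)) ** 2 + (a * math.sin(direction - phi)) ** 2
    )
    lobe_r = r_eq * rng.uniform(0.30, 0.42)
    gap = rng.uniform(8.0, 14.0)  # px between main boundary and lobe boundary
    lobe_dist = r_main + gap + lobe_r
    lobe_rc = (lobe_dist * math.sin(direction), lobe_dist * math.cos(direction))
    lrows = lobe_rc[0] + lobe_r * np.sin(theta)
    lcols = lobe_rc[1] + lobe_r * np.cos(theta)
    bridge_w = rng.uniform(2.0, 4.0)
    lobe_info = {
        "centre": lobe_rc,
        "radius": lobe_r,
        "direction": direction,
        "bridge_from": (r_main * math.sin(direction), r_main * math.cos(direction)),
        "bridge_to": lobe_rc,
        "bridge_width": bridge_w,
    }
    return [(rows, cols), (lrows, lcols)], lobe_info


def _rasterise(polys, lobe_info, shape_hw):
    """Rasterise outlines into (mask, lobe_region) boolean arrays."""
    mask = np.zeros(shape_hw, bool)
    for rows, cols in polys:
        rr, cc = skdraw.polygon(rows, cols, shape=shape_hw)
        mask[rr, cc] = True
    lobe_region = np.zeros(shape_hw, bool)
    if lobe_info is not None:
        # bridge: thick line between boundary of main body and lobe centre
        (r0, c0), (r1, c1) = lobe_info["bridge_from"], lobe_info["bridge_to"]
        length = math.hypot(r1 - r0, c1 - c0)
        n_steps = max(int(length * 2), 2)
        half_w = lobe_info["bridge_width"] / 2.0
        for t in np.linspace(0.0, 1.0, n_steps):
            rr, cc = skdraw.disk(
                (r0 + t * (r1 - r0), c0 + t * (c1 - c0)), half_w, shape=shape_hw
            )
            mask[rr, cc] = True
        # everything beyond the main body belongs to the extrusion
        main = np.zeros(shape_hw, bool)
        rr, cc = skdraw.polygon(*polys[0], shape=shape_hw)
        main[rr, cc] = True
        lobe_region = mask & ~main
    return mask, lobe_region


def _polygon_metrics(rows, cols, pixel_size):
    """Analytic area/perimeter/circularity of a closed polygon outline."""
    x, y = np.asarray(cols, float), np.asarray(rows, float)
    area_px = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
    seg = np.hypot(np.diff(np.r_[x, x[0]]), np.diff(np.r_[y, y[0]]))
    perim_px = float(seg.sum())
    area = area_px * pixel_size**2
    perim = perim_px * pixel_size
    return area, perim, shape_metrics.circularity(area, perim)


@dataclass
class SyntheticImage:
    """Generated multi-channel image plus label mask and ground truth."""

    channels: np.ndarray  # (n_channels, H, W) float
    labels: np.ndarray  # (H, W) int, 0 = background
    ground_truth: pd.DataFrame
    pixel_size: float


def generate_nucleus_image(spec: ImageSpec) -> SyntheticImage:
    """Render a DNA + envelope-marker image of nuclei with ground truth.

    Nuclei are placed by rejection sampling without overlap; a placement
    failure after bounded retries raises an error naming the density limit.
    The ground-truth table records the true phenotype, noise-free shape
    metrics (analytic polygon values for normal/deformed nuclei, contour
    measurements of the noise-free mask for fragmented ones) and the true
    envelope-rim coverage of each object.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    labels = np.zeros((H, W), np.int32)
    dna = np.zeros((H, W), float)
    env = np.zeros((H, W), float)
    occupied = np.zeros((H, W), bool)

    phenos = rng.choice(
        PHENOTYPES, size=spec.n_nuclei, p=[spec.phenotype_mix[k] for k in PHENOTYPES]
    )

    records = []
    max_tries = 200 * max(spec.n_nuclei, 1)
    tries = 0
    for obj_id, pheno in enumerate(phenos, start=1):
        placed = False
        while not placed:
            tries += 1
            if tries > max_tries:
                density = occupied.mean()
                raise ValueError(
                    f"could not place nucleus {obj_id}/{spec.n_nuclei} after "
                    f"{max_tries} tries; occupied fraction {density:.2f} - "
                    "reduce n_nuclei or enlarge the image"
                )
            polys, lobe_info = _polar_contour(rng, pheno, spec.pixel_size)
            extent = max(
                float(np.max(np.hypot(r, c))) for r, c in polys
            ) + (0 if lobe_info is None else 2)
            margin = extent + 4
            if 2 * margin >= min(H, W):
                continue
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            shifted = [(r + cy, c + cx) for r, c in polys]
            if lobe_info is not None:
                lobe_info = dict(lobe_info)
                lobe_info["bridge_from"] = (
                    lobe_info["bridge_from"][0] + cy,
                    lobe_info["bridge_from"][1] + cx,
                )
                lobe_info["bridge_to"] = (
                    lobe_info["bridge_to"][0] + cy,
                    lobe_info["bridge_to"][1] + cx,
                )
            mask, lobe_region = _rasterise(shifted, lobe_info, (H, W))
            if not mask.any():
                continue
            grown = ndi.binary_dilation(mask, _EIGHT, iterations=3)
            if (grown & occupied).any():
                continue
            placed = True

        occupied |= ndi.binary_dilation(mask, _EIGHT, iterations=1)
        labels[mask] = obj_id

        amp = rng.uniform(0.85, 1.15)
        dna[mask] += amp

        # envelope rim: ~2 px band inside the boundary, omitted over the lobe
        rim = mask & ~ndi.binary_erosion(mask, _EIGHT, iterations=2)
        uncovered = rim & lobe_region if lobe_region is not None else np.zeros_like(rim)
        if pheno == "fragmented":
            covered_rim = rim & ~lobe_region
        else:
            covered_rim = rim
        env[covered_rim] += amp

        rim_n = int(rim.sum())
        coverage = float(covered_rim.sum() / rim_n) if rim_n else 1.0
        lobe_rim_n = int((rim & lobe_region).sum()) if pheno == "fragmented" else 0
        lobe_gap_fraction = 1.0 if lobe_rim_n else 0.0

        if pheno == "fragmented":
            m = shape_metrics.contour_metrics(mask, spec.pixel_size)
            area, perim, circ = m.area, m.perimeter, m.circularity
            aspect = m.aspect_ratio
        else:
            area, perim, circ = _polygon_metrics(
                shifted[0][0], shifted[0][1], spec.pixel_size
            )
            props = shape_metrics.contour_metrics(mask, spec.pixel_size)
            aspect = props.aspect_ratio

        records.append(
            {
                "object_id": obj_id,
                "phenotype": pheno,
                "area_px": int(mask.sum()),
                "area_um2": area,
                "perimeter_um": perim,
                "circularity": circ,
                "aspect_ratio": aspect,
                "rim_coverage": coverage,
                "gap_fraction": 1.0 - coverage,
                "lobe_gap_fraction": lobe_gap_fraction,
            }
        )

    # optics + noise: blur, then signal-dependent Poisson plus additive
    # Gaussian background; snr = mean in-nucleus signal / background sigma
    dna = gaussian(dna, sigma=1.0, preserve_range=True)
    env = gaussian(env, sigma=0.8, preserve_range=True)
    in_nuc = labels > 0
    mean_signal = float(dna[in_nuc].mean()) if in_nuc.any() else 1.0
    bg_sigma = mean_signal / spec.snr
    photons = 200.0
    channels = []
    for clean in (dna, env):
        shot = rng.poisson(np.clip(clean, 0, None) * photons) / photons
        noisy = shot + rng.normal(0.0, bg_sigma, size=clean.shape)
        channels.append(noisy)
    gt = pd.DataFrame(
        records,
        columns=[
            "object_id",
            "phenotype",
            "area_px",
            "area_um2",
            "perimeter_um",
            "circularity",
            "aspect_ratio",
            "rim_coverage",
            "gap_fraction",
            "lobe_gap_fraction",
        ],
    )
    return SyntheticImage(
        channels=np.stack(channels),
        labels=labels,
        ground_truth=gt,
        pixel_size=spec.pixel_size,
    )


def match_labels(true_labels: np.ndarray, predicted_labels: np.ndarray) -> pd.DataFrame:
    """Match each ground-truth object to its best-overlapping prediction.

    Returns one row per ground-truth object with the predicted label of
    maximal overlap (0 when nothing overlaps) and the IoU of the pair.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label masks must share geometry")
    rows = []
    for obj_id in np.unique(true_labels):
        if obj_id == 0:
            continue
        gt_mask = true_labels == obj_id
        ids, counts = np.unique(predicted_labels[gt_mask], return_counts=True)
        fg = ids > 0
        if not fg.any():
            rows.append({"object_id": int(obj_id), "matched_id": 0, "iou": 0.0})
            continue
        best = ids[fg][np.argmax(counts[fg])]
        pred = predicted_labels == best
        iou = float((gt_mask & pred).sum() / (gt_mask | pred).sum())
        rows.append({"object_id": int(obj_id), "matched_id": int(best), "iou": iou})
    return pd.DataFrame(rows, columns=["object_id", "matched_id", "iou"])


# --------------------------------------------------------------------------
# reporter trace generation
# --------------------------------------------------------------------------

_TAU_OPEN = 1.0  # min; rupture equilibration completes within one 2-min frame
_TAU_CLOSED = 3.0  # min; re-import after resealing
_GAIN = 100.0  # a.u. per unit reporter amount
_MITOSIS_LENGTH = 30.0  # min flagged around a division decoy


def _draw_events(
    rng: np.random.Generator, spec: TraceSpec, n_extra_windows=()
) -> list[tuple[float, float]]:
    """Non-overlapping (open_time, recovery_onset) pairs for one cell."""
    lam = spec.event_rate * spec.duration / 60.0
    n_ev = rng.poisson(lam)
    if n_ev == 0:
        return []
    for _ in range(200):
        opens = np.sort(rng.uniform(0.0, spec.duration, size=n_ev))
        durs = []
        for _ in range(n_ev):
            d = rng.gamma(3.0, spec.mean_event_duration / 3.0)
            for _ in range(100):
                if d >= 2.0 * spec.frame_interval:
                    break
                d = rng.gamma(3.0, spec.mean_event_duration / 3.0)
            durs.append(d)
        events = [(o, o + d) for o, d in zip(opens, durs)]
        windows = list(events) + list(n_extra_windows)
        windows.sort()
        if all(windows[i][1] < windows[i + 1][0] for i in range(len(windows) - 1)):
            return events
    raise ValueError("could not draw non-overlapping events; event_rate too high")


def _integrate_fraction(
    frame_times: np.ndarray,
    open_windows: list[tuple[float, float]],
    n0: float,
    n_closed: float,
    n_open: float,
) -> np.ndarray:
    """Nuclear amount fraction on the frame grid, piecewise-exact.

    Within each regime the amount relaxes exponentially towards the regime
    equilibrium (``n_closed`` or ``n_open``) with the regime time constant,
    so total reporter amount is conserved exactly.
    """
    changes = []
    for o, r in open_windows:
        changes.append((o, "open"))
        changes.append((r, "closed"))
    changes.sort()
    out = np.empty_like(frame_times)
    t_prev, n = 0.0, n0
    state = "closed"
    ci = 0
    for k, t_frame in enumerate(frame_times):
        t = t_prev
        while ci < len(changes) and changes[ci][0] <= t_frame:
            t_change, new_state = changes[ci]
            if t_change > t:
                tau = _TAU_OPEN if state == "open" else _TAU_CLOSED
                target = n_open if state == "open" else n_closed
                n = target + (n - target) * math.exp(-(t_change - t) / tau)
                t = t_change
            state = new_state
            ci += 1
        if t_frame > t:
            tau = _TAU_OPEN if state == "open" else _TAU_CLOSED
            target = n_open if state == "open" else n_closed
            n = target + (n - target) * math.exp(-(t_frame - t) / tau)
        out[k] = n
        t_prev = t_frame
    return out


def generate_reporter_traces(
    spec: TraceSpec,
) -> tuple[list[ReporterTrace], pd.DataFrame]:
    """Simulate a cohort of dual-reporter traces.

    Returns the traces and a ground-truth table with one row per injected
    rupture event (``cell_id``, ``open_time``, ``recovery_onset``).  Mitosis
    decoys (if ``mitosis_rate`` > 0) collapse the ratio like a rupture but
    are flagged in ``mitosis_flag`` and do not appear in the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(spec.duration // spec.frame_interval)
    t = np.arange(n_frames) * spec.frame_interval
    B = spec.open_ratio_baseline
    n_nls_closed = B / (1.0 + B)
    n_nes_closed = 1.0 / (1.0 + B)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    traces: list[ReporterTrace] = []
    gt_rows = []
    for cell in range(spec.n_cells):
        cell_id = f"cell{cell:04d}"
        # mitosis decoys first so real events avoid them
        mito_windows: list[tuple[float, float]] = []
        n_mito = rng.poisson(spec.mitosis_rate * spec.duration / 60.0)
        for _ in range(n_mito):
            start = rng.uniform(0.0, spec.duration)
            mito_windows.append((start, min(start + _MITOSIS_LENGTH, spec.duration)))
        mito_windows.sort()
        mito_windows = [
            w
            for i, w in enumerate(mito_windows)
            if i == 0 or w[0] > mito_windows[i - 1][1]
        ]

        events = _draw_events(rng, spec, n_extra_windows=mito_windows)
        open_windows = sorted(events + [(o, r - 5.0) for o, r in mito_windows])
        # (mitotic envelope reformation begins ~5 min before the flag clears)

        n_nls = _integrate_fraction(t, open_windows, n_nls_closed, n_nls_closed, 0.5)
        n_nes = _integrate_fraction(t, open_windows, n_nes_closed, n_nes_closed, 0.5)

        def noisy(x):
            if sigma == 0.0:
                return x * _GAIN
            f = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=x.shape))
            return x * _GAIN * f

        mito_flag = np.zeros(n_frames, bool)
        for o, r in mito_windows:
            mito_flag |= (t >= o) & (t <= r)

        traces.append(
            ReporterTrace(
                cell_id=cell_id,
                time=t.copy(),
                nls_nuc=noisy(n_nls),
                nls_cyt=noisy(1.0 - n_nls),
                nes_nuc=noisy(n_nes),
                nes_cyt=noisy(1.0 - n_nes),
                mitosis=mito_flag,
            )
        )
        for o, r in events:
            gt_rows.append(
                {"cell_id": cell_id, "open_time": o, "recovery_onset": r}
            )
    gt = pd.DataFrame(gt_rows, columns=["cell_id", "open_time", "recovery_onset"])
    return traces, gt


# --------------------------------------------------------------------------
# shape trajectories
# --------------------------------------------------------------------------

_TRAJECTORY_PRESETS = {
    # fraction of base perimeter, absolute circularity sd, absolute AR sd
    "quiescent": {"perimeter_frac": 0.02, "circularity": 0.015, "aspect_ratio": 0.03},
    "dynamic": {"perimeter_frac": 0.10, "circularity": 0.09, "aspect_ratio": 0.25},
}


def generate_shape_trajectories(
    n_cells: int,
    k_timepoints: int = 5,
    dynamics: str = "quiescent",
    seed: int = 0,
    noise_scale: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell (perimeter, circularity, aspect ratio) tuples over time.

    The quiescent preset jitters a per-cell base shape slightly; the dynamic
    preset adds large independent frame-to-frame excursions, emulating
    actively deforming nuclei.  ``noise_scale`` scales the preset spread
    (0 gives constant series).  Returns (trajectory table, ground truth with
    the generative per-cell standard deviations).
    """
    if k_timepoints < 2:
        raise ValueError("k_timepoints must be >= 2 (variance undefined otherwise)")
    if dynamics not in _TRAJECTORY_PRESETS:
        raise ValueError(f"dynamics must be one of {sorted(_TRAJECTORY_PRESETS)}")
    preset = _TRAJECTORY_PRESETS[dynamics]
    rng = np.random.default_rng(seed)
    rows, gt_rows = [], []
    for cell in range(n_cells):
        cell_id = f"cell{cell:04d}"
        base_per = rng.normal(48.0, 5.0)  # um
        base_circ = rng.uniform(0.72, 0.92)
        base_ar = rng.uniform(1.05, 1.5)
        sd_per = preset["perimeter_frac"] * base_per * noise_scale
        sd_circ = preset["circularity"] * noise_scale
        sd_ar = preset["aspect_ratio"] * noise_scale
        for k in range(k_timepoints):
            per = max(base_per + rng.normal(0.0, sd_per) if sd_per else base_per, 1.0)
            circ = base_circ + (rng.normal(0.0, sd_circ) if sd_circ else 0.0)
            ar = base_ar + (rng.normal(0.0, sd_ar) if sd_ar else 0.0)
            rows.append(
                {
                    "cell_id": cell_id,
                    "timepoint": k,
                    "perimeter": per,
                    "circularity": float(np.clip(circ, 0.05, 1.0)),
                    "aspect_ratio": float(max(ar, 1.0)),
                }
            )
        gt_rows.append(
            {
                "cell_id": cell_id,
                "dynamics": dynamics,
                "sd_perimeter": sd_per,
                "sd_circularity": sd_circ,
                "sd_aspect_ratio": sd_ar,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(gt_rows)


# --------------------------------------------------------------------------
# damage-marker assays
# --------------------------------------------------------------------------


def _place_disks(rng, n, radius_range, shape_hw, margin_extra=4.0, max_tries=None):
    """Non-overlapping disk centres/radii by rejection sampling."""
    H, W = shape_hw
    placed = []
    max_tries = max_tries or 200 * max(n, 1)
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n} disks in {H}x{W}; reduce the count"
            )
        r = rng.uniform(*radius_range)
        m = r + margin_extra
        cy, cx = rng.uniform(m, H - m), rng.uniform(m, W - m)
        if all(
            math.hypot(cy - py, cx - px) > r + pr + margin_extra
            for py, px, pr in placed
        ):
            placed.append((cy, cx, r))
    return placed


def _add_gaussian_spot(img, cy, cx, sigma_px, amplitude):
    size = max(int(6 * sigma_px) + 1, 3)
    y0, x0 = int(cy) - size, int(cx) - size
    yy, xx = np.mgrid[y0 : y0 + 2 * size + 1, x0 : x0 + 2 * size + 1]
    valid = (yy >= 0) & (yy < img.shape[0]) & (xx >= 0) & (xx < img.shape[1])
    g = amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2))
    img[yy[valid], xx[valid]] += g[valid]


def generate_focus_image(
    n_nuclei: int = 20,
    spots_per_nucleus=None,
    width: int = 512,
    height: int = 512,
    pixel_size: float = 0.25,
    snr: float = 10.0,
    spot_diameter_um: tuple[float, float] = (0.4, 1.0),
    spot_amplitude: float = 3.0,
    nuclear_level: float = 1.0,
    seed: int = 0,
):
    """Punctate repair-focus image (e.g. 53BP1) with known spot counts.

    ``spots_per_nucleus`` may be an int (same count everywhere), a sequence
    of per-nucleus counts, or None (counts drawn uniformly from 0-12).
    Returns (marker image, label mask, ground truth with true_spot_count).
    """
    rng = np.random.default_rng(seed)
    disks = _place_disks(rng, n_nuclei, (24.0, 32.0), (height, width))
    labels = np.zeros((height, width), np.int32)
    marker = np.zeros((height, width), float)
    if spots_per_nucleus is None:
        counts = rng.integers(0, 13, size=n_nuclei)
    elif np.isscalar(spots_per_nucleus):
        counts = np.full(n_nuclei, int(spots_per_nucleus))
    else:
        counts = np.asarray(spots_per_nucleus, int)
        if counts.size != n_nuclei:
            raise ValueError("spots_per_nucleus length must equal n_nuclei")

    gt_rows = []
    for obj_id, ((cy, cx, r), count) in enumerate(zip(disks, counts), start=1):
        rr, cc = skdraw.disk((cy, cx), r, shape=labels.shape)
        labels[rr, cc] = obj_id
        marker[rr, cc] += nuclear_level
        spot_pos = []
        tries = 0
        while len(spot_pos) < count:
            tries += 1
            if tries > 500 * max(count, 1):
                raise ValueError("could not place well-separated spots; too many")
            rho = math.sqrt(rng.uniform(0.0, 1.0)) * (r - 6.0)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            sy, sx = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
            if all(math.hypot(sy - py, sx - px) > 6.0 for py, px in spot_pos):
                spot_pos.append((sy, sx))
        for sy, sx in spot_pos:
            d_um = rng.uniform(*spot_diameter_um)
            sigma_px = d_um / 2.355 / pixel_size  # FWHM = diameter
            _add_gaussian_spot(marker, sy, sx, sigma_px, spot_amplitude)
        gt_rows.append({"object_id": obj_id, "true_spot_count": int(count)})

    bg_sigma = nuclear_level / snr
    marker = marker + rng.normal(0.0, bg_sigma, size=marker.shape)
    gt = pd.DataFrame(gt_rows, columns=["object_id", "true_spot_count"])
    return marker, labels, gt


def generate_intensity_image(
    n_nuclei: int = 30,
    mean_intensity: float = 1.0,
    cell_cv: float = 0.15,
    background: float = 0.2,
    width: int = 512,
    height: int = 512,
    snr: float = 10.0,
    seed: int = 0,
):
    """Uniform per-nucleus marker intensity (gamma-H2AX-like) with ground truth.

    Each nucleus gets a lognormal intensity around ``mean_intensity`` on a
    constant background offset; Gaussian noise at ``mean/snr``.  Returns
    (marker, labels, ground truth with true_mean_intensity).
    """
    rng = np.random.default_rng(seed)
    disks = _place_disks(rng, n_nuclei, (18.0, 26.0), (height, width))
    labels = np.zeros((height, width), np.int32)
    marker = np.full((height, width), float(background))
    sigma = math.sqrt(math.log(1.0 + cell_cv**2)) if cell_cv > 0 else 0.0
    gt_rows = []
    for obj_id, (cy, cx, r) in enumerate(disks, start=1):
        level = mean_intensity * (
            math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0
        )
        rr, cc = skdraw.disk((cy, cx), r, shape=labels.shape)
        labels[rr, cc] = obj_id
        marker[rr, cc] += level
        gt_rows.append({"object_id": obj_id, "true_mean_intensity": level})
    marker = marker + rng.normal(0.0, mean_intensity / snr, size=marker.shape)
    gt = pd.DataFrame(gt_rows, columns=["object_id", "true_mean_intensity"])
    return marker, labels, gt


def generate_aggregate_image(
    n_cells: int = 8,
    aggregates_per_cell=2,
    nuclear_spots_per_cell=0,
    width: int = 768,
    height: int = 768,
    pixel_size: float = 0.2,
    snr: float = 10.0,
    aggregate_diameter_um: tuple[float, float] = (0.3, 0.9),
    seed: int = 0,
):
    """Cytoplasmic aggregate assay (PML-like bodies, 0.1-1 um).

    Each cell is a large disk (cytoplasm) with a concentric nuclear disk;
    aggregates are small Gaussian spots placed in the cytoplasmic band,
    ``nuclear_spots_per_cell`` optionally adds intranuclear decoys that a
    cytoplasmic scorer must ignore.  Returns (marker, nucleus labels, cell
    labels, ground truth with true_aggregate_count).
    """
    rng = np.random.default_rng(seed)
    cell_r, nuc_r = 70.0, 30.0
    disks = _place_disks(rng, n_cells, (cell_r, cell_r), (height, width))
    nuc_labels = np.zeros((height, width), np.int32)
    cell_labels = np.zeros((height, width), np.int32)
    marker = np.zeros((height, width), float)

    if np.isscalar(aggregates_per_cell):
        agg_counts = np.full(n_cells, int(aggregates_per_cell))
    else:
        agg_counts = np.asarray(aggregates_per_cell, int)

    gt_rows = []
    for obj_id, (cy, cx, _r) in enumerate(disks, start=1):
        rr, cc = skdraw.disk((cy, cx), cell_r, shape=marker.shape)
        cell_labels[rr, cc] = obj_id
        rr, cc = skdraw.disk((cy, cx), nuc_r, shape=marker.shape)
        nuc_labels[rr, cc] = obj_id
        marker[rr, cc] += 0.5  # diffuse nuclear pool of the marker

        def _spots(n, rho_range):
            pos = []
            tries = 0
            while len(pos) < n:
                tries += 1
                if tries > 500 * max(n, 1):
                    raise ValueError("could not place aggregates")
                rho = rng.uniform(*rho_range)
                ang = rng.uniform(0.0, 2.0 * np.pi)
                sy, sx = cy + rho * math.sin(ang), cx + rho * math.cos(ang)
                if all(math.hypot(sy - py, sx - px) > 8.0 for py, px in pos):
                    pos.append((sy, sx))
            return pos

        for sy, sx in _spots(int(agg_counts[obj_id - 1]), (nuc_r + 6, cell_r - 6)):
            d_um = rng.uniform(*aggregate_diameter_um)
            _add_gaussian_spot(marker, sy, sx, d_um / 2.355 / pixel_size, 3.0)
        for sy, sx in _spots(int(nuclear_spots_per_cell), (0.0, nuc_r - 6)):
            d_um = rng.uniform(*aggregate_diameter_um)
            _add_gaussian_spot(marker, sy, sx, d_um / 2.355 / pixel_size, 3.0)
        gt_rows.append(
            {"object_id": obj_id, "true_aggregate_count": int(agg_counts[obj_id - 1])}
        )

    marker = marker + rng.normal(0.0, 0.5 / snr, size=marker.shape)
    gt = pd.DataFrame(gt_rows, columns=["object_id", "true_aggregate_count"])
    return marker, nuc_labels, cell_labels, gt
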