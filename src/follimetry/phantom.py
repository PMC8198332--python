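"""Synthetic three-channel follicular-tissue phantoms with exact ground truth.

A thyroid mid-section is, to first order, a field of discrete round
follicles: a colloid-filled lumen wrapped in a single epithelial cell
layer whose outer face is sheathed by a thin basal lamina.  The phantom
renders exactly that geometry, channel by channel:

* marker (green role): a 1-px basal-lamina ring at the outer edge of each
  epithelium, vesicular puncta inside the epithelium, and a diffuse
  luminal signal whose share of the total marker signal is set by
  ``luminal_marker_fraction``;
* cytoplasm (red role): the epithelial annulus, filled uniformly;
* nuclei (blue role): one Gaussian-blurred disc per nucleus, with a
  configurable fraction of nuclei dropped into lumina as dead-cell
  remnants.

Every rendered object is also recorded in a truth table whose areas are
the rasterized pixel counts times the pixel area, so segmentation
recovery can be scored exactly.  Identical specs (including the seed)
produce bit-identical images and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .channels import ChannelStack

__all__ = ["PhantomSpec", "PhantomTruth", "PlacementError", "generate_phantom",
           "write_truth", "read_truth"]

# rendering constants (intensity units; nominal channel range [0, 1])
_RING_AMP = 0.9
_PUNCTA_AMP = 0.6
_CYTO_AMP = 0.8
_NUCLEUS_AMP = 1.0
_NUCLEUS_RADIUS = 3.5       # filled disc, 7 px diameter
_NUCLEUS_BLUR_SD = 0.8      # px
_PUNCTUM_RADIUS = 1.5       # px
_MIN_NUCLEUS_SPACING = 9.5  # px between nucleus centres; keeps blobs separable
_PLACEMENT_RETRIES = 2000


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a follicle."""


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic section.

    Defaults emulate a 2048x2048 field at 0.62 µm/px holding 30
    non-touching follicles with lumen radii 18-55 px (11-34 µm),
    epithelia 12-18 px (7-11 µm) thick, 8-20 epithelial nuclei per
    follicle, ~4% of nuclei shed into lumina, and 31% of the marker
    signal located in the lumina (the wild-type extracellular share
    reported for cathepsin B).
    """

    image_size: tuple[int, int] = (2048, 2048)
    pixel_size: float = 0.62
    n_follicles: int = 30
    lumen_radius_range: tuple[float, float] = (18.0, 55.0)
    epithelium_thickness_range: tuple[float, float] = (12.0, 18.0)
    nuclei_per_follicle_range: tuple[int, int] = (8, 20)
    dead_cell_fraction: float = 0.04
    luminal_marker_fraction: float = 0.31
    puncta_per_cell: int = 3
    noise_sd: float = 0.01
    min_gap: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("lumen_radius_range", "epithelium_thickness_range",
                     "nuclei_per_follicle_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must satisfy min <= max, got ({lo}, {hi})")
        for name in ("dead_cell_fraction", "luminal_marker_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_follicles < 0:
            raise ValueError("n_follicles must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside a phantom image.

    ``follicles`` has one row per follicle: id, centre (px), areas (µm²),
    nucleus counts, and the true epithelial extension (µm).  The
    image-level marker sums are taken on the noiseless rendering.
    """

    follicles: pd.DataFrame
    total_marker_signal: float
    intracellular_marker_signal: float
    pixel_size: float

    FOLLICLE_COLUMNS = (
        "follicle_id", "center_y", "center_x", "lumen_area_um2",
        "follicle_area_um2", "epithelium_area_um2", "n_epithelial_nuclei",
        "n_intraluminal_nuclei", "true_eext_um",
    )

    def validate(self) -> None:
        f = self.follicles
        if list(f.columns) != list(self.FOLLICLE_COLUMNS):
            raise ValueError("unexpected truth columns")
        if len(f) and not np.allclose(
            f["follicle_area_um2"].astype(float),
            f["lumen_area_um2"].astype(float) + f["epithelium_area_um2"].astype(float),
        ):
            raise ValueError("follicle_area must equal lumen_area + epithelium_area")
        if self.intracellular_marker_signal > self.total_marker_signal + 1e-6:
            raise ValueError("intracellular marker signal exceeds total")


def _disc_offsets(radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    inside = yy**2 + xx**2 < radius**2
    return yy[inside], xx[inside]


def _paint_disc(img: np.ndarray, cy: float, cx: float, radius: float, value: float) -> None:
    dy, dx = _disc_offsets(radius)
    rr = np.clip(np.round(cy + dy).astype(int), 0, img.shape[0] - 1)
    cc = np.clip(np.round(cx + dx).astype(int), 0, img.shape[1] - 1)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def _place_points(
    rng: np.random.Generator,
    n: int,
    r_lo: float,
    r_hi: float,
    min_spacing: float,
) -> list[tuple[float, float]]:
    """Place up to ``n`` points in a radial band with pairwise spacing."""
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n and tries < _PLACEMENT_RETRIES:
        tries += 1
        rad = np.sqrt(rng.uniform(r_lo**2, max(r_hi, r_lo + 1e-9) ** 2))
        ang = rng.uniform(0, 2 * np.pi)
        y, x = rad * np.sin(ang), rad * np.cos(ang)
        if all((y - py) ** 2 + (x - px) ** 2 >= min_spacing**2 for py, px in pts):
            pts.append((y, x))
    return pts


def generate_phantom(
    spec: PhantomSpec, return_labels: bool = False
) -> tuple[ChannelStack, PhantomTruth] | tuple[ChannelStack, PhantomTruth, dict]:
    """Render a phantom section and its ground truth.

    With ``return_labels=True`` the rendered ground-truth label maps
    (lumen / follicle / epithelium label rasters, nucleus centres, and the
    cytoplasm extent) are returned as a third element for recovery tests.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    ps = spec.pixel_size

    # --- follicle centres by bounded rejection sampling -----------------
    centers: list[tuple[float, float]] = []
    radii: list[tuple[float, float]] = []  # (lumen radius, outer radius)
    for i in range(spec.n_follicles):
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            r_l = rng.uniform(*spec.lumen_radius_range)
            t = rng.uniform(*spec.epithelium_thickness_range)
            R = r_l + t
            if 2 * R + 4 > min(H, W):
                continue
            cy = rng.uniform(R + 2, H - R - 2)
            cx = rng.uniform(R + 2, W - R - 2)
            if all(
                np.hypot(cy - oy, cx - ox) >= R + oR + spec.min_gap
                for (oy, ox), (_, oR) in zip(centers, radii)
            ):
                centers.append((cy, cx))
                radii.append((r_l, R))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place follicle {i} after {_PLACEMENT_RETRIES} attempts; "
                "reduce n_follicles or follicle sizes"
            )

    marker = np.zeros((H, W))
    cytoplasm = np.zeros((H, W))
    nuclei_ch = np.zeros((H, W))
    lumen_labels = np.zeros((H, W), dtype=np.int32)
    follicle_labels = np.zeros((H, W), dtype=np.int32)
    epithelium_labels = np.zeros((H, W), dtype=np.int32)

    rows = []
    nucleus_centers: list[tuple[float, float, int, bool]] = []  # y, x, follicle, dead
    epi_counts = []
    for k, ((cy, cx), (r_l, R)) in enumerate(zip(centers, radii), start=1):
        r = int(np.ceil(R)) + 1
        y0, y1 = int(cy) - r, int(cy) + r + 1
        x0, x1 = int(cx) - r, int(cx) + r + 1
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dd = (yy - cy) ** 2 + (xx - cx) ** 2
        lumen = dd < r_l**2
        follicle = dd < (R - 1) ** 2          # excludes the 1-px lamina line
        ring = (dd >= (R - 1) ** 2) & (dd < R**2)
        annulus = (dd >= r_l**2) & (dd < R**2)  # cytoplasm incl. lamina zone
        sl = (slice(y0, y1), slice(x0, x1))
        lumen_labels[sl][lumen] = k
        follicle_labels[sl][follicle] = k
        epithelium_labels[sl][follicle & ~lumen] = k
        cytoplasm[sl][annulus] = _CYTO_AMP
        marker[sl][ring] = np.maximum(marker[sl][ring], _RING_AMP)

        # epithelial nuclei, spaced so blob detection can count them exactly
        n_req = int(rng.integers(spec.nuclei_per_follicle_range[0],
                                 spec.nuclei_per_follicle_range[1] + 1))
        band_lo = r_l + _NUCLEUS_RADIUS + 1.0
        band_hi = R - 1 - _NUCLEUS_RADIUS - 1.5
        if band_hi <= band_lo:  # degenerate thin epithelium: use mid-annulus
            band_lo = band_hi = (r_l + R - 1) / 2
        pts = _place_points(rng, n_req, band_lo, band_hi, _MIN_NUCLEUS_SPACING)
        for (dy, dx) in pts:
            nucleus_centers.append((cy + dy, cx + dx, k, False))
        epi_counts.append(len(pts))

        # vesicular puncta in the cytoplasm, clear of the lamina line
        p_lo = r_l + _PUNCTUM_RADIUS + 1.0
        p_hi = R - 1 - _PUNCTUM_RADIUS - 1.0
        if p_hi > p_lo:
            n_p = spec.puncta_per_cell * len(pts)
            for _ in range(n_p):
                rad = np.sqrt(rng.uniform(p_lo**2, p_hi**2))
                ang = rng.uniform(0, 2 * np.pi)
                _paint_disc(marker, cy + rad * np.sin(ang), cx + rad * np.cos(ang),
                            _PUNCTUM_RADIUS, _PUNCTA_AMP)

    # --- dead-cell remnants inside lumina -------------------------------
    # n_dead/(n_epi + n_dead) ~= dead_cell_fraction
    n_epi_total = sum(epi_counts)
    f = spec.dead_cell_fraction
    n_dead = int(round(f / (1 - f) * n_epi_total)) if f < 1 else n_epi_total
    dead_counts = [0] * len(centers)
    eligible = [
        j for j, (r_l, _) in enumerate(radii) if r_l > _NUCLEUS_RADIUS + 3.5
    ]
    dead_pts: dict[int, list[tuple[float, float]]] = {j: [] for j in eligible}
    placed_dead = 0
    attempts = 0
    while placed_dead < n_dead and eligible and attempts < _PLACEMENT_RETRIES:
        attempts += 1
        j = int(rng.choice(eligible))
        cy, cx = centers[j]
        r_l = radii[j][0]
        pt = _place_points(rng, 1, 0.0, r_l - _NUCLEUS_RADIUS - 3.0,
                           _MIN_NUCLEUS_SPACING)
        if not pt:
            continue
        dy, dx = pt[0]
        if all((dy - py) ** 2 + (dx - px) ** 2 >= _MIN_NUCLEUS_SPACING**2
               for py, px in dead_pts[j]):
            dead_pts[j].append((dy, dx))
            nucleus_centers.append((cy + dy, cx + dx, j + 1, True))
            dead_counts[j] += 1
            placed_dead += 1

    for (ny, nx, _, _) in nucleus_centers:
        _paint_disc(nuclei_ch, ny, nx, _NUCLEUS_RADIUS, _NUCLEUS_AMP)
    if nucleus_centers:
        nuclei_ch = ndi.gaussian_filter(nuclei_ch, _NUCLEUS_BLUR_SD)

    # --- diffuse luminal marker: set the luminal share exactly ----------
    lumen_mask = lumen_labels > 0
    intracellular = float(marker.sum())  # ring + puncta; all within cytoplasm
    n_lumen_px = int(lumen_mask.sum())
    lf = spec.luminal_marker_fraction
    if n_lumen_px > 0:
        if lf >= 1.0:
            marker[:] = 0.0
            intracellular = 0.0
            marker[lumen_mask] = 0.1
        elif lf > 0 and intracellular > 0:
            luminal_total = lf / (1 - lf) * intracellular
            marker[lumen_mask] += luminal_total / n_lumen_px
    total = float(marker.sum())

    # --- truth table (areas = rasterized pixel counts x pixel area) -----
    for k, ((cy, cx), (r_l, R)) in enumerate(zip(centers, radii), start=1):
        a_lum = float((lumen_labels == k).sum()) * ps**2
        a_fol = float((follicle_labels == k).sum()) * ps**2
        a_epi = a_fol - a_lum
        eext = np.sqrt(a_fol / np.pi) - np.sqrt(a_lum / np.pi)
        rows.append((k, cy, cx, a_lum, a_fol, a_epi,
                     epi_counts[k - 1], dead_counts[k - 1], eext))
    follicle_df = pd.DataFrame(rows, columns=list(PhantomTruth.FOLLICLE_COLUMNS))
    truth = PhantomTruth(
        follicles=follicle_df,
        total_marker_signal=total,
        intracellular_marker_signal=intracellular,
        pixel_size=ps,
    )
    truth.validate()

    if spec.noise_sd > 0:
        for ch in (marker, cytoplasm, nuclei_ch):
            ch += rng.normal(0.0, spec.noise_sd, size=ch.shape)
            np.clip(ch, 0.0, None, out=ch)

    stack = ChannelStack(marker, cytoplasm, nuclei_ch, ps)
    if return_labels:
        labels = {
            "lumen": lumen_labels,
            "follicle": follicle_labels,
            "epithelium": epithelium_labels,
            "cytoplasm_extent": cytoplasm > 0,
            "nucleus_centers": nucleus_centers,
        }
        return stack, truth, labels
    return stack, truth


def write_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Write the truth table as CSV: follicle rows plus one image summary row."""
    df = truth.follicles.copy()
    df.insert(0, "row_kind", "follicle")
    extra = ["total_marker_signal", "intracellular_marker_signal", "pixel_size"]
    for c in extra:
        df[c] = np.nan
    if len(df):
        summary = {c: np.nan for c in df.columns}
        summary.update(
            row_kind="image",
            total_marker_signal=truth.total_marker_signal,
            intracellular_marker_signal=truth.intracellular_marker_signal,
            pixel_size=truth.pixel_size,
        )
        df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    df.to_csv(path, index=False)


def read_truth(path: str | Path) -> PhantomTruth:
    raw = pd.read_csv(path)
    follicles = (
        raw[raw.get("row_kind", pd.Series(dtype=object)) == "follicle"]
        .loc[:, list(PhantomTruth.FOLLICLE_COLUMNS)]
        .reset_index(drop=True)
    )
    for col in ("follicle_id", "n_epithelial_nuclei", "n_intraluminal_nuclei"):
        follicles[col] = follicles[col].astype(int)
    image_rows = raw[raw.get("row_kind", pd.Series(dtype=object)) == "image"]
    if len(image_rows):
        image = image_rows.iloc[0]
        total = float(image["total_marker_signal"])
        intra = float(image["intracellular_marker_signal"])
        ps = float(image["pixel_size"])
    else:  # header-only file from an empty truth
        total = intra = 0.0
        ps = float("nan")
    truth = PhantomTruth(
        follicles=follicles,
        total_marker_signal=total,
        intracellular_marker_signal=intra,
        pixel_size=ps,
    )
    truth.validate()
    return truth
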