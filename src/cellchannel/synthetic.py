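"""Synthetic multi-channel microscopy fields with per-cell ground truth.

The generator emulates dishes of cultured hematopoietic progenitors imaged in
four channels: a phase-contrast-like segmentation channel (dark cell body with
a bright halo), two auxiliary transmitted-light texture channels (DIC-like and
bright-field-like), and a fluorescence surface-marker channel whose per-cell
total intensity is bimodal — high for the committed progenitor ("proB-like")
and low for the uncommitted one ("LMPP-like") — riding on a smoothly varying
illumination background.

Two cell types are mixed at a configurable fraction.  The types differ only
through three controllable effect sizes: mean pixel area (``size_means``),
internal texture variance (``texture_effect``) and the separation of the log
marker-intensity means (``marker_separation``).  With all three at their null
values the non-marker appearance of the two types is drawn from identical
distributions, so any downstream classifier must perform at chance.

Cells are rendered as smoothed ellipses with per-cell eccentricity jitter;
texture is per-cell band-passed Gaussian noise whose standard deviation is
scaled by ``1 + texture_effect`` for proB-like cells.  Focal offsets are
emulated by isotropic Gaussian blur of width proportional to the offset;
time points are noise-independent re-acquisitions of the same scene.  Pixels
are stored as 16-bit unsigned integers with fixed gain.

Everything is reproducible from a single seed, hierarchically split per dish
and per field with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

TYPE_LMPP = "LMPP-like"   # marker-low type (index 0)
TYPE_PROB = "proB-like"   # marker-high type (index 1)
TYPE_NAMES = (TYPE_LMPP, TYPE_PROB)

#: channel role names; "ph" is the segmentation channel
CHANNELS = ("ph", "dic", "bf", "marker")

# fixed rendering constants (16-bit intensity units)
_BACKGROUND = 20000.0
_BODY_OFFSET = {"ph": -6000.0, "dic": 3000.0, "bf": -2500.0}
_RIM_GAIN = {"ph": 7000.0, "dic": 2000.0, "bf": 1000.0}
_TEXTURE_GAIN = {"ph": 1.0, "dic": 1.2, "bf": 0.8}
_TEXTURE_BASE_SD = 1200.0     # within-cell texture sd for LMPP-like cells
_TEXTURE_BANDPASS_SIGMA = 1.5
_MARKER_BASELINE = 1.0        # autofluorescence emission per pixel
_MARKER_LOG_MEAN_LOW = math.log(10000.0)  # log total emission, LMPP-like
_MARKER_GAIN = 10.0           # emission -> 16-bit conversion
_HALO_WIDTH_PX = 2
_PAIR_OVERLAP_PX = 6.0        # center-line overlap of a touching pair
_DEFOCUS_SIGMA_PER_UM = 2.0   # px of Gaussian blur per micron of defocus
_DISH_GAIN_SD = 0.06          # sd of the per-dish illumination gain (about 1)
_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults reproduce the imaging regime the pipeline is designed for:
    three culture dishes, round cells of two types mixed ~1:1 at a few
    hundred cells per field, cell areas inside the (2000, 8000) px band
    that the segmentation stage keeps, and a strongly bimodal marker
    (separation of 6 log-units at unit log-sd).
    """

    n_dishes: int = 3
    fields_per_dish: int = 2
    field_shape: tuple[int, int] = (2048, 2048)
    cells_per_field: int = 300
    type_fraction: float = 0.5           # fraction of proB-like cells
    size_means: tuple[float, float] = (3400.0, 4800.0)  # px area (LMPP, proB)
    size_sd: float = 450.0
    texture_effect: float = 1.0          # proB texture sd = base * (1 + effect)
    marker_separation: float = 6.0       # distance of log marker-total means
    marker_sd: float = 1.0               # sd of log marker totals, both types
    touching_fraction: float = 0.1       # fraction of cells placed in pairs
    background_amplitude: float = 0.3    # relative amplitude of smooth field
    noise_sd: float = 100.0              # additive sensor noise, 16-bit units
    n_focal_planes: int = 1
    n_time_planes: int = 1
    focal_offsets_um: tuple[float, ...] | None = None  # default: symmetric grid
    placement_margin_px: int = 0         # extra keep-out from the border
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name in ("n_dishes", "fields_per_dish", "cells_per_field",
                     "n_focal_planes", "n_time_planes", "placement_margin_px"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("type_fraction", "touching_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must be in [0, 1]")
        for name in ("size_sd", "marker_sd", "noise_sd", "texture_effect",
                     "background_amplitude"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if min(self.size_means) <= 0:
            problems.append("size_means must be positive")
        if self.n_focal_planes < 1 or self.n_time_planes < 1:
            problems.append("n_focal_planes and n_time_planes must be >= 1")
        if (self.focal_offsets_um is not None
                and len(self.focal_offsets_um) != self.n_focal_planes):
            problems.append("focal_offsets_um length must equal n_focal_planes")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    @property
    def focal_offsets(self) -> tuple[float, ...]:
        if self.focal_offsets_um is not None:
            return tuple(self.focal_offsets_um)
        n = self.n_focal_planes
        if n == 1:
            return (0.0,)
        # symmetric grid at 1.5 um steps around the reference plane
        half = (n - 1) / 2.0
        return tuple(1.5 * (i - half) for i in range(n))

    @property
    def reference_plane(self) -> int:
        offs = self.focal_offsets
        return int(np.argmin(np.abs(offs)))


@dataclass
class FieldImage:
    """One multi-channel field: per channel a (focal, time, H, W) uint16 stack."""

    dish_id: int
    field_id: int
    channels: dict[str, np.ndarray]
    focal_offsets_um: tuple[float, ...]

    def plane(self, channel: str, focal: int | None = None, time: int = 0) -> np.ndarray:
        """A single 2D plane; ``focal=None`` selects the in-focus plane."""
        stack = self.channels[channel]
        if focal is None:
            focal = int(np.argmin(np.abs(self.focal_offsets_um)))
        return stack[focal, time]

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape[-2:]


@dataclass
class GroundTruth:
    """Per-cell truth for one field plus its label-mask image."""

    cells: pd.DataFrame   # cell_id, dish_id, field_id, y, x, true_type, area_px, marker_total
    label_mask: np.ndarray
    n_placement_failures: int = 0


def draw_marker_log_totals(rng: np.random.Generator, types: np.ndarray,
                           config: SyntheticConfig) -> np.ndarray:
    """Log total marker emission per cell: Normal(mu_type, marker_sd).

    The two type means are separated by exactly ``marker_separation``
    log-units, with the proB-like type high.
    """
    mu = _MARKER_LOG_MEAN_LOW + config.marker_separation * np.asarray(types, float)
    return mu + config.marker_sd * rng.standard_normal(len(types))


def _ellipse_radius(a: float, b: float, theta: float, phi: float) -> float:
    """Radius of an ellipse (semi-axes a, b, orientation theta) along phi."""
    c = math.cos(phi - theta)
    s = math.sin(phi - theta)
    return a * b / math.sqrt((b * c) ** 2 + (a * s) ** 2)


def _place_cells(config: SyntheticConfig, rng: np.random.Generator,
                 shape: tuple[int, int]):
    """Rejection-sample cell centers, sizes and orientations.

    Returns (list of cell dicts, n_failures).  Cells come in singletons and
    designated touching pairs; non-pair cells keep a clearance of 3 px
    between bounding circles, pair partners overlap by ~_PAIR_OVERLAP_PX
    along the line of centers.
    """
    h, w = shape
    n = config.cells_per_field
    n_pairs = int(config.touching_fraction * n / 2)
    order = []  # each entry: "single" or "pair"
    order += ["pair"] * n_pairs
    order += ["single"] * (n - 2 * n_pairs)

    cells: list[dict] = []
    placed_xy: list[tuple[float, float, float]] = []  # (y, x, bound_radius)
    failures = 0

    def sample_geometry(tid: int) -> tuple[float, float, float, float]:
        area = max(500.0, rng.normal(config.size_means[tid], config.size_sd))
        q = rng.uniform(0.75, 1.0)
        a = math.sqrt(area / (math.pi * q))
        b = q * a
        theta = rng.uniform(0.0, math.pi)
        return a, b, theta, area

    def fits(y: float, x: float, r: float) -> bool:
        m = r + 3 + config.placement_margin_px
        if not (m <= y <= h - 1 - m and m <= x <= w - 1 - m):
            return False
        for (py, px, pr) in placed_xy:
            if (y - py) ** 2 + (x - px) ** 2 < (r + pr + 3.0) ** 2:
                return False
        return True

    for kind in order:
        tid = int(rng.random() < config.type_fraction)
        a, b, theta, _ = sample_geometry(tid)
        ok = False
        for _ in range(_PLACEMENT_RETRIES):
            y = rng.uniform(0, h - 1)
            x = rng.uniform(0, w - 1)
            if fits(y, x, a):
                ok = True
                break
        if not ok:
            failures += 1
            if kind == "pair":
                failures += 1
            continue
        if kind == "single":
            cells.append(dict(y=y, x=x, a=a, b=b, theta=theta, type=tid))
            placed_xy.append((y, x, a))
            continue
        # touching pair: place the partner overlapping along a random direction
        tid2 = int(rng.random() < config.type_fraction)
        a2, b2, theta2, _ = sample_geometry(tid2)
        partner = None
        for _ in range(_PLACEMENT_RETRIES):
            phi = rng.uniform(0.0, 2 * math.pi)
            d = (_ellipse_radius(a, b, theta, phi)
                 + _ellipse_radius(a2, b2, theta2, phi + math.pi)
                 - _PAIR_OVERLAP_PX)
            y2, x2 = y + d * math.sin(phi), x + d * math.cos(phi)
            m = a2 + 3 + config.placement_margin_px
            if not (m <= y2 <= h - 1 - m and m <= x2 <= w - 1 - m):
                continue
            clear = True
            for (py, px, pr) in placed_xy:
                if (y2 - py) ** 2 + (x2 - px) ** 2 < (a2 + pr + 3.0) ** 2:
                    clear = False
                    break
            if clear:
                partner = dict(y=y2, x=x2, a=a2, b=b2, theta=theta2, type=tid2)
                break
        cells.append(dict(y=y, x=x, a=a, b=b, theta=theta, type=tid))
        placed_xy.append((y, x, a))
        if partner is None:
            failures += 1
        else:
            cells.append(partner)
            placed_xy.append((partner["y"], partner["x"], partner["a"]))
    return cells, failures


def _cell_footprint(cell: dict, shape: tuple[int, int]):
    """Binary ellipse mask of one cell on its local bounding box.

    Returns (row slice, col slice, mask, rho2) where rho2 is the squared
    normalized elliptical radius on the box (<= 1 inside the cell).
    """
    h, w = shape
    y, x, a, b, th = cell["y"], cell["x"], cell["a"], cell["b"], cell["theta"]
    r = int(math.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - y
    dx = xx - x
    ct, st = math.cos(th), math.sin(th)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho2 = (u / a) ** 2 + (v / b) ** 2
    return slice(r0, r1), slice(c0, c1), rho2 <= 1.0, rho2


def _smooth_background(rng: np.random.Generator, shape: tuple[int, int],
                       amplitude: float) -> np.ndarray:
    """Multiplicative illumination surface in [1 - a/2, 1 + a/2].

    A vignetting-like gradient (cubic upsampling of a 2x2 grid): its
    spatial wavelength is about twice the field, much slower than the
    sigma-200 flat-fielding blur, so dividing by the blurred image can
    actually remove it.
    """
    coarse = rng.standard_normal((2, 2))
    zoom = (shape[0] / 2, shape[1] / 2)
    surf = ndi.zoom(coarse, zoom, order=3, mode="reflect", grid_mode=True)
    lo, hi = surf.min(), surf.max()
    if hi - lo < 1e-12:
        return np.ones(shape)
    unit = (surf - lo) / (hi - lo)  # in [0, 1]
    return 1.0 + amplitude * (unit - 0.5)


def _to_uint16(img: np.ndarray) -> np.ndarray:
    out = np.rint(np.clip(img, 0.0, 65535.0)).astype(np.uint16)
    if not np.isfinite(img).all():
        raise RuntimeError("internal error: non-finite pixel in rendered field")
    return out


def generate_field(config: SyntheticConfig, dish_id: int, field_id: int,
                   rng_state, dish_gain: float = 1.0,
                   first_cell_id: int = 0) -> tuple[FieldImage, GroundTruth]:
    """Render one field and its ground truth.

    ``rng_state`` is a :class:`numpy.random.SeedSequence` or Generator;
    ``dish_gain`` is the dish-level illumination multiplier shared by all
    fields of the dish.
    """
    config.validate()
    h, w = config.field_shape
    mean_r = math.sqrt(max(config.size_means) / math.pi)
    if config.cells_per_field > 0 and min(h, w) < 2 * (mean_r + 5):
        raise ValueError(
            f"field {dish_id}/{field_id}: field_shape {config.field_shape} too "
            f"small for cells of mean radius {mean_r:.0f} px")
    if isinstance(rng_state, np.random.Generator):
        rng = rng_state
    else:
        rng = np.random.default_rng(rng_state)

    cells, failures = _place_cells(config, rng, (h, w))
    n = len(cells)
    density = config.cells_per_field * math.pi * mean_r ** 2 / (h * w)
    if config.cells_per_field > 0 and n < config.cells_per_field / 2:
        raise RuntimeError(
            f"placement failure in dish {dish_id} field {field_id}: placed only "
            f"{n}/{config.cells_per_field} cells at packing density {density:.2f}")

    types = np.array([c["type"] for c in cells], dtype=int)
    log_totals = draw_marker_log_totals(rng, types, config)

    # --- label mask (overlap pixels go to the nearer center) ---------------
    label_mask = np.zeros((h, w), dtype=np.uint16)
    dist_own = np.full((h, w), np.inf)
    footprints = []
    for i, cell in enumerate(cells):
        rs, cs, mask, rho2 = _cell_footprint(cell, (h, w))
        footprints.append((rs, cs, mask, rho2))
        sub_d = dist_own[rs, cs]
        sub_l = label_mask[rs, cs]
        closer = mask & (rho2 < sub_d)
        sub_l[closer] = i + 1
        sub_d[closer] = rho2[closer]
        label_mask[rs, cs] = sub_l
        dist_own[rs, cs] = sub_d

    areas = np.bincount(label_mask.ravel(), minlength=n + 1)[1:].astype(int)

    # --- noiseless channel rendering ---------------------------------------
    base = {ch: np.full((h, w), _BACKGROUND, dtype=np.float64)
            for ch in ("ph", "dic", "bf")}
    emission = np.full((h, w), _MARKER_BASELINE, dtype=np.float64)

    for i, cell in enumerate(cells):
        rs, cs, _, rho2 = _cell_footprint(cell, (h, w))
        own = label_mask[rs, cs] == i + 1
        if not own.any():
            continue
        # band-passed texture, unit sd inside the cell
        tex = ndi.gaussian_filter(rng.standard_normal(rho2.shape),
                                  _TEXTURE_BANDPASS_SIGMA)
        sd = tex[own].std()
        tex = tex / sd if sd > 0 else tex
        amp = _TEXTURE_BASE_SD * (1.0 + config.texture_effect * cell["type"])
        for ch in ("ph", "dic", "bf"):
            sub = base[ch][rs, cs]
            sub[own] += _BODY_OFFSET[ch] + _TEXTURE_GAIN[ch] * amp * tex[own]
            base[ch][rs, cs] = sub
        # radial emission profile (1 - rho^2)^2, normalized to total 1
        prof = np.where(own, np.maximum(0.0, 1.0 - rho2) ** 2, 0.0)
        tot = prof.sum()
        if tot > 0:
            emission[rs, cs] += math.exp(log_totals[i]) * prof / tot

    # phase-contrast halo: bright rim just outside the foreground
    fg = label_mask > 0
    rim = ndi.binary_dilation(fg, ndi.generate_binary_structure(2, 2),
                              iterations=_HALO_WIDTH_PX) & ~fg
    for ch in ("ph", "dic", "bf"):
        base[ch][rim] += _RIM_GAIN[ch]

    illum = _smooth_background(rng, (h, w), config.background_amplitude)
    base["marker"] = emission * illum * _MARKER_GAIN
    for ch in ("ph", "dic", "bf"):
        base[ch] *= dish_gain
    base["marker"] *= dish_gain

    # --- focal planes and time points --------------------------------------
    offsets = config.focal_offsets
    channels: dict[str, np.ndarray] = {}
    noise_rng = np.random.default_rng(rng.integers(0, 2**31))
    for ch in CHANNELS:
        stack = np.empty((len(offsets), config.n_time_planes, h, w), np.uint16)
        for fi, off in enumerate(offsets):
            sigma = _DEFOCUS_SIGMA_PER_UM * abs(off)
            plane = ndi.gaussian_filter(base[ch], sigma) if sigma > 0 else base[ch]
            for ti in range(config.n_time_planes):
                noisy = plane + config.noise_sd * noise_rng.standard_normal((h, w))
                stack[fi, ti] = _to_uint16(noisy)
        channels[ch] = stack

    cells_df = pd.DataFrame({
        "cell_id": np.arange(first_cell_id, first_cell_id + n),
        "dish_id": dish_id,
        "field_id": field_id,
        "y": [c["y"] for c in cells],
        "x": [c["x"] for c in cells],
        "true_type": [TYPE_NAMES[c["type"]] for c in cells],
        "area_px": areas,
        "marker_total": np.exp(log_totals),
        "pair_partner": _pair_partners(cells, first_cell_id),
    })
    image = FieldImage(dish_id=dish_id, field_id=field_id, channels=channels,
                       focal_offsets_um=tuple(offsets))
    truth = GroundTruth(cells=cells_df, label_mask=label_mask,
                        n_placement_failures=failures)
    return image, truth


def _pair_partners(cells: list[dict], first_cell_id: int) -> list[int]:
    """Ground-truth pair bookkeeping: partner cell_id or -1 for singletons.

    Pairs are consecutive in placement order; a cell whose neighbour overlaps
    it (center distance below the sum of bounding radii) is its partner.
    """
    partners = [-1] * len(cells)
    i = 0
    while i + 1 < len(cells):
        a, b = cells[i], cells[i + 1]
        d2 = (a["y"] - b["y"]) ** 2 + (a["x"] - b["x"]) ** 2
        if partners[i] == -1 and d2 < (a["a"] + b["a"]) ** 2:
            partners[i] = first_cell_id + i + 1
            partners[i + 1] = first_cell_id + i
            i += 2
        else:
            i += 1
    return partners


def generate_experiment(config: SyntheticConfig):
    """Generate all dishes and fields of one experiment.

    Returns a list of ``(FieldImage, GroundTruth)`` of length
    ``n_dishes * fields_per_dish``.  Dish illumination gains are drawn once
    per dish and shared across its fields; cell ids are unique across the
    experiment; everything is reproducible from ``config.seed``.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    dish_seqs = root.spawn(config.n_dishes)
    out = []
    next_id = 0
    for d in range(config.n_dishes):
        dish_rng = np.random.default_rng(dish_seqs[d])
        gain = 1.0 + _DISH_GAIN_SD * dish_rng.standard_normal()
        field_seqs = dish_seqs[d].spawn(config.fields_per_dish)
        for f in range(config.fields_per_dish):
            img, truth = generate_field(config, dish_id=d + 1, field_id=f + 1,
                                        rng_state=field_seqs[f], dish_gain=gain,
                                        first_cell_id=next_id)
            next_id += len(truth.cells)
            out.append((img, truth))
    return out


def write_experiment(fields, out_dir: str | Path) -> None:
    """Write TIFFs + ground-truth CSV + sidecar JSON for a generated experiment."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = []
    for img, truth in fields:
        stem = f"d{img.dish_id}_f{img.field_id}"
        sidecar = {"dish_id": img.dish_id, "field_id": img.field_id,
                   "focal_offsets_um": list(img.focal_offsets_um),
                   "page_order": "pages = focal planes (outer) x time points (inner)"}
        for ch, stack in img.channels.items():
            nf, nt, h, w = stack.shape
            tifffile.imwrite(out / f"{stem}_{ch}.tif",
                             stack.reshape(nf * nt, h, w))
        tifffile.imwrite(out / f"{stem}_labels.tif", truth.label_mask)
        (out / f"{stem}_meta.json").write_text(json.dumps(sidecar, indent=2))
        tables.append(truth.cells)
    pd.concat(tables, ignore_index=True).to_csv(out / "ground_truth.csv",
                                                index=False)


def read_experiment(in_dir: str | Path):
    """Read back an experiment written by :func:`write_experiment`."""
    import tifffile

    src = Path(in_dir)
    gt = pd.read_csv(src / "ground_truth.csv")
    fields = []
    for meta_path in sorted(src.glob("d*_f*_meta.json")):
        meta = json.loads(meta_path.read_text())
        stem = f"d{meta['dish_id']}_f{meta['field_id']}"
        offs = tuple(meta["focal_offsets_um"])
        channels = {}
        for ch in CHANNELS:
            pages = tifffile.imread(src / f"{stem}_{ch}.tif")
            if pages.ndim == 2:
                pages = pages[None]
            nf = len(offs)
            nt = pages.shape[0] // nf
            channels[ch] = pages.reshape(nf, nt, *pages.shape[1:])
        mask = tifffile.imread(src / f"{stem}_labels.tif")
        cells = gt[(gt.dish_id == meta["dish_id"])
                   & (gt.field_id == meta["field_id"])].reset_index(drop=True)
        img = FieldImage(meta["dish_id"], meta["field_id"], channels, offs)
        fields.append((img, GroundTruth(cells=cells, label_mask=mask)))
    return fields


def null_config(**overrides) -> SyntheticConfig:
    """A configuration with no classifier-visible effect between types.

    Sizes equal, texture effect zero.  The marker separation is kept so the
    gating stage still produces well-defined labels; the marker channel is
    never a classifier input, so image-based classification must be at
    chance under this configuration.
    """
    base = SyntheticConfig(size_means=(4000.0, 4000.0), texture_effect=0.0)
    return replace(base, **overrides)
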