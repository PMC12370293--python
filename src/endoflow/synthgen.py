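"""Synthetic confluent endothelial-monolayer images with ground truth.

Renders the three-channel (nuclei / actin / VE-cadherin) fluorescence
stacks the measurement pipeline consumes, with full knowledge of the
underlying geometry: cells are a Lloyd-relaxed Voronoi tessellation of
the frame (polygonal, confluent, HUVEC-like), nuclei are ellipses at
the cell centroids, actin has a cortical rim plus stress-fiber chords,
and VE-cadherin follows one of three junction phenotypes:

``continuous``
    a uniform bright band of ``band_width`` px along every shared edge;
``fingers``
    the continuous band plus perpendicular spikes protruding beyond the
    band into the neighbouring cell (lengths ~ truncated normal);
``disrupted``
    the band attenuated by ``disruption_factor`` with bright cytoplasmic
    puncta (internalised VE-cadherin).

Optional Poisson-then-Gaussian noise approximates fluorescence
statistics.  All randomness flows from a single seeded generator, so a
spec renders bit-identically given the same seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import draw

from .segment import ImageStack, measure_intensity, membrane_ring

__all__ = ["SyntheticSpec", "GroundTruth", "PackingError", "generate_monolayer", "sweep"]


class PackingError(RuntimeError):
    """Raised when the requested cell count cannot be packed."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic field of view.

    Defaults emulate a 40x-63x confocal field of a confluent HUVEC
    monolayer: 1024 px square at 0.16 um/px with ~90 cells.  Intensities
    are arbitrary fluorescence units on a 16-bit scale.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.16  # um/px
    n_cells: int = 90
    phenotype: str = "continuous"  # continuous | fingers | disrupted
    aspect: float = 1.0  # >1 elongates cells along x (columns)
    band_width: int = 5  # px, drawn VE-cadherin band width (odd)
    finger_density: float = 0.02  # expected fingers per boundary px
    finger_length_mean: float = 10.0  # px beyond the band edge
    finger_length_sd: float = 2.0
    nucleus_intensity: float = 180.0
    actin_fiber_intensity: float = 140.0
    cortical_actin_intensity: float = 120.0
    actin_cytoplasm_intensity: float = 40.0
    membrane_vecad_intensity: float = 150.0
    cytoplasm_vecad_intensity: float = 30.0
    background: float = 5.0
    disruption_factor: float = 0.2  # delta in [0, 1]
    puncta_per_cell: int = 30
    puncta_radius: int = 2
    nucleus_area_fraction: float = 0.15
    fibers_per_cell: tuple[int, int] = (3, 8)
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        if not 0.0 <= self.disruption_factor <= 1.0:
            raise ValueError("disruption_factor must lie in [0, 1]")
        if self.phenotype not in ("continuous", "fingers", "disrupted"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        for name in (
            "nucleus_intensity", "actin_fiber_intensity", "cortical_actin_intensity",
            "actin_cytoplasm_intensity", "membrane_vecad_intensity",
            "cytoplasm_vecad_intensity", "background",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """What was actually drawn, for validating the measurement pipeline."""

    cell_labels: np.ndarray
    nuclei_labels: np.ndarray
    cells: pd.DataFrame  # per-cell: true junctional ratio, interior flag
    fingers: pd.DataFrame  # per-finger: edge, base, tip, drawn length (px)
    band_width: int
    phenotype: str


def _place_seeds(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    """Minimum-distance rejection sampling in anisotropy-scaled coordinates."""
    h, w = spec.shape
    # 0.75 keeps every Voronoi region at >= ~0.4x the mean cell area, so no
    # cell is so small that its nucleus fills it; the 3-px floor rules out
    # sub-cellular packings outright
    min_d = max(0.75 * np.sqrt(h * (w / spec.aspect) / spec.n_cells), 3.0)
    pts: list[np.ndarray] = []
    tries = 0
    max_tries = 300 * spec.n_cells
    while len(pts) < spec.n_cells:
        if tries >= max_tries:
            raise PackingError(
                f"could not place {spec.n_cells} seeds at min distance {min_d:.1f}px"
            )
        tries += 1
        cand = np.array([rng.uniform(0, h), rng.uniform(0, w) / spec.aspect])
        if all(np.hypot(*(cand - p)) >= min_d for p in pts):
            pts.append(cand)
    return np.array(pts)  # scaled coords (y, x/aspect)

def _tessellate(
    rng: np.random.Generator, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Voronoi raster of the frame after one Lloyd relaxation step.

    Returns the label map and the relaxed generator points (y, x); after
    the relaxation step the generators sit within a pixel or two of their
    region centroids, so they double as nucleus centres.
    """
    h, w = spec.shape
    seeds = _place_seeds(rng, spec)
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.column_stack([yy.ravel().astype(float), xx.ravel() / spec.aspect])
    _, idx = cKDTree(seeds).query(grid)
    labels = (idx + 1).reshape(h, w).astype(np.int32)
    # Lloyd: move each generator to its region's centroid, re-assign
    coms = ndi.center_of_mass(np.ones_like(labels), labels, np.arange(1, spec.n_cells + 1))
    seeds = np.array([[c[0], c[1] / spec.aspect] for c in coms])
    _, idx = cKDTree(seeds).query(grid)
    labels = (idx + 1).reshape(h, w).astype(np.int32)
    pts = np.column_stack([seeds[:, 0], seeds[:, 1] * spec.aspect])
    return labels, pts


def _draw_nuclei(
    rng: np.random.Generator,
    labels: np.ndarray,
    centres: np.ndarray,
    spec: SyntheticSpec,
) -> np.ndarray:
    """Filled ellipses (~15% of the mean cell area, random orientation).

    All nuclei share one target area: real endothelial nuclei vary far
    less in size than the cells do, and size-uniform seeds keep the
    seeded-watershed cell boundaries unbiased.
    """
    h, w = labels.shape
    nuclei = np.zeros_like(labels)
    target = spec.nucleus_area_fraction * (h * w / spec.n_cells)
    for lab, (cy, cx) in enumerate(centres, start=1):
        q = rng.uniform(1.15, 1.5)  # mild elongation
        a = np.sqrt(target * q / np.pi)
        b = a / q
        theta = rng.uniform(0, np.pi)
        rr, cc = draw.ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        keep = labels[rr, cc] == lab
        nuclei[rr[keep], cc[keep]] = lab
    return nuclei


def _interface_mask(labels: np.ndarray) -> np.ndarray:
    """1-px half-open interface between differing labels (no frame border)."""
    m = np.zeros(labels.shape, dtype=bool)
    m[:-1, :] |= labels[:-1, :] != labels[1:, :]
    m[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    return m


def _edge_groups(labels: np.ndarray, interface: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Interface pixels grouped by the (lo, hi) label pair they separate."""
    groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
    ys, xs = np.nonzero(interface)
    h, w = labels.shape
    for y, x in zip(ys.tolist(), xs.tolist()):
        la = labels[y, x]
        lb = labels[y + 1, x] if y + 1 < h and labels[y + 1, x] != la else (
            labels[y, x + 1] if x + 1 < w else la
        )
        if lb == la:
            continue
        key = (min(la, lb), max(la, lb))
        groups.setdefault(key, []).append((y, x))
    return {k: np.array(v) for k, v in groups.items()}


def generate_monolayer(spec: SyntheticSpec) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Deterministic for a given ``spec.rng_seed``.  The per-cell "true"
    junctional ratio in the ground truth is computed on the noise-free
    rendering using the true cell labels and the same 3-px membrane-ring
    definition the pipeline applies, so pipeline error can be attributed
    to segmentation rather than to the truth's own discretization.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.shape
    labels, seeds_yx = _tessellate(rng, spec)
    nuclei_lab = _draw_nuclei(rng, labels, seeds_yx, spec)
    interface = _interface_mask(labels)

    # --- nuclei channel ---
    nuc_ch = np.full((h, w), spec.background)
    gains = rng.uniform(0.85, 1.15, spec.n_cells + 1)
    nuc_ch[nuclei_lab > 0] = spec.background + (
        spec.nucleus_intensity * gains[nuclei_lab[nuclei_lab > 0]]
    )

    # --- actin channel ---
    act_ch = np.full((h, w), spec.background)
    act_ch[labels > 0] = spec.actin_cytoplasm_intensity
    rim_src = interface.copy()
    rim_src[0, :] = rim_src[-1, :] = True  # cortical actin also along the frame
    rim_src[:, 0] = rim_src[:, -1] = True
    rim = ndi.distance_transform_cdt(~rim_src, metric="chessboard") <= 1
    act_ch[rim] = spec.cortical_actin_intensity
    lo_f, hi_f = spec.fibers_per_cell
    for lab in range(1, spec.n_cells + 1):
        ys, xs = np.nonzero(labels == lab)
        n_fib = int(rng.integers(lo_f, hi_f + 1))
        for _ in range(n_fib):
            i, j = rng.integers(0, ys.size, 2)
            rr, cc = draw.line(ys[i], xs[i], ys[j], xs[j])
            inside = labels[rr, cc] == lab
            act_ch[rr[inside], cc[inside]] = spec.actin_fiber_intensity

    # --- VE-cadherin channel ---
    vec_ch = np.full((h, w), spec.background)
    vec_ch[labels > 0] = spec.cytoplasm_vecad_intensity
    # threshold at half the nominal width so the drawn band has true
    # perpendicular width band_width at any boundary orientation
    r_band = spec.band_width / 2.0
    band_zone = ndi.distance_transform_edt(~interface) <= r_band
    if spec.phenotype == "disrupted":
        band_val = max(
            spec.membrane_vecad_intensity * spec.disruption_factor,
            spec.cytoplasm_vecad_intensity,
        )
    else:
        band_val = spec.membrane_vecad_intensity
    vec_ch[band_zone] = band_val

    finger_rows: list[dict] = []
    if spec.phenotype == "fingers":
        groups = _edge_groups(labels, interface)
        for (la, lb), px in groups.items():
            if len(px) < 10:
                continue  # too short an edge to carry a finger
            # edge tangent via PCA; fingers protrude along the normal
            coords = px.astype(float)
            cov = np.cov((coords - coords.mean(axis=0)).T)
            evals, evecs = np.linalg.eigh(cov)
            tangent = evecs[:, np.argmax(evals)]
            normal = np.array([-tangent[1], tangent[0]])
            proj = coords @ tangent
            lo, hi = np.percentile(proj, [20, 80])
            central = np.nonzero((proj >= lo) & (proj <= hi))[0]
            if central.size == 0:
                continue
            n_spikes = rng.poisson(spec.finger_density * len(px))
            if n_spikes == 0:
                continue
            picks = central[rng.integers(0, central.size, n_spikes)]
            for pi in picks:
                by, bx = px[pi]
                d = normal if rng.random() < 0.5 else -normal
                flen = max(rng.normal(spec.finger_length_mean, spec.finger_length_sd), 1.0)
                tip = np.array([by, bx], float) + d * (r_band + flen)
                tip = np.clip(tip, [0, 0], [h - 1, w - 1])
                rr, cc = draw.line(int(by), int(bx), int(round(tip[0])), int(round(tip[1])))
                y0, y1 = max(rr.min() - 2, 0), min(rr.max() + 3, h)
                x0, x1 = max(cc.min() - 2, 0), min(cc.max() + 3, w)
                stamp = np.zeros((y1 - y0, x1 - x0), dtype=bool)
                stamp[rr - y0, cc - x0] = True
                stamp = ndi.binary_dilation(stamp, structure=np.ones((3, 3), bool))
                sub = vec_ch[y0:y1, x0:x1]
                sub[stamp] = spec.membrane_vecad_intensity
                finger_rows.append(
                    {
                        "edge": (int(la), int(lb)),
                        "base_y": int(by),
                        "base_x": int(bx),
                        "tip_y": float(tip[0]),
                        "tip_x": float(tip[1]),
                        "length_px": float(flen),
                    }
                )
    elif spec.phenotype == "disrupted" and spec.puncta_per_cell > 0:
        for lab in range(1, spec.n_cells + 1):
            ys, xs = np.nonzero((labels == lab) & (nuclei_lab == 0) & ~band_zone)
            if ys.size == 0:
                continue
            picks = rng.integers(0, ys.size, spec.puncta_per_cell)
            for pi in picks:
                rr, cc = draw.disk((ys[pi], xs[pi]), spec.puncta_radius, shape=(h, w))
                vec_ch[rr, cc] = spec.membrane_vecad_intensity

    # --- ground-truth junctional ratio from the noise-free rendering ---
    ring, _, _ = membrane_ring(labels, 3)
    whole = measure_intensity(labels, vec_ch)
    memb = measure_intensity(ring, vec_ch)
    edge_ids = set(np.unique(np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])))
    cells = pd.DataFrame(
        {
            "cell_id": whole.index,
            "true_junctional_ratio": (memb["mean_fi"] / whole["mean_fi"]).values,
            "interior": [cid not in edge_ids for cid in whole.index],
            "area_px": whole["n_px"].values,
        }
    ).set_index("cell_id")

    # --- noise ---
    channels = {"nuclei": nuc_ch, "actin": act_ch, "ve_cadherin": vec_ch}
    if spec.poisson_noise:
        channels = {k: rng.poisson(v).astype(float) for k, v in channels.items()}
    if spec.gaussian_noise_sd > 0:
        channels = {
            k: v + rng.normal(0.0, spec.gaussian_noise_sd, v.shape) for k, v in channels.items()
        }
    channels = {k: np.clip(v, 0.0, None) for k, v in channels.items()}

    stack = ImageStack(
        nuclei=channels["nuclei"],
        actin=channels["actin"],
        ve_cadherin=channels["ve_cadherin"],
        pixel_size=spec.pixel_size,
    )
    fingers = pd.DataFrame(
        finger_rows,
        columns=["edge", "base_y", "base_x", "tip_y", "tip_x", "length_px"],
    )
    truth = GroundTruth(
        cell_labels=labels,
        nuclei_labels=nuclei_lab,
        cells=cells,
        fingers=fingers,
        band_width=spec.band_width,
        phenotype=spec.phenotype,
    )
    return stack, truth


def sweep(specs: list[SyntheticSpec], out_dir) -> pd.DataFrame:
    """Render a list of specs to disk with a reproducibility manifest."""
    from . import imgio

    if len(specs) == 0:
        raise ValueError("at least one spec required")
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, spec in enumerate(specs):
        stem = f"field_{i:03d}_{spec.phenotype}_s{spec.rng_seed}"
        try:
            stack, truth = generate_monolayer(spec)
            paths = imgio.write_dataset(out / stem, stack, truth)
        except OSError as exc:
            raise OSError(f"failed writing spec #{i} ({spec.phenotype}): {exc}") from exc
        checks = {k: imgio.sha256_of(p) for k, p in paths.items()}
        rows.append(
            {
                "index": i,
                "stem": stem,
                "seed": spec.rng_seed,
                "phenotype": spec.phenotype,
                "spec_hash": spec.spec_hash(),
                **{f"path_{k}": str(p) for k, p in paths.items()},
                **{f"sha256_{k}": v for k, v in checks.items()},
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_json(out / "manifest.json", orient="records", indent=2)
    return manifest
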