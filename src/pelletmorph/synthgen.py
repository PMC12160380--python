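"""Seeded synthetic data with known ground truth.

Generates the three kinds of input the analysis pipeline consumes:

- 2D micrographs of pellet suspensions: bright, radially shaded, roughly
  circular pellets dominating the red channel on a dark background, with
  small noise objects, optional touching pairs and border-clipped pellets;
- 3D pellet volumes: one or more spore cores with branched hyphae grown
  outward by a discrete off-lattice segment model, optional embedded talc,
  and the geometric skeleton recorded as ground truth before voxelization;
- regression tables: replicate median diameters drawn from the ln-linear
  prediction model plus lognormal noise over a cultivation-condition grid.

All randomness flows through one `numpy.random.Generator` derived from an
explicit seed; fixed seed means bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .micro3d import HYPHAE, SPORE, TALC, Volume3D

#: full cultivation-condition grid: 3 spore titres × 2 shaking frequencies
#: × 4 talc concentrations × baffled/unbaffled = 48 conditions
SPORE_LEVELS = (5e4, 5e5, 5e6)
AGITATION_LEVELS = (150.0, 250.0)
TALC_LEVELS = (0.0, 1.0, 5.0, 10.0)
DEFAULT_CONDITION_GRID = tuple(
    (s, a, t, b)
    for s in SPORE_LEVELS
    for a in AGITATION_LEVELS
    for t in TALC_LEVELS
    for b in (False, True)
)

#: coefficients of the printed reduced prediction model for the median
#: pellet diameter: ln PD = b0 + bA·ln(A) + bT·T
PREDICTION_COEFFICIENTS = (15.863, -1.7769, -0.10856)


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture-of-lognormals diameter population.

    Each component is (weight, median diameter in µm, spread); the spread
    is the log-scale standard deviation, so a component with median m and
    spread s draws m·exp(s·Z) with Z standard normal. One component gives
    a unimodal population; several well-separated components a multimodal
    one.
    """

    components: tuple[tuple[float, float, float], ...]
    n_pellets: int

    def __post_init__(self) -> None:
        if self.n_pellets < 0:
            raise ValueError("n_pellets must be >= 0")
        if not self.components:
            raise ValueError("at least one component required")
        weights = np.array([c[0] for c in self.components], dtype=float)
        if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("component weights must be non-negative and sum to 1")
        for _, median, spread in self.components:
            if not 0 < median < 4000:
                raise ValueError("component medians must lie in (0, 4000) µm")
            if spread < 0:
                raise ValueError("component spread must be >= 0")

    @property
    def modality(self) -> str:
        return "unimodal" if len(self.components) == 1 else "multimodal"


@dataclass
class SceneGroundTruth:
    """Per-pellet geometry of a rendered micrograph (render order)."""

    true_diameters: np.ndarray
    true_centroids: np.ndarray  # (n, 2) pixel (row, col)
    border_flags: np.ndarray
    noise_object_count: int


@dataclass
class VolumeGroundTruth:
    """Ground truth of a generated 3D pellet."""

    n_cores: int
    core_centroids: np.ndarray  # (n_cores, 3) µm, volume frame
    skeleton_length_total: float
    n_tips: int
    n_branch_points: int
    class_label: str
    skeleton_graph: nx.Graph = field(repr=False, default_factory=nx.Graph)


def gen_population_diameters(spec: PopulationSpec, seed: int) -> np.ndarray:
    """Draw n_pellets diameters (µm) from the lognormal mixture."""
    rng = np.random.default_rng(seed)
    n = spec.n_pellets
    if n == 0:
        return np.empty(0, dtype=float)
    weights = np.array([c[0] for c in spec.components])
    comp = rng.choice(len(spec.components), size=n, p=weights)
    z = rng.standard_normal(n)
    medians = np.array([c[1] for c in spec.components])
    spreads = np.array([c[2] for c in spec.components])
    return medians[comp] * np.exp(spreads[comp] * z)


# ---------------------------------------------------------------------------
# 2D micrograph rendering


def _draw_pellet(red: np.ndarray, cy: float, cx: float, radius_px: float,
                 rng: np.random.Generator, roughness: float,
                 edge_intensity: float, peak_intensity: float) -> None:
    """Render one radially shaded pellet into the red channel (max blend)."""
    r_out = radius_px * (1.0 + abs(roughness)) + 2.0
    y0 = max(int(np.floor(cy - r_out)), 0)
    y1 = min(int(np.ceil(cy + r_out)) + 1, red.shape[0])
    x0 = max(int(np.floor(cx - r_out)), 0)
    x1 = min(int(np.ceil(cx + r_out)) + 1, red.shape[1])
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    r = np.hypot(dy, dx)
    k = int(rng.integers(5, 10))
    phi = float(rng.uniform(0, 2 * np.pi))
    r_eff = radius_px * (1.0 + roughness * np.sin(k * np.arctan2(dy, dx) + phi))
    inside = r <= r_eff
    t = np.clip(r / np.maximum(r_eff, 1e-9), 0.0, 1.0)
    intensity = edge_intensity + (peak_intensity - edge_intensity) * (1.0 - t**2)
    patch = red[y0:y1, x0:x1]
    patch[inside] = np.maximum(patch[inside], intensity[inside])


def render_micrograph(
    diameters_um,
    pixel_size: float,
    noise_spec: tuple[int, int] = (30, 3),
    touching_fraction: float = 0.0,
    border_fraction: float = 0.0,
    seed: int = 0,
    *,
    roughness: float = 0.03,
    image_size: tuple[int, int] | None = None,
    background_level: float = 8.0,
    background_noise_sd: float = 2.0,
    edge_intensity: float = 100.0,
    peak_intensity: float = 255.0,
    pad_px: int = 24,
) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a synthetic pellet micrograph plus its ground truth.

    Pellets are packed on shelves with padding; the requested fractions of
    touching pairs and border-clipped pellets are realised by pairing
    pellets at 95% of the sum of their radii and by shifting top/bottom-row
    pellets onto the image edge. Noise objects are speckles strictly
    smaller than the opening structuring element of the default
    segmentation filter.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng(seed)
    d = np.asarray(diameters_um, dtype=float)
    n = d.size
    radii = d / (2.0 * pixel_size)

    # --- group pellets into singles and touching pairs
    order = rng.permutation(n)
    n_pairs = int(round(touching_fraction * n / 2.0))
    pairs = [(int(order[2 * i]), int(order[2 * i + 1])) for i in range(n_pairs)]
    singles = [int(i) for i in order[2 * n_pairs:]]

    # --- shelf packing: each group gets a (w, h) box
    groups: list[tuple[str, tuple[int, ...]]] = [("pair", p) for p in pairs]
    groups += [("single", (i,)) for i in singles]
    boxes = []
    for kind, members in groups:
        if kind == "single":
            r = radii[members[0]]
            boxes.append((2 * r + pad_px, 2 * r + pad_px))
        else:
            r1, r2 = radii[members[0]], radii[members[1]]
            sep = 0.95 * (r1 + r2)
            boxes.append((sep + r1 + r2 + pad_px, 2 * max(r1, r2) + pad_px))
    total_area = sum(w * h for w, h in boxes) if boxes else pad_px**2
    target_w = max(int(math.ceil(math.sqrt(total_area) * 1.35)),
                   int(math.ceil(max((w for w, _ in boxes), default=0))) + 2 * pad_px)

    placements: list[tuple[int, float, float]] = []  # pellet idx, cy, cx
    border_idx: list[int] = []
    x = float(pad_px)
    y = float(pad_px)
    row_h = 0.0
    rows: list[list[int]] = [[]]  # pellet indices per shelf row
    for (kind, members), (w, h) in zip(groups, boxes):
        if x + w > target_w and x > pad_px:
            y += row_h
            x = float(pad_px)
            row_h = 0.0
            rows.append([])
        cy = y + h / 2.0
        if kind == "single":
            i = members[0]
            placements.append((i, cy, x + w / 2.0))
            rows[-1].append(i)
        else:
            i, j = members
            r1, r2 = radii[i], radii[j]
            sep = 0.95 * (r1 + r2)
            cx1 = x + pad_px / 2.0 + r1
            placements.append((i, cy, cx1))
            placements.append((j, cy, cx1 + sep))
            rows[-1].extend([i, j])
        x += w
        row_h = max(row_h, h)
    height = int(math.ceil(y + row_h + pad_px))
    width = int(target_w)

    if image_size is not None:
        req_h, req_w = image_size
        if n and (2 * radii.max() >= min(req_h, req_w) or height > req_h or width > req_w):
            raise ValueError("pellet(s) do not fit in the requested frame")
        height, width = int(req_h), int(req_w)
    elif n == 0:
        height = width = 256

    # --- border-clipped pellets: shift first-row pellets to the top edge,
    #     last-row pellets to the bottom edge
    pos = {i: [cy, cx] for i, cy, cx in placements}
    n_border = int(round(border_fraction * n))
    for i in rows[0][:n_border]:
        pos[i][0] = 0.45 * radii[i]
        border_idx.append(i)
    remaining = n_border - len(border_idx)
    if remaining > 0 and len(rows) > 1:
        for i in rows[-1][:remaining]:
            pos[i][0] = height - 0.45 * radii[i]
            border_idx.append(i)

    # --- render
    red = np.zeros((height, width), dtype=float)
    render_order = [i for i, _, _ in placements]
    for i in render_order:
        cy, cx = pos[i]
        _draw_pellet(red, cy, cx, radii[i], rng, roughness,
                     edge_intensity, peak_intensity)

    noise_count, noise_max = noise_spec
    for _ in range(int(noise_count)):
        size = int(rng.integers(1, max(int(noise_max), 1) + 1))
        for _attempt in range(50):
            ry = int(rng.integers(0, max(height - size, 1)))
            rx = int(rng.integers(0, max(width - size, 1)))
            if red[ry:ry + size, rx:rx + size].max(initial=0.0) < edge_intensity / 2:
                red[ry:ry + size, rx:rx + size] = float(rng.uniform(120, 200))
                break

    signal = red.copy()
    red = red + background_level + background_noise_sd * rng.standard_normal(red.shape)
    rgb = np.empty((height, width, 3), dtype=np.uint8)
    rgb[..., 0] = np.clip(red, 0, 255).astype(np.uint8)
    rgb[..., 1] = np.clip(0.30 * signal + 0.6 * background_level, 0, 255).astype(np.uint8)
    rgb[..., 2] = np.clip(0.25 * signal + 0.5 * background_level, 0, 255).astype(np.uint8)

    centroids = np.array([pos[i] for i in render_order], dtype=float).reshape(-1, 2)
    truth = SceneGroundTruth(
        true_diameters=d[render_order] if n else np.empty(0),
        true_centroids=centroids,
        border_flags=np.array([i in border_idx for i in render_order], dtype=bool),
        noise_object_count=int(noise_count),
    )
    return rgb, truth


# ---------------------------------------------------------------------------
# 3D pellet volumes


def _unit(v: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def _grow_hyphae(
    rng: np.random.Generator,
    graph: nx.Graph,
    core_centre: np.ndarray,
    core_radius: float,
    segment_length: float,
    branch_probability: float,
    radial_bias: float,
    n_steps: int,
    tips_per_core: int,
    direction_noise: float,
    max_tips: int,
    other_cores: np.ndarray | None = None,
) -> None:
    """Off-lattice segment growth from one spore core into ``graph``.

    If ``other_cores`` is given, a tip stops once it would step into
    another core's territory (closer to that core than to its own):
    multi-core pellets show little or no hyphal growth towards their other
    spore cores.
    """

    def new_node(pos: np.ndarray) -> int:
        nid = graph.number_of_nodes()
        graph.add_node(nid, pos=pos.copy())
        return nid

    tips: list[tuple[int, np.ndarray]] = []  # (node id, direction)
    for _ in range(tips_per_core):
        direction = _unit(rng.standard_normal(3))
        start = core_centre + core_radius * direction
        tips.append((new_node(start), direction))
    for _ in range(n_steps):
        next_tips: list[tuple[int, np.ndarray]] = []
        for node, direction in tips:
            pos = graph.nodes[node]["pos"]
            radial = _unit(pos - core_centre)
            direction = _unit(
                direction
                + radial_bias * radial
                + direction_noise * rng.standard_normal(3)
            )
            new_pos = pos + segment_length * direction
            if other_cores is not None and len(other_cores):
                d_own = np.linalg.norm(new_pos - core_centre)
                d_other = np.linalg.norm(other_cores - new_pos, axis=1).min()
                if d_other < d_own:
                    continue  # tip terminates at the inter-core boundary
            nid = new_node(new_pos)
            graph.add_edge(node, nid, length=float(segment_length))
            next_tips.append((nid, direction))
            if len(next_tips) < max_tips and rng.uniform() < branch_probability:
                branch_dir = _unit(direction + 0.9 * rng.standard_normal(3))
                next_tips.append((nid, branch_dir))
        tips = next_tips


def _core_centres(rng: np.random.Generator, n_cores: int, separation: float) -> np.ndarray:
    if n_cores == 1:
        return np.zeros((1, 3))
    # equally spaced on a circle in a random plane, adjacent distance = separation
    rho = separation / (2.0 * math.sin(math.pi / n_cores))
    basis = np.linalg.qr(rng.standard_normal((3, 3)))[0][:, :2]
    angles = 2 * np.pi * np.arange(n_cores) / n_cores
    pts = np.stack([rho * np.cos(angles), rho * np.sin(angles)], axis=1)
    return pts @ basis.T


def _sample_spores(
    rng: np.random.Generator, centre: np.ndarray, radius: float,
    n_target: int, voxel_size: float,
) -> np.ndarray:
    """Sample spore points until they occupy >= n_target distinct voxels."""
    pts = np.empty((0, 3))
    while True:
        extra = centre + rng.standard_normal((max(n_target, 50), 3)) * (radius / 2.0)
        dist = np.linalg.norm(extra - centre, axis=1)
        pts = np.vstack([pts, extra[dist <= radius]])
        vox = np.unique(np.floor(pts / voxel_size).astype(int), axis=0)
        if vox.shape[0] >= n_target:
            return pts


def gen_pellet_volume(
    n_cores: int = 1,
    core_separation: float = 150.0,
    growth: tuple[float, float, float] = (5.0, 0.08, 0.6),
    talc_fraction: float = 0.0,
    voxel_size: float = 2.0,
    seed: int = 0,
    *,
    core_radius_um: float = 12.0,
    spores_per_core: int = 150,
    tips_per_core: int = 12,
    n_steps: int = 40,
    direction_noise: float = 0.5,
    max_tips_per_core: int = 2000,
    class_label: str | None = None,
    core_centres: np.ndarray | None = None,
    growth_inhibition: bool = True,
) -> tuple[Volume3D, VolumeGroundTruth]:
    """Generate a 3D pellet: spore cores + radially grown branched hyphae.

    ``growth`` is (segment length µm, branch probability per tip per step,
    radial bias). The geometric skeleton graph is recorded before
    voxelization and its exact edge/degree statistics are stored as ground
    truth. Talc voxels are sprinkled into void voxels inside the occupied
    sphere so that they make up ``talc_fraction`` of the solid volume.
    """
    if n_cores < 1:
        raise ValueError("n_cores must be >= 1")
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    if not 0 <= talc_fraction < 1:
        raise ValueError("talc_fraction must be in [0, 1)")
    if n_cores > 1 and core_separation <= 2.5 * core_radius_um:
        raise ValueError(
            "core_separation too small to keep spore cores disjoint "
            f"(need > {2.5 * core_radius_um} µm)"
        )
    segment_length, branch_probability, radial_bias = growth
    rng = np.random.default_rng(seed)

    centres = core_centres if core_centres is not None else _core_centres(rng, n_cores, core_separation)
    graph = nx.Graph()
    spore_pts = []
    for k, c in enumerate(centres):
        spore_pts.append(_sample_spores(rng, c, core_radius_um, spores_per_core, voxel_size))
        if n_steps > 0 and tips_per_core > 0:
            others = (
                np.delete(centres, k, axis=0)
                if growth_inhibition and len(centres) > 1
                else None
            )
            _grow_hyphae(
                rng, graph, c, core_radius_um, segment_length,
                branch_probability, radial_bias, n_steps, tips_per_core,
                direction_noise, max_tips_per_core, other_cores=others,
            )
    spore_pts = np.vstack(spore_pts) if spore_pts else np.empty((0, 3))

    # ground-truth skeleton metrics from the geometric graph
    total_len = sum(d["length"] for _, _, d in graph.edges(data=True))
    degrees = dict(graph.degree())
    n_tips = sum(1 for v in degrees.values() if v == 1) if graph.number_of_edges() else 0
    n_branch = sum(1 for v in degrees.values() if v >= 3)

    # --- voxelize: sample hyphal edges densely, then bin everything
    edge_pts = []
    for u, v in graph.edges():
        pu = graph.nodes[u]["pos"]
        pv = graph.nodes[v]["pos"]
        n_samp = max(int(np.ceil(np.linalg.norm(pv - pu) / (voxel_size / 2.0))), 1)
        t = np.linspace(0.0, 1.0, n_samp + 1)[:, None]
        edge_pts.append(pu + t * (pv - pu))
    hyphae_pts = np.vstack(edge_pts) if edge_pts else np.empty((0, 3))

    all_pts = np.vstack([p for p in (spore_pts, hyphae_pts, centres) if p.size])
    margin = core_radius_um + 2 * voxel_size
    origin = np.floor((all_pts.min(axis=0) - margin) / voxel_size) * voxel_size
    extent = all_pts.max(axis=0) + margin - origin
    shape = tuple(int(math.ceil(e / voxel_size)) + 1 for e in extent)
    labels = np.zeros(shape, dtype=np.uint8)

    def to_idx(pts: np.ndarray) -> tuple[np.ndarray, ...]:
        idx = np.floor((pts - origin) / voxel_size).astype(int)
        idx = np.clip(idx, 0, np.array(shape) - 1)
        return tuple(idx.T)

    if hyphae_pts.size:
        labels[to_idx(hyphae_pts)] = HYPHAE
    if spore_pts.size:
        labels[to_idx(spore_pts)] = SPORE

    if talc_fraction > 0:
        n_hyphae = int(np.sum(labels == HYPHAE))
        n_talc = int(round(talc_fraction / (1.0 - talc_fraction) * max(n_hyphae, 1)))
        centre_um = all_pts.mean(axis=0)
        r_occ = np.linalg.norm(all_pts - centre_um, axis=1).max()
        placed = 0
        while placed < n_talc:
            cand = centre_um + rng.uniform(-r_occ, r_occ, size=(4 * n_talc + 8, 3))
            cand = cand[np.linalg.norm(cand - centre_um, axis=1) <= r_occ]
            ii = to_idx(cand)
            for a, b, c in zip(*ii):
                if labels[a, b, c] == 0:
                    labels[a, b, c] = TALC
                    placed += 1
                    if placed >= n_talc:
                        break

    if class_label is None:
        class_label = "I" if n_cores == 1 else "II"
    truth = VolumeGroundTruth(
        n_cores=n_cores,
        core_centroids=centres - origin,
        skeleton_length_total=float(total_len),
        n_tips=int(n_tips),
        n_branch_points=int(n_branch),
        class_label=class_label,
        skeleton_graph=graph,
    )
    return Volume3D(labels=labels, voxel_size=voxel_size), truth


def gen_fused_pellet_volume(
    seed: int = 0,
    fusion_separation: float | None = None,
    growth: tuple[float, float, float] = (5.0, 0.08, 0.6),
    voxel_size: float = 2.0,
    **kwargs,
) -> tuple[Volume3D, VolumeGroundTruth]:
    """Two mature single-core pellets fused through their outer hyphae.

    The two cores are placed roughly 1.45 pellet radii apart so only the
    outer hyphal shells entangle, producing the Class III morphology in
    which each spore core carries its own full hyphal envelope.
    """
    segment_length, _, _ = growth
    n_steps = kwargs.get("n_steps", 40)
    core_radius = kwargs.get("core_radius_um", 12.0)
    nominal_radius = core_radius + 0.8 * segment_length * n_steps
    if fusion_separation is None:
        fusion_separation = 1.45 * nominal_radius
    centres = np.array([[0.0, 0.0, 0.0], [fusion_separation, 0.0, 0.0]])
    vol, truth = gen_pellet_volume(
        n_cores=2,
        core_separation=fusion_separation,
        growth=growth,
        voxel_size=voxel_size,
        seed=seed,
        class_label="III",
        core_centres=centres,
        growth_inhibition=False,  # each pellet matured before fusing
        **kwargs,
    )
    return vol, truth


# ---------------------------------------------------------------------------
# regression datasets


def gen_regression_dataset(
    conditions=DEFAULT_CONDITION_GRID,
    replicates: int = 3,
    coefficients: tuple[float, float, float] = PREDICTION_COEFFICIENTS,
    noise_sd_ln: float = 0.1,
    seed: int = 0,
    *,
    spore_coefficient: float = 0.0,
    baffle_coefficient: float = 0.0,
    n_pellets: int = 100,
) -> pd.DataFrame:
    """Replicate median diameters from the ln-linear model plus noise.

    ln(median ED) = b0 + bA·ln(A) + bT·T (+ optional spore/baffle terms)
    + Normal(0, noise_sd_ln). Returns one row per condition × replicate in
    the replicate-table schema consumed by :mod:`pelletmorph.regress`.
    """
    b0, b_a, b_t = coefficients
    rng = np.random.default_rng(seed)
    rows = []
    ln_s_ref = math.log(SPORE_LEVELS[-1])
    for spore, agitation, talc, baffled in conditions:
        if agitation <= 0:
            raise ValueError("agitation must be positive")
        if talc < 0:
            raise ValueError("talc must be >= 0")
        for rep in range(replicates):
            ln_pd = (
                b0
                + b_a * math.log(agitation)
                + b_t * talc
                + spore_coefficient * (math.log(spore) - ln_s_ref)
                + baffle_coefficient * float(baffled)
            )
            if noise_sd_ln > 0:
                ln_pd += noise_sd_ln * rng.standard_normal()
            rows.append(
                {
                    "spore_conc": float(spore),
                    "agitation_rpm": float(agitation),
                    "talc_g_per_l": float(talc),
                    "baffled": bool(baffled),
                    "replicate_id": f"r{rep + 1}",
                    "median_ed_um": float(math.exp(ln_pd)),
                    "n_pellets": int(n_pellets),
                    "modality": "unimodal",
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers (images as PNG/TIFF, volumes as TIFF stacks, ground truth sidecars)


def write_scene(
    rgb: np.ndarray, truth: SceneGroundTruth, path: str | Path, params: dict | None = None
) -> None:
    """Write a micrograph plus CSV/JSON ground-truth sidecars."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, rgb)
    df = pd.DataFrame(
        {
            "true_diameter_um": truth.true_diameters,
            "centroid_r": truth.true_centroids[:, 0] if truth.true_centroids.size else [],
            "centroid_c": truth.true_centroids[:, 1] if truth.true_centroids.size else [],
            "touches_border": truth.border_flags,
        }
    )
    df.to_csv(path.with_suffix(".truth.csv"), index=False)
    sidecar = {"noise_object_count": truth.noise_object_count}
    if params:
        sidecar["params"] = params
    path.with_suffix(".truth.json").write_text(json.dumps(sidecar, default=str))
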