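"""Synthetic sections, score distributions and alignment fixtures.

Every generator is a pure function of its seed so fixtures are reproducible.
The synthetic section emulates an imaging-based spatial transcriptomics
experiment at desk scale: cells are 3D Gaussian transcript blobs with
division-specific, mutually exclusive marker blocks (so incongruent-gene
logic is exercisable), extracellular noise is sprinkled uniformly, blank
codewords are added at a configurable rate, doublets are planted as cell
pairs closer than 5 μm, and low-quality cells are planted with few genes, few
transcripts or elevated blank fractions. It does not attempt to emulate
instrument optics, codebook decoding or real tissue morphology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import make_spot_table
from .density import VolumeImage
from .registration import AnnotationVolume

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_section",
    "generate_mapping_scores",
    "generate_alignment_fixture",
]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic section."""

    n_cells: int = 100
    n_genes: int = 24
    n_divisions: int = 3
    cell_radius_um: Tuple[float, float] = (6.0, 1.0)  # mean, sd
    z_planes: int = 3
    z_spacing_um: float = 1.5
    transcripts_per_cell: float = 200.0
    noise_rate_per_um2: float = 0.002
    # typical blank-codeword detection is a fraction of a percent of spots,
    # far below the 2% per-cell QC line
    blank_rate: float = 0.002
    n_blank_codes: int = 5
    doublet_rate: float = 0.0
    low_quality_frac: float = 0.0
    extent_um: Tuple[float, float] = (400.0, 400.0)
    dapi_voxel_um: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.blank_rate, self.doublet_rate, self.low_quality_frac):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class GroundTruth:
    cells: pd.DataFrame  # center x/y/z, radius, division, flags
    doublet_pairs: List[Tuple[str, str]] = field(default_factory=list)
    low_quality: List[str] = field(default_factory=list)
    division_markers: Dict[str, List[str]] = field(default_factory=dict)


def _place_centers(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson-disc-ish placement with minimum separation 2.5× mean radius."""
    min_sep = 2.5 * cfg.cell_radius_um[0]
    margin = 2.0 * cfg.cell_radius_um[0]
    w, h = cfg.extent_um
    centers: List[np.ndarray] = []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > 200 * cfg.n_cells:
            raise ValueError("section extent too small for requested n_cells")
        p = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(p - c)) >= min_sep for c in centers):
            centers.append(p)
    return np.asarray(centers)


def generate_section(cfg: SynthConfig):
    """Generate (spot table, DAPI-like volume, ground truth) for one section.

    The spot table carries a ``true_cell`` column (None for extracellular
    noise) so segmentation and filtering stages can be scored against the
    plant.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    blocks = np.array_split(np.arange(cfg.n_genes), cfg.n_divisions)
    divisions = [f"D{i}" for i in range(cfg.n_divisions)]
    markers = {d: [genes[g] for g in blocks[i]] for i, d in enumerate(divisions)}

    centers = _place_centers(cfg, rng)
    radii = np.clip(rng.normal(*cfg.cell_radius_um, size=cfg.n_cells), 2.0, None)
    division_of = rng.integers(0, cfg.n_divisions, size=cfg.n_cells)
    cell_ids = [f"cell{i:04d}" for i in range(cfg.n_cells)]

    n_doublets = int(round(cfg.doublet_rate * cfg.n_cells / 2))
    doublet_pairs: List[Tuple[str, str]] = []
    partner_centers = centers.copy()
    extra = []
    for d in range(n_doublets):
        host = d  # first cells host a planted partner
        angle = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(2.0, 4.5)  # < 5 μm apart
        pc = centers[host] + dist * np.array([np.cos(angle), np.sin(angle)])
        extra.append((host, pc))
        doublet_pairs.append((cell_ids[host], f"cell{cfg.n_cells + d:04d}"))

    n_lq = int(round(cfg.low_quality_frac * cfg.n_cells))
    # plant low-quality cells at the end of the id range (non-doublet hosts)
    lq_ids = cell_ids[cfg.n_cells - n_lq :] if n_lq else []
    lq_kind = {cid: ("few_tx" if i % 2 == 0 else "blanky") for i, cid in enumerate(lq_ids)}

    z_max = cfg.z_planes * cfg.z_spacing_um
    rows_gene, rows_x, rows_y, rows_z, rows_cell = [], [], [], [], []

    def emit_cell(cid, center, radius, div_idx, kind: Optional[str]):
        if kind == "few_tx":
            n_tx = int(rng.integers(8, 20))  # below the 30-transcript floor
            gene_pool = rng.choice(blocks[div_idx], size=min(4, len(blocks[div_idx])), replace=False)
        else:
            n_tx = rng.poisson(cfg.transcripts_per_cell)
            gene_pool = blocks[div_idx]
        probs = rng.dirichlet(np.ones(len(gene_pool)) * 2.0)
        gidx = rng.choice(gene_pool, size=n_tx, p=probs)
        pos = rng.normal(loc=center, scale=radius / 2.0, size=(n_tx, 2))
        # transcripts are detected on discrete imaging planes
        zs = (rng.integers(0, cfg.z_planes, size=n_tx) + 0.5) * cfg.z_spacing_um
        blank_p = 0.08 if kind == "blanky" else cfg.blank_rate
        is_blank = rng.uniform(size=n_tx) < blank_p
        for t in range(n_tx):
            g = f"Blank-{rng.integers(1, cfg.n_blank_codes + 1)}" if is_blank[t] else genes[gidx[t]]
            rows_gene.append(g)
            rows_x.append(pos[t, 0]), rows_y.append(pos[t, 1]), rows_z.append(zs[t])
            rows_cell.append(cid)

    for i, cid in enumerate(cell_ids):
        emit_cell(cid, centers[i], radii[i], division_of[i], lq_kind.get(cid))
    partner_rows = []
    for d, (host, pc) in enumerate(extra):
        pid = f"cell{cfg.n_cells + d:04d}"
        div = (division_of[host] + 1) % cfg.n_divisions  # different type -> mixed profile
        emit_cell(pid, pc, radii[host], div, None)
        partner_rows.append((pid, pc, radii[host], div))

    # extracellular noise
    area = cfg.extent_um[0] * cfg.extent_um[1]
    n_noise = rng.poisson(cfg.noise_rate_per_um2 * area)
    for _ in range(n_noise):
        rows_gene.append(genes[rng.integers(0, cfg.n_genes)])
        rows_x.append(rng.uniform(0, cfg.extent_um[0]))
        rows_y.append(rng.uniform(0, cfg.extent_um[1]))
        rows_z.append((rng.integers(0, cfg.z_planes) + 0.5) * cfg.z_spacing_um)
        rows_cell.append(None)

    spots = make_spot_table(rows_gene, rows_x, rows_y, rows_z, section_id=f"synth-{cfg.seed}")
    spots["true_cell"] = rows_cell

    truth_cells = pd.DataFrame(
        {
            "cell_id": cell_ids + [p[0] for p in partner_rows],
            "x": list(centers[:, 0]) + [p[1][0] for p in partner_rows],
            "y": list(centers[:, 1]) + [p[1][1] for p in partner_rows],
            "radius": list(radii) + [p[2] for p in partner_rows],
            "division": [divisions[d] for d in division_of] + [divisions[p[3]] for p in partner_rows],
        }
    ).set_index("cell_id")
    truth_cells["is_doublet_partner"] = [False] * cfg.n_cells + [True] * len(partner_rows)
    truth_cells["low_quality"] = [cid in lq_kind for cid in truth_cells.index]

    dapi = _render_dapi(cfg, truth_cells)
    truth = GroundTruth(
        cells=truth_cells,
        doublet_pairs=doublet_pairs,
        low_quality=list(lq_ids),
        division_markers=markers,
    )
    return spots, dapi, truth


def _render_dapi(cfg: SynthConfig, cells: pd.DataFrame) -> VolumeImage:
    v = cfg.dapi_voxel_um
    nx = int(np.ceil(cfg.extent_um[0] / v))
    ny = int(np.ceil(cfg.extent_um[1] / v))
    nz = cfg.z_planes
    img = np.zeros((nz, ny, nx))
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _, row in cells.iterrows():
        cx, cy, r = row["x"] / v, row["y"] / v, max(row["radius"] / v, 1.0)
        blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * (0.6 * r) ** 2)))
        img += blob[None, :, :]
    return VolumeImage(img, origin=(0.0, 0.0, 0.0), voxel_size=(v, v, cfg.z_spacing_um))


def generate_mapping_scores(
    n_supertypes: int = 5,
    n_cells_per: int = 300,
    contaminant_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell (supertype, score) table with an optional planted low mode.

    Each supertype's main mode is Normal(μ, 0.03²) with μ drawn in
    [0.45, 0.8]; contaminants form a mode 0.25 lower. The ground-truth
    contaminant flag is returned alongside.
    """
    if not 0 <= contaminant_frac < 0.5:
        raise ValueError("contaminant_frac must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_supertypes):
        mu = rng.uniform(0.45, 0.8)
        n_cont = int(round(contaminant_frac * n_cells_per))
        n_main = n_cells_per - n_cont
        for v in rng.normal(mu, 0.03, size=n_main):
            rows.append((f"ST{s:03d}", float(v), False))
        for v in rng.normal(mu - 0.25, 0.03, size=n_cont):
            rows.append((f"ST{s:03d}", float(v), True))
    df = pd.DataFrame(rows, columns=["supertype", "avg_correlation", "is_contaminant"])
    df.index = [f"c{i:05d}" for i in range(len(df))]
    return df


def generate_alignment_fixture(
    n_sections: int = 2,
    n_landmarks: int = 9,
    warp_amplitude: float = 0.0,
    seed: int = 0,
    width: float = 400.0,
    height: float = 300.0,
    n_cells: int = 50,
    out_dir=None,
):
    """Alignment fixture with an exactly recoverable (affine) landmark warp.

    The planted warp is affine (shear/scale perturbation of strength
    ``warp_amplitude``), so barycentric interpolation over the landmark
    triangulation reproduces it exactly and the analytic truth coordinates
    are valid at machine precision. Returns (anchoring dict, landmark dict,
    AnnotationVolume, truth frame); when ``out_dir`` is given the two JSON
    files are also written there.
    """
    if n_landmarks < 3:
        raise ValueError("need at least 3 landmarks")
    rng = np.random.default_rng(seed)
    side = max(int(np.ceil(np.sqrt(n_landmarks))), 2)
    gx = np.linspace(0, width, side)
    gy = np.linspace(0, height, side)
    grid = np.array([(x, y) for y in gy for x in gx])[:n_landmarks]
    if len(grid) < n_landmarks:
        grid = np.array([(x, y) for y in gy for x in gx])

    A = np.eye(2) + warp_amplitude * np.array([[0.0, 0.3], [0.2, 0.0]])
    b = warp_amplitude * np.array([5.0, -3.0])

    anchors, lm_slices, truth_rows = [], [], []
    for s in range(n_sections):
        name = f"section_{s:02d}.png"
        o = np.array([0.0, 25.0 * (s + 1), 0.0])
        u = np.array([float(width), 0.0, 0.0])
        v = np.array([0.0, 0.0, float(height)])
        anchors.append(
            {
                "filename": name,
                "nr": s,
                "width": float(width),
                "height": float(height),
                "anchoring": [*o, *u, *v],
            }
        )
        target = grid @ A.T + b
        lm_slices.append(
            {
                "filename": name,
                "width": float(width),
                "height": float(height),
                "markers": [[float(sx), float(sy), float(tx), float(ty)]
                            for (sx, sy), (tx, ty) in zip(grid, target)],
            }
        )
        pts = rng.uniform([0.1 * width, 0.1 * height], [0.9 * width, 0.9 * height], size=(n_cells, 2))
        warped = pts @ A.T + b
        xn, yn = warped[:, 0] / width, warped[:, 1] / height
        ccf = o[None, :] + xn[:, None] * u[None, :] + yn[:, None] * v[None, :]
        for i in range(n_cells):
            truth_rows.append(
                {
                    "section": name,
                    "x": pts[i, 0],
                    "y": pts[i, 1],
                    "warped_x": warped[i, 0],
                    "warped_y": warped[i, 1],
                    "ccf_x": ccf[i, 0],
                    "ccf_y": ccf[i, 1],
                    "ccf_z": ccf[i, 2],
                }
            )

    anchoring = {"slices": anchors}
    landmarks = {"slices": lm_slices}
    # small labeled volume: octant labels 1..8 over a 20-voxel cube (25 μm voxels)
    nvox = 20
    lab = np.zeros((nvox, nvox, nvox), dtype=np.int32)
    half = nvox // 2
    code = 1
    for ox in (0, half):
        for oy in (0, half):
            for oz in (0, half):
                lab[ox : ox + half, oy : oy + half, oz : oz + half] = code
                code += 1
    vol = AnnotationVolume(labels=lab, voxel_size_um=25.0,
                           label_names={i: f"region_{i}" for i in range(1, 9)})
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "anchoring.json"), "w") as fh:
            json.dump(anchoring, fh, indent=1)
        with open(os.path.join(out_dir, "landmarks.json"), "w") as fh:
            json.dump(landmarks, fh, indent=1)
    return anchoring, landmarks, vol, truth
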