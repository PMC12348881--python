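"""Synthetic 3D co-culture data with known ground truth.

Emulates the imaging and omics inputs of a scaffold-based leukemia-stroma
co-culture so every downstream stage can be exercised against planted truth:

* multi-channel z-stacks (nuclear stain, CD19, CD3, CD90/phalloidin, cleaved
  caspase-3) containing three nucleated populations — malignant B cells
  (CD19-high), T cells (CD3-high) and marker-negative bystander nuclei
  (stromal and other mononuclear cells picked up by any nuclear stain);
* instance label volumes and a per-cell ground-truth table;
* a stromal filament network rendered in the CD90 channel (not a cell);
* toy differential-expression and protein-interaction tables with planted
  cross-compartment edges and decoys.

Nuclei are rendered as Gaussian blobs whose full width at half maximum equals
the nominal nucleus diameter (default 6.2 voxels). A configurable fraction of
T cells is placed directly adjacent (surface gap <= 1 voxel) to a B cell, and
a configurable fraction of B cells carries caspase-3 signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .stack import ImageStack3D, write_stack

__all__ = [
    "SimParams",
    "GroundTruth",
    "ToyOmicsBundle",
    "PackingError",
    "generate_coculture_stack",
    "generate_scaffold_volume",
    "generate_omics_bundle",
    "write_ground_truth",
    "read_ground_truth",
    "write_omics_bundle",
    "read_omics_bundle",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian profile
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

CHANNELS = ("nuc", "CD19", "CD3", "CD90", "CASP3")


class PackingError(ValueError):
    """Requested cell count does not fit the volume at the given diameter."""


@dataclass(frozen=True)
class SimParams:
    """Study conditions for one synthetic co-culture stack.

    The default composition keeps B cells at 60% and T cells at 5% of all
    nucleated masks (remainder marker-negative), the skewed composition the
    asymmetric 40th/95th percentile marker thresholds are designed for.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    n_b_cells: int = 120
    n_t_cells: int = 10
    n_other_cells: int = 70
    nucleus_diameter_px: float = 6.2
    frac_coloc: float = 0.6
    frac_apoptotic_b: float = 0.1
    marker_snr: float = 8.0
    background: float = 100.0
    bleed_through: float = 0.05
    noise_model: str = "poisson"  # {poisson, gaussian, none}
    noise_scale: float = 10.0  # gaussian sigma; ignored by poisson/none
    filament_density: float = 1.0
    filament_radius: int = 4
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"shape must be three axes >= 1, got {self.shape}")
        for name in ("n_b_cells", "n_t_cells", "n_other_cells"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_coloc", "frac_apoptotic_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.bleed_through < 1.0:
            raise ValueError("bleed_through must be in [0, 1)")
        if self.nucleus_diameter_px <= 0:
            raise ValueError("nucleus_diameter_px must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.marker_snr <= 0 or self.background < 0:
            raise ValueError("marker_snr must be > 0 and background >= 0")


@dataclass
class GroundTruth:
    """Planted truth for one stack: per-cell table plus scaffold mask.

    ``cells`` columns: id, z, y, x (centroid, voxels), type in {B, T, other},
    apoptotic (bool), coloc_partner_id (nullable int). Co-localization
    partners are mutual; apoptosis occurs only on B cells.
    """

    cells: pd.DataFrame
    scaffold_mask: np.ndarray | None = None

    def count(self, cell_type: str) -> int:
        return int((self.cells["type"] == cell_type).sum())

    @property
    def n_coloc_pairs(self) -> int:
        return int(self.cells["coloc_partner_id"].notna().sum()) // 2


@dataclass
class ToyOmicsBundle:
    """Toy DE / PPI tables with planted crosstalk edges and decoys."""

    b_de_table: pd.DataFrame       # gene, direction, lfc, adj_p
    cluster_de_table: pd.DataFrame  # gene, cluster, pct_expressing, lfc, adj_p
    ppi_table: pd.DataFrame        # gene_a, gene_b, confidence
    planted_interactions: pd.DataFrame  # gene_a, gene_b, class


# ---------------------------------------------------------------------------
# cell placement

def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _sphere_voxels(center: np.ndarray, radius: float) -> np.ndarray:
    """Integer voxel coordinates with centers within `radius` of `center`."""
    lo = np.floor(center - radius).astype(int)
    hi = np.ceil(center + radius).astype(int)
    grids = np.mgrid[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
    pts = grids.reshape(3, -1).T
    d2 = ((pts - center) ** 2).sum(axis=1)
    return pts[d2 <= radius * radius]

def _min_chebyshev(a: np.ndarray, b: np.ndarray) -> int:
    diff = np.abs(a[:, None, :] - b[None, :, :]).max(axis=2)
    return int(diff.min())


def _place_cells(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    d = params.nucleus_diameter_px
    radius = d / 2.0
    margin = radius + 1.5
    shape = np.asarray(params.shape, dtype=float)
    lo, hi = margin, shape - 1 - margin
    if np.any(hi < lo):
        usable = 0
    else:
        usable = float(np.prod(hi - lo + 1))

    n_total = params.n_b_cells + params.n_t_cells + params.n_other_cells
    if n_total == 0:
        return pd.DataFrame(
            columns=["id", "z", "y", "x", "type", "apoptotic", "coloc_partner_id"]
        )
    # quick feasibility estimate: exclusion balls of radius 0.6 d
    cap = max(0, int(usable / max(1.0, (4.0 / 3.0) * math.pi * (0.6 * d) ** 3 * 0.55)))
    if usable == 0:
        raise PackingError(
            f"volume {params.shape} cannot host any nucleus of diameter {d}; "
            "achievable maximum is 0 cells"
        )

    min_same = 1.2 * d
    min_bt = d + 5.0  # non-partner B-T pairs stay outside the adjacency radius
    n_coloc = round(params.frac_coloc * params.n_t_cells) if params.n_b_cells else 0

    placed: list[dict] = []
    coords = np.empty((0, 3))

    def _dists(c: np.ndarray) -> np.ndarray:
        if coords.shape[0] == 0:
            return np.empty(0)
        return np.sqrt(((coords - c) ** 2).sum(axis=1))

    def _try_place(cell_type: str, extra_checks=None, max_attempts: int = 5000):
        nonlocal coords
        for _ in range(max_attempts):
            c = rng.uniform(lo, hi)
            dist = _dists(c)
            if dist.size and dist.min() < min_same:
                continue
            if cell_type == "T":
                b_mask = np.array([p["type"] == "B" for p in placed], dtype=bool)
                if b_mask.any() and dist[b_mask].min() < min_bt:
                    continue
            if cell_type == "B" and placed:
                t_mask = np.array([p["type"] == "T" for p in placed], dtype=bool)
                if t_mask.any() and dist[t_mask].min() < min_bt:
                    continue
            return c
        raise PackingError(
            f"could not place cell {len(placed) + 1} of {n_total} "
            f"(type {cell_type}) after {max_attempts} attempts; achievable "
            f"maximum for this volume/diameter is about {max(len(placed), cap)} cells"
        )

    def _add(cell_type: str, c: np.ndarray, partner: int | None = None):
        nonlocal coords
        placed.append(
            {
                "id": len(placed) + 1,
                "z": float(c[0]),
                "y": float(c[1]),
                "x": float(c[2]),
                "type": cell_type,
                "apoptotic": False,
                "coloc_partner_id": partner,
            }
        )
        coords = np.vstack([coords, c[None, :]])

    for _ in range(params.n_b_cells):
        _add("B", _try_place("B"))
    for _ in range(params.n_other_cells):
        _add("other", _try_place("other"))

    # adjacent T cells: center distance = diameter + 1, nudged until the
    # rasterized regions sit within a 1-voxel surface gap; a crowded partner
    # candidate with no admissible direction is skipped for the next one
    candidates = list(rng.permutation(params.n_b_cells) + 1) if n_coloc else []
    for _ in range(n_coloc):
        placement = None
        while candidates and placement is None:
            pid = int(candidates.pop(0))
            b_center = coords[pid - 1]
            for _ in range(500):
                u = _unit_vector(rng)
                c = b_center + (d + 1.0) * u
                if np.any(c < lo) or np.any(c > hi):
                    continue
                dist = _dists(c)
                others = np.ones(len(placed), dtype=bool)
                others[pid - 1] = False
                if dist[others].size and dist[others].min() < min_same:
                    continue
                b_mask = np.array([p["type"] == "B" for p in placed], dtype=bool)
                b_mask[pid - 1] = False
                if b_mask.any() and dist[b_mask].min() < min_bt:
                    continue
                # ensure voxelized adjacency (gap <= 1 voxel, Chebyshev)
                vox_b = _sphere_voxels(b_center, radius)
                dd = d + 1.0
                while dd >= d - 0.5:
                    c = b_center + dd * u
                    vox_t = _sphere_voxels(c, radius)
                    if _min_chebyshev(vox_b, vox_t) <= 2:
                        break
                    dd -= 0.25
                placement = (pid, c)
                break
        if placement is None:
            raise PackingError(
                f"could not place an adjacent T cell next to any remaining B cell; "
                f"achievable maximum for this volume/diameter is about "
                f"{max(len(placed), cap)} cells"
            )
        pid, c = placement
        _add("T", c, partner=pid)
        placed[pid - 1]["coloc_partner_id"] = len(placed)

    for _ in range(params.n_t_cells - n_coloc):
        _add("T", _try_place("T"))

    cells = pd.DataFrame(placed)
    cells["coloc_partner_id"] = cells["coloc_partner_id"].astype("Int64")

    if params.n_b_cells:
        n_apo = round(params.frac_apoptotic_b * params.n_b_cells)
        apo_ids = rng.choice(params.n_b_cells, size=n_apo, replace=False) + 1
        cells.loc[cells["id"].isin(apo_ids), "apoptotic"] = True
    return cells


# ---------------------------------------------------------------------------
# rendering

def _render_blob(volume: np.ndarray, center: np.ndarray, sigma: float, amp: float):
    ext = int(math.ceil(3.5 * sigma))
    lo = np.maximum(np.floor(center).astype(int) - ext, 0)
    hi = np.minimum(np.floor(center).astype(int) + ext + 1, volume.shape)
    if np.any(hi <= lo):
        return
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-d2 / (2 * sigma**2))


def _rasterize_labels(shape, cells: pd.DataFrame, radius: float) -> np.ndarray:
    """One unique positive id per cell; overlap resolved by nearest center."""
    labels = np.zeros(shape, dtype=np.uint16)
    claim = np.full(shape, np.inf, dtype=np.float64)
    for row in cells.itertuples():
        center = np.array([row.z, row.y, row.x])
        vox = _sphere_voxels(center, radius)
        keep = (
            (vox[:, 0] >= 0) & (vox[:, 0] < shape[0])
            & (vox[:, 1] >= 0) & (vox[:, 1] < shape[1])
            & (vox[:, 2] >= 0) & (vox[:, 2] < shape[2])
        )
        vox = vox[keep]
        d2 = ((vox - center) ** 2).sum(axis=1)
        idx = tuple(vox.T)
        better = d2 < claim[idx]
        idx_b = tuple(vox[better].T)
        labels[idx_b] = row.id
        claim[idx_b] = d2[better]
    return labels


def _filament_mask(shape, rng: np.random.Generator, density: float, radius: int) -> np.ndarray:
    """Connected random filament network as a binary volume (26-connected)."""
    from scipy import ndimage as ndi

    mask = np.zeros(shape, dtype=bool)
    if density <= 0:
        return mask
    span = min(shape)
    base = max(3, int(round(np.prod(shape) ** (1 / 3) / 6)))
    n_segments = max(1, int(round(density * base)))
    hi = np.asarray(shape, dtype=float) - 1.0
    nodes = [rng.uniform(0.25 * hi, 0.75 * hi)]
    skeleton = np.zeros(shape, dtype=bool)
    for _ in range(n_segments):
        anchor = nodes[rng.integers(len(nodes))]
        u = _unit_vector(rng)
        length = rng.uniform(0.3, 0.7) * span
        end = np.clip(anchor + length * u, 0.0, hi)
        nodes.append(end)
        n_steps = int(2 * math.ceil(np.linalg.norm(end - anchor))) + 2
        pts = np.rint(np.linspace(anchor, end, n_steps)).astype(int)
        skeleton[tuple(pts.T)] = True
    if radius > 0:
        # thicken by alternating 6- and 26-connected dilations: a fast
        # chamfer approximation of a euclidean ball of the given radius
        mask = skeleton
        face = ndi.generate_binary_structure(3, 1)
        full = ndi.generate_binary_structure(3, 3)
        for i in range(int(radius)):
            mask = ndi.binary_dilation(mask, structure=face if i % 2 else full)
    else:
        mask = skeleton
    return mask


def _apply_noise(volume: np.ndarray, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "poisson":
        volume = rng.poisson(np.clip(volume, 0, None)).astype(np.float64)
    elif params.noise_model == "gaussian":
        volume = volume + rng.normal(0.0, params.noise_scale, size=volume.shape)
    return np.clip(np.rint(volume), 0, 65535).astype(np.uint16)


def generate_coculture_stack(
    params: SimParams,
) -> tuple[ImageStack3D, np.ndarray, GroundTruth]:
    """Render one synthetic co-culture z-stack with labels and ground truth.

    Returns the stack (channels nuc/CD19/CD3/CD90/CASP3, uint16), the planted
    instance label volume, and the ground-truth table. Deterministic for a
    given parameter set including the seed.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    cells = _place_cells(params, rng)
    shape = tuple(int(s) for s in params.shape)
    radius = params.nucleus_diameter_px / 2.0
    sigma = params.nucleus_diameter_px / _FWHM
    amp = params.marker_snr * max(params.background, 1.0)

    signal = {name: np.zeros(shape, dtype=np.float64) for name in CHANNELS}
    for row in cells.itertuples():
        center = np.array([row.z, row.y, row.x])
        _render_blob(signal["nuc"], center, sigma, amp)
        if row.type == "B":
            _render_blob(signal["CD19"], center, sigma, amp)
            if row.apoptotic:
                _render_blob(signal["CASP3"], center, sigma, amp)
        elif row.type == "T":
            _render_blob(signal["CD3"], center, sigma, amp)

    scaffold = _filament_mask(shape, rng, params.filament_density, params.filament_radius)
    signal["CD90"][scaffold] += amp

    if params.bleed_through > 0:
        cd19, cd3 = signal["CD19"].copy(), signal["CD3"].copy()
        signal["CD19"] += params.bleed_through * cd3
        signal["CD3"] += params.bleed_through * cd19

    channels = {}
    for name in CHANNELS:
        channels[name] = _apply_noise(signal[name] + params.background, params, rng)

    labels = _rasterize_labels(shape, cells, radius)
    truth = GroundTruth(cells=cells, scaffold_mask=scaffold)
    return ImageStack3D(channels), labels, truth


def generate_scaffold_volume(params: SimParams) -> tuple[ImageStack3D, np.ndarray]:
    """A CD90/phalloidin-like channel with a planted filament network.

    The channel carries the filament signal, impulse (salt) noise, and the
    configured background noise model; the planted binary mask is returned as
    ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    shape = tuple(int(s) for s in params.shape)
    mask = _filament_mask(shape, rng, params.filament_density, params.filament_radius)
    amp = params.marker_snr * max(params.background, 1.0)
    volume = np.zeros(shape, dtype=np.float64)
    volume[mask] = amp
    # impulse noise: isolated saturated voxels the median filter must reject
    n_salt = int(round(0.002 * volume.size))
    if n_salt:
        flat = rng.choice(volume.size, size=n_salt, replace=False)
        volume.ravel()[flat] = 2.0 * amp
    channel = _apply_noise(volume + params.background, params, rng)
    return ImageStack3D({"CD90": channel}), mask


# ---------------------------------------------------------------------------
# toy omics tables

def generate_omics_bundle(
    n_genes: int = 120,
    n_clusters: int = 8,
    n_planted: int = 6,
    seed: int = 0,
    n_decoys: int = 30,
) -> ToyOmicsBundle:
    """Toy DE/PPI tables with planted crosstalk edges and guaranteed decoys.

    Planted edges cycle through the three interaction classes (tumor-stroma,
    tumor-tumor core/periphery, self-ligand). Decoy edges are constructed so
    that exact cross-referencing must reject them: edges with no
    differentially expressed partner, edges whose stromal partner is expressed
    in fewer than 10% of cells in every cluster, and self-edges of
    non-qualifying genes.
    """
    if n_genes < 20:
        raise ValueError("need at least 20 genes for role assignment")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    perm = rng.permutation(n_genes)
    n_b = max(4, n_genes // 4)
    n_m = max(3, n_genes // 5)
    n_low = max(2, n_genes // 10)
    b_genes = [genes[i] for i in perm[:n_b]]
    m_genes = [genes[i] for i in perm[n_b:n_b + n_m]]
    low_genes = [genes[i] for i in perm[n_b + n_m:n_b + n_m + n_low]]
    null_genes = [genes[i] for i in perm[n_b + n_m + n_low:]]

    classes = ["B_BMSC", "B_B", "self_ligand"]
    need_b = sum(1 + (c == "B_B") for c in (classes[i % 3] for i in range(n_planted)))
    if need_b > n_b or n_planted > 3 * n_m:
        raise ValueError(
            f"n_planted={n_planted} too large for {n_genes} genes"
        )

    b_rows = [
        {
            "gene": g,
            "direction": ("core_up", "periphery_up")[int(rng.integers(2))],
            "lfc": float(np.round(rng.uniform(0.5, 4.0) * (1 if rng.random() < 0.5 else -1), 3)),
            "adj_p": float(np.round(rng.uniform(1e-6, 0.04), 6)),
        }
        for g in b_genes
    ]
    # distractor rows present in the table but not significant
    for g in null_genes[: max(2, len(null_genes) // 5)]:
        b_rows.append(
            {
                "gene": g,
                "direction": ("core_up", "periphery_up")[int(rng.integers(2))],
                "lfc": float(np.round(rng.uniform(-1, 1), 3)),
                "adj_p": float(np.round(rng.uniform(0.06, 0.9), 6)),
            }
        )
    b_de = pd.DataFrame(b_rows)

    c_rows = []
    for g in m_genes:
        hits = rng.choice(n_clusters, size=int(rng.integers(1, max(2, n_clusters // 2))),
                          replace=False)
        for cl in range(n_clusters):
            pct = rng.uniform(0.10, 0.60) if cl in hits else rng.uniform(0.0, 0.09)
            c_rows.append(
                {
                    "gene": g,
                    "cluster": cl,
                    "pct_expressing": float(np.round(pct, 4)),
                    "lfc": float(np.round(rng.uniform(-3, 3), 3)),
                    "adj_p": float(np.round(rng.uniform(1e-6, 0.04), 6))
                    if cl == hits[0]
                    else float(np.round(rng.uniform(0.06, 0.9), 6)),
                }
            )
    for g in low_genes:
        for cl in range(n_clusters):
            c_rows.append(
                {
                    "gene": g,
                    "cluster": cl,
                    "pct_expressing": float(np.round(rng.uniform(0.0, 0.099), 4)),
                    "lfc": float(np.round(rng.uniform(-3, 3), 3)),
                    "adj_p": float(np.round(rng.uniform(1e-6, 0.04), 6)),
                }
            )
    cluster_de = pd.DataFrame(c_rows)

    edges: list[dict] = []
    planted: list[dict] = []

    def _edge(a: str, b: str) -> dict:
        return {"gene_a": a, "gene_b": b, "confidence": float(np.round(rng.uniform(0.5, 1.0), 3))}

    bi, mi = 0, 0
    for i in range(n_planted):
        cls = classes[i % 3]
        if cls == "B_BMSC":
            a, b = b_genes[bi], m_genes[mi % n_m]
            bi += 1
            mi += 1
        elif cls == "B_B":
            a, b = b_genes[bi], b_genes[bi + 1]
            bi += 2
        else:
            a = b = b_genes[bi]
            bi += 1
        edges.append(_edge(a, b))
        planted.append({"gene_a": min(a, b), "gene_b": max(a, b), "class": cls})

    # decoys, none of which may survive cross-referencing
    used_b = set(b_genes[:bi])
    free_b = [g for g in b_genes[bi:]] or b_genes[:1]
    for k in range(n_decoys):
        kind = k % 3
        if kind == 0 and len(null_genes) >= 2:  # neither partner DE
            a, b = rng.choice(null_genes, size=2, replace=False)
        elif kind == 1:  # stromal partner under-expressed everywhere
            a = free_b[int(rng.integers(len(free_b)))]
            b = low_genes[int(rng.integers(len(low_genes)))]
        else:  # self-edge of a non-qualifying gene
            a = b = null_genes[int(rng.integers(len(null_genes)))]
        pair = (min(a, b), max(a, b))
        if any((e["gene_a"], e["gene_b"]) in (pair, pair[::-1]) for e in edges):
            continue
        if kind == 0 and (a in used_b or b in used_b):
            continue
        edges.append(_edge(str(a), str(b)))

    ppi = pd.DataFrame(edges).drop_duplicates(subset=["gene_a", "gene_b"])
    planted_df = pd.DataFrame(planted, columns=["gene_a", "gene_b", "class"])
    return ToyOmicsBundle(b_de, cluster_de, ppi, planted_df)


# ---------------------------------------------------------------------------
# persistence

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    cells = truth.cells.copy()
    cells["coloc_partner_id"] = cells["coloc_partner_id"].astype(object).where(
        cells["coloc_partner_id"].notna(), None
    )
    payload = {"cells": cells.to_dict(orient="records")}
    path.write_text(json.dumps(payload, indent=2, default=int) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    cells = pd.DataFrame(
        data["cells"],
        columns=["id", "z", "y", "x", "type", "apoptotic", "coloc_partner_id"],
    )
    cells["coloc_partner_id"] = cells["coloc_partner_id"].astype("Int64")
    return GroundTruth(cells=cells)


def write_omics_bundle(bundle: ToyOmicsBundle, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "b_de": out_dir / "b_de.tsv",
        "cluster_de": out_dir / "cluster_de.tsv",
        "ppi": out_dir / "ppi.tsv",
        "planted": out_dir / "planted_interactions.tsv",
    }
    bundle.b_de_table.to_csv(paths["b_de"], sep="\t", index=False)
    bundle.cluster_de_table.to_csv(paths["cluster_de"], sep="\t", index=False)
    bundle.ppi_table.to_csv(paths["ppi"], sep="\t", index=False)
    bundle.planted_interactions.to_csv(paths["planted"], sep="\t", index=False)
    return paths


def read_omics_bundle(out_dir: str | Path) -> ToyOmicsBundle:
    out_dir = Path(out_dir)
    return ToyOmicsBundle(
        b_de_table=pd.read_csv(out_dir / "b_de.tsv", sep="\t"),
        cluster_de_table=pd.read_csv(out_dir / "cluster_de.tsv", sep="\t"),
        ppi_table=pd.read_csv(out_dir / "ppi.tsv", sep="\t"),
        planted_interactions=pd.read_csv(out_dir / "planted_interactions.tsv", sep="\t"),
    )


def stack_for_condition(params: SimParams, stack_seed: int) -> SimParams:
    """Derive per-stack parameters from a condition-level seed."""
    return replace(params, seed=stack_seed)
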