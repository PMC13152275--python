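"""Synthetic data with known ground truth for every pipeline stage.

Generators mirror the study design: a pure-birth (Yule) phylogeny
rescaled to unit height; tip traits drawn from the multivariate normal
implied by a chosen evolution model, optionally with an additive
elevation effect; daily egg-mass series with balance noise at the 0.01 g
precision of a field scale; and SEM-like fields containing dark
functional pores and lighter occluded holes on a speckled bright
background.  Every generator is a pure function of its arguments and a
seed, and each dataset can be serialised next to its ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ovoflux.phylo import PhyloCovariance, Tree, TreeNode, transform_covariance, vcv_matrix
from ovoflux.conductance import DEFAULT_BANDS

__all__ = [
    "simulate_tree",
    "simulate_trait",
    "simulate_mass_series",
    "generate_sem_image",
    "assign_elevations",
    "SimulationConfig",
    "ImageTruth",
    "simulate_bundle",
]


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int = 0) -> Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, rescaled to
    height 1 (ultrametric by construction).

    Tips are labelled ``sp_001`` … in simulation order.
    """
    if n_tips < 2:
        raise ValueError("need >= 2 tips")
    rng = np.random.default_rng(seed)
    # active lineages: (parent_node_id, birth_time)
    nodes: list[TreeNode] = [TreeNode(id=0, parent=None, length=0.0, label=None)]
    active: list[tuple[int, float]] = [(0, 0.0), (0, 0.0)]
    t = 0.0
    next_id = 1
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        parent, birth = active.pop(i)
        nodes.append(TreeNode(id=next_id, parent=parent, length=t - birth, label=None))
        active.append((next_id, t))
        active.append((next_id, t))
        next_id += 1
    t_end = t + rng.exponential(1.0 / len(active))
    for k, (parent, birth) in enumerate(active):
        nodes.append(TreeNode(id=next_id, parent=parent, length=t_end - birth,
                              label=f"sp_{k + 1:03d}"))
        next_id += 1
    # rescale to unit height
    for nd in nodes:
        nd.length /= t_end
    return Tree(nodes)


# ---------------------------------------------------------------------------
# Traits and elevations
# ---------------------------------------------------------------------------

def assign_elevations(
    labels: Sequence[str],
    seed: int = 0,
    bands: Optional[Mapping[str, tuple[float, float]]] = None,
    phylo_clustered: bool = False,
    tree: Optional[Tree] = None,
) -> pd.Series:
    """Assign an elevation (m) to each species.

    Default: sample a band label uniformly, then a uniform elevation
    within the band — matching a design with stations clustered in
    discrete elevation belts.  With ``phylo_clustered`` a latent Brownian
    trait on the tree is thresholded into bands, producing phylogenetically
    clumped elevations for probing confounded designs.
    """
    bands = dict(bands or DEFAULT_BANDS)
    rng = np.random.default_rng(seed)
    names = list(bands)
    if phylo_clustered:
        if tree is None:
            raise ValueError("phylo_clustered requires the tree")
        C = vcv_matrix(tree).reorder(list(labels))
        L = np.linalg.cholesky(C.matrix + 1e-10 * np.eye(C.n))
        z = L @ rng.standard_normal(C.n)
        qs = np.quantile(z, np.linspace(0, 1, len(names) + 1)[1:-1])
        band_idx = np.searchsorted(qs, z)
    else:
        band_idx = rng.integers(len(names), size=len(labels))
    elevs = np.empty(len(labels))
    for i, b in enumerate(band_idx):
        lo, hi = bands[names[b]]
        elevs[i] = rng.uniform(lo, hi)
    return pd.Series(elevs, index=list(labels), name="elevation_m")


def simulate_trait(
    tree: Tree,
    model: str = "BM",
    params: Optional[dict] = None,
    sigma2: float = 1.0,
    z0: float = 0.0,
    elevation_m: Optional[Mapping[str, float]] = None,
    beta_per_km: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Draw one tip-trait vector from N(z₀·1 + β·elev_km, σ²·C_model).

    Uses the same covariance construction as the fitting code, so
    simulation and inference share a single definition of each model.
    """
    rng = np.random.default_rng(seed)
    C = vcv_matrix(tree)
    Ct = transform_covariance(C, model, params or {})
    labels = Ct.labels
    mean = np.full(len(labels), float(z0))
    if elevation_m is not None:
        mean = mean + beta_per_km * np.array([elevation_m[lab] for lab in labels]) / 1000.0
    if sigma2 == 0.0:
        return pd.Series(mean, index=labels)
    L = np.linalg.cholesky(Ct.matrix + 1e-12 * np.eye(len(labels)))
    x = mean + math.sqrt(sigma2) * (L @ rng.standard_normal(len(labels)))
    return pd.Series(x, index=labels)


# ---------------------------------------------------------------------------
# Egg mass series
# ---------------------------------------------------------------------------

BALANCE_NOISE_SD_G = 0.005  # half the 0.01 g resolution of the field balance


def simulate_mass_series(
    true_g: float,
    deltap_torr: float = 23.77,
    m0_g: float = 10.0,
    days: int = 8,
    noise_sd_g: float = BALANCE_NOISE_SD_G,
    seed: int = 0,
    fracture_day: Optional[int] = None,
    fracture_drop_g: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily masses for one egg with conductance ``true_g``.

    mass(d) = M0 − G·ΔP·d/1000 + ε_d with ε ~ N(0, noise²) in grams.  An
    optional fracture adds a step drop from ``fracture_day`` onward, for
    QC-detector testing.  Returns ``(days, masses_g)``.
    """
    if true_g <= 0:
        raise ValueError("true conductance must be positive")
    if not 4 <= days <= 30:
        raise ValueError("days must be in [4, 30]")
    rng = np.random.default_rng(seed)
    d = np.arange(days, dtype=float)
    loss_g_per_day = true_g * deltap_torr / 1000.0
    masses = m0_g - loss_g_per_day * d
    if fracture_day is not None:
        masses = masses - fracture_drop_g * (d >= fracture_day)
    if noise_sd_g > 0:
        masses = masses + rng.normal(0.0, noise_sd_g, size=days)
    if np.any(masses <= 0):
        raise ValueError("egg mass would reach zero within the window; "
                         "increase m0_g or shorten the series")
    return d, masses


# ---------------------------------------------------------------------------
# SEM-like images
# ---------------------------------------------------------------------------

@dataclass
class ImageTruth:
    centers: list[tuple[float, float]]  # (row, col)
    radii_px: list[float]
    classes: list[str]
    scale_um_per_px: float
    size_px: tuple[int, int]


BACKGROUND_MEAN = 0.8
BACKGROUND_SD = 0.05
FUNCTIONAL_INTENSITY = 0.05
OCCLUDED_INTENSITY = 0.35


def generate_sem_image(
    n_functional: int,
    n_occluded: int,
    radius_px: tuple[float, float] = (4.0, 6.0),
    size_px: int = 128,
    scale_um_per_px: float = 0.1,
    min_separation_px: float = 5.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, ImageTruth]:
    """Synthetic SEM field: speckled bright shell matrix with dark
    (functional) and gray (occluded) disk-shaped holes.

    Placement is rejection-sampled so disk rims stay at least
    ``min_separation_px`` apart and clear of the border.  Returns the raw
    intensity array (clipped to [0, 1]) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    img = np.clip(rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, (size_px, size_px)), 0.0, 1.0)
    n_total = n_functional + n_occluded
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    classes = ["functional"] * n_functional + ["occluded"] * n_occluded
    attempts = 0
    while len(centers) < n_total:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_total} pores in {max_attempts} attempts; "
                "reduce count, radius or separation"
            )
        attempts += 1
        r = rng.uniform(*radius_px)
        margin = r + min_separation_px + 1
        cr = rng.uniform(margin, size_px - margin)
        cc = rng.uniform(margin, size_px - margin)
        ok = all(
            math.hypot(cr - pr, cc - pc) >= r + prr + min_separation_px
            for (pr, pc), prr in zip(centers, radii)
        )
        if ok:
            centers.append((cr, cc))
            radii.append(r)
    rows, cols = np.ogrid[:size_px, :size_px]
    for (cr, cc), r, cls in zip(centers, radii, classes):
        disk = (rows - cr) ** 2 + (cols - cc) ** 2 <= r ** 2
        level = FUNCTIONAL_INTENSITY if cls == "functional" else OCCLUDED_INTENSITY
        img[disk] = np.clip(level + rng.normal(0.0, 0.01, int(disk.sum())), 0.0, 1.0)
    truth = ImageTruth(
        centers=centers, radii_px=radii, classes=classes,
        scale_um_per_px=scale_um_per_px, size_px=(size_px, size_px),
    )
    return img, truth


# ---------------------------------------------------------------------------
# Full input bundles
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study-scale defaults for a complete synthetic input bundle."""

    seed: int = 0
    n_species: int = 60
    trait_model: str = "OU"
    trait_params: dict = field(default_factory=lambda: {"alpha": 2.0})
    sigma2: float = 1.0
    z0: float = 0.0
    beta_per_km: float = -0.5       # log conductance declines with elevation
    eggs_per_species: tuple[int, int] = (1, 3)
    days: int = 8
    noise_sd_g: float = BALANCE_NOISE_SD_G
    deltap_torr: float = 23.77
    mean_log_g: float = 0.0         # log-scale centre of true conductance
    phylo_clustered_elevation: bool = False


def simulate_bundle(config: SimulationConfig, outdir: Optional[str] = None) -> dict:
    """Generate a full pipeline input bundle with its ground truth.

    Returns a dict with the tree, a long-format egg-mass table, a
    species morphometry table, and the ground-truth sidecar.  When
    ``outdir`` is given, everything is also written to disk (Newick, CSVs
    and a JSON truth file).
    """
    from ovoflux.phylo import write_newick

    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_species, seed=int(rng.integers(2**31)))
    labels = tree.tip_labels
    elev = assign_elevations(
        labels, seed=int(rng.integers(2**31)),
        phylo_clustered=config.phylo_clustered_elevation, tree=tree,
    )
    log_g = simulate_trait(
        tree, model=config.trait_model, params=config.trait_params,
        sigma2=config.sigma2, z0=config.mean_log_g + config.z0,
        elevation_m=elev.to_dict(), beta_per_km=config.beta_per_km,
        seed=int(rng.integers(2**31)),
    )
    true_g = np.exp(log_g)

    mass_rows = []
    for sp in labels:
        n_eggs = int(rng.integers(config.eggs_per_species[0],
                                  config.eggs_per_species[1] + 1))
        for e in range(n_eggs):
            m0 = float(rng.uniform(5.0, 15.0))
            d, m = simulate_mass_series(
                float(true_g[sp]), deltap_torr=config.deltap_torr, m0_g=m0,
                days=config.days, noise_sd_g=config.noise_sd_g,
                seed=int(rng.integers(2**31)),
            )
            for di, mi in zip(d, m):
                mass_rows.append({
                    "egg_id": f"{sp}_egg{e + 1}", "species": sp,
                    "station": f"st_{elevation_station(elev[sp])}",
                    "elevation_m": float(elev[sp]), "temp_c": 25.0,
                    "day": float(di), "mass_g": float(mi),
                })
    mass_df = pd.DataFrame(mass_rows)

    # morphometry: width from a plausible avian shape ratio, mass ~ volume
    width = rng.uniform(1.5, 3.5, len(labels))
    length = width * rng.uniform(1.25, 1.45, len(labels))
    volume = 0.51 * length * width ** 2
    fresh_mass = volume * rng.normal(1.09, 0.02, len(labels))  # ~density of egg
    morpho_df = pd.DataFrame({
        "species": labels,
        "length_cm": length, "width_cm": width, "mass_g": fresh_mass,
        "elevation_m": [float(elev[sp]) for sp in labels],
        "family": [f"fam_{(i % 6) + 1}" for i in range(len(labels))],
    })

    truth = {
        "seed": config.seed,
        "trait_model": config.trait_model,
        "trait_params": config.trait_params,
        "sigma2": config.sigma2,
        "beta_per_km": config.beta_per_km,
        "true_g": {sp: float(true_g[sp]) for sp in labels},
        "elevation_m": {sp: float(elev[sp]) for sp in labels},
    }
    bundle = {"tree": tree, "mass_series": mass_df, "morphometry": morpho_df,
              "truth": truth}
    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_newick(tree, os.path.join(outdir, "tree.nwk"))
        mass_df.to_csv(os.path.join(outdir, "mass_series.csv"), index=False)
        morpho_df.to_csv(os.path.join(outdir, "morphometry.csv"), index=False)
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2)
    return bundle


def elevation_station(elevation_m: float) -> str:
    from ovoflux.conductance import elevation_category

    return elevation_category(float(elevation_m))
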