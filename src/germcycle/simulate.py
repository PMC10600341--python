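"""Synthetic ground-truth generators.

Two generators anchor the test strategy:

``simulate_counts``
    A negative-binomial scRNA-seq count simulator with planted five-phase
    marker structure.  Each cell belongs to one true phase (or an optional
    non-cycling state); markers of that phase have their mean multiplied by
    a fold change, everything else sits at a common baseline, and per-cell
    library-size factors plus NB dispersion supply realistic noise.  Groups
    (e.g. control vs a G1/S-depleted mutant) differ only in their phase
    composition, which is the property the downstream classifier must
    recover.

``simulate_cell_image``
    Two-channel fluorescence fields of non-overlapping model cells, each a
    nuclear disk inside a concentric cytoplasmic annulus, with a known true
    nuclear/cytoplasmic signal ratio, uneven illumination, additive Gaussian
    noise, and bit-depth quantization.  A truth table carries the geometry
    so oracle masks and exact expected ratios are available downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from germcycle.genesets import PHASES, PhaseGeneSets

NONCYCLING = "non-cycling"

_PHASE_TAG = {"G1/S": "G1S", "S": "S", "G2": "G2", "G2/M": "G2M", "M/G1": "MG1"}


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

def _default_proportions() -> dict[str, tuple[float, ...]]:
    # control: balanced cycling population; mutant: G1/S-depleted, the
    # remaining mass spread over the other four phases.
    return {
        "control": (0.2, 0.2, 0.2, 0.2, 0.2),
        "mutant": (0.02, 0.245, 0.245, 0.245, 0.245),
    }


@dataclass
class SimDesign:
    """Design of a two-group synthetic count matrix.

    Parameters
    ----------
    n_cells_per_group
        Cells simulated for every group in ``group_phase_proportions``.
    group_phase_proportions
        Map group name -> 5-vector of true phase proportions in the fixed
        phase order (G1/S, S, G2, G2/M, M/G1); each must sum to 1.
    noncycling_fraction
        Optional fraction of cells per group in a sixth state with no marker
        elevation (a G0-like state); the five phase proportions are rescaled
        by ``1 - noncycling_fraction``.
    n_markers_per_phase, n_background_genes
        Gene panel sizes.
    marker_fold_change
        Mean multiplier (>= 1) a marker receives in cells of its own phase.
    base_mean
        Expected counts per gene in cells where it is not elevated.
    nb_dispersion
        NB dispersion phi with variance mu + phi * mu**2; 0 gives Poisson.
    library_size_cv
        Coefficient of variation of log-normal per-cell size factors
        (mean 1); 0 gives identical libraries.
    stratified
        If True, per-group phase counts are exact (largest-remainder
        rounding) instead of i.i.d. multinomial draws.
    seed
        Global seed; substreams are spawned per group and stage.
    """

    n_cells_per_group: int = 1000
    group_phase_proportions: Mapping[str, Sequence[float]] = field(
        default_factory=_default_proportions
    )
    noncycling_fraction: float = 0.0
    n_markers_per_phase: int = 20
    n_background_genes: int = 500
    marker_fold_change: float = 2.5
    base_mean: float = 5.0
    nb_dispersion: float = 0.1
    library_size_cv: float = 0.1
    stratified: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_group <= 0:
            raise ValueError("n_cells_per_group must be positive")
        if self.n_markers_per_phase <= 0:
            raise ValueError("every phase needs at least one marker gene")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.marker_fold_change < 1:
            raise ValueError("marker_fold_change must be >= 1")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.nb_dispersion < 0 or self.library_size_cv < 0:
            raise ValueError("dispersion and library_size_cv must be >= 0")
        if not 0 <= self.noncycling_fraction < 1:
            raise ValueError("noncycling_fraction must be in [0, 1)")
        if not self.group_phase_proportions:
            raise ValueError("at least one group is required")
        for group, props in self.group_phase_proportions.items():
            props = np.asarray(props, dtype=float)
            if props.shape != (5,):
                raise ValueError(f"group {group!r}: proportions must be a 5-vector")
            if (props < 0).any():
                raise ValueError(f"group {group!r}: negative proportion")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"group {group!r}: proportions sum to {props.sum()!r}, not 1"
                )


def _marker_gene_names(n_per_phase: int) -> dict[str, tuple[str, ...]]:
    return {
        phase: tuple(
            f"{_PHASE_TAG[phase]}_M{i + 1:03d}" for i in range(n_per_phase)
        )
        for phase in PHASES
    }


def _stratified_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n cells over states."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    short = n - counts.sum()
    for idx in np.argsort(-rem)[:short]:
        counts[idx] += 1
    return counts


def simulate_counts(design: SimDesign) -> tuple[ad.AnnData, PhaseGeneSets]:
    """Simulate a grouped count matrix with planted phase structure.

    Returns an :class:`~anndata.AnnData` with integer counts in ``X``,
    ``obs['group']`` and ``obs['true_phase']`` (the ground-truth labels), and
    ``var['phase']`` marking marker genes, together with the matching
    :class:`PhaseGeneSets`.
    """
    design.validate()

    marker_names = _marker_gene_names(design.n_markers_per_phase)
    genesets = PhaseGeneSets(marker_names)
    background = tuple(
        f"BG{i + 1:04d}" for i in range(design.n_background_genes)
    )
    gene_ids = list(genesets.all_genes) + list(background)
    gene_phase = np.array(
        [p for p in PHASES for _ in marker_names[p]]
        + [""] * design.n_background_genes,
        dtype=object,
    )
    n_genes = len(gene_ids)

    groups = list(design.group_phase_proportions)
    states = list(PHASES) + [NONCYCLING]
    ss = np.random.SeedSequence(design.seed)
    group_seeds = ss.spawn(len(groups))

    blocks: list[np.ndarray] = []
    obs_rows: list[pd.DataFrame] = []
    for group, gseed in zip(groups, group_seeds):
        rng = np.random.default_rng(gseed)
        n = design.n_cells_per_group
        probs = np.asarray(design.group_phase_proportions[group], dtype=float)
        probs = np.append(probs * (1 - design.noncycling_fraction),
                          design.noncycling_fraction)
        if design.stratified:
            counts = _stratified_counts(probs, n)
            labels = np.repeat(states, counts)
            rng.shuffle(labels)
        else:
            labels = rng.choice(states, size=n, p=probs / probs.sum())

        if design.library_size_cv > 0:
            sigma2 = math.log1p(design.library_size_cv ** 2)
            size_factors = rng.lognormal(-sigma2 / 2, math.sqrt(sigma2), n)
        else:
            size_factors = np.ones(n)

        mu = np.full((n, n_genes), design.base_mean)
        for phase in PHASES:
            in_phase = labels == phase
            marker_cols = gene_phase == phase
            mu[np.ix_(in_phase, marker_cols)] *= design.marker_fold_change
        mu *= size_factors[:, None]

        if design.nb_dispersion == 0:
            block = rng.poisson(mu)
        else:
            r = 1.0 / design.nb_dispersion
            block = rng.negative_binomial(r, r / (r + mu))
        blocks.append(block)
        obs_rows.append(pd.DataFrame({"group": group, "true_phase": labels}))

    obs = pd.concat(obs_rows, ignore_index=True)
    obs.index = [f"cell_{i:05d}" for i in range(len(obs))]
    obs["group"] = obs["group"].astype("category")
    adata = ad.AnnData(
        X=np.vstack(blocks).astype(np.int64),
        obs=obs,
        var=pd.DataFrame({"phase": gene_phase}, index=gene_ids),
    )
    adata.uns["sim_design"] = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in vars(design).items()
    }
    return adata, genesets


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass
class ImageSpec:
    """Design of a two-channel synthetic fluorescence field.

    Channel 0 (DAPI) shows nuclear disks of intensity ``dapi_mean`` over
    ``background_mean``; channel 1 (signal) shows, per cell, a nuclear disk
    at ``true_nc_ratio * cytoplasm_mean`` inside a cytoplasmic annulus at
    ``cytoplasm_mean`` over ``background_mean``.  Both channels are
    multiplied by a horizontal linear illumination field spanning
    ``1 ± illumination_gradient / 2``, perturbed by additive Gaussian noise
    of ``noise_sd``, clipped to the bit-depth range and rounded to integers.
    """

    image_size: tuple[int, int] = (384, 384)
    n_cells: int = 12
    nucleus_radius: int = 9
    cytoplasm_radius: int = 18
    true_nc_ratio: float = 2.0
    cytoplasm_mean: float = 50.0
    background_mean: float = 8.0
    dapi_mean: float = 180.0
    noise_sd: float = 2.5
    illumination_gradient: float = 0.0
    bit_depth: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if not (0 < self.nucleus_radius < self.cytoplasm_radius):
            raise ValueError("need cytoplasm_radius > nucleus_radius > 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        maxval = 2 ** self.bit_depth - 1
        for name in ("cytoplasm_mean", "background_mean", "dapi_mean"):
            v = getattr(self, name)
            if not 0 <= v <= maxval:
                raise ValueError(f"{name} outside [0, {maxval}]")
        if self.true_nc_ratio < 0 or self.noise_sd < 0:
            raise ValueError("true_nc_ratio and noise_sd must be >= 0")


def _place_cells(spec: ImageSpec, rng: np.random.Generator,
                 max_tries: int = 20000) -> np.ndarray:
    """Non-overlapping cell centers, kept clear of the image border."""
    h, w = spec.image_size
    margin = spec.cytoplasm_radius + 4
    min_dist = 2 * spec.cytoplasm_radius + 6
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError("image too small for the requested cell size")
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{spec.n_cells} cells "
                f"after {max_tries} tries"
            )
        tries += 1
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist ** 2
               for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers, dtype=int)


def _disk_mask(shape: tuple[int, int], center: tuple[int, int],
               radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def simulate_cell_image(spec: ImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel field of model cells.

    Returns ``(image, truth)`` where ``image`` has shape ``(2, H, W)``
    (page 0 = DAPI, page 1 = signal) in the integer dtype of the bit depth,
    and ``truth`` has one row per cell: center, radii, and the noise-free
    expected nuclear and cytoplasmic signal means (illumination included,
    which cancels in the ratio because disk and annulus are concentric).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    centers = _place_cells(spec, rng)

    dapi = np.full((h, w), spec.background_mean, dtype=float)
    signal = np.full((h, w), spec.background_mean, dtype=float)
    nuclear_level = spec.true_nc_ratio * spec.cytoplasm_mean
    for r, c in centers:
        cell = _disk_mask((h, w), (r, c), spec.cytoplasm_radius)
        nuc = _disk_mask((h, w), (r, c), spec.nucleus_radius)
        signal[cell] = spec.cytoplasm_mean
        signal[nuc] = nuclear_level
        dapi[nuc] = spec.dapi_mean

    illum = 1.0 + spec.illumination_gradient * (
        np.arange(w) / max(w - 1, 1) - 0.5
    )
    dapi *= illum
    signal *= illum
    if spec.noise_sd > 0:
        dapi = dapi + rng.normal(0, spec.noise_sd, (h, w))
        signal = signal + rng.normal(0, spec.noise_sd, (h, w))

    maxval = 2 ** spec.bit_depth - 1
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    image = np.stack([
        np.rint(np.clip(dapi, 0, maxval)).astype(dtype),
        np.rint(np.clip(signal, 0, maxval)).astype(dtype),
    ])

    illum_at = illum[centers[:, 1]]
    truth = pd.DataFrame({
        "cell_id": np.arange(len(centers)),
        "center_row": centers[:, 0],
        "center_col": centers[:, 1],
        "nucleus_radius": spec.nucleus_radius,
        "cytoplasm_radius": spec.cytoplasm_radius,
        "nuclear_mean_true": nuclear_level * illum_at,
        "cytoplasmic_mean_true": spec.cytoplasm_mean * illum_at,
        "true_nc_ratio": spec.true_nc_ratio,
    })
    return image, truth


def oracle_masks(truth: pd.DataFrame,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth nuclear and whole-cell masks from the truth geometry."""
    dapi_mask = np.zeros(shape, dtype=bool)
    cell_mask = np.zeros(shape, dtype=bool)
    for row in truth.itertuples():
        center = (row.center_row, row.center_col)
        dapi_mask |= _disk_mask(shape, center, row.nucleus_radius)
        cell_mask |= _disk_mask(shape, center, row.cytoplasm_radius)
    return dapi_mask, cell_mask
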