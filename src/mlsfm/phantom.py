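"""Seeded synthetic phantoms: neuron trees, beads, dye pools, spike tracks.

These stand in for cleared-brain specimens: sparsely labelled neurons with
branching axons at two brightness classes, sub-resolution fluorescent beads
for PSF work, a uniform dye pool for brightness-law measurements, and a
narrow/wide-spiking unit table along an electrode track crossing a nuclear
boundary.  Every generator is a pure function of (config, seed).

Conventions: volumes are indexed (z, y, x) with ``voxel_size_um`` in the same
order; SWC node coordinates are (x, y, z) in micrometres as the format
prescribes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .seeding import as_rng

__all__ = [
    "NeuronTreeSWC",
    "PhantomVolume",
    "PhantomConfig",
    "SpikeTrackData",
    "generate_neurons",
    "assign_snr_classes",
    "swc_stats",
    "rasterize",
    "generate_beads",
    "generate_bead_grid",
    "render_gaussian_beads",
    "generate_dye_pool",
    "generate_spike_track",
]


@dataclass
class NeuronTreeSWC:
    """A neuron morphology as a single-rooted tree in SWC column layout."""

    ids: np.ndarray          # (n,) int
    type_code: np.ndarray    # (n,) int, SWC structure codes (1 soma, 2 axon)
    xyz_um: np.ndarray       # (n, 3) float, (x, y, z)
    radius_um: np.ndarray    # (n,) float
    parent: np.ndarray       # (n,) int, -1 for the root

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("type_code", "radius_um", "parent"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if self.xyz_um.shape != (n, 3):
            raise ValueError("xyz_um must be (n, 3)")

    def validate(self) -> None:
        """Check unique ids, a single root, and a connected acyclic graph."""
        ids = np.asarray(self.ids)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("node ids are not unique")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        index = {int(i): k for k, i in enumerate(ids)}
        # walk each node to the root; cycle or missing parent -> invalid
        for k in range(len(ids)):
            seen = set()
            j = k
            while self.parent[j] != -1:
                if j in seen:
                    raise ValueError("cycle detected in tree")
                seen.add(j)
                p = int(self.parent[j])
                if p not in index:
                    raise ValueError(f"parent id {p} not present")
                j = index[p]

    def n_nodes(self) -> int:
        return len(self.ids)

    def child_counts(self) -> np.ndarray:
        counts = np.zeros(len(self.ids), dtype=int)
        index = {int(i): k for k, i in enumerate(self.ids)}
        for p in self.parent:
            if p != -1:
                counts[index[int(p)]] += 1
        return counts


@dataclass
class PhantomVolume:
    """A ground-truth 3D scene: expected photon flux per voxel per ms."""

    intensity: np.ndarray                     # (z, y, x) float, >= 0
    voxel_size_um: tuple[float, float, float]  # (z, y, x)
    truth_masks: dict[str, np.ndarray] = field(default_factory=dict)
    snr_class: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        for name, mask in self.truth_masks.items():
            if mask.shape != self.intensity.shape:
                raise ValueError(f"truth mask {name!r} shape mismatch")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.intensity.shape, self.voxel_size_um))


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the neuron-tree phantom generator.

    ``intensity_bright``/``intensity_dim`` are rasterized peak amplitudes
    (photon flux per ms at unit relative brightness); their defaults were
    calibrated once so the default acquisition yields triage SNR near the
    bright/dim operating points (about 34.5 and 4.5) and then frozen.
    """

    extent_um: tuple[float, float, float] = (40.0, 400.0, 400.0)  # (z, y, x)
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_neurons: int = 6
    bright_fraction: float = 0.67
    branch_prob: float = 0.08
    step_um: float = 6.0
    persistence: float = 0.85
    node_budget_range: tuple[int, int] = (80, 480)
    soma_radius_um: float = 6.0
    axon_radius_um: float = 1.5
    intensity_bright: float = 180.0
    intensity_dim: float = 20.0
    background_level: float = 4.0
    vessel_density_per_mm3: float = 0.0
    vessel_intensity: float = 8.0
    vessel_radius_um: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(e <= 0 for e in self.extent_um):
            raise ValueError("volume extent must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel size must be positive")
        for name in (
            "branch_prob", "intensity_bright", "intensity_dim",
            "background_level", "vessel_density_per_mm3",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_neurons < 0:
            raise ValueError("n_neurons must be >= 0")


@dataclass
class SpikeTrackData:
    """Units along an electrode track: signed distance to the boundary
    (positive = inside the target structure) and a narrow-spiking label."""

    distance_um: np.ndarray
    is_narrow: np.ndarray
    track_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.distance_um)):
            raise ValueError("distances must be finite")
        self.is_narrow = np.asarray(self.is_narrow, dtype=bool)
        if len(self.is_narrow) != len(self.distance_um):
            raise ValueError("length mismatch")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_neurons(config: PhantomConfig, rng=None) -> list[NeuronTreeSWC]:
    """Grow branching axon trees by a persistent random walk.

    Each tree starts at a soma, extends in discrete steps with direction
    persistence, and bifurcates with a fixed per-step probability until a
    per-tree node budget is exhausted or the walk leaves the volume.  Node
    budgets are drawn per tree, which makes total cable length and branch
    count covary strongly across a population (as real sparse-labelled
    populations do).
    """
    rng = as_rng(rng if rng is not None else config.seed)
    ez, ey, ex = config.extent_um
    trees: list[NeuronTreeSWC] = []
    for _ in range(config.n_neurons):
        budget = int(rng.integers(*config.node_budget_range))
        soma = np.array([
            rng.uniform(0.1 * ex, 0.9 * ex),
            rng.uniform(0.1 * ey, 0.9 * ey),
            rng.uniform(0.1 * ez, 0.9 * ez),
        ])
        ids = [1]
        type_code = [1]
        xyz = [soma]
        radius = [config.soma_radius_um]
        parent = [-1]
        # active tips: (parent node index, direction)
        tips = [(0, _random_unit(rng))]
        next_id = 2
        while tips and next_id <= budget:
            tip_idx, direction = tips.pop(0)
            direction = direction * config.persistence + _random_unit(rng) * (
                1.0 - config.persistence
            )
            direction /= np.linalg.norm(direction)
            pos = xyz[tip_idx] + direction * config.step_um
            # reflect at the tissue boundary (axons stay inside the slab)
            for c, hi in enumerate((ex, ey, ez)):
                if pos[c] < 0.0 or pos[c] > hi:
                    direction[c] = -direction[c]
            pos = np.clip(xyz[tip_idx] + direction * config.step_um, 0.0, (ex, ey, ez))
            ids.append(next_id)
            type_code.append(2)
            xyz.append(pos)
            radius.append(config.axon_radius_um)
            parent.append(int(tip_idx))  # index for now; mapped to ids below
            node_idx = len(ids) - 1
            tips.append((node_idx, direction))
            if rng.random() < config.branch_prob:
                tips.append((node_idx, _random_unit(rng)))
            next_id += 1
        parent_ids = [-1] + [ids[p] for p in parent[1:]]
        tree = NeuronTreeSWC(
            ids=np.array(ids, dtype=int),
            type_code=np.array(type_code, dtype=int),
            xyz_um=np.array(xyz, dtype=float),
            radius_um=np.array(radius, dtype=float),
            parent=np.array(parent_ids, dtype=int),
        )
        tree.validate()
        trees.append(tree)
    return trees


def assign_snr_classes(n_neurons: int, bright_fraction: float) -> list[str]:
    """Deterministic bright/dim labels: the first round(n*f) neurons are bright."""
    n_bright = int(round(n_neurons * bright_fraction))
    return ["bright"] * n_bright + ["dim"] * (n_neurons - n_bright)


def swc_stats(tree: NeuronTreeSWC) -> tuple[float, int, int]:
    """(total cable length um, branch points, terminals).

    Length sums parent-child Euclidean distances; a branch point has >= 2
    children; a terminal has none (a bare root counts as one terminal).
    """
    tree.validate()
    index = {int(i): k for k, i in enumerate(tree.ids)}
    total = 0.0
    for k in range(tree.n_nodes()):
        p = int(tree.parent[k])
        if p != -1:
            total += float(np.linalg.norm(tree.xyz_um[k] - tree.xyz_um[index[p]]))
    counts = tree.child_counts()
    n_branch = int(np.sum(counts >= 2))
    n_term = int(np.sum(counts == 0))
    return total, n_branch, n_term


def _empty_volume(config: PhantomConfig) -> np.ndarray:
    shape = tuple(
        max(1, int(round(e / v)))
        for e, v in zip(config.extent_um, config.voxel_size_um)
    )
    return np.zeros(shape, dtype=np.float64)


def _splat_polyline(
    skeleton: np.ndarray,
    points_zyx_vox: np.ndarray,
    density: float,
    spacing_vox: float,
) -> None:
    """Deposit line mass at nearest voxels along a sampled polyline."""
    idx = np.round(points_zyx_vox).astype(int)
    for ax in range(3):
        np.clip(idx[:, ax], 0, skeleton.shape[ax] - 1, out=idx[:, ax])
    np.add.at(skeleton, (idx[:, 0], idx[:, 1], idx[:, 2]), density * spacing_vox)


def _sample_segment(a: np.ndarray, b: np.ndarray, spacing: float) -> np.ndarray:
    length = float(np.linalg.norm(b - a))
    n = max(2, int(np.ceil(length / spacing)) + 1)
    t = np.linspace(0.0, 1.0, n)
    return a[None, :] + t[:, None] * (b - a)[None, :]


def rasterize(
    trees: list[NeuronTreeSWC],
    config: PhantomConfig,
    snr_classes: list[str] | None = None,
    rng=None,
) -> PhantomVolume:
    """Draw neuron trees (and optional vessels) into an intensity volume.

    Each tree is drawn as a 3D polyline with a Gaussian radial cross-section
    whose sigma equals the axon radius and whose peak equals the class
    amplitude; somata are Gaussian blobs.  Composition is additive on top of
    a uniform background.  The truth mask marks voxels within the axon radius
    of any segment, split per brightness class.
    """
    if snr_classes is None:
        snr_classes = assign_snr_classes(len(trees), config.bright_fraction)
    if len(snr_classes) != len(trees):
        raise ValueError("need one snr class per tree")
    vz, vy, vx = config.voxel_size_um
    voxel_mean = float(np.mean(config.voxel_size_um))
    sigma_vox = config.axon_radius_um / voxel_mean
    shape = _empty_volume(config).shape
    ez, ey, ex = config.extent_um

    intensity = np.full(shape, float(config.background_level), dtype=np.float64)
    masks = {"bright": np.zeros(shape, bool), "dim": np.zeros(shape, bool)}
    amplitudes = {"bright": config.intensity_bright, "dim": config.intensity_dim}
    spacing_vox = 0.5

    for klass in ("bright", "dim"):
        skeleton = np.zeros(shape, dtype=np.float64)
        mask_seed = np.zeros(shape, dtype=bool)
        any_drawn = False
        # peak amplitude A after blur of a line of linear density rho:
        # rho = A * 2 pi sigma^2 (2D Gaussian cross-section normalisation)
        density = amplitudes[klass] * 2.0 * np.pi * sigma_vox**2
        for tree, kls in zip(trees, snr_classes):
            if kls != klass:
                continue
            index = {int(i): k for k, i in enumerate(tree.ids)}
            xyz = tree.xyz_um
            for k in range(tree.n_nodes()):
                x, y, z = xyz[k]
                if not (0 <= x <= ex and 0 <= y <= ey and 0 <= z <= ez):
                    raise ValueError(
                        f"node id {int(tree.ids[k])} at {tuple(xyz[k])} is "
                        "outside the volume bounds"
                    )
            any_drawn = True
            for k in range(tree.n_nodes()):
                p = int(tree.parent[k])
                if p == -1:
                    continue
                a = xyz[index[p]]
                b = xyz[k]
                pts_um = _sample_segment(a, b, spacing_vox * voxel_mean)
                pts_vox = np.column_stack(
                    [pts_um[:, 2] / vz, pts_um[:, 1] / vy, pts_um[:, 0] / vx]
                )
                _splat_polyline(skeleton, pts_vox, density, spacing_vox)
                idx = np.round(pts_vox).astype(int)
                for ax in range(3):
                    np.clip(idx[:, ax], 0, shape[ax] - 1, out=idx[:, ax])
                mask_seed[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            # soma blob, twice the axon amplitude
            sx, sy, sz = xyz[0]
            soma_sig = config.soma_radius_um / voxel_mean
            blob = np.zeros(shape)
            iz = int(round(sz / vz)); iy = int(round(sy / vy)); ix = int(round(sx / vx))
            iz = min(max(iz, 0), shape[0] - 1)
            iy = min(max(iy, 0), shape[1] - 1)
            ix = min(max(ix, 0), shape[2] - 1)
            blob[iz, iy, ix] = (
                2.0 * amplitudes[klass] * (2.0 * np.pi) ** 1.5 * soma_sig**3
            )
            intensity += ndimage.gaussian_filter(blob, soma_sig)
            mask_seed[iz, iy, ix] = True
        if any_drawn:
            intensity += ndimage.gaussian_filter(skeleton, sigma_vox)
            dist = ndimage.distance_transform_edt(
                ~mask_seed, sampling=(vz, vy, vx)
            )
            masks[klass] = dist <= config.axon_radius_um

    # vessels: random bright autofluorescent tubes, off by default
    n_vessels = 0
    if config.vessel_density_per_mm3 > 0:
        rng = as_rng(rng if rng is not None else config.seed + 1)
        vol_mm3 = np.prod(np.array(config.extent_um)) / 1e9
        n_vessels = int(rng.poisson(config.vessel_density_per_mm3 * vol_mm3))
        vessel_sig = config.vessel_radius_um / voxel_mean
        skeleton = np.zeros(shape)
        density = config.vessel_intensity * 2.0 * np.pi * vessel_sig**2
        for _ in range(n_vessels):
            a = rng.uniform([0, 0, 0], [ex, ey, ez])
            b = rng.uniform([0, 0, 0], [ex, ey, ez])
            pts_um = _sample_segment(a, b, spacing_vox * voxel_mean)
            pts_vox = np.column_stack(
                [pts_um[:, 2] / vz, pts_um[:, 1] / vy, pts_um[:, 0] / vx]
            )
            _splat_polyline(skeleton, pts_vox, density, spacing_vox)
        intensity += ndimage.gaussian_filter(skeleton, vessel_sig)

    masks["signal"] = masks["bright"] | masks["dim"]
    return PhantomVolume(
        intensity=intensity,
        voxel_size_um=config.voxel_size_um,
        truth_masks=masks,
        snr_class=list(snr_classes),
        meta={"config": config, "n_vessels": n_vessels},
    )


def _splat_trilinear(vol: np.ndarray, pos_vox: np.ndarray, amplitude: float) -> None:
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                z, y, x = base[0] + dz, base[1] + dy, base[2] + dx
                if 0 <= z < vol.shape[0] and 0 <= y < vol.shape[1] and 0 <= x < vol.shape[2]:
                    vol[z, y, x] += amplitude * w


def generate_beads(
    density_per_mm3: float,
    extent_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    amplitude: float = 500.0,
    background_level: float = 2.0,
    bead_diameter_um: float = 0.2,
    rng=None,
) -> PhantomVolume:
    """Sub-resolution beads at uniformly random positions.

    Beads are point emitters (diameter below the voxel size) splatted with
    trilinear weights so sub-voxel positions are preserved; exact positions
    are recorded as truth in ``meta['bead_positions_um']`` (z, y, x).
    """
    if density_per_mm3 < 0:
        raise ValueError("density must be >= 0")
    if bead_diameter_um >= min(voxel_size_um):
        raise ValueError("beads must be sub-resolution (diameter < voxel size)")
    rng = as_rng(rng)
    shape = tuple(
        max(1, int(round(e / v))) for e, v in zip(extent_um, voxel_size_um)
    )
    vol = np.full(shape, float(background_level))
    vol_mm3 = float(np.prod(np.array(extent_um))) / 1e9
    n = int(rng.poisson(density_per_mm3 * vol_mm3))
    positions = rng.uniform(low=[0, 0, 0], high=list(extent_um), size=(n, 3))
    for pos in positions:
        pos_vox = pos / np.array(voxel_size_um)
        _splat_trilinear(vol, pos_vox, amplitude)
    return PhantomVolume(
        intensity=vol,
        voxel_size_um=tuple(voxel_size_um),
        meta={"bead_positions_um": positions, "n_beads": n},
    )


def generate_bead_grid(
    spacing_um: tuple[float, float, float],
    extent_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    amplitude: float = 1000.0,
    background_level: float = 0.0,
    margin_um: float = 10.0,
) -> PhantomVolume:
    """Deterministic regular bead lattice, snapped to voxel centres.

    Used to probe spatial uniformity of the simulated axial response.
    """
    shape = tuple(
        max(1, int(round(e / v))) for e, v in zip(extent_um, voxel_size_um)
    )
    vol = np.full(shape, float(background_level))
    axes = [
        np.arange(margin_um, e - margin_um + 1e-9, s)
        for e, s in zip(extent_um, spacing_um)
    ]
    positions = []
    for z in axes[0]:
        for y in axes[1]:
            for x in axes[2]:
                idx = tuple(
                    int(round(c / v)) for c, v in zip((z, y, x), voxel_size_um)
                )
                if all(0 <= i < s for i, s in zip(idx, shape)):
                    vol[idx] += amplitude
                    positions.append([i * v for i, v in zip(idx, voxel_size_um)])
    return PhantomVolume(
        intensity=vol,
        voxel_size_um=tuple(voxel_size_um),
        meta={"bead_positions_um": np.array(positions), "n_beads": len(positions)},
    )


def render_gaussian_beads(
    positions_um: np.ndarray,
    fwhm_um: tuple[float, float, float],
    extent_um: tuple[float, float, float],
    voxel_size_um: tuple[float, float, float],
    amplitude: float = 2000.0,
    background_level: float = 10.0,
) -> PhantomVolume:
    """Beads already convolved with an anisotropic Gaussian PSF.

    The Gaussian is evaluated analytically at voxel centres, so fitted widths
    can be compared against the generative FWHM without rasterisation bias.
    ``fwhm_um`` is (z, y, x).
    """
    shape = tuple(
        max(1, int(round(e / v))) for e, v in zip(extent_um, voxel_size_um)
    )
    vol = np.full(shape, float(background_level))
    sigmas = np.array(fwhm_um) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    grids = [np.arange(s) * v for s, v in zip(shape, voxel_size_um)]
    for pos in np.atleast_2d(positions_um):
        profs = [
            np.exp(-0.5 * ((g - p) / s) ** 2)
            for g, p, s in zip(grids, pos, sigmas)
        ]
        vol += amplitude * profs[0][:, None, None] * profs[1][None, :, None] * profs[2][None, None, :]
    return PhantomVolume(
        intensity=vol,
        voxel_size_um=tuple(voxel_size_um),
        meta={"bead_positions_um": np.atleast_2d(positions_um), "fwhm_um": fwhm_um},
    )


def generate_dye_pool(
    level: float,
    extent_um: tuple[float, float, float] = (20.0, 100.0, 100.0),
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PhantomVolume:
    """Spatially uniform fluorophore pool of the given expected flux level."""
    if level < 0:
        raise ValueError("level must be >= 0")
    shape = tuple(
        max(1, int(round(e / v))) for e, v in zip(extent_um, voxel_size_um)
    )
    return PhantomVolume(
        intensity=np.full(shape, float(level)),
        voxel_size_um=tuple(voxel_size_um),
        meta={"level": level},
    )


def generate_spike_track(
    d0_um: float,
    slope_um: float,
    n: int,
    rng=None,
    distance_range_um: tuple[float, float] = (-150.0, 150.0),
    track_id: int | None = None,
) -> SpikeTrackData:
    """Units along a track with a logistic narrow-spiking probability.

    Distances are uniform on the range; labels are Bernoulli with
    P(narrow | d) = 1 / (1 + exp(-(d - d0)/slope)), so ``d0_um`` is the
    half-probability boundary distance and ``slope_um`` the transition width.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if slope_um <= 0:
        raise ValueError("slope_um must be > 0")
    from scipy.special import expit

    rng = as_rng(rng)
    d = rng.uniform(*distance_range_um, size=n)
    p = expit((d - d0_um) / slope_um)
    labels = rng.random(n) < p
    tids = None if track_id is None else np.full(n, track_id, dtype=int)
    return SpikeTrackData(distance_um=d, is_narrow=labels, track_id=tids)
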