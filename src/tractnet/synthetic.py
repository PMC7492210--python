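"""Phantom parcellations, FA maps, tractograms and whole cohorts.

The generator emulates the per-subject data triplet the analysis consumes —
an integer parcellation, an FA map in [0, 1], and a whole-brain streamline
set in world mm — together with cohort-level clinical structure: group
labels (patients and controls), motor scores for the patients, and an
injectable monotone association between the motor score and the FA weights
of a designated set of connections.

Motor scores are drawn uniformly over ``updrs_range`` (default (8, 29),
giving mean 18.5 and SD ≈ 6.1, matching a typical moderately affected PD
cohort) rather than from a normal distribution: the uniform spreads leverage
evenly for correlation recovery and cannot produce negative scores.

The association is injected at the level of edge FA weights.  For each
affected connection, a dedicated pair of endpoint voxels carries an FA value

    w = fa_mean + r * sigma * z + sqrt(1 - r^2) * sigma * eps

where ``z`` is the population-standardized motor score, ``eps`` standard
normal noise, ``sigma = fa_noise_sd``, and ``r = effect_r``; the population
correlation between the score and the resulting edge weight is exactly
``effect_r``.  Because streamlines of an affected edge terminate at those
dedicated voxel centres, the connectome builder recovers ``w`` exactly, so
the injected association propagates through the genuine pipeline path
(volume -> tractogram -> matrix -> efficiency) rather than being written
into any matrix directly.

Randomness uses one seed sequence per cohort, split per subject by counter,
so adding a subject never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Group, LabelVolume, ScalarVolume, SubjectData, Tractogram

__all__ = [
    "CohortConfig",
    "make_phantom_parcellation",
    "make_phantom_fa",
    "make_phantom_tractogram",
    "make_synthetic_cohort",
]


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort.

    Defaults mirror the clinical study design this pipeline targets:
    14 patients and 15 controls, 87 network nodes, moderate edge density,
    FA centred at 0.5 with SD 0.05.
    """

    n_pd: int = 14
    n_hc: int = 15
    n_rois: int = 87
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    edge_density: float = 0.2
    streamlines_per_edge: int = 5
    fa_mean: float = 0.5
    fa_noise_sd: float = 0.05
    updrs_range: tuple[float, float] = (8.0, 29.0)
    effect_r: float = 0.0
    affected_edges: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_mean < 1.0:
            raise ValueError("fa_mean must lie in (0, 1)")
        if self.fa_noise_sd < 0:
            raise ValueError("fa_noise_sd must be nonnegative")
        lo = self.fa_mean - 3 * self.fa_noise_sd
        hi = self.fa_mean + 3 * self.fa_noise_sd
        if lo <= 0.0 or hi >= 1.0:
            raise ValueError("fa_mean +/- 3*fa_noise_sd must stay within (0, 1)")
        if not -1.0 <= self.effect_r <= 1.0:
            raise ValueError("effect_r must lie in [-1, 1]")
        if abs(self.effect_r) == 1.0 and self.fa_noise_sd > 0:
            raise ValueError(
                "effect_r of +/-1 is unattainable with nonzero noise (fa_noise_sd > 0)"
            )
        if self.effect_r != 0 and self.n_pd < 2:
            raise ValueError("injecting a correlation requires n_pd >= 2")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must lie in (0, 1]")
        for a, b in self.affected_edges:
            if a == b:
                raise ValueError(f"affected edge ({a}, {b}) is a self-connection")


def _block_grid(n_rois: int, grid_shape: tuple[int, int, int]) -> tuple[np.ndarray, tuple]:
    """Choose a cell subdivision of the interior with >= n_rois cells of >= 8 voxels."""
    interior = tuple(s - 2 for s in grid_shape)  # 1-voxel background margin
    if min(interior) < 2:
        raise ValueError(f"grid {grid_shape} too small; each dimension must be >= 4")
    best = None
    for c0 in range(1, interior[0] // 2 + 1):
        for c1 in range(1, interior[1] // 2 + 1):
            c2 = -(-n_rois // (c0 * c1))  # ceil
            if c2 < 1 or interior[2] // c2 < 2:
                continue
            cells = c0 * c1 * c2
            waste = cells - n_rois
            if best is None or waste < best[0]:
                best = (waste, (c0, c1, c2))
    if best is None:
        need = int(np.ceil(2 * n_rois ** (1 / 3))) + 2
        raise ValueError(
            f"grid {grid_shape} cannot host {n_rois} ROIs of >= 8 voxels; "
            f"a grid of at least ({need}, {need}, {need}) is required"
        )
    return np.array(interior), best[1]


def make_phantom_parcellation(
    n_rois: int, grid_shape: tuple[int, int, int], seed: int = 0
) -> LabelVolume:
    """Partition a grid into ``n_rois`` contiguous rectangular blocks.

    A one-voxel background margin surrounds the labelled interior; every
    block owns at least 8 voxels; labels run 1..n_rois.  The seed permutes
    which block receives which label, deterministically.
    """
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    interior, (c0, c1, c2) = _block_grid(n_rois, grid_shape)
    edges0 = np.linspace(1, 1 + interior[0], c0 + 1).astype(int)
    edges1 = np.linspace(1, 1 + interior[1], c1 + 1).astype(int)
    edges2 = np.linspace(1, 1 + interior[2], c2 + 1).astype(int)

    rng = np.random.default_rng(seed)
    cell_order = rng.permutation(c0 * c1 * c2)
    data = np.zeros(grid_shape, dtype=np.int32)
    label = 0
    for cell in cell_order:
        if label >= n_rois:
            break
        i, rem = divmod(int(cell), c1 * c2)
        j, k = divmod(rem, c2)
        label += 1
        data[edges0[i]:edges0[i + 1], edges1[j]:edges1[j + 1], edges2[k]:edges2[k + 1]] = label
    labels = {i: f"roi{i:03d}" for i in range(1, n_rois + 1)}
    return LabelVolume(data, np.eye(4), labels)


def make_phantom_fa(
    labels: LabelVolume, fa_mean: float, fa_noise_sd: float, seed: int = 0
) -> ScalarVolume:
    """Gaussian FA field clipped to [0, 1] inside labelled voxels, 0 outside."""
    if not 0.0 < fa_mean < 1.0:
        raise ValueError("fa_mean must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    data = np.zeros(labels.shape, dtype=float)
    inside = labels.data > 0
    data[inside] = np.clip(
        fa_mean + fa_noise_sd * rng.standard_normal(int(inside.sum())), 0.0, 1.0
    )
    return ScalarVolume(data, labels.affine.copy())


def make_phantom_tractogram(
    labels: LabelVolume,
    edges: list[tuple[int, int]],
    counts: list[int],
    seed: int = 0,
    endpoint_voxels: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] | None = None,
) -> Tractogram:
    """Streamlines realizing the requested per-edge counts.

    Each streamline for edge (a, b) is a two-point polyline whose first
    point is a voxel centre of ROI ``a`` and last point a voxel centre of
    ROI ``b``, so every endpoint maps back into its ROI under the
    nearest-voxel rule.  ``endpoint_voxels`` optionally pins an edge's
    streamlines to one fixed voxel pair (used for controlled FA injection).
    """
    if len(edges) != len(counts):
        raise ValueError("edges and counts must have equal length")
    rng = np.random.default_rng(seed)
    vox_of: dict[int, np.ndarray] = {}

    def voxels(lab: int) -> np.ndarray:
        if lab not in vox_of:
            vv = np.argwhere(labels.data == lab)
            if len(vv) == 0:
                raise ValueError(f"ROI label {lab} has no voxels")
            vox_of[lab] = vv
        return vox_of[lab]

    A = labels.affine
    streamlines: list[np.ndarray] = []
    for (a, b), cnt in zip(edges, counts):
        if a == b:
            raise ValueError(f"edge ({a}, {b}) connects a node to itself")
        if endpoint_voxels is not None and (a, b) in endpoint_voxels:
            va = np.tile(endpoint_voxels[(a, b)][0], (cnt, 1))
            vb = np.tile(endpoint_voxels[(a, b)][1], (cnt, 1))
        else:
            va = voxels(a)[rng.integers(0, len(voxels(a)), cnt)]
            vb = voxels(b)[rng.integers(0, len(voxels(b)), cnt)]
        pa = va @ A[:3, :3].T + A[:3, 3]
        pb = vb @ A[:3, :3].T + A[:3, 3]
        for s in range(cnt):
            streamlines.append(np.vstack([pa[s], pb[s]]))
    return Tractogram(streamlines)


def make_synthetic_cohort(config: CohortConfig) -> list[SubjectData]:
    """Generate a full cohort of subjects under one configuration.

    All subjects share one phantom geometry (parcellation and edge set), so
    the consensus threshold retains every generated connection.  Patients
    receive a uniform motor score; affected edges carry FA weights
    correlated with that score at the configured population correlation;
    controls receive baseline (noise-only) weights on those edges.
    """
    geom_rng = np.random.default_rng([config.seed, 0xA11CE])
    parc = make_phantom_parcellation(
        config.n_rois, config.grid_shape, seed=int(geom_rng.integers(2**31))
    )

    pairs = [(a, b) for a in range(1, config.n_rois + 1)
             for b in range(a + 1, config.n_rois + 1)]
    n_edges = max(1, round(config.edge_density * len(pairs)))
    chosen = [pairs[i] for i in geom_rng.choice(len(pairs), n_edges, replace=False)]
    affected = [tuple(sorted(e)) for e in config.affected_edges]
    edges = sorted(set(chosen) | set(affected))

    # one dedicated endpoint-voxel pair per affected edge, distinct per ROI
    taken: dict[int, int] = {}
    dedicated: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    vox_of = {lab: np.argwhere(parc.data == lab) for lab in parc.labels}
    for e in affected:
        pick = []
        for lab in e:
            k = taken.get(lab, 0)
            if k >= len(vox_of[lab]):
                raise ValueError(f"ROI {lab} too small for its affected edges")
            pick.append(vox_of[lab][k])
            taken[lab] = k + 1
        dedicated[e] = (pick[0], pick[1])
    dedicated_vox = {tuple(v) for pair in dedicated.values() for v in
                     (pair[0].tolist(), pair[1].tolist())}

    u_lo, u_hi = config.updrs_range
    u_mean, u_sd = (u_lo + u_hi) / 2.0, (u_hi - u_lo) / np.sqrt(12.0)
    r, sigma = config.effect_r, config.fa_noise_sd

    subjects: list[SubjectData] = []
    for idx in range(config.n_pd + config.n_hc):
        rng = np.random.default_rng([config.seed, 1 + idx])
        is_pd = idx < config.n_pd
        updrs = float(rng.uniform(u_lo, u_hi)) if is_pd else None

        fa = make_phantom_fa(parc, config.fa_mean, config.fa_noise_sd,
                             seed=int(rng.integers(2**31)))
        # controlled FA at dedicated voxels of affected edges
        for e in affected:
            if is_pd and u_sd > 0:
                z = (updrs - u_mean) / u_sd
                w = config.fa_mean + r * sigma * z \
                    + np.sqrt(max(0.0, 1 - r * r)) * sigma * rng.standard_normal()
            else:
                w = config.fa_mean + sigma * rng.standard_normal()
            w = float(np.clip(w, 0.0, 1.0))
            for v in dedicated[e]:
                fa.data[tuple(v)] = w
        # keep random endpoints of unaffected edges off the dedicated voxels
        counts = [1 + int(rng.poisson(max(0, config.streamlines_per_edge - 1)))
                  for _ in edges]
        tract = _tractogram_avoiding(parc, edges, counts, rng, dedicated, dedicated_vox)

        subjects.append(SubjectData(
            subject_id=f"{'pd' if is_pd else 'hc'}{idx:03d}",
            group=Group.PD if is_pd else Group.HC,
            updrs_motor=updrs,
            label_volume=parc,
            fa_volume=fa,
            tractogram=tract,
        ))
    return subjects


def _tractogram_avoiding(parc, edges, counts, rng, dedicated, dedicated_vox) -> Tractogram:
    """Per-subject tractogram; unaffected endpoints avoid dedicated voxels."""
    A = parc.affine
    free_of = {}
    for lab in parc.labels:
        vv = np.argwhere(parc.data == lab)
        keep = [v for v in vv if tuple(v.tolist()) not in dedicated_vox]
        free_of[lab] = np.array(keep) if keep else vv
    streamlines: list[np.ndarray] = []
    for e, cnt in zip(edges, counts):
        if e in dedicated:
            va = np.tile(dedicated[e][0], (cnt, 1))
            vb = np.tile(dedicated[e][1], (cnt, 1))
        else:
            va = free_of[e[0]][rng.integers(0, len(free_of[e[0]]), cnt)]
            vb = free_of[e[1]][rng.integers(0, len(free_of[e[1]]), cnt)]
        pa = va @ A[:3, :3].T + A[:3, 3]
        pb = vb @ A[:3, :3].T + A[:3, 3]
        for s in range(cnt):
            streamlines.append(np.vstack([pa[s], pb[s]]))
    return Tractogram(streamlines)
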