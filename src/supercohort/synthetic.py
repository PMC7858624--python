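"""Synthetic multi-cohort slide generator with a planted similarity hierarchy.

Real multi-cohort corpora (e.g. TCGA frozen sections) come with an unknown
true relatedness between cohorts. Here the relatedness is *planted*: cohorts
sit at the leaves of a rooted tree, their texture parameters evolve by
Brownian motion along the branches, so the expected squared parameter
distance between two cohorts is proportional to their tree path length.
Positive slides carry a cancer perturbation along a per-cohort direction
that mixes a globally shared component with a tree-correlated,
cohort-specific one, so related cohorts share cancer morphology too.

Patches are procedural RGB textures (band-pass filtered noise plus dark
nuclei-like blobs on a colored background), not realistic H&E images; they
preserve the *statistical* structure the downstream analysis consumes:
graded cohort similarity, a cancer perturbation, and noisy slide-inherited
patch labels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantedHierarchy", "CohortParams", "SyntheticPatch", "SyntheticSlide",
    "MultiCohortDataset", "GenerationConfig", "generate_planted_hierarchy",
    "derive_cohort_params", "generate_slide", "generate_dataset",
    "save_dataset", "load_dataset", "dataset_digest",
]

# theta indexes twelve texture parameters:
# [R, G, B base color, frequency center, bandwidth, blob rate, blob radius,
#  blob darkness, R/G/B texture amplitude, orientation anisotropy]
THETA_DIM = 12


# ---------------------------------------------------------------------------
# Planted hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedHierarchy:
    """Rooted binary merge tree over cohorts 0..n_cohorts-1.

    ``merges[k] = (a, b, height)`` creates internal node ``n_cohorts + k``
    from nodes ``a`` and ``b``; heights are nondecreasing from leaves to the
    root. Leaves sit at height 0.
    """

    n_cohorts: int
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = self.n_cohorts
        if n < 2:
            raise ValueError("a hierarchy needs at least 2 cohorts")
        if len(self.merges) != n - 1:
            raise ValueError(f"expected {n - 1} merges, got {len(self.merges)}")
        heights = self.node_heights()
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            for child in (a, b):
                if not (0 <= child < node):
                    raise ValueError(f"merge {k} references invalid node {child}")
                if h < heights[child]:
                    raise ValueError("merge heights must be nondecreasing from leaves to root")

    def node_heights(self) -> np.ndarray:
        h = np.zeros(2 * self.n_cohorts - 1)
        for k, (_, _, height) in enumerate(self.merges):
            h[self.n_cohorts + k] = height
        return h

    def parents(self) -> dict[int, int]:
        par: dict[int, int] = {}
        for k, (a, b, _) in enumerate(self.merges):
            par[a] = self.n_cohorts + k
            par[b] = self.n_cohorts + k
        return par

    def branch_lengths(self) -> dict[int, float]:
        """Branch length from each non-root node to its parent."""
        heights = self.node_heights()
        return {node: float(heights[p] - heights[node]) for node, p in self.parents().items()}

    def path_length(self, i: int, j: int) -> float:
        """Sum of branch lengths on the path between leaves i and j."""
        if i == j:
            return 0.0
        par, heights = self.parents(), self.node_heights()
        anc_i = {i: 0.0}
        node, acc = i, 0.0
        while node in par:
            p = par[node]
            acc += heights[p] - heights[node]
            anc_i[p] = acc
            node = p
        node, acc = j, 0.0
        while True:
            if node in anc_i:
                return acc + anc_i[node]
            p = par[node]
            acc += heights[p] - heights[node]
            node = p

    def partition_at(self, S: int) -> tuple[tuple[int, ...], ...]:
        """Ground-truth grouping with S groups: undo the S-1 highest merges."""
        n = self.n_cohorts
        if not 1 <= S <= n:
            raise ValueError(f"S must be in [1, {n}], got {S}")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        order = sorted(range(n - 1), key=lambda k: (self.merges[k][2], k))
        for k in order[: n - S]:
            a, b, _ = self.merges[k]
            root = n + k
            parent[find(a)] = root
            parent[find(b)] = root
        groups: dict[int, list[int]] = {}
        for leaf in range(n):
            groups.setdefault(find(leaf), []).append(leaf)
        return tuple(sorted(tuple(sorted(g)) for g in groups.values()))

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        heights = self.node_heights()
        labels = {i: str(i) for i in range(self.n_cohorts)}
        for k, (a, b, h) in enumerate(self.merges):
            node = self.n_cohorts + k
            la = f"{labels[a]}:{h - heights[a]:g}"
            lb = f"{labels[b]}:{h - heights[b]:g}"
            labels[node] = f"({la},{lb})"
        return labels[2 * self.n_cohorts - 2] + ";"


def generate_planted_hierarchy(
    n_cohorts: int,
    layout: str | tuple | list = "balanced",
    seed: int = 0,
) -> PlantedHierarchy:
    """Build a planted merge tree over ``n_cohorts`` cohorts.

    Parameters
    ----------
    layout
        ``"balanced"`` pairs cohorts level by level (unit height per level,
        leaf order permuted by ``seed``); ``"random"`` merges uniformly
        random cluster pairs at heights 1, 2, ...; a nested tuple such as
        ``((0, 1, 0.25), (2, 3, 0.25), 4.0)`` is an explicit tree whose
        third elements, when present, are merge heights.
    """
    if n_cohorts < 2:
        raise ValueError("n_cohorts must be >= 2")
    rng = np.random.default_rng(seed)

    if isinstance(layout, (tuple, list)):
        return PlantedHierarchy(n_cohorts, tuple(_rebuild_explicit(layout, n_cohorts)))

    if layout == "balanced":
        perm = list(rng.permutation(n_cohorts))
        clusters: list[int] = [int(c) for c in perm]
        merges = []
        next_id = n_cohorts
        level = 1.0
        while len(clusters) > 1:
            nxt: list[int] = []
            i = 0
            while i + 1 < len(clusters):
                merges.append((clusters[i], clusters[i + 1], level))
                nxt.append(next_id)
                next_id += 1
                i += 2
            if i < len(clusters):
                nxt.append(clusters[i])
            clusters = nxt
            level += 1.0
        return PlantedHierarchy(n_cohorts, tuple(merges))

    if layout == "random":
        clusters = list(range(n_cohorts))
        merges = []
        next_id = n_cohorts
        height = 1.0
        while len(clusters) > 1:
            i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
            merges.append((clusters[i], clusters[j], height))
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [next_id]
            next_id += 1
            height += 1.0
        return PlantedHierarchy(n_cohorts, tuple(merges))

    raise ValueError(f"unknown layout {layout!r}")


def _rebuild_explicit(tree, n_cohorts: int) -> list[tuple[int, int, float]]:
    """Flatten a nested-tuple tree into height-ordered merges with proper ids."""
    raw: list[tuple[object, object, float]] = []

    def walk(node) -> tuple[object, float]:
        if isinstance(node, (int, np.integer)):
            return int(node), 0.0
        if not isinstance(node, (tuple, list)) or len(node) not in (2, 3):
            raise ValueError(f"bad explicit tree node: {node!r}")
        a, ha = walk(node[0])
        b, hb = walk(node[1])
        h = float(node[2]) if len(node) == 3 else max(ha, hb) + 1.0
        if h < max(ha, hb):
            raise ValueError("explicit merge height below a child's height")
        raw.append((a, b, h))
        return ("m", len(raw) - 1), h

    walk(tree)
    leaves = {x for a, b, _ in raw for x in (a, b) if isinstance(x, int)}
    if leaves != set(range(n_cohorts)):
        raise ValueError("explicit tree leaves must be exactly 0..n_cohorts-1")
    # raw is post-order, so children precede parents; sort by height keeping
    # that property (stable sort: equal heights keep post-order)
    order = sorted(range(len(raw)), key=lambda k: raw[k][2])
    pos = {old: new for new, old in enumerate(order)}
    merges: list[tuple[int, int, float]] = []
    for old in order:
        a, b, h = raw[old]
        ia = a if isinstance(a, int) else n_cohorts + pos[a[1]]
        ib = b if isinstance(b, int) else n_cohorts + pos[b[1]]
        merges.append((int(ia), int(ib), h))
    return merges


# ---------------------------------------------------------------------------
# Cohort parameters via Brownian motion on the tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Texture parameters of one cohort and its cancer perturbation.

    ``theta`` parameterizes the normal-tissue texture; positive (cancer)
    patches are rendered from ``theta + cancer_effect * cancer_direction``.
    """

    theta: np.ndarray
    cancer_direction: np.ndarray
    cancer_effect: float

    def __post_init__(self) -> None:
        if self.cancer_effect < 0:
            raise ValueError("cancer_effect must be nonnegative")
        if self.theta.shape != self.cancer_direction.shape:
            raise ValueError("theta and cancer_direction dimensions differ")



def derive_cohort_params(
    hierarchy: PlantedHierarchy,
    sigma_walk: float = 1.0,
    cancer_effect: float = 1.5,
    shared_cancer_weight: float = 0.3,
    seed: int = 0,
    theta_dim: int = THETA_DIM,
) -> list[CohortParams]:
    """Brownian motion along the planted tree.

    Each branch adds N(0, sigma_walk^2 * branch_length) per dimension to
    theta, so E||theta_i - theta_j||^2 = theta_dim * sigma_walk^2 *
    path_length(i, j): cohorts merging low in the tree get close normal
    textures.

    The cancer direction of cohort c is the convex mix ``w * g + (1 - w) *
    u_c`` of a shared unit vector g (w = shared_cancer_weight) and a
    cohort-specific unit vector u_c built from the tree: every tree node
    carries its own direction vector, and u_c sums the node vectors on the
    path from the root to leaf c, each scaled by the square root of the
    branch length into that node (the Brownian-bridge decomposition of a
    walk along the tree). When the theta dimension allows, the node vectors
    are orthogonalized, so the cosine between two leaves' directions is a
    *deterministic* increasing function of their shared path: closely
    related cohorts share the way cancer perturbs their texture - which is
    what lets cross-cohort detection transfer follow the tree - while
    distantly related cohorts get nearly orthogonal cancer directions.
    """
    if sigma_walk < 0:
        raise ValueError("sigma_walk must be nonnegative")
    if not 0 <= shared_cancer_weight <= 1:
        raise ValueError("shared_cancer_weight must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = hierarchy.n_cohorts
    root = 2 * n - 2
    lengths = hierarchy.branch_lengths()

    def tree_walk(root_value: np.ndarray, scale: float) -> dict[int, np.ndarray]:
        values = {root: root_value}
        # merges are height-ordered, so reverse order visits parents first
        for k in range(n - 2, -1, -1):
            a, b, _ = hierarchy.merges[k]
            node = n + k
            for child in (a, b):
                step = rng.normal(0.0, 1.0, size=theta_dim) * scale * np.sqrt(
                    max(lengths[child], 0.0))
                values[child] = values[node] + step
        return values

    theta = tree_walk(rng.normal(0.0, 0.5, size=theta_dim), sigma_walk)

    def unit(v: np.ndarray) -> np.ndarray:
        nv = np.linalg.norm(v)
        return v / nv if nv > 0 else v

    # one direction vector per tree node (plus the shared g); orthogonalized
    # when the dimension allows so leaf-direction cosines are the exact
    # shared-path fractions, otherwise independent random units
    n_nodes = 2 * n - 1
    raw = rng.normal(size=(n_nodes + 1, theta_dim))
    if n_nodes + 1 <= theta_dim:
        q, _ = np.linalg.qr(raw.T)
        vecs = q.T[: n_nodes + 1]
    else:
        vecs = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    g = vecs[n_nodes]
    node_vec = {node: vecs[node] for node in range(n_nodes)}

    parents = hierarchy.parents()
    root_weight = 1.0  # variance share of the root component
    u_leaf: dict[int, np.ndarray] = {}
    for c in range(n):
        acc = np.sqrt(root_weight) * node_vec[2 * n - 2]
        node = c
        while node in parents:
            acc = acc + np.sqrt(max(lengths[node], 0.0)) * node_vec[node]
            node = parents[node]
        u_leaf[c] = unit(acc)

    params = []
    for c in range(n):
        direction = (shared_cancer_weight * g
                     + (1.0 - shared_cancer_weight) * u_leaf[c])
        params.append(CohortParams(theta[c], direction, float(cancer_effect)))
    return params


# ---------------------------------------------------------------------------
# Patch / slide rendering
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPatch:
    """One texture patch; ``assigned_label`` is inherited from the slide and
    may disagree with the hidden ``latent_state`` (noisy labels)."""

    pixels: np.ndarray  # H x W x 3, float32 in [0, 1]
    cohort_id: int
    slide_id: str
    assigned_label: int
    latent_state: str  # "normal" | "cancer"


@dataclass
class SyntheticSlide:
    slide_id: str
    patient_id: str
    cohort_id: int
    label: int  # 0 = negative, 1 = positive
    patches: list[SyntheticPatch]
    tumor_fraction: float

    @property
    def pixels(self) -> np.ndarray:
        """(n_patches, H, W, 3) stack of this slide's patches."""
        return np.stack([p.pixels for p in self.patches])


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _param_bounds(size: int) -> tuple[np.ndarray, np.ndarray]:
    """(lower, upper) bounds of the twelve rendering parameters:
    [R, G, B base color; frequency center (cycles/patch); bandwidth;
    blob rate; blob radius (px); blob darkness; R, G, B texture amplitude;
    orientation anisotropy]. Frequency is a fraction of Nyquist and blob
    count scales with patch area, so the same theta renders consistent
    texture at any patch size."""
    lo = np.array([0.30, 0.30, 0.30, 0.25 * size / 2, 0.8 * size / 32,
                   0.0, 1.2, 0.15, 0.05, 0.05, 0.05, 0.2])
    hi = np.array([0.75, 0.75, 0.75, 0.80 * size / 2, 2.2 * size / 32,
                   8.0 * (size / 32) ** 2, 3.0, 0.45, 0.25, 0.25, 0.25, 0.8])
    return lo, hi


def _param_ranges(size: int) -> np.ndarray:
    lo, hi = _param_bounds(size)
    return hi - lo


def _render_params(theta: np.ndarray, size: int) -> np.ndarray:
    """Map an unconstrained theta to valid rendering parameters."""
    lo, hi = _param_bounds(size)
    return lo + (hi - lo) * _sigmoid(theta)


# fraction of each parameter's dynamic range moved per unit cancer_effect
_CANCER_RENDER_SCALE = 0.1


def cancer_render_params(params: "CohortParams", size: int) -> np.ndarray:
    """Rendering parameters of a latent-cancer patch: the normal-tissue
    parameters shifted along the cohort's cancer direction by a fixed
    fraction of each parameter's dynamic range per unit cancer_effect.
    Operating in render space keeps the perturbation equally perceptible in
    every cohort regardless of where theta sits."""
    base = _render_params(params.theta, size)
    shift = (params.cancer_effect * _CANCER_RENDER_SCALE
             * _param_ranges(size) * params.cancer_direction)
    lo, hi = _param_bounds(size)
    return np.clip(base + shift, lo, hi)


_BAND_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _radial_freq(shape: tuple[int, int]) -> np.ndarray:
    if shape not in _BAND_CACHE:
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.rfftfreq(shape[1])[None, :]
        _BAND_CACHE[shape] = np.sqrt(fy**2 + fx**2) * shape[0]  # cycles per patch
    return _BAND_CACHE[shape]


_GRID_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_ANGLE_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _angle_weights(shape: tuple[int, int]) -> np.ndarray:
    """cos^2 of the spectral angle: 1 on the horizontal-frequency axis."""
    if shape not in _ANGLE_CACHE:
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.rfftfreq(shape[1])[None, :]
        _ANGLE_CACHE[shape] = fx**2 / np.maximum(fy**2 + fx**2, 1e-12)
    return _ANGLE_CACHE[shape]


def render_patch(p: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Render one patch from rendering parameters (see ``_param_bounds``):
    colored background + oriented band-pass noise texture + dark
    nuclei-like blobs, clipped to [0, 1]."""
    color = p[:3]
    freq, bandwidth, blob_rate, blob_radius, blob_dark = p[3:8]
    amp = p[8:11]
    aniso = p[11]
    white = rng.normal(size=(size, size))
    spec = np.fft.rfft2(white)
    r = _radial_freq((size, size))
    band = np.exp(-0.5 * ((r - freq) / bandwidth) ** 2)
    ang = _angle_weights((size, size))
    band = band * (2.0 * (aniso * ang + (1.0 - aniso) * (1.0 - ang)))
    tex = np.fft.irfft2(spec * band, s=(size, size))
    sd = tex.std()
    if sd > 0:
        tex = tex / sd
    img = color[None, None, :] + tex[:, :, None] * amp[None, None, :]

    n_blobs = rng.poisson(blob_rate)
    if n_blobs > 0:
        if size not in _GRID_CACHE:
            _GRID_CACHE[size] = np.mgrid[0:size, 0:size]
        yy, xx = _GRID_CACHE[size]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, size, size=2)
            rad = blob_radius * rng.uniform(0.8, 1.2)
            mask = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * rad**2))
            img -= blob_dark * mask[:, :, None]

    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_slide(
    params: CohortParams,
    label: int,
    patches_per_slide: int,
    tumor_fraction: float,
    rng: np.random.Generator,
    slide_id: str = "slide",
    patient_id: str = "patient",
    cohort_id: int = 0,
    patch_size: int = 32,
) -> SyntheticSlide:
    """Generate one slide as a bag of patches.

    A positive slide has exactly ``round(tumor_fraction * patches_per_slide)``
    latent-cancer patches at random positions; every patch's
    ``assigned_label`` is the slide label regardless of latent state
    (slide-inherited noisy labels). Negative slides are all-normal.
    """
    if patches_per_slide < 1:
        raise ValueError("patches_per_slide must be >= 1")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must be in [0, 1]")
    if label not in (0, 1):
        raise ValueError("label must be 0 or 1")
    eff_fraction = tumor_fraction if label == 1 else 0.0
    n_cancer = int(round(eff_fraction * patches_per_slide))
    cancer_pos = set(rng.permutation(patches_per_slide)[:n_cancer].tolist())

    p_normal = _render_params(params.theta, patch_size)
    p_cancer = cancer_render_params(params, patch_size)
    patches = []
    for k in range(patches_per_slide):
        is_cancer = k in cancer_pos
        patches.append(
            SyntheticPatch(
                pixels=render_patch(p_cancer if is_cancer else p_normal,
                                    patch_size, rng),
                cohort_id=cohort_id,
                slide_id=slide_id,
                assigned_label=label,
                latent_state="cancer" if is_cancer else "normal",
            )
        )
    return SyntheticSlide(slide_id, patient_id, cohort_id, label,
                          patches, eff_fraction)


# ---------------------------------------------------------------------------
# Whole dataset
# ---------------------------------------------------------------------------

@dataclass
class GenerationConfig:
    """Conditions of the synthetic multi-cohort corpus.

    Defaults emulate a balanced study corpus at desk scale: every cohort
    supplies the same number of positive and negative slides, positive
    slides carry 70% latent-cancer patches (tumor purity is otherwise
    unconstrained), and one patient owns one slide unless
    ``two_slides_per_patient`` pairs a positive and a negative slide under
    one patient.
    """

    n_pos_slides: int = 40
    n_neg_slides: int = 40
    patches_per_slide: int = 12
    tumor_fraction: float = 0.7
    patch_size: int = 32
    sigma_walk: float = 1.0
    cancer_effect: float = 1.5
    shared_cancer_weight: float = 0.3
    two_slides_per_patient: bool = False
    min_slides_per_class: int | None = None  # downstream sub-dataset demand

    def validate(self) -> None:
        if self.n_pos_slides < 1 or self.n_neg_slides < 1:
            raise ValueError("need at least one slide per class")
        if self.min_slides_per_class is not None and (
            self.n_pos_slides < self.min_slides_per_class
            or self.n_neg_slides < self.min_slides_per_class
        ):
            raise ValueError(
                f"sub-dataset demand ({self.min_slides_per_class}/class) exceeds "
                f"configured supply ({self.n_pos_slides} pos, {self.n_neg_slides} neg)"
            )


@dataclass
class MultiCohortDataset:
    hierarchy: PlantedHierarchy
    cohorts: dict[int, list[SyntheticSlide]]
    generation_seed: int
    params: list[CohortParams] = field(default_factory=list)

    @property
    def n_cohorts(self) -> int:
        return self.hierarchy.n_cohorts

    def slides(self, cohort_id: int, label: int | None = None) -> list[SyntheticSlide]:
        out = self.cohorts[cohort_id]
        if label is None:
            return list(out)
        return [s for s in out if s.label == label]


def generate_dataset(
    hierarchy: PlantedHierarchy,
    config: GenerationConfig,
    seed: int,
) -> MultiCohortDataset:
    """Generate the full multi-cohort corpus, deterministic given seed."""
    config.validate()
    root_ss = np.random.SeedSequence(seed)
    param_seed = int(root_ss.spawn(1)[0].generate_state(1)[0] % 2**31)
    params = derive_cohort_params(
        hierarchy,
        sigma_walk=config.sigma_walk,
        cancer_effect=config.cancer_effect,
        shared_cancer_weight=config.shared_cancer_weight,
        seed=param_seed,
    )

    cohorts: dict[int, list[SyntheticSlide]] = {}
    for c in range(hierarchy.n_cohorts):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 1000 + c)))
        slides: list[SyntheticSlide] = []
        if config.two_slides_per_patient:
            n_patients = max(config.n_pos_slides, config.n_neg_slides)
            for k in range(n_patients):
                pid = f"P{c:02d}_{k:04d}"
                if k < config.n_pos_slides:
                    slides.append(generate_slide(
                        params[c], 1, config.patches_per_slide, config.tumor_fraction,
                        rng, slide_id=f"C{c:02d}S{k:04d}p", patient_id=pid,
                        cohort_id=c, patch_size=config.patch_size))
                if k < config.n_neg_slides:
                    slides.append(generate_slide(
                        params[c], 0, config.patches_per_slide, config.tumor_fraction,
                        rng, slide_id=f"C{c:02d}S{k:04d}n", patient_id=pid,
                        cohort_id=c, patch_size=config.patch_size))
        else:
            k = 0
            for label, count in ((1, config.n_pos_slides), (0, config.n_neg_slides)):
                for _ in range(count):
                    tag = "p" if label == 1 else "n"
                    slides.append(generate_slide(
                        params[c], label, config.patches_per_slide,
                        config.tumor_fraction, rng,
                        slide_id=f"C{c:02d}S{k:04d}{tag}",
                        patient_id=f"P{c:02d}_{k:04d}",
                        cohort_id=c, patch_size=config.patch_size))
                    k += 1
        cohorts[c] = slides
    return MultiCohortDataset(hierarchy, cohorts, seed, params)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def manifest(dataset: MultiCohortDataset) -> pd.DataFrame:
    rows = [
        {
            "slide_id": s.slide_id, "patient_id": s.patient_id,
            "cohort_id": s.cohort_id, "label": s.label,
            "n_patches": len(s.patches), "tumor_fraction": s.tumor_fraction,
        }
        for c in sorted(dataset.cohorts) for s in dataset.cohorts[c]
    ]
    return pd.DataFrame(rows)


def save_dataset(dataset: MultiCohortDataset, prefix: str) -> None:
    """Persist as <prefix>.npz (pixels), <prefix>.csv (manifest), and
    <prefix>.nwk (planted hierarchy as Newick)."""
    arrays: dict[str, np.ndarray] = {}
    for c in sorted(dataset.cohorts):
        for s in dataset.cohorts[c]:
            arrays[f"pixels/{s.slide_id}"] = s.pixels
            arrays[f"latent/{s.slide_id}"] = np.array(
                [p.latent_state == "cancer" for p in s.patches], dtype=bool)
    meta = {
        "generation_seed": dataset.generation_seed,
        "n_cohorts": dataset.n_cohorts,
        "merges": [list(m) for m in dataset.hierarchy.merges],
    }
    np.savez_compressed(prefix + ".npz", __meta__=json.dumps(meta), **arrays)
    manifest(dataset).to_csv(prefix + ".csv", index=False)
    with open(prefix + ".nwk", "w") as fh:
        fh.write(dataset.hierarchy.to_newick() + "\n")


def load_dataset(prefix: str) -> MultiCohortDataset:
    npz = np.load(prefix + ".npz")
    meta = json.loads(str(npz["__meta__"]))
    hierarchy = PlantedHierarchy(
        meta["n_cohorts"], tuple((int(a), int(b), float(h)) for a, b, h in meta["merges"]))
    man = pd.read_csv(prefix + ".csv")
    cohorts: dict[int, list[SyntheticSlide]] = {c: [] for c in range(meta["n_cohorts"])}
    for row in man.itertuples():
        pix = npz[f"pixels/{row.slide_id}"]
        latent = npz[f"latent/{row.slide_id}"]
        patches = [
            SyntheticPatch(pix[k], int(row.cohort_id), row.slide_id,
                           int(row.label), "cancer" if latent[k] else "normal")
            for k in range(pix.shape[0])
        ]
        cohorts[int(row.cohort_id)].append(SyntheticSlide(
            row.slide_id, row.patient_id, int(row.cohort_id), int(row.label),
            patches, float(row.tumor_fraction)))
    return MultiCohortDataset(hierarchy, cohorts, int(meta["generation_seed"]))


def dataset_digest(dataset: MultiCohortDataset) -> str:
    """SHA-256 over all pixel bytes and slide metadata (reproducibility check)."""
    h = hashlib.sha256()
    for c in sorted(dataset.cohorts):
        for s in dataset.cohorts[c]:
            h.update(s.slide_id.encode())
            h.update(s.patient_id.encode())
            h.update(bytes([s.label]))
            h.update(s.pixels.tobytes())
    return h.hexdigest()
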