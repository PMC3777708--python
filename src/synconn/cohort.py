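"""Synthetic two-group cohort generator.

Generates node sets, paired functional/structural connectomes and phenotype
tables with the statistical structure the downstream analysis assumes, so
the whole pipeline is testable without access to subject data.

Functional model
----------------
Node time series follow a low-rank factor model sampled i.i.d. over time
points:

    x_i(t) = a_i f_{m(i)}(t) + b_i f_{sec(i)}(t) + s_{m(i)} g_i h(t) + e_i(t)

with one latent factor f_m per planted module, a signed global factor h
(half the modules load positively, half negatively, producing mildly
anticorrelated module pairs, as between task-positive and default-mode
systems), sparse positive cross-loadings b_i ("connector" nodes, which keep
thresholded graphs connected across anticorrelated blocks), and white
residual noise scaled so every node has unit variance. The population
correlation between two nodes is then exactly the inner product of their
loading vectors, which makes the group-mean within-module and between-module
edge strengths calibrable in closed form: per group, two scale parameters
(module loading scale and global-factor scale) are solved so the population
means equal the configured Fisher-z targets.

Structural model
----------------
Fiber counts are negative-binomial (gamma-Poisson), with log-rate
    log mu_ij = intercept - d_ij / decay + within-module boost
                + long-range tract boost + group offset + c * z_ij
where d is inter-node Euclidean distance, spatial modules come from
k-means on node coordinates (~9 locally clustered communities), and the
coupling coefficient c is calibrated by bisection so the per-subject Pearson
correlation between fiber counts and functional z over mask-eligible edges
hits the configured target (r ~ 0.32 by default). The intercept is
calibrated so the expected fraction of nonzero edges matches the configured
unthresholded density.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.cluster import KMeans

from ._seeds import child_int_seed, child_rng
from .community import Partition
from .connectivity import FunctionalConnectome, StructuralConnectome, build_functional_matrix
from .exceptions import ConfigError, DataError

__all__ = [
    "NodeSet",
    "CohortConfig",
    "Cohort",
    "generate_node_set",
    "generate_functional_cohort",
    "generate_structural_cohort",
    "generate_phenotypes",
    "generate_cohort",
    "block_edge_means",
]

GROUP_A = "TD-like"
GROUP_B = "ASD-like"

# printed scale conventions for the four severity subscales:
# (mean, sd, minimum, maximum)
_SEVERITY_SCALES = {
    "ados_social": (7.5, 2.6, 1, 14),
    "ados_comm": (3.8, 1.6, 1, 8),
    "adi_social": (19.0, 5.5, 8, 30),
    "adi_comm": (15.0, 4.5, 7, 26),
}


@dataclass(frozen=True)
class NodeSet:
    """Parcellation nodes: id, MNI-like coordinate (mm), label, sphere radius."""

    coordinates: np.ndarray
    labels: tuple[str, ...]
    sphere_radius: float = 5.0

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
            raise ConfigError("node set needs >= 2 nodes with 3-D coordinates")
        if not np.all(np.isfinite(coords)):
            raise ConfigError("node coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != coords.shape[0]:
            raise ConfigError("one label per node required")

    @property
    def n_nodes(self) -> int:
        return self.coordinates.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances, mm."""
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.linalg.norm(diff, axis=2)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "x": self.coordinates[:, 0],
                "y": self.coordinates[:, 1],
                "z": self.coordinates[:, 2],
                "label": list(self.labels),
            }
        )


def generate_node_set(n_nodes: int, seed: int = 0, sphere_radius: float = 5.0) -> NodeSet:
    """Uniformly scattered nodes in an MNI-sized bounding box."""
    if n_nodes < 2:
        raise ConfigError("n_nodes must be >= 2")
    rng = child_rng(seed, "node-set")
    lo = np.array([-70.0, -105.0, -45.0])
    hi = np.array([70.0, 70.0, 75.0])
    coords = rng.uniform(lo, hi, size=(n_nodes, 3))
    labels = tuple(f"ROI_{i:03d}" for i in range(n_nodes))
    return NodeSet(coordinates=coords, labels=labels, sphere_radius=sphere_radius)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort, with defaults matching the study
    conditions being emulated (264-node parcellation, 120 time points,
    4 planted functional modules, ~9 spatially local structural modules,
    group-mean within-module z of 0.26 vs 0.16, structure-function coupling
    r = 0.32)."""

    n_per_group: int = 35
    n_nodes: int = 264
    n_timepoints: int = 120
    functional_module_sizes: tuple[int, ...] | None = None  # None -> 4 near-equal
    structural_module_count: int = 9
    # group order is (TD-like, ASD-like)
    within_module_mean_z: tuple[float, float] = (0.26, 0.16)
    between_module_mean_z: tuple[float, float] = (-0.03, -0.015)
    loading_cv: float = 0.15  # node-loading spread -> between-edge variance
    subject_sd: float = 0.08  # subject scale jitter -> between-subject variance
    bridge_fraction: float = 0.3
    bridge_strength: float = 0.35
    anchor_strength: float = 0.45  # shared variance of each anchor pair
    cross_anchor_strength: float = 0.4  # shared variance of cross-module anchors
    # structural generator
    fiber_decay_scale_mm: float = 10.0
    fiber_dispersion: float = 8.0
    fiber_density: float = 0.10  # unthresholded fraction of nonzero edges
    fiber_within_boost: float = 3.0  # log-rate boost inside a spatial module
    fiber_log_jitter_sd: float = 0.8  # edge-level log-rate spread (heavy-tailed counts)
    fiber_long_range_fraction: float = 0.02
    structure_function_coupling: float = 0.32
    fiber_count_group_log_effect: float = 0.05  # ASD-like log-rate offset
    fa_group_effect: float = -0.01  # ASD-like mean FA offset
    md_group_effect: float = 1.0e-5  # ASD-like mean MD offset (mm^2/s)
    fiber_mask_threshold: float = 5.0
    # phenotypes
    age_range: tuple[float, float] = (9.0, 18.0)
    motion_mean: float = 0.10
    motion_sd: float = 0.06
    motion_min: float = 0.03
    severity_latent_corr: float = -0.4
    seed: int = 0

    def module_sizes(self) -> tuple[int, ...]:
        if self.functional_module_sizes is not None:
            sizes = tuple(int(s) for s in self.functional_module_sizes)
        else:
            base = self.n_nodes // 4
            rem = self.n_nodes - 4 * base
            sizes = tuple(base + (1 if i < rem else 0) for i in range(4))
        return sizes

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        if self.n_nodes < 2:
            raise ConfigError("n_nodes must be >= 2")
        if self.n_timepoints < 3:
            raise ConfigError("n_timepoints must be >= 3")
        sizes = self.module_sizes()
        if any(s < 1 for s in sizes) or sum(sizes) != self.n_nodes:
            raise ConfigError("functional module sizes must be positive and sum to n_nodes")
        if len(sizes) < 2:
            raise ConfigError("need at least 2 functional modules")
        if not (-1.0 < self.structure_function_coupling < 1.0):
            raise ConfigError("structure_function_coupling must lie in (-1, 1)")
        if self.fiber_density < 0 or self.fiber_dispersion <= 0 or self.fiber_decay_scale_mm <= 0:
            raise ConfigError("fiber rate parameters must be positive (density may be 0)")
        if not (2 <= self.structural_module_count <= self.n_nodes):
            raise ConfigError("structural_module_count out of range")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be increasing")
        for g in range(2):
            if not (0 < math.tanh(self.within_module_mean_z[g]) < 1):
                raise ConfigError("within-module mean z targets must be positive")
        if not (0 <= self.anchor_strength < 0.8):
            raise ConfigError("anchor_strength must lie in [0, 0.8)")
        if self.anchor_strength + max(math.tanh(z) for z in self.within_module_mean_z) > 0.95:
            raise ConfigError(
                "implied covariance would not be positive definite: "
                "anchor_strength plus the within-module correlation target "
                "exceeds the unit variance budget"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """A generated cohort bundle (functional, structural, phenotypes)."""

    config: CohortConfig
    node_set: NodeSet
    groups: np.ndarray  # 0 = TD-like, 1 = ASD-like
    subject_ids: list[str]
    timeseries: list[np.ndarray]  # T x N per subject
    functional: list[FunctionalConnectome] = field(default_factory=list)
    structural: list[StructuralConnectome] = field(default_factory=list)
    phenotypes: pd.DataFrame | None = None
    planted_functional_partition: Partition | None = None
    planted_structural_partition: Partition | None = None
    subject_latent: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def group_labels(self) -> list[str]:
        return [GROUP_A if g == 0 else GROUP_B for g in self.groups]

    def functional_weights(self) -> list[np.ndarray]:
        return [f.weights for f in self.functional]

    def average_functional(self) -> np.ndarray:
        return np.mean([f.weights for f in self.functional], axis=0)


# ---------------------------------------------------------------- functional


def _simplex_directions(n_mod: int) -> np.ndarray:
    """Rows: unit vectors of a regular simplex, pairwise dot -1/(n_mod - 1).

    Loading each module on its own simplex direction makes every
    between-module pair equally (mildly) anticorrelated, with no two modules
    coupled more than any other pair.
    """
    e = np.eye(n_mod) - 1.0 / n_mod
    u, s, _ = np.linalg.svd(e, full_matrices=False)
    basis = (u[:, : n_mod - 1] * s[: n_mod - 1])  # n_mod x (n_mod - 1)
    return basis / np.linalg.norm(basis, axis=1, keepdims=True)


def _architecture(config: CohortConfig, rng: np.random.Generator):
    """Cohort-level loading architecture shared by the two groups."""
    sizes = config.module_sizes()
    n_mod = len(sizes)
    labels = np.repeat(np.arange(n_mod), sizes)
    simplex = _simplex_directions(n_mod)
    # base module loadings around 1 (rescaled per group below); the clip keeps
    # every node firmly attached to its module once thresholded
    base = np.clip(1.0 + config.loading_cv * rng.standard_normal(config.n_nodes), 0.75, 1.35)
    # bridge (connector) nodes: positive cross-loading on one other module.
    # Secondary modules are dealt round-robin over the ordered module pairs so
    # every pair of modules is bridged by several connectors (what keeps
    # thresholded graphs connected across the anticorrelated blocks).
    n_bridge = int(round(config.bridge_fraction * config.n_nodes))
    bridge_idx = rng.choice(config.n_nodes, size=n_bridge, replace=False)
    sec = np.full(config.n_nodes, -1, dtype=int)
    beta = np.zeros(config.n_nodes)
    offset = np.zeros(n_mod, dtype=int)
    for i in bridge_idx:
        m = labels[i]
        others = [o for o in range(n_mod) if o != m]
        sec[i] = others[offset[m] % len(others)]
        offset[m] += 1
        beta[i] = min(rng.uniform(0.6, 1.1) * config.bridge_strength, 0.4)
    # per-node jitter on the simplex-factor loading
    gjit = np.clip(1.0 + 0.1 * rng.standard_normal(config.n_nodes), 0.8, 1.1)
    # anchor triples: every node shares one dedicated strong factor with two
    # module mates. This emulates the very strong short-range couplings of
    # real parcellations and guarantees each node a couple of edges far above
    # the thresholding cutoff, keeping graphs connected at the low end of the
    # sparsity grid (a whole triple detaching would need three simultaneous
    # node-level sampling failures).
    anchors: list[tuple[int, ...]] = []
    for m in range(n_mod):
        members = rng.permutation(np.flatnonzero(labels == m))
        k = len(members)
        if k < 2:
            continue
        groups = [tuple(members[i : i + 3]) for i in range(0, k - (k % 3), 3)]
        if k % 3 and groups:
            groups[-1] = groups[-1] + tuple(members[-(k % 3):])  # fold remainder in
        elif k % 3:
            groups = [tuple(members)]
        anchors.extend(groups)
    # cross-module anchors: a couple of dedicated strong pair factors per
    # module pair (endpoints used at most once), guaranteeing that no module
    # can detach wholesale from the rest at the lowest grid sparsity
    cross_anchors: list[tuple[int, int]] = []
    queues = {
        m: list(rng.permutation(np.flatnonzero(labels == m))) for m in range(n_mod)
    }
    per_pair = 2 if min(sizes) >= 12 else 1
    for m in range(n_mod):
        for mp in range(m + 1, n_mod):
            for _ in range(per_pair):
                if not queues[m] or not queues[mp]:
                    continue
                cross_anchors.append((int(queues[m].pop()), int(queues[mp].pop())))
    return {
        "labels": labels,
        "simplex": simplex,
        "base": base,
        "sec": sec,
        "beta": beta,
        "gjit": gjit,
        "n_mod": n_mod,
        "anchors": anchors,
        "cross_anchors": cross_anchors,
        "anchor_strength": config.anchor_strength,
        "cross_anchor_strength": config.cross_anchor_strength,
    }


def _loading_matrix(arch: dict, alpha_scale: float, gamma_scale: float) -> np.ndarray:
    """Factor-loading matrix for given group scales.

    Columns: two sub-factors per module (loaded equally, 1/sqrt(2) each:
    population correlations are identical to a single factor, but a node's
    sampling fluctuation against its module signal halves in variance),
    the (n_mod - 1)-dimensional simplex subspace, and one fixed-strength
    factor per anchor pair/triple. Rows whose squared loadings approach the
    unit variance budget are rescaled to keep residual variance positive.
    """
    n = arch["labels"].size
    n_mod = arch["n_mod"]
    anchors = arch["anchors"]
    L = np.zeros((n, 2 * n_mod + (n_mod - 1) + len(anchors) + len(arch["cross_anchors"])))
    rows = np.arange(n)
    half = 1.0 / math.sqrt(2.0)
    L[rows, 2 * arch["labels"]] = alpha_scale * arch["base"] * half
    L[rows, 2 * arch["labels"] + 1] = alpha_scale * arch["base"] * half
    bridge = np.flatnonzero(arch["sec"] >= 0)
    L[bridge, 2 * arch["sec"][bridge]] += arch["beta"][bridge] * half
    L[bridge, 2 * arch["sec"][bridge] + 1] += arch["beta"][bridge] * half
    L[:, 2 * n_mod : 3 * n_mod - 1] = (
        gamma_scale * arch["gjit"][:, None] * arch["simplex"][arch["labels"]]
    )
    root = math.sqrt(arch["anchor_strength"])
    for a, members in enumerate(anchors):
        L[list(members), 3 * n_mod - 1 + a] = root
    cross = arch["cross_anchors"]
    croot = math.sqrt(arch["cross_anchor_strength"])
    base_col = 3 * n_mod - 1 + len(anchors)
    for a, (i, j) in enumerate(cross):
        L[[i, j], base_col + a] = croot
    budget = (L**2).sum(axis=1)
    over = budget > 0.93
    if np.any(over):
        L[over] *= np.sqrt(0.93 / budget[over])[:, None]
    return L


def _population_block_means(arch: dict, L: np.ndarray) -> tuple[float, float]:
    """Population mean Fisher-z over within- and between-module pairs."""
    rho = np.clip(L @ L.T, -0.99, 0.99)
    z = np.arctanh(rho)
    labels = arch["labels"]
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(labels.size, k=1)
    within = z[iu][same[iu]]
    between = z[iu][~same[iu]]
    return float(within.mean()), float(between.mean())


def _calibrate_group_scales(config: CohortConfig, arch: dict, group: int) -> tuple[float, float]:
    """Solve (alpha_scale, gamma_scale) so population block means hit targets."""
    target_w = config.within_module_mean_z[group]
    target_b = config.between_module_mean_z[group]

    def residuals(v):
        a, g = abs(v[0]), abs(v[1])
        w, b = _population_block_means(arch, _loading_matrix(arch, a, g))
        return [w - target_w, b - target_b]

    sol = scipy.optimize.root(residuals, x0=[0.3, 0.3], method="hybr")
    alpha, gamma = float(abs(sol.x[0])), float(abs(sol.x[1]))
    final = residuals([alpha, gamma])
    if max(abs(final[0]), abs(final[1])) > 0.01:
        raise ConfigError(
            "could not calibrate loadings to the configured within/between block "
            f"means (residual {final}); targets are infeasible for this architecture"
        )
    return alpha, gamma


def generate_functional_cohort(config: CohortConfig) -> Cohort:
    """Per-subject node time series plus planted structure and latents.

    Subjects 0..n-1 are TD-like, n..2n-1 ASD-like. Each subject's module
    loadings are jittered by a scalar latent (1 + delta), delta ~
    N(0, subject_sd); delta is returned as the subject latent factor and is
    what severity scores are planted against.
    """
    config.validate()
    node_set = generate_node_set(config.n_nodes, seed=child_int_seed(config.seed, "nodes"))
    rng_arch = child_rng(config.seed, "architecture")
    arch = _architecture(config, rng_arch)
    scales = [_calibrate_group_scales(config, arch, g) for g in range(2)]

    n = config.n_per_group
    groups = np.repeat([0, 1], n)
    subject_ids = [f"sub-{i:03d}" for i in range(2 * n)]
    rng_subj = child_rng(config.seed, "subject-latents")
    latents = rng_subj.normal(0.0, config.subject_sd, size=2 * n)

    timeseries = []
    for s in range(2 * n):
        alpha, gamma = scales[groups[s]]
        delta = float(np.clip(latents[s], -0.45, 0.45))
        L = _loading_matrix(arch, alpha * (1.0 + delta), gamma)
        resid = 1.0 - (L**2).sum(axis=1)
        if np.any(resid <= 0):  # extreme latent pushed loadings past unit variance
            scale = math.sqrt(0.95 / float((L**2).sum(axis=1).max()))
            L = L * scale
            resid = 1.0 - (L**2).sum(axis=1)
        rng_s = child_rng(config.seed, f"timeseries-{s}")
        f = rng_s.standard_normal((config.n_timepoints, L.shape[1]))
        e = rng_s.standard_normal((config.n_timepoints, config.n_nodes))
        x = f @ L.T + e * np.sqrt(resid)
        timeseries.append(x)

    planted = Partition(arch["labels"])
    return Cohort(
        config=config,
        node_set=node_set,
        groups=groups,
        subject_ids=subject_ids,
        timeseries=timeseries,
        planted_functional_partition=planted,
        subject_latent=latents,
        diagnostics={
            "group_scales": {GROUP_A: scales[0], GROUP_B: scales[1]},
            "module_sizes": config.module_sizes(),
        },
    )


def block_edge_means(z: np.ndarray, partition: Partition) -> tuple[float, float]:
    """Mean Fisher-z over within-module and between-module edges."""
    labels = partition.labels
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    vals = np.asarray(z)[iu]
    return float(vals[same[iu]].mean()), float(vals[~same[iu]].mean())


# ---------------------------------------------------------------- structural


def _nb_p_zero(mu: np.ndarray, k: float) -> np.ndarray:
    return (k / (k + mu)) ** k


def _structural_log_rate(config: CohortConfig, node_set: NodeSet, rng: np.random.Generator):
    """Subject-independent part of the log fiber rate, plus the spatial partition."""
    d = node_set.distances()
    km = KMeans(
        n_clusters=config.structural_module_count,
        n_init=4,
        random_state=child_int_seed(config.seed, "spatial-kmeans"),
    ).fit(node_set.coordinates)
    spatial = Partition(km.labels_)
    same = spatial.labels[:, None] == spatial.labels[None, :]
    eta = -d / config.fiber_decay_scale_mm + config.fiber_within_boost * same
    n = node_set.n_nodes
    iu = np.triu_indices(n, k=1)
    # edge-level log-rate jitter shared across subjects: real fiber counts
    # are heavy-tailed
    if config.fiber_log_jitter_sd > 0:
        jit = np.zeros((n, n))
        jit[iu] = rng.normal(0.0, config.fiber_log_jitter_sd, size=iu[0].size)
        eta = eta + jit + jit.T
    # long-range "tracts": a small set of distant pairs carries fiber counts
    # near the top of the distribution (as homotopic and association tracts
    # do), which keeps low-sparsity structural graphs from fragmenting into
    # spatial clumps
    n_tract = int(round(config.fiber_long_range_fraction * iu[0].size))
    high = float(np.quantile(eta[iu], 0.97))
    if n_tract > 0:
        far = np.argsort(d[iu])[-(4 * n_tract):]  # among the 4x most distant pairs
        chosen = rng.choice(far, size=n_tract, replace=False)
        vals = high + rng.normal(0.5, 0.8, size=n_tract)
        tract = np.zeros((n, n))
        tract[iu[0][chosen], iu[1][chosen]] = vals - eta[iu[0][chosen], iu[1][chosen]]
        eta = eta + tract + tract.T
    # a strong short-range web along the Euclidean minimum spanning tree
    # (u-fiber-like local connections): guarantees the binarized graph stays
    # connected at the low end of the structural sparsity grid
    import scipy.sparse.csgraph as _csgraph

    mst = _csgraph.minimum_spanning_tree(d).toarray()
    mi, mj = np.nonzero(mst)
    boost = high + rng.normal(2.2, 0.3, size=mi.size)
    eta[mi, mj] = np.maximum(eta[mi, mj], boost)
    eta[mj, mi] = eta[mi, mj]
    # cap the rate scale so no single edge dominates count variance
    eta = np.minimum(eta, high + 2.4)
    np.fill_diagonal(eta, -np.inf)
    return eta, spatial


def _subject_log_rates(config, eta_base, z_list, groups, coupling_coef, intercept):
    rates = []
    for s, z in enumerate(z_list):
        eta = eta_base + intercept + coupling_coef * (z - z.mean())
        if groups[s] == 1:
            eta = eta + config.fiber_count_group_log_effect
        rates.append(np.exp(eta))
    return rates


def _expected_density(rates, k: float) -> float:
    iu = np.triu_indices(rates[0].shape[0], k=1)
    pnz = [1.0 - _nb_p_zero(r[iu], k) for r in rates]
    return float(np.mean(pnz))


def _calibrate_intercept(config, eta_base, z_list, groups, coupling_coef) -> float:
    def f(b):
        rates = _subject_log_rates(config, eta_base, z_list, groups, coupling_coef, b)
        return _expected_density(rates, config.fiber_dispersion) - config.fiber_density

    return float(scipy.optimize.brentq(f, -15.0, 15.0, xtol=1e-4))


def _draw_counts(rate: np.ndarray, k: float, rng: np.random.Generator) -> np.ndarray:
    """Symmetric negative-binomial (gamma-Poisson) counts for one subject."""
    n = rate.shape[0]
    iu = np.triu_indices(n, k=1)
    mu = rate[iu]
    lam = rng.gamma(shape=k, scale=mu / k)
    c = rng.poisson(lam)
    out = np.zeros((n, n), dtype=np.int64)
    out[iu] = c
    return out + out.T


def _mean_coupling_r(config, eta_base, z_list, groups, c, rng, n_reps: int = 2) -> float:
    """Mean per-subject Pearson r between counts and z on mask-eligible edges."""
    b = _calibrate_intercept(config, eta_base, z_list, groups, c)
    rates = _subject_log_rates(config, eta_base, z_list, groups, c, b)
    iu = np.triu_indices(rates[0].shape[0], k=1)
    rs = []
    for _ in range(n_reps):
        counts = [_draw_counts(r, config.fiber_dispersion, rng) for r in rates]
        mask = np.mean(counts, axis=0) >= config.fiber_mask_threshold
        keep = mask[iu]
        if keep.sum() < 3:
            continue
        for cnt, z in zip(counts, z_list):
            cv, zv = cnt[iu][keep].astype(float), z[iu][keep]
            if cv.std() == 0 or zv.std() == 0:
                continue
            rs.append(np.corrcoef(cv, zv)[0, 1])
    return float(np.mean(rs)) if rs else 0.0


def generate_structural_cohort(
    config: CohortConfig,
    node_set: NodeSet,
    functional_z: list[np.ndarray],
    groups: np.ndarray,
) -> tuple[list[StructuralConnectome], Partition, dict]:
    """Structural connectomes coupled to the given functional z matrices.

    Returns the per-subject connectomes, the planted spatial partition and a
    diagnostics dict (calibrated coupling coefficient and intercept).
    """
    config.validate()
    if len(functional_z) != len(groups):
        raise DataError("one functional matrix per subject required")
    for z in functional_z:
        if z.shape != (node_set.n_nodes, node_set.n_nodes):
            raise DataError("functional matrices must share the cohort node set")
    rng_struct = child_rng(config.seed, "structural-base")
    eta_base, spatial = _structural_log_rate(config, node_set, rng_struct)
    n = node_set.n_nodes

    if config.fiber_density == 0:
        warnings.warn("fiber_density is 0: structural matrices are empty", stacklevel=2)
        zeros = np.zeros((n, n), dtype=np.int64)
        nanm = np.full((n, n), np.nan)
        conns = [
            StructuralConnectome(zeros.copy(), nanm.copy(), nanm.copy(), subject_id=f"sub-{s:03d}")
            for s in range(len(groups))
        ]
        return conns, spatial, {"coupling_coefficient": 0.0, "intercept": -np.inf}

    target = config.structure_function_coupling
    if target == 0.0:
        coef = 0.0
    else:
        # calibrate the coupling coefficient on a subject subsample with a
        # dedicated generator: the mean count-vs-z correlation rises
        # monotonically with the coefficient until it plateaus
        half = min(10, (len(groups) + 1) // 2)
        sub_idx = sorted(
            set(list(range(half)) + list(range(len(groups) - half, len(groups))))
        )
        z_sub = [functional_z[i] for i in sub_idx]
        g_sub = np.asarray(groups)[sub_idx]

        def f(c):
            rng_cal = child_rng(config.seed, f"coupling-cal-{c:.6f}")
            return _mean_coupling_r(config, eta_base, z_sub, g_sub, c, rng_cal)

        # scan outward until the (noisily evaluated, eventually plateauing)
        # response first crosses the target, then interpolate linearly
        sign = 1.0 if target > 0 else -1.0
        step = 0.5 * sign
        c_prev, r_prev = 0.0, 0.0
        coef = None
        for k in range(1, 17):
            c_next = k * step
            r_next = f(c_next)
            if sign * r_next >= sign * target:
                # refine inside the bracketing interval
                lo, r_lo, hi, r_hi = c_prev, r_prev, c_next, r_next
                for _ in range(4):
                    mid = 0.5 * (lo + hi)
                    r_mid = f(mid)
                    if sign * r_mid >= sign * target:
                        hi, r_hi = mid, r_mid
                    else:
                        lo, r_lo = mid, r_mid
                frac = (target - r_lo) / (r_hi - r_lo) if r_hi != r_lo else 0.5
                coef = float(lo + frac * (hi - lo))
                break
            c_prev, r_prev = c_next, r_next
        if coef is None:
            raise ConfigError(
                f"could not calibrate structure-function coupling to r = {target}: "
                f"response saturates near r = {r_prev:.3f}"
            )

    intercept = _calibrate_intercept(config, eta_base, functional_z, groups, coef)
    rates = _subject_log_rates(config, eta_base, functional_z, groups, coef, intercept)

    d = node_set.distances()
    iu = np.triu_indices(n, k=1)
    conns = []
    for s, rate in enumerate(rates):
        rng_s = child_rng(config.seed, f"fibers-{s}")
        counts = _draw_counts(rate, config.fiber_dispersion, rng_s)
        fa = np.full((n, n), np.nan)
        md = np.full((n, n), np.nan)
        nz = counts[iu] > 0
        n_nz = int(nz.sum())
        if n_nz:
            fa_mu = 0.45 - 0.0008 * d[iu][nz] + (config.fa_group_effect if groups[s] == 1 else 0.0)
            fa_v = np.clip(fa_mu + rng_s.normal(0.0, 0.04, size=n_nz), 0.05, 0.95)
            md_mu = 8.0e-4 + (config.md_group_effect if groups[s] == 1 else 0.0)
            md_v = np.clip(md_mu + rng_s.normal(0.0, 4.0e-5, size=n_nz), 1.0e-4, None)
            ii, jj = iu[0][nz], iu[1][nz]
            fa[ii, jj] = fa[jj, ii] = fa_v
            md[ii, jj] = md[jj, ii] = md_v
        conns.append(
            StructuralConnectome(
                fiber_count=counts, fa_mean=fa, md_mean=md, subject_id=f"sub-{s:03d}"
            )
        )
    return conns, spatial, {"coupling_coefficient": coef, "intercept": intercept}


# ---------------------------------------------------------------- phenotypes


def generate_phenotypes(
    config: CohortConfig,
    groups: np.ndarray | None = None,
    latents: np.ndarray | None = None,
) -> pd.DataFrame:
    """Phenotype table: group, age, motion summaries, severity subscales.

    Severity subscales exist only for ASD-like subjects and are planted to
    correlate (Pearson ``severity_latent_corr``) with the standardized
    subject latent network factor; with the default negative sign, subjects
    with weaker planted connectivity score as more severe.
    """
    config.validate()
    n = config.n_per_group
    if groups is None:
        groups = np.repeat([0, 1], n)
    groups = np.asarray(groups)
    n_sub = groups.size
    rng = child_rng(config.seed, "phenotypes")
    if latents is None:
        latents = rng.normal(0.0, config.subject_sd, size=n_sub)
    lat_std = (latents - latents.mean()) / (latents.std() if latents.std() > 0 else 1.0)

    age = rng.uniform(*config.age_range, size=n_sub)
    mean_motion = np.clip(
        rng.normal(config.motion_mean, config.motion_sd, size=n_sub), config.motion_min, None
    )
    max_motion = mean_motion * rng.uniform(4.0, 9.0, size=n_sub)

    rho = config.severity_latent_corr
    rows = {
        "subject_id": [f"sub-{i:03d}" for i in range(n_sub)],
        "group": [GROUP_A if g == 0 else GROUP_B for g in groups],
        "age": np.round(age, 2),
        "mean_motion": np.round(mean_motion, 4),
        "max_motion": np.round(max_motion, 4),
    }
    for name, (mu, sd, lo, hi) in _SEVERITY_SCALES.items():
        noise = rng.standard_normal(n_sub)
        latent_part = rho * lat_std + math.sqrt(max(1.0 - rho**2, 0.0)) * noise
        score = np.clip(np.round(mu + sd * latent_part), lo, hi)
        score[groups == 0] = np.nan
        rows[name] = score
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- everything


def generate_cohort(config: CohortConfig, with_structural: bool = True) -> Cohort:
    """Full synthetic cohort: time series, z matrices, fibers, phenotypes."""
    cohort = generate_functional_cohort(config)
    cohort.functional = [
        build_functional_matrix(ts, subject_id=sid)
        for ts, sid in zip(cohort.timeseries, cohort.subject_ids)
    ]
    if with_structural:
        conns, spatial, diag = generate_structural_cohort(
            config, cohort.node_set, cohort.functional_weights(), cohort.groups
        )
        cohort.structural = conns
        cohort.planted_structural_partition = spatial
        cohort.diagnostics.update(diag)
    cohort.phenotypes = generate_phenotypes(config, cohort.groups, cohort.subject_latent)
    return cohort
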