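"""Synthetic cohorts of BOLD-like time series on planted networks.

This module defines the study conditions every downstream stage is tested
on: a pediatric-like cohort of ~26 subjects whose brain-network size varies
with a nuisance covariate (age / cortical volume), while a scale-invariant
small-world topology parameter (the Watts–Strogatz rewiring probability
``beta``) carries the real association with the continuous outcome
("IQ").  Raw global metrics are thereby confounded by network scale;
metrics normalized to size-matched random networks recover the planted
association.

Generative model
----------------
* **Planted network** — a weighted Watts–Strogatz ring lattice of
  ``mean_degree`` neighbors, edges rewired with probability ``beta`` at
  the subject's own node count.  Outcome-neutral heterogeneity axes —
  hub-biased rewiring targets, triadic closure, per-subject edge-weight
  skew — emulate clinically realistic inter-subject variability.
* **BOLD signals** — a zero-mean Gaussian graph moving-average process:
  ``x_i = alpha z_i + sum_j B_ij z_j + gamma u + noise e_i`` with
  ``B_ij = sqrt(g^2 w_ij / s_i)`` (``s_i`` the node strength,
  ``alpha^2 + g^2 = 1``), a per-subject global fluctuation ``gamma u``
  (residual whole-brain nuisance), and white observation noise whose
  amplitude grows with the subject's node count (finer parcels are
  measured at lower per-node SNR).  The implied covariance is positive
  definite by construction and edge correlations grow with edge weight.
* **Node heterogeneity** — at coarse scales each node's series is blended
  with its ring neighbor's in proportion to ``node_heterogeneity *
  (1 - S / true_resolution)``: large parcels average functionally
  distinct regions, so coarse parcellations measure the planted topology
  less faithfully and prediction accuracy improves with node count.
* **Outcome** — ``intercept + effect_size * (clustering_proxy(beta) -
  path_proxy(beta)) + noise`` with closed-form proxies
  ``clustering_proxy = (1 - beta)^3`` and ``path_proxy =
  exp(-beta / 0.06)``; over the default ``beta`` range (0.15, 0.45) the
  planted signal is monotone in ``beta`` and independent of node count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse as _sparse

from ._seeds import derive, rng_from
from .connectivity import BoldTimeSeries
from .network import WeightedNetwork

#: Decay constant of the closed-form path-length proxy in beta units.
PATH_PROXY_DECAY = 0.06


def clustering_proxy(beta: np.ndarray | float) -> np.ndarray | float:
    """Closed-form lattice-clustering decay under rewiring, ``(1 - beta)^3``."""
    return (1.0 - np.asarray(beta)) ** 3


def path_proxy(beta: np.ndarray | float) -> np.ndarray | float:
    """Closed-form excess-path-length decay under rewiring."""
    return np.exp(-np.asarray(beta) / PATH_PROXY_DECAY)


@dataclass
class SyntheticCohortSpec:
    """Parameters of one synthetic cohort (defaults mirror the study design).

    26 subjects, 300 acquired volumes at TR 2 s (295 usable after dropping
    5), node counts of 420 +- 35 at the default scale (705 +- 65 and
    1620 +- 144 at the finer scales), and a node count positively coupled
    to the age covariate while the outcome depends on topology only.
    """

    n_subjects: int = 26
    node_count_mean: int = 420
    node_count_sd: float = 35.0
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    rewiring_prob_range: tuple[float, float] = (0.15, 0.45)
    mean_degree: int = 6
    # reference scale for the node-heterogeneity penalty: parcels at the
    # finest scale (~1620 nodes) are taken as functionally homogeneous
    true_resolution: int = 1620
    node_heterogeneity: float = 0.35
    heterogeneity_exponent: float = 2.2
    effect_size: float = 60.0
    outcome_noise_sd: float = 6.0
    covariate_confound_strength: float = 0.5
    seed: int = 0
    # observation / acquisition details
    bold_noise_sd: float = 0.4
    snr_scale_exponent: float = 2.0
    global_signal_range: tuple[float, float] = (0.2, 0.5)
    hub_bias_range: tuple[float, float] = (0.0, 3.0)
    triadic_closure_range: tuple[float, float] = (0.0, 0.35)
    spurious_degree_range: tuple[float, float] = (0.0, 0.0)
    weight_shape_range: tuple[float, float] = (0.5, 2.5)
    weight_range: tuple[float, float] = (0.2, 1.0)
    outcome_intercept: float = 89.0
    age_mean: float = 13.9
    age_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_timepoints < 30:
            raise ValueError("need at least 30 timepoints")
        lo, hi = self.rewiring_prob_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("rewiring_prob_range must lie within [0, 1]")
        if self.node_count_sd < 0:
            raise ValueError("node_count_sd must be nonnegative")
        if self.mean_degree < 2 or self.mean_degree % 2:
            raise ValueError("mean_degree must be an even integer >= 2")
        if self.node_count_sd == 0 and self.covariate_confound_strength > 0:
            warnings.warn(
                "node_count_sd is 0: the requested node-count/age confound "
                "cannot be expressed; proceeding"
            )


@dataclass
class SyntheticSubject:
    """One synthetic subject: planted truth plus observed data."""

    subject_id: str
    planted_network: WeightedNetwork
    beta: float
    timeseries: BoldTimeSeries
    covariates: dict[str, float]
    outcome: float


@dataclass
class SyntheticCohort:
    subjects: list[SyntheticSubject]
    spec: SyntheticCohortSpec
    metadata: dict = field(default_factory=dict)

    def covariate_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, **s.covariates, "outcome": s.outcome}
            rows.append(row)
        return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# planted networks
# ---------------------------------------------------------------------------

def generate_planted_network(
    n_nodes: int,
    mean_degree: int,
    beta: float,
    weight_law: str = "uniform",
    seed: int = 0,
    weight_range: tuple[float, float] = (0.2, 1.0),
    hub_bias: float = 0.0,
    triadic_closure: float = 0.0,
    weight_shape: float = 1.0,
    spurious_degree: float = 0.0,
    bundle_width: int = 1,
    max_retries: int = 20,
) -> WeightedNetwork:
    """Weighted Watts–Strogatz small-world network with optional heterogeneity.

    Starts from a ring lattice where every node links to its
    ``mean_degree / 2`` nearest neighbors on each side, then rewires the far
    endpoint of each edge with probability ``beta`` (avoiding self-loops
    and duplicate edges).  Two additional, outcome-neutral axes of
    individual topology heterogeneity are available:

    * ``hub_bias > 0`` draws rewiring targets preferentially (probability
      proportional to ``1 + hub_bias * degree``), skewing the degree
      distribution toward hubs — degree-sequence variance that
      degree-conserving null models absorb;
    * ``triadic_closure > 0`` then re-targets each edge with that
      probability to a two-step neighbor of its near endpoint, closing
      triangles and raising local clustering independently of ``beta``;
    * ``spurious_degree > 0`` adds that many random extra edges per node
      (uninformative connectivity that dilutes clustering and modularity
      in proportion to density; off by default).

    With ``bundle_width = b > 1`` a rewired edge carries its ``b - 1``
    ring-parallel companions to consecutive targets, so long-range
    shortcuts connect small *neighborhoods* rather than single nodes (the
    axon-bundle picture).  The per-edge rewiring probability stays
    ``beta``.  Edge weights are drawn from ``weight_law`` (``"uniform"``
    over ``weight_range``, or ``"unit"`` for all-1 weights).  If rewiring
    disconnects the graph the draw is repeated with an incremented seed,
    up to ``max_retries`` times.
    """
    if mean_degree % 2 or mean_degree < 2:
        raise ValueError("mean_degree must be even and >= 2")
    if n_nodes <= mean_degree:
        raise ValueError("n_nodes must exceed mean_degree")
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    if hub_bias < 0:
        raise ValueError("hub_bias must be nonnegative")
    if not 0 <= triadic_closure <= 1:
        raise ValueError("triadic_closure must lie in [0, 1]")

    half = mean_degree // 2
    for attempt in range(max_retries):
        rng = rng_from(seed + attempt)
        neighbors: list[set[int]] = [set() for _ in range(n_nodes)]
        for j in range(1, half + 1):
            for i in range(n_nodes):
                u, v = i, (i + j) % n_nodes
                neighbors[u].add(v)
                neighbors[v].add(u)
        degree = np.full(n_nodes, float(mean_degree))

        def lattice_order():
            return sorted(
                (min(u, v), max(u, v)) for u in range(n_nodes) for v in neighbors[u] if v > u
            )

        if beta > 0:
            b = max(1, int(bundle_width))
            # a bundle start moves up to b parallel edges; per-edge move
            # probability stays beta
            beta_start = 1.0 - (1.0 - beta) ** (1.0 / b)
            for (u, v) in lattice_order():
                j = (v - u) % n_nodes
                if j > half:
                    j = n_nodes - j
                    u, v = v, u  # ensure v = u + j on the ring
                if v not in neighbors[u] or rng.random() >= beta_start:
                    continue
                for _ in range(200):
                    w = int(rng.integers(0, n_nodes))
                    if w == u or w in neighbors[u]:
                        continue
                    if hub_bias > 0:
                        # rejection sampling toward high-degree targets;
                        # the exponent makes the preference superlinear so
                        # hubs actually emerge at moderate bias
                        accept = ((1.0 + degree[w]) / (1.0 + degree.max())) ** hub_bias
                        if rng.random() >= accept:
                            continue
                    for t in range(b):
                        uu = (u + t) % n_nodes
                        vv = (uu + j) % n_nodes
                        ww = (w + t) % n_nodes
                        if vv not in neighbors[uu] or ww == uu or ww in neighbors[uu]:
                            continue
                        neighbors[uu].discard(vv)
                        neighbors[vv].discard(uu)
                        neighbors[uu].add(ww)
                        neighbors[ww].add(uu)
                        degree[vv] -= 1
                        degree[ww] += 1
                    break
        if triadic_closure > 0:
            for (u, v) in lattice_order():
                if v not in neighbors[u] or rng.random() >= triadic_closure:
                    continue
                for _ in range(20):
                    x = int(rng.choice(sorted(neighbors[u])))
                    cands = sorted(neighbors[x] - neighbors[u] - {u, v})
                    if not cands:
                        continue
                    w = int(rng.choice(cands))
                    neighbors[u].discard(v)
                    neighbors[v].discard(u)
                    neighbors[u].add(w)
                    neighbors[w].add(u)
                    break
        if spurious_degree > 0:
            # outcome-neutral spurious connectivity: random extra edges
            # dilute clustering and modularity in proportion to their
            # density, which size/degree-conserving nulls account for
            n_extra = int(round(spurious_degree * n_nodes / 2.0))
            added = 0
            while added < n_extra:
                u = int(rng.integers(0, n_nodes))
                v = int(rng.integers(0, n_nodes))
                if u == v or v in neighbors[u]:
                    continue
                neighbors[u].add(v)
                neighbors[v].add(u)
                added += 1
        edge_set = {
            (u, v) for u in range(n_nodes) for v in neighbors[u] if v > u
        }
        edges = np.array(sorted(edge_set))
        if weight_law == "uniform":
            # weight_shape skews the draw: 1 = uniform, >1 weak-heavy, <1
            # strong-heavy; the range endpoints are preserved
            lo, hi = weight_range
            weights = lo + (hi - lo) * rng.random(len(edges)) ** weight_shape
        elif weight_law == "unit":
            weights = np.ones(len(edges))
        else:
            raise ValueError(f"unknown weight_law {weight_law!r}")
        net = WeightedNetwork.from_edges(n_nodes, edges, weights)
        if net.is_connected():
            return net
    raise RuntimeError(
        f"failed to generate a connected network after {max_retries} attempts"
    )


def weighted_erdos_renyi(
    n_nodes: int,
    edge_prob: float,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.2, 1.0),
) -> WeightedNetwork:
    """Weighted G(n, p) graph; the reference family for self-normalization."""
    rng = rng_from(seed)
    iu, iv = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu)) < edge_prob
    edges = np.stack([iu[keep], iv[keep]], axis=1)
    weights = rng.uniform(*weight_range, size=len(edges))
    return WeightedNetwork.from_edges(n_nodes, edges, weights)


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _mixing_matrix(
    net: WeightedNetwork, neighbor_variance_fraction: float
) -> tuple[np.ndarray, _sparse.csr_matrix]:
    """Per-node self-weights alpha_i and the sparse neighbor-mixing matrix B.

    ``B_ij = sqrt(g^2 w_ij / s_i)`` for connected pairs; isolated nodes get
    ``alpha_i = 1``.  Node signal variance is exactly 1 for every node.
    """
    g2 = float(neighbor_variance_fraction)
    if not 0 <= g2 < 1:
        raise ValueError("neighbor_variance_fraction must lie in [0, 1)")
    s = net.strengths()
    alpha = np.where(s > 0, np.sqrt(1.0 - g2), 1.0)
    iu, iv, w = net.edge_array()
    rows = np.concatenate([iu, iv])
    cols = np.concatenate([iv, iu])
    vals = np.sqrt(g2 * np.concatenate([w, w]) / s[rows])
    b = _sparse.csr_matrix((vals, (rows, cols)), shape=(net.n_nodes, net.n_nodes))
    return alpha, b


def simulate_bold(
    network: WeightedNetwork,
    n_timepoints: int,
    noise_sd: float = 0.4,
    seed: int = 0,
    neighbor_variance_fraction: float = 0.5,
    global_signal_amplitude: float = 0.0,
) -> np.ndarray:
    """Sample node-by-time signals whose correlations mirror the network.

    Gaussian graph moving-average process: node ``i`` observes
    ``alpha z_i + sum_j B_ij z_j + gamma u + noise_sd e_i`` with iid
    standard-normal innovations ``z``, a shared global fluctuation ``u``
    of amplitude ``gamma = global_signal_amplitude`` (the classic
    whole-brain nuisance component), and white noise ``e``.  The implied
    covariance ``(alpha I + B)(alpha I + B)^T + gamma^2 J + noise_sd^2 I``
    is positive definite by construction, and the correlation of a
    connected pair grows with its edge weight.  Deterministic given
    ``seed``.
    """
    if n_timepoints < 30:
        raise ValueError("need at least 30 timepoints")
    alpha, b = _mixing_matrix(network, neighbor_variance_fraction)
    rng = rng_from(seed)
    z = rng.standard_normal((network.n_nodes, n_timepoints))
    x = alpha[:, None] * z + b @ z
    if global_signal_amplitude > 0:
        x = x + global_signal_amplitude * rng.standard_normal(n_timepoints)[None, :]
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(x.shape)
    return x


def implied_correlation_matrix(
    net: WeightedNetwork,
    noise_sd: float = 0.4,
    neighbor_variance_fraction: float = 0.5,
    global_signal_amplitude: float = 0.0,
) -> np.ndarray:
    """Population correlation matrix implied by :func:`simulate_bold`."""
    alpha, b = _mixing_matrix(net, neighbor_variance_fraction)
    m = _sparse.diags(alpha) + b
    cov = (m @ m.T).toarray() + noise_sd**2 * np.eye(net.n_nodes)
    cov = cov + global_signal_amplitude**2
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def draw_cohort_latents(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Subject-level latent draws, independent of the node-count scale.

    Two cohorts generated from specs that differ only in
    ``node_count_mean`` / ``node_count_sd`` share betas, covariates and
    outcomes, which lets the pipeline compare network scales on paired
    subjects.
    """
    rng = rng_from(spec.seed, 1)
    n = spec.n_subjects
    z_age = rng.standard_normal(n)
    eps = rng.standard_normal(n)
    rho = spec.covariate_confound_strength
    z_node = rho * z_age + np.sqrt(max(0.0, 1 - rho**2)) * eps
    lo, hi = spec.rewiring_prob_range
    beta = rng.uniform(lo, hi, size=n)
    out_noise = rng.standard_normal(n) * spec.outcome_noise_sd
    c_proxy = clustering_proxy(beta)
    p_proxy = path_proxy(beta)
    signal = spec.effect_size * (c_proxy - p_proxy)
    outcome = spec.outcome_intercept + signal + out_noise
    age = spec.age_mean + spec.age_sd * z_age
    g_lo, g_hi = spec.global_signal_range
    h_lo, h_hi = spec.hub_bias_range
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "beta": beta,
            "z_node": z_node,
            "global_signal": rng.uniform(g_lo, g_hi, size=n),
            "hub_bias": rng.uniform(h_lo, h_hi, size=n),
            "triadic_closure": rng.uniform(*spec.triadic_closure_range, size=n),
            "spurious_degree": rng.uniform(*spec.spurious_degree_range, size=n),
            "weight_shape": rng.uniform(*spec.weight_shape_range, size=n),
            "age": age,
            "gender": rng.integers(0, 2, size=n).astype(float),
            "motion_rotational": np.exp(rng.normal(-2.5, 0.5, size=n)),
            "motion_translational": np.exp(rng.normal(-1.5, 0.5, size=n)),
            "clustering_proxy": c_proxy,
            "path_proxy": p_proxy,
            "signal": signal,
            "outcome": outcome,
        }
    )


def _node_counts(spec: SyntheticCohortSpec, z_node: np.ndarray) -> np.ndarray:
    n = np.rint(spec.node_count_mean + spec.node_count_sd * z_node).astype(int)
    return np.maximum(n, spec.mean_degree + 4)


def generate_cohort(
    spec: SyntheticCohortSpec,
    fixed_node_count: int | None = None,
    extra_noise_sd: float = 0.0,
    seed_tag: int = 0,
) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``spec``.

    Each subject's network is planted at their own node count for the
    requested scale.  Coarse scales carry a *node-heterogeneity* penalty:
    every node's series is blended with its ring neighbor's series with
    mixing fraction ``node_heterogeneity * (1 - S / true_resolution)``,
    emulating large parcels averaging functionally distinct regions — so
    finer parcellations genuinely measure the planted topology better.

    ``fixed_node_count`` regenerates every subject's network at the same
    node count from the subject's own planted ``beta`` (the shared-node-set
    condition); ``extra_noise_sd`` then adds node-level observation noise
    emulating registration error.  ``seed_tag`` separates network
    realizations of otherwise identical draws (conditions must not share
    graph noise).
    """
    latents = draw_cohort_latents(spec)
    z_node = latents["z_node"].to_numpy()
    if fixed_node_count is not None:
        counts = np.full(spec.n_subjects, int(fixed_node_count))
        scale = int(fixed_node_count)
    else:
        counts = _node_counts(spec, z_node)
        scale = int(spec.node_count_mean)
    mix = spec.node_heterogeneity * max(
        0.0, 1.0 - scale / spec.true_resolution
    ) ** spec.heterogeneity_exponent
    subjects = []
    for i in range(spec.n_subjects):
        n_i = int(counts[i])
        beta_i = float(latents.loc[i, "beta"])
        net = generate_planted_network(
            n_i,
            spec.mean_degree,
            beta_i,
            seed=derive(spec.seed, 2, i, seed_tag),
            weight_range=spec.weight_range,
            hub_bias=float(latents.loc[i, "hub_bias"]),
            triadic_closure=float(latents.loc[i, "triadic_closure"]),
            weight_shape=float(latents.loc[i, "weight_shape"]),
            spurious_degree=float(latents.loc[i, "spurious_degree"]),
        )
        rel = n_i / spec.node_count_mean if fixed_node_count is None else 1.0
        # floor at 0.75x baseline: below that, residual global correlations
        # sit at the significance threshold and density explodes
        noise_i = spec.bold_noise_sd * max(0.75, rel**spec.snr_scale_exponent)
        noise_i = float(np.sqrt(noise_i**2 + extra_noise_sd**2))
        ts = simulate_bold(
            net,
            spec.n_timepoints,
            noise_sd=noise_i,
            seed=derive(spec.seed, 3, i, seed_tag),
            global_signal_amplitude=float(latents.loc[i, "global_signal"]),
        )
        if mix > 0:
            # parcel-heterogeneity contamination: blend each node with a
            # functionally distant (randomly paired) node, preserving
            # per-node variance — large parcels average signals of
            # functionally distinct regions, attenuating true edges and
            # adding spurious ones
            rng_mix = rng_from(derive(spec.seed, 5, i, seed_tag))
            partner = rng_mix.permutation(n_i)
            ts = np.sqrt(1.0 - mix) * ts + np.sqrt(mix) * ts[partner]
        cortical_volume = 520_000.0 * (1.0 + 0.12 * float(latents.loc[i, "z_node"]))
        covariates = {
            "age": float(latents.loc[i, "age"]),
            "gender": float(latents.loc[i, "gender"]),
            "cortical_volume": cortical_volume,
            "n_nodes": float(n_i),
            "motion_rotational": float(latents.loc[i, "motion_rotational"]),
            "motion_translational": float(latents.loc[i, "motion_translational"]),
        }
        subject = SyntheticSubject(
            subject_id=str(latents.loc[i, "subject_id"]),
            planted_network=net,
            beta=beta_i,
            timeseries=BoldTimeSeries(
                ts, tr_seconds=spec.tr_seconds, subject_id=str(latents.loc[i, "subject_id"])
            ),
            covariates=covariates,
            outcome=float(latents.loc[i, "outcome"]),
        )
        subjects.append(subject)
    signal = latents["signal"].to_numpy()
    var_sig = float(np.var(signal))
    planted_r2 = var_sig / (var_sig + spec.outcome_noise_sd**2)
    meta = {
        "seed": spec.seed,
        "planted_r2": planted_r2,
        "fixed_node_count": fixed_node_count,
        "extra_noise_sd": extra_noise_sd,
        "node_counts": counts.tolist(),
    }
    return SyntheticCohort(subjects=subjects, spec=spec, metadata=meta)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write a cohort to disk: per-subject time-series TSVs, a cohort-level
    covariate/outcome TSV, and a JSON metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in cohort.subjects:
        s.timeseries.to_tsv(outdir / f"{s.subject_id}_timeseries.tsv")
    cohort.covariate_frame().to_csv(outdir / "cohort.tsv", sep="\t")
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(cohort.metadata, fh, indent=2)


# ---------------------------------------------------------------------------
# labeled meshes (fixture generator for the parcellation stage)
# ---------------------------------------------------------------------------

def generate_labeled_mesh(
    grid_shape: tuple[int, int],
    element_mm: float = 1.0,
    parcel_layout: str | int | np.ndarray = "single",
    z_amplitude: float = 0.0,
    seed: int = 0,
):
    """Planar triangulated grid with per-vertex parcel labels.

    ``grid_shape = (nx, ny)`` counts cells; the mesh has
    ``(nx + 1) (ny + 1)`` vertices, two triangles per cell, and (at
    ``z_amplitude = 0``) total area exactly ``nx * ny * element_mm**2``.
    ``parcel_layout`` is ``"single"`` (one parcel), an integer ``p``
    (``p`` vertical strips), or an explicit per-vertex label array.
    ``z_amplitude`` adds a smooth out-of-plane undulation for non-flat
    test surfaces.
    """
    from .parcellation import TriMesh

    nx, ny = grid_shape
    if nx < 2 or ny < 2:
        raise ValueError("grid must be at least 2x2 cells")
    xs = np.arange(nx + 1) * element_mm
    ys = np.arange(ny + 1) * element_mm
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    z = np.zeros_like(gx)
    if z_amplitude > 0:
        rng = rng_from(seed)
        fx, fy = rng.uniform(0.5, 1.5, size=2)
        z = z_amplitude * np.sin(fx * gx / (nx * element_mm) * np.pi) * np.cos(
            fy * gy / (ny * element_mm) * np.pi
        )
    vertices = np.stack([gx.ravel(), gy.ravel(), z.ravel()], axis=1)

    def vid(i, j):
        return i * (ny + 1) + j

    faces = []
    for i in range(nx):
        for j in range(ny):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append((a, b, c))
            faces.append((a, c, d))
    mesh = TriMesh(vertices=vertices, faces=np.array(faces, dtype=int))

    n_vertices = len(vertices)
    if isinstance(parcel_layout, str) and parcel_layout == "single":
        labels = np.zeros(n_vertices, dtype=int)
    elif isinstance(parcel_layout, (int, np.integer)):
        strips = int(parcel_layout)
        col = (np.arange(n_vertices) // (ny + 1))
        labels = np.minimum((col * strips) // (nx + 1), strips - 1).astype(int)
    else:
        labels = np.asarray(parcel_layout, dtype=int)
        if len(labels) != n_vertices:
            raise ValueError("label array length must match vertex count")
    return mesh, labels


# ---------------------------------------------------------------------------
# importance-probe cohorts (Fig-1-style feature recovery testbed)
# ---------------------------------------------------------------------------

def importance_probe_network(
    u_clustering: float,
    u_path: float,
    u_hub_weights: float,
    u_weight_scale: float,
    seed: int = 0,
    core_seed: int = 20260925,
) -> WeightedNetwork:
    """A network whose five global metrics vary along decorrelated axes.

    All structure (a two-block core, hub spokes, 14 pendant-triangle
    gadgets, a 10-edge tendril, filler fans; 150 nodes total) is drawn
    once from ``core_seed`` and shared by every subject.  Four latent
    coordinates in [0, 1] then steer only edge weights:

    * ``u_clustering`` redistributes each gadget's fixed total weight onto
      its closing edge, moving the geometric-mean triangle intensity (and
      hence the node-averaged clustering coefficient) of the gadget
      corners;
    * ``u_path`` sets the weight *dispersion* along the tendril at fixed
      total weight — the path length is the harmonic sum, so it varies
      several-fold while the weight mass that modularity sees is pinned;
    * ``u_hub_weights`` jitters the hub-spoke weights (an outcome-neutral
      variance source for transitivity, whose triple count the hubs
      dominate);
    * ``u_weight_scale`` rescales all weights (an outcome-neutral variance
      source for global efficiency and the path-length scale).

    Planting the outcome on the first two latents therefore makes
    clustering and path length the only informative metrics, without the
    other three tracking them through a shared cause.
    """
    core_rng = rng_from(core_seed)
    rng = rng_from(seed)
    n_core, n_hubs, n_total = 48, 4, 150
    block = n_core // 2
    edges: list[tuple[int, int]] = []
    weights: list[float] = []

    def add(u, v, w):
        if u != v:
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                edges.append(key)
                weights.append(w)

    seen: set[tuple[int, int]] = set()
    # two-block core: structure and weights fixed across subjects
    for i in range(n_core):
        for j in range(i + 1, n_core):
            same = (i < block) == (j < block)
            p = 0.25 if same else 0.06
            if core_rng.random() < p:
                add(i, j, core_rng.uniform(0.5, 1.0))
    # hub spokes: fixed structure, per-subject weight jitter (kept <= 1 so
    # the max-weight normalization of clustering never sees it)
    hub_scale = 0.7 + 0.3 * u_hub_weights
    for h in range(n_core, n_core + n_hubs):
        for i in range(n_core):
            if core_rng.random() < 0.9:
                add(h, i, core_rng.uniform(0.5, 1.0) * hub_scale)
    nxt = n_core + n_hubs
    # pendant triangle gadgets: fixed count, attachment and total weight;
    # only the closing-edge share follows u_clustering
    for _ in range(14):
        a, b, c = nxt, nxt + 1, nxt + 2
        nxt += 3
        w_close = 0.05 + 0.9 * u_clustering * rng.uniform(0.85, 1.0)
        w_side = (1.9 - w_close) / 2.0
        add(a, b, w_side)
        add(b, c, w_side)
        add(a, c, w_close)
        add(a, int(core_rng.integers(0, n_core)), 0.5)
    # tendril: fixed chain and total weight; u_path sets the dispersion
    w_lo = 0.15 * (1.0 - 0.92 * u_path)
    w_hi = 0.30 - w_lo
    prev = int(core_rng.integers(0, n_core))
    for t in range(10):
        add(prev, nxt, w_lo if t % 2 else w_hi)
        prev = nxt
        nxt += 1
    # neutral filler fans keep the node count at n_total
    while nxt < n_total:
        add(nxt, int(core_rng.integers(0, n_core)), core_rng.uniform(0.5, 1.0))
        add(nxt, int(core_rng.integers(0, n_core)), core_rng.uniform(0.5, 1.0))
        nxt += 1
    scale = 0.8 + 0.2 * u_weight_scale
    w = np.array(weights) * scale  # all weights < 1: no clipping, so the
    # max-normalized clustering is exactly scale-free
    return WeightedNetwork.from_edges(n_total, np.array(edges), w)


def importance_probe_cohort(
    n_subjects: int = 60,
    effect_clustering: float = 3.0,
    effect_path: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    louvain_restarts: int = 4,
) -> pd.DataFrame:
    """Cohort table whose outcome is planted on clustering and path length.

    Each subject's five metrics are *measured* on an
    :func:`importance_probe_network`; the outcome is a linear combination
    of the clustering and path latents (standardized) plus noise, so that
    permutation importance should flag exactly those two metrics.
    """
    from .metrics import METRIC_NAMES, compute_all

    rng = rng_from(seed, 5)
    u = rng.random((n_subjects, 4))
    rows = []
    for i in range(n_subjects):
        net = importance_probe_network(*u[i], seed=derive(seed, 6, i))
        gm = compute_all(net, seed=derive(seed, 7, i), louvain_restarts=louvain_restarts)
        rows.append(gm.as_dict())
    table = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    z = (u - 0.5) / np.sqrt(1 / 12)  # standardized uniforms
    table["outcome"] = (
        100.0
        + effect_clustering * z[:, 0]
        - effect_path * z[:, 1]
        + noise_sd * rng.standard_normal(n_subjects)
    )
    return table
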