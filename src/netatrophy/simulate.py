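"""Synthetic cohort generator with planted, recoverable network structure.

Emulates the ingredients of a case-control cortical-thickness study on a
bilateral 68-region parcellation: per-hemisphere spherical centroids; a
sparse structural connectome (SC) whose edges are distance-dependent but
also carry bilateral community structure, homotopic (mirror-pair) edges and
a rich club of interconnected hubs, as real tractography-derived networks
do; a functional connectome (FC) from a latent-factor model sharing those
communities; and control/patient thickness tables in which patient atrophy
combines epicenter-seeded diffusion along the SC with a hub-susceptibility
component. Patient severity is driven by drug-use variables (log-duration,
log-dose), clinical scores load on the same severity latent, and a
two-biotype mixture shifts drug use (and hence severity) in a low-exposure
subgroup. Every planted quantity is returned in a :class:`SimulationTruth`
so downstream stages can be tested for recovery.

The generator's statistical realism is deliberately minimal: connectivity
is geometric/community-driven rather than tractography-derived, and
thickness covariance comes from a small latent-factor model. See
``docs/methods.md`` for what this does and does not establish about real
data.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import CohortData, ConnectomeSet, ParcellationScheme

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "LatentStructure",
    "simulate_parcellation",
    "simulate_connectomes",
    "simulate_cohort",
    "simulate_study",
    "atrophy_profile",
]

# fixed per-operation salts so each op draws from its own reproducible stream
_OP_SALT = {"parcellation": 101, "connectomes": 211, "cohort": 307}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _OP_SALT[op]]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Sample sizes default to the emulated study (139 patients, 119
    controls). ``spread_strength`` scales the planted atrophy (0 disables
    it); ``spread_decay`` is the per-step retention of the truncated
    diffusion; ``hub_vulnerability`` mixes in the degree-linked
    susceptibility component; ``atrophy_scale`` is the peak thinning in mm
    per unit severity. Covariate slopes are in mm per unit of the
    covariate. ``latent_loadings`` are the clinical-score loadings on the
    severity latent for (craving, panss, hars, hdrs); craving is 0 by
    default. ``biotype_frac`` is the fraction of patients in the
    low-exposure subgroup, whose severity is shifted down by
    ``biotype_shift_d`` within-group standard deviations via lower drug
    use.
    """

    n_regions: int = 68
    n_controls: int = 119
    n_patients: int = 139
    epicenters: tuple[int, ...] | None = None
    n_epicenters: int = 3
    spread_strength: float = 1.0
    spread_decay: float = 0.85
    spread_steps: int = 10
    spread_smooth: int = 2               # neighbor-averaging passes on the profile
    hub_vulnerability: float = 0.4       # weight of the degree-linked component
    atrophy_scale: float = 0.3           # mm per unit severity at the peak region
    age_slope: float = -0.005            # mm / year
    sex_offset: float = 0.03             # mm
    icv_slope: float = 2.0e-7            # mm / mm^3
    noise_sd: float = 0.08               # mm, per-region i.i.d. measurement noise
    factor_sd: float = 0.12              # mm, latent-factor (covariance) scale
    baseline_mean: float = 2.5           # mm
    baseline_sd: float = 0.15            # mm across regions
    sc_density: float = 0.15
    sc_length_scale: float = 0.75        # distance decay of edge weight
    sc_weight_noise: float = 0.5         # lognormal sigma on edge weights
    sc_weight_temper: float = 0.5        # compresses the weight dynamic range
    hub_fraction: float = 0.2            # fraction of regions forming the rich club
    hub_edge_bonus: float = 1.5          # log-weight bonus per hub endpoint
    hub_participation: float = 0.3       # hub loading on every community factor
    homotopic_bonus: float = 3.0         # log-weight bonus for mirror-pair edges
    community_bonus: float = 1.8         # log-weight bonus within a community
    core_edge_bonus: float = 0.8         # extra bonus inside the core community
    core_loading_boost: float = 0.7      # relative factor-loading boost, core regions
    n_communities: int = 6
    latent_loadings: tuple[float, float, float, float] = (0.0, 8.0, 4.0, 4.0)
    clinical_noise_sd: tuple[float, float, float, float] = (3.0, 12.0, 6.0, 6.0)
    clinical_baseline: tuple[float, float, float, float] = (5.0, 45.0, 12.0, 14.0)
    biotype_frac: float = 45.0 / 139.0
    biotype_shift_d: float = 1.5
    severity_coupling: float = 0.5       # severity weight on each z-scored drug variable
    severity_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_regions % 2:
            raise ValueError("n_regions must be even (bilateral parcellation)")
        if not (0 < self.sc_density < 1):
            raise ValueError("sc_density must lie in (0, 1)")
        if not (0 <= self.spread_decay < 1):
            raise ValueError("spread_decay must lie in [0, 1)")
        if self.spread_strength < 0:
            raise ValueError("spread_strength must be non-negative")
        if not (0 <= self.hub_vulnerability <= 1):
            raise ValueError("hub_vulnerability must lie in [0, 1]")
        for name in ("noise_sd", "factor_sd", "baseline_sd", "severity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.epicenters is not None:
            if any(not (0 <= e < self.n_regions) for e in self.epicenters):
                raise ValueError("epicenter index out of range")


@dataclass
class LatentStructure:
    """Latent drivers of the simulated connectomes, reused by the cohort."""

    mixing: np.ndarray        # regions x factors loading matrix
    communities: np.ndarray   # bilateral community label per region
    hubs: np.ndarray          # boolean rich-club membership per region
    core_community: int       # the hub-dense, high-covariance community


@dataclass
class SimulationTruth:
    """Planted ground truth: the oracle for recovery tests."""

    epicenters: np.ndarray               # region indices
    beta: np.ndarray                     # mm thinning per unit severity, per region
    severity: np.ndarray                 # per patient, unitless
    biotype: np.ndarray                  # per patient, 1 (high exposure) or 2
    loadings: np.ndarray                 # clinical loadings used
    latent: LatentStructure | None


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def simulate_parcellation(config: SimulationConfig, seed: int | None = None) -> ParcellationScheme:
    """Bilateral parcellation with mirror-symmetric quasi-uniform centroids.

    Half the regions per hemisphere; the left-hemisphere lattice is given a
    random (seeded) rotation and the right hemisphere mirrors it in x, the
    way bilateral atlases pair homologous regions. Region ``i`` of the left
    hemisphere mirrors region ``i + n/2`` of the right.
    """
    if config.n_regions % 2:
        raise ValueError("n_regions must be even")
    n_hemi = config.n_regions // 2
    if n_hemi < 2:
        raise ValueError("need at least 2 regions per hemisphere")
    rng = _rng(config.seed if seed is None else seed, "parcellation")
    from scipy.spatial.transform import Rotation

    pts = _fibonacci_sphere(n_hemi)
    rot = Rotation.random(rng=rng).as_matrix()
    left = pts @ rot.T
    right = left * np.array([-1.0, 1.0, 1.0])
    names = np.array(
        [f"lh_region{i:02d}" for i in range(n_hemi)]
        + [f"rh_region{i:02d}" for i in range(n_hemi)],
        dtype=object,
    )
    hemi = np.array(["left"] * n_hemi + ["right"] * n_hemi, dtype=object)
    return ParcellationScheme(names=names, hemisphere=hemi,
                              centroids=np.vstack([left, right]))


def _positions(scheme: ParcellationScheme) -> np.ndarray:
    """Embed the two hemisphere spheres side by side for physical distances."""
    pos = scheme.centroids.copy()
    offset = np.where(scheme.hemisphere == "left", -1.2, 1.2)
    pos[:, 0] += offset
    return pos


def simulate_connectomes(
    scheme: ParcellationScheme, config: SimulationConfig, seed: int | None = None
) -> tuple[ConnectomeSet, LatentStructure]:
    """SC with distance, community, homotopic and rich-club structure; FC to match.

    SC log-edge-weights combine exponential distance decay, Gaussian noise,
    a within-community bonus (bilateral geometric communities), a homotopic
    mirror-pair bonus, and a per-endpoint hub bonus for a random bilateral
    rich-club subset; the strongest edges are kept to hit the target density
    and minimal bridging edges are added if the graph is disconnected. FC is
    the correlation matrix implied by a latent-factor model with one factor
    per community plus a global factor, loading magnitude growing with SC
    degree, so hubs are strong in every modality. The morphological network
    is NOT emitted here: the pipeline builds it from simulated controls.
    Returns the connectome set (``smn=None``) and the latent structure
    (mixing, communities, hubs) reused for thickness covariance and
    epicenter placement.
    """
    rng = _rng(config.seed if seed is None else seed, "connectomes")
    n = scheme.n_regions
    n_half = n // 2
    pos = _positions(scheme)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)

    # bilateral communities from left-hemisphere geometry, mirrored right
    from sklearn.cluster import KMeans

    k = max(2, min(config.n_communities, n_half // 3))
    left_idx = scheme.hemisphere_indices("left")
    right_idx = scheme.hemisphere_indices("right")
    comm_left = KMeans(n_clusters=k, n_init=10,
                       random_state=int(rng.integers(2**31 - 1))
                       ).fit_predict(scheme.centroids[left_idx])
    comm = np.empty(n, dtype=int)
    comm[left_idx] = comm_left
    comm[right_idx] = comm_left
    same_comm = comm[:, None] == comm[None, :]

    # bilateral rich-club hubs
    n_hub_pairs = max(1, int(round(config.hub_fraction * n_half)))
    hub_left = rng.choice(n_half, size=n_hub_pairs, replace=False)
    hubs = np.zeros(n, dtype=bool)
    hubs[left_idx[hub_left]] = True
    hubs[right_idx[hub_left]] = True
    hub_bonus = np.where(hubs, config.hub_edge_bonus, 0.0)

    # the core (association-like) community: hub-dense, extra-cohesive, and
    # later the site of the default epicenters — mirroring the co-location of
    # hubs, high covariance and disease vulnerability in association cortex
    pair_count = Counter(comm[i] for i in left_idx[hub_left])
    top_pairs = max(pair_count.values())
    core = int(min(c for c, cnt in pair_count.items() if cnt == top_pairs))
    in_core = comm == core
    core_edge = in_core[:, None] & in_core[None, :]

    noise = rng.normal(0.0, config.sc_weight_noise, size=(n, n))
    noise = (noise + noise.T) / np.sqrt(2.0)
    # rank and store weights in log space so tiny length scales cannot underflow
    logw = (
        -d / config.sc_length_scale
        + noise
        + hub_bonus[:, None] + hub_bonus[None, :]
        + config.community_bonus * same_comm
        + config.core_edge_bonus * core_edge
    )
    homotopic = (np.arange(n) + n_half) % n
    logw[np.arange(n), homotopic] += config.homotopic_bonus
    np.fill_diagonal(logw, -np.inf)

    m_target = int(round(config.sc_density * n * (n - 1) / 2))
    if m_target < n - 1:
        raise ValueError("sc_density too low for a connected graph")
    iu = np.triu_indices(n, k=1)
    order = np.argsort(logw[iu])[::-1]
    keep = np.zeros(len(iu[0]), dtype=bool)
    keep[order[:m_target]] = True
    shift = logw[iu][order[0]]
    temper = config.sc_weight_temper
    sc = np.zeros((n, n))
    sc[iu[0][keep], iu[1][keep]] = np.maximum(
        np.exp(temper * (logw[iu][keep] - shift)), np.finfo(float).tiny)
    sc = sc + sc.T

    # bridge disconnected components with their minimal-distance edges
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components((sc > 0).astype(np.int8), directed=False)
    while n_comp > 1:
        best = None
        for a in range(n):
            for b in range(a + 1, n):
                if labels[a] != labels[b] and (best is None or d[a, b] < d[best]):
                    best = (a, b)
        a, b = best
        sc[a, b] = sc[b, a] = max(
            np.exp(temper * (-d[a, b] / config.sc_length_scale - shift)),
            np.finfo(float).tiny)
        n_comp, labels = connected_components((sc > 0).astype(np.int8), directed=False)

    deg = sc.sum(axis=1)
    # rank-based so a single extreme hub cannot compress everyone's loading
    deg_rank = np.argsort(np.argsort(deg)) / (n - 1)
    hub_load = 0.25 + 0.75 * deg_rank
    hub_load = hub_load * (1.0 + config.core_loading_boost * in_core)
    mixing = np.zeros((n, k + 1))
    mixing[np.arange(n), comm] = 0.8 * hub_load
    mixing[:, k] = 0.6 * hub_load
    # hubs are connector nodes: they load (weakly) on every community factor
    mixing[hubs, :k] += config.hub_participation * hub_load[hubs, None]
    # small idiosyncratic wobble so no two regions are exactly collinear
    mixing += rng.normal(0.0, 0.05, size=mixing.shape)

    psi = 1.0  # unique variance per region, same units as mixing^2
    cov = mixing @ mixing.T + psi * np.eye(n)
    s = np.sqrt(np.diag(cov))
    fc = cov / np.outer(s, s)
    np.fill_diagonal(fc, 0.0)
    fc = np.clip(fc, -0.999999, 0.999999)

    latent = LatentStructure(mixing=mixing, communities=comm, hubs=hubs,
                             core_community=core)
    return ConnectomeSet(frame=scheme, sc=sc, fc=fc, smn=None), latent


def atrophy_profile(
    sc: np.ndarray,
    epicenters,
    decay: float,
    steps: int = 10,
    smooth: int = 0,
) -> np.ndarray:
    """Truncated diffusion of an epicenter indicator on the normalized SC.

    The indicator e is diffused with the symmetrically normalized adjacency
    S = D^{-1/2} A D^{-1/2}: sum_{k=0..steps} decay^k S^k e, followed by
    ``smooth`` neighbor-averaging passes (x -> (x + A_row x) / 2) that
    spread the seed spike over its neighborhood, and normalized to a
    maximum of 1. Non-negative everywhere and strictly positive wherever
    reachable from an epicenter when decay > 0.
    """
    n = sc.shape[0]
    deg = sc.sum(axis=1)
    inv_sqrt = np.divide(1.0, np.sqrt(deg), out=np.zeros_like(deg), where=deg > 0)
    s_hat = sc * np.outer(inv_sqrt, inv_sqrt)
    e = np.zeros(n)
    e[list(epicenters)] = 1.0
    term = e.copy()
    total = e.copy()
    for _ in range(steps):
        term = decay * (s_hat @ term)
        total += term
    a_row = np.divide(sc, deg[:, None], out=np.zeros_like(sc), where=deg[:, None] > 0)
    for _ in range(smooth):
        total = 0.5 * total + 0.5 * (a_row @ total)
    return total / total.max()


def default_epicenters(
    sc: np.ndarray,
    latent: LatentStructure,
    n_half: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """A connected hub trio in one community: a bilateral pair plus a neighbor hub.

    Reflects the hub-vulnerability picture the analysis targets: epicenters
    are interconnected high-degree regions concentrated in one brain system
    (preferring a community that holds at least two hub pairs).
    """
    hubs = np.flatnonzero(latent.hubs)
    comm = latent.communities
    core_left = [i for i in hubs if i < n_half and comm[i] == latent.core_community]
    if core_left:
        h = int(rng.choice(core_left))
        others = [j for j in hubs
                  if comm[j] == latent.core_community and j not in (h, h + n_half)]
        if not others:
            others = [j for j in hubs if j not in (h, h + n_half)]
    else:
        h = int(rng.choice([i for i in hubs if i < n_half]))
        others = [j for j in hubs if j not in (h, h + n_half)]
    third = int(others[int(np.argmax(sc[h, others]))])
    return np.array(sorted([h, h + n_half, third]))


def simulate_cohort(
    scheme: ParcellationScheme,
    connectomes: ConnectomeSet,
    config: SimulationConfig,
    seed: int | None = None,
    latent: LatentStructure | None = None,
) -> tuple[CohortData, SimulationTruth]:
    """Control/patient thickness with planted network-dependent atrophy.

    thickness[i, j] = mu_j + covariate effects + factor structure
    - 1{patient} * severity_i * beta_j + noise, with

    beta = atrophy_scale * normalize((1 - w) * spread + w * hubness),

    where spread is the smoothed truncated diffusion from the epicenters
    (:func:`atrophy_profile`) and hubness the min-max-scaled SC degree — a
    network-spread component plus a nodal-stress (wear-and-tear)
    susceptibility component, mixed by ``hub_vulnerability``. Severity is a
    linear function of z-scored log-duration and log-dose plus noise, mean
    1 over the cohort. The low-exposure biotype draws both drug variables
    lower, sized so its severity is shifted by ``biotype_shift_d``
    within-group standard deviations. Clinical scores load on severity;
    craving does not (default loadings).
    """
    rng = _rng(config.seed if seed is None else seed, "cohort")
    n = scheme.n_regions
    n_sub = config.n_controls + config.n_patients
    is_patient = np.repeat([False, True], [config.n_controls, config.n_patients])

    if config.epicenters is not None:
        epicenters = np.asarray(config.epicenters, dtype=int)
    elif latent is not None:
        epicenters = default_epicenters(connectomes.sc, latent, n // 2, rng)
    else:
        deg = connectomes.sc.sum(axis=1)
        top = np.argsort(deg)[::-1][: max(config.n_epicenters, int(0.2 * n))]
        epicenters = np.sort(rng.choice(top, size=config.n_epicenters, replace=False))

    spread = atrophy_profile(connectomes.sc, epicenters, config.spread_decay,
                             config.spread_steps, config.spread_smooth)
    deg = connectomes.sc.sum(axis=1)
    rng_span = deg.max() - deg.min()
    hubness = (deg - deg.min()) / rng_span if rng_span > 0 else np.zeros(n)
    w = config.hub_vulnerability
    profile = (1 - w) * spread + w * hubness
    profile = profile / profile.max()
    beta = config.spread_strength * config.atrophy_scale * profile

    # covariates
    age = rng.uniform(18.0, 45.0, n_sub)
    sex = rng.integers(0, 2, n_sub).astype(float)
    education = np.clip(rng.normal(12.0, 3.0, n_sub), 6.0, 20.0)
    icv = rng.normal(1.45e6, 1.2e5, n_sub)

    # drug use and severity (patients); biotype 2 = low exposure
    n_pat = config.n_patients
    biotype = np.where(rng.random(n_pat) < config.biotype_frac, 2, 1)
    c = config.severity_coupling
    sigma_w = np.sqrt(2 * c**2 + config.severity_noise_sd**2)
    # the biotype gap is d standard deviations of the FULL severity mixture;
    # solving gap = d * sd_total with sd_total^2 = sigma_w^2 + f(1-f) gap^2
    d = config.biotype_shift_d
    f = config.biotype_frac
    feas = 1.0 - d**2 * f * (1 - f)
    if feas <= 0:
        raise ValueError("biotype_shift_d too large for this mixture fraction")
    gap = d * sigma_w / np.sqrt(feas)
    delta = gap / (2 * c) if c > 0 else 0.0
    mu_dur, sd_dur = np.log(60.0), 0.6
    mu_dose, sd_dose = np.log(100.0), 0.7
    log_dur = rng.normal(mu_dur, sd_dur, n_pat) - delta * sd_dur * (biotype == 2)
    log_dose = rng.normal(mu_dose, sd_dose, n_pat) - delta * sd_dose * (biotype == 2)
    # intercept keeps the cohort-mean severity at 1 despite the low-exposure mix
    center = 1.0 + f * gap
    severity = (
        center
        + c * (log_dur - mu_dur) / sd_dur
        + c * (log_dose - mu_dose) / sd_dose
        + config.severity_noise_sd * rng.standard_normal(n_pat)
    )

    # thickness: factor loadings shift variance COMPOSITION, not magnitude —
    # per-region total variance is noise_sd^2 + factor_sd^2 everywhere, so
    # strongly covarying (hub/core) regions are no noisier than the rest
    mu = config.baseline_mean + rng.normal(0.0, config.baseline_sd, n)
    mixing = latent.mixing if latent is not None else np.zeros((n, 1))
    row_norm = np.sqrt((mixing**2).sum(axis=1))
    mix_scaled = config.factor_sd * mixing / max(1e-12, row_norm.max())
    factor_var = (mix_scaled**2).sum(axis=1)
    unique_sd = np.sqrt(config.noise_sd**2 + config.factor_sd**2 - factor_var)
    factors = rng.standard_normal((n_sub, mixing.shape[1]))
    structured = factors @ mix_scaled.T

    effect = np.zeros((n_sub, n))
    effect[is_patient] = severity[:, None] * beta[None, :]

    base = (
        mu[None, :]
        + config.age_slope * (age - 30.0)[:, None]
        + config.sex_offset * sex[:, None]
        + config.icv_slope * (icv - 1.45e6)[:, None]
        + structured
        - effect
    )
    thickness = base + rng.normal(0.0, 1.0, size=(n_sub, n)) * unique_sd
    if np.any(thickness <= 0):
        thickness = base + rng.normal(0.0, 1.0, size=(n_sub, n)) * unique_sd
        if np.any(thickness <= 0):
            raise ValueError("simulated thickness non-positive; check effect sizes")

    # clinical scores load on severity; controls are missing
    loadings = np.asarray(config.latent_loadings, dtype=float)
    clin_base = np.asarray(config.clinical_baseline, dtype=float)
    clin_noise = np.asarray(config.clinical_noise_sd, dtype=float)
    clinical = (
        clin_base[None, :]
        + severity[:, None] * loadings[None, :]
        + rng.standard_normal((n_pat, 4)) * clin_noise[None, :]
    )
    clinical[:, 0] = np.clip(clinical[:, 0], 0.0, 10.0)  # craving is a 0-10 VAS
    clinical[:, 1:] = np.maximum(clinical[:, 1:], 0.0)

    subjects = pd.DataFrame(
        {
            "subject": [f"sub-{i:04d}" for i in range(n_sub)],
            "group": np.where(is_patient, "patient", "control"),
            "sex": sex,
            "age": age,
            "education": education,
            "icv": icv,
        }
    )
    for j, col in enumerate(CohortData.CLINICAL):
        vals = np.full(n_sub, np.nan)
        vals[is_patient] = clinical[:, j]
        subjects[col] = vals
    dur = np.full(n_sub, np.nan)
    dose = np.full(n_sub, np.nan)
    dur[is_patient] = np.exp(log_dur)
    dose[is_patient] = np.exp(log_dose)
    subjects["duration"] = dur
    subjects["dose"] = dose

    cohort = CohortData(frame=scheme, thickness=thickness, subjects=subjects)
    truth = SimulationTruth(
        epicenters=epicenters,
        beta=beta,
        severity=severity,
        biotype=biotype,
        loadings=loadings,
        latent=latent,
    )
    return cohort, truth


def simulate_study(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ParcellationScheme, ConnectomeSet, CohortData, SimulationTruth]:
    """Convenience wrapper: parcellation, connectomes, cohort in one call."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    scheme = simulate_parcellation(config)
    connectomes, latent = simulate_connectomes(scheme, config)
    cohort, truth = simulate_cohort(scheme, connectomes, config, latent=latent)
    return scheme, connectomes, cohort, truth
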