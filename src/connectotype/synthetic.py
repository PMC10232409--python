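"""Synthetic cortical-surface cohorts with planted ground truth.

This module generates everything the downstream pipeline consumes:

* subject-specific functional topography, obtained by stochastically
  shifting ROI boundaries of a population atlas along the mesh;
* network-structured vertex x time signals, in which every vertex carries
  its ROI's latent time series plus independent noise (the signal model
  the individual parcellation step assumes);
* framewise-displacement / DVARS motion traces with outlier frames, plus
  motion-parameter and tissue-signal proxies for nuisance regression;
* symptom scores generated as a linear function of a small planted set of
  between-network connections plus age/sex confounding and noise, clamped
  to instrument-like ranges.

Clinical group differences are encoded as mean shifts of the planted
effect connections (|deviation| ordered AD > MCI > NA), and the two
genotype groups may carry different planted effect maps — the substrate
for testing genotype-stratified prediction.

Every output is a pure function of the configuration seed: per-subject
seeds are derived from (config seed, subject index) so changing the
cohort size does not reshuffle existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .atlas import Atlas, make_atlas
from .mesh import ConfigurationError, SurfaceMesh, make_mesh

GROUPS = ("NA", "MCI", "AD")
GENOTYPES = ("carrier", "noncarrier")

# severity multiplier applied to the per-connection group effect
GROUP_SEVERITY = {"NA": 0.0, "MCI": 1.0, "AD": 2.0}


def derive_seed(*parts: int) -> int:
    """Stable sub-seed from a tuple of integers (always < 2**31)."""
    ss = np.random.SeedSequence(list(int(p) for p in parts))
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# topography perturbation
# ---------------------------------------------------------------------------

def _roi_stays_connected(mesh: SurfaceMesh, members: np.ndarray, remove: int) -> bool:
    rest = members[members != remove]
    if rest.size == 0:
        return False
    if rest.size == 1:
        return True
    sub = mesh.adjacency[np.ix_(rest, rest)]
    n_comp, _ = connected_components(sub, directed=False)
    return n_comp == 1


def perturb_topography(atlas: Atlas, mesh: SurfaceMesh, boundary_shift_sd: float,
                       seed: int, scope: str = "network") -> np.ndarray:
    """Shift region boundaries to emulate subject-specific topography.

    Boundary vertices are stochastically reassigned to a geodesically
    neighboring ROI with probability scaling in ``boundary_shift_sd``
    (mesh edge-length units; larger values add extra sweeps so vertices
    can travel further).  Moves that would empty or disconnect the source
    ROI are rejected, so all ROIs stay nonempty and connected; a move to
    an adjacent ROI always leaves the target connected.

    ``scope='network'`` (default) perturbs only vertices on network
    boundaries, reassigning them across the network border — the kind of
    topographic variation an individual network parcellation can actually
    observe.  ``scope='roi'`` perturbs any ROI boundary vertex, including
    within-network ROI borders.

    Returns the per-vertex true ROI labels; ``boundary_shift_sd = 0``
    returns the atlas labels unchanged.
    """
    if boundary_shift_sd < 0:
        raise ConfigurationError("boundary_shift_sd must be >= 0")
    if scope not in ("network", "roi"):
        raise ConfigurationError(f"unknown perturbation scope: {scope!r}")
    labels = atlas.roi_of_vertex.copy()
    if boundary_shift_sd == 0:
        return labels
    net_of_roi = atlas.network_of_roi
    rng = np.random.default_rng(seed)
    n_sweeps = max(1, int(round(boundary_shift_sd)))
    p_move = min(0.5, boundary_shift_sd / (2.0 * n_sweeps))
    for _ in range(n_sweeps):
        order = rng.permutation(mesh.n_vertices)
        for v in order:
            src = labels[v]
            neigh = mesh.neighbors[v]
            if scope == "network":
                differs = net_of_roi[labels[neigh] - 1] != net_of_roi[src - 1]
            else:
                differs = labels[neigh] != src
            targets = np.unique(labels[neigh][differs])
            if targets.size == 0 or rng.random() >= p_move:
                continue
            members = np.flatnonzero(labels == src)
            if not _roi_stays_connected(mesh, members, v):
                continue  # rejected: would empty or disconnect the source ROI
            labels[v] = int(targets[rng.integers(targets.size)])
    return labels


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def _roi_covariance(network_of_roi: np.ndarray, network_cov: np.ndarray) -> np.ndarray:
    """ROI x ROI latent covariance implied by a network-level covariance.

    Off-diagonal entries take the value of ``network_cov`` at the ROIs'
    network pair; the diagonal is 1.  PSD whenever ``network_cov`` is PSD
    with diagonal <= 1.
    """
    idx = network_of_roi - 1
    C = network_cov[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(C, 1.0)
    return C


def _nearest_psd_corr(C: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clip to PSD and rescale back to unit diagonal."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    if w.min() >= floor:
        return C
    w = np.clip(w, floor, None)
    C = (V * w) @ V.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


def simulate_timeseries(true_labels: np.ndarray, network_of_roi: np.ndarray,
                        timepoints: int, network_cov: np.ndarray,
                        vertex_noise_sd, seed: int,
                        conn_shift: dict | None = None,
                        latent_band: tuple | None = (0.009, 0.08),
                        frame_interval_s: float = 3.0):
    """Sample network-structured vertex x time signals.

    Each ROI carries one latent series; latents of ROIs in networks (k, l)
    correlate according to ``network_cov[k-1, l-1]`` (unit variance per
    latent).  ``conn_shift`` maps ROI pairs ``(i, j)`` (1-based) to an
    additive correlation shift, used to plant group effects.  A vertex's
    signal is its ROI latent plus independent white Gaussian noise with
    SD ``vertex_noise_sd`` (scalar or per-vertex).

    By default the latents are band-limited to ``latent_band`` (Hz):
    resting-state fluctuations concentrate at low frequencies, and a
    band-limited latent keeps its degrees of freedom through the
    analysis band-pass while the white measurement noise does not.
    Filtering every latent identically preserves the planted zero-lag
    correlation structure; latents are re-standardized to unit SD.
    Pass ``latent_band=None`` for temporally white latents.

    Returns ``(signals, latents)`` with shapes (V, T) and (n_rois, T).
    """
    network_cov = np.asarray(network_cov, dtype=float)
    if timepoints < 20:
        raise ConfigurationError("timepoints must be >= 20")
    if not np.allclose(network_cov, network_cov.T):
        raise ConfigurationError("network_cov must be symmetric")
    w = np.linalg.eigvalsh(0.5 * (network_cov + network_cov.T))
    if w.min() < -1e-10:
        raise ConfigurationError("network_cov must be positive semi-definite")

    n_rois = len(network_of_roi)
    C = _roi_covariance(network_of_roi, network_cov)
    if conn_shift:
        for (i, j), delta in conn_shift.items():
            C[i - 1, j - 1] += delta
            C[j - 1, i - 1] += delta
        C = _nearest_psd_corr(C)

    rng = np.random.default_rng(seed)
    ew, V = np.linalg.eigh(C)
    L = V * np.sqrt(np.clip(ew, 0, None))
    latents = L @ rng.standard_normal((n_rois, timepoints))
    if latent_band is not None:
        from .qc import bandpass
        latents = bandpass(latents, low=latent_band[0], high=latent_band[1],
                           frame_interval_s=frame_interval_s)
        sd = latents.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        latents = latents / sd

    noise_sd = np.broadcast_to(np.asarray(vertex_noise_sd, dtype=float),
                               (len(true_labels),))
    signals = latents[true_labels - 1]
    signals = signals + noise_sd[:, None] * rng.standard_normal(signals.shape)
    return signals, latents


# ---------------------------------------------------------------------------
# motion
# ---------------------------------------------------------------------------

FD_THRESHOLD = 0.2     # mm
DVARS_THRESHOLD = 50.0


def simulate_motion(timepoints: int, outlier_rate: float, seed: int):
    """Generate FD (mm) and DVARS traces with a planted outlier subset.

    Baseline FD stays below 0.2 mm and baseline DVARS below 50; a
    Bernoulli(``outlier_rate``) subset of frames receives FD and/or DVARS
    above threshold, so the expected raw outlier count is
    ``rate * timepoints``.
    """
    if not 0 <= outlier_rate <= 1:
        raise ConfigurationError("outlier_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fd = np.clip(rng.gamma(shape=4.0, scale=0.02, size=timepoints), 0.005, 0.18)
    dvars = np.clip(rng.normal(30.0, 5.0, size=timepoints), 10.0, 45.0)
    hit = rng.random(timepoints) < outlier_rate
    which = rng.integers(0, 3, size=timepoints)  # 0: fd, 1: dvars, 2: both
    fd_hit = hit & (which != 1)
    dv_hit = hit & (which != 0)
    fd[fd_hit] = FD_THRESHOLD + rng.exponential(0.15, size=fd_hit.sum())
    dvars[dv_hit] = DVARS_THRESHOLD + rng.exponential(15.0, size=dv_hit.sum())
    return fd, dvars


def simulate_nuisance(timepoints: int, seed: int) -> dict:
    """Smooth random-walk proxies for the nuisance regressors.

    Returns six motion parameters plus mean white-matter and ventricle
    signal proxies, each a slowly drifting series (cumulative Gaussian
    steps, lightly smoothed) — enough structure for the regression design
    to be full rank without claiming physiological realism.
    """
    rng = np.random.default_rng(seed)
    def walk(scale):
        x = np.cumsum(rng.normal(0, scale, size=timepoints))
        k = np.ones(5) / 5.0
        return np.convolve(x, k, mode="same")
    motion = np.column_stack([walk(0.02) for _ in range(6)])
    return {"motion_params": motion, "wm": walk(0.5), "ventricle": walk(0.5)}


# ---------------------------------------------------------------------------
# symptoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreModel:
    """Linear generative model for one bounded symptom score."""
    intercept: float
    beta_scale: float      # multiplies each planted connection coefficient
    gamma_age: float       # per year relative to age_ref
    gamma_sex: float
    noise_sd: float
    clamp: tuple = (0.0, 30.0)
    age_ref: float = 72.0


DEFAULT_SCORE_MODELS = {
    # ranges and rough group spreads mirror MMSE-like (0-30) and immediate
    # recall-like (0-25) instruments
    "mmse_like": ScoreModel(intercept=27.5, beta_scale=8.0, gamma_age=-0.05,
                            gamma_sex=0.2, noise_sd=1.5, clamp=(0.0, 30.0)),
    "limm_like": ScoreModel(intercept=11.0, beta_scale=10.0, gamma_age=-0.08,
                            gamma_sex=0.3, noise_sd=2.0, clamp=(0.0, 25.0)),
}


def simulate_symptoms(true_connectivity: np.ndarray, effect_connections,
                      age: float, sex: int,
                      score_models: dict | None = None,
                      seed: int = 0) -> dict:
    """Scores as a linear function of planted connections + confounds + noise.

    score = intercept + beta_scale * sum_k coeff_k * conn(i_k, j_k)
          + gamma_age * (age - age_ref) + gamma_sex * sex + Normal(0, noise_sd),
    clamped to the instrument range of each score model.
    """
    score_models = score_models or DEFAULT_SCORE_MODELS
    rng = np.random.default_rng(seed)
    scores = {}
    for name, m in score_models.items():
        s = m.intercept
        for (i, j, coeff) in effect_connections:
            s += m.beta_scale * coeff * true_connectivity[i - 1, j - 1]
        s += m.gamma_age * (age - m.age_ref) + m.gamma_sex * sex
        s += rng.normal(0.0, m.noise_sd) if m.noise_sd > 0 else 0.0
        scores[name] = float(np.clip(s, *m.clamp))
    return scores


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    """One synthetic participant, plus the generator's ground truth."""
    subject_id: str
    signals: np.ndarray          # (V, T)
    fd: np.ndarray               # (T,)
    dvars: np.ndarray            # (T,)
    nuisance: dict               # motion_params (T, 6), wm, ventricle
    age: float
    sex: int                     # 0 / 1
    group: str                   # NA / MCI / AD
    genotype: str                # carrier / noncarrier
    symptom_scores: dict         # mmse_like, limm_like
    true_labels: np.ndarray      # (V,) planted ROI labels
    true_connectivity: np.ndarray  # (R, R) empirical latent correlation


# cell counts of the emulated two-genotype cohort: three clinical subgroups
# in ~120 carriers and ~115 noncarriers
DEFAULT_CELLS = {
    ("NA", "carrier"): 42, ("MCI", "carrier"): 39, ("AD", "carrier"): 39,
    ("NA", "noncarrier"): 43, ("MCI", "noncarrier"): 39, ("AD", "noncarrier"): 33,
}


@dataclass
class CohortConfig:
    cells: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    n_vertices: int = 642
    topology: str = "icosphere"
    n_networks: int = 18
    n_rois: int = 116
    timepoints: int = 196
    boundary_shift_sd: float = 1.0
    vertex_noise_sd: float = 0.5          # latent SD is 1: SNR ~ 2
    network_cov_within: float = 0.6
    network_cov_between: float = 0.1
    motion_outlier_rate: float = 0.05
    latent_band: tuple | None = (0.009, 0.08)  # Hz; None = white latents
    frame_interval_s: float = 3.0
    group_effect: float = -0.15           # per severity step, per connection
    n_effect_connections: int = 2
    effect_connections: dict | None = None  # genotype -> [(i, j, coeff)]
    score_models: dict = field(default_factory=lambda: dict(DEFAULT_SCORE_MODELS))
    seed: int = 0

    def network_cov(self) -> np.ndarray:
        C = np.full((self.n_networks, self.n_networks), self.network_cov_between)
        np.fill_diagonal(C, self.network_cov_within)
        return C


def pick_effect_connections(atlas: Atlas, n_effects: int, seed: int,
                            coeff: float = 1.0, exclude=()) -> list:
    """Deterministically pick between-network ROI pairs as planted effects."""
    rng = np.random.default_rng(seed)
    taken = {tuple(sorted((i, j))) for (i, j, _) in exclude}
    out = []
    net = atlas.network_of_roi
    for _ in range(10000):
        if len(out) >= n_effects:
            break
        i, j = sorted(rng.integers(1, atlas.n_rois + 1, size=2))
        if i == j or net[i - 1] == net[j - 1] or (i, j) in taken:
            continue
        taken.add((i, j))
        out.append((int(i), int(j), coeff))
    if len(out) < n_effects:
        raise ConfigurationError("could not place the requested effect connections")
    return out


@dataclass
class CohortTruth:
    mesh: SurfaceMesh
    atlas: Atlas
    effect_connections: dict      # genotype -> [(i, j, coeff)]
    group_effect: float


def truth_variability_map(atlas: Atlas, mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex inter-individual variability prior derived from truth.

    Boundary perturbation only ever moves vertices near atlas ROI
    boundaries, so variability is encoded as graph distance to the nearest
    boundary: 1 on boundary vertices, 0.5 one step away, 0 elsewhere.
    """
    lab = atlas.roi_of_vertex
    boundary = np.array([np.any(lab[mesh.neighbors[v]] != lab[v])
                         for v in range(mesh.n_vertices)])
    var = np.zeros(mesh.n_vertices)
    var[boundary] = 1.0
    near = np.array([np.any(boundary[mesh.neighbors[v]]) for v in range(mesh.n_vertices)])
    var[near & ~boundary] = 0.5
    return var


def truth_snr_map(vertex_noise_sd, n_vertices: int) -> np.ndarray:
    """Map generator noise SDs onto a [0, 1] SNR weight (1 = noise-free)."""
    sd = np.broadcast_to(np.asarray(vertex_noise_sd, dtype=float), (n_vertices,))
    return 1.0 / (1.0 + sd)


def make_cohort(config: CohortConfig):
    """Generate the full cohort: (list of SubjectRecord, CohortTruth).

    Per subject: perturbed topography -> latent/vertex time series (with
    group mean shifts on the genotype's effect connections) -> motion and
    nuisance traces -> symptom scores from the subject's realized latent
    connectivity.  All randomness derives from ``config.seed``.
    """
    for k, v in config.cells.items():
        if v <= 0:
            raise ConfigurationError(f"cell count must be positive: {k}")
    mesh = make_mesh(config.n_vertices, config.topology)
    atlas = make_atlas(mesh, config.n_networks, config.n_rois,
                       seed=derive_seed(config.seed, 101))
    effects = config.effect_connections
    if effects is None:
        eff_c = pick_effect_connections(atlas, config.n_effect_connections,
                                        derive_seed(config.seed, 202))
        eff_n = pick_effect_connections(atlas, config.n_effect_connections,
                                        derive_seed(config.seed, 203), exclude=eff_c)
        effects = {"carrier": eff_c, "noncarrier": eff_n}
    for geno, lst in effects.items():
        for (i, j, _) in lst:
            if not (1 <= i <= config.n_rois and 1 <= j <= config.n_rois and i != j):
                raise ConfigurationError(f"invalid effect connection ({i}, {j})")

    net_cov = config.network_cov()
    records = []
    idx = 0
    for group in GROUPS:
        for genotype in GENOTYPES:
            n = config.cells.get((group, genotype), 0)
            for _ in range(n):
                rng = np.random.default_rng(derive_seed(config.seed, idx, 1))
                age = float(np.clip(rng.normal(72.0, 6.5), 55.0, 95.0))
                sex = int(rng.integers(2))
                labels = perturb_topography(atlas, mesh, config.boundary_shift_sd,
                                            derive_seed(config.seed, idx, 2))
                sev = GROUP_SEVERITY[group]
                shift = {(i, j): sev * config.group_effect * np.sign(c) if c != 0
                         else 0.0
                         for (i, j, c) in effects[genotype]}
                signals, latents = simulate_timeseries(
                    labels, atlas.network_of_roi, config.timepoints, net_cov,
                    config.vertex_noise_sd, derive_seed(config.seed, idx, 3),
                    conn_shift=shift, latent_band=config.latent_band,
                    frame_interval_s=config.frame_interval_s)
                true_conn = np.corrcoef(latents)
                fd, dvars = simulate_motion(config.timepoints,
                                            config.motion_outlier_rate,
                                            derive_seed(config.seed, idx, 4))
                nuis = simulate_nuisance(config.timepoints,
                                         derive_seed(config.seed, idx, 5))
                scores = simulate_symptoms(true_conn, effects[genotype], age, sex,
                                           config.score_models,
                                           derive_seed(config.seed, idx, 6))
                records.append(SubjectRecord(
                    subject_id=f"sub-{idx:04d}", signals=signals, fd=fd,
                    dvars=dvars, nuisance=nuis, age=age, sex=sex, group=group,
                    genotype=genotype, symptom_scores=scores, true_labels=labels,
                    true_connectivity=true_conn))
                idx += 1
    truth = CohortTruth(mesh=mesh, atlas=atlas, effect_connections=effects,
                        group_effect=config.group_effect)
    return records, truth
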