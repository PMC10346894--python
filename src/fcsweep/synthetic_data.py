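"""Multi-subject synthetic BOLD cohorts with a planted node correlation structure.

The generator emulates the acquisition geometry of the target study (3 s TR,
3 mm isotropic voxels, a 300 s resting run and a 288 s block-design encoding
run) while planting a known block correlation matrix over the ROI nodes, so
that every downstream stage — smoothing, connectivity, graph metrics,
decomposition — can be validated against ground truth without any download.

Latent node signals are Gaussian with a prescribed correlation matrix;
every voxel inside an ROI carries its node's latent signal plus independent
Gaussian noise, and background voxels are pure noise. Between-subject
heterogeneity perturbs the Fisher-z-transformed correlations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .types import FmriImage, RoiAtlas

# The 32 node labels, ordered by major network block (8 networks):
# default mode, somatomotor, visual, salience, dorsal attention,
# frontoparietal, language, cerebellar.
DEFAULT_NODE_NAMES: tuple[str, ...] = (
    "DMN.MPFC", "DMN.LP.l", "DMN.LP.r", "DMN.PCC",
    "SMN.Lateral.l", "SMN.Lateral.r", "SMN.Superior",
    "VN.Medial", "VN.Occipital", "VN.Lateral.l", "VN.Lateral.r",
    "SN.ACC", "SN.AInsula.l", "SN.AInsula.r", "SN.RPFC.l", "SN.RPFC.r",
    "SN.SMG.l", "SN.SMG.r",
    "DAN.FEF.l", "DAN.FEF.r", "DAN.IPS.l", "DAN.IPS.r",
    "FPN.LPFC.l", "FPN.LPFC.r", "FPN.PPC.l", "FPN.PPC.r",
    "LN.IFG.l", "LN.IFG.r", "LN.pSTG.l", "LN.pSTG.r",
    "C.Anterior", "C.Posterior",
)


@dataclass
class TaskDesign:
    """Block-design timing: leading baseline, then stimulus/gap trials."""

    baseline_s: float = 30.0
    stim_s: float = 6.0
    gap_s: float = 1.0
    n_trials: int = 24

    def __post_init__(self) -> None:
        if self.baseline_s < 0 or self.stim_s <= 0 or self.gap_s < 0:
            raise ValueError("task durations must be positive")
        if self.n_trials < 0:
            raise ValueError("n_trials must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.n_trials * (self.stim_s + self.gap_s)

    def stimulus_onsets_s(self) -> np.ndarray:
        return self.baseline_s + np.arange(self.n_trials) * (self.stim_s + self.gap_s)


@dataclass
class SimulationConfig:
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr_s: float = 3.0
    n_volumes: int = 100
    n_subjects: int = 20
    n_nodes: int = 32
    n_blocks: int = 8
    rho_within: float = 0.6
    rho_between: float = 0.1
    subject_tau: float = 0.1
    noise_sd: float = 1.0
    roi_radius_vox: int = 2
    task: TaskDesign | None = None
    task_amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(g) for g in self.grid_shape)
        if len(self.grid_shape) != 3 or any(g < 1 for g in self.grid_shape):
            raise ValueError(f"invalid grid shape {self.grid_shape}")
        if not (-1 < self.rho_within < 1 and -1 < self.rho_between < 1):
            raise ValueError("planted correlations must lie in (-1, 1)")
        if self.n_volumes < 2:
            raise ValueError("need at least 2 volumes")
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        if self.n_nodes < 1 or self.n_blocks < 1 or self.n_blocks > self.n_nodes:
            raise ValueError("need 1 <= n_blocks <= n_nodes")
        if self.voxel_size_mm <= 0 or self.tr_s <= 0 or self.noise_sd < 0:
            raise ValueError("geometry/noise parameters must be positive")

    def node_names(self) -> list[str]:
        if self.n_nodes == len(DEFAULT_NODE_NAMES):
            return list(DEFAULT_NODE_NAMES)
        return [f"node{i:02d}" for i in range(1, self.n_nodes + 1)]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        if d.get("task") is not None:
            d["task"] = TaskDesign(**d["task"])
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted for one subject: shared sigma/atlas + subject specifics."""

    sigma_true: np.ndarray
    sigma_subject: np.ndarray
    atlas: RoiAtlas
    node_timeseries: np.ndarray  # N x T latent signals, standardized rows


def _seed_streams(seed: int, n_subjects: int) -> dict[str, object]:
    """Deterministic per-stage RNG derivation from one master seed."""
    root = np.random.SeedSequence(seed)
    atlas_ss, sigma_ss, subj_ss = root.spawn(3)
    per_subject = subj_ss.spawn(n_subjects)
    return {
        "atlas": np.random.default_rng(atlas_ss),
        "sigma": np.random.default_rng(sigma_ss),
        "subjects": [
            # separate streams for the latent signal, the subject's sigma
            # perturbation and the voxel noise of each subject
            tuple(np.random.default_rng(s) for s in ss.spawn(3))
            for ss in per_subject
        ],
    }


def planted_sigma(n_nodes: int, n_blocks: int,
                  rho_within: float, rho_between: float) -> np.ndarray:
    """Block-constant correlation matrix over an even split of the nodes.

    Entries are ``rho_within`` inside a block, ``rho_between`` across blocks
    and 1 on the diagonal. Raises if the combination is not positive definite.
    """
    if not (1 <= n_blocks <= n_nodes):
        raise ValueError("need 1 <= n_blocks <= n_nodes")
    membership = np.concatenate(
        [np.full(len(chunk), b)
         for b, chunk in enumerate(np.array_split(np.arange(n_nodes), n_blocks))]
    )
    same_block = membership[:, None] == membership[None, :]
    sigma = np.where(same_block, rho_within, rho_between).astype(np.float64)
    np.fill_diagonal(sigma, 1.0)
    min_eig = float(np.linalg.eigvalsh(sigma).min())
    if min_eig <= 0:
        raise ValueError(
            f"planted correlation matrix is not positive definite "
            f"(smallest eigenvalue {min_eig:.3e})"
        )
    return sigma


def block_membership(n_nodes: int, n_blocks: int) -> np.ndarray:
    """Block index of each node under the even split used by planted_sigma."""
    return np.concatenate(
        [np.full(len(chunk), b)
         for b, chunk in enumerate(np.array_split(np.arange(n_nodes), n_blocks))]
    )


def sample_node_timeseries(sigma: np.ndarray, n_volumes: int,
                           rng: np.random.Generator | int) -> np.ndarray:
    """Draw N x T Gaussian signals with population correlation ``sigma``.

    Rows are standardized to zero mean / unit variance after sampling.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sigma = np.asarray(sigma, dtype=np.float64)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sigma must be positive definite") from exc
    raw = chol @ rng.standard_normal((sigma.shape[0], n_volumes))
    return standardize_rows(raw)


def standardize_rows(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return centered / sd


def hrf_double_gamma(t_s: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response, amplitude-normalized.

    Unit-scale gamma densities peaking at ``peak_s`` and ``undershoot_s``
    (shape = peak + 1 for a mode at the requested time), combined with the
    given undershoot ratio, then scaled so the positive peak equals 1.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    peak = stats.gamma.pdf(t_s, a=peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(t_s, a=undershoot_s + 1.0, scale=1.0)
    h = peak - undershoot_ratio * under
    m = h.max()
    return h / m if m > 0 else h


def make_task_regressor(task: TaskDesign, tr_s: float, n_volumes: int,
                        dt_s: float = 0.1) -> np.ndarray:
    """Boxcar of stimulus intervals convolved with the double-gamma response.

    The convolution is evaluated on a fine grid (``dt_s``) and sampled at the
    TR, truncated to ``n_volumes`` samples.
    """
    run_s = n_volumes * tr_s
    if task.duration_s > run_s + 1e-9:
        raise ValueError(
            f"task design of {task.duration_s:.1f}s does not fit a {run_s:.1f}s run"
        )
    if task.n_trials == 0:
        return np.zeros(n_volumes)
    t_fine = np.arange(0.0, run_s + 32.0, dt_s)
    boxcar = np.zeros_like(t_fine)
    for onset in task.stimulus_onsets_s():
        boxcar[(t_fine >= onset) & (t_fine < onset + task.stim_s)] = 1.0
    hrf = hrf_double_gamma(np.arange(0.0, 32.0, dt_s))
    response = np.convolve(boxcar, hrf)[: t_fine.size] * dt_s
    sample_idx = np.round(np.arange(n_volumes) * tr_s / dt_s).astype(int)
    return response[sample_idx]


def make_parcellation(config: SimulationConfig, max_tries: int = 20000) -> RoiAtlas:
    """Place ``n_nodes`` disjoint spherical ROIs on the grid by rejection sampling.

    ROIs are discrete balls of ``roi_radius_vox``; centers are kept at least
    ``2*radius + 1`` apart, guaranteeing disjointness. Deterministic per seed.
    """
    rng = _seed_streams(config.seed, config.n_subjects)["atlas"]
    r = config.roi_radius_vox
    shape = np.array(config.grid_shape)
    lo, hi = r, shape - r  # keep full ball inside the grid
    if np.any(hi <= lo):
        raise ValueError(
            f"grid too small: shape {config.grid_shape} cannot host ROIs of "
            f"radius {r} voxels"
        )
    min_dist2 = (2 * r + 1) ** 2
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < config.n_nodes:
        if tries >= max_tries:
            raise ValueError(
                f"grid too small: placed {len(centers)}/{config.n_nodes} ROIs of "
                f"radius {r} with min center distance {2 * r + 1} after "
                f"{max_tries} tries on grid {config.grid_shape}"
            )
        tries += 1
        c = np.array([rng.integers(lo, h) for h in hi])
        if all(np.sum((c - p) ** 2) >= min_dist2 for p in centers):
            centers.append(c)

    off = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
    ball = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    ball = ball[np.sum(ball**2, axis=1) <= r**2]

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    for i, c in enumerate(centers, start=1):
        vox = c + ball
        labels[vox[:, 0], vox[:, 1], vox[:, 2]] = i
    return RoiAtlas(labels=labels, node_names=config.node_names(),
                    voxel_size_mm=(config.voxel_size_mm,) * 3)


def _nearest_correlation_pd(sigma: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalization to unit diagonal."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() > floor:
        return sigma
    vals = np.clip(vals, floor, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def perturb_subject_sigma(sigma_true: np.ndarray, tau: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Subject-specific correlations: N(0, tau^2) jitter on the Fisher-z scale."""
    n = sigma_true.shape[0]
    if tau == 0:
        return sigma_true.copy()
    z = np.arctanh(np.clip(sigma_true, -1 + 1e-12, 1 - 1e-12))
    noise = rng.normal(0.0, tau, size=(n, n))
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    sigma = np.tanh(z + noise)
    np.fill_diagonal(sigma, 1.0)
    return _nearest_correlation_pd(sigma)


def sample_cohort_timeseries(config: SimulationConfig) -> list[np.ndarray]:
    """Latent node signals for every subject, without volumetric rendering.

    Fast path for statistical validation of the group pipeline: returns the
    same per-subject latent series that render_cohort embeds in the voxels.
    """
    sigma_true = planted_sigma(config.n_nodes, config.n_blocks,
                               config.rho_within, config.rho_between)
    streams = _seed_streams(config.seed, config.n_subjects)
    out = []
    for signal_rng, sigma_rng, _noise_rng in streams["subjects"]:
        sigma_s = perturb_subject_sigma(sigma_true, config.subject_tau, sigma_rng)
        out.append(sample_node_timeseries(sigma_s, config.n_volumes, signal_rng))
    return out


def render_cohort(config: SimulationConfig) -> list[tuple[FmriImage, GroundTruth]]:
    """Render the full cohort of 4D images.

    Every voxel of node k carries that subject's latent node-k signal (plus
    the task response scaled by ``task_amplitude`` when a task is configured);
    background voxels are pure Gaussian noise of SD ``noise_sd``. Fully
    reproducible from ``config.seed``.
    """
    atlas = make_parcellation(config)
    sigma_true = planted_sigma(config.n_nodes, config.n_blocks,
                               config.rho_within, config.rho_between)
    streams = _seed_streams(config.seed, config.n_subjects)
    regressor = None
    if config.task is not None:
        regressor = make_task_regressor(config.task, config.tr_s, config.n_volumes)

    cohort = []
    flat_labels = atlas.labels.ravel()
    for signal_rng, sigma_rng, noise_rng in streams["subjects"]:
        sigma_s = perturb_subject_sigma(sigma_true, config.subject_tau, sigma_rng)
        node_ts = sample_node_timeseries(sigma_s, config.n_volumes, signal_rng)
        signal = node_ts
        if regressor is not None:
            signal = node_ts + config.task_amplitude * regressor[None, :]
        data = np.zeros((flat_labels.size, config.n_volumes))
        in_roi = flat_labels > 0
        data[in_roi] = signal[flat_labels[in_roi] - 1]
        if config.noise_sd > 0:
            data += noise_rng.normal(0.0, config.noise_sd,
                                     size=data.shape)
        image = FmriImage(
            data=data.reshape(*config.grid_shape, config.n_volumes),
            voxel_size_mm=(config.voxel_size_mm,) * 3,
            tr_s=config.tr_s,
        )
        cohort.append((image, GroundTruth(sigma_true=sigma_true, sigma_subject=sigma_s,
                                          atlas=atlas, node_timeseries=node_ts)))
    return cohort


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> list[Path]:
    """Write NIfTI images, the atlas, sigma/node-name TSVs and the config JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = render_cohort(config)
    paths = []
    for i, (image, _truth) in enumerate(cohort, start=1):
        p = out_dir / f"subject{i:02d}.nii.gz"
        image.save(p)
        paths.append(p)
    atlas = cohort[0][1].atlas
    atlas.save(out_dir / "atlas.nii.gz")
    names = atlas.node_names
    sigma = cohort[0][1].sigma_true
    with open(out_dir / "sigma_true.tsv", "w") as fh:
        fh.write("\t".join(["node"] + names) + "\n")
        for name, row in zip(names, sigma):
            fh.write(name + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    (out_dir / "node_names.tsv").write_text("\n".join(names) + "\n")
    (out_dir / "config.json").write_text(config.to_json() + "\n")
    return paths
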