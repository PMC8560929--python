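"""Source-to-sensor forward model and synthetic seizure datasets.

The forward model maps regional source activity to SEEG sensors through a
gain matrix with inverse-square distance decay (no dipole-orientation
dependence).  The synthetic-data half of the module stands in for a patient
connectome and electrode implantation: it builds a reproducible random
geometry, couples 5D Epileptor nodes on it, and generates ground-truth
seizure propagation datasets in the standard scenario — two epileptogenic
regions at excitability x0 = -1.8, four strongly-connected propagation
regions at x0 = -2.3, all remaining regions at the background value -3.0 —
with optional zero-mean Gaussian sensor noise at a target channel-averaged
SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dynamics import (
    Epileptor5DParams,
    Trajectory,
    derivatives_5d,
    fixed_point_5d,
    integrate_heun,
)

__all__ = [
    "Connectome",
    "RegionSurface",
    "SensorArray",
    "GainMatrix",
    "SeizureScenario",
    "SyntheticDataset",
    "compute_gain",
    "project_to_sensors",
    "generate_synthetic_network",
    "scenario_network",
    "simulate_seizure_dataset",
    "add_observation_noise",
    "load_connectome",
    "load_sensors",
    "load_surfaces",
]


@dataclass
class Connectome:
    """Nonnegative coupling matrix, max-normalized, with region labels."""

    weights: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float).copy()
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectome must be a square matrix")
        if np.any(w < 0):
            raise ValueError("connectome weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        m = w.max()
        if m > 0:
            w = w / m  # normalize so the maximum entry equals one
        self.weights = w
        if not self.region_labels:
            self.region_labels = [f"region-{i}" for i in range(w.shape[0])]
        if len(self.region_labels) != w.shape[0]:
            raise ValueError("label count must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def save(self, path) -> None:
        np.savetxt(path, self.weights)
        Path(str(path) + ".labels").write_text("\n".join(self.region_labels) + "\n")


@dataclass
class RegionSurface:
    """Vertex cloud representing one region's surface, with per-vertex areas."""

    region_index: int
    vertices: np.ndarray  # (n_vertices, 3)
    areas: np.ndarray  # (n_vertices,)

    def __post_init__(self):
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        self.areas = np.atleast_1d(np.asarray(self.areas, dtype=float))
        if self.vertices.shape[0] < 1:
            raise ValueError("region needs at least one vertex")
        if self.vertices.shape[1] != 3:
            raise ValueError("vertices must be 3-D points")
        if self.areas.shape[0] != self.vertices.shape[0]:
            raise ValueError("one area per vertex required")
        if np.any(self.areas <= 0):
            raise ValueError("vertex areas must be positive")


@dataclass
class SensorArray:
    """SEEG contact positions and channel labels."""

    positions: np.ndarray  # (M, 3)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 1 or self.positions.shape[1] != 3:
            raise ValueError("need M >= 1 sensors with 3-D positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        if not self.labels:
            self.labels = [f"ch-{i}" for i in range(self.positions.shape[0])]
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("one label per sensor required")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]


@dataclass
class GainMatrix:
    """M x N source-to-sensor mixing matrix with scaling coefficient c."""

    G: np.ndarray
    c: float = 1.0

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        if np.any(self.G < 0) or not np.all(np.isfinite(self.G)):
            raise ValueError("gain entries must be nonnegative and finite")

    @property
    def shape(self):
        return self.G.shape


def compute_gain(
    surfaces: Sequence[RegionSurface],
    sensors: SensorArray,
    c: float = 1.0,
    dist_floor: float = 1.0,
    row_normalize: bool = False,
) -> GainMatrix:
    """Inverse-square distance gain: G_ij = sum_k c*A_k / |x_i^s - x_k^v|^2.

    Distances are clamped below at ``dist_floor`` (same length unit as the
    coordinates; default 1) to avoid the 1/r^2 singularity when a contact
    sits essentially on a vertex.  Set ``dist_floor=0`` to disable clamping,
    in which case a coincident sensor/vertex pair raises.  With
    ``row_normalize`` each sensor row is scaled to unit sum; the global
    scale is otherwise absorbed by the likelihood's amplitude parameter.
    """
    order = np.argsort([s.region_index for s in surfaces])
    surfaces = [surfaces[i] for i in order]
    M = sensors.n_sensors
    N = len(surfaces)
    G = np.zeros((M, N))
    for j, surf in enumerate(surfaces):
        # (M, n_vertices) squared distances
        diff = sensors.positions[:, None, :] - surf.vertices[None, :, :]
        d2 = np.sum(diff ** 2, axis=-1)
        if dist_floor > 0:
            d2 = np.maximum(d2, dist_floor ** 2)
        elif np.any(d2 == 0):
            raise ValueError(
                "sensor coincides with a surface vertex and clamping is disabled"
            )
        G[:, j] = np.sum(c * surf.areas[None, :] / d2, axis=1)
    if row_normalize:
        G = G / G.sum(axis=1, keepdims=True)
    return GainMatrix(G=G, c=c)


def project_to_sensors(source_activity: np.ndarray, gain: GainMatrix) -> np.ndarray:
    """Linear mixing: sensor signals (M, T) from source activity (N, T)."""
    phi = np.atleast_2d(np.asarray(source_activity, dtype=float))
    G = gain.G
    if G.shape[1] != phi.shape[0]:
        raise ValueError(
            f"gain has {G.shape[1]} source columns but activity has "
            f"{phi.shape[0]} rows"
        )
    return G @ phi


# ---------------------------------------------------------------------------
# synthetic network fixture
# ---------------------------------------------------------------------------

def generate_synthetic_network(
    n_regions: int = 24,
    n_sensors: int = 96,
    ez: Sequence[int] = (0, 1),
    pz: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    box_size: float = 80.0,
    vertices_per_region: int = 12,
) -> tuple[Connectome, list[RegionSurface], SensorArray]:
    """Reproducible random brain-like geometry and connectome.

    Region centroids are scattered in an ``box_size`` mm cube, each carrying
    a small vertex cloud with positive areas.  Sensors are placed in the
    vicinity of the EZ/PZ centroids (mimicking a clinical implantation
    targeting the suspected focus), the remainder near random other
    regions.  Connectome weights are log-normal background values with
    strong EZ-PZ (and EZ-EZ) links, then max-normalized to one.
    """
    ez = sorted(set(int(i) for i in ez))
    pz = sorted(set(int(i) for i in pz))
    if set(ez) & set(pz):
        raise ValueError("EZ and PZ region sets must be disjoint")
    for i in ez + pz:
        if not 0 <= i < n_regions:
            raise ValueError(f"region index {i} out of range")
    rng = np.random.default_rng(seed)

    centroids = rng.uniform(0.0, box_size, size=(n_regions, 3))
    surfaces = []
    for j in range(n_regions):
        verts = centroids[j] + rng.normal(0.0, 4.0, size=(vertices_per_region, 3))
        areas = rng.lognormal(mean=0.3, sigma=0.3, size=vertices_per_region)
        surfaces.append(RegionSurface(region_index=j, vertices=verts, areas=areas))

    # sparse log-normal background weights, strong links within the seizure
    # network; the scale separation lets the seizure recruit the PZ without
    # the rest of the network dragging the EZ back to rest.  The connectome
    # is drawn before the sensors so the source dynamics for a given seed
    # do not depend on the implantation size.
    w = rng.lognormal(mean=-4.0, sigma=0.8, size=(n_regions, n_regions))
    for p in pz:
        for e in ez:
            w[p, e] = w[e, p] = rng.uniform(2.0, 3.0)
    for a in ez:
        for b in ez:
            if a != b:
                w[a, b] = w[b, a] = rng.uniform(2.0, 3.0)
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    connectome = Connectome(weights=w)  # max-normalizes

    # implantation: cycle sensors through EZ/PZ centroids first, then others
    targets = list(ez) + list(pz)
    others = [j for j in range(n_regions) if j not in targets]
    sensor_pos = np.empty((n_sensors, 3))
    for s in range(n_sensors):
        if s < 2 * len(targets):
            region = targets[s % len(targets)]
        else:
            region = others[int(rng.integers(len(others)))] if others else targets[0]
        sensor_pos[s] = centroids[region] + rng.normal(0.0, 5.0, size=3)
    sensors = SensorArray(positions=sensor_pos)
    return connectome, surfaces, sensors


def scenario_network(
    n_regions: int = 24,
    n_sensors: int = 96,
    ez: Sequence[int] = (0, 1),
    pz: Sequence[int] = (2, 3, 4, 5),
    seed: int = 0,
    row_normalize: bool = True,
) -> tuple[Connectome, GainMatrix]:
    """Network + gain matrix for the standard validation scenario.

    Convenience wrapper: generates the synthetic geometry and builds the
    gain matrix with row normalization (each contact sees a weighted
    average of regional activity, keeping channel power on a common scale
    as in clinical recordings; the likelihood's amplitude and offset
    parameters absorb the global scale).
    """
    connectome, surfaces, sensors = generate_synthetic_network(
        n_regions=n_regions, n_sensors=n_sensors, ez=ez, pz=pz, seed=seed)
    gain = compute_gain(surfaces, sensors, row_normalize=row_normalize)
    return connectome, gain


# ---------------------------------------------------------------------------
# scenario simulation
# ---------------------------------------------------------------------------

@dataclass
class SeizureScenario:
    """Ground-truth seizure configuration and simulation settings.

    Excitabilities follow the standard validation scenario: EZ regions at
    -1.8 (autonomously seizing), PZ regions at -2.3 (recruited through
    coupling), background at -3.0.  Model time is dimensionless; the
    simulated span is mapped onto a nominal recording of
    ``recording_duration_s`` seconds so that onset tolerances can be stated
    in seconds.
    """

    ez_regions: tuple[int, ...] = (0, 1)
    pz_regions: tuple[int, ...] = (2, 3, 4, 5)
    x0_ez: float = -1.8
    x0_pz: float = -2.3
    x0_background: float = -3.0
    K: float = 1.0
    dt: float = 0.04
    duration: float = 2500.0
    record_every: int = 5
    recording_duration_s: float = 300.0
    onset_threshold: float = 0.0
    target_snr: Optional[float] = None  # None = noiseless
    init_perturbation: float = 0.0
    init_z: float = 3.5  # starting permittivity (interictal branch)
    process_noise_sd: float = 0.05  # on the fast variables only

    def __post_init__(self):
        self.ez_regions = tuple(sorted(set(int(i) for i in self.ez_regions)))
        self.pz_regions = tuple(sorted(set(int(i) for i in self.pz_regions)))
        if set(self.ez_regions) & set(self.pz_regions):
            raise ValueError("EZ and PZ region sets must be disjoint")
        if not (self.x0_ez > self.x0_pz > self.x0_background):
            raise ValueError("expected x0_ez > x0_pz > x0_background")

    def x0_map(self, n_regions: int) -> np.ndarray:
        x0 = np.full(n_regions, self.x0_background)
        x0[list(self.ez_regions)] = self.x0_ez
        x0[list(self.pz_regions)] = self.x0_pz
        return x0

    @property
    def seconds_per_unit(self) -> float:
        return self.recording_duration_s / self.duration

    def feature_config(self, **overrides):
        """Log-power settings matched to this scenario's time mapping.

        The nominal time mapping puts the ictal discharge fundamental near
        2 Hz (rather than the >10 Hz of clinical SEEG), so the high-pass
        that separates discharges from the slow envelope sits at 1 Hz
        here; everything else keeps the standard defaults.
        """
        from .features import FeatureConfig

        kwargs = {"highpass_hz": 1.0}
        kwargs.update(overrides)
        return FeatureConfig(**kwargs)

    def to_dict(self) -> dict:
        return {
            "ez_regions": list(self.ez_regions),
            "pz_regions": list(self.pz_regions),
            "x0_ez": self.x0_ez,
            "x0_pz": self.x0_pz,
            "x0_background": self.x0_background,
            "K": self.K,
            "dt": self.dt,
            "duration": self.duration,
            "record_every": self.record_every,
            "recording_duration_s": self.recording_duration_s,
            "onset_threshold": self.onset_threshold,
            "target_snr": self.target_snr,
            "init_perturbation": self.init_perturbation,
            "init_z": self.init_z,
            "process_noise_sd": self.process_noise_sd,
        }


@dataclass
class SyntheticDataset:
    """A complete simulated recording with its ground truth."""

    source: Trajectory  # states (T, 6, N)
    seeg_clean: np.ndarray  # (M, T)
    seeg_noisy: np.ndarray  # (M, T)
    times_s: np.ndarray  # (T,) recording time in seconds
    gain: GainMatrix
    scenario: SeizureScenario
    seed: int
    true_recruited: np.ndarray  # (N,) bool
    true_onsets_s: np.ndarray  # (N,) seconds; NaN where not recruited
    connectome: Optional[Connectome] = None

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times_s[1] - self.times_s[0])

    @property
    def n_regions(self) -> int:
        return self.source.states.shape[2]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "dataset.npz",
            source_times=self.source.times,
            source_states=self.source.states,
            seeg_clean=self.seeg_clean,
            seeg_noisy=self.seeg_noisy,
            times_s=self.times_s,
            gain=self.gain.G,
            true_recruited=self.true_recruited,
            true_onsets_s=self.true_onsets_s,
            connectome=(self.connectome.weights if self.connectome is not None
                        else np.empty((0, 0))),
        )
        meta = {
            "scenario": self.scenario.to_dict(),
            "seed": self.seed,
            "true_recruited": [int(i) for i in np.flatnonzero(self.true_recruited)],
            "true_onsets_s": {
                str(i): float(self.true_onsets_s[i])
                for i in np.flatnonzero(self.true_recruited)
            },
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "SyntheticDataset":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        with np.load(directory / "dataset.npz") as f:
            cw = f["connectome"] if "connectome" in f else np.empty((0, 0))
            return cls(
                source=Trajectory(f["source_times"], f["source_states"]),
                seeg_clean=f["seeg_clean"],
                seeg_noisy=f["seeg_noisy"],
                times_s=f["times_s"],
                gain=GainMatrix(G=f["gain"]),
                scenario=SeizureScenario(**meta["scenario"]),
                seed=meta["seed"],
                true_recruited=f["true_recruited"],
                true_onsets_s=f["true_onsets_s"],
                connectome=Connectome(weights=cw) if cw.size else None,
            )


def _detect_source_onsets(
    x1: np.ndarray, times: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """First upward threshold crossing per region; (recruited, onset times)."""
    above = x1 >= threshold  # (T, N)
    recruited = above.any(axis=0)
    onsets = np.full(x1.shape[1], np.nan)
    for i in np.flatnonzero(recruited):
        onsets[i] = times[int(np.argmax(above[:, i]))]
    return recruited, onsets


def simulate_seizure_dataset(
    scenario: SeizureScenario,
    connectome: Connectome,
    gain: GainMatrix,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate the 5D Epileptor network and project to SEEG sensors.

    All nodes start at the interictal fixed point of an isolated node with
    background excitability; EZ nodes then drift into seizure on the slow
    permittivity timescale, recruiting connected PZ nodes.  The local field
    potential x1 + x2 is mixed into sensor space by the gain matrix;
    Gaussian noise is added when the scenario requests a finite SNR.
    Ground-truth recruitment and onset times come from thresholding the
    simulated source activity x1.
    """
    n = connectome.n_regions
    if gain.G.shape[1] != n:
        raise ValueError("gain matrix columns must match the connectome size")
    x0 = scenario.x0_map(n)
    params = Epileptor5DParams(x0=x0, K=scenario.K, C=connectome.weights)
    fp = fixed_point_5d(scenario.x0_background, params, z_value=scenario.init_z)
    init = np.tile(fp[:, None], (1, n))  # (6, N)
    rng = np.random.default_rng(seed)
    if scenario.init_perturbation > 0:
        init = init + scenario.init_perturbation * rng.standard_normal(init.shape)

    # process noise emulates ongoing background activity on the fast
    # subsystems; the slow permittivity and the convolution state stay
    # deterministic so recruitment is governed by the coupling
    noise_sd = np.zeros((6, 1))
    noise_sd[[0, 1, 3, 4], 0] = scenario.process_noise_sd
    traj = integrate_heun(
        lambda s: derivatives_5d(s, params),
        init,
        dt=scenario.dt,
        duration=scenario.duration,
        record_every=scenario.record_every,
        noise_sd=noise_sd,
        rng=rng,
    )
    times_s = traj.times * scenario.seconds_per_unit
    x1 = traj.states[:, 0, :]  # (T, N)
    x2 = traj.states[:, 3, :]
    lfp = (x1 + x2).T  # (N, T)
    seeg_clean = project_to_sensors(lfp, gain)
    if scenario.target_snr is None or np.isinf(scenario.target_snr):
        seeg_noisy = seeg_clean.copy()
    else:
        seeg_noisy = add_observation_noise(
            seeg_clean, scenario.target_snr, seed=int(rng.integers(2 ** 31))
        )
    recruited, onsets = _detect_source_onsets(
        x1, times_s, scenario.onset_threshold
    )
    return SyntheticDataset(
        connectome=connectome,
        source=traj,
        seeg_clean=seeg_clean,
        seeg_noisy=seeg_noisy,
        times_s=times_s,
        gain=gain,
        scenario=scenario,
        seed=seed,
        true_recruited=recruited,
        true_onsets_s=onsets,
    )


def add_observation_noise(
    clean_seeg: np.ndarray, target_snr: float, seed: int = 0
) -> np.ndarray:
    """Add zero-mean Gaussian noise with one SD shared across channels.

    The SD is chosen so the channel-averaged SNR — mean over channels of
    the clean signal variance, divided by the noise variance — equals
    ``target_snr``.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    clean = np.asarray(clean_seeg, dtype=float)
    if np.isinf(target_snr):
        return clean.copy()
    mean_var = float(np.mean(np.var(clean, axis=-1)))
    if mean_var == 0:
        raise ValueError("clean signal has zero variance; SNR is undefined")
    sd = np.sqrt(mean_var / target_snr)
    rng = np.random.default_rng(seed)
    return clean + sd * rng.standard_normal(clean.shape)


# ---------------------------------------------------------------------------
# text I/O
# ---------------------------------------------------------------------------

def load_connectome(path, labels_path=None) -> Connectome:
    """Delimited numeric matrix (whitespace or comma), optional label sidecar."""
    try:
        w = np.loadtxt(path)
    except ValueError:
        w = np.loadtxt(path, delimiter=",")
    labels = []
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    return Connectome(weights=w, region_labels=labels)


def load_sensors(path) -> SensorArray:
    """TSV of (label, x, y, z) rows."""
    labels, pos = [], []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        labels.append(parts[0])
        pos.append([float(v) for v in parts[1:4]])
    return SensorArray(positions=np.array(pos), labels=labels)


def load_surfaces(path) -> list[RegionSurface]:
    """TSV of (region, x, y, z, area) rows grouped into RegionSurface objects."""
    rows = np.loadtxt(path)
    rows = np.atleast_2d(rows)
    surfaces = []
    for region in np.unique(rows[:, 0]).astype(int):
        sel = rows[rows[:, 0] == region]
        surfaces.append(
            RegionSurface(
                region_index=int(region), vertices=sel[:, 1:4], areas=sel[:, 4]
            )
        )
    return surfaces
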