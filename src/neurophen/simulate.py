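"""Seeded synthetic-data generators with ground truth for every analysis stage.

Four generators are provided:

* wired neuronal clusters — a network topology, a discrete-time branching
  cascade of spikes on it, and a calcium-indicator fluorescence synthesis;
* ``control_like`` / ``mutant_like`` cluster sets realising the hypothesis
  that sparse (small-world / scale-free) versus dense random wiring produces
  solo-dominated versus fully synchronous network activity;
* two-channel puncta scenes along near-parallel neurite pairs with a
  controllable truly-colocalized fraction;
* paired left/right ventral-root traces with controllable left-right phase.

Every generator is deterministic given its seed. A top-level seed is expanded
into independent per-cluster child seeds with ``numpy.random.SeedSequence``
spawning (child ``i`` of seed ``s`` is ``SeedSequence(s).spawn(...)[i]``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import networkx as nx
import numpy as np

from .events import EventRaster, FluorescenceRecording
from .rhythm import VRTracePair

__all__ = [
    "TopologySpec",
    "CascadeParams",
    "IndicatorParams",
    "PunctaSceneSpec",
    "VRSimSpec",
    "PunctaScene",
    "VRGroundTruth",
    "ClusterSample",
    "build_topology",
    "simulate_cascades",
    "spikes_to_fluorescence",
    "generate_cluster_set",
    "generate_full_sync_benchmark",
    "generate_puncta_scene",
    "render_puncta_scene",
    "generate_vr_traces",
    "CONTROL_LIKE",
    "MUTANT_LIKE",
]

TopologyKind = Literal["scale_free", "random", "small_world", "complete"]


@dataclass(frozen=True)
class TopologySpec:
    """Wiring diagram of one neuronal cluster.

    ``kind`` selects the generative model: preferential attachment
    (``scale_free``, parameter ``attachment_m``), Erdős–Rényi (``random``,
    parameter ``edge_prob``), Watts–Strogatz (``small_world``, parameters
    ``ring_degree`` — even — and ``rewire_beta``), or ``complete``.
    """

    n_neurons: int
    kind: TopologyKind
    attachment_m: int = 2
    edge_prob: float = 0.5
    rewire_beta: float = 0.1
    ring_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.kind not in ("scale_free", "random", "small_world", "complete"):
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if self.kind == "scale_free":
            if not 1 <= self.attachment_m < self.n_neurons:
                raise ValueError("attachment_m must be in [1, n_neurons)")
        if self.kind == "random" and not 0 <= self.edge_prob <= 1:
            raise ValueError("edge_prob must be in [0, 1]")
        if self.kind == "small_world":
            if self.ring_degree % 2 or self.ring_degree <= 0:
                raise ValueError("ring_degree must be a positive even count")
            if self.ring_degree >= self.n_neurons:
                raise ValueError("ring_degree must be < n_neurons")
            if not 0 <= self.rewire_beta <= 1:
                raise ValueError("rewire_beta must be in [0, 1]")


def build_topology(spec: TopologySpec) -> np.ndarray:
    """Symmetric binary zero-diagonal adjacency matrix for ``spec``."""
    n = spec.n_neurons
    if spec.kind == "complete":
        g = nx.complete_graph(n)
    elif spec.kind == "random":
        g = nx.gnp_random_graph(n, spec.edge_prob, seed=spec.seed)
    elif spec.kind == "scale_free":
        g = nx.barabasi_albert_graph(n, spec.attachment_m, seed=spec.seed)
    else:
        g = nx.watts_strogatz_graph(
            n, spec.ring_degree, spec.rewire_beta, seed=spec.seed
        )
    adjacency = nx.to_numpy_array(g, nodelist=range(n), dtype=float)
    return (adjacency > 0).astype(np.uint8)


@dataclass(frozen=True)
class CascadeParams:
    """Discrete-time branching-cascade dynamics on a wiring diagram.

    Per frame each neuron initiates spontaneously with probability
    ``1 - exp(-spontaneous_rate * dt_s)``; each spike excites each neighbour
    on the next frame with probability ``transmission_prob``; a neuron within
    ``refractory_frames`` of its last spike cannot fire. Defaults give a
    2-minute recording at a 100 ms frame interval.
    """

    spontaneous_rate: float = 0.01
    transmission_prob: float = 0.2
    refractory_frames: int = 10
    duration_s: float = 120.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.spontaneous_rate < 0:
            raise ValueError("spontaneous_rate must be >= 0")
        if not 0 <= self.transmission_prob <= 1:
            raise ValueError("transmission_prob must be in [0, 1]")
        if self.refractory_frames < 1:
            raise ValueError("refractory_frames must be >= 1")
        if self.dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("duration_s and dt_s must be positive")
        n = self.duration_s / self.dt_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s / dt_s must be an integer frame count")

    @property
    def n_frames(self) -> int:
        return round(self.duration_s / self.dt_s)


def simulate_cascades(
    adjacency: np.ndarray,
    params: CascadeParams,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    seed_spikes: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Binary (neurons x frames) spike raster of the branching cascade.

    ``seed_spikes`` optionally forces spikes at given ``(neuron, frame)``
    positions (still subject to refractoriness), e.g. to probe propagation.
    """
    adjacency = np.asarray(adjacency)
    if adjacency.ndim != 2 or adjacency.shape[0] != adjacency.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("adjacency must be symmetric")
    rng = np.random.default_rng(seed)
    n = adjacency.shape[0]
    n_frames = params.n_frames
    forced = np.zeros((n, n_frames), dtype=bool)
    if seed_spikes:
        for i, t in seed_spikes:
            forced[i, t] = True

    p_spont = 1.0 - math.exp(-params.spontaneous_rate * params.dt_s)
    raster = np.zeros((n, n_frames), dtype=np.uint8)
    last_spike = np.full(n, -params.refractory_frames - 1, dtype=int)
    adjacency_f = adjacency.astype(float)
    for t in range(n_frames):
        # fixed two draws per frame keep the stream independent of history
        u_spont = rng.random(n)
        u_trans = rng.random(n)
        fire = (u_spont < p_spont) | forced[:, t]
        if t > 0:
            k_active = adjacency_f @ raster[:, t - 1]
            p_trans = 1.0 - (1.0 - params.transmission_prob) ** k_active
            fire |= u_trans < p_trans
        fire &= (t - last_spike) > params.refractory_frames
        raster[fire, t] = 1
        last_spike[fire] = t
    return raster


@dataclass(frozen=True)
class IndicatorParams:
    """Generic fast synthetic calcium-dye kinetics.

    Instantaneous rise, single-exponential decay with time constant
    ``decay_tau_s``; transients of ``spike_amplitude`` ΔF/F sum linearly on a
    ``baseline_f0`` baseline; ``noise_sd`` is additive Gaussian noise in
    ΔF/F units.
    """

    baseline_f0: float = 100.0
    spike_amplitude: float = 0.3
    decay_tau_s: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be > 0")
        if self.decay_tau_s <= 0:
            raise ValueError("decay_tau_s must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def spikes_to_fluorescence(
    raster: np.ndarray,
    params: IndicatorParams = IndicatorParams(),
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    dt_s: float = 0.1,
    cluster_id: str | None = None,
) -> FluorescenceRecording:
    """Render a spike raster into noisy fluorescence traces.

    ``F(t) = baseline_f0 * (1 + sum over spikes of
    spike_amplitude * exp(-(t - t_spike)/tau))``, plus Gaussian noise of SD
    ``baseline_f0 * noise_sd``. With ``noise_sd=0`` the output is
    deterministic.
    """
    raster = np.asarray(raster)
    if not np.isin(raster, (0, 1)).all():
        raise ValueError("raster must be binary")
    rng = np.random.default_rng(seed)
    n, n_frames = raster.shape
    k = np.arange(n_frames)
    kernel = params.spike_amplitude * np.exp(-k * dt_s / params.decay_tau_s)
    dff = np.empty((n, n_frames))
    for i in range(n):
        dff[i] = np.convolve(raster[i].astype(float), kernel)[:n_frames]
    values = params.baseline_f0 * (1.0 + dff)
    if params.noise_sd > 0:
        values = values + params.baseline_f0 * params.noise_sd * rng.standard_normal(
            (n, n_frames)
        )
    return FluorescenceRecording(values, dt_s=dt_s, cluster_id=cluster_id)


# Default study conditions for the two cluster phenotypes: sparse short-range
# wiring with weak transmission (control-like) versus dense random wiring with
# strong transmission (mutant-like).
CONTROL_LIKE = {
    "topology": dict(kind="small_world", ring_degree=4, rewire_beta=0.1),
    "cascade": dict(transmission_prob=0.2),
}
MUTANT_LIKE = {
    "topology": dict(kind="random", edge_prob=0.8),
    "cascade": dict(transmission_prob=0.6),
}
_MODES = {"control_like": CONTROL_LIKE, "mutant_like": MUTANT_LIKE}


@dataclass(frozen=True)
class ClusterSample:
    """One simulated cluster: traces plus full ground truth."""

    recording: FluorescenceRecording
    truth_raster: EventRaster
    adjacency: np.ndarray
    mode: str
    cluster_id: str


def _child_seed(ss: np.random.SeedSequence) -> int:
    """31-bit integer seed for libraries that want a plain int."""
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def generate_cluster_set(
    n_clusters: int,
    mode: Literal["control_like", "mutant_like"],
    size_range: tuple[int, int] = (9, 25),
    seed: int = 0,
    cascade: CascadeParams | None = None,
    indicator: IndicatorParams = IndicatorParams(),
) -> list[ClusterSample]:
    """Simulate a set of wired clusters of one phenotype.

    Cluster sizes are drawn uniformly from ``size_range`` (inclusive).
    ``cascade`` overrides the mode's cascade defaults wholesale when given.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    lo, hi = size_range
    if not (2 <= lo <= hi <= 200):
        raise ValueError("size_range must satisfy 2 <= lo <= hi <= 200")
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    defaults = _MODES[mode]
    if cascade is None:
        cascade = CascadeParams(**defaults["cascade"])

    master, *children = np.random.SeedSequence(seed).spawn(n_clusters + 1)
    sizes = np.random.default_rng(master).integers(lo, hi + 1, size=n_clusters)
    samples = []
    for i, (n, child) in enumerate(zip(sizes, children)):
        ss_topo, ss_casc, ss_ind = child.spawn(3)
        spec = TopologySpec(int(n), seed=_child_seed(ss_topo), **defaults["topology"])
        adjacency = build_topology(spec)
        raster = simulate_cascades(adjacency, cascade, seed=ss_casc)
        cid = f"{mode}_{i:03d}"
        rec = spikes_to_fluorescence(
            raster, indicator, seed=ss_ind, dt_s=cascade.dt_s, cluster_id=cid
        )
        samples.append(
            ClusterSample(
                recording=rec,
                truth_raster=EventRaster(raster, dt_s=cascade.dt_s, cluster_id=cid),
                adjacency=adjacency,
                mode=mode,
                cluster_id=cid,
            )
        )
    return samples


def generate_full_sync_benchmark(
    n_clusters: int = 35,
    n_full_sync: int = 21,
    size_range: tuple[int, int] = (9, 25),
    seed: int = 0,
    n_frames: int = 1200,
    dt_s: float = 0.1,
    slot_spacing_frames: int = 100,
    first_slot_frame: int = 30,
    indicator: IndicatorParams = IndicatorParams(noise_sd=0.0),
) -> tuple[list[ClusterSample], np.ndarray]:
    """Constructed cluster set with an exact number of fully-synchronous clusters.

    Exactly ``n_full_sync`` of the ``n_clusters`` rasters contain one frame on
    which every neuron emits an onset; the rest have maximal co-active group
    size <= n-1. Events are laid out on a coarse frame grid
    (``slot_spacing_frames`` apart) so that consecutive transients of one
    neuron are fully resolvable by onset detection. Fluorescence is noiseless
    by default. Returns the samples and the boolean ground-truth
    full-sync labels.
    """
    if not 0 <= n_full_sync <= n_clusters:
        raise ValueError("n_full_sync must be in [0, n_clusters]")
    lo, hi = size_range
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sizes = rng.integers(lo, hi + 1, size=n_clusters)
    labels = np.zeros(n_clusters, dtype=bool)
    labels[:n_full_sync] = True
    rng.shuffle(labels)

    slots = np.arange(first_slot_frame, n_frames - 10, slot_spacing_frames)
    samples = []
    for i, (n, full) in enumerate(zip(sizes, labels)):
        n = int(n)
        raster = np.zeros((n, n_frames), dtype=np.uint8)
        full_slot = rng.integers(len(slots)) if full else -1
        for j, frame in enumerate(slots):
            if j == full_slot:
                members = np.arange(n)
            else:
                size_j = int(rng.integers(1, n))  # 1 .. n-1
                members = rng.choice(n, size=size_j, replace=False)
            raster[members, frame] = 1
        cid = f"bench_{i:03d}"
        rec = spikes_to_fluorescence(
            raster, indicator, seed=0, dt_s=dt_s, cluster_id=cid
        )
        samples.append(
            ClusterSample(
                recording=rec,
                truth_raster=EventRaster(raster, dt_s=dt_s, cluster_id=cid),
                adjacency=np.zeros((n, n), dtype=np.uint8),
                mode="benchmark",
                cluster_id=cid,
            )
        )
    return samples, labels


@dataclass(frozen=True)
class PunctaSceneSpec:
    """Two-channel puncta scene along near-parallel neurite pairs.

    ``coloc_fraction`` of channel-A puncta receive a channel-B partner within
    ``coloc_jitter_um``; remaining B puncta are placed independently on the
    B neurite. The field is a square of side ``field_um`` (the default matches
    a 105.9 um confocal field).
    """

    n_pairs: int = 16
    pair_separation_um: float = 0.3
    pixel_size_um: float = 0.1
    field_um: float = 105.9
    puncta_per_um: float = 0.2
    coloc_fraction: float = 0.5
    psf_sigma_um: float = 0.15
    pair_length_um: float = 40.0
    lateral_jitter_um: float = 0.05
    coloc_jitter_um: float = 0.1
    pair_clearance_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.pair_separation_um <= 0:
            raise ValueError("pair_separation_um must be > 0")
        if not 0 <= self.coloc_fraction <= 1:
            raise ValueError("coloc_fraction must be in [0, 1]")
        if self.field_um < self.pair_length_um + 2:
            raise ValueError("field too small for the requested neurite pairs")
        if self.puncta_per_um < 0:
            raise ValueError("puncta_per_um must be >= 0")


@dataclass(frozen=True)
class PunctaScene:
    """Spot coordinates (um), neurite polylines, and colocalization truth."""

    spots_a: np.ndarray  # (n_a, 2) x,y in um
    spots_b: np.ndarray
    polylines_a: list[np.ndarray]
    polylines_b: list[np.ndarray]
    true_pairs: list[tuple[int, int]]  # (index into spots_a, index into spots_b)
    spec: PunctaSceneSpec


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_puncta_scene(spec: PunctaSceneSpec) -> PunctaScene:
    """Sample a two-channel spot field with known colocalization ground truth."""
    rng = np.random.default_rng(spec.seed)
    margin = spec.pair_length_um / 2 + 1.0
    spots_a: list[np.ndarray] = []
    spots_b: list[np.ndarray] = []
    polylines_a, polylines_b, true_pairs = [], [], []
    placed_samples: list[np.ndarray] = []  # coarse samples of placed lines
    for _ in range(spec.n_pairs):
        # rejection-sample so distinct pairs keep a clearance between them;
        # otherwise chance proximity of unrelated neurites contaminates both
        # pairing and colocalization ground truth
        for attempt in range(500):
            center = rng.uniform(margin, spec.field_um - margin, size=2)
            theta = rng.uniform(0, np.pi)
            d = np.array([np.cos(theta), np.sin(theta)])
            half = spec.pair_length_um / 2
            line_a = np.stack([center - half * d, center + half * d])
            samples = line_a[0] + np.linspace(0, 1, 80)[:, None] * (
                line_a[1] - line_a[0]
            )
            if all(
                np.min(
                    np.hypot(
                        *(samples[:, None, :] - other[None, :, :]).transpose(2, 0, 1)
                    )
                )
                >= spec.pair_clearance_um
                for other in placed_samples
            ):
                break
        else:
            raise ValueError("field too small for the requested neurite pairs")
        placed_samples.append(samples)
        normal = np.array([-d[1], d[0]])
        line_b = line_a + spec.pair_separation_um * normal
        polylines_a.append(line_a)
        polylines_b.append(line_b)

        length = spec.pair_length_um
        n_a = rng.poisson(spec.puncta_per_um * length)
        pos_a = rng.uniform(0, length, size=n_a)
        jit_a = rng.uniform(-spec.lateral_jitter_um, spec.lateral_jitter_um, n_a)
        pts_a = line_a[0] + pos_a[:, None] * d + jit_a[:, None] * normal

        coloc = rng.random(n_a) < spec.coloc_fraction
        n_b_free = rng.poisson(spec.puncta_per_um * length)
        pos_b = rng.uniform(0, length, size=n_b_free)
        jit_b = rng.uniform(-spec.lateral_jitter_um, spec.lateral_jitter_um, n_b_free)
        pts_b_free = line_b[0] + pos_b[:, None] * d + jit_b[:, None] * normal

        partners = []
        for j, k in enumerate(np.flatnonzero(coloc)):
            # B partner within coloc_jitter_um of its A spot, random direction
            displacement = spec.coloc_jitter_um * rng.random() * _unit(
                rng.standard_normal(2)
            )
            partners.append(pts_a[k] + displacement)
            true_pairs.append((len(spots_a) + int(k), len(spots_b) + n_b_free + j))
        pts_b = (
            np.vstack([pts_b_free, np.array(partners)])
            if partners
            else pts_b_free
        )

        spots_a.extend(pts_a)
        spots_b.extend(pts_b)

    coords_a = np.array(spots_a).reshape(-1, 2)
    coords_b = np.array(spots_b).reshape(-1, 2)
    coords_a = np.clip(coords_a, 0, spec.field_um)
    coords_b = np.clip(coords_b, 0, spec.field_um)
    return PunctaScene(
        spots_a=coords_a,
        spots_b=coords_b,
        polylines_a=polylines_a,
        polylines_b=polylines_b,
        true_pairs=true_pairs,
        spec=spec,
    )


def render_puncta_scene(scene: PunctaScene) -> np.ndarray:
    """Render a scene into a two-channel image stack (channel, row, col).

    Each spot deposits unit mass at its sub-pixel position (bilinear) and the
    image is blurred with a Gaussian of the scene's PSF sigma. Pixel (r, c)
    has its centre at (c * pixel_size, r * pixel_size) um.
    """
    from scipy.ndimage import gaussian_filter

    spec = scene.spec
    npx = int(np.ceil(spec.field_um / spec.pixel_size_um)) + 1
    stack = np.zeros((2, npx, npx))
    for ch, coords in enumerate((scene.spots_a, scene.spots_b)):
        img = stack[ch]
        for x, y in coords:
            c, r = x / spec.pixel_size_um, y / spec.pixel_size_um
            c0, r0 = int(np.floor(c)), int(np.floor(r))
            fc, fr = c - c0, r - r0
            for dr, dc, w in (
                (0, 0, (1 - fr) * (1 - fc)),
                (0, 1, (1 - fr) * fc),
                (1, 0, fr * (1 - fc)),
                (1, 1, fr * fc),
            ):
                rr, cc = r0 + dr, c0 + dc
                if 0 <= rr < npx and 0 <= cc < npx:
                    img[rr, cc] += w
        stack[ch] = gaussian_filter(img, spec.psf_sigma_um / spec.pixel_size_um)
    return stack


VRMode = Literal["alternating", "synchronous", "arrhythmic", "silent"]


@dataclass(frozen=True)
class VRSimSpec:
    """Rhythmic ventral-root burst simulation.

    ``mode`` sets the right-onset phase within the left cycle: 0.5
    (alternating), 0.0 (synchronous), uniform at random (arrhythmic);
    ``silent`` renders baseline noise only. Bursts are rendered as
    high-variance noise epochs (SD ``burst_amplitude``) on a baseline of SD
    ``noise_sd``.
    """

    mode: VRMode = "alternating"
    cycle_period_s: float = 2.0
    burst_duty: float = 0.3
    sample_rate_hz: float = 1000.0
    noise_sd: float = 0.1
    burst_amplitude: float = 1.0
    duration_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.burst_duty < 1:
            raise ValueError("burst_duty must be in (0, 1)")
        if self.mode not in ("alternating", "synchronous", "arrhythmic", "silent"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.duration_s < self.cycle_period_s:
            raise ValueError("duration shorter than one burst cycle")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")


@dataclass(frozen=True)
class VRGroundTruth:
    """True burst intervals (s) and right-onset phases of a simulated pair."""

    left_bursts: list[tuple[float, float]]
    right_bursts: list[tuple[float, float]]
    phases: np.ndarray


def generate_vr_traces(spec: VRSimSpec) -> tuple[VRTracePair, VRGroundTruth]:
    """Simulate one left/right ventral-root recording with ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t_start = 0.25 * spec.cycle_period_s
    burst_len = spec.burst_duty * spec.cycle_period_s

    left_onsets = []
    t = t_start
    while t + burst_len < spec.duration_s:
        left_onsets.append(t)
        t += spec.cycle_period_s

    right_onsets, phases = [], []
    if spec.mode != "silent":
        for onset in left_onsets:
            if spec.mode == "alternating":
                phase = 0.5
            elif spec.mode == "synchronous":
                phase = 0.0
            else:
                phase = float(rng.random())
            r_on = onset + phase * spec.cycle_period_s
            if r_on + burst_len <= spec.duration_s:
                right_onsets.append(r_on)
                phases.append(phase)

    def render(onsets: list[float]) -> np.ndarray:
        trace = spec.noise_sd * rng.standard_normal(n)
        for on in onsets:
            i0 = int(round(on * spec.sample_rate_hz))
            i1 = min(int(round((on + burst_len) * spec.sample_rate_hz)), n)
            trace[i0:i1] += spec.burst_amplitude * rng.standard_normal(i1 - i0)
        return trace

    left_list = left_onsets if spec.mode != "silent" else []
    left = render(left_list)
    right = render(right_onsets)
    pair = VRTracePair(left=left, right=right, sample_rate_hz=spec.sample_rate_hz)
    truth = VRGroundTruth(
        left_bursts=[(o, o + burst_len) for o in left_list],
        right_bursts=[(o, o + burst_len) for o in right_onsets],
        phases=np.asarray(phases, dtype=float),
    )
    return pair, truth
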