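"""Ground-truth synthetic data: AIS/node images, STED profiles, puncta
channels, condition populations, longitudinal pairs, and current-clamp
sweeps.

Every generator draws from a single seeded :class:`numpy.random.Generator`
and emits a manifest record linking the object to its ground-truth
parameters, so that downstream measurements can be scored against known
truth without consulting generator internals.  Identical spec + seed give
byte-identical output.

Image model
-----------
An axon is a polyline path through the canvas (gentle sinusoidal curvature
by default).  The AIS occupies a plateau of elevated fluorescence along the
path arclength, beginning ``true_distance_to_soma`` µm from the trace start
and extending ``true_length`` µm, with smooth error-function onset/offset
edges (``edge_rise_um`` is the 10–90% rise distance).  The rendered line is
convolved with a Gaussian PSF and corrupted with additive Gaussian noise.
Default pixel size is 0.21 µm/pixel.

Electrophysiology model
-----------------------
A template-insertion leaky integrator: between spikes the membrane relaxes
exponentially toward ``rest + I * R_in``; when it reaches the spike
threshold, a stereotyped AP template (quarter-sine rise, half-cosine fall,
exact specified amplitude and half-width) is inserted and the integrator
resets to rest.  Subthreshold steps therefore obey Ohm's law at steady
state exactly, and first-spike latency decreases with injected current.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .errors import PathOutsideCanvasError, UndersampledError
from .straighten import ImageStack, PolylineROI, resample_path, path_normals
from .ephys_features import Sweep, SweepSet

#: default pixel size, µm/pixel
PIXEL_SIZE_UM = 0.21
#: 10-90% rise distance of an erf edge, in units of its Gaussian sigma
_RISE_PER_SIGMA = 2.5631031310892007

#: Reference condition statistics (mean, SD of AIS length in µm) of the
#: organotypic plasticity experiments: control and pharmacological network
#: manipulation (NMDA-receptor block by 10 mM MgSO4, chronic depolarization
#: by 6 mM KCl) for 10/20 days, plus return-to-baseline rescues.
PLASTICITY_CONDITIONS = {
    "ctrl_20d": (27.9, 3.0),
    "mgso4_20d": (32.1, 2.4),
    "kcl_20d": (27.0, 2.7),
    "ctrl_10d": (32.1, 3.5),
    "mgso4_10d": (35.9, 1.2),
    "kcl_10d": (29.9, 1.8),
    "mgso4_rescue": (30.6, 2.3),
    "kcl_rescue": (28.9, 1.9),
}

#: Reference per-AIS puncta counts (mean) for the cisternal-organelle
#: (synaptopodin) and axo-axonic innervation (vGAT) quantifications.
PUNCTA_GROUPS = {
    "synpo_gfp_neg": 3.1,
    "synpo_gfp_pos": 3.3,
    "vgat_gfp_neg": 20.7,
    "vgat_gfp_pos": 20.8,
}

#: Reference longitudinal in vivo statistics (week-1 / week-2 length, µm).
LONGITUDINAL_DEFAULTS = {
    "n_ais": 30, "mean_week1": 17.3, "sd_week1": 3.9,
    "mean_week2": 16.8, "sd_week2": 3.9, "correlation": 0.888,
}


# ---------------------------------------------------------------------------
# Specs

@dataclass
class AISGroundTruth:
    true_length: float                       # µm
    true_distance_to_soma: float = 3.0       # µm from trace start
    path_control_points: np.ndarray | None = None  # (N,2) px; auto if None
    plateau_intensity: float = 1000.0        # a.u.
    background_intensity: float = 100.0      # a.u.
    psf_sigma: float = 0.10                  # µm
    noise_sd: float = 27.0                   # a.u. (3% of default contrast)
    pixel_size: float = PIXEL_SIZE_UM        # µm/pixel
    edge_rise_um: float = 0.5                # 10-90% rise distance
    distal_margin_um: float = 5.0            # trace extends past the AIS end

    def __post_init__(self) -> None:
        if self.true_length <= 0:
            raise ValueError("true_length must be positive")
        if self.plateau_intensity <= self.background_intensity:
            raise ValueError("degenerate contrast: plateau must exceed "
                             "background")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.true_distance_to_soma < 0:
            raise ValueError("distance to soma cannot be negative")


@dataclass
class ConditionSpec:
    name: str
    n_otc: int = 6
    n_ais_per_otc: int = 50
    mean_length: float = 27.9     # µm
    sd_length: float = 3.0        # µm, between AIS
    between_otc_sd: float = 0.0   # µm

    def __post_init__(self) -> None:
        if self.n_otc < 1 or self.n_ais_per_otc < 1:
            raise ValueError("need at least one OTC and one AIS per OTC")
        if self.sd_length < 0 or self.between_otc_sd < 0:
            raise ValueError("SDs must be nonnegative")

    @classmethod
    def from_library(cls, name: str, **kwargs) -> "ConditionSpec":
        mean, sd = PLASTICITY_CONDITIONS[name]
        return cls(name=name, mean_length=mean, sd_length=sd, **kwargs)


@dataclass
class StedProfileSpec:
    period: float = 190.0            # nm
    region_length: float = 2000.0    # nm
    sample_spacing: float = 10.0     # nm
    envelope: str = "plateau"        # plateau | gaussian
    modulation_depth: float = 0.5    # 0-1
    noise_sd: float = 0.1            # fraction of envelope amplitude

    def __post_init__(self) -> None:
        if not 0 <= self.modulation_depth <= 1:
            raise ValueError("modulation_depth must be in [0, 1]")
        if self.envelope not in ("plateau", "gaussian"):
            raise ValueError("envelope must be 'plateau' or 'gaussian'")
        if self.region_length < 2000:
            warnings.warn("profiles shorter than 2 µm are not analysis-grade",
                          stacklevel=2)


@dataclass
class PunctaSpec:
    mean_count: float = 3.3
    count_model: str = "poisson"     # poisson | fixed
    punctum_sigma: float = 0.15      # µm
    punctum_intensity: float = 600.0  # a.u. peak above background
    placement: str = "uniform-along-extent"
    min_spacing_um: float = 0.7      # hard-core repulsion between centers
    edge_margin_um: float = 0.5      # keep centers inside the extent
    background_intensity: float = 50.0
    noise_sd: float = 8.0
    label: str = "puncta"

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValueError("mean_count must be nonnegative")
        if self.count_model not in ("poisson", "fixed"):
            raise ValueError("count_model must be 'poisson' or 'fixed'")


@dataclass
class StepProtocol:
    step_duration_ms: float = 500.0
    step_start_pa: float = -200.0
    step_stop_pa: float = 400.0
    step_increment_pa: float = 25.0
    step_onset_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.step_increment_pa <= 0:
            raise ValueError("step_increment must be positive")

    def currents(self) -> np.ndarray:
        return np.arange(self.step_start_pa,
                         self.step_stop_pa + self.step_increment_pa / 2,
                         self.step_increment_pa)


#: the acute-slice variant of the step protocol
SLICE_PROTOCOL = StepProtocol(step_duration_ms=250.0, step_stop_pa=250.0)


@dataclass
class MembraneModel:
    rest_mv: float = -65.0
    threshold_mv: float = -45.0
    ap_amplitude_mv: float = 85.0
    ap_halfwidth_ms: float = 1.0
    input_resistance_mohm: float = 150.0
    tau_ms: float = 20.0
    noise_sd_mv: float = 0.0

    @property
    def rheobase_pa(self) -> float:
        """Current at which the steady state just reaches threshold."""
        return (self.threshold_mv - self.rest_mv) \
            / self.input_resistance_mohm * 1e3


@dataclass
class EphysTraceSpec:
    protocol: StepProtocol = field(default_factory=StepProtocol)
    sample_rate_khz: float = 20.0
    model: MembraneModel = field(default_factory=MembraneModel)
    tail_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.model.ap_halfwidth_ms * self.sample_rate_khz < 10:
            raise ValueError("sample rate too low: AP half-width must span "
                             ">= 10 samples")


@dataclass
class GroundTruthManifest:
    """Per-object ground truth records plus the global seed."""

    seed: int | None
    records: list = field(default_factory=list)

    def add(self, record: dict) -> dict:
        record = dict(record)
        record["object_id"] = record.get("object_id", len(self.records))
        self.records.append(record)
        return record

    def to_jsonable(self) -> dict:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, (np.integer, np.floating)):
                return v.item()
            return v
        return {"seed": self.seed,
                "records": [{k: _clean(v) for k, v in r.items()}
                            for r in self.records]}


# ---------------------------------------------------------------------------
# Paths and image rendering

def make_axon_path(trace_length_um: float, pixel_size: float = PIXEL_SIZE_UM,
                   amplitude_um: float = 1.0, wavelength_um: float = 30.0,
                   phase: float = 0.0, margin_px: float = 8.0,
                   point_spacing_um: float = 1.0) -> np.ndarray:
    """Control points of a gently curved axon path (px), somatic end first.

    The path runs left to right with a sinusoidal transverse offset; its
    arclength slightly exceeds ``trace_length_um`` so callers can rely on at
    least that much measurable path.
    """
    n = max(2, int(math.ceil(trace_length_um / point_spacing_um)) + 1)
    x_um = np.linspace(0.0, trace_length_um, n)
    y_um = amplitude_um * np.sin(2 * np.pi * x_um / wavelength_um + phase)
    y_um -= y_um.min()
    x = margin_px + x_um / pixel_size
    y = margin_px + y_um / pixel_size
    return np.column_stack([x, y])


def _dense_path(roi: PolylineROI, pixel_size: float, spacing_px: float = 0.4):
    pts = resample_path(roi, spacing_px)
    s_um = np.arange(pts.shape[0]) * spacing_px * pixel_size
    return pts, s_um


def _plateau_profile(s_um: np.ndarray, start_um: float, stop_um: float,
                     edge_rise_um: float) -> np.ndarray:
    """Unit plateau over [start, stop] with erf edges (0 for sharp edges)."""
    if edge_rise_um <= 0:
        return ((s_um >= start_um) & (s_um <= stop_um)).astype(float)
    sigma = edge_rise_um / _RISE_PER_SIGMA
    z = sigma * math.sqrt(2)
    return 0.5 * (erf((s_um - start_um) / z) - erf((s_um - stop_um) / z))


def _stamp_max(canvas: np.ndarray, pts: np.ndarray, values: np.ndarray) -> None:
    ix = np.rint(pts[:, 0]).astype(int)
    iy = np.rint(pts[:, 1]).astype(int)
    ny, nx = canvas.shape
    if ix.min() < 0 or iy.min() < 0 or ix.max() >= nx or iy.max() >= ny:
        raise PathOutsideCanvasError("path exits the image canvas")
    np.maximum.at(canvas, (iy, ix), values)


def _auto_shape(pts: np.ndarray, pad_px: float) -> tuple:
    ny = int(math.ceil(pts[:, 1].max() + pad_px)) + 1
    nx = int(math.ceil(pts[:, 0].max() + pad_px)) + 1
    return ny, nx


def generate_ais_image(gt: AISGroundTruth, seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       canvas_shape: tuple | None = None,
                       channel_label: str = "ankG-GFP"):
    """Render one AIS image along its path.

    Returns ``(ImageStack, PolylineROI, record)``.  The ROI runs from the
    somatic domain through the AIS into the distal axon, as the extent rule
    requires; the rendered plateau spans exactly ``true_length`` µm of path
    arclength before blur and noise.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if gt.path_control_points is None:
        trace = gt.true_distance_to_soma + gt.true_length + gt.distal_margin_um
        ctrl = make_axon_path(trace, gt.pixel_size, amplitude_um=0.0)
    else:
        ctrl = np.asarray(gt.path_control_points, dtype=float)
    roi = PolylineROI(ctrl)

    pts, s_um = _dense_path(roi, gt.pixel_size)
    start = gt.true_distance_to_soma
    stop = start + gt.true_length
    if stop > s_um[-1] + 1e-9:
        raise ValueError("path too short for the requested AIS extent")
    # evaluate the longitudinal model at pixel-center arclengths (the same
    # grid the straightened profile lives on), so a plateau of L µm spans
    # round(L / pixel_size) suprathreshold pixels before blur and noise
    s_snapped = np.rint(s_um / gt.pixel_size) * gt.pixel_size
    profile = _plateau_profile(s_snapped, start, stop, gt.edge_rise_um)
    values = gt.background_intensity \
        + (gt.plateau_intensity - gt.background_intensity) * profile

    psf_px = gt.psf_sigma / gt.pixel_size
    pad = max(6.0, 4 * psf_px + 4)
    shape = canvas_shape or _auto_shape(pts, pad)
    canvas = np.full(shape, gt.background_intensity, dtype=float)
    _stamp_max(canvas, pts, values)
    if psf_px > 0:
        canvas = ndimage.gaussian_filter(canvas, psf_px)
    if gt.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, gt.noise_sd, canvas.shape)

    image = ImageStack(canvas[None], gt.pixel_size, [channel_label])
    record = {"kind": "ais", "true_length": gt.true_length,
              "true_distance_to_soma": gt.true_distance_to_soma,
              "pixel_size": gt.pixel_size,
              "plateau_intensity": gt.plateau_intensity,
              "background_intensity": gt.background_intensity,
              "psf_sigma": gt.psf_sigma, "noise_sd": gt.noise_sd,
              "edge_rise_um": gt.edge_rise_um, "seed": seed}
    return image, roi, record


def generate_node_image(true_length_um: float = 1.5, seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        channels: tuple = ("ankG-GFP", "Nav1.6"),
                        **gt_kwargs):
    """Render a node of Ranvier: a short plateau on a short straight trace,
    one rendered channel per nodal marker (independent noise per channel)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    gt = AISGroundTruth(true_length=true_length_um, true_distance_to_soma=2.0,
                        distal_margin_um=2.0, edge_rise_um=0.2, **gt_kwargs)
    stacks = []
    roi = record = None
    for label in channels:
        img, roi, record = generate_ais_image(gt, rng=rng,
                                              channel_label=label)
        stacks.append(img.pixels[0])
    image = ImageStack(np.stack(stacks), gt.pixel_size, list(channels))
    record = dict(record, kind="node", channels=list(channels))
    return image, roi, record


# ---------------------------------------------------------------------------
# Condition populations

@dataclass
class AISSample:
    otc: int
    image: ImageStack | None
    roi: PolylineROI | None
    record: dict


def draw_condition_lengths(spec: ConditionSpec,
                           rng: np.random.Generator,
                           min_length_um: float = 1.0):
    """Per-AIS true lengths: mean + OTC offset + per-AIS noise, clipped
    positive (a warning is raised if clipping touches >1% of draws)."""
    offsets = rng.normal(0.0, spec.between_otc_sd, spec.n_otc)
    raw = (spec.mean_length + offsets[:, None]
           + rng.normal(0.0, spec.sd_length, (spec.n_otc, spec.n_ais_per_otc)))
    clipped = raw < min_length_um
    if clipped.mean() > 0.01:
        warnings.warn(f"{clipped.mean():.1%} of drawn lengths clipped at "
                      f"{min_length_um} µm", stacklevel=2)
    return np.clip(raw, min_length_um, None)


def generate_condition_population(spec: ConditionSpec, seed: int | None = None,
                                  rng: np.random.Generator | None = None,
                                  render: bool = True,
                                  gt_kwargs: dict | None = None):
    """Dataset of AIS for one condition: ``(samples, manifest)``.

    Each AIS gets its own gently curved path, onset distance ~ U(2, 5) µm,
    and a true length drawn from the condition's hierarchical model; OTC
    membership is recorded in the manifest.  With ``render=False`` only the
    ground-truth records are produced (for large-n statistical checks).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    gt_kwargs = gt_kwargs or {}
    lengths = draw_condition_lengths(spec, rng)
    manifest = GroundTruthManifest(seed=seed)
    samples = []
    for otc in range(spec.n_otc):
        for length in lengths[otc]:
            distance = rng.uniform(2.0, 5.0)
            phase = rng.uniform(0.0, 2 * np.pi)
            trace = distance + length + 5.0
            path = make_axon_path(trace, amplitude_um=1.0, phase=phase)
            gt = AISGroundTruth(true_length=float(length),
                                true_distance_to_soma=float(distance),
                                path_control_points=path, **gt_kwargs)
            if render:
                image, roi, record = generate_ais_image(gt, rng=rng)
            else:
                image = roi = None
                record = {"kind": "ais", "true_length": gt.true_length,
                          "true_distance_to_soma": gt.true_distance_to_soma,
                          "pixel_size": gt.pixel_size}
            record.update(condition=spec.name, otc=otc)
            record = manifest.add(record)
            samples.append(AISSample(otc, image, roi, record))
    return samples, manifest


# ---------------------------------------------------------------------------
# STED profiles

def generate_sted_profile(spec: StedProfileSpec, seed: int | None = None,
                          rng: np.random.Generator | None = None):
    """1-D nanoscale intensity profile: envelope × (1 + m·cos(2πx/T)) plus
    fractional Gaussian noise.  Returns ``(x_nm, profile)``."""
    if spec.sample_spacing > spec.period / 4:
        raise UndersampledError(
            f"sample spacing {spec.sample_spacing} nm undersamples a "
            f"{spec.period} nm period")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = int(round(spec.region_length / spec.sample_spacing))
    x = np.arange(n) * spec.sample_spacing
    if spec.envelope == "plateau":
        env = np.ones(n)
    else:
        env = np.exp(-0.5 * ((x - x.mean()) / (spec.region_length / 4)) ** 2)
    profile = env * (1 + spec.modulation_depth
                     * np.cos(2 * np.pi * x / spec.period))
    if spec.noise_sd > 0:
        profile = profile + spec.noise_sd * rng.standard_normal(n)
    return x, profile


# ---------------------------------------------------------------------------
# Puncta

def _place_puncta(extent_um: tuple, spec: PunctaSpec,
                  rng: np.random.Generator):
    """Punctum arclength centers inside the extent with hard-core spacing."""
    if spec.count_model == "fixed":
        n = int(round(spec.mean_count))
    else:
        n = int(rng.poisson(spec.mean_count))
    lo = extent_um[0] + spec.edge_margin_um
    hi = extent_um[1] - spec.edge_margin_um
    avail = hi - lo
    flags = []
    if n > 0 and avail <= 0:
        n, flags = 0, ["extent-too-short"]
    if n > 1 and (n - 1) * spec.min_spacing_um > avail:
        n = int(avail // spec.min_spacing_um) + 1
        flags.append("count-truncated")
    if n == 0:
        return np.empty(0), flags
    slack = avail - (n - 1) * spec.min_spacing_um
    u = np.sort(rng.uniform(0.0, slack, n))
    return lo + u + np.arange(n) * spec.min_spacing_um, flags


def generate_puncta_channel(extent_um: tuple, spec: PunctaSpec,
                            rng: np.random.Generator, roi: PolylineROI,
                            shape: tuple, pixel_size: float = PIXEL_SIZE_UM,
                            psf_sigma_um: float = 0.10):
    """Render a puncta channel along a path.

    Returns ``(channel, centers_um, flags)``; the true count is
    ``len(centers_um)`` and every center lies strictly within the extent.
    """
    centers_s, flags = _place_puncta(extent_um, spec, rng)
    channel = np.full(shape, spec.background_intensity, dtype=float)
    if centers_s.size:
        pts, s_um = _dense_path(roi, pixel_size)
        normals = path_normals(pts)
        sigma_px = math.sqrt(spec.punctum_sigma ** 2 + psf_sigma_um ** 2) \
            / pixel_size
        yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
        for s in centers_s:
            i = int(np.searchsorted(s_um, s))
            i = min(i, pts.shape[0] - 1)
            offset = rng.normal(0.0, 0.3)  # px, slight transverse jitter
            cx = pts[i, 0] + offset * normals[i, 0]
            cy = pts[i, 1] + offset * normals[i, 1]
            w = int(math.ceil(4 * sigma_px))
            x0, x1 = max(0, int(cx) - w), min(shape[1], int(cx) + w + 1)
            y0, y1 = max(0, int(cy) - w), min(shape[0], int(cy) + w + 1)
            d2 = ((xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2)
            channel[y0:y1, x0:x1] += spec.punctum_intensity \
                * np.exp(-0.5 * d2 / sigma_px ** 2)
    if spec.noise_sd > 0:
        channel = channel + rng.normal(0.0, spec.noise_sd, shape)
    return channel, centers_s, flags


def generate_ais_with_puncta(gt: AISGroundTruth, pspec: PunctaSpec,
                             seed: int | None = None,
                             rng: np.random.Generator | None = None):
    """Two-channel AIS image: scaffold channel + puncta channel.

    Returns ``(ImageStack, PolylineROI, record)`` with the placed puncta
    count and centers in the record.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    image, roi, record = generate_ais_image(gt, rng=rng)
    extent = (gt.true_distance_to_soma,
              gt.true_distance_to_soma + gt.true_length)
    channel, centers, flags = generate_puncta_channel(
        extent, pspec, rng, roi, image.pixels[0].shape, gt.pixel_size,
        gt.psf_sigma)
    stack = ImageStack(np.stack([image.pixels[0], channel]), gt.pixel_size,
                       [image.channel_labels[0], pspec.label])
    record = dict(record, true_count=int(centers.size),
                  puncta_centers_um=centers, puncta_flags=flags,
                  puncta_spec=asdict(pspec))
    return stack, roi, record


# ---------------------------------------------------------------------------
# Longitudinal pairs and rapid-plasticity series

def generate_longitudinal_pairs(n_ais: int = 30, seed: int | None = None,
                                rng: np.random.Generator | None = None,
                                mean_week1: float = 17.3, sd_week1: float = 3.9,
                                mean_week2: float = 16.8, sd_week2: float = 3.9,
                                correlation: float = 0.888,
                                render: bool = True,
                                gt_kwargs: dict | None = None):
    """Paired week-1/week-2 AIS observed along the same axon path.

    True week-2 lengths are drawn conditionally on week 1 with the given
    correlation; length changes occur at the distal end (onset fixed).
    Returns ``(samples, manifest)`` where each sample record carries both
    true lengths and, when rendered, both images share the path.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    gt_kwargs = gt_kwargs or {}
    w1 = mean_week1 + sd_week1 * rng.standard_normal(n_ais)
    resid = math.sqrt(max(0.0, 1 - correlation ** 2)) * sd_week2
    w2 = (mean_week2 + correlation * (sd_week2 / sd_week1) * (w1 - mean_week1)
          + resid * rng.standard_normal(n_ais))
    w1 = np.clip(w1, 2.0, None)
    w2 = np.clip(w2, 2.0, None)
    manifest = GroundTruthManifest(seed=seed)
    samples = []
    for i in range(n_ais):
        distance = rng.uniform(2.0, 5.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        trace = distance + max(w1[i], w2[i]) + 5.0
        path = make_axon_path(trace, amplitude_um=1.0, phase=phase)
        record = {"kind": "ais-pair", "true_length_week1": float(w1[i]),
                  "true_length_week2": float(w2[i]),
                  "true_distance_to_soma": float(distance)}
        pair = {}
        if render:
            for week, length in (("week1", w1[i]), ("week2", w2[i])):
                gt = AISGroundTruth(true_length=float(length),
                                    true_distance_to_soma=float(distance),
                                    path_control_points=path, **gt_kwargs)
                image, roi, _ = generate_ais_image(gt, rng=rng)
                pair[week] = (image, roi)
        record = manifest.add(record)
        samples.append((pair, record))
    return samples, manifest


def generate_retraction_series(gt: AISGroundTruth, relative_lengths,
                               seed: int | None = None,
                               rng: np.random.Generator | None = None):
    """Time series of one AIS undergoing proximal-onset retraction.

    ``relative_lengths[t]`` is the fraction of the baseline length present
    at time t; the distal end stays fixed while the onset moves distally,
    as observed under focal depolarization.  Returns a list of
    ``(image, roi, record)``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    if gt.path_control_points is None:
        trace = gt.true_distance_to_soma + gt.true_length + gt.distal_margin_um
        gt = AISGroundTruth(**{**asdict(gt), "path_control_points":
                               make_axon_path(trace, amplitude_um=0.0)})
    out = []
    stop = gt.true_distance_to_soma + gt.true_length
    for t, rel in enumerate(relative_lengths):
        length_t = gt.true_length * float(rel)
        gt_t = AISGroundTruth(**{**asdict(gt),
                                 "true_length": length_t,
                                 "true_distance_to_soma": stop - length_t})
        image, roi, record = generate_ais_image(gt_t, rng=rng)
        record.update(time_index=t, relative_true=float(rel))
        out.append((image, roi, record))
    return out


# ---------------------------------------------------------------------------
# Electrophysiology

def _ap_template_values(dt_from_onset: np.ndarray, thr: float, amp: float,
                        halfwidth_ms: float) -> np.ndarray:
    """Quarter-sine rise + half-cosine fall; half-width at thr + amp/2 is
    exactly ``halfwidth_ms`` by construction (rise tr = hw/2, fall tf = hw:
    time above the half level is 2/3·tr + 2/3·tf = hw)."""
    tr = halfwidth_ms / 2
    tf = halfwidth_ms
    v = np.empty_like(dt_from_onset)
    rise = dt_from_onset < tr
    v[rise] = thr + amp * np.sin(np.pi * dt_from_onset[rise] / (2 * tr))
    fall = ~rise
    v[fall] = thr + amp * np.cos(np.pi * (dt_from_onset[fall] - tr) / (2 * tf))
    return v


def ap_template_duration_ms(halfwidth_ms: float) -> float:
    return 1.5 * halfwidth_ms


def generate_ephys_traces(spec: EphysTraceSpec,
                          seed: int | None = None,
                          rng: np.random.Generator | None = None) -> SweepSet:
    """Synthesize one voltage sweep per current step of the protocol."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    p, m = spec.protocol, spec.model
    dt = 1.0 / spec.sample_rate_khz
    total = p.step_onset_ms + p.step_duration_ms + spec.tail_ms
    t = np.arange(0.0, total + dt / 2, dt)
    step_end = p.step_onset_ms + p.step_duration_ms
    sweeps = []
    for current in p.currents():
        v = np.full(t.shape, m.rest_mv)
        vss = m.rest_mv + current * m.input_resistance_mohm * 1e-3
        t_cur, v_cur = p.step_onset_ms, m.rest_mv
        while t_cur < step_end - 1e-9:
            if vss > m.threshold_mv and v_cur < m.threshold_mv:
                t_cross = t_cur + m.tau_ms * math.log(
                    (vss - v_cur) / (vss - m.threshold_mv))
            elif vss > m.threshold_mv:
                t_cross = t_cur
            else:
                t_cross = math.inf
            seg_end = min(t_cross, step_end)
            sel = (t >= t_cur) & (t < seg_end)
            v[sel] = vss + (v_cur - vss) * np.exp(-(t[sel] - t_cur) / m.tau_ms)
            if t_cross >= step_end:
                v_cur = vss + (v_cur - vss) * math.exp(
                    -(step_end - t_cur) / m.tau_ms)
                t_cur = step_end
                break
            tmpl_end = t_cross + ap_template_duration_ms(m.ap_halfwidth_ms)
            sel = (t >= t_cross) & (t < min(tmpl_end, total))
            v[sel] = _ap_template_values(t[sel] - t_cross, m.threshold_mv,
                                         m.ap_amplitude_mv, m.ap_halfwidth_ms)
            t_cur, v_cur = tmpl_end, m.rest_mv
        # post-step relaxation back to rest
        t0 = max(t_cur, step_end)
        sel = t >= t0
        v[sel] = m.rest_mv + (v_cur - m.rest_mv) * np.exp(
            -(t[sel] - t0) / m.tau_ms)
        if m.noise_sd_mv > 0:
            v = v + rng.normal(0.0, m.noise_sd_mv, v.shape)
        sweeps.append(Sweep(float(current), t.copy(), v))
    return SweepSet(sweeps, p.step_onset_ms, p.step_duration_ms,
                    spec.sample_rate_khz)
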