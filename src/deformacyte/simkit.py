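"""Synthetic cohorts, impedance traces and brightfield-like frames.

The generator emulates a shear deformability cytometer in which cells in a
viscoelastic carrier flow along a 40 x 30 um channel, pass two differential
electrode configurations (producing two consecutive anti-symmetric double
Gaussians in the impedance trace), and are then photographed in a downstream
optical window by an LED flash fired from the impedance trigger.  Every
generated object carries its ground truth so recovery tests can compare the
analysis chain against what was injected.

Modelling conventions
---------------------
* y runs across the channel width (image vertical axis), x along the flow
  (image horizontal axis), z along the optical axis.
* The electrically sensed axis ratio ``deform_true`` maps to the config-1 /
  config-2 amplitude ratio through an identity link (A1/A2 = deform_true), a
  documented convenience that makes the ground truth trivially invertible.
* Cells near the walls acquire a tear-drop asymmetry (``tail_skew``) and an
  inflated *optical* elongation (``deform_optical``); the electrical shape
  signal is independent of lateral position, as observed on the instrument.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps

from .stats import hill_curve

__all__ = [
    "ChannelGeometry",
    "AcquisitionSettings",
    "ParticleTruth",
    "CohortConfig",
    "ImpedanceTrace",
    "Frame",
    "FrameParticle",
    "sample_cohort",
    "velocity_profile",
    "synthesize_trace",
    "render_frame",
    "render_triggered_frames",
    "simulate_dose_response",
    "particles_to_frame",
]

#: half-width of one sensing electrode in um; sets the Gaussian width of the
#: impedance lobes through sigma = ELECTRODE_HALFWIDTH_UM / velocity.
ELECTRODE_HALFWIDTH_UM = 10.0

#: image grey levels: light background, dark cell interior.
BACKGROUND_LEVEL = 1.0
FOREGROUND_LEVEL = 0.2
IMAGE_CONTRAST = BACKGROUND_LEVEL - FOREGROUND_LEVEL


@dataclass(frozen=True)
class ChannelGeometry:
    """Microfluidic channel and electrode layout (all lengths in um)."""

    width_um: float = 40.0      # channel width along y
    height_um: float = 30.0     # channel height along z
    d1_um: float = 40.0         # centre-to-centre spacing of config-1 pairs
    d2_um: float = 350.0        # config-1 midpoint -> optical window centre
    roi_width_um: float = 34.0  # optical capture window width along flow
    config2_offset_um: float = 175.0  # config-1 midpoint -> config-2 midpoint

    def __post_init__(self) -> None:
        for name in ("width_um", "height_um", "d1_um", "d2_um",
                     "roi_width_um", "config2_offset_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.roi_width_um >= self.d2_um:
            raise ValueError("roi_width_um must be smaller than d2_um")


@dataclass(frozen=True)
class AcquisitionSettings:
    """ADC, camera and illumination parameters."""

    sample_rate_hz: float = 87_000.0
    frame_rate_hz: float = 100.0
    led_pulse_s: float = 2e-6
    pixel_scale_um: float = 0.63
    latency_jitter_s: float = 30e-6  # SD of trigger-to-flash latency

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel_scale_um must be positive")
        if self.sample_rate_hz <= 10 * self.frame_rate_hz:
            raise ValueError("sample_rate_hz must greatly exceed frame rate")


@dataclass
class ParticleTruth:
    """Ground-truth record for one simulated particle."""

    id: int
    kind: str                 # "bead" or "cell"
    diameter_um: float        # volume-equivalent diameter
    deform_true: float        # electrically sensed axis ratio, >= 1
    deform_optical: float     # rendered in-plane elongation (wall-inflated)
    tail_skew: float          # tear-drop asymmetry in [0, 1)
    y_um: float
    z_um: float
    velocity_m_s: float
    t_entry_s: float          # time at the first config-1 electrode pair
    group: str
    flow_ul_min: float


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one simulated acquisition run.

    Defaults reproduce the untreated-cell conditions: ~12 um cells whose
    sensed deformability is N(deform_mean, deform_sd), mixed with 10 um rigid
    calibration beads, partly focused around the channel midline.
    """

    n_cells: int = 500
    n_beads: int = 100
    group: str = "untreated"
    flow_ul_min: float = 10.0
    deform_mean: float = 1.16
    deform_sd: float = 0.06
    cell_diameter_mean_um: float = 12.0
    cell_diameter_sd_um: float = 1.0
    bead_diameter_um: float = 10.0
    bead_diameter_sd_um: float = 0.1
    wall_deform_gain: float = 0.25   # quadratic OD inflation vs |y|
    wall_skew_gain: float = 0.5      # tear-drop coefficient vs |y|
    focusing_sd_um: float = 7.0      # lateral (y) spread
    z_sd_um: float = 4.0             # height (z) spread
    event_rate_hz: float = 10.0      # Poisson arrival rate
    trace_snr: float = 20.0          # bead amplitude / trace noise SD
    image_noise_sd: float = 0.05     # fraction of image contrast
    seed: int = 0

    def validate(self, geom: ChannelGeometry) -> None:
        if self.n_cells < 0 or self.n_beads < 0:
            raise ValueError("particle counts must be non-negative")
        if self.deform_mean < 1:
            raise ValueError("deform_mean must be >= 1")
        if self.focusing_sd_um <= 0 or self.z_sd_um <= 0:
            raise ValueError("position spreads must be positive")
        if self.event_rate_hz <= 0:
            raise ValueError("event_rate_hz must be positive")
        big = max(self.cell_diameter_mean_um, self.bead_diameter_um)
        if big >= geom.height_um:
            raise ValueError(
                f"particle diameter {big} um does not fit the "
                f"{geom.height_um} um channel height")


@dataclass
class ImpedanceTrace:
    """Two-channel differential impedance recording.

    ``data`` has shape (n_samples, 2): column 0 is electrode configuration 1
    (vertical pairs, volume-sensitive), column 1 configuration 2 (coplanar
    pairs, flow-axis-shape-sensitive).  Amplitudes are in units of the signal
    of a 10 um bead (A = (d/10)^3).
    """

    data: np.ndarray
    sample_rate_hz: float
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.data.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass
class FrameParticle:
    """Position and shape of one particle at the illumination instant."""

    x_um: float                # offset from window centre along flow
    y_um: float                # offset from channel midline
    diameter_um: float
    elongation: float = 1.0    # optical axis ratio (area preserving)
    tail_skew: float = 0.0
    velocity_m_s: float = 0.0
    particle_id: int = -1


@dataclass
class Frame:
    """One rendered camera frame."""

    image: np.ndarray
    timestamp_s: float
    frame_index: int
    n_objects: int             # particles whose centre lies inside the ROI
    particles: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# flow profile
# ---------------------------------------------------------------------------

def velocity_profile(y_um, z_um, flow_ul_min: float,
                     geom: ChannelGeometry, n_terms: int = 51):
    """Laminar axial velocity at (y, z) in a rectangular duct, in m/s.

    Newtonian series solution for pressure-driven flow in a rectangular
    cross-section, scaled so the cross-sectional mean equals Q/A.  The maximum
    sits at the channel centre (0, 0) and the velocity vanishes at the walls.
    """
    y = np.asarray(y_um, dtype=float) * 1e-6
    z = np.asarray(z_um, dtype=float) * 1e-6
    a = geom.width_um / 2 * 1e-6
    b = geom.height_um / 2 * 1e-6
    if np.any(np.abs(y) > a * (1 + 1e-12)) or np.any(np.abs(z) > b * (1 + 1e-12)):
        raise ValueError("position outside channel cross-section")

    n = np.arange(1, 2 * n_terms, 2, dtype=float)           # odd harmonics
    sign = np.where((((n - 1) // 2) % 2) == 0, 1.0, -1.0)
    k = n * np.pi / (2 * a)

    yy = y[..., None]
    zz = z[..., None]
    series = (sign / n**3
              * (1.0 - np.cosh(k * zz) / np.cosh(k * b))
              * np.cos(k * yy))
    u0 = series.sum(axis=-1)

    mean0 = np.sum((2.0 / (n * np.pi)) / n**3
                   * (1.0 - (2 * a / (n * np.pi * b)) * np.tanh(k * b)))

    q = flow_ul_min * 1e-9 / 60.0                            # m^3/s
    area = 4 * a * b
    u = (q / area) * u0 / mean0
    if u.ndim == 0:
        return float(u)
    return u


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def sample_cohort(config: CohortConfig, geom: ChannelGeometry,
                  rng: np.random.Generator | None = None) -> list[ParticleTruth]:
    """Draw one mixed bead/cell cohort with Poisson arrival times.

    Arrival times at the first config-1 electrode pair follow a Poisson
    process at ``event_rate_hz``; lateral positions follow a truncated normal
    (viscoelastic partial focusing); the axial velocity comes from the duct
    flow profile at (y, z).
    """
    config.validate(geom)
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_cells + config.n_beads
    kinds = np.array(["cell"] * config.n_cells + ["bead"] * config.n_beads)
    rng.shuffle(kinds)
    is_bead = kinds == "bead"

    diam = np.where(
        is_bead,
        rng.normal(config.bead_diameter_um, config.bead_diameter_sd_um, n),
        rng.normal(config.cell_diameter_mean_um, config.cell_diameter_sd_um, n),
    )
    diam = np.clip(diam, 4.0, geom.height_um - 1.0)

    t_entry = np.cumsum(rng.exponential(1.0 / config.event_rate_hz, n))

    y_bound = geom.width_um / 2 - diam / 2
    z_bound = geom.height_um / 2 - diam / 2
    y = sps.truncnorm.rvs(-y_bound / config.focusing_sd_um,
                          y_bound / config.focusing_sd_um,
                          scale=config.focusing_sd_um, size=n, random_state=rng)
    z = sps.truncnorm.rvs(-z_bound / config.z_sd_um,
                          z_bound / config.z_sd_um,
                          scale=config.z_sd_um, size=n, random_state=rng)

    velocity = velocity_profile(y, z, config.flow_ul_min, geom)

    deform = np.where(
        is_bead, 1.0,
        np.clip(rng.normal(config.deform_mean, config.deform_sd, n), 1.0, None))
    yhat2 = (2.0 * np.abs(y) / geom.width_um) ** 2
    deform_opt = np.where(is_bead, 1.0,
                          deform * (1.0 + config.wall_deform_gain * yhat2))
    skew = np.where(is_bead, 0.0,
                    np.clip(config.wall_skew_gain * yhat2, 0.0, 0.9))

    order = np.argsort(t_entry)
    particles = []
    for i, j in enumerate(order):
        particles.append(ParticleTruth(
            id=i, kind=str(kinds[j]), diameter_um=float(diam[j]),
            deform_true=float(deform[j]), deform_optical=float(deform_opt[j]),
            tail_skew=float(skew[j]), y_um=float(y[j]), z_um=float(z[j]),
            velocity_m_s=float(velocity[j]), t_entry_s=float(t_entry[j]),
            group=config.group, flow_ul_min=config.flow_ul_min))
    return particles


def particles_to_frame(particles: Sequence[ParticleTruth]) -> pd.DataFrame:
    """Ground-truth table, one row per particle, unit-suffixed headers."""
    return pd.DataFrame([dataclasses.asdict(p) for p in particles])


# ---------------------------------------------------------------------------
# impedance traces
# ---------------------------------------------------------------------------

def _gauss(t: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (t / sigma) ** 2)


def signal_amplitude(diameter_um: float) -> float:
    """Config-1 amplitude law: proportional to particle volume."""
    return (diameter_um / 10.0) ** 3


def synthesize_trace(particles: Sequence[ParticleTruth],
                     geom: ChannelGeometry, acq: AcquisitionSettings,
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     duration_s: float | None = None,
                     pad_s: float = 2e-3) -> ImpedanceTrace:
    """Superpose per-particle anti-symmetric double Gaussians plus noise.

    Each particle adds, on configuration 1,
    ``A1 * [g(t - t0; sigma) - g(t - t0 - dt1; sigma)]`` with
    ``dt1 = D1 / velocity`` and ``sigma = electrode half-width / velocity``,
    and the same bi-Gaussian shifted downstream on configuration 2 with
    amplitude ``A2 = A1 / deform_true`` (identity link, so A1/A2 inverts the
    ground truth and equals 1 for rigid beads).
    """
    fs = acq.sample_rate_hz
    if duration_s is None:
        if particles:
            t_last = max(
                p.t_entry_s
                + (geom.config2_offset_um + geom.d1_um) * 1e-6 / p.velocity_m_s
                + 6 * ELECTRODE_HALFWIDTH_UM * 1e-6 / p.velocity_m_s
                for p in particles)
            duration_s = t_last + pad_s
        else:
            duration_s = 10e-3
    n = int(np.ceil(duration_s * fs))
    data = np.zeros((n, 2), dtype=np.float64)

    for p in particles:
        v = p.velocity_m_s
        if v <= 0:
            raise ValueError("particle velocity must be positive")
        sigma = ELECTRODE_HALFWIDTH_UM * 1e-6 / v
        if fs * 4 * sigma < 8:
            raise ValueError(
                "sample rate too low to resolve the Gaussian width "
                f"(need >= 8 samples per 4*sigma, got {fs * 4 * sigma:.1f})")
        dt1 = geom.d1_um * 1e-6 / v
        a1 = signal_amplitude(p.diameter_um)
        a2 = a1 / p.deform_true

        t0 = p.t_entry_s                       # peak: first electrode pair
        tm = t0 + dt1 / 2                      # config-1 midpoint
        c2 = tm + geom.config2_offset_um * 1e-6 / v  # config-2 midpoint

        for ch, amp, t_peak, t_valley in (
                (0, a1, t0, t0 + dt1),
                (1, a2, c2 - dt1 / 2, c2 + dt1 / 2)):
            lo = max(0, int((t_peak - 6 * sigma) * fs))
            hi = min(n, int((t_valley + 6 * sigma) * fs) + 1)
            if hi <= lo:
                continue
            t = np.arange(lo, hi) / fs
            data[lo:hi, ch] += amp * (_gauss(t - t_peak, sigma)
                                      - _gauss(t - t_valley, sigma))

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        data += rng.normal(0.0, noise_sd, size=data.shape)

    return ImpedanceTrace(data=data.astype(np.float32), sample_rate_hz=fs,
                          meta={"n_particles": len(particles),
                                "noise_sd": noise_sd})


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

def box_blur_kernel(length_px: float) -> np.ndarray:
    """Fractional-length 1-D box kernel (area 1) for motion blur.

    A box of width < 1 px lies within one pixel bin and degenerates to the
    identity kernel.
    """
    if length_px <= 1.0:
        return np.array([1.0])
    m = int(np.ceil(length_px / 2 + 0.5))
    offsets = np.arange(-m, m + 1, dtype=float)
    lo = np.maximum(offsets - 0.5, -length_px / 2)
    hi = np.minimum(offsets + 0.5, length_px / 2)
    w = np.clip(hi - lo, 0.0, None)
    w = w[w > 0]
    return w / w.sum()


def frame_shape(geom: ChannelGeometry, acq: AcquisitionSettings) -> tuple[int, int]:
    """(rows, cols) of the rendered ROI image."""
    return (int(round(geom.width_um / acq.pixel_scale_um)),
            int(round(geom.roi_width_um / acq.pixel_scale_um)))


def particle_coverage(p: FrameParticle, geom: ChannelGeometry,
                      acq: AcquisitionSettings, supersample: int = 3,
                      blur: bool = True,
                      pulse_s: float | None = None) -> np.ndarray:
    """Fractional pixel coverage of one particle over the full frame.

    The cell outline in polar form around its centre is
    ``r(theta) = r_ell(theta) * (1 + tail_skew * ((1 + cos theta)/2)^3)``
    where ``r_ell`` is an area-preserving ellipse stretched along the flow
    axis by ``elongation`` and the cubed raised-cosine term grows a smooth
    tear-drop tail on the downstream side, inflating the flow-axis second
    moment (and hence the measured OD) as wall-adjacent cells do.  Motion
    blur is a 1-D box convolution along the flow of length velocity x LED
    pulse.
    """
    h, w = frame_shape(geom, acq)
    scale = acq.pixel_scale_um
    e = p.elongation
    if e < 1:
        raise ValueError("elongation must be >= 1")
    a_ax = (p.diameter_um / 2) * np.sqrt(e)      # semi-axis along flow, um
    b_ax = (p.diameter_um / 2) / np.sqrt(e)      # semi-axis across, um
    rmax = a_ax * (1 + p.tail_skew)
    if abs(p.x_um) > geom.roi_width_um / 2 + rmax:
        raise ValueError("particle fully outside the optical ROI")

    col_c = w / 2 + p.x_um / scale
    row_c = h / 2 + p.y_um / scale
    pad = rmax / scale + 2
    c0 = max(0, int(np.floor(col_c - pad)))
    c1 = min(w, int(np.ceil(col_c + pad)) + 1)
    r0 = max(0, int(np.floor(row_c - pad)))
    r1 = min(h, int(np.ceil(row_c + pad)) + 1)

    ss = supersample
    sub = (np.arange(ss) + 0.5) / ss
    cols = (c0 + np.add.outer(np.arange(c1 - c0), sub)).reshape(-1)
    rows = (r0 + np.add.outer(np.arange(r1 - r0), sub)).reshape(-1)
    dx = (cols[None, :] - col_c) * scale
    dy = (rows[:, None] - row_c) * scale
    theta = np.arctan2(dy, dx)
    r = np.hypot(dx, dy)
    ct, st = np.cos(theta), np.sin(theta)
    r_ell = a_ax * b_ax / np.sqrt((b_ax * ct) ** 2 + (a_ax * st) ** 2)
    inside = r <= r_ell * (1 + p.tail_skew * ((1 + ct) / 2) ** 3)
    cov_block = inside.reshape(r1 - r0, ss, c1 - c0, ss).mean(axis=(1, 3))

    cov = np.zeros((h, w))
    cov[r0:r1, c0:c1] = cov_block

    pulse = acq.led_pulse_s if pulse_s is None else pulse_s
    if blur and p.velocity_m_s > 0 and pulse > 0:
        length_px = p.velocity_m_s * 1e6 * pulse / scale
        kern = box_blur_kernel(length_px)
        if kern.size > 1:
            cov = ndi.convolve1d(cov, kern, axis=1, mode="constant")
    return cov


def render_frame(particles_in_window: Sequence[FrameParticle],
                 geom: ChannelGeometry, acq: AcquisitionSettings,
                 noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None,
                 blur: bool = True, timestamp_s: float = 0.0,
                 frame_index: int = 0, supersample: int = 3) -> Frame:
    """Render dark particle outlines on a light background.

    ``noise_sd`` is the Gaussian pixel-noise SD as a fraction of the
    foreground/background contrast.  ``n_objects`` counts the particles whose
    centre lies inside the ROI (partially visible edge particles render but
    do not count).
    """
    h, w = frame_shape(geom, acq)
    cov = np.zeros((h, w))
    n_objects = 0
    for p in particles_in_window:
        cov = np.maximum(cov, particle_coverage(p, geom, acq,
                                                supersample=supersample,
                                                blur=blur))
        if abs(p.x_um) <= geom.roi_width_um / 2:
            n_objects += 1
    image = BACKGROUND_LEVEL - IMAGE_CONTRAST * np.clip(cov, 0.0, 1.0)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        image = image + rng.normal(0.0, noise_sd * IMAGE_CONTRAST, image.shape)
    return Frame(image=image.astype(np.float32), timestamp_s=timestamp_s,
                 frame_index=frame_index, n_objects=n_objects,
                 particles=list(particles_in_window))


def render_triggered_frames(particles: Sequence[ParticleTruth],
                            flash_times_s: Sequence[float],
                            geom: ChannelGeometry, acq: AcquisitionSettings,
                            noise_sd: float = 0.0,
                            rng: np.random.Generator | None = None,
                            blur: bool = True) -> list[Frame]:
    """Render camera frames for a set of LED flash instants.

    Each flash exposes every particle currently inside (or overlapping) the
    optical window; flashes landing in the same camera frame accumulate into
    one image, which is how optical coincidences arise.  A particle caught by
    several flashes of one frame is drawn once, at its position closest to
    the window centre.
    """
    fps = acq.frame_rate_hz
    t_centre = np.array([
        p.t_entry_s + (geom.d1_um / 2 + geom.d2_um) * 1e-6 / p.velocity_m_s
        for p in particles])
    v = np.array([p.velocity_m_s for p in particles])

    by_frame: dict[int, dict[int, FrameParticle]] = {}
    for t_flash in np.sort(np.asarray(flash_times_s, dtype=float)):
        idx = int(np.floor(t_flash * fps))
        x_um = (t_flash - t_centre) * v * 1e6
        half = geom.roi_width_um / 2
        rmax = np.array([p.diameter_um / 2 * np.sqrt(p.deform_optical)
                         * (1 + p.tail_skew) for p in particles])
        for j in np.nonzero(np.abs(x_um) <= half + rmax)[0]:
            p = particles[j]
            fp = FrameParticle(
                x_um=float(x_um[j]), y_um=p.y_um, diameter_um=p.diameter_um,
                elongation=p.deform_optical, tail_skew=p.tail_skew,
                velocity_m_s=p.velocity_m_s, particle_id=p.id)
            bucket = by_frame.setdefault(idx, {})
            prev = bucket.get(p.id)
            if prev is None or abs(fp.x_um) < abs(prev.x_um):
                bucket[p.id] = fp

    frames = []
    for idx in sorted(by_frame):
        fps_list = list(by_frame[idx].values())
        frames.append(render_frame(
            fps_list, geom, acq, noise_sd=noise_sd, rng=rng, blur=blur,
            timestamp_s=idx / fps, frame_index=idx))
    return frames


# ---------------------------------------------------------------------------
# dose-response cohorts
# ---------------------------------------------------------------------------

def simulate_dose_response(concentrations: Sequence[float],
                           hill_params: tuple[float, float, float],
                           n_reps: int, seed: int,
                           base_config: CohortConfig | None = None,
                           geom: ChannelGeometry | None = None,
                           ) -> dict[float, list[list[ParticleTruth]]]:
    """Cohorts whose group deformability follows a Hill dose-response.

    ``hill_params = (y_max, y_min, ec50)``: the per-concentration group mean
    is ``hill_curve(c, y_max, y_min, ec50)``; ``n_reps`` replicate cohorts
    per concentration get seeds derived from the master ``seed``.
    """
    y_max, y_min, ec50 = hill_params
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    concentrations = list(concentrations)
    if any(c < 0 for c in concentrations):
        raise ValueError("concentrations must be non-negative")
    if base_config is None:
        base_config = CohortConfig()
    if geom is None:
        geom = ChannelGeometry()

    children = np.random.SeedSequence(seed).spawn(
        len(concentrations) * n_reps)
    out: dict[float, list[list[ParticleTruth]]] = {}
    k = 0
    for c in concentrations:
        mean = float(hill_curve(c, y_max, y_min, ec50))
        reps = []
        for _ in range(n_reps):
            sub_seed = int(children[k].generate_state(1)[0] % (2**31))
            cfg = dataclasses.replace(
                base_config, deform_mean=mean,
                group=f"{base_config.group}:GA={c:g}", seed=sub_seed)
            reps.append(sample_cohort(cfg, geom))
            k += 1
        out[float(c)] = reps
    return out
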