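"""Synthetic standing-dog pressure recordings.

Generates 10-second forelimb stance recordings on a simulated pressure
platform so the whole analysis pipeline can be exercised without access to
real animals.  The physical picture:

* Each forepaw is a template of five elastic pads (one metacarpal, four
  digital) rendered as isotropic 2-D Gaussian pressure bumps at fixed
  positions — a standing dog keeps its paws planted, so the footprint does
  not translate during a valid trial.
* The two limbs share the forequarter load according to ``load_split``;
  a lame animal unloads the painful limb (e.g. 40/60 instead of 50/50).
* Pad contact area grows with load (pads spread under pressure); modelled
  as pad radius ∝ (limb load / half load)**elasticity_gamma.
* Postural sway is an Ornstein-Uhlenbeck (OU) excursion of the body centre
  of pressure (COP).  Latero-lateral sway is realised as a weight shift
  between the limbs (modulating the instantaneous load split); craniocaudal
  sway as a fore/aft re-weighting of each paw's pads.  Per-limb COP jitter
  re-weights pads within each paw independently.
* The sensor model samples the continuous field at sensor centres, adds
  i.i.d. Gaussian noise, zeroes readings below the sensitivity floor,
  quantises to the device step and clips at the ceiling.

``load_split`` governs the *measured* load division: after the floor zeroes
sub-threshold tails, each limb's field is renormalised so its quadrature
force matches the target.  This mirrors the fact that a real platform's
"pressure distribution" statistic is computed from measured pressures, and
it makes the generator's truth directly comparable to pipeline estimates.

OU parameterisation: dX = -theta (X - mu) dt + sigma dW, whose stationary
per-axis SD is sigma / sqrt(2 theta) (see :func:`ou_stationary_sd`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ConfigurationError, PlatformSpec, PressureRecording

__all__ = [
    "PawTemplate", "SwayModel", "SimulationConfig", "GroupSpec",
    "simulate_recording", "simulate_cohort", "ou_stationary_sd", "ou_path",
    "default_group_specs", "CHI2_90_2D",
]

# chi-square 0.90 quantile with 2 df; ellipse area = pi * this * sd_x * sd_y
CHI2_90_2D = 4.605170185988092


@dataclass(frozen=True)
class PawTemplate:
    """Five-pad forepaw footprint in paw-local mm (x medial+, y cranial+).

    ``pad_centers_mm`` rows are ordered metacarpal, digital 2..5; the right
    template is the left one mirrored in x unless overridden.
    """

    pad_centers_mm: np.ndarray
    pad_amplitudes: np.ndarray
    pad_radii_mm: np.ndarray
    side: str = "left"

    def __post_init__(self) -> None:
        centers = np.asarray(self.pad_centers_mm, dtype=float)
        amps = np.asarray(self.pad_amplitudes, dtype=float)
        radii = np.asarray(self.pad_radii_mm, dtype=float)
        if centers.shape != (5, 2):
            raise ConfigurationError("a paw template has exactly 5 pads (x, y)")
        if amps.shape != (5,) or radii.shape != (5,):
            raise ConfigurationError("need 5 pad amplitudes and 5 pad radii")
        if np.any(radii <= 0) or np.any(amps <= 0):
            raise ConfigurationError("pad radii and amplitudes must be > 0")
        if self.side not in ("left", "right"):
            raise ConfigurationError("side must be 'left' or 'right'")
        object.__setattr__(self, "pad_centers_mm", centers)
        object.__setattr__(self, "pad_amplitudes", amps)
        object.__setattr__(self, "pad_radii_mm", radii)

    @classmethod
    def default(cls, side: str = "left") -> "PawTemplate":
        """Canonical large-breed forepaw: big caudal metacarpal pad plus a
        cranial arc of four digital pads.  For the left paw, +x is medial
        (toward the platform midline); digit 2 is the most medial."""
        centers = np.array([
            [0.0, -16.0],   # metacarpal
            [19.0, 14.0],   # digital 2 (medial)
            [7.0, 22.0],    # digital 3
            [-7.0, 22.0],   # digital 4
            [-19.0, 14.0],  # digital 5 (lateral)
        ])
        amps = np.array([1.0, 0.45, 0.45, 0.45, 0.45])
        radii = np.array([13.0, 7.0, 7.0, 7.0, 7.0])
        tpl = cls(centers, amps, radii, side="left")
        return tpl if side == "left" else tpl.mirrored()

    def mirrored(self) -> "PawTemplate":
        centers = self.pad_centers_mm * np.array([-1.0, 1.0])
        other = "right" if self.side == "left" else "left"
        return PawTemplate(centers, self.pad_amplitudes.copy(),
                           self.pad_radii_mm.copy(), side=other)


@dataclass(frozen=True)
class SwayModel:
    """OU (or white-noise) model of COP excursion around a mean position.

    ``sigma_mm`` is the OU diffusion coefficient per axis (mm / sqrt(s));
    the stationary per-axis SD is ``sigma / sqrt(2 theta)``.  With
    ``process='filtered-noise'`` samples are drawn i.i.d. with SD equal to
    that same stationary value (theta only sets the scale).
    """

    process: str = "ou"
    mean_xy_mm: tuple[float, float] = (0.0, 0.0)
    theta_per_s: float = 1.0
    sigma_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.process not in ("ou", "filtered-noise"):
            raise ConfigurationError("process must be 'ou' or 'filtered-noise'")
        if self.theta_per_s < 0:
            raise ConfigurationError("theta_per_s must be >= 0")
        if any(s < 0 for s in self.sigma_mm):
            raise ConfigurationError("sigma_mm must be >= 0")

    @classmethod
    def from_stationary_sd(cls, sd_x_mm: float, sd_y_mm: float,
                           theta_per_s: float = 1.0,
                           mean_xy_mm: tuple[float, float] = (0.0, 0.0),
                           ) -> "SwayModel":
        """Build an OU model whose stationary per-axis SDs are given."""
        k = math.sqrt(2.0 * theta_per_s)
        return cls("ou", mean_xy_mm, theta_per_s, (sd_x_mm * k, sd_y_mm * k))

    def stationary_sd_mm(self) -> tuple[float, float]:
        if self.theta_per_s == 0:
            return (0.0 if self.sigma_mm[0] == 0 else math.inf,
                    0.0 if self.sigma_mm[1] == 0 else math.inf)
        return (ou_stationary_sd(self.theta_per_s, self.sigma_mm[0]),
                ou_stationary_sd(self.theta_per_s, self.sigma_mm[1]))


def ou_stationary_sd(theta: float, sigma: float) -> float:
    """Stationary per-axis SD of dX = -theta X dt + sigma dW: sigma/sqrt(2 theta)."""
    if theta <= 0:
        raise ConfigurationError("theta must be > 0 for a stationary OU process")
    return sigma / math.sqrt(2.0 * theta)


def ou_path(n: int, dt: float, theta: float, sigma: float,
            rng: np.random.Generator, mean: float = 0.0) -> np.ndarray:
    """Exact-discretisation OU sample path of length n, started stationary."""
    if sigma == 0.0:
        return np.full(n, mean)
    if theta == 0.0:  # Brownian motion from 0 displacement
        steps = rng.normal(0.0, sigma * math.sqrt(dt), n)
        return mean + np.concatenate(([0.0], np.cumsum(steps[:-1])))
    sd_stat = ou_stationary_sd(theta, sigma)
    a = math.exp(-theta * dt)
    innov_sd = sd_stat * math.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd_stat)
    eps = rng.normal(0.0, innov_sd, n - 1)
    for i in range(1, n):
        x[i] = a * x[i - 1] + eps[i - 1]
    return mean + x


def _sway_paths(model: SwayModel, n: int, dt: float,
                rng: np.random.Generator) -> np.ndarray:
    """(n, 2) array of COP displacement from the model mean, plus the mean."""
    out = np.empty((n, 2))
    if model.process == "filtered-noise":
        for ax in range(2):
            theta = model.theta_per_s if model.theta_per_s > 0 else 1.0
            sd = (0.0 if model.sigma_mm[ax] == 0
                  else ou_stationary_sd(theta, model.sigma_mm[ax]))
            out[:, ax] = model.mean_xy_mm[ax] + rng.normal(0.0, sd, n)
        return out
    for ax in range(2):
        out[:, ax] = ou_path(n, dt, model.theta_per_s, model.sigma_mm[ax],
                             rng, mean=model.mean_xy_mm[ax])
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic standing trial.

    Defaults represent a sound large-breed dog standing square: 50/50 load
    split, body-COP sway with stationary SD 0.5 mm (latero-lateral) and
    0.3 mm (craniocaudal), 2 kPa sensor noise, 0.5 kPa quantisation.
    """

    spec: PlatformSpec = field(default_factory=PlatformSpec)
    template_left: PawTemplate = None  # type: ignore[assignment]
    template_right: PawTemplate = None  # type: ignore[assignment]
    paw_centers_mm: tuple[tuple[float, float], tuple[float, float]] = (
        (-80.0, 0.0), (80.0, 0.0))
    total_force_N: float = 900.0
    load_split: tuple[float, float] = (0.5, 0.5)
    elasticity_gamma: float = 0.25
    sway: SwayModel = None  # type: ignore[assignment]
    limb_jitter: SwayModel = None  # type: ignore[assignment]
    noise_kPa: float = 2.0
    quantize_kPa: float = 0.5
    apply_calibration_cap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.template_left is None:
            object.__setattr__(self, "template_left", PawTemplate.default("left"))
        if self.template_right is None:
            object.__setattr__(self, "template_right",
                               self.template_left.mirrored())
        if self.sway is None:
            object.__setattr__(self, "sway",
                               SwayModel.from_stationary_sd(0.5, 0.3))
        if self.limb_jitter is None:
            object.__setattr__(self, "limb_jitter",
                               SwayModel.from_stationary_sd(0.3, 0.3))
        lf, rf = self.load_split
        if not (0 < lf < 1 and 0 < rf < 1) or abs(lf + rf - 1.0) > 1e-9:
            raise ConfigurationError(
                f"load_split fractions must lie in (0,1) and sum to 1, got "
                f"{self.load_split}")
        if self.total_force_N <= 0:
            raise ConfigurationError("total_force_N must be > 0")
        if self.noise_kPa < 0 or self.quantize_kPa < 0:
            raise ConfigurationError("noise and quantisation must be >= 0")
        self._check_midline_separation()

    def _check_midline_separation(self) -> None:
        # templates must not cross the inter-paw midline (2 radii of slack)
        (lx, _), (rx, _) = self.paw_centers_mm
        if lx >= rx:
            raise ConfigurationError("left paw centre must be left of right")
        mid = 0.5 * (lx + rx)
        l_extent = lx + np.max(self.template_left.pad_centers_mm[:, 0]
                               + 2 * self.template_left.pad_radii_mm)
        r_extent = rx + np.min(self.template_right.pad_centers_mm[:, 0]
                               - 2 * self.template_right.pad_radii_mm)
        if l_extent >= mid or r_extent <= mid:
            raise ConfigurationError(
                "paw templates overlap across the midline; move the paw "
                "centres apart or shrink the pads")


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated recording."""

    load_split: tuple[float, float]
    left_mask: np.ndarray          # stable footprint of the left limb
    right_mask: np.ndarray
    limb_cop_mm: dict              # side -> (x, y) of the noiseless limb COP
    body_sway_mm: np.ndarray       # (T, 2) imposed body-COP displacement
    body_cop_mean_mm: tuple[float, float]
    sway_stationary_sd_mm: tuple[float, float]


def _pad_basis(template: PawTemplate, center: tuple[float, float],
               radii: np.ndarray, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """(5, rows, cols) unit-amplitude Gaussian bumps sampled at sensor centres."""
    px = center[0] + template.pad_centers_mm[:, 0]
    py = center[1] + template.pad_centers_mm[:, 1]
    d2 = ((X[None] - px[:, None, None]) ** 2
          + (Y[None] - py[:, None, None]) ** 2)
    return np.exp(-d2 / (2.0 * radii[:, None, None] ** 2))


def _limb_frames(template: PawTemplate, center: tuple[float, float],
                 radii: np.ndarray, forces_N: np.ndarray,
                 cop_shift_mm: np.ndarray, spec: PlatformSpec) -> np.ndarray:
    """Render one limb's (T, rows, cols) pressure field.

    ``forces_N`` is the per-frame target measured force; ``cop_shift_mm``
    (T, 2) the within-paw COP displacement imposed by sway/jitter, realised
    by linearly re-weighting the pads about their mass centroid.
    """
    X, Y = spec.sensor_centers_mm()
    basis = _pad_basis(template, center, radii, X, Y)  # (5, R, C)
    # pad "mass" (force contribution) at unit field amplitude: A * 2 pi r^2
    mass = template.pad_amplitudes * 2.0 * math.pi * radii ** 2
    w = mass / mass.sum()
    px = center[0] + template.pad_centers_mm[:, 0]
    py = center[1] + template.pad_centers_mm[:, 1]
    cx, cy = float(w @ px), float(w @ py)
    var_x = float(w @ (px - cx) ** 2)
    var_y = float(w @ (py - cy) ** 2)
    tilt = np.ones((len(forces_N), 5))
    if var_x > 0:
        tilt += np.outer(cop_shift_mm[:, 0] / var_x, px - cx)
    if var_y > 0:
        tilt += np.outer(cop_shift_mm[:, 1] / var_y, py - cy)
    np.clip(tilt, 0.05, None, out=tilt)
    amp = template.pad_amplitudes[None, :] * tilt          # (T, 5)
    # scale so the continuous field mass equals the frame's target force;
    # 1 kPa over 1 mm^2 carries 1e-3 N
    frame_mass = (amp * (2.0 * math.pi * radii ** 2)[None, :]).sum(axis=1)
    scale = forces_N / (1e-3 * frame_mass)
    coeff = amp * scale[:, None]                           # (T, 5) in kPa
    return np.einsum("tk,krc->trc", coeff, basis)


def _renormalize_measured_force(fields: np.ndarray, forces_N: np.ndarray,
                                floor: float, area_mm2: float,
                                iters: int = 3) -> np.ndarray:
    """Rescale each frame so the post-floor quadrature force hits the target."""
    out = fields
    for _ in range(iters):
        measured = np.where(out >= floor, out, 0.0)
        f = 1e-3 * measured.sum(axis=(1, 2)) * area_mm2
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(f > 0, forces_N / f, 1.0)
        out = out * ratio[:, None, None]
    return out


def _measured_cop(field: np.ndarray, X: np.ndarray, Y: np.ndarray,
                  floor: float) -> tuple[float, float]:
    m = np.where(field >= floor, field, 0.0)
    s = m.sum()
    return float((m * X).sum() / s), float((m * Y).sum() / s)


def _tilt_gains(template: PawTemplate, center: tuple[float, float],
                radii: np.ndarray, force_N: float,
                spec: PlatformSpec) -> tuple[float, float]:
    """Measured-COP response per mm of requested pad-tilt shift.

    The sensor floor truncates the Gaussian tails asymmetrically when the
    pads are re-weighted, so the measured centroid moves further than the
    continuous-field centroid; probing the response with small symmetric
    shifts lets the simulator divide the requested displacement by this
    gain and impose sway dispersions faithfully.
    """
    delta = 1.0
    X, Y = spec.sensor_centers_mm()
    floor = spec.pressure_floor_kPa
    area_mm2 = spec.sensor_area_cm2 * 100.0
    gains = []
    for ax in range(2):
        shifts = np.zeros((2, 2))
        shifts[0, ax], shifts[1, ax] = delta, -delta
        f = _limb_frames(template, center, radii,
                         np.array([force_N, force_N]), shifts, spec)
        f = _renormalize_measured_force(f, np.array([force_N, force_N]),
                                        floor, area_mm2)
        c_plus = _measured_cop(f[0], X, Y, floor)
        c_minus = _measured_cop(f[1], X, Y, floor)
        g = (c_plus[ax] - c_minus[ax]) / (2.0 * delta)
        gains.append(g if g > 0.2 else 1.0)
    return gains[0], gains[1]


def simulate_recording(config: SimulationConfig, duration_s: float = 10.0,
                       subject_id: str = "sim", trial_id: str = "t1",
                       rng: np.random.Generator | None = None,
                       return_truth: bool = False):
    """Simulate one standing trial; seeded configs are bit-reproducible.

    Returns the :class:`~pawpress.core.PressureRecording`, or a
    ``(recording, SimulationTruth)`` pair when ``return_truth`` is set.
    """
    spec = config.spec
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = round(duration_s * spec.sampling_hz)
    dt = 1.0 / spec.sampling_hz
    body = _sway_paths(config.sway, n, dt, rng)           # (T, 2) incl. mean
    jit_l = _sway_paths(config.limb_jitter, n, dt, rng)
    jit_r = _sway_paths(config.limb_jitter, n, dt, rng)

    (lx, ly), (rx, ry) = config.paw_centers_mm
    lf, rf = config.load_split
    # latero-lateral body sway = weight shift between the limbs
    span = rx - lx
    ds = body[:, 0] / span
    right_frac = np.clip(rf + ds, 0.02, 0.98)
    left_frac = 1.0 - right_frac
    f_left = left_frac * config.total_force_N
    f_right = right_frac * config.total_force_N

    gamma = config.elasticity_gamma
    radii_l = config.template_left.pad_radii_mm * (2.0 * lf) ** gamma
    radii_r = config.template_right.pad_radii_mm * (2.0 * rf) ** gamma

    # craniocaudal body sway shifts both paws' COP; jitter is per-limb;
    # requested displacements are divided by the measured actuation gain
    gx_l, gy_l = _tilt_gains(config.template_left, (lx, ly), radii_l,
                             lf * config.total_force_N, spec)
    gx_r, gy_r = _tilt_gains(config.template_right, (rx, ry), radii_r,
                             rf * config.total_force_N, spec)
    shift_l = np.column_stack([jit_l[:, 0] / gx_l,
                               (body[:, 1] + jit_l[:, 1]) / gy_l])
    shift_r = np.column_stack([jit_r[:, 0] / gx_r,
                               (body[:, 1] + jit_r[:, 1]) / gy_r])

    fl = _limb_frames(config.template_left, (lx, ly), radii_l, f_left,
                      shift_l, spec)
    fr = _limb_frames(config.template_right, (rx, ry), radii_r, f_right,
                      shift_r, spec)
    floor = spec.pressure_floor_kPa
    area_mm2 = spec.sensor_area_cm2 * 100.0
    fl = _renormalize_measured_force(fl, f_left, floor, area_mm2)
    fr = _renormalize_measured_force(fr, f_right, floor, area_mm2)
    frames = fl + fr

    if config.noise_kPa > 0:
        frames = frames + rng.normal(0.0, config.noise_kPa, frames.shape)
    frames[frames < floor] = 0.0
    cap = (spec.calibration_cap_kPa if config.apply_calibration_cap
           else spec.pressure_ceiling_kPa)
    np.clip(frames, 0.0, cap, out=frames)
    if config.quantize_kPa > 0:
        np.round(frames / config.quantize_kPa, out=frames)
        frames *= config.quantize_kPa
    frames[frames < floor] = 0.0  # quantisation may round down across floor
    frames[:, ~spec.mask_array()] = 0.0

    rec = PressureRecording(spec, frames, subject_id=subject_id,
                            trial_id=trial_id, duration_s=duration_s,
                            cap_applied=config.apply_calibration_cap)
    if not return_truth:
        return rec

    base_l = _limb_frames(config.template_left, (lx, ly), radii_l,
                          np.array([lf * config.total_force_N]),
                          np.zeros((1, 2)), spec)[0]
    base_r = _limb_frames(config.template_right, (rx, ry), radii_r,
                          np.array([rf * config.total_force_N]),
                          np.zeros((1, 2)), spec)[0]

    def _cop(field: np.ndarray) -> tuple[float, float]:
        X, Y = spec.sensor_centers_mm()
        m = np.where(field >= floor, field, 0.0)
        s = m.sum()
        return float((m * X).sum() / s), float((m * Y).sum() / s)

    cop_l, cop_r = _cop(base_l), _cop(base_r)
    body_mean = (lf * cop_l[0] + rf * cop_r[0],
                 lf * cop_l[1] + rf * cop_r[1])
    truth = SimulationTruth(
        load_split=config.load_split,
        left_mask=base_l >= floor,
        right_mask=base_r >= floor,
        limb_cop_mm={"left": cop_l, "right": cop_r},
        body_sway_mm=body - np.asarray(config.sway.mean_xy_mm),
        body_cop_mean_mm=body_mean,
        sway_stationary_sd_mm=config.sway.stationary_sd_mm(),
    )
    return rec, truth


@dataclass(frozen=True)
class GroupSpec:
    """Population a cohort group is drawn from.

    ``asym_mean_pct``/``asym_sd_pct`` parameterise the between-limb load
    asymmetry (difference of the two shares, percentage points);
    ``area_mean_mm2``/``area_sd_mm2`` the 90% sway-ellipse area the group's
    body-COP dispersion is reverse-engineered from (area =
    pi * chi2_{0.90,2} * sd_x * sd_y at a fixed axis ratio).
    """

    name: str
    group: str                 # 'control' or 'lame'
    day: int | None            # 0 / 90 for the lame group, None for controls
    asym_mean_pct: float
    asym_sd_pct: float
    area_mean_mm2: float
    area_sd_mm2: float
    sway_axis_ratio: float = 5.0 / 3.0   # sd_x / sd_y
    lame_side: str = "left"


def default_group_specs() -> dict[str, GroupSpec]:
    """Study conditions: 5 sound dogs, 5 lame dogs seen pre-treatment and at
    day 90, with group-level asymmetries and sway-ellipse areas matching the
    cohort means/SDs the study design targets."""
    return {
        "control": GroupSpec("control", "control", None, 3.63, 2.48,
                             2.17, 1.10),
        "lame_d0": GroupSpec("lame_d0", "lame", 0, 20.56, 5.00,
                             44.71, 26.82),
        "lame_d90": GroupSpec("lame_d90", "lame", 90, 8.51, 5.25,
                              13.91, 4.12),
    }


def _subject_config(gspec: GroupSpec, base: SimulationConfig,
                    z_asym: float, z_area: float,
                    seed: int) -> tuple[SimulationConfig, dict]:
    asym = gspec.asym_mean_pct + gspec.asym_sd_pct * z_asym
    asym = float(np.clip(asym, 0.0, 60.0))
    hi, lo = (50.0 + asym / 2.0) / 100.0, (50.0 - asym / 2.0) / 100.0
    if gspec.lame_side == "left":
        split = (lo, hi)
    else:
        split = (hi, lo)
    area = float(np.clip(gspec.area_mean_mm2 + gspec.area_sd_mm2 * z_area,
                         0.3, None))
    sd_prod = area / (math.pi * CHI2_90_2D)
    sd_x = math.sqrt(sd_prod * gspec.sway_axis_ratio)
    sd_y = sd_prod / sd_x
    cfg = replace(base,
                  load_split=split,
                  sway=SwayModel.from_stationary_sd(sd_x, sd_y),
                  seed=seed)
    truth = {"true_asym_pct": asym, "true_split_left": split[0],
             "true_split_right": split[1], "true_area_mm2": area,
             "true_sd_x_mm": sd_x, "true_sd_y_mm": sd_y}
    return cfg, truth


def simulate_cohort(n_per_group: int = 5,
                    group_specs: dict[str, GroupSpec] | None = None,
                    n_trials: int = 3, duration_s: float = 10.0,
                    seed: int = 0,
                    base_config: SimulationConfig | None = None,
                    day_correlation: float = 0.9,
                    ) -> tuple[list[PressureRecording], pd.DataFrame]:
    """Simulate a full study cohort: ``n_trials`` standing trials per
    synthetic subject per group, subject parameters drawn from each group's
    population.  Returns the recordings and a ground-truth table.

    Conditions sharing a ``group`` label (a lame dog seen at day 0 and day
    90) describe repeated measures on the same animal: the dog's latent
    severity is drawn once and its per-condition parameters correlate with
    coefficient ``day_correlation``, so treatment-response contrasts are
    paired rather than independent.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    if group_specs is None:
        group_specs = default_group_specs()
    if base_config is None:
        base_config = SimulationConfig()
    if not 0 <= day_correlation <= 1:
        raise ConfigurationError("day_correlation must be in [0, 1]")
    grouped: dict[str, list[GroupSpec]] = {}
    for gspec in group_specs.values():
        grouped.setdefault(gspec.group, []).append(gspec)
    root = np.random.SeedSequence(seed)
    recordings: list[PressureRecording] = []
    rows = []
    for group_label, conds in grouped.items():
        gseq = root.spawn(1)[0]
        rng = np.random.default_rng(gseq)
        rho = day_correlation if len(conds) > 1 else 0.0
        for i in range(n_per_group):
            dog = f"{group_label}_s{i + 1:02d}"
            z_shared = rng.normal(size=2)  # latent severity: asym, sway
            for gspec in conds:
                subject = f"{gspec.name}_s{i + 1:02d}"
                z_ind = rng.normal(size=2)
                z_asym = rho * z_shared[0] + math.sqrt(1 - rho * rho) * z_ind[0]
                z_area = rho * z_shared[1] + math.sqrt(1 - rho * rho) * z_ind[1]
                sub_seed = int(gseq.spawn(1)[0].generate_state(1)[0]
                               % (2 ** 31))
                cfg, truth = _subject_config(gspec, base_config, z_asym,
                                             z_area, sub_seed)
                sub_rng = np.random.default_rng(sub_seed)
                for t in range(n_trials):
                    rec = simulate_recording(cfg, duration_s=duration_s,
                                             subject_id=subject,
                                             trial_id=f"trial{t + 1}",
                                             rng=sub_rng)
                    recordings.append(rec)
                rows.append({"subject": subject, "dog": dog,
                             "group": gspec.group,
                             "day": gspec.day if gspec.day is not None else -1,
                             "condition": gspec.name, **truth})
    return recordings, pd.DataFrame(rows)
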