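"""Synthetic chemotactic-migration fields and TIRF-like timelapses.

Every downstream stage of the pipeline (track metrics, polarity regions,
punctum event calling, colocalisation, adhesion kinetics) is exercised
against data produced here, with the ground truth planted by construction:
which cells invade the chemoattractant spot, which puncta disappear (and
where), which cross-channel pairs are genuinely colocalised, and when each
focal adhesion disassembles.

Treatment presets are frozen constants encoding the relative effect sizes
of the perturbations studied in the agarose-spot assay: dynamin inhibition
(Dynasore) reduces the invading fraction to 40% of control and halves cell
speed; AP2 (α-adaptin) knock-down reduces the invading fraction to 35% of
control; caveolin1 knock-down and the non-silencing control are
indistinguishable from control.

The migration model is a biased persistent random walk: each step the
heading is a persistence-weighted mix of the previous heading and the unit
vector toward the spot interior, perturbed by wrapped-Gaussian noise.  Cells
are seeded outside the spot; a planted fraction (``migration_probability``)
is invasion-competent and crosses the edge, the remainder are reflected at
the agarose interface.  The per-step heading noise is calibrated so that a
control ensemble's mean unsigned endpoint angle to the edge perpendicular
is 2.80°, the packaged migration-axis calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CellTrack,
    ConfigurationError,
    SpotGeometry,
    TimelapseStack,
    write_json,
    write_tracks_csv,
)

# ---------------------------------------------------------------------------
# Treatment presets (frozen constants)
# ---------------------------------------------------------------------------

CONTROL_MIGRATION_PROBABILITY = 0.5   # fraction of seeded cells that invade
CONTROL_SPEED_UM_PER_MIN = 0.6        # mean step speed of a control cell
CONTROL_PERSISTENCE = 0.7             # heading memory weight, 0..1

#: Per-step heading noise (degrees, wrapped normal).  Calibrated once so the
#: control ensemble's mean unsigned endpoint angle to the spot-edge
#: perpendicular is 2.80 degrees under the default walk configuration
#: (84 steps of 10 min over 14 h, persistence 0.7).
HEADING_NOISE_SD_DEG = 9.35

#: Multiplicative lognormal sd of per-step length noise.
STEP_NOISE_SIGMA = 0.2


@dataclass(frozen=True)
class TreatmentPreset:
    """Frozen per-condition migration parameters."""

    name: str
    migration_probability: float
    speed_scale: float = 1.0
    persistence: float = CONTROL_PERSISTENCE

    def __post_init__(self) -> None:
        if not 0.0 <= self.migration_probability <= 1.0:
            raise ConfigurationError("migration_probability must be in [0, 1]")
        if self.speed_scale <= 0:
            raise ConfigurationError("speed_scale must be positive")
        if not 0.0 <= self.persistence <= 1.0:
            raise ConfigurationError("persistence must be in [0, 1]")


PRESETS: dict[str, TreatmentPreset] = {
    "control": TreatmentPreset("control", CONTROL_MIGRATION_PROBABILITY),
    # Dynasore: 60% fewer migrated cells, remaining cells at half speed.
    "dynasore": TreatmentPreset("dynasore", 0.4 * CONTROL_MIGRATION_PROBABILITY,
                                speed_scale=0.5),
    # Non-silencing control siRNA: no effect.
    "nsc_sirna": TreatmentPreset("nsc_sirna", CONTROL_MIGRATION_PROBABILITY),
    # AP2 alpha-adaptin knock-down: 65% fewer migrated cells.
    "alpha_adaptin_sirna": TreatmentPreset(
        "alpha_adaptin_sirna", 0.35 * CONTROL_MIGRATION_PROBABILITY),
    # Caveolin1 knock-down: no effect on migration.
    "cav1_sirna": TreatmentPreset("cav1_sirna", CONTROL_MIGRATION_PROBABILITY),
}


def preset(name: str) -> TreatmentPreset:
    """Look up a packaged treatment preset by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------

@dataclass
class GeneratorConfig:
    """Parameters of the synthetic field and timelapse generators.

    Image-side fields describe TIRF-like rendering (field size, PSF width,
    SNR, fates, colocalisation); track-side fields describe the overnight
    migration field (cell count, sampling interval, window length).
    """

    # imaging geometry
    field_px: int = 512
    pixel_size_um: float = 0.1
    frame_interval_s: float = 2.0
    n_frames: int = 40
    # migration field
    n_cells: int = 50
    track_interval_s: float = 600.0
    track_duration_h: float = 14.0
    field_um: float = 400.0                 # lateral extent of seeded band
    seed_band_um: tuple[float, float] = (20.0, 60.0)  # start distance to edge
    heading_noise_sd_deg: float | None = None   # None -> packaged calibration
    # cell and puncta rendering
    cell_halfaxes_um: tuple[float, float] = (20.0, 10.0)
    n_puncta: int = 60
    punctum_sigma_px: float = 1.5
    min_punctum_separation_px: float = 4.0   # planted spots stay resolvable
    snr: float = 10.0
    background: float = 100.0
    noise_sd: float = 10.0
    bleach_rate: float = 0.0                # per-frame fractional decay
    # punctum fates and events
    fate_fractions: dict = field(default_factory=lambda: {
        "static": 0.6, "lateral": 0.2, "disappearing": 0.2})
    n_reappearing: int = 0                  # designed reappearance negatives
    n_gradual: int = 0                      # designed slow-fade negatives
    gradual_fade_frames: int = 15
    reappear_gap_frames: tuple[int, int] = (3, 8)
    lateral_displacement_um: tuple[float, float] = (1.0, 2.5)
    front_bias: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # second channel
    second_channel: bool = False
    coloc_fraction: float = 0.05
    coloc_jitter_px: float = 0.5
    n_distractors: int = 15
    # focal adhesions
    n_adhesions: int = 0
    fa_sigma_px: tuple[float, float] = (5.0, 1.25)    # (major, minor)
    fa_amplitude_snr: float = 30.0
    fa_disassemble_fraction: float = 0.0
    fa_onset_range: tuple[int, int] = (15, 30)
    fa_duration_range: tuple[int, int] = (20, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.field_px, self.n_cells, self.n_puncta, self.n_frames) < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.snr <= 0:
            raise ConfigurationError("SNR must be positive")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ConfigurationError("coloc_fraction must be in [0, 1]")
        if any(b < 0 for b in self.front_bias):
            raise ConfigurationError("front_bias entries must be non-negative")
        if self.bleach_rate < 0:
            raise ConfigurationError("bleach_rate must be non-negative")

    @property
    def punctum_amplitude(self) -> float:
        return self.snr * self.noise_sd

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Independent-punctum density (per µm² of cell area) packaged for the
#: chance-overlap adhesion fields: chosen so the expected fraction of
#: detected adhesions containing >= 1 punctum by chance alone is ~7%
#: (Poisson overlap with the default adhesion footprint dilated by 2 px).
FA_CHANCE_PUNCTA_DENSITY_PER_UM2 = 0.0272


# ---------------------------------------------------------------------------
# Ground-truth containers
# ---------------------------------------------------------------------------

@dataclass
class FieldGroundTruth:
    """One synthetic migration field with its planted truth."""

    tracks: list[CellTrack]
    spot: SpotGeometry
    migrated_ids: set[int]
    planted_migrator_ids: set[int]
    preset: TreatmentPreset

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tracks_csv(self.tracks, outdir / "tracks.csv")
        self.spot.to_yaml(outdir / "spot.yaml")
        write_json({"migrated_ids": self.migrated_ids,
                    "planted_migrator_ids": self.planted_migrator_ids,
                    "preset": dataclasses.asdict(self.preset)},
                   outdir / "ground_truth.json")


@dataclass
class PlantedPunctum:
    """Ground truth for one rendered punctum.

    ``x_px``/``y_px``/``amp`` are per-frame arrays covering the whole stack
    (amplitude 0 after a disappearance).  A punctum with fate
    ``disappearing`` but a set ``reappear_frame`` or ``fade_frames`` larger
    than 2 is a designed negative for the event caller: it vanishes from the
    field but must not be accepted as an internalisation event.
    """

    id: int
    fate: str
    x_px: np.ndarray
    y_px: np.ndarray
    amp: np.ndarray
    region: str
    coloc: bool = False
    event_frame: int | None = None
    reappear_frame: int | None = None
    fade_frames: int = 1

    @property
    def is_true_event(self) -> bool:
        return (self.fate == "disappearing" and self.event_frame is not None
                and self.reappear_frame is None and self.fade_frames <= 2)


@dataclass
class PlantedAdhesion:
    id: int
    x_px: float
    y_px: float
    sigma_major_px: float
    sigma_minor_px: float
    theta_rad: float
    amplitude: float
    onset_frame: int | None = None     # last frame at full plateau
    end_frame: int | None = None       # first frame at zero


@dataclass
class TirfGroundTruth:
    """Planted truth for one TIRF-like timelapse."""

    puncta: list[PlantedPunctum]
    adhesions: list[PlantedAdhesion]
    bleach_rate: float
    cell_mask: np.ndarray
    spot: SpotGeometry
    config: GeneratorConfig

    @property
    def coloc_labels(self) -> np.ndarray:
        return np.array([p.coloc for p in self.puncta], dtype=bool)

    @property
    def true_event_ids(self) -> set[int]:
        return {p.id for p in self.puncta if p.is_true_event}

    def initial_positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions at frame 0."""
        return np.array([[p.x_px[0], p.y_px[0]] for p in self.puncta])


# ---------------------------------------------------------------------------
# Migration field generator
# ---------------------------------------------------------------------------

def default_spot(config: GeneratorConfig | None = None) -> SpotGeometry:
    """Straight agarose-spot edge at x=0 with interior toward +x."""
    return SpotGeometry(kind="line", point_um=(0.0, 0.0), normal=(1.0, 0.0))


def make_spot_field(config: GeneratorConfig,
                    treatment: TreatmentPreset | str = "control",
                    spot: SpotGeometry | None = None) -> FieldGroundTruth:
    """Simulate one field of view of the agarose-spot invasion assay.

    Cells are seeded in a band outside the spot edge and perform a biased
    persistent random walk toward the spot interior over the configured
    window (default 14 h sampled every 10 min).  A planted Bernoulli
    fraction (the preset's ``migration_probability``) may cross the edge;
    the rest are mirrored back at the agarose interface.  Per-frame cell
    width/length descriptors are attached (invading cells elongate).
    """
    if isinstance(treatment, str):
        treatment = preset(treatment)
    spot = spot or default_spot(config)
    rng = np.random.default_rng(config.seed)

    n = config.n_cells
    if n < 1:
        raise ConfigurationError("n_cells must be >= 1")
    n_steps = int(round(config.track_duration_h * 3600.0 / config.track_interval_s))
    dt_min = config.track_interval_s / 60.0
    step_um = CONTROL_SPEED_UM_PER_MIN * treatment.speed_scale * dt_min
    noise_deg = (HEADING_NOISE_SD_DEG if config.heading_noise_sd_deg is None
                 else config.heading_noise_sd_deg)
    sigma = np.deg2rad(noise_deg)
    p = treatment.persistence

    # seed positions: band outside the straight edge
    d0 = rng.uniform(*config.seed_band_um, size=n)
    lat = rng.uniform(0.0, config.field_um, size=n)
    u = spot.perpendicular_at(np.zeros((1, 2)))[0]        # inward normal
    tvec = np.array([-u[1], u[0]])                        # edge tangent
    pos = (np.asarray(spot.point_um) - np.outer(d0, u) + np.outer(lat, tvec))
    migrator = rng.random(n) < treatment.migration_probability

    heading = np.tile(np.arctan2(u[1], u[0]), n)
    traj = np.empty((n_steps + 1, n, 2))
    traj[0] = pos
    for k in range(n_steps):
        bias = spot.perpendicular_at(pos)
        mix = (p * np.column_stack([np.cos(heading), np.sin(heading)])
               + (1.0 - p) * bias)
        heading = np.arctan2(mix[:, 1], mix[:, 0])
        if sigma > 0:
            heading = heading + rng.normal(0.0, sigma, size=n)
        steps = step_um * rng.lognormal(-0.5 * STEP_NOISE_SIGMA ** 2,
                                        STEP_NOISE_SIGMA, size=n)
        pos = pos + steps[:, None] * np.column_stack(
            [np.cos(heading), np.sin(heading)])
        # non-invading cells are blocked at the agarose interface
        blocked = ~migrator & (spot.signed_distance(pos) > 0)
        if np.any(blocked):
            pos[blocked] = spot.reflect_inside(pos[blocked])
        traj[k + 1] = pos

    t_s = np.arange(n_steps + 1) * config.track_interval_s
    # shape descriptors: invading cells elongate, blocked cells stay rounder
    ef_mean = np.where(migrator, 0.5, 0.8)
    tracks = []
    for i in range(n):
        length = rng.normal(45.0, 5.0, size=n_steps + 1).clip(20.0, None)
        ef = rng.normal(ef_mean[i], 0.06, size=n_steps + 1).clip(0.15, 1.0)
        tracks.append(CellTrack(
            id=i, t_s=t_s, x_um=traj[:, i, 0], y_um=traj[:, i, 1],
            width_um=length * ef, length_um=length))

    final_inside = spot.is_inside(traj[-1])
    migrated_ids = {i for i in range(n) if final_inside[i]}
    return FieldGroundTruth(tracks=tracks, spot=spot, migrated_ids=migrated_ids,
                            planted_migrator_ids=set(np.flatnonzero(migrator)),
                            preset=treatment)


# ---------------------------------------------------------------------------
# TIRF timelapse generator
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: tuple[int, int], center_px: tuple[float, float],
                  halfaxes_px: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cx, cy = center_px
    a, b = halfaxes_px
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _sample_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator,
                    x_range: tuple[float, float] | None = None,
                    margin_px: float = 0.0) -> np.ndarray:
    """Uniform (x, y) samples inside a boolean mask by rejection."""
    h, w = mask.shape
    out = np.empty((n, 2))
    got = 0
    guard = 0
    while got < n:
        guard += 1
        if guard > 10000:
            raise RuntimeError("rejection sampling failed; mask too small?")
        m = max(4 * (n - got), 64)
        lo, hi = (margin_px, w - 1 - margin_px)
        x = rng.uniform(lo if x_range is None else max(lo, x_range[0]),
                        hi if x_range is None else min(hi, x_range[1]), size=m)
        y = rng.uniform(margin_px, h - 1 - margin_px, size=m)
        ok = mask[np.round(y).astype(int).clip(0, h - 1),
                  np.round(x).astype(int).clip(0, w - 1)]
        take = min(int(ok.sum()), n - got)
        sel = np.flatnonzero(ok)[:take]
        out[got:got + take, 0] = x[sel]
        out[got:got + take, 1] = y[sel]
        got += take
    return out


def _sample_separated(mask: np.ndarray, n: int, rng: np.random.Generator,
                      placed: list, min_sep: float,
                      x_range: tuple[float, float] | None = None,
                      margin_px: float = 0.0) -> np.ndarray:
    """Uniform in-mask samples keeping ``min_sep`` px from already-placed
    points (so planted spots remain resolvable); appends to ``placed``."""
    out = []
    guard = 0
    while len(out) < n:
        guard += 1
        if guard > 500:
            raise RuntimeError("cannot place puncta at the requested "
                               "density and separation")
        for c in _sample_in_mask(mask, n - len(out), rng, x_range, margin_px):
            if min_sep > 0 and placed:
                d = np.linalg.norm(np.asarray(placed) - c, axis=1)
                if d.min() < min_sep:
                    continue
            out.append(c)
            placed.append(c)
    return np.asarray(out)


def _add_gaussian(img: np.ndarray, x: float, y: float, amp: float,
                  sigma: float) -> None:
    if amp == 0.0:
        return
    h, w = img.shape
    r = int(np.ceil(4 * sigma))
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0c, x1c = max(x0, 0), min(x1, w)
    y0c, y1c = max(y0, 0), min(y1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
    img[y0c:y1c, x0c:x1c] += amp * g


def _add_aniso_gaussian(img: np.ndarray, x: float, y: float, amp: float,
                        smaj: float, smin: float, theta: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * smaj))
    x0c, x1c = max(int(x) - r, 0), min(int(x) + r + 1, w)
    y0c, y1c = max(int(y) - r, 0), min(int(y) + r + 1, h)
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - x
    ys = np.arange(y0c, y1c) - y
    X, Y = np.meshgrid(xs, ys)
    ct, st = np.cos(theta), np.sin(theta)
    um = X * ct + Y * st
    vm = -X * st + Y * ct
    img[y0c:y1c, x0c:x1c] += amp * np.exp(
        -(um ** 2 / (2 * smaj ** 2) + vm ** 2 / (2 * smin ** 2)))


def _region_of_x(x_px: np.ndarray, cx: float, a_px: float) -> np.ndarray:
    """Front/middle/back of the cell ellipse by thirds of its x-extent
    (front = toward the spot interior at +x; frontward tie-break)."""
    b1, b2 = cx - a_px / 3.0, cx + a_px / 3.0
    out = np.full(np.shape(x_px), "back", dtype=object)
    out[np.asarray(x_px) >= b1] = "middle"
    out[np.asarray(x_px) >= b2] = "front"
    return out


def make_tirf_timelapse(config: GeneratorConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[TimelapseStack, TirfGroundTruth]:
    """Render a TIRF-like timelapse of puncta (and optionally adhesions).

    Channel 0 carries diffraction-limited Gaussian puncta inside an
    elliptical cell footprint on a flat background with Gaussian read
    noise; fates are planted per punctum (static / laterally mobile /
    disappearing, the latter dropping to background within <= 2 frames at a
    planted event frame, optionally reappearing or fading slowly as
    designed negatives).  With ``second_channel`` a channel of puncta
    co-positioned with a planted subset of channel-0 puncta plus
    independent distractors is rendered.  With ``n_adhesions > 0`` channel 0
    instead carries elongated adhesion objects with plateau/linear-decay
    intensity profiles and the second channel carries independent puncta.

    Global photobleaching (``bleach_rate``) is applied multiplicatively to
    all pixels before noise.  All randomness flows from ``config.seed``
    unless an explicit generator is passed.
    """
    if config.snr <= 0:
        raise ConfigurationError("SNR must be positive")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_px = config.field_px
    nt = config.n_frames
    center = (n_px / 2.0, n_px / 2.0)
    halfaxes_px = (config.cell_halfaxes_um[0] / config.pixel_size_um,
                   config.cell_halfaxes_um[1] / config.pixel_size_um)
    mask = _ellipse_mask((n_px, n_px), center, halfaxes_px)
    # spot edge just beyond the +x side of the field; front of cell = +x
    spot = SpotGeometry(kind="line",
                        point_um=(n_px * config.pixel_size_um, 0.0),
                        normal=(1.0, 0.0))

    if config.n_adhesions > 0:
        return _make_adhesion_timelapse(config, rng, mask, center,
                                        halfaxes_px, spot)

    puncta = _plant_puncta(config, rng, mask, center, halfaxes_px)

    channels = [_render_puncta_channel(
        config, rng, [(p.x_px, p.y_px, p.amp) for p in puncta])]
    if config.second_channel:
        n_co = int(round(config.coloc_fraction * len(puncta)))
        co_ids = rng.choice(len(puncta), size=n_co, replace=False) if n_co else []
        for i in co_ids:
            puncta[i].coloc = True
        second = []
        for i in co_ids:
            p = puncta[i]
            jit = rng.uniform(-config.coloc_jitter_px, config.coloc_jitter_px,
                              size=2) / np.sqrt(2.0)
            amp = np.full(nt, config.punctum_amplitude)
            second.append((p.x_px + jit[0], p.y_px + jit[1], amp))
        dpos = _sample_in_mask(mask, config.n_distractors, rng, margin_px=8)
        for x, y in dpos:
            second.append((np.full(nt, x), np.full(nt, y),
                           np.full(nt, config.punctum_amplitude)))
        channels.append(_render_puncta_channel(config, rng, second))

    stack = TimelapseStack(np.stack(channels), config.pixel_size_um,
                           config.frame_interval_s)
    gt = TirfGroundTruth(puncta=puncta, adhesions=[], bleach_rate=config.bleach_rate,
                         cell_mask=mask, spot=spot, config=config)
    return stack, gt


def _plant_puncta(config: GeneratorConfig, rng: np.random.Generator,
                  mask: np.ndarray, center: tuple[float, float],
                  halfaxes_px: tuple[float, float]) -> list[PlantedPunctum]:
    nt = config.n_frames
    fr = config.fate_fractions
    n_dis = int(round(fr.get("disappearing", 0.0) * config.n_puncta)) if nt > 1 else 0
    n_lat = int(round(fr.get("lateral", 0.0) * config.n_puncta)) if nt > 1 else 0
    n_static = config.n_puncta - n_dis - n_lat
    n_reapp = config.n_reappearing if nt > 1 else 0
    n_grad = config.n_gradual if nt > 1 else 0

    puncta: list[PlantedPunctum] = []
    pid = 0
    amp0 = config.punctum_amplitude
    cx, a_px = center[0], halfaxes_px[0]
    e_lo, e_hi = 6, max(nt - 11, 7)
    placed: list = []
    min_sep = config.min_punctum_separation_px

    def vanishing_positions(n: int) -> np.ndarray:
        """Positions for vanishing puncta, with per-region rates per front_bias."""
        w = np.asarray(config.front_bias, dtype=float)
        if w.sum() == 0:
            w = np.ones(3)
        regions = rng.choice(3, size=n, p=w / w.sum())  # 0=front,1=middle,2=back
        b1, b2 = cx - a_px / 3.0, cx + a_px / 3.0
        ranges = {0: (b2, cx + a_px), 1: (b1, b2), 2: (cx - a_px, b1)}
        pos = np.empty((n, 2))
        for r in range(3):
            idx = np.flatnonzero(regions == r)
            if len(idx):
                pos[idx] = _sample_separated(mask, len(idx), rng, placed,
                                             min_sep, x_range=ranges[r],
                                             margin_px=8)
        return pos

    # true step-disappearance events (and designed negatives)
    for kind, count in (("event", n_dis), ("reappear", n_reapp), ("grad", n_grad)):
        if count == 0:
            continue
        pos = vanishing_positions(count)
        for (x, y) in pos:
            e = int(rng.integers(e_lo, e_hi + 1))
            amp = np.full(nt, amp0)
            reappear = None
            fade = 1
            if kind == "event":
                amp[e:] = 0.0
            elif kind == "reappear":
                reappear = e + int(rng.integers(*config.reappear_gap_frames))
                amp[e:min(reappear, nt)] = 0.0
            else:  # gradual linear fade
                fade = config.gradual_fade_frames
                ramp = np.linspace(1.0, 0.0, fade + 1)[1:]
                hi = min(e + fade, nt)
                amp[e:hi] = amp0 * ramp[:hi - e]
                amp[hi:] = 0.0
            puncta.append(PlantedPunctum(
                id=pid, fate="disappearing",
                x_px=np.full(nt, x), y_px=np.full(nt, y), amp=amp,
                region=str(_region_of_x(np.array([x]), cx, a_px)[0]),
                event_frame=e, reappear_frame=reappear, fade_frames=fade))
            pid += 1

    # laterally mobile puncta: constant-velocity drift staying inside the cell
    if n_lat:
        pos = _sample_separated(mask, n_lat, rng, placed, min_sep, margin_px=30)
        for (x, y) in pos:
            disp_um = rng.uniform(*config.lateral_displacement_um)
            disp_px = disp_um / config.pixel_size_um
            for _ in range(50):
                phi = rng.uniform(0, 2 * np.pi)
                ex = x + disp_px * np.cos(phi)
                ey = y + disp_px * np.sin(phi)
                if mask[int(np.clip(round(ey), 0, mask.shape[0] - 1)),
                        int(np.clip(round(ex), 0, mask.shape[1] - 1))]:
                    break
            puncta.append(PlantedPunctum(
                id=pid, fate="lateral",
                x_px=np.linspace(x, ex, nt), y_px=np.linspace(y, ey, nt),
                amp=np.full(nt, amp0),
                region=str(_region_of_x(np.array([x]), cx, a_px)[0])))
            pid += 1

    if n_static:
        pos = _sample_separated(mask, n_static, rng, placed, min_sep,
                                margin_px=8)
        for (x, y) in pos:
            puncta.append(PlantedPunctum(
                id=pid, fate="static",
                x_px=np.full(nt, x), y_px=np.full(nt, y),
                amp=np.full(nt, amp0),
                region=str(_region_of_x(np.array([x]), cx, a_px)[0])))
            pid += 1
    return puncta


def _render_puncta_channel(config: GeneratorConfig, rng: np.random.Generator,
                           emitters: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
                           ) -> np.ndarray:
    """Render one channel from per-frame (x, y, amplitude) emitter arrays."""
    nt, n_px = config.n_frames, config.field_px
    out = np.empty((nt, n_px, n_px), dtype=np.float32)
    for t in range(nt):
        img = np.full((n_px, n_px), config.background, dtype=float)
        for (xs, ys, amps) in emitters:
            _add_gaussian(img, float(xs[t]), float(ys[t]), float(amps[t]),
                          config.punctum_sigma_px)
        if config.bleach_rate > 0:
            img *= np.exp(-config.bleach_rate * t)
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        out[t] = img
    return out


def _make_adhesion_timelapse(config: GeneratorConfig, rng: np.random.Generator,
                             mask: np.ndarray, center: tuple[float, float],
                             halfaxes_px: tuple[float, float],
                             spot: SpotGeometry
                             ) -> tuple[TimelapseStack, TirfGroundTruth]:
    nt, n_px = config.n_frames, config.field_px
    smaj, smin = config.fa_sigma_px
    amp = config.fa_amplitude_snr * config.noise_sd
    pos = _sample_separated(mask, config.n_adhesions, rng, [], 5 * smaj,
                            margin_px=5 * smaj)
    n_dis = int(round(config.fa_disassemble_fraction * config.n_adhesions))
    adhesions: list[PlantedAdhesion] = []
    traces = np.ones((config.n_adhesions, nt))
    for i, (x, y) in enumerate(pos):
        onset = end = None
        if i < n_dis and nt > 2:
            onset = int(rng.integers(*config.fa_onset_range))
            dur = int(rng.integers(*config.fa_duration_range))
            end = min(onset + dur, nt - 1)
            ramp = np.linspace(1.0, 0.0, end - onset + 1)
            traces[i, onset:end + 1] = ramp
            traces[i, end + 1:] = 0.0
        adhesions.append(PlantedAdhesion(
            id=i, x_px=float(x), y_px=float(y), sigma_major_px=smaj,
            sigma_minor_px=smin, theta_rad=float(rng.uniform(0, np.pi)),
            amplitude=amp, onset_frame=onset, end_frame=end))

    out = np.empty((nt, n_px, n_px), dtype=np.float32)
    for t in range(nt):
        img = np.full((n_px, n_px), config.background, dtype=float)
        for i, fa in enumerate(adhesions):
            _add_aniso_gaussian(img, fa.x_px, fa.y_px, amp * traces[i, t],
                                fa.sigma_major_px, fa.sigma_minor_px,
                                fa.theta_rad)
        if config.bleach_rate > 0:
            img *= np.exp(-config.bleach_rate * t)
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        out[t] = img
    channels = [out]

    # independent punctum channel at the packaged chance density
    cell_area_um2 = float(mask.sum()) * config.pixel_size_um ** 2
    n_pts = config.n_puncta if config.n_puncta else int(
        round(FA_CHANCE_PUNCTA_DENSITY_PER_UM2 * cell_area_um2))
    puncta: list[PlantedPunctum] = []
    if config.second_channel and n_pts:
        ppos = _sample_in_mask(mask, n_pts, rng, margin_px=8)
        emitters = []
        cx, a_px = center[0], halfaxes_px[0]
        for i, (x, y) in enumerate(ppos):
            emitters.append((np.full(nt, x), np.full(nt, y),
                             np.full(nt, config.punctum_amplitude)))
            puncta.append(PlantedPunctum(
                id=i, fate="static", x_px=np.full(nt, x), y_px=np.full(nt, y),
                amp=np.full(nt, config.punctum_amplitude),
                region=str(_region_of_x(np.array([x]), cx, a_px)[0])))
        channels.append(_render_puncta_channel(config, rng, emitters))

    stack = TimelapseStack(np.stack(channels), config.pixel_size_um,
                           config.frame_interval_s)
    gt = TirfGroundTruth(puncta=puncta, adhesions=adhesions,
                         bleach_rate=config.bleach_rate, cell_mask=mask,
                         spot=spot, config=config)
    return stack, gt


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_tirf_outputs(stack: TimelapseStack, gt: TirfGroundTruth,
                       outdir: str | Path, interleaved: bool = True) -> None:
    """Write a rendered timelapse plus its ground truth (CSV + JSON)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stack.save(outdir / "stack.ome.tif", interleaved=interleaved)
    rows = []
    for p in gt.puncta:
        for t in range(len(p.amp)):
            rows.append({"track_id": p.id, "frame": t, "x_px": p.x_px[t],
                         "y_px": p.y_px[t], "amp": p.amp[t]})
    pd.DataFrame(rows).to_csv(outdir / "truth_tracks.csv", index=False)
    events = [{"track_id": p.id, "frame": p.event_frame, "region": p.region}
              for p in gt.puncta if p.is_true_event]
    pd.DataFrame(events, columns=["track_id", "frame", "region"]).to_csv(
        outdir / "truth_events.csv", index=False)
    write_json({"config": gt.config.to_dict(),
                "coloc_ids": [p.id for p in gt.puncta if p.coloc],
                "fates": {p.id: p.fate for p in gt.puncta}},
               outdir / "truth.json")
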